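"""Similarity-map reconstruction, attention cascade, fusion, enhancement."""

import numpy as np
import pytest
from oracles import enhance_naive, fuse_naive, spatial_attention_naive, stamp

from headcount._autograd import Parameter, as_tensor
from headcount.enhancement import (enhance, enhance_t, fuse_scales,
                                   init_enhance_params, msfem_iterate,
                                   msfem_once_t, reconstruct,
                                   spatial_attention)
from headcount.matching import init_mapping_params
from headcount.rve import PrototypeSet


class TestReconstruct:
    def test_single_impulse_stamps_prototype(self, rng):
        p = rng.normal(size=(1, 3, 3, 3))
        r = np.zeros((1, 6, 6))
        r[0, 2, 3] = 1.0
        out = reconstruct(r, p)
        assert np.allclose(out[:, 1:4, 2:5], p[0])
        out[:, 1:4, 2:5] = 0
        assert np.allclose(out, 0)

    def test_zero_similarity_gives_zero(self, rng):
        assert np.allclose(reconstruct(np.zeros((2, 5, 5)),
                                       rng.normal(size=(2, 2, 3, 3))), 0)

    def test_matches_stamping_oracle(self, rng):
        r = rng.normal(size=(2, 6, 6))
        p = rng.normal(size=(2, 2, 3, 3))
        assert np.max(np.abs(reconstruct(r, p) - stamp(r, p))) < 1e-6

    def test_mismatched_exemplars_rejected(self, rng):
        with pytest.raises(ValueError):
            reconstruct(np.zeros((3, 4, 4)), rng.normal(size=(2, 2, 3, 3)))


class TestSpatialAttention:
    def test_zero_kernel_halves_features(self, rng):
        fr = rng.normal(size=(4, 5, 5))
        head = {"w": Parameter(np.zeros((1, 2, 7, 7))), "b": Parameter(np.zeros(1))}
        assert np.allclose(spatial_attention(fr, head), 0.5 * fr)

    def test_single_channel_mean_equals_max(self, rng):
        fr = rng.normal(size=(1, 6, 6))
        head = {"w": Parameter(rng.normal(size=(1, 2, 7, 7))),
                "b": Parameter(rng.normal(size=1))}
        # with C=1 the mean and max planes both equal the input plane
        head2 = {"w": Parameter(head["w"].data.sum(axis=1, keepdims=True)
                                 .repeat(2, axis=1) * 0.5),
                 "b": head["b"]}
        assert np.allclose(spatial_attention(fr, head),
                           spatial_attention(fr, head2), atol=1e-10)

    def test_matches_compositional_oracle(self, rng):
        fr = rng.normal(size=(3, 6, 6))
        w, b = rng.normal(size=(1, 2, 7, 7)), rng.normal(size=1)
        head = {"w": Parameter(w), "b": Parameter(b)}
        expect = spatial_attention_naive(fr, w, b)
        assert np.max(np.abs(spatial_attention(fr, head) - expect)) < 1e-6


def _fusion_numpy(fusion):
    return {
        "dw5_w": fusion["dw5_w"].data, "dw5_b": fusion["dw5_b"].data,
        "strips": [(a.data, b.data) for a, b in fusion["strips"]],
        "att_w": fusion["att_w"].data, "att_b": fusion["att_b"].data,
        "red_w": fusion["red_w"].data, "red_b": fusion["red_b"].data,
    }


class TestFuseScales:
    @pytest.fixture
    def params(self, rng):
        return init_enhance_params(3, (1, 3, 5), rng)

    def test_zero_inputs_zero_biases_give_zero(self, params):
        for name in ("dw5_b", "att_b", "red_b"):
            params.fusion[name].data[:] = 0
        out = fuse_scales([np.zeros((3, 6, 6))] * 3, params.fusion)
        assert np.allclose(out, 0)

    def test_matches_stagewise_oracle(self, rng, params):
        frs = [rng.normal(size=(3, 6, 6)) for _ in range(3)]
        expect = fuse_naive(frs, _fusion_numpy(params.fusion))
        assert np.max(np.abs(fuse_scales(frs, params.fusion) - expect)) < 1e-5

    def test_conv_attention_off_skips_attention_path(self, rng, params):
        frs = [rng.normal(size=(3, 6, 6)) for _ in range(3)]
        expect = fuse_naive(frs, _fusion_numpy(params.fusion),
                            conv_attention=False)
        out = fuse_scales(frs, params.fusion, conv_attention=False)
        assert np.max(np.abs(out - expect)) < 1e-5

    def test_mismatched_shapes_rejected(self, rng, params):
        with pytest.raises(ValueError):
            fuse_scales([np.zeros((3, 6, 6)), np.zeros((3, 5, 5)),
                         np.zeros((3, 6, 6))], params.fusion)


class TestEnhance:
    def test_zero_h_reduces_to_layer_norm(self, rng):
        params = init_enhance_params(4, (3,), rng, multiscale=False)
        for name in ("w1", "b1", "w2", "b2"):
            params.h[name].data[:] = 0
        fq = rng.normal(size=(4, 5, 5))
        out = enhance(fq, rng.normal(size=(4, 5, 5)), params)
        mu, var = fq.mean(axis=0), fq.var(axis=0)
        assert np.allclose(out, (fq - mu) / np.sqrt(var + 1e-5), atol=1e-10)

    def test_matches_two_step_oracle(self, rng):
        params = init_enhance_params(3, (3,), rng, multiscale=False)
        fq, fc = rng.normal(size=(3, 5, 5)), rng.normal(size=(3, 5, 5))
        h = {k: v.data for k, v in params.h.items()}
        ln = {k: v.data for k, v in params.ln.items()}
        expect = enhance_naive(fq, fc, h, ln)
        assert np.max(np.abs(enhance(fq, fc, params) - expect)) < 1e-5

    def test_post_layer_norm_statistics(self, rng):
        params = init_enhance_params(16, (3,), rng, multiscale=False)
        out = enhance(rng.normal(size=(16, 6, 6)),
                      rng.normal(size=(16, 6, 6)), params)
        assert np.max(np.abs(out.mean(axis=0))) < 1e-4      # shift = 0
        assert np.max(np.abs(out.var(axis=0) - 1.0)) < 1e-4  # gain = 1


class TestIterate:
    @pytest.fixture
    def setup(self, rng):
        scales = (1, 3, 5)
        protos = PrototypeSet(
            prototypes={k: rng.normal(size=(2, 4, k, k)) for k in scales},
            scales=scales, source_feature_channels=4)
        mapping = init_mapping_params(4, 6, scales, rng)
        fq = rng.normal(size=(4, 6, 6))
        return fq, protos, mapping, scales

    def test_one_iteration_equals_manual_composition(self, rng, setup):
        fq, protos, mapping, scales = setup
        params = init_enhance_params(4, scales, rng, n_iterations=1)
        out = msfem_iterate(fq, protos, mapping, params)
        manual = msfem_once_t(as_tensor(fq), protos.prototypes, mapping,
                              params, scales)
        assert np.array_equal(out.values, manual.data)

    def test_two_iterations_unroll(self, rng, setup):
        fq, protos, mapping, scales = setup
        params = init_enhance_params(4, scales, rng, n_iterations=2)
        out = msfem_iterate(fq, protos, mapping, params)
        once = msfem_once_t(as_tensor(fq), protos.prototypes, mapping, params,
                            scales)
        twice = msfem_once_t(once, protos.prototypes, mapping, params, scales)
        assert np.array_equal(out.values, twice.data)

    def test_outputs_finite_after_four_iterations(self, rng, setup):
        fq, protos, mapping, scales = setup
        params = init_enhance_params(4, scales, rng, n_iterations=4)
        out = msfem_iterate(fq, protos, mapping, params)
        assert np.all(np.isfinite(out.values))
        assert np.abs(out.values).max() < 1e3  # layer norm bounds growth

    def test_single_scale_skips_fusion_parameters(self, rng):
        params = init_enhance_params(4, (3,), rng, multiscale=False,
                                     use_spatial_attention=False)
        assert params.fusion is None and params.sa is None
        names = params.named_parameters()
        assert not any("fusion" in n or ".sa." in n for n in names)
        protos = PrototypeSet(prototypes={3: rng.normal(size=(2, 4, 3, 3))},
                              scales=(3,), source_feature_channels=4)
        mapping = init_mapping_params(4, 6, (3,), rng)
        out = msfem_iterate(rng.normal(size=(4, 6, 6)), protos, mapping, params)
        assert out.values.shape == (4, 6, 6)
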