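"""Similarity comparison: projection, sliding comparison, dual normalization."""

import numpy as np
import pytest
from oracles import (exemplar_norm_naive, map_features_naive, sliding_dot,
                     spatial_norm_naive)

from headcount._autograd import Parameter
from headcount.encoding import FeatureGrid
from headcount.matching import (MappingParams, compare, exemplar_norm,
                                init_mapping_params, map_features,
                                msscm_forward, spatial_norm)
from headcount.rve import PrototypeSet


def _identity_head(c):
    return {"w": Parameter(np.eye(c)), "b": Parameter(np.zeros(c)),
            "gain": Parameter(np.ones(c)), "shift": Parameter(np.zeros(c))}


class TestMapFeatures:
    def test_identity_weights_give_channel_standardized_input(self, rng):
        x = rng.normal(size=(6, 4, 4))
        out = map_features(x, _identity_head(6))
        mu = x.mean(axis=0, keepdims=True)
        var = x.var(axis=0, keepdims=True)
        assert np.allclose(out, (x - mu) / np.sqrt(var + 1e-5), atol=1e-10)

    def test_constant_channel_input_returns_shift(self, rng):
        head = _identity_head(5)
        head["shift"] = Parameter(np.full(5, 1.5))
        out = map_features(np.full((5, 3, 3), 7.0), head)
        assert np.allclose(out, 1.5)

    def test_matches_two_step_oracle(self, rng):
        x = rng.normal(size=(8, 5, 5))
        head = {"w": Parameter(rng.normal(size=(6, 8))),
                "b": Parameter(rng.normal(size=6)),
                "gain": Parameter(rng.normal(size=6)),
                "shift": Parameter(rng.normal(size=6))}
        expect = map_features_naive(x, head["w"].data, head["b"].data,
                                    head["gain"].data, head["shift"].data)
        assert np.max(np.abs(map_features(x, head) - expect)) < 1e-5

    def test_prototype_stack_mapping_matches_grid_mapping(self, rng):
        head = {"w": Parameter(rng.normal(size=(4, 3))),
                "b": Parameter(rng.normal(size=4)),
                "gain": Parameter(rng.normal(size=4)),
                "shift": Parameter(rng.normal(size=4))}
        protos = rng.normal(size=(2, 3, 3, 3))
        out = map_features(protos, head)
        for n in range(2):
            assert np.allclose(out[n], map_features(protos[n], head), atol=1e-12)


class TestCompare:
    def test_scalar_prototype_multiplies_query(self):
        q = np.array([[[1.0, 2.0], [3.0, 4.0]]])
        p = np.array([[[[2.0]]]])
        assert np.array_equal(compare(q, p)[0], [[2, 4], [6, 8]])

    def test_matches_triple_loop_oracle(self, rng):
        q = rng.normal(size=(2, 6, 6))
        p = rng.normal(size=(2, 2, 3, 3))
        assert np.max(np.abs(compare(q, p) - sliding_dot(q, p))) < 1e-6

    def test_shift_equivariance_on_interior(self, rng):
        q = rng.normal(size=(2, 6, 6))
        p = rng.normal(size=(1, 2, 3, 3))
        q_shift = np.zeros_like(q)
        q_shift[:, :, 1:] = q[:, :, :-1]          # shift right by one column
        r, r_shift = compare(q, p), compare(q_shift, p)
        assert np.allclose(r_shift[:, 1:-1, 2:-1], r[:, 1:-1, 1:-2], atol=1e-12)

    def test_even_kernel_rejected(self, rng):
        with pytest.raises(ValueError):
            compare(rng.normal(size=(2, 4, 4)), rng.normal(size=(1, 2, 2, 2)))

    def test_channel_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            compare(rng.normal(size=(3, 4, 4)), rng.normal(size=(1, 2, 3, 3)))


class TestNormalization:
    def test_single_exemplar_norm_is_one(self, rng):
        r = rng.normal(size=(1, 5, 5))
        assert np.allclose(exemplar_norm(r, 3, 3, 8), 1.0)

    def test_equal_maps_split_evenly(self, rng):
        plane = rng.normal(size=(5, 5))
        r = np.stack([plane, plane])
        assert np.allclose(exemplar_norm(r, 1, 1, 4), 0.5)

    def test_exemplar_norm_matches_softmax_oracle(self, rng):
        r = rng.normal(size=(3, 6, 6)) * 5
        out = exemplar_norm(r, 3, 3, 2)
        assert np.allclose(out.sum(axis=0), 1.0, atol=1e-6)
        assert np.max(np.abs(out - exemplar_norm_naive(r, 3 * 3 * 2))) < 1e-6

    def test_constant_plane_spatial_norm_is_one(self):
        r = np.full((2, 4, 4), 3.7)
        assert np.allclose(spatial_norm(r, 1, 1, 2), 1.0)

    def test_unique_max_location(self):
        r = np.zeros((1, 4, 4))
        r[0, 2, 1] = 5.0
        out = spatial_norm(r, 1, 1, 1)
        assert out[0, 2, 1] == 1.0
        out[0, 2, 1] = 0
        assert (out < 1).all()

    def test_spatial_norm_matches_naive_formula(self, rng):
        r = rng.normal(size=(3, 5, 5))
        out = spatial_norm(r, 3, 3, 4)
        assert np.max(np.abs(out - spatial_norm_naive(r, 3 * 3 * 4))) < 1e-6
        assert np.allclose(out.max(axis=(1, 2)), 1.0)


class TestMsscmForward:
    @pytest.fixture
    def setup(self, rng):
        scales = (1, 3, 5)
        params = init_mapping_params(4, 6, scales, rng)
        protos = PrototypeSet(
            prototypes={k: rng.normal(size=(3, 4, k, k)) for k in scales},
            scales=scales, source_feature_channels=4)
        fq = FeatureGrid(values=rng.normal(size=(4, 7, 7)), stride=4)
        return fq, protos, params

    def test_values_in_unit_interval(self, setup):
        sims = msscm_forward(*setup)
        for k, r in sims.normalized.items():
            assert r.min() > 0 and r.max() <= 1.0
            assert r.shape == (3, 7, 7)

    def test_composition_of_normalization_oracles(self, setup):
        fq, protos, params = setup
        sims = msscm_forward(fq, protos, params)
        for k in protos.scales:
            d = k * k * params.projected_channels
            expect = (exemplar_norm_naive(sims.raw[k], d)
                      * spatial_norm_naive(sims.raw[k], d))
            assert np.max(np.abs(sims.normalized[k] - expect)) < 1e-6

    def test_single_exemplar_constant_response_is_one(self, rng):
        params = init_mapping_params(2, 4, (1,), rng)
        # zero gain/shift make the mapped prototype vanish, so the raw
        # response plane is constant; with N=1 both norms are then exactly 1
        params.heads[1]["gain"].data[:] = 0.0
        params.heads[1]["shift"].data[:] = 0.0
        protos = PrototypeSet(prototypes={1: rng.normal(size=(1, 2, 1, 1))},
                              scales=(1,), source_feature_channels=2)
        fq = FeatureGrid(values=rng.normal(size=(2, 5, 5)), stride=4)
        sims = msscm_forward(fq, protos, params)
        assert np.allclose(sims.normalized[1], 1.0)

    def test_sqrt_logit_scale_option(self, setup):
        fq, protos, params = setup
        params.logit_scale = "sqrt"
        sims = msscm_forward(fq, protos, params)
        d = np.sqrt(3 * 3 * params.projected_channels)
        expect = (exemplar_norm_naive(sims.raw[3], d)
                  * spatial_norm_naive(sims.raw[3], d))
        assert np.max(np.abs(sims.normalized[3] - expect)) < 1e-6


def test_head_location_scores_above_background_median(small_field, toy_extractor):
    """A prototype sampled at a head must score higher at that head than the
    background median response (discriminability smoke test)."""
    from headcount.encoding import extract_features
    from headcount.rve import build_prototypes

    rng = np.random.default_rng(0)
    fq = extract_features(small_field.image, toy_extractor)
    protos = build_prototypes(small_field.image, small_field.boxes[:1],
                              toy_extractor, mask_provider="otsu")
    params = init_mapping_params(fq.channels, 16, protos.scales, rng)
    sims = msscm_forward(fq, protos, params)
    x0, y0, x1, y1 = small_field.boxes[0]
    r, c = int((y0 + y1) / 2) // 4, int((x0 + x1) / 2) // 4
    for k in (3, 5):
        plane = sims.normalized[k][0]
        assert plane[r, c] > np.median(plane)
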