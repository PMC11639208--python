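"""Multiscale feature enhancement (MSFEM).

Similarity maps are turned back into spatial feature maps by convolving each
exemplar's plane with its spatially *flipped* prototype and summing over
exemplars (equivalently: every similarity value stamps a prototype-shaped
contribution at its location).  Each scale then receives spatial attention
(sigmoid of a 7x7 convolution over the channel-mean/channel-max stack), the
scales are fused by strip-convolution attention (5x5 depthwise base, 1x7/7x1,
1x11/11x1, 1x21/21x1 depthwise branches, 1x1 channel mixing), and the fused
map is added residually to the query features through a two-layer
convolutional head followed by layer normalization.  The whole block can be
iterated, feeding the enhanced features back in as the query.

Reconstruction uses the *unmapped* (backbone-space) prototypes so that the
residual addition stays in the query's channel space; the projection heads
of the comparison module act only inside the similarity computation.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ._autograd import (Parameter, Tensor, as_tensor, concat_channels, conv2d,
                        depthwise_conv2d, layer_norm)
from .encoding import FeatureGrid
from .matching import MappingParams, msscm_forward_t
from .rve import PrototypeSet

__all__ = [
    "EnhanceParams",
    "init_enhance_params",
    "reconstruct",
    "spatial_attention",
    "fuse_scales",
    "enhance",
    "msfem_iterate",
]

STRIP_SIZES = (7, 11, 21)


@dataclasses.dataclass
class EnhanceParams:
    sa: dict | None           # per scale: {"w": (1,2,7,7), "b": (1,)}
    fusion: dict | None       # dw5/strips/att/reduce weights (multiscale only)
    h: dict                   # two 3x3 conv layers C->C
    ln: dict                  # final layer-norm gain/shift
    n_iterations: int
    spatial_attention: bool = True
    conv_attention: bool = True

    def named_parameters(self, prefix="enhance"):
        out = {}
        if self.sa is not None:
            for k, head in self.sa.items():
                out[f"{prefix}.sa.{k}.w"] = head["w"]
                out[f"{prefix}.sa.{k}.b"] = head["b"]
        if self.fusion is not None:
            f = self.fusion
            out[f"{prefix}.fusion.dw5_w"] = f["dw5_w"]
            out[f"{prefix}.fusion.dw5_b"] = f["dw5_b"]
            for i, (wa, wb) in enumerate(f["strips"]):
                out[f"{prefix}.fusion.strip{i}a"] = wa
                out[f"{prefix}.fusion.strip{i}b"] = wb
            out[f"{prefix}.fusion.att_w"] = f["att_w"]
            out[f"{prefix}.fusion.att_b"] = f["att_b"]
            out[f"{prefix}.fusion.red_w"] = f["red_w"]
            out[f"{prefix}.fusion.red_b"] = f["red_b"]
        for name in ("w1", "b1", "w2", "b2"):
            out[f"{prefix}.h.{name}"] = self.h[name]
        out[f"{prefix}.ln.gain"] = self.ln["gain"]
        out[f"{prefix}.ln.shift"] = self.ln["shift"]
        return out


def init_enhance_params(c: int, scales, rng: np.random.Generator,
                        n_iterations: int = 2, multiscale: bool = True,
                        use_spatial_attention: bool = True,
                        use_conv_attention: bool = True) -> EnhanceParams:
    def glorot(shape, fan_in, fan_out):
        return Parameter(rng.normal(0, np.sqrt(2.0 / (fan_in + fan_out)), size=shape))

    sa = None
    if use_spatial_attention:
        sa = {k: {"w": glorot((1, 2, 7, 7), 2 * 49, 49), "b": Parameter(np.zeros(1))}
              for k in scales}
    fusion = None
    if multiscale:
        cc = c * len(scales)
        fusion = {
            "dw5_w": Parameter(rng.normal(0, np.sqrt(2.0 / 25), size=(cc, 5, 5))),
            "dw5_b": Parameter(np.zeros(cc)),
            "strips": [
                (Parameter(rng.normal(0, np.sqrt(2.0 / s), size=(cc, 1, s))),
                 Parameter(rng.normal(0, np.sqrt(2.0 / s), size=(cc, s, 1))))
                for s in STRIP_SIZES
            ],
            "att_w": glorot((cc, cc, 1, 1), cc, cc),
            "att_b": Parameter(np.zeros(cc)),
            "red_w": glorot((c, cc, 1, 1), cc, c),
            "red_b": Parameter(np.zeros(c)),
        }
    h = {
        "w1": glorot((c, c, 3, 3), c * 9, c * 9),
        "b1": Parameter(np.zeros(c)),
        "w2": glorot((c, c, 3, 3), c * 9, c * 9),
        "b2": Parameter(np.zeros(c)),
    }
    ln = {"gain": Parameter(np.ones(c)), "shift": Parameter(np.zeros(c))}
    return EnhanceParams(sa=sa, fusion=fusion, h=h, ln=ln,
                         n_iterations=n_iterations,
                         spatial_attention=use_spatial_attention,
                         conv_attention=use_conv_attention)


# ---------------------------------------------------------------------------
# tensor kernels
# ---------------------------------------------------------------------------

def reconstruct_t(r: Tensor, prototypes: np.ndarray) -> Tensor:
    """Convolve similarity planes with flipped prototypes, sum over exemplars.

    r: (N, H, W); prototypes: (N, C, k, k) constants (the frozen support
    path).  Returns (C, H, W).
    """
    protos = np.asarray(prototypes, dtype=np.float64)
    N, C, k, k2 = protos.shape
    if r.shape[0] != N:
        raise ValueError(f"{r.shape[0]} similarity planes but {N} prototypes")
    if k != k2 or k % 2 == 0:
        raise ValueError(f"prototype kernels must be square and odd, got {k}x{k2}")
    # stamping == correlation with the flipped kernel; exemplars act as the
    # input channels of a standard multi-channel convolution
    w = Tensor(protos[:, :, ::-1, ::-1].transpose(1, 0, 2, 3).copy())
    return conv2d(r, w)


def spatial_attention_t(fr: Tensor, head) -> Tensor:
    avg = fr.mean(axis=0, keepdims=True)
    mx = fr.max(axis=0, keepdims=True)
    att = conv2d(concat_channels([avg, mx]), head["w"], head["b"]).sigmoid()
    return fr * att


def fuse_scales_t(frs: list[Tensor], fusion, conv_attention: bool = True) -> Tensor:
    if len({f.shape for f in frs}) != 1:
        raise ValueError("fuse_scales inputs must share one shape")
    fc = concat_channels(frs)
    if conv_attention:
        base = depthwise_conv2d(fc, fusion["dw5_w"], fusion["dw5_b"])
        agg = base
        for wa, wb in fusion["strips"]:
            agg = agg + depthwise_conv2d(depthwise_conv2d(base, wa), wb)
        att = conv2d(agg, fusion["att_w"], fusion["att_b"])
        fc = fc * att
    return conv2d(fc, fusion["red_w"], fusion["red_b"])


def enhance_t(fq: Tensor, fcp: Tensor, params: EnhanceParams) -> Tensor:
    if fq.shape != fcp.shape:
        raise ValueError(f"shape mismatch: fQ {fq.shape} vs fused {fcp.shape}")
    h = conv2d(fcp, params.h["w1"], params.h["b1"]).relu()
    h = conv2d(h, params.h["w2"], params.h["b2"])
    return layer_norm(fq + h, params.ln["gain"], params.ln["shift"])


def msfem_once_t(fq: Tensor, protos: dict, mapping: MappingParams,
                 params: EnhanceParams, scales) -> Tensor:
    sims = msscm_forward_t(fq, protos, mapping, scales)
    frs = []
    for k in scales:
        fr = reconstruct_t(sims[k], protos[k])
        if params.spatial_attention and params.sa is not None:
            fr = spatial_attention_t(fr, params.sa[k])
        frs.append(fr)
    if params.fusion is not None and len(scales) > 1:
        fused = fuse_scales_t(frs, params.fusion, params.conv_attention)
    else:
        fused = frs[0]
    return enhance_t(fq, fused, params)


def msfem_iterate_t(fq: Tensor, protos: dict, mapping: MappingParams,
                    params: EnhanceParams, scales) -> Tensor:
    if params.n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    out = fq
    for _ in range(params.n_iterations):
        out = msfem_once_t(out, protos, mapping, params, scales)
    return out


# ---------------------------------------------------------------------------
# numpy-facing API
# ---------------------------------------------------------------------------

def reconstruct(r: np.ndarray, prototypes: np.ndarray) -> np.ndarray:
    return reconstruct_t(as_tensor(r), prototypes).data


def spatial_attention(fr: np.ndarray, head) -> np.ndarray:
    return spatial_attention_t(as_tensor(fr), head).data


def fuse_scales(frs, fusion, conv_attention: bool = True) -> np.ndarray:
    return fuse_scales_t([as_tensor(f) for f in frs], fusion, conv_attention).data


def enhance(fq: np.ndarray, fcp: np.ndarray, params: EnhanceParams) -> np.ndarray:
    return enhance_t(as_tensor(fq), as_tensor(fcp), params).data


def msfem_iterate(fq, protos: PrototypeSet, mapping: MappingParams,
                  params: EnhanceParams) -> FeatureGrid:
    fq_grid = fq if isinstance(fq, FeatureGrid) else FeatureGrid(np.asarray(fq), 1)
    out = msfem_iterate_t(as_tensor(fq_grid.values), protos.prototypes, mapping,
                          params, protos.scales)
    return FeatureGrid(values=out.data, stride=fq_grid.stride)
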