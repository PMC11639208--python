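"""Multiscale similarity comparison (MSSCM).

Query features and exemplar prototypes are projected into a shared embedding
space by a per-position linear map plus channel layer normalization; each
prototype is then slid over the query grid as a cross-correlation kernel,
and the raw responses are dual-normalized:

* exemplar norm — softmax across exemplars at every location, after scaling
  the logits by 1/(HS*WS*C);
* spatial norm — per exemplar plane, exp of the scaled response divided by
  its spatial maximum (computed stably as exp(z - max z)).

The final similarity map is the elementwise product of the two, so values
lie in (0, 1] and, with a single exemplar, the exemplar norm is identically
one.

Public functions take and return numpy arrays; the ``*_t`` kernels operate
on autograd tensors and are what training differentiates through.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ._autograd import Parameter, Tensor, as_tensor, layer_norm, softmax0
from .encoding import FeatureGrid
from .rve import PrototypeSet

__all__ = [
    "MappingParams",
    "SimilarityMaps",
    "init_mapping_params",
    "map_features",
    "compare",
    "exemplar_norm",
    "spatial_norm",
    "msscm_forward",
]


@dataclasses.dataclass
class MappingParams:
    """One projection head (1x1 conv + layer norm) per scale plus one for
    the query; trainable in stage 1 only."""

    heads: dict  # key: "query" or scale int -> dict of Tensors w, b, gain, shift
    projected_channels: int
    logit_scale: str = "product"  # divisor HS*WS*C, or its square root

    def named_parameters(self, prefix="mapping"):
        out = {}
        for key, head in self.heads.items():
            for name, t in head.items():
                out[f"{prefix}.{key}.{name}"] = t
        return out


def init_mapping_params(c_in: int, c_out: int, scales, rng: np.random.Generator,
                        shared: bool = False) -> MappingParams:
    def one_head():
        std = np.sqrt(2.0 / (c_in + c_out))
        return {
            "w": Parameter(rng.normal(0, std, size=(c_out, c_in))),
            "b": Parameter(np.zeros(c_out)),
            "gain": Parameter(np.ones(c_out)),
            "shift": Parameter(np.zeros(c_out)),
        }

    if shared:
        head = one_head()
        heads = {"query": head, **{k: head for k in scales}}
    else:
        heads = {"query": one_head(), **{k: one_head() for k in scales}}
    return MappingParams(heads=heads, projected_channels=c_out)


# ---------------------------------------------------------------------------
# tensor kernels
# ---------------------------------------------------------------------------

def map_grid_t(x: Tensor, head) -> Tensor:
    """Project a (C, H, W) grid: per-position linear map, then channel LN."""
    C, H, W = x.shape
    y = (head["w"] @ x.reshape(C, H * W) + head["b"].reshape(-1, 1))
    y = y.reshape(head["w"].shape[0], H, W)
    return layer_norm(y, head["gain"], head["shift"])


def map_protos_t(p: Tensor, head) -> Tensor:
    """Project an (N, C, k, k) prototype stack with the same head."""
    N, C, k, _ = p.shape
    flat = p.transpose((1, 0, 2, 3)).reshape(C, N * k * k)
    y = head["w"] @ flat + head["b"].reshape(-1, 1)
    c_out = head["w"].shape[0]
    y = layer_norm(y.reshape(c_out, N, k * k), head["gain"], head["shift"])
    return y.reshape(c_out, N, k, k).transpose((1, 0, 2, 3))


def compare_t(fq: Tensor, protos: Tensor) -> Tensor:
    """Slide each (C, k, k) prototype over the (C, H, W) query grid.

    Zero-padded 'same' cross-correlation; one response plane per exemplar.
    """
    N, C, k, k2 = protos.shape
    if k != k2 or k % 2 == 0:
        raise ValueError(f"prototype kernels must be square and odd, got {k}x{k2}")
    if fq.shape[0] != C:
        raise ValueError(f"channel mismatch: query {fq.shape[0]}, prototypes {C}")
    H, W = fq.shape[1:]
    cols = fq.unfold(k, k)                      # (H*W, C*k*k)
    pm = protos.reshape(N, C * k * k)
    return (cols @ pm.transpose((1, 0))).transpose((1, 0)).reshape(N, H, W)


def _logit_divisor(hs: int, ws: int, c: int, logit_scale: str = "product") -> float:
    d = float(hs * ws * c)
    if logit_scale == "sqrt":
        return float(np.sqrt(d))
    if logit_scale != "product":
        raise ValueError(f"logit_scale must be 'product' or 'sqrt', got {logit_scale!r}")
    return d


def exemplar_norm_t(r: Tensor, hs: int, ws: int, c: int,
                    logit_scale: str = "product") -> Tensor:
    return softmax0(r * (1.0 / _logit_divisor(hs, ws, c, logit_scale)))


def spatial_norm_t(r: Tensor, hs: int, ws: int, c: int,
                   logit_scale: str = "product") -> Tensor:
    z = r * (1.0 / _logit_divisor(hs, ws, c, logit_scale))
    return (z - z.max(axis=(1, 2), keepdims=True)).exp()


# ---------------------------------------------------------------------------
# numpy-facing API
# ---------------------------------------------------------------------------

def map_features(x: np.ndarray, head) -> np.ndarray:
    """Project query grid (C,H,W) or prototype stack (N,C,k,k)."""
    t = as_tensor(np.asarray(x, dtype=np.float64))
    if t.ndim == 3:
        return map_grid_t(t, head).data
    if t.ndim == 4:
        return map_protos_t(t, head).data
    raise ValueError(f"expected 3-D grid or 4-D prototype stack, got {t.shape}")


def compare(fq_mapped: np.ndarray, prototypes_mapped: np.ndarray) -> np.ndarray:
    return compare_t(as_tensor(fq_mapped), as_tensor(prototypes_mapped)).data


def exemplar_norm(r_o: np.ndarray, hs: int, ws: int, c: int) -> np.ndarray:
    return exemplar_norm_t(as_tensor(r_o), hs, ws, c).data


def spatial_norm(r_o: np.ndarray, hs: int, ws: int, c: int) -> np.ndarray:
    return spatial_norm_t(as_tensor(r_o), hs, ws, c).data


@dataclasses.dataclass
class SimilarityMaps:
    """Per scale: normalized similarity in (0,1] and the raw responses."""

    normalized: dict[int, np.ndarray]
    raw: dict[int, np.ndarray]

    def __post_init__(self):
        for k, r in self.normalized.items():
            if not np.all(np.isfinite(r)):
                raise ValueError(f"non-finite similarity at scale {k}")
            if r.min() <= 0 or r.max() > 1 + 1e-12:
                raise ValueError(f"scale {k} similarity outside (0, 1]")


def msscm_forward_t(fq: Tensor, protos: dict, params: MappingParams,
                    scales) -> dict[int, Tensor]:
    """Tensor path returning the normalized similarity map per scale."""
    q = map_grid_t(fq, params.heads["query"])
    c = params.projected_channels
    ls = params.logit_scale
    out = {}
    for k in scales:
        p = map_protos_t(as_tensor(protos[k]), params.heads[k])
        r_o = compare_t(q, p)
        out[k] = exemplar_norm_t(r_o, k, k, c, ls) * spatial_norm_t(r_o, k, k, c, ls)
    return out


def msscm_forward(fq, protos: PrototypeSet, params: MappingParams) -> SimilarityMaps:
    fq_arr = fq.values if isinstance(fq, FeatureGrid) else np.asarray(fq)
    q = map_grid_t(as_tensor(fq_arr), params.heads["query"])
    c = params.projected_channels
    ls = params.logit_scale
    normalized, raw = {}, {}
    for k in protos.scales:
        p = map_protos_t(as_tensor(protos.prototypes[k]), params.heads[k])
        r_o = compare_t(q, p)
        raw[k] = r_o.data
        normalized[k] = (exemplar_norm_t(r_o, k, k, c, ls)
                         * spatial_norm_t(r_o, k, k, c, ls)).data
    return SimilarityMaps(normalized=normalized, raw=raw)
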