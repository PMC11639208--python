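"""Refined vision encoder: mask-gated multiscale prototype extraction.

A support (exemplar) crop is summarised as one small C x k x k prototype per
scale k.  Instead of pooling everything inside the exemplar's bounding box —
which in cereal-crop imagery drags leaves and stems into the prototype — the
support features are first gated by a foreground mask of the head, and
pooling bins average over mask-active feature cells only.  This path is
frozen: it has no trainable state in either training stage.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .encoding import ExemplarMask, FeatureGrid, extract_features, make_mask

__all__ = ["PrototypeSet", "gate_features", "pool_prototypes", "build_prototypes"]

DEFAULT_SCALES = (1, 3, 5)


@dataclasses.dataclass
class PrototypeSet:
    """Per scale k: an (N, C, k, k) array of exemplar prototypes."""

    prototypes: dict[int, np.ndarray]
    scales: tuple[int, ...]
    source_feature_channels: int

    def __post_init__(self):
        ns = {self.prototypes[k].shape[0] for k in self.scales}
        if len(ns) != 1:
            raise ValueError(f"inconsistent exemplar counts across scales: {ns}")
        if min(ns) < 1:
            raise ValueError("PrototypeSet needs at least one exemplar")
        for k in self.scales:
            p = self.prototypes[k]
            if p.shape[1:] != (self.source_feature_channels, k, k):
                raise ValueError(f"scale {k} prototype has shape {p.shape}")
            if not np.all(np.isfinite(p)):
                raise ValueError("prototypes must be finite")

    @property
    def n_exemplars(self) -> int:
        return self.prototypes[self.scales[0]].shape[0]


def downsample_mask(mask: np.ndarray, stride: int) -> np.ndarray:
    """Area-average an image-resolution binary mask to the feature grid and
    binarize at > 0 (any coverage keeps the cell)."""
    rows, cols = mask.shape
    hf, wf = rows // stride, cols // stride
    block = mask[: hf * stride, : wf * stride].reshape(hf, stride, wf, stride)
    return (block.mean(axis=(1, 3)) > 0).astype(np.float64)


def gate_features(fp: FeatureGrid, mask: ExemplarMask) -> FeatureGrid:
    """Zero support features outside the (downsampled) exemplar mask."""
    m = downsample_mask(np.asarray(mask.values, dtype=np.float64), fp.stride)
    if m.shape != fp.values.shape[1:]:
        raise ValueError(
            f"mask {mask.values.shape} does not map onto feature grid "
            f"{fp.values.shape[1:]} at stride {fp.stride}"
        )
    if not m.any():
        raise ValueError("downsampled mask is entirely zero (empty support)")
    return FeatureGrid(values=fp.values * m[None], stride=fp.stride)


def _box_to_cells(box, stride: int, hf: int, wf: int):
    """Map an image-space half-open box to the feature cells it touches."""
    x0, y0, x1, y1 = box
    c0, c1 = int(np.floor(x0 / stride)), int(np.ceil(x1 / stride))
    r0, r1 = int(np.floor(y0 / stride)), int(np.ceil(y1 / stride))
    r0, c0 = max(r0, 0), max(c0, 0)
    r1, c1 = min(r1, hf), min(c1, wf)
    if r1 <= r0 or c1 <= c0:
        raise ValueError(f"box {box} maps to zero feature cells at stride {stride}")
    return r0, r1, c0, c1


def _adaptive_bins(n: int, k: int):
    """Partition n cells into k contiguous bins (adaptive average pooling)."""
    return [(int(np.floor(i * n / k)), int(np.ceil((i + 1) * n / k))) for i in range(k)]


def pool_prototypes(gated: FeatureGrid, box, scales=DEFAULT_SCALES,
                    active: np.ndarray | None = None) -> dict[int, np.ndarray]:
    """Pool the boxed region of a gated feature grid into k x k prototypes.

    Each pooling bin averages over mask-active cells only; a bin containing
    no active cell inherits the mean over active cells of the whole box.
    ``active`` is the feature-resolution activity mask; by default any cell
    with a nonzero feature vector counts as active.
    """
    C, hf, wf = gated.values.shape
    r0, r1, c0, c1 = _box_to_cells(box, gated.stride, hf, wf)
    patch = gated.values[:, r0:r1, c0:c1]
    if active is None:
        act = np.any(patch != 0, axis=0)
    else:
        act = np.asarray(active, dtype=bool)[r0:r1, c0:c1]
    if not act.any():
        act = np.ones(patch.shape[1:], dtype=bool)  # boxfill degenerate case
    box_mean = patch[:, act].mean(axis=1)

    out = {}
    for k in scales:
        proto = np.empty((C, k, k))
        rbins = _adaptive_bins(patch.shape[1], k)
        cbins = _adaptive_bins(patch.shape[2], k)
        for i, (a0, a1) in enumerate(rbins):
            for j, (b0, b1) in enumerate(cbins):
                sub_act = act[a0:a1, b0:b1]
                if sub_act.any():
                    proto[:, i, j] = patch[:, a0:a1, b0:b1][:, sub_act].mean(axis=1)
                else:
                    proto[:, i, j] = box_mean
        out[k] = proto
    return out


def build_prototypes(support_image: np.ndarray, boxes, extractor,
                     mask_provider="boxfill",
                     scales=DEFAULT_SCALES) -> PrototypeSet:
    """Full frozen support path: encode, mask-gate, pool, one slice per box."""
    if len(boxes) < 1:
        raise ValueError("at least one exemplar box is required")
    fp = extract_features(support_image, extractor)
    per_scale: dict[int, list[np.ndarray]] = {k: [] for k in scales}
    for box in boxes:
        mask = make_mask(support_image, box, mask_provider)
        gated = gate_features(fp, mask)
        act = downsample_mask(np.asarray(mask.values, dtype=np.float64), fp.stride)
        protos = pool_prototypes(gated, box, scales, active=act.astype(bool))
        for k in scales:
            per_scale[k].append(protos[k])
    return PrototypeSet(
        prototypes={k: np.stack(per_scale[k]) for k in scales},
        scales=tuple(scales),
        source_feature_channels=fp.channels,
    )
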