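"""Frozen image-encoder and exemplar-mask-provider contracts.

The counting pipeline is backbone-agnostic: any callable that maps an RGB
image to a channels x Hf x Wf feature grid at a fixed stride can serve as
the encoder, and any callable that maps (image, box) to a binary foreground
mask can serve as the mask provider.  Built-ins:

* ``toy`` extractor -- two blocks of (3x3 convolution, ReLU, 2x average
  downsampling), stride 4, seeded random weights, frozen.  It mimics the
  geometry and frozen-backbone protocol of a large pretrained ViT at desk
  scale.
* ``boxfill`` mask provider -- the whole box interior (the no-refinement
  baseline).
* ``otsu`` mask provider -- intensity threshold inside the box, keeping the
  largest connected component; degrades to ``boxfill`` with a warning when
  thresholding finds no foreground.
* ``external:<module>:<attr>`` -- delegate to a plugged segmentation
  callable (e.g. a promptable-segmentation wrapper) honouring the same
  contract.

Frozen means frozen: extractor parameters are never updated by training and
a checksum over them is part of the training-purity test surface.
"""

from __future__ import annotations

import dataclasses
import hashlib
import importlib
import warnings

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

__all__ = [
    "FeatureGrid",
    "ExemplarMask",
    "MaskFallbackWarning",
    "ToyExtractor",
    "get_extractor",
    "get_mask_provider",
    "extract_features",
    "make_mask",
]


@dataclasses.dataclass
class FeatureGrid:
    values: np.ndarray   # (C, Hf, Wf)
    stride: int          # pixels per feature cell

    def __post_init__(self):
        if self.values.ndim != 3:
            raise ValueError(f"FeatureGrid values must be 3-D, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("FeatureGrid values must be finite")
        if self.stride < 1:
            raise ValueError(f"stride must be >= 1, got {self.stride}")

    @property
    def channels(self) -> int:
        return self.values.shape[0]


@dataclasses.dataclass
class ExemplarMask:
    values: np.ndarray       # (rows, cols) binary, 1 = head pixel
    source_box: list         # [x0, y0, x1, y1] half-open

    def __post_init__(self):
        x0, y0, x1, y1 = self.source_box
        outside = self.values.copy()
        outside[y0:y1, x0:x1] = 0
        if outside.any():
            raise ValueError("mask has foreground outside its source box")
        if not self.values.any():
            raise ValueError("mask must contain at least one foreground pixel")


class MaskFallbackWarning(UserWarning):
    """Thresholding found no foreground; the provider fell back to boxfill."""


def _checksum(arrays) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a, dtype=np.float64).tobytes())
    return h.hexdigest()


class ToyExtractor:
    """Seeded random two-block convolutional encoder, stride 4, frozen."""

    stride = 4

    def __init__(self, channels: int = 64, seed: int = 0):
        self.channels = channels
        rng = np.random.default_rng(seed)
        mid = max(channels // 2, 4)
        self.w1 = rng.normal(0, np.sqrt(2.0 / (3 * 9)), size=(mid, 3, 3, 3))
        self.b1 = np.zeros(mid)
        self.w2 = rng.normal(0, np.sqrt(2.0 / (mid * 9)), size=(channels, mid, 3, 3))
        self.b2 = np.zeros(channels)

    def parameter_checksum(self) -> str:
        return _checksum([self.w1, self.b1, self.w2, self.b2])

    @staticmethod
    def _conv(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
        Cout, Cin, kh, kw = w.shape
        C, H, W = x.shape
        pad = np.pad(x, ((0, 0), (kh // 2, kh // 2), (kw // 2, kw // 2)))
        win = np.lib.stride_tricks.sliding_window_view(pad, (kh, kw), axis=(1, 2))
        cols = win.transpose(1, 2, 0, 3, 4).reshape(H * W, C * kh * kw)
        out = cols @ w.reshape(Cout, -1).T + b
        return out.T.reshape(Cout, H, W)

    @staticmethod
    def _pool2(x: np.ndarray) -> np.ndarray:
        C, H, W = x.shape
        return x.reshape(C, H // 2, 2, W // 2, 2).mean(axis=(2, 4))

    def __call__(self, image: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(image.transpose(2, 0, 1), dtype=np.float64)
        x = self._pool2(np.maximum(self._conv(x, self.w1, self.b1), 0.0))
        x = self._pool2(np.maximum(self._conv(x, self.w2, self.b2), 0.0))
        return x


def get_extractor(key: str, channels: int = 64, seed: int = 0):
    """Resolve an extractor by registry key.

    ``"toy"`` is built in; ``"external:<module>:<attr>"`` imports a callable
    with attributes ``stride`` and ``channels`` honouring the same contract
    (e.g. a self-supervised ViT wrapper whose native patch grid has been
    resampled to the required geometry).
    """
    if key == "toy":
        return ToyExtractor(channels=channels, seed=seed)
    if key.startswith("external:"):
        return _load_entrypoint(key)
    raise KeyError(f"unknown extractor key: {key!r}")


def _load_entrypoint(key: str):
    _, mod, attr = key.split(":", 2)
    return getattr(importlib.import_module(mod), attr)


def extract_features(image: np.ndarray, extractor) -> FeatureGrid:
    """Run the frozen encoder on an (rows, cols, 3) image in [0, 1]."""
    rows, cols = image.shape[:2]
    stride = extractor.stride
    if rows % stride or cols % stride:
        raise ValueError(
            f"image size {rows}x{cols} not divisible by extractor stride {stride}"
        )
    values = np.asarray(extractor(image), dtype=np.float64)
    return FeatureGrid(values=values, stride=stride)


# ---------------------------------------------------------------------------
# mask providers
# ---------------------------------------------------------------------------

def _boxfill(image: np.ndarray, box) -> np.ndarray:
    x0, y0, x1, y1 = box
    mask = np.zeros(image.shape[:2], dtype=np.uint8)
    mask[y0:y1, x0:x1] = 1
    return mask


def _otsu(image: np.ndarray, box) -> np.ndarray:
    x0, y0, x1, y1 = box
    crop = image[y0:y1, x0:x1]
    gray = crop.mean(axis=2)
    if np.ptp(gray) < 1e-9:
        return np.zeros(image.shape[:2], dtype=np.uint8)  # triggers fallback
    thr = threshold_otsu(gray)
    bright = gray > thr
    # exemplar boxes are tight around the head, so the head covers the box
    # centre: foreground is the intensity class at the centre pixel, and we
    # keep the centre's connected component (falling back to the largest)
    h, w = gray.shape
    cy, cx = h // 2, w // 2
    fg = bright if bright[cy, cx] else ~bright
    if not fg.any():
        return np.zeros(image.shape[:2], dtype=np.uint8)
    lab = cc_label(fg, connectivity=2)
    keep = lab[cy, cx]
    if keep == 0:
        keep = np.argmax(np.bincount(lab.ravel())[1:]) + 1
    mask = np.zeros(image.shape[:2], dtype=np.uint8)
    mask[y0:y1, x0:x1] = (lab == keep).astype(np.uint8)
    return mask


def get_mask_provider(key: str):
    if key == "boxfill":
        return _boxfill
    if key == "otsu":
        return _otsu
    if key.startswith("external:"):
        return _load_entrypoint(key)
    raise KeyError(f"unknown mask provider key: {key!r}")


def make_mask(image: np.ndarray, box, provider) -> ExemplarMask:
    """Produce a refined foreground mask for one exemplar box.

    Never returns an empty mask: if the provider finds no foreground the box
    interior is used instead and a :class:`MaskFallbackWarning` is emitted.
    """
    x0, y0, x1, y1 = box
    rows, cols = image.shape[:2]
    if not (0 <= x0 < x1 <= cols and 0 <= y0 < y1 <= rows):
        raise ValueError(f"box {box} not inside {rows}x{cols} image with positive area")
    if isinstance(provider, str):
        provider = get_mask_provider(provider)
    mask = np.asarray(provider(image, box), dtype=np.uint8)
    clipped = np.zeros_like(mask)
    clipped[y0:y1, x0:x1] = mask[y0:y1, x0:x1] > 0
    if not clipped.any():
        warnings.warn(
            f"mask provider found no foreground in box {box}; using box interior",
            MaskFallbackWarning,
        )
        clipped = _boxfill(image, box)
    return ExemplarMask(values=clipped, source_box=list(box))
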