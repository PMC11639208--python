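"""Deterministic synthetic crop-field generator.

Produces small RGB "field" images in which grain heads appear as golden
elliptical blobs over a cluttered green background (low-frequency colour
noise plus dark leaf/stem stripes), together with exact head-centre point
annotations, tight exemplar bounding boxes, and per-exemplar foreground
masks.  Every downstream stage of the counting pipeline is testable on these
fields without any external dataset.

Conventions (used package-wide): coordinates are 0-based with ``x`` the
column and ``y`` the row; boxes are axis-aligned ``[x0, y0, x1, y1]`` and
half-open.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line as draw_line
from skimage.transform import resize

__all__ = [
    "SyntheticFieldSpec",
    "AnnotatedField",
    "PlacementError",
    "generate_field",
    "write_dataset",
]


class PlacementError(RuntimeError):
    """Raised when heads cannot be placed under the spec's constraints."""


@dataclasses.dataclass(frozen=True)
class SyntheticFieldSpec:
    image_size: tuple[int, int] = (64, 64)          # (rows, cols)
    count_range: tuple[int, int] = (5, 15)          # inclusive head count
    head_semiaxes_range: tuple[float, float] = (3.0, 6.0)   # major semiaxis, px
    eccentricity_range: tuple[float, float] = (0.3, 0.8)
    overlap_allowed: bool = True
    clutter_level: float = 0.3
    n_exemplars: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.count_range[0] < 1 or self.count_range[0] > self.count_range[1]:
            raise ValueError(
                f"count_range must satisfy 1 <= min <= max, got {self.count_range}"
            )
        if self.head_semiaxes_range[0] < 2:
            raise ValueError(
                f"head_semiaxes_range.min must be >= 2 px, got {self.head_semiaxes_range}"
            )
        if not (0.0 <= self.clutter_level <= 1.0):
            raise ValueError(f"clutter_level must be in [0,1], got {self.clutter_level}")
        if not (0.0 <= self.eccentricity_range[0] <= self.eccentricity_range[1] < 1.0):
            raise ValueError(
                f"eccentricity_range must lie in [0,1), got {self.eccentricity_range}"
            )
        if self.n_exemplars < 1:
            raise ValueError(f"n_exemplars must be >= 1, got {self.n_exemplars}")


@dataclasses.dataclass
class AnnotatedField:
    image: np.ndarray                  # (rows, cols, 3) float in [0,1]
    points: list[tuple[float, float]]  # (x, y) head centres
    boxes: list[list[int]]             # [x0, y0, x1, y1], half-open
    masks: list[np.ndarray]            # per box: (rows, cols) uint8 {0,1}
    count: int


_HEAD_COLOR = np.array([0.82, 0.70, 0.32])
_BG_COLOR = np.array([0.26, 0.42, 0.20])
_STRIPE_COLOR = np.array([0.10, 0.22, 0.08])


def _render_background(rng: np.random.Generator, rows: int, cols: int,
                       clutter: float) -> np.ndarray:
    coarse = rng.normal(0.0, 0.08, size=(max(rows // 8, 2), max(cols // 8, 2), 3))
    noise = resize(coarse, (rows, cols, 3), order=1, mode="edge",
                   anti_aliasing=False)
    img = np.clip(_BG_COLOR[None, None] + noise, 0.0, 1.0)
    n_stripes = int(round(clutter * rows * cols / 180.0))
    for _ in range(n_stripes):
        r0, c0 = rng.integers(0, rows), rng.integers(0, cols)
        angle = rng.uniform(0, np.pi)
        length = rng.uniform(0.2, 0.6) * min(rows, cols)
        r1 = int(np.clip(r0 + length * np.sin(angle), 0, rows - 1))
        c1 = int(np.clip(c0 + length * np.cos(angle), 0, cols - 1))
        shade = rng.uniform(0.6, 1.2)
        for dr in (0, 1):  # 2-px-thick stripe
            rr, cc = draw_line(min(r0 + dr, rows - 1), c0, min(r1 + dr, rows - 1), c1)
            img[rr, cc] = np.clip(_STRIPE_COLOR * shade, 0, 1)
    return img


def generate_field(spec: SyntheticFieldSpec) -> AnnotatedField:
    """Render one annotated field deterministically from ``spec``.

    Raises :class:`PlacementError` if the requested count cannot be placed
    (only possible with ``overlap_allowed=False`` and crowded settings).
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.image_size
    count = int(rng.integers(spec.count_range[0], spec.count_range[1] + 1))
    if count < spec.n_exemplars:
        raise ValueError(
            f"count_range yields {count} heads but n_exemplars={spec.n_exemplars}"
        )

    img = _render_background(rng, rows, cols, spec.clutter_level)
    occupancy = np.zeros((rows, cols), dtype=bool)
    centers: list[tuple[float, float]] = []
    pixsets: list[tuple[np.ndarray, np.ndarray]] = []

    for _ in range(count):
        placed = False
        for _attempt in range(300):
            a = rng.uniform(*spec.head_semiaxes_range)
            ecc = rng.uniform(*spec.eccentricity_range)
            b = max(a * np.sqrt(1.0 - ecc**2), 1.2)
            theta = rng.uniform(0.0, np.pi)
            margin = int(np.ceil(a)) + 3  # box + 2-px margin must stay inside
            if 2 * margin >= min(rows, cols):
                continue
            cy = rng.uniform(margin, rows - 1 - margin)
            cx = rng.uniform(margin, cols - 1 - margin)
            rr, cc = draw_ellipse(cy, cx, b, a, shape=(rows, cols), rotation=theta)
            if rr.size == 0:
                continue
            if not spec.overlap_allowed and occupancy[rr, cc].any():
                continue
            placed = True
            break
        if not placed:
            raise PlacementError(
                "cannot place heads without overlap; relax count_range, "
                "head_semiaxes_range, or overlap_allowed"
            )
        shade = rng.uniform(-0.08, 0.08, size=3)
        img[rr, cc] = np.clip(_HEAD_COLOR + shade, 0, 1)
        occupancy[rr, cc] = True
        centers.append((float(cx), float(cy)))
        pixsets.append((rr, cc))

    # quantize so PNG round-trips are lossless
    img = (np.round(img * 255).astype(np.uint8) / 255.0).astype(np.float64)

    exemplar_idx = rng.choice(count, size=spec.n_exemplars, replace=False)
    boxes, masks = [], []
    for i in exemplar_idx:
        rr, cc = pixsets[i]
        x0, x1 = int(cc.min()) - 2, int(cc.max()) + 3   # tight + 2-px margin
        y0, y1 = int(rr.min()) - 2, int(rr.max()) + 3
        x0, y0 = max(x0, 0), max(y0, 0)
        x1, y1 = min(x1, cols), min(y1, rows)
        mask = np.zeros((rows, cols), dtype=np.uint8)
        mask[rr, cc] = 1
        keep = np.zeros_like(mask)
        keep[y0:y1, x0:x1] = mask[y0:y1, x0:x1]
        boxes.append([x0, y0, x1, y1])
        masks.append(keep)

    return AnnotatedField(image=img, points=centers, boxes=boxes,
                          masks=masks, count=count)


def write_dataset(fields: list[AnnotatedField], directory) -> Path:
    """Write fields to ``directory`` (PNG/CSV/mask-PNG) plus a JSON manifest.

    Returns the manifest path.  The manifest schema is the one the pipeline
    readers consume: ``{"records": [{"image", "points", "boxes", "masks"}],
    "split": str}``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    records = []
    for i, f in enumerate(fields):
        stem = f"field_{i:04d}"
        img_path = directory / f"{stem}.png"
        Image.fromarray(np.round(f.image * 255).astype(np.uint8)).save(img_path)
        pts_path = directory / f"{stem}_points.csv"
        pd.DataFrame(f.points, columns=["x", "y"]).to_csv(
            pts_path, index=False, float_format="%.17g")
        mask_paths = []
        for j, m in enumerate(f.masks):
            mp = directory / f"{stem}_mask{j}.png"
            Image.fromarray((m * 255).astype(np.uint8)).save(mp)
            mask_paths.append(mp.name)
        records.append({
            "image": img_path.name,
            "points": pts_path.name,
            "boxes": [list(map(int, b)) for b in f.boxes],
            "masks": mask_paths,
        })
    manifest = directory / "manifest.json"
    manifest.write_text(json.dumps({"records": records, "split": "synthetic"},
                                   indent=1))
    return manifest
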