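"""Density decoding, ground-truth density construction, and the training loss.

The decoder is a light regression head: three (3x3 convolution, ReLU) blocks
with channel plan C -> C/2 -> C/4 -> 1 and 2x bilinear upsampling after the
first two blocks, so a stride-4 feature grid returns to image resolution.
The output nonlinearity is a softplus: nonnegative everywhere (the map's sum
is the count) but without a zero-gradient region, which matters because
density targets are zero almost everywhere.

Ground-truth density maps place one discrete Gaussian kernel per annotated
head centre.  The kernel width adapts to local crowding: sigma_i = beta
times the mean distance of point i to its 3 nearest neighbours (beta = 0.3,
clamped to [1, 15] px), falling back to 4 px when fewer than 4 points exist.
Kernels are truncated at 4 sigma and renormalized to unit mass, so the map
sums to the count exactly, border points included.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import tifffile
from scipy.spatial import cKDTree

from ._autograd import Parameter, Tensor, as_tensor, conv2d, upsample_bilinear
from .encoding import FeatureGrid

__all__ = [
    "DensityMap",
    "DecoderParams",
    "init_decoder_params",
    "decode",
    "gt_density",
    "mse_loss",
    "write_density",
]


@dataclasses.dataclass
class DensityMap:
    values: np.ndarray  # (rows, cols), nonnegative

    def __post_init__(self):
        if not np.all(np.isfinite(self.values)):
            raise ValueError("density values must be finite")
        if self.values.min() < 0:
            raise ValueError("density values must be nonnegative")

    @property
    def count(self) -> float:
        return float(self.values.sum())


@dataclasses.dataclass
class DecoderParams:
    blocks: list  # three dicts of {"w": (Cout,Cin,3,3), "b": (Cout,)}

    def named_parameters(self, prefix="decoder"):
        out = {}
        for i, blk in enumerate(self.blocks):
            out[f"{prefix}.{i}.w"] = blk["w"]
            out[f"{prefix}.{i}.b"] = blk["b"]
        return out


#: initial bias of the output layer.  The output nonlinearity is a softplus
#: (nonnegative like a ReLU but with no zero-gradient region, so the output
#: path cannot die when most density targets are zero); biasing it negative
#: starts the predicted mass near a typical object count rather than
#: proportional to the image area, the usual prior-style bias initialization
#: for sparse targets.
OUTPUT_BIAS_INIT = -6.0


def init_decoder_params(c: int, rng: np.random.Generator) -> DecoderParams:
    plan = [(c, max(c // 2, 1)), (max(c // 2, 1), max(c // 4, 1)),
            (max(c // 4, 1), 1)]
    blocks = []
    for i, (cin, cout) in enumerate(plan):
        std = np.sqrt(2.0 / (cin * 9))
        bias = np.full(cout, OUTPUT_BIAS_INIT) if i == len(plan) - 1 else np.zeros(cout)
        blocks.append({
            "w": Parameter(rng.normal(0, std, size=(cout, cin, 3, 3))),
            "b": Parameter(bias),
        })
    return DecoderParams(blocks=blocks)


def decode_t(fp: Tensor, params: DecoderParams) -> Tensor:
    x = conv2d(fp, params.blocks[0]["w"], params.blocks[0]["b"]).relu()
    x = upsample_bilinear(x, 2)
    x = conv2d(x, params.blocks[1]["w"], params.blocks[1]["b"]).relu()
    x = upsample_bilinear(x, 2)
    x = conv2d(x, params.blocks[2]["w"], params.blocks[2]["b"]).softplus()
    return x.reshape(x.shape[1], x.shape[2])


def decode(fp: FeatureGrid, params: DecoderParams) -> DensityMap:
    """Decode enhanced stride-4 features to an image-resolution density map."""
    return DensityMap(values=decode_t(as_tensor(fp.values), params).data)


def _adaptive_sigmas(points: np.ndarray, beta: float, k: int,
                     clamp: tuple[float, float], fallback: float) -> np.ndarray:
    n = len(points)
    if n < k + 1:
        return np.full(n, fallback)
    tree = cKDTree(points)
    dists, _ = tree.query(points, k=k + 1)  # first neighbour is the point itself
    sig = beta * dists[:, 1:].mean(axis=1)
    return np.clip(sig, clamp[0], clamp[1])


def gt_density(points, image_size, beta: float = 0.3, k_neighbors: int = 3,
               sigma_clamp: tuple[float, float] = (1.0, 15.0),
               sigma_fallback: float = 4.0) -> DensityMap:
    """Adaptive-window Gaussian ground truth from head-centre annotations."""
    rows, cols = image_size
    pts = np.asarray(list(points), dtype=np.float64).reshape(-1, 2)
    for x, y in pts:
        if not (0 <= x < cols and 0 <= y < rows):
            raise ValueError(f"point ({x}, {y}) outside {rows}x{cols} image")
    dm = np.zeros((rows, cols))
    if len(pts) == 0:
        return DensityMap(values=dm)
    sigmas = _adaptive_sigmas(pts, beta, k_neighbors, sigma_clamp, sigma_fallback)
    for (x, y), sig in zip(pts, sigmas):
        cx, cy = int(round(x)), int(round(y))
        cx, cy = min(cx, cols - 1), min(cy, rows - 1)
        rad = int(np.ceil(4 * sig))
        r0, r1 = max(cy - rad, 0), min(cy + rad + 1, rows)
        c0, c1 = max(cx - rad, 0), min(cx + rad + 1, cols)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        ker = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sig**2))
        dm[r0:r1, c0:c1] += ker / ker.sum()  # unit mass even when truncated
    return DensityMap(values=dm)


def mse_loss_t(pred: list[Tensor], target: list[np.ndarray]) -> Tensor:
    m = len(pred)
    if m == 0 or m != len(target):
        raise ValueError("mse_loss needs equal, nonzero batch sizes")
    total = None
    for d, g in zip(pred, target):
        if d.shape != np.shape(g):
            raise ValueError(f"shape mismatch: {d.shape} vs {np.shape(g)}")
        diff = d - as_tensor(g)
        sq = (diff * diff).sum()
        total = sq if total is None else total + sq
    return total * (1.0 / m)


def mse_loss(pred, target) -> float:
    """Batch MSE of density supervision: (1/M) * sum ||D - DGT||^2."""
    def arr(d):
        return d.values if isinstance(d, DensityMap) else np.asarray(d)

    pred = [pred] if isinstance(pred, (DensityMap, np.ndarray)) else list(pred)
    target = [target] if isinstance(target, (DensityMap, np.ndarray)) else list(target)
    return float(mse_loss_t([as_tensor(arr(p)) for p in pred],
                            [arr(t) for t in target]).data)


def write_density(dm: DensityMap, path) -> None:
    """32-bit float TIFF plus a JSON side-car with the count."""
    tifffile.imwrite(path, dm.values.astype(np.float32))
    sidecar = str(path) + ".json"
    with open(sidecar, "w") as fh:
        json.dump({"count": dm.count, "shape": list(dm.values.shape),
                   "format": "headcount-density-v1"}, fh)
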