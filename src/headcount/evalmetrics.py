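"""Counting metrics: MAE, RMSE, counting accuracy, and R^2 agreement.

Counting accuracy is 100 * (1 - mean relative counting error); it is not
clamped and can be negative for severe over- or under-counts.  Images with a
zero ground-truth count are rejected explicitly (the relative error is
undefined for them), never skipped silently.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd

__all__ = ["mae", "rmse", "counting_accuracy", "r_squared", "CountReport"]


def _paired(c, cgt):
    c = np.asarray(c, dtype=np.float64)
    g = np.asarray(cgt, dtype=np.float64)
    if c.shape != g.shape or c.ndim != 1 or c.size == 0:
        raise ValueError(
            f"need equal-length nonempty 1-D count lists, got {c.shape} vs {g.shape}"
        )
    return c, g


def mae(c, cgt) -> float:
    c, g = _paired(c, cgt)
    return float(np.abs(c - g).mean())


def rmse(c, cgt) -> float:
    c, g = _paired(c, cgt)
    return float(np.sqrt(((c - g) ** 2).mean()))


def counting_accuracy(c, cgt) -> float:
    c, g = _paired(c, cgt)
    zero = np.nonzero(g == 0)[0]
    if zero.size:
        raise ZeroDivisionError(
            f"counting accuracy undefined for zero ground-truth counts at "
            f"indices {zero.tolist()}"
        )
    return float((1.0 - (np.abs(c - g) / g).mean()) * 100.0)


def r_squared(c, cgt) -> float:
    c, g = _paired(c, cgt)
    if c.size < 2:
        raise ValueError("r_squared needs at least 2 pairs")
    ss_tot = float(((g - g.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("r_squared undefined for constant ground truth")
    ss_res = float(((g - c) ** 2).sum())
    return 1.0 - ss_res / ss_tot


@dataclasses.dataclass
class CountReport:
    predicted: list[float]
    ground_truth: list[float]
    mae: float
    rmse: float
    counting_accuracy: float
    r_squared: float
    m_eval: int

    @classmethod
    def from_counts(cls, predicted, ground_truth) -> "CountReport":
        return cls(
            predicted=[float(v) for v in predicted],
            ground_truth=[float(v) for v in ground_truth],
            mae=mae(predicted, ground_truth),
            rmse=rmse(predicted, ground_truth),
            counting_accuracy=counting_accuracy(predicted, ground_truth),
            r_squared=r_squared(predicted, ground_truth),
            m_eval=len(list(predicted)),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    def to_csv(self, path) -> None:
        pd.DataFrame({"predicted": self.predicted,
                      "ground_truth": self.ground_truth}).to_csv(path, index=False)
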