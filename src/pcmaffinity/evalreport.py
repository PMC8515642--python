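"""Evaluation metrics, |d| distribution and importance-ranking reports.

The five regression metrics are computed exactly as printed in standard
QSAR reporting: SSE, MSE, RMSE, MAE and the coefficient of determination
R^2 = 1 - SSE / sum((y - mean(y))^2).  The |d| histogram summarises
absolute prediction errors on the log2-affinity scale in half-open 0.5-wide
bins with an open-ended fifth bin at |d| >= 2, plus the percentage of
predictions within 2 log2 units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from pcmaffinity.boruta_select import SelectionResult

HISTOGRAM_EDGES = (0.0, 0.5, 1.0, 1.5, 2.0)


@dataclass(frozen=True)
class MetricsBundle:
    sse: float
    mse: float
    rmse: float
    mae: float
    r2: float  # nan when the actual values have zero variance
    n: int

    def as_dict(self) -> dict[str, float]:
        return {"SSE": self.sse, "MSE": self.mse, "RMSE": self.rmse,
                "MAE": self.mae, "R2": self.r2, "n": self.n}


def metrics(actual, predicted) -> MetricsBundle:
    """The five printed error formulas on a pair of equal-length vectors."""
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape or a.ndim != 1:
        raise ValueError("actual and predicted must be equal-length vectors")
    if len(a) < 2:
        raise ValueError("need at least 2 samples")
    if not (np.isfinite(a).all() and np.isfinite(p).all()):
        raise ValueError("metrics require finite inputs")
    d = a - p
    sse = float(np.sum(d**2))
    mse = sse / len(a)
    sst = float(np.sum((a - a.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else math.nan
    return MetricsBundle(
        sse=sse, mse=mse, rmse=math.sqrt(mse), mae=float(np.mean(np.abs(d))),
        r2=r2, n=len(a),
    )


@dataclass(frozen=True)
class AbsDiffHistogram:
    counts: tuple[int, ...]      # 5 bins: [0,.5) [.5,1) [1,1.5) [1.5,2) [2,inf)
    n: int
    within_2_percent: float

    def as_frame(self) -> pd.DataFrame:
        labels = ["[0,0.5)", "[0.5,1)", "[1,1.5)", "[1.5,2)", "[2,inf)"]
        return pd.DataFrame({"bin": labels, "count": self.counts})


def abs_diff_histogram(actual, predicted) -> AbsDiffHistogram:
    """Bin |actual - predicted| at 0.5 steps; report the within-2.0 percent."""
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape:
        raise ValueError("actual and predicted must have the same length")
    d = np.abs(a - p)
    counts = np.histogram(d, bins=list(HISTOGRAM_EDGES) + [np.inf])[0]
    within = float(np.mean(d < 2.0) * 100.0) if len(d) else 0.0
    return AbsDiffHistogram(counts=tuple(int(c) for c in counts), n=len(d),
                            within_2_percent=within)


def importance_report(
    result: SelectionResult,
    origins: dict[str, str],
    cutoff: float = 0.85,
) -> dict[str, pd.DataFrame]:
    """Descending importance tables split by origin, scores above ``cutoff``.

    Ties break lexicographically by descriptor name for determinism.
    Returns ``{"mol": ..., "prot": ...}`` tables with feature and score.
    """
    frame = result.to_frame(origins)
    frame = frame[frame["score"] > cutoff]
    frame = frame.sort_values(["score", "feature"], ascending=[False, True],
                              kind="mergesort")
    out = {}
    for origin in ("mol", "prot"):
        sub = frame[frame["origin"] == origin][["feature", "score"]]
        out[origin] = sub.reset_index(drop=True)
    return out


def export_scatter(actual, predicted, path) -> None:
    """Two-column CSV (actual, predicted) for external plotting."""
    pd.DataFrame({"actual": np.asarray(actual, float),
                  "predicted": np.asarray(predicted, float)}).to_csv(path, index=False)
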