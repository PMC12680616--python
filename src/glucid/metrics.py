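"""Fit-quality metrics for the identification experiments."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["EvaluationResult", "rmse", "fit_percent", "evaluate", "write_results_table"]


@dataclass(frozen=True)
class EvaluationResult:
    """RMSE and FIT% of one model on one partition."""

    rmse: float
    fit_percent: float
    n: int
    partition: str


def _aligned(observed: Sequence[float], predicted: Sequence[float]):
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError("observed and predicted must be 1-D series of equal length")
    if len(y) < 1:
        raise ValueError("series must be non-empty")
    return y, yhat


def rmse(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Root mean square error sqrt(mean((y - yhat)^2))."""
    y, yhat = _aligned(observed, predicted)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def fit_percent(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Normalized fit (1 - ||y - yhat|| / ||y - mean(y)||) * 100.

    100 means perfect prediction; 0 means no better than the series mean.
    Both norms are Euclidean over the evaluated partition.  Undefined for a
    constant observed series (zero denominator).
    """
    y, yhat = _aligned(observed, predicted)
    denom = float(np.linalg.norm(y - y.mean()))
    if denom == 0.0:
        raise ValueError("fit_percent is undefined for a constant observed series")
    return float((1.0 - np.linalg.norm(y - yhat) / denom) * 100.0)


def evaluate(
    observed: Sequence[float], predicted: Sequence[float], partition: str
) -> EvaluationResult:
    y, yhat = _aligned(observed, predicted)
    return EvaluationResult(
        rmse=rmse(y, yhat),
        fit_percent=fit_percent(y, yhat),
        n=len(y),
        partition=partition,
    )


def write_results_table(rows: Iterable[dict], path: str | Path) -> pd.DataFrame:
    """Write `model,case,partition,rmse,fit_percent` rows as CSV."""
    frame = pd.DataFrame(list(rows), columns=["model", "case", "partition", "rmse", "fit_percent"])
    frame.to_csv(path, index=False)
    return frame
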