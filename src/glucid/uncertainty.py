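"""Quantile-regression prediction intervals with PICP / MPI summaries.

Point predictions of the identifier carry residual uncertainty.  A linear
quantile regression of the observed output on the predicted output,

    y = a_tau * yhat + b_tau,

fitted at tau = 0.05 and tau = 0.95 by minimizing the pinball (check) loss
sum_k rho_tau(y_k - a yhat_k - b), brackets the one-step prediction with a
nominal 90% band.  Two summaries grade the band: PICP, the fraction of
observations strictly inside it, and MPI, its average width.  A well
calibrated band has PICP near the nominal coverage; a sharp one has small
MPI.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "QuantileFit",
    "PredictionInterval",
    "quantile_fit",
    "interval",
    "picp",
    "mpi",
    "uncertainty_summary",
    "write_interval",
]


@dataclass(frozen=True)
class QuantileFit:
    """Linear conditional-quantile line y = slope * yhat + intercept."""

    tau: float
    slope: float
    intercept: float

    def __call__(self, predicted: Sequence[float]) -> np.ndarray:
        return self.slope * np.asarray(predicted, dtype=float) + self.intercept


@dataclass(frozen=True)
class PredictionInterval:
    """Elementwise lower/upper band around a predicted series."""

    lower: np.ndarray
    upper: np.ndarray
    confidence: float = 0.90

    def __post_init__(self) -> None:
        if self.lower.shape != self.upper.shape:
            raise ValueError("lower/upper must be aligned")
        if np.any(self.upper < self.lower):
            raise ValueError("upper must be >= lower elementwise")

    def widen(self, delta: float) -> "PredictionInterval":
        return PredictionInterval(self.lower - delta, self.upper + delta, self.confidence)

    def __len__(self) -> int:
        return len(self.lower)


def quantile_fit(
    predicted: Sequence[float], observed: Sequence[float], tau: float
) -> QuantileFit:
    """Fit the tau-quantile line of observed given predicted (pinball loss).

    A constant predictor makes the slope unidentifiable; in that degenerate
    case a rank warning is issued and an intercept-only fit (the empirical
    tau-quantile of the observations) is returned.
    """
    yhat = np.asarray(predicted, dtype=float)
    y = np.asarray(observed, dtype=float)
    if yhat.shape != y.shape or y.ndim != 1 or len(y) < 3:
        raise ValueError("need aligned 1-D series of length >= 3")
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must lie in (0, 1)")
    if np.ptp(yhat) == 0.0:
        warnings.warn(
            "constant predictor: slope unidentifiable, intercept-only quantile fit",
            RuntimeWarning,
            stacklevel=2,
        )
        return QuantileFit(tau=tau, slope=0.0,
                           intercept=float(np.quantile(y, tau)))
    exog = sm.add_constant(yhat)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # IterationLimitWarning on flat data
        res = sm.QuantReg(y, exog).fit(q=tau)
    intercept, slope = res.params
    return QuantileFit(tau=tau, slope=float(slope), intercept=float(intercept))


def interval(
    fit05: QuantileFit, fit95: QuantileFit, predicted: Sequence[float]
) -> PredictionInterval:
    """Evaluate the low/high quantile lines; reorder any crossing pairs."""
    lo = fit05(predicted)
    hi = fit95(predicted)
    lower = np.minimum(lo, hi)
    upper = np.maximum(lo, hi)
    return PredictionInterval(
        lower=lower, upper=upper, confidence=fit95.tau - fit05.tau
    )


def picp(observed: Sequence[float], band: PredictionInterval) -> float:
    """Prediction-interval coverage probability (strict inclusion, mean over k)."""
    y = np.asarray(observed, dtype=float)
    if y.shape != band.lower.shape:
        raise ValueError("observed series must align with the interval")
    inside = (band.lower < y) & (y < band.upper)
    return float(inside.mean())


def mpi(band: PredictionInterval) -> float:
    """Mean prediction-interval width."""
    return float(np.mean(band.upper - band.lower))


def uncertainty_summary(
    predicted_train: Sequence[float],
    observed_train: Sequence[float],
    predicted_test: Sequence[float],
    observed_test: Sequence[float],
    tau_low: float = 0.05,
    tau_high: float = 0.95,
    refit_per_partition: bool = False,
) -> dict:
    """Fit the quantile band and summarize PICP/MPI on both partitions.

    The band is fitted on the training partition and applied to both (the
    default); ``refit_per_partition`` refits the quantile lines on the test
    partition instead of reusing the training fit.
    """
    fit_lo = quantile_fit(predicted_train, observed_train, tau_low)
    fit_hi = quantile_fit(predicted_train, observed_train, tau_high)
    band_train = interval(fit_lo, fit_hi, predicted_train)
    if refit_per_partition:
        fit_lo_t = quantile_fit(predicted_test, observed_test, tau_low)
        fit_hi_t = quantile_fit(predicted_test, observed_test, tau_high)
        band_test = interval(fit_lo_t, fit_hi_t, predicted_test)
    else:
        band_test = interval(fit_lo, fit_hi, predicted_test)
    return {
        "picp_train": picp(observed_train, band_train),
        "mpi_train": mpi(band_train),
        "picp_test": picp(observed_test, band_test),
        "mpi_test": mpi(band_test),
    }


def write_interval(
    predicted: Sequence[float],
    observed: Sequence[float],
    band: PredictionInterval,
    path: str | Path,
    summary_path: str | Path | None = None,
) -> None:
    """Write the per-sample band as CSV (and optionally a PICP/MPI JSON)."""
    y = np.asarray(observed, dtype=float)
    frame = pd.DataFrame(
        {
            "k": np.arange(len(y)),
            "predicted": np.asarray(predicted, dtype=float),
            "observed": y,
            "lower": band.lower,
            "upper": band.upper,
            "inside": ((band.lower < y) & (y < band.upper)).astype(int),
        }
    )
    frame.to_csv(path, index=False)
    if summary_path is not None:
        Path(summary_path).write_text(
            json.dumps({"picp": picp(y, band), "mpi": mpi(band)}, indent=2)
        )
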