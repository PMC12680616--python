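"""End-to-end disorder-case experiments: train, evaluate, quantify uncertainty.

Five identifier variants are compared on each disorder scenario, all under
the same preset hyperparameters (fractional order and per-layer learning
rates):

========  ============================  ======  =========================
name      architecture                  alpha   learning rates (i, h, o)
========  ============================  ======  =========================
drnn-gd   diagonal recurrent, GD        --      0.1, 0.21, 0.1
drnn-fo   diagonal recurrent, FO        0.3999  0.77, 0.55, 0.97
dfnn      feedforward sigmoid, GD       --      0.01, 0.01, 0.01
frnn-gd   fully recurrent, GD           --      0.1, 0.05, 0.95
frnn-fo   fully recurrent, FO           0.3109  0.05, 0.05, 0.9
========  ============================  ======  =========================

A case run builds the 4000-sample scenario dataset (70/30 train/test),
trains online on the training partition, evaluates RMSE and FIT% on both
partitions, and fits the 5-95% quantile-regression band on the training
residual structure.  ``multi_run_stats`` repeats a run over independent
seeds and reports best / worst / standard deviation per metric.
"""

from __future__ import annotations

import dataclasses
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import glucose_ode, metrics, uncertainty
from .estimators import DFNNRegressor, DRNNRegressor, FRNNRegressor
from .fo_learning import TrainingConfig
from .glucose_ode import DEFAULT_DT, DEFAULT_X0, RegressionDataset

__all__ = [
    "MODEL_PRESETS",
    "CaseResult",
    "MultiRunSummary",
    "make_estimator",
    "run_case",
    "run_comparison",
    "multi_run_stats",
    "reproduce_all",
]

#: Online passes over the training partition used by the headline case
#: runs: the per-epoch training-RMSE traces of the gradient-descent models
#: flatten out by roughly this many passes at the preset rates.
DEFAULT_EPOCHS = 30

#: Preset hyperparameters per identifier variant.
MODEL_PRESETS: dict[str, dict] = {
    "drnn-gd": dict(cls=DRNNRegressor, algorithm="gd",
                    eta_input=0.1, eta_hidden=0.21, eta_output=0.1),
    "drnn-fo": dict(cls=DRNNRegressor, algorithm="fo", alpha=0.3999,
                    eta_input=0.77, eta_hidden=0.55, eta_output=0.97),
    "dfnn": dict(cls=DFNNRegressor,
                 eta_input=0.01, eta_hidden=0.01, eta_output=0.01),
    "frnn-gd": dict(cls=FRNNRegressor, algorithm="gd",
                    eta_input=0.1, eta_hidden=0.05, eta_output=0.95),
    "frnn-fo": dict(cls=FRNNRegressor, algorithm="fo", alpha=0.3109,
                    eta_input=0.05, eta_hidden=0.05, eta_output=0.9),
}


@dataclass
class CaseResult:
    """One (case, model, seed) run: metrics and uncertainty per partition."""

    case: str
    model: str
    seed: int
    train: metrics.EvaluationResult
    test: metrics.EvaluationResult
    uncertainty: dict
    config: dict = field(default_factory=dict)
    error: str | None = None  # set when training diverged (metrics are inf)

    def rows(self) -> list[dict]:
        return [
            {
                "model": self.model,
                "case": self.case,
                "partition": part.partition,
                "rmse": part.rmse,
                "fit_percent": part.fit_percent,
            }
            for part in (self.train, self.test)
        ]


@dataclass(frozen=True)
class MultiRunSummary:
    """Best / worst / std of each metric over independent seeded runs."""

    case: str
    model: str
    n_runs: int
    stats: dict  # metric name -> {"best": .., "worst": .., "std": ..}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"case": self.case, "model": self.model, "metric": name, **vals}
            for name, vals in self.stats.items()
        ]
        return pd.DataFrame(rows)


def make_estimator(model: str, cfg: TrainingConfig | None = None, seed: int = 0):
    """Build the preset estimator for a model name, optionally overridden.

    ``cfg`` overrides epochs, memory length, rate mode and — for explicit
    non-default values — the fractional order and learning rates.
    """
    if model not in MODEL_PRESETS:
        raise KeyError(f"unknown model {model!r}; choose from {sorted(MODEL_PRESETS)}")
    preset = dict(MODEL_PRESETS[model])
    cls = preset.pop("cls")
    kwargs = dict(preset)
    kwargs.setdefault("epochs", DEFAULT_EPOCHS)
    if cfg is not None:
        kwargs["epochs"] = cfg.epochs  # an explicit config owns the pass count
        defaults = TrainingConfig()
        for name in ("eta_input", "eta_hidden", "eta_output", "alpha", "h",
                     "memory_length", "rate_mode", "eta_cap"):
            value = getattr(cfg, name)
            if value != getattr(defaults, name):
                kwargs[name] = value
    if cls is DFNNRegressor:
        for name in ("algorithm", "alpha", "h", "memory_length"):
            kwargs.pop(name, None)
    return cls(random_state=seed, **kwargs)


def _evaluate_case(
    dataset: RegressionDataset, estimator, case: str, model: str, seed: int
) -> CaseResult:
    estimator.fit(dataset.X_train, dataset.y_train)
    pred_train = estimator.predict(dataset.X_train)
    pred_test = estimator.predict(dataset.X_test)
    uq = uncertainty.uncertainty_summary(
        pred_train, dataset.y_train, pred_test, dataset.y_test
    )
    return CaseResult(
        case=case,
        model=model,
        seed=seed,
        train=metrics.evaluate(dataset.y_train, pred_train, "train"),
        test=metrics.evaluate(dataset.y_test, pred_test, "test"),
        uncertainty=uq,
        config=estimator.get_params(),
    )


def _diverged_result(case: str, model: str, seed: int, exc: Exception) -> CaseResult:
    """Record an unstable run: infinite RMSE, so it sorts strictly worst."""
    inf, ninf = float("inf"), float("-inf")
    return CaseResult(
        case=case,
        model=model,
        seed=seed,
        train=metrics.EvaluationResult(inf, ninf, 0, "train"),
        test=metrics.EvaluationResult(inf, ninf, 0, "test"),
        uncertainty={},
        error=str(exc),
    )


def run_case(
    case: str | glucose_ode.DisorderScenario,
    model: str,
    cfg: TrainingConfig | None = None,
    seed: int = 0,
    dt: float = DEFAULT_DT,
    samples_per_value: int | None = None,
    x0: Sequence[float] = DEFAULT_X0,
) -> CaseResult:
    """Train and evaluate one model on one disorder case."""
    scenario = (
        case
        if isinstance(case, glucose_ode.DisorderScenario)
        else glucose_ode.scenario(case, samples_per_value)
    )
    dataset = glucose_ode.build_dataset(scenario, x0=x0, dt=dt, seed=seed)
    estimator = make_estimator(model, cfg, seed)
    return _evaluate_case(dataset, estimator, scenario.name, model, seed)


def run_comparison(
    case: str,
    models: Sequence[str] = tuple(MODEL_PRESETS),
    cfg: TrainingConfig | None = None,
    seed: int = 0,
    dt: float = DEFAULT_DT,
    samples_per_value: int | None = None,
) -> list[CaseResult]:
    """Run several models on the same dataset (shared simulation)."""
    from .fo_learning import TrainingInstabilityError

    scenario = glucose_ode.scenario(case, samples_per_value)
    dataset = glucose_ode.build_dataset(scenario, dt=dt, seed=seed)
    results = []
    for m in models:
        try:
            results.append(
                _evaluate_case(dataset, make_estimator(m, cfg, seed),
                               scenario.name, m, seed)
            )
        except TrainingInstabilityError as exc:
            results.append(_diverged_result(scenario.name, m, seed, exc))
    return results


def multi_run_stats(
    case: str,
    model: str,
    cfg: TrainingConfig | None = None,
    n_runs: int = 10,
    base_seed: int = 0,
    dt: float = DEFAULT_DT,
    samples_per_value: int | None = None,
) -> MultiRunSummary:
    """Best / worst / std of RMSE and FIT% over independent seeds.

    The dataset is deterministic; the seeds vary the weight initialization,
    mirroring a repeated-runs protocol.
    """
    from .fo_learning import TrainingInstabilityError

    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    records = []
    for i in range(n_runs):
        try:
            res = run_case(case, model, cfg, seed=base_seed + i, dt=dt,
                           samples_per_value=samples_per_value)
        except TrainingInstabilityError as exc:
            res = _diverged_result(case, model, base_seed + i, exc)
        records.append(
            {
                "rmse_train": res.train.rmse,
                "rmse_test": res.test.rmse,
                "fit_train": res.train.fit_percent,
                "fit_test": res.test.fit_percent,
            }
        )
    frame = pd.DataFrame(records)
    stats = {}
    for name in frame.columns:
        values = frame[name].to_numpy()
        best, worst = (
            (values.min(), values.max())
            if name.startswith("rmse")
            else (values.max(), values.min())
        )
        stats[name] = {
            "best": float(best),
            "worst": float(worst),
            "std": float(values.std(ddof=0)),
        }
    return MultiRunSummary(case=case, model=model, n_runs=n_runs, stats=stats)


def reproduce_all(
    out_dir: str | Path,
    cfg: TrainingConfig | None = None,
    seed: int = 0,
    dt: float = DEFAULT_DT,
    samples_per_value: int | None = None,
    cases: Sequence[str] = tuple(glucose_ode.SCENARIOS),
    models: Sequence[str] = tuple(MODEL_PRESETS),
    log=None,
) -> pd.DataFrame:
    """Run the full five-model / four-case comparison and write result CSVs.

    Writes one metrics CSV and one uncertainty CSV per case (filenames embed
    case, model and seed for audit) plus a combined `results.csv`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    all_rows, uq_rows = [], []
    for case in cases:
        t0 = time.perf_counter()
        results = run_comparison(case, models, cfg, seed, dt, samples_per_value)
        for res in results:
            all_rows.extend(res.rows())
            uq_rows.append({"case": case, "model": res.model, "seed": seed,
                            **res.uncertainty})
        case_frame = pd.DataFrame(
            [row for res in results for row in res.rows()]
        )
        case_frame.to_csv(out_dir / f"metrics_{case}_seed{seed}.csv", index=False)
        if log is not None:
            log(f"[{case}] {len(models)} models in "
                f"{time.perf_counter() - t0:.1f}s")
    frame = pd.DataFrame(all_rows)
    frame.to_csv(out_dir / "results.csv", index=False)
    pd.DataFrame(uq_rows).to_csv(out_dir / f"uncertainty_seed{seed}.csv", index=False)
    return frame
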