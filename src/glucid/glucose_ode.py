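"""Chaotic insulin-glucose regulatory dynamics and supervised dataset construction.

The regulatory system couples three dimensionless state variables — insulin
concentration ``x1``, glucose concentration ``x2`` and pancreatic beta-cell
concentration ``x3`` — through a polynomial vector field with 21 rate
constants ``w1..w21``:

.. math::

    \\dot x_1 &= -w_1 x_1 + w_2 x_1 x_2 + w_3 x_2^2 + w_4 x_2^3
                + w_5 x_3 + w_6 x_3^2 + w_7 x_3^3 + w_{20} \\\\
    \\dot x_2 &= -w_8 x_1 x_2 - w_9 x_1^2 - w_{10} x_1^3
                + w_{11} x_2 (1 - x_2) - w_{12} x_3 - w_{13} x_3^2
                - w_{14} x_3^3 + w_{21} \\\\
    \\dot x_3 &= w_{15} x_2 + w_{16} x_2^2 + w_{17} x_2^3
                - w_{18} x_3 - w_{19} x_2 x_3

Under the nominal rate constants the system is chaotic; shifting a single
parameter emulates four diabetes-related disorders (type-2 diabetes via
``w8``, hypoglycemia via ``w1``, hyperinsulinemia via ``w7``, type-1 diabetes
via ``w15``).  Trajectories are integrated with fixed-step RK4 and turned
into one-step-ahead regression problems: six lagged state inputs
``[x1(k), x1(k-1), x2(k), x2(k-1), x3(k), x3(k-1)]`` predicting the next
glucose value ``x2(k+1)``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ModelParameters",
    "Trajectory",
    "DisorderScenario",
    "RegressionDataset",
    "IntegrationError",
    "DEFAULT_X0",
    "DEFAULT_DT",
    "SCENARIOS",
    "scenario",
    "derivatives",
    "integrate",
    "make_supervised",
    "build_dataset",
    "save_dataset",
    "load_dataset",
]

#: Initial state used throughout: (insulin, glucose, beta-cells).
DEFAULT_X0 = (0.53, 1.31, 1.03)

#: Default sampling step of the simulator, in the model's dimensionless
#: time units.  The discretization step is a free choice of this package;
#: 0.005 keeps every disorder segment (1002 steps, 5.01 time units) well
#: inside the bounded window of the vector field — the hypoglycemia w1=1.3
#: and type-1 w15<=0.16 systems genuinely escape to infinity in finite time
#: (t ~ 10.6 at the earliest) from the standard initial state.
DEFAULT_DT = 0.005

#: Default per-parameter-value sample count (4 values x 1000 = 4000 rows).
DEFAULT_SAMPLES_PER_VALUE = 1000

TRAIN_FRACTION = 0.70

_NOMINAL = {
    "w1": 2.04, "w2": 0.1, "w3": 1.09, "w4": -1.08, "w5": 0.03,
    "w6": -0.06, "w7": 2.01, "w8": 0.22, "w9": -3.84, "w10": -1.2,
    "w11": 0.3, "w12": 1.37, "w13": -0.3, "w14": 0.22, "w15": 0.3,
    "w16": -1.35, "w17": 0.5, "w18": -0.42, "w19": -0.15, "w20": -0.19,
    "w21": -0.56,
}


class IntegrationError(RuntimeError):
    """Raised when the simulated trajectory blows up or turns non-finite."""


@dataclass(frozen=True)
class ModelParameters:
    """The 21 dimensionless rate constants of the regulatory system."""

    w1: float; w2: float; w3: float; w4: float; w5: float; w6: float
    w7: float; w8: float; w9: float; w10: float; w11: float; w12: float
    w13: float; w14: float; w15: float; w16: float; w17: float; w18: float
    w19: float; w20: float; w21: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.as_array())):
            raise ValueError("all rate constants must be finite")

    @classmethod
    def nominal(cls) -> "ModelParameters":
        """Nominal (healthy-regime) rate constants."""
        return cls(**_NOMINAL)

    @classmethod
    def zeros(cls) -> "ModelParameters":
        return cls(**{f"w{i}": 0.0 for i in range(1, 22)})

    def replace(self, **changes: float) -> "ModelParameters":
        """Return a copy with the given rate constants overridden."""
        return dataclasses.replace(self, **changes)

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f"w{i}") for i in range(1, 22)])

    def as_dict(self) -> dict:
        return {f"w{i}": getattr(self, f"w{i}") for i in range(1, 22)}


@dataclass(frozen=True)
class Trajectory:
    """Uniformly sampled state time series.

    ``states`` has shape ``(n, 3)`` with columns (x1, x2, x3); ``times`` is
    strictly increasing with constant spacing.
    """

    times: np.ndarray
    states: np.ndarray

    def __post_init__(self) -> None:
        if len(self.times) != len(self.states) or len(self.times) < 2:
            raise ValueError("trajectory needs >= 2 aligned samples")
        steps = np.diff(self.times)
        if not (np.all(steps > 0) and np.allclose(steps, steps[0])):
            raise ValueError("times must be strictly increasing and uniform")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class DisorderScenario:
    """A diabetes disorder emulated by sweeping one rate constant.

    Each of the four ``values`` of ``varied_parameter`` defines one segment
    of the dataset, simulated from the same initial state.
    """

    name: str
    varied_parameter: str
    values: tuple
    samples_per_value: int = DEFAULT_SAMPLES_PER_VALUE

    def __post_init__(self) -> None:
        if len(self.values) != 4:
            raise ValueError("a disorder scenario sweeps exactly 4 values")
        if self.samples_per_value < 1:
            raise ValueError("samples_per_value must be >= 1")

    def parameter_sets(self, base: ModelParameters | None = None):
        base = base or ModelParameters.nominal()
        return [base.replace(**{self.varied_parameter: v}) for v in self.values]


#: Disorder presets: which rate constant is shifted, and through which values.
SCENARIOS: dict[str, DisorderScenario] = {
    "type2": DisorderScenario("type2", "w8", (0.5, 0.2, 0.42, 0.3)),
    "hypoglycemia": DisorderScenario("hypoglycemia", "w1", (1.3, 1.7, 1.8, 2.04)),
    "hyperinsulinemia": DisorderScenario("hyperinsulinemia", "w7", (1.9, 2.01, 2.5, 3.1)),
    "type1": DisorderScenario("type1", "w15", (0.16, 0.3, 0.25, 0.13)),
}


def scenario(name: str, samples_per_value: int | None = None) -> DisorderScenario:
    """Look up a disorder preset, optionally overriding the segment length."""
    try:
        preset = SCENARIOS[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}"
        ) from None
    if samples_per_value is not None:
        preset = dataclasses.replace(preset, samples_per_value=samples_per_value)
    return preset


@dataclass
class RegressionDataset:
    """Supervised one-step-ahead samples derived from simulated trajectories.

    ``inputs`` has shape ``(n, 6)`` with the lag layout
    ``[x1(k), x1(k-1), x2(k), x2(k-1), x3(k), x3(k-1)]``; ``targets`` holds
    ``x2(k+1)``.  Rows up to ``split_index`` are the training partition.
    """

    inputs: np.ndarray
    targets: np.ndarray
    split_index: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.inputs = np.asarray(self.inputs, dtype=float)
        self.targets = np.asarray(self.targets, dtype=float)
        if self.inputs.ndim != 2 or self.inputs.shape[1] != 6:
            raise ValueError("inputs must be (n, 6)")
        if len(self.inputs) != len(self.targets):
            raise ValueError("inputs/targets length mismatch")
        if not 0 <= self.split_index <= len(self.targets):
            raise ValueError("split_index out of range")

    def __len__(self) -> int:
        return len(self.targets)

    @property
    def X_train(self) -> np.ndarray:
        return self.inputs[: self.split_index]

    @property
    def y_train(self) -> np.ndarray:
        return self.targets[: self.split_index]

    @property
    def X_test(self) -> np.ndarray:
        return self.inputs[self.split_index:]

    @property
    def y_test(self) -> np.ndarray:
        return self.targets[self.split_index:]

    def to_frame(self) -> pd.DataFrame:
        cols = ["x1_k", "x1_km1", "x2_k", "x2_km1", "x3_k", "x3_km1"]
        frame = pd.DataFrame(self.inputs, columns=cols)
        frame["target"] = self.targets
        frame["partition"] = np.where(
            np.arange(len(self)) < self.split_index, "train", "test"
        )
        return frame


def derivatives(state: Sequence[float], params: ModelParameters) -> np.ndarray:
    """Evaluate the polynomial vector field at ``state``.

    Returns the rate of change ``(dx1, dx2, dx3)``.  Raises
    :class:`IntegrationError` if any component overflows to a non-finite
    value (possible for large states, the field being cubic).
    """
    x1, x2, x3 = np.asarray(state, dtype=float)
    p = params
    d1 = (-p.w1 * x1 + p.w2 * x1 * x2 + p.w3 * x2**2 + p.w4 * x2**3
          + p.w5 * x3 + p.w6 * x3**2 + p.w7 * x3**3 + p.w20)
    d2 = (-p.w8 * x1 * x2 - p.w9 * x1**2 - p.w10 * x1**3
          + p.w11 * x2 * (1.0 - x2) - p.w12 * x3 - p.w13 * x3**2
          - p.w14 * x3**3 + p.w21)
    d3 = (p.w15 * x2 + p.w16 * x2**2 + p.w17 * x2**3
          - p.w18 * x3 - p.w19 * x2 * x3)
    out = np.array([d1, d2, d3])
    if not np.all(np.isfinite(out)):
        bad = ("dx1", "dx2", "dx3")[int(np.argmax(~np.isfinite(out)))]
        raise IntegrationError(f"non-finite derivative component {bad} at state {state!r}")
    return out


def integrate(
    params: ModelParameters,
    x0: Sequence[float] = DEFAULT_X0,
    dt: float = DEFAULT_DT,
    n: int = 1000,
    blowup: float = 1e6,
) -> Trajectory:
    """Fixed-step classical RK4 integration of the regulatory system.

    Deterministic for fixed inputs.  Raises :class:`IntegrationError` if any
    state magnitude exceeds ``blowup`` (chaotic parameter choices can diverge
    under a too-coarse step).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if n < 2:
        raise ValueError("need at least 2 samples")
    states = np.empty((n, 3))
    x = np.asarray(x0, dtype=float)
    if x.shape != (3,):
        raise ValueError("x0 must have 3 components")
    states[0] = x
    for k in range(1, n):
        k1 = derivatives(x, params)
        k2 = derivatives(x + 0.5 * dt * k1, params)
        k3 = derivatives(x + 0.5 * dt * k2, params)
        k4 = derivatives(x + dt * k3, params)
        x = x + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if not np.all(np.isfinite(x)) or np.any(np.abs(x) > blowup):
            raise IntegrationError(
                f"trajectory exceeded blow-up bound {blowup:g} at step {k}"
            )
        states[k] = x
    times = np.arange(n) * dt
    return Trajectory(times=times, states=states)


def make_supervised(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Extract lagged input rows and next-step glucose targets.

    A trajectory of length ``n`` yields ``n - 2`` rows: row ``k`` (for
    ``k = 1 .. n-2``) is ``[x1(k), x1(k-1), x2(k), x2(k-1), x3(k), x3(k-1)]``
    with target ``x2(k+1)``.
    """
    s = traj.states
    k = np.arange(1, len(s) - 1)
    inputs = np.column_stack(
        [s[k, 0], s[k - 1, 0], s[k, 1], s[k - 1, 1], s[k, 2], s[k - 1, 2]]
    )
    targets = s[k + 1, 1]
    return inputs, targets


def build_dataset(
    scenario: DisorderScenario,
    x0: Sequence[float] = DEFAULT_X0,
    dt: float = DEFAULT_DT,
    seed: int = 0,
    base_params: ModelParameters | None = None,
    chain_segments: bool = False,
) -> RegressionDataset:
    """Simulate the four disorder segments and assemble the regression set.

    Each parameter value is simulated for ``samples_per_value + 2`` states
    (two states are consumed to form the lags), so the supervised row count
    is exactly ``4 * samples_per_value``, split 70/30 train/test.  By default
    every segment restarts from ``x0``; with ``chain_segments`` the final
    state of one segment seeds the next.  ``seed`` does not influence the
    (noise-free, deterministic) simulation; it is recorded in the metadata so
    downstream training runs can be tied back to their dataset.
    """
    rows, targets = [], []
    x_start = np.asarray(x0, dtype=float)
    for params in scenario.parameter_sets(base_params):
        try:
            traj = integrate(params, x_start, dt, scenario.samples_per_value + 2)
        except IntegrationError as exc:
            raise IntegrationError(
                f"scenario {scenario.name!r} ({scenario.varied_parameter}="
                f"{getattr(params, scenario.varied_parameter)}): {exc}"
            ) from exc
        seg_x, seg_y = make_supervised(traj)
        rows.append(seg_x)
        targets.append(seg_y)
        if chain_segments:
            x_start = traj.states[-1]
    inputs = np.vstack(rows)
    y = np.concatenate(targets)
    split = int(round(TRAIN_FRACTION * len(y)))
    meta = {
        "scenario": scenario.name,
        "varied_parameter": scenario.varied_parameter,
        "values": list(scenario.values),
        "samples_per_value": scenario.samples_per_value,
        "x0": list(np.asarray(x0, dtype=float)),
        "dt": dt,
        "seed": seed,
        "chain_segments": chain_segments,
    }
    return RegressionDataset(inputs=inputs, targets=y, split_index=split, metadata=meta)


def save_dataset(dataset: RegressionDataset, path: str | Path) -> None:
    """Write the dataset as CSV with a JSON sidecar of provenance metadata."""
    path = Path(path)
    dataset.to_frame().to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(dataset.metadata, indent=2))


def load_dataset(path: str | Path) -> RegressionDataset:
    path = Path(path)
    frame = pd.read_csv(path)
    split = int((frame["partition"] == "train").sum())
    cols = ["x1_k", "x1_km1", "x2_k", "x2_km1", "x3_k", "x3_km1"]
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return RegressionDataset(
        inputs=frame[cols].to_numpy(),
        targets=frame["target"].to_numpy(),
        split_index=split,
        metadata=meta,
    )
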