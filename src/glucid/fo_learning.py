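"""Grünwald–Letnikov fractional-order online learning for the identifier nets.

The online cost is the instantaneous squared error E(k) = e(k)^2 / 2 with
e(k) = y(k) - yhat(k).  Plain gradient descent updates each weight as
theta <- theta - eta * dE/dtheta.  The fractional-order (FO) variant replaces
the integer-order derivative of the continuous-time descent flow
d(theta)/dt = -eta dE/dtheta with a Grünwald–Letnikov derivative of order
alpha in (0, 1], whose discretization yields

    theta(k+1) = -eta * dE/dtheta * h^alpha
                 - sum_{j=1}^{J} C_j^alpha * theta(k+1-j),

where h is the GL step, J = min(k+1, memory_length) and the coefficients
follow the binomial recursion C_0 = 1, C_j = (1 - (alpha+1)/j) C_{j-1}
(equivalently C_j = (-1)^j binom(alpha, j)).  At alpha = 1 the coefficients
collapse to (1, -1, 0, ...) and the rule reduces exactly to plain gradient
descent with step eta * h; the sub-unit orders blend a power-law-weighted
memory of past weight values into every update.

A Lyapunov argument on L(k) = e(k)^2 / 2 bounds the stable learning rate by
0 <= eta <= 2 / (dY/dtheta)^2 per tuned weight; ``adaptive_rate_bound``
implements that band (with a cap absorbing the vanishing-gradient case) and
``train_online`` can run either with fixed per-layer rates or with the
adaptive per-weight rule.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import yaml

from . import networks
from .glucose_ode import RegressionDataset

__all__ = [
    "TrainingConfig",
    "GLCoefficients",
    "WeightHistory",
    "TrainingInstabilityError",
    "gl_coefficients",
    "fo_update",
    "gd_update",
    "adaptive_rate_bound",
    "train_online",
]


class TrainingInstabilityError(RuntimeError):
    """Raised when a tuned weight diverges during online training."""


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of one online training run.

    alpha — fractional order in (0, 1]; 1 recovers integer-order descent.
    h — GL discretization step (the update scales gradients by h**alpha).
    eta_input / eta_hidden / eta_output — per-layer learning rates (the
    hidden rate drives the recurrent weights; biases, where present, follow
    their layer's rate).
    memory_length — GL history truncation (number of past weight values).
    rate_mode — "fixed" uses the eta triple; "adaptive" applies the Lyapunov
    rule min(2 / (dY/dtheta)^2, eta_cap) per weight.
    """

    alpha: float = 1.0
    h: float = 1.0
    eta_input: float = 0.1
    eta_hidden: float = 0.1
    eta_output: float = 0.1
    memory_length: int = 50
    epochs: int = 1
    seed: int = 0
    rate_mode: Literal["fixed", "adaptive"] = "fixed"
    eta_cap: float = 1.0
    blowup: float = 1e6

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")
        if self.h <= 0:
            raise ValueError("h must be positive")
        if min(self.eta_input, self.eta_hidden, self.eta_output) < 0:
            raise ValueError("learning rates must be non-negative")
        if self.memory_length < 1:
            raise ValueError("memory_length must be >= 1")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.rate_mode not in ("fixed", "adaptive"):
            raise ValueError("rate_mode must be 'fixed' or 'adaptive'")

    def layer_rate(self, layer: str) -> float:
        if layer == "output" or layer == "output_bias":
            return self.eta_output
        if layer == "recurrent":
            return self.eta_hidden
        return self.eta_input  # input weights and hidden biases

    def replace(self, **changes) -> "TrainingConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (yaml.safe_dump(self.to_dict(), sort_keys=False)
                if path.suffix in (".yml", ".yaml")
                else json.dumps(self.to_dict(), indent=2))
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "TrainingConfig":
        path = Path(path)
        data = (yaml.safe_load(path.read_text())
                if path.suffix in (".yml", ".yaml")
                else json.loads(path.read_text()))
        return cls(**data)


@dataclass(frozen=True)
class GLCoefficients:
    """Binomial-recursion GL coefficients C_0..C_n for a fractional order."""

    alpha: float
    c: np.ndarray

    def __len__(self) -> int:
        return len(self.c)

    def __getitem__(self, j):
        return self.c[j]


def gl_coefficients(alpha: float, n: int) -> GLCoefficients:
    """C_0 = 1; C_j = (1 - (alpha+1)/j) C_{j-1} for j = 1..n.

    Equals the alternating binomial expansion (-1)^j binom(alpha, j), the
    weights of the Grünwald–Letnikov derivative of order alpha.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    c = np.empty(n + 1)
    c[0] = 1.0
    for j in range(1, n + 1):
        c[j] = (1.0 - (alpha + 1.0) / j) * c[j - 1]
    return GLCoefficients(alpha=alpha, c=c)


class WeightHistory:
    """Most-recent-first ring buffer of past values of one weight array.

    ``stack[0]`` is theta(k), ``stack[1]`` is theta(k-1), and so on, up to
    ``memory_length`` entries.
    """

    def __init__(self, initial: np.ndarray, memory_length: int):
        if memory_length < 1:
            raise ValueError("memory_length must be >= 1")
        initial = np.asarray(initial, dtype=float)
        self._stack = np.zeros((memory_length,) + initial.shape)
        self._stack[0] = initial
        self.length = 1

    @property
    def stack(self) -> np.ndarray:
        return self._stack[: self.length]

    def push(self, value: np.ndarray) -> None:
        self._stack[1:] = self._stack[:-1]
        self._stack[0] = value
        self.length = min(self.length + 1, self._stack.shape[0])

    def newest(self) -> np.ndarray:
        return self._stack[0]

    def __len__(self) -> int:
        return self.length


def _fo_step(
    history: WeightHistory,
    grad: np.ndarray,
    eta: float | np.ndarray,
    coeffs: GLCoefficients,
    h_alpha: float,
) -> np.ndarray:
    """One GL update over the stacked history (vectorized over the array)."""
    J = history.length
    memory = np.tensordot(coeffs.c[1 : J + 1], history.stack, axes=(0, 0))
    return -eta * grad * h_alpha - memory


def fo_update(
    theta_history: Sequence[np.ndarray] | WeightHistory,
    grad: np.ndarray,
    eta: float | np.ndarray,
    cfg: TrainingConfig,
) -> np.ndarray:
    """Fractional-order update of one weight (scalar or array).

    ``theta_history`` lists past values most-recent-first (theta(k) first).
    Returns theta(k+1) = -eta * grad * h^alpha - sum_j C_j * theta(k+1-j).
    With alpha = 1 and h = 1 this reduces exactly to theta(k) - eta * grad.
    """
    if isinstance(theta_history, WeightHistory):
        hist = theta_history
    else:
        values = [np.asarray(v, dtype=float) for v in theta_history]
        if not values:
            raise ValueError("theta_history must be non-empty")
        hist = WeightHistory(values[0], cfg.memory_length)
        n = min(len(values), cfg.memory_length)
        for i in range(n):  # index 0 is the newest value theta(k)
            hist._stack[i] = values[i]
        hist.length = n
    grad = np.asarray(grad, dtype=float)
    if not np.all(np.isfinite(grad)):
        raise ValueError("gradient must be finite")
    coeffs = gl_coefficients(cfg.alpha, hist.length)
    return _fo_step(hist, grad, eta, coeffs, cfg.h**cfg.alpha)


def gd_update(theta: np.ndarray, grad: np.ndarray, eta: float | np.ndarray) -> np.ndarray:
    """Plain gradient descent: theta - eta * grad."""
    return np.asarray(theta, dtype=float) - eta * np.asarray(grad, dtype=float)


def adaptive_rate_bound(
    output_grad: float | np.ndarray, eta_cap: float = 1.0
) -> float | np.ndarray:
    """Lyapunov-stable learning rate 2 / (dY/dtheta)^2, capped at ``eta_cap``.

    The cap absorbs the singular dY/dtheta -> 0 case (a weight the output is
    momentarily insensitive to can take any bounded rate without violating
    the one-step error-decrease condition).  ``output_grad`` may be the
    scalar sensitivity of one tuned weight or the Euclidean norm of the
    stacked-parameter sensitivity vector; the band applies to whichever
    parameter block the update touches.
    """
    g = np.asarray(output_grad, dtype=float)
    with np.errstate(divide="ignore"):
        bound = np.where(g == 0.0, eta_cap, 2.0 / np.square(g))
    result = np.minimum(bound, eta_cap)
    return float(result) if np.isscalar(output_grad) or result.ndim == 0 else result


def train_online(
    dataset: RegressionDataset,
    weights,
    cfg: TrainingConfig,
    algorithm: Literal["fo", "gd"] = "fo",
):
    """Sample-by-sample online training over the train partition.

    Per sample: forward pass -> error e(k) = y(k) - yhat(k) -> truncated
    chain-rule gradients -> per-layer FO or GD update.  Each weight array
    keeps its own GL history (FO mode).  The hidden state is reset at the
    start of every epoch; weight histories persist across epochs (the run is
    one continuous online stream).  Returns the trained weights and the
    per-epoch training RMSE trace.

    Raises :class:`TrainingInstabilityError` naming epoch and sample if any
    weight magnitude exceeds ``cfg.blowup``.
    """
    if algorithm not in ("fo", "gd"):
        raise ValueError("algorithm must be 'fo' or 'gd'")
    X, y = dataset.X_train, dataset.y_train
    if len(y) == 0:
        raise ValueError("dataset has no training partition")

    # Flatten the per-layer weight arrays into one parameter vector; the GL
    # memory is then a single ring-buffer matvec per sample.
    names, slices, shapes = [], {}, {}
    offset = 0
    for name, arr in weights.layers().items():
        arr = np.asarray(arr, dtype=float)
        names.append(name)
        shapes[name] = arr.shape
        slices[name] = slice(offset, offset + arr.size)
        offset += arr.size
    n_params = offset
    flat = np.concatenate(
        [np.asarray(weights.layers()[n], dtype=float).ravel() for n in names]
    )
    eta_vec = np.concatenate(
        [np.full(shapes[n] or (1,), cfg.layer_rate(n)).ravel() for n in names]
    )

    mem = cfg.memory_length
    coeffs = gl_coefficients(cfg.alpha, mem).c
    h_alpha = cfg.h**cfg.alpha
    # Ring buffer of past parameter vectors in insertion order; row ``pos``
    # is theta(k).  P[pos] permutes C_1..C_mem to align with the ring, so
    # the GL memory sum is P[pos] @ ring.  Unfilled rows are zero and drop
    # out of the sum, which reproduces the short-history warm-up exactly.
    ring = np.zeros((mem, n_params))
    ring[0] = flat
    pos = 0
    P = np.empty((mem, mem))
    idx = np.arange(mem)
    for p in range(mem):
        P[p] = coeffs[((p - idx) % mem) + 1]

    rmse_trace = []
    for epoch in range(cfg.epochs):
        weights.reset_state()
        sq_sum = 0.0
        for k, (row, target) in enumerate(zip(X, y)):
            record = networks.forward(weights, row)
            e = float(target) - record.output
            sq_sum += e * e
            grads = networks.gradients(record, weights, row, e)
            grad_flat = np.concatenate(
                [np.asarray(grads.dE[n]).ravel() for n in names]
            )
            if cfg.rate_mode == "adaptive":
                g2 = sum(float(np.sum(np.square(g))) for g in grads.dY.values())
                # Midpoint-optimal rate from the one-step Lyapunov decrease
                # (the band edge 2/g^2 only oscillates); theta is the full
                # stacked parameter vector.
                eta = cfg.eta_cap if g2 == 0.0 else min(1.0 / g2, cfg.eta_cap)
            else:
                eta = eta_vec
            if algorithm == "fo":
                memory = P[pos] @ ring
                new = -eta * grad_flat * h_alpha - memory
                pos = (pos + 1) % mem
                ring[pos] = new
            else:
                new = flat - eta * grad_flat
            if np.any(np.abs(new) > cfg.blowup):
                raise TrainingInstabilityError(
                    f"weights diverged at epoch {epoch}, sample {k}"
                )
            flat = new
            for n in names:
                _assign_layer(weights, n, flat[slices[n]].reshape(shapes[n]))
        rmse_trace.append(float(np.sqrt(sq_sum / len(y))))
    return weights, rmse_trace


def _assign_layer(weights, name: str, value: np.ndarray) -> None:
    if isinstance(weights, networks.FRNNWeights):
        attr = {"input": "input_weights", "recurrent": "recurrent_weights",
                "output": "output_weights"}[name]
        setattr(weights, attr, value)
    elif isinstance(weights, networks.DRNNWeights):
        attr = {"input": "input_weights", "recurrent": "self_feedback",
                "output": "output_weights"}[name]
        setattr(weights, attr, value)
    elif isinstance(weights, networks.DFNNWeights):
        if name == "output_bias":
            weights.output_bias = float(np.asarray(value).reshape(-1)[0])
        else:
            attr = {"input": "hidden_weights", "output": "output_weights",
                    "hidden_bias": "hidden_biases"}[name]
            setattr(weights, attr, value)
    else:
        raise TypeError(f"unsupported weight container {type(weights).__name__}")


def save_trace(trace: Sequence[float], path: str | Path) -> None:
    """Write the per-epoch training RMSE trace as CSV."""
    lines = ["epoch,rmse"]
    lines += [f"{i},{v:.10g}" for i, v in enumerate(trace)]
    Path(path).write_text("\n".join(lines) + "\n")
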