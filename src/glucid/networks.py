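"""Forward evaluation and truncated gradients for the three identifier nets.

Three small architectures share the 6-input / 1-output interface of the
one-step identification problem:

* FRNN — fully recurrent: every tanh hidden neuron feeds back to every
  hidden neuron through a dense recurrent matrix ``W^r``.
* DRNN — diagonal recurrent: each tanh hidden neuron sees only its own
  previous activation (``W^r`` is a vector of self-feedback gains).
* DFNN — deep feedforward baseline: one sigmoid hidden layer (28 units by
  default) with biases and a linear output.

Gradients are the depth-1 truncated chain rules of online recurrent
training: the previous hidden state ``Y^H(k-1)`` is treated as a constant,
so its own dependence on the weights is not back-propagated.  This is the
standard real-time simplification for per-sample updates (full BPTT is out
of scope).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "FRNNWeights",
    "DRNNWeights",
    "DFNNWeights",
    "ForwardRecord",
    "Gradients",
    "initialize_weights",
    "frnn_forward",
    "drnn_forward",
    "dfnn_forward",
    "forward",
    "gradients",
    "predict_series",
    "save_weights",
    "load_weights",
]

#: Half-width of the seeded uniform weight initialization.  Keeps the tanh
#: units in their responsive region for inputs of order one.
INIT_SCALE = 0.5


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


@dataclass
class FRNNWeights:
    """Fully recurrent net: dense M x M recurrence over tanh hidden units."""

    input_weights: np.ndarray      # (M, L)
    recurrent_weights: np.ndarray  # (M, M)
    output_weights: np.ndarray     # (M,)
    hidden_state: np.ndarray = field(default=None)  # (M,), Y^H(k-1)

    def __post_init__(self) -> None:
        self.input_weights = np.asarray(self.input_weights, dtype=float)
        self.recurrent_weights = np.asarray(self.recurrent_weights, dtype=float)
        self.output_weights = np.asarray(self.output_weights, dtype=float)
        m, _ = self.input_weights.shape
        if self.recurrent_weights.shape != (m, m) or self.output_weights.shape != (m,):
            raise ValueError("inconsistent FRNN weight shapes")
        if self.hidden_state is None:
            self.hidden_state = np.zeros(m)
        self.hidden_state = np.asarray(self.hidden_state, dtype=float)

    @property
    def n_hidden(self) -> int:
        return self.input_weights.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.input_weights.shape[1]

    def reset_state(self) -> None:
        self.hidden_state = np.zeros(self.n_hidden)

    def layers(self) -> dict[str, np.ndarray]:
        return {
            "input": self.input_weights,
            "recurrent": self.recurrent_weights,
            "output": self.output_weights,
        }


@dataclass
class DRNNWeights:
    """Diagonal recurrent net: per-neuron self-feedback gains only."""

    input_weights: np.ndarray   # (M, L)
    self_feedback: np.ndarray   # (M,)
    output_weights: np.ndarray  # (M,)
    hidden_state: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.input_weights = np.asarray(self.input_weights, dtype=float)
        self.self_feedback = np.asarray(self.self_feedback, dtype=float)
        self.output_weights = np.asarray(self.output_weights, dtype=float)
        m = self.input_weights.shape[0]
        if self.self_feedback.shape != (m,) or self.output_weights.shape != (m,):
            raise ValueError("inconsistent DRNN weight shapes")
        if self.hidden_state is None:
            self.hidden_state = np.zeros(m)
        self.hidden_state = np.asarray(self.hidden_state, dtype=float)

    @property
    def n_hidden(self) -> int:
        return self.input_weights.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.input_weights.shape[1]

    def reset_state(self) -> None:
        self.hidden_state = np.zeros(self.n_hidden)

    def layers(self) -> dict[str, np.ndarray]:
        return {
            "input": self.input_weights,
            "recurrent": self.self_feedback,
            "output": self.output_weights,
        }

    def to_frnn(self) -> FRNNWeights:
        """Embed as an FRNN with a diagonal recurrent matrix (exact)."""
        return FRNNWeights(
            input_weights=self.input_weights.copy(),
            recurrent_weights=np.diag(self.self_feedback),
            output_weights=self.output_weights.copy(),
            hidden_state=self.hidden_state.copy(),
        )


@dataclass
class DFNNWeights:
    """Feedforward baseline: sigmoid hidden layer with biases, linear output."""

    hidden_weights: np.ndarray  # (M, L)
    output_weights: np.ndarray  # (M,)
    hidden_biases: np.ndarray = field(default=None)
    output_bias: float = 0.0
    use_biases: bool = True

    def __post_init__(self) -> None:
        self.hidden_weights = np.asarray(self.hidden_weights, dtype=float)
        self.output_weights = np.asarray(self.output_weights, dtype=float)
        m = self.hidden_weights.shape[0]
        if self.output_weights.shape != (m,):
            raise ValueError("inconsistent DFNN weight shapes")
        if self.hidden_biases is None:
            self.hidden_biases = np.zeros(m)
        self.hidden_biases = np.asarray(self.hidden_biases, dtype=float)

    @property
    def n_hidden(self) -> int:
        return self.hidden_weights.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.hidden_weights.shape[1]

    def reset_state(self) -> None:  # stateless; symmetry with the RNNs
        pass

    def layers(self) -> dict[str, np.ndarray]:
        out = {"input": self.hidden_weights, "output": self.output_weights}
        if self.use_biases:
            out["hidden_bias"] = self.hidden_biases
            out["output_bias"] = np.atleast_1d(np.float64(self.output_bias))
        return out


@dataclass(frozen=True)
class ForwardRecord:
    """One forward pass: induced fields, activations and scalar output."""

    net: np.ndarray          # net^H_m(k)
    hidden: np.ndarray       # Y^H_m(k) = F(net^H_m(k))
    prev_hidden: np.ndarray  # Y^H(k-1) as used in this pass
    output: float            # Y(k)


@dataclass(frozen=True)
class Gradients:
    """Per-layer partials of the instantaneous cost E = e^2 / 2.

    ``dE`` maps layer name to dE/dtheta; ``dY`` holds the matching output
    sensitivities dY/dtheta (used by the Lyapunov adaptive learning rate).
    The two are related by ``dE = -e * dY``.
    """

    dE: dict[str, np.ndarray]
    dY: dict[str, np.ndarray]


def initialize_weights(
    kind: str,
    n_hidden: int,
    n_inputs: int = 6,
    rng: np.random.Generator | int | None = 0,
    use_biases: bool = True,
):
    """Seeded uniform(-0.5, 0.5) initialization for any architecture."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    u = lambda *shape: rng.uniform(-INIT_SCALE, INIT_SCALE, size=shape)
    if kind == "frnn":
        return FRNNWeights(u(n_hidden, n_inputs), u(n_hidden, n_hidden), u(n_hidden))
    if kind == "drnn":
        return DRNNWeights(u(n_hidden, n_inputs), u(n_hidden), u(n_hidden))
    if kind == "dfnn":
        return DFNNWeights(
            u(n_hidden, n_inputs), u(n_hidden),
            hidden_biases=u(n_hidden) if use_biases else np.zeros(n_hidden),
            output_bias=float(u(1)[0]) if use_biases else 0.0,
            use_biases=use_biases,
        )
    raise ValueError(f"unknown architecture {kind!r}")


def frnn_forward(weights: FRNNWeights, x: np.ndarray) -> ForwardRecord:
    """net_m = sum_l W^I_ml x_l + sum_j W^r_mj Y^H_j(k-1); Y = W^O . tanh(net).

    Stores the new hidden activations back into ``weights.hidden_state``.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (weights.n_inputs,):
        raise ValueError(f"input must have shape ({weights.n_inputs},)")
    prev = weights.hidden_state.copy()
    net = weights.input_weights @ x + weights.recurrent_weights @ prev
    hidden = np.tanh(net)
    output = float(weights.output_weights @ hidden)
    weights.hidden_state = hidden
    return ForwardRecord(net=net, hidden=hidden, prev_hidden=prev, output=output)


def drnn_forward(weights: DRNNWeights, x: np.ndarray) -> ForwardRecord:
    """net_m = W^r_m Y^H_m(k-1) + sum_l W^I_ml x_l (self-feedback only)."""
    x = np.asarray(x, dtype=float)
    if x.shape != (weights.n_inputs,):
        raise ValueError(f"input must have shape ({weights.n_inputs},)")
    prev = weights.hidden_state.copy()
    net = weights.input_weights @ x + weights.self_feedback * prev
    hidden = np.tanh(net)
    output = float(weights.output_weights @ hidden)
    weights.hidden_state = hidden
    return ForwardRecord(net=net, hidden=hidden, prev_hidden=prev, output=output)


def dfnn_forward(weights: DFNNWeights, x: np.ndarray) -> ForwardRecord:
    """Sigmoid hidden layer, linear output; stateless."""
    x = np.asarray(x, dtype=float)
    if x.shape != (weights.n_inputs,):
        raise ValueError(f"input must have shape ({weights.n_inputs},)")
    net = weights.hidden_weights @ x
    if weights.use_biases:
        net = net + weights.hidden_biases
    hidden = _sigmoid(net)
    output = float(weights.output_weights @ hidden)
    if weights.use_biases:
        output += weights.output_bias
    return ForwardRecord(
        net=net, hidden=hidden, prev_hidden=np.zeros_like(net), output=output
    )


_FORWARD = {FRNNWeights: frnn_forward, DRNNWeights: drnn_forward, DFNNWeights: dfnn_forward}


def forward(weights, x: np.ndarray) -> ForwardRecord:
    """Dispatch the forward pass on the weight container type."""
    return _FORWARD[type(weights)](weights, x)


def gradients(record: ForwardRecord, weights, x: np.ndarray, error: float) -> Gradients:
    """Truncated chain-rule partials of E = e^2/2 for one sample.

    Output layer: dE/dW^O_m = -e Y^H_m.  Hidden layers: dE/dW^I_ml =
    -e W^O_m F'(net_m) x_l and, for the recurrent weights, the same factor
    times the frozen previous activation.  F' is 1 - tanh^2 for the RNNs and
    s(1-s) for the sigmoid baseline.
    """
    x = np.asarray(x, dtype=float)
    e = float(error)
    dY: dict[str, np.ndarray] = {"output": record.hidden.copy()}
    if isinstance(weights, DFNNWeights):
        fprime = record.hidden * (1.0 - record.hidden)
        back = weights.output_weights * fprime            # (M,)
        dY["input"] = np.outer(back, x)
        if weights.use_biases:
            dY["hidden_bias"] = back.copy()
            dY["output_bias"] = np.ones(1)
    elif isinstance(weights, FRNNWeights):
        fprime = 1.0 - record.hidden**2
        back = weights.output_weights * fprime
        dY["input"] = np.outer(back, x)
        dY["recurrent"] = np.outer(back, record.prev_hidden)
    elif isinstance(weights, DRNNWeights):
        fprime = 1.0 - record.hidden**2
        back = weights.output_weights * fprime
        dY["input"] = np.outer(back, x)
        dY["recurrent"] = back * record.prev_hidden
    else:
        raise TypeError(f"unsupported weight container {type(weights).__name__}")
    if record.hidden.shape != (weights.n_hidden,):
        raise ValueError("forward record does not match the weight container")
    dE = {name: -e * g for name, g in dY.items()}
    return Gradients(dE=dE, dY=dY)


def predict_series(weights, X: np.ndarray, reset_state: bool = True) -> np.ndarray:
    """Run the net over a sequence of input rows, evolving the hidden state.

    With ``reset_state`` (default) the recurrent state starts from zero, so
    an evaluation pass does not leak earlier history.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if reset_state:
        weights.reset_state()
    return np.array([forward(weights, row).output for row in X])


def save_weights(weights, path: str | Path) -> None:
    """Serialize any weight container to JSON with architecture metadata."""
    kind = {FRNNWeights: "frnn", DRNNWeights: "drnn", DFNNWeights: "dfnn"}[type(weights)]
    payload = {"architecture": kind,
               "n_hidden": weights.n_hidden, "n_inputs": weights.n_inputs}
    for name, arr in weights.layers().items():
        payload[name] = np.asarray(arr).tolist()
    if kind == "dfnn":
        payload["use_biases"] = weights.use_biases
    Path(path).write_text(json.dumps(payload, indent=2))


def load_weights(path: str | Path):
    payload = json.loads(Path(path).read_text())
    kind = payload["architecture"]
    if kind == "frnn":
        return FRNNWeights(payload["input"], payload["recurrent"], payload["output"])
    if kind == "drnn":
        return DRNNWeights(payload["input"], payload["recurrent"], payload["output"])
    if kind == "dfnn":
        use_biases = payload.get("use_biases", True)
        return DFNNWeights(
            payload["input"], payload["output"],
            hidden_biases=payload.get("hidden_bias"),
            output_bias=float(payload.get("output_bias", [0.0])[0]),
            use_biases=use_biases,
        )
    raise ValueError(f"unknown architecture {kind!r} in {path}")
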