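"""Forward passes, truncated gradients, architecture equivalences."""

import numpy as np
import pytest

from glucid import networks as nw


def _perturb(weights, layer, i, eps):
    if layer == "output_bias":
        weights.output_bias += eps
    else:
        np.asarray(weights.layers()[layer]).reshape(-1)[i] += eps


def _finite_difference(weights_factory, layer, x, target, eps=1e-6):
    """Central finite differences of E = e^2/2 with frozen previous hidden
    state, matching the depth-1 truncation of the analytic gradients."""
    base = weights_factory()
    grad = np.zeros_like(np.asarray(base.layers()[layer], dtype=float))
    flat = grad.reshape(-1)
    for i in range(flat.size):
        plus = weights_factory()
        minus = weights_factory()
        _perturb(plus, layer, i, eps)
        _perturb(minus, layer, i, -eps)
        ep = target - nw.forward(plus, x).output
        em = target - nw.forward(minus, x).output
        flat[i] = (0.5 * ep**2 - 0.5 * em**2) / (2 * eps)
    return grad


def _random_weights(kind, rng, n_hidden=4):
    w = nw.initialize_weights(kind, n_hidden, 6, rng)
    if kind != "dfnn":
        w.hidden_state = rng.uniform(-0.8, 0.8, n_hidden)
    return w


class TestForward:
    def test_zero_weights_give_zero_output(self):
        w = nw.FRNNWeights(np.zeros((3, 6)), np.zeros((3, 3)), np.zeros(3))
        rec = nw.frnn_forward(w, np.ones(6))
        assert rec.output == 0.0
        np.testing.assert_array_equal(rec.hidden, np.zeros(3))

    def test_without_recurrence_equals_feedforward_tanh(self, rng):
        wi = rng.normal(size=(4, 6))
        wo = rng.normal(size=4)
        w = nw.FRNNWeights(wi, np.zeros((4, 4)), wo)
        w.hidden_state = rng.normal(size=4)  # must be ignored through W^r = 0
        x = rng.normal(size=6)
        rec = nw.frnn_forward(w, x)
        assert rec.output == pytest.approx(float(wo @ np.tanh(wi @ x)), rel=1e-14)

    def test_single_neuron_hand_value(self):
        w = nw.FRNNWeights(np.array([[1.0]]), np.array([[0.0]]), np.array([2.0]))
        rec = nw.frnn_forward(w, np.array([0.5]))
        assert rec.output == pytest.approx(2.0 * np.tanh(0.5), rel=1e-15)

    def test_hidden_state_advances(self, rng):
        w = _random_weights("frnn", rng)
        x = rng.normal(size=6)
        rec = nw.frnn_forward(w, x)
        np.testing.assert_array_equal(w.hidden_state, rec.hidden)
        rec2 = nw.frnn_forward(w, x)
        np.testing.assert_array_equal(rec2.prev_hidden, rec.hidden)

    def test_hidden_activations_inside_unit_interval(self, rng):
        w = _random_weights("frnn", rng)
        for _ in range(20):
            rec = nw.frnn_forward(w, rng.normal(scale=5, size=6))
            assert np.all(np.abs(rec.hidden) < 1.0)

    def test_output_linear_in_output_weights(self, rng):
        w = _random_weights("frnn", rng)
        x = rng.normal(size=6)
        state = w.hidden_state.copy()
        out1 = nw.frnn_forward(w, x).output
        w2 = nw.FRNNWeights(w.input_weights, w.recurrent_weights,
                            2.0 * w.output_weights, state)
        assert nw.frnn_forward(w2, x).output == pytest.approx(2 * out1, rel=1e-12)

    def test_drnn_matches_diagonal_frnn_exactly(self, rng):
        for _ in range(100):
            d = _random_weights("drnn", rng)
            f = d.to_frnn()
            x = rng.normal(size=6)
            rd, rf = nw.drnn_forward(d, x), nw.frnn_forward(f, x)
            assert rd.output == rf.output
            np.testing.assert_array_equal(rd.hidden, rf.hidden)

    def test_dfnn_zero_output_weights(self, rng):
        w = nw.DFNNWeights(rng.normal(size=(5, 6)), np.zeros(5),
                           output_bias=0.0)
        assert nw.dfnn_forward(w, rng.normal(size=6)).output == 0.0

    def test_dfnn_hand_value(self):
        hw = np.array([[1.0, 0, 0, 0, 0, 0], [0, -1.0, 0, 0, 0, 0]])
        w = nw.DFNNWeights(hw, np.array([0.5, 0.25]),
                           hidden_biases=np.array([0.1, -0.2]), output_bias=0.3)
        x = np.array([0.4, 0.8, 0, 0, 0, 0])
        sig = lambda z: 1 / (1 + np.exp(-z))
        expected = 0.5 * sig(0.5) + 0.25 * sig(-1.0) + 0.3
        assert nw.dfnn_forward(w, x).output == pytest.approx(expected, rel=1e-14)

    def test_dimension_mismatch_rejected(self, rng):
        w = _random_weights("frnn", rng)
        with pytest.raises(ValueError):
            nw.frnn_forward(w, np.ones(5))


class TestGradients:
    def test_zero_error_zeroes_every_partial(self, rng):
        w = _random_weights("frnn", rng)
        x = rng.normal(size=6)
        rec = nw.forward(w, x)
        grads = nw.gradients(rec, w, x, 0.0)
        for g in grads.dE.values():
            np.testing.assert_array_equal(g, np.zeros_like(g))

    @pytest.mark.parametrize("kind", ["frnn", "drnn", "dfnn"])
    def test_matches_frozen_history_finite_differences(self, kind):
        rng = np.random.default_rng(99)
        for _ in range(17):  # ~50 (architecture, layer) oracle instances each run
            seed_state = rng.integers(1 << 31)

            def factory():
                r = np.random.default_rng(seed_state)
                return _random_weights(kind, r)

            w = factory()
            x = np.random.default_rng(seed_state + 1).normal(size=6)
            target = float(np.random.default_rng(seed_state + 2).normal())
            rec = nw.forward(w, x)
            e = target - rec.output
            grads = nw.gradients(rec, factory(), x, e)
            for layer in grads.dE:
                fd = _finite_difference(factory, layer, x, target)
                np.testing.assert_allclose(
                    grads.dE[layer], fd, rtol=1e-6, atol=1e-9,
                    err_msg=f"{kind}/{layer}",
                )

    def test_drnn_gradients_equal_diagonal_frnn_gradients(self, rng):
        d = _random_weights("drnn", rng)
        f = d.to_frnn()
        x = rng.normal(size=6)
        rd, rf = nw.drnn_forward(d, x), nw.frnn_forward(f, x)
        gd = nw.gradients(rd, d, x, 0.7)
        gf = nw.gradients(rf, f, x, 0.7)
        np.testing.assert_array_equal(gd.dE["input"], gf.dE["input"])
        np.testing.assert_array_equal(gd.dE["output"], gf.dE["output"])
        np.testing.assert_array_equal(gd.dE["recurrent"], np.diag(gf.dE["recurrent"]))

    def test_dY_and_dE_are_consistent(self, rng):
        w = _random_weights("frnn", rng)
        x = rng.normal(size=6)
        rec = nw.forward(w, x)
        g = nw.gradients(rec, w, x, 0.3)
        for layer in g.dE:
            np.testing.assert_allclose(g.dE[layer], -0.3 * g.dY[layer], rtol=1e-14)


class TestWeightIO:
    @pytest.mark.parametrize("kind", ["frnn", "drnn", "dfnn"])
    def test_json_roundtrip(self, kind, tmp_path, rng):
        w = nw.initialize_weights(kind, 3, 6, rng)
        path = tmp_path / "w.json"
        nw.save_weights(w, path)
        back = nw.load_weights(path)
        assert type(back) is type(w)
        x = np.random.default_rng(0).normal(size=6)
        assert nw.forward(back, x).output == pytest.approx(
            nw.forward(w, x).output, rel=1e-15
        )

    def test_seeded_initialization_reproducible(self):
        a = nw.initialize_weights("frnn", 5, 6, 42)
        b = nw.initialize_weights("frnn", 5, 6, 42)
        np.testing.assert_array_equal(a.input_weights, b.input_weights)
        assert np.all(np.abs(a.input_weights) <= 0.5)
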