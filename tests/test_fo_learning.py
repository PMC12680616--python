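"""GL coefficients, fractional-order updates, stability band, online loop."""

import math

import numpy as np
import pytest

from glucid import networks as nw
from glucid.fo_learning import (
    TrainingConfig,
    TrainingInstabilityError,
    WeightHistory,
    adaptive_rate_bound,
    fo_update,
    gd_update,
    gl_coefficients,
    train_online,
)
from glucid.glucose_ode import RegressionDataset

ALPHAS = [0.25, 0.3109, 0.3999, 0.5, 0.9]


def closed_form(alpha, j):
    """(-1)^j * Gamma(alpha+1) / (j! * Gamma(alpha-j+1))."""
    return ((-1) ** j * math.gamma(alpha + 1)
            / (math.factorial(j) * math.gamma(alpha - j + 1)))


class TestGLCoefficients:
    def test_base_case_is_one(self):
        for alpha in ALPHAS:
            assert gl_coefficients(alpha, 0)[0] == 1.0

    def test_integer_order_collapses_to_first_difference(self):
        c = gl_coefficients(1.0, 5).c
        np.testing.assert_array_equal(c, [1.0, -1.0, 0.0, 0.0, 0.0, 0.0])

    def test_half_order_hand_values(self):
        c = gl_coefficients(0.5, 2).c
        np.testing.assert_allclose(c, [1.0, -0.5, -0.125], rtol=1e-15)

    @pytest.mark.parametrize("alpha", ALPHAS)
    def test_recursion_matches_gamma_closed_form(self, alpha):
        c = gl_coefficients(alpha, 30).c
        expected = [closed_form(alpha, j) for j in range(31)]
        np.testing.assert_allclose(c, expected, rtol=1e-10)

    @pytest.mark.parametrize("alpha", ALPHAS)
    def test_magnitudes_nonincreasing_beyond_first(self, alpha):
        c = np.abs(gl_coefficients(alpha, 100).c)
        assert np.all(np.diff(c[1:]) <= 1e-16)

    def test_truncated_series_decays_toward_zero(self):
        # sum_j C_j is the expansion of (1-1)^alpha = 0; the truncated sum
        # decays like n^(-alpha), so only moderately large orders are close
        # to zero by n = 200.
        for alpha in ALPHAS:
            partial = np.cumsum(gl_coefficients(alpha, 200).c)
            assert abs(partial[200]) < abs(partial[10])
            assert abs(partial[200]) < abs(partial[50])
        for alpha in (0.5, 0.9):
            assert abs(np.sum(gl_coefficients(alpha, 200).c)) < 0.05


class TestUpdates:
    def test_integer_order_reduces_to_gradient_descent(self):
        cfg = TrainingConfig(alpha=1.0, h=1.0)
        new = fo_update([np.array(0.5)], np.array(0.2), 0.1, cfg)
        assert float(new) == pytest.approx(0.48, abs=1e-15)

    def test_integer_order_fixed_point_at_zero_gradient(self):
        cfg = TrainingConfig(alpha=1.0, h=1.0)
        new = fo_update([np.array(0.37)], np.array(0.0), 0.5, cfg)
        assert float(new) == 0.37

    def test_half_order_memory_sum_hand_value(self):
        cfg = TrainingConfig(alpha=0.5, h=1.0)
        new = fo_update([np.array(0.4), np.array(0.2)], np.array(0.0), 0.9, cfg)
        # -(C1*0.4 + C2*0.2) = 0.5*0.4 + 0.125*0.2
        assert float(new) == pytest.approx(0.225, abs=1e-15)

    def test_empty_history_rejected(self):
        with pytest.raises(ValueError):
            fo_update([], np.array(0.1), 0.1, TrainingConfig())

    def test_gd_update_arithmetic(self):
        assert float(gd_update(np.array(1.0), np.array(2.0), 0.25)) == 0.5
        assert float(gd_update(np.array(0.3), np.array(0.0), 0.9)) == 0.3
        assert float(gd_update(np.array(0.3), np.array(5.0), 0.0)) == 0.3

    def test_adaptive_rate_band_values(self):
        assert adaptive_rate_bound(1.0, eta_cap=5.0) == 2.0
        assert adaptive_rate_bound(2.0, eta_cap=5.0) == 0.5
        assert adaptive_rate_bound(0.0, eta_cap=5.0) == 5.0
        np.testing.assert_allclose(
            adaptive_rate_bound(np.array([1.0, 0.0]), 3.0), [2.0, 3.0]
        )


class TestWeightHistoryBuffer:
    def test_most_recent_first_and_truncation(self):
        h = WeightHistory(np.array(1.0), 3)
        for v in (2.0, 3.0, 4.0):
            h.push(np.array(v))
        np.testing.assert_array_equal(h.stack, [4.0, 3.0, 2.0])
        assert len(h) == 3


def _tiny_dataset(n=60, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.uniform(-1, 1, size=(n, 6))
    y = np.tanh(X @ rng.normal(size=6) * 0.5)
    return RegressionDataset(inputs=X, targets=y, split_index=n)


class TestTrainOnline:
    def test_zero_rates_leave_weights_unchanged(self):
        ds = _tiny_dataset()
        w = nw.initialize_weights("frnn", 4, 6, 3)
        before = {k: v.copy() for k, v in w.layers().items()}
        cfg = TrainingConfig(eta_input=0.0, eta_hidden=0.0, eta_output=0.0,
                             epochs=3)
        w, trace = train_online(ds, w, cfg, "gd")
        for k, v in w.layers().items():
            np.testing.assert_array_equal(v, before[k])
        assert trace[0] == pytest.approx(trace[-1], rel=1e-12)

    @pytest.mark.parametrize("kind", ["frnn", "drnn", "dfnn"])
    @pytest.mark.parametrize("memory_length", [1, 7])
    def test_integer_order_training_equals_gd_bitwise(self, kind, memory_length):
        ds = _tiny_dataset()
        cfg = TrainingConfig(alpha=1.0, h=1.0, memory_length=memory_length,
                             epochs=2, eta_input=0.05, eta_hidden=0.05,
                             eta_output=0.1)
        wf = nw.initialize_weights(kind, 4, 6, 11)
        wg = nw.initialize_weights(kind, 4, 6, 11)
        wf, tf = train_online(ds, wf, cfg, "fo")
        wg, tg = train_online(ds, wg, cfg, "gd")
        for k in wf.layers():
            np.testing.assert_array_equal(wf.layers()[k], wg.layers()[k])
        assert tf == tg

    def test_training_reduces_rmse_across_epochs(self, small_type2_dataset):
        w = nw.initialize_weights("frnn", 5, 6, 0)
        cfg = TrainingConfig(eta_input=0.1, eta_hidden=0.05, eta_output=0.95,
                             epochs=5)
        w, trace = train_online(small_type2_dataset, w, cfg, "gd")
        assert trace[-1] < trace[0]

    def test_divergence_raises_with_location(self):
        ds = _tiny_dataset()
        w = nw.initialize_weights("frnn", 4, 6, 3)
        cfg = TrainingConfig(eta_input=50.0, eta_hidden=50.0, eta_output=50.0,
                             epochs=1)
        with pytest.raises(TrainingInstabilityError, match="epoch 0"):
            train_online(ds, w, cfg, "gd")

    def test_lyapunov_one_step_error_nonincrease(self):
        # Output-layer-only update with eta inside the stability band
        # 0 <= eta <= 2/||dY/dW_O||^2: since the output is linear in W_O the
        # Taylor step is exact and |e| cannot grow.
        rng = np.random.default_rng(2024)
        for _ in range(100):
            w = nw.initialize_weights("frnn", 5, 6, rng)
            w.hidden_state = rng.uniform(-0.9, 0.9, 5)
            x = rng.normal(size=6)
            target = float(rng.normal(scale=1.5))
            rec = nw.forward(w, x)
            e = target - rec.output
            g = nw.gradients(rec, w, x, e)
            band = 2.0 / float(np.sum(np.square(g.dY["output"])))
            eta = float(rng.uniform(0.0, band))
            new_out = gd_update(w.output_weights, g.dE["output"], eta)
            e_new = target - float(new_out @ rec.hidden)
            assert e_new**2 <= e**2 + 1e-12


class TestTrainingConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            TrainingConfig(alpha=0.0)
        with pytest.raises(ValueError):
            TrainingConfig(alpha=1.5)
        with pytest.raises(ValueError):
            TrainingConfig(h=0.0)
        with pytest.raises(ValueError):
            TrainingConfig(memory_length=0)
        with pytest.raises(ValueError):
            TrainingConfig(eta_input=-0.1)
        with pytest.raises(ValueError):
            TrainingConfig(rate_mode="annealed")

    @pytest.mark.parametrize("suffix", [".json", ".yaml"])
    def test_file_roundtrip(self, suffix, tmp_path):
        cfg = TrainingConfig(alpha=0.3109, eta_output=0.9, memory_length=25,
                             epochs=4, rate_mode="adaptive")
        path = tmp_path / f"cfg{suffix}"
        cfg.save(path)
        assert TrainingConfig.load(path) == cfg
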