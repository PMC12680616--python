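"""Scikit-learn style estimators wrapping the online identifier training.

Each estimator follows the fit/predict contract: ``fit(X, y)`` runs
sample-by-sample online training over the rows of ``X`` in order (the rows
are a time series of lagged states, so order matters), and ``predict(X)``
evaluates the trained network over a sequence, evolving the recurrent state
from zero.  Hyperparameters mirror :class:`glucid.fo_learning.TrainingConfig`;
fitted state lives in trailing-underscore attributes, so the estimators
compose with sklearn model selection (``get_params`` / ``set_params`` /
``clone``).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from . import networks
from .fo_learning import TrainingConfig, train_online
from .glucose_ode import RegressionDataset

__all__ = ["FRNNRegressor", "DRNNRegressor", "DFNNRegressor"]


class _BaseIdentifier(RegressorMixin, BaseEstimator):
    """Shared online-training plumbing for the recurrent identifiers."""

    _architecture: str  # set by subclasses

    def __init__(
        self,
        n_hidden: int = 5,
        algorithm: str = "fo",
        alpha: float = 1.0,
        h: float = 1.0,
        eta_input: float = 0.1,
        eta_hidden: float = 0.1,
        eta_output: float = 0.1,
        memory_length: int = 50,
        epochs: int = 1,
        rate_mode: str = "fixed",
        eta_cap: float = 1.0,
        random_state: int = 0,
    ):
        self.n_hidden = n_hidden
        self.algorithm = algorithm
        self.alpha = alpha
        self.h = h
        self.eta_input = eta_input
        self.eta_hidden = eta_hidden
        self.eta_output = eta_output
        self.memory_length = memory_length
        self.epochs = epochs
        self.rate_mode = rate_mode
        self.eta_cap = eta_cap
        self.random_state = random_state

    # -- internal -----------------------------------------------------------
    def _config(self) -> TrainingConfig:
        return TrainingConfig(
            alpha=self.alpha,
            h=self.h,
            eta_input=self.eta_input,
            eta_hidden=self.eta_hidden,
            eta_output=self.eta_output,
            memory_length=self.memory_length,
            epochs=self.epochs,
            seed=self.random_state,
            rate_mode=self.rate_mode,
            eta_cap=self.eta_cap,
        )

    def _init_weights(self, n_inputs: int):
        rng = np.random.default_rng(self.random_state)
        return networks.initialize_weights(
            self._architecture, self.n_hidden, n_inputs, rng
        )

    @staticmethod
    def _validate(X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D array of lagged-state rows")
        if not np.all(np.isfinite(X)):
            raise ValueError("X must be finite")
        if y is None:
            return X
        y = np.asarray(y, dtype=float).ravel()
        if len(y) != len(X):
            raise ValueError("X and y length mismatch")
        if not np.all(np.isfinite(y)):
            raise ValueError("y must be finite")
        return X, y

    # -- sklearn API --------------------------------------------------------
    def fit(self, X, y):
        """Online training over (X, y) in row order."""
        X, y = self._validate(X, y)
        dataset = RegressionDataset(
            inputs=X, targets=y, split_index=len(y)
        ) if X.shape[1] == 6 else None
        if dataset is None:
            raise ValueError("identifiers expect the 6-lag input layout")
        self.n_features_in_ = X.shape[1]
        weights = self._init_weights(X.shape[1])
        weights, trace = train_online(dataset, weights, self._config(), self.algorithm)
        self.weights_ = weights
        self.rmse_trace_ = np.asarray(trace)
        return self

    def predict(self, X):
        """Sequential one-step predictions (recurrent state starts at zero)."""
        check_is_fitted(self, "weights_")
        X = self._validate(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("X has a different number of features than at fit time")
        return networks.predict_series(self.weights_, X, reset_state=True)


class FRNNRegressor(_BaseIdentifier):
    """Fully recurrent identifier (dense recurrence, tanh hidden units).

    With ``algorithm='fo'`` the weights follow the Grünwald–Letnikov
    fractional-order update of order ``alpha``; ``algorithm='gd'`` is the
    plain gradient-descent baseline.
    """

    _architecture = "frnn"


class DRNNRegressor(_BaseIdentifier):
    """Diagonal recurrent identifier (self-feedback only)."""

    _architecture = "drnn"


class DFNNRegressor(_BaseIdentifier):
    """Feedforward baseline (sigmoid hidden layer with biases, linear output).

    Trained by plain online backpropagation; the fractional-order algorithm
    is not defined for this baseline.
    """

    _architecture = "dfnn"

    def __init__(
        self,
        n_hidden: int = 28,
        eta_input: float = 0.01,
        eta_hidden: float = 0.01,
        eta_output: float = 0.01,
        epochs: int = 1,
        rate_mode: str = "fixed",
        eta_cap: float = 1.0,
        random_state: int = 0,
    ):
        super().__init__(
            n_hidden=n_hidden,
            algorithm="gd",
            eta_input=eta_input,
            eta_hidden=eta_hidden,
            eta_output=eta_output,
            epochs=epochs,
            rate_mode=rate_mode,
            eta_cap=eta_cap,
            random_state=random_state,
        )
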