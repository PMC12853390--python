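"""LSTM deviation forecaster with a TEa-referenced red-alert rule.

From the last 100 accepted patient results the model predicts the mean
deviation of the next 10 results from the analyte target.  A red alert is
raised when the predicted deviation strictly exceeds 50% of the total
allowable error (TEa), giving QC staff lead time before conventional
control rules are breached.

Inputs and targets are standardized by the analyte target mean/SD; the
model is a single-layer 64-unit tanh LSTM with a linear head trained on
mean absolute error, seeded for exact reproducibility.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from datetime import datetime
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from ._lstm import LSTMNet, train_mae
from .core import AnalyteSpec, LSTMConfig


@dataclass
class Forecast:
    """One forecast: predicted deviation, its TEa fraction, alert flag."""

    predicted_deviation: float       # analyte units, vs target mean
    deviation_fraction_tea: float
    red_alert: bool
    issued_at: Optional[datetime] = None


def build_windows(series: Sequence[float], spec: AnalyteSpec,
                  config: Optional[LSTMConfig] = None):
    """Supervised pairs from an accepted-value series.

    Inputs are stride-1 windows of ``input_len`` values standardized by the
    analyte target mean/SD; the target is the standardized mean deviation
    of the following ``horizon`` values from the target mean.

    Returns ``(X, y)`` with X of shape (n_pairs, input_len), float32.
    """
    config = config or LSTMConfig()
    arr = np.asarray(series, dtype=np.float64)
    need = config.input_len + config.horizon
    if arr.size < need:
        raise ValueError(
            f"series length {arr.size} < input_len + horizon = {need}")
    z = (arr - spec.target_mean) / spec.target_sd
    n_pairs = arr.size - need + 1
    idx = np.arange(config.input_len)[None, :] + np.arange(n_pairs)[:, None]
    X = z[idx].astype(np.float32)
    tgt_idx = (np.arange(config.horizon)[None, :]
               + np.arange(n_pairs)[:, None] + config.input_len)
    y = z[tgt_idx].mean(axis=1).astype(np.float32)
    return X, y


class LSTMForecaster(RegressorMixin, BaseEstimator):
    """Sklearn-style regressor predicting the standardized mean deviation
    of the next ``horizon`` samples from an ``input_len`` window.

    ``fit`` splits the pairs 8:2 (seeded shuffle) into train/validation,
    optionally runs k-fold cross-validation inside the training portion
    (``fold_maes_``), then trains on the full training portion with early
    stopping monitored on the held-out validation MAE
    (``validation_mae_``).
    """

    def __init__(self, input_len: int = 100, horizon: int = 10,
                 hidden_units: int = 64, activation: str = "tanh",
                 split_ratio: float = 0.8, cv_folds: int = 5,
                 warn_fraction_of_tea: float = 0.5, max_epochs: int = 200,
                 patience: int = 10, learning_rate: float = 3e-3,
                 batch_size: int = 128, seed: int = 0):
        self.input_len = input_len
        self.horizon = horizon
        self.hidden_units = hidden_units
        self.activation = activation
        self.split_ratio = split_ratio
        self.cv_folds = cv_folds
        self.warn_fraction_of_tea = warn_fraction_of_tea
        self.max_epochs = max_epochs
        self.patience = patience
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.seed = seed

    # ------------------------------------------------------------------
    def _train_one(self, Xtr, ytr, Xva, yva, seed):
        net = LSTMNet(self.hidden_units, seed=seed)
        val, history = train_mae(
            net, Xtr, ytr, Xva, yva, max_epochs=self.max_epochs,
            patience=self.patience, lr=self.learning_rate,
            batch_size=self.batch_size, seed=seed + 1)
        return net, val, history

    def fit(self, X, y):
        if self.activation != "tanh":
            raise ValueError("only tanh cell activation is supported")
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=np.float32)
        if X.ndim != 2 or X.shape[1] != self.input_len:
            raise ValueError(f"X must be (n, {self.input_len})")
        n = X.shape[0]
        min_pairs = max(self.cv_folds, 1) * 10
        if n < min_pairs:
            raise ValueError(f"need at least {min_pairs} pairs, got {n}")
        rng = np.random.default_rng(self.seed)
        order = rng.permutation(n)
        n_train = max(1, int(round(self.split_ratio * n)))
        tr_idx, va_idx = order[:n_train], order[n_train:]
        if va_idx.size == 0:
            raise ValueError("validation split is empty")
        Xtr, ytr = X[tr_idx], y[tr_idx]
        Xva, yva = X[va_idx], y[va_idx]

        # k-fold CV inside the training portion (model-selection report)
        self.fold_maes_ = []
        if self.cv_folds and self.cv_folds > 1:
            folds = np.array_split(np.arange(n_train), self.cv_folds)
            for k, fold in enumerate(folds):
                mask = np.ones(n_train, dtype=bool)
                mask[fold] = False
                _, fold_mae, _ = self._train_one(
                    Xtr[mask], ytr[mask], Xtr[~mask], ytr[~mask],
                    seed=self.seed + 100 + k)
                self.fold_maes_.append(fold_mae)

        net, val_mae, history = self._train_one(Xtr, ytr, Xva, yva,
                                                seed=self.seed)
        self.net_ = net
        self.validation_mae_ = val_mae
        self.history_ = history
        self.n_features_in_ = self.input_len
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 2 or X.shape[1] != self.input_len:
            raise ValueError(f"X must be (n, {self.input_len})")
        return np.asarray(self.net_.forward(X), dtype=float)

    # ------------------------------------------------------------------
    def save(self, path) -> None:
        """Serialize weights + hyper-parameters (text .npz sidecar-free)."""
        w = self.net_.get_weights()
        payload = {
            "params": self.get_params(),
            "validation_mae": self.validation_mae_,
            "fold_maes": self.fold_maes_,
            "weights": [np.asarray(x).tolist() for x in w],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "LSTMForecaster":
        with open(path) as fh:
            payload = json.load(fh)
        est = cls(**payload["params"])
        est.net_ = LSTMNet(est.hidden_units, seed=est.seed)
        est.net_.set_weights([np.asarray(w, dtype=np.float32)
                              for w in payload["weights"]])
        est.validation_mae_ = payload["validation_mae"]
        est.fold_maes_ = payload["fold_maes"]
        est.n_features_in_ = est.input_len
        return est


def _estimator_from_config(config: LSTMConfig) -> LSTMForecaster:
    return LSTMForecaster(
        input_len=config.input_len, horizon=config.horizon,
        hidden_units=config.hidden_units, activation=config.activation,
        split_ratio=config.split_ratio, cv_folds=config.cv_folds,
        warn_fraction_of_tea=config.warn_fraction_of_tea,
        max_epochs=config.max_epochs, patience=config.patience,
        learning_rate=config.learning_rate, batch_size=config.batch_size,
        seed=config.seed)


def train_forecaster(pairs, config: Optional[LSTMConfig] = None):
    """Train on (X, y) pairs; returns (model, validation MAE, fold MAEs)."""
    config = config or LSTMConfig()
    config.validate()
    X, y = pairs
    est = _estimator_from_config(config).fit(X, y)
    return est, est.validation_mae_, list(est.fold_maes_)


def predict_and_warn(model: LSTMForecaster, last_window: Sequence[float],
                     spec: AnalyteSpec, config: Optional[LSTMConfig] = None,
                     issued_at: Optional[datetime] = None) -> Forecast:
    """Forecast from the latest raw-value window and apply the alert rule.

    The red alert fires when the predicted deviation strictly exceeds
    ``warn_fraction_of_tea`` of TEa (an exact 50%-of-TEa prediction does
    not alert).
    """
    config = config or LSTMConfig()
    arr = np.asarray(last_window, dtype=np.float64)
    if arr.size != config.input_len:
        raise ValueError(
            f"window length {arr.size} != input_len {config.input_len}")
    z = ((arr - spec.target_mean) / spec.target_sd).astype(np.float32)
    pred_std = float(model.predict(z[None, :])[0])
    deviation = pred_std * spec.target_sd
    fraction = deviation / spec.tea_units
    red = abs(fraction) > config.warn_fraction_of_tea
    return Forecast(predicted_deviation=deviation,
                    deviation_fraction_tea=fraction,
                    red_alert=red, issued_at=issued_at)
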