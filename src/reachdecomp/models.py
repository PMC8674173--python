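"""Gaussian-process estimation of clinical severity from feature vectors.

`GPSeverityRegressor` and `GPGroupClassifier` are scikit-learn
estimators (fit/predict, ``get_params``/``set_params``, fitted
attributes with trailing underscores) wrapping an RBF-kernel Gaussian
process with the preprocessing the evaluation protocol requires:
features min-max scaled to the training fold's [0, 1] range and
regression labels z-scored on the training fold. ``loso_regress`` /
``loso_classify`` drive them through leave-one-subject-out cross
validation, grouping all visits of a participant in one fold and
optionally excluding pediatric participants from training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.gaussian_process import GaussianProcessClassifier, GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from sklearn.preprocessing import MinMaxScaler
from sklearn.utils.validation import check_is_fitted, validate_data


@dataclass
class ModelConfig:
    length_scale: float = 1.0
    length_scale_bounds: tuple[float, float] = (1e-2, 1e3)
    noise_level: float = 0.1
    n_restarts: int = 5
    random_seed: int = 0
    exclude_pediatric_from_training: bool = True


class GPSeverityRegressor(RegressorMixin, BaseEstimator):
    """RBF-kernel GP regression with fold-local feature/label scaling.

    Features are min-max scaled to the training range (test values are
    not clipped); labels are z-scored on the training data and
    predictions transformed back to the clinical scale. If the training
    labels have zero variance the model predicts that constant.
    """

    def __init__(
        self,
        length_scale: float = 1.0,
        length_scale_bounds: tuple[float, float] = (1e-2, 1e3),
        noise_level: float = 0.1,
        n_restarts: int = 5,
        random_seed: int = 0,
    ):
        self.length_scale = length_scale
        self.length_scale_bounds = length_scale_bounds
        self.noise_level = noise_level
        self.n_restarts = n_restarts
        self.random_seed = random_seed

    def _kernel(self):
        return ConstantKernel(1.0, (1e-3, 1e3)) * RBF(
            self.length_scale, self.length_scale_bounds
        ) + WhiteKernel(self.noise_level, (1e-7, 1e2))

    def fit(self, X, y):
        X, y = validate_data(self, X, y, y_numeric=True)
        if X.shape[0] < 2:
            raise ValueError(
                f"n_samples={X.shape[0]}: need at least two training samples"
            )
        self.scaler_ = MinMaxScaler().fit(X)
        xs = self.scaler_.transform(X)
        self.y_mean_ = float(np.mean(y))
        self.y_std_ = float(np.std(y))
        if self.y_std_ == 0.0:
            self.gp_ = None
            return self
        ys = (y - self.y_mean_) / self.y_std_
        with warnings.catch_warnings():
            # hyperparameters pinned at a bound are acceptable here
            warnings.simplefilter("ignore", ConvergenceWarning)
            self.gp_ = GaussianProcessRegressor(
                kernel=self._kernel(),
                n_restarts_optimizer=self.n_restarts,
                normalize_y=False,
                random_state=self.random_seed,
            ).fit(xs, ys)
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        if self.gp_ is None:
            return np.full(X.shape[0], self.y_mean_)
        ys = self.gp_.predict(self.scaler_.transform(X))
        return ys * self.y_std_ + self.y_mean_


class GPGroupClassifier(ClassifierMixin, BaseEstimator):
    """RBF-kernel GP classifier with fold-local min-max feature scaling."""

    def __init__(
        self,
        length_scale: float = 1.0,
        length_scale_bounds: tuple[float, float] = (1e-2, 1e3),
        n_restarts: int = 5,
        random_seed: int = 0,
    ):
        self.length_scale = length_scale
        self.length_scale_bounds = length_scale_bounds
        self.n_restarts = n_restarts
        self.random_seed = random_seed

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("binary classification only")
        self.scaler_ = MinMaxScaler().fit(X)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            self.gp_ = GaussianProcessClassifier(
                kernel=RBF(self.length_scale, self.length_scale_bounds),
                n_restarts_optimizer=self.n_restarts,
                random_state=self.random_seed,
            ).fit(self.scaler_.transform(X), y)
        return self

    def predict_proba(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return self.gp_.predict_proba(self.scaler_.transform(X))

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]


@dataclass
class EstimateSet:
    """LOSO estimates plus per-fold fitted artifacts for leakage audits."""

    estimates: pd.DataFrame  # index as input rows; columns estimate, fold
    fold_artifacts: dict = field(repr=False, default_factory=dict)


def _fold_iter(participants: np.ndarray):
    for pid in pd.unique(participants):
        test = participants == pid
        yield pid, ~test, test


def _training_mask(train: np.ndarray, pediatric, exclude_pediatric: bool):
    if exclude_pediatric and pediatric is not None:
        return train & ~np.asarray(pediatric, dtype=bool)
    return train


def loso_regress(
    X,
    y,
    participants,
    pediatric=None,
    config: ModelConfig | None = None,
) -> EstimateSet:
    """Leave-one-subject-out GP regression.

    All visits of the held-out participant are predicted by a model fit
    on the remaining participants only. Returns clinical-scale
    estimates and, per fold, the fitted scaler/label transforms and
    kernel hyperparameters (for no-leakage audits).
    """
    config = config or ModelConfig()
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    participants = np.asarray(participants)
    if len(pd.unique(participants)) < 3:
        raise ValueError("need at least 3 participants for LOSO")

    est = np.full(len(y), np.nan)
    artifacts = {}
    for pid, train, test in _fold_iter(participants):
        tr = _training_mask(train, pediatric, config.exclude_pediatric_from_training)
        if tr.sum() < 2:
            raise ValueError(f"fold {pid!r}: empty or degenerate training set")
        model = GPSeverityRegressor(
            length_scale=config.length_scale,
            length_scale_bounds=config.length_scale_bounds,
            noise_level=config.noise_level,
            n_restarts=config.n_restarts,
            random_seed=config.random_seed,
        ).fit(X.values[tr], y[tr])
        est[test] = model.predict(X.values[test])
        artifacts[pid] = dict(
            x_min=model.scaler_.data_min_.copy(),
            x_max=model.scaler_.data_max_.copy(),
            y_mean=model.y_mean_,
            y_std=model.y_std_,
            kernel_theta=None if model.gp_ is None else model.gp_.kernel_.theta.copy(),
        )
    frame = pd.DataFrame(
        {"participant_id": participants, "label": y, "estimate": est}, index=X.index
    )
    return EstimateSet(estimates=frame, fold_artifacts=artifacts)


def loso_classify(
    X,
    y,
    participants,
    pediatric=None,
    config: ModelConfig | None = None,
    positive_class=None,
) -> EstimateSet:
    """Leave-one-subject-out GP classification; estimates are P(positive)."""
    config = config or ModelConfig()
    X = pd.DataFrame(X)
    y = np.asarray(y)
    participants = np.asarray(participants)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("binary labels required")
    if positive_class is None:
        positive_class = classes[-1]

    proba = np.full(len(y), np.nan)
    artifacts = {}
    for pid, train, test in _fold_iter(participants):
        tr = _training_mask(train, pediatric, config.exclude_pediatric_from_training)
        if len(np.unique(y[tr])) < 2:
            raise ValueError(f"fold {pid!r}: single-class training set")
        model = GPGroupClassifier(
            length_scale=config.length_scale,
            length_scale_bounds=config.length_scale_bounds,
            n_restarts=config.n_restarts,
            random_seed=config.random_seed,
        ).fit(X.values[tr], y[tr])
        col = int(np.where(model.classes_ == positive_class)[0][0])
        proba[test] = model.predict_proba(X.values[test])[:, col]
        artifacts[pid] = dict(
            x_min=model.scaler_.data_min_.copy(),
            x_max=model.scaler_.data_max_.copy(),
            kernel_theta=model.gp_.kernel_.theta.copy(),
        )
    frame = pd.DataFrame(
        {"participant_id": participants, "label": y, "estimate": proba}, index=X.index
    )
    return EstimateSet(estimates=frame, fold_artifacts=artifacts)


def upper_limb_regress(
    X, y_upper_limb, participants, pediatric=None, config: ModelConfig | None = None
) -> EstimateSet:
    """Identical machinery on the summed upper-limb score scale (0-8)."""
    return loso_regress(X, y_upper_limb, participants, pediatric, config)
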