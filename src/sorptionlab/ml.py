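"""Machine-learning regressors for equilibrium moisture content.

Four techniques predict ``xe`` from the feature row
``(aw, temperature_c, d1, d2)`` where ``d1`` indicates the semidry method
and ``d2`` the adsorption branch (documented column order):

* RT  -- regression tree with cost-complexity post-pruning selected by a
  cross-validated standard-error rule (multiplier 0.1 by default),
* RF  -- random forest with 100 trees,
* KNN -- k-nearest neighbors with k = 4,
* SVM -- nu-support-vector regression with a Laplacian kernel and C = 500.5.

Distance/kernel methods (KNN, SVM) standardize ``aw`` and temperature to
zero mean / unit variance by default; indicator columns stay 0/1; trees are
unscaled.  Scaling can be disabled in :class:`MLConfig`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics.pairwise import laplacian_kernel
from sklearn.model_selection import KFold
from sklearn.neighbors import KNeighborsRegressor
from sklearn.svm import NuSVR
from sklearn.tree import DecisionTreeRegressor

from .errors import SchemaError
from .synthetic import BRANCHES, METHODS, IsothermDataset

__all__ = [
    "FEATURE_COLUMNS",
    "MLConfig",
    "MLRegressor",
    "encode_features",
    "train_rt",
    "train_rf",
    "train_knn",
    "train_svm",
    "train_ml",
    "predict",
]

#: Documented feature column order used at train and predict time.
FEATURE_COLUMNS = ("aw", "temperature_c", "d1", "d2")


@dataclass(frozen=True)
class MLConfig:
    """Hyperparameters for the four regressors (defaults as used throughout)."""

    rt_se: float = 0.1
    rf_trees: int = 100
    knn_k: int = 4
    svm_kernel: str = "laplacian"
    svm_type: str = "nu-regression"
    svm_c: float = 500.5
    svm_nu: float = 0.5
    svm_sigma: float | str = "heuristic"
    scale_features: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.rf_trees < 1 or self.knn_k < 1:
            raise SchemaError("rf_trees and knn_k must be >= 1")
        if self.svm_kernel != "laplacian" or self.svm_type != "nu-regression":
            raise SchemaError("only the laplacian-kernel nu-regression SVM is supported")
        if not 0 < self.svm_nu <= 1:
            raise SchemaError("svm_nu must lie in (0, 1]")


def encode_features(data) -> np.ndarray:
    """Encode records into the (aw, temperature_c, d1, d2) design matrix.

    Accepts an :class:`IsothermDataset`, a DataFrame with either raw
    ``method``/``branch`` labels or pre-encoded ``d1``/``d2`` columns, or an
    ndarray already in feature order.
    """
    if isinstance(data, IsothermDataset):
        data = data.frame
    if isinstance(data, np.ndarray):
        arr = np.asarray(data, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 4:
            raise SchemaError("feature array must have shape (n, 4)")
        return arr
    if not isinstance(data, pd.DataFrame):
        raise SchemaError(f"cannot encode features from {type(data).__name__}")
    for col in ("aw", "temperature_c"):
        if col not in data.columns:
            raise SchemaError(f"missing feature column {col!r}")
    if "d1" in data.columns and "d2" in data.columns:
        d1 = data["d1"].to_numpy(float)
        d2 = data["d2"].to_numpy(float)
    else:
        for col in ("method", "branch"):
            if col not in data.columns:
                raise SchemaError(f"missing feature column {col!r}")
        bad = set(data["method"]) - set(METHODS)
        if bad:
            raise SchemaError(f"unknown method level(s): {sorted(bad)}")
        bad = set(data["branch"]) - set(BRANCHES)
        if bad:
            raise SchemaError(f"unknown branch level(s): {sorted(bad)}")
        d1 = (data["method"].to_numpy() == "semidry").astype(float)
        d2 = (data["branch"].to_numpy() == "adsorption").astype(float)
    return np.column_stack([
        data["aw"].to_numpy(float),
        data["temperature_c"].to_numpy(float),
        d1,
        d2,
    ])


class MLRegressor:
    """A trained predictor mapping feature rows to ``xe``.

    Holds the fitted estimator together with the feature scaling state and
    the config/seed it was trained with, so persisted models are
    reproducible.
    """

    def __init__(self, kind: str, config: MLConfig, estimator,
                 center: np.ndarray, scale: np.ndarray, x_train=None):
        self.kind = kind
        self.config = config
        self.estimator = estimator
        self.center = center
        self.scale = scale
        self._x_train = x_train  # scaled training matrix (SVM callable kernel)

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (x - self.center) / self.scale

    def predict(self, rows) -> np.ndarray:
        x = self.transform(encode_features(rows))
        return np.asarray(self.estimator.predict(x), dtype=float)


def _scaling(x: np.ndarray, config: MLConfig, scaled_cols=(0, 1)):
    """Standardization of continuous columns; indicators left untouched."""
    center = np.zeros(x.shape[1])
    scale = np.ones(x.shape[1])
    if config.scale_features:
        for j in scaled_cols:
            sd = x[:, j].std()
            center[j] = x[:, j].mean()
            scale[j] = sd if sd > 0 else 1.0  # constant feature: mean-centered only
    return center, scale


def _train_matrix(dataset):
    if isinstance(dataset, IsothermDataset):
        x = encode_features(dataset)
        y = dataset.frame["xe"].to_numpy(float)
    else:
        x, y = dataset
        x = encode_features(x)
        y = np.asarray(y, dtype=float)
    if len(y) == 0:
        raise SchemaError("empty training set")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise SchemaError("non-finite values in training data")
    return x, y


def train_rt(dataset, config: MLConfig = MLConfig()) -> MLRegressor:
    """Regression tree with cross-validated cost-complexity post-pruning.

    The pruning level is the largest complexity parameter whose CV error is
    within ``rt_se`` standard errors of the CV minimum (an SE-rule scaled to
    the configured multiplier).
    """
    x, y = _train_matrix(dataset)
    full = DecisionTreeRegressor(random_state=config.seed)
    path = full.cost_complexity_pruning_path(x, y)
    alphas = np.unique(np.maximum(path.ccp_alphas, 0.0))
    if len(alphas) > 50:  # cap the CV grid; keeps endpoints
        alphas = alphas[np.unique(np.linspace(0, len(alphas) - 1, 50).astype(int))]
    if len(alphas) > 1 and len(y) >= 4:
        n_folds = min(10, len(y))
        kf = KFold(n_splits=n_folds, shuffle=True, random_state=config.seed)
        cv_err = np.zeros((len(alphas), n_folds))
        for f, (tr, te) in enumerate(kf.split(x)):
            for i, a in enumerate(alphas):
                t = DecisionTreeRegressor(random_state=config.seed, ccp_alpha=a)
                t.fit(x[tr], y[tr])
                cv_err[i, f] = np.mean((y[te] - t.predict(x[te])) ** 2)
        mean_err = cv_err.mean(axis=1)
        se_err = cv_err.std(axis=1, ddof=1) / np.sqrt(n_folds)
        best = int(np.argmin(mean_err))
        threshold = mean_err[best] + config.rt_se * se_err[best]
        chosen = alphas[np.max(np.flatnonzero(mean_err <= threshold))]
    else:
        chosen = 0.0
    tree = DecisionTreeRegressor(random_state=config.seed, ccp_alpha=float(chosen))
    center, scale = np.zeros(x.shape[1]), np.ones(x.shape[1])  # trees unscaled
    tree.fit(x, y)
    return MLRegressor("RT", config, tree, center, scale)


def train_rf(dataset, config: MLConfig = MLConfig()) -> MLRegressor:
    """Random forest regressor (default 100 trees), seeded reproducibly."""
    x, y = _train_matrix(dataset)
    rf = RandomForestRegressor(n_estimators=config.rf_trees, random_state=config.seed)
    rf.fit(x, y)
    center, scale = np.zeros(x.shape[1]), np.ones(x.shape[1])
    return MLRegressor("RF", config, rf, center, scale)


def train_knn(dataset, config: MLConfig = MLConfig()) -> MLRegressor:
    """k-nearest-neighbor regressor (default k = 4, Euclidean on scaled features)."""
    x, y = _train_matrix(dataset)
    if config.knn_k > len(y):
        raise SchemaError(
            f"knn_k={config.knn_k} exceeds the training size {len(y)}"
        )
    center, scale = _scaling(x, config)
    knn = KNeighborsRegressor(n_neighbors=config.knn_k)
    knn.fit((x - center) / scale, y)
    return MLRegressor("KNN", config, knn, center, scale)


def _laplacian_gamma(x_scaled: np.ndarray, config: MLConfig) -> float:
    if config.svm_sigma != "heuristic":
        sigma = float(config.svm_sigma)
        if sigma <= 0:
            raise SchemaError("svm_sigma must be positive")
        return 1.0 / sigma
    # median pairwise L1 distance heuristic (subsampled for large n)
    n = len(x_scaled)
    idx = np.arange(n) if n <= 400 else np.random.default_rng(config.seed).choice(n, 400, replace=False)
    sub = x_scaled[idx]
    dists = np.abs(sub[:, None, :] - sub[None, :, :]).sum(axis=2)
    med = np.median(dists[np.triu_indices(len(sub), k=1)]) if len(sub) > 1 else 0.0
    return 1.0 / med if med > 0 else 1.0


def train_svm(dataset, config: MLConfig = MLConfig()) -> MLRegressor:
    """nu-SVR with Laplacian kernel ``exp(-gamma * ||x - x'||_1)`` and C = 500.5."""
    x, y = _train_matrix(dataset)
    center, scale = _scaling(x, config)
    xs = (x - center) / scale
    gamma = _laplacian_gamma(xs, config)

    def kernel(a, b):
        return laplacian_kernel(a, b, gamma=gamma)

    # the libsvm solver can stall for many minutes at large C on noisy data;
    # the iteration cap bounds runtime at no practical accuracy cost
    svr = NuSVR(kernel=kernel, C=config.svm_c, nu=config.svm_nu,
                max_iter=200_000, cache_size=500)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        svr.fit(xs, y)
    reg = MLRegressor("SVM", config, svr, center, scale, x_train=xs)
    reg.gamma = gamma
    return reg


_TRAINERS = {"RT": train_rt, "RF": train_rf, "KNN": train_knn, "SVM": train_svm}
ML_NAMES = tuple(_TRAINERS)


def train_ml(kind: str, dataset, config: MLConfig = MLConfig()) -> MLRegressor:
    """Dispatch to one of the four trainers by name (RT, RF, KNN, SVM)."""
    if kind not in _TRAINERS:
        raise SchemaError(f"unknown ML model {kind!r}; valid: {ML_NAMES}")
    return _TRAINERS[kind](dataset, config)


def predict(regressor: MLRegressor, rows) -> np.ndarray:
    """Order-aligned predictions for encoded or raw feature rows."""
    out = regressor.predict(rows)
    if not np.all(np.isfinite(out)):
        raise SchemaError("regressor produced non-finite predictions")
    return out
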