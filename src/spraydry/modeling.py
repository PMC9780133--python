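"""Regression zoo, leave-one-API-out cross-validation and the averaging ensemble.

The zoo spans the families routinely benchmarked on formulation/process
tables: PLS, regularized linear models, kernel methods (SVR, kernel ridge
with RBF kernels), tree ensembles and a multilayer perceptron. Defaults are
the optimized hyperparameters found for this problem class (e.g. PLS with 8
components; SVR with C=79.91, epsilon=0.035).

Cross-validation is leave-one-API-out: for each fold the *entire* encoder —
including the nozzle target encoding, which is a function of D50 — is refit
on the fold's fit rows only, so held-out targets can never leak into
held-out features. Fold scores are RMSEs in microns; the CV score is their
unweighted mean over APIs.

The ensemble averages member predictions with no additional fitting.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.kernel_ridge import KernelRidge
from sklearn.linear_model import ElasticNet, Lasso, Ridge
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR
from sklearn.utils.validation import check_is_fitted

from .encoding import SprayFeatureEncoder
from .splitting import logo_folds

__all__ = [
    "ModelSpec",
    "CVResult",
    "FAMILIES",
    "rmse",
    "make_model",
    "train_final",
    "cv_score",
    "EnsembleRegressor",
    "make_ensemble",
]

# Hyperparameter bound kinds: ("int", lo, hi) | ("float", lo, hi) | ("log", lo, hi).
DEFAULT_BOUNDS: dict[str, dict[str, tuple]] = {
    "pls": {"n_components": ("int", 1, 12)},
    "ridge": {"alpha": ("log", 1e-3, 1e2)},
    "lasso": {"alpha": ("log", 1e-4, 1.0)},
    "elastic_net": {"alpha": ("log", 1e-4, 1.0), "l1_ratio": ("float", 0.05, 0.95)},
    "svr": {"C": ("log", 0.1, 1e3), "epsilon": ("log", 1e-3, 1.0)},
    "kernel_ridge": {"alpha": ("log", 1e-4, 10.0), "gamma": ("log", 1e-4, 10.0)},
    "random_forest": {"n_estimators": ("int", 50, 400), "max_depth": ("int", 2, 12)},
    "gbtree": {
        "n_estimators": ("int", 20, 300),
        "max_depth": ("int", 2, 8),
        "eta": ("log", 0.01, 0.5),
        "subsample": ("float", 0.4, 1.0),
        "colsample_bytree": ("float", 0.4, 1.0),
        "min_child_weight": ("log", 0.5, 20.0),
    },
    "neural_net": {
        "n_neurons_1": ("int", 5, 100),
        "n_neurons_2": ("int", 5, 100),
        "alpha": ("log", 1e-5, 1e-1),
    },
}

# Optimized defaults for this problem class.
DEFAULT_HYPERPARAMS: dict[str, dict] = {
    "pls": {"n_components": 8},
    "ridge": {"alpha": 0.78},
    "lasso": {"alpha": 0.027},
    "elastic_net": {"alpha": 0.05, "l1_ratio": 0.5},
    "svr": {"C": 79.91, "epsilon": 0.035},
    "kernel_ridge": {"alpha": 0.075, "gamma": 0.075},
    "random_forest": {"n_estimators": 200, "max_depth": 8},
    "gbtree": {
        "n_estimators": 92,
        "max_depth": 3,
        "eta": 0.1,
        "subsample": 0.58,
        "colsample_bytree": 0.79,
        "min_child_weight": 7.21,
    },
    "neural_net": {"n_neurons_1": 30, "n_neurons_2": 70, "alpha": 1e-4},
}

FAMILIES = tuple(DEFAULT_BOUNDS)


@dataclass
class ModelSpec:
    """One model family plus a concrete hyperparameter assignment."""

    family: str
    hyperparams: dict = field(default_factory=dict)
    bounds: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.family == "mars":
            raise NotImplementedError(
                "multivariate adaptive regression splines are not available in "
                "this build; choose another family"
            )
        if self.family not in DEFAULT_BOUNDS:
            raise ValueError(f"unknown model family {self.family!r}")
        self.bounds = self.bounds or dict(DEFAULT_BOUNDS[self.family])
        merged = dict(DEFAULT_HYPERPARAMS[self.family])
        merged.update(self.hyperparams)
        self.hyperparams = merged
        for name, value in self.hyperparams.items():
            if name in self.bounds:
                kind, lo, hi = self.bounds[name]
                if not lo <= value <= hi:
                    raise ValueError(
                        f"{self.family}.{name}={value} outside bounds [{lo}, {hi}]"
                    )

    def key(self) -> str:
        blob = json.dumps({"family": self.family, **self.hyperparams}, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


class _Ravel(BaseEstimator, RegressorMixin):
    """Flatten the (n, 1) predictions some sklearn regressors emit."""

    def __init__(self, inner):
        self.inner = inner

    def fit(self, X, y):
        self.model_ = clone(self.inner).fit(X, y)
        return self

    def predict(self, X):
        return np.asarray(self.model_.predict(X)).ravel()


def make_model(spec: ModelSpec, seed: int = 0):
    """Instantiate an unfitted sklearn-compatible regressor from a spec."""
    h = spec.hyperparams
    family = spec.family
    if family == "pls":
        return _Ravel(PLSRegression(n_components=int(h["n_components"])))
    if family == "ridge":
        return Ridge(alpha=h["alpha"])
    if family == "lasso":
        return Lasso(alpha=h["alpha"], max_iter=20000)
    if family == "elastic_net":
        return ElasticNet(alpha=h["alpha"], l1_ratio=h["l1_ratio"], max_iter=20000)
    if family == "svr":
        return SVR(kernel="rbf", C=h["C"], epsilon=h["epsilon"])
    if family == "kernel_ridge":
        return KernelRidge(kernel="rbf", alpha=h["alpha"], gamma=h["gamma"])
    if family == "random_forest":
        return RandomForestRegressor(
            n_estimators=int(h["n_estimators"]),
            max_depth=int(h["max_depth"]),
            random_state=seed,
        )
    if family == "gbtree":
        from xgboost import XGBRegressor  # heavyweight; imported on demand

        return XGBRegressor(
            n_estimators=int(h["n_estimators"]),
            max_depth=int(h["max_depth"]),
            learning_rate=h["eta"],
            subsample=h["subsample"],
            colsample_bytree=h["colsample_bytree"],
            min_child_weight=h["min_child_weight"],
            random_state=seed,
            verbosity=0,
        )
    if family == "neural_net":
        return MLPRegressor(
            hidden_layer_sizes=(int(h["n_neurons_1"]), int(h["n_neurons_2"])),
            alpha=h["alpha"],
            max_iter=2000,
            random_state=seed,
        )
    raise ValueError(f"unknown model family {family!r}")


def rmse(predicted, observed) -> float:
    """Root mean square error, microns."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError(f"length mismatch: {predicted.shape} vs {observed.shape}")
    if predicted.size == 0:
        raise ValueError("rmse needs at least one pair")
    return float(np.sqrt(np.mean((predicted - observed) ** 2)))


def train_final(spec: ModelSpec, X: pd.DataFrame, y, seed: int = 0):
    """Fit a model on the full (already encoded) training matrix."""
    X_arr = np.asarray(X, dtype=float)
    if not np.isfinite(X_arr).all():
        raise ValueError("feature matrix contains non-finite values")
    model = make_model(spec, seed=seed)
    return model.fit(X_arr, np.asarray(y, dtype=float))


@dataclass
class CVResult:
    per_group_rmse: dict[str, float]
    mean_rmse: float


def encode_folds(
    train: pd.DataFrame, encoder: SprayFeatureEncoder | None = None
) -> list[tuple[str, np.ndarray, np.ndarray, np.ndarray, np.ndarray]]:
    """Precompute per-fold encodings for LOGO-CV.

    For each fold the *entire* encoder (target encoding included) is refit
    on the fold's fit rows only; the held-out rows are then transformed with
    that fold's state, so held-out D50 values never touch held-out features.
    The result is reusable across model specs — encoding does not depend on
    the regressor being scored.
    """
    template = encoder if encoder is not None else SprayFeatureEncoder()
    folds = []
    for fit_idx, hold_idx in logo_folds(train):
        fit_rows, hold_rows = train.loc[fit_idx], train.loc[hold_idx]
        enc = clone(template).fit(fit_rows)
        folds.append(
            (
                str(hold_rows["api_id"].iloc[0]),
                np.asarray(enc.transform(fit_rows), dtype=float),
                fit_rows["d50"].to_numpy(dtype=float),
                np.asarray(enc.transform(hold_rows), dtype=float),
                hold_rows["d50"].to_numpy(dtype=float),
            )
        )
    return folds


def cv_score(
    spec: ModelSpec,
    train: pd.DataFrame | None = None,
    encoder: SprayFeatureEncoder | None = None,
    seed: int = 0,
    folds=None,
) -> CVResult:
    """Leave-one-API-out CV with a per-fold refit of the full encoder.

    ``encoder`` is an *unfitted* template (cloned per fold); defaults to the
    standard target-encoding + min-max stack. Pass precomputed ``folds``
    (from :func:`encode_folds`) when scoring many specs on the same data.
    """
    if folds is None:
        if train is None:
            raise ValueError("cv_score needs either train data or precomputed folds")
        folds = encode_folds(train, encoder)
    per_group: dict[str, float] = {}
    for api, X_fit, y_fit, X_hold, y_hold in folds:
        try:
            model = train_final(spec, X_fit, y_fit, seed=seed)
            pred = np.asarray(model.predict(X_hold))
        except Exception as exc:  # pragma: no cover - surfaced with fold context
            raise RuntimeError(f"model training failed in fold for API {api!r}: {exc}") from exc
        per_group[api] = rmse(pred.ravel(), y_hold)
    return CVResult(per_group, float(np.mean(list(per_group.values()))))


class EnsembleRegressor(BaseEstimator, RegressorMixin):
    """Prediction-averaging ensemble.

    ``members`` are unfitted sklearn regressors or ModelSpecs; ``fit`` trains
    each on the same matrix and ``predict`` returns the exact arithmetic mean
    of member predictions — there is no ensemble-level training step.
    """

    def __init__(self, members: list, seed: int = 0):
        self.members = members
        self.seed = seed

    def fit(self, X, y):
        if not self.members:
            raise ValueError("ensemble needs at least one member")
        X_arr = np.asarray(X, dtype=float)
        y_arr = np.asarray(y, dtype=float)
        self.members_ = []
        for member in self.members:
            if isinstance(member, ModelSpec):
                self.members_.append(train_final(member, X_arr, y_arr, seed=self.seed))
            else:
                self.members_.append(clone(member).fit(X_arr, y_arr))
        return self

    def predict(self, X):
        check_is_fitted(self, "members_")
        X_arr = np.asarray(X, dtype=float)
        preds = [np.asarray(m.predict(X_arr)).ravel() for m in self.members_]
        return np.mean(preds, axis=0)


def make_ensemble(members: list, encoder=None) -> EnsembleRegressor:
    """Wrap already-trained members; no additional fitting is performed."""
    if not members:
        raise ValueError("ensemble needs at least one member")
    ens = EnsembleRegressor(members=list(members))
    ens.members_ = list(members)
    ens.encoder_ = encoder
    return ens
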