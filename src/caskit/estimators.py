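"""Scikit-learn-style estimators over the three algorithm families.

The cassette models come in three flavours — a single decision tree (CART),
a Gaussian-kernel margin classifier (SVM with one-vs-rest decomposition for
multiclass), and an extremely randomized tree ensemble (ERT) — each with the
hyperparameter grid of exactly 20 combinations used for model selection:

==================== ============================== ==========================
algorithm            hyperparameter 1               hyperparameter 2
==================== ============================== ==========================
decision_tree        max_depth {5, 10, 15, max}     min_samples_leaf {5..9}
kernel_margin        C {1, 10, 100, 1000}           gamma {0.01, 0.1, 1, 10, 100}
randomized_ensemble  n_estimators {25, 50, 75, 100} max_features {25%, 50%, 75%, 100%, sqrt(m)}
==================== ============================== ==========================

Features are normalized bit scores in [0, 1], so no extra standardization is
applied before the kernel machine.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.ensemble import ExtraTreesClassifier, ExtraTreesRegressor
from sklearn.multiclass import OneVsRestClassifier
from sklearn.svm import SVC, SVR
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor
from sklearn.utils.validation import check_is_fitted, validate_data

ALGORITHMS = ("decision_tree", "kernel_margin", "randomized_ensemble")

_GRIDS = {
    "decision_tree": ("max_depth", [5, 10, 15, None],
                      "min_samples_leaf", [5, 6, 7, 8, 9]),
    "kernel_margin": ("C", [1, 10, 100, 1000],
                      "gamma", [0.01, 0.1, 1, 10, 100]),
    "randomized_ensemble": ("n_estimators", [25, 50, 75, 100],
                            "max_features", [0.25, 0.5, 0.75, 1.0, "sqrt"]),
}


def hyperparameter_grid(algorithm: str) -> list[dict]:
    """Full Cartesian grid for one algorithm, in documented order.

    ``max_depth=None`` encodes an unbounded tree; ``max_features="sqrt"`` is
    resolved from the matrix width at fit time.
    """
    if algorithm not in _GRIDS:
        raise KeyError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
    k1, v1, k2, v2 = _GRIDS[algorithm]
    return [{k1: a, k2: b} for a, b in product(v1, v2)]


class EstimatorSpec:
    """Algorithm + task + hyperparameters, the unit the CV machinery selects over."""

    def __init__(self, algorithm: str, task: str = "classification",
                 hyperparams: dict | None = None):
        if algorithm not in ALGORITHMS:
            raise KeyError(f"unknown algorithm {algorithm!r}")
        if task not in ("classification", "regression"):
            raise ValueError(f"unknown task {task!r}")
        hyperparams = dict(hyperparams or {})
        k1, _, k2, _ = _GRIDS[algorithm]
        unknown = set(hyperparams) - {k1, k2}
        if unknown:
            raise ValueError(f"hyperparameters {sorted(unknown)} not valid for {algorithm}")
        self.algorithm = algorithm
        self.task = task
        self.hyperparams = hyperparams

    def grid(self) -> list[dict]:
        return hyperparameter_grid(self.algorithm)

    def with_params(self, hyperparams: dict) -> "EstimatorSpec":
        return EstimatorSpec(self.algorithm, self.task, hyperparams)

    def make(self, random_state=None):
        est = (CassetteClassifier if self.task == "classification" else CasScoreRegressor)(
            algorithm=self.algorithm, random_state=random_state, **self.hyperparams)
        return est

    def __repr__(self) -> str:
        return f"EstimatorSpec({self.algorithm}, {self.task}, {self.hyperparams})"


def _build_backend(algorithm: str, task: str, params: dict, random_state):
    p = dict(params)
    if algorithm == "decision_tree":
        cls = DecisionTreeClassifier if task == "classification" else DecisionTreeRegressor
        return cls(random_state=random_state, **p)
    if algorithm == "kernel_margin":
        if task == "classification":
            return OneVsRestClassifier(SVC(kernel="rbf", random_state=random_state, **p))
        return SVR(kernel="rbf", **p)
    if algorithm == "randomized_ensemble":
        cls = ExtraTreesClassifier if task == "classification" else ExtraTreesRegressor
        return cls(random_state=random_state, n_jobs=1, **p)
    raise KeyError(f"unknown algorithm {algorithm!r}")


class _CassetteBase(BaseEstimator):
    _task = "classification"

    def __init__(self, algorithm="randomized_ensemble", max_depth=None,
                 min_samples_leaf=1, C=1.0, gamma="scale", n_estimators=100,
                 max_features="sqrt", random_state=None):
        self.algorithm = algorithm
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.C = C
        self.gamma = gamma
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.random_state = random_state

    def _backend_params(self) -> dict:
        if self.algorithm == "decision_tree":
            return {"max_depth": self.max_depth,
                    "min_samples_leaf": self.min_samples_leaf}
        if self.algorithm == "kernel_margin":
            return {"C": self.C, "gamma": self.gamma}
        if self.algorithm == "randomized_ensemble":
            return {"n_estimators": self.n_estimators,
                    "max_features": self.max_features}
        raise KeyError(f"unknown algorithm {self.algorithm!r}")

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 training rows")
        self.model_ = _build_backend(self.algorithm, self._task,
                                     self._backend_params(), self.random_state)
        self.model_.fit(X, y)
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        X = validate_data(self, X, reset=False)
        return self.model_.predict(X)


class CassetteClassifier(ClassifierMixin, _CassetteBase):
    """Subtype classifier over normalized bit-score features.

    Parameters mirror the three algorithm grids; only the parameters of the
    chosen ``algorithm`` are consulted.  ``feature_importances_`` is exposed
    for tree-based backends after fitting.
    """

    _task = "classification"

    def fit(self, X, y):
        y = np.asarray(y)
        if np.unique(y).size < 2:
            raise ValueError("classification requires >= 2 classes in y")
        super().fit(X, y)
        self.classes_ = np.unique(y)
        return self

    @property
    def feature_importances_(self):
        check_is_fitted(self, "model_")
        if not hasattr(self.model_, "feature_importances_"):
            raise AttributeError(f"{self.algorithm} exposes no impurity importances")
        return self.model_.feature_importances_


class CasScoreRegressor(RegressorMixin, _CassetteBase):
    """Normalized-bit-score regressor (one target family from the others)."""

    _task = "regression"

    @property
    def feature_importances_(self):
        check_is_fitted(self, "model_")
        if not hasattr(self.model_, "feature_importances_"):
            raise AttributeError(f"{self.algorithm} exposes no impurity importances")
        return self.model_.feature_importances_
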