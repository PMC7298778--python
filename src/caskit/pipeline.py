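"""Nested cross-validation protocol, fold-aggregated scoring, signature proteins.

Model selection and model evaluation are separated into two loops: the outer
loop splits the data into K1 stratified folds for evaluation; within each
outer training set an inner K2-fold grid search picks the hyperparameters
with the best fold-aggregated inner metric, the winning configuration is
refit on the whole outer training set, and the outer-test predictions of all
folds are aggregated into a single prediction vector before the metric is
computed — one value per repetition, so imbalanced subtypes are never
averaged away fold-by-fold.  The whole procedure is repeated R times with
fresh splits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .estimators import EstimatorSpec
from .features import FeatureMatrix
from .metrics import binary_f_score, get_metric


@dataclass
class CVConfig:
    """Nested cross-validation protocol parameters (defaults: K1 = K2 = 10, R = 50)."""

    outer_folds: int = 10
    inner_folds: int = 10
    repetitions: int = 50
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("K1 and K2 must both be >= 2")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


@dataclass
class EvaluationReport:
    """Per-repetition fold-aggregated scores and the selected hyperparameters."""

    metric_name: str
    scores: list[float]
    selected_params: list[list[dict]]      # [repetition][outer fold]
    predictions: list[pd.Series]           # aggregated outer-test predictions
    seeds: list[int]
    config: CVConfig = field(default_factory=CVConfig)
    algorithm: str = ""

    @property
    def median_score(self) -> float:
        return float(np.median(self.scores))

    def to_json(self, path=None) -> str:
        payload = {
            "metric": self.metric_name,
            "algorithm": self.algorithm,
            "config": asdict(self.config),
            "seeds": self.seeds,
            "scores": self.scores,
            "median_score": self.median_score,
            "selected_params": self.selected_params,
        }
        text = json.dumps(payload, indent=2, default=str)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def fit(spec: EstimatorSpec, X, y, seed: int | None = None):
    """Train one estimator from a spec; deterministic given ``seed``."""
    return spec.make(random_state=seed).fit(X, y)


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31 - 1)]


def _kfold(n_splits: int, seed: int) -> StratifiedKFold:
    return StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)


def grid_search_select(spec: EstimatorSpec, X, y, inner_folds: int, seed: int,
                       metric) -> dict:
    """Inner-loop selection: fold-aggregated metric per grid point; first
    best combination (documented grid order) wins ties."""
    splits = list(_kfold(inner_folds, seed).split(X, y))
    best_params, best_score = None, -np.inf
    for params in spec.grid():
        candidate = spec.with_params(params)
        agg_pred = np.empty_like(y)
        for fi, (tr, te) in enumerate(splits):
            model = candidate.make(random_state=seed + fi).fit(X[tr], y[tr])
            agg_pred[te] = model.predict(X[te])
        score = metric(y, agg_pred)
        if score > best_score:
            best_params, best_score = params, score
    return best_params


def nested_cv(matrix: FeatureMatrix, spec: EstimatorSpec, cv: CVConfig,
              metric: str = "adjusted_balanced_accuracy",
              y=None) -> EvaluationReport:
    """Run the full nested protocol on a labeled feature matrix.

    ``y`` overrides the matrix labels (used for one-vs-rest binarization).
    Requires every class to hold at least ``cv.outer_folds`` rows, so that
    stratification places each class in every outer fold.
    """
    metric_fn = metric if callable(metric) else get_metric(metric)
    metric_name = metric if isinstance(metric, str) else getattr(metric, "__name__", "metric")
    X = matrix.X
    y = np.asarray(matrix.y if y is None else y)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < cv.outer_folds:
        raise ValueError(
            f"smallest class has {counts.min()} rows < K1 = {cv.outer_folds}; "
            "apply the minimum-class-size filter first")
    rep_seeds = _child_seeds(cv.seed, cv.repetitions)
    scores: list[float] = []
    selected: list[list[dict]] = []
    predictions: list[pd.Series] = []
    for rep_seed in rep_seeds:
        outer = _kfold(cv.outer_folds, rep_seed)
        agg_pred = np.empty_like(y)
        fold_params: list[dict] = []
        for fold_i, (train, test) in enumerate(outer.split(X, y)):
            inner_seed = (rep_seed + 7919 * (fold_i + 1)) % (2**31 - 1)
            params = grid_search_select(spec, X[train], y[train],
                                        cv.inner_folds, inner_seed, metric_fn)
            model = spec.with_params(params).make(random_state=inner_seed).fit(
                X[train], y[train])
            agg_pred[test] = model.predict(X[test])
            fold_params.append(params)
        scores.append(float(metric_fn(y, agg_pred)))
        selected.append(fold_params)
        predictions.append(pd.Series(agg_pred, index=matrix.data.index))
    return EvaluationReport(metric_name=metric_name, scores=scores,
                            selected_params=selected, predictions=predictions,
                            seeds=rep_seeds, config=cv, algorithm=spec.algorithm)


# -- one-vs-rest, importances, signatures --------------------------------

_REST_LABEL = "__rest__"


def train_one_vs_rest(matrix: FeatureMatrix, spec: EstimatorSpec, cv: CVConfig
                      ) -> tuple[dict, pd.Series]:
    """One binary classifier per subtype plus its cross-validated F-score.

    Each subtype is relabeled positive-vs-rest; the per-subtype score is the
    F1 of the positive class on the fold-aggregated predictions (median over
    repetitions), and the returned models are refit on the full data.
    """
    if matrix.labels is None:
        raise ValueError("one-vs-rest training needs a labeled matrix")
    models: dict[str, object] = {}
    f_scores: dict[str, float] = {}
    subtypes = sorted(matrix.labels.unique())
    for subtype in subtypes:
        y_bin = np.where(matrix.y == subtype, subtype, _REST_LABEL)
        metric_fn = lambda yt, yp, s=subtype: binary_f_score(yt, yp, s)
        metric_fn.__name__ = "binary_f_score"
        report = nested_cv(matrix, spec, cv, metric=metric_fn, y=y_bin)
        f_scores[subtype] = report.median_score
        models[subtype] = fit(spec, matrix.X, y_bin, seed=cv.seed)
    return models, pd.Series(f_scores, name="f_score")


@dataclass
class ImportanceProfile:
    """Mean and standard deviation of per-tree normalized impurity importances."""

    families: list[str]
    mean: np.ndarray
    std: np.ndarray

    def __post_init__(self) -> None:
        if (np.asarray(self.mean) < 0).any():
            raise ValueError("importances must be non-negative")

    def ranked(self) -> pd.DataFrame:
        df = pd.DataFrame({"family": self.families, "importance": self.mean,
                           "std": self.std})
        return df.sort_values("importance", ascending=False, kind="stable",
                              ignore_index=True)


def impurity_importance(model, families: list[str] | None = None) -> ImportanceProfile:
    """Per-family impurity importance of a fitted tree ensemble.

    Each tree's importances (sample-weighted impurity decreases) are
    normalized to sum 1; mean and standard deviation are taken across the
    trees that performed at least one split.
    """
    backend = getattr(model, "model_", model)
    if not hasattr(backend, "estimators_") or not hasattr(backend, "feature_importances_"):
        raise TypeError("impurity importance requires a fitted tree-ensemble model")
    per_tree = []
    for tree in backend.estimators_:
        imp = tree.feature_importances_
        if imp.sum() > 0:
            per_tree.append(imp)
    if not per_tree:
        n = backend.n_features_in_
        mat = np.zeros((1, n))
    else:
        mat = np.vstack(per_tree)
    if families is None:
        families = [f"f{i}" for i in range(mat.shape[1])]
    return ImportanceProfile(list(families), mat.mean(axis=0), mat.std(axis=0))


def signature_proteins(matrix: FeatureMatrix, subtype: str,
                       spec: EstimatorSpec | None = None, top_k: int = 5,
                       seed: int = 0) -> pd.DataFrame:
    """Top families discriminating one subtype from all others.

    Fits the subtype's one-vs-rest binary ensemble on the full matrix and
    ranks families by mean impurity importance; high-ranking families are
    candidate signature proteins of the subtype.
    """
    if matrix.labels is None or subtype not in set(matrix.labels):
        raise KeyError(f"subtype {subtype!r} not present in the matrix labels")
    if spec is None:
        spec = EstimatorSpec("randomized_ensemble")
    if spec.algorithm != "randomized_ensemble":
        raise ValueError("signature extraction requires the tree-ensemble algorithm")
    y_bin = np.where(matrix.y == subtype, subtype, _REST_LABEL)
    model = fit(spec, matrix.X, y_bin, seed=seed)
    profile = impurity_importance(model, matrix.families)
    return profile.ranked().head(top_k)


def ablate_families(matrix: FeatureMatrix, families_to_drop: list[str]) -> FeatureMatrix:
    """Remove feature columns (e.g. the universal cas1/cas2/cas4/cas6 set)."""
    unknown = [f for f in families_to_drop if f not in matrix.families]
    if unknown:
        raise KeyError(f"unknown families {unknown}")
    data = matrix.data.drop(columns=list(families_to_drop))
    return FeatureMatrix(data, matrix.labels)
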