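"""Prediction of missing Cas-protein evidence by per-family regressor banks.

For a scope (one subtype, or "global" = all cassettes) with protein support
f_1 .. f_l (the families with nonzero evidence in at least one cassette of
the scope), a bank trains l regressors: the j-th predicts family j's
normalized bit score from the other l - 1 scores.  A zero entry whose
predicted evidence reaches a threshold is flagged as a candidate missing
protein, optionally imputed, and the cassette can then be classified as if
the protein had been detected.  The impurity importances of each target's
ensemble regressor read out as association rules: which proteins carry the
information about the target — putative functional modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted

from .estimators import EstimatorSpec
from .features import FeatureMatrix
from .metrics import mean_absolute_error
from .pipeline import impurity_importance

GLOBAL_SCOPE = "global"


def subtype_protein_support(matrix: FeatureMatrix, scope: str) -> list[str]:
    """Families with nonzero evidence in >= 1 cassette of the scope, in
    collection column order.  ``scope`` is a subtype label or ``"global"``."""
    if scope == GLOBAL_SCOPE:
        block = matrix.data
    else:
        if matrix.labels is None or scope not in set(matrix.labels):
            raise KeyError(f"subtype {scope!r} not present in the matrix labels")
        block = matrix.data[matrix.labels == scope]
    support = [fam for fam in matrix.families if (block[fam] > 0).any()]
    if not support:
        raise ValueError(f"scope {scope!r} has all-zero rows: empty protein support")
    return support


@dataclass
class RegressorBank:
    """l fitted regressors for one scope, the j-th predicting family j."""

    scope: str
    support: list[str]
    regressors: dict[str, object]
    spec: EstimatorSpec
    seed: int = 0
    cv_mae: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.regressors) != set(self.support):
            raise ValueError("bank must hold exactly one regressor per support family")

    def inputs_for(self, target: str) -> list[str]:
        if target not in self.support:
            raise KeyError(f"family {target!r} outside bank support")
        return [f for f in self.support if f != target]

    def save(self, path) -> None:
        """Versioned archive: spec, support, seed and the fitted regressors."""
        import joblib

        from . import __version__

        joblib.dump({"format": 1, "version": __version__, "scope": self.scope,
                     "support": self.support, "seed": self.seed,
                     "algorithm": self.spec.algorithm, "task": self.spec.task,
                     "hyperparams": self.spec.hyperparams,
                     "cv_mae": self.cv_mae, "regressors": self.regressors}, path)

    @classmethod
    def load(cls, path) -> "RegressorBank":
        import joblib

        payload = joblib.load(path)
        if payload.get("format") != 1:
            raise ValueError(f"unrecognized bank archive format in {path}")
        spec = EstimatorSpec(payload["algorithm"], payload["task"],
                             payload["hyperparams"])
        return cls(scope=payload["scope"], support=payload["support"],
                   regressors=payload["regressors"], spec=spec,
                   seed=payload["seed"], cv_mae=payload["cv_mae"])

    def predict(self, vector: pd.Series, target: str) -> float:
        """Predicted normalized score of ``target``, clipped to [0, 1].

        Only the support families other than the target are read from the
        vector; everything else is ignored.
        """
        inputs = self.inputs_for(target)
        x = vector.reindex(inputs).to_numpy(dtype=float)[None, :]
        raw = float(self.regressors[target].predict(x)[0])
        return float(np.clip(raw, 0.0, 1.0))


def train_regressor_bank(matrix: FeatureMatrix, scope: str = GLOBAL_SCOPE,
                         spec: EstimatorSpec | None = None, seed: int = 0,
                         min_rows: int = 10, cv_folds: int = 5) -> RegressorBank:
    """Train one regressor per support family on the scope's rows.

    Also records each target's ``cv_folds``-fold cross-validated MAE on the
    training rows, the bank's own estimate of its prediction error.
    """
    if spec is None:
        spec = EstimatorSpec("randomized_ensemble", task="regression")
    if spec.task != "regression":
        raise ValueError("regressor bank needs a regression spec")
    support = subtype_protein_support(matrix, scope)
    if len(support) < 2:
        raise ValueError(f"scope {scope!r}: support of size {len(support)} < 2")
    if scope == GLOBAL_SCOPE:
        block = matrix.data[support]
    else:
        block = matrix.data.loc[matrix.labels == scope, support]
    if len(block) < min_rows:
        raise ValueError(f"scope {scope!r} has {len(block)} rows < {min_rows}")
    rng_seeds = np.random.SeedSequence(seed).generate_state(len(support)) % (2**31 - 1)
    regressors: dict[str, object] = {}
    cv_mae: dict[str, float] = {}
    for child, target in zip(rng_seeds, support):
        X = block.drop(columns=[target]).to_numpy(dtype=float)
        y = block[target].to_numpy(dtype=float)
        child = int(child)
        folds = KFold(n_splits=min(cv_folds, len(block)), shuffle=True, random_state=child)
        preds = np.empty_like(y)
        for tr, te in folds.split(X):
            est = spec.make(random_state=child).fit(X[tr], y[tr])
            preds[te] = np.clip(est.predict(X[te]), 0.0, 1.0)
        cv_mae[target] = mean_absolute_error(y, preds)
        regressors[target] = spec.make(random_state=child).fit(X, y)
    return RegressorBank(scope=scope, support=support, regressors=regressors,
                         spec=spec, seed=seed, cv_mae=cv_mae)


def predict_missing(bank: RegressorBank, vector: pd.Series, target: str) -> float:
    return bank.predict(vector, target)


def flag_missing_candidates(bank: RegressorBank, vector: pd.Series,
                            evidence_threshold: float = 0.5
                            ) -> list[tuple[str, float]]:
    """Support families observed at 0 whose predicted evidence reaches the
    threshold, sorted by predicted score descending."""
    flags = []
    for fam in bank.support:
        if float(vector.get(fam, 0.0)) == 0.0:
            pred = bank.predict(vector, fam)
            if pred >= evidence_threshold:
                flags.append((fam, pred))
    flags.sort(key=lambda t: -t[1])
    return flags


def association_rules(bank: RegressorBank, targets: list[str] | None = None,
                      top_k: int = 3) -> dict[str, list[tuple[str, float]]]:
    """Per target, the ``top_k`` most important input proteins.

    Importances are the impurity importances of the target's tree-ensemble
    regressor, normalized to sum 1 over its l - 1 inputs.
    """
    if bank.spec.algorithm != "randomized_ensemble":
        raise TypeError("association rules require a tree-ensemble bank")
    out: dict[str, list[tuple[str, float]]] = {}
    for target in (targets or bank.support):
        inputs = bank.inputs_for(target)
        profile = impurity_importance(bank.regressors[target], inputs)
        total = profile.mean.sum()
        weights = profile.mean / total if total > 0 else profile.mean
        ranked = sorted(zip(inputs, weights), key=lambda t: -t[1])
        out[target] = [(fam, float(w)) for fam, w in ranked[:top_k]]
    return out


def impute_vector(bank: RegressorBank, vector: pd.Series,
                  evidence_threshold: float = 0.5) -> tuple[pd.Series, list[tuple[str, float]]]:
    flags = flag_missing_candidates(bank, vector, evidence_threshold)
    imputed = vector.copy()
    for fam, pred in flags:
        imputed[fam] = pred
    return imputed, flags


def impute_then_classify(vector: pd.Series, global_bank: RegressorBank,
                         classifier, evidence_threshold: float = 0.5) -> dict:
    """Impute flagged zeros with the global bank, then classify the cassette.

    The classifier must have been trained on the same family space as the
    vector.  Returns the predicted subtype, the imputed vector, the flags and
    the untouched original vector.
    """
    n_features = getattr(classifier, "n_features_in_", None)
    if n_features is not None and n_features != len(vector):
        raise ValueError(f"classifier expects {n_features} families, vector has {len(vector)}")
    imputed, flags = impute_vector(global_bank, vector, evidence_threshold)
    subtype = classifier.predict(imputed.to_numpy(dtype=float)[None, :])[0]
    return {"subtype": subtype, "imputed": imputed, "flags": flags,
            "original": vector}


class MissingScoreImputer(TransformerMixin, BaseEstimator):
    """Transformer view of the global regressor bank for pipeline composition.

    ``fit`` trains a bank on the (complete) training matrix; ``transform``
    replaces zero entries whose predicted evidence reaches
    ``evidence_threshold`` with their predictions.
    """

    def __init__(self, algorithm: str = "randomized_ensemble",
                 evidence_threshold: float = 0.5, random_state: int = 0):
        self.algorithm = algorithm
        self.evidence_threshold = evidence_threshold
        self.random_state = random_state

    def fit(self, X, y=None):
        df = X.data if isinstance(X, FeatureMatrix) else pd.DataFrame(np.asarray(X, float))
        self.bank_ = train_regressor_bank(
            FeatureMatrix(df), GLOBAL_SCOPE,
            EstimatorSpec(self.algorithm, task="regression"),
            seed=self.random_state)
        self.n_features_in_ = df.shape[1]
        self.columns_ = list(df.columns)
        return self

    def transform(self, X):
        check_is_fitted(self, "bank_")
        df = X.data if isinstance(X, FeatureMatrix) else pd.DataFrame(
            np.asarray(X, float), columns=self.columns_)
        out = df.copy()
        for idx, row in df.iterrows():
            imputed, _ = impute_vector(self.bank_, row, self.evidence_threshold)
            out.loc[idx] = imputed
        if isinstance(X, FeatureMatrix):
            return FeatureMatrix(out, X.labels)
        return out.to_numpy(dtype=float)
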