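"""Evaluation measures: chance-adjusted balanced accuracy, macro F-score, MAE.

Both classification measures weight all subtypes equally, so the abundant
subtypes cannot dominate the score.  Balanced accuracy (mean per-class
recall) is additionally chance-adjusted so that a random classifier scores 0
and a perfect one scores 1 regardless of the number of classes.
"""

from __future__ import annotations

import numpy as np


def _check_pair(y_true, y_pred):
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty label sequence")
    if y_true.shape != y_pred.shape:
        raise ValueError("label sequences differ in length")
    return y_true, y_pred


def adjusted_balanced_accuracy(y_true, y_pred) -> float:
    """(BA - 1/k) / (1 - 1/k) with BA the mean per-class recall.

    k counts the classes present in ``y_true`` (k >= 2 required); constant
    chance-level prediction maps to 0, perfect prediction to 1.
    """
    y_true, y_pred = _check_pair(y_true, y_pred)
    classes = np.unique(y_true)
    k = classes.size
    if k < 2:
        raise ValueError("adjusted balanced accuracy needs >= 2 classes in y_true")
    recalls = [(y_pred[y_true == c] == c).mean() for c in classes]
    ba = float(np.mean(recalls))
    chance = 1.0 / k
    return (ba - chance) / (1.0 - chance)


def macro_f_score(y_true, y_pred) -> float:
    """Unweighted mean of per-class F1 over the classes in ``y_true``.

    A class with zero precision + recall contributes F1 = 0.
    """
    y_true, y_pred = _check_pair(y_true, y_pred)
    classes = np.unique(y_true)
    f_scores = []
    for c in classes:
        tp = float(np.sum((y_true == c) & (y_pred == c)))
        fp = float(np.sum((y_true != c) & (y_pred == c)))
        fn = float(np.sum((y_true == c) & (y_pred != c)))
        denom = 2 * tp + fp + fn
        f_scores.append(2 * tp / denom if denom > 0 else 0.0)
    return float(np.mean(f_scores))


def binary_f_score(y_true, y_pred, positive) -> float:
    """F1 of the positive class in a one-vs-rest binary problem."""
    y_true, y_pred = _check_pair(y_true, y_pred)
    tp = float(np.sum((y_true == positive) & (y_pred == positive)))
    fp = float(np.sum((y_true != positive) & (y_pred == positive)))
    fn = float(np.sum((y_true == positive) & (y_pred != positive)))
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom > 0 else 0.0


def mean_absolute_error(y, y_hat) -> float:
    """Mean |y_i - y_hat_i| over equal-length real sequences."""
    y, y_hat = _check_pair(y, y_hat)
    return float(np.mean(np.abs(np.asarray(y, float) - np.asarray(y_hat, float))))


CLASSIFICATION_METRICS = {
    "adjusted_balanced_accuracy": adjusted_balanced_accuracy,
    "macro_f_score": macro_f_score,
}


def get_metric(name: str):
    if name in CLASSIFICATION_METRICS:
        return CLASSIFICATION_METRICS[name]
    if name == "mean_absolute_error":
        return mean_absolute_error
    raise KeyError(f"unknown metric {name!r}")
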