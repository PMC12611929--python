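"""Evaluation metrics: categorical accuracy, one-vs-rest AUC, macro
precision/recall, and categorical cross-entropy.

Multiclass precision, recall and the confusion counts come from one-vs-rest
binarization of argmax predictions; AUC is computed per class from the
Mann-Whitney rank statistic (equivalent to trapezoidal integration of the
empirical ROC curve, with half-credit for ties) and macro-averaged.
Precision here is the positive predictive value TP/(TP+FP); true
specificity TN/(TN+FP) is reported separately since the two are sometimes
conflated.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ConfusionCounts", "MetricsReport", "confusion_counts", "confusion_matrix",
    "accuracy", "ovr_auc", "recall", "precision", "specificity",
    "categorical_cross_entropy", "evaluate_predictions",
]

EPS = 1e-7


@dataclass
class ConfusionCounts:
    """Per-class one-vs-rest TP/FP/TN/FN over argmax predictions."""

    classes: list[int]
    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray

    @property
    def n_samples(self) -> int:
        return int(self.tp[0] + self.fp[0] + self.tn[0] + self.fn[0]) if len(self.classes) else 0

    def validate(self) -> None:
        n = self.n_samples
        for k in range(len(self.classes)):
            if self.tp[k] + self.fp[k] + self.tn[k] + self.fn[k] != n:
                raise ValueError("inconsistent confusion counts")


def _check_probs(y_true, y_prob, tol: float = 1e-5):
    y_true = np.asarray(y_true, dtype=int)
    y_prob = np.asarray(y_prob, dtype=float)
    if y_prob.ndim != 2 or len(y_true) != len(y_prob):
        raise ValueError(f"length mismatch: {len(y_true)} labels vs {y_prob.shape} probabilities")
    sums = y_prob.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > tol):
        bad = int(np.argmax(np.abs(sums - 1.0)))
        raise ValueError(f"probability row {bad} sums to {sums[bad]:.6f}, expected 1")
    return y_true, y_prob


def confusion_counts(y_true, y_prob) -> ConfusionCounts:
    y_true, y_prob = _check_probs(y_true, y_prob)
    pred = np.argmax(y_prob, axis=1)  # ties break to the lowest class index
    classes = list(range(y_prob.shape[1]))
    tp = np.array([np.sum((pred == c) & (y_true == c)) for c in classes])
    fp = np.array([np.sum((pred == c) & (y_true != c)) for c in classes])
    fn = np.array([np.sum((pred != c) & (y_true == c)) for c in classes])
    tn = np.array([np.sum((pred != c) & (y_true != c)) for c in classes])
    return ConfusionCounts(classes=classes, tp=tp, fp=fp, tn=tn, fn=fn)


def confusion_matrix(y_true, y_prob) -> np.ndarray:
    y_true, y_prob = _check_probs(y_true, y_prob)
    pred = np.argmax(y_prob, axis=1)
    k = y_prob.shape[1]
    mat = np.zeros((k, k), dtype=int)
    np.add.at(mat, (y_true, pred), 1)
    return mat


def accuracy(y_true, y_prob) -> float:
    """Categorical accuracy: fraction of samples whose argmax matches."""
    y_true, y_prob = _check_probs(y_true, y_prob, tol=1e-6)
    return float(np.mean(np.argmax(y_prob, axis=1) == y_true))


def _binary_auc(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """Mann-Whitney AUC with half-credit for ties."""
    scores = np.concatenate([pos_scores, neg_scores])
    ranks = rankdata(scores)  # average ranks on ties
    n_pos, n_neg = len(pos_scores), len(neg_scores)
    return float((ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def ovr_auc(y_true, y_prob, average: str = "macro") -> float:
    """One-vs-rest ROC AUC averaged over evaluable classes.

    A class absent from ``y_true`` is skipped with a warning; if no class
    has both positives and negatives the AUC is undefined.
    """
    y_true, y_prob = _check_probs(y_true, y_prob)
    if len(np.unique(y_true)) < 2:
        raise ValueError("AUC undefined: y_true contains a single class")
    aucs, weights = [], []
    for c in range(y_prob.shape[1]):
        pos = y_prob[y_true == c, c]
        neg = y_prob[y_true != c, c]
        if len(pos) == 0 or len(neg) == 0:
            warnings.warn(f"class {c} absent from y_true; skipped in AUC", stacklevel=2)
            continue
        aucs.append(_binary_auc(pos, neg))
        weights.append(len(pos))
    if average == "macro":
        return float(np.mean(aucs))
    if average == "micro":
        return float(np.average(aucs, weights=weights))
    raise ValueError(f"unknown average {average!r}")


def _macro_ratio(num: np.ndarray, den: np.ndarray, present: np.ndarray, what: str) -> float:
    vals = []
    for k in np.flatnonzero(present):
        if den[k] == 0:
            warnings.warn(f"{what}: class {k} has zero denominator, scored 0", stacklevel=3)
            vals.append(0.0)
        else:
            vals.append(num[k] / den[k])
    return float(np.mean(vals))


def _present(counts: ConfusionCounts) -> np.ndarray:
    return (counts.tp + counts.fn) > 0  # classes present in y_true


def recall(counts: ConfusionCounts) -> float:
    """Macro recall (sensitivity): mean over present classes of TP/(TP+FN)."""
    counts.validate()
    return _macro_ratio(counts.tp, counts.tp + counts.fn, _present(counts), "recall")


def precision(counts: ConfusionCounts) -> float:
    """Macro precision (positive predictive value): mean of TP/(TP+FP)."""
    counts.validate()
    return _macro_ratio(counts.tp, counts.tp + counts.fp, _present(counts), "precision")


def specificity(counts: ConfusionCounts) -> float:
    """Macro true specificity TN/(TN+FP) — reported alongside precision."""
    counts.validate()
    return _macro_ratio(counts.tn, counts.tn + counts.fp, _present(counts), "specificity")


def categorical_cross_entropy(y_true_onehot, y_prob) -> float:
    """Mean of -sum_i y_i log p_i (natural log, probabilities clipped at 1e-7)."""
    y = np.asarray(y_true_onehot, dtype=float)
    p = np.asarray(y_prob, dtype=float)
    if y.shape != p.shape:
        raise ValueError(f"shape mismatch {y.shape} vs {p.shape}")
    sums = p.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-5):
        bad = int(np.argmax(np.abs(sums - 1.0)))
        raise ValueError(f"probability row {bad} sums to {sums[bad]:.6f}")
    p = np.clip(p, EPS, 1.0)
    return float(np.mean(-np.sum(y * np.log(p), axis=1)))


@dataclass
class MetricsReport:
    """One evaluation row: loss, accuracy, AUC, macro precision and recall."""

    loss: float
    accuracy: float
    auc: float
    precision: float
    recall: float

    def __post_init__(self) -> None:
        for name in ("accuracy", "auc", "precision", "recall"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.loss < 0:
            raise ValueError("loss must be >= 0")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, payload: str) -> "MetricsReport":
        return cls(**json.loads(payload))


def evaluate_predictions(y_true, y_prob) -> MetricsReport:
    """Full report from integer labels and per-class probabilities."""
    y_true, y_prob = _check_probs(y_true, y_prob)
    onehot = np.eye(y_prob.shape[1])[y_true]
    counts = confusion_counts(y_true, y_prob)
    return MetricsReport(
        loss=categorical_cross_entropy(onehot, y_prob),
        accuracy=accuracy(y_true, y_prob),
        auc=ovr_auc(y_true, y_prob),
        precision=precision(counts),
        recall=recall(counts),
    )
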