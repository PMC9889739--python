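"""Turning anomaly scores into a classifier: ROC, best cutoff, metrics.

Label convention: 0 = normal, 1 = abnormal; a volume is called abnormal
when its total loss is strictly greater than the cutoff.  The group
metrics keep this field's reporting convention in which "sensitivity"
is the accuracy within the normal group, TN / (TN + FP), and
"specificity" the accuracy within the abnormal group, TP / (TP + FN);
the F1 score takes abnormal as the positive class.  These are exposed
under the unambiguous names ``normal_group_accuracy`` and
``abnormal_group_accuracy``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class ScoreSet:
    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.scores, dtype=np.float64)
        l = np.asarray(self.labels)
        object.__setattr__(self, "scores", s)
        object.__setattr__(self, "labels", l)
        if s.shape != l.shape or s.ndim != 1:
            raise EvaluationError("scores and labels must be equal-length vectors")
        if not np.all(np.isin(l, (0, 1))):
            raise EvaluationError("labels must be 0 (normal) or 1 (abnormal)")


@dataclass(frozen=True)
class RocResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    best_cutoff: float


@dataclass(frozen=True)
class GroupMetrics:
    tn: int
    fp: int
    fn: int
    tp: int
    normal_group_accuracy: float   # TN / (TN + FP); the field's "sensitivity"
    abnormal_group_accuracy: float  # TP / (TP + FN); the field's "specificity"
    overall_accuracy: float
    f1: float
    undefined: tuple[str, ...] = ()  # rates whose denominator was zero


def roc_analysis(s: ScoreSet) -> RocResult:
    """ROC curve (abnormal positive), trapezoidal AUC, Youden-J cutoff."""
    if len(np.unique(s.labels)) < 2:
        raise EvaluationError("ROC analysis needs both classes present")
    fpr, tpr, thr = _sk_roc_curve(s.labels, s.scores, drop_intermediate=False)
    area = float(_sk_auc(fpr, tpr))
    return RocResult(thresholds=thr, fpr=fpr, tpr=tpr, auc=area,
                     best_cutoff=_best_cutoff_scan(s))


def _best_cutoff_scan(s: ScoreSet) -> float:
    """Maximize J = TPR - FPR over candidate cutoffs (the unique scores),
    under the "score > t -> abnormal" rule; ties go to the lower cutoff."""
    pos = np.sort(s.scores[s.labels == 1])
    neg = np.sort(s.scores[s.labels == 0])
    best_t, best_j = None, -np.inf
    for t in np.unique(s.scores):
        tpr = np.mean(pos > t)
        fpr = np.mean(neg > t)
        j = tpr - fpr
        if j > best_j + 1e-12:
            best_j, best_t = j, float(t)
    return best_t


def best_cutoff(r: RocResult) -> float:
    return r.best_cutoff


def classify(scores, cutoff: float) -> np.ndarray:
    """score > cutoff -> 1 (abnormal); ties at the cutoff stay normal."""
    return (np.asarray(scores, dtype=np.float64) > cutoff).astype(int)


def group_metrics(true_labels, predicted_labels) -> GroupMetrics:
    """Confusion counts and the reporting-convention rates (see module doc)."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape or t.ndim != 1 or t.size == 0:
        raise EvaluationError("labels must be equal-length non-empty vectors")
    if not (np.all(np.isin(t, (0, 1))) and np.all(np.isin(p, (0, 1)))):
        raise EvaluationError("labels must be 0 or 1")
    tn = int(np.sum((t == 0) & (p == 0)))
    fp = int(np.sum((t == 0) & (p == 1)))
    fn = int(np.sum((t == 1) & (p == 0)))
    tp = int(np.sum((t == 1) & (p == 1)))

    undefined = []

    def rate(num, den, name):
        if den == 0:
            undefined.append(name)
            return float("nan")
        return num / den

    normal_acc = rate(tn, tn + fp, "normal_group_accuracy")
    abnormal_acc = rate(tp, tp + fn, "abnormal_group_accuracy")
    overall = (tn + tp) / t.size
    precision = rate(tp, tp + fp, "precision")
    recall = abnormal_acc
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        undefined.append("f1")
        f1 = float("nan")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return GroupMetrics(tn=tn, fp=fp, fn=fn, tp=tp,
                        normal_group_accuracy=normal_acc,
                        abnormal_group_accuracy=abnormal_acc,
                        overall_accuracy=overall, f1=f1,
                        undefined=tuple(undefined))


def confusion_from_group_rates(n_normal: int, normal_acc: float,
                               n_abnormal: int, abnormal_acc: float):
    """Reconstruct integer (TN, FP, FN, TP) from group sizes and accuracies.

    Used for worked examples where only per-group accuracies are printed:
    TN is the nearest integer to n_normal * normal_acc, TP likewise.
    """
    tn = int(round(n_normal * normal_acc))
    tp = int(round(n_abnormal * abnormal_acc))
    return tn, n_normal - tn, n_abnormal - tp, tp


def metrics_from_confusion(tn: int, fp: int, fn: int, tp: int) -> GroupMetrics:
    """GroupMetrics straight from confusion counts."""
    t = np.concatenate([np.zeros(tn + fp, int), np.ones(fn + tp, int)])
    p = np.concatenate([np.zeros(tn, int), np.ones(fp, int),
                        np.zeros(fn, int), np.ones(tp, int)])
    return group_metrics(t, p)
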