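"""Confusion-matrix construction and the binary classification metric suite:
accuracy, precision, recall/sensitivity, specificity, F1, NPV, MCC, fall-out
(false-positive rate), miss rate (false-negative rate), and trapezoidal ROC
AUC.

Zero-denominator ratios are reported as 0.0 and the metric name is listed in
``MetricReport.degenerate`` rather than raising, so reports on extreme
classifiers stay machine-readable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ConfusionCounts", "MetricReport", "confusion",
           "classification_metrics", "roc_auc"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricReport:
    accuracy: float
    precision: float
    recall_sensitivity: float
    specificity: float
    f1: float
    npv: float
    mcc: float
    fall_out: float
    miss_rate: float
    auc: float | None = None
    degenerate: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        out = {k: getattr(self, k) for k in
               ("accuracy", "precision", "recall_sensitivity", "specificity",
                "f1", "npv", "mcc", "fall_out", "miss_rate")}
        if self.auc is not None:
            out["auc"] = self.auc
        out["degenerate"] = list(self.degenerate)
        return out


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Tally TP/TN/FP/FN with positive class 1."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors differ in length")
    if not (np.isin(y_true, (0, 1)).all() and np.isin(y_pred, (0, 1)).all()):
        raise ValueError("labels must be binary 0/1")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return ConfusionCounts(tp, tn, fp, fn)


def _ratio(num: float, den: float, name: str, degenerate: list[str]) -> float:
    if den == 0:
        degenerate.append(name)
        return 0.0
    return num / den


def classification_metrics(c: ConfusionCounts) -> MetricReport:
    """Full metric suite from a confusion table.

    accuracy = (TP+TN)/total, precision = TP/(TP+FP),
    recall = TP/(TP+FN), specificity = TN/(TN+FP),
    F1 = 2PR/(P+R), NPV = TN/(TN+FN), fall-out = FP/(FP+TN),
    miss rate = FN/(FN+TP), and the Matthews correlation coefficient.
    """
    if c.total == 0:
        raise ValueError("empty confusion table")
    deg: list[str] = []
    tp, tn, fp, fn = float(c.tp), float(c.tn), float(c.fp), float(c.fn)
    accuracy = (tp + tn) / c.total
    precision = _ratio(tp, tp + fp, "precision", deg)
    recall = _ratio(tp, tp + fn, "recall_sensitivity", deg)
    specificity = _ratio(tn, tn + fp, "specificity", deg)
    f1 = _ratio(2.0 * precision * recall, precision + recall, "f1", deg)
    npv = _ratio(tn, tn + fn, "npv", deg)
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _ratio(tp * tn - fp * fn, mcc_den, "mcc", deg)
    fall_out = _ratio(fp, fp + tn, "fall_out", deg)
    miss_rate = _ratio(fn, fn + tp, "miss_rate", deg)
    return MetricReport(accuracy, precision, recall, specificity, f1,
                        npv, mcc, fall_out, miss_rate, degenerate=deg)


def roc_auc(y_true, scores) -> tuple[np.ndarray, float]:
    """ROC points and trapezoidal AUC over thresholds at all distinct scores.

    The trapezoid over tied-score groups makes the area equal to the
    pairwise-concordance probability with ties counted half.
    Returns (array of (fpr, tpr) points, auc).
    """
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if y_true.shape != scores.shape:
        raise ValueError("length mismatch")
    n_pos = int((y_true == 1).sum())
    n_neg = int((y_true == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-scores, kind="mergesort")
    y = y_true[order]
    s = scores[order]
    # cumulative counts at each distinct-score boundary
    distinct = np.r_[np.flatnonzero(np.diff(s)), len(s) - 1]
    tps = np.cumsum(y)[distinct]
    fps = np.cumsum(1 - y)[distinct]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc
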