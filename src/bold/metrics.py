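"""Confusion-matrix scores, Cohen's kappa, RMSE and ROC/AUC.

All scores are computed and stored on the 0-1 scale; multiply by 100 only
at report-formatting time.  Ratios with a zero denominator are returned as
``None`` and recorded in the report's ``undefined`` list rather than being
silently coerced to 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


class MetricError(ValueError):
    pass


def _check_binary(v, name):
    v = np.asarray(v)
    if v.size == 0:
        raise MetricError(f"{name} is empty")
    if not np.isin(v, (0, 1)).all():
        raise MetricError(f"{name} must contain only 0/1 entries")
    return v.astype(int)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise MetricError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Tally the 2x2 confusion matrix with class 1 as positive."""
    y_true = _check_binary(y_true, "y_true")
    y_pred = _check_binary(y_pred, "y_pred")
    if y_true.shape != y_pred.shape:
        raise MetricError("y_true and y_pred must have equal length")
    return ConfusionCounts(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def _ratio(num, den):
    return num / den if den > 0 else None


def classification_scores(c: ConfusionCounts) -> dict:
    """Accuracy, precision, recall/sensitivity, specificity and F1.

    Recall and sensitivity are the same quantity (TP / (TP + FN)) and are
    reported under both names.  Undefined ratios are None.
    """
    if c.total == 0:
        raise MetricError("cannot score an empty confusion matrix")
    accuracy = (c.tp + c.tn) / c.total
    precision = _ratio(c.tp, c.tp + c.fp)
    recall = _ratio(c.tp, c.tp + c.fn)
    specificity = _ratio(c.tn, c.tn + c.fp)
    if precision is None or recall is None or (precision + recall) == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return {
        "accuracy": accuracy,
        "precision": precision,
        "recall": recall,
        "sensitivity": recall,
        "specificity": specificity,
        "f1": f1,
        "miss_rate": 1.0 - accuracy,
    }


def cohens_kappa(y_true, y_pred):
    """Chance-corrected agreement k = (p_o - p_e) / (1 - p_e); None if p_e = 1."""
    y_true = _check_binary(y_true, "y_true")
    y_pred = _check_binary(y_pred, "y_pred")
    if y_true.shape != y_pred.shape:
        raise MetricError("y_true and y_pred must have equal length")
    n = len(y_true)
    po = float((y_true == y_pred).mean())
    p1t, p1p = y_true.mean(), y_pred.mean()
    pe = p1t * p1p + (1 - p1t) * (1 - p1p)
    if pe >= 1.0 - 1e-15:
        return None
    return (po - pe) / (1 - pe)


def rmse(probabilities, labels) -> float:
    """Root-mean-square error of predicted probabilities against 0/1 labels."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    if p.size == 0:
        raise MetricError("empty input")
    if p.shape != y.shape:
        raise MetricError("probabilities and labels must have equal length")
    if ((p < 0) | (p > 1)).any():
        raise MetricError("probabilities must lie in [0, 1]")
    return float(np.sqrt(np.mean((p - y) ** 2)))


def roc_curve(probabilities, labels):
    """(thresholds, fpr, tpr) over all distinct scores, descending.

    Tied scores move the curve in a single diagonal segment, so the
    trapezoidal area equals the rank-averaged Mann-Whitney statistic.
    """
    p = np.asarray(probabilities, dtype=float)
    y = _check_binary(labels, "labels")
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise MetricError("ROC requires both classes present")
    order = np.argsort(-p, kind="stable")
    p_sorted, y_sorted = p[order], y[order]
    distinct = np.r_[np.flatnonzero(np.diff(p_sorted)), len(p_sorted) - 1]
    tps = np.cumsum(y_sorted)[distinct]
    fps = np.cumsum(1 - y_sorted)[distinct]
    thresholds = np.r_[np.inf, p_sorted[distinct]]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    return thresholds, fpr, tpr


def roc_auc(probabilities, labels) -> tuple:
    """ROC points and trapezoidal AUC (equals the Mann-Whitney statistic)."""
    thresholds, fpr, tpr = roc_curve(probabilities, labels)
    auc = float(np.trapezoid(tpr, fpr))
    return (thresholds, fpr, tpr), auc


@dataclass
class MetricReport:
    """Consolidated score report; proportions stored on the 0-1 scale."""

    counts: ConfusionCounts
    accuracy: float
    precision: float | None
    recall: float | None
    sensitivity: float | None
    specificity: float | None
    f1: float | None
    miss_rate: float
    kappa: float | None
    rmse: float | None = None
    auc: float | None = None
    undefined: list = field(default_factory=list)

    @classmethod
    def from_predictions(cls, y_true, y_pred, probabilities=None) -> "MetricReport":
        c = confusion(y_true, y_pred)
        scores = classification_scores(c)
        kappa = cohens_kappa(y_true, y_pred)
        r = auc = None
        if probabilities is not None:
            r = rmse(probabilities, y_true)
            if len(np.unique(np.asarray(y_true))) == 2:
                _, auc = roc_auc(probabilities, y_true)
        report = cls(
            counts=c,
            kappa=kappa,
            rmse=r,
            auc=auc,
            **scores,
        )
        report.undefined = [
            k
            for k in ("precision", "recall", "sensitivity", "specificity", "f1", "kappa")
            if getattr(report, k) is None
        ]
        return report

    def to_dict(self, scale: str = "unit") -> dict:
        """Serialize; ``scale='percent'`` multiplies proportions by 100."""
        if scale not in ("unit", "percent"):
            raise MetricError("scale must be 'unit' or 'percent'")
        factor = 100.0 if scale == "percent" else 1.0
        prop = lambda v: None if v is None else v * factor
        return {
            "counts": {"tp": self.counts.tp, "tn": self.counts.tn, "fp": self.counts.fp, "fn": self.counts.fn},
            "accuracy": prop(self.accuracy),
            "precision": prop(self.precision),
            "recall": prop(self.recall),
            "sensitivity": prop(self.sensitivity),
            "specificity": prop(self.specificity),
            "f1": prop(self.f1),
            "miss_rate": prop(self.miss_rate),
            "kappa": self.kappa,
            "rmse": self.rmse,
            "auc": self.auc,
            "undefined": list(self.undefined),
        }
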