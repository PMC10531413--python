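"""Confusion-matrix metrics and ROC/AUC for the two-class problem.

Rows of the confusion matrix are true labels, columns predicted labels, in
the fixed order (benign, malignant). Precision, recall and F1 are computed
per class (each class treated as positive in turn); the "macro" values are
the unweighted means over the two classes. All percentages are kept at full
precision and only rounded for display.

The ROC sweep treats *malignant* as the positive class (disease-detection
framing) and the area under the curve is the trapezoidal integral, which
for a finite sample equals the pairwise concordance (Mann-Whitney)
statistic with ties counted 1/2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "CLASSES",
    "ConfusionMatrix",
    "MetricsReport",
    "ROCPoints",
    "confusion",
    "metrics_report",
    "roc_auc",
]

CLASSES = ("benign", "malignant")
_ALIASES = {"benign": 0, "malignant": 1, "b": 0, "m": 1, 0: 0, 1: 1}


def _canon(labels) -> np.ndarray:
    out = []
    for lab in labels:
        key = lab.lower() if isinstance(lab, str) else int(lab)
        if key not in _ALIASES:
            raise ValueError(f"unknown class label {lab!r}")
        out.append(_ALIASES[key])
    return np.asarray(out, dtype=int)


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts; rows true (benign, malignant), columns predicted."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (2, 2) or np.any(c < 0):
            raise ValueError("confusion matrix must be 2x2 with non-negative counts")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def as_binary(self, positive: int) -> tuple[int, int, int, int]:
        """(TP, FP, TN, FN) treating class ``positive`` (0 or 1) as positive."""
        c = self.counts
        neg = 1 - positive
        return (
            int(c[positive, positive]),
            int(c[neg, positive]),
            int(c[neg, neg]),
            int(c[positive, neg]),
        )


@dataclass(frozen=True)
class MetricsReport:
    """Percent-scale metrics in the layout of a per-class + macro table."""

    accuracy: float
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    macro_precision: float
    macro_recall: float
    macro_f1: float

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "per_class": {
                c: {"precision": self.precision[c], "recall": self.recall[c], "f1": self.f1[c]}
                for c in CLASSES
            },
            "macro": {
                "precision": self.macro_precision,
                "recall": self.macro_recall,
                "f1": self.macro_f1,
            },
        }

    def format_table(self) -> str:
        lines = [f"{'':12s}{'Precision':>11s}{'Recall':>11s}{'F1':>11s}"]
        for c in CLASSES:
            lines.append(
                f"{c.capitalize():12s}{self.precision[c]:>10.2f}%{self.recall[c]:>10.2f}%"
                f"{self.f1[c]:>10.2f}%"
            )
        lines.append(
            f"{'Total':12s}{self.macro_precision:>10.2f}%{self.macro_recall:>10.2f}%"
            f"{self.macro_f1:>10.2f}%"
        )
        lines.append(f"Accuracy: {self.accuracy:.2f}%")
        return "\n".join(lines)


@dataclass(frozen=True)
class ROCPoints:
    thresholds: np.ndarray  # descending
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """Tally the 2x2 confusion matrix from paired label lists."""
    t, p = _canon(y_true), _canon(y_pred)
    if t.shape != p.shape or t.size < 1:
        raise ValueError("y_true and y_pred must be non-empty and of equal length")
    return ConfusionMatrix(_sk_confusion(t, p, labels=[0, 1]))


def _safe_ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"zero denominator for {what}; defining the metric as 0", stacklevel=3)
        return 0.0
    return num / den


def metrics_report(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy plus per-class and macro precision/recall/F1, in percent."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    precision, recall, f1 = {}, {}, {}
    for idx, name in enumerate(CLASSES):
        tp, fp, _tn, fn = cm.as_binary(idx)
        prec = _safe_ratio(tp, tp + fp, f"{name} precision")
        rec = _safe_ratio(tp, tp + fn, f"{name} recall")
        f1_val = _safe_ratio(2 * prec * rec, prec + rec, f"{name} F1")
        precision[name], recall[name], f1[name] = 100 * prec, 100 * rec, 100 * f1_val
    return MetricsReport(
        accuracy=100.0 * np.trace(cm.counts) / cm.total,
        precision=precision,
        recall=recall,
        f1=f1,
        macro_precision=float(np.mean(list(precision.values()))),
        macro_recall=float(np.mean(list(recall.values()))),
        macro_f1=float(np.mean(list(f1.values()))),
    )


def roc_auc(y_true, scores) -> ROCPoints:
    """Threshold sweep and trapezoidal AUC with malignant as positive."""
    t = _canon(y_true)
    s = np.asarray(scores, dtype=np.float64)
    if t.shape != s.shape:
        raise ValueError("y_true and scores must have equal length")
    if np.any(~np.isfinite(s)) or s.min() < 0 or s.max() > 1:
        raise ValueError("scores must be finite probabilities in [0, 1]")
    if len(np.unique(t)) < 2:
        raise ValueError("ROC/AUC undefined with a single class present")
    fpr, tpr, thresholds = _sk_roc_curve(t, s, pos_label=1)
    return ROCPoints(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=float(_sk_auc(fpr, tpr)))
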