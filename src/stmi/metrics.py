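"""Confusion matrices and chance-corrected performance metrics.

All rates are reported in percent:

    Acc  = (TP + TN) / (TP + FP + TN + FN) * 100
    Sens = TP / (TP + FN) * 100        (per class)
    Prec = TP / (TP + FP) * 100        (per class)

and the kappa score corrects accuracy for the chance rate rAcc = 1/N_c:

    kappa = (Acc - rAcc) / (1 - rAcc),   Acc as a fraction,

so for two balanced classes kappa = 2 Acc - 1.  Undefined metrics (zero
denominators) raise rather than silently returning zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from .errors import DataError, UndefinedMetricError

__all__ = [
    "ConfusionMatrix",
    "MetricReport",
    "confusion",
    "accuracy",
    "sensitivity",
    "precision",
    "kappa",
    "report",
]


@dataclass
class ConfusionMatrix:
    """2x2 table: counts[i, j] = # samples of class i predicted as class j."""

    counts: np.ndarray
    classes: tuple

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.classes), len(self.classes)):
            raise DataError("counts shape must match the class list")
        if (self.counts < 0).any():
            raise DataError("counts must be non-negative")

    @property
    def percent(self) -> np.ndarray:
        """Row-normalized view: each true-class row sums to 100."""
        totals = self.counts.sum(axis=1, keepdims=True)
        if (totals == 0).any():
            raise UndefinedMetricError("a class has no samples; rates undefined")
        return 100.0 * self.counts / totals

    @classmethod
    def from_rates(cls, rates: np.ndarray, classes: tuple, n_per_class: int = 10000):
        """Build a (scaled) count table from printed row percentages.

        Assumes equal class sizes, the convention of the reported
        confusion tables.
        """
        rates = np.asarray(rates, dtype=np.float64)
        counts = np.rint(rates / 100.0 * n_per_class).astype(np.int64)
        return cls(counts=counts, classes=classes)


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """Standard 2x2 confusion matrix over the union of observed labels."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise DataError("label vectors must have equal length")
    classes = np.unique(np.concatenate([y_true, y_pred]))
    if len(classes) > 2:
        raise DataError(f"binary task expected, got classes {classes}")
    counts = _sk_confusion(y_true, y_pred, labels=classes)
    return ConfusionMatrix(counts=counts, classes=tuple(classes))


def _class_index(cm: ConfusionMatrix, cls) -> int:
    try:
        return cm.classes.index(cls)
    except ValueError as exc:
        raise DataError(f"class {cls!r} not in {cm.classes}") from exc


def accuracy(cm: ConfusionMatrix) -> float:
    """Overall accuracy in percent."""
    total = cm.counts.sum()
    if total == 0:
        raise UndefinedMetricError("empty confusion matrix")
    return 100.0 * np.trace(cm.counts) / total


def sensitivity(cm: ConfusionMatrix, cls) -> float:
    """Recall of one class in percent: TP / (TP + FN)."""
    i = _class_index(cm, cls)
    denom = cm.counts[i].sum()
    if denom == 0:
        raise UndefinedMetricError(f"no samples of class {cls!r}")
    return 100.0 * cm.counts[i, i] / denom


def precision(cm: ConfusionMatrix, cls) -> float:
    """Precision of one class in percent: TP / (TP + FP)."""
    i = _class_index(cm, cls)
    denom = cm.counts[:, i].sum()
    if denom == 0:
        raise UndefinedMetricError(f"no predictions of class {cls!r}")
    return 100.0 * cm.counts[i, i] / denom


def kappa(acc_percent: float, n_classes: int = 2) -> float:
    """Chance-corrected accuracy with rAcc = 1/N_c."""
    if not 0.0 <= acc_percent <= 100.0:
        raise DataError(f"accuracy must be in [0, 100], got {acc_percent}")
    if n_classes < 2:
        raise DataError("need at least two classes")
    r = 1.0 / n_classes
    return (acc_percent / 100.0 - r) / (1.0 - r)


@dataclass
class MetricReport:
    """Per-classifier evaluation bundle."""

    confusion: ConfusionMatrix
    accuracy: float  # percent
    kappa: float
    sensitivity: dict  # class -> percent
    precision: dict

    def to_dict(self) -> dict:
        return {
            "accuracy": round(self.accuracy, 2),
            "kappa": round(self.kappa, 3),
            "sensitivity": {str(k): round(v, 2) for k, v in self.sensitivity.items()},
            "precision": {str(k): round(v, 2) for k, v in self.precision.items()},
            "confusion": self.confusion.counts.tolist(),
            "classes": [str(c) for c in self.confusion.classes],
        }


def report(y_true, y_pred) -> MetricReport:
    """Full metric bundle from true and predicted labels."""
    cm = confusion(y_true, y_pred)
    acc = accuracy(cm)
    return MetricReport(
        confusion=cm,
        accuracy=acc,
        kappa=kappa(acc, len(cm.classes)),
        sensitivity={c: sensitivity(cm, c) for c in cm.classes},
        precision={c: precision(cm, c) for c in cm.classes},
    )
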