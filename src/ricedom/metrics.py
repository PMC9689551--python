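"""Confusion-matrix evaluation for multiclass grading.

Per-class precision, recall and F1 are computed from the one-vs-rest
marginals of a K×K confusion matrix (rows = actual class, columns =
predicted class); overall accuracy is trace/total. Summary precision,
recall and F1 are macro averages (unweighted class means), the convention
that matches per-model reporting on balanced class sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion",
    "class_counts",
    "report",
]


@dataclass
class ConfusionMatrix:
    """K×K integer counts; entry (a, p) counts samples of actual class a
    predicted as class p."""

    counts: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("confusion matrix entries must be non-negative")
        if not self.labels:
            self.labels = [str(i) for i in range(self.counts.shape[0])]
        if len(self.labels) != self.counts.shape[0]:
            raise ValueError("label count must match matrix size")

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.counts, index=self.labels, columns=self.labels)
        df.to_csv(path, index_label="actual\\predicted")


@dataclass
class MetricsReport:
    """Per-class and macro-averaged classification metrics, all in [0, 1]."""

    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    labels: list[str]

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "per_class": {
                lab: {
                    "precision": float(self.precision[i]),
                    "recall": float(self.recall[i]),
                    "f1": float(self.f1[i]),
                }
                for i, lab in enumerate(self.labels)
            },
        }

    def as_table(self) -> str:
        lines = [f"{'class':<28}{'precision':>10}{'recall':>10}{'f1':>10}"]
        for i, lab in enumerate(self.labels):
            lines.append(
                f"{lab:<28}{self.precision[i]:>10.4f}"
                f"{self.recall[i]:>10.4f}{self.f1[i]:>10.4f}"
            )
        lines.append(
            f"{'macro':<28}{self.macro_precision:>10.4f}"
            f"{self.macro_recall:>10.4f}{self.macro_f1:>10.4f}"
        )
        lines.append(f"accuracy: {self.accuracy:.4f}")
        return "\n".join(lines)


def confusion(
    actual: Sequence[int], predicted: Sequence[int], n_classes: int,
    labels: Sequence[str] | None = None,
) -> ConfusionMatrix:
    """Accumulate actual/predicted integer label pairs into a confusion matrix.

    Raises on length mismatch, empty input, or labels outside 0..n_classes-1.
    """
    actual = np.asarray(actual, dtype=np.int64)
    predicted = np.asarray(predicted, dtype=np.int64)
    if actual.shape != predicted.shape:
        raise ValueError(
            f"length mismatch: {actual.shape[0]} actual vs {predicted.shape[0]} predicted"
        )
    if actual.size == 0:
        raise ValueError("cannot build a confusion matrix from empty label lists")
    for name, arr in (("actual", actual), ("predicted", predicted)):
        if arr.min() < 0 or arr.max() >= n_classes:
            raise ValueError(f"{name} labels must lie in 0..{n_classes - 1}")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (actual, predicted), 1)
    return ConfusionMatrix(counts, list(labels) if labels else [])


def class_counts(cm: ConfusionMatrix, k: int) -> tuple[int, int, int, int]:
    """One-vs-rest (TP, FP, FN, TN) for class k by marginalization."""
    if not 0 <= k < cm.n_classes:
        raise ValueError(f"class index {k} out of range")
    c = cm.counts
    tp = int(c[k, k])
    fp = int(c[:, k].sum()) - tp
    fn = int(c[k, :].sum()) - tp
    tn = cm.total - tp - fp - fn
    return tp, fp, fn, tn


def _safe_div(num: float, den: float, what: str, label: str) -> float:
    if den == 0:
        warnings.warn(
            f"{what} undefined for class {label!r} (zero denominator); reporting 0",
            RuntimeWarning,
            stacklevel=3,
        )
        return 0.0
    return num / den


def report(cm: ConfusionMatrix) -> MetricsReport:
    """Per-class precision/recall/F1, overall accuracy and macro averages.

    Precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = 2PR/(P+R); overall
    accuracy = trace/total. Zero-denominator classes yield 0 with a warning.
    """
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    K = cm.n_classes
    precision = np.zeros(K)
    recall = np.zeros(K)
    f1 = np.zeros(K)
    for k in range(K):
        tp, fp, fn, _tn = class_counts(cm, k)
        precision[k] = _safe_div(tp, tp + fp, "precision", cm.labels[k])
        recall[k] = _safe_div(tp, tp + fn, "recall", cm.labels[k])
        f1[k] = _safe_div(
            2 * precision[k] * recall[k], precision[k] + recall[k], "F1", cm.labels[k]
        )
    accuracy = float(np.trace(cm.counts)) / cm.total
    return MetricsReport(
        precision=precision,
        recall=recall,
        f1=f1,
        accuracy=accuracy,
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
        labels=list(cm.labels),
    )
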