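"""Confusion matrices, accuracy, per-class sensitivity, subset pooling.

Percentages are computed exactly and rounded only at presentation, to one
decimal with round-half-up.  "Overall" figures pool the initial and extended
subsets by item-count weighting, which is algebraically identical to the
accuracy of the merged confusion matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np

from histopatch.labels import BINARY_CLASSES, CLASSES, to_binary_label

__all__ = [
    "ConfusionMatrix",
    "EvalReport",
    "confusion_and_metrics",
    "pool_subset_metrics",
    "group_labels_binary",
    "round_half_up",
]


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round with ties away from zero (the tables' convention), not banker's."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    classes: tuple[str, ...]
    counts: np.ndarray  # (K, K) int, rows = true, cols = predicted

    def __post_init__(self) -> None:
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError("counts shape must match class count")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def merged_with(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.classes != other.classes:
            raise ValueError("class sets differ")
        return ConfusionMatrix(self.classes, self.counts + other.counts)


@dataclass(frozen=True)
class EvalReport:
    task: str  # "4class" or "binary"
    granularity: str  # "patch" or "image"
    subset: str  # "initial", "extended", "overall", ...
    confusion: ConfusionMatrix
    accuracy: float  # percent, exact
    sensitivity: dict[str, float]  # percent per class, exact

    def accuracy_rounded(self) -> float:
        return round_half_up(self.accuracy, 1)

    def sensitivity_rounded(self) -> dict[str, float]:
        return {c: round_half_up(v, 1) for c, v in self.sensitivity.items()}


def confusion_and_metrics(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    classes: Sequence[str] = CLASSES,
    task: str = "4class",
    granularity: str = "image",
    subset: str = "overall",
) -> EvalReport:
    """Build the confusion matrix and derive accuracy and per-class
    sensitivity (recall), as percentages."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label lists differ in length")
    classes = tuple(classes)
    index = {c: i for i, c in enumerate(classes)}
    k = len(classes)
    counts = np.zeros((k, k), dtype=np.int64)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index:
            raise ValueError(f"unknown true label {t!r}")
        if p not in index:
            raise ValueError(f"unknown predicted label {p!r}")
        counts[index[t], index[p]] += 1
    cm = ConfusionMatrix(classes, counts)
    accuracy = 100.0 * counts.trace() / max(cm.total, 1)
    sensitivity = {}
    for c in classes:
        row = counts[index[c]]
        row_total = row.sum()
        sensitivity[c] = 100.0 * row[index[c]] / row_total if row_total else float("nan")
    return EvalReport(
        task=task, granularity=granularity, subset=subset,
        confusion=cm, accuracy=float(accuracy), sensitivity=sensitivity,
    )


def pool_subset_metrics(values: Sequence[float], weights: Sequence[float]) -> float:
    """Item-count-weighted mean of subset percentages (exact, unrounded)."""
    if len(values) != len(weights):
        raise ValueError("values and weights differ in length")
    if len(values) == 0:
        raise ValueError("nothing to pool")
    w = np.asarray(weights, dtype=np.float64)
    if np.any(w <= 0):
        raise ValueError("weights must be > 0")
    v = np.asarray(values, dtype=np.float64)
    return float((v * w).sum() / w.sum())


def group_labels_binary(labels: Sequence[str]) -> list[str]:
    """Map 4-class labels onto the carcinoma / non-carcinoma vocabulary."""
    return [to_binary_label(l) for l in labels]


def binary_report(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    granularity: str = "image",
    subset: str = "overall",
    already_binary: bool = False,
) -> EvalReport:
    t = list(true_labels) if already_binary else group_labels_binary(true_labels)
    p = list(predicted_labels) if already_binary else group_labels_binary(predicted_labels)
    return confusion_and_metrics(
        t, p, classes=BINARY_CLASSES, task="binary",
        granularity=granularity, subset=subset,
    )


def format_report(report: EvalReport) -> str:
    lines = [
        f"task={report.task} granularity={report.granularity} subset={report.subset}",
        f"accuracy: {report.accuracy_rounded()}%",
    ]
    for c, v in report.sensitivity_rounded().items():
        lines.append(f"sensitivity[{c}]: {v}%")
    header = " ".join(f"{c:>12}" for c in report.confusion.classes)
    corner = "true/pred"
    lines.append(f"{corner:>12} {header}")
    for i, c in enumerate(report.confusion.classes):
        row = " ".join(f"{n:>12d}" for n in report.confusion.counts[i])
        lines.append(f"{c:>12} {row}")
    return "\n".join(lines)
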