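"""Fuse per-patch class probabilities into one image-level label.

Three rules: majority voting over patch argmax labels, maximum probability
(the single most confident patch decides), and sum of probabilities.  All
draws — within-patch argmax ties included — resolve by malignancy priority:
invasive > in situ > benign > normal.  The binary carcinoma label groups
normal with benign and in situ with invasive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from histopatch.labels import (
    BINARY_CLASSES,
    CLASSES,
    CLASS_INDEX,
    PRIORITY,
    to_binary_label,
)

__all__ = [
    "FusionRule",
    "ImagePrediction",
    "fuse_majority",
    "fuse_max",
    "fuse_sum",
    "fuse",
    "to_binary",
    "FUSION_RULES",
]

FUSION_RULES = ("majority", "max", "sum")

#: Class indices ordered by draw priority (most malignant first).
_PRIORITY_IDX = tuple(CLASS_INDEX[c] for c in PRIORITY)


@dataclass(frozen=True)
class FusionRule:
    rule: str = "majority"
    priority: tuple[str, ...] = PRIORITY

    def __post_init__(self) -> None:
        if self.rule not in FUSION_RULES:
            raise ValueError(f"unknown fusion rule {self.rule!r}")


@dataclass(frozen=True)
class ImagePrediction:
    image_id: str
    label: str
    binary_label: str
    rule: str
    patch_probs: np.ndarray = field(compare=False, default=None)


def _check_probs(patch_probs: Sequence[np.ndarray] | np.ndarray) -> np.ndarray:
    probs = np.atleast_2d(np.asarray(patch_probs, dtype=np.float64))
    if probs.shape[0] < 1:
        raise ValueError("at least one patch is required")
    if probs.shape[1] != len(CLASSES):
        raise ValueError(f"expected {len(CLASSES)}-class probabilities")
    if np.any(probs < 0) or np.any(np.abs(probs.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("rows must be non-negative and sum to 1")
    return probs


def _argmax_priority(values: np.ndarray, priority_idx: Sequence[int] = _PRIORITY_IDX) -> int:
    """Index of the maximum value; exact ties resolve by priority order."""
    m = values.max()
    for idx in priority_idx:
        if values[idx] == m:
            return idx
    raise AssertionError("unreachable")


def _patch_labels(probs: np.ndarray) -> np.ndarray:
    return np.array([_argmax_priority(row) for row in probs], dtype=np.int64)


def fuse_majority(patch_probs, priority: Sequence[str] = PRIORITY) -> str:
    """Most common patch argmax label; all ties resolve by priority."""
    probs = _check_probs(patch_probs)
    pri_idx = [CLASS_INDEX[c] for c in priority]
    labels = np.array([_argmax_priority(row, pri_idx) for row in probs])
    counts = np.bincount(labels, minlength=len(CLASSES))
    best = counts.max()
    for idx in pri_idx:
        if counts[idx] == best:
            return CLASSES[idx]
    raise AssertionError("unreachable")


def fuse_max(patch_probs, priority: Sequence[str] = PRIORITY) -> str:
    """The patch with the globally largest class probability decides."""
    probs = _check_probs(patch_probs)
    pri_idx = [CLASS_INDEX[c] for c in priority]
    peak = probs.max()
    # classes achieving the global peak in any patch, resolved by priority
    for idx in pri_idx:
        if np.any(probs[:, idx] == peak):
            return CLASSES[idx]
    raise AssertionError("unreachable")


def fuse_sum(patch_probs, priority: Sequence[str] = PRIORITY) -> str:
    """Element-wise sum of patch probabilities; argmax with priority ties."""
    probs = _check_probs(patch_probs)
    pri_idx = [CLASS_INDEX[c] for c in priority]
    total = probs.sum(axis=0)
    return CLASSES[_argmax_priority(total, pri_idx)]


def fuse(patch_probs, rule: str = "majority", priority: Sequence[str] = PRIORITY) -> str:
    if rule == "majority":
        return fuse_majority(patch_probs, priority)
    if rule == "max":
        return fuse_max(patch_probs, priority)
    if rule == "sum":
        return fuse_sum(patch_probs, priority)
    raise ValueError(f"unknown fusion rule {rule!r}")


def group_probs_binary(probs: np.ndarray) -> np.ndarray:
    """Group 4-class probability rows into (non-carcinoma, carcinoma) rows."""
    probs = _check_probs(probs)
    non = probs[:, CLASS_INDEX["normal"]] + probs[:, CLASS_INDEX["benign"]]
    car = probs[:, CLASS_INDEX["insitu"]] + probs[:, CLASS_INDEX["invasive"]]
    return np.stack([non, car], axis=1)


def to_binary(
    prediction: str | None = None,
    patch_probs=None,
    mode: str = "label",
    rule: str = "majority",
) -> str:
    """Derive the carcinoma / non-carcinoma label.

    ``label`` mode maps the fused 4-class label through the class grouping.
    ``prob`` mode first groups the per-patch probabilities into two classes
    and re-fuses them with ``rule``; ties resolve toward carcinoma.
    """
    if mode == "label":
        if prediction is None:
            raise ValueError("label mode requires a 4-class label")
        return to_binary_label(prediction)
    if mode != "prob":
        raise ValueError(f"unknown binary mode {mode!r}")
    if patch_probs is None:
        raise ValueError("prob mode requires patch probabilities")
    grouped = group_probs_binary(np.asarray(patch_probs))
    # Re-fuse on the 2-class vectors; carcinoma (index 1) wins ties.
    if rule == "majority":
        labels = (grouped[:, 1] >= grouped[:, 0]).astype(int)
        counts = np.bincount(labels, minlength=2)
        return BINARY_CLASSES[1] if counts[1] >= counts[0] else BINARY_CLASSES[0]
    if rule == "max":
        peak = grouped.max()
        return BINARY_CLASSES[1] if np.any(grouped[:, 1] == peak) else BINARY_CLASSES[0]
    if rule == "sum":
        total = grouped.sum(axis=0)
        return BINARY_CLASSES[1] if total[1] >= total[0] else BINARY_CLASSES[0]
    raise ValueError(f"unknown fusion rule {rule!r}")


def predict_image(
    image_id: str,
    patch_probs,
    rule: str = "majority",
    binary_mode: str = "label",
) -> ImagePrediction:
    """Convenience wrapper producing the full per-image prediction record."""
    probs = _check_probs(patch_probs)
    label = fuse(probs, rule)
    if binary_mode == "label":
        binary = to_binary(prediction=label, mode="label")
    else:
        binary = to_binary(patch_probs=probs, mode="prob", rule=rule)
    return ImagePrediction(
        image_id=image_id, label=label, binary_label=binary, rule=rule,
        patch_probs=probs,
    )
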