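"""Class vocabulary shared by every pipeline stage."""

from __future__ import annotations

#: Canonical 4-class order used for probability vectors and confusion matrices.
CLASSES: tuple[str, ...] = ("normal", "benign", "insitu", "invasive")

#: Draw-resolution priority: malignant classes first.
PRIORITY: tuple[str, ...] = ("invasive", "insitu", "benign", "normal")

#: Binary task vocabulary; carcinoma first so ties resolve toward it.
BINARY_CLASSES: tuple[str, ...] = ("noncarcinoma", "carcinoma")

CARCINOMA_CLASSES = frozenset({"insitu", "invasive"})

CLASS_INDEX = {c: i for i, c in enumerate(CLASSES)}

#: Priority rank per class index (lower rank wins a tie).
PRIORITY_RANK = {c: r for r, c in enumerate(PRIORITY)}


def validate_label(label: str) -> str:
    if label not in CLASS_INDEX:
        raise ValueError(
            f"unknown label {label!r}; expected one of {sorted(CLASSES)}"
        )
    return label


def to_binary_label(label: str) -> str:
    """Group a 4-class label into carcinoma / non-carcinoma."""
    validate_label(label)
    return "carcinoma" if label in CARCINOMA_CLASSES else "noncarcinoma"
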