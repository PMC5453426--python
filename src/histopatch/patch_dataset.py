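"""Patch grids, dihedral augmentation, channel centering, dataset assembly.

Grid windows are half-open ``[r, r+size) x [c, c+size)`` in 0-based row-major
pixel coordinates.  With edge anchoring, when the stride lattice does not
reach the far edge an extra offset anchored at ``dim - patch_size`` is
appended per axis, so the grid always covers the full image.

Augmentation ids 0-7 encode the dihedral group of the square in a fixed
order: ids 0-3 are counter-clockwise rotations by ``k * 90`` degrees
(k = id), ids 4-7 are a vertical (up-down) reflection followed by the same
rotations (k = id - 4).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from histopatch.labels import validate_label

__all__ = [
    "PatchGrid",
    "PatchRecord",
    "LabeledImage",
    "plan_patch_grid",
    "augment_patch",
    "decode_augmentation",
    "apply_augmentation",
    "center_channels",
    "extract_patch",
    "iter_patch_records",
    "build_augmented_dataset",
    "count_augmented_records",
]

N_AUGMENTATIONS = 8


@dataclass(frozen=True)
class LabeledImage:
    """An 8-bit RGB image with an image-level label and provenance id."""

    image_id: str
    pixels: np.ndarray  # (H, W, 3) uint8
    label: str
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        validate_label(self.label)
        p = self.pixels
        if p.ndim != 3 or p.shape[2] != 3:
            raise ValueError(f"expected (H, W, 3) pixels, got {p.shape}")


@dataclass(frozen=True)
class PatchGrid:
    patch_size: int
    stride: int
    offsets: tuple[tuple[int, int], ...]  # row-major, strictly increasing
    edge_anchored: bool

    @property
    def n_patches(self) -> int:
        return len(self.offsets)


@dataclass(frozen=True)
class PatchRecord:
    source_image_id: str
    offset: tuple[int, int]
    augmentation_id: int
    label: str
    pixels: np.ndarray | None = None  # centered float32 when materialized

    def __post_init__(self) -> None:
        validate_label(self.label)
        if not 0 <= self.augmentation_id < N_AUGMENTATIONS:
            raise ValueError("augmentation_id must be in 0..7")


def _axis_offsets(dim: int, patch: int, stride: int, anchor: bool) -> list[int]:
    offs = list(range(0, dim - patch + 1, stride))
    if anchor and offs[-1] != dim - patch:
        offs.append(dim - patch)
    return offs


def plan_patch_grid(
    height: int,
    width: int,
    patch_size: int,
    stride: int,
    edge_anchor: bool = True,
) -> PatchGrid:
    """Enumerate patch offsets on the regular stride lattice.

    Raises ``ValueError`` if the patch does not fit or the stride is invalid.
    """
    if patch_size > min(height, width):
        raise ValueError(
            f"patch {patch_size} larger than image ({height}x{width})"
        )
    if not 1 <= stride <= patch_size:
        raise ValueError("stride must satisfy 1 <= stride <= patch_size")
    rows = _axis_offsets(height, patch_size, stride, edge_anchor)
    cols = _axis_offsets(width, patch_size, stride, edge_anchor)
    offsets = tuple((r, c) for r in rows for c in cols)
    return PatchGrid(patch_size, stride, offsets, edge_anchor)


def decode_augmentation(augmentation_id: int) -> tuple[int, bool]:
    """Return (rotation k, vertical-reflection flag) for an id in 0..7."""
    if not 0 <= augmentation_id < N_AUGMENTATIONS:
        raise ValueError("augmentation_id must be in 0..7")
    return augmentation_id % 4, augmentation_id >= 4


def apply_augmentation(patch: np.ndarray, augmentation_id: int) -> np.ndarray:
    patch = np.asarray(patch)
    if patch.shape[0] != patch.shape[1]:
        raise ValueError("augmentation requires a square patch")
    k, reflect = decode_augmentation(augmentation_id)
    out = np.flipud(patch) if reflect else patch
    return np.rot90(out, k)


def augment_patch(patch: np.ndarray) -> list[np.ndarray]:
    """All 8 dihedral transforms of a square patch, in augmentation-id order."""
    return [apply_augmentation(patch, a) for a in range(N_AUGMENTATIONS)]


def center_channels(patch: np.ndarray) -> np.ndarray:
    """Subtract the per-channel mean; returns float32 with zero-mean channels."""
    patch = np.asarray(patch)
    if patch.ndim != 3 or patch.shape[2] != 3:
        raise ValueError(f"expected a 3-channel patch, got shape {patch.shape}")
    out = patch.astype(np.float64)
    out -= out.mean(axis=(0, 1), keepdims=True)
    return out.astype(np.float32)


def extract_patch(pixels: np.ndarray, offset: tuple[int, int], size: int) -> np.ndarray:
    r, c = offset
    return pixels[r : r + size, c : c + size]


def iter_patch_records(
    image: LabeledImage,
    grid: PatchGrid,
    augment: bool = True,
    center: bool = True,
) -> Iterator[PatchRecord]:
    """Yield patch records for one image in deterministic (offset, aug) order."""
    aug_ids = range(N_AUGMENTATIONS) if augment else (0,)
    for offset in grid.offsets:
        window = extract_patch(image.pixels, offset, grid.patch_size)
        for aug_id in aug_ids:
            pix = apply_augmentation(window, aug_id)
            if center:
                pix = center_channels(pix)
            else:
                pix = np.ascontiguousarray(pix)
            yield PatchRecord(
                source_image_id=image.image_id,
                offset=offset,
                augmentation_id=aug_id,
                label=image.label,
                pixels=pix,
            )


def build_augmented_dataset(
    images: Sequence[LabeledImage],
    patch_size: int,
    stride: int,
    edge_anchor: bool = True,
    augment: bool = True,
    center: bool = True,
    skip_undersized: bool = False,
) -> list[PatchRecord]:
    """Materialize the augmented patch set for a list of labeled images.

    Records are ordered by (image, grid offset, augmentation id), so the
    output is deterministic for a fixed input ordering.
    """
    records: list[PatchRecord] = []
    for image in images:
        h, w = image.pixels.shape[:2]
        if patch_size > min(h, w):
            if skip_undersized:
                continue
            raise ValueError(
                f"image {image.image_id!r} ({h}x{w}) smaller than patch {patch_size}"
            )
        grid = plan_patch_grid(h, w, patch_size, stride, edge_anchor)
        records.extend(iter_patch_records(image, grid, augment=augment, center=center))
    return records


def count_augmented_records(
    image_shapes: Iterable[tuple[int, int]],
    patch_size: int,
    stride: int,
    edge_anchor: bool = True,
    augment: bool = True,
) -> int:
    """Record count without materializing pixels (offset enumeration only)."""
    n_aug = N_AUGMENTATIONS if augment else 1
    total = 0
    for h, w in image_shapes:
        grid = plan_patch_grid(h, w, patch_size, stride, edge_anchor)
        total += grid.n_patches * n_aug
    return total
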