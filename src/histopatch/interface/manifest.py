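"""CSV dataset manifest: one image per row, columns path,label,subset."""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from PIL import Image

from histopatch.labels import CLASSES
from histopatch.patch_dataset import LabeledImage

__all__ = [
    "ManifestEntry",
    "DatasetManifest",
    "load_manifest",
    "save_manifest",
    "load_image",
]

SUBSETS = ("train", "test_initial", "test_extended")
_COLUMNS = ("path", "label", "subset")


@dataclass(frozen=True)
class ManifestEntry:
    path: str
    label: str
    subset: str

    def __post_init__(self) -> None:
        if self.label not in CLASSES:
            raise ValueError(
                f"unknown label token {self.label!r}; expected one of {sorted(CLASSES)}"
            )
        if self.subset not in SUBSETS:
            raise ValueError(
                f"unknown subset token {self.subset!r}; expected one of {sorted(SUBSETS)}"
            )


@dataclass
class DatasetManifest:
    entries: list[ManifestEntry]
    root: Path | None = None
    validate_paths: bool = True

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for i, e in enumerate(self.entries):
            if e.path in seen:
                raise ValueError(f"duplicate image path {e.path!r} (row {i + 1})")
            seen.add(e.path)
        if self.validate_paths:
            for i, e in enumerate(self.entries):
                if not self.resolve(e).exists():
                    raise FileNotFoundError(
                        f"row {i + 1}: image file not found: {self.resolve(e)}"
                    )

    def resolve(self, entry: ManifestEntry) -> Path:
        p = Path(entry.path)
        if self.root is not None and not p.is_absolute():
            return self.root / p
        return p

    def subset(self, name: str) -> list[ManifestEntry]:
        if name not in SUBSETS:
            raise ValueError(f"unknown subset {name!r}")
        return [e for e in self.entries if e.subset == name]

    def __len__(self) -> int:
        return len(self.entries)


def load_image(manifest: DatasetManifest, entry: ManifestEntry) -> LabeledImage:
    """Load one manifest row as an 8-bit RGB :class:`LabeledImage`."""
    path = manifest.resolve(entry)
    try:
        with Image.open(path) as im:
            if im.mode != "RGB":
                raise ValueError(f"image is {im.mode}, expected 8-bit RGB: {path}")
            pixels = np.asarray(im, dtype=np.uint8)
    except (OSError, ValueError) as exc:
        raise ValueError(f"unreadable image for path {entry.path!r}: {exc}") from exc
    return LabeledImage(image_id=entry.path, pixels=pixels, label=entry.label)


def load_manifest(path: str | Path, validate_paths: bool = True) -> DatasetManifest:
    """Read and validate a CSV manifest.

    Errors name the offending row and token.  Duplicate image paths are
    rejected.  ``validate_paths=False`` skips the file-existence check
    (useful for in-memory datasets).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    entries: list[ManifestEntry] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != list(_COLUMNS):
            raise ValueError(
                f"manifest header must be {','.join(_COLUMNS)}; got {reader.fieldnames}"
            )
        for row_no, row in enumerate(reader, start=2):
            try:
                entries.append(
                    ManifestEntry(
                        path=row["path"].strip(),
                        label=row["label"].strip(),
                        subset=row["subset"].strip(),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"manifest row {row_no}: {exc}") from exc
    return DatasetManifest(entries=entries, root=path.parent, validate_paths=validate_paths)


def save_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COLUMNS)
        for e in manifest.entries:
            writer.writerow([e.path, e.label, e.subset])
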