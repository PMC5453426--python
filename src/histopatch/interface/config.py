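"""Pipeline configuration with lossless YAML round-tripping."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from histopatch.image_fusion import FUSION_RULES

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end pipeline settings.

    Defaults follow the reference protocol: 512-px patches with 50% overlap
    for training, 0.42 um/px, a 0.75 train fraction and 50 epochs.  Reduced
    geometry runs override ``patch_size`` (and usually ``epochs``).
    """

    patch_size: int = 512
    overlap_fraction: float = 0.5
    pixel_size_um: float = 0.42
    augmentations_enabled: bool = True
    stain_normalize: bool = True
    fusion_rule: str = "majority"
    binary_mode: str = "label"  # "label" | "prob"
    train_fraction: float = 0.75
    epochs: int = 50
    batch_size: int = 16
    learning_rate: float = 1e-3
    seed: int = 0
    architecture: str = "default"  # "default" | "compact"
    train_svm_head: bool = True
    svm_c_grid: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    svm_gamma_grid: tuple[float, ...] = (1e-3, 1e-2, 1e-1, 1.0)
    svm_folds: int = 3

    def __post_init__(self) -> None:
        if self.patch_size < 1:
            raise ValueError("patch_size must be >= 1")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError(
                f"overlap_fraction must lie in [0, 1); {self.overlap_fraction} "
                "gives a degenerate stride"
            )
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.fusion_rule not in FUSION_RULES:
            raise ValueError(f"unknown fusion rule {self.fusion_rule!r}")
        if self.binary_mode not in ("label", "prob"):
            raise ValueError(f"unknown binary mode {self.binary_mode!r}")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.architecture not in ("default", "compact"):
            raise ValueError(f"unknown architecture {self.architecture!r}")

    @property
    def train_stride(self) -> int:
        """Stride implied by the overlap fraction, at least 1 px."""
        return max(1, int(round(self.patch_size * (1.0 - self.overlap_fraction))))

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["svm_c_grid"] = list(self.svm_c_grid)
        data["svm_gamma_grid"] = list(self.svm_gamma_grid)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("svm_c_grid", "svm_gamma_grid"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)
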