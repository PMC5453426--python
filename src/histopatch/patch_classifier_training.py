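"""Patch-wise CNN training: image-level train/validation splitting, the
epoch loop with categorical cross-entropy and class-balanced validation
accuracy, best-weight checkpointing, and per-patch probability prediction.

The train/validation split is done at the image level so that augmented
copies of one tissue region never straddle the split.  Per-epoch validation
resampling is supported (as described) but defaults off, since resampling
leaks every image into training over enough epochs; enabling it logs a
warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from histopatch import _nn
from histopatch.labels import CLASS_INDEX
from histopatch.patch_dataset import PatchRecord

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "TrainingHistory",
    "split_train_val",
    "train_patch_classifier",
    "predict_patch_probs",
]


@dataclass(frozen=True)
class TrainConfig:
    train_fraction: float = 0.75
    epochs: int = 50
    batch_size: int = 16
    learning_rate: float = 1e-3
    optimizer: str = "adam"  # the adaptive per-parameter default
    seed: int = 0
    resample_validation_each_epoch: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


@dataclass
class EpochStats:
    epoch: int
    train_loss: float
    val_accuracy: float  # class-balanced, in [0, 1]


@dataclass
class TrainingHistory:
    epochs: list[EpochStats] = field(default_factory=list)
    best_epoch: int = -1
    best_val_accuracy: float = -1.0

    def __len__(self) -> int:
        return len(self.epochs)


def split_train_val(
    image_ids: Sequence[str], fraction: float, seed: int, epoch: int = 0
) -> tuple[list[str], list[str]]:
    """Split image ids into train / validation at the image level.

    Deterministic under ``(seed, epoch)``: the same pair always yields the
    same membership.  Train size is ``floor(n * fraction)``.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    ids = sorted(image_ids)
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate image ids")
    rng = np.random.default_rng([seed, epoch])
    perm = rng.permutation(len(ids))
    n_train = int(np.floor(len(ids) * fraction))
    train = sorted(ids[i] for i in perm[:n_train])
    val = sorted(ids[i] for i in perm[n_train:])
    return train, val


def _stack_patches(patches: Sequence[PatchRecord]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([p.pixels for p in patches]).astype(np.float32)
    y = np.array([CLASS_INDEX[p.label] for p in patches], dtype=np.int64)
    return x, y


def _balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean per-class recall over the classes present (equal class weight)."""
    recalls = []
    for c in np.unique(y_true):
        mask = y_true == c
        recalls.append(float((y_pred[mask] == c).mean()))
    return float(np.mean(recalls))


def train_patch_classifier(
    model: _nn.Sequential,
    patches: Sequence[PatchRecord],
    config: TrainConfig,
) -> tuple[_nn.Sequential, TrainingHistory]:
    """Train the patch classifier; returns the model with the best-validation
    weights restored, plus the per-epoch history."""
    labels = {p.label for p in patches}
    if len(labels) < 2:
        raise ValueError("training requires patches from at least 2 classes")

    image_ids = sorted({p.source_image_id for p in patches})
    if config.resample_validation_each_epoch:
        logger.warning(
            "per-epoch validation resampling enabled: images cross the "
            "train/validation boundary between epochs"
        )

    by_image: dict[str, list[int]] = {}
    for i, p in enumerate(patches):
        by_image.setdefault(p.source_image_id, []).append(i)

    x_all, y_all = _stack_patches(patches)
    rng = np.random.default_rng([config.seed, 0xC0FFEE])
    optimizer = _nn.Adam(learning_rate=config.learning_rate)
    history = TrainingHistory()
    best_weights = model.get_weights()

    for epoch in range(config.epochs):
        split_epoch = epoch if config.resample_validation_each_epoch else 0
        train_ids, val_ids = split_train_val(
            image_ids, config.train_fraction, config.seed, split_epoch
        )
        train_idx = np.array(
            [i for iid in train_ids for i in by_image[iid]], dtype=np.int64
        )
        val_idx = np.array(
            [i for iid in val_ids for i in by_image[iid]], dtype=np.int64
        )

        order = rng.permutation(len(train_idx))
        losses = []
        for start in range(0, len(order), config.batch_size):
            batch = train_idx[order[start : start + config.batch_size]]
            loss = model.train_batch(x_all[batch], y_all[batch], optimizer)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}, step "
                    f"{start // config.batch_size}: {loss}"
                )
            losses.append(loss)

        val_probs = model.predict_proba(x_all[val_idx], config.batch_size)
        val_acc = _balanced_accuracy(y_all[val_idx], val_probs.argmax(axis=1))
        stats = EpochStats(epoch=epoch, train_loss=float(np.mean(losses)),
                           val_accuracy=val_acc)
        history.epochs.append(stats)
        logger.info(
            "epoch %d: loss=%.4f val_balanced_acc=%.4f", epoch, stats.train_loss, val_acc
        )
        if val_acc > history.best_val_accuracy:
            history.best_val_accuracy = val_acc
            history.best_epoch = epoch
            best_weights = model.get_weights()

    model.set_weights(best_weights)
    return model, history


def save_checkpoint(model: _nn.Sequential, config: TrainConfig, path) -> None:
    """Serialize weights with the embedded architecture and train config."""
    import json
    from dataclasses import asdict
    from histopatch.network_architecture import spec_to_dict

    weights = model.get_weights()
    meta = {
        "architecture": spec_to_dict(model.spec),
        "train_config": asdict(config),
        "n_weights": len(weights),
    }
    arrays = {f"w{i}": w for i, w in enumerate(weights)}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path) -> tuple[_nn.Sequential, TrainConfig]:
    import json
    from histopatch.network_architecture import spec_from_dict

    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        spec = spec_from_dict(meta["architecture"])
        model = _nn.Sequential.from_spec(spec, seed=0)
        weights = [data[f"w{i}"] for i in range(meta["n_weights"])]
    model.set_weights(weights)
    return model, TrainConfig(**meta["train_config"])


def predict_patch_probs(
    model: _nn.Sequential, patches: Sequence[PatchRecord], batch_size: int = 16
) -> np.ndarray:
    """Per-patch class probabilities, one row per input patch, rows sum to 1."""
    expected = model.spec.input_shape
    for p in patches:
        if p.pixels is None or p.pixels.shape != expected:
            raise ValueError(
                f"patch geometry {None if p.pixels is None else p.pixels.shape} "
                f"does not match model input {expected}"
            )
    x = np.stack([p.pixels for p in patches]).astype(np.float32)
    return model.predict_proba(x, batch_size)
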