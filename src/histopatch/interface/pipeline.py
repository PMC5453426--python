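"""End-to-end orchestration: normalize -> patchify -> train -> predict ->
fuse -> evaluate, with every artifact written under a run directory.

All randomness flows from ``config.seed``; two runs with identical config
and seed produce byte-identical prediction tables.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from histopatch import _nn
from histopatch.evaluation import EvalReport, binary_report, confusion_and_metrics
from histopatch.image_fusion import predict_image, ImagePrediction
from histopatch.interface.config import PipelineConfig
from histopatch.interface.manifest import DatasetManifest, ManifestEntry, load_image
from histopatch.labels import CLASSES, to_binary_label
from histopatch.network_architecture import (
    build_model,
    compact_architecture,
    default_architecture,
)
from histopatch.patch_classifier_training import (
    TrainConfig,
    TrainingHistory,
    predict_patch_probs,
    train_patch_classifier,
)
from histopatch.patch_dataset import (
    LabeledImage,
    build_augmented_dataset,
    iter_patch_records,
    plan_patch_grid,
)
from histopatch.stain_norm import StainNormParams, normalize_image
from histopatch.svm_head import (
    SvmConfig,
    extract_fc_features,
    fit_feature_svm,
    predict_svm_probs,
)

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "PipelineResult", "PipelineStageError"]


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class PipelineResult:
    reports: dict[tuple[str, str, str, str], EvalReport]
    # key: (classifier, task, granularity, subset)
    predictions: dict[str, list[ImagePrediction]]  # classifier -> per image
    history: TrainingHistory
    run_dir: Path | None

    def report(self, classifier: str = "cnn", task: str = "4class",
               granularity: str = "image", subset: str = "overall") -> EvalReport:
        return self.reports[(classifier, task, granularity, subset)]


def _load_images(manifest: DatasetManifest,
                 images: Sequence[LabeledImage] | None) -> dict[str, LabeledImage]:
    if images is not None:
        by_id = {img.image_id: img for img in images}
        missing = [e.path for e in manifest.entries if e.path not in by_id]
        if missing:
            raise ValueError(f"in-memory images missing for manifest paths: {missing[:5]}")
        return {e.path: by_id[e.path] for e in manifest.entries}
    return {e.path: load_image(manifest, e) for e in manifest.entries}


def _check_coverage(manifest: DatasetManifest) -> None:
    train_labels = {e.label for e in manifest.subset("train")}
    test_labels = {
        e.label
        for e in manifest.entries
        if e.subset in ("test_initial", "test_extended")
    }
    for required, side in ((train_labels, "train"), (test_labels, "test")):
        missing = set(CLASSES) - required
        if missing:
            raise ValueError(f"{side} subset lacks images for classes: {sorted(missing)}")


def _write_patch_csv(path: Path, rows: list[tuple]) -> None:
    header = ["image_id", "row", "col"] + [f"p_{c}" for c in CLASSES] + [
        "fused_label", "binary_label",
    ]
    lines = [",".join(header)]
    for r in rows:
        lines.append(",".join(str(v) for v in r))
    path.write_text("\n".join(lines) + "\n")


def run_pipeline(
    config: PipelineConfig,
    manifest: DatasetManifest,
    images: Sequence[LabeledImage] | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Execute the full pipeline on a manifest.

    ``images`` may supply the pixel data in memory (ids matching manifest
    paths); otherwise images are loaded from disk.  When ``out_dir`` is set,
    the config, prediction tables and evaluation reports are written there.
    """
    run_dir = Path(out_dir) if out_dir is not None else None
    if run_dir is not None:
        run_dir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(run_dir / "config.yaml")

    stage = "load"
    try:
        _check_coverage(manifest)
        loaded = _load_images(manifest, images)

        stage = "normalize"
        t0 = time.perf_counter()
        if config.stain_normalize:
            params = StainNormParams()
            loaded = {
                k: LabeledImage(v.image_id, normalize_image(v.pixels, params),
                                v.label, v.meta)
                for k, v in loaded.items()
            }
        logger.info("normalize: %d images in %.1fs", len(loaded), time.perf_counter() - t0)

        stage = "patchify"
        train_images = [loaded[e.path] for e in manifest.subset("train")]
        train_patches = build_augmented_dataset(
            train_images,
            patch_size=config.patch_size,
            stride=config.train_stride,
            edge_anchor=True,
            augment=config.augmentations_enabled,
        )
        logger.info("patchify: %d training patches", len(train_patches))

        stage = "train"
        if config.architecture == "default":
            arch = default_architecture(config.patch_size)
        else:
            arch = compact_architecture(config.patch_size)
        model = build_model(arch, seed=config.seed)
        train_cfg = TrainConfig(
            train_fraction=config.train_fraction,
            epochs=config.epochs,
            batch_size=config.batch_size,
            learning_rate=config.learning_rate,
            seed=config.seed,
        )
        model, history = train_patch_classifier(model, train_patches, train_cfg)

        stage = "predict"
        test_entries = [
            e for e in manifest.entries if e.subset in ("test_initial", "test_extended")
        ]
        heads = {"cnn": None}
        if config.train_svm_head:
            svm_cfg = SvmConfig(
                c_grid=config.svm_c_grid, gamma_grid=config.svm_gamma_grid,
                folds=config.svm_folds, seed=config.seed,
            )
            # the SVM mirrors the CNN's training set (same patches, same
            # augmentation state), so its features stay on-distribution
            train_feats = extract_fc_features(model, train_patches)
            svm = fit_feature_svm(train_feats, [p.label for p in train_patches], svm_cfg)
            heads["svm"] = svm

        predictions: dict[str, list[ImagePrediction]] = {h: [] for h in heads}
        patch_rows: dict[str, list[tuple]] = {h: [] for h in heads}
        patch_truth: list[str] = []
        patch_subset: list[str] = []
        patch_preds: dict[str, list[str]] = {h: [] for h in heads}

        for entry in test_entries:
            image = loaded[entry.path]
            h, w = image.pixels.shape[:2]
            grid = plan_patch_grid(h, w, config.patch_size, config.patch_size,
                                   edge_anchor=True)
            records = list(iter_patch_records(image, grid, augment=False))
            cnn_probs = predict_patch_probs(model, records, config.batch_size)
            probs_by_head = {"cnn": cnn_probs}
            if "svm" in heads:
                feats = extract_fc_features(model, records)
                probs_by_head["svm"] = predict_svm_probs(heads["svm"], feats)

            patch_truth.extend([entry.label] * len(records))
            patch_subset.extend([entry.subset] * len(records))
            for head, probs in probs_by_head.items():
                pred = predict_image(entry.path, probs, rule=config.fusion_rule,
                                     binary_mode=config.binary_mode)
                predictions[head].append(pred)
                for rec, p in zip(records, probs):
                    patch_rows[head].append(
                        (entry.path, rec.offset[0], rec.offset[1])
                        + tuple(f"{v:.6f}" for v in p)
                        + (pred.label, pred.binary_label)
                    )
                patch_preds[head].extend(
                    CLASSES[int(np.argmax(p))] for p in probs
                )

        stage = "evaluate"
        reports: dict[tuple[str, str, str, str], EvalReport] = {}
        subset_names = sorted({e.subset for e in test_entries})
        for head in heads:
            truth_by_img = [
                next(e.label for e in test_entries if e.path == p.image_id)
                for p in predictions[head]
            ]
            subset_by_img = [
                next(e.subset for e in test_entries if e.path == p.image_id)
                for p in predictions[head]
            ]
            pred_by_img = [p.label for p in predictions[head]]

            scopes = [("overall", [True] * len(pred_by_img))]
            if len(subset_names) > 1:
                for s in subset_names:
                    scopes.append((s, [ss == s for ss in subset_by_img]))
            for scope, mask in scopes:
                t = [l for l, m in zip(truth_by_img, mask) if m]
                p = [l for l, m in zip(pred_by_img, mask) if m]
                reports[(head, "4class", "image", scope)] = confusion_and_metrics(
                    t, p, subset=scope, granularity="image",
                )
                reports[(head, "binary", "image", scope)] = binary_report(
                    t, p, subset=scope, granularity="image",
                )
            reports[(head, "4class", "patch", "overall")] = confusion_and_metrics(
                patch_truth, patch_preds[head], subset="overall", granularity="patch",
            )
            reports[(head, "binary", "patch", "overall")] = binary_report(
                patch_truth, patch_preds[head], subset="overall", granularity="patch",
            )

        if run_dir is not None:
            for head in heads:
                _write_patch_csv(run_dir / f"predictions_{head}.csv", patch_rows[head])
            summary = ["classifier,task,granularity,subset,accuracy_percent"]
            for (head, task, gran, scope), rep in sorted(reports.items()):
                summary.append(f"{head},{task},{gran},{scope},{rep.accuracy_rounded()}")
            (run_dir / "reports.csv").write_text("\n".join(summary) + "\n")

        return PipelineResult(
            reports=reports, predictions=predictions, history=history, run_dir=run_dir,
        )
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc
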