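"""CNN+SVM variant: RBF-kernel SVM on the activations of the second
fully-connected layer, tuned by exhaustive grid search with stratified
3-fold cross-validation, then refit on the whole training set.

Probability outputs (Platt-style calibration as provided by scikit-learn's
``SVC(probability=True)``) make the SVM head interchangeable with the CNN
head for every fusion rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from histopatch import _nn
from histopatch.labels import CLASSES, CLASS_INDEX
from histopatch.patch_dataset import PatchRecord

__all__ = [
    "SvmConfig",
    "FeatureSvm",
    "extract_fc_features",
    "fit_feature_svm",
    "predict_svm_probs",
]

_DEFAULT_C_GRID = (0.1, 1.0, 10.0, 100.0)
_DEFAULT_GAMMA_GRID = (1e-3, 1e-2, 1e-1, 1.0)


@dataclass(frozen=True)
class SvmConfig:
    c_grid: tuple[float, ...] = _DEFAULT_C_GRID
    gamma_grid: tuple[float, ...] = _DEFAULT_GAMMA_GRID
    folds: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.c_grid or not self.gamma_grid:
            raise ValueError("parameter grids must be non-empty")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


@dataclass
class FeatureSvm:
    classifier: object  # calibrated scaler+SVC pipeline
    best_c: float
    best_gamma: float
    cv_accuracy: float
    grid_report: list[tuple[float, float, float]]  # (C, gamma, mean CV acc)
    n_features: int


def extract_fc_features(
    model: _nn.Sequential,
    patches: Sequence[PatchRecord],
    fc_index: int = 1,
    batch_size: int = 16,
) -> np.ndarray:
    """Post-ReLU activations of the ``fc_index``-th fully-connected layer
    (0-based; default the second fc layer), one row per patch."""
    fc_layers = model.spec.fc_layer_indices()
    if len(fc_layers) < fc_index + 1:
        raise ValueError(
            f"architecture has {len(fc_layers)} fc layers; need >= {fc_index + 1}"
        )
    spec_layer = fc_layers[fc_index]
    chunks = []
    for i in range(0, len(patches), batch_size):
        x = np.stack([p.pixels for p in patches[i : i + batch_size]]).astype(np.float32)
        chunks.append(model.activations_at_spec_layer(x, spec_layer, batch_size))
    return np.concatenate(chunks, axis=0)


def fit_feature_svm(
    features: np.ndarray,
    labels: Sequence[str],
    config: SvmConfig | None = None,
) -> FeatureSvm:
    """Exhaustive (C, gamma) grid search by stratified k-fold CV accuracy,
    then refit on the full training set with probability outputs."""
    config = config or SvmConfig()
    x = np.asarray(features, dtype=np.float64)
    y = np.array([CLASS_INDEX[l] for l in labels], dtype=np.int64)
    counts = np.bincount(y, minlength=len(CLASSES))
    present = counts[counts > 0]
    if np.any(present < config.folds):
        raise ValueError(
            f"every class needs >= {config.folds} samples for {config.folds}-fold CV"
        )

    def make_svc(c: float, gamma: float) -> Pipeline:
        # features are post-ReLU activations with arbitrary scale; standardize.
        # libsvm trains one-vs-one internally; the exposed decision function
        # must stay 'ovr' for multiclass sigmoid calibration to be valid.
        return Pipeline([
            ("scale", StandardScaler()),
            ("svc", SVC(kernel="rbf", C=c, gamma=gamma)),
        ])

    cv = StratifiedKFold(n_splits=config.folds, shuffle=True, random_state=config.seed)
    splits = list(cv.split(x, y))
    report: list[tuple[float, float, float]] = []
    best = (-1.0, None, None)
    for c in config.c_grid:
        for gamma in config.gamma_grid:
            accs = []
            for train_idx, test_idx in splits:
                clf = make_svc(c, gamma)
                clf.fit(x[train_idx], y[train_idx])
                accs.append(float((clf.predict(x[test_idx]) == y[test_idx]).mean()))
            mean_acc = float(np.mean(accs))
            report.append((c, gamma, mean_acc))
            if mean_acc > best[0]:
                best = (mean_acc, c, gamma)

    cv_acc, best_c, best_gamma = best
    # Platt-style posterior calibration fit on CV folds, then the calibrated
    # ensemble of the winning (C, gamma) refit over the whole training set.
    final = CalibratedClassifierCV(
        make_svc(best_c, best_gamma), method="sigmoid",
        cv=StratifiedKFold(n_splits=config.folds, shuffle=True,
                           random_state=config.seed),
        ensemble=False,
    )
    final.fit(x, y)
    return FeatureSvm(
        classifier=final, best_c=best_c, best_gamma=best_gamma,
        cv_accuracy=cv_acc, grid_report=report, n_features=x.shape[1],
    )


def predict_svm_probs(svm: FeatureSvm, features: np.ndarray) -> np.ndarray:
    """Per-patch class probabilities in canonical class order."""
    x = np.asarray(features, dtype=np.float64)
    if x.shape[1] != svm.n_features:
        raise ValueError(
            f"feature length {x.shape[1]} does not match training ({svm.n_features})"
        )
    raw = svm.classifier.predict_proba(x)
    probs = np.zeros((x.shape[0], len(CLASSES)), dtype=np.float64)
    for col, cls_idx in enumerate(svm.classifier.classes_):
        probs[:, int(cls_idx)] = raw[:, col]
    # renormalize away any calibration drift so downstream contracts hold
    probs /= probs.sum(axis=1, keepdims=True)
    return probs
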