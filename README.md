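# histopatch

Patch-based, multi-scale CNN pipeline for classifying H&E-stained breast
histology images into **normal / benign / in situ carcinoma / invasive
carcinoma** (plus the grouped **carcinoma / non-carcinoma** binary task).

The pipeline comprises:

- **Stain normalization** (`histopatch.stain_norm`) — decadic optical-density
  transform, SVD estimation of the 2D stain plane, per-stain concentration
  recovery, and a histogram stretch covering the lower 90% of the data.
- **Patch dataset** (`histopatch.patch_dataset`) — 512×512 patch grids with
  50% overlap and edge anchoring (35 training / 12 inference patches on a
  2040×1536 image), 8-fold dihedral augmentation, per-patch channel centering.
- **Network architecture** (`histopatch.network_architecture`) — the 13-layer
  stack (conv16-pool3 / conv32-pool2 / conv64-pool2 / conv64-pool3 /
  conv32-pool3 / fc256 / fc128 / fc4) as a declarative spec with shape and
  effective-receptive-field propagation (3→224 px; ×0.42 µm/px).
- **NumPy model backend** (`histopatch._nn`) — seeded im2col convolutions,
  max pooling with stride equal to pool size, dense layers, softmax
  cross-entropy and Adam. No deep-learning framework is required.
- **Training** (`histopatch.patch_classifier_training`) — image-level 75/25
  train/validation split, class-balanced validation accuracy, best-epoch
  checkpointing, optional per-epoch validation resampling.
- **Fusion** (`histopatch.image_fusion`) — majority / max / sum patch
  probability fusion with malignancy-priority draw resolution
  (invasive → in situ → benign → normal) and binary grouping.
- **SVM head** (`histopatch.svm_head`) — RBF SVM on the second
  fully-connected layer's 128 activations, exhaustive (C, γ) grid search with
  stratified 3-fold CV, probability calibration for fusion compatibility.
- **Evaluation** (`histopatch.evaluation`) — confusion matrices, accuracy,
  per-class sensitivity, count-weighted subset pooling, 1-decimal
  round-half-up presentation.
- **Synthetic fixtures** (`histopatch.synthetic_fixtures`) — seeded
  histology-like image generator with class-dependent nucleus density, size
  variability and spatial organization, so the whole pipeline runs offline.

## CLI

```bash
histopatch synth --out-dir data --images-per-class 8 --test-per-class 2 --seed 7
histopatch rf-report                        # per-layer shapes + receptive fields
histopatch normalize --manifest data/manifest.csv --out-dir normed
histopatch run --manifest data/manifest.csv --seed 7 --out-dir runs/demo
histopatch train   --manifest data/manifest.csv --out-dir runs/model
histopatch predict --manifest data/manifest.csv --model runs/model/model.npz --out-dir runs/pred
histopatch evaluate --manifest data/manifest.csv --predictions runs/pred/predictions.csv
```

The dataset manifest is a CSV with header `path,label,subset`; labels are
`normal|benign|insitu|invasive`, subsets `train|test_initial|test_extended`.
Run directories record the full config (`config.yaml`), per-patch prediction
tables (`predictions_*.csv`) and evaluation summaries (`reports.csv`); every
artifact is regenerable from the recorded config and seed.

## Defaults

Patch size 512, overlap 0.5, pixel size 0.42 µm/px, train fraction 0.75,
50 epochs, seed-controlled throughout. Reduced-geometry runs (e.g. 256-px
patches on 512×384 synthetic images) use the same layer stack on a smaller
input; a `compact` architecture is available for very small patches.
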