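"""Seeded generator of histology-like labeled RGB images.

Classes differ along the axes a pathologist would use: nucleus density,
nucleus size and size variability, and spatial organization (regular lattice,
clustered, or disordered).  Nuclei are rendered as filled ellipses in the
purple family over a textured pink background; a light Gaussian blur softens
edges.  Everything is a pure function of (spec, dims, seed).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import ellipse

from histopatch.labels import CLASSES, validate_label
from histopatch.patch_dataset import LabeledImage

__all__ = [
    "SyntheticClassSpec",
    "SyntheticDatasetConfig",
    "render_tissue_image",
    "generate_labeled_dataset",
    "default_class_suite",
    "identical_class_suite",
]

_ORGANIZATIONS = ("regular", "clustered", "disordered")


@dataclass(frozen=True)
class SyntheticClassSpec:
    label: str
    density_per_1e4px: float  # expected nuclei per 10^4 px^2
    radius_range: tuple[float, float] = (3.0, 11.0)
    radius_variability: float = 0.1  # eccentricity / per-nucleus radius jitter
    organization: str = "disordered"
    nucleus_color: tuple[int, int, int] = (100, 60, 150)  # purple family
    nucleus_color_spread: float = 12.0
    background_color: tuple[int, int, int] = (235, 205, 220)  # pink family
    background_spread: float = 6.0

    def __post_init__(self) -> None:
        validate_label(self.label)
        if self.density_per_1e4px <= 0:
            raise ValueError("density must be > 0")
        if self.organization not in _ORGANIZATIONS:
            raise ValueError(f"unknown organization {self.organization!r}")
        lo, hi = self.radius_range
        if not 1 <= lo <= hi:
            raise ValueError("radius range must satisfy 1 <= lo <= hi")


@dataclass(frozen=True)
class SyntheticDatasetConfig:
    dims: tuple[int, int] = (512, 384)  # (width, height)
    images_per_class_train: int = 8
    images_per_class_test: int = 2
    images_per_class_test_extended: int = 0
    seed: int = 0
    suite: dict[str, SyntheticClassSpec] | None = None  # default_class_suite()

    def resolved_suite(self) -> dict[str, SyntheticClassSpec]:
        suite = self.suite if self.suite is not None else default_class_suite()
        if set(suite) != set(CLASSES):
            raise ValueError("suite must define exactly the four classes")
        return suite


def default_class_suite() -> dict[str, SyntheticClassSpec]:
    """Four class phenotypes ordered so that density and variability follow
    invasive > insitu > benign >= normal."""
    return {
        "normal": SyntheticClassSpec(
            label="normal", density_per_1e4px=3.0, radius_range=(4.0, 6.0),
            radius_variability=0.05, organization="regular",
        ),
        "benign": SyntheticClassSpec(
            label="benign", density_per_1e4px=9.0, radius_range=(4.0, 7.0),
            radius_variability=0.10, organization="regular",
        ),
        "insitu": SyntheticClassSpec(
            label="insitu", density_per_1e4px=20.0, radius_range=(3.0, 8.0),
            radius_variability=0.20, organization="clustered",
        ),
        "invasive": SyntheticClassSpec(
            label="invasive", density_per_1e4px=40.0, radius_range=(3.0, 10.0),
            radius_variability=0.35, organization="disordered",
        ),
    }


def identical_class_suite() -> dict[str, SyntheticClassSpec]:
    """All four labels share one phenotype — the no-signal control suite."""
    base = default_class_suite()["benign"]
    return {c: replace(base, label=c) for c in CLASSES}


def _place_centers(spec: SyntheticClassSpec, height: int, width: int,
                   n: int, rng: np.random.Generator) -> np.ndarray:
    if n == 0:
        return np.empty((0, 2))
    if spec.organization == "disordered":
        return np.column_stack([rng.uniform(0, height, n), rng.uniform(0, width, n)])
    if spec.organization == "clustered":
        n_clusters = max(1, int(round(n / 12)))
        centers = np.column_stack(
            [rng.uniform(0, height, n_clusters), rng.uniform(0, width, n_clusters)]
        )
        idx = rng.integers(0, n_clusters, n)
        sigma = 0.06 * min(height, width)
        pts = centers[idx] + rng.normal(0, sigma, (n, 2))
        return np.clip(pts, 0, [height - 1, width - 1])
    # regular: jittered hexagonal-ish lattice, take the first n sites
    spacing = np.sqrt(height * width / max(n, 1))
    rows = np.arange(spacing / 2, height, spacing)
    cols = np.arange(spacing / 2, width, spacing)
    grid = np.array([(r, c) for r in rows for c in cols])
    jitter = rng.normal(0, spacing * 0.12, grid.shape)
    pts = np.clip(grid + jitter, 0, [height - 1, width - 1])
    if len(pts) >= n:
        order = rng.permutation(len(pts))[:n]
        return pts[order]
    extra = np.column_stack(
        [rng.uniform(0, height, n - len(pts)), rng.uniform(0, width, n - len(pts))]
    )
    return np.vstack([pts, extra])


def render_tissue_image(
    spec: SyntheticClassSpec,
    dims: tuple[int, int],
    seed: int,
    image_id: str | None = None,
) -> LabeledImage:
    """Render one labeled image; deterministic in (spec, dims, seed).

    ``dims`` is (width, height) to mirror how image sizes are quoted.
    The realized nucleus count is stored in ``meta['nucleus_count']``.
    """
    width, height = dims
    rng = np.random.default_rng(seed)

    bg = np.array(spec.background_color, dtype=np.float64)
    img = bg + rng.normal(0, spec.background_spread, (height, width, 3))
    # low-frequency eosin texture
    texture = gaussian_filter(rng.normal(0, 18.0, (height, width)), sigma=12)
    img += texture[..., None] * np.array([0.6, 0.9, 0.7])

    mean_count = spec.density_per_1e4px * height * width / 1e4
    n = int(rng.poisson(mean_count))
    centers = _place_centers(spec, height, width, n, rng)

    lo, hi = spec.radius_range
    for r, c in centers:
        base_r = rng.uniform(lo, hi)
        ecc = 1.0 + abs(rng.normal(0, spec.radius_variability))
        angle = rng.uniform(0, np.pi)
        color = np.array(spec.nucleus_color) + rng.normal(
            0, spec.nucleus_color_spread, 3
        )
        rr, cc = ellipse(
            r, c, base_r * ecc, base_r / ecc, shape=(height, width), rotation=angle
        )
        img[rr, cc] = 0.85 * color + 0.15 * img[rr, cc]

    img = gaussian_filter(img, sigma=(0.6, 0.6, 0))
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    if image_id is None:
        image_id = f"{spec.label}-{width}x{height}-s{seed}"
    return LabeledImage(
        image_id=image_id, pixels=pixels, label=spec.label,
        meta={"nucleus_count": int(n), "seed": int(seed)},
    )


def _stable_seed(master_seed: int, *parts) -> int:
    digest = hashlib.sha256(repr((master_seed,) + parts).encode()).digest()
    return int.from_bytes(digest[:8], "little")


def generate_labeled_dataset(
    config: SyntheticDatasetConfig,
) -> tuple[list[LabeledImage], "DatasetManifest"]:
    """Balanced, seeded dataset plus its manifest (paths unset until saved)."""
    from histopatch.interface.manifest import DatasetManifest, ManifestEntry

    suite = config.resolved_suite()
    subsets = (
        ("train", config.images_per_class_train),
        ("test_initial", config.images_per_class_test),
        ("test_extended", config.images_per_class_test_extended),
    )
    images: list[LabeledImage] = []
    entries: list[ManifestEntry] = []
    for subset, count in subsets:
        for label in CLASSES:
            spec = suite[label]
            for i in range(count):
                seed = _stable_seed(config.seed, subset, label, i)
                image_id = f"{subset}-{label}-{i:03d}.png"
                img = render_tissue_image(spec, config.dims, seed, image_id=image_id)
                images.append(img)
                entries.append(
                    ManifestEntry(path=image_id, label=label, subset=subset)
                )
    return images, DatasetManifest(entries=entries, validate_paths=False)
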