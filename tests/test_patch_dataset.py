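import numpy as np
import pytest

from histopatch.patch_dataset import (
    LabeledImage,
    N_AUGMENTATIONS,
    apply_augmentation,
    augment_patch,
    build_augmented_dataset,
    center_channels,
    count_augmented_records,
    decode_augmentation,
    extract_patch,
    iter_patch_records,
    plan_patch_grid,
)


def brute_force_offsets(dim, patch, stride, anchor):
    offs = [r for r in range(0, dim - patch + 1) if r % stride == 0]
    if anchor and offs[-1] != dim - patch:
        offs.append(dim - patch)
    return offs


class TestPlanPatchGrid:
    def test_training_grid_2040x1536(self):
        grid = plan_patch_grid(1536, 2040, 512, 256, edge_anchor=True)
        assert grid.n_patches == 35  # 5 rows x 7 columns
        rows = sorted({r for r, _ in grid.offsets})
        cols = sorted({c for _, c in grid.offsets})
        assert len(rows) == 5 and len(cols) == 7
        assert cols[-1] == 2040 - 512  # anchored final column

    def test_inference_grid_2040x1536(self):
        grid = plan_patch_grid(1536, 2040, 512, 512, edge_anchor=True)
        assert grid.n_patches == 12  # 3 rows x 4 columns

    def test_exact_fit_single_offset(self):
        grid = plan_patch_grid(512, 512, 512, 256, edge_anchor=True)
        assert grid.offsets == ((0, 0),)

    def test_patch_larger_than_image(self):
        with pytest.raises(ValueError):
            plan_patch_grid(100, 100, 128, 64)

    def test_bad_stride(self):
        with pytest.raises(ValueError):
            plan_patch_grid(512, 512, 256, 0)
        with pytest.raises(ValueError):
            plan_patch_grid(512, 512, 256, 300)

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(1000):
            patch = int(rng.integers(1, 40)) * 2
            dim = int(rng.integers(patch, 4 * patch))
            stride = patch // 2
            expected = brute_force_offsets(dim, patch, stride, True)
            grid = plan_patch_grid(dim, dim, patch, stride, edge_anchor=True)
            rows = sorted({r for r, _ in grid.offsets})
            assert rows == expected
            # closed-form count check
            extra = 1 if (dim - patch) % stride else 0
            assert len(rows) == (dim - patch) // stride + 1 + extra

    def test_transpose_symmetry(self, rng):
        for _ in range(50):
            h = int(rng.integers(64, 300))
            w = int(rng.integers(64, 300))
            g1 = plan_patch_grid(h, w, 64, 32, edge_anchor=True)
            g2 = plan_patch_grid(w, h, 64, 32, edge_anchor=True)
            assert sorted({r for r, _ in g1.offsets}) == sorted({c for _, c in g2.offsets})

    def test_windows_inside_image(self):
        grid = plan_patch_grid(130, 170, 64, 32, edge_anchor=True)
        for r, c in grid.offsets:
            assert 0 <= r <= 130 - 64 and 0 <= c <= 170 - 64
        assert len(set(grid.offsets)) == grid.n_patches
        assert list(grid.offsets) == sorted(grid.offsets)


class TestAugmentation:
    def test_eight_distinct_for_generic_patch(self, rng):
        patch = rng.integers(0, 256, (16, 16, 3)).astype(np.uint8)
        outs = augment_patch(patch)
        assert len(outs) == N_AUGMENTATIONS
        keys = {o.tobytes() for o in outs}
        assert len(keys) == 8

    def test_constant_patch_all_equal(self):
        patch = np.full((8, 8, 3), 7, dtype=np.uint8)
        outs = augment_patch(patch)
        assert all(np.array_equal(o, patch) for o in outs)

    def test_dihedral_closure(self, rng):
        patch = rng.integers(0, 256, (12, 12, 3)).astype(np.uint8)
        base = {o.tobytes() for o in augment_patch(patch)}
        for o in augment_patch(patch):
            regenerated = {x.tobytes() for x in augment_patch(o)}
            assert regenerated == base

    def test_decode_bijective(self):
        seen = set()
        for a in range(8):
            k, reflect = decode_augmentation(a)
            assert 0 <= k <= 3
            seen.add((k, reflect))
        assert len(seen) == 8

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            apply_augmentation(np.zeros((4, 6, 3)), 1)


class TestCenterChannels:
    def test_constant_patch_zeroed(self):
        patch = np.full((8, 8, 3), (10, 20, 30), dtype=np.uint8)
        out = center_channels(patch)
        assert np.allclose(out, 0.0)
        assert out.dtype == np.float32

    def test_zero_mean_property(self, rng):
        patch = rng.integers(0, 256, (32, 32, 3)).astype(np.uint8)
        out = center_channels(patch)
        assert np.abs(out.mean(axis=(0, 1))).max() < 1e-6

    def test_shift_invariance(self, rng):
        patch = rng.integers(0, 200, (16, 16, 3)).astype(np.int64)
        shifted = patch + np.array([5, 11, 23])
        assert np.allclose(center_channels(patch), center_channels(shifted), atol=1e-4)

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            center_channels(np.zeros((8, 8)))


class TestDatasetAssembly:
    def test_single_full_size_image_gives_280_records(self):
        assert count_augmented_records([(1536, 2040)], 512, 256) == 35 * 8

    def test_250_images_give_70000_records(self):
        shapes = [(1536, 2040)] * 250
        assert count_augmented_records(shapes, 512, 256) == 70000

    def test_augmentation_disabled_gives_35(self):
        assert count_augmented_records([(1536, 2040)], 512, 256, augment=False) == 35

    def test_records_inherit_label_and_order(self, rng):
        pixels = rng.integers(0, 256, (96, 128, 3)).astype(np.uint8)
        image = LabeledImage("img-1", pixels, "insitu")
        records = build_augmented_dataset([image], 64, 32)
        grid = plan_patch_grid(96, 128, 64, 32)
        assert len(records) == grid.n_patches * 8
        assert all(r.label == "insitu" for r in records)
        assert all(r.source_image_id == "img-1" for r in records)
        expected_order = [(o, a) for o in grid.offsets for a in range(8)]
        assert [(r.offset, r.augmentation_id) for r in records] == expected_order

    def test_undersized_image_raises_or_skips(self, rng):
        small = LabeledImage("tiny", rng.integers(0, 255, (32, 32, 3)).astype(np.uint8), "normal")
        with pytest.raises(ValueError):
            build_augmented_dataset([small], 64, 32)
        assert build_augmented_dataset([small], 64, 32, skip_undersized=True) == []

    def test_reassembly_exact(self, rng):
        pixels = rng.integers(0, 256, (128, 192, 3)).astype(np.uint8)
        image = LabeledImage("img", pixels, "normal")
        grid = plan_patch_grid(128, 192, 64, 64, edge_anchor=False)
        recon = np.zeros_like(pixels)
        for rec in iter_patch_records(image, grid, augment=False, center=False):
            r, c = rec.offset
            recon[r : r + 64, c : c + 64] = rec.pixels
        assert np.array_equal(recon, pixels)

    def test_extract_patch_window(self, rng):
        pixels = rng.integers(0, 256, (64, 64, 3)).astype(np.uint8)
        win = extract_patch(pixels, (8, 16), 32)
        assert np.array_equal(win, pixels[8:40, 16:48])
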