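import numpy as np
import pytest
from click.testing import CliRunner
from PIL import Image

from histopatch.interface.cli import main as cli_main
from histopatch.interface.config import PipelineConfig
from histopatch.interface.manifest import (
    DatasetManifest,
    ManifestEntry,
    load_image,
    load_manifest,
    save_manifest,
)
from histopatch.interface.pipeline import PipelineStageError, run_pipeline
from histopatch.labels import CLASSES
from histopatch.synthetic_fixtures import SyntheticDatasetConfig, generate_labeled_dataset


def _write_images(tmp_path, rng, names_labels):
    rows = ["path,label,subset"]
    for name, label, subset in names_labels:
        pixels = rng.integers(0, 256, (32, 32, 3)).astype(np.uint8)
        Image.fromarray(pixels).save(tmp_path / name)
        rows.append(f"{name},{label},{subset}")
    manifest_path = tmp_path / "manifest.csv"
    manifest_path.write_text("\n".join(rows) + "\n")
    return manifest_path


class TestManifest:
    def test_four_row_manifest(self, tmp_path, rng):
        path = _write_images(tmp_path, rng, [
            (f"{c}.png", c, "train") for c in CLASSES
        ])
        manifest = load_manifest(path)
        assert len(manifest) == 4
        assert {e.label for e in manifest.entries} == set(CLASSES)
        img = load_image(manifest, manifest.entries[0])
        assert img.pixels.shape == (32, 32, 3)

    def test_unknown_label_names_row_and_token(self, tmp_path, rng):
        path = _write_images(tmp_path, rng, [("a.png", "normal", "train")])
        path.write_text(path.read_text() + "b.png,cancer,train\n")
        with pytest.raises(ValueError, match=r"row 3.*cancer"):
            load_manifest(path, validate_paths=False)

    def test_missing_manifest(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_manifest(tmp_path / "nope.csv")

    def test_missing_image_reported_with_row(self, tmp_path):
        (tmp_path / "m.csv").write_text("path,label,subset\nghost.png,normal,train\n")
        with pytest.raises(FileNotFoundError, match="row 1"):
            load_manifest(tmp_path / "m.csv")

    def test_duplicate_paths_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            DatasetManifest(entries=[
                ManifestEntry("a.png", "normal", "train"),
                ManifestEntry("a.png", "benign", "train"),
            ], validate_paths=False)

    def test_bad_subset_token(self):
        with pytest.raises(ValueError, match="subset"):
            ManifestEntry("a.png", "normal", "validation")

    def test_round_trip_250_entries(self, tmp_path, rng):
        entries = [
            ManifestEntry(f"img_{i:03d}.png", CLASSES[i % 4],
                          "train" if i < 200 else "test_initial")
            for i in range(250)
        ]
        manifest = DatasetManifest(entries=entries, validate_paths=False)
        save_manifest(manifest, tmp_path / "m.csv")
        loaded = load_manifest(tmp_path / "m.csv", validate_paths=False)
        assert loaded.entries == entries


class TestPipelineConfig:
    def test_reference_defaults(self):
        cfg = PipelineConfig()
        assert cfg.patch_size == 512
        assert cfg.overlap_fraction == 0.5
        assert cfg.pixel_size_um == 0.42
        assert cfg.epochs == 50
        assert cfg.train_fraction == 0.75
        assert cfg.train_stride == 256

    def test_yaml_round_trip(self, tmp_path):
        cfg = PipelineConfig(patch_size=128, epochs=3, seed=99, fusion_rule="sum")
        cfg.to_yaml(tmp_path / "c.yaml")
        assert PipelineConfig.from_yaml(tmp_path / "c.yaml") == cfg

    def test_degenerate_overlap_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            PipelineConfig(overlap_fraction=1.0)

    def test_unknown_key_rejected(self, tmp_path):
        (tmp_path / "c.yaml").write_text("patch_size: 64\nbogus: 1\n")
        with pytest.raises(ValueError, match="bogus"):
            PipelineConfig.from_yaml(tmp_path / "c.yaml")


def _tiny_dataset(seed=0):
    config = SyntheticDatasetConfig(
        dims=(128, 96), images_per_class_train=1, images_per_class_test=1, seed=seed
    )
    return generate_labeled_dataset(config)


def _tiny_config(**overrides):
    defaults = dict(
        patch_size=64, overlap_fraction=0.5, epochs=2, batch_size=8,
        architecture="compact", augmentations_enabled=True, seed=3,
        train_svm_head=False,
    )
    defaults.update(overrides)
    return PipelineConfig(**defaults)


class TestRunPipeline:
    def test_smoke_run_emits_4x4_confusion(self, tmp_path):
        images, manifest = _tiny_dataset()
        result = run_pipeline(_tiny_config(), manifest, images=images,
                              out_dir=tmp_path / "run")
        report = result.report("cnn", "4class", "image", "overall")
        assert report.confusion.counts.shape == (4, 4)
        assert report.confusion.total == 4
        assert (tmp_path / "run" / "config.yaml").exists()
        assert (tmp_path / "run" / "predictions_cnn.csv").exists()
        assert (tmp_path / "run" / "reports.csv").exists()

    def test_determinism_byte_identical_predictions(self, tmp_path):
        images, manifest = _tiny_dataset()
        outputs = []
        for name in ("a", "b"):
            run_pipeline(_tiny_config(), manifest, images=images,
                         out_dir=tmp_path / name)
            outputs.append((tmp_path / name / "predictions_cnn.csv").read_bytes())
        assert outputs[0] == outputs[1]

    def test_missing_class_coverage_aborts_with_stage(self):
        images, manifest = _tiny_dataset()
        entries = [e for e in manifest.entries if e.label != "benign" or e.subset != "train"]
        broken = DatasetManifest(entries=entries, validate_paths=False)
        with pytest.raises(PipelineStageError) as err:
            run_pipeline(_tiny_config(), broken, images=images)
        assert err.value.stage == "load"


class TestCli:
    def test_rf_report_prints_receptive_fields(self):
        runner = CliRunner()
        result = runner.invoke(cli_main, ["rf-report"])
        assert result.exit_code == 0
        assert "152" in result.output and "94.1" in result.output

    def test_synth_writes_images_and_manifest(self, tmp_path):
        runner = CliRunner()
        result = runner.invoke(cli_main, [
            "synth", "--out-dir", str(tmp_path / "ds"), "--images-per-class", "1",
            "--test-per-class", "1", "--width", "96", "--height", "96", "--seed", "1",
        ])
        assert result.exit_code == 0, result.output
        manifest = load_manifest(tmp_path / "ds" / "manifest.csv")
        assert len(manifest) == 8
        img = load_image(manifest, manifest.entries[0])
        assert img.pixels.shape == (96, 96, 3)

    def test_normalize_command(self, tmp_path):
        runner = CliRunner()
        runner.invoke(cli_main, [
            "synth", "--out-dir", str(tmp_path / "ds"), "--images-per-class", "1",
            "--test-per-class", "1", "--width", "192", "--height", "160",
        ])
        result = runner.invoke(cli_main, [
            "normalize", "--manifest", str(tmp_path / "ds" / "manifest.csv"),
            "--out-dir", str(tmp_path / "norm"),
        ])
        assert result.exit_code == 0, result.output
        assert len(list((tmp_path / "norm").glob("*.png"))) == 8

    def test_train_predict_evaluate_stages(self, tmp_path):
        runner = CliRunner()
        runner.invoke(cli_main, [
            "synth", "--out-dir", str(tmp_path / "ds"), "--images-per-class", "2",
            "--test-per-class", "1", "--width", "128", "--height", "96", "--seed", "2",
        ])
        cfg = _tiny_config()
        cfg.to_yaml(tmp_path / "cfg.yaml")
        manifest = str(tmp_path / "ds" / "manifest.csv")
        result = runner.invoke(cli_main, [
            "train", "--manifest", manifest, "--config", str(tmp_path / "cfg.yaml"),
            "--out-dir", str(tmp_path / "model"),
        ])
        assert result.exit_code == 0, result.output
        result = runner.invoke(cli_main, [
            "predict", "--manifest", manifest, "--config", str(tmp_path / "cfg.yaml"),
            "--model", str(tmp_path / "model" / "model.npz"),
            "--out-dir", str(tmp_path / "pred"),
        ])
        assert result.exit_code == 0, result.output
        result = runner.invoke(cli_main, [
            "evaluate", "--manifest", manifest,
            "--predictions", str(tmp_path / "pred" / "predictions.csv"),
        ])
        assert result.exit_code == 0, result.output
        assert "accuracy" in result.output
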