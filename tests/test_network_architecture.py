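from dataclasses import replace

import numpy as np
import pytest

from histopatch.network_architecture import (
    EXPECTED_TABLE_SHAPES,
    ArchitectureSpec,
    LayerSpec,
    build_model,
    compact_architecture,
    compute_receptive_field_trace,
    default_architecture,
    format_rf_report,
    propagate_shapes,
    spec_from_dict,
    spec_to_dict,
)

RF_PX = (3, 5, 11, 14, 26, 32, 56, 80, 152, 224)


class TestDefaultArchitecture:
    def test_thirteen_layers(self):
        arch = default_architecture()
        assert len(arch.layers) == 13
        kinds = [l.kind for l in arch.layers]
        assert kinds.count("conv") == 5
        assert kinds.count("maxpool") == 5
        assert kinds.count("fc") == 3

    def test_map_counts_and_fc_sizes(self):
        arch = default_architecture()
        convs = [l.maps_or_units for l in arch.layers if l.kind == "conv"]
        fcs = [l.maps_or_units for l in arch.layers if l.kind == "fc"]
        assert convs == [16, 32, 64, 64, 32]
        assert fcs == [256, 128, 4]

    def test_final_layer_softmax_four_units(self):
        arch = default_architecture()
        assert arch.layers[-1].maps_or_units == 4
        assert arch.layers[-1].activation == "softmax"

    def test_pool_stride_equals_kernel_enforced(self):
        with pytest.raises(ValueError):
            LayerSpec("maxpool", kernel=3, stride=1)

    def test_spec_serialization_round_trip(self):
        arch = default_architecture()
        assert spec_from_dict(spec_to_dict(arch)) == arch


class TestPropagateShapes:
    def test_first_conv_output_510(self):
        traces, _ = propagate_shapes(default_architecture())
        assert traces[0].output_shape == (16, 510, 510)

    def test_layer2_pool_gives_170(self):
        traces, _ = propagate_shapes(default_architecture())
        assert traces[1].output_shape == (16, 170, 170)

    def test_layer9_conv_gives_12(self):
        traces, _ = propagate_shapes(default_architecture())
        assert traces[8].output_shape == (32, 12, 12)

    def test_layer10_conflict_flagged_stride_rule_wins(self):
        traces, discrepancies = propagate_shapes(
            default_architecture(), EXPECTED_TABLE_SHAPES
        )
        assert traces[9].output_shape == (32, 4, 4)
        assert len(discrepancies) == 1
        assert "layer 10" in discrepancies[0]

    def test_all_printed_shapes_except_layer10(self):
        traces, _ = propagate_shapes(default_architecture())
        spatial = [t.output_shape[1] for t in traces if len(t.output_shape) == 3]
        assert spatial[:9] == [510, 170, 168, 84, 84, 42, 42, 14, 12]

    def test_infeasible_spec_raises(self):
        with pytest.raises(ValueError):
            propagate_shapes(default_architecture(input_size=64))


class TestReceptiveField:
    def test_px_column_matches_table(self):
        trace = compute_receptive_field_trace(default_architecture())
        assert tuple(trace.px_column()[:10]) == RF_PX

    def test_layer3_and_layer9_values(self):
        trace = compute_receptive_field_trace(default_architecture(), 0.42)
        assert trace.steps[2].receptive_field_px == 11
        assert trace.steps[2].receptive_field_um == pytest.approx(4.62)
        assert trace.steps[8].receptive_field_px == 152
        assert trace.steps[8].receptive_field_um_rounded == 63.8

    def test_um_column_is_px_times_pixel_size(self):
        trace = compute_receptive_field_trace(default_architecture(), 0.42)
        for step in trace.steps:
            assert step.receptive_field_um == pytest.approx(
                step.receptive_field_px * 0.42
            )

    def test_fc_layers_report_full_extent(self):
        trace = compute_receptive_field_trace(default_architecture())
        for step in trace.steps[10:]:
            assert step.receptive_field_px == 512

    def test_single_1x1_conv_identity(self):
        spec = ArchitectureSpec(
            input_shape=(8, 8, 3),
            layers=(
                LayerSpec("conv", 4, kernel=1, stride=1, activation="relu"),
                LayerSpec("fc", 4, activation="softmax"),
            ),
        )
        trace = compute_receptive_field_trace(spec)
        assert trace.steps[0].receptive_field_px == 1

    def test_invariant_to_map_counts(self):
        arch = default_architecture()
        perturbed_layers = tuple(
            replace(l, maps_or_units=l.maps_or_units * 2) if l.kind == "conv" else l
            for l in arch.layers
        )
        perturbed = ArchitectureSpec(arch.input_shape, perturbed_layers)
        a = compute_receptive_field_trace(arch).px_column()
        b = compute_receptive_field_trace(perturbed).px_column()
        assert a == b

    def test_non_decreasing_with_depth(self):
        trace = compute_receptive_field_trace(default_architecture())
        px = trace.px_column()
        assert all(a <= b for a, b in zip(px, px[1:]))


class TestBuildModel:
    def test_shape_trace_matches_propagation_compact(self):
        arch = compact_architecture(48)
        model = build_model(arch, seed=3)
        expected = [t.output_shape for t in propagate_shapes(arch)[0]]
        assert model.shape_trace() == expected

    def test_shape_trace_matches_propagation_default_512(self):
        arch = default_architecture(512)
        model = build_model(arch, seed=0)
        expected = [t.output_shape for t in propagate_shapes(arch)[0]]
        assert model.shape_trace() == expected

    def test_softmax_output_contract(self, rng):
        arch = compact_architecture(32)
        model = build_model(arch, seed=1)
        x = rng.normal(size=(3, 32, 32, 3)).astype(np.float32)
        probs = model.predict_proba(x)
        assert probs.shape == (3, 4)
        assert np.all(probs >= 0)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_same_seed_identical_weights(self):
        arch = compact_architecture(32)
        w1 = build_model(arch, seed=42).get_weights()
        w2 = build_model(arch, seed=42).get_weights()
        assert all(np.array_equal(a, b) for a, b in zip(w1, w2))

    def test_different_seed_different_weights(self):
        arch = compact_architecture(32)
        w1 = build_model(arch, seed=1).get_weights()
        w2 = build_model(arch, seed=2).get_weights()
        assert any(not np.array_equal(a, b) for a, b in zip(w1, w2))

    def test_infeasible_spec_rejected(self):
        with pytest.raises(ValueError):
            build_model(default_architecture(input_size=100), seed=0)


def test_rf_report_formatting():
    text = format_rf_report(default_architecture())
    assert "152" in text and "94.1" in text
    assert "note: layer 10" in text


def test_spec_validation_rules():
    with pytest.raises(ValueError):
        ArchitectureSpec(input_shape=(64, 64, 3), layers=(
            LayerSpec("fc", 4, activation="relu"),  # final must be softmax
        ))
    with pytest.raises(ValueError):
        ArchitectureSpec(input_shape=(64, 64, 3), layers=(
            LayerSpec("conv", 8, kernel=3, stride=1, activation="none"),
            LayerSpec("fc", 4, activation="softmax"),
        ))
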