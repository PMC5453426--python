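"""Declarative CNN architecture: layer specs, shape and receptive-field
propagation, and construction of the trainable NumPy model.

The default stack is five conv/max-pool pairs followed by three
fully-connected layers: conv16-pool3 / conv32-pool2 / conv64-pool2 /
conv64-pool3 / conv32-pool3 / fc256 / fc128 / fc4, with 3x3 convolution
kernels, ReLU activations and a softmax output.  Max-pooling always uses a
stride equal to the pooling size.  The padding schedule is mixed: the printed
per-layer output sizes require 'valid' at conv layers 1, 3 and 9 and 'same'
at conv layers 5 and 7.

Note: with stride-equals-size pooling, the final 3x3 pool on a 12x12 map
yields 4x4, not the 12x12 the reference table prints for that row; the
stride rule wins and :func:`propagate_shapes` flags the discrepancy.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "LayerSpec",
    "ArchitectureSpec",
    "LayerTrace",
    "ReceptiveFieldTrace",
    "default_architecture",
    "compact_architecture",
    "propagate_shapes",
    "compute_receptive_field_trace",
    "build_model",
    "EXPECTED_TABLE_SHAPES",
]

_KINDS = ("conv", "maxpool", "fc")
_PADDINGS = ("valid", "same")
_ACTIVATIONS = ("relu", "softmax", "none")


@dataclass(frozen=True)
class LayerSpec:
    kind: str
    maps_or_units: int | None = None  # None for maxpool
    kernel: int | None = None  # conv/pool kernel size (square)
    stride: int | None = None
    padding: str = "valid"
    activation: str = "none"

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.padding not in _PADDINGS:
            raise ValueError(f"unknown padding {self.padding!r}")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.kind == "maxpool":
            if self.stride != self.kernel:
                raise ValueError("max pooling must use a stride equal to the pooling size")
        if self.kind in ("conv", "fc") and (self.maps_or_units or 0) <= 0:
            raise ValueError(f"{self.kind} layer needs a positive unit count")


@dataclass(frozen=True)
class ArchitectureSpec:
    input_shape: tuple[int, int, int]  # (H, W, C)
    layers: tuple[LayerSpec, ...]

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("architecture needs at least one layer")
        if self.layers[-1].kind != "fc":
            raise ValueError("final layer must be fully connected")
        if self.layers[-1].activation != "softmax":
            raise ValueError("final layer must use softmax activation")
        for spec in self.layers[:-1]:
            if spec.kind in ("conv", "fc") and spec.activation != "relu":
                raise ValueError("hidden conv/fc layers must use relu activation")

    @property
    def n_classes(self) -> int:
        return int(self.layers[-1].maps_or_units)

    def fc_layer_indices(self) -> list[int]:
        return [i for i, l in enumerate(self.layers) if l.kind == "fc"]


def spec_to_dict(spec: ArchitectureSpec) -> dict:
    return {
        "input_shape": list(spec.input_shape),
        "layers": [
            {
                "kind": l.kind,
                "maps_or_units": l.maps_or_units,
                "kernel": l.kernel,
                "stride": l.stride,
                "padding": l.padding,
                "activation": l.activation,
            }
            for l in spec.layers
        ],
    }


def spec_from_dict(data: dict) -> ArchitectureSpec:
    layers = tuple(LayerSpec(**d) for d in data["layers"])
    return ArchitectureSpec(input_shape=tuple(data["input_shape"]), layers=layers)


def _conv(maps: int, padding: str) -> LayerSpec:
    return LayerSpec("conv", maps, kernel=3, stride=1, padding=padding, activation="relu")


def _pool(size: int) -> LayerSpec:
    return LayerSpec("maxpool", kernel=size, stride=size)


def default_architecture(input_size: int = 512, in_channels: int = 3) -> ArchitectureSpec:
    """The 13-layer default stack, optionally at a reduced input size.

    The layer structure (kinds, kernels, map counts, padding schedule) is
    fixed; only the input spatial size is configurable so the same stack can
    run on reduced-geometry patches.
    """
    layers = (
        _conv(16, "valid"),
        _pool(3),
        _conv(32, "valid"),
        _pool(2),
        _conv(64, "same"),
        _pool(2),
        _conv(64, "same"),
        _pool(3),
        _conv(32, "valid"),
        _pool(3),
        LayerSpec("fc", 256, activation="relu"),
        LayerSpec("fc", 128, activation="relu"),
        LayerSpec("fc", 4, activation="softmax"),
    )
    return ArchitectureSpec(input_shape=(input_size, input_size, in_channels), layers=layers)


def compact_architecture(input_size: int = 64, in_channels: int = 3, n_classes: int = 4) -> ArchitectureSpec:
    """A small stack for low-resolution patches (unit tests, quick runs)."""
    layers = (
        _conv(8, "valid"),
        _pool(2),
        _conv(16, "valid"),
        _pool(2),
        _conv(32, "same"),
        _pool(2),
        LayerSpec("fc", 64, activation="relu"),
        LayerSpec("fc", 32, activation="relu"),
        LayerSpec("fc", n_classes, activation="softmax"),
    )
    return ArchitectureSpec(input_shape=(input_size, input_size, in_channels), layers=layers)


#: Printed per-layer spatial sizes of the reference table for the 512 stack
#: (None for fc layers).  Row 10 prints 12 although stride-3 pooling on a
#: 12x12 map gives 4x4; propagate_shapes reports the conflict.
EXPECTED_TABLE_SHAPES: tuple[int | None, ...] = (
    510, 170, 168, 84, 84, 42, 42, 14, 12, 12, None, None, None,
)


@dataclass(frozen=True)
class LayerTrace:
    index: int  # 1-based, matching the table rows
    spec: LayerSpec
    output_shape: tuple[int, ...]  # (maps, h, w) or (units,)


def propagate_shapes(
    spec: ArchitectureSpec,
    expected: Sequence[int | None] | None = None,
) -> tuple[list[LayerTrace], list[str]]:
    """Propagate per-layer output shapes.

    Returns the trace and a list of human-readable discrepancies against the
    optional ``expected`` spatial-size table.  Raises ``ValueError`` if any
    intermediate dimension becomes non-positive (infeasible spec).
    """
    h, w, c = spec.input_shape
    traces: list[LayerTrace] = []
    discrepancies: list[str] = []
    flat: int | None = None
    for i, layer in enumerate(spec.layers, start=1):
        if layer.kind == "conv":
            if layer.padding == "valid":
                h = h - layer.kernel + 1
                w = w - layer.kernel + 1
            c = layer.maps_or_units
            shape = (c, h, w)
        elif layer.kind == "maxpool":
            h = (h - layer.kernel) // layer.stride + 1
            w = (w - layer.kernel) // layer.stride + 1
            shape = (c, h, w)
        else:  # fc
            if flat is None:
                flat = c * h * w
            flat = layer.maps_or_units
            shape = (flat,)
        if layer.kind != "fc" and (h <= 0 or w <= 0):
            raise ValueError(
                f"layer {i} ({layer.kind}) yields non-positive spatial size "
                f"{h}x{w}: spec infeasible for input {spec.input_shape}"
            )
        traces.append(LayerTrace(index=i, spec=layer, output_shape=shape))
        if expected is not None and i <= len(expected) and expected[i - 1] is not None:
            exp = expected[i - 1]
            if layer.kind != "fc" and h != exp:
                discrepancies.append(
                    f"layer {i}: computed {h}x{w}, table prints {exp}x{exp}"
                )
    return traces, discrepancies


@dataclass(frozen=True)
class ReceptiveFieldStep:
    index: int
    kind: str
    output_shape: tuple[int, ...]
    receptive_field_px: int
    cumulative_stride: int
    receptive_field_um: float  # exact, = px * pixel_size

    @property
    def receptive_field_um_rounded(self) -> float:
        """One-decimal presentation value (round-half-up)."""
        from histopatch.evaluation import round_half_up

        return round_half_up(self.receptive_field_um, 1)


@dataclass(frozen=True)
class ReceptiveFieldTrace:
    pixel_size_um: float
    steps: tuple[ReceptiveFieldStep, ...]

    def px_column(self) -> list[int]:
        return [s.receptive_field_px for s in self.steps]

    def um_column(self) -> list[float]:
        return [s.receptive_field_um for s in self.steps]


def compute_receptive_field_trace(
    spec: ArchitectureSpec, pixel_size_um: float = 0.42
) -> ReceptiveFieldTrace:
    """Recursive effective-receptive-field propagation.

    rf <- rf + (kernel - 1) * cumulative_stride; cumulative_stride <- *stride.
    Fully-connected layers see the full input extent.  Padding does not enter
    the receptive-field arithmetic.
    """
    shapes, _ = propagate_shapes(spec)
    rf = 1
    jump = 1
    steps: list[ReceptiveFieldStep] = []
    for trace in shapes:
        layer = trace.spec
        if layer.kind in ("conv", "maxpool"):
            rf += (layer.kernel - 1) * jump
            jump *= layer.stride
            layer_rf = rf
        else:
            layer_rf = spec.input_shape[0]  # full input extent
        steps.append(
            ReceptiveFieldStep(
                index=trace.index,
                kind=layer.kind,
                output_shape=trace.output_shape,
                receptive_field_px=layer_rf,
                cumulative_stride=jump,
                receptive_field_um=layer_rf * pixel_size_um,
            )
        )
    return ReceptiveFieldTrace(pixel_size_um=pixel_size_um, steps=tuple(steps))


def build_model(spec: ArchitectureSpec, seed: int):
    """Build the trainable NumPy model for a validated, feasible spec.

    Weights are randomly initialized (He fan-in scaling) from ``seed``; two
    builds with the same seed produce identical initial weights.
    """
    from histopatch import _nn

    propagate_shapes(spec)  # raises if infeasible
    return _nn.Sequential.from_spec(spec, seed=seed)


def format_rf_report(spec: ArchitectureSpec, pixel_size_um: float = 0.42) -> str:
    """Plain-text shape / receptive-field table for a spec."""
    expected = EXPECTED_TABLE_SHAPES if spec == default_architecture(512) else None
    shapes, discrepancies = propagate_shapes(spec, expected)
    rf = compute_receptive_field_trace(spec, pixel_size_um)
    lines = [
        f"input: {spec.input_shape[0]}x{spec.input_shape[1]}x{spec.input_shape[2]}  "
        f"pixel size: {pixel_size_um} um/px",
        f"{'layer':>5}  {'type':<8} {'output':<16} {'rf(px)':>7} {'rf(um)':>8} {'rf(um,1dp)':>10}",
    ]
    for step in rf.steps:
        shape = "x".join(str(d) for d in step.output_shape)
        lines.append(
            f"{step.index:>5}  {step.kind:<8} {shape:<16} "
            f"{step.receptive_field_px:>7} {step.receptive_field_um:>8.4f} "
            f"{step.receptive_field_um_rounded:>10}"
        )
    for d in discrepancies:
        lines.append(f"note: {d}")
    return "\n".join(lines)
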