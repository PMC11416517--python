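"""Declarative 3D CNN architecture: layer specs, shapes and parameter counts.

The network is four convolutional blocks (Conv3D 3x3x3, stride 1, valid
padding, ELU -> channel-wise batch normalization -> 2x2x2 max pooling)
followed by flatten and three fully connected layers (40 ELU, dropout 0.2,
10 ELU, dropout 0.2, 1 sigmoid), with He initialization and an L2 penalty
of 0.05 on every convolutional and dense kernel.  Kernel size, stride and
padding are recovered uniquely from the published layer-shape/parameter
table: e.g. block 1 maps (120,128,128,1) -> (59,63,63,8) with 256
parameters, which forces kernel 3, stride 1, no padding, pool 2
(120 -> 118 -> 59; 8*(27+1) + 4*8 = 256).

A ``reduced`` profile keeps the identical block structure at desk scale
(24x32x32 input, three conv blocks) for fast training and CI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

L2_DEFAULT = 0.05
DROPOUT_DEFAULT = 0.2

#: input shape / conv filters per named profile
PROFILES = {
    "paper": {"input_shape": (120, 128, 128, 1), "conv_filters": (8, 16, 32, 64)},
    "reduced": {"input_shape": (24, 32, 32, 1), "conv_filters": (8, 16, 32)},
}


@dataclass
class LayerSpec:
    name: str
    kind: str  # input | conv3d | batchnorm | maxpool3d | flatten | dense | dropout
    input_shape: Tuple[int, ...]
    output_shape: Tuple[int, ...]
    filters_or_units: int = 0
    kernel: Tuple[int, int, int] = (0, 0, 0)
    stride: Tuple[int, int, int] = (1, 1, 1)
    padding: str = "valid"
    activation: str = "none"  # elu | sigmoid | none
    l2_coeff: float = 0.0
    dropout_rate: float = 0.0
    param_count: int = 0
    trainable_count: int = 0
    nontrainable_count: int = 0
    block: Optional[int] = None  # conv-block grouping for the summary table


@dataclass
class ArchitectureSpec:
    layers: List[LayerSpec]
    input_shape: Tuple[int, ...]
    l2_coeff: float = L2_DEFAULT

    def layer(self, name: str) -> LayerSpec:
        for lyr in self.layers:
            if lyr.name == name:
                return lyr
        raise KeyError(name)


@dataclass(frozen=True)
class ParameterCount:
    total: int
    trainable: int
    non_trainable: int

    def __post_init__(self) -> None:
        if self.total != self.trainable + self.non_trainable:
            raise ValueError("total != trainable + non_trainable")


def _conv_out(n: int, k: int, s: int) -> int:
    # valid padding: floor((n - k) / s) + 1
    return (n - k) // s + 1


def elu(x, alpha: float = 1.0):
    """ELU activation: x for x > 0, alpha*(e^x - 1) otherwise."""
    x = np.asarray(x, dtype=float)
    return np.where(x > 0, x, alpha * np.expm1(np.minimum(x, 0.0)))


def sigmoid(x):
    """Numerically stable logistic function 1 / (1 + e^-x)."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out if out.ndim else float(out)


def he_init(shape: Sequence[int], n_in: int, seed: int) -> np.ndarray:
    """He-initialized weight tensor: i.i.d. Normal(0, 2/n_in)."""
    if n_in < 1:
        raise ValueError(f"fan-in must be >= 1, got {n_in}")
    rng = np.random.default_rng(seed)
    return rng.normal(0.0, math.sqrt(2.0 / n_in), size=tuple(shape))


def build_architecture(
    input_shape: Tuple[int, int, int, int],
    conv_filters: Sequence[int],
    dense_units: Sequence[int] = (40, 10),
    dropout_rate: float = DROPOUT_DEFAULT,
    l2_coeff: float = L2_DEFAULT,
    kernel: Tuple[int, int, int] = (3, 3, 3),
    pool: int = 2,
) -> ArchitectureSpec:
    """Assemble a conv-block + FC-head architecture spec with chained shapes.

    Raises ValueError if any conv block would not fit the incoming spatial
    extent (each block needs every spatial axis >= kernel size).
    """
    layers: List[LayerSpec] = [
        LayerSpec(name="input", kind="input", input_shape=input_shape, output_shape=input_shape)
    ]
    shape = input_shape
    for bi, f in enumerate(conv_filters, start=1):
        d, h, w, c = shape
        if min(d, h, w) < max(kernel):
            raise ValueError(
                f"conv block {bi}: spatial extent {shape[:3]} smaller than kernel {kernel}"
            )
        conv_shape = (
            _conv_out(d, kernel[0], 1),
            _conv_out(h, kernel[1], 1),
            _conv_out(w, kernel[2], 1),
            f,
        )
        n_weights = f * (kernel[0] * kernel[1] * kernel[2] * c)
        layers.append(
            LayerSpec(
                name=f"conv_block{bi}_conv",
                kind="conv3d",
                input_shape=shape,
                output_shape=conv_shape,
                filters_or_units=f,
                kernel=kernel,
                stride=(1, 1, 1),
                activation="elu",
                l2_coeff=l2_coeff,
                param_count=n_weights + f,
                trainable_count=n_weights + f,
                block=bi,
            )
        )
        layers.append(
            LayerSpec(
                name=f"conv_block{bi}_bn",
                kind="batchnorm",
                input_shape=conv_shape,
                output_shape=conv_shape,
                filters_or_units=f,
                param_count=4 * f,
                trainable_count=2 * f,  # gamma, beta
                nontrainable_count=2 * f,  # running mean, running variance
                block=bi,
            )
        )
        pooled = (conv_shape[0] // pool, conv_shape[1] // pool, conv_shape[2] // pool, f)
        layers.append(
            LayerSpec(
                name=f"conv_block{bi}_pool",
                kind="maxpool3d",
                input_shape=conv_shape,
                output_shape=pooled,
                kernel=(pool, pool, pool),
                stride=(pool, pool, pool),
                block=bi,
            )
        )
        shape = pooled

    flat = int(np.prod(shape))
    layers.append(
        LayerSpec(name="flatten", kind="flatten", input_shape=shape, output_shape=(flat,))
    )
    width = flat
    for di, units in enumerate(dense_units, start=1):
        layers.append(
            LayerSpec(
                name=f"dense{di}",
                kind="dense",
                input_shape=(width,),
                output_shape=(units,),
                filters_or_units=units,
                activation="elu",
                l2_coeff=l2_coeff,
                param_count=width * units + units,
                trainable_count=width * units + units,
            )
        )
        layers.append(
            LayerSpec(
                name=f"dropout{di}",
                kind="dropout",
                input_shape=(units,),
                output_shape=(units,),
                dropout_rate=dropout_rate,
            )
        )
        width = units
    layers.append(
        LayerSpec(
            name="output",
            kind="dense",
            input_shape=(width,),
            output_shape=(1,),
            filters_or_units=1,
            activation="sigmoid",
            l2_coeff=l2_coeff,
            param_count=width + 1,
            trainable_count=width + 1,
        )
    )
    return ArchitectureSpec(layers=layers, input_shape=input_shape, l2_coeff=l2_coeff)


def default_architecture(profile: str = "paper") -> ArchitectureSpec:
    """The published architecture (or its reduced desk-scale profile)."""
    try:
        p = PROFILES[profile]
    except KeyError:
        raise ValueError(f"unknown profile {profile!r}; expected one of {sorted(PROFILES)}")
    return build_architecture(p["input_shape"], p["conv_filters"])


def count_parameters(spec: ArchitectureSpec) -> Tuple[ParameterCount, List[Tuple[str, int]]]:
    """Validate the shape chain and tally per-layer and total parameter counts.

    conv3d: filters * (k^3 * in_channels + 1); batchnorm: 4 * channels
    (2 trainable scale/shift + 2 non-trainable running statistics);
    dense: in * units + units; pooling/flatten/dropout: 0.
    """
    per_layer: List[Tuple[str, int]] = []
    trainable = 0
    non_trainable = 0
    prev_out: Optional[Tuple[int, ...]] = None
    for lyr in spec.layers:
        if prev_out is not None and tuple(lyr.input_shape) != tuple(prev_out):
            raise ValueError(
                f"shape mismatch at layer {lyr.name!r}: input {lyr.input_shape} "
                f"!= previous output {prev_out}"
            )
        prev_out = lyr.output_shape
        if lyr.kind == "conv3d":
            k = int(np.prod(lyr.kernel))
            cin = lyr.input_shape[-1]
            n = lyr.filters_or_units * (k * cin + 1)
            if n != lyr.param_count:
                raise ValueError(f"inconsistent conv parameter count at {lyr.name!r}")
            trainable += n
        elif lyr.kind == "batchnorm":
            n = 4 * lyr.filters_or_units
            trainable += 2 * lyr.filters_or_units
            non_trainable += 2 * lyr.filters_or_units
        elif lyr.kind == "dense":
            n = lyr.input_shape[0] * lyr.filters_or_units + lyr.filters_or_units
            trainable += n
        else:
            n = 0
        per_layer.append((lyr.name, n))
    return ParameterCount(trainable + non_trainable, trainable, non_trainable), per_layer


def block_parameter_rows(spec: ArchitectureSpec) -> List[Tuple[str, Tuple, Tuple, int]]:
    """Summary-table rows: conv blocks merged into single rows.

    Returns (layer name, input shape, output shape, parameter count) per row.
    """
    rows: List[Tuple[str, Tuple, Tuple, int]] = []
    _, per_layer = count_parameters(spec)
    counts = dict(per_layer)
    i = 0
    dense_seen = 0
    while i < len(spec.layers):
        lyr = spec.layers[i]
        if lyr.block is not None:  # conv + bn + pool constitute one block row
            block_layers = [l for l in spec.layers if l.block == lyr.block]
            n = sum(counts[l.name] for l in block_layers)
            rows.append(
                (
                    f"Conv Block{lyr.block}",
                    block_layers[0].input_shape,
                    block_layers[-1].output_shape,
                    n,
                )
            )
            i += len(block_layers)
            continue
        if lyr.kind == "input":
            name = "Input Layer"
        elif lyr.kind == "flatten":
            name = "Flatten"
        elif lyr.kind == "dense":
            name = "Fully Connected"
            dense_seen += 1
        elif lyr.kind == "dropout":
            name = "Dropout"
        else:
            name = lyr.name
        rows.append((name, lyr.input_shape, lyr.output_shape, counts[lyr.name]))
        i += 1
    return rows


def format_model_table(spec: Optional[ArchitectureSpec] = None) -> str:
    """Render the layer/shape/parameter summary table as text."""
    if spec is None:
        spec = default_architecture()
    totals, _ = count_parameters(spec)

    def _shape(s: Tuple[int, ...]) -> str:
        return "(None, " + ", ".join(str(v) for v in s) + ")"

    rows = [("Layer", "Input Shape", "Output Shape", "Parameters")]
    for name, ins, outs, n in block_parameter_rows(spec):
        rows.append((name, _shape(ins), _shape(outs), str(n)))
    rows.append(("Total Parameters", "", "", f"{totals.total:,}"))
    rows.append(("Trainable Parameters", "", "", f"{totals.trainable:,}"))
    rows.append(("Non-Trainable Parameters", "", "", f"{totals.non_trainable:,}"))
    widths = [max(len(r[c]) for r in rows) for c in range(4)]
    lines = []
    for r in rows:
        lines.append("  ".join(r[c].ljust(widths[c]) for c in range(4)).rstrip())
    return "\n".join(lines)
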