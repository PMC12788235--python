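"""1D residual network for joint-angle regression from pelvis IMU windows.

The estimator maps a standardized 6-channel, 200-frame inertial window
(3-axis accelerometer + 3-axis gyroscope at 100 Hz) to the six sagittal
joint angles (bilateral hip, knee, ankle) at the window's final frame.

Architecture: a convolutional stem (k7 conv -> BN -> GELU -> k3/s2 max
pool), four residual stages of two BasicBlocks each with channel widths
64/128/256/512 (first block of stages 2-4 downsamples with stride 2 and
a 1x1-conv + BN projection on the skip path), global average pooling,
and a regression head of three Linear -> GELU -> Dropout(0.2) layers
(256/128/64) followed by a linear output of width 6.  Convolutions are
bias-free with batch normalization after each; linear layers carry
biases.  At reference width this network has exactly 4,019,014 trainable
parameters and intermediate temporal lengths 200, 100, 100, 50, 25, 13.

``width_multiplier`` scales the convolutional channel widths for
desk-scale experiments; the head widths are fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (
    Adam,
    BatchNorm1d,
    Conv1d,
    Dropout,
    GELU,
    GlobalAvgPool1d,
    Layer,
    Linear,
    MaxPool1d,
    Param,
    Sequential,
    conv_out_len,
)

__all__ = [
    "ModelSpec",
    "JointAngleEstimator",
    "build_model",
    "count_parameters",
    "model_size_mb",
    "model_summary",
]


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of the estimator architecture."""

    in_channels: int = 6
    input_len: int = 200
    stem_channels: int = 64
    stem_kernel: int = 7
    stage_channels: tuple[int, ...] = (64, 128, 256, 512)
    blocks_per_stage: int = 2
    stage_strides: tuple[int, ...] = (1, 2, 2, 2)
    head_widths: tuple[int, ...] = (256, 128, 64)
    dropout: float = 0.2
    out_dim: int = 6
    width_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.out_dim != 6:
            raise ValueError("estimator predicts exactly 6 joint angles")
        for a, b in zip(self.stage_channels, self.stage_channels[1:]):
            if b != 2 * a:
                raise ValueError("stage channels must double at each stage")
        if len(self.stage_strides) != len(self.stage_channels):
            raise ValueError("one stride per stage required")
        if self.width_multiplier <= 0:
            raise ValueError("width_multiplier must be positive")

    def scaled_channels(self) -> tuple[int, tuple[int, ...]]:
        """Stem and stage channel widths after the width multiplier."""
        scale = self.width_multiplier
        stem = max(1, round(self.stem_channels * scale))
        stages = tuple(max(1, round(c * scale)) for c in self.stage_channels)
        return stem, stages

    def feature_lengths(self) -> list[int]:
        """Temporal length after the stem conv, pool, and each stage."""
        lengths = [conv_out_len(self.input_len, self.stem_kernel, 1,
                                self.stem_kernel // 2)]
        lengths.append(conv_out_len(lengths[-1], 3, 2, 1))  # max pool
        cur = lengths[-1]
        for stride in self.stage_strides:
            cur = conv_out_len(cur, 3, stride, 1)
            lengths.append(cur)
        if lengths[-1] < 2:
            raise ValueError(
                f"input_len={self.input_len} too short to survive the "
                "stem pooling and stride-2 stages")
        return lengths


class BasicBlock(Layer):
    """Two k3 convolutions with BN, skip connection, GELU at the join.

    When stride or channel width changes, the skip path is a 1x1
    convolution (bias-free) followed by BN.
    """

    def __init__(self, in_ch: int, out_ch: int, stride: int,
                 rng: np.random.Generator):
        self.body = Sequential(
            Conv1d(in_ch, out_ch, 3, stride=stride, padding=1, rng=rng),
            BatchNorm1d(out_ch),
            GELU(),
            Conv1d(out_ch, out_ch, 3, stride=1, padding=1, rng=rng),
            BatchNorm1d(out_ch),
        )
        if stride != 1 or in_ch != out_ch:
            self.shortcut: Sequential | None = Sequential(
                Conv1d(in_ch, out_ch, 1, stride=stride, padding=0, rng=rng),
                BatchNorm1d(out_ch),
            )
        else:
            self.shortcut = None
        self.act = GELU()

    def parameters(self) -> list[Param]:
        params = self.body.parameters()
        if self.shortcut is not None:
            params += self.shortcut.parameters()
        return params

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = self.body.forward(x, train=train)
        skip = x if self.shortcut is None else self.shortcut.forward(x, train=train)
        return self.act.forward(out + skip, train=train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.act.backward(dy)
        dx = self.body.backward(d)
        if self.shortcut is None:
            dx = dx + d
        else:
            dx = dx + self.shortcut.backward(d)
        return dx


class JointAngleEstimator:
    """The realized regression network built from a :class:`ModelSpec`."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.dropout_rng = np.random.default_rng((seed, 0xD0))
        stem_ch, stage_chs = spec.scaled_channels()

        self.stem = Sequential(
            Conv1d(spec.in_channels, stem_ch, spec.stem_kernel, stride=1,
                   padding=spec.stem_kernel // 2, rng=rng),
            BatchNorm1d(stem_ch),
            GELU(),
            MaxPool1d(3, 2, padding=1),
        )
        blocks: list[BasicBlock] = []
        in_ch = stem_ch
        for out_ch, stride in zip(stage_chs, spec.stage_strides):
            for b in range(spec.blocks_per_stage):
                blocks.append(BasicBlock(in_ch, out_ch,
                                         stride if b == 0 else 1, rng))
                in_ch = out_ch
        self.blocks = blocks
        self.gap = GlobalAvgPool1d()
        head_layers: list[Layer] = []
        width_in = in_ch
        for width in spec.head_widths:
            head_layers += [Linear(width_in, width, rng=rng), GELU(),
                            Dropout(spec.dropout, rng=self.dropout_rng)]
            width_in = width
        head_layers.append(Linear(width_in, spec.out_dim, rng=rng))
        self.head = Sequential(*head_layers)

        spec.feature_lengths()  # raises if input_len is too short
        self.last_feature_lengths: list[int] | None = None

    # -- inference / training ------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 3 or x.shape[1] != self.spec.in_channels \
                or x.shape[2] != self.spec.input_len:
            raise ValueError(
                f"expected (B, {self.spec.in_channels}, "
                f"{self.spec.input_len}) input, got {x.shape}")
        lengths = []
        h = self.stem.layers[0].forward(x, train=train)
        lengths.append(h.shape[2])
        for layer in self.stem.layers[1:]:
            h = layer.forward(h, train=train)
        lengths.append(h.shape[2])
        for i, block in enumerate(self.blocks):
            h = block.forward(h, train=train)
            if i % self.spec.blocks_per_stage == self.spec.blocks_per_stage - 1:
                lengths.append(h.shape[2])
        self.last_feature_lengths = lengths
        h = self.gap.forward(h, train=train)
        return self.head.forward(h, train=train)

    __call__ = forward

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.head.backward(dy)
        d = self.gap.backward(d)
        for block in reversed(self.blocks):
            d = block.backward(d)
        return self.stem.backward(d)

    def predict(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Deterministic evaluation-mode forward pass in minibatches."""
        outs = [self.forward(x[i:i + batch_size], train=False)
                for i in range(0, len(x), batch_size)]
        self.free_caches()
        return np.concatenate(outs, axis=0)

    def free_caches(self) -> None:
        """Drop layer activation caches (only needed between a train-mode
        forward and its backward); keeps long-lived models small."""
        for layer in self._all_layers():
            for attr in ("_cache", "_mask"):
                if hasattr(layer, attr):
                    setattr(layer, attr, None)

    # -- bookkeeping ---------------------------------------------------------

    def parameters(self) -> list[Param]:
        params = self.stem.parameters()
        for block in self.blocks:
            params += block.parameters()
        params += self.head.parameters()
        return params

    def make_optimizer(self, lr: float = 1e-3) -> Adam:
        return Adam(self.parameters(), lr=lr)

    def state_arrays(self) -> list[np.ndarray]:
        """All trainable values plus BN running statistics, in order."""
        arrays = [p.value for p in self.parameters()]
        for layer in self._all_layers():
            if isinstance(layer, BatchNorm1d):
                arrays += [layer.running_mean, layer.running_var]
        return arrays

    def _all_layers(self):
        for layer in self.stem.layers:
            yield layer
        for block in self.blocks:
            yield from block.body.layers
            if block.shortcut is not None:
                yield from block.shortcut.layers
            yield block.act
        for layer in self.head.layers:
            yield layer


def build_model(spec: ModelSpec, seed: int = 0) -> JointAngleEstimator:
    """Instantiate the network with seeded initialization."""
    return JointAngleEstimator(spec, seed=seed)


def count_parameters(est: JointAngleEstimator) -> int:
    """Number of trainable scalars (BN running stats excluded)."""
    return sum(p.size for p in est.parameters())


def model_size_mb(est: JointAngleEstimator, bytes_per_param: int = 4) -> float:
    """Serialized weight size in MiB at the given precision."""
    return count_parameters(est) * bytes_per_param / (1024 ** 2)


def model_summary(spec: ModelSpec | None = None, seed: int = 0) -> str:
    """Layer table (type, channels, kernel/stride, output shape)."""
    spec = spec or ModelSpec()
    est = build_model(spec, seed=seed)
    stem_ch, stage_chs = spec.scaled_channels()
    lengths = spec.feature_lengths()
    rows = [
        ("Input", spec.in_channels, "-", f"{spec.in_channels}x{spec.input_len}"),
        ("Conv1D -> BN -> GELU", stem_ch, f"{spec.stem_kernel}/1",
         f"{stem_ch}x{lengths[0]}"),
        ("MaxPool1D", stem_ch, "3/2", f"{stem_ch}x{lengths[1]}"),
    ]
    for i, (ch, stride) in enumerate(zip(stage_chs, spec.stage_strides)):
        rows.append((f"Stage {i + 1}: BasicBlock x{spec.blocks_per_stage}",
                     ch, f"3/{stride}", f"{ch}x{lengths[2 + i]}"))
    rows.append(("GlobalAvgPool1D", stage_chs[-1], "-", f"{stage_chs[-1]}"))
    rows.append(("Linear -> GELU -> Dropout x3", "-", "-",
                 "->".join(str(w) for w in spec.head_widths)))
    rows.append(("Linear (Output)", "-", "-", str(spec.out_dim)))
    lines = [f"{'Layer':<32}{'Ch.':>6}  {'K/S':>5}  Output"]
    for name, ch, ks, out in rows:
        lines.append(f"{name:<32}{str(ch):>6}  {ks:>5}  {out}")
    lines.append(f"Trainable parameters: {count_parameters(est):,}")
    lines.append(f"FP32 size: {model_size_mb(est):.2f} MB")
    return "\n".join(lines)
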