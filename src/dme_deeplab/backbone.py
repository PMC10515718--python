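"""MobileNetV2-style encoder for OCT B-scans.

The backbone stacks inverted-residual blocks: a 1x1 expansion convolution,
a 3x3 depthwise convolution (stride 1 or 2), and a 1x1 linear-bottleneck
projection (no nonlinearity after the projection, to preserve information in
the low-dimensional embedding).  A residual shortcut is used only when the
block keeps both stride and channel count.

The stage table is the standard MobileNetV2 layout truncated at output
stride 16; the decoder's low-level branch taps the feature map after the
stride-4 stage.  A width multiplier scales every channel count so a compact
variant can be trained quickly on CPU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (
    BatchNorm2d,
    Conv2d,
    DepthwiseConv2d,
    Identity,
    Module,
    ReLU6,
    Sequential,
)

__all__ = [
    "InvertedResidualSpec",
    "InvertedResidual",
    "MobileNetV2Encoder",
    "EncoderOutputs",
    "build_inverted_residual",
    "encode",
    "dense_conv_equivalent_parameters",
]

# (expansion, out_channels, repeats, first_stride) — truncated at stride 16.
STAGE_TABLE: tuple[tuple[int, int, int, int], ...] = (
    (1, 16, 1, 1),
    (6, 24, 2, 2),   # stride 4 after this stage -> low-level tap
    (6, 32, 3, 2),   # stride 8
    (6, 64, 4, 2),   # stride 16
    (6, 96, 3, 1),
)
STEM_CHANNELS = 32
LOW_LEVEL_STAGE = 1  # index into STAGE_TABLE after which the low-level tap sits
MIN_INPUT_SIDE = 64


@dataclass(frozen=True)
class InvertedResidualSpec:
    in_channels: int
    out_channels: int
    stride: int
    expansion_factor: float = 6.0

    def __post_init__(self) -> None:
        if self.stride not in (1, 2):
            raise ValueError(f"stride must be 1 or 2, got {self.stride}")
        if self.in_channels < 1 or self.out_channels < 1:
            raise ValueError("channel counts must be positive")
        if self.expansion_factor <= 0:
            raise ValueError("expansion factor must be positive")

    @property
    def use_shortcut(self) -> bool:
        return self.stride == 1 and self.in_channels == self.out_channels


@dataclass(frozen=True)
class EncoderOutputs:
    """Feature maps at 1/4 (low-level) and 1/16 (high-level) input resolution."""

    low_level: np.ndarray
    high_level: np.ndarray

    @property
    def low_level_channels(self) -> int:
        return self.low_level.shape[1]

    @property
    def high_level_channels(self) -> int:
        return self.high_level.shape[1]


def _scaled(channels: int, width_mult: float) -> int:
    return max(8, int(round(channels * width_mult / 8.0)) * 8) if width_mult != 1.0 else channels


class _ConvBNReLU(Sequential):
    def __init__(self, cin: int, cout: int, k: int, stride: int,
                 rng: np.random.Generator) -> None:
        super().__init__(
            Conv2d(cin, cout, k, stride=stride, bias=False, rng=rng),
            BatchNorm2d(cout),
            ReLU6(),
        )


class InvertedResidual(Module):
    """Expand (1x1) -> depthwise (3x3) -> linear project (1x1), optional shortcut."""

    def __init__(self, spec: InvertedResidualSpec,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.spec = spec
        hidden = max(1, int(round(spec.in_channels * spec.expansion_factor)))
        layers: list[Module] = []
        if hidden != spec.in_channels:
            layers += [Conv2d(spec.in_channels, hidden, 1, bias=False, rng=rng),
                       BatchNorm2d(hidden), ReLU6()]
        layers += [DepthwiseConv2d(hidden, 3, stride=spec.stride, rng=rng),
                   BatchNorm2d(hidden), ReLU6(),
                   Conv2d(hidden, spec.out_channels, 1, bias=False, rng=rng),
                   BatchNorm2d(spec.out_channels), Identity()]  # linear bottleneck
        self.branch = Sequential(*layers)
        self.add_module("branch", self.branch)

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = self.branch(x)
        if self.spec.use_shortcut:
            return x + y
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        gx = self.branch.backward(grad)
        if self.spec.use_shortcut:
            return gx + grad
        return gx


def build_inverted_residual(spec: InvertedResidualSpec,
                            rng: np.random.Generator | None = None) -> InvertedResidual:
    """Construct a single inverted-residual block from its spec."""
    return InvertedResidual(spec, rng=rng)


class MobileNetV2Encoder(Module):
    """Truncated MobileNetV2 trunk emitting stride-4 and stride-16 features."""

    def __init__(self, in_channels: int = 3, width_mult: float = 1.0,
                 seed: int = 0) -> None:
        super().__init__()
        rng = np.random.default_rng(seed)
        self.width_mult = width_mult
        stem_ch = _scaled(STEM_CHANNELS, width_mult)
        self.stem = _ConvBNReLU(in_channels, stem_ch, 3, 2, rng)
        self.add_module("stem", self.stem)

        blocks: list[InvertedResidual] = []
        cin = stem_ch
        self._low_tap_index = 0
        for stage_idx, (t, c, n, s) in enumerate(STAGE_TABLE):
            cout = _scaled(c, width_mult)
            for i in range(n):
                stride = s if i == 0 else 1
                blocks.append(InvertedResidual(
                    InvertedResidualSpec(cin, cout, stride, t), rng=rng))
                cin = cout
            if stage_idx == LOW_LEVEL_STAGE:
                self._low_tap_index = len(blocks)
                self.low_level_channels = cout
        self.blocks = blocks
        for i, b in enumerate(blocks):
            self.add_module(f"block{i}", b)
        self.high_level_channels = cin

    def forward(self, x: np.ndarray) -> EncoderOutputs:
        h, w = x.shape[2], x.shape[3]
        if h < MIN_INPUT_SIDE or w < MIN_INPUT_SIDE:
            raise ValueError(
                f"input {h}x{w} too small: the encoder needs at least "
                f"{MIN_INPUT_SIDE}x{MIN_INPUT_SIDE} pixels")
        y = self.stem(x)
        low = None
        for i, block in enumerate(self.blocks):
            y = block(y)
            if i + 1 == self._low_tap_index:
                low = y
        return EncoderOutputs(low_level=low, high_level=y)

    def backward(self, grad_low: np.ndarray, grad_high: np.ndarray) -> np.ndarray:
        g = grad_high
        for i in range(len(self.blocks) - 1, -1, -1):
            if i + 1 == self._low_tap_index:
                g = g + grad_low
            g = self.blocks[i].backward(g)
        return self.stem.backward(g)


#  (out_channels, repeats, first_stride) — entry-flow-like channel ramp
#  truncated at stride 16, after the Xception channel progression.
DENSE_STAGE_TABLE: tuple[tuple[int, int, int], ...] = (
    (64, 1, 1),
    (128, 2, 2),   # stride 4 -> low-level tap
    (256, 2, 2),   # stride 8
    (728, 3, 2),   # stride 16
)


class DenseEncoder(Module):
    """Heavier ablation backbone: dense 3x3 convolutions with an
    Xception-class channel progression (64 -> 128 -> 256 -> 728), truncated
    at output stride 16.  Exercises the lightweight comparison and the
    ablation hook; not a recommended configuration."""

    def __init__(self, in_channels: int = 3, width_mult: float = 1.0,
                 seed: int = 0) -> None:
        super().__init__()
        rng = np.random.default_rng(seed)
        stem_ch = _scaled(STEM_CHANNELS, width_mult)
        self.stem = _ConvBNReLU(in_channels, stem_ch, 3, 2, rng)
        self.add_module("stem", self.stem)
        self.stages: list[Sequential] = []
        cin = stem_ch
        self._low_stage = LOW_LEVEL_STAGE
        for stage_idx, (c, n, s) in enumerate(DENSE_STAGE_TABLE):
            cout = _scaled(c, width_mult)
            layers: list[Module] = []
            for i in range(n):
                layers.append(_ConvBNReLU(cin, cout, 3, s if i == 0 else 1, rng))
                cin = cout
            stage = Sequential(*layers)
            self.stages.append(stage)
            self.add_module(f"stage{stage_idx}", stage)
            if stage_idx == LOW_LEVEL_STAGE:
                self.low_level_channels = cout
        self.high_level_channels = cin

    def forward(self, x: np.ndarray) -> EncoderOutputs:
        h, w = x.shape[2], x.shape[3]
        if h < MIN_INPUT_SIDE or w < MIN_INPUT_SIDE:
            raise ValueError(
                f"input {h}x{w} too small: the encoder needs at least "
                f"{MIN_INPUT_SIDE}x{MIN_INPUT_SIDE} pixels")
        y = self.stem(x)
        low = None
        for i, stage in enumerate(self.stages):
            y = stage(y)
            if i == self._low_stage:
                low = y
        return EncoderOutputs(low_level=low, high_level=y)

    def backward(self, grad_low: np.ndarray, grad_high: np.ndarray) -> np.ndarray:
        g = grad_high
        for i in range(len(self.stages) - 1, -1, -1):
            if i == self._low_stage:
                g = g + grad_low
            g = self.stages[i].backward(g)
        return self.stem.backward(g)


def encode(image: np.ndarray, encoder: MobileNetV2Encoder | None = None,
           seed: int = 0) -> EncoderOutputs:
    """Run the encoder on a single H x W (grayscale) or H x W x 3 image.

    Grayscale inputs are replicated to three channels.  Parameters come from
    a seeded initializer when no encoder is supplied.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 2:
        img = img[:, :, None]
    if img.shape[2] == 1:
        img = np.repeat(img, 3, axis=2)
    if img.shape[2] != 3:
        raise ValueError(f"expected 1 or 3 channels, got {img.shape[2]}")
    x = img.transpose(2, 0, 1)[None]
    if encoder is None:
        encoder = MobileNetV2Encoder(seed=seed)
    encoder.eval()
    return encoder(x)


def dense_conv_equivalent_parameters(encoder: MobileNetV2Encoder) -> int:
    """Parameter count of a conventional dense-convolution encoder with the
    same layer widths: every depthwise-separable pair (k x k depthwise over C
    channels followed by a 1x1 pointwise C->C') is recounted as one dense
    k x k C->C' convolution, the comparison behind the lightweight claim."""
    from .nn import Conv2d as _C, DepthwiseConv2d as _D, BatchNorm2d as _B

    # Pair each depthwise layer with the pointwise that follows it.
    total = 0
    layers: list[Module] = []

    def collect(mod: Module) -> None:
        if isinstance(mod, (_C, _D)):
            layers.append(mod)
        for child in mod._modules.values():
            collect(child)

    collect(encoder)
    i = 0
    while i < len(layers):
        layer = layers[i]
        if isinstance(layer, _D):
            nxt = layers[i + 1] if i + 1 < len(layers) else None
            if isinstance(nxt, _C) and nxt.k == 1:
                total += layer.k * layer.k * layer.channels * nxt.out_channels
                i += 2
                continue
            total += layer.k * layer.k * layer.channels * layer.channels
        else:
            total += layer.weight.data.size + (0 if layer.bias is None else layer.bias.data.size)
        i += 1
    # batch-norm affine parameters, same in both designs
    def bn_params(mod: Module) -> int:
        n = 2 * mod.channels if isinstance(mod, _B) else 0
        return n + sum(bn_params(c) for c in mod._modules.values())

    return total + bn_params(encoder)
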