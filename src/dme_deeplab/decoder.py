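"""Decoder head: fuse low-level and high-level features, refine, upsample.

Pipeline: 1x1-reduce the stride-4 low-level features; bilinearly upsample the
stride-16 high-level features by 4; concatenate; refine with a few 3x3
convolutions; classify with a 1x1 convolution; bilinearly upsample by 4 to
input resolution.  Output is a per-pixel class score map (background / DME).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import BatchNorm2d, BilinearResize, Conv2d, Module, ReLU, Sequential

__all__ = ["DecoderConfig", "DecoderHead"]


@dataclass(frozen=True)
class DecoderConfig:
    low_level_reduced_channels: int = 48
    refine_channels: int = 256
    refine_convs: int = 2
    num_classes: int = 2

    def __post_init__(self) -> None:
        for name in ("low_level_reduced_channels", "refine_channels",
                     "refine_convs", "num_classes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")


class DecoderHead(Module):
    def __init__(self, low_channels: int, high_channels: int,
                 config: DecoderConfig = DecoderConfig(),
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.config = config
        red = config.low_level_reduced_channels
        self.reduce = Sequential(Conv2d(low_channels, red, 1, bias=False, rng=rng),
                                 BatchNorm2d(red), ReLU())
        self.add_module("reduce", self.reduce)
        refine: list[Module] = []
        cin = red + high_channels
        for _ in range(config.refine_convs):
            refine += [Conv2d(cin, config.refine_channels, 3, bias=False, rng=rng),
                       BatchNorm2d(config.refine_channels), ReLU()]
            cin = config.refine_channels
        self.refine = Sequential(*refine)
        self.add_module("refine", self.refine)
        self.classifier = Conv2d(cin, config.num_classes, 1, bias=True, rng=rng)
        self.add_module("classifier", self.classifier)
        self._cache = None

    def forward(self, low: np.ndarray, high: np.ndarray) -> np.ndarray:
        lh, lw = low.shape[2], low.shape[3]
        hh, hw = high.shape[2], high.shape[3]
        if (hh * 4, hw * 4) != (lh, lw):
            raise ValueError(
                f"decoder spatial contract violated: high-level {hh}x{hw} "
                f"upsampled x4 is {hh * 4}x{hw * 4}, but low-level is {lh}x{lw}")
        self.up_mid = BilinearResize(lh, lw)
        self.up_out = BilinearResize(lh * 4, lw * 4)
        red = self.reduce(low)
        up = self.up_mid(high)
        cat = np.concatenate([red, up], axis=1)
        y = self.refine(cat)
        scores = self.classifier(y)
        self._cache = red.shape[1]
        return self.up_out(scores)

    def backward(self, grad: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (grad_low, grad_high)."""
        red_ch = self._cache
        g = self.up_out.backward(grad)
        g = self.classifier.backward(g)
        gcat = self.refine.backward(g)
        glow = self.reduce.backward(gcat[:, :red_ch])
        ghigh = self.up_mid.backward(gcat[:, red_ch:])
        return glow, ghigh
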