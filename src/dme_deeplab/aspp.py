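"""High-level feature module: sawtooth-cascade ASPP and the parallel baseline.

The improved module replaces the classic parallel atrous spatial pyramid
pooling (ASPP) rates with a sawtooth dilation schedule applied as a *cascade*
of 3x3 dilated convolutions: the composite receptive field then spans
``1 + 2 * sum(rates)`` pixels per side with no gridding gaps (every pixel in
the receptive field carries weight paths to the output).  With the default
schedule ``[1, 3, 9, 1, 3, 9]`` the cascade sees a gap-free 53 x 53 field.

The classical parallel form (independent dilated branches, e.g. rates
``[1, 6, 12, 18]``, plus a 1x1 branch and optional image pooling) is kept for
ablation comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Literal

import numpy as np

from .nn import BatchNorm2d, Conv2d, Module, ReLU, Sequential
from .rf_analysis import DilationSchedule, is_sawtooth

__all__ = ["AsppConfig", "SawtoothCascadeASPP", "ParallelASPP", "build_aspp"]

SAWTOOTH_RATES = (1, 3, 9, 1, 3, 9)
BASELINE_RATES = (1, 6, 12, 18)


@dataclass(frozen=True)
class AsppConfig:
    mode: Literal["sawtooth_cascade", "baseline_parallel"] = "sawtooth_cascade"
    rates: tuple[int, ...] = SAWTOOTH_RATES
    branch_channels: int = 256
    use_global_pooling_branch: bool = False

    def __post_init__(self) -> None:
        schedule = DilationSchedule(self.rates)
        if self.mode == "sawtooth_cascade":
            if not is_sawtooth(schedule):
                raise ValueError(
                    f"rates {list(self.rates)} are not a sawtooth schedule "
                    "(a strictly increasing run repeated twice)")
        elif self.mode == "baseline_parallel":
            if not all(a < b for a, b in zip(self.rates, self.rates[1:])):
                raise ValueError(
                    f"baseline parallel ASPP requires strictly increasing rates, "
                    f"got {list(self.rates)}")
        else:
            raise ValueError(f"unknown ASPP mode {self.mode!r}")
        if self.branch_channels < 1:
            raise ValueError("branch_channels must be positive")


class SawtoothCascadeASPP(Module):
    """Sequential 3x3 dilated convolutions with sawtooth rates.

    Each stage is conv(3x3, dilation=r, same padding) -> batch norm -> ReLU;
    a final 1x1 projection sets the output width.  Spatial size is preserved
    at every stage (padding = rate for a 3x3 kernel).
    """

    def __init__(self, in_channels: int, config: AsppConfig,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.config = config
        ch = config.branch_channels
        layers: list[Module] = []
        cin = in_channels
        for r in config.rates:
            layers += [Conv2d(cin, ch, 3, dilation=r, bias=False, rng=rng),
                       BatchNorm2d(ch), ReLU()]
            cin = ch
        layers += [Conv2d(ch, ch, 1, bias=False, rng=rng), BatchNorm2d(ch), ReLU()]
        self.body = Sequential(*layers)
        self.add_module("body", self.body)
        self.out_channels = ch

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.body(x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.body.backward(grad)


class ParallelASPP(Module):
    """Classical ASPP: parallel dilated 3x3 branches + 1x1 branch (+ pooling),
    concatenated and projected by 1x1 convolution."""

    def __init__(self, in_channels: int, config: AsppConfig,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.config = config
        ch = config.branch_channels
        self.branches: list[Sequential] = []
        branch_defs = [(1, 1)] + [(3, r) for r in config.rates]
        for bi, (k, r) in enumerate(branch_defs):
            br = Sequential(Conv2d(in_channels, ch, k, dilation=r, bias=False, rng=rng),
                            BatchNorm2d(ch), ReLU())
            self.branches.append(br)
            self.add_module(f"branch{bi}", br)
        self.use_pool = config.use_global_pooling_branch
        if self.use_pool:
            self.pool_proj = Sequential(Conv2d(in_channels, ch, 1, bias=False, rng=rng),
                                        BatchNorm2d(ch), ReLU())
            self.add_module("pool_proj", self.pool_proj)
        n_branches = len(self.branches) + (1 if self.use_pool else 0)
        self.project = Sequential(Conv2d(n_branches * ch, ch, 1, bias=False, rng=rng),
                                  BatchNorm2d(ch), ReLU())
        self.add_module("project", self.project)
        self.out_channels = ch
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        outs = [br(x) for br in self.branches]
        pool_hw = None
        if self.use_pool:
            n, c, h, w = x.shape
            pooled = x.mean(axis=(2, 3), keepdims=True)
            proj = self.pool_proj(pooled)
            outs.append(np.broadcast_to(proj, (n, proj.shape[1], h, w)).copy())
            pool_hw = (h, w)
        cat = np.concatenate(outs, axis=1)
        self._cache = ([o.shape[1] for o in outs], x.shape, pool_hw)
        return self.project(cat)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        widths, xshape, pool_hw = self._cache
        gcat = self.project.backward(grad)
        gx = np.zeros(xshape)
        offset = 0
        for bi, br in enumerate(self.branches):
            gslice = gcat[:, offset:offset + widths[bi]]
            offset += widths[bi]
            gx += br.backward(gslice)
        if self.use_pool:
            h, w = pool_hw
            gpool = gcat[:, offset:].sum(axis=(2, 3), keepdims=True)
            gpooled = self.pool_proj.backward(gpool)
            gx += gpooled / (h * w)
        return gx


def build_aspp(in_channels: int, config: AsppConfig,
               rng: np.random.Generator | None = None) -> Module:
    """Construct the ASPP variant named by ``config.mode``."""
    if config.mode == "sawtooth_cascade":
        return SawtoothCascadeASPP(in_channels, config, rng=rng)
    return ParallelASPP(in_channels, config, rng=rng)
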