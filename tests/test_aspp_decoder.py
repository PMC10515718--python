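"""ASPP variants and decoder head: construction rules, shapes, and the
impulse-response agreement between the built cascade and the analyzer."""

import numpy as np
import pytest

from dme_deeplab import (
    AsppConfig,
    DecoderConfig,
    DecoderHead,
    DilationSchedule,
    ParallelASPP,
    SawtoothCascadeASPP,
    build_aspp,
    calculation_count_grid,
)
from dme_deeplab.nn import BatchNorm2d, Conv2d


class TestAsppConfig:
    def test_sawtooth_mode_requires_sawtooth_rates(self):
        with pytest.raises(ValueError, match="sawtooth"):
            AsppConfig(mode="sawtooth_cascade", rates=(1, 6, 12, 18))

    def test_parallel_mode_requires_increasing_rates(self):
        with pytest.raises(ValueError, match="increasing"):
            AsppConfig(mode="baseline_parallel", rates=(3, 1, 2))

    def test_default_is_the_sawtooth_schedule(self):
        cfg = AsppConfig()
        assert cfg.rates == (1, 3, 9, 1, 3, 9)
        assert cfg.mode == "sawtooth_cascade"

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            AsppConfig(mode="fancy")


class TestAsppForward:
    def test_cascade_preserves_spatial_size_and_sets_channels(self, rng):
        aspp = SawtoothCascadeASPP(12, AsppConfig(branch_channels=16),
                                   rng=np.random.default_rng(0))
        y = aspp(rng.random((2, 12, 32, 32)).astype(np.float32))
        assert y.shape == (2, 16, 32, 32)

    def test_parallel_has_one_branch_per_rate_plus_1x1(self, rng):
        cfg = AsppConfig(mode="baseline_parallel", rates=(1, 6, 12, 18),
                         branch_channels=8)
        aspp = ParallelASPP(6, cfg, rng=np.random.default_rng(0))
        assert len(aspp.branches) == 5  # 1x1 + four dilated branches
        y = aspp(rng.random((1, 6, 16, 16)).astype(np.float32))
        assert y.shape == (1, 8, 16, 16)

    def test_global_pooling_branch_optional(self, rng):
        cfg = AsppConfig(mode="baseline_parallel", rates=(1, 2), branch_channels=4,
                         use_global_pooling_branch=True)
        aspp = ParallelASPP(3, cfg, rng=np.random.default_rng(0))
        y = aspp(rng.random((1, 3, 8, 8)).astype(np.float32))
        assert y.shape == (1, 4, 8, 8)

    def test_build_dispatches_on_mode(self):
        assert isinstance(build_aspp(4, AsppConfig()), SawtoothCascadeASPP)
        assert isinstance(
            build_aspp(4, AsppConfig(mode="baseline_parallel", rates=(1, 2))),
            ParallelASPP)


def indicator_impulse_response(rates, size):
    """Feed a centered impulse through conv layers whose weights are
    indicator kernels (all ones) and return the output support."""
    x = np.zeros((1, 1, size, size), dtype=np.float32)
    x[0, 0, size // 2, size // 2] = 1.0
    for r in rates:
        conv = Conv2d(1, 1, 3, dilation=r, bias=False)
        conv.weight.data[...] = 1.0
        x = conv(x)
    return x[0, 0] > 0


class TestCascadeMatchesAnalyzer:
    @pytest.mark.parametrize("rates", [(1, 3, 9, 1, 3, 9), (1, 6, 12, 18),
                                       (1, 2, 1, 2)])
    def test_impulse_support_equals_count_grid_support(self, rates):
        # The built cascade and the path-count calculus must agree exactly
        # on which input pixels reach the center output unit.
        grid = calculation_count_grid(DilationSchedule(list(rates)))
        size = grid.side + 16  # margin so padding does not clip the support
        support = indicator_impulse_response(rates, size)
        m = (size - grid.side) // 2
        inner = support[m:m + grid.side, m:m + grid.side]
        np.testing.assert_array_equal(inner, grid.counts > 0)
        assert support.sum() == inner.sum()  # nothing outside the RF square

    def test_impulse_count_values_match_analyzer(self):
        # With indicator weights the impulse response carries the path
        # counts themselves, not just the support.
        rates = (1, 2)
        grid = calculation_count_grid(DilationSchedule(list(rates)))
        size = grid.side + 8
        x = np.zeros((1, 1, size, size), dtype=np.float32)
        x[0, 0, size // 2, size // 2] = 1.0
        for r in rates:
            conv = Conv2d(1, 1, 3, dilation=r, bias=False)
            conv.weight.data[...] = 1.0
            x = conv(x)
        m = (size - grid.side) // 2
        np.testing.assert_array_equal(
            x[0, 0, m:m + grid.side, m:m + grid.side].astype(int), grid.counts)


class TestDecoder:
    def _head(self, **kw):
        return DecoderHead(6, 5, DecoderConfig(low_level_reduced_channels=4,
                                               refine_channels=8, **kw),
                           rng=np.random.default_rng(0))

    @pytest.mark.parametrize("low, high, out", [(128, 32, 512), (16, 4, 64)])
    def test_output_resolution_is_four_times_low_level(self, low, high, out, rng):
        head = self._head()
        scores = head(rng.random((1, 6, low, low)).astype(np.float32),
                      rng.random((1, 5, high, high)).astype(np.float32))
        assert scores.shape == (1, 2, out, out)

    def test_spatial_contract_violation_raises(self, rng):
        with pytest.raises(ValueError, match="contract"):
            self._head()(rng.random((1, 6, 128, 128)), rng.random((1, 5, 30, 30)))

    def test_argmax_masks_are_binary(self, rng):
        head = self._head()
        scores = head(rng.random((1, 6, 16, 16)).astype(np.float32),
                      rng.random((1, 5, 4, 4)).astype(np.float32))
        assert set(np.unique(scores.argmax(axis=1))) <= {0, 1}


class TestBilinearUpsampling:
    def test_constant_map_stays_constant(self):
        from dme_deeplab.nn import BilinearResize

        up = BilinearResize(20, 20)
        y = up(np.full((1, 1, 5, 5), 3.25, dtype=np.float32))
        np.testing.assert_allclose(y, 3.25, rtol=1e-6)

    def test_deterministic_and_linear(self, rng):
        from dme_deeplab.nn import BilinearResize

        x = rng.random((1, 2, 7, 7)).astype(np.float32)
        up = BilinearResize(13, 13)
        np.testing.assert_array_equal(up(x), up(x))
        np.testing.assert_allclose(up(2.0 * x), 2.0 * up(x), rtol=1e-6)
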