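"""Embedding, correlation integrals, K2, and MSE surfaces."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import naive_correlation_integral, naive_joint_counts
from msekit import (EmbeddingConfig, FgnSpec, TimeSeries, correlation_integral,
                    embed, k2_at_scale, k2_curve, mse_surface, simulate_fgn,
                    simulate_white_noise)
from msekit._kernels import (_joint_hist_np, _single_hist_np,
                             count_pairs_joint, count_pairs_single)


class TestEmbed:
    def test_small_example(self):
        v = embed(TimeSeries([1, 2, 3]), EmbeddingConfig(m=2, L=1))
        assert np.array_equal(v, [[1, 2], [2, 3]])

    def test_m1_returns_scalars(self):
        v = embed(TimeSeries([4, 5, 6]), EmbeddingConfig(m=1, L=1))
        assert v.shape == (3, 1)

    def test_vector_count(self):
        x = TimeSeries(np.arange(4097, dtype=float))
        assert embed(x, EmbeddingConfig(m=5, L=1)).shape == (4093, 5)

    def test_too_short_raises(self):
        with pytest.raises(ValueError, match="too short"):
            embed(TimeSeries([1, 2, 3]), EmbeddingConfig(m=4, L=1))


class TestCorrelationIntegral:
    def test_eps_covering_range_gives_one(self):
        x = TimeSeries([0.0, 1.0, 2.0, 3.0])
        assert correlation_integral(x, EmbeddingConfig(m=2), 10.0) == 1.0

    def test_identical_vectors_match_at_any_eps(self):
        x = TimeSeries([1.0, 1.0, 1.0])
        assert correlation_integral(x, EmbeddingConfig(m=2), 1e-12) == 1.0

    def test_nonpositive_eps_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            correlation_integral(TimeSeries([1.0, 2.0, 3.0]),
                                 EmbeddingConfig(m=1), 0.0)

    @pytest.mark.parametrize("m", [1, 2, 5, 6])
    @pytest.mark.parametrize("n", [10, 47, 200])
    def test_equals_naive_double_loop(self, m, n):
        rng = np.random.default_rng(n * 10 + m)
        x = TimeSeries(rng.standard_normal(n))
        for eps in (0.05, 0.3, 1.0, 2.5):
            got = correlation_integral(x, EmbeddingConfig(m=m), eps)
            want = naive_correlation_integral(x.values, m, 1, eps)
            assert got == want  # identical counts, exact equality

    def test_tie_at_exact_eps_counts_as_match(self):
        # distances between scalar vectors: 1 and 2; eps=1 must catch the tie
        x = TimeSeries([0.0, 1.0, 2.0])
        assert correlation_integral(x, EmbeddingConfig(m=1), 1.0) == pytest.approx(2 / 3)

    def test_quantized_data_matches_naive(self):
        # heavy ties stress the boundary convention
        rng = np.random.default_rng(3)
        x = TimeSeries(np.round(rng.standard_normal(80), 1))
        for m in (1, 2, 5):
            for eps in (0.1, 0.2, 0.45):
                got = correlation_integral(x, EmbeddingConfig(m=m), eps)
                assert got == naive_correlation_integral(x.values, m, 1, eps)

    def test_theiler_window_excludes_near_diagonal(self):
        rng = np.random.default_rng(8)
        x = TimeSeries(rng.standard_normal(60))
        got = correlation_integral(x, EmbeddingConfig(m=2, theiler=3), 0.5)
        want = naive_correlation_integral(x.values, 2, 1, 0.5, theiler=3)
        assert got == pytest.approx(want)


class TestKernelConsistency:
    def test_numpy_fallback_matches_active_kernel(self):
        rng = np.random.default_rng(12)
        x = rng.standard_normal(300)
        grid = np.array([0.05, 0.2, 0.5, 1.0, 3.0])
        cm, cm1 = count_pairs_joint(x, 2, 1, grid)
        hm, hm1 = _joint_hist_np(x, 2, 1, grid, 0)
        assert np.array_equal(cm, np.cumsum(hm)[:-1])
        assert np.array_equal(cm1, np.cumsum(hm1)[:-1])
        cs = count_pairs_single(x, 3, 1, grid)
        assert np.array_equal(cs, np.cumsum(_single_hist_np(x, 3, 1, grid, 0))[:-1])

    def test_joint_counts_match_naive(self):
        rng = np.random.default_rng(21)
        x = rng.standard_normal(120)
        grid = np.array([0.1, 0.4, 1.2])
        cm, cm1 = count_pairs_joint(x, 2, 1, grid)
        for g, eps in enumerate(grid):
            want = naive_joint_counts(x, 2, 1, eps)
            assert (cm[g], cm1[g]) == want


class TestK2:
    def test_constant_series_has_zero_entropy(self):
        x = TimeSeries(np.full(50, 3.14))
        val = k2_at_scale(x, EmbeddingConfig(m=2), eps=0.1)
        assert val == 0.0

    def test_matches_naive_counts_on_toy_series(self):
        rng = np.random.default_rng(1)
        x = TimeSeries(rng.standard_normal(10))
        eps = 0.8
        cm, cm1 = naive_joint_counts(x.values, 2, 1, eps)
        want = np.log(cm) - np.log(cm1)
        got = k2_at_scale(x, EmbeddingConfig(m=2), eps, min_pairs=1)
        assert got == pytest.approx(want, rel=1e-12)

    def test_white_noise_k2_increases_as_eps_shrinks(self):
        x = simulate_white_noise(4096, seed=2)
        grid = np.geomspace(0.05, 1.0, 12)
        c = k2_curve(x, grid, EmbeddingConfig(m=2))
        k = c.k2[c.defined]
        assert np.all(np.diff(k) < 0)  # decreasing in eps

    def test_undefined_flagged_not_zero(self):
        x = simulate_white_noise(128, seed=5)
        c = k2_curve(x, np.array([1e-6, 1.0]), EmbeddingConfig(m=2), min_pairs=10)
        assert np.isnan(c.k2[0]) and np.isfinite(c.k2[1])

    def test_k2_nonnegative_and_counts_monotone(self, fgn_medium):
        grid = np.geomspace(0.02, 1.5, 20)
        c = k2_curve(fgn_medium, grid, EmbeddingConfig(m=2))
        assert np.all(c.k2[c.defined] >= 0)
        assert np.all(np.diff(c.pair_counts_m) >= 0)
        assert np.all(c.pair_counts_m1 <= c.pair_counts_m)

    def test_dt_scales_entropy_rate(self):
        x = simulate_white_noise(512, seed=9)
        a = k2_at_scale(x, EmbeddingConfig(m=2), 0.4, dt=1.0)
        b = k2_at_scale(x, EmbeddingConfig(m=2), 0.4, dt=0.5)
        assert b == pytest.approx(2 * a)


class TestMSESurface:
    def test_first_row_equals_raw_curve(self, fgn_medium):
        grid = np.geomspace(0.1, 1.0, 8)
        surf = mse_surface(fgn_medium, [1, 2, 4], grid, EmbeddingConfig(m=2))
        raw = k2_curve(fgn_medium, grid, EmbeddingConfig(m=2))
        assert np.allclose(surf.k2[0], raw.k2, equal_nan=True)
        assert np.allclose(surf.row(1).k2, raw.k2, equal_nan=True)

    def test_eps_held_in_original_units(self, fgn_medium):
        surf = mse_surface(fgn_medium, [1, 5], [0.2], EmbeddingConfig(m=2))
        assert surf.eps_abs[0] == pytest.approx(0.2 * fgn_medium.std())

    def test_entries_nonnegative_where_defined(self, fgn_medium):
        surf = mse_surface(fgn_medium, range(1, 8), np.geomspace(0.05, 1, 6),
                           EmbeddingConfig(m=2))
        assert np.all(surf.k2[np.isfinite(surf.k2)] >= 0)

    def test_self_similar_shift_property(self):
        # K2^(bs)(bs^(H-1) eps) = K2(eps): the bs=10 curve equals the raw
        # curve shifted left by 10^(H-1) in eps.  Compare K2^(10) at
        # eps' = 10^(H-1)*eps against K2 at eps on a matched grid.
        h = 0.7
        x = simulate_fgn(FgnSpec(h, 2 ** 14, seed=3))
        eps = np.geomspace(0.15, 0.6, 6)
        shifted = eps * 10 ** (h - 1)
        raw = k2_curve(x, eps, EmbeddingConfig(m=2))
        from msekit import TimeSeries as TS
        from msekit.coarsegrain import coarse_grain
        sm = TS(coarse_grain(x, 10).values)
        smoothed = k2_curve(sm, shifted * x.std(), EmbeddingConfig(m=2),
                            eps_units="absolute")
        d = raw.defined & smoothed.defined
        assert d.sum() >= 4
        assert np.allclose(raw.k2[d], smoothed.k2[d], atol=0.25)
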