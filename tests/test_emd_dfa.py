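import numpy as np
import pytest

from swayfractal import (
    EmdDfaConfig,
    decompose,
    emd_dfa,
    fit_crossover,
    fluctuation_function,
    generate_composite,
    generate_fgn,
    intrinsic_scales,
    reconstruct_at_scale,
)
from swayfractal.emd import ImfSet
from swayfractal.emd_dfa import NoIntrinsicScalesError


def make_imfset(imfs, residual=None):
    imfs = np.atleast_2d(np.asarray(imfs, float))
    if residual is None:
        residual = np.zeros(imfs.shape[1])
    return ImfSet(
        imfs=imfs,
        residual=np.asarray(residual, float),
        n_sift_iterations=[1] * imfs.shape[0],
        source_length=imfs.shape[1],
    )


def naive_minima(x):
    return [i for i in range(1, len(x) - 1) if x[i - 1] > x[i] < x[i + 1]]


class TestIntrinsicScales:
    def test_sine_imf_has_single_scale(self):
        n, period = 200, 20
        imf = np.sin(2 * np.pi * np.arange(n) / period)
        table = intrinsic_scales(make_imfset([imf]))
        assert set(table.segment_counts) == {period}
        np.testing.assert_array_equal(table.per_imf_distances[0], [period] * 9)

    def test_trend_only_raises(self):
        with pytest.raises(NoIntrinsicScalesError):
            intrinsic_scales(make_imfset([np.linspace(0, 1, 50)]))

    def test_matches_bruteforce_minima_scan(self):
        x = generate_fgn(0.5, 1024, 5)
        imfset = decompose(np.cumsum(x - x.mean()))
        table = intrinsic_scales(imfset)
        expected = {}
        for imf in imfset.imfs:
            mins = naive_minima(imf)
            for d in np.diff(mins):
                expected[int(d)] = expected.get(int(d), 0) + 1
        assert table.segment_counts == expected


class TestReconstructAtScale:
    def test_uniform_scale_keeps_whole_imf_between_minima(self):
        n, period = 200, 20
        imf = np.sin(2 * np.pi * np.arange(n) / period)
        imfset = make_imfset([imf])
        table = intrinsic_scales(imfset)
        y, mask = reconstruct_at_scale(imfset, table, period)
        mins = naive_minima(imf)
        inside = np.zeros(n, dtype=bool)
        inside[mins[0] : mins[-1]] = True
        np.testing.assert_array_equal(mask, inside)
        np.testing.assert_array_equal(y[inside], imf[inside])
        np.testing.assert_array_equal(y[~inside], 0.0)

    def test_absent_scale_rejected(self):
        imf = np.sin(2 * np.pi * np.arange(200) / 20.0)
        imfset = make_imfset([imf])
        table = intrinsic_scales(imfset)
        with pytest.raises(ValueError):
            reconstruct_at_scale(imfset, table, 7)

    def test_interleaved_scales_match_bruteforce_segment_scan(self):
        n = 400
        imf1 = np.sin(2 * np.pi * np.arange(n) / 10.0)
        imf2 = np.sin(2 * np.pi * np.arange(n) / 20.0)
        imfset = make_imfset([imf1, imf2])
        table = intrinsic_scales(imfset)
        for s in (10, 20):
            _, mask = reconstruct_at_scale(imfset, table, s)
            expected = np.zeros(n, dtype=bool)
            for imf in (imf1, imf2):
                mins = naive_minima(imf)
                for a, b in zip(mins, mins[1:]):
                    if b - a == s:
                        expected[a:b] = True
            np.testing.assert_array_equal(mask, expected)

    def test_scales_partition_each_imf_span(self):
        x = generate_fgn(0.7, 2048, 9)
        imfset = decompose(np.cumsum(x - x.mean()))
        table = intrinsic_scales(imfset)
        for k, minima in enumerate(table.per_imf_minima):
            if minima.size < 2:
                continue
            coverage = np.zeros(imfset.source_length, dtype=int)
            sub = make_imfset([imfset.imfs[k]])
            sub_table = intrinsic_scales(sub)
            for s in sub_table.segment_counts:
                _, mask = reconstruct_at_scale(sub, sub_table, s)
                coverage += mask
            span = np.zeros(imfset.source_length, dtype=int)
            span[minima[0] : minima[-1]] = 1
            np.testing.assert_array_equal(coverage, span)


class TestFluctuationFunction:
    def test_full_mode_example(self):
        y = np.array([3.0, 0.0, 0.0, 0.0])
        mask = np.ones(4, dtype=bool)
        assert fluctuation_function(y, mask, "full") == pytest.approx(1.5)

    def test_retained_mode_example(self):
        y = np.array([3.0, 0.0, 0.0, 0.0])
        mask = np.array([True, False, False, False])
        assert fluctuation_function(y, mask, "retained") == pytest.approx(3.0)

    def test_matches_sum_of_squares_oracle(self, rng):
        y = rng.standard_normal(256)
        mask = rng.random(256) < 0.3
        y = np.where(mask, y, 0.0)
        full = np.sqrt(sum(v * v for v in y) / 256)
        retained = np.sqrt(sum(v * v for v in y) / mask.sum())
        assert fluctuation_function(y, mask, "full") == pytest.approx(full, rel=1e-12)
        assert fluctuation_function(y, mask, "retained") == pytest.approx(retained, rel=1e-12)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            fluctuation_function(np.zeros(10), np.zeros(10, dtype=bool))


class TestFitCrossover:
    def test_pure_power_law_gives_equal_slopes(self):
        s = np.logspace(np.log10(4), np.log10(1000), 20)
        res = fit_crossover(s, s**0.5)
        assert res.alpha_short == pytest.approx(0.5, abs=1e-10)
        assert res.alpha_long == pytest.approx(0.5, abs=1e-10)
        assert res.no_distinct_regimes

    def _piecewise_curve(self):
        s_left = np.logspace(np.log10(2), np.log10(10), 12)
        s_right = np.logspace(np.log10(11), np.log10(1000), 12)
        f_left = s_left**1.0
        f_right = 10.0 * (s_right / 10.0) ** 0.5  # continuous at s = 10
        return np.concatenate([s_left, s_right]), np.concatenate([f_left, f_right])

    def test_recovers_piecewise_slopes_and_crossover(self):
        s, f = self._piecewise_curve()
        res = fit_crossover(s, f, min_points_per_segment=3)
        assert res.alpha_short == pytest.approx(1.0, abs=1e-6)
        assert res.alpha_long == pytest.approx(0.5, abs=1e-6)
        assert 8 <= res.crossover_scale <= 13
        assert not res.single_slope

    def test_robust_to_small_log_noise(self):
        s, f = self._piecewise_curve()
        rng = np.random.default_rng(7)
        noisy = f * 10 ** (rng.normal(0, 0.01, f.size))
        res = fit_crossover(s, noisy, min_points_per_segment=3)
        assert res.alpha_short == pytest.approx(1.0, abs=0.05)
        assert res.alpha_long == pytest.approx(0.5, abs=0.05)

    def test_too_few_points_falls_back_to_single_slope(self):
        s = np.array([4.0, 8.0, 16.0, 32.0, 64.0])
        res = fit_crossover(s, s**0.7, min_points_per_segment=3)
        assert res.single_slope
        assert res.alpha_short == res.alpha_long == pytest.approx(0.7, abs=1e-10)
        assert np.isnan(res.crossover_scale)

    def test_nonpositive_points_dropped(self):
        s = np.logspace(0.5, 3, 15)
        f = s**0.5
        f[3] = 0.0
        res = fit_crossover(s, f)
        assert res.n_points_short + res.n_points_long == 14


class TestEmdDfaPipeline:
    def test_white_noise_global_slope_near_half(self):
        alphas = [
            emd_dfa(generate_fgn(0.5, 2**14, seed), sample_rate=1000.0)[1].alpha_global
            for seed in range(10)
        ]
        assert 0.4 <= np.mean(alphas) <= 0.6

    def test_pink_noise_short_exponent_near_one(self):
        alphas = [
            emd_dfa(
                generate_composite(1.0, 1.0, 64, 2**14, seed), sample_rate=1000.0
            )[1].alpha_short
            for seed in range(10)
        ]
        assert 0.85 <= np.mean(alphas) <= 1.15

    def test_deterministic_rerun(self):
        x = generate_fgn(0.6, 4096, 4)
        c1, r1 = emd_dfa(x, sample_rate=1000.0)
        c2, r2 = emd_dfa(x, sample_rate=1000.0)
        np.testing.assert_array_equal(c1.scales, c2.scales)
        np.testing.assert_array_equal(c1.F, c2.F)
        assert r1 == r2

    def test_crossover_reported_in_ms(self):
        x = generate_composite(1.0, 0.5, 64, 2**14, 0)
        _, res = emd_dfa(x, sample_rate=1000.0)
        if np.isfinite(res.crossover_scale):
            assert res.crossover_ms == pytest.approx(res.crossover_scale, rel=1e-12)

    def test_rejects_short_series(self):
        with pytest.raises(ValueError, match="512"):
            emd_dfa(np.random.default_rng(0).standard_normal(256), sample_rate=100.0)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            EmdDfaConfig(normalization="bogus")
        with pytest.raises(ValueError):
            EmdDfaConfig(binning="bogus")
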