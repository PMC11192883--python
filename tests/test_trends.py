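"""Annual aggregation and the Mann-Kendall / Sen slope trend machinery."""

import math

import numpy as np
import pytest
from scipy import stats

from lake_tsi.pipeline import TsiRaster
from lake_tsi.trends import (
    AnnualRecord,
    annualize,
    forty_year_average,
    lake_scene_mean,
    mann_kendall,
)
from lake_tsi.synthetic import simulate_annual_series


def brute_force_mk(values, years):
    """O(n^2) oracle: direct pair enumeration and exhaustive slope median."""
    x = [v for v in values if v is not None]
    t = [y for y, v in zip(years, values) if v is not None]
    s = 0
    slopes = []
    for i in range(len(x)):
        for j in range(i + 1, len(x)):
            d = float(x[j] - x[i])
            s += (1 if d > 0 else 0) - (1 if d < 0 else 0)
            if t[j] != t[i]:
                slopes.append(d / (t[j] - t[i]))
    n = len(x)
    var = n * (n - 1) * (2 * n + 5) / 18
    from collections import Counter

    for cnt in Counter(x).values():
        if cnt > 1:
            var -= cnt * (cnt - 1) * (2 * cnt + 5) / 18
    z = 0.0 if s == 0 or var == 0 else (s - math.copysign(1, s)) / math.sqrt(var)
    # exhaustive median: middle element(s) of the fully sorted slope list
    ss = sorted(slopes)
    k = len(ss)
    sen = ss[k // 2] if k % 2 else (ss[k // 2 - 1] + ss[k // 2]) / 2
    return s, sen, z


def raster(values, lake_total):
    grid = np.full((1, len(values)), np.nan) if values else np.full((1, 1), np.nan)
    for i, v in enumerate(values):
        grid[0, i] = v
    return TsiRaster(values=grid, valid_count=len(values), lake_total=lake_total)


class TestLakeSceneMean:
    def test_mean_and_coverage(self):
        mean, count, cover = lake_scene_mean(raster([40.0, 50.0, 60.0], 10))
        assert mean == pytest.approx(50.0) and count == 3 and cover == pytest.approx(30.0)

    def test_empty_raster_missing(self):
        mean, count, cover = lake_scene_mean(raster([], 10))
        assert mean is None and count == 0 and cover == 0.0

    def test_full_coverage(self):
        mean, count, cover = lake_scene_mean(raster([72.47] * 10, 10))
        assert mean == pytest.approx(72.47) and cover == 100.0

    def test_zero_total_error(self):
        with pytest.raises(ValueError):
            lake_scene_mean(raster([50.0], 0))


class TestAnnualize:
    def test_mean_of_scene_means(self):
        rec = annualize("LK", [("a", 48.0, 100, 80.0), ("b", 52.0, 120, 90.0)], 2001)
        assert rec.tsi_mean == pytest.approx(50.0)
        assert rec.pixel_count == 110
        assert rec.coverage_pct == pytest.approx(85.0)

    def test_empty_year_missing(self):
        rec = annualize("LK", [], 2001)
        assert rec.tsi_mean is None and rec.pixel_count == 0

    def test_single_scene(self):
        rec = annualize("LK", [("a", 61.2, 50, 40.0)], 1999)
        assert rec.tsi_mean == pytest.approx(61.2)

    def test_scenes_without_pixels_skipped(self):
        rec = annualize("LK", [("a", None, 0, 0.0), ("b", 44.0, 10, 10.0)], 2000)
        assert rec.tsi_mean == pytest.approx(44.0)


class TestFortyYearAverage:
    def records(self, values, start=1984):
        return [
            AnnualRecord("LK", start + i, v, 10, 50.0) for i, v in enumerate(values)
        ]

    def test_constant_series(self):
        avg, level = forty_year_average(self.records([55.0] * 5))
        assert avg == 55.0 and level.label == "light eutrophic"

    def test_boundary_mean_upper_bin(self):
        avg, level = forty_year_average(self.records([40.0, 60.0]))
        assert avg == 50.0 and level.label == "light eutrophic"

    def test_oligotrophic_40_years(self):
        avg, level = forty_year_average(self.records([25.0] * 40))
        assert avg == 25.0 and level.label == "oligotrophic"

    def test_order_invariant_and_gaps(self):
        recs = self.records([40.0, None, 60.0, 50.0])
        assert forty_year_average(recs) == forty_year_average(recs[::-1])

    def test_all_missing_error(self):
        with pytest.raises(ValueError):
            forty_year_average(self.records([None, None]))


class TestMannKendall:
    def test_strictly_increasing(self):
        res = mann_kendall(list(range(1, 11)))
        assert res.s_statistic == 45
        assert res.z == pytest.approx(44 / math.sqrt(125))
        assert res.p_value == pytest.approx(2 * stats.norm.sf(44 / math.sqrt(125)), rel=1e-9)
        assert res.trend == "increase"

    def test_constant_series_no_trend(self):
        res = mann_kendall([5.0] * 10)
        assert res.s_statistic == 0 and res.z == 0.0 and res.trend == "no trend"

    def test_reversal_antisymmetry(self, rng):
        x = list(rng.normal(50, 5, 15))
        a = mann_kendall(x)
        b = mann_kendall(x[::-1])
        assert b.s_statistic == -a.s_statistic
        assert b.sen_slope == pytest.approx(-a.sen_slope)

    def test_linear_series_sen_slope_exact(self):
        for n in (4, 7, 40):
            res = mann_kendall([2 * t + 7 for t in range(n)])
            assert res.sen_slope == pytest.approx(2.0, abs=1e-12)

    def test_constant_shift_invariance(self, rng):
        x = list(rng.normal(0, 1, 20))
        a = mann_kendall(x)
        b = mann_kendall([v + 123.4 for v in x])
        assert (a.s_statistic, a.z, a.p_value, a.sen_slope) == pytest.approx(
            (b.s_statistic, b.z, b.p_value, b.sen_slope)
        )

    def test_gaps_use_actual_year_spacing(self):
        years = [1984, 1985, 1990, 1995, 2000]
        vals = [10.0, 11.0, None, 21.0, 26.0]
        res = mann_kendall(vals, years=years)
        oracle_s, oracle_sen, _ = brute_force_mk(vals, years)
        assert res.s_statistic == oracle_s
        assert res.sen_slope == pytest.approx(oracle_sen)

    def test_short_series_warns_no_trend(self, caplog):
        with caplog.at_level("WARNING"):
            res = mann_kendall([1.0, 2.0, 3.0])
        assert res.trend == "no trend"
        with pytest.raises(ValueError):
            mann_kendall([1.0])

    def test_agrees_with_brute_force_oracle(self):
        """S and Sen slope exactly, Z to 1e-12, on many random series."""
        rng = np.random.default_rng(2024)
        for rep in range(200):
            n = int(rng.integers(4, 41))
            x = rng.normal(50, 5, n)
            if rng.uniform() < 0.3:  # inject ties
                x = np.round(x)
            years = sorted(rng.choice(np.arange(1984, 2024), size=n, replace=False))
            vals = list(x)
            res = mann_kendall(vals, years=years)
            s, sen, z = brute_force_mk(vals, list(years))
            assert res.s_statistic == s
            assert res.sen_slope == pytest.approx(sen, abs=1e-12)
            assert res.z == pytest.approx(z, abs=1e-12)

    def test_sen_slope_matches_theilslopes_on_gapfree_series(self, rng):
        x = rng.normal(50, 4, 30)
        res = mann_kendall(list(x))
        ts = stats.theilslopes(x, np.arange(30))
        assert res.sen_slope == pytest.approx(ts.slope, abs=1e-12)


class TestTrendRecovery:
    def test_injected_trend_detected(self):
        hits = 0
        for seed in range(50):
            years, vals = simulate_annual_series(40, base=45, slope=0.3, noise_sd=2.0, seed=seed)
            if mann_kendall(vals, years=years).trend == "increase" :
                hits += 1
        assert hits >= 47  # ~power 95%+

    def test_null_rejection_rate_near_alpha(self):
        fp = 0
        for seed in range(100):
            years, vals = simulate_annual_series(40, base=45, slope=0.0, noise_sd=2.0, seed=seed)
            if mann_kendall(vals, years=years).trend != "no trend":
                fp += 1
        assert fp <= 12  # alpha 0.05 with Monte-Carlo slack
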