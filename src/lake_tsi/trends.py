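"""Annual aggregation and long-term trend testing of per-lake TSI.

Scene-level lake means are averaged per calendar year, the annual series
is averaged over the study period and binned into a trophic class, and a
Mann-Kendall test with Sen's slope classifies the multi-decadal trend.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .indices import TROPHIC_LEVELS, TrophicLevel, trophic_level
from .pipeline import TsiRaster

log = logging.getLogger(__name__)

__all__ = [
    "AnnualRecord",
    "TrendResult",
    "lake_scene_mean",
    "annualize",
    "forty_year_average",
    "mann_kendall",
    "archive_summary",
]


@dataclass(frozen=True)
class AnnualRecord:
    """Per-lake, per-year mean TSI and pixel statistics."""

    lake_id: str
    year: int
    tsi_mean: Optional[float]  # None for a year with no usable scenes
    pixel_count: int
    coverage_pct: float


@dataclass(frozen=True)
class TrendResult:
    """Mann-Kendall trend of an annual TSI series.

    s_statistic: signed count of increasing minus decreasing pairs.
    z: continuity-corrected normal deviate; p_value two-sided.
    sen_slope: median of pairwise slopes, TSI units per year.
    trend: 'increase' / 'decrease' / 'no trend' at level alpha.
    """

    lake_id: str
    s_statistic: int
    z: float
    p_value: float
    sen_slope: float
    trend: str
    n: int
    alpha: float = 0.05


def lake_scene_mean(raster: TsiRaster) -> Tuple[Optional[float], int, float]:
    """Lake mean TSI, valid-pixel count and percent coverage for one scene."""
    if raster.lake_total <= 0:
        raise ValueError("lake_total must be > 0")
    coverage = 100.0 * raster.valid_count / raster.lake_total
    if raster.valid_count == 0:
        return None, 0, 0.0
    mean = float(np.nanmean(raster.values))
    return mean, raster.valid_count, coverage


def annualize(
    lake_id: str,
    scene_results: Iterable[Tuple[object, Optional[float], int, float]],
    year: int,
) -> AnnualRecord:
    """Collapse one year's scene results into an AnnualRecord.

    ``scene_results`` holds (date, mean_tsi, valid_count, coverage_pct)
    tuples; entries with no valid pixels are skipped.  The annual mean is
    the unweighted mean of per-scene lake means (equal weight per
    observation date); pixel_count is the rounded mean of per-scene valid
    counts.  A year with no usable scenes yields a missing record.
    """
    means, counts, covers = [], [], []
    for _date, mean, count, cover in scene_results:
        if mean is None or not math.isfinite(mean):
            continue
        means.append(mean)
        counts.append(count)
        covers.append(cover)
    if not means:
        return AnnualRecord(lake_id, year, None, 0, 0.0)
    return AnnualRecord(
        lake_id=lake_id,
        year=year,
        tsi_mean=float(np.mean(means)),
        pixel_count=int(round(float(np.mean(counts)))),
        coverage_pct=float(np.mean(covers)),
    )


def forty_year_average(records: Sequence[AnnualRecord]) -> Tuple[float, TrophicLevel]:
    """Unweighted mean over non-missing annual values, with its trophic class."""
    vals = [r.tsi_mean for r in records if r.tsi_mean is not None]
    if not vals:
        raise ValueError("no non-missing annual values")
    avg = float(np.mean(vals))
    return avg, trophic_level(min(max(avg, 0.0), 100.0))


def _mk_s_and_var(x: np.ndarray) -> Tuple[int, float]:
    diff = np.sign(x[None, :] - x[:, None])
    s = int(np.triu(diff, k=1).sum())
    n = x.size
    var = n * (n - 1) * (2 * n + 5) / 18.0
    _, counts = np.unique(x, return_counts=True)
    for t in counts[counts > 1]:
        var -= t * (t - 1) * (2 * t + 5) / 18.0
    return s, var


def mann_kendall(
    values: Sequence[Optional[float]],
    years: Optional[Sequence[int]] = None,
    alpha: float = 0.05,
    lake_id: str = "",
) -> TrendResult:
    """Mann-Kendall trend test with Sen's slope on an annual series.

    Missing values (None/NaN) are dropped and the remaining actual year
    spacing is used for Sen's slope.  S is the signed pair count; its
    variance uses the tie correction n(n-1)(2n+5)/18 - sum t(t-1)(2t+5)/18;
    Z applies the +/-1 continuity correction; p is two-sided normal.
    Fewer than 4 values yields 'no trend' with a warning (>= 2 required).
    """
    if years is None:
        years = list(range(len(values)))
    pairs = [
        (int(t), float(v))
        for t, v in zip(years, values)
        if v is not None and math.isfinite(v)
    ]
    if len(pairs) < 2:
        raise ValueError("need >= 2 non-missing values")
    pairs.sort()
    t = np.array([p[0] for p in pairs], dtype=float)
    x = np.array([p[1] for p in pairs], dtype=float)
    n = x.size

    s, var = _mk_s_and_var(x)
    if var > 0 and s != 0:
        z = (s - np.sign(s)) / math.sqrt(var)
    else:
        z = 0.0
    p = 2.0 * stats.norm.sf(abs(z))

    slopes = [
        (x[j] - x[i]) / (t[j] - t[i])
        for i in range(n)
        for j in range(i + 1, n)
        if t[j] != t[i]
    ]
    sen = float(np.median(slopes)) if slopes else 0.0

    if n < 4:
        log.warning("lake %s: only %d values; trend reported as 'no trend'", lake_id, n)
        trend = "no trend"
    elif p < alpha:
        trend = "increase" if s > 0 else "decrease"
    else:
        trend = "no trend"
    return TrendResult(lake_id=lake_id, s_statistic=s, z=float(z), p_value=float(p),
                       sen_slope=sen, trend=trend, n=n, alpha=alpha)


def archive_summary(annual: pd.DataFrame, lake_info: pd.DataFrame) -> Dict[str, float]:
    """Completeness and size-structure statistics of an annual-TSI archive.

    ``annual`` must carry one row per lake with TSI_YYYY columns; ``lake_info``
    one row per lake with 'Lake Area' (km^2) and 'Lake Zone'.  Returns the
    fraction of lakes with >= 30 annual values, with a complete series,
    the share of 1-10 km^2 and > 500 km^2 lakes, and the count per zone.
    """
    tsi_cols = [c for c in annual.columns if c.startswith("TSI_")]
    n_years_per_lake = annual[tsi_cols].notna().sum(axis=1)
    n_lakes = len(annual)
    area = lake_info["Lake Area"].astype(float)
    out = {
        "n_lakes": float(n_lakes),
        "n_years": float(len(tsi_cols)),
        "pct_lakes_ge30_years": 100.0 * float((n_years_per_lake >= 30).mean()),
        "pct_lakes_complete": 100.0 * float((n_years_per_lake == len(tsi_cols)).mean()),
        "pct_lakes_1_10_km2": 100.0 * float(((area >= 1) & (area < 10)).mean()),
        "pct_lakes_gt500_km2": 100.0 * float((area > 500).mean()),
    }
    for zone, cnt in lake_info["Lake Zone"].value_counts().items():
        out[f"n_lakes_{zone}"] = float(cnt)
    return out
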