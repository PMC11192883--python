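"""Fitting and scoring of the per-type ABI->TSI linear models.

The inversion for each optical water type is an ordinary least-squares
line TSI = slope*ABI + intercept fitted on matchups (in-situ TSI from
measured chlorophyll-a, paired with satellite ABI at the sample point).
Validation reports R^2, RMSE, MRE, MAE and trophic-level agreement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .indices import ModelCoefficients, TypeCoefficients, trophic_level

__all__ = [
    "Matchup",
    "MetricsReport",
    "fit_type_model",
    "fit_all_types",
    "clear_threshold",
    "score",
    "matchups_to_frame",
    "coefficients_to_frame",
]


@dataclass(frozen=True)
class Matchup:
    """One in-situ sample paired with a concurrent satellite observation."""

    lake_id: str
    date: str  # ISO-8601
    water_type: int
    abi: float
    tsi_measured: float
    chla: Optional[float] = None

    def __post_init__(self) -> None:
        if self.water_type not in (1, 2, 3):
            raise ValueError(f"water_type must be 1, 2 or 3, got {self.water_type}")
        if not (0.0 <= self.tsi_measured <= 100.0):
            raise ValueError("tsi_measured must lie in [0, 100]")


@dataclass(frozen=True)
class MetricsReport:
    """Agreement between estimated and measured TSI series.

    r2 is the coefficient of determination of the OLS regression of
    estimated on measured (the primary statistic; for a simple regression
    it equals the squared Pearson correlation).  r2_identity scores the
    fit about the 1:1 line instead, 1 - SS(e - m)/SS(m - mean m); it can
    be negative and is not symmetric in its arguments.  rmse/mae in TSI
    units, mre in percent, level_accuracy the percentage of pairs falling
    in the same trophic class.
    """

    r2: float
    rmse: float
    mre: float
    mae: float
    n: int
    level_accuracy: float
    r2_identity: float


def fit_type_model(matchups: Iterable[Matchup], water_type: int) -> TypeCoefficients:
    """OLS fit of measured TSI on ABI for one water type.

    Returns slope, intercept, r^2 and the two-sided p-value for slope != 0
    (t distribution on n-2 df).  Requires >= 3 matchups of the type with
    non-constant ABI.
    """
    pts = [m for m in matchups if m.water_type == water_type]
    if len(pts) < 3:
        raise ValueError(
            f"need >= 3 matchups for type {water_type}, got {len(pts)}"
        )
    x = np.array([m.abi for m in pts])
    y = np.array([m.tsi_measured for m in pts])
    if np.ptp(x) == 0:
        raise ValueError("singular fit: all ABI values identical")
    res = stats.linregress(x, y)
    return TypeCoefficients(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=len(pts),
    )


def fit_all_types(matchups: Sequence[Matchup]) -> ModelCoefficients:
    return {wt: fit_type_model(matchups, wt) for wt in (1, 2, 3)}


def clear_threshold(mu: float, sigma: float) -> float:
    """Green-reflectance cut for clear water: mu + 2*sigma of the clear-lake
    green-band distribution (~95% one-sided coverage).  The production
    value is reported rounded to 2 decimals."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    return mu + 2.0 * sigma


def score(estimated, measured, require_positive: bool = True) -> MetricsReport:
    """Validation metrics for paired estimated/measured TSI.

    mre is mean(|e - m| / m) * 100, relative to the measured value, so
    measured values must be positive.
    """
    e = np.asarray(estimated, dtype=float)
    m = np.asarray(measured, dtype=float)
    if e.shape != m.shape:
        raise ValueError(f"length mismatch: {e.shape} vs {m.shape}")
    if e.size < 2:
        raise ValueError("need >= 2 pairs")
    if require_positive and np.any(m <= 0):
        raise ValueError("measured values must be > 0 for MRE")
    diff = e - m
    rmse = float(np.sqrt(np.mean(diff**2)))
    mae = float(np.mean(np.abs(diff)))
    mre = float(np.mean(np.abs(diff) / m) * 100.0)
    ss_tot = float(np.sum((m - m.mean()) ** 2))
    if np.ptp(m) == 0 or np.ptp(e) == 0:
        r2 = 1.0 if np.array_equal(e, m) else 0.0
    else:
        res = stats.linregress(m, e)
        r2 = float(res.rvalue**2)
    r2_ident = 1.0 - float(np.sum(diff**2)) / ss_tot if ss_tot > 0 else (
        1.0 if np.array_equal(e, m) else 0.0
    )
    same = trophic_level(np.clip(e, 0, 100)) == trophic_level(np.clip(m, 0, 100))
    acc = float(100.0 * np.mean(same))
    return MetricsReport(r2=r2, rmse=rmse, mre=mre, mae=mae, n=int(e.size),
                         level_accuracy=acc, r2_identity=r2_ident)


def matchups_to_frame(matchups: Sequence[Matchup]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lake_id": [m.lake_id for m in matchups],
            "date": [m.date for m in matchups],
            "water_type": [m.water_type for m in matchups],
            "abi": [m.abi for m in matchups],
            "chla": [m.chla if m.chla is not None else math.nan for m in matchups],
            "tsi_measured": [m.tsi_measured for m in matchups],
        }
    )


def coefficients_to_frame(coeffs: ModelCoefficients) -> pd.DataFrame:
    """Coefficient table mirroring the published per-type layout."""
    rows = []
    names = {1: "1 (algal-dominated)", 2: "2 (turbid)", 3: "3 (clear)"}
    for wt in sorted(coeffs):
        c = coeffs[wt]
        rows.append(
            {
                "Lake Type": names.get(wt, str(wt)),
                "R2": c.r2,
                "p-value": c.p_value,
                "number": c.n,
                "slope": c.slope,
                "intercept": c.intercept,
            }
        )
    return pd.DataFrame(rows)
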