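"""Forward-model generator for scenes, matchups and annual series.

The generator emulates the statistical structure the retrieval pipeline
assumes: a land background with negative water index, elliptical lakes
whose pixels belong to the three optical water types (algal-dominated,
turbid, clear) plus floating scum and aquatic vegetation, cloud blobs in
the QA layer, and per-pixel TSI known exactly.  Water-pixel spectra are
constructed by inverting the ABI definition in closed form subject to the
decision-tree constraints of the pixel's type, so that with zero noise
the pipeline recovers class and TSI exactly.

Everything is driven by an explicit seed and is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from shapely.geometry import Point

from .calibration import Matchup
from .indices import (
    DEFAULT_COEFFICIENTS,
    ModelCoefficients,
    SensorSpec,
    abi,
    get_sensor,
    tsi_from_chla,
)
from .pipeline import CLASS_CODES, GeoTransform, LakeOutline, QA_CODES, Scene, Thresholds

__all__ = [
    "InfeasibleTarget",
    "LakeSpec",
    "SceneRecipe",
    "SceneTruth",
    "solve_bands_for_abi",
    "simulate_scene",
    "simulate_matchups",
    "noise_sd_for_r2",
    "simulate_annual_series",
]


class InfeasibleTarget(ValueError):
    """The requested ABI cannot be realized under the type's constraints."""


# Per-type anchor values for spectrum construction.  FAI and TWI targets sit
# safely inside the decision-tree bands for the type; the red-band anchor
# centers the solved reflectances inside [0, 0.6].
_TYPE_ANCHORS: Dict[int, Dict[str, float]] = {
    1: {"fai": -0.02, "twi": 0.03, "r": 0.30},
    2: {"fai": -0.02, "twi": 0.12, "r": 0.30},
    3: {"fai": -0.02, "twi": 0.02, "r": 0.07},
}
_REFL_MAX = 0.6  # physical-plausibility bound on generated reflectance


def solve_bands_for_abi(
    target_abi: float,
    water_type: int,
    sensor: SensorSpec | str,
    rng: Optional[np.random.Generator] = None,
    thresholds: Thresholds | None = None,
) -> Dict[str, float]:
    """Spectrum with ``abi(spectrum) == target_abi`` (to 1e-9) that the
    decision tree classifies as ``water_type``.

    Closed form: fix the type's FAI and TWI at anchor values, which makes
    ABI linear in R; solve R, derive SWIR = R - TWI and
    NIR = FAI + R - TWI*k from the anchors, pick B to keep R in bounds and
    G to keep the pixel water-like (G > NIR) while satisfying the type's
    green/blue constraints.  With ``rng`` the anchors and the free green
    band are jittered, still in closed form, so the ABI stays exact.

    Raises :class:`InfeasibleTarget` naming the violated constraint when
    the target is outside the type's feasible envelope (reflectance must
    stay within [0, 0.6]).
    """
    if isinstance(sensor, str):
        sensor = get_sensor(sensor)
    if water_type not in (1, 2, 3):
        raise ValueError(f"water_type must be 1, 2 or 3, got {water_type}")
    thresholds = thresholds or Thresholds()
    anchors = dict(_TYPE_ANCHORS[water_type])
    if rng is not None:
        anchors["fai"] += rng.uniform(-0.006, 0.004)
        anchors["twi"] *= rng.uniform(0.85, 1.15)
        anchors["r"] += rng.uniform(-0.02, 0.02)

    lam_b, lam_g, lam_r = sensor["B"], sensor["G"], sensor["R"]
    lam_n, lam_s = sensor["NIR"], sensor["SWIR"]
    c1 = (lam_g - lam_b) / (lam_r - lam_b)
    c2 = (lam_g - lam_b) / (lam_n - lam_b)
    k = (lam_n - lam_r) / (lam_s - lam_r)

    f_t, w_t, r_anchor = anchors["fai"], anchors["twi"], anchors["r"]
    # With FAI and TWI pinned, NIR = f_t + R - w_t*k and SWIR = R - w_t, so
    # ABI = (R - B)*c1 - (NIR - B)*c2 is linear in (R - B):
    delta = (target_abi + (f_t - w_t * k) * c2) / (c1 - c2)
    b = float(np.clip(r_anchor - delta, 0.02, _REFL_MAX - 0.02))
    r = b + delta
    if not (0.005 <= r <= _REFL_MAX):
        raise InfeasibleTarget(
            f"type {water_type}, ABI {target_abi:.4g}: required R={r:.3f} "
            f"outside [0.005, {_REFL_MAX}]"
        )
    swir = r - w_t
    if not (0.0 <= swir <= _REFL_MAX):
        raise InfeasibleTarget(f"SWIR={swir:.3f} outside [0, {_REFL_MAX}]")
    nir = f_t + r - w_t * k
    if not (0.0 <= nir <= _REFL_MAX):
        raise InfeasibleTarget(f"NIR={nir:.3f} outside [0, {_REFL_MAX}]")

    if water_type in (1, 2):
        g = max(thresholds.green_clear + 0.005, b + 0.005, nir + 0.03)
        if rng is not None:
            g += rng.uniform(0.0, 0.03)
        if g > _REFL_MAX:
            raise InfeasibleTarget(f"green band G={g:.3f} exceeds {_REFL_MAX}")
    else:
        g_lo = nir + 0.02
        g_hi = thresholds.green_clear - 0.005
        if g_lo >= g_hi:
            raise InfeasibleTarget(
                f"type 3 needs NIR < G < {g_hi:.3f}, but NIR={nir:.3f}"
            )
        g = g_lo + (0.6 if rng is None else rng.uniform(0.2, 0.95)) * (g_hi - g_lo)

    spec = {"B": b, "G": g, "R": r, "NIR": nir, "SWIR": swir}
    check = abi(b, r, nir, sensor)
    if abs(check - target_abi) > 1e-9:
        raise InfeasibleTarget(f"round-trip ABI error {check - target_abi:.2e}")
    return spec


# -- scene simulation -------------------------------------------------------

#: Non-typed in-lake spectra (seeded jitter applied on top).
_SCUM_BASE = {"B": 0.08, "G": 0.25, "R": 0.10, "SWIR": 0.05}
_SCUM_FAI = 0.12
_VEG_BASE = {"B": 0.05, "G": 0.13, "R": 0.06, "SWIR": 0.04}
_VEG_FAI = 0.008
_LAND_BASE = {"B": 0.06, "G": 0.08, "R": 0.12, "NIR": 0.25, "SWIR": 0.20}


@dataclass(frozen=True)
class LakeSpec:
    """One elliptical lake in a recipe: geometry, class mix, TSI field.

    fractions are of the lake's pixels and must sum to <= 1; any remainder
    becomes dry in-lake margin (land-like spectra).  tsi_range gives the
    per-type (lo, hi) TSI span; 'gradient' ramps TSI west-to-east across
    the lake, 'constant' uses the lower bound.  Defaults sit inside the
    envelope that reflectance bounds allow for each type's inversion line.
    """

    lake_id: str
    center: Tuple[float, float]  # (row, col)
    radii: Tuple[float, float]  # (row, col) semi-axes, pixels
    fractions: Dict[str, float] = field(
        default_factory=lambda: {"type1": 0.4, "type2": 0.3, "type3": 0.3}
    )
    tsi_range: Dict[int, Tuple[float, float]] = field(
        default_factory=lambda: {1: (55.0, 75.0), 2: (45.0, 60.0), 3: (18.0, 28.0)}
    )
    tsi_mode: str = "gradient"
    name: str = ""
    zone: str = "EPL"
    elevation_m: float = 10.0

    def validate(self) -> List[str]:
        errs = []
        total = sum(self.fractions.values())
        if any(v < 0 or v > 1 for v in self.fractions.values()) or total > 1 + 1e-9:
            errs.append(f"lake {self.lake_id}: fractions must be in [0,1], sum <= 1")
        unknown = set(self.fractions) - {"type1", "type2", "type3", "scum", "vegetation"}
        if unknown:
            errs.append(f"lake {self.lake_id}: unknown classes {sorted(unknown)}")
        for wt, (lo, hi) in self.tsi_range.items():
            if not (0 <= lo <= hi <= 100):
                errs.append(f"lake {self.lake_id}: bad TSI range for type {wt}")
        if min(self.radii) < 5:
            errs.append(f"lake {self.lake_id}: radii must be >= 5 pixels")
        return errs


@dataclass(frozen=True)
class SceneRecipe:
    """Deterministic description of one synthetic scene."""

    shape: Tuple[int, int] = (128, 128)
    lakes: Tuple[LakeSpec, ...] = ()
    sensor_id: str = "OLI"
    noise_sd: float = 0.0  # per-band additive Gaussian, reflectance units
    cloud_fraction: float = 0.0
    seed: int = 0
    pixel_size_m: float = 30.0

    def validate(self) -> None:
        errs = []
        if self.noise_sd < 0:
            errs.append("noise_sd must be >= 0")
        if not (0 <= self.cloud_fraction <= 1):
            errs.append("cloud_fraction must be in [0, 1]")
        if self.sensor_id not in ("TM", "ETM+", "OLI"):
            errs.append(f"unknown sensor {self.sensor_id!r}")
        for lake in self.lakes:
            errs.extend(lake.validate())
        if errs:
            raise ValueError("invalid recipe: " + "; ".join(errs))


@dataclass
class SceneTruth:
    """Ground truth accompanying a simulated scene."""

    class_map: np.ndarray  # uint8, CLASS_CODES
    tsi: np.ndarray  # float, NaN outside typed water
    abi: np.ndarray  # float, NaN outside typed water
    outlines: List[LakeOutline] = field(default_factory=list)


def _largest_remainder_counts(fractions: Dict[str, float], n: int) -> Dict[str, int]:
    """Integer class counts within +/-1 of fraction*n, summing to
    round(sum(fractions)*n)."""
    exact = {c: f * n for c, f in fractions.items()}
    counts = {c: int(math.floor(v)) for c, v in exact.items()}
    target = int(round(sum(exact.values())))
    leftovers = sorted(exact, key=lambda c: exact[c] - counts[c], reverse=True)
    i = 0
    while sum(counts.values()) < target:
        counts[leftovers[i % len(leftovers)]] += 1
        i += 1
    return counts


def _cloud_mask(shape, fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Contiguous cloud blobs from seeded random walks, ~fraction coverage."""
    mask = np.zeros(shape, dtype=bool)
    n_target = int(round(fraction * mask.size))
    while mask.sum() < n_target:
        r, c = rng.integers(0, shape[0]), rng.integers(0, shape[1])
        steps = max(20, n_target // 4)
        for _ in range(steps):
            mask[max(0, r - 1) : r + 2, max(0, c - 1) : c + 2] = True
            r = int(np.clip(r + rng.integers(-1, 2), 0, shape[0] - 1))
            c = int(np.clip(c + rng.integers(-1, 2), 0, shape[1] - 1))
            if mask.sum() >= n_target:
                break
    return mask


def _jittered(base: Dict[str, float], rng: np.random.Generator, scale=0.01):
    return {b: v + rng.uniform(-scale, scale) for b, v in base.items()}


def simulate_scene(recipe: SceneRecipe) -> Tuple[Scene, SceneTruth]:
    """Render a recipe into a Scene plus its ground truth.

    Land fills the background; each lake's pixels are split among the
    recipe classes (largest-remainder rounding, so realized counts are
    within one pixel of the targets) in contiguous west-to-east bands.
    Typed water pixels get spectra from :func:`solve_bands_for_abi` with
    ABI = (TSI - intercept)/slope of the default inversion line.  Band
    noise is added after construction; clouds only touch the QA layer.
    """
    recipe.validate()
    rng = np.random.default_rng(recipe.seed)
    sensor = get_sensor(recipe.sensor_id)
    shape = tuple(recipe.shape)
    bands = {b: np.empty(shape) for b in ("B", "G", "R", "NIR", "SWIR")}

    # land background
    for b, v in _LAND_BASE.items():
        bands[b][:] = v + rng.uniform(-0.01, 0.01, size=shape)

    class_map = np.full(shape, CLASS_CODES["land"], dtype=np.uint8)
    tsi_truth = np.full(shape, np.nan)
    abi_truth = np.full(shape, np.nan)
    outlines: List[LakeOutline] = []

    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    for lake in recipe.lakes:
        (cy, cx), (ry, rx) = lake.center, lake.radii
        inside = ((rows - cy) / ry) ** 2 + ((cols - cx) / rx) ** 2 <= 1.0
        idx = np.argwhere(inside)
        if idx.size == 0:
            continue
        order = np.lexsort((idx[:, 0], idx[:, 1]))  # west-to-east bands
        idx = idx[order]
        counts = _largest_remainder_counts(lake.fractions, len(idx))
        col_lo, col_hi = idx[:, 1].min(), idx[:, 1].max()
        span = max(1, col_hi - col_lo)

        pos = 0
        for cls in ("type3", "type2", "type1", "vegetation", "scum"):
            n_cls = counts.get(cls, 0)
            for r_i, c_i in idx[pos : pos + n_cls]:
                if cls in ("type1", "type2", "type3"):
                    wt = int(cls[-1])
                    lo, hi = lake.tsi_range[wt]
                    if lake.tsi_mode == "constant":
                        tsi = lo
                    else:
                        tsi = lo + (hi - lo) * (c_i - col_lo) / span
                    coef = DEFAULT_COEFFICIENTS[wt]
                    target = (tsi - coef.intercept) / coef.slope
                    spec = solve_bands_for_abi(target, wt, sensor, rng)
                    tsi_truth[r_i, c_i] = tsi
                    abi_truth[r_i, c_i] = target
                elif cls == "scum":
                    spec = _jittered(_SCUM_BASE, rng, 0.005)
                    k = (sensor["NIR"] - sensor["R"]) / (sensor["SWIR"] - sensor["R"])
                    spec["NIR"] = spec["R"] + (spec["SWIR"] - spec["R"]) * k + _SCUM_FAI
                else:  # vegetation
                    spec = _jittered(_VEG_BASE, rng, 0.003)
                    k = (sensor["NIR"] - sensor["R"]) / (sensor["SWIR"] - sensor["R"])
                    spec["NIR"] = spec["R"] + (spec["SWIR"] - spec["R"]) * k + _VEG_FAI
                for b in bands:
                    bands[b][r_i, c_i] = spec[b]
                class_map[r_i, c_i] = CLASS_CODES[cls]
            pos += n_cls
        # any remainder (fractions summing < 1) stays land-like margin

        n_px = len(idx)
        area = max(1.0, n_px * (recipe.pixel_size_m / 1000.0) ** 2)
        outlines.append(
            LakeOutline(
                lake_id=lake.lake_id,
                polygon=_ellipse_polygon(cx, cy, rx, ry),
                name=lake.name,
                area_km2=area,
                zone=lake.zone,
                elevation_m=lake.elevation_m,
            )
        )

    if recipe.noise_sd > 0:
        for b in bands:
            bands[b] = bands[b] + rng.normal(0.0, recipe.noise_sd, size=shape)

    qa = np.full(shape, QA_CODES["clear"], dtype=np.uint8)
    if recipe.cloud_fraction > 0:
        clouds = _cloud_mask(shape, recipe.cloud_fraction, rng)
        qa[clouds] = QA_CODES["high"]
        class_map[clouds] = CLASS_CODES["cloud"]
        tsi_truth[clouds] = np.nan
        abi_truth[clouds] = np.nan

    scene = Scene(bands=bands, qa=qa, sensor=sensor, transform=GeoTransform())
    return scene, SceneTruth(class_map=class_map, tsi=tsi_truth, abi=abi_truth,
                             outlines=outlines)


def _ellipse_polygon(cx: float, cy: float, rx: float, ry: float):
    """Shapely ellipse in pixel-center coordinates (x = col+0.5, y = row+0.5).

    Slightly inflated (+0.5 px per axis) so pixels whose centers satisfy the
    raster ellipse test also fall inside the vector outline.
    """
    circ = Point(cx + 0.5, cy + 0.5).buffer(1.0, quad_segs=64)
    from shapely import affinity

    return affinity.scale(circ, xfact=rx + 0.5, yfact=ry + 0.5, origin=(cx + 0.5, cy + 0.5))


# -- matchups ---------------------------------------------------------------


def noise_sd_for_r2(
    target_r2: float, chla_log_mu: float = 2.0, chla_log_sigma: float = 1.0
) -> float:
    """TSI noise standard deviation giving an expected model r^2.

    The clean TSI signal is 10*(2.5 + 1.086 ln Chla) with ln Chla normal,
    censored into [20, 90]; its variance follows from censored-normal
    moments, and r^2 = var_signal / (var_signal + sd^2).
    """
    if not (0 < target_r2 < 1):
        raise ValueError("target_r2 must be in (0, 1)")
    mu = 25.0 + 10.86 * chla_log_mu
    sd = 10.86 * chla_log_sigma
    a, b = (20.0 - mu) / sd, (90.0 - mu) / sd
    # censored (clipped) normal moments
    pa, pb = stats.norm.cdf(a), stats.norm.sf(b)
    da, db = stats.norm.pdf(a), stats.norm.pdf(b)
    mid = 1.0 - pa - pb
    # E[Z] and E[Z^2] of Z = clip(N(0,1), a, b)
    ez = a * pa + b * pb + (da - db)
    ez2 = a**2 * pa + b**2 * pb + mid + (a * da - b * db)
    var_signal = (ez2 - ez**2) * sd**2
    return math.sqrt(var_signal * (1.0 - target_r2) / target_r2)


def simulate_matchups(
    n: int,
    water_type: int,
    coeffs: ModelCoefficients | None = None,
    chla_log_mu: float = 2.0,
    chla_log_sigma: float = 1.0,
    tsi_noise_sd: float = 0.0,
    seed: int = 0,
) -> List[Matchup]:
    """Synthetic matchup set for one water type.

    Chla is lognormal (log-scale mean 2.0, sd 1.0 by default, spreading
    TSI across all five trophic classes); clean TSI from the Carlson
    formula is clipped to the sampled range [20, 90]; ABI lies exactly on
    the type's inversion line; measurement noise is added to the measured
    TSI (exogenous error, so an OLS refit of TSI on ABI is unbiased).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    coeffs = coeffs or DEFAULT_COEFFICIENTS
    c = coeffs[water_type]
    rng = np.random.default_rng(seed)
    chla = np.exp(rng.normal(chla_log_mu, chla_log_sigma, size=n))
    tsi_clean = np.clip(tsi_from_chla(chla), 20.0, 90.0)
    abi_vals = (tsi_clean - c.intercept) / c.slope
    tsi_meas = tsi_clean + rng.normal(0.0, tsi_noise_sd, size=n) if tsi_noise_sd > 0 else tsi_clean
    tsi_meas = np.clip(tsi_meas, 0.0, 100.0)
    return [
        Matchup(
            lake_id=f"SYN{water_type}{i:04d}",
            date="2020-07-01",
            water_type=water_type,
            abi=float(abi_vals[i]),
            tsi_measured=float(tsi_meas[i]),
            chla=float(chla[i]),
        )
        for i in range(n)
    ]


# -- scene archives ---------------------------------------------------------


def archive_recipes(
    base: SceneRecipe,
    n_years: int,
    scenes_per_year: int = 2,
    trend_by_lake: Optional[Dict[str, float]] = None,
    start_year: int = 1984,
    seed: int = 0,
) -> List[Tuple["_dt.date", SceneRecipe]]:
    """Dated recipes for a multi-year archive with injected TSI trends.

    Each year yields ``scenes_per_year`` recipes; lake TSI ranges are
    shifted by trend*(year - start_year) (TSI units per year), staying a
    valid recipe as long as the shifted ranges remain inside each type's
    feasible envelope.  Seeds are derived deterministically from ``seed``.
    """
    import datetime as _dt

    trend_by_lake = trend_by_lake or {}
    out: List[Tuple[_dt.date, SceneRecipe]] = []
    counter = 0
    for yi in range(n_years):
        year = start_year + yi
        for si in range(scenes_per_year):
            month = 4 + (si * 6) // max(1, scenes_per_year)  # spread Apr..Sep
            date = _dt.date(year, min(12, month), 15)
            lakes = []
            for lake in base.lakes:
                shift = trend_by_lake.get(lake.lake_id, 0.0) * yi
                rng = {
                    wt: (lo + shift, hi + shift)
                    for wt, (lo, hi) in lake.tsi_range.items()
                }
                lakes.append(replace(lake, tsi_range=rng))
            out.append(
                (date, replace(base, lakes=tuple(lakes), seed=seed + 1000 + counter))
            )
            counter += 1
    return out


# -- annual series ----------------------------------------------------------


def simulate_annual_series(
    n_years: int,
    base: float = 50.0,
    slope: float = 0.0,
    noise_sd: float = 2.0,
    missing_fraction: float = 0.0,
    seed: int = 0,
    start_year: int = 1984,
) -> Tuple[List[int], List[Optional[float]]]:
    """Annual TSI series base + slope*t + N(0, noise_sd^2) with a seeded
    subset of years set missing.  Returns (years, values)."""
    if n_years < 4:
        raise ValueError("n_years must be >= 4")
    rng = np.random.default_rng(seed)
    t = np.arange(n_years)
    x = base + slope * t + rng.normal(0.0, noise_sd, size=n_years)
    values: List[Optional[float]] = [float(v) for v in x]
    n_missing = int(round(missing_fraction * n_years))
    if n_missing > 0:
        drop = rng.choice(n_years, size=n_missing, replace=False)
        for i in drop:
            values[int(i)] = None
    years = [start_year + int(i) for i in t]
    return years, values
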