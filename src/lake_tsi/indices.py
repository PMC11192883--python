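"""Spectral indices and trophic-state formulas.

Everything here is pure, scalar-or-array arithmetic: the Carlson-style
trophic state index from chlorophyll-a, the trophic-level bins, the four
spectral indices used to extract and type water pixels (NDWI, FAI, TWI,
ABI), and the per-water-type linear inversion from ABI to TSI.

Reflectances are dimensionless surface-reflectance floats.  Integer-scaled
products (the x10000 dialect) must be rescaled by the reader before they
reach this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Tuple

import numpy as np

__all__ = [
    "SensorSpec",
    "SENSORS",
    "get_sensor",
    "TrophicLevel",
    "TROPHIC_LEVELS",
    "TypeCoefficients",
    "ModelCoefficients",
    "DEFAULT_COEFFICIENTS",
    "tsi_from_chla",
    "trophic_level",
    "ndwi",
    "fai",
    "twi",
    "abi",
    "tsi_from_abi",
]

BAND_ORDER = ("B", "G", "R", "NIR", "SWIR")


@dataclass(frozen=True)
class SensorSpec:
    """Band-center wavelengths (nm) for one Landsat-class instrument.

    Green through SWIR centers are the published values for each sensor;
    the blue center is the nominal band center (it is needed only by the
    ABI baselines) and can be overridden.
    """

    sensor_id: str
    wavelengths: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [b for b in BAND_ORDER if b not in self.wavelengths]
        if missing:
            raise ValueError(f"sensor {self.sensor_id!r} missing bands: {missing}")
        lam = [self.wavelengths[b] for b in BAND_ORDER]
        if any(w <= 0 for w in lam):
            raise ValueError("wavelengths must be positive")
        if not all(a < b for a, b in zip(lam, lam[1:])):
            raise ValueError("wavelengths must increase B < G < R < NIR < SWIR")

    def __getitem__(self, band: str) -> float:
        return float(self.wavelengths[band])

    def with_blue(self, lambda_b: float) -> "SensorSpec":
        wl = dict(self.wavelengths)
        wl["B"] = float(lambda_b)
        return replace(self, wavelengths=wl)


SENSORS: Dict[str, SensorSpec] = {
    "OLI": SensorSpec("OLI", {"B": 482.0, "G": 563.0, "R": 665.0, "NIR": 865.0, "SWIR": 1609.0}),
    "TM": SensorSpec("TM", {"B": 485.0, "G": 560.0, "R": 660.0, "NIR": 835.0, "SWIR": 1650.0}),
    "ETM+": SensorSpec("ETM+", {"B": 485.0, "G": 560.0, "R": 660.0, "NIR": 835.0, "SWIR": 1650.0}),
}


def get_sensor(sensor_id: str) -> SensorSpec:
    try:
        return SENSORS[sensor_id]
    except KeyError:
        raise KeyError(
            f"unknown sensor {sensor_id!r}; expected one of {sorted(SENSORS)}"
        ) from None


@dataclass(frozen=True)
class TrophicLevel:
    label: str
    lo: float
    hi: float  # half-open [lo, hi); the final bin is closed at 100

    def __contains__(self, tsi: float) -> bool:
        if self.hi == 100.0:
            return self.lo <= tsi <= self.hi
        return self.lo <= tsi < self.hi


#: Trophic classes on the 0-100 TSI scale.  Written boundaries overlap
#: ("0-30", "30-50"); bins are half-open with the boundary going to the
#: upper class, and the last bin closed at 100.
TROPHIC_LEVELS: Tuple[TrophicLevel, ...] = (
    TrophicLevel("oligotrophic", 0.0, 30.0),
    TrophicLevel("mesotrophic", 30.0, 50.0),
    TrophicLevel("light eutrophic", 50.0, 60.0),
    TrophicLevel("moderate eutrophic", 60.0, 70.0),
    TrophicLevel("hyper eutrophic", 70.0, 100.0),
)

_LEVEL_EDGES = np.array([30.0, 50.0, 60.0, 70.0])


def tsi_from_chla(chla):
    """Trophic state index from chlorophyll-a (ug/L).

    TSI(Chla) = 10 * (2.5 + 1.086 ln Chla).  Not clamped to [0, 100];
    callers decide how to treat out-of-scale values.
    """
    chla = np.asarray(chla, dtype=float)
    if not np.all(np.isfinite(chla)) or np.any(chla <= 0):
        raise ValueError("chla must be finite and > 0")
    out = 10.0 * (2.5 + 1.086 * np.log(chla))
    return float(out) if out.ndim == 0 else out


def trophic_level(tsi) -> "TrophicLevel | np.ndarray":
    """Map TSI in [0, 100] to its trophic class.

    Scalar input returns a :class:`TrophicLevel`; array input returns an
    array of bin indices 0..4 (oligotrophic .. hyper eutrophic).
    """
    arr = np.asarray(tsi, dtype=float)
    if np.any(arr < 0) or np.any(arr > 100) or not np.all(np.isfinite(arr)):
        raise ValueError("tsi must lie in [0, 100]")
    idx = np.searchsorted(_LEVEL_EDGES, arr, side="right")
    if arr.ndim == 0:
        return TROPHIC_LEVELS[int(idx)]
    return idx


def ndwi(g, nir, form: str = "difference"):
    """Water index from green and NIR reflectance.

    The production form is the plain difference G - NIR; the conventional
    normalized ratio (G - NIR)/(G + NIR) is available via ``form``.
    """
    g = np.asarray(g, dtype=float)
    nir = np.asarray(nir, dtype=float)
    if form == "difference":
        out = g - nir
    elif form == "normalized":
        denom = g + nir
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(denom != 0, (g - nir) / denom, 0.0)
    else:
        raise ValueError(f"unknown ndwi form {form!r}")
    return float(out) if out.ndim == 0 else out


def fai(r, nir, swir, sensor: SensorSpec):
    """Floating algae index: NIR peak height above the R-SWIR baseline.

    FAI = NIR - R - (SWIR - R) * (lam_NIR - lam_R) / (lam_SWIR - lam_R).
    """
    lam_r, lam_n, lam_s = sensor["R"], sensor["NIR"], sensor["SWIR"]
    if lam_s == lam_r:
        raise ValueError("degenerate sensor: lambda_SWIR == lambda_R")
    k = (lam_n - lam_r) / (lam_s - lam_r)
    out = np.asarray(nir, dtype=float) - np.asarray(r, dtype=float) - (
        np.asarray(swir, dtype=float) - np.asarray(r, dtype=float)
    ) * k
    return float(out) if out.ndim == 0 else out


def twi(r, swir):
    """Turbid water index R - SWIR; high values flag sediment-dominated water."""
    out = np.asarray(r, dtype=float) - np.asarray(swir, dtype=float)
    return float(out) if out.ndim == 0 else out


def abi(b, r, nir, sensor: SensorSpec):
    """Algal biomass index: difference of two baseline heights at the green
    wavelength, one baseline through (B, NIR) and one through (B, R).

    ABI = (R - B)*(lam_G - lam_B)/(lam_R - lam_B)
        - (NIR - B)*(lam_G - lam_B)/(lam_NIR - lam_B)

    The green reflectance itself cancels out of the printed form; only the
    green *wavelength* enters, through the baseline evaluation point.
    """
    lam_b, lam_g, lam_r, lam_n = sensor["B"], sensor["G"], sensor["R"], sensor["NIR"]
    if lam_r == lam_b or lam_n == lam_b:
        raise ValueError("degenerate sensor wavelengths for ABI")
    c1 = (lam_g - lam_b) / (lam_r - lam_b)
    c2 = (lam_g - lam_b) / (lam_n - lam_b)
    b_ = np.asarray(b, dtype=float)
    out = (np.asarray(r, dtype=float) - b_) * c1 - (np.asarray(nir, dtype=float) - b_) * c2
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class TypeCoefficients:
    """slope/intercept of the TSI = slope*ABI + intercept line for one type."""

    slope: float
    intercept: float
    r2: float | None = None
    p_value: float | None = None
    n: int | None = None


ModelCoefficients = Dict[int, TypeCoefficients]

#: Production coefficients of the per-type ABI->TSI lines, fitted on 649
#: matchup samples (type 1 algal-dominated, type 2 turbid, type 3 clear).
DEFAULT_COEFFICIENTS: ModelCoefficients = {
    1: TypeCoefficients(-601.94, 72.47, r2=0.66, p_value=0.01, n=310),
    2: TypeCoefficients(-325.78, 55.39, r2=0.67, p_value=0.01, n=272),
    3: TypeCoefficients(-118.28, 16.04, r2=0.66, p_value=0.01, n=71),
}


def tsi_from_abi(abi_value, water_type: int, coeffs: ModelCoefficients | None = None,
                 clamp: bool = True):
    """Invert ABI to TSI with the water-type-specific line, clamped to [0, 100].

    Raw values outside the Carlson scale are clamped by default; pass
    ``clamp=False`` to inspect them.
    """
    if coeffs is None:
        coeffs = DEFAULT_COEFFICIENTS
    try:
        c = coeffs[int(water_type)]
    except (KeyError, ValueError):
        raise ValueError(f"unknown water type {water_type!r}; expected 1, 2 or 3") from None
    out = c.slope * np.asarray(abi_value, dtype=float) + c.intercept
    if clamp:
        out = np.clip(out, 0.0, 100.0)
    return float(out) if out.ndim == 0 else out
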