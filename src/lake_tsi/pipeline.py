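"""Per-scene processing: cloud mask, water extraction, pixel typing, TSI.

A Scene is a stack of five reflectance grids plus a categorical cloud-
confidence QA grid.  Processing of one lake in one scene runs

    mask_clouds -> extract_water -> classify_pixels -> invert_tsi

yielding a per-pixel water-type map and a TSI raster restricted to the
retrieved (type 1/2/3) pixels.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
from scipy import ndimage
from shapely.geometry.base import BaseGeometry
from shapely import contains_xy

from .indices import (
    DEFAULT_COEFFICIENTS,
    ModelCoefficients,
    SensorSpec,
    abi,
    fai,
    ndwi,
    tsi_from_abi,
    twi,
)

log = logging.getLogger(__name__)

__all__ = [
    "QA_CATEGORIES",
    "CLASS_CODES",
    "CLASS_NAMES",
    "Thresholds",
    "GeoTransform",
    "Scene",
    "LakeOutline",
    "TsiRaster",
    "mask_clouds",
    "bimodal_threshold",
    "rasterize_outline",
    "extract_water",
    "classify_pixels",
    "classify_spectrum",
    "invert_tsi",
    "harmonize_bands",
]

#: Cloud-confidence categories of the QA grid, in increasing confidence.
QA_CATEGORIES = ("clear", "low", "medium", "high")
QA_CODES = {name: i for i, name in enumerate(QA_CATEGORIES)}

#: Pixel label codes of a ClassMap (uint8 grid).
CLASS_CODES: Dict[str, int] = {
    "invalid": 0,
    "land": 1,
    "cloud": 2,
    "scum": 3,
    "vegetation": 4,
    "type1": 5,
    "type2": 6,
    "type3": 7,
}
CLASS_NAMES = {v: k for k, v in CLASS_CODES.items()}
WATER_TYPE_CODES = (CLASS_CODES["type1"], CLASS_CODES["type2"], CLASS_CODES["type3"])


@dataclass(frozen=True)
class Thresholds:
    """Decision-tree constants for water-pixel typing.

    fai_scum: above this, thick floating algae (excluded).
    fai_vegetation: above this (and <= fai_scum), aquatic vegetation (excluded).
    fai_suspended: optional stricter cut; with ``strict_suspended`` pixels
        below it are flagged invalid rather than typed.
    twi_turbid: at or above this, turbid water (type 2).
    green_clear: below this green reflectance, clear water (type 3).
    buffer_pixels: boundary erosion depth applied to the water mask.
    """

    fai_scum: float = 0.02
    fai_vegetation: float = -0.004
    fai_suspended: float = -0.01
    strict_suspended: bool = False
    twi_turbid: float = 0.076
    green_clear: float = 0.11
    buffer_pixels: int = 3
    ndwi_form: str = "difference"


@dataclass(frozen=True)
class GeoTransform:
    """North-up pixel->CRS mapping: x = x0 + col*dx, y = y0 + row*dy.

    dy is negative for the usual row-down / y-up rasters.  Synthetic scenes
    default to pixel coordinates (x0=0, dx=1, y0=0, dy=1).
    """

    x0: float = 0.0
    dx: float = 1.0
    y0: float = 0.0
    dy: float = 1.0

    def pixel_centers(self, shape) -> tuple[np.ndarray, np.ndarray]:
        rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
        x = self.x0 + (cols + 0.5) * self.dx
        y = self.y0 + (rows + 0.5) * self.dy
        return x, y

    def to_tuple(self):
        return (self.x0, self.dx, self.y0, self.dy)


@dataclass
class Scene:
    """Georeferenced reflectance stack with QA and acquisition metadata."""

    bands: Dict[str, np.ndarray]  # keys B, G, R, NIR, SWIR
    qa: np.ndarray  # uint8 codes into QA_CATEGORIES
    sensor: SensorSpec
    transform: GeoTransform = field(default_factory=GeoTransform)
    date: Optional[_dt.date] = None
    crs: Optional[str] = None

    def __post_init__(self) -> None:
        shapes = {b: a.shape for b, a in self.bands.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"band grids disagree in shape: {shapes}")
        if self.qa.shape != next(iter(shapes.values())):
            raise ValueError("qa grid shape differs from bands")
        for name in ("B", "G", "R", "NIR", "SWIR"):
            if name not in self.bands:
                raise ValueError(f"missing band {name!r}")
        n_out = int(np.sum((self.band("G") < -0.05) | (self.band("G") > 1.5)))
        if n_out:
            log.warning("%d pixels with green reflectance outside [-0.05, 1.5]", n_out)

    @property
    def shape(self):
        return self.qa.shape

    def band(self, name: str) -> np.ndarray:
        return self.bands[name]


@dataclass(frozen=True)
class LakeOutline:
    """A lake polygon with catalogue attributes, in the scene CRS."""

    lake_id: str
    polygon: BaseGeometry
    name: str = ""
    area_km2: float = 1.0
    zone: str = ""
    elevation_m: float = 0.0
    row: int = 0
    path: int = 0

    def __post_init__(self) -> None:
        if self.polygon.is_empty or not self.polygon.is_valid:
            raise ValueError(f"lake {self.lake_id}: invalid or empty polygon")
        if self.area_km2 < 1.0:
            raise ValueError(f"lake {self.lake_id}: area must be >= 1 km^2")


@dataclass
class TsiRaster:
    """Per-pixel TSI over one lake; NaN outside retrieved pixels."""

    values: np.ndarray
    valid_count: int
    lake_total: int
    n_clamped: int = 0


def mask_clouds(scene: Scene) -> np.ndarray:
    """True where the pixel is usable (cloud confidence clear or low)."""
    return scene.qa <= QA_CODES["low"]


def bimodal_threshold(values: np.ndarray) -> float:
    """Threshold between the two modes of a sample, by maximizing the
    between-class variance over a 256-bin histogram (Otsu's criterion).

    When the two modes are separated by an empty histogram gap the
    criterion is flat across the gap; the tie is broken at the midpoint of
    the maximizing plateau, so the cut lands between the modes rather than
    at the edge of one.  Deterministic for fixed input; raises on a
    degenerate (constant) sample.
    """
    values = np.asarray(values, dtype=float).ravel()
    values = values[np.isfinite(values)]
    if values.size < 2 or np.unique(values).size < 2:
        raise ValueError("bimodal threshold undefined: fewer than 2 distinct values")
    hist, edges = np.histogram(values, bins=256)
    centers = (edges[:-1] + edges[1:]) / 2.0
    hist = hist.astype(float)
    w0 = np.cumsum(hist)[:-1]
    w1 = hist.sum() - w0
    csum = np.cumsum(hist * centers)[:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        m0 = csum / w0
        m1 = ((hist * centers).sum() - csum) / w1
        var_between = w0 * w1 * (m0 - m1) ** 2
    var_between[(w0 == 0) | (w1 == 0)] = -np.inf
    best = var_between.max()
    plateau = np.flatnonzero(var_between >= best * (1 - 1e-12) if best > 0 else var_between == best)
    return float(centers[plateau].mean())


def rasterize_outline(outline: LakeOutline, transform: GeoTransform, shape) -> np.ndarray:
    """Boolean in-lake mask: pixels whose centers fall inside the polygon."""
    x, y = transform.pixel_centers(shape)
    return contains_xy(outline.polygon, x.ravel(), y.ravel()).reshape(shape)


def extract_water(
    scene: Scene,
    outline: LakeOutline,
    thresholds: Thresholds | None = None,
    usable: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Water mask for one lake: per-lake bimodal NDWI threshold inside the
    outline, then a boundary erosion to drop land-mixed edge pixels.

    Cloud-masked pixels are removed before thresholding and from the result.
    Returns an all-False mask (with a warning) when the outline misses the
    scene or everything is cloudy.
    """
    thresholds = thresholds or Thresholds()
    if usable is None:
        usable = mask_clouds(scene)
    in_lake = rasterize_outline(outline, scene.transform, scene.shape)
    if not in_lake.any():
        log.warning("lake %s: outline entirely outside scene", outline.lake_id)
        return np.zeros(scene.shape, dtype=bool)
    nd = ndwi(scene.band("G"), scene.band("NIR"), form=thresholds.ndwi_form)
    sample = nd[in_lake & usable]
    if sample.size < 2 or np.unique(sample).size < 2:
        log.warning("lake %s: no usable pixels for NDWI thresholding", outline.lake_id)
        return np.zeros(scene.shape, dtype=bool)
    cut = bimodal_threshold(sample)
    water = in_lake & usable & (nd > cut)
    if thresholds.buffer_pixels > 0:
        water = ndimage.binary_erosion(
            water,
            structure=np.ones((3, 3), dtype=bool),
            iterations=thresholds.buffer_pixels,
        )
    return water


def classify_pixels(
    scene: Scene,
    water: np.ndarray,
    thresholds: Thresholds | None = None,
    usable: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Type every pixel; water pixels run through the decision tree.

    Tree order (exclusions first, clear test before the turbidity split):
      1. FAI > fai_scum                      -> scum
      2. fai_vegetation < FAI <= fai_scum    -> vegetation
      (strict mode: FAI < fai_suspended      -> invalid)
      3. G < green_clear or B > G            -> type3 (clear)
      4. TWI >= twi_turbid                   -> type2 (turbid)
      5. otherwise                           -> type1 (algal-dominated)

    Non-water pixels are labelled cloud where the QA mask removed them and
    land elsewhere.  Returns a uint8 grid of CLASS_CODES.
    """
    thresholds = thresholds or Thresholds()
    if usable is None:
        usable = mask_clouds(scene)
    b, g = scene.band("B"), scene.band("G")
    f = fai(scene.band("R"), scene.band("NIR"), scene.band("SWIR"), scene.sensor)
    t = twi(scene.band("R"), scene.band("SWIR"))

    labels = np.full(scene.shape, CLASS_CODES["land"], dtype=np.uint8)
    labels[~usable] = CLASS_CODES["cloud"]

    w = water
    scum = w & (f > thresholds.fai_scum)
    veg = w & ~scum & (f > thresholds.fai_vegetation)
    rest = w & ~scum & ~veg
    if thresholds.strict_suspended:
        suspended = rest & (f < thresholds.fai_suspended)
        labels[suspended] = CLASS_CODES["invalid"]
        rest = rest & ~suspended
    clear = rest & ((g < thresholds.green_clear) | (b > g))
    turbid = rest & ~clear & (t >= thresholds.twi_turbid)
    algal = rest & ~clear & ~turbid

    labels[scum] = CLASS_CODES["scum"]
    labels[veg] = CLASS_CODES["vegetation"]
    labels[clear] = CLASS_CODES["type3"]
    labels[turbid] = CLASS_CODES["type2"]
    labels[algal] = CLASS_CODES["type1"]
    return labels


def classify_spectrum(b, g, r, nir, swir, sensor: SensorSpec,
                      thresholds: Thresholds | None = None) -> str:
    """Run the water-pixel decision tree on a single spectrum (assumed water)."""
    thresholds = thresholds or Thresholds()
    f = fai(r, nir, swir, sensor)
    if f > thresholds.fai_scum:
        return "scum"
    if f > thresholds.fai_vegetation:
        return "vegetation"
    if thresholds.strict_suspended and f < thresholds.fai_suspended:
        return "invalid"
    if g < thresholds.green_clear or b > g:
        return "type3"
    if twi(r, swir) >= thresholds.twi_turbid:
        return "type2"
    return "type1"


def invert_tsi(
    scene: Scene,
    labels: np.ndarray,
    outline: LakeOutline,
    coeffs: ModelCoefficients | None = None,
) -> TsiRaster:
    """Per-pixel TSI for retrieved (type 1/2/3) pixels; NaN elsewhere.

    Out-of-scale raw values are clamped to [0, 100] and counted.
    """
    coeffs = coeffs or DEFAULT_COEFFICIENTS
    a = abi(scene.band("B"), scene.band("R"), scene.band("NIR"), scene.sensor)
    values = np.full(scene.shape, np.nan)
    n_clamped = 0
    for wt, code in zip((1, 2, 3), WATER_TYPE_CODES):
        sel = labels == code
        if not sel.any():
            continue
        raw = tsi_from_abi(a[sel], wt, coeffs, clamp=False)
        raw = np.atleast_1d(raw)
        n_clamped += int(np.sum((raw < 0) | (raw > 100)))
        values[sel] = np.clip(raw, 0.0, 100.0)
    in_lake = rasterize_outline(outline, scene.transform, scene.shape)
    valid = int(np.sum(np.isfinite(values)))
    if n_clamped:
        log.info("lake %s: clamped %d TSI values to [0, 100]", outline.lake_id, n_clamped)
    return TsiRaster(values=values, valid_count=valid,
                     lake_total=int(in_lake.sum()), n_clamped=n_clamped)


def harmonize_bands(
    bands: Dict[str, np.ndarray],
    gains: Optional[Dict[str, float]] = None,
    offsets: Optional[Dict[str, float]] = None,
) -> Dict[str, np.ndarray]:
    """Cross-sensor per-band linear transform hook (default identity).

    Surface reflectance from older instruments can be recalibrated to the
    OLI scale with published per-band gain/offset pairs; none are applied
    unless provided.
    """
    gains = gains or {}
    offsets = offsets or {}
    return {
        name: arr * gains.get(name, 1.0) + offsets.get(name, 0.0)
        for name, arr in bands.items()
    }
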