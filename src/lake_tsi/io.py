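"""Readers and writers for scenes, rasters, outlines, tables and config.

Rasters travel as TIFF with a JSON metadata block in the image description
tag (band names, sensor, acquisition date, geotransform, CRS); lake
outlines as GeoJSON; tabular products as CSV with the published attribute
names (lake_info.csv, annual_TSI.csv, annual_pixel.csv).  All writers are
deterministic: fixed column order and fixed float formatting, so identical
inputs produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import tifffile
import yaml
from shapely.geometry import mapping as shapely_mapping, shape as shapely_shape

from .calibration import Matchup
from .indices import (
    DEFAULT_COEFFICIENTS,
    ModelCoefficients,
    SENSORS,
    SensorSpec,
    TypeCoefficients,
    get_sensor,
)
from .pipeline import (
    CLASS_CODES,
    GeoTransform,
    LakeOutline,
    QA_CATEGORIES,
    Scene,
    Thresholds,
    TsiRaster,
)
from .trends import AnnualRecord, TrendResult

__all__ = [
    "RunConfig",
    "read_scene",
    "write_scene",
    "write_class_map",
    "read_class_map",
    "write_tsi_raster",
    "read_tsi_raster",
    "read_outlines",
    "write_outlines",
    "write_tables",
    "read_tables",
    "write_matchups",
    "read_matchups",
    "write_coefficients",
    "read_coefficients",
    "decode_cloud_confidence",
]

_BAND_ORDER = ("B", "G", "R", "NIR", "SWIR")


# -- configuration ----------------------------------------------------------


@dataclasses.dataclass
class RunConfig:
    """Every tunable constant of the pipeline, serializable to YAML.

    Defaults are the production values: FAI cuts 0.02 (scum) and -0.004
    (vegetation, with the optional strict suspended cut at -0.01), TWI cut
    0.076, clear-water green cut 0.11, the per-type inversion coefficients,
    and trend significance alpha = 0.05.
    """

    thresholds: Thresholds = dataclasses.field(default_factory=Thresholds)
    coefficients: ModelCoefficients = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_COEFFICIENTS)
    )
    lambda_b: Dict[str, float] = dataclasses.field(default_factory=dict)  # per-sensor override
    harmonization_gains: Dict[str, Dict[str, float]] = dataclasses.field(default_factory=dict)
    alpha: float = 0.05
    seed: int = 0
    verbosity: str = "info"

    def sensor(self, sensor_id: str) -> SensorSpec:
        s = get_sensor(sensor_id)
        if sensor_id in self.lambda_b:
            s = s.with_blue(self.lambda_b[sensor_id])
        return s

    def to_dict(self) -> dict:
        return {
            "thresholds": dataclasses.asdict(self.thresholds),
            "coefficients": {
                str(wt): dataclasses.asdict(c) for wt, c in sorted(self.coefficients.items())
            },
            "lambda_b": dict(self.lambda_b),
            "harmonization_gains": {k: dict(v) for k, v in self.harmonization_gains.items()},
            "alpha": self.alpha,
            "seed": self.seed,
            "verbosity": self.verbosity,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        coeffs = {
            int(wt): TypeCoefficients(**c) for wt, c in d.get("coefficients", {}).items()
        } or dict(DEFAULT_COEFFICIENTS)
        return cls(
            thresholds=Thresholds(**d.get("thresholds", {})),
            coefficients=coeffs,
            lambda_b={k: float(v) for k, v in d.get("lambda_b", {}).items()},
            harmonization_gains={
                k: {b: float(g) for b, g in v.items()}
                for k, v in d.get("harmonization_gains", {}).items()
            },
            alpha=float(d.get("alpha", 0.05)),
            seed=int(d.get("seed", 0)),
            verbosity=str(d.get("verbosity", "info")),
        )

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# -- rasters ----------------------------------------------------------------


def decode_cloud_confidence(qa_raw: np.ndarray, scheme: str = "categorical") -> np.ndarray:
    """Normalize a QA layer to category codes 0..3 (clear/low/medium/high).

    'categorical' expects codes 0..3 already (the synthetic contract);
    'pixel_qa' decodes Collection-1 pixel_qa cloud-confidence bits 6-7.
    """
    qa_raw = np.asarray(qa_raw)
    if scheme == "categorical":
        qa = qa_raw.astype(np.uint8)
        if qa.size and qa.max() > 3:
            raise ValueError("categorical QA must hold codes 0..3")
        return qa
    if scheme == "pixel_qa":
        return ((qa_raw.astype(np.uint32) >> 6) & 0b11).astype(np.uint8)
    raise ValueError(f"unknown QA scheme {scheme!r}")


def _meta_json(extra: dict) -> str:
    return json.dumps(extra, sort_keys=True)


def write_scene(path, scene: Scene) -> None:
    """Write a scene as a 6-page TIFF (B, G, R, NIR, SWIR, QA)."""
    stack = np.stack([scene.band(b) for b in _BAND_ORDER] + [scene.qa.astype(float)])
    meta = {
        "bands": list(_BAND_ORDER) + ["QA"],
        "sensor": scene.sensor.sensor_id,
        "wavelengths": {b: scene.sensor[b] for b in _BAND_ORDER},
        "date": scene.date.isoformat() if scene.date else None,
        "transform": list(scene.transform.to_tuple()),
        "crs": scene.crs,
    }
    tifffile.imwrite(path, stack, photometric="minisblack", description=_meta_json(meta))


def read_scene(path, sensor_id: Optional[str] = None, qa_scheme: str = "categorical") -> Scene:
    """Read a multiband scene TIFF.

    Bands must be ordered B, G, R, NIR, SWIR(, QA) or named in the embedded
    metadata.  Integer-scaled surface reflectance (the x10000 dialect) is
    rescaled to floats when the value range implies it.  A missing QA page
    yields an all-clear QA grid.
    """
    with tifffile.TiffFile(path) as tf:
        stack = tf.asarray()
        desc = tf.pages[0].description or ""
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except json.JSONDecodeError:
            meta = {}
    if stack.ndim == 2:
        raise ValueError(f"{path}: expected a multiband stack, got a single band")
    names = meta.get("bands") or list(_BAND_ORDER[: stack.shape[0]]) + (
        ["QA"] if stack.shape[0] == 6 else []
    )
    if stack.shape[0] < 5:
        raise ValueError(
            f"{path}: need bands B,G,R,NIR,SWIR(,QA); found {stack.shape[0]} bands"
        )
    sensor_id = sensor_id or meta.get("sensor")
    if sensor_id is None:
        raise ValueError(f"{path}: sensor id neither given nor stored in metadata")
    sensor = get_sensor(sensor_id)
    if meta.get("wavelengths"):
        sensor = SensorSpec(sensor_id, {b: float(w) for b, w in meta["wavelengths"].items()})

    arrays = {name: stack[i] for i, name in enumerate(names)}
    bands = {}
    for b in _BAND_ORDER:
        if b not in arrays:
            raise ValueError(f"{path}: band {b} missing")
        arr = np.asarray(arrays[b])
        if np.issubdtype(arr.dtype, np.integer) or (
            np.isfinite(arr).any() and np.nanmax(np.abs(arr)) > 2.0
        ):
            arr = arr.astype(float) * 1e-4  # integer-scaled SR dialect
        else:
            arr = arr.astype(float)
        bands[b] = arr
    if "QA" in arrays:
        qa = decode_cloud_confidence(arrays["QA"].astype(np.uint16), qa_scheme)
    else:
        qa = np.zeros(bands["B"].shape, dtype=np.uint8)

    t = meta.get("transform") or [0.0, 1.0, 0.0, 1.0]
    date = _dt.date.fromisoformat(meta["date"]) if meta.get("date") else None
    return Scene(bands=bands, qa=qa, sensor=sensor, transform=GeoTransform(*t),
                 date=date, crs=meta.get("crs"))


def write_class_map(path, labels: np.ndarray, transform: GeoTransform = GeoTransform()) -> None:
    meta = {"labels": CLASS_CODES, "transform": list(transform.to_tuple())}
    tifffile.imwrite(path, labels.astype(np.uint8), photometric="minisblack", description=_meta_json(meta))


def read_class_map(path) -> np.ndarray:
    return tifffile.imread(path).astype(np.uint8)


def write_tsi_raster(path, raster: TsiRaster, transform: GeoTransform = GeoTransform()) -> None:
    meta = {
        "valid_count": raster.valid_count,
        "lake_total": raster.lake_total,
        "n_clamped": raster.n_clamped,
        "transform": list(transform.to_tuple()),
        "nodata": "nan",
    }
    tifffile.imwrite(path, raster.values.astype(np.float32), photometric="minisblack", description=_meta_json(meta))


def read_tsi_raster(path) -> TsiRaster:
    with tifffile.TiffFile(path) as tf:
        values = tf.asarray().astype(float)
        meta = json.loads(tf.pages[0].description or "{}")
    return TsiRaster(
        values=values,
        valid_count=int(meta.get("valid_count", np.sum(np.isfinite(values)))),
        lake_total=int(meta.get("lake_total", values.size)),
        n_clamped=int(meta.get("n_clamped", 0)),
    )


def write_average_raster(out_dir, lake_id: str, values: np.ndarray,
                         transform: GeoTransform = GeoTransform()) -> Path:
    """Long-term average TSI raster for one lake, named '<LakeID>_40avg'."""
    out = Path(out_dir) / f"{lake_id}_40avg.tif"
    tifffile.imwrite(out, values.astype(np.float32), photometric="minisblack",
                     description=_meta_json({"transform": list(transform.to_tuple())}))
    return out


# -- outlines ---------------------------------------------------------------


def write_outlines(path, outlines: Sequence[LakeOutline]) -> None:
    features = []
    for o in outlines:
        features.append(
            {
                "type": "Feature",
                "geometry": shapely_mapping(o.polygon),
                "properties": {
                    "lake_id": o.lake_id,
                    "name": o.name,
                    "area_km2": o.area_km2,
                    "zone": o.zone,
                    "elevation_m": o.elevation_m,
                    "row": o.row,
                    "path": o.path,
                },
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, sort_keys=True)
    )


def read_outlines(path) -> List[LakeOutline]:
    data = json.loads(Path(path).read_text())
    out = []
    for feat in data["features"]:
        p = feat.get("properties", {})
        out.append(
            LakeOutline(
                lake_id=str(p.get("lake_id", p.get("id", ""))),
                polygon=shapely_shape(feat["geometry"]),
                name=str(p.get("name", "") or ""),
                area_km2=float(p.get("area_km2", 1.0)),
                zone=str(p.get("zone", "")),
                elevation_m=float(p.get("elevation_m", 0.0)),
                row=int(p.get("row", 0)),
                path=int(p.get("path", 0)),
            )
        )
    return out


# -- tables -----------------------------------------------------------------


def _fmt(x: Optional[float], nd: int = 2) -> str:
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return ""
    return f"{x:.{nd}f}"


def write_tables(
    out_dir,
    outlines: Sequence[LakeOutline],
    annual: Mapping[str, Sequence[AnnualRecord]],
    trends: Mapping[str, TrendResult],
    averages: Mapping[str, Tuple[float, object]],
    years: Sequence[int],
    total_pixels: Optional[Mapping[str, int]] = None,
    full_precision: bool = False,
) -> Dict[str, Path]:
    """Write lake_info.csv, annual_TSI.csv and annual_pixel.csv.

    ``annual`` maps lake_id -> AnnualRecords, ``averages`` maps lake_id ->
    (average TSI, TrophicLevel).  TSI cells carry 2 decimals (matching the
    published precision) unless ``full_precision``; missing years are empty
    cells.  Raises on duplicate lake ids.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ids = [o.lake_id for o in outlines]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate lake ids in outlines")
    nd = 6 if full_precision else 2

    info_rows = []
    for o in outlines:
        centroid = o.polygon.centroid
        info_rows.append(
            {
                "Lake ID": o.lake_id,
                "Lake Name": o.name,
                "Lon (DD)": f"{centroid.x:.6f}",
                "Lat (DD)": f"{centroid.y:.6f}",
                "Lake Area": f"{o.area_km2:.4f}",
                "Lake Zone": o.zone,
                "Elevation (m)": f"{o.elevation_m:.1f}",
                "Row": o.row,
                "Path": o.path,
            }
        )
    info = pd.DataFrame(info_rows)

    tsi_rows, pix_rows = [], []
    for o in outlines:
        recs = {r.year: r for r in annual.get(o.lake_id, [])}
        avg, level = averages[o.lake_id]
        tr = trends[o.lake_id]
        row = {"Lake ID": o.lake_id}
        for y in years:
            r = recs.get(y)
            row[f"TSI_{y}"] = _fmt(r.tsi_mean if r else None, nd)
        row["Average TSI"] = _fmt(avg, nd)
        row["Trophic Level"] = getattr(level, "label", str(level))
        row["Trend_40y"] = tr.trend
        row["Slope_40y"] = _fmt(tr.sen_slope, 4)
        tsi_rows.append(row)

        prow = {"Lake ID": o.lake_id}
        if total_pixels:
            prow["Total Pixels"] = total_pixels.get(o.lake_id, 0)
        for y in years:
            r = recs.get(y)
            prow[f"Pixel_{y}"] = "" if r is None or r.tsi_mean is None else r.pixel_count
        pix_rows.append(prow)

    paths = {
        "lake_info": out_dir / "lake_info.csv",
        "annual_tsi": out_dir / "annual_TSI.csv",
        "annual_pixel": out_dir / "annual_pixel.csv",
    }
    info.to_csv(paths["lake_info"], index=False)
    pd.DataFrame(tsi_rows).to_csv(paths["annual_tsi"], index=False)
    pd.DataFrame(pix_rows).to_csv(paths["annual_pixel"], index=False)
    return paths


def read_tables(out_dir) -> Dict[str, pd.DataFrame]:
    out_dir = Path(out_dir)
    return {
        "lake_info": pd.read_csv(out_dir / "lake_info.csv"),
        "annual_tsi": pd.read_csv(out_dir / "annual_TSI.csv"),
        "annual_pixel": pd.read_csv(out_dir / "annual_pixel.csv"),
    }


def write_matchups(path, matchups: Sequence[Matchup]) -> None:
    from .calibration import matchups_to_frame

    matchups_to_frame(list(matchups)).to_csv(path, index=False)


def read_matchups(path) -> List[Matchup]:
    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        chla = r.get("chla")
        out.append(
            Matchup(
                lake_id=str(r["lake_id"]),
                date=str(r["date"]),
                water_type=int(r["water_type"]),
                abi=float(r["abi"]),
                tsi_measured=float(r["tsi_measured"]),
                chla=None if chla is None or pd.isna(chla) else float(chla),
            )
        )
    return out


def write_coefficients(path, coeffs: ModelCoefficients) -> None:
    rows = []
    for wt in sorted(coeffs):
        c = coeffs[wt]
        rows.append(
            {
                "water_type": wt,
                "slope": c.slope,
                "intercept": c.intercept,
                "r2": c.r2,
                "p_value": c.p_value,
                "n": c.n,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_coefficients(path) -> ModelCoefficients:
    df = pd.read_csv(path)
    out: ModelCoefficients = {}
    for _, r in df.iterrows():
        out[int(r["water_type"])] = TypeCoefficients(
            slope=float(r["slope"]),
            intercept=float(r["intercept"]),
            r2=None if pd.isna(r.get("r2")) else float(r["r2"]),
            p_value=None if pd.isna(r.get("p_value")) else float(r["p_value"]),
            n=None if pd.isna(r.get("n")) else int(r["n"]),
        )
    return out
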