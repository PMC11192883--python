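# lake-tsi

Retrieval of lake trophic state from Landsat-class surface reflectance:
per-pixel optical water-type classification, an algal-biomass-index (ABI)
inversion to Carlson's trophic state index (TSI), and aggregation of
per-scene retrievals into annual per-lake records with Mann–Kendall trend
tests. It is written for limnologists and remote-sensing practitioners who
want a tested, scriptable reimplementation of this kind of national-scale
lake monitoring pipeline — together with a forward-model scene simulator
that provides per-pixel ground truth, so the whole chain can be validated
end to end without a satellite archive.

## The method

Trophic state is indexed on Carlson's 0–100 scale from chlorophyll-a:

    TSI(Chla) = 10 · (2.5 + 1.086 ln Chla)       [Chla in µg/L]

with classes oligotrophic [0, 30), mesotrophic [30, 50), light eutrophic
[50, 60), moderate eutrophic [60, 70) and hyper eutrophic [70, 100].

Per scene, water pixels are found inside each lake outline by a per-lake
bimodal (between-class-variance) threshold on the water index
NDWI = G − NIR, then eroded by 3 pixels to drop land-mixed boundaries.
Each water pixel runs through a decision tree built on three further
indices —

    FAI = NIR − R − (SWIR − R)·(λ_NIR − λ_R)/(λ_SWIR − λ_R)
    TWI = R − SWIR
    ABI = (R − B)·(λ_G − λ_B)/(λ_R − λ_B) − (NIR − B)·(λ_G − λ_B)/(λ_NIR − λ_B)

— excluding floating scum (FAI > 0.02) and aquatic vegetation
(−0.004 < FAI ≤ 0.02), then typing the rest as clear water (G < 0.11 or
B > G), turbid water (TWI ≥ 0.076) or algal-dominated water. TSI follows
from the per-type linear inversion TSI = slope·ABI + intercept with
coefficients (−601.94, 72.47), (−325.78, 55.39) and (−118.28, 16.04) for
the algal, turbid and clear types, refittable from matchup tables by OLS.
Scene-level lake means are averaged per calendar year, and each lake's
annual series gets a Mann–Kendall trend test (tie-corrected variance,
continuity-corrected Z, α = 0.05) with Sen's slope.

## Worked example

```python
import numpy as np
from lake_tsi import (LakeSpec, SceneRecipe, simulate_scene, process_scene,
                      mann_kendall, simulate_annual_series)

lake = LakeSpec("L1", center=(48, 48), radii=(30, 34),
                fractions={"type1": 0.8, "scum": 0.1, "vegetation": 0.1},
                tsi_range={1: (55.0, 70.0)})
scene, truth = simulate_scene(SceneRecipe(shape=(128, 128), lakes=(lake,), seed=20))
res = process_scene(scene, truth.outlines)[0]
print(f"retrieved {res.valid_count} pixels ({res.coverage_pct:.1f}% coverage), "
      f"lake mean TSI {res.mean_tsi:.2f}")

years, vals = simulate_annual_series(40, base=45, slope=0.3, noise_sd=2.0, seed=1)
t = mann_kendall(vals, years=years)
print(f"trend: {t.trend}, Sen slope {t.sen_slope:+.3f} TSI/yr, p={t.p_value:.2g}")
```

prints

```
retrieved 2069 pixels (62.5% coverage), lake mean TSI 61.53
trend: increase, Sen slope +0.282 TSI/yr, p=4.6e-11
```

The 2069 retrieved pixels are the algal-dominated interior of the lake
after the 3-pixel boundary erosion and the scum/vegetation exclusions;
the mean TSI of 61.53 sits inside the simulated 55–70 gradient, and on
this noise-free scene every retrieved pixel matches its true type and TSI
exactly. The 40-year series with a +0.3 TSI/yr drift is correctly flagged
as a significant increase with a Sen slope near the injected value.

The `analysis/` scripts run the same machinery as a narrative study —
`01_simulate_archive.py` builds a 3-lake, 12-year scene archive with
injected trends, `02_run_pipeline.py` retrieves it,
`03_aggregate_trends.py` writes the dataset tables (lake_info.csv,
annual_TSI.csv, annual_pixel.csv) and trend tests, and
`04_calibrate_models.py` refits the inversion coefficients from synthetic
matchups. A `lake-tsi` console script exposes the same steps
(`simulate`, `run`, `aggregate`, `trend`, `calibrate`, `validate`).

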