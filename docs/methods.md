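# Methods

This note records the model the package implements, the choices made
where the published workflow leaves the design open, what the synthetic
generator does and does not emulate, and the numerical conventions.

## Trophic state and its inversion

TSI is Carlson's chlorophyll-based index, TSI = 10·(2.5 + 1.086 ln Chla),
on a 0–100 scale where each 10-unit step corresponds roughly to a
doubling of algal biomass. Trophic classes are half-open bins
[0,30), [30,50), [50,60), [60,70), [70,100]; the published class bounds
overlap at their endpoints ("0–30", "30–50"), so a shared boundary is
assigned to the upper class, with the last bin closed at 100.

Retrieval inverts the algal biomass index, ABI — the difference between
the heights, at the green wavelength, of two straight baselines drawn
from the blue band to the NIR and to the red band respectively. In the
printed form the green *reflectance* cancels; only the green wavelength
enters. The cited original formulation describes ABI as green reflectance
minus a baseline, which differs; the package implements the printed
difference-of-baselines expression verbatim. The per-type inversion lines
TSI = slope·ABI + intercept use the published coefficients as defaults
(algal −601.94/72.47, turbid −325.78/55.39, clear −118.28/16.04) and can
be refitted from matchup CSVs by unweighted OLS (weighting across lakes
is unspecified in the source workflow; unweighted is assumed). Slope
p-values use the t distribution on n−2 df. Inverted TSI outside [0,100]
is clamped to the scale and counted in the processing log; whether the
original production run clamped or discarded such pixels is unstated.

Blue-band center wavelengths are never printed in the source tables; the
registry uses the nominal band centers 482 nm (OLI) and 485 nm (TM/ETM+),
overridable per sensor in `RunConfig.lambda_b`. Cross-sensor
harmonization is exposed as a per-band linear gain/offset hook defaulting
to identity.

## Water extraction and classification

NDWI is implemented literally as the printed difference G − NIR; the
conventional normalized ratio is available behind `ndwi_form =
"normalized"` but the difference form is the default for fidelity. The
per-lake water threshold maximizes the between-class variance over a
256-bin histogram of in-lake, cloud-free NDWI (Otsu's criterion — the
cited thresholding method is not printed). When the two modes are
separated by an empty histogram gap the criterion is flat across the gap,
so the tie is broken at the midpoint of the maximizing plateau; this puts
the cut between the modes instead of at the edge of one, and keeps the
result deterministic. The water mask is then eroded by 3 pixels (~100 m
at 30 m pixels) with a 3×3 square structuring element — the buffer's
connectivity is not specified; the square element is the conservative
choice.

Cloud handling follows the QA contract: cloud-confidence medium and high
are masked, clear and low are kept. Synthetic scenes carry a categorical
4-value QA layer; for real Collection-1 `pixel_qa` files the reader
decodes cloud-confidence bits 6–7 to the same categories.

The water-pixel decision tree runs in a fixed order that the source does
not state: scum exclusion (FAI > 0.02), vegetation exclusion
(−0.004 < FAI ≤ 0.02), the clear-water test (G < 0.11 or B > G), the
turbidity split (TWI ≥ 0.076 → turbid), else algal-dominated. Exclusions
come first so contaminated pixels never reach the typing stage, and the
clear test precedes the TWI split because a clear pixel also has small
TWI and would otherwise land in the algal class. The clear-water green
threshold is µ + 2σ of the green reflectance of surveyed oligotrophic
lakes (0.065 + 2·0.021 = 0.107, reported as 0.11). The source also
mentions removing "high suspended" pixels at FAI < −0.01, which conflicts
with typing turbid water by TWI; the package keeps FAI ≤ −0.004 pixels as
water by default and offers a strict mode (`strict_suspended`) that flags
FAI < −0.01 pixels invalid instead.

## Aggregation and trends

The annual lake value is the unweighted mean of per-scene lake means
(equal weight per observation date), not a pool of pixels across scenes;
the annual pixel count is the rounded mean of per-scene valid counts (the
published column description is ambiguous between mean and maximum).
Coverage is retrieved pixels over total in-outline pixels. The long-term
average is the unweighted mean over non-missing years.

The Mann–Kendall test uses the signed pair count S, tie-corrected
variance n(n−1)(2n+5)/18 − Σ t(t−1)(2t+5)/18, the ±1 continuity
correction in Z, and a two-sided normal p-value; Sen's slope is the
median of pairwise slopes using actual year spacing, so gap years are
simply dropped. Significance defaults to α = 0.05 (the level the dataset
documentation states; one figure caption says 0.01) and is configurable.
Series shorter than 4 non-missing years report "no trend" with a warning.

## The synthetic generator

The generator emulates the statistical structure the pipeline assumes: a
land background with negative NDWI, elliptical lakes whose pixels belong
to the three optical types plus scum and vegetation in recipe-controlled
fractions (realized within one pixel via largest-remainder rounding),
per-pixel TSI constant or ramped west-to-east, cloud blobs grown by
seeded random walks (only the QA labels matter downstream), and additive
Gaussian band noise. Water spectra are constructed by a closed-form
inversion of ABI: pinning the pixel's FAI and TWI at type-specific anchor
values makes ABI linear in R − B, so R, NIR and SWIR follow exactly from
the target ABI and the anchors, B is chosen to keep R inside the [0, 0.6]
reflectance bound, and G is the free band (jittered per seed) kept above
NIR so the pixel stays NDWI-positive, and above 0.11 with B ≤ G for types
1–2 or below 0.11 for type 3. The construction is exact algebra, so with
zero noise the pipeline's classify-and-invert recovers type and TSI to
machine precision — the basis of the round-trip acceptance property.

The [0, 0.6] reflectance bound makes some (type, TSI) combinations
infeasible: the turbid line cannot reach TSI ≳ 85 and the clear line
TSI ≳ 31 without reflectances leaving the bound, and the solver raises a
descriptive infeasibility error there. Default recipe TSI ranges sit
inside the feasible envelopes — 55–75 (algal), 45–60 (turbid), 18–28
(clear) — which also match where each optical type plausibly lives.

Matchups draw Chla from a lognormal with log-scale mean 2.0 and sd 1.0,
spreading clean TSI across all five trophic classes; TSI is clipped to
the sampled field range [20, 90]. ABI lies exactly on the type's
inversion line and measurement noise is added to the measured TSI
(exogenous error), so an OLS refit of TSI on ABI is unbiased and its
confidence intervals have nominal coverage; noise placed on ABI instead
would attenuate the slope by the factor r². The noise sd for a target r²
comes from censored-normal moments of the clipped TSI signal.

What the generator does *not* emulate: radiative-transfer realism
(spectra satisfy the classifier's constraints but are not water-leaving
reflectance spectra), sensor revisit geometry, SLC-off striping, mixed
pixels, adjacency effects, or spatially correlated noise. Passing tests
therefore demonstrate the correctness and statistical behaviour of the
algorithms under the stated assumptions, not retrieval accuracy on real
imagery.

## Problem sizes and numerics

The test suite and acceptance script use a 256×256 three-lake scene for
the exact round trip, 20 random scenes for the classifier-vs-oracle
check, 500 random series for the Mann–Kendall oracle check, 200
replicates for coefficient-recovery coverage and trend power/size, and a
192×192, 12-year, 2-scenes-per-year archive for the end-to-end trend
study — sizes chosen so the full study re-runs in well under a minute on
one core while keeping Monte-Carlo error comfortably inside the asserted
margins. Rasters are plain TIFF with a JSON metadata block (band names,
sensor, date, a 4-parameter north-up geotransform, CRS) in the image
description tag; the missing-value sentinel in float rasters is NaN.
Table writers fix column order and format TSI cells to 2 decimals
(full precision behind an option), so identical inputs give
byte-identical CSVs. All randomness flows through explicit integer seeds
via numpy Generators; identical recipe and seed reproduce scenes bit for
bit.

## Known limitations

Lake outlines are handled as shapely geometries in scene pixel/CRS
coordinates; there is no reprojection support, and rasterization tests
pixel centers only. The bimodal threshold assumes the in-lake NDWI sample
is genuinely bimodal (lake plus some shoreline/land); a lake entirely
covered by water with no contrast degrades to an arbitrary interior cut,
which the boundary erosion then largely absorbs. The archive summary
statistics describe whatever archive they are given — they reproduce the
published national-scale completeness figures only when run on that
published dataset, which is not bundled.
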