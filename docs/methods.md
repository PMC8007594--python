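# Methods

This note records the models, parameter choices and numerical decisions
behind `soilplant`, and what the synthetic experiments do and do not
demonstrate about real field data.

## Coordinate and raster conventions

All modules assume a projected CRS in meters, x east / y north. Rasters are
stored with row 0 as the southernmost row; pixel (col i, row j) covers the
half-open square [x0+i·s, x0+(i+1)·s) × [y0+j·s, y0+(j+1)·s). A point
exactly on a shared cell edge therefore belongs to exactly one cell
(left/bottom inclusive). Nodata defaults to −9999 for float products.
GeoTIFFs are written through `tifffile` with the standard GeoTIFF tags
(pixel scale, tiepoint, geo-key directory, GDAL nodata); geographic
(degree) CRSs are rejected because every downstream statistic is
distance-based. Reprojection is out of scope — inputs are expected already
co-registered, as orthomosaic products typically are.

## Attribute profiles and classification

The contextual features are area attribute profiles: per band, area
openings and closings at an increasing ladder of area thresholds λ
(pixels), stacked with the original band. Area is an increasing attribute,
so max-tree pruning with the direct rule is exact; non-increasing
attributes (moment of inertia, standard deviation) are deliberately not
implemented. Connectivity defaults to 4 to limit diagonal leakage between
adjacent crop rows.

The max-tree is built with Berger's union-find algorithm (numba-compiled),
canonicalized, and reused across all thresholds: one profile needs two tree
builds per band (one per polarity) regardless of the ladder length. This
was chosen over per-threshold library filtering for throughput — a full
three-band, three-λ profile of a 10⁶-pixel mosaic takes a few seconds — and
is verified in the tests both against a brute-force level-set oracle and
against scikit-image's independent implementation, exactly, on batches of
random small images.

The default ladder λ ∈ {25, 100, 400, 1600, 6400} px spans ≈0.25–64 m² at
10 cm pixels, i.e. sub-plant to row-segment scales. The pipeline and tests
use the lower rungs {25, 100(, 400)}: on 0.9 m row spacing the
discriminative structure saturates there, and the larger scales add cost
without changing the synthetic results. The ladder is a free parameter of
`build_profile`.

Classification is an RBF-kernel SVM (C = 10, gamma = 1/(n_features ·
variance)); with two classes the one-against-one scheme reduces to a single
binary machine. Feature z-scoring is fit on training data only and travels
inside the fitted pipeline, so cross-validation folds cannot leak scaling
statistics. Accuracy reporting (per-class, overall, Cohen's κ) averages
over stratified five-fold splits with across-fold standard deviations;
training defaults to 1000 pixels per class. An optional decision-margin
threshold can label low-confidence pixels "unclassified" (off by default;
there is no principled default margin).

## Plant products

- **Abundance**: % vegetation pixels per analysis cell (default 2 m),
  nodata pixels excluded from numerator and denominator, partial edge
  cells use their valid-pixel count. The grid is anchored to the mosaic's
  lower-left corner.
- **Vigor**: mean GCC = G/(R+G+B) over vegetation pixels per cell;
  cells without vegetation are nodata rather than zero, since a mean over
  an empty set is undefined, not "no vigor". Zero-DN-sum pixels are nodata.
- **Height**: DSM − reference DEM with negatives clipped to 0 (the bare
  ground surface is assumed stable between acquisitions; negative
  differences are photogrammetric noise). The clipped fraction is logged
  as a data-quality signal.
- **Ground-plot validation**: plot photos are segmented by a GCC
  threshold — per-image Otsu by default, a fixed threshold optionally —
  and compared to UAV abundance by OLS. R² is symmetric for simple OLS
  with intercept, so the regression direction (ground on UAV here) only
  affects the residual scale used in the RMSE.

## EMI processing

- **Temperature correction** uses the exponential model
  EC₂₅ = EC_a · [0.4470 + 1.4034·e^(−T/26.815)]; the factor is strictly
  decreasing in T and equals 0.99944 at the 25 °C reference. Temperatures
  outside the model's validated 3–43 °C range trigger a warning, not an
  error. The alternative ratio-form correction is not implemented. The
  soil temperature may come per point from the survey file or as a
  per-survey scalar override.
- **Antenna offset**: each fix is translated along the local track heading
  (centered finite differences, one-sided at endpoints, normalized so the
  displacement is exactly |offset|). The offset magnitude is 4.5 m for the
  sled setup emulated here; its sign encodes whether the instrument leads
  or trails the antenna and must be supplied by the operator — geometry
  alone cannot recover it.
- **Gridding** is inverse-distance weighting (power 2, configurable search
  radius, exact at coincident points) rather than kriging: IDW is
  deterministic, oracle-testable, bounded by the data range, and adequate
  for the ~2 m grids used downstream of ~1 m-spaced samples. Ordinary
  kriging would add a variogram-fitting stage whose choices would dominate
  the result near the transect gaps.
- **Ratio maps** are earlier/later per cell, so a drying later survey
  raises the ratio; cells with non-positive later values are nodata.
- **Zones**: median split of a surface's valid cells; meant for an
  early-season survey where the signal is textural rather than
  management-driven. The default analysis coil is the 1.0 m effective
  depth (root-zone scale); the in-phase channel is ignored.

## Corrected correlation

For block series x, y at locations s₁…s_n, the test follows the
Clifford–Richardson–Hémon procedure: pairwise distances are binned into
K = ⌈1 + log₂ n⌉ equal-width classes from 0 to the maximum distance
(Sturges' rule on the block count, not the pair count — both readings
exist; the choice is configurable by passing a different K upstream). Per
class the autocovariance of each variable is the mean cross-product of
deviations over the pairs in the class, normalized by the plug-in variance.
The variance of r is estimated as

    var̂(r) = [n + 2 Σ_k N_k ρ̂_x(k) ρ̂_y(k)] / n²,

the trace of the product of the two spatial correlation matrices under
within-class constancy. The effective sample size is M̂ = 1 + 1/var̂(r),
capped at n (sampling noise can push it above n), and the corrected
p-value refers t = r·√((M̂−2)/(1−r²)) to Student-t with M̂−2 df; if
M̂ ≤ 2 the p-value is reported as 1. r itself is never adjusted — the
method corrects the test, not the estimate. Monte-Carlo calibration at the
study geometry (20×20 blocks of 20 m, exponential covariance with range a
quarter of the extent) gives naive type-I error ≈0.6 versus corrected
≈0.03–0.05 at α = 0.05, and M̂ within a few percent of n for white noise;
the acceptance tests rerun this experiment.

Moran's I uses rook contiguity by default (neighbors at the minimum
positive inter-point distance, which is rook adjacency on a regular block
grid); an explicit weight matrix can be passed. Constant inputs are an
error (the statistic is undefined), as are fully coincident coordinates.

Strata (field sections west/center/east from x-boundaries, default equal
thirds; high/low EC zones) with fewer than 10 complete blocks are skipped
with a warning rather than reported with meaningless df. Significance
coding is *p<.05, **p<.01, ***p<.001, (−) otherwise, two-sided, on the
corrected p-value; no multiple-testing correction is applied across the
report table.

## Yield data

Yield records whose swath field differs from the configured harvester
width (default 11 rows) are removed outright — a wrong swath makes the
per-area value unreliable. Unit conversion bu/ac → kg/ha uses 67.25
(soybean 60 lb/bu standard test weight; 60 × 0.453592 / 0.404686 =
67.2511), configurable for other crops.

## Synthetic scenes

The generator emulates the surveyed system: a square field (default
100 m × 100 m) at 10 cm pixels; north–south rows 0.9 m apart; plants as
jittered disks (radius 0.15 m, candidate spacing 0.3 m, presence
probability `plant_density`); soil as a brown mean triplet with
low-frequency brightness variation (so a single DN threshold cannot
separate the classes and the contextual features are actually exercised);
plant pixels with G raised by `green_contrast` (default 60 DN) and R/B
slightly lowered, then additive Gaussian noise (default sd 5 DN). EC_a
ground truth is a Gaussian random field with exponential covariance
(default range 20 m, sill 25 (mS/m)², mean 30 mS/m) synthesized by
circulant embedding on a doubled grid (exact covariance on the torus;
negative embedding eigenvalues are clipped — negligible at these sizes);
`eca_suppression` scales plant survival by the local EC_a quantile to plant
a negative soil–plant relationship. The DSM adds a constant canopy height
(0.35 m) over plant pixels to a gently sloping reference DEM. EMI surveys
sample east–west serpentine transects 9 m apart (phase = half the spacing,
giving 10 traverses on a 90 m extent) with monotone timestamps; yield
clouds follow 11-row harvest passes at ≈9.9 m spacing, one record per 2 s,
value affine in local plant cover, with 5% wrong-swath artifacts.

All randomness flows through `numpy.random.Generator` (PCG64); a fixed
seed regenerates scenes bit-identically across platforms. The pipeline
spawns per-stage seeds from the configured seed via `SeedSequence`.

What passing these experiments shows: the implementation recovers known
truths under controlled contrast, noise, and spatial structure, and the
corrected test is calibrated at the study geometry. What it does not show:
performance under real-world radiometric variation (shadows, bidirectional
reflectance, weeds, senescent tissue), georeferencing error between
acquisition dates, EMI drift, or non-stationary soil structure. Reported
synthetic accuracies (OA ≈ 1.0 at default contrast) characterize the
pipeline, not expected field accuracy; on real mosaics the classifier's
ceiling is set by label quality and scene complexity.

## Problem sizes in tests and the acceptance script

Unit tests run on 20–30 m scenes and ≤ 40×40 point sets; the recovery
experiments use ten full 100 m scenes; calibration experiments use 300–500
replicates on 20×20 block grids (standard errors ≈ 0.01 on rejection
rates). The acceptance script processes one full scene plus a 300-replicate
calibration; its experiment sizes are stated in the output JSON (`n` per
quantity).

## Known limitations

- Single-date workflow in the pipeline orchestrator; multi-date time
  series are composed by running stages per date and joining block tables.
- IDW only (no kriging variance surfaces); the interpolation uncertainty
  is not propagated into the correlation test beyond what block averaging
  absorbs.
- The unclassified-pixel margin rule is available but off by default.
- The automatic λ-ladder selector (`suggest_thresholds`) is a plain
  granulometry heuristic — it picks the scales where opening residual
  energy grows fastest — not a tuned procedure; users with different row
  geometry should set the ladder from the expected structure scales.

The acceptance script's ground-plot experiment selects 31 one-square-meter
plots spanning the cover range, identifies a single GCC threshold from the
pooled plot histogram, and reads the UAV abundance from a window placed
with ±1-pixel (~0.15 m) co-location uncertainty — the frame-placement and
GNSS error that separates ground frames from mosaic coordinates in a real
campaign. Without that term the two estimates derive from identical pixels
and the regression is degenerate.
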