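# soilplant

Integration of UAV RGB imagery and ground-based electromagnetic-induction
(EMI) soil surveys into a single gridded analysis of soil–plant
co-variability for row crops.

Early-season crop stands are spatially heterogeneous, and much of that
heterogeneity traces back to the soil: clay-rich, high-conductivity ground
drains slowly, saturates during furrow irrigation, and suppresses plant
development. Quantifying that link requires (a) plant state mapped at the
scale of individual row segments, (b) subsurface variability mapped across
the whole field, and (c) statistics that do not overstate significance when
both maps are spatially autocorrelated. `soilplant` provides all three as a
Python library plus a `soilplant` command-line tool, aimed at precision-
agriculture and field-phenotyping researchers working with centimeter-scale
orthomosaics and towed geophysical instruments.

## What it computes

**Plant products from RGB orthomosaics (10 cm pixels).** Pixels are
classified plant vs soil by an RBF-kernel SVM on an *attribute profile*: the
original bands plus area openings and closings at an increasing ladder of
scale thresholds λ (connected-component filtering on the max-tree), which
encodes the spatial arrangement of crop rows, not just color. From the
binary mask the toolkit derives

- **plant spatial abundance** — % vegetation pixels per 2 m × 2 m cell;
- **plant-specific vigor** — the green chromatic coordinate
  GCC = G_DN / (R_DN + G_DN + B_DN) averaged over vegetation pixels only,
  so soil background does not dilute the greenness signal;
- **plant height** — canopy surface model minus bare-soil reference DEM,
  negatives clipped at 0.

Classification quality is reported as per-class accuracy, overall accuracy
and Cohen's κ over stratified five-fold cross-validation, and abundance can
be validated against ground-plot photos segmented by GCC thresholding
(OLS R², RMSE, slope p-value).

**EMI soil products.** Apparent electrical conductivity EC_a (mS/m, three
coil depths: 0.5 / 1.0 / 1.8 m) is corrected to the 25 °C reference via the
exponential model EC₂₅ = EC_a · [0.4470 + 1.4034 · e^(−T/26.815)], corrected
for the 4.5 m along-track offset between instrument and GPS antenna, gridded
by inverse-distance weighting, and compared across acquisition dates with
ratio maps (ratio > 1 ⇒ the soil dried between surveys). A median split of
an early-season surface yields high/low-conductivity zones driven by soil
texture.

**Spatially corrected co-variability.** All products are block-averaged to a
common 20 m grid and compared with Pearson's r. Significance uses the
Clifford–Richardson–Hémon corrected test: per-distance-class spatial
autocorrelations (class count from Sturges' rule, K = ⌈1 + log₂ n⌉)
estimate var(r), giving an effective sample size M̂ = 1 + 1/var̂(r) and a
t-test on M̂ − 2 degrees of freedom. Moran's I is provided as the
autocorrelation diagnostic.

**Synthetic scenes.** No field data ship with the package; the
`soilplant.synth` module generates georeferenced scenes with exact ground
truth — row crops on 0.9 m beds at 10 cm pixels, Gaussian-random-field EC_a
surfaces, transect-sampled EMI point clouds (≈9 m between traverses), and
combine yield clouds with swath artifacts — so every stage is testable and
every reported number is a measured recovery of a known truth.

## Worked example

```python
from soilplant import (make_scene, build_profile, extract_training_samples,
                       train_svm, predict_mask_like, kfold_report,
                       compute_abundance, compute_gcc, compute_vigor)
from soilplant.grids import GridSpec
from soilplant.spatial import (block_average, blocks_to_table,
                               corrected_correlation)

scene = make_scene(extent_m=(60.0, 60.0), seed=42, eca_suppression=0.6)
profile = build_profile(scene.rgb, thresholds=(25, 100, 400))
train = extract_training_samples(profile, scene.true_mask, 1000, seed=42)
model = train_svm(train)
mask = predict_mask_like(model, profile, scene.true_mask)
print(kfold_report(train, k=5, seed=42))

grid = GridSpec.from_extent(scene.true_mask.extent, 2.0)
abundance = compute_abundance(mask, grid)
vigor = compute_vigor(compute_gcc(scene.rgb), mask, grid)
print(f"mean abundance: {abundance.values.mean():.1f}%")
print(f"mean vigor (GCC): {vigor.values[vigor.values > 0].mean():.3f}")

bgrid = GridSpec.from_extent(scene.true_mask.extent, 10.0)
tbl = blocks_to_table({
    "eca": block_average(scene.true_eca, bgrid),
    "abundance": block_average(abundance.percent, bgrid),
}).dropna()
res = corrected_correlation(tbl["eca"], tbl["abundance"],
                            tbl[["x", "y"]].to_numpy())
print(f"EC_a vs abundance: r = {res.r:.2f}, n = {res.n}, "
      f"effective n = {res.m_hat:.1f}, p_naive = {res.p_naive:.3g}, "
      f"p_corrected = {res.p_corrected:.3g} {res.stars}")
```

prints

```
class     accuracy      sd
soil        1.0000  0.0000
plant       1.0000  0.0000
OA          1.0000  0.0000
kappa       1.0000  0.0000
mean abundance: 16.3%
mean vigor (GCC): 0.480
EC_a vs abundance: r = -0.97, n = 36, effective n = 5.9, p_naive = 8.36e-22, p_corrected = 0.00184 **
```

The high-contrast synthetic scene separates perfectly (OA 1.0, κ 1.0). The
scene was generated with plant stands thinned on high-conductivity ground
(`eca_suppression=0.6`), and the analysis recovers that negative soil–plant
relationship; note how 36 spatially autocorrelated blocks carry only ≈6
effective observations, weakening the naive p-value by nineteen orders of
magnitude while the relationship remains significant.

The same workflow runs end to end from the shell:

```bash
soilplant pipeline run --seed 42 --out-dir run_out
```

writing GeoTIFF products, the EMI surface and zones, block tables,
zone summaries, the co-variability report, and a SHA-256 manifest that is
bit-identical on rerun with the same seed.

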