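"""UAV plant products: spatial abundance, GCC vigor, and canopy height.

Plant spatial abundance is the percentage of vegetation-classified pixels
per grid cell (default 2 m x 2 m). Vigor is the green chromatic
coordinate GCC = G / (R + G + B) averaged over vegetation pixels only, so
the soil background does not dilute the greenness signal. Height is the
difference between the canopy surface model and a bare-soil reference
elevation model, negatives clipped to zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .grids import DEFAULT_NODATA, GeoGrid, GridSpec, MultibandImage

log = logging.getLogger("soilplant")


def compute_gcc(image: MultibandImage) -> GeoGrid:
    """Green chromatic coordinate per pixel: G_DN / (R_DN + G_DN + B_DN).

    Pixels whose digital numbers sum to zero become nodata.
    """
    r = np.asarray(image.r, float)
    g = np.asarray(image.g, float)
    b = np.asarray(image.b, float)
    total = r + g + b
    out = np.full(total.shape, DEFAULT_NODATA)
    ok = total > 0
    out[ok] = g[ok] / total[ok]
    return GeoGrid(out, image.cell_size, image.origin, nodata=DEFAULT_NODATA,
                   epsg=image.epsg, band_names=["GCC"])


def _cell_bins(grid: GridSpec, raster: GeoGrid) -> tuple[np.ndarray, np.ndarray]:
    """Flat analysis-cell index for each raster pixel center (-1 = outside)."""
    ratio = grid.cell_size / raster.cell_size
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("analysis cell size must be an integer multiple of "
                         "the raster pixel size")
    xs, ys = raster.cell_centers()
    i, _, ix_in = grid.cell_index(xs, np.full_like(xs, grid.origin[1]))
    _, j, jy_in = grid.cell_index(np.full_like(ys, grid.origin[0]), ys)
    col = np.where(ix_in, i, -1)
    row = np.where(jy_in, j, -1)
    flat = np.where((row[:, None] >= 0) & (col[None, :] >= 0),
                    row[:, None] * grid.n_cols + col[None, :], -1)
    return flat.ravel(), np.flatnonzero(flat.ravel() >= 0)


@dataclass
class AbundanceGrid:
    """Gridded plant cover percentage with per-cell valid-pixel counts."""

    percent: GeoGrid
    valid_count: np.ndarray

    @property
    def values(self) -> np.ndarray:
        return self.percent.values


@dataclass
class VigorGrid:
    """Gridded mean GCC over vegetation pixels, with vegetation counts."""

    gcc_mean: GeoGrid
    vegetation_count: np.ndarray

    @property
    def values(self) -> np.ndarray:
        return self.gcc_mean.values


def compute_abundance(mask: GeoGrid, grid: GridSpec) -> AbundanceGrid:
    """Percentage of vegetation pixels per analysis cell.

    Nodata pixels are excluded from numerator and denominator; cells with
    no valid pixel are nodata. Partial edge cells use whatever valid
    pixels they contain.
    """
    flat, inside = _cell_bins(grid, mask)
    m = mask.values.ravel()
    valid = (m != mask.nodata)
    use = np.zeros(m.size, bool)
    use[inside] = True
    use &= valid
    ncell = grid.n_cols * grid.n_rows
    n_valid = np.bincount(flat[use], minlength=ncell)
    n_veg = np.bincount(flat[use], weights=(m[use] == 1).astype(float),
                        minlength=ncell)
    pct = np.full(ncell, DEFAULT_NODATA)
    ok = n_valid > 0
    pct[ok] = 100.0 * n_veg[ok] / n_valid[ok]
    out = GeoGrid(pct.reshape(grid.n_rows, grid.n_cols), grid.cell_size,
                  grid.origin, nodata=DEFAULT_NODATA,
                  band_names=["abundance_pct"])
    return AbundanceGrid(out, n_valid.reshape(grid.n_rows, grid.n_cols))


def compute_vigor(gcc: GeoGrid, mask: GeoGrid, grid: GridSpec) -> VigorGrid:
    """Mean GCC over vegetation pixels per analysis cell (nodata if none)."""
    if gcc.values.shape != mask.values.shape:
        raise ValueError("GCC and mask rasters are misaligned")
    flat, inside = _cell_bins(grid, mask)
    g = gcc.values.ravel()
    m = mask.values.ravel()
    use = np.zeros(g.size, bool)
    use[inside] = True
    use &= (m == 1) & (g != gcc.nodata) & np.isfinite(g)
    ncell = grid.n_cols * grid.n_rows
    n_veg = np.bincount(flat[use], minlength=ncell)
    total = np.bincount(flat[use], weights=g[use], minlength=ncell)
    mean = np.full(ncell, DEFAULT_NODATA)
    ok = n_veg > 0
    mean[ok] = total[ok] / n_veg[ok]
    out = GeoGrid(mean.reshape(grid.n_rows, grid.n_cols), grid.cell_size,
                  grid.origin, nodata=DEFAULT_NODATA, band_names=["gcc_mean"])
    return VigorGrid(out, n_veg.reshape(grid.n_rows, grid.n_cols))


def compute_height(dsm: GeoGrid, reference_dem: GeoGrid) -> GeoGrid:
    """Plant height as canopy surface minus bare-soil reference elevation.

    Negative differences (noise around bare ground) are clipped to zero;
    the clipped fraction is logged. Nodata in either input propagates.
    """
    if dsm.values.shape != reference_dem.values.shape:
        raise ValueError("DSM and reference DEM shapes differ")
    a = np.asarray(dsm.values, float)
    b = np.asarray(reference_dem.values, float)
    valid = (a != dsm.nodata) & (b != reference_dem.nodata) \
        & np.isfinite(a) & np.isfinite(b)
    height = a - b
    n_neg = int((height[valid] < 0).sum())
    if valid.any() and n_neg:
        log.info("height clipping: %.1f%% of valid pixels were negative",
                 100.0 * n_neg / valid.sum())
    height = np.where(height < 0, 0.0, height)
    height[~valid] = DEFAULT_NODATA
    return GeoGrid(height, dsm.cell_size, dsm.origin, nodata=DEFAULT_NODATA,
                   epsg=dsm.epsg, band_names=["height_m"])


def plot_abundance_from_ground_image(image: MultibandImage,
                                     gcc_threshold: float | None = None
                                     ) -> float:
    """Plant cover percent of a nadir ground-plot photo via GCC thresholding.

    With no threshold given, Otsu's method on the in-frame GCC histogram
    picks one per image. Returns the percentage of pixels above the
    threshold.
    """
    gcc = compute_gcc(image)
    vals = gcc.values[gcc.valid_mask()]
    if vals.size == 0:
        raise ValueError("ground image has no valid pixels")
    if gcc_threshold is None:
        from skimage.filters import threshold_otsu
        gcc_threshold = float(threshold_otsu(vals))
    return float(100.0 * np.mean(vals > gcc_threshold))


def validate_abundance(uav_estimates, ground_estimates
                       ) -> tuple[float, float, float]:
    """Agreement between UAV and ground plot-cover estimates.

    Ordinary least squares of ground on UAV values; returns (R^2, RMSE of
    the residuals, two-sided p-value of the slope). R^2 is symmetric in
    the two variables for simple OLS with intercept, so the regression
    direction only affects the residual scale.
    """
    x = np.asarray(uav_estimates, float)
    y = np.asarray(ground_estimates, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired estimates")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor")
    res = sstats.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    return float(res.rvalue ** 2), rmse, float(res.pvalue)
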