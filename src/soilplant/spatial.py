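"""Soil-plant co-variability statistics with spatial autocorrelation control.

Products and surveys are averaged onto a common coarse block grid
(default 20 m, matching the along-y spacing of the EMI and yield tracks)
and compared with Pearson's r. Because both variables are spatially
autocorrelated, the naive t-test on n - 2 degrees of freedom is
anticonservative; the corrected test estimates the variance of r from
the product of the two variables' spatial autocorrelation functions
(estimated in distance classes, their number set by Sturges' rule),
converts it into an effective sample size M_hat = 1 + 1 / var(r), and
refers t = r * sqrt((M_hat - 2) / (1 - r^2)) to a Student t distribution
with M_hat - 2 degrees of freedom. Moran's I is provided as the global
autocorrelation diagnostic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
from scipy.spatial.distance import pdist

from .grids import DEFAULT_NODATA, GeoGrid, GridSpec, SurveyPointCloud

log = logging.getLogger("soilplant")


def block_average(obj: GeoGrid | SurveyPointCloud, grid: GridSpec,
                  value_col: str | None = None) -> GeoGrid:
    """Arithmetic mean of raster pixels or cloud points per block.

    Blocks use the half-open assignment convention; blocks receiving no
    valid data are nodata.
    """
    ncell = grid.n_cols * grid.n_rows
    if isinstance(obj, GeoGrid):
        xs, ys = obj.cell_centers()
        gx, gy = np.meshgrid(xs, ys)
        x, y = gx.ravel(), gy.ravel()
        v = np.asarray(obj.values, float).ravel()
        good = (v != obj.nodata) & np.isfinite(v)
    else:
        x, y = obj.xy.T
        if value_col is None:
            value_col = {"emi": "eca_10", "yield": "yield",
                         "value": "value"}[obj.schema]
        v = obj.data[value_col].to_numpy(float)
        good = np.isfinite(v)
    i, j, inside = grid.cell_index(x, y)
    use = good & inside
    if not use.any():
        raise ValueError("no data overlap the block grid")
    flat = j[use] * grid.n_cols + i[use]
    count = np.bincount(flat, minlength=ncell)
    total = np.bincount(flat, weights=v[use], minlength=ncell)
    mean = np.full(ncell, DEFAULT_NODATA)
    ok = count > 0
    mean[ok] = total[ok] / count[ok]
    return GeoGrid(mean.reshape(grid.n_rows, grid.n_cols), grid.cell_size,
                   grid.origin, nodata=DEFAULT_NODATA)


def sturges_classes(n: int) -> int:
    """Number of distance classes by Sturges' rule: ceil(1 + log2(n))."""
    if n < 2:
        raise ValueError("need n >= 2")
    return math.ceil(1.0 + math.log2(n))


def _rook_weights(coords: np.ndarray) -> np.ndarray:
    """Binary contiguity: pairs at the minimum positive pairwise distance."""
    d = pdist(coords)
    dmin = d[d > 1e-12].min()
    from scipy.spatial.distance import squareform
    full = squareform(d)
    w = ((full > 1e-12) & (full <= dmin * (1 + 1e-9))).astype(float)
    return w


def morans_i(values, coords, weights="rook") -> float:
    """Global Moran's I with the given spatial weights.

    ``weights`` is ``"rook"`` (contiguity at the minimum positive
    inter-point distance, i.e. rook neighbours on a regular grid) or an
    explicit (n, n) matrix with zero diagonal. The expectation under the
    permutation null is -1/(n-1).
    """
    x = np.asarray(values, float).ravel()
    coords = np.asarray(coords, float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("Moran's I undefined for constant values")
    if isinstance(weights, str):
        if weights != "rook":
            raise ValueError(f"unknown weight scheme {weights!r}")
        w = _rook_weights(coords)
    else:
        w = np.asarray(weights, float)
        if w.shape != (n, n):
            raise ValueError("weight matrix shape mismatch")
    np.fill_diagonal(w, 0.0)
    wsum = w.sum()
    z = x - x.mean()
    num = z @ w @ z
    den = np.sum(z * z)
    return float(n / wsum * num / den)


@dataclass
class CorrelationResult:
    """Pearson r with spatially corrected significance."""

    r: float
    n: int
    m_hat: float
    p_naive: float
    p_corrected: float
    k_classes: int
    class_edges: np.ndarray
    pair_counts: np.ndarray
    rho_x: np.ndarray
    rho_y: np.ndarray

    @property
    def stars(self) -> str:
        p = self.p_corrected
        if p < 0.001:
            return "***"
        if p < 0.01:
            return "**"
        if p < 0.05:
            return "*"
        return "(-)"


def corrected_correlation(x, y, coords,
                          k_classes: int | None = None) -> CorrelationResult:
    """Pearson correlation with autocorrelation-corrected significance.

    Distance classes: equal-width bins from 0 to the maximum pairwise
    distance, their number from Sturges' rule on the observation count
    unless ``k_classes`` overrides it.
    Per class k the spatial autocovariance of each variable is the mean
    cross-product of deviations over the N_k pairs falling in the class;
    normalised by the variance it yields the per-class autocorrelation
    rho(k). The variance of r is estimated as

        var(r) = [n + 2 * sum_k N_k rho_x(k) rho_y(k)] / n^2

    (the trace of the product of the two spatial correlation matrices,
    with within-class constancy assumed), giving the effective sample
    size M_hat = 1 + 1 / var(r), capped at n. Both p-values are two
    sided; the naive one uses n - 2 degrees of freedom.
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    coords = np.asarray(coords, float)
    n = x.size
    if y.size != n or coords.shape[0] != n:
        raise ValueError("x, y, coords must be aligned")
    if n < 10:
        raise ValueError("need at least 10 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant variable")
    d = pdist(coords)
    dmax = d.max()
    if dmax <= 0:
        raise ValueError("all points coincide")
    r, p_naive = sstats.pearsonr(x, y)
    r = float(r)

    k = sturges_classes(n) if k_classes is None else int(k_classes)
    if k < 2:
        raise ValueError("need at least 2 distance classes")
    edges = np.linspace(0.0, dmax, k + 1)
    # bin index per unordered pair; right edge inclusive in the last class
    cls = np.minimum(np.searchsorted(edges, d, side="right") - 1, k - 1)
    zx = x - x.mean()
    zy = y - y.mean()
    iu, ju = np.triu_indices(n, 1)
    px = zx[iu] * zx[ju]
    py = zy[iu] * zy[ju]
    counts = np.bincount(cls, minlength=k).astype(float)
    sx = np.bincount(cls, weights=px, minlength=k)
    sy = np.bincount(cls, weights=py, minlength=k)
    var_x = np.mean(zx * zx)
    var_y = np.mean(zy * zy)
    with np.errstate(invalid="ignore"):
        rho_x = np.where(counts > 0, sx / counts, 0.0) / var_x
        rho_y = np.where(counts > 0, sy / counts, 0.0) / var_y

    var_r = (n + 2.0 * np.sum(counts * rho_x * rho_y)) / (n * n)
    if var_r <= 0:
        m_hat = float(n)
    else:
        m_hat = min(1.0 + 1.0 / var_r, float(n))
    df = m_hat - 2.0
    if df <= 0 or abs(r) >= 1.0:
        p_corr = 0.0 if abs(r) >= 1.0 and df > 0 else 1.0
    else:
        t = r * math.sqrt(df / (1.0 - r * r))
        p_corr = 2.0 * sstats.t.sf(abs(t), df)
    return CorrelationResult(r=r, n=n, m_hat=float(m_hat),
                             p_naive=float(p_naive), p_corrected=float(p_corr),
                             k_classes=k, class_edges=edges,
                             pair_counts=counts.astype(int),
                             rho_x=rho_x, rho_y=rho_y)


# -- block tables, sections, and report tables ------------------------------

def blocks_to_table(named_grids: dict[str, GeoGrid]) -> pd.DataFrame:
    """Stack aligned block grids into a table of block centers + variables."""
    grids = list(named_grids.values())
    g0 = grids[0]
    for g in grids[1:]:
        if g.values.shape != g0.values.shape or g.origin != g0.origin \
                or g.cell_size != g0.cell_size:
            raise ValueError("block grids are not aligned")
    xs, ys = g0.cell_centers()
    gx, gy = np.meshgrid(xs, ys)
    data = {"x": gx.ravel(), "y": gy.ravel()}
    for name, g in named_grids.items():
        v = np.asarray(g.values, float).ravel()
        v = np.where((v == g.nodata) | ~np.isfinite(v), np.nan, v)
        data[name] = v
    return pd.DataFrame(data)


def assign_sections(table: pd.DataFrame,
                    boundaries: tuple[float, float] | None = None,
                    extent: tuple[float, float] | None = None) -> pd.DataFrame:
    """Label blocks west/center/east by x-coordinate boundaries.

    Without explicit boundaries the field extent is split into equal
    thirds.
    """
    out = table.copy()
    if boundaries is None:
        if extent is None:
            xmin, xmax = table["x"].min(), table["x"].max()
        else:
            xmin, xmax = extent
        boundaries = (xmin + (xmax - xmin) / 3, xmin + 2 * (xmax - xmin) / 3)
    b1, b2 = boundaries
    x = out["x"].to_numpy(float)
    section = np.where(x < b1, "west", np.where(x < b2, "center", "east"))
    out["section"] = section
    return out


def zone_summary(table: pd.DataFrame, variables: list[str],
                 zone_col: str = "eca_zone",
                 section_col: str = "section") -> pd.DataFrame:
    """Mean of each variable per (section x high/low EC zone) stratum.

    Long-format output with one row per stratum and variable; empty
    strata are reported as NaN with a warning.
    """
    rows = []
    for (section, zone), sub in table.groupby([section_col, zone_col],
                                              dropna=True):
        for var in variables:
            vals = sub[var].dropna()
            if vals.empty:
                log.warning("empty stratum %s/%s for %s", section, zone, var)
            rows.append({"section": section, "zone": zone, "variable": var,
                         "mean": vals.mean() if not vals.empty else np.nan,
                         "n_blocks": int(vals.size)})
    return pd.DataFrame(rows)


def covariability_report(table: pd.DataFrame,
                         pairs: list[tuple[str, str]],
                         section_col: str | None = "section",
                         min_blocks: int = 10) -> pd.DataFrame:
    """Corrected-correlation table over variable pairs and field sections.

    Incomplete blocks are dropped pairwise; strata with fewer than
    ``min_blocks`` complete blocks are skipped with a warning.
    Significance stars follow *p<.05, **p<.01, ***p<.001, (-) otherwise,
    on the corrected p-value.
    """
    strata = [(None, table)] if section_col is None \
        else list(table.groupby(section_col))
    rows = []
    for name, sub in strata:
        for vx, vy in pairs:
            cols = list(dict.fromkeys([vx, vy, "x", "y"]))
            ok = sub[cols].dropna()
            if len(ok) < min_blocks:
                log.warning("stratum %s %s~%s skipped: %d complete blocks",
                            name, vx, vy, len(ok))
                continue
            res = corrected_correlation(ok[vx], ok[vy],
                                        ok[["x", "y"]].to_numpy())
            rows.append({"section": name, "var_x": vx, "var_y": vy,
                         "r": res.r, "n": res.n, "m_hat": res.m_hat,
                         "p_naive": res.p_naive,
                         "p_corrected": res.p_corrected,
                         "significance": res.stars})
    return pd.DataFrame(rows)
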