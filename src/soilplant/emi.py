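"""EMI apparent-conductivity survey processing.

A towed multi-coil electromagnetic-induction instrument records apparent
electrical conductivity EC_a (mS/m) over three effective depths (0.5,
1.0, 1.8 m). Processing steps: (1) temperature correction to the 25 degC
reference via the exponential model EC_25 = EC_a * (0.4470 + 1.4034 *
exp(-T / 26.815)); (2) correction of the along-track offset between the
instrument and the GPS antenna (4.5 m apart in the sled setup); (3)
inverse-distance-weighted gridding; (4) ratio maps between successive
surveys, in which values above 1 flag ground that dried (lower EC_a)
between acquisitions; (5) high/low conductivity zoning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .grids import DEFAULT_NODATA, GeoGrid, GridSpec, SurveyPointCloud

log = logging.getLogger("soilplant")

ECA_COLUMNS = ("eca_05", "eca_10", "eca_18")
#: coil effective depths in meters, by column
COIL_DEPTHS = {"eca_05": 0.5, "eca_10": 1.0, "eca_18": 1.8}
#: validated temperature range of the correction model, degC
TEMP_MODEL_RANGE = (3.0, 43.0)


def temperature_factor(temp_c) -> np.ndarray:
    """Multiplicative factor bringing EC_a at soil temperature T to 25 degC.

    ``0.4470 + 1.4034 * exp(-T / 26.815)``: strictly decreasing in T,
    equal to 1 within 0.1% at 25 degC, and 1.8504 exactly at 0 degC.
    """
    t = np.asarray(temp_c, float)
    if not np.all(np.isfinite(t)):
        raise ValueError("soil temperature must be finite")
    if np.any(t < TEMP_MODEL_RANGE[0]) or np.any(t > TEMP_MODEL_RANGE[1]):
        log.warning("soil temperature outside the model's validated "
                    "range %s degC", TEMP_MODEL_RANGE)
    return 0.4470 + 1.4034 * np.exp(-t / 26.815)


def temperature_correct(cloud: SurveyPointCloud,
                        soil_temp_c=None) -> SurveyPointCloud:
    """Correct every EC_a column of an EMI cloud to the 25 degC reference.

    The soil temperature is taken from the cloud's ``soil_temp`` column
    unless a scalar (or per-point array) override is given.
    """
    if cloud.schema != "emi":
        raise ValueError("temperature correction applies to EMI clouds")
    df = cloud.data.copy()
    temps = df["soil_temp"].to_numpy(float) if soil_temp_c is None \
        else np.broadcast_to(np.asarray(soil_temp_c, float), (len(df),))
    factor = temperature_factor(temps)
    for col in ECA_COLUMNS:
        df[col] = df[col].to_numpy(float) * factor
    out = SurveyPointCloud(df, "emi", meta=dict(cloud.meta))
    out.meta["temperature_corrected"] = True
    return out


def shift_correct(cloud: SurveyPointCloud,
                  offset_m: float = 4.5) -> SurveyPointCloud:
    """Translate each fix by ``offset_m`` along the local track direction.

    Headings come from centered finite differences of consecutive fixes
    (one-sided at the endpoints), normalized so every point moves exactly
    ``|offset_m|``. A positive offset moves points forward along the
    direction of travel (instrument trailing the antenna needs a negative
    offset); the sign is the caller's antenna-lead convention.
    """
    if len(cloud) == 0 or offset_m == 0.0:
        return cloud
    if len(cloud) == 1:
        log.warning("single-point track: heading unknown, no shift applied")
        return cloud
    srt = cloud.sorted_by_time()
    df = srt.data.copy()
    x = df["x"].to_numpy(float)
    y = df["y"].to_numpy(float)
    dx = np.gradient(x)
    dy = np.gradient(y)
    norm = np.hypot(dx, dy)
    # repeated fixes: reuse the nearest defined heading
    bad = norm == 0
    if bad.any():
        good = np.flatnonzero(~bad)
        if good.size == 0:
            log.warning("track has no displacement; no shift applied")
            return srt
        nearest = good[np.searchsorted(good, np.flatnonzero(bad)).clip(0, good.size - 1)]
        dx[bad] = dx[nearest]
        dy[bad] = dy[nearest]
        norm = np.hypot(dx, dy)
    df["x"] = x + offset_m * dx / norm
    df["y"] = y + offset_m * dy / norm
    out = SurveyPointCloud(df, cloud.schema, cloud.yield_units, dict(cloud.meta))
    out.meta["shift_offset_m"] = offset_m
    return out


@dataclass
class ECaSurface:
    """Gridded EC_25 surface for one acquisition and coil depth."""

    grid: GeoGrid
    method: str
    params: dict = field(default_factory=dict)

    @property
    def values(self) -> np.ndarray:
        return self.grid.values


def interpolate_to_grid(cloud: SurveyPointCloud, grid: GridSpec,
                        value_col: str = "eca_10", power: float = 2.0,
                        search_radius_m: float = 10.0) -> ECaSurface:
    """Inverse-distance-weighted gridding of a point cloud.

    Every point within ``search_radius_m`` of a cell center contributes
    with weight 1/d^power; cells with no point in range are nodata. A
    point coincident with a cell center (d < 1e-9 m) supplies its value
    exactly. The interpolant never overshoots the local data range.
    """
    if len(cloud) < 3:
        raise ValueError("need at least 3 points to interpolate")
    pts = cloud.xy
    vals = cloud.data[value_col].to_numpy(float)
    tree = cKDTree(pts)
    xs, ys = grid.cell_centers()
    gx, gy = np.meshgrid(xs, ys)
    centers = np.column_stack([gx.ravel(), gy.ravel()])
    out = np.full(centers.shape[0], DEFAULT_NODATA)
    neighbors = tree.query_ball_point(centers, search_radius_m)
    for k, idx in enumerate(neighbors):
        if not idx:
            continue
        d = np.hypot(*(pts[idx] - centers[k]).T)
        hit = d < 1e-9
        if hit.any():
            out[k] = vals[np.asarray(idx)[hit][0]]
            continue
        w = 1.0 / d ** power
        out[k] = np.sum(w * vals[idx]) / np.sum(w)
    surface = GeoGrid(out.reshape(grid.n_rows, grid.n_cols), grid.cell_size,
                      grid.origin, nodata=DEFAULT_NODATA)
    return ECaSurface(surface, "idw",
                      dict(power=power, search_radius_m=search_radius_m,
                           value_col=value_col))


def ratio_map(earlier: ECaSurface | GeoGrid, later: ECaSurface | GeoGrid
              ) -> GeoGrid:
    """Per-cell ratio earlier / later between two co-gridded surfaces.

    A later survey with lower EC_a (drying soil) raises the ratio above
    1. Cells are nodata where either input is nodata or the later value
    is non-positive.
    """
    a = earlier.grid if isinstance(earlier, ECaSurface) else earlier
    b = later.grid if isinstance(later, ECaSurface) else later
    if a.values.shape != b.values.shape or a.cell_size != b.cell_size \
            or a.origin != b.origin:
        raise ValueError("surfaces are not on the same grid")
    av, bv = np.asarray(a.values, float), np.asarray(b.values, float)
    ok = (av != a.nodata) & (bv != b.nodata) & (bv > 0) \
        & np.isfinite(av) & np.isfinite(bv)
    out = np.full(av.shape, DEFAULT_NODATA)
    out[ok] = av[ok] / bv[ok]
    return a.like(out, nodata=DEFAULT_NODATA)


def classify_eca_zones(surface: ECaSurface | GeoGrid,
                       rule: str = "median") -> GeoGrid:
    """Label each valid cell high (1) or low (0) conductivity.

    The default rule splits at the median of valid cells; zones are
    usually derived from an early-season survey unaffected by irrigation,
    so the signal reflects soil texture rather than management.
    """
    g = surface.grid if isinstance(surface, ECaSurface) else surface
    vals = np.asarray(g.values, float)
    valid = (vals != g.nodata) & np.isfinite(vals)
    if not valid.any():
        raise ValueError("surface has no valid cells")
    if rule != "median":
        raise ValueError(f"unknown zoning rule {rule!r}")
    pool = vals[valid]
    if np.ptp(pool) == 0:
        raise ValueError("constant surface: no high/low split possible")
    cut = float(np.median(pool))
    out = np.full(vals.shape, 255.0)
    out[valid] = (vals[valid] > cut).astype(float)
    zones = g.like(out, nodata=255.0)
    return zones
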