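"""Synthetic field scenes with known ground truth.

No field data ship with this package, so every pipeline stage is exercised
on generated scenes that emulate the surveyed system: a soybean field
planted on raised beds 0.9 m apart, imaged at 10 cm pixels, with a
spatially autocorrelated apparent-conductivity (EC_a) subsurface sampled
along parallel instrument traverses roughly 9 m apart, and a yield point
cloud recorded by an 11-row combine.

All randomness flows through :class:`numpy.random.Generator` seeded with
PCG64, so a scene regenerates bit-identically for a given seed on any
platform. Gaussian random fields use circulant-embedding FFT synthesis
with an exponential covariance (exact on the torus; negative embedding
eigenvalues, which are negligible at the sizes used here, are clipped).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import GeoGrid, GridSpec, MultibandImage, SurveyPointCloud

SOIL_RGB = (120.0, 100.0, 80.0)  # brownish soil mean digital numbers


def gaussian_random_field(n_rows: int, n_cols: int, cell_size: float,
                          range_m: float, sill: float,
                          rng: np.random.Generator,
                          mean: float = 0.0) -> np.ndarray:
    """Stationary Gaussian field with covariance ``sill * exp(-h/range_m)``.

    Synthesised by circulant embedding on a doubled grid: the covariance is
    evaluated on the torus, its FFT gives the embedding eigenvalues, and a
    complex white-noise spectrum is coloured by their square root. Both the
    real and imaginary parts of the result are valid fields; the real part
    of the top-left block is returned.
    """
    if range_m <= 0:
        return mean + np.sqrt(sill) * rng.standard_normal((n_rows, n_cols))
    m1, m2 = 2 * n_rows, 2 * n_cols
    ky = np.minimum(np.arange(m1), m1 - np.arange(m1)) * cell_size
    kx = np.minimum(np.arange(m2), m2 - np.arange(m2)) * cell_size
    dist = np.hypot(ky[:, None], kx[None, :])
    cov = sill * np.exp(-dist / range_m)
    lam = np.fft.fft2(cov).real
    np.clip(lam, 0.0, None, out=lam)
    noise = rng.standard_normal((m1, m2)) + 1j * rng.standard_normal((m1, m2))
    spectrum = np.sqrt(lam) * noise
    field = np.sqrt(m1 * m2) * np.fft.ifft2(spectrum)
    return mean + field.real[:n_rows, :n_cols]


@dataclass
class FieldScene:
    """Synthetic ground-truth bundle: imagery, terrain, soil, and yield."""

    rgb: MultibandImage
    true_mask: GeoGrid
    true_eca: GeoGrid
    dsm: GeoGrid
    reference_dem: GeoGrid
    yield_cloud: SurveyPointCloud
    seed: int
    params: dict

    @property
    def cell_size(self) -> float:
        return self.true_mask.cell_size


def _disk_offsets(radius_px: float) -> tuple[np.ndarray, np.ndarray]:
    r = int(np.floor(radius_px))
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
    inside = dy * dy + dx * dx <= radius_px * radius_px
    return dy[inside], dx[inside]


def make_scene(extent_m: tuple[float, float] = (100.0, 100.0),
               cell_size: float = 0.10,
               row_spacing_m: float = 0.9,
               plant_density: float = 0.7,
               plant_radius_m: float = 0.15,
               green_contrast: float = 60.0,
               noise_sd: float = 5.0,
               eca_range_m: float = 20.0,
               eca_sill: float = 25.0,
               seed: int = 0,
               eca_mean: float = 30.0,
               eca_suppression: float = 0.0,
               plant_height_m: float = 0.35,
               plant_spacing_m: float = 0.30,
               origin: tuple[float, float] = (0.0, 0.0)) -> FieldScene:
    """Generate a row-crop scene with exact plant-mask ground truth.

    Plants are disks of radius ``plant_radius_m`` centred on north-south
    rows ``row_spacing_m`` apart, with candidate positions every
    ``plant_spacing_m`` along the row, each present with probability
    ``plant_density`` and jittered a few centimetres. Plant pixels have
    their green digital number raised by ``green_contrast`` (and red/blue
    slightly lowered) relative to a spatially varying brown soil
    background, before additive Gaussian noise of sd ``noise_sd``; the
    soil background carries low-frequency brightness variation so a single
    DN threshold cannot separate the classes.

    ``eca_suppression`` in [0, 1] links soil to plants: the survival
    probability of a candidate plant is scaled by
    ``1 - eca_suppression * q`` with ``q`` the local EC_a quantile, so
    high-conductivity (clay-rich) ground carries thinner stands.
    """
    ex, ey = extent_m
    n_cols = int(round(ex / cell_size))
    n_rows = int(round(ey / cell_size))
    if n_cols < 1 or n_rows < 1:
        raise ValueError("degenerate extent")
    if not 0.0 <= plant_density <= 1.0:
        raise ValueError("plant_density must be in [0, 1]")
    rng = np.random.default_rng(seed)

    # soil EC_a ground truth (mS/m), clipped away from zero
    eca = gaussian_random_field(n_rows, n_cols, cell_size, eca_range_m,
                                eca_sill, rng, mean=eca_mean)
    np.clip(eca, 1.0, None, out=eca)
    # EC_a quantile per pixel for the optional plant-suppression link
    order = eca.ravel().argsort()
    quant = np.empty(eca.size)
    quant[order] = np.arange(eca.size) / max(eca.size - 1, 1)
    quant = quant.reshape(eca.shape)

    # plant centres on rows running south-north
    mask = np.zeros((n_rows, n_cols), dtype=np.uint8)
    row_xs = np.arange(row_spacing_m / 2, ex, row_spacing_m)
    along_ys = np.arange(plant_spacing_m / 2, ey, plant_spacing_m)
    if plant_density > 0 and row_xs.size and along_ys.size:
        cx = np.repeat(row_xs, along_ys.size)
        cy = np.tile(along_ys, row_xs.size)
        cx = cx + rng.normal(0.0, 0.03, cx.size)
        cy = cy + rng.normal(0.0, 0.03, cy.size)
        ci = np.clip((cx / cell_size).astype(int), 0, n_cols - 1)
        cj = np.clip((cy / cell_size).astype(int), 0, n_rows - 1)
        p = plant_density * (1.0 - eca_suppression * quant[cj, ci])
        keep = rng.random(cx.size) < p
        ci, cj = ci[keep], cj[keep]
        dy, dx = _disk_offsets(plant_radius_m / cell_size)
        jj = (cj[:, None] + dy[None, :]).ravel()
        ii = (ci[:, None] + dx[None, :]).ravel()
        ok = (jj >= 0) & (jj < n_rows) & (ii >= 0) & (ii < n_cols)
        mask[jj[ok], ii[ok]] = 1

    # RGB digital numbers
    brightness = gaussian_random_field(n_rows, n_cols, cell_size, 15.0,
                                       64.0, rng)
    plant = mask.astype(bool)
    r = np.full((n_rows, n_cols), SOIL_RGB[0]) + brightness
    g = np.full((n_rows, n_cols), SOIL_RGB[1]) + brightness
    b = np.full((n_rows, n_cols), SOIL_RGB[2]) + brightness
    g[plant] += green_contrast
    r[plant] -= 0.25 * green_contrast
    b[plant] -= 0.25 * green_contrast
    if noise_sd > 0:
        r += rng.normal(0.0, noise_sd, r.shape)
        g += rng.normal(0.0, noise_sd, g.shape)
        b += rng.normal(0.0, noise_sd, b.shape)
    for band in (r, g, b):
        np.clip(band, 0.0, 255.0, out=band)

    geo = dict(cell_size=cell_size, origin=origin)
    rgb = MultibandImage(r.astype(np.float32), g.astype(np.float32),
                         b.astype(np.float32), **geo)
    true_mask = GeoGrid(mask, **geo, nodata=255)
    true_eca = GeoGrid(eca, **geo)

    # terrain: a gentle east-west ramp plus smooth undulation
    xs = (np.arange(n_cols) + 0.5) * cell_size
    ramp = 0.002 * xs[None, :] * np.ones((n_rows, 1))
    undul = gaussian_random_field(n_rows, n_cols, cell_size, 30.0, 0.01, rng)
    ref = 50.0 + ramp + undul
    dsm_vals = ref + plant_height_m * mask
    reference_dem = GeoGrid(ref, **geo)
    dsm = GeoGrid(dsm_vals, **geo)

    yield_cloud = _make_yield_cloud(true_mask, rng)

    params = dict(extent_m=extent_m, cell_size=cell_size,
                  row_spacing_m=row_spacing_m, plant_density=plant_density,
                  plant_radius_m=plant_radius_m, green_contrast=green_contrast,
                  noise_sd=noise_sd, eca_range_m=eca_range_m,
                  eca_sill=eca_sill, eca_mean=eca_mean,
                  eca_suppression=eca_suppression,
                  plant_height_m=plant_height_m,
                  plant_spacing_m=plant_spacing_m)
    return FieldScene(rgb, true_mask, true_eca, dsm, reference_dem,
                      yield_cloud, seed, params)


def _make_yield_cloud(true_mask: GeoGrid, rng: np.random.Generator,
                      swath_rows: int = 11, row_spacing_m: float = 0.9,
                      point_step_m: float = 1.5, base_bu_ac: float = 25.0,
                      gain_bu_ac: float = 35.0, noise_bu_ac: float = 3.0,
                      bad_swath_frac: float = 0.05) -> SurveyPointCloud:
    """Yield point cloud from harvest passes over the plant mask.

    The latent yield at a point is an affine function of the local plant
    cover fraction in a 3 m neighbourhood; a small fraction of records
    carries a wrong swath value, mimicking operator error.
    """
    from scipy.ndimage import uniform_filter

    cover = uniform_filter(true_mask.values.astype(float),
                           size=max(1, int(3.0 / true_mask.cell_size)))
    cover_grid = true_mask.like(cover, nodata=-9999.0)
    xmin, ymin, xmax, ymax = true_mask.extent
    pass_spacing = swath_rows * row_spacing_m
    ys = np.arange(ymin + pass_spacing / 2, ymax, pass_spacing)
    rows = []
    t = 0.0
    for k, y in enumerate(ys):
        xs = np.arange(xmin + point_step_m / 2, xmax, point_step_m)
        if k % 2:  # serpentine harvest pattern
            xs = xs[::-1]
        for x in xs:
            rows.append((x, y, t))
            t += 2.0  # one record every 2 s
    arr = np.array(rows) if rows else np.empty((0, 3))
    cov = cover_grid.value_at(arr[:, 0], arr[:, 1]) if len(arr) else np.array([])
    vals = base_bu_ac + gain_bu_ac * cov + rng.normal(0, noise_bu_ac, len(arr))
    np.clip(vals, 0.0, None, out=vals)
    swath = np.full(len(arr), swath_rows, dtype=int)
    n_bad = int(round(bad_swath_frac * len(arr)))
    if n_bad:
        bad = rng.choice(len(arr), size=n_bad, replace=False)
        swath[bad] = swath_rows - 4
    import pandas as pd
    df = pd.DataFrame({"x": arr[:, 0], "y": arr[:, 1],
                       "timestamp": arr[:, 2], "yield": vals, "swath": swath})
    return SurveyPointCloud(df, "yield", yield_units="bu/ac")


def sample_transects(grid: GeoGrid, transect_spacing_m: float = 9.0,
                     along_track_step_m: float = 1.0, noise_sd: float = 0.0,
                     seed: int = 0,
                     phase: float | None = None) -> SurveyPointCloud:
    """Sample a grid along parallel east-west traverses.

    Traverses sit at ``y = phase + k * transect_spacing_m`` (default phase
    is half the spacing, centring the first traverse inside the field) and
    alternate direction like a towed-instrument survey; timestamps are
    monotone along the track. Values are the grid value at the point plus
    Gaussian noise.
    """
    import pandas as pd

    if transect_spacing_m <= 0:
        raise ValueError("spacing must be positive")
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = grid.extent
    if phase is None:
        phase = transect_spacing_m / 2
    ys = np.arange(ymin + phase, ymax, transect_spacing_m)
    if ys.size == 0:
        import logging
        logging.getLogger("soilplant").warning(
            "transect spacing exceeds extent; falling back to one transect")
        ys = np.array([(ymin + ymax) / 2])
    rows = []
    t = 0.0
    for k, y in enumerate(ys):
        xs = np.arange(xmin + along_track_step_m / 2, xmax, along_track_step_m)
        if k % 2:
            xs = xs[::-1]
        for x in xs:
            rows.append((x, y, t))
            t += 1.0
    arr = np.array(rows)
    vals = grid.value_at(arr[:, 0], arr[:, 1])
    if noise_sd > 0:
        vals = vals + rng.normal(0.0, noise_sd, vals.shape)
    df = pd.DataFrame({"x": arr[:, 0], "y": arr[:, 1],
                       "timestamp": arr[:, 2], "value": vals})
    return SurveyPointCloud(df, "value")


def emi_survey(eca_grid: GeoGrid, soil_temp_c: float = 20.0,
               transect_spacing_m: float = 9.0,
               along_track_step_m: float = 1.0, noise_sd: float = 0.5,
               seed: int = 0, antenna_offset_m: float = 0.0) -> SurveyPointCloud:
    """Full EMI survey cloud sampled from a true EC_a field.

    The three coil depths report scaled copies of the same field (shallow
    coils read lower EC_a). ``antenna_offset_m`` displaces the *recorded*
    GPS position forward along the track, emulating the instrument
    trailing the antenna; the shift correction should undo it.
    """
    import pandas as pd

    cloud = sample_transects(eca_grid, transect_spacing_m,
                             along_track_step_m, noise_sd, seed)
    df = cloud.data
    eca10 = np.clip(df["value"].to_numpy(), 0.1, None)
    out = pd.DataFrame({
        "x": df["x"], "y": df["y"], "timestamp": df["timestamp"],
        "eca_05": 0.8 * eca10, "eca_10": eca10, "eca_18": 1.15 * eca10,
        "soil_temp": soil_temp_c,
    })
    if antenna_offset_m != 0.0:
        dx = np.gradient(out["x"].to_numpy())
        dy = np.gradient(out["y"].to_numpy())
        norm = np.hypot(dx, dy)
        norm[norm == 0] = 1.0
        out["x"] = out["x"] + antenna_offset_m * dx / norm
        out["y"] = out["y"] + antenna_offset_m * dy / norm
    return SurveyPointCloud(out, "emi")


def make_correlated_fields(n_cells: int, range_m: float, rho: float,
                           seed: int, cell_size: float = 20.0,
                           sill: float = 1.0) -> tuple[GeoGrid, GeoGrid]:
    """Two Gaussian fields with shared covariance and pointwise correlation rho.

    Built by mixing independent fields: ``Y = rho * X + sqrt(1 - rho^2) * Z``
    with X, Z independent draws from the same exponential-covariance model,
    so corr(X, Y) = rho at every point while both fields keep the same
    spatial structure.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    x = gaussian_random_field(n_cells, n_cells, cell_size, range_m, sill, rng)
    z = gaussian_random_field(n_cells, n_cells, cell_size, range_m, sill, rng)
    y = rho * x + np.sqrt(1.0 - rho * rho) * z
    gx = GeoGrid(x, cell_size, (0.0, 0.0))
    gy = GeoGrid(y, cell_size, (0.0, 0.0))
    return gx, gy
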