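"""Georeferenced rasters, analysis grids, and survey point clouds.

Conventions shared by every module:

* projected CRS in meters, x east / y north;
* raster row 0 is the *southernmost* row, so ``values[j, i]`` covers the
  half-open square ``[x0 + i*s, x0 + (i+1)*s) x [y0 + j*s, y0 + (j+1)*s)``
  with ``s`` the cell size and ``(x0, y0)`` the lower-left corner;
* a point exactly on a shared cell edge belongs to the higher-index cell
  of the left/bottom-inclusive convention (half-open assignment).

GeoTIFF files are read and written through :mod:`tifffile` with the
standard GeoTIFF tags (ModelPixelScale, ModelTiepoint, GeoKeyDirectory)
and the GDAL nodata tag, restricted to projected CRSs in meters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

log = logging.getLogger("soilplant")

DEFAULT_NODATA = -9999.0
#: kg/ha per bu/ac for soybean at the 60 lb/bu standard test weight.
SOYBEAN_KG_HA_PER_BU_AC = 67.25

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEO_KEYS = 34735
_TAG_GDAL_NODATA = 42113

_KEY_MODEL_TYPE = 1024
_KEY_RASTER_TYPE = 1025
_KEY_PROJECTED_CS = 3072
_KEY_LINEAR_UNITS = 3076
_MODEL_PROJECTED = 1
_MODEL_GEOGRAPHIC = 2
_UNIT_METER = 9001


class GeoreferencingError(ValueError):
    """Raised for missing or unusable raster georeferencing."""


@dataclass
class GeoGrid:
    """A single-band georeferenced raster (row 0 = south)."""

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float]
    nodata: float = DEFAULT_NODATA
    band_names: list[str] | None = None
    epsg: int = 32615

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("GeoGrid values must be 2-D")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the covered rectangle."""
        x0, y0 = self.origin
        s = self.cell_size
        return (x0, y0, x0 + self.n_cols * s, y0 + self.n_rows * s)

    def valid_mask(self) -> np.ndarray:
        v = self.values
        return np.isfinite(v) & (v != self.nodata)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """1-D arrays of cell-center x (len n_cols) and y (len n_rows)."""
        x0, y0 = self.origin
        s = self.cell_size
        xs = x0 + (np.arange(self.n_cols) + 0.5) * s
        ys = y0 + (np.arange(self.n_rows) + 0.5) * s
        return xs, ys

    def value_at(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Grid value of the cell containing each point (half-open)."""
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        i = np.floor((x - self.origin[0]) / self.cell_size).astype(int)
        j = np.floor((y - self.origin[1]) / self.cell_size).astype(int)
        inside = (i >= 0) & (i < self.n_cols) & (j >= 0) & (j < self.n_rows)
        out = np.full(np.shape(x), self.nodata, dtype=float)
        out[inside] = self.values[j[inside], i[inside]]
        return out

    def like(self, values: np.ndarray, **kw) -> "GeoGrid":
        """New grid with the same georeferencing and different values."""
        opts = dict(nodata=self.nodata, epsg=self.epsg)
        opts.update(kw)
        return GeoGrid(values, self.cell_size, self.origin, **opts)


@dataclass
class MultibandImage:
    """Georeferenced RGB digital-number image (same conventions as GeoGrid)."""

    r: np.ndarray
    g: np.ndarray
    b: np.ndarray
    cell_size: float
    origin: tuple[float, float]
    nodata: float = DEFAULT_NODATA
    epsg: int = 32615

    def __post_init__(self) -> None:
        self.r, self.g, self.b = (np.asarray(a) for a in (self.r, self.g, self.b))
        if not (self.r.shape == self.g.shape == self.b.shape):
            raise ValueError("R, G, B bands must share one shape")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    @property
    def shape(self) -> tuple[int, int]:
        return self.r.shape

    @property
    def bands(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.r, self.g, self.b

    def band_grid(self, name: str) -> GeoGrid:
        arr = {"r": self.r, "g": self.g, "b": self.b}[name.lower()]
        return GeoGrid(arr, self.cell_size, self.origin, nodata=self.nodata,
                       epsg=self.epsg, band_names=[name.upper()])


@dataclass(frozen=True)
class GridSpec:
    """Geometry of an analysis grid (e.g. the 2 m product or 20 m block grid)."""

    cell_size: float
    origin: tuple[float, float]
    n_cols: int
    n_rows: int

    def __post_init__(self) -> None:
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("grid must have at least one cell")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")

    @classmethod
    def from_extent(cls, extent: tuple[float, float, float, float],
                    cell_size: float) -> "GridSpec":
        xmin, ymin, xmax, ymax = extent
        n_cols = max(1, int(np.ceil((xmax - xmin) / cell_size - 1e-9)))
        n_rows = max(1, int(np.ceil((ymax - ymin) / cell_size - 1e-9)))
        return cls(cell_size, (xmin, ymin), n_cols, n_rows)

    def cell_index(self, x, y) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(col, row, inside) arrays using the half-open convention."""
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        i = np.floor((x - self.origin[0]) / self.cell_size).astype(int)
        j = np.floor((y - self.origin[1]) / self.cell_size).astype(int)
        inside = (i >= 0) & (i < self.n_cols) & (j >= 0) & (j < self.n_rows)
        return i, j, inside

    def empty_grid(self, nodata: float = DEFAULT_NODATA) -> GeoGrid:
        vals = np.full((self.n_rows, self.n_cols), nodata, dtype=float)
        return GeoGrid(vals, self.cell_size, self.origin, nodata=nodata)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        xs = self.origin[0] + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = self.origin[1] + (np.arange(self.n_rows) + 0.5) * self.cell_size
        return xs, ys


# -- survey point clouds -----------------------------------------------------

EMI_COLUMNS = ["x", "y", "timestamp", "eca_05", "eca_10", "eca_18", "soil_temp"]
YIELD_COLUMNS = ["x", "y", "timestamp", "yield", "swath"]
VALUE_COLUMNS = ["x", "y", "timestamp", "value"]

_SCHEMAS = {"emi": EMI_COLUMNS, "yield": YIELD_COLUMNS, "value": VALUE_COLUMNS}


@dataclass
class SurveyPointCloud:
    """Timestamped georeferenced point records (EMI, yield, or plain values)."""

    data: pd.DataFrame
    schema: str
    yield_units: str = "bu/ac"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.schema not in _SCHEMAS:
            raise ValueError(f"unknown point schema {self.schema!r}")
        missing = [c for c in _SCHEMAS[self.schema] if c not in self.data.columns]
        if missing:
            raise ValueError(f"point cloud missing columns {missing}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def xy(self) -> np.ndarray:
        return self.data[["x", "y"]].to_numpy(float)

    def sorted_by_time(self) -> "SurveyPointCloud":
        df = self.data.sort_values("timestamp", kind="stable").reset_index(drop=True)
        return SurveyPointCloud(df, self.schema, self.yield_units, dict(self.meta))


def read_point_csv(path, schema: str) -> SurveyPointCloud:
    """Read a point cloud from a headed CSV; drops non-finite coordinates.

    ``schema`` is ``"emi"`` (x, y, timestamp, eca_05, eca_10, eca_18,
    soil_temp), ``"yield"`` (x, y, timestamp, yield, swath) or ``"value"``.
    """
    if schema not in _SCHEMAS:
        raise ValueError(f"unknown point schema {schema!r}")
    df = pd.read_csv(path)
    missing = [c for c in _SCHEMAS[schema] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    finite = np.isfinite(df["x"].to_numpy(float)) & np.isfinite(df["y"].to_numpy(float))
    dropped = int((~finite).sum())
    if dropped:
        log.warning("%s: dropped %d rows with non-finite coordinates", path, dropped)
    df = df.loc[finite].reset_index(drop=True)
    return SurveyPointCloud(df, schema)


def write_point_csv(cloud: SurveyPointCloud, path) -> None:
    cloud.data.to_csv(path, index=False)


def filter_yield_artifacts(cloud: SurveyPointCloud,
                           expected_swath: int) -> SurveyPointCloud:
    """Drop yield records whose recorded swath differs from the expected one.

    A wrong swath setting on the combine makes the per-area yield value
    unreliable, so mismatched records are removed outright.
    """
    if cloud.schema != "yield":
        raise ValueError("swath filtering applies to yield clouds only")
    keep = cloud.data["swath"].to_numpy() == expected_swath
    removed = int((~keep).sum())
    if removed:
        log.warning("swath filter removed %d of %d yield records", removed, len(cloud))
    if removed == len(cloud):
        log.warning("swath filter removed every record")
    df = cloud.data.loc[keep].reset_index(drop=True)
    out = SurveyPointCloud(df, "yield", cloud.yield_units, dict(cloud.meta))
    out.meta["swath_removed"] = removed
    return out


def convert_yield_units(cloud: SurveyPointCloud, direction: str,
                        factor: float = SOYBEAN_KG_HA_PER_BU_AC) -> SurveyPointCloud:
    """Convert yield values between bu/ac and kg/ha (strict linear bijection)."""
    if cloud.schema != "yield":
        raise ValueError("unit conversion applies to yield clouds only")
    df = cloud.data.copy()
    if direction == "bu_ac_to_kg_ha":
        df["yield"] = df["yield"] * factor
        units = "kg/ha"
    elif direction == "kg_ha_to_bu_ac":
        df["yield"] = df["yield"] / factor
        units = "bu/ac"
    else:
        raise ValueError(f"unknown conversion direction {direction!r}")
    return SurveyPointCloud(df, "yield", units, dict(cloud.meta))


# -- GeoTIFF I/O -------------------------------------------------------------

def _geo_extratags(cell_size: float, x0: float, y_top: float,
                   nodata: float, epsg: int) -> list:
    keys = (1, 1, 0, 4,
            _KEY_MODEL_TYPE, 0, 1, _MODEL_PROJECTED,
            _KEY_RASTER_TYPE, 0, 1, 1,
            _KEY_PROJECTED_CS, 0, 1, epsg,
            _KEY_LINEAR_UNITS, 0, 1, _UNIT_METER)
    nd = repr(float(nodata))
    return [
        (_TAG_PIXEL_SCALE, "d", 3, (cell_size, cell_size, 0.0), True),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x0, y_top, 0.0), True),
        (_TAG_GEO_KEYS, "H", len(keys), keys, True),
        (_TAG_GDAL_NODATA, "s", len(nd) + 1, nd, True),
    ]


def write_geotiff(obj: GeoGrid | MultibandImage, path) -> None:
    """Write a grid or RGB image as a projected GeoTIFF.

    Values round-trip bit-exactly (the array dtype is preserved) and the
    georeferencing to well below 1e-9 m.
    """
    if isinstance(obj, MultibandImage):
        data = np.flipud(np.stack([obj.r, obj.g, obj.b], axis=-1))
        photometric = "rgb"
        n_rows = obj.shape[0]
    else:
        data = np.flipud(obj.values)
        photometric = "minisblack"
        n_rows = obj.n_rows
    y_top = obj.origin[1] + n_rows * obj.cell_size
    tags = _geo_extratags(obj.cell_size, obj.origin[0], y_top, obj.nodata, obj.epsg)
    tifffile.imwrite(path, np.ascontiguousarray(data), photometric=photometric,
                     extratags=tags)


def read_geotiff(path) -> GeoGrid | MultibandImage:
    """Read a projected GeoTIFF into a GeoGrid (1 band) or MultibandImage (3).

    Raises :class:`GeoreferencingError` when georeferencing tags are absent
    or the CRS is geographic (degrees) rather than projected (meters).
    """
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        tags = page.tags
        if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
            raise GeoreferencingError(f"{path}: no GeoTIFF georeferencing tags")
        scale = tags[_TAG_PIXEL_SCALE].value
        tie = tags[_TAG_TIEPOINT].value
        epsg = 0
        if _TAG_GEO_KEYS in tags:
            keys = list(tags[_TAG_GEO_KEYS].value)
            kv = {keys[i]: keys[i + 3] for i in range(4, len(keys), 4)
                  if keys[i + 1] == 0}
            if kv.get(_KEY_MODEL_TYPE) == _MODEL_GEOGRAPHIC:
                raise GeoreferencingError(
                    f"{path}: geographic (degree) CRS; a projected CRS in "
                    "meters is required")
            epsg = int(kv.get(_KEY_PROJECTED_CS, 0))
        nodata = DEFAULT_NODATA
        if _TAG_GDAL_NODATA in tags:
            nodata = float(tags[_TAG_GDAL_NODATA].value)
        data = page.asarray()
    sx, sy = float(scale[0]), float(scale[1])
    if abs(sx - sy) > 1e-9:
        raise GeoreferencingError(f"{path}: anisotropic pixels unsupported")
    n_rows = data.shape[0]
    x0 = float(tie[3])
    y0 = float(tie[4]) - n_rows * sy
    if data.ndim == 3 and data.shape[2] == 3:
        flipped = np.flipud(data)
        return MultibandImage(flipped[..., 0], flipped[..., 1], flipped[..., 2],
                              sx, (x0, y0), nodata=nodata, epsg=epsg or 32615)
    if data.ndim != 2:
        raise GeoreferencingError(f"{path}: unsupported band layout {data.shape}")
    return GeoGrid(np.flipud(data), sx, (x0, y0), nodata=nodata,
                   epsg=epsg or 32615)
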