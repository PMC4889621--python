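"""Georeferenced raster data model and GeoTIFF I/O.

All grids are regular geographic-degree grids with square cells, row 0 at
the north edge, pixel-is-area semantics and half-open cells: pixel (r, c)
covers [origin_lon + c*cell, origin_lon + (c+1)*cell) in longitude and
(origin_lat - (r+1)*cell, origin_lat - r*cell] in latitude.  Reprojection
between coordinate systems is out of scope.

GeoTIFF files are written/read through :mod:`tifffile` using the standard
GeoTIFF tags (ModelPixelScale, ModelTiepoint, GeoKeyDirectory) plus the
GDAL_NODATA convention, one band per file.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import tifffile

#: Tolerance (degrees) below which two grid geotransforms are considered equal.
#: Geotransforms read from files carry float noise.
SPEC_TOL = 1e-9

#: Default nodata sentinel for float rasters.
DEFAULT_NODATA = -9999.0

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEY_DIRECTORY = 34735
_TAG_GDAL_NODATA = 42113

# Minimal geographic / WGS84 / pixel-is-area key directory.
_GEO_KEYS = (1, 1, 0, 3, 1024, 0, 1, 2, 1025, 0, 1, 1, 2048, 0, 1, 4326)


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular geographic grid (degrees, row 0 at top)."""

    origin_lon: float
    origin_lat: float
    cell_size: float
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(lon, lat) of the center of pixel (row, col)."""
        lon = self.origin_lon + (col + 0.5) * self.cell_size
        lat = self.origin_lat - (row + 0.5) * self.cell_size
        return lon, lat

    def center_lons(self) -> np.ndarray:
        return self.origin_lon + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def center_lats(self) -> np.ndarray:
        return self.origin_lat - (np.arange(self.n_rows) + 0.5) * self.cell_size

    def index_of(self, lon: float | np.ndarray, lat: float | np.ndarray):
        """(row, col) of the half-open cell containing a point.

        Points on a shared vertical edge belong to the cell to their east;
        points on a shared horizontal edge to the cell to their south
        (consistent with the half-open box definition).
        """
        col = np.floor((np.asarray(lon) - self.origin_lon) / self.cell_size)
        row = np.floor((self.origin_lat - np.asarray(lat)) / self.cell_size)
        return row.astype(np.int64), col.astype(np.int64)

    def contains(self, lon, lat) -> np.ndarray:
        row, col = self.index_of(lon, lat)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(west, south, east, north) extent in degrees."""
        return (
            self.origin_lon,
            self.origin_lat - self.n_rows * self.cell_size,
            self.origin_lon + self.n_cols * self.cell_size,
            self.origin_lat,
        )

    def approx_equal(self, other: "GridSpec", tol: float = SPEC_TOL) -> bool:
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and abs(self.origin_lon - other.origin_lon) <= tol
            and abs(self.origin_lat - other.origin_lat) <= tol
            and abs(self.cell_size - other.cell_size) <= tol
        )


@dataclass
class Raster:
    """A single-band georeferenced array with a nodata sentinel."""

    spec: GridSpec
    values: np.ndarray
    nodata: float = DEFAULT_NODATA
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.spec.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.spec.shape}"
            )

    def valid_mask(self) -> np.ndarray:
        """Boolean mask of cells that are neither nodata nor NaN."""
        mask = ~np.isclose(self.values, self.nodata, rtol=0.0, atol=0.0, equal_nan=False)
        if np.issubdtype(self.values.dtype, np.floating):
            mask &= np.isfinite(self.values)
        return mask

    def masked(self) -> np.ndarray:
        """float64 copy with nodata replaced by NaN, safe for arithmetic."""
        out = self.values.astype(np.float64, copy=True)
        out[~self.valid_mask()] = np.nan
        return out

    def with_values(self, values: np.ndarray, units: str | None = None) -> "Raster":
        return Raster(self.spec, values, nodata=self.nodata,
                      units=self.units if units is None else units)


def full_raster(spec: GridSpec, fill: float, nodata: float = DEFAULT_NODATA,
                units: str = "") -> Raster:
    return Raster(spec, np.full(spec.shape, fill, dtype=np.float64), nodata, units)


class MonthlyStack:
    """An ordered sequence of co-registered monthly rasters.

    Keys are (year, month) tuples; they must be strictly increasing in
    calendar order with no gaps inside the covered span, and every member
    raster must share one GridSpec.
    """

    def __init__(self, rasters: Mapping[tuple[int, int], Raster]):
        if not rasters:
            raise ValueError("MonthlyStack requires at least one raster")
        keys = sorted(rasters.keys())
        spec = rasters[keys[0]].spec
        for k in keys:
            if not 1 <= k[1] <= 12:
                raise ValueError(f"month out of range in key {k}")
            if not rasters[k].spec.approx_equal(spec):
                raise ValueError(f"raster {k} does not share the stack GridSpec")
        for a, b in zip(keys, keys[1:]):
            if _month_index(b) != _month_index(a) + 1:
                raise ValueError(f"gap or disorder in monthly keys between {a} and {b}")
        self._rasters = {k: rasters[k] for k in keys}
        self.spec = spec

    def keys(self) -> list[tuple[int, int]]:
        return list(self._rasters.keys())

    def __getitem__(self, key: tuple[int, int]) -> Raster:
        return self._rasters[key]

    def __contains__(self, key) -> bool:
        return key in self._rasters

    def __len__(self) -> int:
        return len(self._rasters)

    def __iter__(self) -> Iterator[tuple[int, int]]:
        return iter(self._rasters)

    def items(self):
        return self._rasters.items()

    def subset(self, keys: Sequence[tuple[int, int]]) -> "MonthlyStack":
        return MonthlyStack({k: self._rasters[k] for k in keys})

    def map(self, fn) -> "MonthlyStack":
        """New stack with fn(raster) applied to every member."""
        return MonthlyStack({k: fn(r) for k, r in self._rasters.items()})


def _month_index(key: tuple[int, int]) -> int:
    year, month = key
    return year * 12 + (month - 1)


def month_range(start: tuple[int, int], n_months: int) -> list[tuple[int, int]]:
    """n_months consecutive (year, month) keys starting at `start`."""
    i0 = _month_index(start)
    return [(i // 12, i % 12 + 1) for i in range(i0, i0 + n_months)]


# ---------------------------------------------------------------------------
# GeoTIFF I/O
# ---------------------------------------------------------------------------

def write_geotiff(raster: Raster, path: str | Path) -> None:
    """Write a single-band GeoTIFF.

    Float payloads are stored as float32 (internal computation stays
    float64); integer payloads keep their dtype.  The geotransform is
    encoded with ModelPixelScale + ModelTiepoint and nodata with the
    GDAL_NODATA ascii tag, so the file round-trips through
    :func:`read_geotiff` and is readable by GDAL-based tools.
    """
    values = raster.values
    if np.issubdtype(values.dtype, np.floating):
        values = values.astype(np.float32)
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3,
         (raster.spec.cell_size, raster.spec.cell_size, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6,
         (0.0, 0.0, 0.0, raster.spec.origin_lon, raster.spec.origin_lat, 0.0)),
        (_TAG_GEO_KEY_DIRECTORY, "H", len(_GEO_KEYS), _GEO_KEYS),
        (_TAG_GDAL_NODATA, "s", 0, repr(raster.nodata)),
    ]
    tifffile.imwrite(path, values, extratags=extratags,
                     description=raster.units or "")


def read_geotiff(path: str | Path, band: int | None = None) -> Raster:
    """Read a single band from a GeoTIFF written by this package (or GDAL).

    Multi-band files require an explicit 0-based ``band``; passing none for
    such a file raises with the band count in the message.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such raster file: {path}")
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = tif.asarray()
        n_bands = 1
        if data.ndim == 3:
            # bands may be the first (separate pages/planes) or last
            # (contiguous samples) axis
            n_bands = data.shape[0] if data.shape[0] < data.shape[-1] else data.shape[-1]
            if band is None:
                raise ValueError(
                    f"{path} has {n_bands} bands; select one with band=<0..{n_bands - 1}>"
                )
            data = data[band] if data.shape[0] == n_bands else data[..., band]
        elif band not in (None, 0):
            raise ValueError(f"{path} is single-band; band={band} is out of range")

        tags = page.tags
        try:
            scale = tags[_TAG_MODEL_PIXEL_SCALE].value
            tiepoint = tags[_TAG_MODEL_TIEPOINT].value
        except KeyError as exc:
            raise ValueError(f"{path} carries no GeoTIFF geotransform tags") from exc
        i, j, _, x, y, _ = tiepoint[:6]
        cell = float(scale[0])
        origin_lon = float(x) - float(i) * cell
        origin_lat = float(y) + float(j) * float(scale[1])

        nodata = DEFAULT_NODATA
        if _TAG_GDAL_NODATA in tags:
            nodata = float(tags[_TAG_GDAL_NODATA].value)
        units = ""
        if 270 in tags:  # ImageDescription
            units = str(tags[270].value)

    spec = GridSpec(origin_lon, origin_lat, cell, data.shape[0], data.shape[1])
    return Raster(spec, data, nodata=nodata, units=units)


def resample_nearest(raster: Raster, target_spec: GridSpec) -> Raster:
    """Nearest-neighbour resampling by target-cell-center containment.

    Each target cell takes the value of the source cell that contains the
    target cell's center; target centers outside the source extent, or on a
    source nodata cell, become nodata.  Source and target extents must
    overlap.
    """
    if raster.spec.approx_equal(target_spec):
        return Raster(target_spec, raster.values.copy(), raster.nodata, raster.units)

    sw, ss, se, sn = raster.spec.bounds
    tw, ts, te, tn = target_spec.bounds
    if se <= tw or te <= sw or sn <= ts or tn <= ss:
        raise ValueError("source and target extents are disjoint")

    lons = target_spec.center_lons()
    lats = target_spec.center_lats()
    rows, cols = raster.spec.index_of(lons[None, :], lats[:, None])
    rows, cols = np.broadcast_arrays(rows, cols)
    inside = (rows >= 0) & (rows < raster.spec.n_rows) & \
             (cols >= 0) & (cols < raster.spec.n_cols)

    out = np.full(target_spec.shape, raster.nodata,
                  dtype=np.result_type(raster.values.dtype, np.float64)
                  if np.issubdtype(raster.values.dtype, np.floating)
                  else raster.values.dtype)
    out[inside] = raster.values[rows[inside], cols[inside]]
    return Raster(target_spec, out, nodata=raster.nodata, units=raster.units)
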