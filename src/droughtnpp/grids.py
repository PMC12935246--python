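"""Gridded raster containers and I/O.

Every analysis stage in this package operates on the same three containers:

``GridMeta``
    the grid geometry contract — two rasters may be combined if and only if
    their metadata match exactly; nothing in this package resamples silently.
``GridCube``
    a gap-free monthly stack ``(time, row, col)`` with an explicit validity
    mask and explicit ``(year, month)`` time labels.
``LandCoverMap``
    a static categorical raster over six classes
    (1 farmland, 2 woodland, 3 grassland, 4 water, 5 construction, 6 ice/bare).

Rasters are persisted either as single-band TIFF files (grid metadata carried
in the ImageDescription tag as JSON) or as NetCDF3 files written through
xarray's scipy backend. Both round-trip bit-identically.

The convention is north-up: row 0 is the northernmost row; ``origin_x``,
``origin_y`` are the coordinates of the outer corner of the top-left cell.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import tifffile
import xarray as xr

FARMLAND, WOODLAND, GRASSLAND, WATER, CONSTRUCTION, ICE_BARE = 1, 2, 3, 4, 5, 6
VEGETATED_CLASSES = (FARMLAND, WOODLAND, GRASSLAND)
CLASS_NAMES = {
    FARMLAND: "farmland",
    WOODLAND: "woodland",
    GRASSLAND: "grassland",
    WATER: "water",
    CONSTRUCTION: "construction",
    ICE_BARE: "ice_bare",
}


class GridError(ValueError):
    """Raised on grid-contract violations (geometry mismatch, time gaps...)."""


@dataclass(frozen=True)
class GridMeta:
    """Grid geometry. Cubes are combinable iff all fields match exactly."""

    n_rows: int
    n_cols: int
    cell_size: float
    origin_x: float = 0.0
    origin_y: float = 0.0
    crs_tag: str = ""
    nodata_value: float = -9999.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise GridError("grid must have at least one row and column")
        if not self.cell_size > 0:
            raise GridError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def row_center_latitudes(self) -> np.ndarray:
        """Latitude (y coordinate) of each row center, north-up."""
        rows = np.arange(self.n_rows)
        return self.origin_y - (rows + 0.5) * self.cell_size

    def check_match(self, other: "GridMeta", what: str = "grids") -> None:
        if self != other:
            raise GridError(f"{what}: grid metadata mismatch: {self} != {other}")


def month_range(start: tuple[int, int], end: tuple[int, int]) -> list[tuple[int, int]]:
    """Inclusive list of (year, month) pairs from start to end."""
    (y0, m0), (y1, m1) = start, end
    if (y0, m0) > (y1, m1):
        raise GridError(f"start {start} after end {end}")
    out = []
    y, m = y0, m0
    while (y, m) <= (y1, m1):
        out.append((y, m))
        m += 1
        if m > 12:
            m, y = 1, y + 1
    return out


def _check_times(times: list[tuple[int, int]]) -> None:
    for y, m in times:
        if not (1 <= m <= 12):
            raise GridError(f"month out of range in {(y, m)}")
    for (y0, m0), (y1, m1) in zip(times, times[1:]):
        nxt = (y0, m0 + 1) if m0 < 12 else (y0 + 1, 1)
        if (y1, m1) == (y0, m0):
            raise GridError(f"duplicate time step {(y0, m0)}")
        if (y1, m1) != nxt:
            raise GridError(
                f"missing {nxt[0]}-{nxt[1]:02d}: times must be gap-free monthly"
            )


@dataclass
class GridCube:
    """Monthly raster stack with explicit time labels and validity mask."""

    meta: GridMeta
    times: list[tuple[int, int]]
    values: np.ndarray
    units: str = ""
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = [tuple(t) for t in self.times]
        _check_times(self.times)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise GridError("values must be 3-D (time, row, col)")
        if self.values.shape != (len(self.times), *self.meta.shape):
            raise GridError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.times)} time steps on a {self.meta.shape} grid"
            )
        if self.valid_mask is None:
            self.valid_mask = np.isfinite(self.values)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.values.shape:
                raise GridError("valid_mask shape must match values")
        if not np.all(np.isfinite(self.values[self.valid_mask])):
            raise GridError("values must be finite wherever valid_mask is true")

    @property
    def n_times(self) -> int:
        return len(self.times)

    def copy_with(self, values: np.ndarray, units: str | None = None,
                  valid_mask: np.ndarray | None = None) -> "GridCube":
        return GridCube(
            meta=self.meta,
            times=list(self.times),
            values=values,
            units=self.units if units is None else units,
            valid_mask=self.valid_mask.copy() if valid_mask is None else valid_mask,
        )

    def masked(self) -> np.ndarray:
        """Values with invalid cells as NaN."""
        out = self.values.astype(np.float64).copy()
        out[~self.valid_mask] = np.nan
        return out

    def years(self) -> list[int]:
        return sorted({y for y, _ in self.times})

    def time_index(self, year: int, month: int) -> int:
        try:
            return self.times.index((year, month))
        except ValueError:
            raise GridError(f"time step {year}-{month:02d} not in cube") from None

    def calendar_month_indices(self, month: int) -> np.ndarray:
        return np.array([i for i, (_, m) in enumerate(self.times) if m == month],
                        dtype=int)

    def align_check(self, *others: "GridCube") -> None:
        """Hard-fail unless all cubes share geometry and time axis."""
        for o in others:
            self.meta.check_match(o.meta)
            if o.times != self.times:
                raise GridError("cubes have different time axes")

    def annual_aggregate(self, how: str = "sum") -> "tuple[list[int], np.ndarray]":
        """Per-pixel calendar-year aggregate (NaN where any month invalid).

        Returns (years, array of shape (n_years, rows, cols)). Only complete
        years (all 12 months present) are aggregated.
        """
        vals = self.masked()
        years = [y for y in self.years()
                 if sum(1 for yy, _ in self.times if yy == y) == 12]
        out = np.full((len(years), *self.meta.shape), np.nan)
        for k, y in enumerate(years):
            idx = [i for i, (yy, _) in enumerate(self.times) if yy == y]
            block = vals[idx]
            if how == "sum":
                out[k] = block.sum(axis=0)
            elif how == "mean":
                out[k] = block.mean(axis=0)
            else:
                raise ValueError(f"unknown aggregate {how!r}")
        return years, out


@dataclass
class LandCoverMap:
    """Static 6-class land-cover raster; 0 encodes nodata."""

    meta: GridMeta
    classes: np.ndarray

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype=np.int16)
        if self.classes.shape != self.meta.shape:
            raise GridError("land-cover shape does not match grid metadata")
        bad = ~np.isin(self.classes, [0, 1, 2, 3, 4, 5, 6])
        if bad.any():
            raise GridError(f"invalid land-cover codes: {np.unique(self.classes[bad])}")

    def vegetated_mask(self) -> np.ndarray:
        return np.isin(self.classes, VEGETATED_CLASSES)

    def class_mask(self, code: int) -> np.ndarray:
        return self.classes == code


# ---------------------------------------------------------------------------
# field (2-D) I/O


def _meta_to_attrs(meta: GridMeta, units: str = "",
                   extra: dict | None = None) -> dict:
    d = {"grid_meta": asdict(meta), "units": units}
    if extra:
        d.update(extra)
    return d


def write_field(values: np.ndarray, meta: GridMeta, path: str | os.PathLike,
                fmt: str | None = None, units: str = "",
                extra_attrs: dict | None = None) -> str:
    """Write a 2-D field as TIFF or NetCDF; NaN cells become the nodata value.

    ``fmt`` is inferred from the file suffix when omitted (``.tif``/``.tiff``
    vs ``.nc``). Round-trip through :func:`read_field` is bit-identical.
    """
    path = os.fspath(path)
    values = np.asarray(values, dtype=np.float64)
    if values.shape != meta.shape:
        raise GridError(f"field shape {values.shape} != grid {meta.shape}")
    if fmt is None:
        fmt = "netcdf" if path.endswith(".nc") else "geotiff"
    filled = values.copy()
    filled[~np.isfinite(filled)] = meta.nodata_value
    attrs = _meta_to_attrs(meta, units, extra_attrs)
    if fmt == "geotiff":
        tifffile.imwrite(path, filled, description=json.dumps(attrs))
    elif fmt == "netcdf":
        da = xr.DataArray(filled, dims=("y", "x"), name="field")
        ds = xr.Dataset({"field": da})
        ds.attrs["meta_json"] = json.dumps(attrs)
        ds.to_netcdf(path, engine="scipy")
        ds.close()
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def read_field(path: str | os.PathLike) -> tuple[np.ndarray, GridMeta, str]:
    """Read a 2-D field written by :func:`write_field`.

    Returns (values with nodata as NaN, meta, units).
    """
    path = os.fspath(path)
    if path.endswith(".nc"):
        with xr.open_dataset(path, engine="scipy") as ds:
            attrs = json.loads(ds.attrs["meta_json"])
            vals = np.asarray(ds["field"].values, dtype=np.float64)
    else:
        with tifffile.TiffFile(path) as tf:
            attrs = json.loads(tf.pages[0].description)
            vals = np.asarray(tf.pages[0].asarray(), dtype=np.float64)
    meta = GridMeta(**attrs["grid_meta"])
    vals[vals == meta.nodata_value] = np.nan
    return vals, meta, attrs.get("units", "")


# ---------------------------------------------------------------------------
# cube I/O


def write_cube(cube: GridCube, path: str | os.PathLike,
               fmt: str | None = None, extra_attrs: dict | None = None) -> str:
    """Write a GridCube as NetCDF (preferred) or a multi-page TIFF."""
    path = os.fspath(path)
    if fmt is None:
        fmt = "netcdf" if path.endswith(".nc") else "geotiff"
    filled = cube.values.copy()
    filled[~cube.valid_mask] = cube.meta.nodata_value
    attrs = _meta_to_attrs(cube.meta, cube.units, extra_attrs)
    attrs["times"] = [list(t) for t in cube.times]
    if fmt == "netcdf":
        da = xr.DataArray(filled, dims=("time", "y", "x"), name="values")
        ds = xr.Dataset({"values": da})
        ds.attrs["meta_json"] = json.dumps(attrs)
        ds.to_netcdf(path, engine="scipy")
        ds.close()
    elif fmt == "geotiff":
        tifffile.imwrite(path, filled, description=json.dumps(attrs))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def read_cube_file(path: str | os.PathLike) -> GridCube:
    """Read a cube written by :func:`write_cube`."""
    path = os.fspath(path)
    if path.endswith(".nc"):
        with xr.open_dataset(path, engine="scipy") as ds:
            attrs = json.loads(ds.attrs["meta_json"])
            vals = np.asarray(ds["values"].values, dtype=np.float64)
    else:
        with tifffile.TiffFile(path) as tf:
            attrs = json.loads(tf.pages[0].description)
            vals = np.asarray(tf.asarray(), dtype=np.float64)
            if vals.ndim == 2:
                vals = vals[None]
    meta = GridMeta(**attrs["grid_meta"])
    mask = vals != meta.nodata_value
    vals = vals.copy()
    vals[~mask] = np.nan
    return GridCube(meta=meta, times=[tuple(t) for t in attrs["times"]],
                    values=np.where(mask, vals, 0.0), units=attrs.get("units", ""),
                    valid_mask=mask)


def read_cube(paths: list[str | os.PathLike] | str | os.PathLike,
              band_units: str = "") -> GridCube:
    """Assemble a monthly cube from per-month field files or one cube file.

    With a list of paths, each file must be a field written by
    :func:`write_field` whose ``extra_attrs`` carry ``year`` and ``month``;
    files are ordered by their time stamps and must form a gap-free monthly
    sequence on a single grid. A single path is read via
    :func:`read_cube_file`.
    """
    if isinstance(paths, (str, os.PathLike)):
        cube = read_cube_file(paths)
        if band_units:
            cube.units = band_units
        return cube
    records = []
    for p in paths:
        p = os.fspath(p)
        if p.endswith(".nc"):
            with xr.open_dataset(p, engine="scipy") as ds:
                attrs = json.loads(ds.attrs["meta_json"])
                vals = np.asarray(ds["field"].values, dtype=np.float64)
        else:
            with tifffile.TiffFile(p) as tf:
                attrs = json.loads(tf.pages[0].description)
                vals = np.asarray(tf.pages[0].asarray(), dtype=np.float64)
        if "year" not in attrs or "month" not in attrs:
            raise GridError(f"{p}: missing year/month metadata")
        records.append((int(attrs["year"]), int(attrs["month"]), p,
                        GridMeta(**attrs["grid_meta"]), vals))
    records.sort(key=lambda r: (r[0], r[1]))
    meta0 = records[0][3]
    for y, m, p, meta, _ in records:
        if meta != meta0:
            raise GridError(f"{p}: grid geometry mismatch against {records[0][2]}")
    times = [(y, m) for y, m, *_ in records]
    _check_times(times)
    stack = np.stack([r[4] for r in records])
    mask = stack != meta0.nodata_value
    stack = np.where(mask, stack, 0.0)
    return GridCube(meta=meta0, times=times, values=stack,
                    units=band_units, valid_mask=mask)


def write_monthly_fields(cube: GridCube, directory: str | os.PathLike,
                         prefix: str, fmt: str = "geotiff") -> list[str]:
    """Write one field file per month, suitable for :func:`read_cube`."""
    os.makedirs(directory, exist_ok=True)
    ext = ".nc" if fmt == "netcdf" else ".tif"
    out = []
    for i, (y, m) in enumerate(cube.times):
        vals = cube.values[i].copy()
        vals[~cube.valid_mask[i]] = np.nan
        path = os.path.join(directory, f"{prefix}_{y}{m:02d}{ext}")
        write_field(vals, cube.meta, path, fmt=fmt, units=cube.units,
                    extra_attrs={"year": y, "month": m})
        out.append(path)
    return out


# ---------------------------------------------------------------------------
# land cover and event-catalog I/O


def write_landcover(lc: LandCoverMap, path: str | os.PathLike,
                    fmt: str | None = None) -> str:
    vals = lc.classes.astype(np.float64)
    vals[lc.classes == 0] = np.nan
    return write_field(vals, lc.meta, path, fmt=fmt, units="class")


def read_landcover(path: str | os.PathLike) -> LandCoverMap:
    vals, meta, _ = read_field(path)
    classes = np.where(np.isfinite(vals), vals, 0).astype(np.int16)
    return LandCoverMap(meta=meta, classes=classes)


EVENT_COLUMNS = ["start_year", "start_month", "end_year", "end_month", "label"]


def read_event_catalog(path: str | os.PathLike) -> pd.DataFrame:
    """Read a drought-event catalog CSV (start/end year-month plus a label)."""
    df = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise GridError(f"event catalog missing columns: {missing}")
    return df[EVENT_COLUMNS]


def write_event_catalog(df: pd.DataFrame, path: str | os.PathLike) -> str:
    df[EVENT_COLUMNS].to_csv(path, index=False)
    return os.fspath(path)


def resample_field(values: np.ndarray, src: GridMeta, dst: GridMeta,
                   method: str = "nearest") -> np.ndarray:
    """Explicit nearest/bilinear resampling utility.

    Provided for pre-aligning external inputs; nothing in the pipeline calls
    it implicitly — mismatched grids are a hard error everywhere else.
    """
    from scipy.ndimage import map_coordinates

    rows = (dst.origin_y - (np.arange(dst.n_rows) + 0.5) * dst.cell_size)
    cols = (dst.origin_x + (np.arange(dst.n_cols) + 0.5) * dst.cell_size)
    src_r = (src.origin_y - rows) / src.cell_size - 0.5
    src_c = (cols - src.origin_x) / src.cell_size - 0.5
    rr, cc = np.meshgrid(src_r, src_c, indexing="ij")
    order = {"nearest": 0, "bilinear": 1}[method]
    return map_coordinates(np.asarray(values, dtype=np.float64), [rr, cc],
                           order=order, mode="nearest")
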