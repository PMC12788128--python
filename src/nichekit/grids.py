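"""Grid and raster primitives, file I/O, and alignment checks.

The exchange format is the ESRI ASCII grid (``.asc``), the dialect MaxEnt-style
suitability models read and write.  Arrays are stored with row 0 = the
northernmost row (the ESRI convention) and indexed ``(row, col)``, 0-based.
Geographic coordinates refer to cell centers when converting between indices
and lon/lat.  Cell membership uses half-open intervals [west, east) x
[south, north) so a point on a shared edge belongs to exactly one cell.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import shape as _shapely_shape
from shapely.geometry.base import BaseGeometry

logger = logging.getLogger("nichekit")

#: Default no-data sentinel for ASCII grids.
DEFAULT_NODATA = -9999.0

#: Tolerance (degrees) within which two grid specifications count as aligned.
ALIGN_TOL = 1e-9

#: Mean Earth radius in km (IUGG), used for all geodesic cell areas/distances.
EARTH_RADIUS_KM = 6371.0088


class FormatError(ValueError):
    """A file does not conform to its declared format."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular lon/lat grid (square cells, degrees)."""

    ncols: int
    nrows: int
    xll: float
    yll: float
    cellsize: float
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        if self.ncols < 1 or self.nrows < 1:
            raise ValueError("ncols and nrows must be >= 1")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be > 0")
        if not (-180.0 - 1e-9 <= self.xll and self.xll + self.ncols * self.cellsize <= 180.0 + 1e-9):
            raise ValueError("grid extent exceeds [-180, 180] longitude")
        if not (-90.0 - 1e-9 <= self.yll and self.yll + self.nrows * self.cellsize <= 90.0 + 1e-9):
            raise ValueError("grid extent exceeds [-90, 90] latitude")

    # -- geometry ---------------------------------------------------------
    @property
    def xur(self) -> float:
        return self.xll + self.ncols * self.cellsize

    @property
    def yur(self) -> float:
        return self.yll + self.nrows * self.cellsize

    def aligned(self, other: "GridSpec", tol: float = ALIGN_TOL) -> bool:
        """True iff the five geometry fields match within *tol* degrees."""
        return (
            self.ncols == other.ncols
            and self.nrows == other.nrows
            and abs(self.xll - other.xll) <= tol
            and abs(self.yll - other.yll) <= tol
            and abs(self.cellsize - other.cellsize) <= tol
        )

    def contains(self, lon, lat):
        """Vectorized point-in-extent test (half-open east/north edges)."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return (lon >= self.xll) & (lon < self.xur) & (lat >= self.yll) & (lat < self.yur)

    def cell_of(self, lon, lat):
        """(row, col) of the cell containing each point.

        Points must lie inside the extent; membership follows the half-open
        [west, east) x [south, north) convention.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.xll) / self.cellsize).astype(int)
        row_from_south = np.floor((lat - self.yll) / self.cellsize).astype(int)
        row = self.nrows - 1 - row_from_south
        if np.any((col < 0) | (col >= self.ncols) | (row < 0) | (row >= self.nrows)):
            raise ValueError("point outside grid extent")
        return row, col

    def cell_center(self, row, col):
        """(lon, lat) of cell centers for (row, col) indices."""
        row = np.asarray(row)
        col = np.asarray(col)
        lon = self.xll + (col + 0.5) * self.cellsize
        lat = self.yll + (self.nrows - row - 0.5) * self.cellsize
        return lon, lat

    def lon_centers(self) -> np.ndarray:
        return self.xll + (np.arange(self.ncols) + 0.5) * self.cellsize

    def lat_centers(self) -> np.ndarray:
        """Latitudes of row centers, row 0 = north."""
        return self.yur - (np.arange(self.nrows) + 0.5) * self.cellsize

    def cell_areas_by_row(self) -> np.ndarray:
        """Geodesic cell area (km^2) per row on the sphere.

        area = R^2 * dlam * (sin(phi_n) - sin(phi_s)) for the spherical
        rectangle spanned by one cell; constant along a row.
        """
        lat_n = np.deg2rad(self.yur - np.arange(self.nrows) * self.cellsize)
        lat_s = lat_n - np.deg2rad(self.cellsize)
        dlam = np.deg2rad(self.cellsize)
        return EARTH_RADIUS_KM**2 * dlam * (np.sin(lat_n) - np.sin(lat_s))

    def cell_area_grid(self) -> np.ndarray:
        """nrows x ncols array of geodesic cell areas (km^2)."""
        return np.repeat(self.cell_areas_by_row()[:, None], self.ncols, axis=1)


@dataclass
class Raster:
    """A single grid layer: values plus a no-data mask.

    ``values`` is float (nrows x ncols); masked cells hold the nodata
    sentinel and are excluded from every derived computation.
    """

    spec: GridSpec
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # True where nodata

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.spec.nrows, self.spec.ncols):
            raise ValueError(
                f"values shape {self.values.shape} does not match spec "
                f"({self.spec.nrows}, {self.spec.ncols})"
            )
        if self.mask is None:
            self.mask = self.values == self.spec.nodata
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape does not match values")
        self.values = np.where(self.mask, self.spec.nodata, self.values)

    @property
    def valid(self) -> np.ndarray:
        return ~self.mask

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid]

    def masked(self) -> np.ma.MaskedArray:
        return np.ma.masked_array(self.values, self.mask)

    def copy_with(self, values: np.ndarray, mask: np.ndarray | None = None) -> "Raster":
        return Raster(self.spec, values.copy(), self.mask.copy() if mask is None else mask)


# A continuous suitability surface is just a Raster whose valid values lie in
# [0, 1]; the alias documents intent at call sites.
SuitabilityRaster = Raster


@dataclass
class EnvStack:
    """Ordered, aligned collection of named environmental layers."""

    spec: GridSpec
    layers: dict[str, Raster]

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("EnvStack requires at least one layer")
        for name, layer in self.layers.items():
            if not layer.spec.aligned(self.spec):
                raise ValueError(f"layer {name!r} is not aligned to the stack grid")

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def __getitem__(self, name: str) -> Raster:
        return self.layers[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self.layers)

    def __len__(self) -> int:
        return len(self.layers)

    def valid_mask(self) -> np.ndarray:
        """Cells valid in every layer."""
        m = np.ones((self.spec.nrows, self.spec.ncols), dtype=bool)
        for layer in self.layers.values():
            m &= layer.valid
        return m

    def subset(self, names: Sequence[str]) -> "EnvStack":
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"variables not in stack: {missing}")
        return EnvStack(self.spec, {n: self.layers[n] for n in names})


@dataclass
class OccurrenceSet:
    """Species occurrence records (species, lon, lat[, elevation, source])."""

    frame: pd.DataFrame

    REQUIRED = ("species", "lon", "lat")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.frame.columns:
                raise ValueError(f"missing required column {col!r}")
        for col in ("elevation", "source"):
            if col not in self.frame.columns:
                self.frame[col] = np.nan if col == "elevation" else None
        bad_lon = ~self.frame["lon"].between(-180, 180)
        bad_lat = ~self.frame["lat"].between(-90, 90)
        bad = bad_lon | bad_lat
        if bad.any():
            rows = list(self.frame.index[bad])
            raise ValueError(f"coordinates out of range at rows {rows}")
        if (self.frame["species"].astype(str).str.len() == 0).any():
            raise ValueError("empty species name")
        self.frame = self.frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def species(self) -> list[str]:
        return list(dict.fromkeys(self.frame["species"]))

    def for_species(self, name: str) -> "OccurrenceSet":
        return OccurrenceSet(self.frame[self.frame["species"] == name].copy())

    def lonlat(self) -> tuple[np.ndarray, np.ndarray]:
        return self.frame["lon"].to_numpy(float), self.frame["lat"].to_numpy(float)


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------

_HEADER_KEYS = {"ncols", "nrows", "xllcorner", "xllcenter", "yllcorner", "yllcenter", "cellsize", "nodata_value"}


def read_ascii_grid(path: str | Path) -> Raster:
    """Read an ESRI ASCII grid.

    Header keys are accepted case-insensitively; both the ``xllcorner`` and
    ``xllcenter`` dialects are understood (centers are converted to corners).
    """
    path = Path(path)
    header: dict[str, float] = {}
    data_lines: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            parts = stripped.split()
            key = parts[0].lower()
            if not data_lines and key in _HEADER_KEYS:
                if len(parts) != 2:
                    raise FormatError(f"{path}: malformed header line {lineno}: {stripped!r}")
                try:
                    header[key] = float(parts[1])
                except ValueError as exc:
                    raise FormatError(f"{path}: malformed header line {lineno}: {stripped!r}") from exc
            else:
                data_lines.append(stripped)

    for req in ("ncols", "nrows", "cellsize"):
        if req not in header:
            raise FormatError(f"{path}: missing header field {req!r}")
    if "xllcorner" in header:
        xll = header["xllcorner"]
    elif "xllcenter" in header:
        xll = header["xllcenter"] - header["cellsize"] / 2.0
    else:
        raise FormatError(f"{path}: missing xllcorner/xllcenter")
    if "yllcorner" in header:
        yll = header["yllcorner"]
    elif "yllcenter" in header:
        yll = header["yllcenter"] - header["cellsize"] / 2.0
    else:
        raise FormatError(f"{path}: missing yllcorner/yllcenter")

    nodata = header.get("nodata_value", DEFAULT_NODATA)
    spec = GridSpec(
        ncols=int(header["ncols"]),
        nrows=int(header["nrows"]),
        xll=xll,
        yll=yll,
        cellsize=header["cellsize"],
        nodata=nodata,
    )
    try:
        flat = np.array(" ".join(data_lines).split(), dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric cell value") from exc
    if flat.size != spec.nrows * spec.ncols:
        raise FormatError(
            f"{path}: expected {spec.nrows * spec.ncols} cells, found {flat.size}"
        )
    values = flat.reshape(spec.nrows, spec.ncols)
    return Raster(spec, values, values == nodata)


def write_ascii_grid(raster: Raster, path: str | Path, precision: int = 6) -> None:
    """Write an ESRI ASCII grid (xllcorner convention, nodata as sentinel)."""
    spec = raster.spec
    path = Path(path)
    vals = np.where(raster.mask, spec.nodata, raster.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {spec.ncols}\n")
        fh.write(f"nrows {spec.nrows}\n")
        fh.write(f"xllcorner {spec.xll:.10g}\n")
        fh.write(f"yllcorner {spec.yll:.10g}\n")
        fh.write(f"cellsize {spec.cellsize:.10g}\n")
        fh.write(f"NODATA_value {spec.nodata:.{precision}f}\n")
        for row in vals:
            fh.write(" ".join(f"{v:.{precision}f}" for v in row) + "\n")


def read_env_stack(paths: Mapping[str, str | Path]) -> EnvStack:
    """Read a named set of .asc layers into an aligned stack."""
    layers = {name: read_ascii_grid(p) for name, p in paths.items()}
    first = next(iter(layers.values()))
    return EnvStack(first.spec, layers)


# ---------------------------------------------------------------------------
# Occurrence CSV I/O
# ---------------------------------------------------------------------------

def read_occurrences(path: str | Path) -> OccurrenceSet:
    """Read an occurrence CSV with columns species,lon,lat[,elevation,source].

    Rows with non-numeric or out-of-range coordinates are reported by row
    number (1-based, excluding the header) and rejected.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    frame.columns = [c.strip().lower() for c in frame.columns]
    missing = [c for c in OccurrenceSet.REQUIRED if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    lon = pd.to_numeric(frame["lon"], errors="coerce")
    lat = pd.to_numeric(frame["lat"], errors="coerce")
    bad = lon.isna() | lat.isna() | ~lon.between(-180, 180) | ~lat.between(-90, 90)
    if bad.any():
        rows = [int(i) + 1 for i in frame.index[bad]]
        raise FormatError(f"{path}: invalid coordinates at data row(s) {rows}")
    frame["lon"] = lon
    frame["lat"] = lat
    return OccurrenceSet(frame)


def write_occurrences(occ: OccurrenceSet, path: str | Path) -> None:
    occ.frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Polygon I/O (GeoJSON)
# ---------------------------------------------------------------------------

def read_polygons(path: str | Path) -> list[BaseGeometry]:
    """Read (multi)polygons from a GeoJSON file."""
    with open(path) as fh:
        doc = json.load(fh)
    geoms: list[BaseGeometry] = []
    if doc.get("type") == "FeatureCollection":
        for feat in doc.get("features", []):
            geoms.append(_shapely_shape(feat["geometry"]))
    elif doc.get("type") == "Feature":
        geoms.append(_shapely_shape(doc["geometry"]))
    else:
        geoms.append(_shapely_shape(doc))
    return geoms


def write_polygons(geoms: Sequence[BaseGeometry], path: str | Path) -> None:
    from shapely.geometry import mapping

    doc = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "properties": {}, "geometry": mapping(g)} for g in geoms
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def check_alignment(stack: EnvStack, raster: Raster) -> bool:
    """True iff *raster* shares the stack's grid geometry (within 1e-9 deg)."""
    return stack.spec.aligned(raster.spec)


def require_aligned(*rasters: Raster) -> None:
    """Raise if any pair of rasters is unaligned; no silent resampling."""
    first = rasters[0].spec
    for r in rasters[1:]:
        if not first.aligned(r.spec):
            raise ValueError("rasters are not aligned; resampling is not performed")
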