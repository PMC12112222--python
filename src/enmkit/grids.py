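"""Raster data model, ESRI ASCII grid I/O, and spherical geodesy.

All spatial computation in this package runs on :class:`Raster` objects —
single-band georeferenced grids in WGS84 geographic coordinates, with row 0
the northernmost row (ESRI convention) and a boolean validity mask. Stacks of
co-registered layers are held in a :class:`RasterStack`.

Geodesy is spherical: mean Earth radius 6371.0088 km for both great-circle
distances and latitude-corrected cell areas. The printed precision of the
area accounting this feeds (hundredths of 10^4 km^2) does not warrant an
ellipsoid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np

__all__ = [
    "EARTH_RADIUS_KM",
    "KM_PER_DEGREE",
    "GridHeader",
    "Raster",
    "RasterStack",
    "read_ascii_grid",
    "write_ascii_grid",
    "cell_area_km2",
    "haversine_km",
    "initial_bearing_deg",
]

#: Mean Earth radius (IUGG mean radius R1), km.
EARTH_RADIUS_KM = 6371.0088

#: Length of one degree of arc on the sphere, km.
KM_PER_DEGREE = EARTH_RADIUS_KM * math.pi / 180.0  # 111.19493 km/deg

DEFAULT_NODATA = -9999.0


class GridFormatError(ValueError):
    """Malformed ESRI ASCII grid header or body."""


class AlignmentError(ValueError):
    """Rasters do not share a common grid header."""


@dataclass(frozen=True)
class GridHeader:
    """Georeferencing of a regular lon/lat grid (corner registration).

    ``xll``/``yll`` are the west and south *edges* of the grid; center-
    registered files are converted on read.
    """

    ncols: int
    nrows: int
    xll: float
    yll: float
    cellsize: float
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        if self.ncols < 1 or self.nrows < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")
        if not (-180.0 - 1e-9 <= self.xll and self.xll + self.ncols * self.cellsize <= 180.0 + 1e-9):
            raise ValueError("grid extent outside [-180, 180] longitude")
        if not (-90.0 - 1e-9 <= self.yll and self.yll + self.nrows * self.cellsize <= 90.0 + 1e-9):
            raise ValueError("grid extent outside [-90, 90] latitude")

    # -- cell center <-> index maps (row 0 = northernmost row) ------------
    def lon_centers(self) -> np.ndarray:
        return self.xll + (np.arange(self.ncols) + 0.5) * self.cellsize

    def lat_centers(self) -> np.ndarray:
        """Latitude of each row center, row 0 first (north to south)."""
        top = self.yll + self.nrows * self.cellsize
        return top - (np.arange(self.nrows) + 0.5) * self.cellsize

    def rowcol_to_lonlat(self, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lon = self.xll + (np.asarray(col) + 0.5) * self.cellsize
        top = self.yll + self.nrows * self.cellsize
        lat = top - (np.asarray(row) + 0.5) * self.cellsize
        return lon, lat

    def lonlat_to_rowcol(self, lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        col = np.floor((np.asarray(lon) - self.xll) / self.cellsize).astype(int)
        top = self.yll + self.nrows * self.cellsize
        row = np.floor((top - np.asarray(lat)) / self.cellsize).astype(int)
        return row, col

    def contains(self, lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
        row, col = self.lonlat_to_rowcol(lon, lat)
        return (row >= 0) & (row < self.nrows) & (col >= 0) & (col < self.ncols)

    def approx_equal(self, other: "GridHeader", rtol: float = 1e-6) -> bool:
        return (
            self.ncols == other.ncols
            and self.nrows == other.nrows
            and math.isclose(self.xll, other.xll, rel_tol=rtol, abs_tol=1e-9)
            and math.isclose(self.yll, other.yll, rel_tol=rtol, abs_tol=1e-9)
            and math.isclose(self.cellsize, other.cellsize, rel_tol=rtol)
        )


@dataclass
class Raster:
    """A single-band grid: header + values + validity mask.

    ``values`` has shape ``(nrows, ncols)`` with row 0 the northernmost row.
    Masked (invalid / nodata) cells are excluded from every statistic.
    """

    header: GridHeader
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.header.nrows, self.header.ncols):
            raise ValueError(
                f"values shape {self.values.shape} != header "
                f"({self.header.nrows}, {self.header.ncols})"
            )
        if self.mask is None:
            self.mask = np.ones_like(self.values, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape differs from values shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]

    def with_values(self, values: np.ndarray, mask: np.ndarray | None = None) -> "Raster":
        return Raster(self.header, values, self.mask if mask is None else mask)

    def copy(self) -> "Raster":
        return Raster(self.header, self.values.copy(), self.mask.copy())

    def sample(self, lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
        """Values at point locations (NaN outside the grid or on masked cells)."""
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        out = np.full(lon.shape, np.nan)
        inside = self.header.contains(lon, lat)
        row, col = self.header.lonlat_to_rowcol(lon[inside], lat[inside])
        vals = self.values[row, col]
        vals[~self.mask[row, col]] = np.nan
        out[inside] = vals
        return out

    def cell_areas_km2(self) -> np.ndarray:
        """Latitude-corrected area of every cell, shape (nrows, ncols)."""
        lat = self.header.lat_centers()
        per_row = cell_area_km2(lat, self.header.cellsize)
        return np.broadcast_to(per_row[:, None], self.shape)


class RasterStack:
    """Named, ordered collection of co-registered rasters.

    The joint mask is the intersection of the layer masks; every multi-layer
    statistic runs over jointly valid cells only.
    """

    def __init__(self, layers: Mapping[str, Raster]):
        if not layers:
            raise ValueError("RasterStack needs at least one layer")
        items = list(layers.items())
        head = items[0][1].header
        for name, r in items[1:]:
            if not head.approx_equal(r.header):
                raise AlignmentError(f"layer {name!r} not aligned with {items[0][0]!r}")
        self._layers: dict[str, Raster] = dict(items)
        self.header = head

    @property
    def names(self) -> list[str]:
        return list(self._layers)

    def __len__(self) -> int:
        return len(self._layers)

    def __iter__(self) -> Iterator[str]:
        return iter(self._layers)

    def __getitem__(self, name: str) -> Raster:
        return self._layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self._layers

    def joint_mask(self) -> np.ndarray:
        m = np.ones((self.header.nrows, self.header.ncols), dtype=bool)
        for r in self._layers.values():
            m &= r.mask
        return m

    def values_at_cells(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """(n_cells, n_layers) matrix of layer values at the given cells."""
        return np.column_stack([self._layers[n].values[rows, cols] for n in self._layers])

    def subset(self, names: list[str]) -> "RasterStack":
        missing = [n for n in names if n not in self._layers]
        if missing:
            raise KeyError(f"layers not in stack: {missing}")
        return RasterStack({n: self._layers[n] for n in names})

    @classmethod
    def from_dir(cls, directory: str | Path, suffix: str = ".asc") -> "RasterStack":
        directory = Path(directory)
        paths = sorted(directory.glob(f"*{suffix}"))
        if not paths:
            raise FileNotFoundError(f"no {suffix} rasters in {directory}")
        return cls({p.stem: read_ascii_grid(p) for p in paths})

    def write_dir(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, r in self._layers.items():
            write_ascii_grid(r, directory / f"{name}.asc")


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------

_HEADER_KEYS = {"ncols", "nrows", "xllcorner", "xllcenter", "yllcorner", "yllcenter", "cellsize", "nodata_value"}


def read_ascii_grid(path: str | Path) -> Raster:
    """Read an ESRI ASCII grid (.asc).

    Accepts corner- or center-registered headers; center registration is
    converted to the canonical corner convention (subtract cellsize/2).
    Cells equal to the nodata sentinel (relative tolerance 1e-6) are masked.
    """
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS:
            key = parts[0].lower()
            try:
                header[key] = float(parts[1])
            except ValueError as exc:
                raise GridFormatError(f"{path}: bad header line {line.strip()!r}") from exc
            n_header += 1
        else:
            break
    for req in ("ncols", "nrows", "cellsize"):
        if req not in header:
            raise GridFormatError(f"{path}: missing header field {req!r}")
    if "xllcorner" in header:
        xll = header["xllcorner"]
    elif "xllcenter" in header:
        xll = header["xllcenter"] - header["cellsize"] / 2.0
    else:
        raise GridFormatError(f"{path}: missing xllcorner/xllcenter")
    if "yllcorner" in header:
        yll = header["yllcorner"]
    elif "yllcenter" in header:
        yll = header["yllcenter"] - header["cellsize"] / 2.0
    else:
        raise GridFormatError(f"{path}: missing yllcorner/yllcenter")
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])

    body = "".join(lines[n_header:])
    tokens = body.split()
    try:
        flat = np.fromiter(map(float, tokens), dtype=float, count=len(tokens))
    except ValueError as exc:
        raise GridFormatError(f"{path}: non-numeric value in grid body ({exc})") from exc
    if flat.size != nrows * ncols:
        raise GridFormatError(
            f"{path}: expected {nrows}x{ncols}={nrows * ncols} values, got {flat.size}"
        )
    values = flat.reshape(nrows, ncols)
    tol = 1e-6 * max(1.0, abs(nodata))
    mask = ~np.isclose(values, nodata, rtol=0, atol=tol)
    mask &= ~np.isnan(values)
    hdr = GridHeader(ncols=ncols, nrows=nrows, xll=xll, yll=yll, cellsize=header["cellsize"], nodata=nodata)
    return Raster(hdr, values, mask)


def write_ascii_grid(raster: Raster, path: str | Path, fmt: str = "%.10g") -> None:
    """Write a raster as a corner-registered ESRI ASCII grid.

    Masked cells are written as the header's nodata sentinel, so the file
    roundtrips through :func:`read_ascii_grid`.
    """
    h = raster.header
    out = raster.values.copy()
    out[~raster.mask] = h.nodata
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"ncols {h.ncols}\n")
        fh.write(f"nrows {h.nrows}\n")
        fh.write(f"xllcorner {h.xll:.10g}\n")
        fh.write(f"yllcorner {h.yll:.10g}\n")
        fh.write(f"cellsize {h.cellsize:.10g}\n")
        fh.write(f"NODATA_value {h.nodata:.10g}\n")
        np.savetxt(fh, out, fmt=fmt)


# ---------------------------------------------------------------------------
# Geodesy
# ---------------------------------------------------------------------------


def cell_area_km2(lat_center, cellsize: float):
    """Area of a cellsize x cellsize grid cell centered at ``lat_center``.

    area = (cellsize * K)^2 * cos(lat), K = 111.19493 km/degree on the
    mean-radius sphere. Vectorized over latitude.
    """
    lat = np.asarray(lat_center, dtype=float)
    if np.any(np.abs(lat) > 90.0):
        raise ValueError("latitude outside [-90, 90]")
    area = (cellsize * KM_PER_DEGREE) ** 2 * np.cos(np.radians(lat))
    return np.maximum(area, 0.0) if area.ndim else float(max(area, 0.0))


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km on the mean-radius sphere. Vectorized."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return float(d) if d.ndim == 0 else d


def initial_bearing_deg(lon1: float, lat1: float, lon2: float, lat2: float) -> float:
    """Initial great-circle azimuth from point 1 to point 2, degrees in [0, 360)."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dlon = math.radians(lon2 - lon1)
    y = math.sin(dlon) * math.cos(phi2)
    x = math.cos(phi1) * math.sin(phi2) - math.sin(phi1) * math.cos(phi2) * math.cos(dlon)
    return math.degrees(math.atan2(y, x)) % 360.0
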