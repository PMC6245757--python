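"""Geospatial and tabular I/O for the suitability pipeline.

All computation is done in geographic longitude/latitude on the WGS84
datum.  Rasters are regular lon/lat grids (row 0 = northernmost row)
read and written as ESRI ASCII grids; occurrence records are delimited
text with species/longitude/latitude columns; administrative regions
are GeoJSON polygons with a two-level continent -> country hierarchy.

Cell-ownership convention: a point (x, y) belongs to column
``floor((x - west) / dx)`` and row ``floor((north - y) / dy)`` — i.e.
cells are half-open on their east and south edges, so a point on a
shared edge belongs to the cell to its south-east.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape
from shapely.validation import make_valid

__all__ = [
    "RasterGrid",
    "VariableStack",
    "RegionSet",
    "AlignmentError",
    "read_occurrences",
    "write_occurrences",
    "extract_at_points",
    "align_check",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_regions",
    "write_regions",
]

logger = logging.getLogger("nichebox")
if not logger.handlers:  # log record counts to stderr by default
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(name)s: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

#: canonical ecological-factor names, in reporting order
DEFAULT_VARIABLES = (
    "T-aver",          # annual mean temperature, deg C
    "T-warm",          # mean temperature of warmest quarter, deg C
    "T-cold",          # mean temperature of coldest quarter, deg C
    "Precipitation",   # annual precipitation, mm
    "Radiation",       # annual radiation, W m^-2
    "Humidity",        # annual relative humidity, %
)

GEO_TOL = 1e-9  # degrees; geotransform agreement tolerance


class AlignmentError(ValueError):
    """Raised when rasters that must share a grid do not."""


@dataclass(frozen=True)
class RasterGrid:
    """A single-band regular lon/lat raster.

    Parameters
    ----------
    data : 2-D float array, row 0 is the northernmost row.
    west, north : coordinates of the grid's north-west corner, degrees.
    dx, dy : cell width and height, degrees (both > 0).
    nodata : sentinel marking missing cells.
    crs : coordinate-reference tag; geographic WGS84 throughout.
    """

    data: np.ndarray
    west: float
    north: float
    dx: float
    dy: float
    nodata: float = -9999.0
    crs: str = "EPSG:4326"

    def __post_init__(self):
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if not (self.dx > 0 and self.dy > 0):
            raise ValueError("cell width and height must be positive")
        object.__setattr__(self, "data", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def south(self) -> float:
        return self.north - self.shape[0] * self.dy

    @property
    def east(self) -> float:
        return self.west + self.shape[1] * self.dx

    def valid_mask(self) -> np.ndarray:
        return self.data != self.nodata

    def index_of(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates to (row, col) under the half-open convention."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.west) / self.dx).astype(int)
        row = np.floor((self.north - lat) / self.dy).astype(int)
        return row, col

    def contains(self, lon, lat) -> np.ndarray:
        row, col = self.index_of(lon, lat)
        nr, nc = self.shape
        return (row >= 0) & (row < nr) & (col >= 0) & (col < nc)

    def cell_center(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        lon = self.west + (np.asarray(col) + 0.5) * self.dx
        lat = self.north - (np.asarray(row) + 0.5) * self.dy
        return lon, lat

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays of cell-center longitudes (per column) and latitudes (per row)."""
        nr, nc = self.shape
        lons = self.west + (np.arange(nc) + 0.5) * self.dx
        lats = self.north - (np.arange(nr) + 0.5) * self.dy
        return lons, lats

    def same_grid(self, other: "RasterGrid", tol: float = GEO_TOL) -> bool:
        return (
            self.shape == other.shape
            and abs(self.west - other.west) <= tol
            and abs(self.north - other.north) <= tol
            and abs(self.dx - other.dx) <= tol
            and abs(self.dy - other.dy) <= tol
        )

    def with_data(self, data: np.ndarray) -> "RasterGrid":
        return replace(self, data=np.asarray(data, dtype=float))


@dataclass
class VariableStack:
    """Ordered set of co-registered single-variable rasters."""

    grids: dict[str, RasterGrid] = field(default_factory=dict)

    def __post_init__(self):
        names = list(self.grids)
        if len(set(names)) != len(names):
            raise ValueError("variable names must be unique")
        ref = None
        for name, g in self.grids.items():
            if ref is None:
                ref = g
            elif not g.same_grid(ref):
                raise AlignmentError(f"layer {name!r} is not co-registered")

    @property
    def variables(self) -> list[str]:
        return list(self.grids)

    @property
    def reference(self) -> RasterGrid:
        return next(iter(self.grids.values()))

    def valid_mask(self) -> np.ndarray:
        """Cells valid in every layer."""
        m = np.ones(self.reference.shape, dtype=bool)
        for g in self.grids.values():
            m &= g.valid_mask()
        return m

    def cell_matrix(self, mask: np.ndarray | None = None) -> np.ndarray:
        """(n_cells, n_variables) matrix of the cells selected by *mask*."""
        if mask is None:
            mask = self.valid_mask()
        return np.column_stack([g.data[mask] for g in self.grids.values()])


@dataclass
class RegionSet:
    """Named polygons with a continent -> country hierarchy.

    Each entry is ``(name, level, parent, geometry)`` where *level* is
    ``"continent"`` or ``"country"`` and *parent* names the continent a
    country belongs to (``None`` for continents).
    """

    entries: list[tuple] = field(default_factory=list)

    def __post_init__(self):
        per_level: dict[str, set] = {}
        fixed = []
        for name, level, parent, geom in self.entries:
            seen = per_level.setdefault(level, set())
            if name in seen:
                raise ValueError(f"duplicate region name {name!r} at level {level!r}")
            seen.add(name)
            if not geom.is_valid:
                geom = make_valid(geom)
            fixed.append((name, level, parent, geom))
        self.entries = fixed

    def at_level(self, level: str) -> list[tuple]:
        return [e for e in self.entries if e[1] == level]

    @property
    def names(self) -> list[str]:
        return [e[0] for e in self.entries]


# ---------------------------------------------------------------------------
# occurrences

def read_occurrences(path, dedup: bool = True) -> pd.DataFrame:
    """Read an occurrence table (columns species, longitude, latitude[, source]).

    Out-of-range coordinates are rejected with their row number logged;
    with ``dedup`` on, exact duplicate (species, lon, lat) triples are
    dropped keeping the first.  Per-species counts go to the log.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("species", "longitude", "latitude"):
        if col not in df.columns:
            raise ValueError(f"occurrence file missing required column {col!r}")
    lon = pd.to_numeric(df["longitude"], errors="coerce")
    lat = pd.to_numeric(df["latitude"], errors="coerce")
    bad = lon.isna() | lat.isna() | (lon < -180) | (lon > 180) | (lat < -90) | (lat > 90)
    for idx in df.index[bad]:
        logger.info("rejected occurrence row %d: coordinate out of range", idx)
    df = df.loc[~bad].copy()
    df["longitude"] = lon[~bad]
    df["latitude"] = lat[~bad]
    if dedup:
        before = len(df)
        df = df.drop_duplicates(subset=["species", "longitude", "latitude"], keep="first")
        if len(df) < before:
            logger.info("deduplicated %d replicate records", before - len(df))
    counts = df["species"].value_counts()
    for sp, n in counts.items():
        logger.info("species %s: %d records", sp, n)
    logger.info("total records: %d", len(df))
    return df.reset_index(drop=True)


def write_occurrences(df: pd.DataFrame, path) -> None:
    cols = [c for c in ("species", "longitude", "latitude", "source") if c in df.columns]
    df.to_csv(path, columns=cols, index=False)


def thin_one_per_cell(df: pd.DataFrame, grid: RasterGrid) -> pd.DataFrame:
    """Optional cell-level thinning: keep one record per species per cell."""
    row, col = grid.index_of(df["longitude"].to_numpy(), df["latitude"].to_numpy())
    key = pd.DataFrame({"species": df["species"], "row": row, "col": col})
    keep = ~key.duplicated()
    return df.loc[keep].reset_index(drop=True)


def extract_at_points(stack: VariableStack, occ: pd.DataFrame) -> pd.DataFrame:
    """Sample every stack variable at each occurrence record's cell.

    Returns a frame with one column per variable plus a boolean ``valid``
    column; rows falling outside the raster extent or on a nodata cell in
    any variable are flagged invalid (and counted in the log) so callers
    can exclude them from modelling.
    """
    lon = occ["longitude"].to_numpy(dtype=float)
    lat = occ["latitude"].to_numpy(dtype=float)
    ref = stack.reference
    row, col = ref.index_of(lon, lat)
    inside = (row >= 0) & (row < ref.shape[0]) & (col >= 0) & (col < ref.shape[1])
    out = pd.DataFrame(index=occ.index)
    valid = inside.copy()
    r = np.clip(row, 0, ref.shape[0] - 1)
    c = np.clip(col, 0, ref.shape[1] - 1)
    for name, g in stack.grids.items():
        vals = g.data[r, c]
        hit_nodata = vals == g.nodata
        valid &= ~hit_nodata
        vals = np.where(inside & ~hit_nodata, vals, np.nan)
        out[name] = vals
    out["valid"] = valid
    n_out = int((~inside).sum())
    n_nod = int((inside & ~valid).sum())
    if n_out:
        logger.info("%d records outside raster extent (excluded)", n_out)
    if n_nod:
        logger.info("%d records on nodata cells (excluded)", n_nod)
    return out


def align_check(stack: VariableStack, *rasters: RasterGrid, names=None) -> None:
    """Verify extra rasters share the stack's grid; raise AlignmentError if not."""
    ref = stack.reference
    names = list(names) if names else [f"raster {i}" for i in range(len(rasters))]
    for label, g in zip(names, rasters):
        if not g.same_grid(ref):
            raise AlignmentError(f"layer {label!r} does not match the climate grid")


# ---------------------------------------------------------------------------
# ESRI ASCII grid raster dialect (square cells)

def write_ascii_grid(grid: RasterGrid, path) -> None:
    if abs(grid.dx - grid.dy) > GEO_TOL:
        raise ValueError("ESRI ASCII grids require square cells")
    nr, nc = grid.shape
    header = (
        f"NCOLS {nc}\nNROWS {nr}\n"
        f"XLLCORNER {grid.west!r}\nYLLCORNER {grid.south!r}\n"
        f"CELLSIZE {grid.dx!r}\nNODATA_VALUE {grid.nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, grid.data.astype(np.float32), fmt="%.9g")


def read_ascii_grid(path, crs: str = "EPSG:4326") -> RasterGrid:
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        data = np.loadtxt(fh, dtype=float)
    nr, nc = int(header["nrows"]), int(header["ncols"])
    data = data.reshape(nr, nc)
    cell = header["cellsize"]
    return RasterGrid(
        data=data,
        west=header["xllcorner"],
        north=header["yllcorner"] + nr * cell,
        dx=cell,
        dy=cell,
        nodata=header.get("nodata_value", -9999.0),
        crs=crs,
    )


# ---------------------------------------------------------------------------
# regions as GeoJSON

def write_regions(regions: RegionSet, path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"name": name, "level": level, "parent": parent},
            "geometry": mapping(geom),
        }
        for name, level, parent, geom in regions.entries
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_regions(path) -> RegionSet:
    with open(path) as fh:
        fc = json.load(fh)
    entries = []
    for feat in fc["features"]:
        props = feat.get("properties", {})
        entries.append(
            (
                props.get("name"),
                props.get("level", "country"),
                props.get("parent"),
                shape(feat["geometry"]),
            )
        )
    return RegionSet(entries)
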