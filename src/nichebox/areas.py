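"""Suitable-area accounting on the sphere.

Binary suitability masks live on a geographic lon/lat grid, so cell
areas vary with latitude.  Each cell's exact spherical area is

    A = R^2 * d_lambda * (sin phi_north - sin phi_south)

with R = 6371.0088 km (the IUGG mean Earth radius) and the longitudes
and latitudes in radians; the area is constant along a grid row.  A
suitable cell is attributed to the administrative region containing its
centre; country rows aggregate into continents, and cells whose centre
falls in no region (open ocean in real data) are reported under
"unassigned".  Areas are reported both in km^2 and in units of
10^5 km^2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from shapely import STRtree
from shapely.geometry import Point

from .geo_io import RasterGrid, RegionSet

__all__ = ["EARTH_RADIUS_KM", "cell_area", "row_areas", "area_by_region"]

EARTH_RADIUS_KM = 6371.0088


def cell_area(row: int, grid: RasterGrid) -> float:
    """Exact spherical area (km^2) of any cell in the given grid row."""
    if not 0 <= row < grid.shape[0]:
        raise IndexError(f"row {row} outside grid of {grid.shape[0]} rows")
    phi_n = np.deg2rad(grid.north - row * grid.dy)
    phi_s = np.deg2rad(grid.north - (row + 1) * grid.dy)
    dlam = np.deg2rad(grid.dx)
    return float(EARTH_RADIUS_KM**2 * dlam * (np.sin(phi_n) - np.sin(phi_s)))


def row_areas(grid: RasterGrid) -> np.ndarray:
    """Vector of per-row cell areas (km^2)."""
    rows = np.arange(grid.shape[0])
    phi_n = np.deg2rad(grid.north - rows * grid.dy)
    phi_s = np.deg2rad(grid.north - (rows + 1) * grid.dy)
    return EARTH_RADIUS_KM**2 * np.deg2rad(grid.dx) * (np.sin(phi_n) - np.sin(phi_s))


def area_by_region(mask: np.ndarray, grid: RasterGrid, regions: RegionSet,
                   species: str = "species") -> pd.DataFrame:
    """Per-region suitable-area table from a binary mask.

    Returns rows (species, region, level, area_km2, area_1e5km2)
    covering every country and continent plus an "unassigned" row and a
    species-level "Global" total; the global total equals the continent
    sum plus unassigned exactly.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid.shape:
        raise ValueError("mask shape must match the grid")
    per_row = row_areas(grid)
    rows_idx, cols_idx = np.nonzero(mask)
    areas = per_row[rows_idx]
    lon, lat = grid.cell_center(rows_idx, cols_idx)

    countries = regions.at_level("country")
    country_area: dict[str, float] = {name: 0.0 for name, *_ in countries}
    parent_of = {name: parent for name, _, parent, _ in countries}
    unassigned = 0.0
    if len(rows_idx):
        tree = STRtree([geom for *_, geom in countries])
        pts = [Point(x, y) for x, y in zip(lon, lat)]
        hits = tree.query(pts, predicate="within")
        assigned = np.zeros(len(pts), dtype=bool)
        seen = set()
        for pi, gi in zip(*hits):
            key = int(pi)
            if key in seen:      # centre on a shared border: first region wins
                continue
            seen.add(key)
            assigned[key] = True
            country_area[countries[gi][0]] += areas[key]
        unassigned = float(areas[~assigned].sum())

    continent_area: dict[str, float] = {}
    for name, area in country_area.items():
        parent = parent_of.get(name)
        if parent is not None:
            continent_area[parent] = continent_area.get(parent, 0.0) + area
    for name, *_ in regions.at_level("continent"):
        continent_area.setdefault(name, 0.0)

    records = []
    for name, area in country_area.items():
        records.append((species, name, "country", area))
    for name, area in continent_area.items():
        records.append((species, name, "continent", area))
    records.append((species, "unassigned", "unassigned", unassigned))
    total = sum(continent_area.values()) + unassigned
    records.append((species, "Global", "global", total))
    df = pd.DataFrame(records, columns=["species", "region", "level", "area_km2"])
    df["area_1e5km2"] = df["area_km2"] / 1e5
    return df
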