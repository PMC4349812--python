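"""Dual-resolution spatial frame and great-circle distances.

Two grids cover the study region (53-56 S, 34-45 W): coarse 0.5 deg latitude
by 1 deg longitude boxes for seasonal abundance maps, and 10 x 10 km squares
(under a local equirectangular projection) for catch-rate and depredation
analysis.  The region is additionally partitioned into five named fishing
areas.  All binning uses half-open [low, high) intervals with ties to the
larger-index side; the outer region edge is closed so the grids tile the
whole region.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .records import REGION_LAT, REGION_LON

__all__ = [
    "EARTH_RADIUS_KM",
    "Resolution",
    "CellId",
    "GridSpec",
    "Area",
    "AreaScheme",
    "DEFAULT_GRID",
    "DEFAULT_AREAS",
    "OutsideRegionError",
    "haversine_km",
    "assign_halfdeg_box",
    "assign_km_cell",
    "assign_area",
    "project_xy",
    "unproject_xy",
    "km_cell_centroid",
    "km_cell_bounds",
]

EARTH_RADIUS_KM = 6371.0
#: Kilometres per degree of latitude / of longitude at the equator
#: (equirectangular plate-carree constants).
KM_PER_DEG_LAT = 110.574
KM_PER_DEG_LON_EQ = 111.320


class OutsideRegionError(ValueError):
    """Point falls outside the configured region bounds."""


class Resolution(enum.Enum):
    HALFDEG = "halfdeg"
    KM10 = "km10"


@dataclass(frozen=True, order=True)
class CellId:
    """Integer row/column index of a grid cell at one of the two resolutions."""

    resolution: Resolution
    i: int  # row (latitude axis)
    j: int  # column (longitude axis)


@dataclass(frozen=True)
class GridSpec:
    """Geometry of both grids plus the projection origin for the km grid.

    The local equirectangular projection
    ``x = (lon - lon0) * 111.320 * cos(lat0)``, ``y = (lat - lat0) * 110.574``
    (kilometres) is adequate here because the latitudinal span is only 3
    degrees, keeping scale distortion under ~2%.
    """

    lat_min: float = REGION_LAT[0]
    lat_max: float = REGION_LAT[1]
    lon_min: float = REGION_LON[0]
    lon_max: float = REGION_LON[1]
    box_dlat: float = 0.5
    box_dlon: float = 1.0
    km_cell_size: float = 10.0
    origin_lat: float = -54.5
    origin_lon: float = -39.5

    def __post_init__(self) -> None:
        if self.km_cell_size <= 0:
            raise ValueError("km_cell_size must be positive")
        if not (self.lat_min <= self.origin_lat <= self.lat_max):
            raise ValueError("projection origin latitude outside region")
        if not (self.lon_min <= self.origin_lon <= self.lon_max):
            raise ValueError("projection origin longitude outside region")

    @property
    def n_box_rows(self) -> int:
        return round((self.lat_max - self.lat_min) / self.box_dlat)

    @property
    def n_box_cols(self) -> int:
        return round((self.lon_max - self.lon_min) / self.box_dlon)

    def in_region(self, lat: float, lon: float) -> bool:
        return (
            self.lat_min <= lat <= self.lat_max
            and self.lon_min <= lon <= self.lon_max
        )


DEFAULT_GRID = GridSpec()


def _check_coords(lat, lon) -> None:
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.any(np.abs(lat) > 90.0) or np.any(np.abs(lon) > 180.0):
        raise ValueError("latitude must be in [-90, 90], longitude in [-180, 180]")


def haversine_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Great-circle distance in km between two (lat, lon) points.

    Accepts scalars or numpy arrays in either argument (broadcasting).
    Spherical Earth, radius 6371.0 km.
    """
    lat1, lon1 = a
    lat2, lon2 = b
    _check_coords(lat1, lon1)
    _check_coords(lat2, lon2)
    phi1, lam1, phi2, lam2 = (
        np.radians(np.asarray(v, dtype=float)) for v in (lat1, lon1, lat2, lon2)
    )
    s = (
        np.sin((phi2 - phi1) / 2.0) ** 2
        + np.cos(phi1) * np.cos(phi2) * np.sin((lam2 - lam1) / 2.0) ** 2
    )
    out = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(s, 0.0, 1.0)))
    return float(out) if np.ndim(out) == 0 else out


def _bin_index(value: float, low: float, width: float, n: int) -> int:
    # half-open [low, high) bins, ties to the larger index; the outer region
    # edge (value == low + n*width) is closed into the last cell
    idx = math.floor((value - low) / width)
    return min(idx, n - 1)


def assign_halfdeg_box(
    lat: float, lon: float, grid: GridSpec = DEFAULT_GRID, *, strict: bool = True
) -> CellId | None:
    """Assign a point to its 0.5 deg x 1 deg box.

    Out-of-region points raise :class:`OutsideRegionError` when ``strict``,
    otherwise return ``None`` as an "outside" sentinel.
    """
    if not grid.in_region(lat, lon):
        if strict:
            raise OutsideRegionError(f"point ({lat}, {lon}) outside region")
        return None
    i = _bin_index(lat, grid.lat_min, grid.box_dlat, grid.n_box_rows)
    j = _bin_index(lon, grid.lon_min, grid.box_dlon, grid.n_box_cols)
    return CellId(Resolution.HALFDEG, i, j)


def project_xy(lat, lon, grid: GridSpec = DEFAULT_GRID):
    """Local equirectangular forward projection to kilometres east/north of
    the grid origin. Vectorised."""
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    x = (lon - grid.origin_lon) * KM_PER_DEG_LON_EQ * math.cos(
        math.radians(grid.origin_lat)
    )
    y = (lat - grid.origin_lat) * KM_PER_DEG_LAT
    return x, y


def unproject_xy(x, y, grid: GridSpec = DEFAULT_GRID):
    """Inverse of :func:`project_xy`."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lon = grid.origin_lon + x / (
        KM_PER_DEG_LON_EQ * math.cos(math.radians(grid.origin_lat))
    )
    lat = grid.origin_lat + y / KM_PER_DEG_LAT
    return lat, lon


def assign_km_cell(
    lat: float, lon: float, grid: GridSpec = DEFAULT_GRID, *, strict: bool = True
) -> CellId | None:
    """Assign a point to its 10 x 10 km square (indices relative to the
    projection origin, so they may be negative)."""
    if not grid.in_region(lat, lon):
        if strict:
            raise OutsideRegionError(f"point ({lat}, {lon}) outside region")
        return None
    x, y = project_xy(lat, lon, grid)
    return CellId(
        Resolution.KM10,
        math.floor(float(y) / grid.km_cell_size),
        math.floor(float(x) / grid.km_cell_size),
    )


def km_cell_centroid(cell: CellId, grid: GridSpec = DEFAULT_GRID) -> tuple[float, float]:
    """(lat, lon) of the centre of a 10 km cell."""
    if cell.resolution is not Resolution.KM10:
        raise ValueError("centroid defined for KM10 cells only")
    x = (cell.j + 0.5) * grid.km_cell_size
    y = (cell.i + 0.5) * grid.km_cell_size
    lat, lon = unproject_xy(x, y, grid)
    return float(lat), float(lon)


def km_cell_bounds(
    cell: CellId, grid: GridSpec = DEFAULT_GRID
) -> tuple[float, float, float, float]:
    """(lat_min, lat_max, lon_min, lon_max) rectangle of a 10 km cell, for
    exporting hot spots as mappable intervals."""
    if cell.resolution is not Resolution.KM10:
        raise ValueError("bounds defined for KM10 cells only")
    lat0, lon0 = unproject_xy(cell.j * grid.km_cell_size, cell.i * grid.km_cell_size, grid)
    lat1, lon1 = unproject_xy(
        (cell.j + 1) * grid.km_cell_size, (cell.i + 1) * grid.km_cell_size, grid
    )
    return float(lat0), float(lat1), float(lon0), float(lon1)


class Area(enum.Enum):
    """The five named fishing areas around South Georgia."""

    SHAG_ROCKS = "shag_rocks"
    NORTH_WEST = "north_west"
    NORTH_EAST = "north_east"
    SOUTH_WEST = "south_west"
    SOUTH_EAST = "south_east"


@dataclass(frozen=True)
class AreaScheme:
    """Boundary rules partitioning the region into the five areas.

    Shag Rocks is everything west of ``shag_rocks_lon_max``; the remainder is
    split north/south at ``ns_split_lat`` and west/east at ``we_split_lon``.
    Boundary ties go to the larger-coordinate side (north / east), matching
    the half-open binning convention.  These boundaries are a configurable
    approximation to the published area layout, which is shown on a map but
    never listed as coordinates.
    """

    shag_rocks_lon_max: float = -40.0
    ns_split_lat: float = -54.4
    we_split_lon: float = -36.5


DEFAULT_AREAS = AreaScheme()


def assign_area(
    lat: float,
    lon: float,
    scheme: AreaScheme = DEFAULT_AREAS,
    grid: GridSpec = DEFAULT_GRID,
) -> Area:
    """Map an in-region point to exactly one named area."""
    if not grid.in_region(lat, lon):
        raise OutsideRegionError(f"point ({lat}, {lon}) outside region")
    if lon < scheme.shag_rocks_lon_max:
        return Area.SHAG_ROCKS
    north = lat >= scheme.ns_split_lat
    east = lon >= scheme.we_split_lon
    if north:
        return Area.NORTH_EAST if east else Area.NORTH_WEST
    return Area.SOUTH_EAST if east else Area.SOUTH_WEST
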