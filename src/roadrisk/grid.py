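"""Geographic grid and raster-from-vector operations.

The analysis lattice is a north-up grid of square (in degrees) cells, 5
arc-minutes by default — the resolution of the global road-density layers the
method was designed around.  Row 0 is the northern edge, indices are 0-based,
and each cell covers the half-open box ``[west, east) × (south, north]`` so
every point of the extent belongs to exactly one cell (points on the extent's
outer south/east edge are clamped into the boundary cells).

Raster layers are thin wrappers around a ``GridSpec`` plus a numpy array:

* :class:`BinaryLayer` — 0/1 presence (rasterized species ranges, PAs)
* :class:`DensityLayer` — road density, metres of road per km² of cell
* :class:`AreaLayer` — spherical cell area in km²
* :class:`CountLayer` — species richness counts

Raster I/O uses the plain-text ESRI ASCII grid format (georeferencing in the
header, one row of values per line), readable by GDAL, R and QGIS.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import shapely
from shapely.geometry.base import BaseGeometry

from .geodesy import (
    EARTH_RADIUS_KM,
    crosses_antimeridian,
    path_length_km,
    spherical_band_area_km2,
)


class GridError(ValueError):
    """Invalid grid definition or misaligned extent."""


class AlignmentError(GridError):
    """Layers or extents that do not share the same grid."""


class GeometryError(ValueError):
    """Invalid or unsupported input geometry."""


class AntimeridianError(GeometryError):
    """Geometry crosses the ±180° meridian, which this pipeline rejects."""


_SNAP_TOL = 1e-9


@dataclass(frozen=True)
class GridSpec:
    """A north-up geographic lattice of square cells.

    Parameters
    ----------
    resolution_arcmin:
        Angular cell size in arc-minutes (default 5).
    west, south, east, north:
        Extent in decimal degrees; width and height must be exact integer
        multiples of the resolution.
    """

    resolution_arcmin: float = 5.0
    west: float = -180.0
    south: float = -90.0
    east: float = 180.0
    north: float = 90.0
    n_rows: int = field(init=False)
    n_cols: int = field(init=False)

    def __post_init__(self):
        if self.resolution_arcmin <= 0:
            raise GridError(f"resolution must be positive, got {self.resolution_arcmin}")
        if not (-180.0 <= self.west < self.east <= 180.0):
            raise GridError(f"invalid longitude extent [{self.west}, {self.east}]")
        if not (-90.0 <= self.south < self.north <= 90.0):
            raise GridError(f"invalid latitude extent [{self.south}, {self.north}]")
        res = self.resolution_deg
        for name, span in (("width", self.east - self.west), ("height", self.north - self.south)):
            n = span / res
            if abs(n - round(n)) > _SNAP_TOL * max(1.0, abs(n)):
                raise AlignmentError(
                    f"extent {name} {span}° is not an integer multiple of {res}° cells"
                )
        object.__setattr__(self, "n_cols", int(round((self.east - self.west) / res)))
        object.__setattr__(self, "n_rows", int(round((self.north - self.south) / res)))

    @property
    def resolution_deg(self) -> float:
        return self.resolution_arcmin / 60.0

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    # --- closed-form cell geometry -------------------------------------

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(lon, lat) of the center of cell (row, col)."""
        res = self.resolution_deg
        return (self.west + (col + 0.5) * res, self.north - (row + 0.5) * res)

    def cell_bounds(self, row: int, col: int) -> tuple[float, float, float, float]:
        """(west, south, east, north) of cell (row, col)."""
        res = self.resolution_deg
        return (
            self.west + col * res,
            self.north - (row + 1) * res,
            self.west + (col + 1) * res,
            self.north - row * res,
        )

    def lon_centers(self) -> np.ndarray:
        res = self.resolution_deg
        return self.west + (np.arange(self.n_cols) + 0.5) * res

    def lat_centers(self) -> np.ndarray:
        res = self.resolution_deg
        return self.north - (np.arange(self.n_rows) + 0.5) * res

    def index_of(self, lon: float, lat: float) -> tuple[int, int]:
        """Cell (row, col) containing a point, half-open convention, edges clamped."""
        if not (self.west <= lon <= self.east and self.south <= lat <= self.north):
            raise GridError(f"point ({lon}, {lat}) outside grid extent")
        res = self.resolution_deg
        col = min(int(math.floor((lon - self.west) / res)), self.n_cols - 1)
        row_f = (self.north - lat) / res
        if lat >= self.north:
            row = 0
        else:
            row = min(int(math.floor(row_f)), self.n_rows - 1)
            # top edge of a cell belongs to that cell: (south, north] rows
            if abs(row_f - round(row_f)) < _SNAP_TOL and round(row_f) > 0 and lat < self.north:
                row = int(round(row_f))
                row = min(row, self.n_rows - 1)
        return row, col

    def contains(self, lon: float, lat: float) -> bool:
        return self.west <= lon <= self.east and self.south <= lat <= self.north


def make_grid(resolution_arcmin: float = 5.0, extent: Sequence[float] | None = None) -> GridSpec:
    """Build a :class:`GridSpec`; ``extent`` is (west, south, east, north), default global."""
    if extent is None:
        extent = (-180.0, -90.0, 180.0, 90.0)
    w, s, e, n = map(float, extent)
    return GridSpec(resolution_arcmin=float(resolution_arcmin), west=w, south=s, east=e, north=n)


# ---------------------------------------------------------------------------
# Layer containers
# ---------------------------------------------------------------------------


def _check_shape(grid: GridSpec, values: np.ndarray) -> np.ndarray:
    values = np.asarray(values)
    if values.shape != grid.shape:
        raise AlignmentError(f"values shape {values.shape} != grid shape {grid.shape}")
    return values


def _check_same_grid(a: GridSpec, b: GridSpec) -> None:
    if a != b:
        raise AlignmentError("layers are defined on different grids")


@dataclass
class BinaryLayer:
    grid: GridSpec
    values: np.ndarray  # uint8, 0/1

    def __post_init__(self):
        v = _check_shape(self.grid, self.values)
        if not np.isin(v, (0, 1)).all():
            raise ValueError("BinaryLayer values must be 0 or 1")
        self.values = v.astype(np.uint8)


@dataclass
class DensityLayer:
    """Road density layer, metres of road per km² of cell; NaN marks nodata."""

    grid: GridSpec
    values: np.ndarray

    def __post_init__(self):
        v = _check_shape(self.grid, self.values).astype(float)
        if np.any(v[~np.isnan(v)] < 0):
            raise ValueError("road density cannot be negative")
        self.values = v


@dataclass
class AreaLayer:
    grid: GridSpec
    values: np.ndarray  # km², all > 0

    def __post_init__(self):
        v = _check_shape(self.grid, self.values).astype(float)
        if np.any(v <= 0):
            raise ValueError("cell areas must be positive")
        self.values = v


@dataclass
class CountLayer:
    grid: GridSpec
    values: np.ndarray  # nonnegative integers

    def __post_init__(self):
        v = _check_shape(self.grid, self.values)
        if np.any(v < 0):
            raise ValueError("counts must be nonnegative")
        self.values = v.astype(np.int32)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def cell_areas(grid: GridSpec) -> AreaLayer:
    """Spherical surface area of every cell, km².

    Constant along rows; computed per row with the exact spherical-quadrangle
    formula on the authalic sphere (R = 6371.0072 km).
    """
    res = grid.resolution_deg
    row_area = np.empty(grid.n_rows)
    for r in range(grid.n_rows):
        north = grid.north - r * res
        row_area[r] = spherical_band_area_km2(north - res, north, res)
    values = np.repeat(row_area[:, None], grid.n_cols, axis=1)
    return AreaLayer(grid, values)


def _as_polygons(polygons) -> list[BaseGeometry]:
    if isinstance(polygons, BaseGeometry):
        polygons = [polygons]
    geoms = []
    for g in polygons:
        if g.is_empty:
            continue
        if not g.is_valid:
            g = shapely.make_valid(g)
            if not g.is_valid or g.is_empty:
                raise GeometryError("unrepairable invalid polygon in input")
        if g.geom_type not in ("Polygon", "MultiPolygon", "GeometryCollection"):
            raise GeometryError(f"expected polygonal geometry, got {g.geom_type}")
        geoms.append(g)
    return geoms


def rasterize_presence(
    polygons, grid: GridSpec, *, mode: str = "center", coverage_threshold: float = 0.5
) -> BinaryLayer:
    """Rasterize polygons to a 0/1 presence layer.

    ``mode='center'`` (default): a cell is present iff its center lies inside
    or on the boundary of the polygon union — deterministic and matching a
    point-in-polygon oracle.  ``mode='coverage'``: present iff the fraction of
    the cell's lon/lat box covered is ≥ ``coverage_threshold``.
    """
    geoms = _as_polygons(polygons)
    values = np.zeros(grid.shape, dtype=np.uint8)
    if not geoms:
        warnings.warn("empty polygon set: presence layer is all zero", stacklevel=2)
        return BinaryLayer(grid, values)
    union = shapely.union_all(geoms)
    if crosses_antimeridian(np.asarray([[b, 0] for b in union.bounds[::2]])):
        raise AntimeridianError("polygon spans the antimeridian")

    res = grid.resolution_deg
    minx, miny, maxx, maxy = union.bounds
    c0 = max(0, int(math.floor((minx - grid.west) / res)) - 1)
    c1 = min(grid.n_cols, int(math.ceil((maxx - grid.west) / res)) + 1)
    r0 = max(0, int(math.floor((grid.north - maxy) / res)) - 1)
    r1 = min(grid.n_rows, int(math.ceil((grid.north - miny) / res)) + 1)
    if c0 >= c1 or r0 >= r1:
        return BinaryLayer(grid, values)

    if mode == "center":
        lons = grid.lon_centers()[c0:c1]
        lats = grid.lat_centers()[r0:r1]
        gx, gy = np.meshgrid(lons, lats)
        pts = shapely.points(gx.ravel(), gy.ravel())
        shapely.prepare(union)
        inside = shapely.covers(union, pts).reshape(gy.shape)
        values[r0:r1, c0:c1] = inside.astype(np.uint8)
    elif mode == "coverage":
        shapely.prepare(union)
        for r in range(r0, r1):
            for c in range(c0, c1):
                cell = shapely.box(*grid.cell_bounds(r, c))
                frac = union.intersection(cell).area / cell.area
                values[r, c] = 1 if frac >= coverage_threshold else 0
    else:
        raise ValueError(f"unknown rasterization mode {mode!r}")
    return BinaryLayer(grid, values)


def _iter_line_coords(polylines) -> Iterable[np.ndarray]:
    """Yield (n,2) lon/lat coordinate arrays from lines / geometries / sequences."""
    if isinstance(polylines, BaseGeometry):
        polylines = [polylines]
    for item in polylines:
        if isinstance(item, BaseGeometry):
            if item.is_empty:
                continue
            if item.geom_type == "LineString":
                yield np.asarray(item.coords, dtype=float)
            elif item.geom_type in ("MultiLineString", "GeometryCollection"):
                yield from _iter_line_coords(list(item.geoms))
            else:
                raise GeometryError(f"expected line geometry, got {item.geom_type}")
        else:
            arr = np.asarray(item, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2:
                raise GeometryError("line coordinates must be an (n, 2) lon/lat array")
            yield arr


def split_line_by_cells(coords, grid: GridSpec):
    """Split a lon/lat polyline exactly at cell boundaries.

    Yields ``(row, col, piece)`` where ``piece`` is a (2, 2) lon/lat segment
    lying inside a single cell (assigned by its midpoint under the half-open
    cell convention).  Splitting is exact linear interpolation in lon/lat.
    """
    coords = np.asarray(coords, dtype=float)
    if crosses_antimeridian(coords):
        raise AntimeridianError("polyline crosses the antimeridian; split it upstream")
    res = grid.resolution_deg
    for (x0, y0), (x1, y1) in zip(coords[:-1], coords[1:]):
        if x0 == x1 and y0 == y1:
            continue
        ts = [0.0, 1.0]
        if x1 != x0:
            k0 = math.ceil((min(x0, x1) - grid.west) / res)
            k1 = math.floor((max(x0, x1) - grid.west) / res)
            for k in range(k0, k1 + 1):
                t = (grid.west + k * res - x0) / (x1 - x0)
                if 1e-12 < t < 1 - 1e-12:
                    ts.append(t)
        if y1 != y0:
            k0 = math.ceil((min(y0, y1) - grid.south) / res)
            k1 = math.floor((max(y0, y1) - grid.south) / res)
            for k in range(k0, k1 + 1):
                t = (grid.south + k * res - y0) / (y1 - y0)
                if 1e-12 < t < 1 - 1e-12:
                    ts.append(t)
        ts = sorted(set(ts))
        for ta, tb in zip(ts[:-1], ts[1:]):
            pa = (x0 + ta * (x1 - x0), y0 + ta * (y1 - y0))
            pb = (x0 + tb * (x1 - x0), y0 + tb * (y1 - y0))
            mx, my = (pa[0] + pb[0]) / 2.0, (pa[1] + pb[1]) / 2.0
            if not grid.contains(mx, my):
                continue
            row, col = grid.index_of(mx, my)
            yield row, col, np.array([pa, pb])


def line_lengths_by_cell(polylines, grid: GridSpec) -> np.ndarray:
    """Great-circle length (km) of line parts falling in each cell."""
    lengths = np.zeros(grid.shape)
    for coords in _iter_line_coords(polylines):
        for row, col, piece in split_line_by_cells(coords, grid):
            lengths[row, col] += path_length_km(piece)
    return lengths


def line_density(polylines, grid: GridSpec, areas: AreaLayer) -> DensityLayer:
    """Per-cell road density in m/km²: geodesic line length (m) / cell area (km²)."""
    _check_same_grid(grid, areas.grid)
    lengths_km = line_lengths_by_cell(polylines, grid)
    return DensityLayer(grid, lengths_km * 1000.0 / areas.values)


def aggregate_road_types(density_layers: Sequence[DensityLayer]) -> DensityLayer:
    """Cellwise sum of road-type density layers, nodata-aware.

    A nodata (NaN) cell counts as 0 when any sibling layer has data there; it
    stays nodata only where every layer is nodata.  Pass only the road types
    to be analysed (the source data's type 5, local roads, is excluded
    upstream because of its spatial reporting bias).
    """
    if not density_layers:
        raise ValueError("need at least one density layer")
    grid = density_layers[0].grid
    stack = []
    for layer in density_layers:
        _check_same_grid(grid, layer.grid)
        stack.append(layer.values)
    stack = np.stack(stack)
    all_nodata = np.isnan(stack).all(axis=0)
    total = np.nansum(stack, axis=0)
    total[all_nodata] = np.nan
    return DensityLayer(grid, total)


def richness(presence_layers: Sequence[BinaryLayer]) -> CountLayer:
    """Species richness: cellwise sum of presence flags across layers."""
    if not presence_layers:
        # an empty overlay is a valid degenerate richness map
        raise ValueError("need at least one presence layer (use a zero layer explicitly)")
    grid = presence_layers[0].grid
    total = np.zeros(grid.shape, dtype=np.int32)
    for layer in presence_layers:
        _check_same_grid(grid, layer.grid)
        total += layer.values
    return CountLayer(grid, total)


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O (plain-text raster interchange)
# ---------------------------------------------------------------------------

_NODATA = -9999.0


def write_ascii_grid(path, grid: GridSpec, values: np.ndarray) -> None:
    values = _check_shape(grid, values).astype(float)
    out = np.where(np.isnan(values), _NODATA, values)
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.west!r}\n"
        f"yllcorner {grid.south!r}\n"
        f"cellsize {grid.resolution_deg!r}\n"
        f"NODATA_value {_NODATA:g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for row in out:
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


def read_ascii_grid(path) -> tuple[GridSpec, np.ndarray]:
    """Read an ESRI ASCII grid; returns (GridSpec, float array with NaN nodata)."""
    path = Path(path)
    header: dict[str, float] = {}
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0].lower() in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append(np.array(parts, dtype=float))
    n_cols, n_rows = int(header["ncols"]), int(header["nrows"])
    res_deg = header["cellsize"]
    west, south = header["xllcorner"], header["yllcorner"]
    grid = GridSpec(
        resolution_arcmin=res_deg * 60.0,
        west=west,
        south=south,
        east=west + n_cols * res_deg,
        north=south + n_rows * res_deg,
    )
    values = np.vstack(rows)
    if values.shape != grid.shape:
        raise AlignmentError(f"raster body {values.shape} does not match header {grid.shape}")
    nodata = header.get("nodata_value")
    if nodata is not None:
        values = np.where(values == nodata, np.nan, values)
    return grid, values
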