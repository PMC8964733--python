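"""Modelling grid, environmental layer stacks and native-region masks.

Everything downstream (occurrence filtering, maxent fitting, evaluation)
works on a single regular latitude/longitude grid, typically 0.5 degrees
(30 arc minutes, roughly 56 km at the equator).  Cells are addressed by
``(row, col)`` with row 0 at the southern edge.  A point belongs to the
cell whose half-open interval ``[edge, edge + cell_size)`` contains it;
points exactly on the global east/north boundary fall into the last cell.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import xarray as xr
from shapely.geometry import Point, shape
from shapely.geometry.base import BaseGeometry
from shapely.prepared import prep

__all__ = [
    "GridSpec",
    "EnvStack",
    "RegionMask",
    "rasterize_regions",
    "aggregate_mean",
    "aggregate_fractions",
    "polygons_from_geojson",
]


@dataclass(frozen=True)
class GridSpec:
    """A regular unprojected lat/lon grid.

    Parameters
    ----------
    lon_min, lat_min:
        Coordinates of the south-west corner of the grid, in degrees.
    n_cols, n_rows:
        Grid dimensions.
    cell_size:
        Cell edge length in degrees; 0.5 corresponds to 30 arc minutes.
    """

    lon_min: float
    lat_min: float
    n_cols: int
    n_rows: int
    cell_size: float = 0.5

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("grid must have at least one row and column")
        if not (-180.0 <= self.lon_min and self.lon_max <= 180.0):
            raise ValueError("grid longitudes outside [-180, 180]")
        if not (-90.0 <= self.lat_min and self.lat_max <= 90.0):
            raise ValueError("grid latitudes outside [-90, 90]")

    @property
    def lon_max(self) -> float:
        return self.lon_min + self.n_cols * self.cell_size

    @property
    def lat_max(self) -> float:
        return self.lat_min + self.n_rows * self.cell_size

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def lon_centers(self) -> np.ndarray:
        cs = self.cell_size
        return self.lon_min + cs * (np.arange(self.n_cols) + 0.5)

    @property
    def lat_centers(self) -> np.ndarray:
        cs = self.cell_size
        return self.lat_min + cs * (np.arange(self.n_rows) + 0.5)

    def cell_of(self, lon, lat):
        """Map points to ``(row, col)`` using the half-open convention.

        Points on the east/north outer boundary are assigned to the last
        column/row.  Points outside the grid get index -1.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.lon_min) / self.cell_size).astype(int)
        row = np.floor((lat - self.lat_min) / self.cell_size).astype(int)
        # outer boundary belongs to the last cell
        col = np.where((lon == self.lon_max) & (col == self.n_cols), self.n_cols - 1, col)
        row = np.where((lat == self.lat_max) & (row == self.n_rows), self.n_rows - 1, row)
        outside = (col < 0) | (col >= self.n_cols) | (row < 0) | (row >= self.n_rows)
        col = np.where(outside, -1, col)
        row = np.where(outside, -1, row)
        return row, col

    def cell_bounds(self, row: int, col: int) -> tuple[float, float, float, float]:
        """(lon_min, lat_min, lon_max, lat_max) of one cell."""
        cs = self.cell_size
        return (
            self.lon_min + col * cs,
            self.lat_min + row * cs,
            self.lon_min + (col + 1) * cs,
            self.lat_min + (row + 1) * cs,
        )


def _check_grid_match(a: GridSpec, b: GridSpec) -> None:
    if a != b:
        raise ValueError("grids do not match")


@dataclass
class EnvStack:
    """Named environmental layers sharing one :class:`GridSpec`.

    ``layers`` maps a variable code (e.g. ``CHELSA_BIO1`` for annual mean
    temperature or ``X120_ESA_CCI`` for shrubland fraction) to a
    ``(n_rows, n_cols)`` float array.  NaN marks missing cells.
    """

    grid: GridSpec
    layers: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for code, arr in self.layers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != self.grid.shape:
                raise ValueError(f"layer {code!r} shape {arr.shape} != grid {self.grid.shape}")
            self.layers[code] = arr

    @property
    def variables(self) -> list[str]:
        return list(self.layers)

    def values_at(self, variables, rows, cols) -> np.ndarray:
        """Stack layer values at cells into an (n_cells, n_vars) matrix."""
        return np.column_stack([self.layers[v][rows, cols] for v in variables])

    def to_dataset(self) -> xr.Dataset:
        coords = {"lat": self.grid.lat_centers, "lon": self.grid.lon_centers}
        data = {code: (("lat", "lon"), arr) for code, arr in self.layers.items()}
        ds = xr.Dataset(data, coords=coords)
        ds.attrs["cell_size"] = self.grid.cell_size
        return ds

    def to_netcdf(self, path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "EnvStack":
        grid = grid_from_coords(ds["lon"].values, ds["lat"].values)
        layers = {str(k): np.asarray(ds[k].values, dtype=float) for k in ds.data_vars}
        return cls(grid=grid, layers=layers)

    @classmethod
    def from_netcdf(cls, path) -> "EnvStack":
        with xr.open_dataset(path, engine="scipy") as ds:
            return cls.from_dataset(ds.load())


def grid_from_coords(lon_centers: np.ndarray, lat_centers: np.ndarray) -> GridSpec:
    """Reconstruct a GridSpec from evenly spaced cell-center coordinates."""
    lon = np.asarray(lon_centers, dtype=float)
    lat = np.asarray(lat_centers, dtype=float)
    if lon.size < 1 or lat.size < 1:
        raise ValueError("empty coordinate axes")
    cs = float(lon[1] - lon[0]) if lon.size > 1 else (
        float(lat[1] - lat[0]) if lat.size > 1 else 0.5)
    return GridSpec(
        lon_min=float(lon[0] - cs / 2),
        lat_min=float(lat[0] - cs / 2),
        n_cols=lon.size,
        n_rows=lat.size,
        cell_size=cs,
    )


@dataclass
class RegionMask:
    """Boolean membership layer marking cells inside a species' native regions."""

    grid: GridSpec
    member: np.ndarray

    def __post_init__(self) -> None:
        self.member = np.asarray(self.member, dtype=bool)
        if self.member.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")
        if not self.member.any():
            raise ValueError("empty native region")

    @property
    def n_cells(self) -> int:
        return int(self.member.sum())

    def cells(self) -> tuple[np.ndarray, np.ndarray]:
        """(rows, cols) of member cells in row-major order."""
        rows, cols = np.nonzero(self.member)
        return rows, cols

    def contains(self, lon, lat) -> np.ndarray:
        row, col = self.grid.cell_of(lon, lat)
        inside = (row >= 0) & (col >= 0)
        out = np.zeros(np.shape(row), dtype=bool)
        out[inside] = self.member[row[inside], col[inside]]
        return out

    def bounding_box(self) -> tuple[float, float, float, float]:
        """(lon_min, lat_min, lon_max, lat_max) over member cell edges."""
        rows, cols = self.cells()
        cs = self.grid.cell_size
        return (
            self.grid.lon_min + cols.min() * cs,
            self.grid.lat_min + rows.min() * cs,
            self.grid.lon_min + (cols.max() + 1) * cs,
            self.grid.lat_min + (rows.max() + 1) * cs,
        )


def polygons_from_geojson(source) -> list[BaseGeometry]:
    """Read polygons from a GeoJSON file path, string, or parsed dict."""
    if isinstance(source, dict):
        gj = source
    elif isinstance(source, str) and source.lstrip().startswith("{"):
        gj = json.loads(source)
    else:
        with open(source) as fh:
            gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        geoms = [shape(f["geometry"]) for f in gj["features"]]
    elif gj.get("type") == "Feature":
        geoms = [shape(gj["geometry"])]
    else:
        geoms = [shape(gj)]
    return geoms


def rasterize_regions(polygons, grid: GridSpec) -> RegionMask:
    """Rasterize native-region polygons onto the modelling grid.

    A cell is a member iff its center lies inside (or on the boundary of)
    any polygon — the common center-containment rule; fractional coverage
    is not considered.

    Parameters
    ----------
    polygons:
        Iterable of shapely geometries (lat/lon, degrees).
    grid:
        Target grid.

    Raises
    ------
    ValueError
        If no polygons are given or no cell center falls inside any polygon.
    """
    polygons = list(polygons)
    if not polygons:
        raise ValueError("empty polygon set")
    member = np.zeros(grid.shape, dtype=bool)
    lons = grid.lon_centers
    lats = grid.lat_centers
    for poly in polygons:
        if poly.is_empty:
            continue
        prepared = prep(poly)
        minx, miny, maxx, maxy = poly.bounds
        c0 = max(0, int(np.floor((minx - lons[0]) / grid.cell_size)))
        c1 = min(grid.n_cols - 1, int(np.ceil((maxx - lons[0]) / grid.cell_size)))
        r0 = max(0, int(np.floor((miny - lats[0]) / grid.cell_size)))
        r1 = min(grid.n_rows - 1, int(np.ceil((maxy - lats[0]) / grid.cell_size)))
        for r in range(r0, r1 + 1):
            for c in range(c0, c1 + 1):
                if not member[r, c] and prepared.intersects(Point(lons[c], lats[r])):
                    member[r, c] = True
    if not member.any():
        raise ValueError("empty native region: polygons cover no cell center")
    return RegionMask(grid=grid, member=member)


def mask_to_polygons(mask: RegionMask) -> list[BaseGeometry]:
    """Outline each member cell as its bounding box polygon (round-trip aid)."""
    from shapely.geometry import box

    rows, cols = mask.cells()
    return [box(*mask.grid.cell_bounds(int(r), int(c))) for r, c in zip(rows, cols)]


def _aggregation_factor(fine_shape: tuple[int, int], grid: GridSpec, fine_cell_size: float) -> int:
    factor = grid.cell_size / fine_cell_size
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(
            f"grid cell_size {grid.cell_size} is not an integer multiple of fine resolution {fine_cell_size}"
        )
    factor = int(round(factor))
    if fine_shape != (grid.n_rows * factor, grid.n_cols * factor):
        raise ValueError("fine raster shape inconsistent with grid and resolution")
    return factor


def aggregate_mean(fine_layer: np.ndarray, grid: GridSpec, fine_cell_size: float) -> np.ndarray:
    """Aggregate a fine raster to the modelling grid by block averaging.

    Missing fine cells (NaN) are ignored; a coarse cell whose block is
    entirely missing becomes NaN.
    """
    fine = np.asarray(fine_layer, dtype=float)
    f = _aggregation_factor(fine.shape, grid, fine_cell_size)
    blocks = fine.reshape(grid.n_rows, f, grid.n_cols, f)
    with np.errstate(invalid="ignore"):
        out = np.nanmean(blocks, axis=(1, 3))
    return out


def aggregate_fractions(
    fine_classes: np.ndarray, class_id: int, grid: GridSpec, fine_cell_size: float
) -> np.ndarray:
    """Fraction of fine cells equal to ``class_id`` within each coarse cell.

    Mirrors building a binary presence/absence raster for one land-cover
    class and averaging it to the modelling resolution, so each output
    value is the proportion of the coarse cell covered by that class.
    """
    fine = np.asarray(fine_classes)
    present = np.unique(fine[~_isnan_safe(fine)])
    if class_id not in present:
        raise ValueError(f"unknown class_id {class_id!r}: classes present are {present.tolist()}")
    indicator = (fine == class_id).astype(float)
    indicator[_isnan_safe(fine)] = np.nan
    return aggregate_mean(indicator, grid, fine_cell_size)


def _isnan_safe(arr: np.ndarray) -> np.ndarray:
    if np.issubdtype(arr.dtype, np.floating):
        return np.isnan(arr)
    return np.zeros(arr.shape, dtype=bool)
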