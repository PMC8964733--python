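"""Occurrence filtering into the three data types, per-cell counts, Moran's I.

Presence-only archives mix precise recent records with legacy, flagged or
duplicated ones.  The cleaning cascade produces *raw data* (quality +
temporal + native-region filtering + exact dedup); collapsing within-cell
duplicates gives *presence cells*; spatial thinning of presence cells to a
minimum pairwise distance gives *thinned data*.  The three levels trade
pseudo-replication against information loss and each feeds its own model
downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import GridSpec, RegionMask

__all__ = [
    "OccurrenceSet",
    "filter_records",
    "count_per_cell",
    "to_presence_cells",
    "thin",
    "morans_index",
    "haversine_km",
]

EARTH_KM_PER_DEGREE = 111.32  # equatorial great-circle length of one degree
COORD_DECIMALS = 6  # dedup key rounds coordinates to 1e-6 degrees


@dataclass
class OccurrenceSet:
    """A species' records at one filter level, with per-cell bookkeeping.

    ``records`` keeps columns decimalLongitude / decimalLatitude / year
    plus the (row, col) cell assignment.  ``cells`` lists occupied cells
    (row-major order of first appearance); ``counts`` gives raw record
    counts per occupied cell.  For ``presence_cells`` and ``thinned``
    kinds there is exactly one record per cell.
    """

    kind: str
    records: pd.DataFrame
    grid: GridSpec
    cells: list[tuple[int, int]] = field(default_factory=list)
    counts: dict[tuple[int, int], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("raw", "presence_cells", "thinned"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.kind in ("presence_cells", "thinned") and len(self.records) != len(self.cells):
            raise ValueError(f"{self.kind} requires one record per cell")

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def cell_rows_cols(self) -> tuple[np.ndarray, np.ndarray]:
        if not self.cells:
            return np.array([], dtype=int), np.array([], dtype=int)
        arr = np.array(self.cells, dtype=int)
        return arr[:, 0], arr[:, 1]


def _attach_cells(df: pd.DataFrame, grid: GridSpec) -> pd.DataFrame:
    row, col = grid.cell_of(df["decimalLongitude"].values, df["decimalLatitude"].values)
    df = df.copy()
    df["_row"] = row
    df["_col"] = col
    return df


def _occupied(df: pd.DataFrame) -> tuple[list[tuple[int, int]], dict[tuple[int, int], int]]:
    cells: list[tuple[int, int]] = []
    counts: dict[tuple[int, int], int] = {}
    for r, c in zip(df["_row"].values, df["_col"].values):
        key = (int(r), int(c))
        if key not in counts:
            cells.append(key)
            counts[key] = 0
        counts[key] += 1
    return cells, counts


def filter_records(
    table: pd.DataFrame,
    native: RegionMask,
    year_lo: int = 2000,
    year_hi: int = 2020,
    min_recent: int = 25,
) -> OccurrenceSet:
    """Clean a raw occurrence table into the *raw data* set.

    Steps, in order: (1) drop records with missing coordinates or any
    quality flag; (2) count records dated within [year_lo, year_hi] — if
    at least ``min_recent`` the temporal filter applies (records outside
    the window, including undated ones, are dropped), otherwise all years
    are kept so sparse species retain their historical records; (3) drop
    records outside the native region; (4) drop exact duplicates of
    (longitude, latitude, year) after rounding coordinates to 1e-6 deg.
    """
    if native is None:
        raise ValueError("native mask required")
    df = table.copy()
    if df.empty:
        empty = df.assign(_row=pd.Series(dtype=int), _col=pd.Series(dtype=int))
        return OccurrenceSet(kind="raw", records=empty, grid=native.grid)
    lon = pd.to_numeric(df["decimalLongitude"], errors="coerce")
    lat = pd.to_numeric(df["decimalLatitude"], errors="coerce")
    ok = lon.notna() & lat.notna()
    if "flags" in df.columns:
        flagged = df["flags"].apply(lambda f: bool(f) and not (isinstance(f, float) and np.isnan(f)))
        ok &= ~flagged
    df = df[ok]
    year = pd.to_numeric(df.get("year"), errors="coerce")
    recent = year.between(year_lo, year_hi)
    if int(recent.sum()) >= min_recent:
        df = df[recent]
    inside = native.contains(
        df["decimalLongitude"].astype(float).values, df["decimalLatitude"].astype(float).values
    )
    df = df[inside]
    key_lon = df["decimalLongitude"].astype(float).round(COORD_DECIMALS)
    key_lat = df["decimalLatitude"].astype(float).round(COORD_DECIMALS)
    key_year = pd.to_numeric(df.get("year"), errors="coerce")
    dup = pd.DataFrame({"lon": key_lon, "lat": key_lat, "year": key_year}).duplicated()
    df = df[~dup.values].reset_index(drop=True)
    df = _attach_cells(df, native.grid)
    cells, counts = _occupied(df)
    return OccurrenceSet(kind="raw", records=df, grid=native.grid, cells=cells, counts=counts)


def count_per_cell(raw: OccurrenceSet, grid: GridSpec | None = None) -> np.ndarray:
    """Integer layer of raw records per cell; sums to the record count."""
    if raw.kind != "raw":
        raise ValueError("count_per_cell expects the raw data set")
    grid = grid or raw.grid
    out = np.zeros(grid.shape, dtype=int)
    for (r, c), n in raw.counts.items():
        out[r, c] = n
    return out


def to_presence_cells(raw: OccurrenceSet) -> OccurrenceSet:
    """Collapse within-cell duplicates, keeping each cell's first record."""
    if raw.kind != "raw":
        raise ValueError("to_presence_cells expects the raw data set")
    seen: set[tuple[int, int]] = set()
    keep_idx = []
    for i, (r, c) in enumerate(zip(raw.records["_row"].values, raw.records["_col"].values)):
        key = (int(r), int(c))
        if key not in seen:
            seen.add(key)
            keep_idx.append(i)
    df = raw.records.iloc[keep_idx].reset_index(drop=True)
    cells = [(int(r), int(c)) for r, c in zip(df["_row"].values, df["_col"].values)]
    return OccurrenceSet(
        kind="presence_cells",
        records=df,
        grid=raw.grid,
        cells=cells,
        counts={cell: 1 for cell in cells},
    )


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km between (lon, lat) points in degrees."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * 6371.0088 * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def thin(
    presence_cells: OccurrenceSet,
    min_dist_cells: float = 2.0,
    reps: int = 10,
    seed: int = 0,
) -> OccurrenceSet:
    """Spatially thin presence cells to a minimum pairwise distance.

    The distance threshold is ``min_dist_cells * cell_size * 111.32 km``
    (great-circle, anchored to the equatorial width of a cell; two 0.5
    degree cells give roughly 111.32 km).  Each of ``reps`` randomized
    greedy runs repeatedly deletes the point with the most remaining
    conflicts (ties broken at random) until no pair violates the
    threshold; the run retaining the most points wins.  Deterministic for
    a given seed.
    """
    if presence_cells.kind != "presence_cells":
        raise ValueError("thin expects the presence-cells set")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    df = presence_cells.records
    n = len(df)
    threshold_km = min_dist_cells * presence_cells.grid.cell_size * EARTH_KM_PER_DEGREE
    if n <= 1 or min_dist_cells <= 0:
        return OccurrenceSet(
            kind="thinned",
            records=df.copy(),
            grid=presence_cells.grid,
            cells=list(presence_cells.cells),
            counts={cell: 1 for cell in presence_cells.cells},
        )
    lon = df["decimalLongitude"].astype(float).values
    lat = df["decimalLatitude"].astype(float).values
    dist = haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
    conflict = dist < threshold_km
    np.fill_diagonal(conflict, False)
    rng = np.random.default_rng(seed)
    best_keep: np.ndarray | None = None
    for _ in range(reps):
        keep = np.ones(n, dtype=bool)
        degree = conflict.sum(axis=1).astype(float)
        while True:
            active = degree > 0
            if not (keep & active).any():
                break
            cand = np.where(keep & active)[0]
            maxdeg = degree[cand].max()
            top = cand[degree[cand] == maxdeg]
            drop = int(rng.choice(top))
            keep[drop] = False
            neighbors = conflict[drop] & keep
            degree[neighbors] -= 1
            degree[drop] = 0
        if best_keep is None or keep.sum() > best_keep.sum():
            best_keep = keep
    idx = np.where(best_keep)[0]
    out = df.iloc[idx].reset_index(drop=True)
    cells = [(int(r), int(c)) for r, c in zip(out["_row"].values, out["_col"].values)]
    return OccurrenceSet(
        kind="thinned",
        records=out,
        grid=presence_cells.grid,
        cells=cells,
        counts={cell: 1 for cell in cells},
    )


def morans_index(counts: np.ndarray, native: RegionMask) -> float:
    """Global Moran's I of per-cell counts over the native region.

    Uses binary queen-contiguity weights (8 neighbours) among native
    cells, zero-count native cells included, no row standardization:
    ``I = (N / W) * sum_ij w_ij (x_i - m)(x_j - m) / sum_i (x_i - m)^2``.
    Raises for a constant field, where the index is undefined.
    """
    counts = np.asarray(counts, dtype=float)
    rows, cols = native.cells()
    x = counts[rows, cols]
    n = len(x)
    if n < 2:
        raise ValueError("Moran's I needs at least 2 native cells")
    dev = x - x.mean()
    denom = (dev**2).sum()
    if denom == 0:
        raise ValueError("Moran undefined for constant field")
    index_of = {(int(r), int(c)): i for i, (r, c) in enumerate(zip(rows, cols))}
    num = 0.0
    w_sum = 0.0
    for i, (r, c) in enumerate(zip(rows, cols)):
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                j = index_of.get((int(r) + dr, int(c) + dc))
                if j is not None:
                    num += dev[i] * dev[j]
                    w_sum += 1.0
    if w_sum == 0:
        raise ValueError("no contiguous native cells: Moran's I undefined")
    return float((n / w_sum) * num / denom)
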