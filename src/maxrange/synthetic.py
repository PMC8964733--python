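"""Seeded synthetic worlds: environments, native regions, species and references.

These generators stand in for the real inputs of a large-scale range
estimation run — bioclim-style climate layers, land-cover fraction layers,
botanical-country native regions, presence-only occurrence records and
expert-drawn reference ranges — so the entire pipeline can be exercised
end-to-end with a known true niche.  All generators are pure functions of
their parameters and a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .grid import EnvStack, GridSpec, RegionMask

__all__ = [
    "NicheSpec",
    "SyntheticWorld",
    "make_environment",
    "make_native_region",
    "make_bias_layer",
    "make_world",
    "simulate_species",
    "make_reference_range",
    "CONTAMINANT_TYPES",
]

CONTAMINANT_TYPES = ("missing_coords", "old_year", "outside_native", "duplicate")


@dataclass(frozen=True)
class NicheSpec:
    """A known true niche: logistic response to a few environmental variables.

    Suitability at a cell with variable values ``x`` is
    ``sigmoid(intercept + sum(beta * x) + sum(gamma * x**2))`` which is
    strictly inside (0, 1) everywhere.
    """

    active_variables: tuple[str, ...]
    linear: tuple[float, ...]
    quadratic: tuple[float, ...]
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if len(self.active_variables) < 1:
            raise ValueError("niche needs at least one active variable")
        if len(self.linear) != len(self.active_variables) or len(self.quadratic) != len(
            self.active_variables
        ):
            raise ValueError("coefficient lengths must match active_variables")

    def suitability(self, env: EnvStack) -> np.ndarray:
        eta = np.full(env.grid.shape, self.intercept, dtype=float)
        for var, b, g in zip(self.active_variables, self.linear, self.quadratic):
            x = env.layers[var]
            eta = eta + b * x + g * x**2
        return expit(eta)


@dataclass
class SyntheticWorld:
    """Everything needed to test range estimation against a known truth."""

    env: EnvStack
    native: RegionMask
    niche: NicheSpec
    true_suitability: np.ndarray
    seed: int
    bias_layer: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.true_suitability = np.asarray(self.true_suitability, dtype=float)
        if self.true_suitability.shape != self.env.grid.shape:
            raise ValueError("true_suitability shape mismatch")
        ts = self.true_suitability[self.native.member]
        if np.isnan(ts).any():
            raise ValueError("true_suitability undefined on some native cells")

    def to_files(self, nc_path, json_path) -> None:
        ds = self.env.to_dataset()
        ds["native"] = (("lat", "lon"), self.native.member.astype(np.int8))
        ds["true_suitability"] = (("lat", "lon"), self.true_suitability)
        if self.bias_layer is not None:
            ds["bias"] = (("lat", "lon"), self.bias_layer)
        ds.to_netcdf(nc_path, engine="scipy")
        sidecar = {
            "seed": self.seed,
            "niche": {
                "active_variables": list(self.niche.active_variables),
                "linear": list(self.niche.linear),
                "quadratic": list(self.niche.quadratic),
                "intercept": self.niche.intercept,
            },
        }
        with open(json_path, "w") as fh:
            json.dump(sidecar, fh, indent=1)


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], smooth_sigma: float) -> np.ndarray:
    """Sum of a few low-frequency sinusoidal gradients plus smoothed noise."""
    n_rows, n_cols = shape
    yy, xx = np.mgrid[0:n_rows, 0:n_cols]
    yy = yy / max(n_rows - 1, 1)
    xx = xx / max(n_cols - 1, 1)
    out = np.zeros(shape, dtype=float)
    for _ in range(3):
        fx, fy = rng.uniform(0.5, 2.0, size=2)
        phase = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.5, 1.0)
        out += amp * np.sin(2 * np.pi * (fx * xx + fy * yy) + phase)
    noise = gaussian_filter(rng.standard_normal(shape), sigma=smooth_sigma)
    out += noise / max(noise.std(), 1e-12) * 0.6
    out -= out.mean()
    out /= max(out.std(), 1e-12)
    return out


def make_environment(
    grid: GridSpec,
    n_climate: int = 6,
    n_landcover: int = 2,
    seed: int = 0,
    correlated_pair: bool = False,
    smooth_sigma: float = 2.0,
) -> EnvStack:
    """Generate a smooth synthetic environmental stack.

    Climate layers (``CHELSA_BIO1`` ...) are standardized smooth fields;
    land-cover layers (``X30_ESA_CCI`` ...) are squashed into [0, 1] and
    represent per-cell cover fractions.  Some climate layers share latent
    components so that pairwise correlations span low to high; with
    ``correlated_pair=True`` the first two climate layers are near
    duplicates (Spearman |rho| >= 0.9), which exercises the correlated
    variable pruning downstream.
    """
    if n_climate < 0 or n_landcover < 0 or n_climate + n_landcover < 1:
        raise ValueError("need at least one layer in total")
    rng = np.random.default_rng(seed)
    layers: dict[str, np.ndarray] = {}
    shared = _smooth_field(rng, grid.shape, smooth_sigma)
    for i in range(n_climate):
        own = _smooth_field(rng, grid.shape, smooth_sigma)
        mix = rng.uniform(0.0, 0.7)  # varying dependence on the shared component
        f = (1 - mix) * own + mix * shared
        f = (f - f.mean()) / max(f.std(), 1e-12)
        layers[f"CHELSA_BIO{i + 1}"] = f
    if correlated_pair and n_climate >= 2:
        base = layers["CHELSA_BIO1"]
        layers["CHELSA_BIO2"] = base + 0.05 * gaussian_filter(
            rng.standard_normal(grid.shape), sigma=smooth_sigma
        )
    landcover_codes = [30, 40, 50, 60, 70, 80, 90, 100, 110, 120, 130, 140, 150, 160, 170, 180, 200]
    for i in range(n_landcover):
        code = landcover_codes[i % len(landcover_codes)]
        f = _smooth_field(rng, grid.shape, smooth_sigma)
        layers[f"X{code}_ESA_CCI"] = expit(1.5 * f)
    return EnvStack(grid=grid, layers=layers)


def make_native_region(
    grid: GridSpec,
    n_blobs: int = 2,
    seed: int = 0,
    blob_sizes: list[tuple[int, int]] | None = None,
    min_cells: int = 9,
    disjoint: bool = False,
) -> RegionMask:
    """Union of random rectangular blobs standing in for native-region polygons.

    Parameters
    ----------
    blob_sizes:
        Optional explicit (height, width) in cells for each blob; random
        sizes otherwise.  ``n_blobs`` is ignored when given.
    min_cells:
        Resample until the union has at least this many member cells
        (set lower to construct deliberately tiny regions for
        eligibility tests).
    disjoint:
        Require blobs not to touch or overlap (8-neighbourhood separation).
    """
    if blob_sizes is None:
        if n_blobs < 1:
            raise ValueError("n_blobs must be >= 1")
        rng_sz = np.random.default_rng(seed)
        blob_sizes = [
            (int(rng_sz.integers(3, max(4, grid.n_rows // 3))),
             int(rng_sz.integers(3, max(4, grid.n_cols // 3))))
            for _ in range(n_blobs)
        ]
    for h, w in blob_sizes:
        if h > grid.n_rows or w > grid.n_cols:
            raise ValueError("grid too small for requested blobs")
    rng = np.random.default_rng(seed)
    for _attempt in range(200):
        member = np.zeros(grid.shape, dtype=bool)
        ok = True
        for h, w in blob_sizes:
            placed = False
            for _try in range(200):
                r0 = int(rng.integers(0, grid.n_rows - h + 1))
                c0 = int(rng.integers(0, grid.n_cols - w + 1))
                if disjoint:
                    rlo, rhi = max(0, r0 - 1), min(grid.n_rows, r0 + h + 1)
                    clo, chi = max(0, c0 - 1), min(grid.n_cols, c0 + w + 1)
                    if member[rlo:rhi, clo:chi].any():
                        continue
                member[r0 : r0 + h, c0 : c0 + w] = True
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok and member.sum() >= min_cells:
            return RegionMask(grid=grid, member=member)
    raise ValueError("grid too small for requested blobs")


def make_bias_layer(grid: GridSpec, n_hotspots: int = 3, seed: int = 0, decay_cells: float = 6.0) -> np.ndarray:
    """Smooth accessibility field: distance decay from a few sampling hotspots.

    Emulates the road/herbarium aggregation typical of presence-only
    archives; used to inject spatial sampling bias into simulated records.
    """
    rng = np.random.default_rng(seed)
    rows = rng.integers(0, grid.n_rows, size=n_hotspots)
    cols = rng.integers(0, grid.n_cols, size=n_hotspots)
    yy, xx = np.mgrid[0 : grid.n_rows, 0 : grid.n_cols]
    out = np.zeros(grid.shape, dtype=float)
    for r, c in zip(rows, cols):
        d2 = (yy - r) ** 2 + (xx - c) ** 2
        out += np.exp(-d2 / (2 * decay_cells**2))
    out += 0.05  # floor keeps all cells reachable
    return out / out.max()


def _default_niche(env: EnvStack, n_active: int, rng: np.random.Generator) -> NicheSpec:
    climate = [v for v in env.variables if v.startswith("CHELSA")]
    active = climate[:n_active] if len(climate) >= n_active else env.variables[:n_active]
    linear = tuple(rng.uniform(1.0, 2.0) * rng.choice([-1.0, 1.0]) for _ in active)
    quadratic = tuple(-rng.uniform(0.5, 1.5) for _ in active)  # concave: unimodal niche
    return NicheSpec(active_variables=tuple(active), linear=linear, quadratic=quadratic, intercept=0.5)


def make_world(
    grid: GridSpec | None = None,
    n_climate: int = 6,
    n_landcover: int = 0,
    n_active: int = 2,
    n_blobs: int = 2,
    seed: int = 0,
    niche: NicheSpec | None = None,
    with_bias: bool = False,
) -> SyntheticWorld:
    """Assemble a full synthetic world (environment, native region, niche)."""
    if grid is None:
        grid = GridSpec(lon_min=0.0, lat_min=0.0, n_cols=60, n_rows=40, cell_size=0.5)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    env = make_environment(grid, n_climate=n_climate, n_landcover=n_landcover, seed=seed)
    native = make_native_region(grid, n_blobs=n_blobs, seed=seed + 1)
    if niche is None:
        niche = _default_niche(env, n_active, rng)
    suit = niche.suitability(env)
    bias = make_bias_layer(grid, seed=seed + 2) if with_bias else None
    return SyntheticWorld(
        env=env, native=native, niche=niche, true_suitability=suit, seed=seed, bias_layer=bias
    )


def simulate_species(
    world: SyntheticWorld,
    n_records: int = 100,
    year_range: tuple[int, int] = (2000, 2020),
    bias_strength: float = 0.0,
    seed: int = 0,
    species: str = "Synthetica exempli",
    contaminant_fraction: float = 0.0,
) -> pd.DataFrame:
    """Sample presence-only occurrence records from the true suitability.

    Cells are drawn (with replacement) with probability proportional to
    ``true_suitability * bias_layer**bias_strength`` over native cells;
    each record is jittered uniformly within its cell and dated uniformly
    in ``year_range``.  ``contaminant_fraction`` appends that fraction of
    extra labelled bad records — missing coordinates, pre-2000 years,
    points outside the native region and exact duplicates — to exercise
    the occurrence filters.  The ``contaminant_type`` column is empty for
    genuine records.
    """
    if n_records < 1:
        raise ValueError("n_records must be >= 1")
    rng = np.random.default_rng(seed)
    rows, cols = world.native.cells()
    weights = world.true_suitability[rows, cols].astype(float).copy()
    if bias_strength != 0.0:
        if world.bias_layer is None:
            raise ValueError("bias_strength set but world has no bias layer")
        weights = weights * world.bias_layer[rows, cols] ** bias_strength
    total = weights.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError("all-zero sampling weights")
    p = weights / total
    idx = rng.choice(len(rows), size=n_records, p=p)
    grid = world.env.grid
    cs = grid.cell_size
    lon = grid.lon_min + (cols[idx] + rng.uniform(0, 1, n_records)) * cs
    lat = grid.lat_min + (rows[idx] + rng.uniform(0, 1, n_records)) * cs
    years = rng.integers(year_range[0], year_range[1] + 1, size=n_records)
    df = pd.DataFrame(
        {
            "species": species,
            "decimalLongitude": lon,
            "decimalLatitude": lat,
            "year": years.astype(float),
            "contaminant_type": "",
        }
    )
    n_bad = int(round(contaminant_fraction * n_records))
    if n_bad:
        bad_rows = []
        outside = ~world.native.member
        out_r, out_c = np.nonzero(outside)
        for i in range(n_bad):
            kind = CONTAMINANT_TYPES[i % len(CONTAMINANT_TYPES)]
            if kind == "missing_coords":
                bad_rows.append((species, np.nan, np.nan, float(rng.integers(*year_range)), kind))
            elif kind == "old_year":
                j = rng.integers(0, n_records)
                bad_rows.append((species, lon[j] + cs * 0.01, lat[j], float(rng.integers(1950, 1999)), kind))
            elif kind == "outside_native" and len(out_r):
                k = rng.integers(0, len(out_r))
                blon = grid.lon_min + (out_c[k] + 0.5) * cs
                blat = grid.lat_min + (out_r[k] + 0.5) * cs
                bad_rows.append((species, blon, blat, float(rng.integers(*year_range)), kind))
            else:  # exact duplicate of a genuine record
                j = rng.integers(0, n_records)
                bad_rows.append((species, lon[j], lat[j], float(years[j]), "duplicate"))
        df = pd.concat(
            [df, pd.DataFrame(bad_rows, columns=df.columns)], ignore_index=True
        )
    return df


def make_reference_range(world: SyntheticWorld, quantile_q: float = 0.5) -> RegionMask:
    """Expert-style reference range: native cells in the top (1-q) suitability.

    Member cells are the native cells whose true suitability is at least
    the q-quantile of true suitability over native cells — always a
    subset of the native region, approaching it as q -> 0.
    """
    if not (0 < quantile_q < 1):
        raise ValueError("quantile_q must be in (0, 1)")
    rows, cols = world.native.cells()
    suit = world.true_suitability[rows, cols]
    thr = np.quantile(suit, quantile_q)
    member = np.zeros(world.env.grid.shape, dtype=bool)
    keep = suit >= thr
    member[rows[keep], cols[keep]] = True
    return RegionMask(grid=world.env.grid, member=member)
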