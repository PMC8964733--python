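"""End-to-end per-species orchestration and the data-bundle / metadata outputs.

``run_species`` executes the full chain — occurrence filtering into the
three data types, eligibility, Model 0 variable selection, the Models
1-3 candidate grid, evaluation — and returns a :class:`SpeciesBundle`
plus one metadata row.  ``run_pipeline`` loops species independently so
one failure never aborts the batch.  Bundles serialize to multi-layer
netCDF with the field's conventional variable names ("Maxent
prediction", "Presence cells", "Native region", "Model 1/2/3").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from . import maxent
from .calibration import (
    DATA_TYPE_OF_MODEL,
    FEATURE_COMBOS,
    REG_MULTIPLIERS,
    SelectionResult,
    _SpeciesContext,
    eligibility,
    run_candidate_grid,
    select_variables,
)
from .evaluation import binary_thresholds
from .grid import EnvStack, RegionMask
from .occurrences import (
    OccurrenceSet,
    count_per_cell,
    filter_records,
    morans_index,
    thin,
    to_presence_cells,
)

logger = logging.getLogger("maxrange")

__all__ = ["PipelineConfig", "SpeciesBundle", "run_species", "run_pipeline", "write_bundle", "write_metadata"]


@dataclass
class PipelineConfig:
    """Knobs of the per-species workflow, defaulting to the standard protocol.

    Defaults: temporal window 2000-2020 escaping below 25 recent records;
    eligibility 5 records / 3 cells / 9 native cells; thinning distance 2
    cells; correlation cutoff 0.7; regularization multipliers
    (1, 2, 3, 5, 10); all six feature-class combos; 50 hinge/threshold
    knots (reduce for quick experiments).
    """

    year_lo: int = 2000
    year_hi: int = 2020
    min_recent: int = 25
    thin_min_dist_cells: float = 2.0
    thin_reps: int = 10
    n_knots: int = 50
    rms: tuple = REG_MULTIPLIERS
    combos: tuple = FEATURE_COMBOS
    variables: list[str] | None = None  # default: every environment layer
    seed: int = 0


@dataclass
class SpeciesBundle:
    """Per-species output layers on one grid plus the metadata row."""

    species: str
    grid_shape: tuple[int, int]
    native: RegionMask
    presence_counts: np.ndarray
    prediction_cloglog: np.ndarray | None = None
    prediction_raw: np.ndarray | None = None
    model_layers: dict[int, np.ndarray] = field(default_factory=dict)  # model_id -> cloglog grid
    metadata: dict = field(default_factory=dict)
    selection: SelectionResult | None = None

    @property
    def has_prediction(self) -> bool:
        return self.prediction_cloglog is not None


def _vector_to_grid(values: np.ndarray, native: RegionMask) -> np.ndarray:
    grid = np.full(native.grid.shape, np.nan)
    rows, cols = native.cells()
    grid[rows, cols] = values
    return grid


def run_species(
    table: pd.DataFrame,
    native: RegionMask,
    env: EnvStack,
    config: PipelineConfig | None = None,
    species: str | None = None,
) -> SpeciesBundle:
    """Run the full workflow for one species' occurrence table."""
    cfg = config or PipelineConfig()
    if species is None:
        species = str(table["species"].iloc[0]) if len(table) else "unknown"
    meta: dict = {"species": species}
    bbox = native.bounding_box()
    meta.update(
        native_lon_min=bbox[0], native_lat_min=bbox[1],
        native_lon_max=bbox[2], native_lat_max=bbox[3],
        n_native_cells=native.n_cells,
    )

    raw = filter_records(
        table, native, year_lo=cfg.year_lo, year_hi=cfg.year_hi, min_recent=cfg.min_recent
    )
    logger.info("%s: %d raw records in %d cells", species, raw.n_records, raw.n_cells)
    counts = count_per_cell(raw)
    presence_cells = to_presence_cells(raw)
    thinned = thin(
        presence_cells,
        min_dist_cells=cfg.thin_min_dist_cells,
        reps=cfg.thin_reps,
        seed=cfg.seed,
    )
    meta.update(
        n_raw_records=raw.n_records,
        n_presence_cells=presence_cells.n_cells,
        n_thinned=thinned.n_cells,
    )
    try:
        meta["morans_i"] = morans_index(counts, native)
    except ValueError:
        meta["morans_i"] = float("nan")

    bundle = SpeciesBundle(
        species=species,
        grid_shape=native.grid.shape,
        native=native,
        presence_counts=counts,
        metadata=meta,
    )
    elig = eligibility(raw, native, n_thinned=thinned.n_cells)
    meta.update(
        model_1_eligible=elig.model_1_ok,
        model_2_eligible=elig.model_2_ok,
        model_3_eligible=elig.model_3_ok,
    )
    if not elig.any_prediction:
        meta["status"] = "no prediction"
        logger.info("%s: ineligible, no prediction", species)
        return bundle

    ctx = _SpeciesContext(env, native, cfg.n_knots)
    variables = cfg.variables if cfg.variables is not None else env.variables
    selected, details, model0 = select_variables(
        raw, native, env, variables, n_knots=cfg.n_knots, seed=cfg.seed, ctx=ctx
    )
    logger.info("%s: selected variables %s", species, selected)
    sets = {"raw": raw, "presence_cells": presence_cells, "thinned": thinned}
    result = run_candidate_grid(
        sets, native, env, selected, elig,
        n_knots=cfg.n_knots, rms=cfg.rms, combos=cfg.combos, ctx=ctx,
    )
    result.model0_candidates = model0
    result.importances = details["importances"]
    result.spearman_matrix = details["spearman"]
    result.spearman_variables = details["spearman_variables"]
    bundle.selection = result
    meta["n_models_fitted"] = result.n_models_fitted
    if result.overall_best is None:
        meta["status"] = "no prediction"
        return bundle

    for model_id, cand in result.best_per_model.items():
        _, _, F_bg = ctx.expansion_and_bg(tuple(selected), cand.combo)
        raw_vec = maxent.raw_from_features(cand.model, F_bg)
        bundle.model_layers[model_id] = _vector_to_grid(
            maxent.predict_cloglog(cand.model, raw_vec), native
        )
    best = result.overall_best
    _, _, F_bg = ctx.expansion_and_bg(tuple(selected), best.combo)
    raw_vec = maxent.raw_from_features(best.model, F_bg)
    cloglog_vec = maxent.predict_cloglog(best.model, raw_vec)
    bundle.prediction_raw = _vector_to_grid(raw_vec, native)
    bundle.prediction_cloglog = _vector_to_grid(cloglog_vec, native)

    pres_idx = ctx.bg_cell_index(sets[best.data_type])
    bg_idx = np.arange(len(raw_vec))
    thresholds = binary_thresholds(cloglog_vec, pres_idx, bg_idx)
    rep = result.overall_eval
    meta.update(
        status="ok",
        training_data_type=best.data_type,
        n_training_points=len(pres_idx),
        selected_variables=",".join(selected),
        combo=best.combo,
        rm=best.rm,
        n_nonzero_coefficients=best.model.n_nonzero,
        aicc=np.nan if best.aicc is None else best.aicc,
        mean_test_auc=best.mean_test_auc,
        doo=best.doo,
        threshold_no_omission=thresholds["no_omission"],
        threshold_max_f1=thresholds["max_f1"],
        eval_auc=rep.auc,
        eval_auc_pr=rep.auc_pr,
        eval_max_f1=rep.max_f1,
    )
    logger.info(
        "%s: best Model %d (%s, rm=%g) AUC=%.3f AUC_PR=%.3f",
        species, best.model_id, best.combo, best.rm, rep.auc, rep.auc_pr,
    )
    return bundle


def run_pipeline(
    species_inputs: list[tuple[pd.DataFrame, RegionMask]],
    env: EnvStack,
    config: PipelineConfig | None = None,
) -> tuple[list[SpeciesBundle], pd.DataFrame]:
    """Process species independently; failures are recorded, not raised."""
    bundles: list[SpeciesBundle] = []
    rows: list[dict] = []
    for i, (table, native) in enumerate(species_inputs):
        name = str(table["species"].iloc[0]) if len(table) else f"species_{i}"
        try:
            bundle = run_species(table, native, env, config=config, species=name)
        except Exception as exc:  # noqa: BLE001 — isolate per-species failures
            logger.error("%s: failed (%s)", name, exc)
            rows.append({"species": name, "status": f"error: {exc}"})
            continue
        bundles.append(bundle)
        rows.append(bundle.metadata)
    return bundles, write_metadata(rows)


_METADATA_COLUMNS = [
    "species", "status",
    "native_lon_min", "native_lat_min", "native_lon_max", "native_lat_max",
    "n_native_cells", "n_raw_records", "n_presence_cells", "n_thinned",
    "morans_i",
    "model_1_eligible", "model_2_eligible", "model_3_eligible",
    "n_models_fitted", "training_data_type", "n_training_points",
    "selected_variables", "combo", "rm", "n_nonzero_coefficients",
    "aicc", "mean_test_auc", "doo",
    "threshold_no_omission", "threshold_max_f1",
    "eval_auc", "eval_auc_pr", "eval_max_f1",
]


def write_metadata(rows: list[dict], path=None) -> pd.DataFrame:
    """Assemble (and optionally write) the one-row-per-species metadata CSV."""
    df = pd.DataFrame(rows)
    for col in _METADATA_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[_METADATA_COLUMNS]
    if path is not None:
        df.to_csv(path, index=False)
    return df


def write_bundle(bundle: SpeciesBundle, basic_path, advanced_path=None) -> None:
    """Write the species bundle as netCDF files.

    The *basic* file carries the best prediction ("Maxent prediction",
    cloglog, plus "Maxent prediction raw"), the per-cell record counts
    ("Presence cells") and the native mask ("Native region").  The
    optional *advanced* file replaces the best prediction with one layer
    per fitted occurrence data type ("Model 1", "Model 2", "Model 3" —
    absent models are simply not written).
    """
    grid = bundle.native.grid
    coords = {"lat": grid.lat_centers, "lon": grid.lon_centers}

    def dataset(layers: dict[str, np.ndarray]) -> xr.Dataset:
        ds = xr.Dataset(
            {name: (("lat", "lon"), arr.astype(float)) for name, arr in layers.items()},
            coords=coords,
        )
        ds.attrs["species"] = bundle.species
        return ds

    basic_layers = {
        "Presence cells": bundle.presence_counts.astype(float),
        "Native region": bundle.native.member.astype(float),
    }
    if bundle.prediction_cloglog is not None:
        basic_layers["Maxent prediction"] = bundle.prediction_cloglog
        basic_layers["Maxent prediction raw"] = bundle.prediction_raw
    dataset(basic_layers).to_netcdf(basic_path, engine="scipy")
    if advanced_path is not None:
        adv_layers = {
            "Presence cells": bundle.presence_counts.astype(float),
            "Native region": bundle.native.member.astype(float),
        }
        for model_id, layer in bundle.model_layers.items():
            adv_layers[f"Model {model_id}"] = layer
        dataset(adv_layers).to_netcdf(advanced_path, engine="scipy")


def read_bundle(path) -> xr.Dataset:
    with xr.open_dataset(path, engine="scipy") as ds:
        return ds.load()
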