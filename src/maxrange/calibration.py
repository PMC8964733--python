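"""Cross-validated calibration, variable selection and model selection.

The workflow trains an initial all-variables model (Model 0, one
candidate per feature-class combo at regularization multiplier 1) to rank
variables by permutation importance and prune correlated ones
(|Spearman rho| >= 0.7).  The surviving variables feed a candidate grid —
6 combos x 5 regularization multipliers — per occurrence data type
(Model 1: raw, Model 2: presence cells, Model 3: thinned), each candidate
scored by k-fold cross validation (leave-one-out jackknife below 25
points, spatial block quadrants otherwise).  Within a data type the best
candidate is chosen by AICc with a mean-test-AUC fallback; across data
types the winner maximizes the harmonic mean of evaluation AUC and
AUC_PR against the species' presence cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import spearmanr

from . import maxent
from .evaluation import evaluate, roc_auc
from .grid import EnvStack, RegionMask
from .maxent import (
    FEATURE_COMBOS,
    REG_MULTIPLIERS,
    UNAVAILABLE,
    MaxentModel,
    build_features,
    fit_maxent,
    permutation_importance,
)
from .occurrences import OccurrenceSet

__all__ = [
    "Eligibility",
    "PartitionScheme",
    "CandidateModel",
    "SelectionResult",
    "eligibility",
    "partition",
    "crossvalidate",
    "select_variables",
    "run_candidate_grid",
    "select_best_candidate",
]

DATA_TYPE_OF_MODEL = {1: "raw", 2: "presence_cells", 3: "thinned"}
MODEL_OF_DATA_TYPE = {v: k for k, v in DATA_TYPE_OF_MODEL.items()}
_DATA_TYPE_ORDER = {"raw": 0, "presence_cells": 1, "thinned": 2}

MIN_RAW_RECORDS = 5
MIN_OCCUPIED_CELLS = 3
MIN_NATIVE_CELLS = 9
MIN_TYPE_RECORDS = 3
BLOCK_THRESHOLD = 25  # jackknife below, 4-quadrant blocks at or above
RHO_CUTOFF = 0.7
_AICC_TIE = 1e-9


@dataclass(frozen=True)
class Eligibility:
    n_raw_records: int
    n_occupied_cells: int
    n_native_cells: int
    n_presence_cells: int
    n_thinned: int
    model_1_ok: bool
    model_2_ok: bool
    model_3_ok: bool

    @property
    def any_prediction(self) -> bool:
        # without Model 1 no prediction is produced at all
        return self.model_1_ok


def eligibility(raw: OccurrenceSet, native: RegionMask, n_thinned: int | None = None) -> Eligibility:
    """Check the minimum-data rules before any model is attempted.

    Model 1 requires >= 5 raw records spread over >= 3 cells and a native
    region of >= 9 cells; Models 2 and 3 require >= 3 records of their
    data type (and the same native extent).  ``n_thinned`` may be passed
    when thinning has already run; otherwise Model 3 eligibility is
    assessed against the presence-cell count (an upper bound).
    """
    n_native = native.n_cells
    n_pc = raw.n_cells
    n_thin = n_pc if n_thinned is None else n_thinned
    return Eligibility(
        n_raw_records=raw.n_records,
        n_occupied_cells=raw.n_cells,
        n_native_cells=n_native,
        n_presence_cells=n_pc,
        n_thinned=n_thin,
        model_1_ok=(
            raw.n_records >= MIN_RAW_RECORDS
            and raw.n_cells >= MIN_OCCUPIED_CELLS
            and n_native >= MIN_NATIVE_CELLS
        ),
        model_2_ok=(n_pc >= MIN_TYPE_RECORDS and n_native >= MIN_NATIVE_CELLS),
        model_3_ok=(n_thin >= MIN_TYPE_RECORDS and n_native >= MIN_NATIVE_CELLS),
    )


@dataclass
class PartitionScheme:
    """Fold assignment for presences (and background, for block folds)."""

    method: str  # jackknife | block
    k: int
    folds: np.ndarray  # per-presence fold id
    lon_split: float | None = None
    lat_split_left: float | None = None
    lat_split_right: float | None = None

    def background_folds(self, bg_lons: np.ndarray, bg_lats: np.ndarray) -> np.ndarray | None:
        """Assign background cells to the 4 spatial blocks by the same lines."""
        if self.method != "block":
            return None
        right = np.asarray(bg_lons) >= self.lon_split
        out = np.empty(len(bg_lons), dtype=int)
        lat = np.asarray(bg_lats)
        out[~right] = np.where(lat[~right] >= self.lat_split_left, 1, 0)
        out[right] = np.where(lat[right] >= self.lat_split_right, 3, 2)
        return out


def _median_line(sorted_vals: np.ndarray, n_low: int) -> float:
    """Split line between the n_low lowest values and the rest."""
    if n_low >= len(sorted_vals):
        return float(sorted_vals[-1]) + 1.0
    return float((sorted_vals[n_low - 1] + sorted_vals[n_low]) / 2.0)


def partition(lons: np.ndarray, lats: np.ndarray) -> PartitionScheme:
    """Jackknife (n < 25) or 4-block spatial partition (n >= 25).

    Block folds split at the median longitude and, within each half, at
    that half's median latitude, yielding four approximately equal bins
    (sizes differ by at most 2).  Fold ids: 0/1 = west-south/west-north,
    2/3 = east-south/east-north.
    """
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    n = len(lons)
    if n < 2:
        raise ValueError("need at least 2 points to partition")
    if n < BLOCK_THRESHOLD:
        return PartitionScheme(method="jackknife", k=n, folds=np.arange(n))
    order = np.argsort(lons, kind="stable")
    n_left = (n + 1) // 2
    lon_split = _median_line(lons[order], n_left)
    left_idx = order[:n_left]
    right_idx = order[n_left:]
    folds = np.empty(n, dtype=int)
    for side_idx, base in ((left_idx, 0), (right_idx, 2)):
        lat_order = side_idx[np.argsort(lats[side_idx], kind="stable")]
        n_low = (len(side_idx) + 1) // 2
        lat_split = _median_line(lats[lat_order], n_low)
        folds[lat_order[:n_low]] = base
        folds[lat_order[n_low:]] = base + 1
        if base == 0:
            lat_left = lat_split
        else:
            lat_right = lat_split
    return PartitionScheme(
        method="block",
        k=4,
        folds=folds,
        lon_split=lon_split,
        lat_split_left=lat_left,
        lat_split_right=lat_right,
    )


@dataclass
class CandidateModel:
    model_id: int
    data_type: str
    combo: str
    rm: float
    mean_train_auc: float = math.nan
    mean_test_auc: float = math.nan
    doo: float = math.nan  # degree of overfit: train minus test AUC
    aicc: float | None = UNAVAILABLE
    model: MaxentModel | None = None
    n_folds_used: int = 0
    skipped_folds: int = 0
    failed: bool = False


@dataclass
class SelectionResult:
    selected_variables: list[str]
    importances: dict[str, float]
    spearman_matrix: np.ndarray
    spearman_variables: list[str]
    model0_candidates: list[CandidateModel]
    grid_candidates: list[CandidateModel] = field(default_factory=list)
    best_per_model: dict[int, CandidateModel] = field(default_factory=dict)
    eval_per_model: dict[int, object] = field(default_factory=dict)
    overall_best: CandidateModel | None = None
    overall_eval: object | None = None

    @property
    def n_models_fitted(self) -> int:
        return len(self.model0_candidates) + len(self.grid_candidates)


class _SpeciesContext:
    """Shared per-species state: background matrix cache per (vars, combo)."""

    def __init__(self, env: EnvStack, native: RegionMask, n_knots: int):
        self.env = env
        self.native = native
        self.n_knots = n_knots
        rows, cols = native.cells()
        self.bg_rows, self.bg_cols = rows, cols
        self.bg_lons = native.grid.lon_min + (cols + 0.5) * native.grid.cell_size
        self.bg_lats = native.grid.lat_min + (rows + 0.5) * native.grid.cell_size
        self._cell_index = {
            (int(r), int(c)): i for i, (r, c) in enumerate(zip(rows, cols))
        }
        self._cache: dict[tuple, tuple] = {}

    def bg_cell_index(self, occ: OccurrenceSet) -> np.ndarray:
        idx = []
        for r, c in zip(occ.records["_row"].values, occ.records["_col"].values):
            i = self._cell_index.get((int(r), int(c)))
            if i is None:
                raise ValueError("presence outside the native background")
            idx.append(i)
        return np.array(idx, dtype=int)

    def expansion_and_bg(self, variables: tuple[str, ...], combo: str):
        key = (variables, combo)
        if key not in self._cache:
            expansion = build_features(
                self.env, self.native, list(variables), combo, n_knots=self.n_knots
            )
            X_bg = self.env.values_at(expansion.variables, self.bg_rows, self.bg_cols)
            F_bg = expansion.transform(X_bg)
            self._cache[key] = (expansion, X_bg, F_bg)
        return self._cache[key]


def crossvalidate(
    ctx: _SpeciesContext,
    occ: OccurrenceSet,
    variables: tuple[str, ...],
    combo: str,
    rm: float,
    scheme: PartitionScheme,
    model_id: int,
) -> CandidateModel:
    """Fit one candidate: k-fold CV for AUCs, then a full-data refit.

    Jackknife folds use the full background on both sides; block folds
    fit on the training blocks' background and test each fold's presences
    against its own block's background.  AICc is computed on the
    full-data model with raw standardized over the whole native grid.
    """
    cand = CandidateModel(model_id=model_id, data_type=occ.kind, combo=combo, rm=rm)
    expansion, _X_bg, F_bg = ctx.expansion_and_bg(variables, combo)
    pres_idx = ctx.bg_cell_index(occ)
    F_pres = F_bg[pres_idx]
    try:
        full_model = fit_maxent(expansion, F_pres, F_bg, rm=rm)
    except (RuntimeError, ValueError):
        cand.failed = True
        return cand
    bg_folds = scheme.background_folds(ctx.bg_lons, ctx.bg_lats)
    train_aucs, test_aucs = [], []
    skipped = 0
    for fold in range(scheme.k):
        test = scheme.folds == fold
        train = ~test
        if train.sum() == 0 or test.sum() == 0:
            skipped += 1
            continue
        if scheme.method == "block":
            bg_train = bg_folds != fold
            bg_test = bg_folds == fold
            if bg_train.sum() < 2 or bg_test.sum() < 1:
                skipped += 1
                continue
            F_bg_train = F_bg[bg_train]
            F_bg_test = F_bg[bg_test]
        else:
            F_bg_train = F_bg
            F_bg_test = F_bg
        try:
            m = fit_maxent(
                expansion, F_pres[train], F_bg_train, rm=rm, beta0=full_model.beta
            )
        except (RuntimeError, ValueError):
            skipped += 1
            continue
        s_train = F_pres[train] @ m.beta
        s_bg_train = F_bg_train @ m.beta
        s_test = F_pres[test] @ m.beta
        s_bg_test = F_bg_test @ m.beta
        train_aucs.append(roc_auc(s_train, s_bg_train))
        test_aucs.append(roc_auc(s_test, s_bg_test))
    if not train_aucs:
        cand.failed = True
        return cand
    cand.model = full_model
    cand.mean_train_auc = float(np.mean(train_aucs))
    cand.mean_test_auc = float(np.mean(test_aucs))
    cand.doo = cand.mean_train_auc - cand.mean_test_auc
    raw_full = maxent.raw_from_features(full_model, F_bg)
    cand.aicc = maxent.aicc(full_model, raw_full[pres_idx], raw_full.sum())
    cand.n_folds_used = len(train_aucs)
    cand.skipped_folds = skipped
    return cand


def select_best_candidate(candidates: list[CandidateModel]) -> CandidateModel:
    """AICc winner, falling back to mean test AUC when AICc cannot decide.

    The fallback triggers when AICc is unavailable for at least half of
    the (non-failed) candidates, or when no unique finite minimum exists
    (ties within 1e-9).
    """
    live = [c for c in candidates if not c.failed]
    if not live:
        raise ValueError("all candidates failed")
    aiccs = [c.aicc for c in live]
    n_unavail = sum(1 for a in aiccs if a is UNAVAILABLE)
    use_auc = n_unavail >= 0.5 * len(live)
    if not use_auc:
        finite = [(a, c) for a, c in zip(aiccs, live) if a is not UNAVAILABLE]
        best_val = min(a for a, _ in finite)
        near = [c for a, c in finite if a <= best_val + _AICC_TIE]
        if len(near) > 1:
            use_auc = True
        else:
            return near[0]
    return max(live, key=lambda c: (c.mean_test_auc, -(c.model.n_nonzero if c.model else 0)))


def select_variables(
    raw: OccurrenceSet,
    native: RegionMask,
    env: EnvStack,
    all_variables: list[str] | None = None,
    n_knots: int = 50,
    seed: int = 0,
    ctx: _SpeciesContext | None = None,
) -> tuple[list[str], dict, list[CandidateModel]]:
    """Model 0: rank variables by permutation importance, prune correlated ones.

    Fits the six feature-class combos at regularization multiplier 1 on
    the raw data, picks a winner by the AICc/AUC cascade, computes
    permutation importances on it, then greedily keeps variables in
    descending importance whose |Spearman rho| against every already-kept
    variable is < 0.7 (rho over all native background cells).

    Returns (selected variables, details dict, Model 0 candidates).
    """
    variables = tuple(all_variables if all_variables is not None else env.variables)
    if not variables:
        raise ValueError("no candidate variables")
    if ctx is None:
        ctx = _SpeciesContext(env, native, n_knots)
    lons = raw.records["decimalLongitude"].astype(float).values
    lats = raw.records["decimalLatitude"].astype(float).values
    scheme = partition(lons, lats)
    candidates = [
        crossvalidate(ctx, raw, variables, combo, rm=1.0, scheme=scheme, model_id=0)
        for combo in FEATURE_COMBOS
    ]
    winner = select_best_candidate(candidates)
    X_bg = ctx.env.values_at(winner.model.expansion.variables, ctx.bg_rows, ctx.bg_cols)
    pres_idx = ctx.bg_cell_index(raw)
    importances = permutation_importance(winner.model, X_bg[pres_idx], X_bg, seed=seed)
    kept_vars = list(winner.model.expansion.variables)
    if len(kept_vars) > 1:
        rho = spearmanr(X_bg).statistic
        rho = np.atleast_2d(np.asarray(rho, dtype=float))
    else:
        rho = np.ones((1, 1))
    order = sorted(kept_vars, key=lambda v: -importances.get(v, 0.0))
    col = {v: i for i, v in enumerate(kept_vars)}
    selected: list[str] = []
    for v in order:
        if all(abs(rho[col[v], col[u]]) < RHO_CUTOFF for u in selected):
            selected.append(v)
    details = {
        "importances": importances,
        "spearman": rho,
        "spearman_variables": kept_vars,
        "model0_winner": winner,
        "scheme": scheme,
    }
    return selected, details, candidates


def _harmonic_mean(a: float, b: float) -> float:
    if a + b == 0:
        return 0.0
    return 2 * a * b / (a + b)


def run_candidate_grid(
    sets: dict[str, OccurrenceSet],
    native: RegionMask,
    env: EnvStack,
    selected_variables: list[str],
    elig: Eligibility,
    n_knots: int = 50,
    rms: tuple = REG_MULTIPLIERS,
    combos: tuple = FEATURE_COMBOS,
    ctx: _SpeciesContext | None = None,
) -> SelectionResult:
    """Models 1-3: the full combo x RM grid per eligible occurrence data type.

    Each data type contributes ``len(combos) * len(rms)`` candidates; the
    per-type winner comes from the AICc/AUC cascade and the overall best
    maximizes the harmonic mean of evaluation AUC and AUC_PR against the
    species' presence cells (ties: higher AUC, then fewer nonzero
    coefficients, then less-filtered data type).
    """
    if not elig.model_1_ok:
        raise ValueError("species not eligible for any prediction")
    if ctx is None:
        ctx = _SpeciesContext(env, native, n_knots)
    variables = tuple(selected_variables)
    ok = {1: elig.model_1_ok, 2: elig.model_2_ok, 3: elig.model_3_ok}
    result = SelectionResult(
        selected_variables=list(selected_variables),
        importances={},
        spearman_matrix=np.zeros((0, 0)),
        spearman_variables=[],
        model0_candidates=[],
    )
    pc_mask = _presence_cells_mask(sets["presence_cells"], native)
    for model_id, data_type in DATA_TYPE_OF_MODEL.items():
        if not ok[model_id]:
            continue
        occ = sets[data_type]
        lons = occ.records["decimalLongitude"].astype(float).values
        lats = occ.records["decimalLatitude"].astype(float).values
        if len(lons) < 2:
            continue
        scheme = partition(lons, lats)
        type_cands = []
        for combo in combos:
            for rm in rms:
                cand = crossvalidate(ctx, occ, variables, combo, rm, scheme, model_id)
                type_cands.append(cand)
        result.grid_candidates.extend(type_cands)
        try:
            best = select_best_candidate(type_cands)
        except ValueError:
            continue
        result.best_per_model[model_id] = best
        _, _, F_bg = ctx.expansion_and_bg(variables, best.combo)
        raw = maxent.raw_from_features(best.model, F_bg)
        cloglog = maxent.predict_cloglog(best.model, raw)
        result.eval_per_model[model_id] = evaluate(
            cloglog, pc_mask, native, mode="presence_background"
        )
    if not result.best_per_model:
        result.overall_best = None
        return result
    def sort_key(model_id: int):
        rep = result.eval_per_model[model_id]
        cand = result.best_per_model[model_id]
        return (
            _harmonic_mean(rep.auc, rep.auc_pr),
            rep.auc,
            -cand.model.n_nonzero,
            _DATA_TYPE_ORDER[cand.data_type],  # prefer more filtering on full ties
        )
    best_id = max(result.best_per_model, key=sort_key)
    result.overall_best = result.best_per_model[best_id]
    result.overall_eval = result.eval_per_model[best_id]
    return result


def _presence_cells_mask(presence_cells: OccurrenceSet, native: RegionMask) -> RegionMask:
    member = np.zeros(native.grid.shape, dtype=bool)
    for r, c in presence_cells.cells:
        member[r, c] = True
    return RegionMask(grid=native.grid, member=member)
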