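import numpy as np
import pandas as pd
import pytest

import maxrange as mx
from maxrange.calibration import (
    CandidateModel,
    _harmonic_mean,
    _SpeciesContext,
    crossvalidate,
    select_best_candidate,
)

from conftest import records_table


def make_raw(world, n_records, seed=0):
    df = mx.simulate_species(world, n_records=n_records, seed=seed)
    return mx.filter_records(df, world.native)


class TestEligibility:
    def _raw_set(self, full_mask, lons, lats):
        years = [2010] * len(lons)
        return mx.filter_records(records_table(lons, lats, years), full_mask)

    def test_minimum_viable_species(self, full_mask):
        raw = self._raw_set(full_mask, [0.1, 0.2, 1.1, 2.1, 2.2], [0.1] * 5)
        elig = mx.eligibility(raw, full_mask)
        assert raw.n_records == 5 and raw.n_cells == 3
        assert elig.model_1_ok and elig.any_prediction

    def test_records_in_single_cell_ineligible(self, full_mask):
        raw = self._raw_set(full_mask, [0.1, 0.15, 0.2, 0.25, 0.3], [0.1] * 5)
        elig = mx.eligibility(raw, full_mask)
        assert raw.n_cells == 1
        assert not elig.model_1_ok and not elig.any_prediction

    def test_small_native_region_ineligible(self, small_grid):
        member = np.zeros(small_grid.shape, bool)
        member[0, :8] = True  # 8 native cells
        native = mx.RegionMask(grid=small_grid, member=member)
        lons = [0.1, 0.6, 1.1, 1.6, 2.1, 2.6]
        raw = mx.filter_records(records_table(lons, [0.1] * 6, [2010] * 6), native)
        elig = mx.eligibility(raw, native)
        assert raw.n_records == 6 and raw.n_cells == 6
        assert not elig.model_1_ok

    def test_model_2_3_need_three_records(self, full_mask):
        raw = self._raw_set(full_mask, [0.1, 0.2, 1.1, 2.1, 2.2], [0.1] * 5)
        elig = mx.eligibility(raw, full_mask, n_thinned=2)
        assert elig.model_2_ok
        assert not elig.model_3_ok


class TestPartition:
    def test_jackknife_below_25(self):
        sch = mx.partition(np.arange(24.0), np.arange(24.0))
        assert sch.method == "jackknife" and sch.k == 24
        assert sorted(sch.folds.tolist()) == list(range(24))

    def test_block_at_25(self):
        sch = mx.partition(np.arange(25.0), np.arange(25.0))
        assert sch.method == "block" and sch.k == 4
        sizes = np.bincount(sch.folds, minlength=4)
        assert sizes.max() - sizes.min() <= 2

    def test_uniform_grid_gives_equal_quadrants(self):
        xs, ys = np.meshgrid(np.arange(7.0), np.arange(4.0))
        sch = mx.partition(xs.ravel(), ys.ravel())
        assert sorted(np.bincount(sch.folds).tolist()) == [7, 7, 7, 7]

    def test_background_assigned_by_same_lines(self):
        # with no point exactly on a split line, assigning the presence
        # coordinates as background cells reproduces the presence folds
        rng = np.random.default_rng(0)
        lons = np.arange(28.0) + rng.uniform(0.01, 0.4, 28)
        lats = rng.uniform(0.0, 10.0, 28)
        sch = mx.partition(lons, lats)
        bg = sch.background_folds(lons, lats)
        assert np.array_equal(bg, sch.folds)

    def test_too_few_points_error(self):
        with pytest.raises(ValueError):
            mx.partition(np.array([1.0]), np.array([1.0]))


class TestSelectBestCandidate:
    def _cand(self, aicc=None, auc=0.5, failed=False):
        return CandidateModel(
            model_id=1, data_type="raw", combo="l", rm=1.0,
            mean_test_auc=auc, aicc=aicc, failed=failed,
        )

    def test_unique_aicc_minimum_wins(self):
        cands = [self._cand(aicc=100.0, auc=0.2), self._cand(aicc=90.0, auc=0.1),
                 self._cand(aicc=95.0, auc=0.9)]
        assert select_best_candidate(cands).aicc == 90.0

    def test_fallback_when_half_unavailable(self):
        cands = [self._cand(aicc=None, auc=0.9), self._cand(aicc=None, auc=0.3),
                 self._cand(aicc=50.0, auc=0.1), self._cand(aicc=60.0, auc=0.2)]
        assert select_best_candidate(cands).mean_test_auc == 0.9

    def test_fallback_on_tied_minimum(self):
        cands = [self._cand(aicc=90.0, auc=0.4), self._cand(aicc=90.0 + 1e-12, auc=0.8),
                 self._cand(aicc=95.0, auc=0.1)]
        assert select_best_candidate(cands).mean_test_auc == 0.8

    def test_no_fallback_just_below_half_unavailable(self):
        cands = [self._cand(aicc=None, auc=0.9), self._cand(aicc=80.0, auc=0.1),
                 self._cand(aicc=70.0, auc=0.2), self._cand(aicc=75.0, auc=0.3)]
        assert select_best_candidate(cands).aicc == 70.0

    def test_failed_candidates_excluded(self):
        cands = [self._cand(aicc=10.0, failed=True), self._cand(aicc=20.0)]
        assert select_best_candidate(cands).aicc == 20.0
        with pytest.raises(ValueError):
            select_best_candidate([self._cand(failed=True)])


class TestHarmonicMean:
    def test_hand_arithmetic(self):
        assert _harmonic_mean(0.9, 0.5) == pytest.approx(0.6428571428571429)
        assert _harmonic_mean(0.8, 0.7) == pytest.approx(0.7466666666666667)
        assert _harmonic_mean(0.8, 0.7) > _harmonic_mean(0.9, 0.5)


@pytest.fixture(scope="module")
def cv_setup(world):
    raw = make_raw(world, 30, seed=4)
    ctx = _SpeciesContext(world.env, world.native, n_knots=5)
    return world, raw, ctx


class TestCrossvalidate:

    def test_jackknife_uses_one_fold_per_presence(self, world):
        df = mx.simulate_species(world, n_records=5, seed=77)
        raw = mx.filter_records(df, world.native)
        ctx = _SpeciesContext(world.env, world.native, n_knots=5)
        lons = raw.records["decimalLongitude"].values
        lats = raw.records["decimalLatitude"].values
        scheme = mx.partition(lons, lats)
        assert scheme.method == "jackknife"
        cand = crossvalidate(ctx, raw, tuple(world.env.variables[:2]), "l", 1.0, scheme, 1)
        assert cand.n_folds_used == raw.n_records

    def test_doo_is_train_minus_test(self, cv_setup):
        world, raw, ctx = cv_setup
        lons = raw.records["decimalLongitude"].values
        lats = raw.records["decimalLatitude"].values
        scheme = mx.partition(lons, lats)
        cand = crossvalidate(ctx, raw, tuple(world.env.variables[:2]), "lq", 1.0, scheme, 1)
        assert not cand.failed
        assert cand.doo == pytest.approx(cand.mean_train_auc - cand.mean_test_auc)

    def test_perfect_ranking_gives_test_auc_one(self, small_grid):
        # an environment where one corner is categorically distinct
        layer = np.zeros(small_grid.shape)
        layer[6:, 6:] = 5.0
        env = mx.EnvStack(grid=small_grid, layers={"CHELSA_BIO1": layer})
        native = mx.RegionMask(grid=small_grid, member=np.ones(small_grid.shape, bool))
        rng = np.random.default_rng(0)
        lons = 3.0 + rng.uniform(0.05, 2.9, 6)
        lats = 3.0 + rng.uniform(0.05, 1.9, 6)
        raw = mx.filter_records(records_table(lons, lats, [2010] * 6), native)
        ctx = _SpeciesContext(env, native, n_knots=5)
        scheme = mx.partition(lons, lats)
        cand = crossvalidate(ctx, raw, ("CHELSA_BIO1",), "l", 1.0, scheme, 1)
        # every left-out presence sits in the distinct stratum: it beats the
        # 96 low background cells and midrank-ties the 24 high ones,
        # giving test AUC (96 + 24/2) / 120 = 0.9 in every fold
        assert cand.mean_test_auc == pytest.approx(0.9)


class TestSelectVariables:
    def test_correlated_pair_keeps_more_important(self, small_grid):
        env = mx.make_environment(small_grid, n_climate=3, seed=3, correlated_pair=True)
        native = mx.RegionMask(grid=small_grid, member=np.ones(small_grid.shape, bool))
        # presences driven by BIO1 (and so also by its near-duplicate BIO2)
        rows, cols = native.cells()
        vals = env.layers["CHELSA_BIO1"][rows, cols]
        top = np.argsort(vals)[-12:]
        lons = native.grid.lon_min + (cols[top] + 0.5) * native.grid.cell_size
        lats = native.grid.lat_min + (rows[top] + 0.5) * native.grid.cell_size
        raw = mx.filter_records(records_table(lons, lats, [2010] * 12), native)
        selected, details, cands = mx.select_variables(
            raw, native, env, n_knots=5, seed=0
        )
        assert len(cands) == 6
        assert not ("CHELSA_BIO1" in selected and "CHELSA_BIO2" in selected)
        # kept set is pairwise uncorrelated below the cutoff
        rho = details["spearman"]
        col = {v: i for i, v in enumerate(details["spearman_variables"])}
        for i, a in enumerate(selected):
            for b in selected[i + 1:]:
                assert abs(rho[col[a], col[b]]) < 0.7

    def test_uncorrelated_variables_all_kept(self, small_grid):
        rng = np.random.default_rng(0)
        layers = {f"CHELSA_BIO{i+1}": rng.standard_normal(small_grid.shape) for i in range(3)}
        env = mx.EnvStack(grid=small_grid, layers=layers)
        native = mx.RegionMask(grid=small_grid, member=np.ones(small_grid.shape, bool))
        lons, lats = rng.uniform(0.1, 5.9, 15), rng.uniform(0.1, 4.9, 15)
        raw = mx.filter_records(records_table(lons, lats, [2010] * 15), native)
        selected, _, _ = mx.select_variables(raw, native, env, n_knots=5, seed=0)
        assert set(selected) == set(env.variables)


@pytest.fixture(scope="module")
def grid_result(world):
    raw = make_raw(world, 60, seed=21)
    pc = mx.to_presence_cells(raw)
    th = mx.thin(pc, seed=0)
    elig = mx.eligibility(raw, world.native, n_thinned=th.n_cells)
    sets = {"raw": raw, "presence_cells": pc, "thinned": th}
    result = mx.run_candidate_grid(
        sets, world.native, world.env, world.env.variables[:2], elig, n_knots=5
    )
    return result, elig


class TestRunCandidateGrid:

    def test_thirty_candidates_per_eligible_type(self, grid_result):
        result, elig = grid_result
        n_types = sum([elig.model_1_ok, elig.model_2_ok, elig.model_3_ok])
        assert len(result.grid_candidates) == 30 * n_types
        for model_id in result.best_per_model:
            per_type = [c for c in result.grid_candidates if c.model_id == model_id]
            assert len(per_type) == 30
            assert {(c.combo, c.rm) for c in per_type} == {
                (c, r) for c in mx.FEATURE_COMBOS for r in mx.REG_MULTIPLIERS
            }

    def test_overall_best_maximizes_harmonic_mean(self, grid_result):
        result, _ = grid_result
        hms = {
            mid: _harmonic_mean(rep.auc, rep.auc_pr)
            for mid, rep in result.eval_per_model.items()
        }
        best_hm = hms[result.overall_best.model_id]
        assert best_hm == max(hms.values())

    def test_ineligible_without_model1(self, world):
        raw = make_raw(world, 60, seed=21)
        pc = mx.to_presence_cells(raw)
        elig = mx.Eligibility(
            n_raw_records=raw.n_records, n_occupied_cells=raw.n_cells,
            n_native_cells=world.native.n_cells, n_presence_cells=pc.n_cells,
            n_thinned=0, model_1_ok=False, model_2_ok=True, model_3_ok=False,
        )
        with pytest.raises(ValueError, match="not eligible"):
            mx.run_candidate_grid(
                {"raw": raw, "presence_cells": pc, "thinned": pc},
                world.native, world.env, world.env.variables[:2], elig, n_knots=5,
            )

    def test_selection_is_pure_function_of_candidates(self, grid_result):
        result, _ = grid_result
        for mid in result.best_per_model:
            per_type = [c for c in result.grid_candidates if c.model_id == mid]
            assert select_best_candidate(per_type) is result.best_per_model[mid]
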