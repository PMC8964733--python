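import math

import numpy as np
import pytest
from scipy.stats import spearmanr

import maxrange as mx
from maxrange.maxent import (
    FeatureExpansion,
    MaxentModel,
    aicc,
    raw_from_features,
)


@pytest.fixture(scope="module")
def simple_world():
    grid = mx.GridSpec(0, 0, 20, 20, 0.5)
    return mx.make_world(grid=grid, n_climate=3, n_active=1, n_blobs=2, seed=3)


def background_matrix(world, combo, n_knots=5, variables=None):
    variables = variables or world.env.variables
    exp = mx.build_features(world.env, world.native, variables, combo, n_knots=n_knots)
    rows, cols = world.native.cells()
    X = world.env.values_at(exp.variables, rows, cols)
    return exp, X, exp.transform(X)


class TestBuildFeatures:
    @pytest.mark.parametrize(
        "combo,n_vars,n_knots,expected",
        [
            ("l", 1, 5, 1),
            ("lq", 3, 5, 6),
            ("h", 2, 10, 40),
            ("lqh", 2, 10, 44),
            ("lqhp", 2, 10, 45),
            ("lqhpt", 2, 10, 65),  # 2 + 2 + 2*2*10 + 1 + 2*10
        ],
    )
    def test_feature_counts(self, world, combo, n_vars, n_knots, expected):
        variables = world.env.variables[:n_vars]
        exp = mx.build_features(world.env, world.native, variables, combo, n_knots=n_knots)
        assert exp.n_features == expected

    def test_scaled_features_in_unit_interval(self, simple_world):
        exp, _, F = background_matrix(simple_world, "lqhpt")
        assert F.min() >= 0.0 and F.max() <= 1.0

    def test_empty_variables_error(self, simple_world):
        with pytest.raises(ValueError):
            mx.build_features(simple_world.env, simple_world.native, [], "l")

    def test_invalid_combo_error(self, simple_world):
        with pytest.raises(ValueError, match="combo"):
            mx.build_features(simple_world.env, simple_world.native, ["CHELSA_BIO1"], "xy")

    def test_constant_variable_dropped_with_warning(self, simple_world):
        env = mx.EnvStack(
            grid=simple_world.env.grid,
            layers={**simple_world.env.layers, "FLAT": np.zeros(simple_world.env.grid.shape)},
        )
        with pytest.warns(UserWarning, match="constant"):
            exp = mx.build_features(env, simple_world.native, ["CHELSA_BIO1", "FLAT"], "l")
        assert exp.variables == ("CHELSA_BIO1",)


class TestFitMaxent:
    def test_raw_sums_to_one_over_background(self, simple_world):
        exp, _, F = background_matrix(simple_world, "lq")
        model = mx.fit_maxent(exp, F[::7], F, rm=1.0)
        assert abs(raw_from_features(model, F).sum() - 1.0) < 1e-9

    def test_huge_rm_gives_uniform_null(self, simple_world):
        exp, _, F = background_matrix(simple_world, "lq")
        model = mx.fit_maxent(exp, F[:6], F, rm=1e9)
        assert model.n_nonzero == 0
        raw = raw_from_features(model, F)
        np.testing.assert_allclose(raw, 1.0 / len(F), rtol=1e-12)
        assert model.entropy == pytest.approx(math.log(len(F)))

    def test_presences_at_high_variable_get_positive_coefficient(self, simple_world):
        exp, X, F = background_matrix(simple_world, "l", variables=["CHELSA_BIO1"])
        order = np.argsort(X[:, 0])
        presences = F[order[-15:]]  # concentrated at high values
        model = mx.fit_maxent(exp, presences, F, rm=1.0)
        assert model.beta[0] > 0
        # fitted objective no worse than the null model's
        null = -presences.mean(axis=0) @ np.zeros(1) + math.log(len(F))
        assert model.objective <= null + 1e-9

    def test_restarts_reach_same_objective(self, simple_world):
        exp, _, F = background_matrix(simple_world, "lqh")
        pres = F[::5]
        rng = np.random.default_rng(0)
        objs = []
        for _ in range(3):
            beta0 = rng.normal(0, 0.5, exp.n_features)
            m = mx.fit_maxent(exp, pres, F, rm=1.0, beta0=beta0, tol=1e-10)
            objs.append(m.objective)
        assert np.ptp(objs) < 1e-5

    def test_presence_raw_exceeds_background_mean_when_separable(self, simple_world):
        exp, X, F = background_matrix(simple_world, "l", variables=["CHELSA_BIO1"])
        order = np.argsort(X[:, 0])
        pres_idx = order[-12:]
        model = mx.fit_maxent(exp, F[pres_idx], F, rm=0.5)
        raw = raw_from_features(model, F)
        assert raw[pres_idx].mean() > raw.mean()

    def test_degenerate_background_errors(self, simple_world):
        exp, _, F = background_matrix(simple_world, "l")
        with pytest.raises(ValueError):
            mx.fit_maxent(exp, F[:3], F[:1], rm=1.0)

    def test_niche_recovery_on_known_world(self):
        """Cloglog of an lq fit tracks the true suitability (rank correlation)."""
        rhos = []
        for seed in range(3):
            grid = mx.GridSpec(0, 0, 30, 30, 0.5)
            world = mx.make_world(grid=grid, n_climate=2, n_active=2, n_blobs=1, seed=seed)
            df = mx.simulate_species(world, n_records=100, seed=seed + 50)
            raw_set = mx.filter_records(df, world.native)
            exp, _, F = background_matrix(world, "lq", variables=list(world.niche.active_variables))
            rows, cols = world.native.cells()
            index = {cell: i for i, cell in enumerate(zip(rows.tolist(), cols.tolist()))}
            pres = F[[index[c] for c in raw_set.cells]]
            model = mx.fit_maxent(exp, pres, F, rm=1.0)
            pred = mx.predict_cloglog(model, raw_from_features(model, F))
            rhos.append(spearmanr(pred, world.true_suitability[rows, cols]).statistic)
        assert np.median(rhos) >= 0.8


class TestPrediction:
    def test_toy_hand_computed_raw(self):
        # 1 linear feature over 4 cells with hand-set beta
        exp = FeatureExpansion(
            combo="l",
            variables=("v",),
            lo=np.array([0.0]),
            hi=np.array([1.0]),
            descriptors=[],
        )
        from maxrange.maxent import FeatureDescriptor

        exp.descriptors = [FeatureDescriptor("linear", ("v",))]
        F = np.array([[0.0], [0.25], [0.5], [1.0]])
        beta = np.array([2.0])
        z = np.exp(F @ beta).sum()
        model = MaxentModel(
            expansion=exp, beta=beta, rm=1.0,
            log_normalizer=math.log(z), entropy=1.0, n_presence=4,
        )
        raw = raw_from_features(model, F)
        np.testing.assert_allclose(raw, np.exp(F @ beta).ravel() / z, rtol=1e-12)
        assert raw.sum() == pytest.approx(1.0)

    def test_identical_environment_identical_raw(self, simple_world):
        exp, _, F = background_matrix(simple_world, "lq")
        model = mx.fit_maxent(exp, F[:8], F, rm=1.0)
        raw = raw_from_features(model, np.vstack([F[3], F[3]]))
        assert raw[0] == raw[1]

    def test_missing_variable_errors(self, simple_world):
        exp, _, F = background_matrix(simple_world, "l")
        model = mx.fit_maxent(exp, F[:5], F, rm=1.0)
        bad_env = mx.EnvStack(grid=simple_world.env.grid, layers={"OTHER": np.ones(simple_world.env.grid.shape)})
        with pytest.raises(ValueError, match="missing"):
            mx.predict_raw(model, bad_env, simple_world.native)


class TestCloglog:
    def test_zero_maps_to_zero_and_monotone(self, simple_world):
        exp, _, F = background_matrix(simple_world, "lq")
        model = mx.fit_maxent(exp, F[:6], F, rm=1.0)
        assert mx.predict_cloglog(model, np.array([0.0]))[0] == 0.0
        raw = np.sort(raw_from_features(model, F))
        out = mx.predict_cloglog(model, raw)
        assert (np.diff(out) >= 0).all()
        assert ((out > 0) & (out < 1)).all()

    def test_uniform_model_constant_value(self, simple_world):
        exp, _, F = background_matrix(simple_world, "lq")
        model = mx.fit_maxent(exp, F[:6], F, rm=1e9)
        out = mx.predict_cloglog(model, raw_from_features(model, F))
        np.testing.assert_allclose(out, 1 - math.exp(-1), rtol=1e-9)


class TestPermutationImportance:
    def test_single_variable_gets_100(self, simple_world):
        exp, X, F = background_matrix(simple_world, "l", variables=["CHELSA_BIO1"])
        model = mx.fit_maxent(exp, F[:10], F, rm=1.0)
        imp = mx.permutation_importance(model, X[:10], X, seed=0)
        assert imp == {"CHELSA_BIO1": 100.0}

    def test_zero_coefficient_variable_gets_zero(self, simple_world):
        exp, X, F = background_matrix(
            simple_world, "l", variables=["CHELSA_BIO1", "CHELSA_BIO2"]
        )
        model = mx.fit_maxent(exp, F[:10], F, rm=1.0)
        model.beta = np.array([1.5, 0.0])
        imp = mx.permutation_importance(model, X[:10], X, seed=0)
        assert imp["CHELSA_BIO2"] == 0.0
        assert imp["CHELSA_BIO1"] == 100.0

    def test_importances_sum_to_100(self, simple_world):
        exp, X, F = background_matrix(simple_world, "lqh")
        model = mx.fit_maxent(exp, F[::6], F, rm=1.0)
        imp = mx.permutation_importance(model, X[::6], X, seed=1)
        assert sum(imp.values()) == pytest.approx(100.0, abs=1e-6)

    def test_deterministic_per_seed(self, simple_world):
        exp, X, F = background_matrix(simple_world, "lq")
        model = mx.fit_maxent(exp, F[::6], F, rm=1.0)
        a = mx.permutation_importance(model, X[::6], X, seed=5)
        b = mx.permutation_importance(model, X[::6], X, seed=5)
        assert a == b


class TestAicc:
    def _null_model(self, n_features=2, n_presence=5):
        exp = FeatureExpansion(
            combo="l", variables=("a", "b"), lo=np.zeros(2), hi=np.ones(2), descriptors=[]
        )
        return MaxentModel(
            expansion=exp, beta=np.zeros(n_features), rm=1.0,
            log_normalizer=0.0, entropy=0.0, n_presence=n_presence,
        )

    def test_uniform_null_closed_form(self):
        # K=0, n=5, uniform raw over N=20 cells -> AICc = 10 ln 20
        model = self._null_model()
        value = aicc(model, np.full(5, 1 / 20), 1.0)
        assert value == pytest.approx(10 * math.log(20), rel=1e-12)

    def test_unavailable_when_k_too_large(self):
        model = self._null_model()
        model.beta = np.ones(2)
        model.n_presence = 3  # n - K - 1 = 0
        assert aicc(model, np.full(3, 0.1), 1.0) is mx.UNAVAILABLE

    def test_unavailable_on_zero_presence_density(self):
        model = self._null_model()
        assert aicc(model, np.array([0.1, 0.0, 0.1, 0.1, 0.1]), 1.0) is mx.UNAVAILABLE

    def test_decreasing_in_likelihood(self):
        model = self._null_model()
        low = aicc(model, np.full(5, 0.01), 1.0)
        high = aicc(model, np.full(5, 0.05), 1.0)
        assert high < low


class TestSerialization:
    def test_model_json_round_trip(self, simple_world):
        exp, _, F = background_matrix(simple_world, "lqh")
        model = mx.fit_maxent(exp, F[::5], F, rm=2.0)
        back = MaxentModel.from_json(model.to_json())
        np.testing.assert_allclose(back.beta, model.beta)
        np.testing.assert_allclose(
            raw_from_features(back, F), raw_from_features(model, F), rtol=1e-12
        )
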