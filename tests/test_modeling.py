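"""Spline bases, logistic fitting, likelihood-ratio tests, bootstrap
optimism correction, lasso updating and the small utilities."""

import numpy as np
import pandas as pd
import pytest
from scipy import special

from ari_triage.evaluation import calibration_slope
from ari_triage.modeling import (
    FittedRiskModel,
    ModelSpec,
    bootstrap_optimism,
    build_design,
    epp,
    fit_logistic,
    knot_locations,
    lasso_update,
    lowess_explore,
    lrt_interaction,
    rcs_basis,
)


class TestRcsBasis:
    def test_zero_below_first_knot(self):
        x = np.linspace(30, 34.9, 50)
        basis = rcs_basis(x, [35, 36, 39])
        np.testing.assert_array_equal(basis[:, 1], 0.0)
        np.testing.assert_array_equal(basis[:, 0], x)

    def test_linear_tail_beyond_last_knot(self):
        x = np.linspace(39.5, 45, 200)
        basis = rcs_basis(x, [35, 36, 39])
        second_diff = np.diff(basis[:, 1], 2)
        assert np.abs(second_diff).max() < 1e-9

    def test_hand_expanded_value_at_middle_knot(self):
        # knots {35,36,39} at x=36: only (x-35)^3 is active ->
        # c2 = 1 / (39-35)^2 = 0.0625
        basis = rcs_basis([36.0], [35, 36, 39])
        assert basis[0, 1] == pytest.approx(0.0625)

    def test_matches_truncated_power_expansion_between_knots(self):
        k1, k2, k3 = 35.0, 36.0, 39.0
        x = 37.3
        expected = (
            (x - k1) ** 3 - (x - k2) ** 3 * (k3 - k1) / (k3 - k2)
        ) / (k3 - k1) ** 2
        assert rcs_basis([x], [k1, k2, k3])[0, 1] == pytest.approx(expected)

    def test_non_distinct_knots_rejected(self):
        with pytest.raises(ValueError, match="ascending"):
            rcs_basis([36.0], [35, 35, 39])


class TestKnotLocations:
    def test_percentiles_and_physiological_knot(self):
        rng = np.random.default_rng(0)
        temps = rng.normal(37.0, 0.8, 2000)
        knots = knot_locations(temps)
        p5, p95 = np.percentile(temps, [5, 95])
        np.testing.assert_allclose(knots, [p5, 36.0, p95])

    def test_fallback_to_median_when_36_outside(self):
        rng = np.random.default_rng(1)
        temps = rng.normal(38.5, 0.5, 2000)  # p5 ~ 37.7, above 36
        with pytest.warns(UserWarning, match="falling back"):
            knots = knot_locations(temps)
        p5, p50, p95 = np.percentile(temps, [5, 50, 95])
        np.testing.assert_allclose(knots, [p5, p50, p95])

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match=">= 20"):
            knot_locations(np.full(10, 37.0))

    def test_constant_temperatures_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            knot_locations(np.full(100, 37.0))


def simulate_logistic(n, coefs, intercept, seed=0):
    rng = np.random.default_rng(seed)
    cols = {name: rng.normal(size=n) for name in coefs}
    lp = intercept + sum(c * cols[name] for name, c in coefs.items())
    y = (rng.random(n) < special.expit(lp)).astype(float)
    df = pd.DataFrame(cols)
    df["oxygen_outcome"] = y
    df["age_months"] = rng.uniform(0, 24, n)
    return df


class TestFitLogistic:
    def test_parameter_recovery_large_n(self):
        true = {"x1": 0.8, "x2": -1.2}
        df = simulate_logistic(20000, true, intercept=-2.0, seed=1)
        spec = ModelSpec(
            name="sim", continuous=["x1", "x2"], include_age_main_effect=False
        )
        fit = fit_logistic(df, spec)
        for name, b in true.items():
            assert fit.coefficients[name] == pytest.approx(b, rel=0.10)

    def test_intercept_only_equals_logit_prevalence(self):
        df = simulate_logistic(5000, {}, intercept=-1.5, seed=2)
        spec = ModelSpec(name="null", include_age_main_effect=False)
        fit = fit_logistic(df, spec)
        p = df["oxygen_outcome"].mean()
        assert fit.coefficients["const"] == pytest.approx(special.logit(p), abs=1e-6)

    def test_single_class_outcome_rejected(self):
        df = simulate_logistic(100, {"x1": 1.0}, intercept=0.0, seed=3)
        df["oxygen_outcome"] = 0.0
        spec = ModelSpec(name="bad", continuous=["x1"], include_age_main_effect=False)
        with pytest.raises(ValueError, match="single class"):
            fit_logistic(df, spec)

    def test_separation_raises_advising_penalisation(self):
        df = pd.DataFrame(
            {
                "x1": np.r_[np.zeros(50), np.ones(50)],
                "oxygen_outcome": np.r_[np.zeros(50), np.ones(50)],
                "age_months": 6.0,
            }
        )
        spec = ModelSpec(name="sep", continuous=["x1"], include_age_main_effect=False)
        with pytest.raises(ValueError, match="penalis"):
            fit_logistic(df, spec)
        # a ridge-penalised fit succeeds on the same data
        fit = fit_logistic(df, spec, ridge=0.01)
        assert fit.coefficients["x1"] > 0

    def test_rank_deficient_design_rejected(self):
        df = simulate_logistic(200, {"x1": 1.0}, intercept=-1.0, seed=4)
        df["x2"] = df["x1"]
        spec = ModelSpec(
            name="collinear", continuous=["x1", "x2"], include_age_main_effect=False
        )
        with pytest.raises(ValueError, match="rank deficient"):
            fit_logistic(df, spec)

    def test_calibration_slope_is_one_on_training_data(self, completed_cohort):
        spec = ModelSpec.for_score("lqsofa")
        fit = fit_logistic(completed_cohort, spec)
        slope = calibration_slope(
            fit.predict_risk(completed_cohort), completed_cohort["oxygen_outcome"]
        )
        assert slope == pytest.approx(1.0, abs=1e-6)

    def test_parameter_guard(self):
        with pytest.raises(ValueError, match="guard"):
            ModelSpec(name="huge", continuous=[f"x{i}" for i in range(14)])


class TestModelSerialisation:
    def test_json_round_trip_preserves_predictions(self, completed_cohort, tmp_path):
        spec = ModelSpec.for_score("msirs")
        fit = fit_logistic(completed_cohort, spec)
        path = tmp_path / "model.json"
        fit.to_json(path)
        back = FittedRiskModel.from_json(path)
        np.testing.assert_allclose(
            back.predict_risk(completed_cohort.head(200)),
            fit.predict_risk(completed_cohort.head(200)),
        )
        assert back.knots == fit.knots


class TestLrtInteraction:
    def test_identity_when_product_adds_no_rank(self):
        df = simulate_logistic(500, {"x1": 1.0}, intercept=-1.0, seed=5)
        df["ones"] = 1.0
        spec = ModelSpec(name="m", continuous=["x1"], include_age_main_effect=False)
        stat, dof, p = lrt_interaction(df, spec, "x1", "ones")
        assert (stat, dof, p) == (0.0, 0, 1.0)

    def test_type_i_error_near_nominal(self):
        """With no true interaction, rejection at alpha=0.05 should occur
        in roughly 5% of replicates."""
        rejections = 0
        n_reps = 200
        for rep in range(n_reps):
            df = simulate_logistic(600, {"x1": 0.8, "x2": 0.5}, intercept=-1.0, seed=1000 + rep)
            spec = ModelSpec(
                name="m", continuous=["x1", "x2"], include_age_main_effect=False
            )
            _, _, p = lrt_interaction(df, spec, "x1", "x2")
            rejections += p < 0.05
        rate = rejections / n_reps
        assert 0.01 <= rate <= 0.10

    def test_power_against_strong_interaction(self):
        rng = np.random.default_rng(6)
        n = 3000
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        lp = -1.0 + 0.5 * x1 + 0.5 * x2 + 1.0 * x1 * x2
        y = (rng.random(n) < special.expit(lp)).astype(float)
        df = pd.DataFrame({"x1": x1, "x2": x2, "oxygen_outcome": y, "age_months": 6.0})
        spec = ModelSpec(name="m", continuous=["x1", "x2"], include_age_main_effect=False)
        stat, dof, p = lrt_interaction(df, spec, "x1", "x2")
        assert dof == 1
        assert p < 1e-6


class TestBootstrapOptimism:
    def test_deterministic_under_seed(self, small_cohort):
        from ari_triage.imputation import median_impute_by_outcome
        from ari_triage.cohort_synth import CANDIDATE_PREDICTORS

        comp = median_impute_by_outcome(
            small_cohort, [v for v in CANDIDATE_PREDICTORS if small_cohort[v].isna().any()]
        )
        spec = ModelSpec.for_score("qpelod2")
        a = bootstrap_optimism(comp, spec, B=10, seed=7)
        b = bootstrap_optimism(comp, spec, B=10, seed=7)
        assert a.optimism_auc == b.optimism_auc
        assert a.adjusted_slope == b.adjusted_slope

    def test_adjusted_not_above_apparent_with_signal(self, completed_cohort):
        spec = ModelSpec.for_score("lqsofa")
        res = bootstrap_optimism(completed_cohort, spec, B=20, seed=8)
        assert res.optimism_auc >= 0.0
        assert res.adjusted_auc <= res.apparent_auc

    def test_separable_toy_with_ridge_stays_near_one(self):
        rng = np.random.default_rng(9)
        n = 300
        x = rng.normal(size=n)
        y = (x > 0).astype(float)
        df = pd.DataFrame({"x1": x, "oxygen_outcome": y, "age_months": 6.0})
        spec = ModelSpec(name="toy", continuous=["x1"], include_age_main_effect=False)
        res = bootstrap_optimism(df, spec, B=10, seed=10, ridge=0.05)
        assert res.apparent_auc > 0.99
        assert res.adjusted_auc > 0.97

    def test_too_few_events_rejected(self):
        df = simulate_logistic(200, {"x1": 1.0}, intercept=-5.0, seed=11)
        df.loc[:, "oxygen_outcome"] = 0.0
        df.loc[:4, "oxygen_outcome"] = 1.0
        spec = ModelSpec(name="m", continuous=["x1"], include_age_main_effect=False)
        with pytest.raises(ValueError, match="10 events"):
            bootstrap_optimism(df, spec, B=5, seed=0)


class TestLassoUpdate:
    @pytest.fixture(scope="class")
    def sim(self):
        return simulate_logistic(
            2000, {"x1": 1.5, "x2": 0.0, "x3": 0.0}, intercept=-2.0, seed=12
        )

    def test_infinite_penalty_gives_intercept_only(self, sim):
        spec = ModelSpec(
            name="m", continuous=["x1", "x2", "x3"], include_age_main_effect=False
        )
        fit = lasso_update(sim, spec, lam=10.0)
        assert fit.selected_terms == []
        p = sim["oxygen_outcome"].mean()
        assert fit.coefficients["const"] == pytest.approx(special.logit(p), abs=1e-3)

    def test_zero_penalty_matches_mle(self, sim):
        spec = ModelSpec(
            name="m", continuous=["x1", "x2", "x3"], include_age_main_effect=False
        )
        lasso = lasso_update(sim, spec, lam=0.0)
        mle = fit_logistic(sim, spec)
        for k, v in mle.coefficients.items():
            assert lasso.coefficients[k] == pytest.approx(v, abs=1e-4)

    def test_path_monotone_in_selected_terms(self, sim):
        spec = ModelSpec(
            name="m", continuous=["x1", "x2", "x3"], include_age_main_effect=False
        )
        sizes = []
        for lam in [0.3, 0.1, 0.03, 0.01, 0.003, 0.0]:
            fit = lasso_update(sim, spec, lam=lam)
            sizes.append(len(fit.selected_terms))
        assert sizes == sorted(sizes)

    def test_cv_records_both_lambda_rules(self, sim):
        spec = ModelSpec(
            name="m", continuous=["x1", "x2", "x3"], include_age_main_effect=False
        )
        fit = lasso_update(sim, spec, seed=13, n_folds=5, n_lambdas=12)
        assert fit.extra["lambda_1se"] >= fit.extra["lambda_min"]
        assert fit.penalty == fit.extra["lambda_1se"]

    def test_fewer_folds_than_events_rejected(self):
        df = simulate_logistic(80, {"x1": 1.0}, intercept=-3.5, seed=14)
        df["oxygen_outcome"] = 0.0
        df.loc[:3, "oxygen_outcome"] = 1.0
        spec = ModelSpec(name="m", continuous=["x1"], include_age_main_effect=False)
        with pytest.raises(ValueError, match="folds"):
            lasso_update(df, spec, n_folds=10)


class TestEpp:
    @pytest.mark.parametrize(
        "events,params,expected", [(104, 13, 8), (104, 104, 1), (0, 5, 0), (99, 10, 9)]
    )
    def test_floor_division(self, events, params, expected):
        assert epp(events, params) == expected

    def test_zero_parameters_rejected(self):
        with pytest.raises(ValueError):
            epp(104, 0)


class TestLowess:
    def test_flat_under_null(self):
        rng = np.random.default_rng(15)
        x = rng.normal(size=2000)
        y = (rng.random(2000) < 0.3).astype(float)
        curve = lowess_explore(x, y)
        # flat at the prevalence where data are dense (central 90% of x);
        # the sparse tails are only loosely constrained
        lo, hi = np.quantile(x, [0.05, 0.95])
        central = (curve[:, 0] >= lo) & (curve[:, 0] <= hi)
        assert np.all(np.abs(curve[central, 1] - 0.3) < 0.12)
        assert np.all(np.abs(curve[:, 1] - 0.3) < 0.30)

    def test_smooths_through_a_step(self):
        rng = np.random.default_rng(16)
        x = np.sort(rng.uniform(-1, 1, 2000))
        y = (x > 0).astype(float)
        curve = lowess_explore(x, y, bandwidth=0.3)
        low = curve[curve[:, 0] < -0.5, 1]
        high = curve[curve[:, 0] > 0.5, 1]
        assert low.mean() < 0.1 and high.mean() > 0.9

    def test_bandwidth_one_approaches_global_linear_fit(self):
        rng = np.random.default_rng(17)
        x = rng.uniform(0, 1, 500)
        y = (rng.random(500) < 0.2 + 0.5 * x).astype(float)
        curve = lowess_explore(x, y, bandwidth=1.0)
        coeffs = np.polyfit(x, y, 1)
        linear = np.polyval(coeffs, curve[:, 0])
        assert np.abs(curve[:, 1] - linear).mean() < 0.05

    def test_guards(self):
        with pytest.raises(ValueError, match="50"):
            lowess_explore(np.arange(10.0), np.zeros(10))
        with pytest.raises(ValueError, match="constant"):
            lowess_explore(np.full(100, 2.0), np.zeros(100))


def test_build_design_rate_scaling(completed_cohort):
    spec = ModelSpec.for_score("lqsofa")
    X, _ = build_design(completed_cohort, spec)
    np.testing.assert_allclose(
        X["heart_rate_per10"].to_numpy(),
        completed_cohort["heart_rate"].to_numpy() / 10.0,
    )
    assert "age_months" in X.columns
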