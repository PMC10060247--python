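"""Cox/KM primitives against independent oracles, pooling arithmetic,
and the risk-group estimation driver."""

import numpy as np
import pandas as pd
import pytest

from riskstrat.errors import EstimationError
from riskstrat.estimation import (
    KMDifference,
    build_scope_artifacts,
    cox_loglik,
    cox_stratum_hr,
    estimate_effects,
    km_at,
    km_curve,
    km_stratum_rd,
    pool_absolute,
    pool_relative,
)


def brute_force_breslow(tte, event, z, grid=None):
    """Independent oracle: direct scan of the Breslow partial likelihood."""
    tte = np.asarray(tte, float)
    event = np.asarray(event, int)
    z = np.asarray(z, int)

    def loglik(g):
        ll = 0.0
        for t in sorted(set(tte[event == 1])):
            at_event = (tte == t) & (event == 1)
            d1 = int(z[at_event].sum())
            d = int(at_event.sum())
            risk = tte >= t
            denom = np.sum(np.exp(g * z[risk]))
            ll += g * d1 - d * np.log(denom)
        return ll

    from scipy.optimize import minimize_scalar

    res = minimize_scalar(lambda g: -loglik(g), bounds=(-5, 5), method="bounded",
                          options={"xatol": 1e-10})
    return float(res.x)


class TestCox:
    def test_four_subject_fixture_vs_bruteforce(self):
        # target events at days 1 and 3; comparator events at days 2 and 4
        tte = [1, 3, 2, 4]
        event = [1, 1, 1, 1]
        z = [1, 1, 0, 0]
        fit = cox_stratum_hr(tte, event, z)
        oracle = brute_force_breslow(tte, event, z)
        assert fit.log_hr == pytest.approx(oracle, abs=1e-6)

    @pytest.mark.parametrize("seed", range(6))
    def test_small_random_fixtures_vs_bruteforce(self, seed):
        """<= 8 subjects, ties and censoring included."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 9))
        tte = rng.integers(1, 5, n)
        event = rng.integers(0, 2, n)
        z = rng.integers(0, 2, n)
        # ensure events in both arms (the likelihood can still be monotone)
        event[0] = event[1] = 1
        z[0], z[1] = 1, 0
        oracle = brute_force_breslow(tte, event, z)
        try:
            fit = cox_stratum_hr(tte, event, z)
        except EstimationError:
            # monotone partial likelihood: the bounded oracle rails out
            assert abs(oracle) > 4.5
            return
        assert fit.log_hr == pytest.approx(oracle, abs=1e-6)

    def test_exchangeable_arms_zero_loghr(self):
        tte = [5, 10, 15, 5, 10, 15]
        event = [1, 0, 1, 1, 0, 1]
        z = [1, 1, 1, 0, 0, 0]
        fit = cox_stratum_hr(tte, event, z)
        assert fit.log_hr == pytest.approx(0.0, abs=1e-10)

    def test_permuted_labels_cover_null(self):
        rng = np.random.default_rng(10)
        n = 4000
        tte = rng.exponential(300, n)
        event = (tte < 730).astype(int)
        tte = np.minimum(tte, 730)
        z = rng.integers(0, 2, n)
        fit = cox_stratum_hr(tte, event, z)
        assert abs(fit.log_hr) < 3 * fit.se

    def test_agrees_with_lifelines(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(11)
        n = 500
        z = rng.integers(0, 2, n)
        t = rng.exponential(200 / np.exp(0.5 * z))
        # continuous times: tie-free, so Breslow and Efron coincide and the
        # comparison against lifelines is exact
        tte = np.minimum(t, 365.0)
        event = (t <= 365).astype(int)
        fit = cox_stratum_hr(tte, event, z)
        df = pd.DataFrame({"T": tte, "E": event, "z": z})
        cph = CoxPHFitter()
        cph.fit(df, duration_col="T", event_col="E")
        assert fit.log_hr == pytest.approx(float(cph.params_["z"]), abs=1e-5)
        assert fit.se == pytest.approx(float(cph.standard_errors_["z"]), abs=1e-5)

    def test_inestimable_conditions(self):
        with pytest.raises(EstimationError):
            cox_stratum_hr([1, 2], [1, 1], [1, 1])           # single arm
        with pytest.raises(EstimationError):
            cox_stratum_hr([1, 2], [0, 0], [1, 0])           # no events
        with pytest.raises(EstimationError):
            cox_stratum_hr([1, 2, 3, 4], [1, 1, 0, 0], [1, 1, 0, 0])  # monotone


class TestKM:
    def test_hand_product_limit(self):
        # target: 2 subjects, 1 event at t=100 -> S(730) = 0.5
        # comparator: 2 subjects, no events -> S(730) = 1.0
        tte = [100, 730, 730, 730]
        event = [1, 0, 0, 0]
        z = [1, 1, 0, 0]
        res = km_stratum_rd(tte, event, z, horizon=730)
        assert res.surv_target == pytest.approx(0.5)
        assert res.surv_comparator == pytest.approx(1.0)
        assert res.rd == pytest.approx(-0.5)  # favours the comparator

    def test_multi_step_product_limit_exact(self):
        # 5 subjects one arm: events at 2 (n=5), 4 (n=3), censor at 3, 5, 5
        tte = np.array([2, 3, 4, 5, 5], float)
        event = np.array([1, 0, 1, 0, 0])
        times, surv, var = km_curve(tte, event)
        np.testing.assert_allclose(times, [2, 4])
        np.testing.assert_allclose(surv, [4 / 5, 4 / 5 * 2 / 3])
        greenwood = (4 / 5 * 2 / 3) ** 2 * (1 / (5 * 4) + 1 / (3 * 2))
        assert var[1] == pytest.approx(greenwood, abs=1e-12)

    def test_zero_events_rd_zero(self):
        res = km_stratum_rd([100, 200, 150, 250], [0, 0, 0, 0], [1, 1, 0, 0], 730)
        assert res.rd == 0.0 and res.se == 0.0
        assert res.surv_target == 1.0

    def test_identical_event_patterns_rd_zero(self):
        tte = [50, 300, 730, 50, 300, 730]
        event = [1, 1, 0, 1, 1, 0]
        z = [1, 1, 1, 0, 0, 0]
        res = km_stratum_rd(tte, event, z, 730)
        assert res.rd == pytest.approx(0.0, abs=1e-12)

    def test_greenwood_agrees_with_statsmodels(self):
        from statsmodels.duration.survfunc import SurvfuncRight

        rng = np.random.default_rng(12)
        n = 300
        t = rng.exponential(250, n)
        tte = np.ceil(np.minimum(t, 500))
        event = (t <= 500).astype(int)
        times, surv, var = km_curve(tte, event)
        sf = SurvfuncRight(tte, event)
        s_at, v_at = km_at(times, surv, var, 400.0)
        i = np.searchsorted(sf.surv_times, 400.0, side="right") - 1
        assert s_at == pytest.approx(float(sf.surv_prob[i]), abs=1e-10)
        assert np.sqrt(v_at) == pytest.approx(float(sf.surv_prob_se[i]), abs=1e-8)

    def test_horizon_beyond_last_time_warns(self):
        with pytest.warns(UserWarning, match="carried forward"):
            km_stratum_rd([100, 120, 110, 90], [1, 0, 1, 0], [1, 1, 0, 0], 730)


class TestPooling:
    def test_homogeneous_components(self):
        res = pool_relative([(0.3, 0.1)] * 4)
        assert res.estimate == pytest.approx(0.3)
        assert res.se == pytest.approx(0.1 / 2)

    def test_equal_weight_arithmetic(self):
        res = pool_relative([(0.0, 0.2), (np.log(2), 0.2)])
        assert res.estimate == pytest.approx(np.log(2) / 2)

    def test_infinite_se_component_ignored(self):
        res = pool_relative([(0.5, 0.1), (5.0, np.inf)])
        assert res.estimate == pytest.approx(0.5)

    def test_absolute_weighted_mean(self):
        res = pool_absolute([(0.01, 0.005), (0.03, 0.004)], weights=[100, 300])
        assert res.estimate == pytest.approx(0.025)
        expected_se = np.sqrt(0.25**2 * 0.005**2 + 0.75**2 * 0.004**2)
        assert res.se == pytest.approx(expected_se)

    def test_single_component_passthrough(self):
        res = pool_absolute([(0.02, 0.007)], weights=[50])
        assert res.estimate == 0.02 and res.se == 0.007

    def test_no_components_suppressed(self):
        with pytest.raises(EstimationError) as err:
            pool_relative([(np.nan, np.nan)])
        assert err.value.code == "suppressed"

    @pytest.mark.parametrize("seed", range(5))
    def test_pooled_invariants(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 7))
        comps = [(float(rng.normal(0, 1)), float(rng.uniform(0.05, 1))) for _ in range(k)]
        for res in (pool_relative(comps), pool_absolute(comps, weights=rng.integers(1, 100, k))):
            xs = [c[0] for c in comps]
            assert min(xs) - 1e-12 <= res.estimate <= max(xs) + 1e-12
            assert res.se <= max(c[1] for c in comps) + 1e-12
            assert res.ci95[0] <= res.estimate <= res.ci95[1]


class TestEstimateEffects:
    def test_single_stratum_equals_crude(self, small_population):
        """k_strata=1 reduces to the unadjusted analysis."""
        arts = build_scope_artifacts(
            small_population, None, k_strata=1, folds=3, seed=0,
            ps_kw={"n_lambdas": 10},
        )
        res = estimate_effects(
            small_population, None, outcome_ids=["o1"], artifacts=arts,
            suppress_on_diagnostics=False,
        )
        row = res.table.iloc[0]
        aset = small_population.analysis_set("o1")
        crude = cox_stratum_hr(aset["tte"], aset["event"], aset["arm"])
        assert row["log_hr"] == pytest.approx(crude.log_hr, abs=1e-10)
        assert row["se_log_hr"] == pytest.approx(crude.se, abs=1e-10)
        crude_rd = km_stratum_rd(aset["tte"], aset["event"], aset["arm"], 730)
        assert row["rd"] == pytest.approx(crude_rd.rd, abs=1e-12)

    def test_grid_complete_and_audit_components(self, small_population):
        from riskstrat.prediction import assign_risk_groups, fit_risk_model, predict_risk

        model = fit_risk_model(small_population, "o1", folds=3, seed=0, n_lambdas=15)
        groups = assign_risk_groups(predict_risk(model, small_population), n_quantile_groups=2)
        res = estimate_effects(
            small_population, groups, outcome_ids=["o1", "o2"], k_strata=3,
            folds=3, seed=0,
        )
        # grid: (overall + 2 groups) x 2 outcomes
        assert len(res.table) == 6
        assert set(res.table["scope"]) == {"overall", "RG-1", "RG-2"}
        for key, comps in res.components.items():
            assert len(comps) == 3
        assert {"hr", "hr_lo", "hr_hi", "rd", "rd_lo", "rd_hi"} <= set(res.table.columns)
        est = res.table.dropna(subset=["log_hr"])
        assert ((est["hr_lo"] <= est["hr"]) & (est["hr"] <= est["hr_hi"])).all()
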