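"""Propensity scores, preference transform, matching, strata, overlap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from riskstrat.cohort import ARM_COMPARATOR, ARM_TARGET
from riskstrat.errors import DataError
from riskstrat.propensity import (
    PropensityResult,
    fit_propensity,
    match_1to1,
    overlap_fraction,
    preference_score,
    stratify_by_ps,
)


class TestPreferenceScore:
    def test_equipoise_point(self):
        assert preference_score(0.3, 0.3) == pytest.approx(0.5, abs=1e-12)

    def test_identity_at_balanced_prevalence(self):
        s = np.array([0.1, 0.4, 0.9])
        np.testing.assert_allclose(preference_score(s, 0.5), s, atol=1e-12)

    def test_closed_form(self):
        # logit(F) = logit(0.75) - logit(0.25) = ln 3 + ln 3 => F = 9/10
        assert preference_score(0.75, 0.25) == pytest.approx(0.9, abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        s=st.floats(min_value=0.001, max_value=0.999),
        phi=st.floats(min_value=0.01, max_value=0.99),
    )
    def test_bijective_roundtrip(self, s, phi):
        f = preference_score(s, phi)
        assert 0 < f < 1
        # inverse: logit(S) = logit(F) + logit(phi)
        back = 1.0 / (1.0 + np.exp(-(np.log(f / (1 - f)) + np.log(phi / (1 - phi)))))
        assert back == pytest.approx(s, rel=1e-9, abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        s1=st.floats(min_value=0.01, max_value=0.98),
        d=st.floats(min_value=1e-4, max_value=0.01),
        phi=st.floats(min_value=0.05, max_value=0.95),
    )
    def test_strictly_increasing_in_s(self, s1, d, phi):
        assert preference_score(s1 + d, phi) > preference_score(s1, phi)


class TestOverlap:
    def test_identical_samples(self):
        f = np.random.default_rng(0).random(2000)
        assert overlap_fraction(f, f) == pytest.approx(100.0, abs=1e-9)

    def test_disjoint_supports(self):
        assert overlap_fraction([0.1, 0.15], [0.8, 0.85]) == 0.0

    def test_known_histograms(self):
        # target 60/40 vs comparator 40/60 over the same two bins -> 80%
        t = np.array([0.005] * 60 + [0.015] * 40)
        c = np.array([0.005] * 40 + [0.015] * 60)
        assert overlap_fraction(t, c) == pytest.approx(80.0, abs=1e-9)

    def test_arm_relabel_invariance(self):
        rng = np.random.default_rng(1)
        a, b = rng.random(500), rng.beta(2, 5, 700)
        assert overlap_fraction(a, b) == pytest.approx(overlap_fraction(b, a), abs=1e-12)
        assert 0.0 <= overlap_fraction(a, b) <= 100.0


def _ps(scores: dict, phi=0.5) -> PropensityResult:
    idx = list(scores)
    s = pd.Series([scores[k][1] for k in idx], index=idx)
    arm = pd.Series([scores[k][0] for k in idx], index=idx)
    return PropensityResult(
        scores=s,
        preference=preference_score(s, phi),
        intercept=0.0,
        coefficients=pd.Series(dtype=float),
        phi=phi,
        lambda_=0.01,
        arm=arm,
    )


class TestMatching:
    def test_identical_multisets_fully_matched(self):
        scores = {}
        for i, v in enumerate([0.3, 0.5, 0.7]):
            scores[f"t{i}"] = (ARM_TARGET, v)
            scores[f"c{i}"] = (ARM_COMPARATOR, v)
        res = match_1to1(_ps(scores), caliper=0.2, seed=0)
        assert len(res.pairs) == 3
        assert np.allclose(res.pairs["distance"], 0.0)
        assert res.n_unmatched_target == 0

    def test_disjoint_ranges_no_overlap(self):
        scores = {"t1": (ARM_TARGET, 0.95), "t2": (ARM_TARGET, 0.97),
                  "c1": (ARM_COMPARATOR, 0.03), "c2": (ARM_COMPARATOR, 0.05)}
        with pytest.raises(DataError) as err:
            match_1to1(_ps(scores), caliper=0.2, seed=0)
        assert err.value.code == "no_overlap"

    @pytest.mark.parametrize("seed", [0, 1, 2, 7])
    def test_greedy_against_bruteforce_oracle(self, seed):
        """Greedy pairing reproduced by an independent exhaustive oracle
        under the same seeded processing order."""
        t_scores = {"t1": 0.2, "t2": 0.5, "t3": 0.8}
        c_scores = {"c1": 0.25, "c2": 0.45, "c3": 0.9}
        scores = {k: (ARM_TARGET, v) for k, v in t_scores.items()}
        scores.update({k: (ARM_COMPARATOR, v) for k, v in c_scores.items()})
        res = match_1to1(_ps(scores), caliper=1.0, caliper_scale="raw", seed=seed)

        # oracle: same seeded order over targets, scan all available comparators
        order = np.random.default_rng(seed).permutation(3)
        t_ids = list(t_scores)
        avail = dict(c_scores)
        expected = set()
        for i in order:
            tid = t_ids[i]
            best = min(avail, key=lambda c: (abs(avail[c] - t_scores[tid])))
            if abs(avail[best] - t_scores[tid]) <= 1.0:
                expected.add((tid, best))
                del avail[best]
        got = set(zip(res.pairs["target_id"], res.pairs["comparator_id"]))
        assert got == expected

    def test_caliper_respected_on_logit_scale(self):
        rng = np.random.default_rng(3)
        scores = {}
        for i in range(200):
            scores[f"t{i}"] = (ARM_TARGET, float(np.clip(rng.beta(3, 2), 0.01, 0.99)))
            scores[f"c{i}"] = (ARM_COMPARATOR, float(np.clip(rng.beta(2, 3), 0.01, 0.99)))
        ps = _ps(scores)
        res = match_1to1(ps, caliper=0.2, caliper_scale="std_logit", seed=0)
        logit = lambda p: np.log(p / (1 - p))
        all_logits = logit(ps.scores)
        cal = 0.2 * all_logits.std(ddof=1)
        for _, row in res.pairs.iterrows():
            d = abs(logit(ps.scores[row["target_id"]]) - logit(ps.scores[row["comparator_id"]]))
            assert d <= cal + 1e-12

    def test_matched_covariate_means_equal_with_identical_multisets(self):
        # matching symmetry: perfect overlap ensures equal matched score means
        scores = {}
        vals = np.linspace(0.1, 0.9, 17)
        for i, v in enumerate(vals):
            scores[f"t{i}"] = (ARM_TARGET, float(v))
            scores[f"c{i}"] = (ARM_COMPARATOR, float(v))
        ps = _ps(scores)
        res = match_1to1(ps, caliper=0.2, seed=5)
        mt = ps.scores[res.pairs["target_id"]].mean()
        mc = ps.scores[res.pairs["comparator_id"]].mean()
        assert mt == pytest.approx(mc, abs=1e-12)


class TestStratification:
    def test_uniform_scores_give_equal_strata(self):
        rng = np.random.default_rng(4)
        s = pd.Series(rng.random(10_000))
        res = stratify_by_ps(s, k=5)
        counts = res.counts()
        assert counts.sum() == 10_000
        assert (abs(counts - 2000) <= 1).all()

    def test_sorted_blocks_of_two(self):
        s = pd.Series(np.linspace(0.1, 0.9, 10), index=list("abcdefghij"))
        res = stratify_by_ps(s, k=5)
        expected = [1, 1, 2, 2, 3, 3, 4, 4, 5, 5]
        assert list(res.stratum) == expected

    def test_boundary_value_to_lower_stratum(self):
        s = pd.Series([0.1, 0.2, 0.3, 0.4, 0.5])
        res = stratify_by_ps(s, k=5)
        # each quantile boundary equals an observed score; it stays below
        assert res.stratum.iloc[0] == 1

    def test_degenerate_scores_single_stratum(self):
        s = pd.Series([0.4] * 20)
        with pytest.warns(UserWarning, match="degenerate_ps"):
            res = stratify_by_ps(s, k=5)
        assert res.k == 1
        assert (res.stratum == 1).all()

    def test_boundaries_monotone(self):
        rng = np.random.default_rng(5)
        res = stratify_by_ps(pd.Series(rng.beta(2, 2, 1000)), k=5)
        assert np.all(np.diff(res.boundaries) >= 0)


class TestFitPropensity:
    def test_no_confounding_scores_near_prevalence(self, small_population):
        pop = small_population
        rng = np.random.default_rng(6)
        # replace arms with coin flips independent of covariates
        shuffled = pop.subjects.copy()
        shuffled["arm"] = np.where(rng.random(len(pop)) < 0.4, ARM_TARGET, ARM_COMPARATOR)
        pop2 = type(pop)(shuffled, pop.covariates, pop.tte, pop.event, pop.included, pop.spec)
        ps = fit_propensity(pop2, folds=3, seed=0, n_lambdas=20)
        assert abs(ps.scores.mean() - ps.phi) < 0.02
        assert ps.scores.std() < 0.05
        assert abs(ps.preference.mean() - 0.5) < 0.05

    def test_coefficients_close_to_unpenalized_oracle(self, small_population):
        import statsmodels.api as sm

        ps = fit_propensity(small_population, folds=3, seed=0, lambda_min_ratio=1e-6)
        X = small_population.covariates
        y = (small_population.arm == ARM_TARGET).astype(float)
        oracle = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        for name, val in ps.coefficients.items():
            assert val == pytest.approx(oracle.params[name], abs=0.12)

    def test_single_arm_error(self, small_population):
        pop = small_population
        ids = pop.subject_ids[pop.arm == ARM_TARGET]
        with pytest.raises(DataError) as err:
            fit_propensity(pop, subject_ids=ids)
        assert err.value.code == "arm_missing"
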