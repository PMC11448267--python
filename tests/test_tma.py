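"""H-score resolution, log-rank, cut-point search, KM and associations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy.stats import hypergeom

from pdometab import tma
from pdometab.synthetic import default_scenario, gen_tma_cohort


class TestHScore:
    def test_range_extremes(self):
        top = tma.CoreScore("c", "a", pct_positive=100, intensity=3)
        assert tma.h_score(top) == 300
        negative = tma.CoreScore("c", "a", pct_positive=0, intensity=2)
        assert tma.h_score(negative) == 0

    def test_direct_product(self):
        assert tma.h_score(tma.CoreScore("c", "a", 50, 2)) == 100

    @settings(derandomize=True, max_examples=50)
    @given(hst.floats(0, 100), hst.sampled_from([0, 1, 2, 3]))
    def test_bounds_property(self, pct, intensity):
        score = tma.h_score(tma.CoreScore("c", "a", pct, intensity))
        assert 0 <= score <= 300

    @pytest.mark.parametrize("pct,intensity", [(-1, 1), (101, 1), (50, 4), (50, -1)])
    def test_invalid_inputs_rejected(self, pct, intensity):
        with pytest.raises(ValueError):
            tma.CoreScore("c", "a", pct, intensity)

    def test_weighted_variant(self):
        assert tma.weighted_h_score({1: 20, 2: 30, 3: 10}) == 20 + 60 + 30
        with pytest.raises(ValueError):
            tma.weighted_h_score({1: 80, 2: 30})


class TestCaseScore:
    def _cores(self, scores):
        return [
            tma.CoreScore("c", f"k{i}", pct, intensity)
            for i, (pct, intensity) in enumerate(scores)
        ]

    def test_max_rule(self):
        cores = self._cores([(60, 2), (80, 1)])  # H = 120, 80
        assert tma.case_score(cores) == 120

    def test_single_core(self):
        assert tma.case_score(self._cores([(45, 1)])) == 45

    def test_permutation_invariance(self):
        cores = self._cores([(60, 2), (80, 1)])
        assert tma.case_score(cores) == tma.case_score(cores[::-1])

    def test_zero_cores_rejected(self):
        with pytest.raises(ValueError):
            tma.case_score([])

    def test_case_dominates_cores(self):
        cores = self._cores([(30, 3), (95, 1), (10, 2)])
        cs = tma.case_score(cores)
        assert all(cs >= tma.h_score(c) for c in cores)


class TestLogrank:
    def test_identical_arms_null(self):
        time = [1, 2, 3, 1, 2, 3]
        event = [1, 1, 0, 1, 1, 0]
        group = [True, True, True, False, False, False]
        res = tma.logrank(time, event, group)
        assert res.statistic == pytest.approx(0.0)
        assert res.pvalue == pytest.approx(1.0)

    def test_hand_enumerated_example(self):
        # arm A events at 1,2; arm B events at 3,4. Risk tables:
        # t=1: n=4, n_A=2, d=1 -> E=0.5, V=0.25
        # t=2: n=3, n_A=1, d=1 -> E=1/3, V=2/9
        # t=3: n=2, n_A=0, d=1 -> E=0,   V=0
        # t=4: n=1, n_A=0, d=1 -> E=0,   V=0
        # O-E = 2 - 5/6 = 7/6; V = 0.25 + 2/9 = 17/36 -> chi2 = (7/6)^2/(17/36)
        res = tma.logrank([1, 2, 3, 4], [1, 1, 1, 1], [True, True, False, False])
        assert res.statistic == pytest.approx((7 / 6) ** 2 / (17 / 36))

    def test_time_scaling_invariance(self):
        rng = np.random.default_rng(0)
        time = rng.exponential(10, 40)
        event = rng.random(40) < 0.8
        group = rng.random(40) < 0.5
        a = tma.logrank(time, event, group)
        b = tma.logrank(time * 7.3, event, group)
        assert a.statistic == pytest.approx(b.statistic)

    def test_matches_lifelines_oracle(self):
        from lifelines.statistics import logrank_test

        rng = np.random.default_rng(1)
        time = np.round(rng.exponential(10, 60), 1)  # rounding induces ties
        event = rng.random(60) < 0.7
        group = rng.random(60) < 0.4
        ours = tma.logrank(time, event, group)
        ref = logrank_test(time[group], time[~group], event[group], event[~group])
        assert ours.statistic == pytest.approx(ref.test_statistic)
        assert ours.pvalue == pytest.approx(ref.p_value)

    def test_empty_arm_rejected(self):
        with pytest.raises(ValueError):
            tma.logrank([1, 2], [1, 1], [True, True])


class TestCutpoint:
    def test_forced_geometry(self):
        cases = pd.DataFrame(
            {
                "h_score": [10, 10, 90, 90],
                "time_months": [1, 2, 10, 10],
                "dss_event": [1, 1, 0, 0],
            }
        )
        res = tma.find_cutpoint(cases, min_group_frac=0.25)
        assert res.cut == 50.0
        assert len(res.profile) == 1

    def test_profile_matches_brute_force(self):
        from lifelines.statistics import logrank_test

        sc = default_scenario(seed=13)
        sc.tma["n_cases"] = 50
        cohort, _ = gen_tma_cohort(sc)
        cases = tma.cases_from_cohort(cohort)
        res = tma.find_cutpoint(cases)
        scores = cases["h_score"].to_numpy()
        uniq = np.unique(scores)
        expected_cuts = [
            c
            for c in (uniq[:-1] + uniq[1:]) / 2
            if min((scores < c).sum(), (scores >= c).sum()) >= 0.1 * len(scores)
        ]
        assert np.allclose(res.profile["cut"], expected_cuts)
        for _, row in res.profile.iterrows():
            low = scores < row["cut"]
            ref = logrank_test(
                cases.loc[low, "time_months"], cases.loc[~low, "time_months"],
                cases.loc[low, "dss_event"], cases.loc[~low, "dss_event"],
            )
            assert row["statistic"] == pytest.approx(ref.test_statistic)

    def test_cut_is_argmax_and_sizes_consistent(self):
        sc = default_scenario(seed=2)
        cohort, _ = gen_tma_cohort(sc)
        cases = tma.cases_from_cohort(cohort)
        res = tma.find_cutpoint(cases)
        assert res.statistic == res.profile["statistic"].max()
        assert res.n_low + res.n_high == len(cases)

    def test_size_constraint_unsatisfiable_rejected(self):
        cases = pd.DataFrame(
            {"h_score": [10] * 9 + [90], "time_months": range(1, 11),
             "dss_event": [1] * 10}
        )
        with pytest.raises(ValueError):
            tma.find_cutpoint(cases, min_group_frac=0.3)

    def test_recovers_planted_cut(self):
        sc = default_scenario(seed=4)
        cohort, truth = gen_tma_cohort(sc)
        res = tma.find_cutpoint(tma.cases_from_cohort(cohort))
        grid = res.profile["cut"].to_numpy()
        step = np.diff(grid).max()
        assert abs(res.cut - truth["true_cut"]) <= 2 * step


class TestKm:
    def test_all_events_same_time(self):
        med, undefined, _ = tma.km_summary([5, 5, 5], [1, 1, 1])
        assert med == 5 and not undefined

    def test_all_censored_undefined(self):
        med, undefined, _ = tma.km_summary([5, 6, 7], [0, 0, 0])
        assert undefined and np.isnan(med)

    def test_exponential_median_closed_form(self):
        rng = np.random.default_rng(5)
        lam = 0.05
        time = rng.exponential(1 / lam, size=10_000)
        med, undefined, _ = tma.km_summary(time, np.ones_like(time))
        assert not undefined
        assert med == pytest.approx(np.log(2) / lam, rel=0.02)

    def test_curve_is_valid_survival_function(self):
        rng = np.random.default_rng(6)
        time = rng.exponential(10, 200)
        event = rng.random(200) < 0.7
        _, _, curve = tma.km_summary(time, event)
        s = curve["survival"].to_numpy()
        assert s[0] == pytest.approx(1.0)
        assert np.all(np.diff(s) <= 1e-12)


class TestAssociations:
    def _cases(self, n=240, seed=0, dependent=False):
        rng = np.random.default_rng(seed)
        h = rng.uniform(0, 300, n)
        low = h < 55
        p = np.where(low, 0.8, 0.2) if dependent else 0.5
        return pd.DataFrame(
            {
                "h_score": h,
                "time_months": rng.exponential(20, n),
                "dss_event": rng.random(n) < 0.7,
                "lvi": (rng.random(n) < p).astype(int),
                "pni": (rng.random(n) < 0.5).astype(int),
                "grade": rng.choice([1, 2, 3], n),
                "subtype": rng.choice(["basal-like", "classical"], n),
            }
        )

    def test_dependent_covariate_detected(self):
        out = tma.covariate_associations(self._cases(dependent=True), cut=55)
        assert out.set_index("covariate").loc["lvi", "p"] < 0.001

    def test_null_calibration_rejection_rate(self):
        """With covariates independent of the split, Fisher rejects at most
        ~alpha of the time (exact tests are conservative under discreteness)."""
        hits = 0
        reps = 200
        for seed in range(reps):
            out = tma.covariate_associations(self._cases(seed=seed), cut=55)
            hits += out.set_index("covariate").loc["lvi", "p"] <= 0.05
        assert 0.005 <= hits / reps <= 0.08

    def test_perfect_association_minimal_fisher_p(self):
        # 2x2 with margins (10, 10): minimal two-sided p attainable is the
        # hypergeometric mass of the two extreme tables
        n = 20
        cases = pd.DataFrame(
            {
                "h_score": [10.0] * 10 + [90.0] * 10,
                "time_months": np.arange(1, n + 1, dtype=float),
                "dss_event": [1] * n,
                "lvi": [1] * 10 + [0] * 10,
            }
        )
        out = tma.covariate_associations(cases, cut=55)
        minimal = 2 * hypergeom.pmf(10, 20, 10, 10)
        assert out.set_index("covariate").loc["lvi", "p"] == pytest.approx(minimal)

    def test_grade_uses_lr_chisq(self):
        out = tma.covariate_associations(self._cases(), cut=55)
        assert out.set_index("covariate").loc["grade", "test"] == "lr_chisq"


class TestScoresBySubtype:
    def test_identical_groups_null(self):
        cases = pd.DataFrame(
            {"h_score": [10, 20, 30] * 2,
             "subtype": ["basal-like"] * 3 + ["classical"] * 3}
        )
        assert tma.compare_scores_by_subtype(cases)["p"] == pytest.approx(1.0)

    def test_complete_separation_minimal_p(self):
        cases = pd.DataFrame(
            {"h_score": [1, 2, 3, 4, 5, 10, 11, 12, 13, 14],
             "subtype": ["basal-like"] * 5 + ["classical"] * 5}
        )
        out = tma.compare_scores_by_subtype(cases)
        # exact enumeration: 2 extreme rank configurations out of C(10,5)
        assert out["p"] == pytest.approx(2 / 252)

    def test_planted_direction(self):
        sc = default_scenario(seed=9)
        cohort, _ = gen_tma_cohort(sc)
        out = tma.compare_scores_by_subtype(tma.cases_from_cohort(cohort))
        assert out["basal-like"]["median"] < out["classical"]["median"]

    def test_missing_subtype_rejected(self):
        cases = pd.DataFrame({"h_score": [1, 2], "subtype": ["classical", "classical"]})
        with pytest.raises(ValueError):
            tma.compare_scores_by_subtype(cases)
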