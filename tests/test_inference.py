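"""Effect sizes, ANOVA, permutation null, standardization, classification."""

from __future__ import annotations

import math

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from scalediv.inference import (
    AnalysisConfig,
    alpha_scale_test,
    build_standardization_plan,
    classify_scale_dependence,
    combine_pvalues_harmonic,
    gamma_scale_permutation_test,
    log_response_ratio,
    replicate_table,
    run_site_taxon_analysis,
    site_permutation_tests,
)
from scalediv.data_model import StratumError

from conftest import make_table


class TestLogResponseRatio:
    def test_equal_groups_zero(self):
        assert log_response_ratio(5, 5) == 0.0

    def test_e_fold_is_one(self):
        for x in (0.1, 1.0, 42.0):
            assert log_response_ratio(math.e * x, x) == pytest.approx(1.0)

    @given(a=st.floats(0.01, 1e6), b=st.floats(0.01, 1e6))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_antisymmetry(self, a, b):
        assert log_response_ratio(a, b) == pytest.approx(
            -log_response_ratio(b, a), abs=1e-12
        )

    def test_nonpositive_is_missing(self):
        assert np.isnan(log_response_ratio(0.0, 1.0))
        assert np.isnan(log_response_ratio(1.0, -2.0))


class TestAlphaScaleTest:
    def test_no_effect_no_variance(self):
        eff = alpha_scale_test([3, 3], [3, 3])
        assert eff.lrr == 0.0 and eff.p_value == 1.0

    def test_identical_samples(self):
        eff = alpha_scale_test([1, 2, 3], [1, 2, 3])
        assert eff.statistic == 0.0 and eff.p_value == 1.0 and eff.lrr == 0.0

    def test_f_equals_t_squared(self):
        # two-group ANOVA F is the square of the pooled-variance t statistic
        a, b = [0, 1, 2], [10, 11, 12]
        eff = alpha_scale_test(a, b)
        t, p = scipy.stats.ttest_ind(a, b, equal_var=True)
        assert eff.statistic == pytest.approx(t**2, rel=1e-12)
        assert eff.statistic == pytest.approx(150.0, rel=1e-12)
        assert eff.p_value == pytest.approx(p, rel=1e-9)

    def test_permutation_p_option(self):
        # groups large enough that re-drawing the observed split is unlikely
        rng = np.random.default_rng(5)
        a = [0.0, 1.0, 2.0, 0.5, 1.5, 2.5, 1.0, 2.0]
        b = [x + 50 for x in a]
        eff = alpha_scale_test(a, b, n_perm=199, rng=rng)
        assert eff.method == "anova_permutation"
        assert eff.p_value <= 0.01
        assert eff.p_value >= 1 / 200

    def test_too_few_values_undetermined(self):
        eff = alpha_scale_test([1.0], [2.0, 3.0])
        assert np.isnan(eff.p_value)


class TestHarmonicMean:
    def test_equal_values(self):
        assert combine_pvalues_harmonic([0.5, 0.5]) == pytest.approx(0.5)

    def test_worked_value(self):
        # independent reciprocal-sum computation: 2 / (1/0.01 + 1/1.0)
        assert combine_pvalues_harmonic([0.01, 1.0]) == pytest.approx(
            2 / 101, abs=1e-12
        )

    def test_single_value_identity(self):
        assert combine_pvalues_harmonic([0.37]) == pytest.approx(0.37)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            combine_pvalues_harmonic([])
        with pytest.raises(ValueError):
            combine_pvalues_harmonic([0.0, 0.5])

    @given(ps=st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=10))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_never_exceeds_arithmetic_mean(self, ps):
        assert combine_pvalues_harmonic(ps) <= np.mean(ps) + 1e-12


def two_plot_table(rows_p, rows_m, plots_p=1, plots_m=1):
    per_p = len(rows_p) // plots_p
    per_m = len(rows_m) // plots_m
    metas = [(f"p{i // per_p + 1}", "pasture") for i in range(len(rows_p))]
    metas += [(f"m{i // per_m + 1}", "meadow") for i in range(len(rows_m))]
    taxa = [f"t{j}" for j in range(len(rows_p[0]))]
    return make_table(np.vstack([rows_p, rows_m]), taxa, metas)


class TestGammaPermutation:
    def test_exchangeable_duplicate_groups_p_one(self):
        rows = [[4, 2, 1], [9, 1, 0]]
        t = two_plot_table(rows, rows)
        res = site_permutation_tests(t, "s1", n_perm=99, rng=1)
        for m in ("N", "S", "S_n", "S_PIE"):
            assert res[m].lrr == 0.0
            assert res[m].p_value == 1.0

    def test_minimum_p_add_one_rule(self):
        rng = np.random.default_rng(0)
        rows_p = rng.multinomial(500, [0.96, 0.01, 0.01, 0.01, 0.01], size=10)
        rows_m = rng.multinomial(500, [0.2] * 5, size=10)
        t = two_plot_table(rows_p, rows_m)
        eff = gamma_scale_permutation_test(t, "s1", metric="S_PIE",
                                           n_perm=199, seed=3)
        assert eff.p_value >= 1 / 200
        assert eff.p_value == pytest.approx(1 / 200)

    def test_reproducible_and_label_order_invariant(self):
        rng = np.random.default_rng(2)
        rows = rng.poisson(5.0, size=(8, 6))
        t = two_plot_table(rows[:4], rows[4:])
        r1 = site_permutation_tests(t, "s1", n_perm=49, rng=11)
        r2 = site_permutation_tests(t, "s1", n_perm=49, rng=11)
        assert all(r1[m].p_value == r2[m].p_value for m in r1)

    def test_plot_level_unit_runs(self):
        rng = np.random.default_rng(3)
        rows = rng.poisson(8.0, size=(12, 5))
        t = two_plot_table(rows[:6], rows[6:], plots_p=2, plots_m=2)
        res = site_permutation_tests(t, "s1", n_perm=49, rng=1, unit="plot")
        assert all(np.isfinite(res[m].p_value) for m in ("N", "S_n"))


class TestStandardizationPlan:
    def plan_for(self, plots_p, plots_m):
        rows, metas = [], []
        for i in range(plots_p):
            for q in range(2):
                rows.append([3, 2]); metas.append((f"p{i + 1}", "pasture"))
        for i in range(plots_m):
            for q in range(2):
                rows.append([2, 3]); metas.append((f"m{i + 1}", "meadow"))
        t = make_table(rows, ["A", "B"], metas)
        return t, build_standardization_plan(t, "s1", seed=0)

    @pytest.mark.parametrize("pp,pm,expected", [(3, 1, 3), (4, 2, 6), (3, 3, 1)])
    def test_replicate_counts(self, pp, pm, expected):
        _, plan = self.plan_for(pp, pm)
        assert plan.n_replicates == expected
        assert len(set(plan.plot_combinations)) == expected

    def test_balanced_plan_is_identity(self):
        t, plan = self.plan_for(2, 2)
        assert plan.balanced
        rep = replicate_table(t, plan, plan.plot_combinations[0])
        assert rep.sample_ids == t.sample_ids

    def test_replicates_keep_smaller_group_whole(self):
        t, plan = self.plan_for(3, 1)
        for combo in plan.plot_combinations:
            rep = replicate_table(t, plan, combo)
            meadow = [s for s in rep.samples if s.management == "meadow"]
            pasture_plots = {s.plot for s in rep.samples
                             if s.management == "pasture"}
            assert len(meadow) == 2
            assert len(pasture_plots) == 1

    def test_cap_draws_distinct_subsets(self):
        rows, metas = [], []
        for i in range(10):
            rows.append([3, 2]); metas.append((f"p{i + 1}", "pasture"))
        rows += [[2, 3], [2, 3]]
        metas += [("m1", "meadow"), ("m2", "meadow")]
        t = make_table(rows, ["A", "B"], metas)
        plan = build_standardization_plan(t, "s1", cap=20, seed=4)
        assert plan.n_replicates == 20
        assert len(set(plan.plot_combinations)) == 20


class TestClassification:
    def mk(self, metric, lrr, p):
        from scalediv.inference import EffectTest
        return EffectTest("s", "g", metric, "alpha", lrr, 0.0, p, 0, "anova")

    def test_qualitative_reversal(self):
        c = classify_scale_dependence(self.mk("S_n", 0.3, 0.01),
                                      self.mk("S_n", -0.2, 0.02))
        assert c.category == "qualitative_reversal"

    def test_alpha_only(self):
        c = classify_scale_dependence(self.mk("S_n", 0.3, 0.01),
                                      self.mk("S_n", 0.1, 0.40))
        assert c.category == "alpha_only"

    def test_gamma_only_and_consistent_and_none(self):
        assert classify_scale_dependence(
            self.mk("S", 0.3, 0.2), self.mk("S", 0.1, 0.01)
        ).category == "gamma_only"
        assert classify_scale_dependence(
            self.mk("S", 0.3, 0.01), self.mk("S", 0.1, 0.01)
        ).category == "consistent_both"
        assert classify_scale_dependence(
            self.mk("S", 0.3, 0.2), self.mk("S", 0.1, 0.4)
        ).category == "none"

    def test_identity_line_flag(self):
        c = classify_scale_dependence(self.mk("S", 0.25, 0.5),
                                      self.mk("S", 0.25, 0.5))
        assert c.on_identity_line

    def test_missing_effect_undetermined(self):
        c = classify_scale_dependence(self.mk("S", float("nan"), 0.5),
                                      self.mk("S", 0.25, 0.5))
        assert c.category == "undetermined"


class TestSiteAnalysis:
    def test_duplicate_groups_all_lrr_zero(self):
        rng = np.random.default_rng(9)
        rows = rng.poisson(6.0, size=(4, 5))
        t = two_plot_table(rows, rows)
        res = run_site_taxon_analysis(t, "s1", "g",
                                      AnalysisConfig(n_perm=49, seed=1))
        for comb in res.combined.values():
            assert comb.lrr == 0.0

    def test_single_management_type_is_error(self):
        t = make_table([[3, 2], [2, 3]], ["A", "B"],
                       [("p1", "pasture"), ("p2", "pasture")])
        with pytest.raises(StratumError):
            run_site_taxon_analysis(t, "s1", "g", AnalysisConfig(seed=1))

    def test_balanced_design_single_replicate(self, two_group_table):
        res = run_site_taxon_analysis(two_group_table, "s1", "g",
                                      AnalysisConfig(n_perm=49, seed=2))
        assert res.plan.balanced and res.plan.n_replicates == 1
        assert set(res.classifications) == {"N", "S", "S_n", "S_PIE"}

    def test_unbalanced_design_combines_replicates(self):
        rng = np.random.default_rng(4)
        rows_p = rng.poisson(10.0, size=(6, 6))
        rows_m = rng.poisson(10.0, size=(2, 6))
        t = two_plot_table(rows_p, rows_m, plots_p=3, plots_m=1)
        res = run_site_taxon_analysis(t, "s1", "g",
                                      AnalysisConfig(n_perm=49, seed=3))
        assert res.plan.n_replicates == 3
        comb = res.combined[("S_n", "gamma")]
        assert len(comb.replicates) == 3
        lrrs = [r.lrr for r in comb.replicates]
        assert comb.lrr == pytest.approx(np.mean(lrrs))
        ps = [r.p_value for r in comb.replicates]
        assert comb.p_value == pytest.approx(combine_pvalues_harmonic(ps))
        assert min(ps) - 1e-12 <= comb.p_value <= max(ps) + 1e-12
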