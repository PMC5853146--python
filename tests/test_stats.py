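"""Group comparisons, regression adjustments, heterogeneity, stratification."""

import itertools
import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from glycoce.stats import (
    SingularityError,
    add_seropositive,
    adjusted_comparison,
    apply_bonferroni,
    bonferroni,
    categorize,
    expression_fold_change,
    kruskal_dunn,
    mann_whitney,
    slope_heterogeneity,
    treatment_contrast,
)
from glycoce.synth import TABLE1_PRESETS, generate_cohort, generate_expression_table


def exact_mw_two_sided_p(x, y):
    """Independent oracle: full enumeration over all group assignments."""
    pooled = list(x) + list(y)
    n, m = len(x), len(y)

    def u_stat(xs, ys):
        return sum((a > b) + 0.5 * (a == b) for a in xs for b in ys)

    obs = u_stat(x, y)
    total = n * m
    lo, hi = min(obs, total - obs), max(obs, total - obs)
    count = 0
    n_perm = 0
    idx = list(range(n + m))
    for comb in itertools.combinations(idx, n):
        comb_set = set(comb)
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in idx if i not in comb_set]
        u = u_stat(xs, ys)
        count += (u <= lo) or (u >= hi)
        n_perm += 1
    return count / n_perm


class TestMannWhitney:
    def test_identical_samples_give_p_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = mann_whitney(x, x)
        assert res.p_value > 0.95
        assert res.statistic == pytest.approx(len(x) ** 2 / 2)

    def test_fully_separated_groups_exact_p(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)  # 2/20 assignments as extreme

    @pytest.mark.parametrize("n,m,seed", [(3, 3, 0), (4, 5, 1), (6, 4, 2), (8, 8, 3)])
    def test_agrees_with_full_enumeration(self, n, m, seed):
        rng = np.random.default_rng(seed)
        x = list(rng.normal(0, 1, n))
        y = list(rng.normal(0.5, 1, m))
        res = mann_whitney(x, y)
        assert res.p_value == pytest.approx(exact_mw_two_sided_p(x, y), abs=1e-10)

    def test_reports_medians_and_iqrs(self):
        res = mann_whitney([1, 2, 3, 4, 100], [5, 6, 7], ("a", "b"))
        assert res.groups == ("a", "b")
        assert res.medians[0] == 3.0
        assert res.iqrs[1] == (5.5, 6.5)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mann_whitney([], [1.0])


class TestKruskalDunn:
    def test_fewer_than_three_groups_rejected(self):
        with pytest.raises(ValueError, match="3 groups"):
            kruskal_dunn({"a": [1, 2], "b": [3, 4]})

    def test_identical_groups_omnibus_near_one(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0, 1, 30)
        res = kruskal_dunn({"a": vals, "b": vals, "c": vals})
        assert res.p_omnibus > 0.9

    def test_constant_data_handled(self):
        res = kruskal_dunn({"a": [1, 1], "b": [1, 1], "c": [1, 1]})
        assert res.p_omnibus == 1.0

    def test_well_separated_groups_highly_significant(self):
        rng = np.random.default_rng(1)
        hit = 0
        for _ in range(50):
            g = {k: rng.normal(5 * i, 1, 20) for i, k in enumerate("abc")}
            if kruskal_dunn(g).p_omnibus < 0.001:
                hit += 1
        assert hit >= 49  # power > 99% at a 5 SD shift

    def test_tied_heavy_data_matches_midrank_hand_computation(self):
        # a={1,1} b={1,2} c={2,2}: mid-ranks 2,2 | 2,5 | 5,5
        # H = 12/(6*7) * (16/2 + 49/2 + 100/2) - 3*7 = 18/7
        # tie correction C = 1 - (2*(27-3))/(216-6) = 27/35 -> H' = 10/3
        res = kruskal_dunn({"a": [1, 1], "b": [1, 2], "c": [2, 2]})
        assert res.h_statistic == pytest.approx(10 / 3)
        assert res.p_omnibus == pytest.approx(math.exp(-5 / 3))
        # Dunn a-vs-c: z = (2-5)/sqrt((3.5-0.8)*(1/2+1/2)) = -3/sqrt(2.7)
        pair_ac = [p for p in res.pairwise if p.groups == ("a", "c")][0]
        assert pair_ac.statistic == pytest.approx(-3 / math.sqrt(2.7))
        raw = 2 * sps.norm.sf(3 / math.sqrt(2.7))
        assert pair_ac.p_value == pytest.approx(raw)
        assert pair_ac.p_bonferroni == pytest.approx(min(1.0, 3 * raw))


class TestBonferroni:
    def test_printed_example(self):
        assert bonferroni(0.0003, 12) == pytest.approx(0.0036)

    def test_printed_significance_threshold(self):
        assert round(0.05 / 12, 4) == 0.0042

    def test_clamped_at_one_and_zero_fixed_point(self):
        assert bonferroni(0.5, 12) == 1.0
        assert bonferroni(0.0, 7) == 0.0

    def test_monotone_in_p_and_m(self):
        grid = np.linspace(0, 1, 21)
        for m in (1, 3, 12):
            vals = [bonferroni(p, m) for p in grid]
            assert all(b >= a for a, b in zip(vals, vals[1:]))
        for p in grid:
            assert bonferroni(p, 12) >= bonferroni(p, 3)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            bonferroni(1.2)
        with pytest.raises(ValueError):
            bonferroni(0.5, 0)

    def test_double_application_guarded(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        apply_bonferroni(res)
        assert res.p_bonferroni == pytest.approx(min(1.0, 12 * res.p_value))
        with pytest.raises(ValueError, match="already"):
            apply_bonferroni(res)


def null_frame(rng, n=200, effect=0.0):
    g = np.repeat(["A", "B"], n // 2)
    age = rng.normal(50, 10, n)
    sex = rng.choice(["F", "M"], n)
    y = 0.01 * age + effect * (g == "B") + rng.normal(0, 0.3, n)
    return pd.DataFrame({"y": y, "g": g, "age": age, "sex": sex})


class TestAdjustedComparison:
    def test_age_location_shift_leaves_group_coefficient_unchanged(self):
        df = null_frame(np.random.default_rng(0), effect=0.2)
        fit = adjusted_comparison(df, "y", "g")
        shifted = df.assign(age=df.age + 37.0)
        fit2 = adjusted_comparison(shifted, "y", "g")
        assert fit2.params["g[B]"] == pytest.approx(fit.params["g[B]"])

    def test_null_coverage_of_group_ci(self):
        rng = np.random.default_rng(1)
        cover = sum(
            1
            for _ in range(100)
            if (lambda ci: ci[0] <= 0 <= ci[1])(
                adjusted_comparison(null_frame(rng), "y", "g").conf_int["g[B]"]
            )
        )
        assert cover >= 93

    def test_true_group_effect_recovered(self):
        rng = np.random.default_rng(2)
        est = [
            adjusted_comparison(null_frame(rng, n=300, effect=0.3), "y", "g").params["g[B]"]
            for _ in range(100)
        ]
        assert abs(np.median(est) - 0.3) < 0.05

    def test_collinear_design_raises_naming_columns(self):
        df = null_frame(np.random.default_rng(3))
        df["age2"] = df["age"]
        with pytest.raises(SingularityError, match="age"):
            adjusted_comparison(df, "y", "g", covariates=("age", "age2"))

    def test_missing_rows_dropped_and_counted(self):
        df = null_frame(np.random.default_rng(4))
        df.loc[df.index[:7], "age"] = np.nan
        fit = adjusted_comparison(df, "y", "g")
        assert fit.n_dropped == 7
        assert fit.n_used == len(df) - 7

    def test_logistic_variant_two_groups(self):
        df = null_frame(np.random.default_rng(5), effect=0.5)
        fit = adjusted_comparison(df, "y", "g", model="logistic")
        assert fit.model == "logistic"
        assert fit.params["y"] > 0  # higher trait -> higher odds of group B
        assert fit.pvalues["y"] < 0.01

    def test_row_permutation_invariance(self):
        df = null_frame(np.random.default_rng(6), effect=0.1)
        fit = adjusted_comparison(df, "y", "g")
        shuffled = df.sample(frac=1.0, random_state=0)
        fit2 = adjusted_comparison(shuffled, "y", "g")
        assert fit2.params["g[B]"] == pytest.approx(fit.params["g[B]"])
        assert fit2.pvalues["g[B]"] == pytest.approx(fit.pvalues["g[B]"])


def strat_frame(rng, n_per=90, slope0=0.005, slope1=0.005, noise=0.25):
    s = np.repeat([0, 1], n_per)
    a = rng.gamma(0.4, 48.0, 2 * n_per)
    y = (slope0 + (slope1 - slope0) * s) * a + rng.normal(0, noise, 2 * n_per)
    return pd.DataFrame({"y": y, "crp": a, "s": s})


class TestSlopeHeterogeneity:
    def test_null_interaction_p_uniform(self):
        rng = np.random.default_rng(0)
        ps = [
            slope_heterogeneity(strat_frame(rng), "y", "crp", "s").p_value
            for _ in range(500)
        ]
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_swapping_stratum_labels_flips_sign_keeps_p(self):
        rng = np.random.default_rng(1)
        df = strat_frame(rng, slope1=0.012)
        het = slope_heterogeneity(df, "y", "crp", "s")
        flipped = df.assign(s=1 - df.s)
        het2 = slope_heterogeneity(flipped, "y", "crp", "s")
        assert het2.interaction_coef == pytest.approx(-het.interaction_coef)
        assert het2.p_value == pytest.approx(het.p_value)

    def test_detectable_slope_difference_has_high_power(self):
        rng = np.random.default_rng(2)
        rej = sum(
            slope_heterogeneity(
                strat_frame(rng, slope1=0.015), "y", "crp", "s"
            ).p_value
            < 0.05
            for _ in range(200)
        )
        assert rej / 200 > 0.8

    def test_per_stratum_slopes_bracket_truth(self):
        rng = np.random.default_rng(3)
        df = strat_frame(rng, n_per=500, slope0=0.004, slope1=0.010)
        het = slope_heterogeneity(df, "y", "crp", "s")
        (s0, lo0, hi0), (s1, lo1, hi1) = het.slopes["0"], het.slopes["1"]
        assert lo0 <= 0.004 <= hi0
        assert lo1 <= 0.010 <= hi1

    def test_single_stratum_rejected(self):
        df = strat_frame(np.random.default_rng(4)).assign(s=0)
        with pytest.raises(ValueError, match="2 levels"):
            slope_heterogeneity(df, "y", "crp", "s")


class TestCategorize:
    def test_age_boundary_rule(self):
        df = pd.DataFrame({"age": [20, 25, 25.5, 45, 45.5, 65, 70]})
        labels = categorize(df, "age").astype(str).tolist()
        assert labels == ["<=25", "<=25", "25-45", "25-45", "45-65", "45-65", ">65"]

    def test_crp_boundary_rule(self):
        df = pd.DataFrame({"crp": [0.0, 4.9, 5.0, 9.9, 10.0, 15.0, 40.0]})
        labels = categorize(df, "crp").astype(str).tolist()
        assert labels == ["<5", "<5", "5-10", "5-10", "10-15", ">15", ">15"]

    def test_duration_quartiles_split_evenly(self):
        df = pd.DataFrame({"disease_duration": [1, 2, 3, 4, 5, 6, 7, 8]})
        labels = categorize(df, "duration_quartiles")
        assert labels.value_counts().tolist() == [2, 2, 2, 2]

    def test_missing_variable_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            categorize(pd.DataFrame({"x": [1]}), "age")


class TestTreatmentContrast:
    def test_all_treated_rejected(self):
        df = generate_cohort(TABLE1_PRESETS["table1-RA"], 0)
        df["sulfasalazine"] = 1.0
        with pytest.raises(ValueError, match="both arms"):
            treatment_contrast(df)

    def test_null_effect_adjusted_p_uniform(self):
        preset = replace(
            TABLE1_PRESETS["table1-RA"], name="ra-null-ssz", sulfasalazine_effect=0.0
        )
        ps = []
        for seed in range(200):
            df = generate_cohort(preset, seed)
            tc = treatment_contrast(df)
            ps.append(tc.adjusted["g0_g1_ratio"].pvalues["sulfasalazine[1.0]"])
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_log_scale_effect_recovered(self):
        preset = replace(
            TABLE1_PRESETS["table1-RA"], name="ra-strong-ssz", sulfasalazine_effect=-0.15
        )
        est = []
        for seed in range(100):
            df = generate_cohort(preset, seed)
            df["log_ratio"] = np.log(df["g0_g1_ratio"])
            fit = adjusted_comparison(
                df, "log_ratio", "sulfasalazine", covariates=("age", "sex", "crp")
            )
            est.append(fit.params["sulfasalazine[1.0]"])
        assert abs(np.median(est) - (-0.15)) < 0.05

    def test_reports_both_outcomes(self):
        df = generate_cohort(TABLE1_PRESETS["table1-RA"], 1)
        tc = treatment_contrast(df)
        assert set(tc.unadjusted) == {"g0_g1_ratio", "g0_percent"}
        assert set(tc.adjusted) == {"g0_g1_ratio", "g0_percent"}
        assert tc.n_treated + tc.n_untreated == len(df)


class TestExpressionFoldChange:
    def test_simple_ratio(self):
        expr = pd.DataFrame(
            {
                "gene": ["G"] * 4,
                "population": ["p", "p", "b", "b"],
                "intensity": [310, 290, 100, 100],
            }
        )
        fc = expression_fold_change(expr, "G", "p", "b")
        assert fc.value == pytest.approx(3.0)

    def test_identical_populations_give_one(self):
        expr = pd.DataFrame(
            {"gene": ["G"] * 4, "population": ["p", "p", "b", "b"],
             "intensity": [100, 120, 100, 120]}
        )
        assert expression_fold_change(expr, "G", "p", "b").value == pytest.approx(1.0)

    def test_zero_denominator_flagged_undefined(self):
        expr = pd.DataFrame(
            {"gene": ["G"] * 2, "population": ["p", "b"], "intensity": [100, 0]}
        )
        fc = expression_fold_change(expr, "G", "p", "b")
        assert not fc.defined and math.isnan(fc.value)

    def test_planted_threefold_recovered_within_ten_percent(self):
        expr = generate_expression_table(seed=9, b4galt3_fold=3.0, noise_cv=0.05)
        fc = expression_fold_change(expr, "B4GALT3", "plasma_cell", "naive_B")
        assert fc.value == pytest.approx(3.0, rel=0.10)


class TestSerostatus:
    def test_seropositive_is_rf_or_acpa(self):
        df = pd.DataFrame({"rf": [1, 0, 0, 1], "acpa": [0, 1, 0, 1]})
        out = add_seropositive(df)
        assert out["seropositive"].astype(float).tolist() == [1, 1, 0, 1]
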