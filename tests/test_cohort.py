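"""Stratification, adjustment, subgroup, methylation and Table-1 analyses."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coxscreen import (
    cohort_summary,
    compare_cohorts,
    dichotomize,
    methylation_association,
    multivariate_os_model,
    stratified_km,
    subgroup_analysis,
    wald_summary,
)
from coxscreen.cohort import format_percent, pearson_t_test
from coxscreen.io import attach_event

from conftest import make_cohort, surv


def clin(bundle):
    return attach_event(bundle.clinical)


# --- dichotomization --------------------------------------------------------


def test_median_split_even_values():
    a = dichotomize(pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd")))
    assert set(a.low) == {"a", "b"} and set(a.high) == {"c", "d"}
    assert a.cut_value == 2.5


def test_median_split_ties_go_low():
    a = dichotomize(pd.Series([5.0, 5.0, 5.0, 7.0], index=list("abcd")))
    assert len(a.low) == 3 and set(a.high) == {"d"}


def test_lower_tertile_split_sizes_and_tie_stability():
    vals = pd.Series([3.0, 1.0, 2.0, 2.0, 5.0, 4.0, 6.0, 7.0, 8.0],
                     index=[f"p{i}" for i in range(9)])
    a = dichotomize(vals, rule="lower-tertile")
    assert len(a.low) == 3  # floor(9/3)
    assert set(a.low) == {"p1", "p2", "p3"}  # tie at 2.0 broken by id order


def test_dichotomize_rejects_constant_and_tiny_input():
    with pytest.raises(ValueError):
        dichotomize(pd.Series([2.0, 2.0, 2.0]))
    with pytest.raises(ValueError):
        dichotomize(pd.Series([1.0]))


def test_median_split_group_size_invariant():
    rng = np.random.default_rng(0)
    for _ in range(20):
        v = rng.integers(0, 5, rng.integers(4, 30)).astype(float)
        if np.unique(v).size == 1:
            continue
        s = pd.Series(v, index=[f"p{i}" for i in range(v.size)])
        a = dichotomize(s)
        n_ties = int((v == np.median(v)).sum())
        # with the <=-median convention the imbalance is at most twice the
        # number of values tying the median (1 for odd n without ties)
        assert abs(len(a.low) - len(a.high)) <= max(2 * n_ties, 1)


# --- stratified KM ----------------------------------------------------------


def test_stratified_km_planted_effect_orders_medians():
    hits = 0
    for rep in range(10):
        b = make_cohort(seed=200 + rep, n_patients=400, n_genes=1,
                        planted_genes=((0, 0.41),), censoring_target=0.177)
        t, e = surv(b)
        a = dichotomize(pd.Series(b.expression.iloc[0].to_numpy(),
                                  index=b.clinical["patient_id"]))
        rep_km = stratified_km(t, e, a, ids=b.clinical["patient_id"].to_numpy())
        hits += rep_km.median_high < rep_km.median_low
    assert hits >= 9


def test_stratified_km_rejects_empty_group():
    b = make_cohort(seed=1, n_patients=20, n_genes=1)
    t, e = surv(b)
    a = dichotomize(pd.Series(b.expression.iloc[0].to_numpy(),
                              index=b.clinical["patient_id"]))
    a.labels[:] = "low"
    with pytest.raises(ValueError):
        stratified_km(t, e, a, ids=b.clinical["patient_id"].to_numpy())


def test_stratified_km_null_pvalues_uniform():
    pvals = []
    for rep in range(60):
        b = make_cohort(seed=300 + rep, n_patients=120, n_genes=1,
                        covariate_effects={})
        t, e = surv(b)
        a = dichotomize(pd.Series(b.expression.iloc[0].to_numpy(),
                                  index=b.clinical["patient_id"]))
        pvals.append(
            stratified_km(t, e, a, ids=b.clinical["patient_id"].to_numpy())
            .logrank.pvalue
        )
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


# --- multivariate adjustment ------------------------------------------------


def test_multivariate_flipping_sex_reference_negates_coefficient():
    b = make_cohort(seed=2, n_patients=250, n_genes=1)
    c = clin(b)
    x = b.expression.iloc[0].to_numpy()
    f1, _ = multivariate_os_model(c, x, sex_reference="female")
    f2, _ = multivariate_os_model(c, x, sex_reference="male")
    i = f1.names.index("sex")
    assert f1.coef[i] == pytest.approx(-f2.coef[i], abs=1e-6)


def test_multivariate_adjustment_unconfounded_matches_univariate():
    """Covariates independent of both survival and expression barely move the HR."""
    ratios = []
    for rep in range(15):
        b = make_cohort(seed=400 + rep, n_patients=300, n_genes=1,
                        planted_genes=((0, 0.45),), covariate_effects={})
        c = clin(b)
        x = b.expression.iloc[0].to_numpy()
        t, e = surv(b)
        z = (x - x.mean()) / x.std()
        from coxscreen import cox_fit

        uni = cox_fit(z, t, e)
        multi, _ = multivariate_os_model(c, x)
        ratios.append(multi.coef[0] / uni.coef[0])
    assert np.mean(np.abs(np.array(ratios) - 1.0)) < 0.1


def test_multivariate_rare_protective_mutation_has_wide_ci():
    b = make_cohort(seed=3, n_patients=300, n_genes=1,
                    planted_genes=((0, 0.35),), mutation_frequency=0.07)
    fit, _ = multivariate_os_model(clin(b), b.expression.iloc[0].to_numpy())
    tab = wald_summary(fit)
    width = tab.loc["mutation", "ci_high"] / tab.loc["mutation", "ci_low"]
    assert width > 2.0  # 7% prevalence -> imprecise adjusted estimate


def test_multivariate_drops_missing_covariates_with_count():
    b = make_cohort(seed=4, n_patients=100, n_genes=1)
    c = clin(b).copy()
    c.loc[:9, "mutation"] = np.nan
    fit, n_dropped = multivariate_os_model(c, b.expression.iloc[0].to_numpy())
    assert n_dropped == 10
    assert fit.n == 90


def test_multivariate_rejects_too_few_events():
    b = make_cohort(seed=5, n_patients=50, n_genes=1)
    c = clin(b).copy()
    c["event"] = 0
    c.loc[0, "event"] = 1
    with pytest.raises(ValueError):
        multivariate_os_model(c, b.expression.iloc[0].to_numpy())


# --- subgroup analyses ------------------------------------------------------


def test_subgroup_full_cohort_rule_matches_unrestricted():
    b = make_cohort(seed=6, n_patients=200, n_genes=1, planted_genes=((0, 0.4),))
    c = clin(b)
    x = b.expression.iloc[0].to_numpy()
    rep = subgroup_analysis(c, x, "all")
    t, e = surv(b)
    from coxscreen import cox_fit

    z = (x - x.mean()) / x.std()
    assert rep.cox.coef[0] == pytest.approx(cox_fit(z, t, e).coef[0], abs=1e-12)
    assert rep.n == 200


def test_subgroup_expression_effect_present_in_both_treatment_arms():
    b = make_cohort(seed=7, n_patients=700, n_genes=1,
                    planted_genes=((0, 0.5),),
                    covariate_effects={"treatment": -0.69})
    c = clin(b)
    x = b.expression.iloc[0].to_numpy()
    for rule in ("treated", "untreated"):
        rep = subgroup_analysis(c, x, rule)
        assert wald_summary(rep.cox)["p"].iloc[0] < 0.05
        assert rep.cox.coef[0] > 0


def test_subgroup_rejects_eventless_or_unknown_subsets():
    b = make_cohort(seed=8, n_patients=60, n_genes=1)
    c = clin(b).copy()
    c.loc[c["treatment"] == "yes", "event"] = 0
    with pytest.raises(ValueError):
        subgroup_analysis(c, b.expression.iloc[0].to_numpy(), "treated")
    with pytest.raises(ValueError):
        subgroup_analysis(c, b.expression.iloc[0].to_numpy(), "grade-v")


# --- methylation association ------------------------------------------------


def test_perfect_anticorrelation_recovered():
    ids = [f"p{i}" for i in range(30)]
    x = pd.Series(np.linspace(-2, 2, 30), index=ids)
    betas = pd.DataFrame([1.0 / (1.0 + np.exp(x.to_numpy()))], index=["cg0"],
                         columns=ids)
    a = dichotomize(x)
    res = methylation_association(x, betas, a)
    assert res.loc["cg0", "r"] == pytest.approx(-1.0, abs=1e-2)
    assert res.loc["cg0", "p_pearson"] < 1e-20
    assert res.loc["cg0", "mean_beta_low"] > res.loc["cg0", "mean_beta_high"]


def test_calibrated_probe_recovers_target_r_and_direction():
    b = make_cohort(seed=9, n_patients=253, n_genes=1,
                    methylation_targets=(("cgA", 0, -0.59),))
    x = pd.Series(b.expression.iloc[0].to_numpy(),
                  index=b.clinical["patient_id"])
    betas = b.methylation.drop(columns="gene_id")
    betas.columns = list(x.index)
    res = methylation_association(x, betas, dichotomize(x))
    assert res.loc["cgA", "r"] == pytest.approx(-0.59, abs=0.05)
    assert res.loc["cgA", "p_pearson"] < 1e-10
    assert res.loc["cgA", "p_mannwhitney"] < 1e-7
    assert res.loc["cgA", "mean_beta_low"] > res.loc["cgA", "mean_beta_high"]


def test_pearson_t_matches_reference_closed_form():
    rng = np.random.default_rng(10)
    for n in (5, 20, 253):
        x = rng.standard_normal(n)
        y = -0.4 * x + rng.standard_normal(n)
        ours = pearson_t_test(x, y)
        ref = stats.pearsonr(x, y)
        assert ours.detail["r"] == pytest.approx(ref.statistic, abs=1e-12)
        assert ours.pvalue == pytest.approx(ref.pvalue, abs=1e-8)
        expected_t = ref.statistic * math.sqrt(n - 2) / math.sqrt(1 - ref.statistic**2)
        assert ours.statistic == pytest.approx(expected_t, abs=1e-10)


def test_zero_variance_correlation_rejected():
    with pytest.raises(ValueError):
        pearson_t_test([1.0, 2.0, 3.0], [4.0, 4.0, 4.0])


# --- cohort summaries and comparisons --------------------------------------


def _clinical_from_counts(n_f, n_m, n_na, seed=0):
    rng = np.random.default_rng(seed)
    n = n_f + n_m + n_na
    sex = np.array(["female"] * n_f + ["male"] * n_m + [np.nan] * n_na, dtype=object)
    return pd.DataFrame(
        {
            "patient_id": [f"p{i}" for i in range(n)],
            "os_months": rng.exponential(14, n) + 0.1,
            "vital_status": rng.choice(["Alive", "Dead"], n),
            "age": rng.normal(55, 10, n),
            "sex": sex,
            "event": rng.integers(0, 2, n),
        }
    )


def test_summary_reproduces_printed_percentages():
    s = cohort_summary(_clinical_from_counts(159, 265, 0))
    assert format_percent(s.categorical["sex"]["female"][1]) == "37.5"
    s = cohort_summary(_clinical_from_counts(67, 107, 73))
    assert format_percent(s.categorical["sex"]["male"][1]) == "61.5"
    assert s.missing["sex"] == 73
    # 23 mutants of 311 -> 7.40 with the <10 two-decimal convention
    assert format_percent(100.0 * 23 / 311) == "7.40"


def test_summary_percentages_sum_to_hundred_and_empty_levels_zero():
    b = make_cohort(seed=11, n_patients=150, grade_iii_fraction=0.0)
    s = cohort_summary(clin(b))
    for var, levels in s.categorical.items():
        assert sum(p for _, p in levels.values()) == pytest.approx(100.0)
    assert s.categorical["grade"]["III"] == (0, 0.0)
    assert s.n_alive + s.n_dead == s.n
    frame = s.to_frame()
    assert {"variable", "level", "count", "percent", "display"} <= set(frame.columns)


def test_compare_identical_cohorts_is_homogeneous():
    b = make_cohort(seed=12, n_patients=150, grade_iii_fraction=0.3)
    c = clin(b)
    res = compare_cohorts([c, c.copy()])
    assert res["grade"].statistic == pytest.approx(0.0, abs=1e-10)
    assert res["grade"].pvalue == pytest.approx(1.0)
    assert res["os"].pvalue == pytest.approx(1.0, abs=1e-6)
    assert res["age"].pvalue > 0.9


def test_compare_grade_mix_chi_square_matches_printed_value():
    # grade III/IV counts from three published cohorts: 64/183, 21/56, 26/59
    cohorts = []
    for i, (n3, n4) in enumerate([(64, 183), (21, 56), (26, 59)]):
        df = _clinical_from_counts(0, n3 + n4, 0, seed=i)
        df["grade"] = ["III"] * n3 + ["IV"] * n4
        cohorts.append(df)
    res = compare_cohorts(cohorts)
    assert res["grade"].test == "chi-square"
    assert round(res["grade"].pvalue, 2) == 0.70


def test_fisher_exact_matches_hypergeometric_enumeration():
    """Two-sided Fisher p = sum of table probabilities <= observed one."""
    rng = np.random.default_rng(13)
    for _ in range(10):
        a, b, c, d = rng.integers(0, 9, 4) + [1, 0, 0, 1]
        row1, col1, n = a + b, a + c, a + b + c + d
        obs_p = stats.hypergeom.pmf(a, n, row1, col1)
        total = sum(
            p
            for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1)
            if (p := stats.hypergeom.pmf(k, n, row1, col1)) <= obs_p * (1 + 1e-9)
        )
        _, scipy_p = stats.fisher_exact([[a, b], [c, d]])
        assert scipy_p == pytest.approx(total, abs=1e-10)


def test_compare_cohorts_requires_two():
    with pytest.raises(ValueError):
        compare_cohorts([_clinical_from_counts(5, 5, 0)])


@pytest.mark.parametrize("pct,disp", [(37.5, "37.5"), (7.3954, "7.40"),
                                      (9.99, "9.99"), (61.49, "61.5")])
def test_percent_display_convention(pct, disp):
    assert format_percent(pct) == disp
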