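"""GWAS scan behaviour: invariances, inflation factor, QQ tables, KM/log-rank."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from survgwas.containers import ValidationError
from survgwas.coxph import cox_score_test
from survgwas.scan import (CoxPHScan, ScanConfig, genomic_inflation, gwas_scan,
                           km_logrank, qq_manhattan_tables, stratified_analysis)

COVS = ("age_ge50", "t34", "conc_cis_high")


def test_scan_recovers_planted_snp(planted_study):
    cfg, g, cohort, _, _ = planted_study
    res = gwas_scan(g, cohort, cfg=ScanConfig(covariates=COVS)).set_index("variant_id")
    assert res.loc["snp000050", "converged"]
    assert np.log(res.loc["snp000050", "hr"]) == pytest.approx(np.log(2.0), abs=0.35)
    assert res.loc["snp000050", "p"] < 1e-4
    assert res["converged"].mean() > 0.95


def test_scan_invariant_to_variant_and_subject_order(planted_study):
    _, g, cohort, _, _ = planted_study
    res = gwas_scan(g, cohort, cfg=ScanConfig(covariates=COVS))
    rng = np.random.default_rng(0)
    vperm = rng.permutation(g.n_variants)
    g_v = g.select_variants(np.sort(vperm[:50]))  # keep position order valid
    res_v = gwas_scan(g_v, cohort, cfg=ScanConfig(covariates=COVS))
    merged = res.set_index("variant_id").loc[res_v["variant_id"]]
    np.testing.assert_allclose(res_v["beta"].to_numpy(), merged["beta"].to_numpy(),
                               atol=1e-8)
    sperm = rng.permutation(g.n_subjects)
    res_s = gwas_scan(g.select_subjects(sperm), cohort.iloc[sperm].reset_index(drop=True),
                      cfg=ScanConfig(covariates=COVS))
    np.testing.assert_allclose(res_s["beta"].to_numpy(), res["beta"].to_numpy(), atol=1e-8)


def test_wald_p_consistent_with_beta_se(small_null_study):
    g, cohort, _, _ = small_null_study
    res = gwas_scan(g, cohort, cfg=ScanConfig(covariates=COVS))
    ok = res["converged"]
    z2 = (res.loc[ok, "beta"] / res.loc[ok, "se"]) ** 2
    np.testing.assert_allclose(res.loc[ok, "p"], stats.chi2.sf(z2, 1), rtol=1e-12)
    assert ((res.loc[ok, "ci_low"] <= res.loc[ok, "hr"])
            & (res.loc[ok, "hr"] <= res.loc[ok, "ci_high"])).all()


def test_allele_flip_negates_beta(small_null_study):
    g, cohort, _, _ = small_null_study
    g_sub = g.select_variants(np.arange(20))
    res = gwas_scan(g_sub, cohort, cfg=ScanConfig(covariates=COVS))
    flipped = g_sub.select_variants(np.arange(20))
    flipped.dosage[:] = 2.0 - flipped.dosage
    res_f = gwas_scan(flipped, cohort, cfg=ScanConfig(covariates=COVS))
    ok = res["converged"] & res_f["converged"]
    np.testing.assert_allclose(res_f.loc[ok, "beta"], -res.loc[ok, "beta"], atol=1e-7)
    np.testing.assert_allclose(res_f.loc[ok, "p"], res.loc[ok, "p"], rtol=1e-6)


def test_variant_collinear_with_covariate_flagged(small_null_study):
    g, cohort, _, _ = small_null_study
    g_sub = g.select_variants(np.arange(3))
    g_sub.dosage[:, 1] = cohort["t34"].to_numpy()  # duplicates a fixed covariate
    res = gwas_scan(g_sub, cohort, cfg=ScanConfig(covariates=COVS))
    assert not res["converged"].iloc[1]
    assert np.isnan(res["p"].iloc[1])


def test_missing_genotypes_complete_case(small_null_study):
    g, cohort, _, _ = small_null_study
    g_sub = g.select_variants(np.arange(5))
    g_sub.dosage[:30, 2] = np.nan
    res = gwas_scan(g_sub, cohort, cfg=ScanConfig(covariates=COVS))
    assert res["n_used"].iloc[2] == g.n_subjects - 30
    assert res["n_used"].iloc[0] == g.n_subjects


def test_genomic_inflation_definition():
    assert genomic_inflation([0.5] * 10) == pytest.approx(1.0, abs=1e-12)
    rng = np.random.default_rng(1)
    p = rng.random(10_000)
    lam = genomic_inflation(p)
    assert 0.97 <= lam <= 1.03
    assert genomic_inflation(p / 2) > lam  # halving P inflates
    with pytest.raises(ValidationError):
        genomic_inflation([np.nan])


def test_qq_table_conventions(small_null_study):
    g, cohort, _, _ = small_null_study
    res = gwas_scan(g, cohort, cfg=ScanConfig(covariates=COVS))
    qq, man = qq_manhattan_tables(res)
    assert len(qq) == len(man) == int(res["converged"].sum())
    # observed column sorted non-increasing, expected max = -log10(0.5/m)
    assert np.all(np.diff(qq["observed_neglog10p"]) <= 1e-12)
    one = res.iloc[[0]].assign(p=0.2, converged=True)
    qq1, _ = qq_manhattan_tables(one)
    assert qq1["expected_neglog10p"].iloc[0] == pytest.approx(-np.log10(0.5))


def test_stratified_whole_cohort_equals_unstratified(planted_study):
    _, g, cohort, _, _ = planted_study
    cohort = cohort.copy()
    cohort["all"] = "everyone"
    strat = stratified_analysis(g, cohort, "snp000050",
                                {"whole": ("all", "everyone")}, covariates=COVS)
    res = gwas_scan(g.select_variants(g.variant_ids == "snp000050"), cohort,
                    cfg=ScanConfig(covariates=COVS))
    assert strat["hr"].iloc[0] == pytest.approx(res["hr"].iloc[0], rel=1e-9)


def test_stratifying_variable_dropped_from_covariates(planted_study):
    _, g, cohort, _, _ = planted_study
    strat = stratified_analysis(
        g, cohort, "snp000050",
        {"T1-T2": ("t_stage", "T1-T2"), "T3-T4": ("t_stage", "T3-T4")},
        covariates=COVS, drop_map={"t_stage": "t34"})
    assert all("t34" not in c.split(",") for c in strat["covariates"])
    assert strat["n"].sum() == len(cohort)
    assert strat["converged"].all()


def test_km_survival_is_empirical_fraction_without_censoring():
    time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    event = np.ones(6, int)
    groups = np.array(["a"] * 6 + ["b"] * 6)
    curves, chi2, p = km_logrank(np.r_[time, time + 0.1], np.r_[event, event], groups)
    a = curves[curves["group"] == "a"]
    surv_at_3 = a.loc[a["time"] == 3.0, "survival"].iloc[0]
    assert surv_at_3 == pytest.approx(np.mean(time > 3.0))


def test_km_logrank_equals_cox_score_test():
    rng = np.random.default_rng(8)
    n = 60
    grp = rng.integers(0, 2, n)
    t = rng.exponential(1.0, n) * (1 + 0.8 * grp)
    e = (rng.random(n) < 0.8).astype(int)
    _, chi2, p = km_logrank(t, e, np.where(grp == 1, "hi", "lo"))
    stat, p_score = cox_score_test(grp.astype(float), t, e)
    assert chi2 == pytest.approx(stat, abs=1e-8)
    assert p == pytest.approx(p_score, rel=1e-8)


def test_km_single_group_errors():
    with pytest.raises(ValidationError):
        km_logrank([1.0, 2.0], [1, 1], ["a", "a"])


def test_cisplatin_style_subgroup_is_a_cohort_filter(planted_study):
    """Subgroup analysis = scan on the filtered cohort; no separate code path."""
    _, g, cohort, _, _ = planted_study
    mask = cohort["concurrent_cisplatin_dose"] > 0
    sub = cohort.loc[mask].reset_index(drop=True)
    res = gwas_scan(g.select_subjects(mask.to_numpy()).select_variants(np.arange(10)),
                    sub, cfg=ScanConfig(covariates=("age_ge50", "t34")))
    assert (res["n_used"] == int(mask.sum())).all()
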