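"""Risk score: split, scoring arithmetic, IPCW AUC and group hazard ratio."""

import numpy as np
import pandas as pd
import pytest

from survgwas.containers import ValidationError
from survgwas.coxph import ConvergenceError
from survgwas.riskmodel import (CoxRiskScore, auc_at_horizon, group_hazard_ratio,
                                split_train_test)
from survgwas.clinical import univariate_cox

CLIN = ("age_ge50", "t34", "conc_cis_high")


def _simple_cohort(n=200, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)],
        "time": rng.uniform(1, 120, n),
        "event": rng.integers(0, 2, n),
    })


def test_split_sizes_777():
    """A 50/50 partition of 777 subjects yields 389 train / 388 test."""
    cohort = _simple_cohort(777)
    train, test = split_train_test(cohort, ratio=0.5, seed=1)
    assert (len(train), len(test)) == (389, 388)


def test_split_disjoint_exhaustive_and_seeded():
    cohort = _simple_cohort(101)
    tr1, te1 = split_train_test(cohort, seed=3)
    tr2, te2 = split_train_test(cohort, seed=3)
    tr3, _ = split_train_test(cohort, seed=4)
    assert set(tr1["subject_id"]) | set(te1["subject_id"]) == set(cohort["subject_id"])
    assert set(tr1["subject_id"]).isdisjoint(te1["subject_id"])
    assert tr1["subject_id"].tolist() == tr2["subject_id"].tolist()
    assert tr1["subject_id"].tolist() != tr3["subject_id"].tolist()
    with pytest.raises(ValidationError):
        split_train_test(cohort, ratio=1.2)


def test_score_is_exact_linear_predictor(planted_study):
    _, g, cohort, _, _ = planted_study
    model = CoxRiskScore(snp_ids=("snp000050",), clinical_terms=CLIN).fit(cohort, g)
    scores = model.score_subjects(cohort, g)
    # hand-computed three-plus-one-term subject
    row = cohort.iloc[10]
    expected = (model.coef_[0] * g.dosage_for("snp000050")[10]
                + model.coef_[1] * row["age_ge50"] + model.coef_[2] * row["t34"]
                + model.coef_[3] * row["conc_cis_high"])
    assert scores.iloc[10] == pytest.approx(expected, abs=1e-12)
    # all-zero covariates score exactly zero
    zero = cohort.iloc[[0]].copy()
    zero[list(CLIN)] = 0.0
    g0 = g.select_subjects(np.array([0]))
    g0.dosage[:] = 0.0
    assert model.score_subjects(zero, g0).iloc[0] == 0.0
    # doubling a coefficient shifts scores by coef * value exactly
    bumped = model.coef_.copy()
    model.coef_ = bumped * np.r_[2.0, np.ones(3)]
    s2 = model.score_subjects(cohort, g)
    delta = s2 - scores
    np.testing.assert_allclose(delta.to_numpy(),
                               bumped[0] * g.dosage_for("snp000050"), atol=1e-12)


def test_single_clinical_term_matches_univariate_cox(planted_study):
    _, _, cohort, _, _ = planted_study
    model = CoxRiskScore(clinical_terms=("t34",)).fit(cohort)
    uni = univariate_cox(cohort, "t34")
    assert np.exp(model.coef_[0]) == pytest.approx(uni["hr"].iloc[0], rel=1e-9)


def test_auc_identical_scores_is_half():
    t = np.r_[np.linspace(1, 50, 30), np.linspace(70, 120, 30)]
    e = np.r_[np.ones(30, int), np.zeros(30, int)]
    assert auc_at_horizon(np.ones(60), t, e, horizon=60) == 0.5


def test_auc_perfect_ranking_no_censoring_is_one():
    t = np.r_[np.linspace(1, 50, 20), np.linspace(70, 120, 20)]
    e = np.ones(40, int)
    s = np.r_[np.ones(20), np.zeros(20)]
    assert auc_at_horizon(s, t, e, horizon=60) == 1.0


def test_auc_equals_mann_whitney_without_censoring():
    rng = np.random.default_rng(2)
    n = 150
    s = rng.normal(size=n)
    t = rng.uniform(1, 120, n)
    e = np.ones(n, int)  # no censoring at all
    horizon = 60.0
    auc = auc_at_horizon(s, t, e, horizon)
    cases, controls = s[t <= horizon], s[t > horizon]
    mw = np.mean((cases[:, None] > controls[None, :])
                 + 0.5 * (cases[:, None] == controls[None, :]))
    assert auc == pytest.approx(mw, abs=1e-10)


def test_auc_cross_checked_against_scikit_survival():
    sksurv_metrics = pytest.importorskip("sksurv.metrics")
    from sksurv.util import Surv

    rng = np.random.default_rng(4)
    n = 250
    s = rng.normal(size=n)
    t = rng.exponential(80, n) * np.exp(-0.5 * s) + 0.5
    c = rng.uniform(20, 150, n)
    time = np.minimum(t, c)
    event = (t <= c).astype(int)
    auc = auc_at_horizon(s, time, event, horizon=60)
    y = Surv.from_arrays(event=event.astype(bool), time=time)
    ref, _ = sksurv_metrics.cumulative_dynamic_auc(y, y, s, times=[60.0])
    assert auc == pytest.approx(float(ref[0]), abs=0.02)


def test_auc_invariant_under_monotone_transform(planted_study):
    _, g, cohort, _, _ = planted_study
    model = CoxRiskScore(snp_ids=("snp000050",), clinical_terms=CLIN).fit(cohort, g)
    s = model.score_subjects(cohort, g).to_numpy()
    t, e = cohort["time"].to_numpy(), cohort["event"].to_numpy(int)
    a = auc_at_horizon(s, t, e)
    b = auc_at_horizon(np.exp(3 * s) + 5, t, e)
    assert a == pytest.approx(b, abs=1e-12)


def test_auc_requires_cases_and_controls():
    with pytest.raises(ValidationError):
        auc_at_horizon([1.0, 2.0], [70.0, 80.0], [0, 0], horizon=60)


def test_group_hr_degenerate_cutoff_errors():
    rng = np.random.default_rng(0)
    s = rng.normal(size=50)
    t = rng.uniform(1, 100, 50)
    e = np.ones(50, int)
    with pytest.raises(ValidationError, match="empty risk group"):
        group_hazard_ratio(s, s.min() - 1.0, t, e)


def test_group_assignment_deterministic(planted_study):
    _, g, cohort, _, _ = planted_study
    model = CoxRiskScore(snp_ids=("snp000050",), clinical_terms=CLIN).fit(cohort, g)
    ev = model.evaluate(cohort, g)
    s = model.score_subjects(cohort, g).to_numpy()
    assert ev["n_high"] == int((s > model.cutoff_).sum())
    assert ev["n"] == len(cohort)


def test_training_median_cutoff_splits_training_set(planted_study):
    _, g, cohort, _, _ = planted_study
    train, _ = split_train_test(cohort, seed=0)
    model = CoxRiskScore(snp_ids=("snp000050",), clinical_terms=CLIN).fit(train, g)
    s = model.score_subjects(train, g).to_numpy()
    assert model.cutoff_ == pytest.approx(np.median(s))
    # the median subject falls in the low group ("score > cutoff" is high)
    assert (s > model.cutoff_).sum() <= len(s) / 2


def test_constant_term_rejected(planted_study):
    _, g, cohort, _, _ = planted_study
    cohort = cohort.copy()
    cohort["const"] = 1.0
    with pytest.raises(ValidationError, match="constant"):
        CoxRiskScore(clinical_terms=("const", "t34")).fit(cohort, g)


def test_missing_term_values_flagged_and_excluded(planted_study):
    _, g, cohort, _, _ = planted_study
    model = CoxRiskScore(clinical_terms=CLIN).fit(cohort)
    broken = cohort.copy()
    broken.loc[broken.index[:7], "t34"] = np.nan
    ev = model.evaluate(broken)
    assert ev["n_missing_terms"] == 7
    assert ev["n"] == len(cohort) - 7


def test_nested_model_training_auc(planted_study):
    """Combined model's training AUC is not materially below either single model."""
    _, g, cohort, _, _ = planted_study
    train, _ = split_train_test(cohort, seed=2)
    snps = ("snp000050", "snp000120")
    aucs = {}
    for name, kw in (("clinical", dict(clinical_terms=CLIN)),
                     ("genetic", dict(snp_ids=snps)),
                     ("combined", dict(snp_ids=snps, clinical_terms=CLIN))):
        m = CoxRiskScore(**kw).fit(train, g)
        aucs[name] = m.evaluate(train, g)["auc"]
    assert aucs["combined"] >= max(aucs["clinical"], aucs["genetic"]) - 0.01


def test_optimism_training_auc_above_test(planted_study):
    """With real signal, training AUC exceeds test AUC on average over splits."""
    _, g, cohort, _, _ = planted_study
    diffs = []
    for seed in range(8):
        train, test = split_train_test(cohort, seed=seed)
        m = CoxRiskScore(snp_ids=("snp000050", "snp000120"), clinical_terms=CLIN).fit(train, g)
        diffs.append(m.evaluate(train, g)["auc"] - m.evaluate(test, g)["auc"])
    assert np.mean(diffs) > 0
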