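"""Combined genetic + clinical risk score with train/test validation.

One joint Cox fit over SNP dosages and encoded clinical indicators yields
coefficient weights; the linear predictor is the risk score.  The training
median is the high/low cutoff, discrimination is measured by the IPCW
(Uno-type) cumulative/dynamic AUC at a 60-month horizon, and the high-vs-low
contrast by a single-covariate Cox hazard ratio.  Clinical-only,
genetic-only and combined models are the same code path with different term
lists.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .containers import GenotypeMatrix, ValidationError, check_cohort
from .coxph import ConvergenceError, cox_fit
from .scan import km_logrank

DEFAULT_HORIZON = 60.0  # months: five-year risk


def split_train_test(cohort: pd.DataFrame, ratio: float = 0.5, seed: int = 0
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simple random partition; train gets ceil(n * ratio) subjects."""
    if not (0.0 < ratio < 1.0):
        raise ValidationError("ratio must lie strictly between 0 and 1")
    n = len(cohort)
    if n < 4:
        raise ValidationError("need at least 4 subjects to split")
    n_train = int(np.ceil(n * ratio))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train = cohort.iloc[np.sort(perm[:n_train])].reset_index(drop=True)
    test = cohort.iloc[np.sort(perm[n_train:])].reset_index(drop=True)
    return train, test


def _term_matrix(cohort: pd.DataFrame, genotypes: GenotypeMatrix | None,
                 snp_ids, clinical_terms) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Design matrix for the model terms; rows with missing values are flagged."""
    cols, names = [], []
    if snp_ids:
        if genotypes is None:
            raise ValidationError("snp_ids given but no genotype matrix")
        lookup = {s: i for i, s in enumerate(genotypes.subject_ids)}
        rows = np.array([lookup[s] for s in cohort["subject_id"]], dtype=int)
        for vid in snp_ids:
            cols.append(genotypes.dosage_for(vid)[rows])
            names.append(vid)
    for term in clinical_terms:
        cols.append(cohort[term].to_numpy(dtype=float))
        names.append(term)
    X = np.column_stack(cols) if cols else np.empty((len(cohort), 0))
    complete = np.all(np.isfinite(X), axis=1)
    return X, names, complete


class CoxRiskScore(BaseEstimator):
    """Coefficient-weighted Cox risk score (scikit-learn style estimator).

    Parameters
    ----------
    snp_ids : list of variant ids entered as additive dosages.
    clinical_terms : list of numeric cohort columns (e.g. encoded 0/1 factors).
    horizon : evaluation horizon in months (default 60 = 5-year risk).

    Attributes (after fit)
    ----------------------
    coef_ : ndarray of fitted log hazard ratios, one per term
    terms_ : list of term names
    cutoff_ : float, the training-set median risk score
    """

    def __init__(self, snp_ids=(), clinical_terms=(), horizon: float = DEFAULT_HORIZON,
                 ties: str = "efron"):
        self.snp_ids = snp_ids
        self.clinical_terms = clinical_terms
        self.horizon = horizon
        self.ties = ties

    def fit(self, train: pd.DataFrame, genotypes: GenotypeMatrix | None = None) -> "CoxRiskScore":
        check_cohort(train)
        X, names, complete = _term_matrix(train, genotypes, list(self.snp_ids),
                                          list(self.clinical_terms))
        if X.shape[1] == 0:
            raise ValidationError("risk model needs at least one term")
        Xc = X[complete]
        if np.any(np.ptp(Xc, axis=0) == 0):
            const = [names[i] for i in range(Xc.shape[1]) if np.ptp(Xc[:, i]) == 0]
            raise ValidationError(f"constant terms in training data: {const}")
        res = cox_fit(Xc, train["time"].to_numpy(float)[complete],
                      train["event"].to_numpy(int)[complete], ties=self.ties)
        if not res.converged:
            raise ConvergenceError(
                f"risk-model Cox fit did not converge after {res.iterations} iterations "
                f"(n={res.n}, events={res.n_events}); check terms for separation")
        self.coef_ = res.beta
        self.se_ = res.se
        self.terms_ = names
        self.fit_result_ = res
        scores = Xc @ res.beta
        self.cutoff_ = float(np.median(scores))
        return self

    def score_subjects(self, data: pd.DataFrame, genotypes: GenotypeMatrix | None = None
                       ) -> pd.Series:
        """Linear-predictor risk score per subject; NaN where a term is missing."""
        X, names, complete = _term_matrix(data, genotypes, list(self.snp_ids),
                                          list(self.clinical_terms))
        if names != self.terms_:
            raise ValidationError("term mismatch between fit and scoring data")
        s = np.full(len(data), np.nan)
        s[complete] = X[complete] @ self.coef_
        return pd.Series(s, index=data.index, name="risk_score")

    # sklearn-style alias
    def predict(self, data: pd.DataFrame, genotypes: GenotypeMatrix | None = None) -> np.ndarray:
        return self.score_subjects(data, genotypes).to_numpy()

    def evaluate(self, data: pd.DataFrame, genotypes: GenotypeMatrix | None = None
                 ) -> dict[str, float]:
        """AUC at the horizon plus the high-vs-low group hazard ratio."""
        scores = self.score_subjects(data, genotypes)
        ok = scores.notna().to_numpy()
        n_missing = int((~ok).sum())
        sub = data.loc[ok]
        s = scores.to_numpy()[ok]
        auc = auc_at_horizon(s, sub["time"].to_numpy(float), sub["event"].to_numpy(int),
                             horizon=self.horizon)
        hr, ci_low, ci_high, p, _ = group_hazard_ratio(
            s, self.cutoff_, sub["time"].to_numpy(float), sub["event"].to_numpy(int),
            ties=self.ties)
        return dict(auc=auc, group_hr=hr, group_hr_ci_low=ci_low, group_hr_ci_high=ci_high,
                    group_hr_p=p, n=int(ok.sum()), n_missing_terms=n_missing,
                    n_high=int((s > self.cutoff_).sum()))


def fit_risk_model(train: pd.DataFrame, genotypes: GenotypeMatrix | None = None,
                   snp_ids=(), clinical_terms=(), horizon: float = DEFAULT_HORIZON
                   ) -> CoxRiskScore:
    return CoxRiskScore(snp_ids=snp_ids, clinical_terms=clinical_terms,
                        horizon=horizon).fit(train, genotypes)


def score_subjects(model: CoxRiskScore, data: pd.DataFrame,
                   genotypes: GenotypeMatrix | None = None) -> pd.Series:
    return model.score_subjects(data, genotypes)


def _censoring_survival_left(time: np.ndarray, event: np.ndarray):
    """Kaplan-Meier of the censoring distribution, returned as a left-limit
    evaluator G(t-) (product over censoring times strictly before t).

    Events and censorings at the same time are ordered events-first, the
    usual convention, so a censoring at t does not reduce the risk set of
    an event at t.
    """
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    uniq = np.unique(t)
    n_at_risk = len(t)
    g = 1.0
    times_out, g_out = [0.0], [1.0]
    for u in uniq:
        at = t == u
        n_cens = int((1 - e[at]).sum())
        n_here = int(at.sum())
        if n_cens and n_at_risk > 0:
            g *= 1.0 - n_cens / n_at_risk
        times_out.append(u)
        g_out.append(g)
        n_at_risk -= n_here
    times_arr = np.array(times_out)
    g_arr = np.array(g_out)

    def g_left(q: np.ndarray) -> np.ndarray:
        # G just before q: last value at a time strictly < q
        idx = np.searchsorted(times_arr, q, side="left") - 1
        return g_arr[np.clip(idx, 0, None)]

    return g_left


def auc_at_horizon(scores, time, event, horizon: float = DEFAULT_HORIZON) -> float:
    """IPCW cumulative/dynamic AUC at a fixed horizon (Uno-type estimator).

    Cases are subjects with an observed event by the horizon, controls those
    still under observation beyond it; case contributions are weighted by
    the inverse Kaplan-Meier censoring survival at their event time (left
    limit).  Ties in the score count one half.  With no censoring before
    the horizon every weight is 1 and the value reduces to the
    Mann-Whitney AUC of the binary "event by horizon" outcome.
    """
    s = np.asarray(scores, float)
    t = np.asarray(time, float)
    e = np.asarray(event, int)
    cases = (t <= horizon) & (e == 1)
    controls = t > horizon
    if cases.sum() == 0 or controls.sum() == 0:
        raise ValidationError(
            f"AUC at horizon {horizon} needs at least one case and one control "
            f"(got {int(cases.sum())} cases, {int(controls.sum())} controls)")
    g_left = _censoring_survival_left(t, e)
    w = 1.0 / g_left(t[cases])
    sc, sk = s[cases], s[controls]
    # concordance of each case against all controls, ties half
    greater = (sc[:, None] > sk[None, :]).sum(axis=1)
    equal = (sc[:, None] == sk[None, :]).sum(axis=1)
    conc = greater + 0.5 * equal
    return float((w * conc).sum() / (w.sum() * len(sk)))


def group_hazard_ratio(scores, cutoff: float, time, event, ties: str = "efron"
                       ) -> tuple[float, float, float, float, pd.DataFrame]:
    """High-vs-low (score > cutoff) Cox hazard ratio with Wald CI/P and KM tables."""
    s = np.asarray(scores, float)
    t = np.asarray(time, float)
    e = np.asarray(event, int)
    high = s > cutoff
    if high.all() or (~high).all():
        raise ValidationError(f"cutoff {cutoff} leaves an empty risk group")
    if e.sum() == 0:
        raise ValidationError("no events: hazard ratio undefined")
    res = cox_fit(high.astype(float)[:, None], t, e, ties=ties)
    if not res.converged:
        raise ConvergenceError("high-vs-low Cox fit did not converge")
    beta, se = res.beta[0], res.se[0]
    p = float(stats.chi2.sf((beta / se) ** 2, df=1))
    km, _, _ = km_logrank(t, e, np.where(high, "high", "low"))
    return (float(np.exp(beta)), float(np.exp(beta - 1.959963984540054 * se)),
            float(np.exp(beta + 1.959963984540054 * se)), p, km)
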