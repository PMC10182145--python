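"""Clinical-covariate analysis: cohort summaries, ROC cutoffs, Cox models.

Reproduces the standard "Table 1" workflow for a censored cohort: group
summaries, ROC-derived dichotomisation cutoffs for continuous covariates
(Youden's J on the end-of-follow-up event indicator), univariate Cox per
covariate, and a joint multivariate Cox over a chosen covariate set, with
the conventional carry-forward rule (univariate P < 0.05) exposed as a
separate optional step rather than hard-wired.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ValidationError, check_cohort
from .coxph import cox_fit

_CONTINUOUS = ("time", "age", "ebv_dna", "primary_tumor_dose",
               "induction_cisplatin_dose", "concurrent_cisplatin_dose")


def cohort_summary(cohort: pd.DataFrame) -> pd.DataFrame:
    """Event counts/proportion and per-covariate summaries.

    Proportions are percentages rounded to one decimal; medians and IQRs
    use the linear-interpolation convention of sorted-value quantiles.
    """
    check_cohort(cohort)
    if len(cohort) == 0:
        raise ValidationError("cohort is empty")
    rows = [
        {"variable": "n", "level": "", "statistic": "count", "value": float(len(cohort))},
        {"variable": "event", "level": "", "statistic": "count", "value": float(cohort["event"].sum())},
        {"variable": "event", "level": "", "statistic": "percent",
         "value": round(100.0 * cohort["event"].mean(), 1)},
    ]
    for col in _CONTINUOUS:
        if col not in cohort.columns:
            continue
        x = cohort[col].dropna()
        if len(x) == 0:
            continue
        q25, q50, q75 = np.quantile(x, [0.25, 0.5, 0.75])
        rows += [{"variable": col, "level": "", "statistic": s, "value": float(v)}
                 for s, v in (("median", q50), ("q25", q25), ("q75", q75))]
    for col in cohort.columns:
        if col in _CONTINUOUS or col in ("subject_id", "event"):
            continue
        series = cohort[col]
        if series.dtype == object or series.nunique(dropna=False) <= 5:
            counts = series.fillna("NA").value_counts(sort=False)
            for level, n in counts.items():
                rows.append({"variable": col, "level": str(level), "statistic": "count",
                             "value": float(n)})
                rows.append({"variable": col, "level": str(level), "statistic": "percent",
                             "value": round(100.0 * n / len(cohort), 1)})
    return pd.DataFrame(rows)


def roc_cutoff(values, outcome) -> float:
    """ROC-optimal dichotomisation cutoff by Youden's J.

    The rule is "value >= cutoff is positive"; the cutoff maximising
    sensitivity + specificity - 1 over the observed values is returned,
    with ties broken toward the smaller cutoff.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(outcome, dtype=int)
    ok = np.isfinite(x)
    x, y = x[ok], y[ok]
    if len(np.unique(y)) < 2:
        raise ValidationError("both outcome classes must be present")
    if np.ptp(x) == 0:
        raise ValidationError("covariate is constant; no cutoff exists")
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    candidates = np.unique(x)
    # at cutoff c: sens = P(x >= c | y=1), spec = P(x < c | y=0)
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    pos_below = np.searchsorted(xs, candidates, side="left")
    cum_pos = np.concatenate([[0], np.cumsum(ys)])
    tp = n_pos - cum_pos[pos_below]
    tn = pos_below - cum_pos[pos_below]
    j = tp / n_pos + tn / n_neg - 1.0
    best = np.argmax(j)  # argmax takes the first (smallest) candidate on ties
    return float(candidates[best])


def _cox_table(X: np.ndarray, names: list[str], time, event, ties: str) -> pd.DataFrame:
    res = cox_fit(X, np.asarray(time, float), np.asarray(event, int), ties=ties)
    rows = []
    for i, name in enumerate(names):
        beta, se = res.beta[i], res.se[i]
        if res.converged:
            p = float(stats.chi2.sf((beta / se) ** 2, df=1))
            rows.append(dict(variable=name, hr=float(np.exp(beta)),
                             ci_low=float(np.exp(beta - 1.959963984540054 * se)),
                             ci_high=float(np.exp(beta + 1.959963984540054 * se)),
                             p=p, converged=True))
        else:
            rows.append(dict(variable=name, hr=np.nan, ci_low=np.nan, ci_high=np.nan,
                             p=np.nan, converged=False))
    return pd.DataFrame(rows)


def univariate_cox(cohort: pd.DataFrame, variable: str, ties: str = "efron") -> pd.DataFrame:
    """Single-covariate Cox fit: HR, 95% CI, two-sided Wald P."""
    check_cohort(cohort)
    x = cohort[variable].to_numpy(dtype=float)
    if np.ptp(x[np.isfinite(x)]) == 0:
        raise ValidationError(f"covariate {variable!r} is constant")
    ok = np.isfinite(x)
    return _cox_table(x[ok][:, None], [variable],
                      cohort["time"].to_numpy(float)[ok],
                      cohort["event"].to_numpy(int)[ok], ties)


def multivariate_cox(cohort: pd.DataFrame, variables: list[str], ties: str = "efron") -> pd.DataFrame:
    """Joint Cox fit over ``variables``: adjusted HR, CI, P per variable."""
    check_cohort(cohort)
    X = cohort[list(variables)].to_numpy(dtype=float)
    ok = np.all(np.isfinite(X), axis=1)
    X = X[ok]
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if rank < X.shape[1]:
        # name the offending columns for the caller
        bad = []
        for i in range(X.shape[1]):
            others = np.delete(X, i, axis=1)
            if np.linalg.matrix_rank(others - others.mean(axis=0)) == rank:
                bad.append(variables[i])
        raise ValidationError(f"design matrix is rank deficient; collinear columns: {bad}")
    return _cox_table(X, list(variables),
                      cohort["time"].to_numpy(float)[ok],
                      cohort["event"].to_numpy(int)[ok], ties)


def select_univariate_significant(cohort: pd.DataFrame, candidates: list[str],
                                  alpha: float = 0.05, ties: str = "efron") -> list[str]:
    """Carry-forward screening rule: keep covariates with univariate Wald P < alpha."""
    keep = []
    for var in candidates:
        tab = univariate_cox(cohort, var, ties=ties)
        if tab["converged"].iloc[0] and tab["p"].iloc[0] < alpha:
            keep.append(var)
    return keep
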