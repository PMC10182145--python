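"""Genome-wide survival scan: per-SNP additive Cox models plus diagnostics.

Each variant's effect-allele dosage enters an otherwise-fixed Cox model
additively alongside the clinical covariates and genotype principal
components.  Tie handling is Efron by default (Breslow behind a flag);
missing genotypes are handled per variant by complete-case analysis with the
per-variant sample size recorded.  Wald P-values are reported to match the
HR + CI presentation; score and likelihood-ratio statistics are available
through :mod:`survgwas.coxph` for diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .containers import GenotypeMatrix, ValidationError, check_cohort
from .coxph import CoxData, cox_fit

GENOME_WIDE_P = 5.0e-8
SUGGESTIVE_P = 1.0e-5

#: Default fixed covariates of the scan (encoded clinical terms + first two PCs).
DEFAULT_SCAN_COVARIATES = ("age_ge50", "t34", "conc_cis_high", "PC1", "PC2")

_CHI2_1_MEDIAN = stats.chi2.ppf(0.5, df=1)  # 0.4549364...


@dataclass
class ScanConfig:
    covariates: tuple[str, ...] = DEFAULT_SCAN_COVARIATES
    ties: str = "efron"
    tol: float = 1e-9
    max_iter: int = 50
    genome_wide_p: float = GENOME_WIDE_P
    suggestive_p: float = SUGGESTIVE_P

    def __post_init__(self) -> None:
        for thr in (self.genome_wide_p, self.suggestive_p):
            if not (0.0 < thr < 1.0):
                raise ValidationError("significance thresholds must lie in (0, 1)")


class CoxPHScan(BaseEstimator):
    """Per-variant additive Cox scan as an estimator.

    Parameters mirror :class:`ScanConfig`; ``fit(g, cohort)`` expects the
    covariate columns already present (numeric) in the cohort table, e.g.
    after joining encoded clinical terms with genotype PCs.

    Attributes
    ----------
    results_ : pandas.DataFrame
        One row per variant: variant_id, chrom, pos, ref, alt, eaf, beta,
        se, hr, ci_low, ci_high, p, n_used, converged.
    """

    def __init__(self, covariates: tuple[str, ...] = DEFAULT_SCAN_COVARIATES,
                 ties: str = "efron", tol: float = 1e-9, max_iter: int = 50):
        self.covariates = covariates
        self.ties = ties
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, g: GenotypeMatrix, cohort: pd.DataFrame) -> "CoxPHScan":
        check_cohort(cohort)
        if len(cohort) != g.n_subjects:
            raise ValidationError("cohort and genotype matrix must have aligned subjects")
        missing_cov = [c for c in self.covariates if c not in cohort.columns]
        if missing_cov:
            raise ValidationError(f"cohort table lacks scan covariates: {missing_cov}")
        covs = cohort[list(self.covariates)].to_numpy(dtype=float) if self.covariates else \
            np.empty((len(cohort), 0))
        if np.isnan(covs).any():
            raise ValidationError("scan covariates must be complete (no missing values)")
        time = cohort["time"].to_numpy(float)
        event = cohort["event"].to_numpy(int)
        full_data = CoxData(time, event)
        p_fixed = covs.shape[1]
        # warm start every variant fit at the covariates-only solution
        if p_fixed:
            null_fit = cox_fit(covs, data=full_data, ties=self.ties,
                               tol=self.tol, max_iter=self.max_iter)
            init_full = np.append(null_fit.beta if null_fit.converged else np.zeros(p_fixed), 0.0)
        else:
            init_full = np.zeros(1)

        rows = []
        dosage = g.dosage
        any_missing = np.isnan(dosage).any(axis=0)
        for j in range(g.n_variants):
            dos = dosage[:, j]
            if any_missing[j]:
                keep = ~np.isnan(dos)
                n_used = int(keep.sum())
                if n_used == 0 or event[keep].sum() == 0:
                    rows.append(self._failed_row(n_used, np.nan))
                    continue
                res = cox_fit(np.column_stack([covs[keep], dos[keep]]),
                              time[keep], event[keep], ties=self.ties,
                              tol=self.tol, max_iter=self.max_iter, init=init_full)
                eaf = float(dos[keep].mean() / 2.0)
            else:
                n_used = len(dos)
                res = cox_fit(np.column_stack([covs, dos]), data=full_data,
                              ties=self.ties, tol=self.tol, max_iter=self.max_iter,
                              init=init_full)
                eaf = float(dos.mean() / 2.0)
            beta, se = res.beta[-1], res.se[-1]
            if res.converged:
                z2 = (beta / se) ** 2
                p = float(stats.chi2.sf(z2, df=1))
                rows.append(dict(eaf=eaf, beta=beta, se=se, hr=float(np.exp(beta)),
                                 ci_low=float(np.exp(beta - 1.959963984540054 * se)),
                                 ci_high=float(np.exp(beta + 1.959963984540054 * se)),
                                 p=max(p, np.nextafter(0, 1)), n_used=n_used, converged=True))
            else:
                rows.append(self._failed_row(n_used, eaf))
        res_df = pd.concat([g.variants[["variant_id", "chrom", "pos", "ref", "alt"]]
                            .reset_index(drop=True),
                            pd.DataFrame(rows)], axis=1)
        self.results_ = res_df
        return self

    @staticmethod
    def _failed_row(n_used: int, eaf: float) -> dict:
        return dict(eaf=eaf, beta=np.nan, se=np.nan, hr=np.nan, ci_low=np.nan,
                    ci_high=np.nan, p=np.nan, n_used=n_used, converged=False)


def gwas_scan(g: GenotypeMatrix, cohort: pd.DataFrame,
              pcs: pd.DataFrame | None = None,
              cfg: ScanConfig | None = None) -> pd.DataFrame:
    """Run the per-SNP Cox scan; returns the summary-statistics table.

    ``pcs`` (a subject-indexed PC table) is joined onto the cohort before
    fitting; covariates default to the encoded clinical terms plus PC1/PC2.
    """
    cfg = cfg or ScanConfig()
    cohort = cohort.reset_index(drop=True)
    if pcs is not None:
        pcs = pcs.reset_index(drop=True) if not isinstance(pcs.index, pd.MultiIndex) else pcs
        cohort = pd.concat([cohort, pcs.reset_index(drop=True)], axis=1)
    scan = CoxPHScan(covariates=tuple(cfg.covariates), ties=cfg.ties,
                     tol=cfg.tol, max_iter=cfg.max_iter)
    scan.fit(g, cohort)
    return scan.results_


def genomic_inflation(p_values) -> float:
    """Genomic inflation factor: median observed chi2(1) over its null median."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if len(p) == 0:
        raise ValidationError("no valid P-values for genomic inflation")
    chisq = stats.chi2.isf(p, df=1)
    return float(np.median(chisq) / _CHI2_1_MEDIAN)


def qq_manhattan_tables(scan: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Observed-vs-expected quantile table and Manhattan table from scan results."""
    valid = scan.loc[scan["converged"] & np.isfinite(scan["p"])]
    if len(valid) == 0:
        raise ValidationError("scan has no valid P-values")
    m = len(valid)
    obs = -np.log10(np.sort(valid["p"].to_numpy()))  # descending in -log10
    exp = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    qq = pd.DataFrame({"expected_neglog10p": exp, "observed_neglog10p": obs})
    manhattan = valid[["variant_id", "chrom", "pos"]].copy()
    manhattan["neglog10p"] = -np.log10(valid["p"].to_numpy())
    return qq, manhattan.reset_index(drop=True)


def stratified_analysis(g: GenotypeMatrix, cohort: pd.DataFrame, variant_id: str,
                        strata: dict[str, tuple], covariates=DEFAULT_SCAN_COVARIATES,
                        drop_map: dict[str, str] | None = None,
                        ties: str = "efron") -> pd.DataFrame:
    """Per-stratum adjusted HR for one variant.

    ``strata`` maps a stratifying label to ``(column, value)`` pairs; the
    model inside each stratum uses the standard covariates minus the one
    the stratum is defined on (``drop_map`` maps stratifying column ->
    covariate name to drop, e.g. ``{"t_stage": "t34"}``).
    """
    drop_map = drop_map or {}
    dos = g.dosage_for(variant_id)
    rows = []
    for label, (col, value) in strata.items():
        mask = (cohort[col] == value).to_numpy()
        covs = [c for c in covariates if c != drop_map.get(col)]
        sub = cohort.loc[mask]
        row = dict(stratum=label, column=col, value=value, n=int(mask.sum()),
                   n_events=int(sub["event"].sum()) if mask.any() else 0,
                   covariates=",".join(covs))
        if row["n_events"] == 0:
            rows.append({**row, "hr": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                         "p": np.nan, "converged": False})
            continue
        X = np.column_stack([sub[list(covs)].to_numpy(float), dos[mask]])
        res = cox_fit(X, sub["time"].to_numpy(float), sub["event"].to_numpy(int), ties=ties)
        beta, se = res.beta[-1], res.se[-1]
        if res.converged:
            lo, hi = np.exp(beta - 1.96 * se), np.exp(beta + 1.96 * se)
            p = float(stats.chi2.sf((beta / se) ** 2, df=1))
            rows.append({**row, "hr": float(np.exp(beta)), "ci_low": float(lo),
                         "ci_high": float(hi), "p": p, "converged": True})
        else:
            rows.append({**row, "hr": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                         "p": np.nan, "converged": False})
    return pd.DataFrame(rows)


def km_logrank(time, event, groups) -> tuple[pd.DataFrame, float, float]:
    """Kaplan-Meier curves per group plus the log-rank test.

    Returns ``(curves, chi2, p)`` where curves holds per-group step
    functions as (group, time, at_risk, events, survival) rows.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    time = np.asarray(time, float)
    event = np.asarray(event, int)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValidationError("log-rank requires at least two non-empty groups")
    frames = []
    for lab in labels:
        m = groups == lab
        kmf = KaplanMeierFitter().fit(time[m], event[m])
        tab = kmf.event_table.reset_index().rename(columns={"event_at": "time"})
        surv = kmf.survival_function_.iloc[:, 0].to_numpy()
        frames.append(pd.DataFrame({
            "group": lab, "time": tab["time"], "at_risk": tab["at_risk"].astype(int),
            "events": tab["observed"].astype(int), "survival": surv,
        }))
    res = multivariate_logrank_test(time, groups, event)
    return pd.concat(frames, ignore_index=True), float(res.test_statistic), float(res.p_value)
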