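"""Variant-level quality control: call rate, MAF, Hardy-Weinberg, imputation INFO.

The filters mirror standard array-GWAS practice: drop variants with call
rate < 95%, MAF < 1%, exact-test HWE P < 1e-12, and (for imputed dosages)
INFO < 0.8.  Sample-level QC (per-subject call rate, heterozygosity, IBD,
iterative PC-outlier removal) is out of scope here; `sample_qc_hook`
documents that boundary explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.base import BaseEstimator

from .containers import GenotypeMatrix, ValidationError


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact Hardy-Weinberg equilibrium P-value.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts that are no more probable than the observed one
    (the standard two-sided exact formulation).  Counts are genotype counts
    of hard calls.

    Returns P in (0, 1]; degenerate configurations (fewer than two
    subjects, or a monomorphic site) give P = 1.
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 for c in counts):
        raise ValidationError("genotype counts must be non-negative")
    n = sum(counts)
    if n < 1:
        raise ValidationError("need at least one genotyped subject")
    n_a = 2 * n_hom_alt + n_het  # alt allele count
    n_minor = min(n_a, 2 * n - n_a)
    if n_minor == 0 or n <= 1:
        return 1.0
    # log P(het = h | allele counts), up to a shared constant:
    #   log n! - log n_hom_ref! - log h! - log n_hom_alt! + h log 2
    hs = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_minor = (n_minor - hs) // 2
    hom_major = n - hs - hom_minor
    logp = hs * np.log(2.0) - gammaln(hom_minor + 1) - gammaln(hs + 1) - gammaln(hom_major + 1)
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    match = np.flatnonzero(hs == n_het)
    if len(match) == 0:  # parity mismatch: cannot happen with valid counts
        raise ValidationError("heterozygote count inconsistent with allele count parity")
    p_obs = p[match[0]]
    pval = float(p[p <= p_obs * (1 + 1e-12)].sum())
    return min(pval, 1.0)


@dataclass
class QCReport:
    """Per-variant QC metrics and per-filter removal accounting."""

    metrics: pd.DataFrame  # variant_id, call_rate, maf, hwe_p, info_score, kept
    removed_by_filter: dict[str, int]
    n_input: int
    n_retained: int
    notes: tuple[str, ...] = (
        "HWE exact test computed on hard calls (dosages rounded to nearest integer).",
        "MAF folded for filtering only; effect allele remains ALT throughout.",
    )

    def summary(self) -> pd.DataFrame:
        rows = [{"filter": k, "n_removed": v} for k, v in self.removed_by_filter.items()]
        rows.append({"filter": "retained", "n_removed": self.n_retained})
        return pd.DataFrame(rows)


class VariantQC(BaseEstimator):
    """Variant filter as a scikit-learn style transformer on GenotypeMatrix.

    Parameters
    ----------
    call_rate_min : float
        Minimum fraction of non-missing calls (default 0.95).
    maf_min : float
        Minimum minor allele frequency (default 0.01).
    hwe_p_min : float or None
        Exact-test HWE P below which the variant is dropped (default 1e-12);
        None disables the filter.
    info_min : float or None
        Minimum imputation INFO score; None (default) disables, and variants
        without an INFO score always pass.

    Attributes
    ----------
    keep_mask_ : bool array over input variants
    report_ : QCReport
    """

    def __init__(self, call_rate_min: float = 0.95, maf_min: float = 0.01,
                 hwe_p_min: float | None = 1e-12, info_min: float | None = None):
        self.call_rate_min = call_rate_min
        self.maf_min = maf_min
        self.hwe_p_min = hwe_p_min
        self.info_min = info_min

    def fit(self, g: GenotypeMatrix, y=None) -> "VariantQC":
        if g.n_variants == 0:
            raise ValidationError("empty genotype matrix")
        call_rate = g.call_rate()
        maf = g.maf()
        hwe_p = np.ones(g.n_variants)
        hard = np.rint(g.dosage)
        for j in range(g.n_variants):
            col = hard[:, j]
            col = col[~np.isnan(col)]
            if len(col) == 0:
                continue
            n0 = int((col == 0).sum()); n1 = int((col == 1).sum()); n2 = int((col == 2).sum())
            hwe_p[j] = hwe_exact_test(n0, n1, n2)
        info = (g.variants["info_score"].to_numpy(dtype=float)
                if "info_score" in g.variants.columns else np.full(g.n_variants, np.nan))

        fail_call = call_rate < self.call_rate_min
        fail_maf = maf < self.maf_min
        fail_hwe = (hwe_p < self.hwe_p_min) if self.hwe_p_min is not None else np.zeros(g.n_variants, bool)
        fail_info = (np.where(np.isnan(info), np.inf, info) < self.info_min
                     if self.info_min is not None else np.zeros(g.n_variants, bool))
        keep = ~(fail_call | fail_maf | fail_hwe | fail_info)

        self.keep_mask_ = keep
        self.report_ = QCReport(
            metrics=pd.DataFrame({
                "variant_id": g.variant_ids,
                "call_rate": call_rate,
                "maf": maf,
                "hwe_p": hwe_p,
                "info_score": info,
                "kept": keep,
            }),
            removed_by_filter={
                "call_rate": int(fail_call.sum()),
                "maf": int(fail_maf.sum()),
                "hwe": int(fail_hwe.sum()),
                "info": int(fail_info.sum()),
            },
            n_input=g.n_variants,
            n_retained=int(keep.sum()),
        )
        if self.report_.n_retained == 0:
            warnings.warn("all variants removed by QC", UserWarning, stacklevel=2)
        return self

    def transform(self, g: GenotypeMatrix) -> GenotypeMatrix:
        return g.select_variants(self.keep_mask_)

    def fit_transform(self, g: GenotypeMatrix, y=None) -> GenotypeMatrix:
        return self.fit(g).transform(g)


def variant_qc(g: GenotypeMatrix, call_rate_min: float = 0.95, maf_min: float = 0.01,
               hwe_p_min: float | None = 1e-12, info_min: float | None = None,
               ) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the variant filters; returns (filtered matrix, QC report)."""
    qc = VariantQC(call_rate_min, maf_min, hwe_p_min, info_min)
    out = qc.fit_transform(g)
    return out, qc.report_


def sample_qc_hook(g: GenotypeMatrix) -> GenotypeMatrix:
    """Placeholder for sample-level QC.

    Per-subject call rate, heterozygosity outliers, relatedness (IBD) and
    iterative PC-outlier removal are deliberately not implemented: the
    simulator produces clean unrelated samples, and real deployments should
    run these in dedicated tooling (e.g. PLINK) upstream.  Returns the
    matrix unchanged.
    """
    return g
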