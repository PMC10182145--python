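"""Permutation-based gene-set enrichment of survival-GWAS signals.

Tests whether SNPs lying within a flank-extended set of gene regions (for
hearing loss: curated hereditary-deafness genes, 50 kb flanks) are
over-represented among the scan's top signals.  The statistic is the count
of member SNPs below a P threshold; the null is built by jointly permuting
the phenotype block (clinical covariates and the censored outcome) against
the fixed genotypes and genotype-derived PCs, rescanning, and recounting.
The empirical P at each threshold is the fraction of permutations whose
count reaches the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import GenotypeMatrix, ValidationError
from .scan import DEFAULT_SCAN_COVARIATES, CoxPHScan

#: The P thresholds scanned in the enrichment (5e-2 down to 5e-6).
DEFAULT_THRESHOLDS = (5e-2, 5e-3, 5e-4, 1e-4, 5e-5, 1e-5, 5e-6)

DEFAULT_FLANK = 50_000       # enrichment gene-boundary extension, bp
CANDIDATE_FLANK = 20_000     # candidate-gene selection flank, bp


@dataclass
class GeneRegionSet:
    """Gene intervals (0-based half-open) with a symmetric flank in bp."""

    genes: pd.DataFrame  # columns: name, chrom, start, end
    flank: int = DEFAULT_FLANK

    def __post_init__(self) -> None:
        if self.flank < 0:
            raise ValidationError("flank must be non-negative")
        missing = {"name", "chrom", "start", "end"} - set(self.genes.columns)
        if missing:
            raise ValidationError(f"gene table lacks columns: {sorted(missing)}")

    def subset(self, names: list[str]) -> "GeneRegionSet":
        keep = self.genes["name"].isin(set(names))
        return GeneRegionSet(self.genes.loc[keep].reset_index(drop=True), self.flank)


def map_snps_to_regions(variants: pd.DataFrame, regions: GeneRegionSet
                        ) -> tuple[np.ndarray, dict[str, list[str]]]:
    """Assign variants to flank-extended gene regions.

    A variant at 1-based position q on the gene's chromosome is a member
    iff start - flank < q <= end + flank (half-open BED interval extended
    by the flank on both sides, clipped at zero).  Returns a boolean
    membership mask over the variant table's rows and a per-gene list of
    member variant ids (a variant hit by several genes appears in each
    list but once in the mask).
    """
    member = np.zeros(len(variants), dtype=bool)
    per_gene: dict[str, list[str]] = {}
    known_chroms = set(variants["chrom"].unique())
    pos = variants["pos"].to_numpy()
    vids = variants["variant_id"].to_numpy()
    for _, gene in regions.genes.iterrows():
        if gene["chrom"] not in known_chroms:
            import warnings
            warnings.warn(f"gene {gene['name']}: chromosome {gene['chrom']!r} absent "
                          "from variant table; zero matches", UserWarning, stacklevel=2)
            per_gene[gene["name"]] = []
            continue
        on_chrom = (variants["chrom"] == gene["chrom"]).to_numpy()
        lo = max(int(gene["start"]) - regions.flank, 0)
        hi = int(gene["end"]) + regions.flank
        hit = on_chrom & (pos > lo) & (pos <= hi)
        member |= hit
        per_gene[gene["name"]] = list(vids[hit])
    return member, per_gene


def count_significant(scan: pd.DataFrame, membership: np.ndarray, threshold: float) -> int:
    """Member variants with a valid, converged P strictly below the threshold."""
    if not (0.0 < threshold <= 1.0):
        raise ValidationError("threshold must lie in (0, 1]")
    valid = scan["converged"].to_numpy(bool) & np.isfinite(scan["p"].to_numpy(float))
    return int(np.sum(membership & valid & (scan["p"].to_numpy(float) < threshold)))


#: Columns of the phenotype block that are shuffled jointly in each permutation.
PERMUTED_COLUMNS = ("time", "event")


class PermutationEnrichment(BaseEstimator):
    """Permutation null for the member-SNP threshold-count statistic.

    In each shuffle one random permutation of subject rows is applied
    jointly to the phenotype block (scan covariates that are clinical, plus
    time and event) while genotypes and genotype-derived PCs stay fixed,
    the member-variant Cox scan is rerun, and counts per threshold are
    recorded.  Restricting the rescans to member variants leaves every
    count unchanged relative to a genome-wide rescan (non-members never
    enter the statistic) at a fraction of the cost.

    Parameters
    ----------
    thresholds : tuple of float
    n_permutations : int (default 1000, the usual study-scale choice)
    covariates : scan covariate names; those not named ``PC*`` are treated
        as phenotype-side and permuted with the outcome.
    add_one : bool
        If True use the (count + 1) / (B + 1) empirical-P estimator;
        default is the plain count / B.
    max_fits : int
        Refuse jobs whose B x members x subjects product exceeds this
        budget, with guidance to shrink B or the member set.
    """

    def __init__(self, thresholds=DEFAULT_THRESHOLDS, n_permutations: int = 1000,
                 covariates=DEFAULT_SCAN_COVARIATES, ties: str = "efron",
                 add_one: bool = False, seed: int = 0, max_fits: int = 2_000_000_000):
        self.thresholds = thresholds
        self.n_permutations = n_permutations
        self.covariates = covariates
        self.ties = ties
        self.add_one = add_one
        self.seed = seed
        self.max_fits = max_fits

    def fit(self, g: GenotypeMatrix, cohort: pd.DataFrame, membership: np.ndarray) -> "PermutationEnrichment":
        membership = np.asarray(membership, dtype=bool)
        if membership.sum() == 0:
            raise ValidationError("empty membership set: nothing to enrich")
        if self.n_permutations < 1:
            raise ValidationError("need at least one permutation")
        n_member = int(membership.sum())
        if self.n_permutations * n_member * g.n_subjects > self.max_fits:
            raise ValidationError(
                f"permutation budget exceeded ({self.n_permutations} shuffles x "
                f"{n_member} member SNPs x {g.n_subjects} subjects); reduce "
                "n_permutations or the member set, or raise max_fits")
        g_member = g.select_variants(membership)
        scan = CoxPHScan(covariates=tuple(self.covariates), ties=self.ties)
        obs = scan.fit(g_member, cohort).results_
        all_member = np.ones(len(obs), dtype=bool)
        thresholds = tuple(self.thresholds)
        self.observed_counts_ = np.array(
            [count_significant(obs, all_member, t) for t in thresholds])

        pheno_cols = [c for c in self.covariates if not str(c).startswith("PC")]
        pc_cols = [c for c in self.covariates if str(c).startswith("PC")]
        block = list(pheno_cols) + list(PERMUTED_COLUMNS)
        rng = np.random.default_rng(self.seed)
        null = np.empty((self.n_permutations, len(thresholds)), dtype=int)
        work = cohort.reset_index(drop=True).copy()
        for b in range(self.n_permutations):
            perm = rng.permutation(len(work))
            shuffled = work.copy()
            shuffled[block] = work[block].to_numpy()[perm]
            res = scan.fit(g_member, shuffled).results_
            null[b] = [count_significant(res, all_member, t) for t in thresholds]
        self.null_counts_ = null
        num = (null >= self.observed_counts_[None, :]).sum(axis=0)
        if self.add_one:
            self.empirical_p_ = (num + 1) / (self.n_permutations + 1)
        else:
            self.empirical_p_ = num / self.n_permutations
        self.thresholds_ = thresholds
        self.observed_scan_ = obs
        self.pc_covariates_ = tuple(pc_cols)  # fixed to the genotype side, never permuted
        return self

    def result_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": list(self.thresholds_),
            "observed_count": self.observed_counts_,
            "null_mean": self.null_counts_.mean(axis=0),
            "empirical_p": self.empirical_p_,
        })

    def null_histogram(self, threshold: float) -> pd.DataFrame:
        """Histogram of null counts at one threshold (observed count marked)."""
        idx = list(self.thresholds_).index(threshold)
        counts = np.bincount(self.null_counts_[:, idx])
        return pd.DataFrame({
            "count": np.arange(len(counts)),
            "n_permutations": counts,
            "is_observed": np.arange(len(counts)) == self.observed_counts_[idx],
        })


def permutation_enrichment(g: GenotypeMatrix, cohort: pd.DataFrame, membership,
                           thresholds=DEFAULT_THRESHOLDS, n_permutations: int = 1000,
                           seed: int = 0, covariates=DEFAULT_SCAN_COVARIATES,
                           add_one: bool = False) -> PermutationEnrichment:
    """Functional wrapper around :class:`PermutationEnrichment`."""
    enr = PermutationEnrichment(thresholds=thresholds, n_permutations=n_permutations,
                                covariates=covariates, seed=seed, add_one=add_one)
    return enr.fit(g, cohort, membership)
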