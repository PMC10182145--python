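"""SNP-to-region mapping and permutation enrichment."""

import numpy as np
import pandas as pd
import pytest

from survgwas.containers import ValidationError
from survgwas.coxph import cox_fit
from survgwas.enrich import (GeneRegionSet, PermutationEnrichment, count_significant,
                             map_snps_to_regions, permutation_enrichment)

COVS = ("age_ge50", "t34", "conc_cis_high")


def _variants(positions, chrom="chr1"):
    return pd.DataFrame({"variant_id": [f"v{i}" for i in range(len(positions))],
                         "chrom": chrom, "pos": positions, "ref": "G", "alt": "A"})


def test_membership_boundary_conventions():
    genes = pd.DataFrame({"name": ["g"], "chrom": "chr1", "start": [10_000], "end": [12_000]})
    # 0-based half-open [10000, 12000) = 1-based positions 10001..12000
    regions = GeneRegionSet(genes, flank=500)
    pos = np.array([9_500, 9_501, 12_500, 12_501])
    member, _ = map_snps_to_regions(_variants(pos), regions)
    # variant exactly flank bp upstream of gene start (1-based 9501) is included
    assert list(member) == [False, True, True, False]
    regions0 = GeneRegionSet(genes, flank=0)
    member0, _ = map_snps_to_regions(_variants(np.array([12_000, 12_001])), regions0)
    assert list(member0) == [True, False]  # 1 bp past gene end excluded


def test_membership_matches_all_pairs_brute_force():
    rng = np.random.default_rng(5)
    pos = rng.integers(1, 1_000_000, 500)
    starts = np.sort(rng.integers(0, 950_000, 20))
    genes = pd.DataFrame({"name": [f"g{i}" for i in range(20)], "chrom": "chr1",
                          "start": starts, "end": starts + rng.integers(1_000, 30_000, 20)})
    flank = 10_000
    member, per_gene = map_snps_to_regions(_variants(pos), GeneRegionSet(genes, flank))
    brute = np.zeros(len(pos), dtype=bool)
    for i, q in enumerate(pos):
        for _, gene in genes.iterrows():
            if gene["start"] - flank < q <= gene["end"] + flank:
                brute[i] = True
    np.testing.assert_array_equal(member, brute)
    # per-gene lists consistent with the union mask
    union = set()
    for vids in per_gene.values():
        union.update(vids)
    assert union == set(_variants(pos)["variant_id"][member])


def test_unknown_chromosome_warns_zero_matches():
    genes = pd.DataFrame({"name": ["g"], "chrom": "chrX", "start": [0], "end": [100]})
    with pytest.warns(UserWarning, match="chrX"):
        member, per_gene = map_snps_to_regions(_variants(np.array([50])),
                                               GeneRegionSet(genes, 0))
    assert not member.any() and per_gene["g"] == []


def test_count_significant_manual_tally():
    scan = pd.DataFrame({
        "p": [1e-6, 0.02, 0.2, np.nan, 1e-3, 0.04],
        "converged": [True, True, True, False, True, True],
    })
    member = np.array([True, True, False, True, True, False])
    assert count_significant(scan, member, 0.05) == 3
    assert count_significant(scan, member, 1e-4) == 1
    assert count_significant(scan, np.zeros(6, bool), 1.0) == 0
    assert count_significant(scan, member, 1.0) == 3  # all member rows with valid P
    with pytest.raises(ValidationError):
        count_significant(scan, member, 0.0)


def test_threshold_one_saturates_empirical_p(small_null_study):
    g, cohort, _, _ = small_null_study
    member = np.zeros(g.n_variants, bool)
    member[:8] = True
    enr = permutation_enrichment(g, cohort, member, thresholds=(1.0,),
                                 n_permutations=10, covariates=COVS, seed=0)
    assert enr.empirical_p_[0] == 1.0
    assert (enr.null_counts_ == enr.observed_counts_[0]).all()


def test_zero_observed_count_gives_p_one(small_null_study):
    g, cohort, _, _ = small_null_study
    member = np.zeros(g.n_variants, bool)
    member[:5] = True
    enr = permutation_enrichment(g, cohort, member, thresholds=(1e-12,),
                                 n_permutations=10, covariates=COVS, seed=0)
    assert enr.observed_counts_[0] == 0
    assert enr.empirical_p_[0] == 1.0


def test_seed_fixes_null_counts(small_null_study):
    g, cohort, _, _ = small_null_study
    member = np.zeros(g.n_variants, bool)
    member[:6] = True
    a = permutation_enrichment(g, cohort, member, thresholds=(0.05, 0.01),
                               n_permutations=15, covariates=COVS, seed=7)
    b = permutation_enrichment(g, cohort, member, thresholds=(0.05, 0.01),
                               n_permutations=15, covariates=COVS, seed=7)
    np.testing.assert_array_equal(a.null_counts_, b.null_counts_)


def test_permutation_preserves_phenotype_block_jointly(small_null_study):
    """Permuting the phenotype block only relabels subjects: the clinical Cox fit
    on permuted data has exactly the original coefficients."""
    g, cohort, _, _ = small_null_study
    rng = np.random.default_rng(3)
    perm = rng.permutation(len(cohort))
    block = list(COVS) + ["time", "event"]
    shuffled = cohort.copy()
    shuffled[block] = cohort[block].to_numpy()[perm]
    X = cohort[list(COVS)].to_numpy(float)
    orig = cox_fit(X, cohort["time"].to_numpy(), cohort["event"].to_numpy(int))
    Xp = shuffled[list(COVS)].to_numpy(float)
    after = cox_fit(Xp, shuffled["time"].to_numpy(), shuffled["event"].to_numpy(int))
    np.testing.assert_allclose(after.beta, orig.beta, atol=1e-12)


def test_empirical_p_non_increasing_in_observed_count(small_null_study):
    g, cohort, _, _ = small_null_study
    member = np.zeros(g.n_variants, bool)
    member[:10] = True
    enr = permutation_enrichment(g, cohort, member, thresholds=(0.5, 0.05),
                                 n_permutations=25, covariates=COVS, seed=2)
    for idx in range(2):
        null = enr.null_counts_[:, idx]
        ps = [np.mean(null >= n_obs) for n_obs in range(0, null.max() + 2)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


def test_budget_guard_refuses_oversized_jobs(small_null_study):
    g, cohort, _, _ = small_null_study
    member = np.ones(g.n_variants, bool)
    enr = PermutationEnrichment(n_permutations=1000, covariates=COVS, max_fits=1000)
    with pytest.raises(ValidationError, match="budget"):
        enr.fit(g, cohort, member)


def test_empty_membership_rejected(small_null_study):
    g, cohort, _, _ = small_null_study
    with pytest.raises(ValidationError, match="empty membership"):
        permutation_enrichment(g, cohort, np.zeros(g.n_variants, bool),
                               n_permutations=5, covariates=COVS)


def test_add_one_estimator_option(small_null_study):
    g, cohort, _, _ = small_null_study
    member = np.zeros(g.n_variants, bool)
    member[:5] = True
    enr = PermutationEnrichment(thresholds=(1e-12,), n_permutations=9,
                                covariates=COVS, add_one=True, seed=0)
    enr.fit(g, cohort, member)
    assert enr.empirical_p_[0] == pytest.approx(1.0)  # (9+1)/(9+1)


def test_planted_member_signal_detected(planted_study):
    """Planted causal SNPs inside deafness regions push the empirical P down."""
    cfg, g, cohort, genes, deafness = planted_study
    regions = GeneRegionSet(genes, flank=cfg.flank).subset(deafness)
    member, _ = map_snps_to_regions(g.variants, regions)
    member = member.copy()
    for vid in cfg.causal_effects:  # ensure the planted SNPs count as members
        member |= g.variant_ids == vid
    enr = permutation_enrichment(g, cohort, member, thresholds=(1e-3,),
                                 n_permutations=60, covariates=COVS, seed=4)
    assert enr.observed_counts_[0] >= 1
    assert enr.empirical_p_[0] <= 0.05
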