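# survgwas

Survival GWAS for treatment-induced outcomes: per-SNP Cox
proportional-hazards scans, permutation-based gene-set enrichment, clinical
Cox modelling, and a combined genetic + clinical risk score with
train/test validation under censoring.

## Who this is for

Statistical-genetics analysts studying time-to-event treatment toxicities —
the motivating application is chemoradiation-induced hearing loss (CRIHL)
in nasopharyngeal carcinoma, where both cisplatin dose and radiation injure
the cochlea and susceptibility varies between patients. The package covers
the full cohort analysis:

1. **Variant QC** — call rate < 95%, MAF < 1%, exact-test Hardy–Weinberg
   P < 1e-12, optional imputation INFO < 0.8; genotype PCA (EIGENSTRAT
   scaling) for ancestry covariates.
2. **Scan** — for each variant, the effect-allele dosage g enters a Cox
   model additively, `h(t) = h0(t)·exp(γg + β'z)`, with clinical covariates
   and PCs in z; Efron ties, Wald HR/CI/P per variant, genomic inflation
   λ_GC, QQ/Manhattan tables, stratified and subgroup analyses, KM/log-rank
   utilities.
3. **Enrichment** — are SNPs within 50 kb of a curated gene set (e.g.
   hereditary-deafness genes) over-represented among top signals? The
   member-SNP count below a P threshold is compared against a null built by
   B joint permutations of the phenotype block against fixed genotypes;
   empirical P = #{N_b ≥ N_obs}/B.
4. **Risk score** — one joint Cox fit over selected SNP dosages and encoded
   clinical factors on a random half split; linear-predictor score,
   training-median cutoff, IPCW (Uno) AUC at a 60-month horizon, and the
   high-vs-low hazard ratio, evaluated on train/test/all.
5. **Synthetic data** — LD-blocked genotypes in exact Hardy–Weinberg
   proportions (AR(1) Gaussian copula), Table-1-style clinical marginals
   (~777 subjects, ~17% events, median follow-up ~70 months), Weibull
   proportional-hazards outcomes with plantable SNP/clinical effects, so
   every stage is testable without restricted patient data.

The Cox partial-likelihood engine (Newton–Raphson, Efron/Breslow ties,
score test) is implemented in-package and verified against lifelines and
closed-form identities; standard surrounding steps use cyvcf2, lifelines,
pandas and scikit-learn. Analysis stages are scikit-learn-style estimators
(`VariantQC`, `GenotypePCA`, `CoxPHScan`, `PermutationEnrichment`,
`CoxRiskScore`) with thin functional wrappers.

## Worked example

```python
import numpy as np
import pandas as pd
from survgwas import (SimConfig, simulate_dataset, simulate_gene_annotation,
                      variant_qc, genotype_pca, gwas_scan, ScanConfig,
                      genomic_inflation, GeneRegionSet, map_snps_to_regions,
                      permutation_enrichment, split_train_test, CoxRiskScore)
from survgwas.simulate import variant_ids, with_encoded

# lay out the synthetic genome first, then plant a causal SNP inside a
# deafness gene region (the annotation stream ignores causal_effects, so the
# final dataset keeps these positions)
base = SimConfig(n_subjects=777, n_variants=1000, seed=7,
                 member_variant_fraction=0.05,
                 clinical_effects={"age_ge50": np.log(1.7), "t34": np.log(1.7)})
genes, deafness, positions = simulate_gene_annotation(base)
regions = GeneRegionSet(genes, flank=50_000).subset(deafness)
variants = pd.DataFrame({"variant_id": variant_ids(base.n_variants),
                         "chrom": "chr1", "pos": positions, "ref": "G", "alt": "A"})
member, _ = map_snps_to_regions(variants, regions)
lead = variants.loc[member, "variant_id"].iloc[0]
cfg = SimConfig(**{**base.__dict__, "causal_effects": {lead: np.log(2.5)}})

g, cohort, genes, deafness = simulate_dataset(cfg)
print(f"{len(cohort)} subjects, {cohort.event.sum()} events "
      f"({100 * cohort.event.mean():.1f}%); planted SNP {lead}")

g_qc, report = variant_qc(g)
pcs, _ = genotype_pca(g_qc, k=2)
enc = with_encoded(cohort, pcs)

scan = gwas_scan(g_qc, enc, cfg=ScanConfig())
lam = genomic_inflation(scan.loc[scan.converged, "p"])
top = scan.nsmallest(1, "p").iloc[0]
print(f"lambda_GC = {lam:.3f}; top hit {top.variant_id}: "
      f"HR {top.hr:.2f}, P = {top.p:.2e}")

member, _ = map_snps_to_regions(g_qc.variants, regions)
enr = permutation_enrichment(g_qc, enc, member, thresholds=(1e-3,),
                             n_permutations=200, seed=7,
                             covariates=("age_ge50", "t34", "conc_cis_high"))
print(f"member SNPs: {member.sum()}, observed count {enr.observed_counts_[0]}, "
      f"empirical P = {enr.empirical_p_[0]:.3f}")

train, test = split_train_test(enc, seed=7)
model = CoxRiskScore(snp_ids=(lead,),
                     clinical_terms=("age_ge50", "t34", "conc_cis_high"))
model.fit(train, g_qc)
ev = model.evaluate(test, g_qc)
print(f"test AUC(60 mo) = {ev['auc']:.2f}, "
      f"high-vs-low HR = {ev['group_hr']:.2f} (P = {ev['group_hr_p']:.2e})")
```

Output:

```
777 subjects, 105 events (13.5%); planted SNP snp000034
lambda_GC = 0.990; top hit snp000034: HR 3.14, P = 2.01e-15
member SNPs: 169, observed count 2, empirical P = 0.020
test AUC(60 mo) = 0.70, high-vs-low HR = 2.62 (P = 1.69e-03)
```

The planted deafness-region SNP comes out as the top hit (estimated HR 3.14
for a planted 2.5 — top-hit estimates overshoot by selection, the usual
winner's curse); λ_GC near 1 shows the rest of the scan is calibrated; the
planted member signal makes the deafness-region count significant against
the permutation null (empirical P = 0.020); and the combined risk score
separates high- from low-risk patients in the held-out half.

There is also a CLI over the same library (`survgwas simulate | qc | scan |
enrich | risk | run | report`), driven by a YAML config with seeds for
every random stage; rerunning a config reproduces the output manifest
hashes exactly.

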