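# Methods

`survgwas` implements a time-to-event genome-wide association workflow for
treatment-induced outcomes — built around chemoradiation-induced hearing
loss (CRIHL) in nasopharyngeal carcinoma cohorts — together with the
synthetic-data machinery needed to exercise every stage without restricted
patient data. This note records the models, the defaults and why they were
chosen, the numerical choices, and what the synthetic studies do and do not
demonstrate.

## Outcome model and per-SNP scan

The outcome is right-censored time from treatment initiation to first
documented hearing loss, in months. All association models are Cox
proportional hazards:

    h(t | x) = h0(t) · exp(β'x)

For the genome-wide scan, each variant's effect-allele (ALT) dosage
g ∈ [0, 2] enters additively alongside the fixed covariates — by default the
encoded clinical terms (age ≥ 50 years, T3–T4 stage, concurrent cisplatin
dose ≥ 155 mg/m²) and the first two genotype principal components:

    h(t | g, z) = h0(t) · exp(γ·g + β'z)

The partial likelihood is maximised by Newton–Raphson with step-halving
(tolerance 1e-9 on the maximum coefficient change, 50 iterations maximum),
Efron tie handling by default (the convention of the R `survival` engine;
Breslow is available behind a flag). Standard errors come from the inverse
observed information, P-values are two-sided Wald, matching the HR + 95% CI
presentation; the score test at β = 0 is exposed separately and, for a
binary covariate without tied event times, is algebraically the log-rank
chi-square — the test suite uses this identity, plus agreement with
`lifelines`, as independent oracles. When event times carry no ties the
Efron correction terms vanish and the implementation skips them; results
are identical, the scan roughly twice as fast.

Fits that cannot be trusted — singular information (e.g. a dosage collinear
with a covariate), numerical separation (|β| > 100 or non-finite SE), or
iteration-limit exhaustion — are flagged `converged = False` with NaN
statistics rather than reporting fabricated numbers. Missing genotypes are
handled per variant by complete-case analysis with the per-variant sample
size recorded; imputed dosages are typically complete, so this mainly
affects hard-called array data.

Scan diagnostics: the genomic inflation factor λ_GC is the median observed
χ²(1) quantile divided by the χ²(1) median (≈ 0.4549); QQ tables use
expected quantiles −log10((i − 0.5)/m). Fixed significance conventions are
reported (5×10⁻⁸ genome-wide, 1×10⁻⁵ suggestive) with no FDR layer, since
the workflow's multiple-testing presentation is threshold-based.

## Variant QC and PCA

Variants failing any enabled filter are removed: call rate < 95%,
MAF < 1% (MAF folded as min(p, 1−p) for filtering only; effect orientation
is always ALT), exact-test Hardy–Weinberg P < 1e-12, and optionally
imputation INFO < 0.8. The HWE exact test conditions on allele counts and
sums the probabilities of all heterozygote counts no more likely than the
observed one; it is evaluated on hard calls (dosages rounded to the nearest
integer), because the exact test is defined on genotype counts — this is
recorded in the QC report. Filters are order-independent (each is computed
on the input matrix), so QC is idempotent. Sample-level QC (subject call
rate, heterozygosity, relatedness, iterative PC-outlier removal) is out of
scope and documented as an explicit no-op hook; it belongs in upstream
array-QC tooling.

PCA follows the EIGENSTRAT convention: per-variant mean imputation of
missing calls, centering at 2p and scaling by √(2p(1−p)), then the leading
left singular vectors of the standardised matrix. Signs are fixed by making
each component's largest-magnitude loading positive, so results are
reproducible across runs and subject orderings (up to the permutation).

## Clinical analysis

Cohort summaries report proportions as percentages to one decimal and
median/IQR by linear interpolation. Continuous covariates are dichotomised
at the cutoff maximising Youden's J (sensitivity + specificity − 1) over
observed values against the end-of-follow-up event indicator, ties broken
toward the smaller cutoff, with the rule "≥ cutoff"; a plain (not
time-dependent) ROC is the deliberate choice, and censoring is ignored for
cutoff selection only. The carry-forward screening rule (univariate Wald
P < 0.05 enters the multivariate model) is implemented as a separate
optional step; the pipeline's covariate list is explicit configuration, not
hard-wired screening. Missing EBV DNA is treated as an explicit "NA" level
for categorical summaries and codes to 0 in the high-EBV indicator.

## Permutation enrichment

Gene regions (BED, 0-based half-open) are extended symmetrically by a flank
(50 kb for enrichment; 20 kb is the candidate-gene convention), and a
variant at 1-based position q is a member iff start − flank < q ≤ end +
flank for any gene, counted once however many genes cover it. The statistic
is the number of member variants with a converged P below a threshold
(strict inequality). The null is built by applying, in each of B shuffles,
one random permutation of subject rows jointly to the phenotype block —
the clinical scan covariates plus (time, event) — while genotypes stay
fixed; genotype-derived PCs travel with the genotype side and are *not*
permuted, since they are a function of the genotypes alone. The empirical P
at each threshold is #{b : N_b ≥ N_obs}/B (ties count toward the numerator);
an add-one (N+1)/(B+1) variant is available. Two design decisions worth
stating:

* Permutation rescans are restricted to member variants. Non-members never
  enter the count, so the null distribution is identical to a genome-wide
  rescan at a small fraction of the cost; this is recorded in the result
  metadata.
* Because the whole phenotype block moves together, the permuted data are a
  relabeling of subjects: the clinical Cox model refit on permuted data
  reproduces the original coefficients exactly, a property the tests assert.
  Only the genotype–phenotype link is broken.

A budget guard refuses shuffle jobs whose B × members × subjects product
exceeds a configured limit, with guidance, instead of running for hours.

## Risk score

The combined model is one joint Cox fit over SNP dosages (additive) and
encoded clinical indicators on a random half split (train ⌈n/2⌉ — for 777
subjects, 389/388 — no event stratification). The risk score is the raw
linear predictor Σ coefficient × term; the training-set median is the
high/low cutoff with "score > cutoff" defining high (the median subject is
low). Discrimination at a 60-month horizon ("5-year risk", configurable)
uses the IPCW cumulative/dynamic (Uno-type) AUC: cases are subjects with an
observed event by the horizon, controls those followed beyond it, case
contributions weighted by the inverse Kaplan–Meier censoring survival at
the left limit of their event time (censorings tied with events are ordered
events-first), score ties counted one half. With no censoring before the
horizon every weight is 1 and the estimator reduces exactly to the
Mann–Whitney AUC of the binary "event by horizon" outcome — the test
suite's verification hook, alongside a cross-check against
scikit-survival's `cumulative_dynamic_auc`. The high-vs-low contrast is a
single-covariate Cox HR with Wald CI/P plus Kaplan–Meier tables per group.
Clinical-only, genetic-only and combined models are the same code path with
different term lists.

## Synthetic data generator

The generator emulates the statistical structure of the reference cohort so
that planted truths are recoverable:

* **Genotypes.** Per variant, MAF ~ Uniform(maf_range) (default 0.05–0.5).
  Within blocks of `ld_block_size` consecutive variants a first-order
  autoregressive latent Gaussian (parameter `ld_rho`, restarted at block
  boundaries) is thresholded at the Hardy–Weinberg genotype quantiles, so
  marginals are exactly HW while squared correlation decays geometrically
  with within-block distance. This is a copula convenience, not a model of
  human LD: recombination hotspots, allele-frequency–dependent LD and
  inter-block correlation are absent, so passing tests say nothing about
  real LD structure. An optional Gaussian dosage-noise mode (clipped to
  [0, 2]) emulates imputed dosages, attaching an INFO-like score
  2p(1−p) / (2p(1−p) + σ²) per variant.
* **Annotation.** Non-overlapping 20-kb genes on one 10-Mb synthetic
  chromosome (enrichment logic is position-based, so one chromosome
  suffices), a configurable fraction flagged as the "deafness" set, and
  optionally a controllable expected fraction of variants placed inside the
  flank-extended deafness regions.
* **Clinical covariates** are drawn from simple parametric families whose
  medians/IQRs and level frequencies match the reference cohort's Table-1
  marginals (age ≈ N(43.2, 9.6²) years; T3–T4 62.9%; concurrent cisplatin
  dose zero-inflated with median ≈ 160 mg/m², and so on). Covariates are
  mutually independent — real cohorts are not — so clinical-confounding
  behaviour is only weakly exercised.
* **Outcomes** follow a Weibull proportional-hazards model,
  S(t|x) = exp(−(t/scale)^shape · e^lp), with lp the sum of configured
  clinical effects (on encoded 0/1 covariates) and SNP effects (per
  dosage), centered on the hazard scale (mean relative hazard = 1) so
  planted effects redistribute risk between subjects rather than shifting
  the cohort's marginal event rate (Cox fits are invariant to the
  centering, which is absorbed into the baseline). With strong planted
  heterogeneity the marginal event rate still drops somewhat below the
  null-calibrated ~17% — the usual frailty effect of averaging a concave
  event probability — e.g. ~13% in the acceptance script's 8-SNP scenario. Defaults shape 0.75, scale 700 months give a decreasing hazard
  (events concentrate early, as observed). Censoring is staggered-entry
  administrative (database lock at 96 months minus Uniform(0, 48) accrual)
  plus exponential dropout at 0.002/month; with null effects this yields
  ≈ 17% events and a median censored follow-up near 70 months, chosen once
  by closed-form calculation from those target marginals and then verified
  by simulation.

Every stage draws from its own seeded stream, so a fixed `SimConfig` gives
byte-identical outputs and any stage is reproducible in isolation.

## Problem sizes used in the checks

The statistical acceptance checks run at sizes chosen to make their
assertions sharp at desk scale: null scan calibration uses 800 subjects ×
5,000 independent SNPs (binomial standard errors assume independence, so
`ld_rho = 0` there); parameter recovery averages 200 replicates of a
planted HR-2, MAF-0.3 SNP at n = 800; enrichment calibration uses 50
independent null datasets (250 subjects, 40 member SNPs, B = 100, count
threshold P < 0.5 so the count statistic has enough support for a
Kolmogorov–Smirnov uniformity check); enrichment power uses 10 planted
HR-2 member SNPs with B = 200. The acceptance script runs the full
pipeline on 777 subjects × 3,000 variants with B = 1,000 permutation
shuffles.

## Known limitations

* No kinship/mixed-model association, X-chromosome models, multiallelic
  decomposition or meta-analysis.
* The ROC criterion for cutoffs (Youden on the full cohort) and the
  missing-genotype policy (per-variant complete case) are documented
  conventions; other reasonable choices exist and results can shift
  slightly with them.
* IPCW AUC assumes censoring independent of score and outcome; heavy
  informative censoring would bias it.
* The generator's independence assumptions (covariates mutually
  independent, genotypes independent of clinical covariates, no population
  structure unless simulated via separate subpopulations) mean calibration
  results here do not certify robustness to confounding in real cohorts —
  the PC covariates exist precisely for the structure the generator does
  not create by default.
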