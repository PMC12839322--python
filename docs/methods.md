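# Methods

## Model and assumptions

`promethex` treats epigenetic regulation as a two-stage claim about a
gene: (1) its promoter methylation and its expression both differ between
CIMP-H and Non-CIMP tumors, and (2) promoter methylation statistically
explains expression variation across the pooled samples. Stage 1 is a
screening gate (necessary, not sufficient); stage 2 is the scored model.

The scored model for the regression family is ordinary least squares

  y_g = α + Σ_j β_j m_gj + ε,

with y_g the gene's log2-CPM and m_gj either each promoter CpG's beta
value (*single*), their promoter mean (*average*), or the fraction of
CpGs with β ≥ 0.3 (*ratio*). The quantity of interest is not the
coefficient vector but the adjusted R² — the explained-variance share
penalized for predictor count, which makes promoters with 2 and with 30
CpGs comparable — together with the overall F-test p-value. The Spearman
family replaces the linear model by rank correlation, which is robust to
monotone nonlinearity; the *single* variant averages per-CpG correlations
and therefore dilutes strong single-CpG effects — the very contrast the
method comparison is designed to expose.

Underlying assumptions: primary-tumor samples only; two well-separated
methylation strata (the CIMP-L middle is excluded from the contrast);
promoter membership as annotated in the array manifest (TSS1500 ∪ TSS200 ∪
promoter-associated — the manifest's TSS1500 band covers 200–1500 bp, so
the union realizes "within 1500 bp of the TSS"; strand handling is the
manifest's); no adjustment for copy number, purity or batch.

## Statistical components

* **Differential tests.** Welch t-tests on promoter-average betas and on
  log2-CPM, BH-corrected separately within each omic. Moderated-variance
  or count-model machinery (limma/edgeR-style) is intentionally not
  reproduced: the downstream selection consumes only thresholded effect
  sizes and BH-adjusted p-values, and the Welch test is exact about the
  two-group contrast without shrinkage assumptions. Degenerate rows (both
  groups constant) get p = 1 at equal means, p = 0 otherwise.
* **Effect sizes.** Δβ is the difference of group means of promoter-average
  beta (CIMP-H minus Non-CIMP); log2FC is the difference of group-mean
  log2-CPM. Log2-CPM (not raw CPM) is the expression scale throughout —
  it stabilizes variance and makes log2FC a mean difference.
* **TMM.** Implemented following the published algorithm: reference
  library = the one whose 75th-percentile count proportion is closest to
  the cohort mean of that statistic; per-pair gene-wise M (log2 proportion
  ratio) and A (mean log2 abundance) over genes positive in both
  libraries; double trim by rank (30% per tail on M, 5% on A);
  inverse-delta-method-variance weighted mean of the surviving M; factors
  rescaled to geometric mean 1. log2-CPM uses prior counts 0.5 (numerator)
  and 1.0 (effective library size). Two measured properties worth knowing:
  scale invariance to multiplying one library by a constant is exact for
  the M-values and trimming but only approximate (O(1/counts), ~4e-3 on
  the test fixture) through the precision weights; and when ~20% of genes
  shift 1.8–2 log2 in one direction with NB dispersion 0.1, the per-gene
  M noise (sd ≈ 0.65) swamps the ~0.2-log2 composition shift, so TMM
  undercorrects and observed |log2FC| is attenuated by roughly 0.2 — the
  reference implementation behaves identically.
* **CIMP-index.** Raw index = fraction of CpG islands whose mean beta is
  ≥ 0.3 per sample. Because the ±0.5 class thresholds live on a centered
  scale and cannot apply to a proportion, the raw index is standardized
  across the cohort (z-score, sample sd; all-zero when the cohort is
  constant) before thresholding; both scales are reported. Sample-sheet
  labels, when present, take precedence over the index.
* **Spearman-single p-value.** No single p accompanies a mean of per-CpG
  correlations naturally; Fisher's combination over the per-CpG p-values
  is used. Promoter CpGs are co-methylated, so this combination is
  anti-conservative; it is recorded as method metadata and the selection
  threshold on |ρ| does the real gating.
* **Regression details.** Rank-deficient predictor sets (co-methylated or
  constant CpGs) are reduced to an independent column basis by pivoted QR
  on the centered design, with tolerance `diag · max(n,k) · eps`; k_eff is
  the effective rank and enters the adjustment and the F reference
  distribution. Genes need n ≥ k + 3 samples (else "underdetermined") and
  ≥ 3 residual degrees of freedom after reduction (else
  "insufficient-df"); both are reported as statuses, never silently
  dropped. A perfect fit reports adj R² = 1, p = 0. A zero-variance
  response is an error; all-constant predictors score 0 with p = 1.
* **Selection and comparison.** Spearman selection uses |ρ| (silencing
  biology makes the interesting correlations negative; the magnitude
  criterion covers both signs), strict > 0.4, BH-adjusted p < α.
  Regression selection uses adj R² strictly > 0.5 with raw model p < α.
  Ranking is by descending |ρ| / adj R², ties broken lexicographically.
  Kruskal–Wallis compares |ρ| (Spearman family) and adj R² (regression
  family); argmax counts credit every method tied within 1e-12 of a
  gene's family maximum.
* **Silencing calls.** The external definition is under-specified in two
  places, both resolved here and isolated for replacement: expression
  z-scores are standardized per gene over all samples, and the probe-level
  test is a one-sided Welch test (methylated < unmethylated) BH-corrected
  across all probes jointly. The per-(gene, sample) call — needed to count
  silenced samples per group — is: sample silenced for a silenced gene
  when a strict majority of the gene's promoter probes are methylated in
  it. "Methylated" is strict β > 0.3 for silencing but inclusive β ≥ 0.3
  for the ratio metric and the CIMP-index, each following its own
  definition.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `delta_beta_min` | 0.2 | minimum \|Δβ\| (beta units) for differential methylation |
| `abs_log2fc_min` | 1.3 | minimum \|log2FC\| for differential expression |
| `meth_cpg_beta_min` | 0.3 | β at/above which a CpG counts as methylated |
| `spearman_abs_min` | 0.4 | minimum \|ρ\| for Spearman selection (strict) |
| `adj_r2_min` | 0.5 | minimum adjusted R² for regression selection (strict) |
| `alpha` | 0.05 | significance level for adjusted/model p-values |
| `cimp_index_hi/lo` | ±0.5 | standardized CIMP-index class thresholds (inclusive) |
| `silencing_sample_frac` | 0.01 | minimum methylated-sample fraction per probe |
| `silencing_z_max` | −1.65 | maximum mean expression z of the methylated group |
| `silencing_alpha` | 0.001 | FDR level of the probe silencing test |

Boundary conventions follow the definitions: effect-size thresholds and
CIMP-index thresholds are inclusive; score thresholds and significance
levels are strict.

## The synthetic cohort generator

The generator emulates the joint structure the pipeline consumes, not any
particular tumor cohort. Defaults: 200 genes; promoter sizes
2 + Poisson(4) capped at 30; 40 + 40 samples; 10% methylation-driven, 10%
DM-only, 10% DE-only genes; per-probe baseline methylation level
~ Beta(2,10) and hypermethylated level ~ Beta(10,2); per-sample
hypermethylation dose Beta(25,2) in CIMP-H vs Beta(1,30) in Non-CIMP
(interpolating each probe between its two levels, so promoter methylation
varies continuously within groups and a planted gene is an unambiguous
silencing event: Δβ ≈ 0.6, net log2FC ≈ −1.8 at the default slope −3);
per-cell Beta sampling noise with concentration ν = 50; a +0.02 global
CIMP-H shift of non-planted probe means; one CpG island per gene (the
unit of the CIMP-index); baseline log2 abundance ~ U(5,10), a floor that
keeps every gene quantifiable (≥ ~32 baseline counts), as real
differential pipelines filter low-expression genes before testing; NB
dispersion 0.1; library-size factors exp(U(ln 0.5, ln 2)); 5% each of
X/Y, SNP-flagged and NA-bearing decoy probes attached to decoy gene
symbols so the filters are exercised without touching planted promoters.
DE-only genes shift expression by −2 log2 units.

Two scenario constructors fix conditions for specific analyses:

* `opposite_sign_params()` — the multi-CpG mechanism scenario. Every
  probe gets an independent dose and the per-CpG expression coefficients
  follow a mixed-sign 2,−1,2,−1,… pattern normalized to sum to the net
  slope. The mechanism (a joint regression on all CpGs outperforming
  summary predictors) requires within-group per-CpG heterogeneity, so
  this scenario widens the doses to Beta(6,1)/Beta(1,6) and uses net
  slope −4 so the planted genes still clear the |log2FC| gate.
* The silencing-consistency scenario uses 12 CIMP-H vs 68 Non-CIMP. This
  is a mathematical necessity, not a tuning choice: the mean z-score of a
  group holding fraction f of the cohort is bounded by √((1−f)/f) — about
  1 at f = 0.5 — so with balanced groups the z < −1.65 clause can never
  fire. The external definition comes from a pan-cohort analysis in which
  heavily methylated samples are a minority; 15% CIMP-H reproduces that
  regime.

What the generator does **not** model: copy-number variation, tumor
purity, cell-type composition, batch effects, co-methylated domains
spanning genes, gene length (the pipeline is CPM-based by design), or
read-level count structure. Passing tests therefore demonstrate that the
implementation recovers planted linear methylation→expression structure
through the full preprocessing/testing/scoring chain under realistic
noise — they do not certify causal discovery on real tumors, where the
unmodeled confounders above can produce or mask associations.

## Problem sizes used in tests and the acceptance script

Oracle checks run on 100–120 randomized small instances (n ≤ 60,
k ≤ 8; BH on n ≤ 12 against exhaustive step-up search) at 1e-9. The TMM
reference check uses a frozen 200-gene × 4-sample NB fixture against
factors computed once with the reference implementation (agreement to
1e-6). Pipeline recovery uses 20 cohorts at the default size,
type-I control 50 global-null cohorts (10 000 gene-level tests per
omic), the mechanism and silencing scenarios 2–3 cohorts each; the whole
suite and the acceptance script each complete in about a minute on one
CPU.

## Known limitations

* The Welch substitution gives no variance moderation; at very small
  per-group sizes (< ~5) the differential stage loses power relative to
  moderated alternatives.
* Fisher-combined spearman-single p-values are anti-conservative under
  co-methylation (above); interpret them as ordering, not calibrated
  error rates.
* TMM undercorrects asymmetric composition shifts under high dispersion
  (measured above); strongly unbalanced differential expression
  attenuates observed fold changes by design of the normalization, not by
  implementation error.
* The silencing caller inherits the external definition's inability to
  call silencing when methylated samples approach half the cohort.
* Thresholds are global constants; no per-cohort threshold search is
  performed.
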