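# Methods

This note documents the models, conventions and design choices behind
`bloodmark`, in the spirit of a methods appendix: what is computed, under
which assumptions, and where the genuinely open choices were resolved.

## 1. Summary-statistics layer

A summary-statistics table holds one record per variant: id, chromosome,
1-based position, effect/other allele, effect-allele frequency, beta, SE,
p, and sample size. Files are tab-separated with header
`SNP CHR BP A1 A2 FREQ BETA SE P N` (remappable). Malformed rows (SE ≤ 0,
p outside (0,1], non-ACGT alleles) are dropped and counted; duplicated SNP
ids keep the smallest-p record (stable for QTL files listing several probes
per SNP). p/z consistency is checked but only warned about, since public
GWAS files often store truncated p-values.

Harmonization intersects a molecule's QTL table with a disease GWAS table on
SNP id. Identical allele pairs pass through; swapped pairs flip the disease
beta sign; strand-ambiguous (A/T, C/G) SNPs are dropped — the conservative
default when strand provenance is unknown — as are irreconcilable allele
pairs. The cis window is ±1,000,000 bp inclusive around the molecule's site.

LD matrices are Pearson dosage correlations. Constant columns get unit
self-correlation and zero cross terms (flagged); indefinite matrices are
repaired by minimal ridge inflation, and any repair is logged.

## 2. SMR, HEIDI, and sensitivity analyses

**Wald layer.** β̂_md(i) = β_id/β_im with SE_md(i) = SE_id/|β_im| — the
first-order delta method treating β_im as fixed (the absolute value keeps
the SE positive). Instruments with β_im = 0 are rejected, not evaluated.

**Instrument selection.** Cis: QTL p < 5×10⁻⁸ inside the window, greedily
pruned so pairwise r² ≤ 0.9, keeping the smaller-p SNP (ties → smaller
position). Genome-wide (2SMR): p < 1×10⁻⁵ with greedy 1-Mb distance
clumping per chromosome — a proxy for LD clumping when no genome-wide LD
panel is supplied; supply one and LD pruning is used instead.

**Multi-SNP combination.** The per-instrument Wald z-scores are combined by
LD-aware inverse-variance weighting: z_comb = (1ᵀR⁻¹z)/√(1ᵀR⁻¹1) with R the
signed instrument correlation from the LD matrix; the point estimate is the
same-weights mean of the Wald ratios, with SE from the weighted covariance
(Σ_ij = r_ij·SE_i·SE_j). With one instrument this reduces exactly to the
single-SNP Wald test — the anchoring contract of the implementation. A
singular R after pruning is ridge-repaired and logged.

**HEIDI.** Top SNP = smallest QTL p. Test SNPs: 0.05 < r²(·, top) < 0.9,
capped at the 20 strongest QTL signals; fewer than 3 usable test SNPs →
untested (missing p, flag "untested"). For d_i = β̂_md(i) − β̂_md(top), the
covariance uses the full first-order delta method — both the GWAS-side term
r_ij·SE_id,i·SE_id,j/(β_im,i β_im,j) and the QTL-side term
r_ij·β_id,i·β_id,j·SE_im,i·SE_im,j/(β_im,i² β_im,j²) — unlike the scalar SE
above, because ratio differences are sensitive to QTL-side noise. The
statistic T = Σ d_i²/Var(d_i) is referred to the two-moment (Satterthwaite)
scaled chi-square of the correlated quadratic form: T ≈ a·χ²_ν with
a = tr(C²)/tr(C), ν = tr(C)²/tr(C²) for the correlation matrix C of the
standardized differences. HEIDI p ≤ 0.05 labels a marker HEIDI(−)
(colocalization-driven); p > 0.05 labels it HEIDI(+). The boundary value
0.05 counts as "−".

**Sensitivity tools.** Fixed-effect IVW (weights SE_md⁻²); Cochran's Q with
χ²_{k−1} p; stepwise outlier removal (drop the largest Q contributor while
Q p < 0.05, never below 3 instruments, with an audit trail); MR-Egger as a
free-intercept WLS of β_id on β_im (weights SE_id⁻², instruments oriented to
β_im > 0), the intercept testing directional pleiotropy.

**Multiple testing and diagnostics.** Bonferroni threshold α/n applied
separately per omic–disease combination. The inflation factor λ is the
no-intercept least-squares slope of observed on expected 1-df chi-square
quantiles (expected = uniform order statistics i/(n+1)); fewer than 10 tests
flags the report low-confidence. Annotation enrichment is a two-sided Fisher
exact test on the 2×2 table (marker set vs background set) × (inside vs
outside half-open [start, end) intervals), reporting the sample odds ratio.

## 3. Synthetic-data generators

The generators emulate the statistical structure the analysis assumes; their
defaults are the package's standard study conditions.

**Genotypes.** Two latent Gaussian AR(1) haplotypes per locus, thresholded
at Φ⁻¹(1−MAF), summed to 0/1/2 dosages — Hardy–Weinberg at the target MAF
with tunable LD decay and no external reference panel. Thresholding
attenuates the latent correlation (latent ρ = 0.9 → adjacent dosage r ≈ 0.70
at MAF 0.3), so scenarios that need a specific dosage-scale r² select SNPs
by realized correlation, not by the latent parameter.

**QTL cohorts.** Molecule = causal-dosage burden + N(0, noise_sd²),
standardized to unit variance; per-SNP marginal OLS gives (β̂, SE, p); the
LD matrix is the cohort's empirical dosage correlation; positions sit on an
even grid inside the window. Default: one causal SNP, β_im = 0.5 raw
(≈ 0.48 per allele after standardization), MAF 0.3, noise SD 1.

**GWAS cohorts.** Always drawn independently of the QTL cohort (two-sample
design). Standardized liability = β_md·molecule (shared-causal), or a direct
effect of a non-causal SNP chosen by realized r² with the QTL top SNP
(colocalization, with β_md forced to 0), or pure noise; residual variance is
shrunk so liability variance ≈ 1. Cases are liability above the
(1 − prevalence) quantile; the requested numbers of cases and controls are
sampled from the strata. Marginal statistics are computed as the linear
regression of the 0/1 outcome on dosage and rescaled to the liability scale
by K(1−K)/(φ(Φ⁻¹(1−K))·P(1−P)) (K = prevalence, P = sample case fraction) —
this makes the Wald ratio recover β_md on the generator's own scale, which
is the recovery contract the tests assert. β_md is declared on the
standardized-liability scale; a logit-scale output (score-test approximation
β_lin/(p̄(1−p̄))) and an exact per-SNP logistic fit are available behind
flags. QTL cohorts are sampled from the general population (no
ascertainment), matching QTL studies of healthy donors.

**Case/control marker matrices.** Marker j ~ N(shift_j·label, σ²); zero
shifts are null markers. **Conversion cohorts.** Risk score ~ N(0,1) (or
user-supplied, e.g. binary); event times exponential with hazard
h₀·exp(effect·score), h₀ = 1/200 per day; random censoring exponential with
rate h₀·c/(1−c) (so a fraction ≈ c of null subjects censor first) plus
administrative censoring at the follow-up cap (default 1,000 days; the
prognosis stage summarizes survival at a 300-day horizon). The first
n_informative markers load on the score with a configurable loading.

Every generated dataset carries a truth record (planted effects, mediation
scenario, the colocalizing SNP and its realized r², marker shifts,
conversion log-HR) that estimation code never reads.

## 4. Power simulation

Effects are redrawn per replicate from N(β_md, SE_md) to propagate
estimation uncertainty. Expression columns are N(0,1) plus environmental
noise read as variance 0.01 (SD 0.1; a config switch allows SD 0.01, since
"N(0, 0.01)" is ambiguous between the two). The linear score E·B is the
log-odds of being a case with zero intercept — this is the resolution of the
printed probability form 1/(1+odd): the score can be negative, so it must be
the linear predictor, and the zero intercept makes cases and controls
balanced in expectation, which is the stated design. Logistic fits are
maximum likelihood (LBFGS; a mild L2 fallback, flagged, handles perfect
separation); AUC is the rank-based concordance; Nagelkerke R² rescales the
likelihood-ratio R²; AIC = −2ℓℓ + 2(k+1). Nested top-1…top-n panels are
evaluated inside a shared per-replicate dataset so AIC comparisons are
paired; ranking is |β| descending with ties broken by smaller p then id;
medians are taken per panel size across replicates and the optimal panel
minimizes the median AIC. HEIDI(+) and HEIDI(−) strata run separately.
Default 1,000 replicates of 10,000 samples; benchmarks run fewer (below).

## 5. Diagnostic and prognostic panels

The pipeline order is frozen: concordance filter → screen → LASSO → cut
point → frozen validation, mirroring a three-cohort design (feature
selection / training / validation) so no stage sees data from a later one.

The spike-and-slab Gibbs screen plays the Bayesian-lasso role on the 0/1
outcome with a Gaussian likelihood — screening, not calibrated
probabilities, is its job. Each coefficient has a point mass at zero and a
N(0, σ²τ²) slab (τ = 1); inclusion and σ² have conjugate updates and the
inclusion prior is Beta(1,1). A marker is retained when its posterior
inclusion exceeds ½ (equivalently, nonzero posterior median). A split-chain
ratio > 1.2 on σ² warns but still returns the screen. Default 2,000
post-burn-in sweeps after 500 burn-in.

The L1 logistic objective is mean log-loss + λ‖β‖₁ with unpenalized
intercept; the path is 40 log-spaced λ below the all-zero KKT bound
max|xᵀ(y−ȳ)|/n, and λ minimizes 10-fold cross-validated deviance (the
minimum, not the 1-SE rule, keeps the candidate-set reduction tunable). A λ
that zeroes every coefficient raises a distinct "empty panel" error. The
Youden cut point maximizes sensitivity + specificity − 1 over midpoints of
adjacent unique scores, taking the smallest threshold on ties. Validation
applies the frozen coefficients and cut point only; AUC confidence intervals
use DeLong's method; Spearman ties use average ranks. The matched
HEIDI(+)/(−) comparison truncates the HEIDI(−) set, ranked by ascending SMR
p, to the HEIDI(+) size and reports AUC and log-likelihood for both panels.

Prognosis reuses the same stages on converter status (subjects who recovered
from dementia status are excluded when labeling converters; missing
follow-up drops the subject with a warning). Risk groups use strict
inequality — a score exactly at the cut point is low risk. Cox fits are
univariate on the high/low indicator with Efron tie handling (day-resolution
times make ties likely); Kaplan–Meier medians are the earliest time with
S(t) ≤ 0.5 and are reported as "not reached" rather than imputed.

## 6. Pipeline orchestration

`demo_end_to_end` chains all stages on a three-omic synthetic disease
(30 RNA-like + 30 methylation-like + 10 protein-like molecules; 10 causal
with β_md = 0.3; 10,000-sample QTL and GWAS cohorts) and cross-references
planted vs recovered markers. The demo's headline "significant" count uses
the pooled 0.05/n_total Bonferroni threshold across all molecules of the
disease, alongside the per-omic thresholds and λ. `run(RunConfig)` drives
the stages from one YAML config; a single master seed fans out through a
counter-based SeedSequence scheme so inserting a stage does not shift other
stages' streams; outputs are TSV/JSON plus a manifest of content hashes, and
unchanged stages are skipped on rerun (a hash mismatch on an intermediate
raises a stage-level error naming the file).

## 7. Benchmark conditions and what they do (not) show

`bloodmark.benchmarks` freezes the standard evaluation scenarios; the
acceptance script and acceptance tests run them as-is:

- Null calibration: 2,000 all-null loci, 8 SNPs, 5,000 per cohort.
- Recovery: β_md ∈ {0.1, 0.3}, 12-SNP loci, 20,000 per cohort, 200 reps.
- HEIDI discrimination: 15-SNP loci with latent ρ = 0.95 (realized adjacent
  r² ≈ 0.6), direct effect 0.15 per dosage SD, 20,000 per cohort.
- Power grid: β ∈ {0, 0.25, 0.5, 1, 2}, 100 reps × 10,000 samples, against
  a numerical-integration oracle.
- AIC selection: 1 real (β = 1) + 5 exact-null markers, 100 reps × 2,000
  samples per master seed — medians over too few replicates are unstable,
  and 100 replicates is the smallest count at which the selector behaves as
  it does at the full 1,000.
- Cox recovery: binary score, true HR 2, n = 400, ≈ 55% events, 200 reps.
- End-to-end worlds: the demo conditions above, several master seeds each.

Monte-Carlo "fraction of seeds" properties are asserted as one-sided
binomial consistency at the run's seed count.

The generators emulate idealized structure: homogeneous LD blocks, Gaussian
molecule noise, logistic/liability links that match the estimators'
assumptions, no population stratification, no winner's curse from discovery
in the same sample, no batch effects or covariates in the panel matrices.
Passing these benchmarks shows the estimators are correct and calibrated
under their own model — not that real GWAS/QTL resources or clinical
cohorts, with their confounding and heterogeneity, would yield the same
power.

## 8. Known limitations

- The multi-SNP SMR combination is LD-aware IVW of Wald z-scores with exact
  single-SNP reduction; other published multi-SNP integration rules exist.
- HEIDI uses plug-in estimates in the covariance; at weak instruments it is
  mildly anticonservative (the benchmarks use strong instruments).
- Distance clumping (1 Mb) is a coarse stand-in for LD clumping when no
  genome-wide LD reference is given.
- Liability-to-observed scale conversion is first-order; very large per-SNP
  effects or extreme prevalence would bias it.
- No Bayesian colocalization posterior, trans-QTL analysis, covariate
  adjustment inside panels, competing risks, or time-dependent covariates.
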