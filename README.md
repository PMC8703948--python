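# bloodmark

Cross-omics blood-biomarker discovery for complex disease, driven entirely by
summary statistics. `bloodmark` is aimed at statistical geneticists and
biomarker researchers who want to (1) estimate which blood molecules (RNA,
methylation sites, proteins, cytokines, metabolites) are associated with a
disease using molecular-QTL and GWAS summary data, (2) quantify how well
panels of those markers would classify patients, and (3) build and validate
sparse diagnostic and prognostic marker panels — with every step exercisable
on bundled synthetic-data generators that carry known ground truth.

## The statistics at the core

**Summary-based Mendelian randomization (SMR).** For each QTL instrument *i*
of molecule *m* and disease *d*, the Wald ratio

&nbsp;&nbsp;&nbsp;&nbsp;β̂<sub>md</sub>(i) = β<sub>id</sub> / β<sub>im</sub>,&nbsp;&nbsp;
SE<sub>md</sub>(i) = SE<sub>id</sub> / |β<sub>im</sub>|

estimates the effect of one SD of the molecule on disease risk, immune to
environmental confounding. Multiple cis instruments (QTL p < 5×10⁻⁸ within
±1 Mb, pruned to pairwise r² ≤ 0.9) are combined by LD-aware inverse-variance
weighting of the Wald z-scores: with instrument correlation **R**,
z<sub>comb</sub> = (1ᵀ**R**⁻¹z)/√(1ᵀ**R**⁻¹1). For cytokines/metabolites
without a cis anchor, classic two-sample MR applies (genome-wide instruments
at p < 1×10⁻⁵, fixed-effect IVW, Cochran's Q, stepwise outlier removal,
MR-Egger).

**HEIDI.** The heterogeneity-in-dependent-instruments test asks whether the
per-instrument Wald ratios are homogeneous (one shared causal SNP → HEIDI(+),
p > 0.05) or heterogeneous (distinct causal SNPs in LD, i.e. colocalization →
HEIDI(−), p ≤ 0.05), using the delta-method covariance of the ratio
differences and a moment-matched scaled chi-square.

**Panel power simulation.** Given SMR estimates (β, SE) for a marker set,
each replicate redraws effects β̈ ~ N(β, SE), simulates a 10,000-sample
expression matrix with N(0, 0.01) noise, assigns cases by
P = 1/(1+e<sup>−Eβ̈</sup>), and fits a logistic panel; medians of AUC,
Nagelkerke R² and AIC across replicates summarize the panel, and the
cross-omics panel with the lowest median AIC over nested |β|-ranked subsets
is the optimal one.

**Panels.** Diagnostic: Spearman-concordance filter (sign agrees with SMR β
and |ρ| > 0.05) → Bayesian-lasso-style spike-and-slab screen (posterior
inclusion > ½) → cross-validated L1 logistic regression → Youden-index cut
point → frozen validation (DeLong 95% CI). Prognostic: the same machinery on
converter status, then univariate Cox regression (Efron ties) of the
high/low-risk grouping with Kaplan–Meier summaries.

## Worked example

```bash
python examples/01_smr_heidi.py
```

```
instruments used : 6
beta_md estimate : +0.276 (planted truth: +0.300)
p_SMR            : 5.63e-15
p_HEIDI          : 0.770  -> flag HEIDI(+)
```

A cis locus with one causal SNP drives a molecule, which in turn raises
disease liability by 0.3 per SD (the planted truth). From two independent
20,000-sample cohorts' summary statistics alone, multi-SNP SMR recovers the
effect (+0.276, within sampling error), the tiny p_SMR flags the molecule as
a candidate biomarker, and HEIDI(+) says the signal is consistent with a
single shared causal variant rather than colocalization.

The other examples walk the remaining capabilities: `02` two-sample MR with
sensitivity analyses, `03` panel power and AIC-optimal cross-omics selection,
`04` the frozen three-split diagnostic panel (prints validation AUC ≈ 0.74
with 6/11 planted markers recovered), `05` conversion-risk prognosis
(prints HR ≈ 2.2 on a planted HR-2.3 world), and `06` the full pipeline with
a truth-vs-recovered cross-reference.

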