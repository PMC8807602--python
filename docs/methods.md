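# Methods

## The mixture model underlying everything

A surrogate-tissue sample is treated as a two-cell-type mixture. For
sample *i* with immune-cell proportion ρ_i ∈ [0,1] and CpG *j*:

    β_ij = (1 − ρ_i) · e_ij + ρ_i · m_ij,
    e_ij ~ Beta(a0_j, b0_j),   m_ij ~ Beta(a1_j, b1_j).

ρ_i is estimated from the data by reference-based deconvolution (or
supplied precomputed in the sample sheet, which takes precedence). Two
distinct uses of this structure appear downstream and they are not the
same model:

1. The **generator** draws β as the convex combination above — the
   physically motivated picture of pooled DNA from two compartments.
2. The **per-CpG likelihood** used for variance attribution models the
   sample-level density as a ρ-weighted mixture of the two beta
   densities, f(β_i) = (1−ρ_i)·Beta(β_i|a0,b0) + ρ_i·Beta(β_i|a1,b1),
   and minimizes the negative mean log-likelihood. Parameter-recovery
   tests for the likelihood therefore simulate from the density model
   (a latent component per sample), not the convex combination.

## Synthetic cohorts

The generator's defaults are the study conditions used throughout the
tests and analysis scripts:

- cell-type means per CpG ~ U(0.05, 0.95); precision a+b log-uniform on
  [8, 120], giving array-like dispersion and CpGs whose variability is
  epithelial-dominated, immune-dominated, or shared;
- ρ ~ U(0, 1) (immune proportion in cervical cytology spans this range);
- ages ~ U(35, 70); the age effect on methylation defaults to 0 and the
  age coefficient enters only as a nuisance covariate downstream;
- case effects shift the targeted cell type's beta mean by δ at fixed
  precision (a+b held constant), so case draws remain valid beta
  variates; the main planted-effect cohort uses δ = 0.10 on 150
  epithelial and 50 immune CpGs out of 2,000, with 600 controls and
  300 cases. When shapes are default-sampled, affected CpGs' baseline
  means are drawn inside a range that keeps the shifted mean in (0,1);
  explicitly supplied shapes error instead.
- degradation noise is independent Gaussian on the beta scale with
  clipping to [0,1] (a logit-scale option avoids clipping). This
  emulates generic biobank signal loss; it is not a model of any
  specific storage chemistry, so degradation results support monotone
  "more noise, less signal" statements only.

What the generator deliberately omits: probe-type chemistry, batch and
chip effects, spatial artefacts, SNP-contaminated probes, age-related
drift, and more than two cell compartments. Passing tests therefore
demonstrate correctness of the estimators under the assumed mixture
model, not robustness to real-array artefacts.

## Deconvolution

Fractions are estimated per sample by non-negative least squares of the
sample's beta vector on the reference cell-type mean profiles, then
normalized to sum to one. This is an accepted, exactly testable
equivalent of the published robust-partial-correlation estimators for
the contract needed here (recovering ρ); it errors on collinear
references and on empty CpG overlap. `ic` is the sum of the
immune-type columns (not the epithelial complement), so a fibroblast
column, when present, is excluded from `ic`.

## Cell-type-specific delta-betas

Within cases and within controls separately, each CpG's betas are
regressed on ρ, with age centered at the pooled mean as an additional
covariate. The case-minus-control difference of fitted values at ρ=0
estimates the epithelial delta-beta; at ρ=1, the immune delta-beta.
Age centering makes the intercepts fitted values at the cohort mean age
— the evaluation point for the extrapolation was an open choice and is
fixed here as the pooled mean, which removes age confounding without
touching the ρ-extrapolation. Extrapolated values may leave [0,1]; they
are reported unclipped with a flag since only differences are consumed.
Constant-beta CpGs get delta 0 and a degenerate-fit flag. ρ must vary
within each group or the fit is refused naming the group.

The two rankings (by absolute delta, ties broken by CpG ID) are
interleaved epithelial-first; a CpG already emitted is skipped without
consuming the turn, which keeps the two lists in step. "Largest
delta-beta" is read as largest absolute value, since the index uses
both hyper- and hypomethylated CpGs.

## The index

The top-n ranked CpGs feed a penalized logistic regression (ridge = L2,
lasso = L1) with the regularization strength chosen by stratified,
seeded 10-fold cross-validation on the binomial deviance. The index is
(Σ w_iβ_i − μ)/σ with μ and σ the training mean and standard deviation
(ddof 1) of the weighted sum — standardization applies to the whole
sum, once. μ is computed as w·(training mean betas), identical by
linearity and exact enough in floating point that the class-wise
decomposition conserves below 1e-10. The logistic intercept is not part
of the index (absorbed by standardization). n is selected by AUC on a
held-out internal validation split, then the model is refit on the full
discovery set with the winning penalty and its cross-validated strength
frozen (recorded in provenance, so no re-selection leakage). An
all-zero lasso weight vector is refused (σ would be 0). At application
time, missing CpGs up to 1% of the model are mean-imputed from the
training means, otherwise scoring errors listing them; exclusion
experiments zero the excluded weights while keeping μ and σ.

## Beta-mixture fits and decomposition

The per-CpG objective is the negative mean log mixture likelihood,
minimized over (a0,b0,a1,b1) in log-shape space (unconstrained) by
L-BFGS from three starts: method-of-moments on the low-ρ (< 1/3) and
high-ρ (> 2/3) sample subsets, a perturbed pooled-moments start, and a
symmetric start. β is clipped to [1e-4, 1−1e-4] before evaluation (the
beta density is unbounded at the endpoints). When ρ ≡ 0 (or ≡ 1) the
mixture collapses; the identifiable component is fitted by the same
optimizer on the single-beta likelihood and the other component is
flagged unidentifiable. Fitted cell-type variances are
ab/((a+b)²(a+b+1)).

CpGs are classified epithelial if var_epi/var_imm exceeds a threshold,
immune if the inverse ratio does, else shared; thresholds default to 4,
must exceed 1 (which guarantees a partition), and are recorded with the
assignment. The defaults are a declared convention — the original
class boundaries for this kind of scatter are not uniquely determined —
so downstream guarantees rest on the partition and monotonicity
properties, not on particular class counts.

The decomposition centers each class partial sum by
μ_c = Σ_{i∈c} w_i·train_mean_i; the μ_c sum to μ, so the three
subcomponents sum to the full index exactly for every sample.

## Risk statistics

**Median-unbiased odds ratios.** Conditional on the margins of a 2×2
table the exposed-case count follows a Fisher noncentral hypergeometric
distribution with odds θ. The point estimate solves the mid-p median
equation P(X > x) + ½P(X = x) = ½ (root-found by Brent on log θ); the
95% limits invert the mid-p tails at 0.025/0.975. Zero cells need no
continuity correction; when the observed count sits at the support
boundary the estimate and the corresponding limit are 0 or ∞ by
convention and the other limit remains finite. This implementation
reproduces all twelve published non-reference quartile odds ratios to
the printed precision, which fixes the algorithmic reading of
"median-unbiased estimation".

**Quartile tables** use right-closed intervals (matching the printed
interval notation), the lowest interval closed on both sides; scores
outside the reference range fall into the outer quartiles with a
warning.

**Adjusted odds ratios** come from a multivariable logistic model with
the quartile coded as a factor (lowest = reference) plus covariates;
Wald 95% CIs; (quasi-)separation is flagged and the CI withheld.

**AUC** is the Mann–Whitney statistic with a DeLong (midrank structural
components) asymptotic CI clipped to [0,1]. **Recalibration** fits
outcome ~ α + β·index and returns the rescaled score α + β·index plus a
decile calibration curve. **PRS** is the weighted effect-allele dosage
sum over matched SNPs, with unmatched SNPs dropped and counted.

## Overlap and enrichment

Hypo/hyper calls use the prespecified ±0.02 delta-beta threshold; the
delta-betas here are plain group-mean differences, deliberately
unadjusted for cell composition. The concordance test builds the 2×2
(called in A) × (called in B) table and applies the chi-squared test
without continuity correction; the expectation is the product of the
marginal call proportions. The O/E confidence interval is an exact
binomial interval on the observed overlap count scaled by the expected
count. The hyper-methylation call is Δβ > +0.02 (the mirror of the
hypo call). Annotation enrichment generalizes the same O/E logic to
arbitrary CpG → category maps with exact binomial p-values; when the
categories partition the universe the expected counts sum to the
selection size. Binding-site or mQTL membership is consumed as a plain
CpG ID list; peak calling and list derivation are out of scope.

## Problem sizes and numerical choices

The test suite and acceptance script use: 2,000-CpG / 900-sample
cohorts for the pipeline checks; 100 null replicates at 150 CpGs / 120
samples; 200 mixture fits at N = 1,000; 500 overlap replicates at 5,000
CpGs; regularization grids of 5–7 log-spaced values with 5–10 CV folds.
These sizes make every property measurable with comfortable margins
while keeping a full run to a few minutes. Optimizer tolerances: ftol
1e-12 (single beta) and 1e-8 (mixture); OR root-finding xtol 1e-12 on
log θ over |log θ| ≤ 40.

## Known limitations

- The deconvolution is least-squares, not robust; gross outlier probes
  would propagate into ρ.
- The degradation model is generic noise; no claim is made about any
  specific biobank storage mechanism.
- The beta-mixture likelihood assumes ρ known; uncertainty in estimated
  ρ is not propagated into the variance attribution.
- Two mixture components only; fibroblast-specific attribution is not
  modelled.
- Published cohort-level AUCs cannot be reproduced here because the
  underlying cohorts are controlled-access; the pipeline is validated
  by recovery of planted effects and by the published contingency
  tables instead.
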