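# methrisk

A cell-composition-aware DNA-methylation risk index pipeline for
surrogate-tissue samples, built and validated end-to-end on synthetic
cohorts and on published contingency tables.

Cervical (or buccal) liquid-based cytology samples are mixtures of
epithelial and immune cells, so any epithelial-specific disease signal
in a methylation array is diluted in immune-rich samples. This package
implements the full analysis chain for building and interrogating a
risk index under that heterogeneity:

- **`synthetic`** — seeded cohorts with the assumed generative
  structure: β<sub>ij</sub> = (1−ρ<sub>i</sub>)·e<sub>ij</sub> +
  ρ<sub>i</sub>·m<sub>ij</sub> with e ~ Beta(a₀,b₀), m ~ Beta(a₁,b₁),
  planted cell-type-specific case effects, degradation noise, and
  Hardy–Weinberg genotypes. Ground truth is recorded for every CpG.
- **`composition`** — reference-based cell-fraction estimation per
  sample (non-negative least squares, normalized to the simplex) and
  rank-sum group comparison of fractions.
- **`dmp`** — cell-type-specific differential methylation: per CpG,
  β ~ ρ (+ age) fitted within cases and controls; fitted values at
  ρ=0 / ρ=1 give epithelial / immune delta-betas, which are interleaved
  into one ranked CpG list.
- **`index_model`** — the standardized penalized index
  (Σ w<sub>i</sub>β<sub>i</sub> − μ)/σ: ridge/lasso logistic training
  with cross-validated regularization, selection of the number of input
  CpGs on an internal validation split, scoring with CpG exclusion,
  sub-classifier experiments, and a generic two-class tissue index.
- **`decomposition`** — per-CpG two-component beta-mixture maximum
  likelihood with known mixing weights ρ<sub>i</sub>, variance
  attribution to cell types, epithelial/shared/immune CpG
  classification, and an exact split of the index into per-class
  subcomponents.
- **`risk`** — quartile tables, median-unbiased odds ratios (mid-p,
  conditional noncentral hypergeometric), covariate-adjusted logistic
  odds ratios, Mann–Whitney AUC with DeLong confidence intervals,
  logistic recalibration, and polygenic risk scores
  PRS<sub>j</sub> = Σ β̂<sub>i</sub> x<sub>ij</sub>.
- **`overlap`** — cross-tissue delta-beta concordance at annotated CpG
  sets at a fixed ±0.02 threshold, chi-squared test against the
  independence expectation, and observed/expected annotation enrichment.

## Worked example

The numbered scripts under `analysis/` run the pipeline on a seeded
synthetic discovery cohort (2,000 CpGs; 600 controls, 300 cases;
ρ ~ U(0,1); case effects of +0.10 on 150 epithelial-specific and 50
immune-specific CpGs) and write their tables under `results/`:

```sh
python analysis/01_simulate_cohort.py
python analysis/02_estimate_composition.py
python analysis/03_rank_differential_cpgs.py
```

prints, among other lines:

```
immune-fraction recovery MAE vs truth: 0.0037 (over 900 samples, 2000 CpGs)
mean estimated epithelial delta on the 150 planted epithelial CpGs: 0.1006 (true 0.10)
planted CpGs among the top 200 ranked: 151/200
```

i.e. deconvolution recovers the immune proportion to ~0.4%, the
regression extrapolation recovers the planted cell-type-specific effect
essentially unbiased, and the interleaved ranking concentrates the
planted CpGs at the top. `04_train_index.py` then trains the index
(held-out AUC 1.000 on this strongly separable cohort),
`05_decompose_index.py` fits the per-CpG beta mixtures and verifies
that the epithelial + shared + immune subcomponents reproduce the index
to ~1e-14, and `06_risk_statistics.py` recomputes the median-unbiased
odds ratios from the bundled published quartile counts:

```
         cohort  quartile    or  lower  upper
breast_internal         2  2.42   0.48  19.26
breast_internal         3  8.01   2.17  56.31
breast_internal         4 41.11  12.33 275.32
```

and builds a quartile table for the (noise-degraded) synthetic
validation scores. `07_binding_site_overlap.py` runs the fixed-threshold
cross-tissue concordance test on a planted shared-hypomethylation set
(O/E 1.40, chi-squared p ≈ 2e-42).

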