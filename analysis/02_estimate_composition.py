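#!/usr/bin/env python
"""Deconvolve cell-type fractions and compare them between groups.

Estimates per-sample epithelial and immune fractions by constrained
least squares on the reference profiles, scores the recovery against the
generator's true immune proportions, and runs the rank-sum group
comparison of fractions between cases and controls."""

import numpy as np

import common
from methrisk import composition


def main():
    ds, ref, fractions, _ = common.build_cohort()
    out = common.RESULTS
    out.mkdir(parents=True, exist_ok=True)
    fractions.to_csv(out / "cell_fractions.csv")

    mae = np.abs(fractions["ic"].to_numpy() - ds.meta["ic"].to_numpy()).mean()
    print(f"immune-fraction recovery MAE vs truth: {mae:.4f} "
          f"(over {len(fractions)} samples, {ds.betas.shape[0]} CpGs)")

    is_case = (ds.meta["type"] == "case").to_numpy()
    comp = composition.compare_fractions(
        fractions.loc[~is_case], fractions.loc[is_case])
    comp.to_csv(out / "fraction_comparison.csv")
    print("case-vs-control fraction comparison (rank-sum):")
    print(comp.round(4).to_string())
    print("(no group difference is planted, so p-values should be unremarkable)")


if __name__ == "__main__":
    main()
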