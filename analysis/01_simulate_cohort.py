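#!/usr/bin/env python
"""Generate the synthetic discovery cohort and write it to results/cohort/.

The cohort mirrors the assumed data-generating process of the index
pipeline: each sample's beta value is a rho-weighted combination of an
epithelial and an immune beta draw, with case effects planted as
cell-type-specific mean shifts."""

import common


def main():
    ds, ref, _, _ = common.build_cohort()
    out = common.RESULTS / "cohort"
    ds.write(out)
    ref.to_csv(out / "reference.csv")
    n_ctrl = (ds.meta["type"] == "control").sum()
    n_case = (ds.meta["type"] == "case").sum()
    planted = (ds.truth[["delta_epi", "delta_imm"]] != 0).any(axis=1).sum()
    print(f"cohort: {ds.betas.shape[0]} CpGs x {ds.betas.shape[1]} samples "
          f"({n_ctrl} controls, {n_case} cases)")
    print(f"planted effect CpGs: {planted} "
          f"({(ds.truth['delta_epi'] != 0).sum()} epithelial, "
          f"{(ds.truth['delta_imm'] != 0).sum()} immune)")
    print(f"beta range: [{ds.betas.to_numpy().min():.3f}, "
          f"{ds.betas.to_numpy().max():.3f}]")
    print(f"written to {out}")


if __name__ == "__main__":
    main()
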