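#!/usr/bin/env python
"""Train the standardized penalized index and probe its structure.

Selects the number of input CpGs on the internal validation split,
refits on the full discovery set with frozen hyperparameters, reports
the held-out AUC, retrains sub-classifiers on weight-ranked bins, and
re-scores the index after excluding a random CpG subset (the
annotation-exclusion experiment)."""

import numpy as np

import common
from methrisk import index_model, risk


def main():
    ds, _, _, meta = common.build_cohort()
    _, ranked = common.build_ranked(ds, meta)
    out = common.RESULTS
    out.mkdir(parents=True, exist_ok=True)

    split = index_model.split_discovery(meta, 2 / 3, seed=common.SEED)
    curve, final = index_model.select_n(
        ds.betas, meta, ranked, split, grid=[100, 200, 400, 800],
        penalties=("ridge",), seed=common.SEED, Cs=common.CS_GRID, cv=5)
    curve.to_csv(out / "selection_curve.csv", index=False)
    final.to_json(out / "index_model.json")
    print("validation AUC by number of input CpGs:")
    print(curve.round(3).to_string(index=False))
    print(f"selected n = {final.provenance['selected_n']} "
          f"({final.provenance['selected_penalty']}), refit on full discovery")

    val_ids = split[~split].index
    train_model = index_model.train_index(
        ds.betas[split[split].index], meta, ranked,
        final.provenance["selected_n"], penalty="ridge",
        seed=common.SEED, Cs=common.CS_GRID)
    scores = index_model.apply_index(train_model, ds.betas[val_ids])
    y = (meta.set_index("sample_id").loc[val_ids, "type"] == "case")
    auc, lo, hi = risk.auc_ci(scores.to_numpy(), y.to_numpy().astype(int))
    print(f"held-out validation AUC: {auc:.3f} (95% CI {lo:.3f}-{hi:.3f})")

    bins = index_model.subclassifier_experiment(
        ds.betas, meta, train_model, split, mode="bins", bin_size=100,
        cv=5, Cs=common.CS_GRID)
    bins.to_csv(out / "subclassifier_bins.csv", index=False)
    print("sub-classifier AUC by weight-ranked bin of 100 CpGs:")
    print(bins.round(3).to_string(index=False))

    rng = np.random.default_rng(common.SEED)
    drop = set(rng.choice(train_model.cpgs, size=len(train_model.cpgs) // 10,
                          replace=False))
    scores_ex = index_model.apply_index(train_model, ds.betas[val_ids],
                                        exclude=drop)
    auc_ex, *_ = risk.auc_ci(scores_ex.to_numpy(), y.to_numpy().astype(int))
    print(f"AUC after excluding a random 10% of index CpGs: {auc_ex:.3f} "
          f"(delta {auc_ex - auc:+.3f})")


if __name__ == "__main__":
    main()
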