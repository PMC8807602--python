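"""Shared cohort definition for the analysis scripts.

One seeded synthetic discovery cohort is used throughout: 2,000 CpGs,
600 controls / 300 cases, immune proportion ~ U(0, 1), case effects of
+0.10 on the mean of 150 epithelial-specific and 50 immune-specific
CpGs.  Each script rebuilds what it needs from this definition, so the
scripts can be run independently and in any order.
"""

import pathlib

import numpy as np

from methrisk import composition, dmp, index_model, synthetic

SEED = 20260919
RESULTS = pathlib.Path(__file__).resolve().parent.parent / "results"

COHORT = synthetic.SimulationConfig(
    n_controls=600,
    n_cases=300,
    n_cpgs=2000,
    effects=[
        synthetic.Effect(range(0, 150), "epithelial", 0.10),
        synthetic.Effect(range(150, 200), "immune", 0.10),
    ],
    seed=SEED,
)

CS_GRID = np.logspace(-3, 3, 7)


def build_cohort():
    """Cohort + reference + sample sheet with estimated immune fraction."""
    ds = synthetic.generate_dataset(COHORT)
    ref = synthetic.generate_reference(COHORT)
    fractions = composition.estimate_fractions(ds.betas, ref)
    meta = ds.meta.copy()
    meta["ic"] = fractions["ic"].to_numpy()
    return ds, ref, fractions, meta


def build_ranked(ds, meta):
    deltas = dmp.estimate_celltype_deltabeta(ds.betas, meta)
    return deltas, dmp.rank_interleave(deltas)


def build_model(ds, meta, ranked, n=400):
    split = index_model.split_discovery(meta, 2 / 3, seed=SEED)
    train_ids = split[split].index
    model = index_model.train_index(
        ds.betas[train_ids], meta, ranked, n=n, penalty="ridge",
        seed=SEED, Cs=CS_GRID)
    return split, model
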