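"""Shared fixtures: one mid-sized planted-effect cohort reused across the
suite, plus the deconvolution -> ranking -> training products derived
from it.  Everything is generated programmatically and seeded."""

import numpy as np
import pytest

from methrisk import composition, dmp, index_model, synthetic

PIPELINE_SEED = 20260919

# Study conditions for the planted-effect cohort: 2,000 CpGs, 900 samples
# (600 controls / 300 cases), immune proportion ~ U(0,1), case shifts of
# 0.10 on 150 epithelial-specific and 50 immune-specific CpGs.
PIPELINE_CONFIG = synthetic.SimulationConfig(
    n_controls=600,
    n_cases=300,
    n_cpgs=2000,
    effects=[
        synthetic.Effect(range(0, 150), "epithelial", 0.10),
        synthetic.Effect(range(150, 200), "immune", 0.10),
    ],
    seed=PIPELINE_SEED,
)

SMALL_CS = np.logspace(-3, 3, 7)


@pytest.fixture(scope="session")
def pipeline_cohort():
    return synthetic.generate_dataset(PIPELINE_CONFIG)


@pytest.fixture(scope="session")
def pipeline_reference():
    return synthetic.generate_reference(PIPELINE_CONFIG)


@pytest.fixture(scope="session")
def pipeline_meta_estimated(pipeline_cohort, pipeline_reference):
    """Sample sheet with the deconvolution-estimated immune fraction."""
    fractions = composition.estimate_fractions(
        pipeline_cohort.betas, pipeline_reference
    )
    meta = pipeline_cohort.meta.copy()
    meta["ic"] = fractions["ic"].to_numpy()
    return meta


@pytest.fixture(scope="session")
def pipeline_ranked(pipeline_cohort, pipeline_meta_estimated):
    deltas = dmp.estimate_celltype_deltabeta(
        pipeline_cohort.betas, pipeline_meta_estimated
    )
    return dmp.rank_interleave(deltas)


@pytest.fixture(scope="session")
def pipeline_split(pipeline_meta_estimated):
    return index_model.split_discovery(
        pipeline_meta_estimated, fraction=2 / 3, seed=PIPELINE_SEED
    )


@pytest.fixture(scope="session")
def pipeline_model(pipeline_cohort, pipeline_meta_estimated, pipeline_ranked,
                   pipeline_split):
    train_ids = pipeline_split[pipeline_split].index
    return index_model.train_index(
        pipeline_cohort.betas[train_ids],
        pipeline_meta_estimated,
        pipeline_ranked,
        n=400,
        penalty="ridge",
        seed=PIPELINE_SEED,
        Cs=SMALL_CS,
    )
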