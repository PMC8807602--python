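"""Bundled reference tables.

``validation_quartile_tables`` returns the printed case/control counts
per risk-index quartile from a published cervical-sample methylation
index validation study (breast cancer internal and external validation
cohorts, plus ovarian and endometrial cancer cohorts scored against the
same index).  Quartile boundaries were defined on the internal
validation scores.  These counts exercise the odds-ratio machinery on
real published contingency tables without any controlled-access data.
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

__all__ = ["validation_quartile_tables"]


def validation_quartile_tables() -> dict[str, pd.DataFrame]:
    """Published quartile counts, one DataFrame per cohort.

    Each DataFrame has columns ``quartile, lower, upper, controls, cases``
    (quartile 1 is the reference / lowest-score interval).
    """
    ref = importlib.resources.files("methrisk") / "data" / "validation_quartiles.csv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path)
    return {name: g.drop(columns="cohort").reset_index(drop=True)
            for name, g in df.groupby("cohort", sort=False)}
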