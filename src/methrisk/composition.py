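"""Reference-based cell-type deconvolution of methylation profiles.

Estimates per-sample cell-type fractions by constrained least squares:
each sample's beta vector is regressed on the reference cell-type mean
profiles under non-negativity, then normalized to the unit simplex.
The total immune fraction ``ic`` is the mixing weight used throughout the
cell-type-specific differential-methylation and mixture models.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import mannwhitneyu

__all__ = ["estimate_fractions", "compare_fractions"]

_EPITHELIAL_LIKE = ("epithelial", "epi", "fibroblast", "fib")


def estimate_fractions(
    betas: pd.DataFrame,
    reference: pd.DataFrame,
    immune_types: list[str] | None = None,
) -> pd.DataFrame:
    """Estimate cell-type fractions for every sample.

    Parameters
    ----------
    betas : CpG x sample beta matrix.
    reference : CpG x cell-type matrix of reference mean methylation;
        its CpGs must be a subset of ``betas``' CpGs.
    immune_types : reference columns counted into the total immune
        fraction ``ic``; defaults to every column whose name is not
        epithelial- or fibroblast-like.

    Returns
    -------
    DataFrame indexed by sample with one column per cell type plus ``ic``.
    Fractions are non-negative and sum to 1 per sample.
    """
    common = reference.index.intersection(betas.index)
    if len(common) == 0:
        raise ValueError("no CpGs shared between beta matrix and reference")
    if reference.shape[1] < 2:
        raise ValueError("reference must contain at least 2 cell types")
    R = reference.loc[common].to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(R)
    if rank < R.shape[1]:
        raise ValueError(
            f"reference columns are collinear (rank {rank} < "
            f"{R.shape[1]} cell types); fractions are not identifiable"
        )
    Y = betas.loc[common].to_numpy(dtype=float)

    frac = np.empty((betas.shape[1], reference.shape[1]))
    for i in range(Y.shape[1]):
        coef, _ = nnls(R, Y[:, i])
        total = coef.sum()
        frac[i] = coef / total if total > 0 else 1.0 / len(coef)

    out = pd.DataFrame(frac, index=betas.columns, columns=reference.columns)
    if immune_types is None:
        immune_types = [
            c for c in reference.columns
            if not str(c).lower().startswith(_EPITHELIAL_LIKE)
        ]
    out["ic"] = out[immune_types].sum(axis=1) if immune_types else 0.0
    return out


def compare_fractions(frac_a: pd.DataFrame, frac_b: pd.DataFrame) -> pd.DataFrame:
    """Two-sided rank-sum comparison of cell-type fractions between groups.

    Returns per cell type the group medians and the Mann-Whitney p-value.
    No multiplicity adjustment is applied.
    """
    if len(frac_a) < 2 or len(frac_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    cols = [c for c in frac_a.columns if c in frac_b.columns]
    rows = []
    for c in cols:
        a = frac_a[c].to_numpy(dtype=float)
        b = frac_b[c].to_numpy(dtype=float)
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            p = 1.0
        else:
            p = mannwhitneyu(a, b, alternative="two-sided").pvalue
        rows.append(
            {"cell_type": c, "median_a": np.median(a), "median_b": np.median(b),
             "p_value": min(float(p), 1.0)}
        )
    return pd.DataFrame(rows).set_index("cell_type")
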