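"""Cell-type-specific differential methylation by regression extrapolation.

Direct case-vs-control comparisons are confounded by cell composition: an
epithelial-specific effect is diluted in immune-rich samples.  Fitting
``beta ~ rho (+ age)`` separately within cases and controls and comparing
the fitted values at rho = 0 gives the epithelial delta-beta; at rho = 1,
the immune delta-beta.  The two rankings are interleaved into a single
CpG list that feeds the penalized classifier.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["estimate_celltype_deltabeta", "rank_interleave"]


def _group_fit(Y: np.ndarray, rho: np.ndarray, age: np.ndarray | None):
    """Least-squares fit of each CpG's betas on rho (+ centered age).

    Returns (intercepts, slopes): fitted values at rho=0 and the rho
    coefficients, with age (if given) held at the centering point.
    """
    cols = [np.ones_like(rho), rho]
    if age is not None:
        cols.append(age)
    X = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    return coef[0], coef[1]


def estimate_celltype_deltabeta(
    betas: pd.DataFrame,
    meta: pd.DataFrame,
    use_age: bool = True,
) -> pd.DataFrame:
    """Per-CpG epithelial and immune case-control delta-betas.

    ``meta`` needs columns ``sample_id``, ``type`` ('case'/'control'),
    ``ic`` and, when ``use_age``, ``age``.  Age is centered at the pooled
    mean so intercepts are fitted values at the cohort's mean age.
    Extrapolated values may leave [0, 1]; they are reported unclipped
    (only differences are consumed) with an ``extrapolated_outside``
    flag.

    Returns a DataFrame indexed by CpG with ``epi_delta``, ``imm_delta``,
    per-group intercepts/slopes, and a ``degenerate`` flag for
    constant-beta CpGs (whose deltas are exactly 0).
    """
    meta = meta.set_index("sample_id").loc[betas.columns]
    groups = set(meta["type"])
    if not {"case", "control"} <= groups:
        raise ValueError("both case and control samples are required")
    rho = meta["ic"].to_numpy(dtype=float)
    age_all = meta["age"].to_numpy(dtype=float) if use_age else None
    age_center = age_all.mean() if use_age else None

    Y = betas.to_numpy(dtype=float)
    out = {}
    for g in ("case", "control"):
        mask = (meta["type"] == g).to_numpy()
        r = rho[mask]
        if np.ptp(r) == 0:
            raise ValueError(
                f"immune proportion is constant within the {g} group; "
                "cell-type extrapolation is not identifiable"
            )
        a = age_all[mask] - age_center if use_age else None
        intercept, slope = _group_fit(Y[:, mask], r, a)
        out[g] = (intercept, slope)

    int_case, slope_case = out["case"]
    int_ctrl, slope_ctrl = out["control"]
    epi_delta = int_case - int_ctrl
    imm_delta = (int_case + slope_case) - (int_ctrl + slope_ctrl)

    degenerate = Y.std(axis=1) == 0
    epi_delta[degenerate] = 0.0
    imm_delta[degenerate] = 0.0

    fitted = np.stack([int_case, int_ctrl, int_case + slope_case,
                       int_ctrl + slope_ctrl])
    return pd.DataFrame(
        {
            "epi_delta": epi_delta,
            "imm_delta": imm_delta,
            "intercept_case": int_case,
            "intercept_control": int_ctrl,
            "slope_case": slope_case,
            "slope_control": slope_ctrl,
            "degenerate": degenerate,
            "extrapolated_outside": ((fitted < 0) | (fitted > 1)).any(axis=0),
        },
        index=betas.index,
    )


def rank_interleave(deltas: pd.DataFrame) -> pd.DataFrame:
    """Interleave the epithelial and immune delta-beta rankings.

    Both lists are sorted by absolute delta-beta, descending, ties broken
    by CpG ID.  The output alternates epithelial, immune, epithelial, ...
    taking the next CpG not already emitted from each list; a skipped
    duplicate does not consume the turn, so the lists stay in step.

    Returns a DataFrame ordered by rank with columns ``cpg_id``,
    ``source`` ('epithelial'/'immune'), ``rank`` and ``magnitude``.
    """
    if len(deltas) == 0:
        return pd.DataFrame(columns=["cpg_id", "source", "rank", "magnitude"])
    epi = deltas["epi_delta"].abs()
    imm = deltas["imm_delta"].abs()
    order = {
        "epithelial": sorted(epi.index, key=lambda c: (-epi[c], str(c))),
        "immune": sorted(imm.index, key=lambda c: (-imm[c], str(c))),
    }
    mags = {"epithelial": epi, "immune": imm}
    pos = {"epithelial": 0, "immune": 0}
    seen: set = set()
    rows = []
    turn = "epithelial"
    while len(seen) < len(deltas):
        ids = order[turn]
        i = pos[turn]
        while i < len(ids) and ids[i] in seen:
            i += 1
        if i < len(ids):
            cpg = ids[i]
            seen.add(cpg)
            rows.append(
                {"cpg_id": cpg, "source": turn, "rank": len(rows) + 1,
                 "magnitude": float(mags[turn][cpg])}
            )
            i += 1
        pos[turn] = i
        turn = "immune" if turn == "epithelial" else "epithelial"
    return pd.DataFrame(rows)
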