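"""Cross-tissue delta-beta concordance and annotation enrichment.

Given raw case-vs-control mean methylation differences computed in two
tissues over an annotated CpG set (e.g. CpGs inside progesterone-receptor
binding sites), counts CpGs called hypo-/hypermethylated in both tissues
at a fixed prespecified threshold, compares the observed overlap with the
independence expectation (product of the marginal call proportions) by a
chi-squared test, and reports observed/expected ratios with exact
binomial confidence intervals.  A generic category-enrichment routine
covers island/shore/open-sea and mQTL-style annotations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest, chi2_contingency, mannwhitneyu, wilcoxon

__all__ = [
    "compute_group_deltabeta",
    "overlap_test",
    "annotation_enrichment",
    "paired_meanset_test",
    "OverlapResult",
]


def compute_group_deltabeta(
    betas: pd.DataFrame, labels: pd.Series, case_label="case"
) -> pd.Series:
    """Plain per-CpG group-mean difference, case minus control.

    Deliberately unadjusted for cell composition: the binding-site
    concordance analysis compares raw tissue-level means.
    """
    labels = labels.loc[betas.columns]
    is_case = (labels == case_label).to_numpy()
    if is_case.sum() == 0 or (~is_case).sum() == 0:
        raise ValueError("both groups must be non-empty")
    B = betas.to_numpy(dtype=float)
    delta = B[:, is_case].mean(axis=1) - B[:, ~is_case].mean(axis=1)
    return pd.Series(delta, index=betas.index, name="delta_beta")


@dataclass
class DirectionResult:
    observed: int
    marginal_a: int
    marginal_b: int
    expected: float
    oe_ratio: float
    oe_lower: float
    oe_upper: float
    chi2: float
    p_value: float
    degenerate: bool = False


@dataclass
class OverlapResult:
    n_cpgs: int
    threshold: float
    hypo: DirectionResult = None
    hyper: DirectionResult = None


def _direction_result(call_a: np.ndarray, call_b: np.ndarray) -> DirectionResult:
    n = len(call_a)
    obs = int(np.sum(call_a & call_b))
    ma, mb = int(call_a.sum()), int(call_b.sum())
    pa, pb = ma / n, mb / n
    expected = pa * pb * n
    if ma == 0 or mb == 0:
        return DirectionResult(
            observed=obs, marginal_a=ma, marginal_b=mb, expected=expected,
            oe_ratio=np.nan, oe_lower=np.nan, oe_upper=np.nan,
            chi2=np.nan, p_value=np.nan, degenerate=True,
        )
    table = np.array(
        [
            [obs, ma - obs],
            [mb - obs, n - ma - mb + obs],
        ]
    )
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        chi2, p = np.nan, np.nan
    else:
        chi2, p, *_ = chi2_contingency(table, correction=False)
    bt = binomtest(obs, n, pa * pb)
    ci = bt.proportion_ci(confidence_level=0.95)
    return DirectionResult(
        observed=obs, marginal_a=ma, marginal_b=mb, expected=expected,
        oe_ratio=obs / expected,
        oe_lower=ci.low * n / expected,
        oe_upper=ci.high * n / expected,
        chi2=float(chi2), p_value=float(bt.pvalue) if np.isnan(chi2) else float(p),
    )


def overlap_test(
    delta_a: pd.Series, delta_b: pd.Series, threshold: float = 0.02
) -> OverlapResult:
    """Two-tissue concordance of hypo-/hypermethylation calls.

    Hypomethylated: delta < -threshold; hypermethylated: delta > +threshold
    (the threshold is prespecified, not tuned).  The chi-squared test is
    computed without continuity correction on the 2x2 concordance table;
    the O/E confidence interval is an exact binomial interval on the
    observed overlap count divided by the expected count.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    common = delta_a.index.intersection(delta_b.index)
    if len(common) == 0:
        raise ValueError("the annotated CpG set is empty")
    da = delta_a.loc[common].to_numpy(dtype=float)
    db = delta_b.loc[common].to_numpy(dtype=float)
    return OverlapResult(
        n_cpgs=len(common),
        threshold=threshold,
        hypo=_direction_result(da < -threshold, db < -threshold),
        hyper=_direction_result(da > threshold, db > threshold),
    )


def annotation_enrichment(
    selected: set, annotation: pd.Series, universe: set
) -> pd.DataFrame:
    """Observed/expected category enrichment of a CpG selection.

    ``annotation`` maps CpG -> category over (at least) the universe.
    Expected count per category is |selected| * |cat in universe| /
    |universe|; the p-value and CI are exact binomial on the observed
    count.  Categories absent from the universe are skipped.
    """
    selected = set(selected)
    universe = set(universe)
    if not selected <= universe:
        raise ValueError("selected CpGs must be a subset of the universe")
    ann = annotation[annotation.index.isin(universe)]
    if len(ann) < len(universe):
        raise ValueError("annotation must cover the universe")
    n_sel = len(selected)
    rows = []
    for cat, cpgs in ann.groupby(ann).groups.items():
        n_cat = len(cpgs)
        if n_cat == 0:
            continue
        p_cat = n_cat / len(universe)
        obs = len(selected.intersection(cpgs))
        expected = n_sel * p_cat
        bt = binomtest(obs, n_sel, p_cat)
        ci = bt.proportion_ci(confidence_level=0.95)
        rows.append(
            {
                "category": cat, "observed": obs, "expected": expected,
                "oe_ratio": obs / expected if expected > 0 else np.nan,
                "oe_lower": ci.low * n_sel / expected if expected > 0 else np.nan,
                "oe_upper": ci.high * n_sel / expected if expected > 0 else np.nan,
                "p_value": float(bt.pvalue),
            }
        )
    return pd.DataFrame(rows).set_index("category")


def paired_meanset_test(
    betas: pd.DataFrame,
    cpg_set,
    labels: pd.Series,
    group_a,
    group_b,
    paired: bool = False,
):
    """Rank test on per-sample mean methylation over a CpG set.

    Returns (mean_a, mean_b, p_value).  ``paired`` requires equal group
    sizes and uses the signed-rank test; otherwise the rank-sum test.
    """
    cpgs = [c for c in cpg_set if c in betas.index]
    if not cpgs:
        raise ValueError("none of the CpG set is present in the beta matrix")
    means = betas.loc[cpgs].mean(axis=0)
    labels = labels.loc[means.index]
    a = means[labels == group_a].to_numpy(dtype=float)
    b = means[labels == group_b].to_numpy(dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired test requires equal group sizes")
        if np.all(a == b):
            p = 1.0
        else:
            p = float(wilcoxon(a, b, alternative="two-sided").pvalue)
    else:
        p = float(mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return float(a.mean()), float(b.mean()), min(p, 1.0)
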