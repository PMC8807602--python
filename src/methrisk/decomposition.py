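"""Per-CpG beta-mixture fits and index decomposition.

For one CpG with beta values beta_i and known immune proportions rho_i,
the sample-level density is modelled as a rho-weighted mixture of an
epithelial and an immune beta distribution:

    f(beta_i) = (1 - rho_i) Beta(beta_i | a0, b0) + rho_i Beta(beta_i | a1, b1)

The objective minimized is the negative mean log-likelihood

    L(a0, b0, a1, b1) = -(1/N) sum_i log f(beta_i).

The fitted cell-type variances ab/((a+b)^2 (a+b+1)) attribute each CpG's
variability to epithelial or immune cells; CpGs are classified
epithelial / shared / immune by variance ratio, and the index splits by
class into subcomponents that sum exactly to the full score.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import betaln

__all__ = [
    "mixture_objective",
    "fit_beta_mixture",
    "fit_beta_mixtures",
    "classify_cpgs",
    "decompose_index",
]

_CLIP = 1e-4


def _beta_logpdf(x, a, b):
    return (a - 1) * np.log(x) + (b - 1) * np.log1p(-x) - betaln(a, b)


def mixture_objective(log_shapes, beta_vals, rho):
    """Negative mean log-likelihood at log-shape parameters.

    Evaluated stably via logaddexp of the two weighted component
    log-densities; samples with rho exactly 0 or 1 contribute only their
    single component.
    """
    a0, b0, a1, b1 = np.exp(log_shapes)
    lp0 = _beta_logpdf(beta_vals, a0, b0)
    lp1 = _beta_logpdf(beta_vals, a1, b1)
    with np.errstate(divide="ignore"):
        t0 = np.where(rho < 1, np.log1p(-np.clip(rho, 0, 1 - 1e-300)) + lp0, -np.inf)
        t1 = np.where(rho > 0, np.log(np.clip(rho, 1e-300, 1)) + lp1, -np.inf)
    ll = np.logaddexp(t0, t1)
    return -np.mean(ll)


def _moment_shapes(x):
    """Method-of-moments beta shapes, floored away from 0."""
    m = np.mean(x)
    v = np.var(x)
    v = min(v, m * (1 - m) * 0.99) if m * (1 - m) > 0 else v
    if v <= 0:
        return 1.0, 1.0
    common = m * (1 - m) / v - 1
    return max(m * common, 1e-2), max((1 - m) * common, 1e-2)


def _fit_single_beta(x):
    """ML fit of one beta distribution by the package's own optimizer."""
    a_mm, b_mm = _moment_shapes(x)

    def nll(log_ab):
        a, b = np.exp(log_ab)
        return -np.mean(_beta_logpdf(x, a, b))

    res = minimize(
        nll, np.log([a_mm, b_mm]), method="L-BFGS-B",
        options={"ftol": 1e-12, "gtol": 1e-10},
    )
    return np.exp(res.x), res.fun, res.success


def _beta_var(a, b):
    return a * b / ((a + b) ** 2 * (a + b + 1))


def fit_beta_mixture(
    beta_vals,
    rho,
    n_starts: int = 3,
    tol: float = 1e-8,
) -> dict:
    """Fit the two-component beta mixture for one CpG.

    Optimization runs in log-shape space (unconstrained) from multiple
    starts: method-of-moments on the low-rho and high-rho sample subsets,
    and a symmetric pooled-moments start.  When every sample has rho = 0
    (or every sample rho = 1) the mixture collapses and the identifiable
    component is fitted by single-beta maximum likelihood, with the other
    flagged unidentifiable.

    Returns a dict with ``a0 b0 a1 b1 var_epi var_imm objective converged``
    and an ``identifiable`` tag.
    """
    beta_vals = np.clip(np.asarray(beta_vals, dtype=float), _CLIP, 1 - _CLIP)
    rho = np.asarray(rho, dtype=float)
    if len(beta_vals) < 20:
        raise ValueError("at least 20 samples are required per CpG")
    if np.any((rho < 0) | (rho > 1)):
        raise ValueError("rho must lie in [0, 1]")
    if np.ptp(beta_vals) == 0:
        raise ValueError("constant beta vector has no ML solution")

    if np.all(rho == 0) or np.all(rho == 1):
        (a, b), obj, ok = _fit_single_beta(beta_vals)
        if np.all(rho == 0):
            return {
                "a0": a, "b0": b, "a1": np.nan, "b1": np.nan,
                "var_epi": _beta_var(a, b), "var_imm": np.nan,
                "objective": obj, "converged": bool(ok),
                "identifiable": "epithelial_only",
            }
        return {
            "a0": np.nan, "b0": np.nan, "a1": a, "b1": b,
            "var_epi": np.nan, "var_imm": _beta_var(a, b),
            "objective": obj, "converged": bool(ok),
            "identifiable": "immune_only",
        }

    # Multi-start: component moments from rho-extreme subsets where
    # available, else pooled; plus a symmetric pooled start.
    lo = beta_vals[rho < 1 / 3]
    hi = beta_vals[rho > 2 / 3]
    pooled = _moment_shapes(beta_vals)
    start_epi = _moment_shapes(lo) if len(lo) >= 5 else pooled
    start_imm = _moment_shapes(hi) if len(hi) >= 5 else pooled
    starts = [
        np.log([*start_epi, *start_imm]),
        np.log([*pooled, *pooled]) + np.array([0.1, -0.1, -0.1, 0.1]),
        np.log([2.0, 2.0, 2.0, 2.0]),
    ][:max(1, n_starts)]

    best = None
    for x0 in starts:
        res = minimize(
            mixture_objective, x0, args=(beta_vals, rho),
            method="L-BFGS-B", options={"ftol": tol, "gtol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    a0, b0, a1, b1 = np.exp(best.x)
    return {
        "a0": a0, "b0": b0, "a1": a1, "b1": b1,
        "var_epi": _beta_var(a0, b0), "var_imm": _beta_var(a1, b1),
        "objective": float(best.fun), "converged": bool(best.success),
        "identifiable": "both",
    }


def fit_beta_mixtures(betas: pd.DataFrame, rho, **kwargs) -> pd.DataFrame:
    """Fit the mixture for every CpG row of ``betas``; returns a DataFrame."""
    rho = np.asarray(rho, dtype=float)
    rows = {}
    for cpg, vals in betas.iterrows():
        rows[cpg] = fit_beta_mixture(vals.to_numpy(dtype=float), rho, **kwargs)
    return pd.DataFrame.from_dict(rows, orient="index")


def classify_cpgs(
    fits: pd.DataFrame,
    epi_ratio_threshold: float = 4.0,
    imm_ratio_threshold: float = 4.0,
) -> pd.DataFrame:
    """Assign each converged CpG to epithelial / shared / immune.

    epithelial if var_epi/var_imm > ``epi_ratio_threshold``; immune if
    var_imm/var_epi > ``imm_ratio_threshold``; else shared.  The
    thresholds (recorded in ``DataFrame.attrs``) must exceed 1 so the
    three classes partition the CpG set.
    """
    if epi_ratio_threshold <= 1 or imm_ratio_threshold <= 1:
        raise ValueError("variance-ratio thresholds must be > 1")
    ve = fits["var_epi"].to_numpy(dtype=float)
    vi = fits["var_imm"].to_numpy(dtype=float)
    cls = np.where(
        ve / vi > epi_ratio_threshold,
        "epithelial",
        np.where(vi / ve > imm_ratio_threshold, "immune", "shared"),
    )
    out = pd.DataFrame({"class": cls}, index=fits.index)
    out.attrs["epi_ratio_threshold"] = epi_ratio_threshold
    out.attrs["imm_ratio_threshold"] = imm_ratio_threshold
    return out


def decompose_index(model, classes: pd.DataFrame, betas: pd.DataFrame) -> pd.DataFrame:
    """Split index scores into epithelial / shared / immune subcomponents.

    For class c the subcomponent is (sum_{j in c} w_j beta_j - mu_c)/sigma
    with mu_c = sum_{j in c} w_j * train_mean_j, the training mean of the
    class partial sum.  The class centering constants sum to mu, so the
    three subcomponents sum exactly to the full index for every sample.
    """
    missing = [c for c in model.cpgs if c not in classes.index]
    if missing:
        raise ValueError(
            f"{len(missing)} model CpGs lack a class assignment: {missing[:5]}..."
        )
    labels = classes.loc[model.cpgs, "class"].to_numpy()
    X = betas.loc[model.cpgs].to_numpy(dtype=float).T
    out = {}
    for cl in ("epithelial", "shared", "immune"):
        mask = labels == cl
        w_c = np.where(mask, model.weights, 0.0)
        mu_c = float(w_c @ model.train_means)
        out[cl] = (X @ w_c - mu_c) / model.sigma
    df = pd.DataFrame(out, index=betas.columns)
    df["total"] = df["epithelial"] + df["shared"] + df["immune"]
    return df
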