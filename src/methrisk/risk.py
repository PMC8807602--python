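"""Risk statistics for a standardized index: quartile odds ratios,
adjusted logistic models, AUC with DeLong confidence intervals,
calibration, and polygenic risk scores.

The quartile odds ratios use median-unbiased estimation: conditional on
the margins of the 2x2 table, the exposed-case count follows a Fisher
noncentral hypergeometric distribution with odds parameter theta; the
point estimate is the theta at which the observed count sits at the
mid-p median of that distribution, and the 95% interval inverts the
mid-p tail probabilities.  This handles zero cells without continuity
corrections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import brentq
from scipy.stats import nchypergeom_fisher, norm

__all__ = [
    "QuartileTable",
    "ORResult",
    "quartile_table",
    "median_unbiased_or",
    "quartile_or_table",
    "adjusted_or",
    "auc_ci",
    "recalibrate",
    "compute_prs",
]


@dataclass
class ORResult:
    estimate: float
    lower: float
    upper: float
    method: str

    def __post_init__(self):
        if np.isfinite(self.lower) and np.isfinite(self.upper):
            if not (self.lower <= self.estimate <= self.upper):
                raise ValueError("CI must bracket the estimate")


@dataclass
class QuartileTable:
    """Quartile boundaries (from a reference score set) and group counts."""

    boundaries: np.ndarray          # length 5: min, q1, q2, q3, max
    controls: np.ndarray            # length 4
    cases: np.ndarray               # length 4

    def intervals(self):
        b = self.boundaries
        return [(b[k], b[k + 1]) for k in range(4)]


def _assign_quartile(scores, boundaries):
    """Right-closed intervals; the lowest closed on both sides; values
    outside the reference range fall into the outer quartiles."""
    inner = boundaries[1:4]
    return np.searchsorted(inner, scores, side="left")


def quartile_table(reference_scores, control_scores, case_scores) -> QuartileTable:
    """Count controls and cases per quartile of the reference scores."""
    ref = np.asarray(reference_scores, dtype=float)
    if len(ref) == 0:
        raise ValueError("reference score set is empty")
    boundaries = np.quantile(ref, [0, 0.25, 0.5, 0.75, 1.0])
    ctrl = np.asarray(control_scores, dtype=float)
    case = np.asarray(case_scores, dtype=float)
    for name, s in (("control", ctrl), ("case", case)):
        if len(s) and (s.min() < boundaries[0] or s.max() > boundaries[-1]):
            warnings.warn(
                f"{name} scores outside the reference range were assigned "
                "to the outer quartiles"
            )
    ctrl_q = _assign_quartile(ctrl, boundaries)
    case_q = _assign_quartile(case, boundaries)
    controls = np.bincount(ctrl_q, minlength=4)[:4]
    cases = np.bincount(case_q, minlength=4)[:4]
    return QuartileTable(boundaries=boundaries, controls=controls, cases=cases)


def _midp_ge(theta, M, n, N, x):
    """Mid-p P(X >= x) = P(X > x) + 0.5 P(X = x) under odds theta."""
    rv = nchypergeom_fisher(M, n, N, theta)
    return rv.sf(x) + 0.5 * rv.pmf(x)


def median_unbiased_or(a: int, b: int, c: int, d: int) -> ORResult:
    """Mid-p median-unbiased odds ratio for a 2x2 table.

    Layout: reference group (a controls, b cases), exposed group
    (c controls, d cases).  Conditional on margins the exposed-case
    count X has support [max(0, N-(a+c)), min(b+d, N)] with N = c + d.
    The estimate solves mid-p P(X >= d) = 0.5; the CI solves 0.025 /
    0.975.  At the support boundary the corresponding CI limit is 0 or
    infinity.
    """
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("cell counts must be non-negative")
    if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
        raise ValueError("a zero margin leaves the odds ratio undefined")
    M = a + b + c + d
    n_cases = b + d
    N = c + d
    x = d
    lo_sup = max(0, N - (a + c))
    hi_sup = min(n_cases, N)

    def solve(target):
        f = lambda lt: _midp_ge(np.exp(lt), M, n_cases, N, x) - target
        return float(np.exp(brentq(f, -40.0, 40.0, xtol=1e-12, maxiter=500)))

    if x == lo_sup and x == hi_sup:
        raise ValueError("degenerate support; odds ratio unidentifiable")
    # at a support boundary the mid-p tail never crosses 0.5: the median
    # estimate is the corresponding boundary value, one CI limit stays finite
    if x == hi_sup:
        est, upper = np.inf, np.inf
        lower = solve(0.025)
    elif x == lo_sup:
        est, lower = 0.0, 0.0
        upper = solve(0.975)
    else:
        est = solve(0.5)
        lower = solve(0.025)
        upper = solve(0.975)
    return ORResult(estimate=est, lower=lower, upper=upper, method="median-unbiased")


def quartile_or_table(table: QuartileTable) -> pd.DataFrame:
    """Median-unbiased OR per quartile against the lowest quartile."""
    rows = [{"quartile": 1, "controls": int(table.controls[0]),
             "cases": int(table.cases[0]), "or": 1.0,
             "lower": np.nan, "upper": np.nan, "method": "reference"}]
    a, b = int(table.controls[0]), int(table.cases[0])
    for q in range(1, 4):
        c, d = int(table.controls[q]), int(table.cases[q])
        r = median_unbiased_or(a, b, c, d)
        rows.append({"quartile": q + 1, "controls": c, "cases": d,
                     "or": r.estimate, "lower": r.lower, "upper": r.upper,
                     "method": r.method})
    return pd.DataFrame(rows)


def adjusted_or(
    quartile: pd.Series,
    outcome: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Covariate-adjusted quartile odds ratios by multivariable logistic
    regression, quartile coded as a factor with the lowest as reference.

    Returns exponentiated quartile coefficients with Wald 95% CIs; under
    (quasi-)separation the CI is reported as unavailable.
    """
    q = pd.Categorical(quartile)
    dummies = pd.get_dummies(q, prefix="q", drop_first=True, dtype=float)
    X = dummies
    if covariates is not None:
        X = pd.concat([dummies.reset_index(drop=True),
                       covariates.reset_index(drop=True)], axis=1)
    X = sm.add_constant(X.astype(float))
    y = np.asarray(outcome, dtype=float)
    separated = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception:
            separated = True
            fit = sm.Logit(y, X).fit_regularized(disp=0, alpha=1e-6)
    if not separated and not getattr(fit, "mle_retvals", {}).get("converged", True):
        separated = True
    rows = []
    for col in dummies.columns:
        est = float(np.exp(fit.params[col]))
        if separated or abs(fit.params[col]) > 15:
            rows.append({"term": col, "or": est, "lower": np.nan,
                         "upper": np.nan, "separation": True})
        else:
            ci = fit.conf_int().loc[col]
            rows.append({"term": col, "or": est,
                         "lower": float(np.exp(ci[0])),
                         "upper": float(np.exp(ci[1])),
                         "separation": False})
    return pd.DataFrame(rows)


def auc_ci(scores, labels, alpha: float = 0.05):
    """Mann-Whitney AUC with a DeLong asymptotic confidence interval.

    ``labels`` are 0/1 (1 = case).  Returns (auc, lower, upper), the CI
    clipped to [0, 1].  A single-class input is an error.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels != 1]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes are required to compute an AUC")
    m, n = len(pos), len(neg)

    # Midrank-based placement values (DeLong).
    all_s = np.concatenate([pos, neg])
    order = np.argsort(all_s, kind="mergesort")
    ranks = np.empty(m + n)
    sorted_s = all_s[order]
    # midranks over ties
    i = 0
    r = np.empty(m + n)
    while i < m + n:
        j = i
        while j < m + n - 1 and sorted_s[j + 1] == sorted_s[i]:
            j += 1
        r[i:j + 1] = 0.5 * (i + j) + 1
        i = j + 1
    ranks[order] = r

    rank_pos = ranks[:m]
    rank_neg = ranks[m:]
    # within-group midranks
    def midranks(x):
        o = np.argsort(x, kind="mergesort")
        xs = x[o]
        rr = np.empty(len(x))
        i = 0
        while i < len(x):
            j = i
            while j < len(x) - 1 and xs[j + 1] == xs[i]:
                j += 1
            rr[i:j + 1] = 0.5 * (i + j) + 1
            i = j + 1
        out = np.empty(len(x))
        out[o] = rr
        return out

    auc = (rank_pos.sum() - m * (m + 1) / 2) / (m * n)
    v01 = (rank_pos - midranks(pos)) / n          # structural components, cases
    v10 = 1.0 - (rank_neg - midranks(neg)) / m    # controls
    s01 = np.var(v01, ddof=1) if m > 1 else 0.0
    s10 = np.var(v10, ddof=1) if n > 1 else 0.0
    se = np.sqrt(s01 / m + s10 / n)
    z = norm.ppf(1 - alpha / 2)
    return float(auc), float(max(0.0, auc - z * se)), float(min(1.0, auc + z * se))


@dataclass
class CalibrationResult:
    intercept: float
    slope: float
    recalibrated: pd.Series
    curve: pd.DataFrame
    separation: bool


def recalibrate(index_scores, labels, n_bins: int = 10) -> CalibrationResult:
    """Logistic recalibration of an index: fit outcome ~ alpha + beta*index.

    Returns the calibration intercept alpha and slope beta, the rescaled
    score alpha + beta*index per sample, and a calibration curve of
    observed case fraction vs mean predicted probability in score bins.
    """
    s = np.asarray(index_scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes are required for recalibration")
    X = sm.add_constant(s)
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    if not fit.mle_retvals.get("converged", True) or np.abs(fit.params[1]) > 15:
        separation = True
    alpha, beta = float(fit.params[0]), float(fit.params[1])
    recal = alpha + beta * s
    p = 1.0 / (1.0 + np.exp(-recal))
    edges = np.quantile(p, np.linspace(0, 1, n_bins + 1))
    bins = np.clip(np.searchsorted(edges[1:-1], p, side="right"), 0, n_bins - 1)
    curve = (
        pd.DataFrame({"bin": bins, "pred": p, "obs": y})
        .groupby("bin")
        .agg(mean_predicted=("pred", "mean"), observed_fraction=("obs", "mean"),
             n=("obs", "size"))
        .reset_index()
    )
    idx = getattr(index_scores, "index", pd.RangeIndex(len(s)))
    return CalibrationResult(
        intercept=alpha, slope=beta,
        recalibrated=pd.Series(recal, index=idx, name="recalibrated"),
        curve=curve, separation=separation,
    )


def compute_prs(dosages: pd.DataFrame, weight_table: pd.DataFrame) -> pd.DataFrame:
    """Weighted effect-allele dosage sum per subject.

    ``dosages`` is SNP x subject; ``weight_table`` has ``snp_id`` and
    ``weight`` (log odds ratio per effect-allele copy).  Unmatched SNPs
    are dropped and counted; zero matched SNPs is an error.
    """
    w = weight_table.set_index("snp_id")["weight"].astype(float)
    common = dosages.index.intersection(w.index)
    if len(common) == 0:
        raise ValueError("no SNPs shared between dosage matrix and weights")
    D = dosages.loc[common].to_numpy(dtype=float)
    prs = D.T @ w.loc[common].to_numpy()
    return pd.DataFrame(
        {"prs": prs, "n_snps": len(common)},
        index=dosages.columns,
    )
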