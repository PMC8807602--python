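"""Penalized-regression methylation index: training, selection, scoring.

The index is a standardized weighted sum of beta values,

    index_i = (sum_j w_j * beta_ij - mu) / sigma,

with weights from a penalized (ridge or lasso) logistic regression on the
top-n CpGs of the interleaved delta-beta ranking, and mu, sigma the mean
and standard deviation of the unstandardized weighted sum over the
training samples.  The regularization strength is chosen by stratified
10-fold cross-validation inside the training set; n is chosen by AUC on a
held-out internal validation set.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "IndexModel",
    "split_discovery",
    "train_index",
    "select_n",
    "apply_index",
    "subclassifier_experiment",
    "train_tissue_index",
]

_DEFAULT_CS = np.logspace(-4, 4, 25)


class DegenerateModelError(RuntimeError):
    """Raised when the fitted weight vector is all zero (sigma = 0)."""


@dataclass
class IndexModel:
    """A trained, standardized methylation index.

    ``train_means`` holds the training-set mean beta per CpG; ``mu`` is
    defined as ``weights @ train_means`` (identically the training mean of
    the weighted sum, by linearity), which makes class-wise decompositions
    conserve exactly and supplies the constants for mean-imputing CpGs
    missing at application time.
    """

    cpgs: list
    weights: np.ndarray
    intercept: float
    mu: float
    sigma: float
    train_means: np.ndarray
    penalty: str
    C: float
    n: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.train_means = np.asarray(self.train_means, dtype=float)
        if self.sigma <= 0:
            raise DegenerateModelError("sigma must be > 0")
        if len(self.weights) != len(self.cpgs):
            raise ValueError("one weight per CpG required")

    def to_json(self, path):
        obj = {
            "cpgs": list(self.cpgs),
            "weights": self.weights.tolist(),
            "intercept": self.intercept,
            "mu": self.mu,
            "sigma": self.sigma,
            "train_means": self.train_means.tolist(),
            "penalty": self.penalty,
            "C": self.C,
            "n": self.n,
            "provenance": self.provenance,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            obj = json.load(fh)
        return cls(**obj)


def split_discovery(meta: pd.DataFrame, fraction: float = 2 / 3, seed: int = 0) -> pd.Series:
    """Random one-off training / internal-validation split.

    Returns a boolean Series (index = sample_id): True = training.  The
    training size is ``round(fraction * n)``.  Errors if either class is
    absent from either side.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = len(meta)
    n_train = int(round(fraction * n))
    perm = rng.permutation(n)
    is_train = np.zeros(n, dtype=bool)
    is_train[perm[:n_train]] = True
    assign = pd.Series(is_train, index=meta["sample_id"].to_numpy(), name="training")
    types = meta.set_index("sample_id")["type"]
    for side, mask in (("training", assign), ("validation", ~assign)):
        present = set(types[mask[types.index]])
        if not {"case", "control"} <= present:
            raise ValueError(f"{side} split lost a class; reseed or resize")
    return assign


def _design(betas: pd.DataFrame, meta: pd.DataFrame, cpgs):
    X = betas.loc[cpgs].to_numpy(dtype=float).T
    types = meta.set_index("sample_id").loc[betas.columns, "type"]
    y = (types == "case").to_numpy(dtype=int)
    return X, y


def train_index(
    betas: pd.DataFrame,
    meta: pd.DataFrame,
    ranked: pd.DataFrame,
    n: int,
    penalty: str = "ridge",
    cv: int = 10,
    seed: int = 0,
    Cs=None,
    C: float | None = None,
) -> IndexModel:
    """Fit the top-n penalized logistic index on the given samples.

    ``ranked`` is the interleaved ranking (column ``cpg_id``).  When ``C``
    is given the regularization strength is frozen (used for the final
    refit on the full discovery set); otherwise it is selected by
    stratified seeded ``cv``-fold cross-validation over ``Cs`` with the
    binomial deviance criterion.
    """
    if penalty not in ("ridge", "lasso"):
        raise ValueError("penalty must be 'ridge' or 'lasso'")
    if n < 1 or n > len(ranked):
        raise ValueError(f"n={n} outside the ranked list (length {len(ranked)})")
    cpgs = ranked["cpg_id"].iloc[:n].tolist()
    X, y = _design(betas, meta, cpgs)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")

    sk_penalty = "l2" if penalty == "ridge" else "l1"
    solver = "lbfgs" if penalty == "ridge" else "liblinear"
    with warnings.catch_warnings():
        # sklearn's penalty/l1_ratio transition chatter is not actionable here
        warnings.simplefilter("ignore", FutureWarning)
        warnings.filterwarnings("ignore", message=".*penalty.*", category=UserWarning)
        if C is not None:
            from sklearn.linear_model import LogisticRegression

            clf = LogisticRegression(
                penalty=sk_penalty, C=C, solver=solver, max_iter=5000
            ).fit(X, y)
            best_C = float(C)
        else:
            folds = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
            clf = LogisticRegressionCV(
                Cs=Cs if Cs is not None else _DEFAULT_CS,
                cv=folds,
                penalty=sk_penalty,
                solver=solver,
                scoring="neg_log_loss",
                max_iter=5000,
            ).fit(X, y)
            best_C = float(clf.C_[0])

    w = clf.coef_.ravel().astype(float)
    if np.all(w == 0):
        warnings.warn("all-zero weight vector; index cannot be standardized")
        raise DegenerateModelError(
            "penalized fit returned an all-zero weight vector (sigma = 0)"
        )
    train_means = X.mean(axis=0)
    linear = X @ w
    mu = float(w @ train_means)
    sigma = float(np.std(linear, ddof=1))
    return IndexModel(
        cpgs=cpgs,
        weights=w,
        intercept=float(clf.intercept_[0]),
        mu=mu,
        sigma=sigma,
        train_means=train_means,
        penalty=penalty,
        C=best_C,
        n=n,
        provenance={
            "n_train": int(len(y)),
            "cv_folds": cv if C is None else None,
            "seed": seed,
            "C_frozen": C is not None,
        },
    )


def apply_index(
    model: IndexModel,
    betas: pd.DataFrame,
    exclude: set | None = None,
    missing_tolerance: float = 0.01,
) -> pd.Series:
    """Score samples: ``(sum_j w_j beta_j - mu) / sigma``.

    ``exclude`` zeroes the weights of the named CpGs while retaining mu
    and sigma (the exclusion-experiment contract).  CpGs absent from
    ``betas`` are mean-imputed from the training means when they make up
    at most ``missing_tolerance`` of the model's CpGs, else an error
    lists them.
    """
    w = model.weights.copy()
    if exclude:
        excl_mask = np.array([c in exclude for c in model.cpgs])
        w[excl_mask] = 0.0
    present = np.array([c in betas.index for c in model.cpgs])
    missing = [c for c, p in zip(model.cpgs, present) if not p]
    if missing:
        if len(missing) / len(model.cpgs) > missing_tolerance:
            raise ValueError(
                f"{len(missing)} model CpGs missing from the beta matrix "
                f"(tolerance {missing_tolerance:.0%}): {missing[:10]}..."
            )
        X = np.empty((betas.shape[1], len(model.cpgs)))
        X[:, present] = betas.loc[
            [c for c in model.cpgs if c in betas.index]
        ].to_numpy(dtype=float).T
        X[:, ~present] = model.train_means[~present]
    else:
        X = betas.loc[model.cpgs].to_numpy(dtype=float).T
    score = (X @ w - model.mu) / model.sigma
    return pd.Series(score, index=betas.columns, name="index")


def select_n(
    betas: pd.DataFrame,
    meta: pd.DataFrame,
    ranked: pd.DataFrame,
    assignment: pd.Series,
    grid=None,
    penalties=("ridge", "lasso"),
    cv: int = 10,
    seed: int = 0,
    Cs=None,
    max_n: int = 30000,
):
    """Choose the number of CpGs (and penalty) by internal-validation AUC.

    Trains on the training side of ``assignment`` for every (n, penalty)
    on the grid, evaluates AUC on the validation side, picks the argmax,
    then refits on the full discovery set with the winning penalty and
    its cross-validated regularization strength frozen.

    Returns ``(curve, final_model)`` where ``curve`` is a DataFrame of
    n, penalty, validation AUC.
    """
    from .risk import auc_ci

    if grid is None:
        grid = [500, 1000, 2000, 5000, 10000, 20000, 30000]
    grid = [n for n in grid if n <= max_n]
    if not grid:
        raise ValueError("empty n grid")

    train_ids = assignment[assignment].index
    val_ids = assignment[~assignment].index
    betas_tr = betas[train_ids]
    betas_va = betas[val_ids]
    meta_i = meta.set_index("sample_id")
    y_va = (meta_i.loc[val_ids, "type"] == "case").to_numpy(dtype=int)

    rows = []
    best = None
    for pen in penalties:
        for n in grid:
            if n > len(ranked):
                warnings.warn(f"grid value n={n} exceeds ranked list; skipped")
                continue
            try:
                m = train_index(
                    betas_tr, meta, ranked, n, penalty=pen, cv=cv, seed=seed, Cs=Cs
                )
            except DegenerateModelError:
                continue
            scores = apply_index(m, betas_va).to_numpy()
            auc, lo, hi = auc_ci(scores, y_va)
            rows.append(
                {"n": n, "penalty": pen, "auc": auc, "auc_lo": lo,
                 "auc_hi": hi, "C": m.C}
            )
            if best is None or auc > best[0]:
                best = (auc, n, pen, m.C)
    if best is None:
        raise RuntimeError("no model on the grid could be fitted")
    curve = pd.DataFrame(rows)
    _, n_star, pen_star, C_star = best
    final = train_index(
        betas, meta, ranked, n_star, penalty=pen_star, C=C_star, seed=seed
    )
    final.provenance.update(
        {"selected_n": n_star, "selected_penalty": pen_star,
         "refit_on_full_discovery": True, "hyperparameters_frozen": True}
    )
    return curve, final


def subclassifier_experiment(
    betas: pd.DataFrame,
    meta: pd.DataFrame,
    model: IndexModel,
    assignment: pd.Series,
    mode: str = "bins",
    ns=(500, 1000, 2000),
    bin_size: int = 500,
    cv: int = 10,
    seed: int = 0,
    Cs=None,
) -> pd.DataFrame:
    """Retrain classifiers on subsets of the index's CpGs.

    CpGs are ranked by absolute model weight, descending.  ``mode`` is
    ``"top-n"`` (keep the top n), ``"remove-top-n"`` (drop the top n) or
    ``"bins"`` (disjoint consecutive bins of ``bin_size``).  Each subset
    is retrained on the training side and scored by AUC on validation.
    """
    from .risk import auc_ci

    order = np.argsort(-np.abs(model.weights), kind="stable")
    ranked_cpgs = [model.cpgs[i] for i in order]

    if mode == "bins":
        if bin_size >= len(ranked_cpgs):
            subsets = [("bin_1", ranked_cpgs)]
        else:
            subsets = [
                (f"bin_{k + 1}", ranked_cpgs[k * bin_size:(k + 1) * bin_size])
                for k in range((len(ranked_cpgs) + bin_size - 1) // bin_size)
            ]
    elif mode == "top-n":
        subsets = [(f"top_{n}", ranked_cpgs[:n]) for n in ns if n <= len(ranked_cpgs)]
    elif mode == "remove-top-n":
        subsets = [
            (f"without_top_{n}", ranked_cpgs[n:]) for n in ns if n < len(ranked_cpgs)
        ]
    else:
        raise ValueError("mode must be 'top-n', 'remove-top-n' or 'bins'")

    train_ids = assignment[assignment].index
    val_ids = assignment[~assignment].index
    meta_i = meta.set_index("sample_id")
    y_va = (meta_i.loc[val_ids, "type"] == "case").to_numpy(dtype=int)

    rows = []
    for name, cpgs in subsets:
        if not cpgs:
            continue
        pseudo_ranked = pd.DataFrame({"cpg_id": cpgs})
        try:
            m = train_index(
                betas[train_ids], meta, pseudo_ranked, len(cpgs),
                penalty=model.penalty, cv=cv, seed=seed, Cs=Cs,
            )
        except DegenerateModelError:
            rows.append({"subset": name, "n_cpgs": len(cpgs), "auc": np.nan,
                         "auc_lo": np.nan, "auc_hi": np.nan})
            continue
        scores = apply_index(m, betas[val_ids]).to_numpy()
        auc, lo, hi = auc_ci(scores, y_va)
        rows.append({"subset": name, "n_cpgs": len(cpgs), "auc": auc,
                     "auc_lo": lo, "auc_hi": hi})
    return pd.DataFrame(rows)


def train_tissue_index(
    betas: pd.DataFrame,
    meta: pd.DataFrame,
    k: int,
    split_fraction: float = 0.7,
    cv: int = 10,
    seed: int = 0,
    Cs=None,
):
    """Lasso index on the top-k raw differentially methylated CpGs.

    A generic two-class tissue classifier: CpGs are ranked by absolute
    group-mean difference, the top k feed a lasso logistic model, and
    performance is reported on a held-out test split
    (``split_fraction`` train / rest test).

    Returns ``(model, report)`` with ``report`` carrying the test AUC and
    the number of CpGs with non-zero weight.
    """
    from .risk import auc_ci

    if k < 1:
        raise ValueError("k must be >= 1")
    assignment = split_discovery(meta, fraction=split_fraction, seed=seed)
    train_ids = assignment[assignment].index
    test_ids = assignment[~assignment].index

    meta_i = meta.set_index("sample_id")
    tr_case = (meta_i.loc[train_ids, "type"] == "case").to_numpy()
    B = betas[train_ids].to_numpy(dtype=float)
    diff = B[:, tr_case].mean(axis=1) - B[:, ~tr_case].mean(axis=1)
    order = np.argsort(-np.abs(diff), kind="stable")[:k]
    top = betas.index.to_numpy()[order]

    pseudo_ranked = pd.DataFrame({"cpg_id": top})
    model = train_index(
        betas[train_ids], meta, pseudo_ranked, len(top),
        penalty="lasso", cv=cv, seed=seed, Cs=Cs,
    )
    scores = apply_index(model, betas[test_ids]).to_numpy()
    y_te = (meta_i.loc[test_ids, "type"] == "case").to_numpy(dtype=int)
    auc, lo, hi = auc_ci(scores, y_te)
    report = {
        "test_auc": auc, "auc_lo": lo, "auc_hi": hi,
        "n_selected": int(np.sum(model.weights != 0)),
        "n_candidates": int(len(top)),
    }
    return model, report
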