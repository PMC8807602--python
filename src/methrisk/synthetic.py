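"""Synthetic methylation cohorts with known cell-type structure.

Each sample is modelled as a two-cell-type mixture: for CpG j and sample i

    beta_ij = (1 - rho_i) * e_ij + rho_i * m_ij

with e_ij ~ Beta(a0_j, b0_j) (epithelial) and m_ij ~ Beta(a1_j, b1_j)
(immune), rho_i the immune-cell proportion of sample i.  Case/control
effects are planted as mean shifts of the targeted cell type's beta
distribution at fixed precision (a+b held constant), so case draws remain
valid beta variates.  The generator records the full ground truth so every
downstream estimator can be scored against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Effect",
    "SimulationConfig",
    "SyntheticDataset",
    "generate_dataset",
    "resolve_shapes",
    "add_degradation",
    "generate_reference",
    "generate_genotypes",
]


@dataclass(frozen=True)
class Effect:
    """A planted case-vs-control mean shift on a set of CpGs.

    Parameters
    ----------
    cpg_indices : indices (into the CpG axis) of the affected probes.
    cell_type : ``"epithelial"``, ``"immune"`` or ``"both"``.
    delta : additive shift of the targeted cell-type mean in cases.
    """

    cpg_indices: tuple
    cell_type: str
    delta: float

    def __post_init__(self):
        if self.cell_type not in ("epithelial", "immune", "both"):
            raise ValueError(f"unknown cell type {self.cell_type!r}")
        object.__setattr__(self, "cpg_indices", tuple(self.cpg_indices))


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    ``rho_distribution`` may be ``("uniform", lo, hi)``, ``("constant", v)``
    or a callable ``f(rng, n) -> array``.  ``cpg_shapes`` is an
    ``(n_cpgs, 4)`` array of ``a0, b0, a1, b1``; when omitted, shapes are
    sampled once per CpG with cell-type means ~ U(0.05, 0.95) and precision
    a+b log-uniform on [8, 120], which gives array-like dispersion and
    CpGs of both cell-type-dominated and shared variability.
    """

    n_controls: int = 200
    n_cases: int = 100
    n_cpgs: int = 2000
    rho_distribution: tuple | Callable = ("uniform", 0.0, 1.0)
    cpg_shapes: np.ndarray | None = None
    effects: Sequence[Effect] = field(default_factory=list)
    age_range: tuple = (35.0, 70.0)
    age_slope: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_controls < 1 or self.n_cases < 0 or self.n_cpgs < 1:
            raise ValueError("cohort dimensions must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.cpg_shapes is not None:
            shapes = np.asarray(self.cpg_shapes, dtype=float)
            if shapes.shape != (self.n_cpgs, 4):
                raise ValueError("cpg_shapes must have shape (n_cpgs, 4)")
            if np.any(shapes <= 0):
                raise ValueError("all beta shape parameters must be > 0")
            self.cpg_shapes = shapes


@dataclass
class SyntheticDataset:
    """Beta matrix (CpG x sample), sample sheet, and ground truth."""

    betas: pd.DataFrame
    meta: pd.DataFrame
    truth: pd.DataFrame

    def write(self, outdir):
        """Write betas/meta/truth as CSV into ``outdir``."""
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.betas.to_csv(out / "betas.csv")
        self.meta.to_csv(out / "samples.csv", index=False)
        self.truth.to_csv(out / "truth.csv")


def _draw_rho(spec, rng: np.random.Generator, n: int) -> np.ndarray:
    if callable(spec):
        rho = np.asarray(spec(rng, n), dtype=float)
    elif spec[0] == "uniform":
        rho = rng.uniform(spec[1], spec[2], size=n)
    elif spec[0] == "constant":
        rho = np.full(n, float(spec[1]))
    else:
        raise ValueError(f"unknown rho distribution spec {spec!r}")
    if np.any((rho < 0) | (rho > 1)):
        raise ValueError("rho values must lie in [0, 1]")
    return rho


def _default_shapes(rng: np.random.Generator, n_cpgs: int) -> np.ndarray:
    # Cell-type means spread over the unit interval; precision (a+b)
    # log-uniform so per-CpG dispersion varies over an order of magnitude,
    # as on real arrays — this also yields CpGs whose variability is
    # clearly epithelial- or immune-dominated.
    means = rng.uniform(0.05, 0.95, size=(n_cpgs, 2))
    prec = np.exp(rng.uniform(np.log(8.0), np.log(120.0), size=(n_cpgs, 2)))
    a = means * prec
    b = (1.0 - means) * prec
    return np.column_stack([a[:, 0], b[:, 0], a[:, 1], b[:, 1]])


def _planted_deltas(config: SimulationConfig):
    delta_epi = np.zeros(config.n_cpgs)
    delta_imm = np.zeros(config.n_cpgs)
    for eff in config.effects:
        idx = np.asarray(eff.cpg_indices, dtype=int)
        if eff.cell_type in ("epithelial", "both"):
            delta_epi[idx] += eff.delta
        if eff.cell_type in ("immune", "both"):
            delta_imm[idx] += eff.delta
    return delta_epi, delta_imm


def resolve_shapes(config: SimulationConfig) -> np.ndarray:
    """Deterministic per-CpG shapes ``(a0, b0, a1, b1)`` for a config.

    When shapes are default-sampled, CpGs targeted by a planted effect
    get baseline means drawn inside a range that keeps the shifted case
    mean in (0, 1).  Explicitly supplied shapes are returned unchanged
    (an incompatible shift then errors at generation time).
    """
    if config.cpg_shapes is not None:
        return np.array(config.cpg_shapes, dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[0])
    shapes = _default_shapes(rng, config.n_cpgs)
    a0, b0, a1, b1 = (shapes[:, k].copy() for k in range(4))
    delta_epi, delta_imm = _planted_deltas(config)
    for delta, (av, bv) in ((delta_epi, (a0, b0)), (delta_imm, (a1, b1))):
        hit = delta != 0
        if not np.any(hit):
            continue
        lo = 0.05 + np.clip(-delta[hit], 0, None)
        hi = 0.95 - np.clip(delta[hit], 0, None)
        if np.any(lo >= hi):
            raise ValueError("planted shift too large for a valid beta mean")
        mean = rng.uniform(lo, hi)
        prec = av[hit] + bv[hit]
        av[hit] = mean * prec
        bv[hit] = (1.0 - mean) * prec
    return np.column_stack([a0, b0, a1, b1])


def _shift_shapes(a: np.ndarray, b: np.ndarray, delta: np.ndarray):
    """Shift the beta mean by delta at fixed precision a+b."""
    prec = a + b
    mean = a / prec + delta
    if np.any(mean <= 0) or np.any(mean >= 1):
        raise ValueError(
            "planted effect pushes a cell-type mean outside (0, 1); "
            "reduce delta or move the baseline mean"
        )
    return mean * prec, (1.0 - mean) * prec


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate one seeded cohort under ``config``.

    Controls come first in the sample axis, then cases.  The truth table
    records per CpG the four shape parameters, the planted epithelial and
    immune delta-betas (0 where no effect was planted), and the
    control-condition cell-type means.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    n = config.n_controls + config.n_cases
    shapes = resolve_shapes(config)
    a0, b0, a1, b1 = (shapes[:, k] for k in range(4))

    rho = _draw_rho(config.rho_distribution, rng, n)
    age = rng.uniform(*config.age_range, size=n)
    is_case = np.zeros(n, dtype=bool)
    is_case[config.n_controls:] = True

    delta_epi, delta_imm = _planted_deltas(config)

    # Shape matrices (n_cpgs, n_samples): controls use baseline shapes,
    # cases the shifted ones.
    a0c, b0c = _shift_shapes(a0, b0, delta_epi)
    a1c, b1c = _shift_shapes(a1, b1, delta_imm)

    A0 = np.where(is_case[None, :], a0c[:, None], a0[:, None])
    B0 = np.where(is_case[None, :], b0c[:, None], b0[:, None])
    A1 = np.where(is_case[None, :], a1c[:, None], a1[:, None])
    B1 = np.where(is_case[None, :], b1c[:, None], b1[:, None])

    e = rng.beta(A0, B0)
    m = rng.beta(A1, B1)
    betas = (1.0 - rho[None, :]) * e + rho[None, :] * m
    if config.age_slope != 0.0:
        betas = np.clip(
            betas + config.age_slope * (age - age.mean())[None, :], 0.0, 1.0
        )

    cpg_ids = [f"cg{j:07d}" for j in range(config.n_cpgs)]
    sample_ids = [f"S{i:04d}" for i in range(n)]
    betas_df = pd.DataFrame(betas, index=cpg_ids, columns=sample_ids)
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "type": np.where(is_case, "case", "control"),
            "ic": rho,
            "age": age,
        }
    )
    truth = pd.DataFrame(
        {
            "a0": a0, "b0": b0, "a1": a1, "b1": b1,
            "mean_epi": a0 / (a0 + b0),
            "mean_imm": a1 / (a1 + b1),
            "delta_epi": delta_epi,
            "delta_imm": delta_imm,
        },
        index=cpg_ids,
    )
    ds = SyntheticDataset(betas=betas_df, meta=meta, truth=truth)
    if config.noise_sd > 0:
        ds = add_degradation(ds, config.noise_sd, seed=rng.integers(2**31))
    return ds


def add_degradation(
    dataset: SyntheticDataset,
    noise_sd: float,
    seed: int = 0,
    scale: str = "beta",
) -> SyntheticDataset:
    """Emulate biobank-style signal loss by adding independent noise.

    ``scale="beta"`` adds Gaussian noise directly on the beta scale and
    clips to [0, 1]; ``scale="logit"`` perturbs on the logit scale (no
    clipping needed).  The truth record is unchanged: degradation obscures
    the signal, it does not move it.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_sd == 0:
        return SyntheticDataset(
            betas=dataset.betas.copy(),
            meta=dataset.meta.copy(),
            truth=dataset.truth.copy(),
        )
    rng = np.random.default_rng(seed)
    vals = dataset.betas.to_numpy()
    noise = rng.normal(0.0, noise_sd, size=vals.shape)
    if scale == "beta":
        noisy = np.clip(vals + noise, 0.0, 1.0)
    elif scale == "logit":
        z = np.log(np.clip(vals, 1e-6, 1 - 1e-6) / np.clip(1 - vals, 1e-6, 1))
        noisy = 1.0 / (1.0 + np.exp(-(z + noise)))
    else:
        raise ValueError("scale must be 'beta' or 'logit'")
    betas = pd.DataFrame(
        noisy, index=dataset.betas.index, columns=dataset.betas.columns
    )
    return SyntheticDataset(betas=betas, meta=dataset.meta.copy(), truth=dataset.truth.copy())


def generate_reference(config: SimulationConfig) -> pd.DataFrame:
    """True cell-type mean methylation per CpG (control condition).

    Returns a CpG x {epithelial, immune} matrix — the reference profiles a
    deconvolution estimator regresses samples on.
    """
    shapes = resolve_shapes(config)
    cpg_ids = [f"cg{j:07d}" for j in range(config.n_cpgs)]
    return pd.DataFrame(
        {
            "epithelial": shapes[:, 0] / (shapes[:, 0] + shapes[:, 1]),
            "immune": shapes[:, 2] / (shapes[:, 2] + shapes[:, 3]),
        },
        index=cpg_ids,
    )


def generate_genotypes(
    n_subjects: int,
    weight_table: pd.DataFrame,
    freqs: np.ndarray,
    seed: int = 0,
) -> pd.DataFrame:
    """Hardy-Weinberg effect-allele dosages for PRS scoring.

    Returns a SNP x subject matrix of dosages in {0, 1, 2}; each SNP's
    dosage is Binomial(2, freq).
    """
    freqs = np.asarray(freqs, dtype=float)
    if len(freqs) != len(weight_table):
        raise ValueError("one allele frequency per SNP required")
    if np.any((freqs <= 0) | (freqs >= 1)):
        raise ValueError("allele frequencies must lie strictly in (0, 1)")
    if not np.all(np.isfinite(weight_table["weight"].to_numpy(dtype=float))):
        raise ValueError("PRS weights must be finite")
    rng = np.random.default_rng(seed)
    dosages = rng.binomial(2, freqs[:, None], size=(len(freqs), n_subjects))
    return pd.DataFrame(
        dosages,
        index=weight_table["snp_id"].to_numpy(),
        columns=[f"P{i:04d}" for i in range(n_subjects)],
    )
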