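"""Synthetic paired exposure/outcome summary statistics with known truth.

The generator emulates the two-sample MR setting: a set of J variants with
true per-allele effects γ_j on a binary exposure, a true causal effect θ
of the exposure on a binary outcome (log-odds scale), optional horizontal
pleiotropy α_j, and LD-correlated estimation noise:

    β̂_Xj = γ_j + ε_Xj,          ε_X ~ N(0, D_X R D_X)
    β̂_Yj = θ γ_j + α_j + ε_Yj,  ε_Y ~ N(0, D_Y R D_Y)

where R is the instrument LD correlation matrix and D = diag(se).  The
exposure and outcome samples are independent, so ε_X and ε_Y are drawn
independently.  Standard errors follow the standard GWAS approximation
se ≈ 1/sqrt(2 maf (1 − maf) n), with case/control cohorts mapped to an
effective sample size n_eff = 4/(1/cases + 1/controls).

Defaults mirror the chronic-hepatitis-B-on-stroke study design that this
package reproduces: J = 12 instruments, an exposure GWAS of 9114 cases and
9257 controls, an outcome GWAS of 27,413 cases and 237,242 controls, and
per-variant effects sized so single-variant F-statistics span roughly
25–320.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import load_chb_instruments
from .types import LDMatrix, OutcomeDataset, VariantAssociation

__all__ = [
    "SimulationConfig",
    "SyntheticStudy",
    "Truth",
    "effective_n",
    "make_ld_block_matrix",
    "simulate_two_sample",
    "paper_like_study",
    "synthetic_chb_ld",
    "study_to_files",
]


def effective_n(n: int | float | tuple) -> float:
    """Effective sample size of a case/control GWAS: 4/(1/cases + 1/controls).

    A plain number is returned unchanged (already-effective n).
    """
    if isinstance(n, (tuple, list)):
        cases, controls = n
        return 4.0 / (1.0 / cases + 1.0 / controls)
    return float(n)


@dataclass(frozen=True)
class Truth:
    """Ground truth behind a synthetic study."""

    theta: float
    gamma: np.ndarray
    alpha: np.ndarray


@dataclass
class SyntheticStudy:
    """A simulated exposure/outcome pair with its LD matrix and truth."""

    exposure: list[VariantAssociation]
    outcome: OutcomeDataset
    ld: LDMatrix
    truth: Truth


@dataclass
class SimulationConfig:
    """Design of a synthetic two-sample study.

    Parameters
    ----------
    n_variants
        Number of instruments J.
    theta
        True causal effect of exposure on outcome, log-odds per log-odds.
    gamma_range
        Bounds of the uniform distribution of true instrument effects
        (log-odds per allele).
    maf_range
        Bounds of the uniform minor-allele-frequency distribution,
        a sub-interval of (0, 0.5].
    n_exposure, n_outcome
        Cohort sizes controlling SE magnitudes; either an effective n or a
        ``(cases, controls)`` pair.
    pleiotropy_mode
        ``"none"``, ``"balanced"`` (α_j ~ N(0, sd²)) or ``"directional"``
        (α_j ~ N(mean, sd²)).
    ld_blocks
        Block specs ``(size, model, rho)`` with model ``"ar1"`` or
        ``"compound"``; sizes must sum to J.  ``None`` means identity
        (independent instruments).
    seed
        RNG seed; the same config and seed give bit-identical studies.
    """

    n_variants: int = 12
    theta: float = 0.0
    gamma_range: tuple[float, float] = (0.09, 0.20)
    maf_range: tuple[float, float] = (0.10, 0.45)
    n_exposure: int | tuple = (9114, 9257)
    n_outcome: int | tuple = (27413, 237242)
    pleiotropy_mode: str = "none"
    pleiotropy_sd: float = 0.02
    pleiotropy_mean: float = 0.0
    ld_blocks: list[tuple[int, str, float]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if self.ld_blocks is not None:
            total = sum(b[0] for b in self.ld_blocks)
            if total != self.n_variants:
                raise ValueError(
                    f"LD block sizes sum to {total}, expected {self.n_variants}"
                )


def make_ld_block_matrix(
    blocks: Sequence[tuple[int, str, float]], rsids: Sequence[str]
) -> LDMatrix:
    """Block-diagonal LD matrix from ``(size, model, rho)`` specs.

    ``ar1`` blocks have entries rho^|i−j|; ``compound`` blocks have a
    constant off-diagonal rho.  The result is validated positive
    semidefinite (smallest eigenvalue >= −1e-10, then clipped at zero).
    """
    total = sum(b[0] for b in blocks)
    if total != len(rsids):
        raise ValueError(f"block sizes sum to {total}, expected {len(rsids)} rsids")
    mats = []
    for size, model, rho in blocks:
        if not (-1.0 < rho < 1.0):
            raise ValueError(f"block correlation must lie in (-1, 1), got {rho}")
        idx = np.arange(size)
        if model == "ar1":
            m = rho ** np.abs(idx[:, None] - idx[None, :])
        elif model == "compound":
            m = np.full((size, size), rho)
            np.fill_diagonal(m, 1.0)
        else:
            raise ValueError(f"unknown LD block model {model!r}")
        mats.append(m)
    rho_full = _block_diag(mats)
    eig = np.linalg.eigvalsh(rho_full)
    if eig.min() < -1e-10:
        raise ValueError(f"block spec yields an indefinite matrix (min eigenvalue {eig.min():g})")
    if eig.min() < 0:  # clip tiny negative eigenvalues
        vals, vecs = np.linalg.eigh(rho_full)
        rho_full = (vecs * np.clip(vals, 0.0, None)) @ vecs.T
        rho_full = 0.5 * (rho_full + rho_full.T)
        np.fill_diagonal(rho_full, 1.0)
    return LDMatrix(list(rsids), rho_full)


def _block_diag(mats: list[np.ndarray]) -> np.ndarray:
    n = sum(m.shape[0] for m in mats)
    out = np.zeros((n, n))
    k = 0
    for m in mats:
        s = m.shape[0]
        out[k : k + s, k : k + s] = m
        k += s
    return out


def _correlated_noise(rng: np.random.Generator, rho: np.ndarray, se: np.ndarray) -> np.ndarray:
    """One draw of N(0, D R D) via the (PSD-safe) matrix square root of R."""
    try:
        chol = np.linalg.cholesky(rho)
    except np.linalg.LinAlgError:
        vals, vecs = np.linalg.eigh(rho)
        chol = vecs * np.sqrt(np.clip(vals, 0.0, None))
    return se * (chol @ rng.standard_normal(rho.shape[0]))


def _two_sided_p(z: np.ndarray) -> np.ndarray:
    from scipy import stats

    return np.clip(2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)


def simulate_two_sample(config: SimulationConfig) -> SyntheticStudy:
    """Draw one synthetic study from the generative model above.

    All alleles are assigned non-palindromic (A/G), with the outcome
    reported on the same strand and allele order as the exposure, so
    harmonization keeps every variant unchanged.
    """
    rng = np.random.default_rng(config.seed)
    j = config.n_variants
    maf = rng.uniform(*config.maf_range, j)
    gamma = rng.uniform(*config.gamma_range, j)
    n_x = effective_n(config.n_exposure)
    n_y = effective_n(config.n_outcome)
    se_x = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n_x)
    se_y = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n_y)

    if config.pleiotropy_mode == "none":
        alpha = np.zeros(j)
    else:
        mean = config.pleiotropy_mean if config.pleiotropy_mode == "directional" else 0.0
        alpha = rng.normal(mean, config.pleiotropy_sd, j)

    rsids = [f"rs{i + 1}" for i in range(j)]
    if config.ld_blocks is None:
        ld = LDMatrix.identity(rsids)
    else:
        ld = make_ld_block_matrix(config.ld_blocks, rsids)

    beta_x = gamma + _correlated_noise(rng, ld.rho, se_x)
    beta_y = config.theta * gamma + alpha + _correlated_noise(rng, ld.rho, se_y)
    p_x = _two_sided_p(beta_x / se_x)
    p_y = _two_sided_p(beta_y / se_y)

    exposure = []
    outcome_records = []
    for i in range(j):
        pos = 10_000 + i * 50_000
        common = dict(
            rsid=rsids[i], effect_allele="A", other_allele="G",
            eaf=float(maf[i]), chrom="1", pos=pos,
        )
        exposure.append(
            VariantAssociation(
                beta=float(beta_x[i]), se=float(se_x[i]), pvalue=float(p_x[i]),
                n=int(round(n_x)), **common,
            )
        )
        outcome_records.append(
            VariantAssociation(
                beta=float(beta_y[i]), se=float(se_y[i]), pvalue=float(p_y[i]),
                n=int(round(n_y)), **common,
            )
        )
    return SyntheticStudy(
        exposure=exposure,
        outcome=OutcomeDataset.from_records("simulated", outcome_records),
        ld=ld,
        truth=Truth(theta=config.theta, gamma=gamma, alpha=alpha),
    )


# ---------------------------------------------------------------------------
# study-shaped fixture


#: LD-block membership of the packaged instruments: three HLA sub-blocks on
#: chromosome 6 (grouped by physical position) plus one independent variant
#: on chromosome 20.  Synthetic stand-in for an East Asian reference panel;
#: within-block correlation 0.7 (r² = 0.49), across blocks 0.
_CHB_BLOCKS = {
    "A": ("rs1419881", "rs3130542", "rs2853953"),
    "B": ("rs652888", "rs12614", "rs422951", "rs2856718", "rs7453920"),
    "C": ("rs378352", "rs3077", "rs9277535"),
    "chr20": ("rs1883832",),
}
_CHB_RHO = 0.7

#: LAS outcome cohort (1735 cases, 237,242 controls) scaling the outcome SEs
_LAS_COHORT = (1735, 237242)


def synthetic_chb_ld() -> LDMatrix:
    """Synthetic LD matrix over the 12 packaged instruments.

    Not estimated from any genotype panel: a block-structured stand-in
    whose clumping behaviour (4 independent instruments at r² < 0.01)
    matches the real East Asian LD structure of these loci.  Exact
    replication requires a user-supplied LD matrix from a reference panel.
    """
    rsids = [v.rsid for v in load_chb_instruments()]
    block_of = {r: name for name, members in _CHB_BLOCKS.items() for r in members}
    k = len(rsids)
    rho = np.eye(k)
    for i in range(k):
        for jj in range(i + 1, k):
            if block_of[rsids[i]] == block_of[rsids[jj]]:
                rho[i, jj] = rho[jj, i] = _CHB_RHO
    return LDMatrix(rsids, rho)


def paper_like_study(
    seed: int = 0,
    theta: float = 0.0,
    omit_rsids: tuple[str, ...] = ("rs2853953",),
    outcome_label: str = "LAS",
) -> SyntheticStudy:
    """A study shaped like the chronic-hepatitis-B-on-stroke analysis.

    The exposure side is the packaged 12-variant instrument table taken
    verbatim; the outcome side is simulated under ``theta`` with SEs
    scaled to the smallest stroke-subtype cohort (1735 large-artery
    stroke cases, 237,242 controls) and, by default, omits rs2853953 to
    emulate its absence from the real outcome files.  LD follows
    :func:`synthetic_chb_ld`, under which clumping at r² < 0.01 retains
    exactly 4 instruments including the chromosome-20 variant rs1883832.
    """
    rng = np.random.default_rng(seed)
    exposure = load_chb_instruments()
    ld = synthetic_chb_ld()
    avail = [v for v in exposure if v.rsid not in omit_rsids]
    rho = ld.submatrix([v.rsid for v in avail]).rho
    eaf = np.array([v.eaf for v in avail])
    gamma = np.array([v.beta for v in avail])
    n_y = effective_n(_LAS_COHORT)
    se_y = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n_y)
    beta_y = theta * gamma + _correlated_noise(rng, rho, se_y)
    p_y = _two_sided_p(beta_y / se_y)
    records = [
        v.replace(beta=float(beta_y[i]), se=float(se_y[i]), pvalue=float(p_y[i]),
                  n=int(round(sum(_LAS_COHORT))))
        for i, v in enumerate(avail)
    ]
    full_gamma = np.array([v.beta for v in exposure])
    return SyntheticStudy(
        exposure=exposure,
        outcome=OutcomeDataset.from_records(outcome_label, records),
        ld=ld,
        truth=Truth(theta=theta, gamma=full_gamma, alpha=np.zeros(len(exposure))),
    )


def study_to_files(study: SyntheticStudy, out_dir) -> dict[str, str]:
    """Write a study as exposure.tsv / outcome.tsv / ld.tsv readable by the readers."""
    import os

    from . import io as _io

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "exposure": os.path.join(out_dir, "exposure.tsv"),
        "outcome": os.path.join(out_dir, "outcome.tsv"),
        "ld": os.path.join(out_dir, "ld.tsv"),
    }
    _io.write_exposure_table(study.exposure, paths["exposure"])
    _io.write_outcome_table(study.outcome, paths["outcome"])
    _io.write_ld_matrix(study.ld, paths["ld"])
    return paths
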