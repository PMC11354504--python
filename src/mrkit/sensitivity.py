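"""Heterogeneity and pleiotropy diagnostics, plus Bonferroni control.

Cochran's Q measures heterogeneity among the per-variant Wald ratios:

    Q = Σ_j w_j (θ_j − θ̂_FE)²,   w_j = β_Xj²/se_Yj²,

referred to a chi-square with J − 1 df.  Q is always computed about the
fixed-effects IVW estimate — the standard definition — even when the
reported causal estimate uses random effects.  For correlated instrument
sets the generalized form rᵀΩ⁻¹r about the GLS estimate is used instead,
so the statistic respects the LD-induced covariance.

The MR-Egger intercept test reads off the intercept of the Egger
regression: a nonzero intercept indicates directional horizontal
pleiotropy (instruments acting on the outcome around the exposure).
"""
from __future__ import annotations

import math

import numpy as np
from scipy import linalg, stats

from . import estimators
from .types import HarmonizedSet, LDMatrix, SensitivityReport

__all__ = [
    "cochran_q",
    "egger_intercept_test",
    "bonferroni_threshold",
    "is_significant",
    "sensitivity_report",
]


def cochran_q(h: HarmonizedSet, ld: LDMatrix | None = None) -> tuple[float, int, float]:
    """Cochran's Q, its degrees of freedom (J − 1), and its p-value.

    With ``ld`` supplied the generalized (LD-aware) residual form is
    computed about the GLS estimate; otherwise the classical weighted sum
    of squared ratio deviations about the fixed-effects IVW estimate.
    """
    j = h.n_snp
    if j < 2:
        raise ValueError(f"Cochran's Q needs at least 2 instruments, got {j}")
    if ld is None:
        w = h.beta_x**2 / h.se_y**2
        theta_j = h.beta_y / h.beta_x
        theta = float(np.sum(w * theta_j) / np.sum(w))
        q = float(np.sum(w * (theta_j - theta) ** 2))
    else:
        est = estimators.ivw_correlated(h, ld, variance_model="fixed")
        omega = np.outer(h.se_y, h.se_y) * ld.submatrix(h.rsids).rho
        r = h.beta_y - est.log_or * h.beta_x
        q = float(r @ linalg.cho_solve(linalg.cho_factor(omega, lower=True), r))
    df = j - 1
    return q, df, float(stats.chi2.sf(q, df))


def egger_intercept_test(
    h: HarmonizedSet, ld: LDMatrix | None = None
) -> tuple[float, float, float]:
    """Egger intercept, its SE, and its t-based p-value (J − 2 df)."""
    est = (
        estimators.egger(h)
        if ld is None
        else estimators.egger_correlated(h, ld)
    )
    return est.intercept, est.intercept_se, est.intercept_p


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise threshold alpha/n_tests."""
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if n_tests < 1:
        raise ValueError(f"n_tests must be >= 1, got {n_tests}")
    return alpha / n_tests


def is_significant(p: float, threshold: float) -> bool:
    """Non-strict comparison: p equal to the threshold counts as significant."""
    return p <= threshold


def sensitivity_report(
    h: HarmonizedSet,
    outcome: str,
    instrument_set: str,
    ld: LDMatrix | None = None,
) -> SensitivityReport:
    """Q and (when J >= 3) the Egger intercept for one instrument set."""
    q, df, qp = cochran_q(h, ld=ld)
    intercept = intercept_se = intercept_p = None
    if h.n_snp >= 3:
        intercept, intercept_se, intercept_p = egger_intercept_test(h, ld=ld)
    return SensitivityReport(
        outcome=outcome,
        instrument_set=instrument_set,
        n_snp=h.n_snp,
        q_stat=q,
        q_df=df,
        q_p=qp,
        egger_intercept=intercept,
        egger_intercept_se=intercept_se,
        egger_intercept_p=intercept_p,
    )
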