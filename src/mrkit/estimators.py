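"""The five causal-effect estimators.

Each instrument j contributes a Wald ratio θ_j = β_Yj / β_Xj with
first-order standard error se(θ_j) = se_Yj / |β_Xj|.  The estimators
combine these ratios in different ways:

* **IVW (canonical)** — inverse-variance weighted mean of the ratios,
  algebraically identical to weighted through-origin regression of β_Y on
  β_X with weights 1/se_Y²;
* **IVW (all SNPs)** — generalized least squares through the origin under
  the LD-induced covariance Ω_jk = se_Yj se_Yk ρ_jk, allowing correlated
  instruments from a single gene region;
* **MR-Egger (canonical / all SNPs)** — the same regressions with a free
  intercept after orienting every instrument to β_X > 0; the slope is a
  pleiotropy-robust causal estimate and the intercept estimates the
  average directional pleiotropic effect;
* **weighted median** — the 0.5-quantile of the inverse-variance-weighted
  ratio distribution, consistent while instruments carrying at least half
  of the weight are valid; its SE comes from a parametric bootstrap.

``variance_model`` selects fixed effects or multiplicative random effects;
the latter inflates standard errors by max(1, sqrt(Q / (J − 1))) for IVW
(residual df J − 2 for Egger), never deflating them below the fixed-effects
value.  Confidence intervals use the normal 1.96 multiplier for IVW and
the weighted median, and t quantiles with J − 2 df for Egger.
"""
from __future__ import annotations

import logging
import math

import numpy as np
import statsmodels.api as sm
from scipy import linalg, stats

from .types import HarmonizedSet, LDMatrix, MREstimate

logger = logging.getLogger("mrkit")

__all__ = [
    "ratio_estimates",
    "ivw",
    "ivw_correlated",
    "egger",
    "egger_correlated",
    "weighted_median",
    "to_odds_ratio",
]

#: condition-number guard for the GLS covariance
_MAX_CONDITION = 1e10


def ratio_estimates(h: HarmonizedSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant Wald ratios θ_j = β_Yj/β_Xj and first-order SEs."""
    if np.any(h.beta_x == 0):
        bad = [r for r, b in zip(h.rsids, h.beta_x) if b == 0]
        raise ValueError(f"zero exposure effect for {bad}; exclude before computing ratios")
    return h.beta_y / h.beta_x, h.se_y / np.abs(h.beta_x)


def _drop_null_instruments(h: HarmonizedSet) -> HarmonizedSet:
    if not np.any(h.beta_x == 0):
        return h
    keep = [r for r, b in zip(h.rsids, h.beta_x) if b != 0]
    dropped = sorted(set(h.rsids) - set(keep))
    logger.warning("excluding %d variant(s) with zero exposure effect: %s", len(dropped), dropped)
    return h.subset(keep)


def to_odds_ratio(log_or: float, se: float) -> tuple[float, float, float]:
    """(OR, 95% CI) from a log-odds estimate: exp(θ̂), exp(θ̂ ∓ 1.96·se)."""
    if not se > 0:
        raise ValueError("se must be positive")
    return math.exp(log_or), math.exp(log_or - 1.96 * se), math.exp(log_or + 1.96 * se)


def _finish_normal(method: str, n_snp: int, theta: float, se: float, outcome=None) -> MREstimate:
    or_value, ci_low, ci_high = to_odds_ratio(theta, se)
    p = 2.0 * stats.norm.sf(abs(theta) / se)
    return MREstimate(
        method=method, n_snp=n_snp, log_or=theta, se=se,
        ci_low=ci_low, ci_high=ci_high, or_value=or_value, pvalue=float(p), outcome=outcome,
    )


# ---------------------------------------------------------------------------
# IVW


def ivw(h: HarmonizedSet, variance_model: str = "multiplicative_random") -> MREstimate:
    """Inverse-variance-weighted estimate over independent instruments."""
    _check_vm(variance_model)
    h = _drop_null_instruments(h)
    j = h.n_snp
    if j == 0:
        raise ValueError("no instruments")
    w = h.beta_x**2 / h.se_y**2
    theta_j = h.beta_y / h.beta_x
    sw = np.sum(w)
    theta = float(np.sum(w * theta_j) / sw)
    se = float(sw**-0.5)
    if variance_model == "multiplicative_random" and j > 1:
        q = float(np.sum(w * (theta_j - theta) ** 2))
        se *= max(1.0, math.sqrt(q / (j - 1)))
    return _finish_normal("ivw_canonical", j, theta, se)


def _omega(h: HarmonizedSet, ld: LDMatrix, ridge: float, signs: np.ndarray | None = None) -> np.ndarray:
    rho = ld.submatrix(h.rsids).rho
    if signs is not None:
        rho = rho * np.outer(signs, signs)
    omega = np.outer(h.se_y, h.se_y) * rho
    if ridge:
        omega = omega + ridge * np.diag(np.diag(omega))
    return omega


def _cho(omega: np.ndarray):
    try:
        cho = linalg.cho_factor(omega, lower=True)
    except linalg.LinAlgError as exc:
        raise ValueError(
            "instrument covariance is singular; add ridge regularization "
            "(ridge > 0) or reduce the instrument set"
        ) from exc
    cond = np.linalg.cond(omega)
    if cond > _MAX_CONDITION:
        raise ValueError(
            f"instrument covariance condition number {cond:.3g} exceeds {_MAX_CONDITION:.0e}; "
            "increase ridge regularization or use fewer instruments"
        )
    return cho


def ivw_correlated(
    h: HarmonizedSet,
    ld: LDMatrix,
    variance_model: str = "multiplicative_random",
    ridge: float = 0.0,
) -> MREstimate:
    """IVW over correlated instruments: GLS through the origin under Ω.

    θ̂ = (β_Xᵀ Ω⁻¹ β_X)⁻¹ β_Xᵀ Ω⁻¹ β_Y with Ω_jk = se_Yj se_Yk ρ_jk.
    ``ridge`` adds ε·diag(Ω) for near-collinear instrument panels.
    """
    _check_vm(variance_model)
    h = _drop_null_instruments(h)
    j = h.n_snp
    if j == 0:
        raise ValueError("no instruments")
    cho = _cho(_omega(h, ld, ridge))
    oi_bx = linalg.cho_solve(cho, h.beta_x)
    a = float(h.beta_x @ oi_bx)
    theta = float(h.beta_x @ linalg.cho_solve(cho, h.beta_y)) / a
    se = a**-0.5
    if variance_model == "multiplicative_random" and j > 1:
        r = h.beta_y - theta * h.beta_x
        q = float(r @ linalg.cho_solve(cho, r))
        se *= max(1.0, math.sqrt(q / (j - 1)))
    return _finish_normal("ivw_correlated", j, theta, se)


# ---------------------------------------------------------------------------
# MR-Egger


def _orient(h: HarmonizedSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Negate (β_X, β_Y) jointly where needed so every β_X > 0."""
    s = np.where(h.beta_x < 0, -1.0, 1.0)
    return h.beta_x * s, h.beta_y * s, s


def _finish_egger(
    method: str, j: int, theta: float, se_theta: float,
    alpha: float, se_alpha: float,
) -> MREstimate:
    df = j - 2
    tcrit = float(stats.t.ppf(0.975, df))
    p = 2.0 * float(stats.t.sf(abs(theta) / se_theta, df))
    p_int = 2.0 * float(stats.t.sf(abs(alpha) / se_alpha, df))
    return MREstimate(
        method=method, n_snp=j, log_or=theta, se=se_theta,
        ci_low=math.exp(theta - tcrit * se_theta),
        ci_high=math.exp(theta + tcrit * se_theta),
        or_value=math.exp(theta), pvalue=p,
        intercept=alpha, intercept_se=se_alpha, intercept_p=p_int,
    )


def egger(h: HarmonizedSet, variance_model: str = "multiplicative_random") -> MREstimate:
    """MR-Egger over independent instruments: WLS of β_Y on β_X with intercept."""
    _check_vm(variance_model)
    h = _drop_null_instruments(h)
    j = h.n_snp
    if j < 3:
        raise ValueError(f"insufficient instruments for Egger regression ({j} < 3)")
    x, y, _ = _orient(h)
    w = 1.0 / h.se_y**2
    fit = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    alpha, theta = (float(v) for v in fit.params)
    ncov = np.asarray(fit.normalized_cov_params)  # (XᵀWX)⁻¹
    scale = 1.0 if variance_model == "fixed" else max(1.0, float(fit.scale))
    se_alpha = math.sqrt(ncov[0, 0] * scale)
    se_theta = math.sqrt(ncov[1, 1] * scale)
    return _finish_egger("egger_canonical", j, theta, se_theta, alpha, se_alpha)


def egger_correlated(
    h: HarmonizedSet,
    ld: LDMatrix,
    variance_model: str = "multiplicative_random",
    ridge: float = 0.0,
) -> MREstimate:
    """MR-Egger over correlated instruments: GLS with intercept under Ω.

    Instruments are first oriented to β_X > 0; the orientation also
    conjugates Ω (flipping a variant flips the sign of its covariances).
    """
    _check_vm(variance_model)
    h = _drop_null_instruments(h)
    j = h.n_snp
    if j < 3:
        raise ValueError(f"insufficient instruments for Egger regression ({j} < 3)")
    x, y, s = _orient(h)
    cho = _cho(_omega(h, ld, ridge, signs=s))
    design = np.column_stack([np.ones(j), x])
    oi_design = linalg.cho_solve(cho, design)
    a = design.T @ oi_design  # Xᵀ Ω⁻¹ X, 2×2
    b = oi_design.T @ y
    coef = np.linalg.solve(a, b)
    cov0 = np.linalg.inv(a)
    resid = y - design @ coef
    scale = 1.0
    if variance_model == "multiplicative_random":
        q = float(resid @ linalg.cho_solve(cho, resid))
        scale = max(1.0, q / (j - 2))
    alpha, theta = float(coef[0]), float(coef[1])
    se_alpha = math.sqrt(cov0[0, 0] * scale)
    se_theta = math.sqrt(cov0[1, 1] * scale)
    return _finish_egger("egger_correlated", j, theta, se_theta, alpha, se_alpha)


# ---------------------------------------------------------------------------
# weighted median


def _weighted_median_rows(theta: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted median of each row of ``theta`` under row weights ``w``.

    Uses the standard interpolation on the half-mass points
    s_k = Σ_{i<=k} w'_(i) − w'_(k)/2 of the ratio order statistics.
    """
    order = np.argsort(theta, axis=1)
    t = np.take_along_axis(theta, order, axis=1)
    ww = np.take_along_axis(w, order, axis=1)
    wn = ww / ww.sum(axis=1, keepdims=True)
    s = np.cumsum(wn, axis=1) - 0.5 * wn
    below = (s < 0.5).sum(axis=1) - 1
    first = below < 0  # all half-mass points at or above 0.5
    k = np.clip(below, 0, t.shape[1] - 2)
    s_lo = np.take_along_axis(s, k[:, None], axis=1)[:, 0]
    s_hi = np.take_along_axis(s, (k + 1)[:, None], axis=1)[:, 0]
    t_lo = np.take_along_axis(t, k[:, None], axis=1)[:, 0]
    t_hi = np.take_along_axis(t, (k + 1)[:, None], axis=1)[:, 0]
    est = t_lo + (t_hi - t_lo) * (0.5 - s_lo) / (s_hi - s_lo)
    est[first] = t[first, 0]
    return est


def weighted_median(
    h: HarmonizedSet,
    *,
    n_boot: int = 1000,
    seed: int,
    variance_model: str | None = None,
) -> MREstimate:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    Weights are the IVW weights β_X²/se_Y².  The bootstrap resamples
    β_Xj ~ N(β_Xj, se_Xj²) and β_Yj ~ N(β_Yj, se_Yj²) independently,
    recomputes the weighted median ``n_boot`` times, and reports the
    replicate standard deviation; the p-value and 95% CI use the normal
    approximation.  ``seed`` is required: there is no silent global RNG.
    ``variance_model`` is accepted for interface symmetry and ignored.
    """
    h = _drop_null_instruments(h)
    j = h.n_snp
    if j < 3:
        raise ValueError(f"insufficient instruments for the weighted median ({j} < 3)")
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    theta_j = h.beta_y / h.beta_x
    w = h.beta_x**2 / h.se_y**2
    theta = float(_weighted_median_rows(theta_j[None, :], w[None, :])[0])

    rng = np.random.default_rng(seed)
    bx = h.beta_x + h.se_x * rng.standard_normal((n_boot, j))
    by = h.beta_y + h.se_y * rng.standard_normal((n_boot, j))
    bx = np.where(bx == 0, np.finfo(float).tiny, bx)  # measure-zero guard
    est = _weighted_median_rows(by / bx, bx**2 / h.se_y**2)
    se = float(np.std(est, ddof=1))
    res = _finish_normal("weighted_median", j, theta, se)
    return res


def _check_vm(variance_model: str) -> None:
    if variance_model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown variance_model {variance_model!r}")
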