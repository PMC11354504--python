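"""Independent brute-force oracles used to check the estimators.

Deliberately written as naive loops / textbook formulas, taking a
different computational route from the package implementation.
"""
from __future__ import annotations

import numpy as np
import scipy.linalg


def ivw_oracle(bx, by, sy):
    """Through-origin WLS normal equations, summed in a plain loop."""
    num = den = 0.0
    for x, y, s in zip(bx, by, sy):
        w = 1.0 / s**2
        num += w * x * y
        den += w * x * x
    theta = num / den
    return theta, den**-0.5


def egger_oracle(bx, by, sy):
    """Weighted design-matrix normal equations with intercept, solved by
    the explicit 2x2 inverse.  Returns (alpha, theta, se_alpha, se_theta)
    with fixed-effects (unit-scale) standard errors, after orienting to
    bx > 0."""
    bx = np.asarray(bx, float)
    by = np.asarray(by, float)
    sy = np.asarray(sy, float)
    s = np.where(bx < 0, -1.0, 1.0)
    x, y = bx * s, by * s
    w = 1.0 / sy**2
    s0, s1, s2 = w.sum(), (w * x).sum(), (w * x * x).sum()
    t0, t1 = (w * y).sum(), (w * x * y).sum()
    det = s0 * s2 - s1 * s1
    alpha = (s2 * t0 - s1 * t1) / det
    theta = (s0 * t1 - s1 * t0) / det
    # inverse of [[s0, s1], [s1, s2]]
    va, vt = s2 / det, s0 / det
    return alpha, theta, np.sqrt(va), np.sqrt(vt)


def gls_ivw_oracle(bx, by, omega):
    """Through-origin GLS by direct matrix inverse."""
    oi = np.linalg.inv(omega)
    a = bx @ oi @ bx
    return float(bx @ oi @ by) / a, float(a) ** -0.5


def gls_egger_whitening_oracle(bx, by, omega):
    """GLS with intercept by Cholesky whitening followed by ordinary
    least squares, after orienting to bx > 0 (conjugating omega)."""
    bx = np.asarray(bx, float)
    by = np.asarray(by, float)
    s = np.where(bx < 0, -1.0, 1.0)
    x, y = bx * s, by * s
    om = omega * np.outer(s, s)
    L = scipy.linalg.cholesky(om, lower=True)
    X = np.column_stack([np.ones(len(x)), x])
    Xw = scipy.linalg.solve_triangular(L, X, lower=True)
    yw = scipy.linalg.solve_triangular(L, y, lower=True)
    coef, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    cov = np.linalg.inv(Xw.T @ Xw)
    return coef[0], coef[1], np.sqrt(cov[0, 0]), np.sqrt(cov[1, 1])


def weighted_median_oracle(theta, w):
    """Exhaustive scan over all half-mass crossing intervals."""
    theta = np.asarray(theta, float)
    w = np.asarray(w, float)
    order = np.argsort(theta)
    t = theta[order]
    wn = w[order] / w.sum()
    s = []
    run = 0.0
    for wi in wn:
        s.append(run + wi / 2.0)
        run += wi
    if s[0] >= 0.5:
        return t[0]
    for k in range(len(s) - 1):
        if s[k] < 0.5 <= s[k + 1]:
            return t[k] + (t[k + 1] - t[k]) * (0.5 - s[k]) / (s[k + 1] - s[k])
    return t[-1]


def greedy_clump_oracle(variants, ld, r2_threshold, window_kb):
    """Pairwise re-implementation of the greedy clumping rule."""
    def key(v):
        try:
            ck = (0, int(v.chrom))
        except (TypeError, ValueError):
            ck = (1, str(v.chrom))
        return (v.pvalue, ck, v.pos)

    pool = sorted(variants, key=key)
    kept = []
    while pool:
        best = pool.pop(0)
        kept.append(best.rsid)
        survivors = []
        for v in pool:
            prune = False
            if v.chrom == best.chrom and abs(v.pos - best.pos) < window_kb * 1000:
                r = ld.correlation(best.rsid, v.rsid) if (best.rsid in ld and v.rsid in ld) else 0.0
                prune = r * r >= r2_threshold
            if not prune:
                survivors.append(v)
        pool = survivors
    return set(kept)
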