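"""Instrument-strength screening and greedy LD clumping.

Instrument strength is summarized per variant by the variance it explains
in the exposure (R²) and the F-statistic

    F = R² (N − 2) / (1 − R²),

with F > 10 the conventional screen against weak-instrument bias.  Two R²
formulas are exposed:

* ``zscore`` (default): R² = z² / (z² + N − 2) with z = beta/se, which
  makes F equal z² exactly and needs only the printed beta, SE, and N;
* ``eaf``: R² = 2 EAF (1 − EAF) beta², the variance explained by an
  additive per-allele effect on a standardized trait.

Clumping is the standard greedy procedure: rank variants by exposure
p-value and repeatedly keep the best remaining one, removing every
remaining variant on the same chromosome within the distance window whose
squared LD correlation with it reaches the threshold.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .types import InstrumentStrength, LDMatrix, VariantAssociation

logger = logging.getLogger("mrkit")

__all__ = [
    "explained_variance",
    "f_statistic",
    "instrument_strength",
    "ld_clump",
    "clump_report",
    "ClumpDecision",
]


def explained_variance(v: VariantAssociation, mode: str = "zscore") -> float:
    """Variance in the exposure explained by one variant.

    ``mode="eaf"`` uses 2·EAF·(1−EAF)·beta² and requires ``eaf``;
    ``mode="zscore"`` uses z²/(z² + n − 2) and requires ``n``.
    """
    if mode == "eaf":
        if v.eaf is None:
            raise ValueError(f"{v.rsid}: eaf required for mode='eaf'")
        r2 = 2.0 * v.eaf * (1.0 - v.eaf) * v.beta**2
    elif mode == "zscore":
        if v.n is None:
            raise ValueError(f"{v.rsid}: sample size n required for mode='zscore'")
        if v.n <= 2:
            raise ValueError(f"{v.rsid}: n must exceed 2 for mode='zscore'")
        z = v.beta / v.se
        r2 = z**2 / (z**2 + v.n - 2)
    else:
        raise ValueError(f"unknown explained-variance mode {mode!r}")
    if r2 >= 1.0:
        raise ValueError(f"{v.rsid}: degenerate input, explained variance {r2:g} >= 1")
    return r2


def f_statistic(r2: float, n: int) -> float:
    """F = R²(N − 2)/(1 − R²) for a single-variant instrument."""
    if not (0.0 <= r2 < 1.0):
        raise ValueError(f"r2 must lie in [0, 1), got {r2}")
    if n <= 2:
        raise ValueError(f"n must exceed 2, got {n}")
    return r2 * (n - 2) / (1.0 - r2)


def instrument_strength(
    variants: Iterable[VariantAssociation],
    mode: str = "zscore",
    n: int | None = None,
) -> list[InstrumentStrength]:
    """Per-variant R² and F; ``n`` overrides missing per-record sample sizes."""
    out = []
    for v in variants:
        if v.n is None and n is not None:
            v = v.replace(n=n)
        r2 = explained_variance(v, mode=mode)
        nn = v.n if mode == "zscore" else (v.n if v.n is not None else n)
        if nn is None:
            raise ValueError(f"{v.rsid}: sample size required for the F-statistic")
        out.append(InstrumentStrength(rsid=v.rsid, r2=r2, f_stat=f_statistic(r2, nn), mode=mode))
    return out


@dataclass(frozen=True)
class ClumpDecision:
    """Clump-report row: why a variant was kept or removed."""

    rsid: str
    kept: bool
    index_rsid: str | None
    r2_to_index: float | None
    distance_bp: int | None


def _chrom_key(chrom: str | None):
    if chrom is None:
        return (2, "")
    try:
        return (0, int(chrom))
    except ValueError:
        return (1, str(chrom))


def ld_clump(
    variants: Sequence[VariantAssociation],
    ld: LDMatrix,
    r2_threshold: float = 0.01,
    window_kb: float = 10_000,
    return_report: bool = False,
):
    """Greedy p-value-ranked LD clumping to an independent instrument set.

    Variants are ranked by exposure p-value (ties broken by chromosome,
    then position); the best remaining variant is kept and every remaining
    variant on the same chromosome within ``window_kb`` of it with squared
    correlation >= ``r2_threshold`` is removed.  Variants absent from
    ``ld`` are treated as uncorrelated with all others (logged).  Variants
    on different chromosomes are never pruned against each other.

    Returns the kept rsids in the original input order; with
    ``return_report=True`` also a list of :class:`ClumpDecision`.
    """
    if not (0.0 < r2_threshold <= 1.0):
        raise ValueError(f"r2_threshold must lie in (0, 1], got {r2_threshold}")
    variants = list(variants)
    for v in variants:
        if v.rsid not in ld:
            logger.info("%s absent from LD matrix; treated as uncorrelated", v.rsid)
        if v.chrom is None or v.pos is None:
            raise ValueError(f"{v.rsid}: chromosome and position required for clumping")

    order = sorted(variants, key=lambda v: (v.pvalue, _chrom_key(v.chrom), v.pos))
    window_bp = window_kb * 1000.0
    remaining = {v.rsid: v for v in order}
    kept: set[str] = set()
    decisions: dict[str, ClumpDecision] = {}
    for v in order:
        if v.rsid not in remaining:
            continue
        kept.add(v.rsid)
        decisions[v.rsid] = ClumpDecision(v.rsid, True, None, None, None)
        del remaining[v.rsid]
        for other in list(remaining.values()):
            if other.chrom != v.chrom:
                continue
            dist = abs(other.pos - v.pos)
            if dist >= window_bp:
                continue
            if v.rsid in ld and other.rsid in ld:
                r2 = ld.correlation(v.rsid, other.rsid) ** 2
            else:
                r2 = 0.0
            if r2 >= r2_threshold:
                decisions[other.rsid] = ClumpDecision(other.rsid, False, v.rsid, r2, dist)
                del remaining[other.rsid]

    kept_in_order = [v.rsid for v in variants if v.rsid in kept]
    if return_report:
        return kept_in_order, [decisions[v.rsid] for v in variants]
    return kept_in_order


def clump_report(decisions: Iterable[ClumpDecision]) -> list[dict]:
    """Clump decisions as rows (rsid, kept/removed, index, r², distance)."""
    return [
        {
            "rsid": d.rsid,
            "status": "kept" if d.kept else "removed",
            "index_rsid": d.index_rsid or "",
            "r2_to_index": d.r2_to_index,
            "distance_bp": d.distance_bp,
        }
        for d in decisions
    ]
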