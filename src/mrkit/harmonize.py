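"""Allele harmonization of outcome effects onto the exposure's effect allele.

Two-sample MR requires that, for every instrument, the exposure and outcome
effects refer to the same allele.  Outcome records may list the alleles in
swapped order (effect/other exchanged), on the opposite strand (A<->T,
C<->G complements), or both.  Palindromic variants (A/T or C/G pairs) are
strand-ambiguous by construction and are resolved by policy, by default by
comparing effect-allele frequencies with 0.5.

Every exposure variant receives exactly one audit record, so the audit
trail partitions the input: kept + flipped + complemented + dropped_* =
number of exposure variants.  Standard errors are never altered; only the
signs of effects and the frequencies change.
"""
from __future__ import annotations

import logging
from typing import Iterable

import numpy as np

from .types import AuditRecord, HarmonizedSet, OutcomeDataset, VariantAssociation

logger = logging.getLogger("mrkit")

__all__ = ["harmonize", "is_palindromic", "reverse_complement"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def reverse_complement(allele: str) -> str:
    """Reverse complement of an allele string; non-ACGT bases pass through."""
    return "".join(_COMPLEMENT.get(b, b) for b in reversed(allele.upper()))


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True when the allele pair is its own strand complement (A/T or C/G)."""
    return reverse_complement(effect_allele) == other_allele.upper()


def harmonize(
    exposure: Iterable[VariantAssociation],
    outcome: OutcomeDataset,
    palindrome_policy: str = "infer_by_eaf",
    eaf_ambiguity_band: float = 0.08,
) -> HarmonizedSet:
    """Align outcome effects to the exposure effect allele per variant.

    Parameters
    ----------
    exposure
        Exposure instruments (unique rsids).
    outcome
        Outcome associations keyed by rsid; variants absent from it are
        dropped with audit tag ``dropped_missing``.
    palindrome_policy
        ``"drop"`` removes palindromic variants; ``"infer_by_eaf"``
        (default) aligns them by comparing both effect-allele frequencies
        with 0.5, dropping the variant when either frequency lies within
        ``eaf_ambiguity_band`` of 0.5 or is missing; ``"keep"`` trusts the
        reported strand and applies plain swap logic.
    eaf_ambiguity_band
        Half-width of the frequency band around 0.5 inside which a
        palindromic variant is considered unresolvable (default 0.08,
        i.e. drop when EAF is within [0.42, 0.58]).

    Returns
    -------
    HarmonizedSet
        Aligned per-variant effects plus a complete audit trail.
    """
    if palindrome_policy not in ("drop", "infer_by_eaf", "keep"):
        raise ValueError(f"unknown palindrome_policy {palindrome_policy!r}")

    exposure = list(exposure)
    seen: set[str] = set()
    for v in exposure:
        if v.rsid in seen:
            raise ValueError(f"duplicate exposure rsid {v.rsid!r}")
        seen.add(v.rsid)

    rsids: list[str] = []
    bx, sx, by, sy, fx, fy = [], [], [], [], [], []
    actions: list[AuditRecord] = []

    def retain(e: VariantAssociation, o: VariantAssociation, sign: int, action: str, reason: str) -> None:
        rsids.append(e.rsid)
        bx.append(e.beta)
        sx.append(e.se)
        by.append(sign * o.beta)
        sy.append(o.se)
        fx.append(e.eaf if e.eaf is not None else np.nan)
        if o.eaf is None:
            fy.append(np.nan)
        else:
            fy.append(o.eaf if sign == 1 else 1.0 - o.eaf)
        actions.append(AuditRecord(e.rsid, action, reason))

    for e in exposure:
        o = outcome.get(e.rsid)
        if o is None:
            actions.append(AuditRecord(e.rsid, "dropped_missing", "absent from outcome"))
            continue
        ea_x, oa_x = e.effect_allele, e.other_allele
        ea_y, oa_y = o.effect_allele, o.other_allele

        if is_palindromic(ea_x, oa_x):
            if {ea_y, oa_y} != {ea_x, oa_x}:
                actions.append(
                    AuditRecord(e.rsid, "dropped_irreconcilable", f"palindromic exposure {ea_x}/{oa_x} vs outcome {ea_y}/{oa_y}")
                )
                logger.warning("%s: outcome alleles %s/%s irreconcilable with palindromic %s/%s", e.rsid, ea_y, oa_y, ea_x, oa_x)
                continue
            if palindrome_policy == "drop":
                actions.append(AuditRecord(e.rsid, "dropped_palindromic", "policy=drop"))
                continue
            if palindrome_policy == "keep":
                sign = 1 if ea_y == ea_x else -1
                retain(e, o, sign, "kept" if sign == 1 else "flipped", "palindromic, strand trusted")
                continue
            # infer_by_eaf: orientation from which side of 0.5 each frequency falls
            if e.eaf is None or o.eaf is None:
                actions.append(AuditRecord(e.rsid, "dropped_palindromic", "eaf missing, orientation unresolvable"))
                continue
            if abs(e.eaf - 0.5) <= eaf_ambiguity_band or abs(o.eaf - 0.5) <= eaf_ambiguity_band:
                actions.append(
                    AuditRecord(e.rsid, "dropped_palindromic", f"eaf within {eaf_ambiguity_band} of 0.5")
                )
                continue
            eaf_y_nominal = o.eaf if ea_y == ea_x else 1.0 - o.eaf
            nominal = 1 if ea_y == ea_x else -1
            if (eaf_y_nominal < 0.5) == (e.eaf < 0.5):
                sign = nominal  # labels consistent with frequencies
            else:
                sign = -nominal  # opposite strand: stated labels are misleading
            retain(e, o, sign, "kept" if sign == 1 else "flipped", "palindromic, inferred by eaf")
            continue

        if (ea_y, oa_y) == (ea_x, oa_x):
            retain(e, o, 1, "kept", "alleles identical")
        elif (ea_y, oa_y) == (oa_x, ea_x):
            retain(e, o, -1, "flipped", "effect/other swapped")
        elif (reverse_complement(ea_y), reverse_complement(oa_y)) == (ea_x, oa_x):
            retain(e, o, 1, "complemented", "strand complement")
        elif (reverse_complement(ea_y), reverse_complement(oa_y)) == (oa_x, ea_x):
            retain(e, o, -1, "complemented", "strand complement, effect/other swapped")
        else:
            actions.append(
                AuditRecord(e.rsid, "dropped_irreconcilable", f"exposure {ea_x}/{oa_x} vs outcome {ea_y}/{oa_y}")
            )
            logger.warning("%s: alleles irreconcilable after flip and strand complement", e.rsid)

    return HarmonizedSet(
        rsids=rsids,
        beta_x=np.array(bx, dtype=float),
        se_x=np.array(sx, dtype=float),
        beta_y=np.array(by, dtype=float),
        se_y=np.array(sy, dtype=float),
        eaf_x=np.array(fx, dtype=float),
        eaf_y=np.array(fy, dtype=float),
        actions=actions,
    )
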