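"""Core containers for two-sample Mendelian randomization.

Conventions used throughout the package:

* every effect is on the log-odds scale for binary traits (odds-ratio
  columns are converted at parse time);
* genomic coordinates are 1-based base-pair positions;
* ``eaf`` is always the frequency of ``effect_allele``;
* LD is stored as the signed correlation *r*, never r².
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariantAssociation",
    "OutcomeDataset",
    "LDMatrix",
    "HarmonizedSet",
    "AuditRecord",
    "MREstimate",
    "SensitivityReport",
    "InstrumentStrength",
    "LDValidationError",
]

#: audit actions a variant can receive during harmonization
ACTIONS = (
    "kept",
    "flipped",
    "complemented",
    "dropped_missing",
    "dropped_palindromic",
    "dropped_irreconcilable",
)


class LDValidationError(ValueError):
    """Raised when a putative LD matrix fails structural validation."""


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's summary association with a trait.

    Parameters
    ----------
    rsid : str
        Variant identifier.
    effect_allele, other_allele : str
        Allele strings; the effect estimate refers to ``effect_allele``.
    beta : float
        Per-allele effect (log-odds for binary traits).
    se : float
        Standard error of ``beta``; must be positive.
    pvalue : float
        Two-sided association p-value in (0, 1].
    eaf : float, optional
        Effect-allele frequency in [0, 1].
    chrom, pos : optional
        1-based genomic coordinates.
    n : int, optional
        Association sample size (>= 3 when given).
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    eaf: float | None = None
    chrom: str | None = None
    pos: int | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        ea = self.effect_allele.upper()
        oa = self.other_allele.upper()
        object.__setattr__(self, "effect_allele", ea)
        object.__setattr__(self, "other_allele", oa)
        if ea == oa:
            raise ValueError(f"{self.rsid}: effect and other allele are identical ({ea})")
        if not self.se > 0:
            raise ValueError(f"{self.rsid}: se must be > 0, got {self.se}")
        if not (0 < self.pvalue <= 1):
            raise ValueError(f"{self.rsid}: pvalue must lie in (0, 1], got {self.pvalue}")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise ValueError(f"{self.rsid}: eaf must lie in [0, 1], got {self.eaf}")
        if self.n is not None and self.n < 3:
            raise ValueError(f"{self.rsid}: n must be >= 3, got {self.n}")

    def replace(self, **kw) -> "VariantAssociation":
        return dataclasses.replace(self, **kw)


@dataclass
class OutcomeDataset:
    """A labelled collection of outcome associations keyed by rsid."""

    label: str
    records: dict[str, VariantAssociation] = field(default_factory=dict)

    @classmethod
    def from_records(cls, label: str, records: Iterable[VariantAssociation]) -> "OutcomeDataset":
        out: dict[str, VariantAssociation] = {}
        for rec in records:
            if rec.rsid in out:
                raise ValueError(f"duplicate rsid {rec.rsid!r} in outcome {label!r}")
            out[rec.rsid] = rec
        return cls(label=label, records=out)

    def get(self, rsid: str) -> VariantAssociation | None:
        return self.records.get(rsid)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, rsid: str) -> bool:
        return rsid in self.records


@dataclass
class LDMatrix:
    """Symmetric signed-correlation matrix over an ordered variant list."""

    rsids: list[str]
    rho: np.ndarray

    #: asymmetry beyond this tolerance is rejected; below it we symmetrize
    SYM_TOL = 1e-8

    def __post_init__(self) -> None:
        self.rsids = [str(r) for r in self.rsids]
        self.rho = np.asarray(self.rho, dtype=float)
        k = len(self.rsids)
        if self.rho.shape != (k, k):
            raise LDValidationError(
                f"LD matrix shape {self.rho.shape} does not match {k} rsids"
            )
        if len(set(self.rsids)) != k:
            raise LDValidationError("duplicate rsids in LD matrix")
        if not np.all(np.isfinite(self.rho)):
            raise LDValidationError("LD matrix contains non-finite entries")
        asym = np.max(np.abs(self.rho - self.rho.T)) if k else 0.0
        if asym > self.SYM_TOL:
            raise LDValidationError(f"LD matrix asymmetric (max |r_ij - r_ji| = {asym:g})")
        self.rho = 0.5 * (self.rho + self.rho.T)
        if k and np.max(np.abs(np.diag(self.rho) - 1.0)) > self.SYM_TOL:
            raise LDValidationError("LD matrix diagonal must be 1")
        if k and np.max(np.abs(self.rho)) > 1.0 + self.SYM_TOL:
            raise LDValidationError("LD matrix has |entry| > 1")
        self._index = {r: i for i, r in enumerate(self.rsids)}

    @classmethod
    def identity(cls, rsids: Sequence[str]) -> "LDMatrix":
        return cls(list(rsids), np.eye(len(rsids)))

    def correlation(self, a: str, b: str) -> float:
        return float(self.rho[self._index[a], self._index[b]])

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._index

    def submatrix(self, rsids: Sequence[str]) -> "LDMatrix":
        """Reordered submatrix restricted to ``rsids`` (all must be present)."""
        missing = [r for r in rsids if r not in self._index]
        if missing:
            raise KeyError(f"rsids absent from LD matrix: {missing}")
        idx = [self._index[r] for r in rsids]
        return LDMatrix(list(rsids), self.rho[np.ix_(idx, idx)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rho, index=self.rsids, columns=self.rsids)


@dataclass(frozen=True)
class AuditRecord:
    """One harmonization decision: what happened to one exposure variant."""

    rsid: str
    action: str
    reason: str = ""


@dataclass
class HarmonizedSet:
    """Exposure/outcome effects aligned to a shared effect allele.

    Arrays cover the *retained* variants only; ``actions`` records every
    input exposure variant exactly once (retained or dropped).
    """

    rsids: list[str]
    beta_x: np.ndarray
    se_x: np.ndarray
    beta_y: np.ndarray
    se_y: np.ndarray
    eaf_x: np.ndarray
    eaf_y: np.ndarray
    actions: list[AuditRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("beta_x", "se_x", "beta_y", "se_y", "eaf_x", "eaf_y"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        k = len(self.rsids)
        for name in ("beta_x", "se_x", "beta_y", "se_y", "eaf_x", "eaf_y"):
            if getattr(self, name).shape != (k,):
                raise ValueError(f"{name} length does not match {k} rsids")
        if k and (np.any(self.se_x <= 0) or np.any(self.se_y <= 0)):
            raise ValueError("standard errors must be positive")

    @property
    def n_snp(self) -> int:
        return len(self.rsids)

    def action_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for rec in self.actions:
            out[rec.action] = out.get(rec.action, 0) + 1
        return out

    def subset(self, rsids: Sequence[str]) -> "HarmonizedSet":
        """Restrict to ``rsids`` (order as given); audit trail not carried over."""
        index = {r: i for i, r in enumerate(self.rsids)}
        missing = [r for r in rsids if r not in index]
        if missing:
            raise KeyError(f"rsids absent from harmonized set: {missing}")
        idx = [index[r] for r in rsids]
        return HarmonizedSet(
            rsids=list(rsids),
            beta_x=self.beta_x[idx],
            se_x=self.se_x[idx],
            beta_y=self.beta_y[idx],
            se_y=self.se_y[idx],
            eaf_x=self.eaf_x[idx],
            eaf_y=self.eaf_y[idx],
            actions=[],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rsid": self.rsids,
                "beta_x": self.beta_x,
                "se_x": self.se_x,
                "beta_y": self.beta_y,
                "se_y": self.se_y,
                "eaf_x": self.eaf_x,
                "eaf_y": self.eaf_y,
            }
        )


#: canonical method identifiers, in reporting order
METHODS = (
    "ivw_canonical",
    "ivw_correlated",
    "egger_canonical",
    "egger_correlated",
    "weighted_median",
)


@dataclass
class MREstimate:
    """One method's causal-effect estimate for one exposure/outcome pair."""

    method: str
    n_snp: int
    log_or: float
    se: float
    ci_low: float
    ci_high: float
    or_value: float
    pvalue: float
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    outcome: str | None = None

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError("estimate se must be positive")
        if not (self.ci_low <= self.or_value <= self.ci_high):
            raise ValueError("CI does not bracket the odds ratio")


@dataclass
class SensitivityReport:
    """Cochran's Q and MR-Egger intercept diagnostics for one instrument set."""

    outcome: str
    instrument_set: str  # "canonical" | "all_snps"
    n_snp: int
    q_stat: float
    q_df: int
    q_p: float
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None


@dataclass(frozen=True)
class InstrumentStrength:
    """Per-variant instrument strength: explained variance and F-statistic."""

    rsid: str
    r2: float
    f_stat: float
    mode: str
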