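"""End-to-end orchestration: harmonize, clump, estimate five ways, diagnose.

For each outcome the pipeline:

1. reads and harmonizes the outcome against the exposure instruments;
2. derives the *canonical* instrument set by greedy LD clumping and keeps
   the full harmonized set as the *all-SNP* set;
3. produces up to five estimates — IVW and MR-Egger on the canonical set,
   their GLS (LD-aware) counterparts on the all-SNP set, and the weighted
   median on the canonical set;
4. computes heterogeneity/pleiotropy diagnostics for both sets;
5. flags Bonferroni significance at alpha / family_size.

Missing LD downgrades gracefully (correlated methods skipped with a
warning); fewer than three canonical instruments skips Egger and the
weighted median.  Output is a pure function of (input files, config,
seed); the same run twice writes byte-identical files.
"""
from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field

import yaml

from . import estimators, instruments, io, sensitivity
from .harmonize import harmonize
from .types import AuditRecord, LDMatrix, MREstimate, SensitivityReport

logger = logging.getLogger("mrkit")

__all__ = ["StudyConfig", "PipelineResult", "run_full_analysis", "write_outputs"]

#: forest-table outcome order used when the labels match the study design
_OUTCOME_ORDER = ("AS", "AIS", "CES", "LAS", "SVS")


@dataclass
class StudyConfig:
    """Parameters of one full analysis run.

    Defaults mirror the study design this package reproduces: clumping at
    r² < 0.01 within 10,000 kb, exposure N = 18,371, family-wise alpha
    0.05 over the (by default) five outcomes.
    """

    exposure_path: str
    outcome_paths: dict[str, str]
    ld_path: str | None = None
    exposure_n: int = io.CHB_EXPOSURE_N
    clump_r2: float = 0.01
    clump_window_kb: float = 10_000
    variance_model: str = "multiplicative_random"
    palindrome_policy: str = "infer_by_eaf"
    eaf_ambiguity_band: float = 0.08
    n_boot: int = 1000
    seed: int = 0
    alpha: float = 0.05
    family_size: int | None = None  # defaults to the number of outcomes
    ridge: float = 0.0

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "StudyConfig":
        """Load a flat key/value YAML config; keyword overrides win."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)


@dataclass
class PipelineResult:
    estimates: list[MREstimate]
    sensitivity: list[SensitivityReport]
    audit: list[AuditRecord]
    significant: dict[tuple[str, str], bool] = field(default_factory=dict)
    threshold: float = 0.0


def _ordered_outcomes(paths: dict[str, str]) -> list[tuple[str, str]]:
    known = [(k, paths[k]) for k in _OUTCOME_ORDER if k in paths]
    rest = [(k, v) for k, v in paths.items() if k not in _OUTCOME_ORDER]
    return known + rest


def run_full_analysis(config: StudyConfig) -> PipelineResult:
    """Run the full study described by ``config``."""
    exposure = io.read_exposure_instruments(config.exposure_path, n=config.exposure_n)
    exposure_rsids = {v.rsid for v in exposure}
    ld: LDMatrix | None = None
    if config.ld_path:
        ld = io.read_ld_matrix(config.ld_path)

    family = config.family_size or len(config.outcome_paths)
    threshold = sensitivity.bonferroni_threshold(config.alpha, family)

    estimates: list[MREstimate] = []
    reports: list[SensitivityReport] = []
    audit: list[AuditRecord] = []
    flags: dict[tuple[str, str], bool] = {}

    for idx, (label, path) in enumerate(_ordered_outcomes(config.outcome_paths)):
        outcome = io.read_outcome_summary(path, rsid_filter=exposure_rsids, label=label)
        h = harmonize(
            exposure, outcome,
            palindrome_policy=config.palindrome_policy,
            eaf_ambiguity_band=config.eaf_ambiguity_band,
        )
        audit.extend(AuditRecord(f"{label}:{a.rsid}", a.action, a.reason) for a in h.actions)
        logger.info("%s: harmonized %d/%d variants", label, h.n_snp, len(exposure))

        kept = instruments.ld_clump(
            [v for v in exposure if v.rsid in set(h.rsids)],
            ld if ld is not None else LDMatrix.identity(h.rsids),
            r2_threshold=config.clump_r2,
            window_kb=config.clump_window_kb,
        )
        h_canon = h.subset(kept)
        logger.info("%s: %d canonical instruments after clumping", label, h_canon.n_snp)

        out_est: list[MREstimate] = []
        out_est.append(estimators.ivw(h_canon, variance_model=config.variance_model))
        if ld is not None:
            out_est.append(
                estimators.ivw_correlated(
                    h, ld, variance_model=config.variance_model, ridge=config.ridge
                )
            )
        else:
            logger.warning("%s: no LD matrix; correlated-instrument methods skipped", label)
        if h_canon.n_snp >= 3:
            out_est.append(estimators.egger(h_canon, variance_model=config.variance_model))
        else:
            logger.warning("%s: fewer than 3 canonical instruments; Egger skipped", label)
        if ld is not None and h.n_snp >= 3:
            out_est.append(
                estimators.egger_correlated(
                    h, ld, variance_model=config.variance_model, ridge=config.ridge
                )
            )
        if h_canon.n_snp >= 3:
            out_est.append(
                estimators.weighted_median(
                    h_canon, n_boot=config.n_boot, seed=config.seed + idx
                )
            )
        else:
            logger.warning("%s: fewer than 3 canonical instruments; weighted median skipped", label)

        order = {m: i for i, m in enumerate(
            ("ivw_canonical", "ivw_correlated", "egger_canonical", "egger_correlated", "weighted_median")
        )}
        out_est.sort(key=lambda e: order[e.method])
        for e in out_est:
            e.outcome = label
            flags[(label, e.method)] = sensitivity.is_significant(e.pvalue, threshold)
        estimates.extend(out_est)

        if h_canon.n_snp >= 2:
            reports.append(sensitivity.sensitivity_report(h_canon, label, "canonical"))
        if ld is not None and h.n_snp >= 2:
            reports.append(sensitivity.sensitivity_report(h, label, "all_snps", ld=ld))

    return PipelineResult(
        estimates=estimates, sensitivity=reports, audit=audit,
        significant=flags, threshold=threshold,
    )


def write_outputs(result: PipelineResult, out_dir: str) -> dict[str, str]:
    """Write estimates.tsv, sensitivity.tsv and audit.log under ``out_dir``."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "estimates": os.path.join(out_dir, "estimates.tsv"),
        "sensitivity": os.path.join(out_dir, "sensitivity.tsv"),
        "audit": os.path.join(out_dir, "audit.log"),
    }
    io.write_estimates_table(result.estimates, paths["estimates"], significant=result.significant)
    io.write_sensitivity_table(result.sensitivity, paths["sensitivity"])
    io.write_audit_log(result.audit, paths["audit"])
    return paths
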