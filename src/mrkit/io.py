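"""Tabular I/O for summary statistics, LD matrices, and result tables.

All tables are tab-separated UTF-8 text with a header row.  Numeric values
are written with 12 significant digits so that a write/read round trip is
lossless at that precision.  Effects carried in odds-ratio columns are
converted to the log scale at parse time: every in-memory effect is a
log-odds.
"""
from __future__ import annotations

import logging
import math
import re
from importlib import resources
from os import PathLike
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .types import (
    InstrumentStrength,
    LDMatrix,
    LDValidationError,
    MREstimate,
    OutcomeDataset,
    SensitivityReport,
    VariantAssociation,
)

logger = logging.getLogger("mrkit")

__all__ = [
    "TableFormatError",
    "read_exposure_instruments",
    "load_chb_instruments",
    "CHB_EXPOSURE_N",
    "read_outcome_summary",
    "read_ld_matrix",
    "write_ld_matrix",
    "write_exposure_table",
    "write_outcome_table",
    "write_estimates_table",
    "read_estimates_table",
    "write_sensitivity_table",
    "write_audit_log",
    "write_strength_table",
]

#: exposure GWAS sample size attached to the packaged instrument table
#: (9114 chronic-hepatitis-B cases + 9257 controls)
CHB_EXPOSURE_N = 18371

_FLOAT_FMT = "%.12g"


class TableFormatError(ValueError):
    """A required column is missing or a cell cannot be parsed."""


_SCI_RE = re.compile(r"^([0-9]*\.?[0-9]+)[x×]10\^?(-?[0-9]+)\^?$")


def _parse_number(value, column: str, row: int) -> float:
    """Parse a numeric cell, accepting typeset scientific notation.

    Handles strings such as ``1.28 × 10−34`` (multiplication sign, unicode
    minus, superscript carets) in addition to ordinary float literals.
    """
    if isinstance(value, (int, float, np.integer, np.floating)):
        return float(value)
    s = str(value).strip().replace("−", "-").replace("×", "x").replace(" ", "")
    try:
        return float(s)
    except ValueError:
        pass
    m = _SCI_RE.match(s)
    if m:
        return float(m.group(1)) * 10.0 ** int(m.group(2))
    raise TableFormatError(f"cannot parse {column}={value!r} at data row {row}")


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, comment=None)


# ---------------------------------------------------------------------------
# exposure instruments


_EXPOSURE_COLUMNS = ("SNP", "Chr", "Position", "EAF", "EA", "OA", "Beta", "SE", "p")


def read_exposure_instruments(
    path: str | PathLike, n: int | None = None
) -> list[VariantAssociation]:
    """Read an exposure instrument table.

    The file must carry the header columns ``SNP Chr Position EAF EA OA
    Beta SE p`` (an optional ``N`` column overrides the shared ``n``
    argument per row).  Row order is preserved.

    Parameters
    ----------
    path
        Tab-separated instrument table.
    n
        Shared exposure sample size attached to every record when the file
        has no ``N`` column.
    """
    df = _read_tsv(path)
    missing = [c for c in _EXPOSURE_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"exposure table missing required column(s): {missing}")
    if df.empty:
        logger.warning("exposure table %s has a header but no data rows", path)
        return []
    records: list[VariantAssociation] = []
    has_n = "N" in df.columns
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = dict(zip(df.columns, row))
        records.append(
            VariantAssociation(
                rsid=str(row["SNP"]).strip(),
                chrom=str(row["Chr"]).strip(),
                pos=int(float(_parse_number(row["Position"], "Position", i))),
                eaf=_parse_number(row["EAF"], "EAF", i),
                effect_allele=str(row["EA"]).strip(),
                other_allele=str(row["OA"]).strip(),
                beta=_parse_number(row["Beta"], "Beta", i),
                se=_parse_number(row["SE"], "SE", i),
                pvalue=_parse_number(row["p"], "p", i),
                n=int(float(_parse_number(row["N"], "N", i))) if has_n else n,
            )
        )
    return records


def load_chb_instruments(n: int | None = CHB_EXPOSURE_N) -> list[VariantAssociation]:
    """The packaged table of 12 chronic-hepatitis-B-associated variants.

    Genome-wide significant instruments from an East Asian case/control
    GWAS of chronic hepatitis B (9114 cases, 9257 controls); 11 of the 12
    lie in the HLA region on chromosome 6.
    """
    with resources.as_file(
        resources.files("mrkit").joinpath("data/chb_instruments.tsv")
    ) as p:
        return read_exposure_instruments(p, n=n)


# ---------------------------------------------------------------------------
# outcome summary statistics


#: recognized header aliases, lower-cased; GWAS-Catalog harmonised names included
_OUTCOME_ALIASES: Mapping[str, tuple[str, ...]] = {
    "rsid": ("rsid", "snp", "hm_rsid", "variant_id", "markername", "id"),
    "effect_allele": ("effect_allele", "ea", "hm_effect_allele", "alt"),
    "other_allele": ("other_allele", "oa", "hm_other_allele", "ref", "non_effect_allele"),
    "beta": ("beta", "hm_beta", "effect", "b"),
    "or": ("or", "odds_ratio", "hm_odds_ratio"),
    "se": ("se", "standard_error", "stderr"),
    "pvalue": ("p", "pvalue", "p_value", "pval"),
    "eaf": ("eaf", "effect_allele_frequency", "hm_effect_allele_frequency", "af", "maf"),
    "chrom": ("chr", "chrom", "chromosome", "hm_chrom"),
    "pos": ("pos", "position", "base_pair_location", "hm_pos", "bp"),
    "n": ("n", "sample_size", "total_n"),
}

_OUTCOME_REQUIRED = ("rsid", "effect_allele", "other_allele", "se", "pvalue")


def _resolve_columns(
    columns: Sequence[str], aliases: Mapping[str, Sequence[str]] | None
) -> dict[str, str]:
    table = {k: tuple(v) for k, v in _OUTCOME_ALIASES.items()}
    if aliases:
        for key, names in aliases.items():
            extra = (names,) if isinstance(names, str) else tuple(names)
            table[key] = tuple(a.lower() for a in extra) + table.get(key, ())
    lower = {c.lower(): c for c in columns}
    resolved: dict[str, str] = {}
    for key, names in table.items():
        for name in names:
            if name in lower:
                resolved[key] = lower[name]
                break
    return resolved


def read_outcome_summary(
    path: str | PathLike,
    rsid_filter: set[str] | None = None,
    label: str | None = None,
    aliases: Mapping[str, Sequence[str]] | None = None,
) -> OutcomeDataset:
    """Read outcome GWAS summary statistics into an :class:`OutcomeDataset`.

    Column names are resolved through a case-insensitive alias table that
    recognizes GWAS-Catalog harmonised headers (``hm_rsid``,
    ``hm_effect_allele``, ``standard_error``, ``p_value``, ...).  A file
    carrying an odds-ratio column and no beta has its effects converted to
    log odds.  Records are restricted to ``rsid_filter`` when given; rsids
    absent from the file are simply not present in the result.
    """
    df = _read_tsv(path)
    cols = _resolve_columns(df.columns, aliases)
    missing = [k for k in _OUTCOME_REQUIRED if k not in cols]
    if missing:
        raise TableFormatError(
            f"outcome table {path} missing required column(s): {missing}; "
            f"found columns {list(df.columns)}"
        )
    if "beta" not in cols and "or" not in cols:
        raise TableFormatError(f"outcome table {path} has neither a beta nor an OR column")
    if label is None:
        label = re.sub(r"\.(tsv|txt|csv)$", "", str(getattr(path, "name", path)).split("/")[-1])

    records: list[VariantAssociation] = []
    for i, raw in enumerate(df.itertuples(index=False), start=1):
        row = dict(zip(df.columns, raw))
        rsid = str(row[cols["rsid"]]).strip()
        if rsid_filter is not None and rsid not in rsid_filter:
            continue
        if "beta" in cols and not _is_na(row[cols["beta"]]):
            beta = _parse_number(row[cols["beta"]], "beta", i)
        else:
            beta = math.log(_parse_number(row[cols["or"]], "OR", i))
        eaf = None
        if "eaf" in cols and not _is_na(row[cols["eaf"]]):
            eaf = _parse_number(row[cols["eaf"]], "eaf", i)
        records.append(
            VariantAssociation(
                rsid=rsid,
                effect_allele=str(row[cols["effect_allele"]]).strip(),
                other_allele=str(row[cols["other_allele"]]).strip(),
                beta=beta,
                se=_parse_number(row[cols["se"]], "se", i),
                pvalue=_parse_number(row[cols["pvalue"]], "p", i),
                eaf=eaf,
                chrom=str(row[cols["chrom"]]).strip() if "chrom" in cols and not _is_na(row[cols["chrom"]]) else None,
                pos=int(float(_parse_number(row[cols["pos"]], "pos", i))) if "pos" in cols and not _is_na(row[cols["pos"]]) else None,
                n=int(float(_parse_number(row[cols["n"]], "n", i))) if "n" in cols and not _is_na(row[cols["n"]]) else None,
            )
        )
    if not records:
        logger.warning("outcome table %s yielded zero records after filtering", path)
    return OutcomeDataset.from_records(label, records)


def _is_na(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value)) or str(value).strip() in ("", "NA", "nan", "NaN")


# ---------------------------------------------------------------------------
# LD matrices


def read_ld_matrix(path: str | PathLike) -> LDMatrix:
    """Read a square signed-correlation matrix with rsid headers.

    The first column must repeat the header rsids in the same order.
    Asymmetry within 1e-8 is symmetrized; anything beyond it, an
    off-unit diagonal, or |entry| > 1 raises :class:`LDValidationError`.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index.astype(str)) != [str(c) for c in df.columns]:
        raise LDValidationError(f"LD matrix {path}: row and column rsids differ")
    return LDMatrix(list(df.columns.astype(str)), df.to_numpy(dtype=float))


def write_ld_matrix(ld: LDMatrix, path: str | PathLike) -> None:
    ld.to_dataframe().to_csv(path, sep="\t", float_format=_FLOAT_FMT, index_label="")


# ---------------------------------------------------------------------------
# writers


def _write_df(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_exposure_table(records: Iterable[VariantAssociation], path) -> None:
    """Write records in the exposure-table layout (SNP/Chr/Position/...)."""
    rows = [
        {
            "SNP": v.rsid,
            "Chr": v.chrom,
            "Position": v.pos,
            "EAF": v.eaf,
            "EA": v.effect_allele,
            "OA": v.other_allele,
            "Beta": v.beta,
            "SE": v.se,
            "p": v.pvalue,
            "N": v.n,
        }
        for v in records
    ]
    _write_df(pd.DataFrame(rows, columns=["SNP", "Chr", "Position", "EAF", "EA", "OA", "Beta", "SE", "p", "N"]), path)


def write_outcome_table(dataset: OutcomeDataset, path) -> None:
    rows = [
        {
            "rsid": v.rsid,
            "effect_allele": v.effect_allele,
            "other_allele": v.other_allele,
            "eaf": v.eaf,
            "beta": v.beta,
            "se": v.se,
            "p": v.pvalue,
            "n": v.n,
        }
        for v in dataset.records.values()
    ]
    _write_df(
        pd.DataFrame(rows, columns=["rsid", "effect_allele", "other_allele", "eaf", "beta", "se", "p", "n"]),
        path,
    )


_ESTIMATE_COLUMNS = ["outcome", "method", "n_snp", "logOR", "SE", "OR", "CI_low", "CI_high", "p"]


def estimates_to_frame(estimates: Iterable[MREstimate]) -> pd.DataFrame:
    rows = [
        {
            "outcome": e.outcome or "",
            "method": e.method,
            "n_snp": e.n_snp,
            "logOR": e.log_or,
            "SE": e.se,
            "OR": e.or_value,
            "CI_low": e.ci_low,
            "CI_high": e.ci_high,
            "p": e.pvalue,
        }
        for e in estimates
    ]
    return pd.DataFrame(rows, columns=_ESTIMATE_COLUMNS)


def write_estimates_table(
    estimates: Iterable[MREstimate], path, significant: Mapping[tuple[str, str], bool] | None = None
) -> None:
    """Write one row per (outcome, method) in a forest-table layout.

    ``significant`` optionally maps (outcome, method) to a Bonferroni flag,
    written as an extra ``bonferroni_significant`` column.
    """
    estimates = list(estimates)
    df = estimates_to_frame(estimates)
    if significant is not None:
        df["bonferroni_significant"] = [
            bool(significant.get((e.outcome or "", e.method), False)) for e in estimates
        ]
    if df.empty:
        logger.warning("writing empty estimates table to %s", path)
    _write_df(df, path)


def read_estimates_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _ESTIMATE_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"estimates table missing column(s): {missing}")
    return df


def write_sensitivity_table(reports: Iterable[SensitivityReport], path) -> None:
    """Write pleiotropy/heterogeneity diagnostics, one row per outcome.

    Column groups hold the canonical (clumped) and all-SNP instrument
    sets side by side, pairing each Egger intercept with its p-value and
    each Cochran's Q with its df and p-value.
    """
    by_outcome: dict[str, dict[str, SensitivityReport]] = {}
    for rep in reports:
        by_outcome.setdefault(rep.outcome, {})[rep.instrument_set] = rep
    rows = []
    for outcome, sets in by_outcome.items():
        row: dict[str, object] = {"outcome": outcome}
        for key in ("canonical", "all_snps"):
            rep = sets.get(key)
            row[f"{key}_n_snp"] = rep.n_snp if rep else None
            row[f"{key}_intercept"] = rep.egger_intercept if rep else None
            row[f"{key}_intercept_p"] = rep.egger_intercept_p if rep else None
            row[f"{key}_Q"] = rep.q_stat if rep else None
            row[f"{key}_Q_df"] = rep.q_df if rep else None
            row[f"{key}_Q_p"] = rep.q_p if rep else None
        rows.append(row)
    _write_df(pd.DataFrame(rows), path)


def write_audit_log(records, path) -> None:
    """Tab-separated harmonization/clumping audit: rsid, action, reason."""
    rows = [{"rsid": r.rsid, "action": r.action, "reason": r.reason} for r in records]
    _write_df(pd.DataFrame(rows, columns=["rsid", "action", "reason"]), path)


def write_strength_table(strengths: Iterable[InstrumentStrength], path) -> None:
    rows = [{"rsid": s.rsid, "r2": s.r2, "F": s.f_stat, "mode": s.mode} for s in strengths]
    _write_df(pd.DataFrame(rows, columns=["rsid", "r2", "F", "mode"]), path)
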