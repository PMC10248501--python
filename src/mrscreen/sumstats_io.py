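"""Reading, validation, and writing of GWAS summary-statistic tables.

Input tables are delimited text (TSV/CSV, optionally gzipped) with a header
row; arbitrary column names are absorbed by a :class:`ColumnMap`.  Parsing is
total: every call returns the valid records together with a
:class:`ReadReport` describing each rejected or deduplicated row, never a
partial silent result.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .exceptions import ConfigurationError, DomainError, EmptyInputError, InputError

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")

#: canonical field names recognised by :class:`ColumnMap`
CANONICAL_FIELDS = ("snp", "chr", "pos", "ea", "oa", "eaf", "beta", "se", "p", "n")
MANDATORY_FIELDS = ("snp", "ea", "oa", "beta", "se")


@dataclass(frozen=True)
class SummaryStatRecord:
    """One SNP's association with one trait.

    ``beta`` is on the per-effect-allele scale: per-SD units for a continuous
    exposure, log-odds for a binary outcome.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    eaf: float | None = None
    pvalue: float | None = None
    n: int | None = None


@dataclass(frozen=True)
class ColumnMap:
    """Maps canonical field names to the column headers of an input file.

    ``snp``, ``ea``, ``oa``, ``beta``, ``se`` are mandatory; the rest are
    optional and default to absent.
    """

    snp: str = "snp"
    ea: str = "effect_allele"
    oa: str = "other_allele"
    beta: str = "beta"
    se: str = "se"
    chr: str | None = "chr"
    pos: str | None = "pos"
    eaf: str | None = "eaf"
    p: str | None = "pvalue"
    n: str | None = "n"
    delimiter: str = "\t"
    na_token: str = "NA"

    @classmethod
    def from_dict(cls, mapping: Mapping[str, str | None]) -> "ColumnMap":
        unknown = set(mapping) - set(CANONICAL_FIELDS) - {"delimiter", "na_token"}
        if unknown:
            raise ConfigurationError(f"unknown column-map keys: {sorted(unknown)}")
        missing = [f for f in MANDATORY_FIELDS if not mapping.get(f)]
        if missing:
            raise ConfigurationError(f"column map lacks mandatory fields: {missing}")
        return cls(**mapping)  # type: ignore[arg-type]


@dataclass(frozen=True)
class StudyMeta:
    """Study-level metadata: trait name, fallback sample size, trait type."""

    trait_name: str
    default_n: int | None = None
    trait_type: str = "continuous"

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ConfigurationError(f"trait_type must be continuous|binary, got {self.trait_type!r}")
        if self.default_n is not None and self.default_n < 3:
            raise ConfigurationError("default_n must be >= 3")


@dataclass
class ReadReport:
    """Per-file parse accounting: valid, rejected, and deduplicated rows."""

    n_rows: int = 0
    n_valid: int = 0
    n_rejected: int = 0
    n_duplicates_dropped: int = 0
    rejections: list[tuple[int, str]] = field(default_factory=list)  # (row index, reason)
    duplicates: list[str] = field(default_factory=list)  # snp ids with dropped copies


def derive_pvalue(beta: float, se: float) -> float:
    """Two-sided p-value 2*Phi(-|beta/se|) from an effect and its SE."""
    if se <= 0:
        raise DomainError(f"se must be > 0, got {se}")
    return float(min(1.0, 2.0 * norm.sf(abs(beta) / se)))


def _parse_row(
    row: Mapping[str, object], cm: ColumnMap, meta: StudyMeta
) -> tuple[SummaryStatRecord | None, str | None]:
    """Validate one raw row. Returns (record, None) or (None, reason)."""

    def get(canon: str):
        col = getattr(cm, canon)
        if col is None or col not in row:
            return None
        val = row[col]
        if val is None or (isinstance(val, float) and math.isnan(val)):
            return None
        if isinstance(val, str) and (val == cm.na_token or val == ""):
            return None
        return val

    snp_id = get("snp")
    if snp_id is None:
        return None, "missing snp id"
    snp_id = str(snp_id)

    ea, oa = get("ea"), get("oa")
    if ea is None or oa is None:
        return None, "missing allele"
    ea, oa = str(ea).upper(), str(oa).upper()
    if ea not in VALID_ALLELES or oa not in VALID_ALLELES:
        return None, f"non-SNV alleles {ea}/{oa}"
    if ea == oa:
        return None, "identical alleles"

    try:
        beta = float(get("beta"))  # type: ignore[arg-type]
        se = float(get("se"))  # type: ignore[arg-type]
    except (TypeError, ValueError):
        return None, "non-numeric beta/se"
    if not (math.isfinite(beta) and math.isfinite(se)):
        return None, "non-finite beta/se"
    if se <= 0:
        return None, f"se must be > 0, got {se}"

    chrom = get("chr")
    chrom = str(chrom) if chrom is not None else ""
    pos_raw = get("pos")
    pos = 0
    if pos_raw is not None:
        try:
            pos = int(float(pos_raw))  # type: ignore[arg-type]
        except (TypeError, ValueError):
            return None, "non-numeric position"
        if pos < 1:
            return None, f"position must be >= 1, got {pos}"

    eaf_raw = get("eaf")
    eaf = None
    if eaf_raw is not None:
        try:
            eaf = float(eaf_raw)  # type: ignore[arg-type]
        except (TypeError, ValueError):
            return None, "non-numeric eaf"
        if not (0.0 <= eaf <= 1.0):
            return None, f"eaf outside [0,1]: {eaf}"

    p_raw = get("p")
    if p_raw is not None:
        try:
            pvalue = float(p_raw)  # type: ignore[arg-type]
        except (TypeError, ValueError):
            return None, "non-numeric p"
        if not (0.0 < pvalue <= 1.0):
            return None, f"p outside (0,1]: {pvalue}"
        expected = derive_pvalue(beta, se)
        # published p are often truncated: warn (never reject) beyond two-fold
        if expected > 0 and not (0.5 <= pvalue / expected <= 2.0):
            logger.warning(
                "%s: stored p=%.3g disagrees with 2*Phi(-|beta/se|)=%.3g beyond two-fold",
                snp_id, pvalue, expected,
            )
    else:
        pvalue = derive_pvalue(beta, se)

    n_raw = get("n")
    if n_raw is not None:
        try:
            n = int(float(n_raw))  # type: ignore[arg-type]
        except (TypeError, ValueError):
            return None, "non-numeric n"
        if n < 1:
            return None, f"n must be positive, got {n}"
    else:
        n = meta.default_n

    return (
        SummaryStatRecord(
            snp_id=snp_id, chrom=chrom, pos=pos, effect_allele=ea, other_allele=oa,
            beta=beta, se=se, eaf=eaf, pvalue=pvalue, n=n,
        ),
        None,
    )


def read_summary_stats(
    path: str | Path, column_map: ColumnMap | None = None, meta: StudyMeta | None = None
) -> tuple[list[SummaryStatRecord], ReadReport]:
    """Read a summary-statistics table into validated records.

    Rows violating record invariants are rejected and logged in the report.
    Duplicate SNP ids are resolved by keeping the smallest p (ties: first
    occurrence).  Raises :class:`ConfigurationError` when a mandatory column
    is absent from the header and :class:`EmptyInputError` when no valid row
    survives.
    """
    cm = column_map or ColumnMap()
    meta = meta or StudyMeta(trait_name=str(path))
    df = pd.read_csv(path, sep=cm.delimiter, dtype=str, na_values=[cm.na_token], keep_default_na=False)

    missing = [getattr(cm, f) for f in MANDATORY_FIELDS if getattr(cm, f) not in df.columns]
    if missing:
        raise ConfigurationError(f"{path}: mandatory columns missing from header: {missing}")

    report = ReadReport(n_rows=len(df))
    by_snp: dict[str, SummaryStatRecord] = {}
    order: list[str] = []
    for idx, row in enumerate(df.to_dict("records")):
        rec, reason = _parse_row(row, cm, meta)
        if rec is None:
            report.n_rejected += 1
            report.rejections.append((idx, reason or "invalid"))
            logger.info("%s row %d rejected: %s", path, idx, reason)
            continue
        prev = by_snp.get(rec.snp_id)
        if prev is None:
            by_snp[rec.snp_id] = rec
            order.append(rec.snp_id)
        else:
            report.n_duplicates_dropped += 1
            report.duplicates.append(rec.snp_id)
            # keep smallest p; ties keep the first occurrence
            if rec.pvalue is not None and prev.pvalue is not None and rec.pvalue < prev.pvalue:
                by_snp[rec.snp_id] = rec
            logger.info("%s: duplicate snp_id %s, kept p=%.3g", path, rec.snp_id, by_snp[rec.snp_id].pvalue)

    records = [by_snp[s] for s in order]
    report.n_valid = len(records)
    if not records:
        raise EmptyInputError(f"{path}: no valid rows")
    return records, report


def records_to_frame(records: Iterable[SummaryStatRecord]) -> pd.DataFrame:
    """Render records as a canonical DataFrame (stable column order)."""
    return pd.DataFrame(
        [
            {
                "snp": r.snp_id, "chr": r.chrom, "pos": r.pos,
                "effect_allele": r.effect_allele, "other_allele": r.other_allele,
                "eaf": r.eaf, "beta": r.beta, "se": r.se, "pvalue": r.pvalue, "n": r.n,
            }
            for r in records
        ],
        columns=["snp", "chr", "pos", "effect_allele", "other_allele", "eaf", "beta", "se", "pvalue", "n"],
    )


def write_table(
    rows: Sequence[Mapping[str, object]],
    path: str | Path,
    columns: Sequence[str],
    sig_figs: int = 6,
) -> None:
    """Write records to a deterministic TSV (UTF-8, Unix newlines).

    Floats are rendered at ``sig_figs`` significant figures so that a
    write-then-read round trip reproduces values to that precision.
    """
    for i, row in enumerate(rows):
        missing = [c for c in columns if c not in row]
        if missing:
            raise InputError(f"row {i} lacks columns {missing}")
    fmt = f"%.{sig_figs}g"

    def render(value: object) -> str:
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return "NA"
        if isinstance(value, bool) or isinstance(value, np.bool_):
            return "True" if value else "False"
        if isinstance(value, (float, np.floating)):
            return fmt % value
        return str(value)

    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(render(row[c]) for c in columns) + "\n")
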