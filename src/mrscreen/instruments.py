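"""Instrument selection: p-value threshold, greedy LD clumping,
instrument-strength (R^2, F) filtering, and confounder-SNP exclusion."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .exceptions import DomainError, InputError
from .sumstats_io import StudyMeta, SummaryStatRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds for instrument selection.

    All three cutoffs are strict in the stated direction: records with
    p < ``p_threshold`` are kept, pairs with r^2 < ``r2_max`` survive
    clumping, and records with F < ``f_min`` are eliminated (F == f_min is
    kept).
    """

    p_threshold: float = 1e-5
    r2_max: float = 0.1
    window_kb: float = 500.0
    f_min: float = 10.0

    def __post_init__(self) -> None:
        if not (0.0 < self.p_threshold < 1.0):
            raise DomainError(f"p_threshold must be in (0,1), got {self.p_threshold}")
        if not (0.0 <= self.r2_max <= 1.0):
            raise DomainError(f"r2_max must be in [0,1], got {self.r2_max}")
        if self.window_kb <= 0:
            raise DomainError(f"window_kb must be > 0, got {self.window_kb}")
        if self.f_min < 0:
            raise DomainError(f"f_min must be >= 0, got {self.f_min}")


class LDTable:
    """Symmetric pairwise r^2 lookup; absent pairs have r^2 = 0."""

    def __init__(self, pairs: Iterable[tuple[str, str, float]] = ()) -> None:
        self._r2: dict[frozenset[str], float] = {}
        for a, b, r2 in pairs:
            self.set(a, b, r2)

    def set(self, a: str, b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise DomainError(f"r2 must be in [0,1], got {r2} for ({a},{b})")
        if a == b:
            if r2 != 1.0:
                raise DomainError(f"r2({a},{a}) must be 1, got {r2}")
            return
        self._r2[frozenset((a, b))] = r2

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(frozenset((a, b)), 0.0)

    def __len__(self) -> int:
        return len(self._r2)

    def items(self) -> list[tuple[str, str, float]]:
        """Stored off-diagonal pairs as sorted (snp_a, snp_b, r2) triples."""
        return sorted((min(pair), max(pair), r2) for pair, r2 in self._r2.items())

    @classmethod
    def from_file(cls, path: str | Path) -> "LDTable":
        """Load a long-format TSV with columns snp_a, snp_b, r2."""
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        needed = {"snp_a", "snp_b", "r2"}
        if not needed.issubset(df.columns):
            raise InputError(f"{path}: LD table needs columns {sorted(needed)}")
        return cls(zip(df["snp_a"].astype(str), df["snp_b"].astype(str), df["r2"].astype(float)))


@dataclass(frozen=True)
class InstrumentStrength:
    """Per-SNP explained variance and F statistic."""

    snp_id: str
    r_squared: float
    f_stat: float
    n: int


def select_by_pvalue(
    records: Sequence[SummaryStatRecord], p_threshold: float
) -> list[SummaryStatRecord]:
    """Keep records with p strictly below the threshold, preserving order."""
    return [r for r in records if r.pvalue is not None and r.pvalue < p_threshold]


def ld_clump(
    records: Sequence[SummaryStatRecord], ld: LDTable, config: SelectionConfig
) -> list[SummaryStatRecord]:
    """Greedy LD clumping.

    Candidates are ranked by ascending p (ties: chrom, pos, snp_id).  The best
    remaining SNP becomes an index; every remaining SNP on the same chromosome
    within ``window_kb`` kb (pos-to-pos, inclusive) and with r^2 >= ``r2_max``
    against it is discarded.  Different chromosomes never prune each other.
    Output sorted by (chrom, pos).
    """
    for r in records:
        if not r.chrom or r.pos < 1:
            raise InputError(f"{r.snp_id}: clumping requires chrom and pos")

    window_bp = config.window_kb * 1000.0
    pool = sorted(records, key=lambda r: (r.pvalue, r.chrom, r.pos, r.snp_id))
    kept: list[SummaryStatRecord] = []
    while pool:
        index = pool.pop(0)
        kept.append(index)
        pool = [
            r
            for r in pool
            if not (
                r.chrom == index.chrom
                and abs(r.pos - index.pos) <= window_bp
                and ld.r2(r.snp_id, index.snp_id) >= config.r2_max
            )
        ]
    return sorted(kept, key=lambda r: (r.chrom, r.pos, r.snp_id))


def explained_variance(beta: float, se: float, n: int) -> float:
    """Variance of the exposure explained by one SNP: b^2 / (b^2 + se^2 * N)."""
    if se <= 0:
        raise DomainError(f"se must be > 0, got {se}")
    if n < 3:
        raise DomainError(f"n must be >= 3, got {n}")
    b2 = beta * beta
    return b2 / (b2 + se * se * n)


def f_statistic(r_squared: float, n: int) -> float:
    """Instrument-strength F statistic: R^2 / (1 - R^2) * (N - 2)."""
    if not (0.0 <= r_squared < 1.0):
        raise DomainError(f"r_squared must be in [0,1), got {r_squared}")
    if n < 3:
        raise DomainError(f"n must be >= 3, got {n}")
    return r_squared / (1.0 - r_squared) * (n - 2)


def filter_weak_instruments(
    records: Sequence[SummaryStatRecord], meta: StudyMeta, config: SelectionConfig
) -> tuple[list[SummaryStatRecord], list[InstrumentStrength]]:
    """Eliminate records with F < ``config.f_min``; return kept records and
    the per-record strengths (for all inputs, kept or not)."""
    kept: list[SummaryStatRecord] = []
    strengths: list[InstrumentStrength] = []
    for r in records:
        n = r.n if r.n is not None else meta.default_n
        if n is None:
            raise InputError(f"{r.snp_id}: no per-SNP n and no default_n in study metadata")
        r2 = explained_variance(r.beta, r.se, n)
        f = f_statistic(r2, n)
        strengths.append(InstrumentStrength(snp_id=r.snp_id, r_squared=r2, f_stat=f, n=n))
        if f >= config.f_min:
            kept.append(r)
        else:
            logger.info("%s eliminated as weak instrument (F=%.3g < %.3g)", r.snp_id, f, config.f_min)
    return kept, strengths


def filter_excluded(
    records: Sequence[SummaryStatRecord], exclusion_ids: set[str]
) -> list[SummaryStatRecord]:
    """Remove records whose snp_id appears in the exclusion set."""
    present = {r.snp_id for r in records}
    for missing in sorted(exclusion_ids - present):
        logger.warning("exclusion id %s not present in input", missing)
    kept = [r for r in records if r.snp_id not in exclusion_ids]
    for r in records:
        if r.snp_id in exclusion_ids:
            logger.info("%s removed by exclusion list", r.snp_id)
    return kept


def read_exclusion_list(path: str | Path) -> set[str]:
    """One snp_id per line; '#' starts a comment; blank lines ignored."""
    ids: set[str] = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        entry = line.split("#", 1)[0].strip()
        if entry:
            ids.add(entry)
    return ids


@dataclass
class SelectionResult:
    """Outcome of the full selection pipeline for one exposure."""

    records: list[SummaryStatRecord]
    strengths: list[InstrumentStrength]
    n_input: int = 0
    n_after_pvalue: int = 0
    n_after_clump: int = 0
    n_after_strength: int = 0
    n_after_exclusion: int = 0
    log: list[str] = field(default_factory=list)


def select_instruments(
    records: Sequence[SummaryStatRecord],
    meta: StudyMeta,
    config: SelectionConfig,
    ld: LDTable | None = None,
    exclusions: set[str] | None = None,
) -> SelectionResult:
    """Run p-value filter -> LD clump -> F filter -> exclusion list."""
    ld = ld or LDTable()
    exclusions = exclusions or set()
    sig = select_by_pvalue(records, config.p_threshold)
    clumped = ld_clump(sig, ld, config)
    strong, strengths = filter_weak_instruments(clumped, meta, config)
    final = filter_excluded(strong, exclusions)
    return SelectionResult(
        records=final,
        strengths=strengths,
        n_input=len(records),
        n_after_pvalue=len(sig),
        n_after_clump=len(clumped),
        n_after_strength=len(strong),
        n_after_exclusion=len(final),
    )
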