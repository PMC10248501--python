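"""Harmonization of exposure and outcome summary statistics onto a common
effect allele, resolving allele swaps, strand flips, and palindromic SNPs."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

from .exceptions import InputError
from .sumstats_io import SummaryStatRecord

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: default half-width of the EAF band around 0.5 inside which a palindromic
#: SNP's orientation is considered unresolvable
DEFAULT_PALINDROME_TOLERANCE = 0.08


@dataclass(frozen=True)
class HarmonizationFlags:
    swapped: bool = False
    strand_flipped: bool = False
    palindromic: bool = False


@dataclass(frozen=True)
class HarmonizedInstrument:
    """One SNP's exposure and outcome effects expressed on a single effect
    allele (the exposure's)."""

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: float | None = None
    eaf_out: float | None = None
    flags: HarmonizationFlags = HarmonizationFlags()


@dataclass
class HarmonizationReport:
    """Counts and per-SNP action log; counts always reconcile with the input."""

    n_input: int = 0
    n_harmonized: int = 0
    n_dropped_unmatched: int = 0
    n_dropped_palindromic_ambiguous: int = 0
    n_dropped_incompatible: int = 0
    actions: list[tuple[str, str]] = field(default_factory=list)  # (snp_id, action)

    def record(self, snp_id: str, action: str) -> None:
        self.actions.append((snp_id, action))


def is_palindromic(allele_a: str, allele_b: str) -> bool:
    """True for A/T and C/G pairs, whose strand cannot be read off alleles."""
    return _COMPLEMENT.get(allele_a) == allele_b


def _complement_pair(ea: str, oa: str) -> tuple[str, str]:
    return _COMPLEMENT[ea], _COMPLEMENT[oa]


def harmonize_pair(
    exp: SummaryStatRecord,
    out: SummaryStatRecord,
    tolerance: float = DEFAULT_PALINDROME_TOLERANCE,
    drop_all_palindromic: bool = False,
) -> tuple[HarmonizedInstrument | None, str]:
    """Align one outcome record onto the exposure's effect allele.

    Returns ``(instrument, "harmonized")`` on success, or ``(None, reason)``
    with reason ``"palindromic_ambiguous"`` or ``"incompatible"``.

    Decision procedure: same-orientation alleles pass through; swapped alleles
    negate the outcome beta; non-palindromic pairs matching only after
    complementing the outcome alleles are treated as strand flips; palindromic
    pairs are oriented by comparing effect-allele frequencies and dropped when
    either frequency is missing or within ``tolerance`` of 0.5.
    """
    if exp.snp_id != out.snp_id:
        raise InputError(f"snp_id mismatch: {exp.snp_id} vs {out.snp_id}")

    exp_ea, exp_oa = exp.effect_allele, exp.other_allele
    out_ea, out_oa = out.effect_allele, out.other_allele
    beta_out, eaf_out = out.beta, out.eaf
    swapped = strand_flipped = False

    if is_palindromic(exp_ea, exp_oa):
        if drop_all_palindromic:
            return None, "palindromic_ambiguous"
        if {out_ea, out_oa} != {exp_ea, exp_oa}:
            return None, "incompatible"
        if out_ea != exp_ea:  # nominal swap before the frequency check
            beta_out = -beta_out
            eaf_out = None if eaf_out is None else 1.0 - eaf_out
            swapped = True
        if exp.eaf is None or eaf_out is None:
            return None, "palindromic_ambiguous"
        if abs(exp.eaf - 0.5) <= tolerance or abs(eaf_out - 0.5) <= tolerance:
            return None, "palindromic_ambiguous"
        if (exp.eaf - 0.5) * (eaf_out - 0.5) < 0:  # frequencies disagree: flip strand
            beta_out = -beta_out
            eaf_out = 1.0 - eaf_out
            strand_flipped = True
        flags = HarmonizationFlags(swapped=swapped, strand_flipped=strand_flipped, palindromic=True)
    else:
        if (out_ea, out_oa) == (exp_ea, exp_oa):
            pass
        elif (out_ea, out_oa) == (exp_oa, exp_ea):
            beta_out = -beta_out
            eaf_out = None if eaf_out is None else 1.0 - eaf_out
            swapped = True
        else:
            comp = _complement_pair(out_ea, out_oa)
            if comp == (exp_ea, exp_oa):
                strand_flipped = True
            elif comp == (exp_oa, exp_ea):
                beta_out = -beta_out
                eaf_out = None if eaf_out is None else 1.0 - eaf_out
                swapped = True
                strand_flipped = True
            else:
                return None, "incompatible"
        flags = HarmonizationFlags(swapped=swapped, strand_flipped=strand_flipped, palindromic=False)

    return (
        HarmonizedInstrument(
            snp_id=exp.snp_id, chrom=exp.chrom, pos=exp.pos,
            effect_allele=exp_ea, other_allele=exp_oa,
            beta_exp=exp.beta, se_exp=exp.se,
            beta_out=beta_out, se_out=out.se,
            eaf_exp=exp.eaf, eaf_out=eaf_out, flags=flags,
        ),
        "harmonized",
    )


def harmonize_all(
    exp_records: Sequence[SummaryStatRecord],
    out_records: Sequence[SummaryStatRecord],
    tolerance: float = DEFAULT_PALINDROME_TOLERANCE,
    drop_all_palindromic: bool = False,
) -> tuple[list[HarmonizedInstrument], HarmonizationReport]:
    """Join exposure and outcome records on snp_id and harmonize each pair.

    Exposure SNPs absent from the outcome are dropped as unmatched.  Output is
    sorted by (chrom, pos, snp_id); the report's counts always reconcile:
    n_input == n_harmonized + sum of drops.
    """
    out_by_id = {r.snp_id: r for r in out_records}
    report = HarmonizationReport(n_input=len(exp_records))
    harmonized: list[HarmonizedInstrument] = []
    for exp in exp_records:
        out = out_by_id.get(exp.snp_id)
        if out is None:
            report.n_dropped_unmatched += 1
            report.record(exp.snp_id, "dropped_unmatched")
            continue
        inst, action = harmonize_pair(exp, out, tolerance, drop_all_palindromic)
        if inst is None:
            if action == "palindromic_ambiguous":
                report.n_dropped_palindromic_ambiguous += 1
            else:
                report.n_dropped_incompatible += 1
            report.record(exp.snp_id, f"dropped_{action}")
            continue
        harmonized.append(inst)
        report.record(exp.snp_id, action)
    report.n_harmonized = len(harmonized)
    harmonized.sort(key=lambda h: (h.chrom, h.pos, h.snp_id))
    return harmonized, report


def reorient(inst: HarmonizedInstrument) -> HarmonizedInstrument:
    """Express an instrument on the opposite effect allele (test utility)."""
    return replace(
        inst,
        effect_allele=inst.other_allele,
        other_allele=inst.effect_allele,
        beta_exp=-inst.beta_exp,
        beta_out=-inst.beta_out,
        eaf_exp=None if inst.eaf_exp is None else 1.0 - inst.eaf_exp,
        eaf_out=None if inst.eaf_out is None else 1.0 - inst.eaf_out,
    )
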