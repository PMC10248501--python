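"""Shared fixtures and record factories."""

from __future__ import annotations

import pytest

from mrscreen.harmonize import HarmonizedInstrument
from mrscreen.sumstats_io import SummaryStatRecord


def make_record(
    snp_id: str = "rs1",
    chrom: str = "1",
    pos: int = 1_000_000,
    ea: str = "A",
    oa: str = "G",
    beta: float = 0.1,
    se: float = 0.02,
    eaf: float | None = 0.3,
    pvalue: float | None = None,
    n: int | None = 18_340,
) -> SummaryStatRecord:
    from mrscreen.sumstats_io import derive_pvalue

    return SummaryStatRecord(
        snp_id=snp_id, chrom=chrom, pos=pos, effect_allele=ea, other_allele=oa,
        beta=beta, se=se, eaf=eaf,
        pvalue=pvalue if pvalue is not None else derive_pvalue(beta, se), n=n,
    )


def make_inst(
    snp_id: str = "rs1",
    beta_exp: float = 1.0,
    se_exp: float = 0.01,
    beta_out: float = 0.2,
    se_out: float = 0.1,
    chrom: str = "1",
    pos: int = 1_000_000,
) -> HarmonizedInstrument:
    return HarmonizedInstrument(
        snp_id=snp_id, chrom=chrom, pos=pos, effect_allele="A", other_allele="G",
        beta_exp=beta_exp, se_exp=se_exp, beta_out=beta_out, se_out=se_out,
        eaf_exp=0.3, eaf_out=0.3,
    )


@pytest.fixture
def ivw_fixture_pair() -> list[HarmonizedInstrument]:
    """Two instruments with Wald ratios (0.2, se 0.1) and (0.6, se 0.2)."""
    return [
        make_inst("rs1", beta_exp=1.0, beta_out=0.2, se_out=0.1),
        make_inst("rs2", beta_exp=1.0, beta_out=0.6, se_out=0.2, pos=2_000_000),
    ]


@pytest.fixture
def egger_fixture_triplet() -> list[HarmonizedInstrument]:
    """Perfect-fit 3-point Egger design: slope 0.5, intercept 0.1."""
    return [
        make_inst("rs1", beta_exp=1.0, beta_out=0.6, se_out=0.1, pos=1_000_000),
        make_inst("rs2", beta_exp=2.0, beta_out=1.1, se_out=0.1, pos=2_000_000),
        make_inst("rs3", beta_exp=3.0, beta_out=1.6, se_out=0.1, pos=3_000_000),
    ]
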