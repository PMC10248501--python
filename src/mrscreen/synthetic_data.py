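"""Synthetic GWAS summary statistics with known ground truth.

Simulation is at the summary-statistic level: per-SNP true exposure effects
gamma_j, optional direct (pleiotropic) outcome effects alpha_j, a true causal
effect theta, and observed effect estimates drawn around the truth with
standard errors set by allele frequency and sample size,
se = (2*maf*(1-maf)*N)^(-1/2).  Direct effects are drawn independently of
gamma_j by default, so the InSIDE condition holds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import ConfigurationError
from .instruments import LDTable
from .sumstats_io import SummaryStatRecord, derive_pvalue

_NONPALINDROMIC_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]
_PALINDROMIC_PAIRS = [("A", "T"), ("C", "G")]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the generative model for one simulated two-sample study."""

    n_snps: int = 30
    theta: float = 0.0
    gamma_mean: float = 0.15
    gamma_sd: float = 0.03
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    invalid_fraction: float = 0.0
    n_exposure: int = 20_000
    n_outcome: int = 45_000
    maf_low: float = 0.1
    maf_high: float = 0.5
    palindromic_fraction: float = 0.0
    noise_scale: float = 1.0  # 0 gives the noiseless analytic limit
    correlate_pleiotropy: bool = False  # True violates InSIDE (alpha_j ∝ gamma_j + noise)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ConfigurationError(f"n_snps must be >= 1, got {self.n_snps}")
        if not (0.0 <= self.invalid_fraction <= 1.0):
            raise ConfigurationError(f"invalid_fraction must be in [0,1], got {self.invalid_fraction}")
        if not (0.0 < self.maf_low <= self.maf_high <= 0.5):
            raise ConfigurationError(f"need 0 < maf_low <= maf_high <= 0.5, got [{self.maf_low},{self.maf_high}]")
        if not (0.0 <= self.palindromic_fraction <= 1.0):
            raise ConfigurationError("palindromic_fraction must be in [0,1]")
        if self.n_exposure < 3 or self.n_outcome < 3:
            raise ConfigurationError("sample sizes must be >= 3")
        if self.noise_scale < 0:
            raise ConfigurationError("noise_scale must be >= 0")


@dataclass
class SimulationTruth:
    theta: float
    gamma: np.ndarray  # true SNP -> exposure effects
    alpha: np.ndarray  # true direct SNP -> outcome effects
    invalid_ids: list[str] = field(default_factory=list)


@dataclass
class SimulatedStudy:
    exposure_stats: list[SummaryStatRecord]
    outcome_stats: list[SummaryStatRecord]
    truth: SimulationTruth
    ld: LDTable


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Draw one simulated two-sample study; fully reproducible given the seed.

    The true outcome effect of SNP j is theta*gamma_j + alpha_j; alpha_j is
    zero for valid instruments and Normal(pleiotropy_mean, pleiotropy_sd^2)
    for the invalid fraction.  Outcome records carry a randomized allele
    orientation (swapped EA/OA with the beta negated) so harmonization is
    exercised end to end.
    """
    rng = np.random.default_rng(config.seed)
    j = config.n_snps

    maf = rng.uniform(config.maf_low, config.maf_high, size=j)
    gamma = rng.normal(config.gamma_mean, config.gamma_sd, size=j)
    n_invalid = int(round(config.invalid_fraction * j))
    invalid = np.zeros(j, dtype=bool)
    if n_invalid:
        invalid[rng.choice(j, size=n_invalid, replace=False)] = True
    alpha = np.zeros(j)
    if n_invalid:
        direct = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, size=n_invalid)
        if config.correlate_pleiotropy:
            direct = direct + 0.5 * (gamma[invalid] - config.gamma_mean)
        alpha[invalid] = direct
    big_gamma = config.theta * gamma + alpha  # true outcome effects

    se_exp = (2.0 * maf * (1.0 - maf) * config.n_exposure) ** -0.5
    se_out = (2.0 * maf * (1.0 - maf) * config.n_outcome) ** -0.5
    beta_exp = gamma + config.noise_scale * rng.normal(size=j) * se_exp
    beta_out = big_gamma + config.noise_scale * rng.normal(size=j) * se_out

    is_pal = rng.random(j) < config.palindromic_fraction
    pal_idx = rng.integers(0, len(_PALINDROMIC_PAIRS), size=j)
    nonpal_idx = rng.integers(0, len(_NONPALINDROMIC_PAIRS), size=j)
    # effect allele is the minor or major allele at random
    ea_is_minor = rng.random(j) < 0.5
    # outcome rows randomly present the allele pair in swapped order
    out_swap = rng.random(j) < 0.5

    exposure: list[SummaryStatRecord] = []
    outcome: list[SummaryStatRecord] = []
    invalid_ids: list[str] = []
    for k in range(j):
        snp_id = f"rs{k + 1}"
        chrom = str(k % 22 + 1)
        pos = 1_000_000 + 10_000_000 * (k // 22) + 1_000 * k
        ea, oa = (_PALINDROMIC_PAIRS[pal_idx[k]] if is_pal[k] else _NONPALINDROMIC_PAIRS[nonpal_idx[k]])
        eaf = maf[k] if ea_is_minor[k] else 1.0 - maf[k]
        exposure.append(
            SummaryStatRecord(
                snp_id=snp_id, chrom=chrom, pos=pos, effect_allele=ea, other_allele=oa,
                eaf=float(eaf), beta=float(beta_exp[k]), se=float(se_exp[k]),
                pvalue=derive_pvalue(float(beta_exp[k]), float(se_exp[k])),
                n=config.n_exposure,
            )
        )
        if out_swap[k]:
            o_ea, o_oa = oa, ea
            o_beta, o_eaf = -beta_out[k], 1.0 - eaf
        else:
            o_ea, o_oa = ea, oa
            o_beta, o_eaf = beta_out[k], eaf
        outcome.append(
            SummaryStatRecord(
                snp_id=snp_id, chrom=chrom, pos=pos, effect_allele=o_ea, other_allele=o_oa,
                eaf=float(o_eaf), beta=float(o_beta), se=float(se_out[k]),
                pvalue=derive_pvalue(float(o_beta), float(se_out[k])),
                n=config.n_outcome,
            )
        )
        if invalid[k]:
            invalid_ids.append(snp_id)

    truth = SimulationTruth(theta=config.theta, gamma=gamma, alpha=alpha, invalid_ids=invalid_ids)
    return SimulatedStudy(exposure_stats=exposure, outcome_stats=outcome, truth=truth, ld=LDTable())


def simulate_ld_block(
    n_snps: int,
    chrom: str = "1",
    start_pos: int = 1_000_000,
    spacing_bp: int = 25_000,
    decay: float = 1.0,
    r2_near: float = 0.9,
    seed: int | None = None,
) -> tuple[list[tuple[str, str, int]], LDTable]:
    """Emit SNP positions in one window plus a symmetric LD table whose r^2
    decays with distance: r2(i,j) = r2_near * exp(-decay * (|i-j| - 1)).

    With decay 0 every off-diagonal pair has r^2 = r2_near; with n_snps >= 3
    and decay > 0 the block contains both tightly linked adjacent pairs and
    weakly linked distant pairs.
    """
    if n_snps < 1:
        raise ConfigurationError(f"n_snps must be >= 1, got {n_snps}")
    if not (0.0 <= r2_near <= 1.0):
        raise ConfigurationError("r2_near must be in [0,1]")
    snps = [(f"ld{k + 1}", chrom, start_pos + k * spacing_bp) for k in range(n_snps)]
    ld = LDTable()
    for i in range(n_snps):
        for k in range(i + 1, n_snps):
            r2 = r2_near * float(np.exp(-decay * (k - i - 1)))
            ld.set(snps[i][0], snps[k][0], min(1.0, max(0.0, r2)))
    return snps, ld


def study_records_with_positions(
    study: SimulatedStudy, snps: Sequence[tuple[str, str, int]]
) -> list[SummaryStatRecord]:
    """Re-site the first len(snps) exposure records of a study onto the given
    (snp_id, chrom, pos) triples (fixture helper for clumping tests)."""
    from dataclasses import replace

    out = []
    for rec, (snp_id, chrom, pos) in zip(study.exposure_stats, snps):
        out.append(replace(rec, snp_id=snp_id, chrom=chrom, pos=pos))
    return out
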