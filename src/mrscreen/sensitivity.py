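"""Sensitivity battery: Cochran's Q heterogeneity test, MR-Egger intercept
(pleiotropy) test, leave-one-out analysis, and funnel-plot data."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from scipy import stats

from .exceptions import CollinearityError, InsufficientInstrumentsError
from .estimators import (
    EggerResult,
    MREstimate,
    MIN_INSTRUMENTS_EGGER,
    _ratio_arrays,
    ivw_from_ratios,
    mr_egger,
    mr_ivw,
    wald_ratio,
)
from .harmonize import HarmonizedInstrument


@dataclass(frozen=True)
class FunnelPoint:
    snp_id: str
    theta: float
    precision: float  # 1 / se of the Wald ratio


@dataclass
class SensitivityReport:
    """All sensitivity outputs for one exposure."""

    q_stat: float
    q_df: int
    q_p: float
    egger_intercept: float | None
    egger_intercept_se: float | None
    egger_intercept_p: float | None
    loo: list[tuple[str, MREstimate]]
    funnel: list[FunnelPoint]
    loo_flag: bool


def cochrans_q(insts: Sequence[HarmonizedInstrument]) -> tuple[float, int, float]:
    """Cochran's Q against the fixed-effect IVW estimate; chi-square(J-1) p."""
    if len(insts) < 2:
        raise InsufficientInstrumentsError(f"Cochran's Q needs >= 2 instruments, got {len(insts)}")
    theta, se = _ratio_arrays(insts)
    _, _, q_stat, _ = ivw_from_ratios(theta, se)
    df = len(insts) - 1
    return q_stat, df, float(stats.chi2.sf(q_stat, df))


def _single_snp_estimate(inst: HarmonizedInstrument) -> MREstimate:
    """Wald-ratio estimate packaged as an MREstimate (used when a LOO subset
    has a single instrument)."""
    r = wald_ratio(inst)
    crit = stats.norm.ppf(0.975)
    p = float(2.0 * stats.norm.sf(abs(r.theta) / r.se))
    return MREstimate(
        method="IVW", beta=r.theta, se=r.se,
        ci_low=r.theta - crit * r.se, ci_high=r.theta + crit * r.se,
        pvalue=p, n_snps=1,
    )


def leave_one_out(insts: Sequence[HarmonizedInstrument]) -> list[tuple[str, MREstimate]]:
    """IVW re-estimated with each instrument excluded in turn."""
    if len(insts) < 2:
        raise InsufficientInstrumentsError(f"leave-one-out needs >= 2 instruments, got {len(insts)}")
    results: list[tuple[str, MREstimate]] = []
    for j, excluded in enumerate(insts):
        subset = [inst for k, inst in enumerate(insts) if k != j]
        if len(subset) == 1:
            est = _single_snp_estimate(subset[0])
        else:
            est, _ = mr_ivw(subset)
        results.append((excluded.snp_id, est))
    return results


def funnel_data(insts: Sequence[HarmonizedInstrument]) -> list[FunnelPoint]:
    """Per-SNP Wald ratio vs precision (1/se), for funnel plotting."""
    if not insts:
        raise InsufficientInstrumentsError("funnel data needs >= 1 instrument")
    points = []
    for inst in insts:
        r = wald_ratio(inst)
        points.append(FunnelPoint(snp_id=r.snp_id, theta=r.theta, precision=1.0 / r.se))
    return points


def _loo_flag(full: MREstimate, loo: Sequence[tuple[str, MREstimate]], alpha: float) -> bool:
    """True when excluding any single SNP flips the IVW direction or moves the
    estimate across the significance boundary."""
    full_sig = full.pvalue < alpha
    for _, est in loo:
        if (est.beta > 0) != (full.beta > 0) and est.beta != 0 and full.beta != 0:
            return True
        if (est.pvalue < alpha) != full_sig:
            return True
    return False


def sensitivity_report(
    insts: Sequence[HarmonizedInstrument],
    ivw_estimate: MREstimate | None = None,
    egger: EggerResult | None = None,
    alpha: float = 0.05,
) -> SensitivityReport:
    """Assemble the full sensitivity battery for one exposure.

    ``ivw_estimate`` and ``egger`` are recomputed when not supplied; the Egger
    intercept fields stay ``None`` below its instrument minimum.
    """
    q_stat, q_df, q_p = cochrans_q(insts)
    if ivw_estimate is None:
        ivw_estimate, _ = mr_ivw(insts)
    if egger is None and len(insts) >= MIN_INSTRUMENTS_EGGER:
        try:
            egger = mr_egger(insts)
        except CollinearityError:
            egger = None  # degenerate design: report the rest of the battery
    loo = leave_one_out(insts)
    return SensitivityReport(
        q_stat=q_stat, q_df=q_df, q_p=q_p,
        egger_intercept=egger.intercept if egger else None,
        egger_intercept_se=egger.intercept_se if egger else None,
        egger_intercept_p=egger.intercept_p if egger else None,
        loo=loo,
        funnel=funnel_data(insts),
        loo_flag=_loo_flag(ivw_estimate, loo, alpha),
    )
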