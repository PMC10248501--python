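"""Per-exposure pipeline execution across many exposures, evidence
classification, and study-shaped output tables.

Each exposure runs selection -> clumping -> strength filtering -> exclusion ->
harmonization -> IVW/WM/MR-Egger -> sensitivity -> classification.  A
classification is ``risk`` or ``protective`` when the IVW p-value clears alpha
with the matching direction; the caution flag marks significant exposures
whose Egger point estimate points the other way.  Raw p-values drive
classification (no multiple-testing correction); a Benjamini-Hochberg column
is emitted as extra output only.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .estimators import (
    EggerResult,
    MREstimate,
    MIN_INSTRUMENTS_EGGER,
    MIN_INSTRUMENTS_IVW,
    MIN_INSTRUMENTS_WM,
    mr_egger,
    mr_ivw,
    mr_weighted_median,
)
from .harmonize import DEFAULT_PALINDROME_TOLERANCE, HarmonizationReport, harmonize_all
from .instruments import LDTable, SelectionConfig, SelectionResult, select_instruments
from .sensitivity import SensitivityReport, sensitivity_report
from .sumstats_io import StudyMeta, SummaryStatRecord, write_table

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of the per-exposure pipeline."""

    selection: SelectionConfig = field(default_factory=SelectionConfig)
    palindrome_tolerance: float = DEFAULT_PALINDROME_TOLERANCE
    drop_all_palindromic: bool = False
    n_boot: int = 1000
    alpha: float = 0.05
    skip_selection: bool = False  # feed pre-selected instruments straight to harmonization


@dataclass(frozen=True)
class EvidenceClassification:
    """Outcome of the significance/direction-concordance rule for one exposure."""

    category: str  # risk | protective | null
    wm_confirmed: bool | None
    direction_concordant: bool | None
    caution: bool


@dataclass
class ExposureResult:
    """Everything the pipeline produced for one exposure."""

    exposure_name: str
    taxonomic_level: str | None = None
    analyzable: bool = False
    ivw: MREstimate | None = None
    wm: MREstimate | None = None
    egger: EggerResult | None = None
    sensitivity: SensitivityReport | None = None
    classification: EvidenceClassification | None = None
    n_instruments_initial: int = 0
    n_instruments_final: int = 0
    selection: SelectionResult | None = None
    harmonization: HarmonizationReport | None = None
    note: str = ""


def classify_evidence(
    ivw: MREstimate,
    wm: MREstimate | None,
    egger: MREstimate | None,
    alpha: float = 0.05,
) -> EvidenceClassification:
    """Apply the significance/direction-concordance rule.

    ``risk`` when IVW p < alpha with OR > 1, ``protective`` when IVW p < alpha
    with OR < 1, else ``null``.  ``wm_confirmed`` requires WM p < alpha with
    the IVW direction; ``direction_concordant`` requires both WM and Egger
    point estimates to share the IVW direction (point estimates only);
    ``caution`` marks significant exposures with a discordant direction.
    Missing WM/Egger estimates leave the concordance fields ``None``.
    """
    significant = ivw.pvalue < alpha
    if significant and ivw.beta > 0:
        category = "risk"
    elif significant and ivw.beta < 0:
        category = "protective"
    else:
        category = "null"

    direction = np.sign(ivw.beta)
    wm_confirmed = None
    if wm is not None:
        wm_confirmed = bool(wm.pvalue < alpha and np.sign(wm.beta) == direction)
    direction_concordant = None
    if wm is not None and egger is not None:
        direction_concordant = bool(
            np.sign(wm.beta) == direction and np.sign(egger.beta) == direction
        )
    caution = bool(category != "null" and direction_concordant is False)
    return EvidenceClassification(
        category=category,
        wm_confirmed=wm_confirmed,
        direction_concordant=direction_concordant,
        caution=caution,
    )


def run_exposure(
    exposure_name: str,
    exp_stats: Sequence[SummaryStatRecord],
    out_stats: Sequence[SummaryStatRecord],
    config: PipelineConfig,
    exposure_meta: StudyMeta | None = None,
    ld: LDTable | None = None,
    exclusions: set[str] | None = None,
    seed: int | None = None,
    taxonomic_level: str | None = None,
) -> ExposureResult:
    """Run the full pipeline for one exposure.

    An exposure ending with fewer than two harmonized instruments is marked
    not analyzable (recorded, never fatal to a screen).
    """
    meta = exposure_meta or StudyMeta(trait_name=exposure_name)
    result = ExposureResult(exposure_name=exposure_name, taxonomic_level=taxonomic_level)

    if config.skip_selection:
        selected = list(exp_stats)
        result.selection = None
    else:
        sel = select_instruments(exp_stats, meta, config.selection, ld=ld, exclusions=exclusions)
        selected = sel.records
        result.selection = sel
    result.n_instruments_initial = len(selected)

    insts, harm_report = harmonize_all(
        selected, out_stats,
        tolerance=config.palindrome_tolerance,
        drop_all_palindromic=config.drop_all_palindromic,
    )
    result.harmonization = harm_report
    result.n_instruments_final = len(insts)

    if len(insts) < MIN_INSTRUMENTS_IVW:
        result.note = f"not analyzable: {len(insts)} instrument(s) after harmonization"
        logger.warning("%s %s", exposure_name, result.note)
        return result

    result.analyzable = True
    ivw, _ = mr_ivw(insts)
    result.ivw = ivw
    if len(insts) >= MIN_INSTRUMENTS_WM:
        result.wm = mr_weighted_median(insts, n_boot=config.n_boot, seed=seed)
    if len(insts) >= MIN_INSTRUMENTS_EGGER:
        result.egger = mr_egger(insts)
    result.sensitivity = sensitivity_report(insts, ivw_estimate=ivw, egger=result.egger, alpha=config.alpha)
    result.classification = classify_evidence(
        ivw, result.wm, result.egger.slope if result.egger else None, alpha=config.alpha
    )
    return result


def derive_seed(base_seed: int, exposure_name: str) -> int:
    """Stable per-exposure seed: invariant to exposure ordering and to
    splitting a screen across invocations."""
    return (int(base_seed) + zlib.crc32(exposure_name.encode("utf-8"))) % 2**32


def benjamini_hochberg(pvalues: Sequence[float]) -> list[float]:
    """BH-adjusted p-values (emitted as extra output; never drives
    classification)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m == 0:
        return []
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        idx = order[rank_from_top]
        running = min(running, p[idx] * m / (rank_from_top + 1))
        adj[idx] = running
    return adj.tolist()


def screen_all(
    exposures: Mapping[str, Sequence[SummaryStatRecord]],
    out_stats: Sequence[SummaryStatRecord],
    config: PipelineConfig,
    exposure_meta: Mapping[str, StudyMeta] | None = None,
    ld: LDTable | None = None,
    exclusions: set[str] | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
    levels: Mapping[str, str] | None = None,
) -> list[ExposureResult]:
    """Run :func:`run_exposure` for every exposure and optionally write the
    five study-shaped output tables (results, sensitivity, loo, funnel,
    classification).  Per-exposure seeds derive from the base seed and the
    exposure name, so results are independent of ordering and splitting."""
    results: list[ExposureResult] = []
    for name in exposures:
        res = run_exposure(
            exposure_name=name,
            exp_stats=exposures[name],
            out_stats=out_stats,
            config=config,
            exposure_meta=(exposure_meta or {}).get(name),
            ld=ld,
            exclusions=exclusions,
            seed=derive_seed(seed, name),
            taxonomic_level=(levels or {}).get(name),
        )
        results.append(res)
    if out_dir is not None:
        write_screen_tables(results, out_dir)
    return results


def write_screen_tables(results: Sequence[ExposureResult], out_dir: str | Path) -> dict[str, Path]:
    """Write results.tsv, sensitivity.tsv, loo.tsv, funnel.tsv,
    classification.tsv under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    est_rows = []
    for res in results:
        for est in (res.ivw, res.wm, res.egger.slope if res.egger else None):
            if est is None:
                continue
            est_rows.append(
                {
                    "exposure": res.exposure_name, "method": est.method, "n_snps": est.n_snps,
                    "or": est.or_value, "ci_low": est.or_low, "ci_high": est.or_high,
                    "pvalue": est.pvalue,
                }
            )

    sens_rows = [
        {
            "exposure": res.exposure_name,
            "intercept": res.sensitivity.egger_intercept,
            "intercept_p": res.sensitivity.egger_intercept_p,
            "q_stat": res.sensitivity.q_stat,
            "q_p": res.sensitivity.q_p,
        }
        for res in results
        if res.sensitivity is not None
    ]

    loo_rows = []
    funnel_rows = []
    for res in results:
        if res.sensitivity is None:
            continue
        for snp, est in res.sensitivity.loo:
            loo_rows.append(
                {
                    "exposure": res.exposure_name, "excluded_snp": snp,
                    "or": est.or_value, "ci_low": est.or_low, "ci_high": est.or_high,
                    "pvalue": est.pvalue,
                }
            )
        for point in res.sensitivity.funnel:
            funnel_rows.append(
                {
                    "exposure": res.exposure_name, "snp": point.snp_id,
                    "theta": point.theta, "precision": point.precision,
                }
            )

    analyzable = [r for r in results if r.analyzable and r.classification is not None]
    bh = benjamini_hochberg([r.ivw.pvalue for r in analyzable])
    class_rows = [
        {
            "exposure": res.exposure_name,
            "level": res.taxonomic_level or "NA",
            "category": res.classification.category,
            "ivw_or": res.ivw.or_value,
            "ivw_p": res.ivw.pvalue,
            "ivw_p_bh": bh_p,
            "wm_confirmed": res.classification.wm_confirmed,
            "direction_concordant": res.classification.direction_concordant,
            "caution": res.classification.caution,
        }
        for res, bh_p in zip(analyzable, bh)
    ]

    paths = {
        "results": out_dir / "results.tsv",
        "sensitivity": out_dir / "sensitivity.tsv",
        "loo": out_dir / "loo.tsv",
        "funnel": out_dir / "funnel.tsv",
        "classification": out_dir / "classification.tsv",
    }
    write_table(est_rows, paths["results"], ["exposure", "method", "n_snps", "or", "ci_low", "ci_high", "pvalue"])
    write_table(sens_rows, paths["sensitivity"], ["exposure", "intercept", "intercept_p", "q_stat", "q_p"])
    write_table(loo_rows, paths["loo"], ["exposure", "excluded_snp", "or", "ci_low", "ci_high", "pvalue"])
    write_table(funnel_rows, paths["funnel"], ["exposure", "snp", "theta", "precision"])
    write_table(
        class_rows, paths["classification"],
        ["exposure", "level", "category", "ivw_or", "ivw_p", "ivw_p_bh",
         "wm_confirmed", "direction_concordant", "caution"],
    )
    return paths
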