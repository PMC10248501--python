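"""Bundled worked example: published per-method MR estimates for a screen of
gut-microbiome exposures against a periodontitis outcome (11 exposures x
{IVW, WM, MR-Egger} as OR / 95% CI / p), used to exercise the evidence
classification rule without any raw GWAS data."""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .estimators import MREstimate
from .screening import EvidenceClassification, classify_evidence


def load_worked_example() -> pd.DataFrame:
    """Long-format table: exposure, level, method, or, ci_low, ci_high, pvalue."""
    with resources.files("mrscreen.data").joinpath("worked_example_estimates.tsv").open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def worked_example_estimates() -> dict[str, dict[str, MREstimate]]:
    """The worked example regrouped as exposure -> method -> MREstimate."""
    df = load_worked_example().rename(columns={"or": "or_value"})
    out: dict[str, dict[str, MREstimate]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.exposure, {})[row.method] = MREstimate.from_or(
            method=row.method, or_value=row.or_value, or_low=row.ci_low,
            or_high=row.ci_high, pvalue=row.pvalue,
        )
    return out


def classify_worked_example(alpha: float = 0.05) -> dict[str, EvidenceClassification]:
    """Run the evidence-classification rule on every worked-example exposure."""
    return {
        exposure: classify_evidence(ests["IVW"], ests.get("WM"), ests.get("MR-Egger"), alpha=alpha)
        for exposure, ests in worked_example_estimates().items()
    }
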