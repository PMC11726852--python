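"""End-to-end convenience wiring: find -> exclude -> classify -> evaluate."""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .causes import CauseLabel, REOPERATION_CAUSES, composite_label
from .classifier import classify_cohort
from .codesets import CodeSetConfig, default_config
from .finder import apply_exclusions, find_candidates_cohort
from .stats import AccuracyReport, confusion


@dataclass
class PipelineResult:
    candidates: pd.DataFrame
    retained: pd.DataFrame
    excluded: pd.DataFrame
    fracture_table: pd.DataFrame


def run_pipeline(
    events: pd.DataFrame,
    index_surgeries: pd.DataFrame,
    config: CodeSetConfig | None = None,
    window_days: int = 365,
) -> PipelineResult:
    """Identify candidates, apply exclusions, classify, roll up per fracture."""
    config = config or default_config()
    candidates = find_candidates_cohort(
        events, index_surgeries, window_days, chapter_policy=config.chapter_policy
    )
    retained, excluded = apply_exclusions(candidates, config.exclusions)
    fracture_table = classify_cohort(retained, index_surgeries, config)
    return PipelineResult(candidates, retained, excluded, fracture_table)


def evaluate(
    fracture_table: pd.DataFrame, gold_labels: pd.DataFrame
) -> dict[str, AccuracyReport]:
    """Validation-table-shaped accuracy panel of predictions vs gold labels.

    Rows: any-reoperation, the major/minor composites, and each cause.
    Causes with no gold positives and no predictions are omitted.
    """
    pred = fracture_table.set_index("fracture_id")["cause"]
    gold = gold_labels.set_index("fracture_id")["true_cause"].reindex(pred.index)
    if gold.isna().any():
        missing = list(gold[gold.isna()].index[:5])
        raise ValueError(f"gold labels missing for fractures {missing}")

    reports: dict[str, AccuracyReport] = {}
    not_reop = CauseLabel.NOT_REOPERATION.value
    reports["any_reoperation"] = AccuracyReport.from_counts(
        confusion(pred != not_reop, gold != not_reop)
    )
    pred_comp = pred.map(lambda c: composite_label(c).value)
    gold_comp = gold.map(lambda c: composite_label(c).value)
    for comp in ("major", "minor"):
        reports[f"{comp}_reoperations"] = AccuracyReport.from_counts(
            confusion(pred_comp == comp, gold_comp == comp)
        )
    for cause in REOPERATION_CAUSES:
        p = pred == cause.value
        g = gold == cause.value
        if not p.any() and not g.any():
            continue
        reports[cause.value] = AccuracyReport.from_counts(confusion(p, g))
    return reports
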