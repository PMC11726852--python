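"""Assign causes to candidate reoperations and roll up to fracture level.

Cause rules are evaluated in severity order and the first firing rule wins,
so infection takes precedence over everything (a skin-chapter debridement
with infection evidence labels as infection, not wound treatment), and a
candidate can never be both early re-osteosynthesis (day <= 42) and
secondary arthroplasty (day > 42) because their day windows partition the
follow-up.  Candidates matching no cause pattern fall through to "other".
At fracture level the most severe candidate label wins.
"""
from __future__ import annotations

import pandas as pd

from .causes import CauseLabel, REOPERATION_CAUSES, composite_label, worst_cause
from .codes import Code, matches
from .codesets import CauseAlgorithm, CodeSetConfig, window_contains

#: Causes in the order classification tries them (severity order, most
#: severe first; "other" is the fallback, not a rule).
RULE_ORDER: tuple[CauseLabel, ...] = REOPERATION_CAUSES[:-1]


def algorithm_fires(alg: CauseAlgorithm, codes: tuple[str, ...], day: int, step: int | None = None) -> bool:
    """Does the algorithm's (deployed) step fire on this candidate?"""
    parsed = [Code.parse(c) for c in codes]
    for group in alg.step_groups(step):
        if not window_contains(alg.group_window(group), day):
            continue
        for pattern in group.patterns:
            if any(pattern.kind is c.kind and matches(pattern, c) for c in parsed):
                return True
    return False


def classify_candidate(candidate, config: CodeSetConfig) -> CauseLabel:
    """Label one retained candidate with the most severe firing cause."""
    codes = tuple(candidate["procedure_codes"]) + tuple(candidate["diagnosis_codes"])
    day = int(candidate["days_since_index"])
    for cause in RULE_ORDER:
        if algorithm_fires(config.algorithm(cause), codes, day):
            return cause
    return CauseLabel.OTHER


def classify_candidates(candidates: pd.DataFrame, config: CodeSetConfig) -> pd.DataFrame:
    """Candidate table plus a ``cause`` column; total over candidates."""
    out = candidates.copy()
    if out.empty:
        out["cause"] = pd.Series(dtype=str)
        return out
    out["cause"] = [
        classify_candidate(row, config).value for _, row in candidates.iterrows()
    ]
    return out


def fracture_level(
    labeled_candidates: pd.DataFrame,
    index_surgeries: pd.DataFrame,
    config: CodeSetConfig | None = None,
) -> pd.DataFrame:
    """Fracture-level roll-up: worst cause, composite, first day, fired flags.

    Fractures without any retained candidate are labelled not_reoperation.
    """
    rows = []
    by_fracture = (
        dict(tuple(labeled_candidates.groupby("fracture_id")))
        if not labeled_candidates.empty
        else {}
    )
    for _, surg in index_surgeries.iterrows():
        fid = surg["fracture_id"]
        grp = by_fracture.get(fid)
        if grp is None or grp.empty:
            cause = CauseLabel.NOT_REOPERATION
            first_day = None
            fired = set()
        else:
            cause = worst_cause(grp["cause"])
            first_day = int(grp["days_since_index"].min())
            fired = set(grp["cause"])
        row = {
            "fracture_id": fid,
            "cause": cause.value,
            "composite": composite_label(cause).value,
            "first_reop_day": first_day,
        }
        for c in REOPERATION_CAUSES:
            row[f"fired_{c.value}"] = c.value in fired
        rows.append(row)
    return pd.DataFrame(rows)


def classify_cohort(
    candidates: pd.DataFrame,
    index_surgeries: pd.DataFrame,
    config: CodeSetConfig,
) -> pd.DataFrame:
    """Convenience: label candidates, then roll up to fracture level."""
    labeled = classify_candidates(candidates, config)
    return fracture_level(labeled, index_surgeries, config)
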