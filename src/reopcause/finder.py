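"""Identify candidate reoperations for each index fracture surgery.

A hospital contact qualifies as a candidate reoperation when it (i) carries
at least one surgical procedure code from the nervous-system (KA),
musculoskeletal (KN) or skin (KQ) chapter, (ii) falls 1..365 days after the
index procedure (day 0 is the index contact itself, not a reoperation),
(iii) lies in the same anatomical region as the index surgery —
region-neutral codes pass — and (iv) is laterality-compatible with the
index side (same side, or either side unspecified).  Contacts sharing a
contact_id form one candidate; separate contacts on the same day stay
separate.

Configured exclusions (planned K-wire / external-fixation removal,
chronic-wound surgery) then move candidates to an excluded stream with a
machine-readable reason; retained plus excluded always equals the input.
"""
from __future__ import annotations

import pandas as pd

from .codes import (
    Code,
    CodeKind,
    SURGICAL_CHAPTERS,
    chapter_of,
    laterality_compatible,
    region_of,
)
from .codesets import ExclusionRule

CANDIDATE_COLUMNS = (
    "fracture_id",
    "patient_id",
    "contact_id",
    "reop_date",
    "days_since_index",
    "procedure_codes",
    "diagnosis_codes",
    "laterality",
)


def _empty_candidates() -> pd.DataFrame:
    return pd.DataFrame(columns=list(CANDIDATE_COLUMNS))


def _contact_laterality(values) -> str:
    for v in values:
        if v != "unspecified":
            return v
    return "unspecified"


def _contacts(events: pd.DataFrame) -> pd.DataFrame:
    """Collapse event rows to one row per (patient, contact)."""
    ev = events.copy()
    if "kind" not in ev.columns:
        ev["kind"] = ev["code"].map(lambda c: "procedure" if c.startswith("K") else "diagnosis")
    grouped = ev.groupby(["patient_id", "contact_id"], sort=False)
    rows = []
    for (pid, cid), grp in grouped:
        codes = grp["code"].tolist()
        kinds = grp["kind"].tolist()
        rows.append(
            {
                "patient_id": pid,
                "contact_id": cid,
                "reop_date": grp["date"].min(),
                "procedure_codes": tuple(c for c, k in zip(codes, kinds) if k == "procedure"),
                "diagnosis_codes": tuple(c for c, k in zip(codes, kinds) if k == "diagnosis"),
                "laterality": _contact_laterality(grp["laterality"].tolist()),
            }
        )
    return pd.DataFrame(rows)


def find_candidates_cohort(
    events: pd.DataFrame,
    index_surgeries: pd.DataFrame,
    window_days: int = 365,
    chapters: tuple[str, ...] = SURGICAL_CHAPTERS,
    chapter_policy: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Candidate reoperations for every fracture in the cohort."""
    if window_days < 1:
        raise ValueError("window_days must be >= 1")
    if events.empty or index_surgeries.empty:
        return _empty_candidates()

    contacts = _contacts(events)
    merged = contacts.merge(
        index_surgeries[["fracture_id", "patient_id", "surgery_date", "region", "laterality"]],
        on="patient_id",
        how="inner",
        suffixes=("", "_index"),
    )
    if merged.empty:
        return _empty_candidates()

    merged["days_since_index"] = (merged["reop_date"] - merged["surgery_date"]).dt.days
    merged = merged[
        (merged["days_since_index"] >= 1) & (merged["days_since_index"] <= window_days)
    ]

    def qualifies(row) -> bool:
        surgical = [c for c in row.procedure_codes if chapter_of(c) in chapters]
        if not surgical:
            return False
        regions = {region_of(c, chapter_policy) for c in surgical}
        if row.region not in regions and None not in regions:
            return False
        return laterality_compatible(row.laterality_index, row.laterality)

    if merged.empty:
        return _empty_candidates()
    mask = [qualifies(row) for row in merged.itertuples()]
    out = merged.loc[mask, list(CANDIDATE_COLUMNS)].reset_index(drop=True)
    return out


def find_candidates(
    events: pd.DataFrame,
    index: pd.Series | dict,
    window_days: int = 365,
    chapters: tuple[str, ...] = SURGICAL_CHAPTERS,
    chapter_policy: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Candidates for one index surgery; events must belong to its patient."""
    index = dict(index)
    patients = set(events["patient_id"].unique()) if not events.empty else set()
    if patients - {index["patient_id"]}:
        raise ValueError(
            f"events contain patients other than {index['patient_id']!r}: "
            f"{sorted(patients - {index['patient_id']})}"
        )
    surgeries = pd.DataFrame([index])
    return find_candidates_cohort(events, surgeries, window_days, chapters, chapter_policy)


def _matches_any(rule_patterns, code_text: str) -> bool:
    from .codes import matches

    code = Code.parse(code_text)
    return any(p.kind is code.kind and matches(p, code) for p in rule_patterns)


def _excluded_by(rule: ExclusionRule, row) -> bool:
    if rule.mode == "all_procedures":
        procs = [c for c in row.procedure_codes if chapter_of(c) in SURGICAL_CHAPTERS]
        return bool(procs) and all(_matches_any(rule.patterns, c) for c in procs)
    return any(_matches_any(rule.patterns, c) for c in row.diagnosis_codes)


def apply_exclusions(
    candidates: pd.DataFrame, rules: tuple[ExclusionRule, ...]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split candidates into (retained, excluded-with-reason).

    Rules are evaluated in configuration order; the first matching rule
    names the exclusion reason.  With no rules this is the identity.
    """
    if candidates.empty or not rules:
        excluded = candidates.iloc[0:0].copy()
        excluded["exclusion_reason"] = pd.Series(dtype=str)
        return candidates.copy(), excluded

    reasons = []
    for row in candidates.itertuples():
        reason = None
        for rule in rules:
            if _excluded_by(rule, row):
                reason = rule.name
                break
        reasons.append(reason)
    reasons = pd.Series(reasons, index=candidates.index, dtype=object)
    retained = candidates[reasons.isna()].reset_index(drop=True)
    excluded = candidates[reasons.notna()].copy()
    excluded["exclusion_reason"] = reasons[reasons.notna()]
    excluded = excluded.reset_index(drop=True)
    assert len(retained) + len(excluded) == len(candidates)
    return retained, excluded


def write_candidates(candidates: pd.DataFrame, path) -> None:
    out = candidates.copy()
    for col in ("procedure_codes", "diagnosis_codes"):
        if col in out.columns:
            out[col] = out[col].map(lambda t: "|".join(t))
    if "reop_date" in out.columns and len(out):
        out["reop_date"] = pd.to_datetime(out["reop_date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_candidates(path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"fracture_id": str, "patient_id": str, "contact_id": str})
    for col in ("procedure_codes", "diagnosis_codes"):
        frame[col] = frame[col].fillna("").map(lambda s: tuple(c for c in s.split("|") if c))
    frame["reop_date"] = pd.to_datetime(frame["reop_date"])
    return frame
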