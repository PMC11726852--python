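"""Reoperation cause labels, the severity hierarchy, and composites.

When one fracture has several reoperations within follow-up the most severe
condition wins.  Severity, descending: infection, nonunion,
re-osteosynthesis, secondary arthroplasty, hardware removal, wound
treatment, other; "not a reoperation" ranks below everything.
"""
from __future__ import annotations

import enum
from collections.abc import Iterable


class CauseLabel(str, enum.Enum):
    INFECTION = "infection"
    NONUNION = "nonunion"
    RE_OSTEOSYNTHESIS = "re_osteosynthesis"
    SECONDARY_ARTHROPLASTY = "secondary_arthroplasty"
    HARDWARE_REMOVAL = "hardware_removal"
    WOUND_TREATMENT = "wound_treatment"
    OTHER = "other"
    NOT_REOPERATION = "not_reoperation"


#: Descending severity; index 0 is the most severe.
SEVERITY_ORDER: tuple[CauseLabel, ...] = (
    CauseLabel.INFECTION,
    CauseLabel.NONUNION,
    CauseLabel.RE_OSTEOSYNTHESIS,
    CauseLabel.SECONDARY_ARTHROPLASTY,
    CauseLabel.HARDWARE_REMOVAL,
    CauseLabel.WOUND_TREATMENT,
    CauseLabel.OTHER,
    CauseLabel.NOT_REOPERATION,
)

#: The causes a fracture can truly have (everything except the non-event).
REOPERATION_CAUSES: tuple[CauseLabel, ...] = SEVERITY_ORDER[:-1]

MAJOR_CAUSES = frozenset(
    {
        CauseLabel.INFECTION,
        CauseLabel.NONUNION,
        CauseLabel.RE_OSTEOSYNTHESIS,
        CauseLabel.SECONDARY_ARTHROPLASTY,
    }
)
MINOR_CAUSES = frozenset({CauseLabel.HARDWARE_REMOVAL, CauseLabel.WOUND_TREATMENT})


def severity_rank(cause: CauseLabel | str) -> int:
    """0 = most severe (infection); larger = less severe."""
    return SEVERITY_ORDER.index(CauseLabel(cause))


def worst_cause(labels: Iterable[CauseLabel | str]) -> CauseLabel:
    """Most severe label among those observed for one fracture."""
    ranked = sorted((CauseLabel(c) for c in labels), key=severity_rank)
    if not ranked:
        raise ValueError("worst_cause of an empty label collection")
    return ranked[0]


class CompositeLabel(str, enum.Enum):
    MAJOR = "major"
    MINOR = "minor"
    OTHER = "other"
    NONE = "none"


def composite_label(cause: CauseLabel | str) -> CompositeLabel:
    """Roll a cause up to the major/minor reoperation composites."""
    cause = CauseLabel(cause)
    if cause in MAJOR_CAUSES:
        return CompositeLabel.MAJOR
    if cause in MINOR_CAUSES:
        return CompositeLabel.MINOR
    if cause is CauseLabel.OTHER:
        return CompositeLabel.OTHER
    return CompositeLabel.NONE
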