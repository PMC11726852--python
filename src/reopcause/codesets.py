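"""Code-set configuration: per-cause algorithms, exclusion rules, I/O.

A cause algorithm is an ordered list of *pattern groups* composed
cumulatively with "or": step *k* of the algorithm fires when any pattern in
groups 1..k matches.  ``selected_step`` names the deployed step.  Six-week
boundaries are expressed as inclusive day windows on the whole cause (or
per group): early re-osteosynthesis lives in days 1-42, secondary
arthroplasty in days 43-365, hardware removal from day 42 on.

The shipped defaults contain every code named for each cause in the source
registries' main usage (KNxW69/KNxW59 and DT846 for infection; KNxT5,
DT813O, DM841 for nonunion; KNxJ/KNxC and DT840-DT844 for early
re-osteosynthesis; KNxC plus prosthesis stems for secondary arthroplasty;
KNxU for hardware removal; KQ for wound treatment) and are user-editable:
real deployments are expected to extend them from local step tables.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .causes import CauseLabel, SEVERITY_ORDER
from .codes import CodeKind, CodePattern, ConfigurationError

DayWindow = tuple[int | None, int | None]  # inclusive bounds in days since index


def window_contains(window: DayWindow, day: int) -> bool:
    lo, hi = window
    if lo is not None and day < lo:
        return False
    if hi is not None and day > hi:
        return False
    return True


@dataclass(frozen=True)
class PatternGroup:
    """A named family of patterns added to an algorithm as one step."""

    name: str
    patterns: tuple[CodePattern, ...]
    window: DayWindow | None = None  # overrides the cause window when set

    def __post_init__(self) -> None:
        if not self.patterns:
            raise ConfigurationError(f"pattern group {self.name!r} is empty")
        object.__setattr__(self, "patterns", tuple(self.patterns))


@dataclass(frozen=True)
class CauseAlgorithm:
    """Stepwise "or"-composed algorithm for one reoperation cause."""

    cause: CauseLabel
    groups: tuple[PatternGroup, ...]
    selected_step: int
    window: DayWindow = (None, None)

    def __post_init__(self) -> None:
        object.__setattr__(self, "cause", CauseLabel(self.cause))
        object.__setattr__(self, "groups", tuple(self.groups))
        if not self.groups:
            raise ConfigurationError(f"no pattern groups for cause {self.cause.value}")
        if not 1 <= self.selected_step <= len(self.groups):
            raise ConfigurationError(
                f"selected_step {self.selected_step} outside 1..{len(self.groups)}"
                f" for cause {self.cause.value}"
            )

    def step_groups(self, step: int | None = None) -> tuple[PatternGroup, ...]:
        """Groups active at the given step (default: the deployed step)."""
        step = self.selected_step if step is None else step
        return self.groups[:step]

    def group_window(self, group: PatternGroup) -> DayWindow:
        return group.window if group.window is not None else self.window


@dataclass(frozen=True)
class ExclusionRule:
    """Moves candidates to the excluded stream with a machine-readable reason.

    mode "all_procedures": every surgical procedure code on the contact must
    match (the contact did nothing but, say, K-wire removal).  mode
    "any_diagnosis": one matching diagnosis code suffices (chronic-wound
    contacts are flagged by their wound diagnosis).
    """

    name: str
    patterns: tuple[CodePattern, ...]
    mode: str = "all_procedures"

    def __post_init__(self) -> None:
        if self.mode not in ("all_procedures", "any_diagnosis"):
            raise ConfigurationError(f"unknown exclusion mode {self.mode!r}")
        object.__setattr__(self, "patterns", tuple(self.patterns))


@dataclass(frozen=True)
class CodeSetConfig:
    algorithms: dict[CauseLabel, CauseAlgorithm]
    exclusions: tuple[ExclusionRule, ...] = ()
    chapter_policy: dict[str, str] = field(default_factory=dict)

    def algorithm(self, cause: CauseLabel) -> CauseAlgorithm:
        cause = CauseLabel(cause)
        try:
            return self.algorithms[cause]
        except KeyError:
            raise ConfigurationError(f"no algorithm configured for cause {cause.value}")

    def with_selected_steps(self, steps: dict[CauseLabel, int]) -> "CodeSetConfig":
        algs = dict(self.algorithms)
        for cause, step in steps.items():
            algs[CauseLabel(cause)] = replace(algs[CauseLabel(cause)], selected_step=step)
        return replace(self, algorithms=algs)


# ---------------------------------------------------------------------------
# serialisation

def _pattern_to_dict(p: CodePattern) -> dict:
    d = {"template": p.template, "kind": p.kind.value}
    if p.range_end:
        d["range_end"] = p.range_end
    return d


def _pattern_from_dict(d: dict) -> CodePattern:
    return CodePattern(d["template"], CodeKind(d["kind"]), d.get("range_end"))


def config_to_dict(cfg: CodeSetConfig) -> dict:
    return {
        "algorithms": {
            alg.cause.value: {
                "selected_step": alg.selected_step,
                "window": list(alg.window),
                "groups": [
                    {
                        "name": g.name,
                        "window": list(g.window) if g.window is not None else None,
                        "patterns": [_pattern_to_dict(p) for p in g.patterns],
                    }
                    for g in alg.groups
                ],
            }
            for alg in cfg.algorithms.values()
        },
        "exclusions": [
            {"name": r.name, "mode": r.mode, "patterns": [_pattern_to_dict(p) for p in r.patterns]}
            for r in cfg.exclusions
        ],
        "chapter_policy": dict(cfg.chapter_policy),
    }


def config_from_dict(data: dict) -> CodeSetConfig:
    try:
        algorithms = {}
        for cause, spec in data.get("algorithms", {}).items():
            groups = tuple(
                PatternGroup(
                    g["name"],
                    tuple(_pattern_from_dict(p) for p in g["patterns"]),
                    tuple(g["window"]) if g.get("window") is not None else None,
                )
                for g in spec["groups"]
            )
            algorithms[CauseLabel(cause)] = CauseAlgorithm(
                CauseLabel(cause),
                groups,
                spec.get("selected_step", len(groups)),
                tuple(spec.get("window", (None, None))),
            )
        exclusions = tuple(
            ExclusionRule(
                r["name"],
                tuple(_pattern_from_dict(p) for p in r["patterns"]),
                r.get("mode", "all_procedures"),
            )
            for r in data.get("exclusions", [])
        )
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"malformed code-set config: {exc}") from exc
    return CodeSetConfig(algorithms, exclusions, dict(data.get("chapter_policy", {})))


def load_config(path: str | Path) -> CodeSetConfig:
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    return config_from_dict(data)


def save_config(cfg: CodeSetConfig, path: str | Path) -> None:
    path = Path(path)
    data = config_to_dict(cfg)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n", encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")


# ---------------------------------------------------------------------------
# shipped defaults

def _pp(template: str, range_end: str | None = None) -> CodePattern:
    kind = CodeKind.PROCEDURE if template.upper().startswith("K") else CodeKind.DIAGNOSIS
    return CodePattern(template, kind, range_end)


def default_config() -> CodeSetConfig:
    """Deployed default algorithms and exclusion rules.

    The six-week threshold is fixed at 42 days with day <= 42 counting as
    early re-osteosynthesis and day > 42 as secondary-arthroplasty territory;
    hardware removal requires day >= 42.
    """
    algorithms = {
        CauseLabel.INFECTION: CauseAlgorithm(
            CauseLabel.INFECTION,
            (
                PatternGroup("infection_diagnosis_DT846", (_pp("DT846"),)),
                PatternGroup("infection_procedures_KNxW69_KNxW59", (_pp("KNxW69"), _pp("KNxW59"))),
            ),
            selected_step=2,
        ),
        CauseLabel.NONUNION: CauseAlgorithm(
            CauseLabel.NONUNION,
            (
                PatternGroup("nonunion_procedure_KNxT5", (_pp("KNxT5"),)),
                PatternGroup("nonunion_diagnoses_DT813O_DM841", (_pp("DT813O"), _pp("DM841"))),
            ),
            selected_step=2,
        ),
        CauseLabel.RE_OSTEOSYNTHESIS: CauseAlgorithm(
            CauseLabel.RE_OSTEOSYNTHESIS,
            (
                PatternGroup("reosteosynthesis_procedures_KNxJ_KNxC", (_pp("KNxJ"), _pp("KNxC"))),
                PatternGroup("mechanical_complication_DT840_DT844", (_pp("DT840", "DT844"),)),
            ),
            selected_step=2,
            window=(1, 42),
        ),
        CauseLabel.SECONDARY_ARTHROPLASTY: CauseAlgorithm(
            CauseLabel.SECONDARY_ARTHROPLASTY,
            (
                PatternGroup("arthroplasty_revision_KNxC", (_pp("KNxC"),)),
                PatternGroup("prosthesis_insertion_KNxB", (_pp("KNxB"),)),
            ),
            selected_step=2,
            window=(43, None),
        ),
        CauseLabel.HARDWARE_REMOVAL: CauseAlgorithm(
            CauseLabel.HARDWARE_REMOVAL,
            (PatternGroup("implant_removal_KNxU", (_pp("KNxU"),)),),
            selected_step=1,
            window=(42, None),
        ),
        CauseLabel.WOUND_TREATMENT: CauseAlgorithm(
            CauseLabel.WOUND_TREATMENT,
            (PatternGroup("skin_surgery_KQ", (_pp("KQ"),)),),
            selected_step=1,
        ),
    }
    exclusions = (
        ExclusionRule("kwire_removal", (_pp("KNxU19"),), "all_procedures"),
        ExclusionRule("external_fixation_removal", (_pp("KNxU09"),), "all_procedures"),
        ExclusionRule(
            "chronic_wound",
            (_pp("DL89"), _pp("DL97"), _pp("DI83")),
            "any_diagnosis",
        ),
    )
    return CodeSetConfig(algorithms, exclusions)


def default_pattern_pool() -> dict[CauseLabel, tuple[PatternGroup, ...]]:
    """Candidate pattern groups the stepwise builder searches, per cause.

    Supersets of the deployed defaults: beyond the main usage codes they
    include clinically adjacent codes that real coding practice substitutes
    for the specific ones — the neighbouring device-infection diagnosis
    DT845, the delayed-union diagnosis DM842, and prosthesis-insertion stems.
    """
    cfg = default_config()
    pool = {cause: tuple(alg.groups) for cause, alg in cfg.algorithms.items()}
    pool[CauseLabel.INFECTION] = pool[CauseLabel.INFECTION] + (
        PatternGroup("device_infection_adjacent_DT845", (_pp("DT845"),)),
    )
    pool[CauseLabel.NONUNION] = pool[CauseLabel.NONUNION] + (
        PatternGroup("delayed_union_DM842", (_pp("DM842"),)),
    )
    return pool
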