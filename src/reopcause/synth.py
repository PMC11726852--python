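"""Synthetic registry generator with known ground truth.

Emulates the discharge-level structure of a national administrative
register around fracture surgery: one index osteosynthesis per fracture
across seven anatomical regions, true reoperation causes at configurable
prevalences, and — crucially — a *coding-error model*: the contact of a
true reoperation always carries some surgical procedure code (the surgery
happened and was coded), but carries the cause-specific correct code only
with the configured probability, otherwise a plausible nonspecific or
adjacent decoy.  Defaults reflect the code-usage rates observed in validated
fracture cohorts: the correct infection procedure code present in 26% of
true infections, the correct infection diagnosis in 33%, both in 10%, and
so on per cause.  Because real stepwise algorithms reach sensitivities well
above the correct-code rates, infections and nonunions that carry neither
correct code receive an *adjacent* code (device-infection diagnosis DT845,
delayed-union DM842) with a calibrated probability, so that composing code
families genuinely pays off, as it does on real data.

Noise contacts (ER visits, new fractures in other regions, chronic-wound
surgery, planned K-wire / external-fixation removal, contralateral
procedures) exercise the finder's filters and the exclusion rules.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .causes import CauseLabel, REOPERATION_CAUSES, severity_rank
from .codes import REGION_LETTERS
from . import registry_io

#: Approximate primary-surgery volumes per region implied by a national
#: one-year fracture cohort (reoperation counts / region reoperation rates).
DEFAULT_REGION_MIX: dict[str, float] = {
    "B": 1093.0,  # shoulder / upper arm
    "C": 3400.0,  # elbow / forearm
    "D": 886.0,   # wrist / hand
    "E": 75.0,    # pelvis
    "F": 3416.0,  # hip / thigh
    "G": 909.0,   # knee / lower leg
    "H": 1688.0,  # ankle / foot
}

#: One-year cause prevalences in the population at risk.
DEFAULT_CAUSE_PREVALENCES: dict[CauseLabel, float] = {
    CauseLabel.HARDWARE_REMOVAL: 0.075,
    CauseLabel.WOUND_TREATMENT: 0.054,
    CauseLabel.RE_OSTEOSYNTHESIS: 0.017,
    CauseLabel.OTHER: 0.012,
    CauseLabel.INFECTION: 0.010,
    CauseLabel.SECONDARY_ARTHROPLASTY: 0.008,
    CauseLabel.NONUNION: 0.008,
}

#: Admissible reoperation-day windows per cause (inclusive).
CAUSE_DAY_WINDOWS: dict[CauseLabel, tuple[int, int]] = {
    CauseLabel.INFECTION: (1, 365),
    CauseLabel.NONUNION: (1, 365),
    CauseLabel.RE_OSTEOSYNTHESIS: (1, 42),
    CauseLabel.SECONDARY_ARTHROPLASTY: (43, 365),
    CauseLabel.HARDWARE_REMOVAL: (42, 365),
    CauseLabel.WOUND_TREATMENT: (1, 365),
    CauseLabel.OTHER: (1, 365),
}


@dataclass(frozen=True)
class CodingModel:
    """Probabilities that a true reoperation contact carries its correct codes.

    ``p_both`` couples the procedure and diagnosis draws; when neither
    correct code is drawn, an adjacent alternative code (if the cause has
    one) is emitted with ``p_alternative``.
    """

    p_correct_procedure: float = 1.0
    p_correct_diagnosis: float = 1.0
    p_both: float = 1.0
    p_alternative: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p_correct_procedure", "p_correct_diagnosis", "p_both", "p_alternative"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.p_both > min(self.p_correct_procedure, self.p_correct_diagnosis) + 1e-12:
            raise ValueError("p_both exceeds a marginal correct-code probability")
        if self.p_both < self.p_correct_procedure + self.p_correct_diagnosis - 1.0 - 1e-12:
            raise ValueError("p_both below the Frechet lower bound of its marginals")


DEFAULT_CODING_MODELS: dict[CauseLabel, CodingModel] = {
    CauseLabel.INFECTION: CodingModel(0.26, 0.33, 0.10, 0.55),
    CauseLabel.NONUNION: CodingModel(0.18, 0.11, 0.08, 0.77),
    CauseLabel.RE_OSTEOSYNTHESIS: CodingModel(0.90, 0.07, 0.06, 0.0),
    CauseLabel.SECONDARY_ARTHROPLASTY: CodingModel(0.03, 0.0, 0.0, 0.0),
    CauseLabel.HARDWARE_REMOVAL: CodingModel(0.99, 0.0, 0.0, 0.0),
    CauseLabel.WOUND_TREATMENT: CodingModel(0.99, 0.0, 0.0, 0.0),
    CauseLabel.OTHER: CodingModel(1.0, 0.0, 0.0, 0.0),
}

#: Per-fracture probabilities of noise contacts, roughly the false-positive
#: and filtered-contact rates seen in a national validation cohort.
DEFAULT_NOISE_RATES: dict[str, float] = {
    "er_visit": 0.009,          # minor ER procedure, same region -> false positive
    "new_fracture": 0.0016,     # fresh fracture surgery, different region
    "chronic_wound": 0.0011,    # chronic-ulcer surgery, caught by exclusions
    "kwire_removal": 0.0064,    # planned K-wire removal, caught by exclusions
    "exfix_removal": 0.0010,    # external-fixation removal, caught by exclusions
    "contralateral": 0.012,     # same procedure family, opposite side
    "other_region": 0.10,       # surgery in an unrelated region
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic cohort."""

    n_fractures: int
    seed: int
    region_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_REGION_MIX))
    cause_prevalences: dict[CauseLabel, float] = field(
        default_factory=lambda: dict(DEFAULT_CAUSE_PREVALENCES)
    )
    coding: dict[CauseLabel, CodingModel] = field(
        default_factory=lambda: dict(DEFAULT_CODING_MODELS)
    )
    laterality_missing_rate: float = 0.3
    noise_rates: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE_RATES))
    p_nonspecific_diagnosis: float = 0.3
    p_second_reoperation: float = 0.0
    censoring_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_fractures < 1:
            raise ValueError("n_fractures must be >= 1")
        if abs(sum(self.region_mix.values())) <= 0:
            raise ValueError("region_mix weights must have positive total")
        if set(self.region_mix) - set(REGION_LETTERS):
            raise ValueError("region_mix keys must be region letters B..H")
        prev_total = sum(self.cause_prevalences.values())
        if prev_total > 1.0 + 1e-9:
            raise ValueError(f"cause prevalences sum to {prev_total} > 1")
        for name in (
            "laterality_missing_rate",
            "p_nonspecific_diagnosis",
            "p_second_reoperation",
            "censoring_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for k, v in self.noise_rates.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"noise rate {k}={v} outside [0, 1]")

    @classmethod
    def default(cls, n_fractures: int, seed: int) -> "SyntheticConfig":
        return cls(n_fractures=n_fractures, seed=seed)

    @classmethod
    def zero_noise(cls, n_fractures: int, seed: int) -> "SyntheticConfig":
        """Every true cause perfectly coded; no noise contacts, no missing sides."""
        coding = {c: CodingModel(1.0, 1.0, 1.0, 0.0) for c in REOPERATION_CAUSES}
        coding[CauseLabel.OTHER] = CodingModel(1.0, 0.0, 0.0, 0.0)
        return cls(
            n_fractures=n_fractures,
            seed=seed,
            coding=coding,
            laterality_missing_rate=0.0,
            noise_rates={k: 0.0 for k in DEFAULT_NOISE_RATES},
            p_nonspecific_diagnosis=0.0,
        )

    def with_coding(self, cause: CauseLabel, model: CodingModel) -> "SyntheticConfig":
        coding = dict(self.coding)
        coding[CauseLabel(cause)] = model
        return replace(self, coding=coding)


# --- code emission ---------------------------------------------------------

def _correct_procedure(cause: CauseLabel, region: str, rng) -> str:
    if cause is CauseLabel.INFECTION:
        return f"KN{region}W69" if rng.random() < 0.5 else f"KN{region}W59"
    if cause is CauseLabel.NONUNION:
        return f"KN{region}T51"
    if cause is CauseLabel.RE_OSTEOSYNTHESIS:
        return f"KN{region}J62"
    if cause is CauseLabel.SECONDARY_ARTHROPLASTY:
        return f"KN{region}C20"
    if cause is CauseLabel.HARDWARE_REMOVAL:
        return f"KN{region}U29"
    if cause is CauseLabel.WOUND_TREATMENT:
        return f"KQ{region}E10"
    return f"KA{region}A10"  # "other": a nerve-chapter procedure, no cause code


def _correct_diagnosis(cause: CauseLabel, rng) -> str | None:
    if cause is CauseLabel.INFECTION:
        return "DT846"
    if cause is CauseLabel.NONUNION:
        return "DT813O" if rng.random() < 0.5 else "DM841"
    if cause is CauseLabel.RE_OSTEOSYNTHESIS:
        return f"DT84{rng.integers(0, 5)}"
    return None


def _alternative_code(cause: CauseLabel) -> str | None:
    if cause is CauseLabel.INFECTION:
        return "DT845"  # adjacent device-infection diagnosis
    if cause is CauseLabel.NONUNION:
        return "DM842"  # delayed union
    return None


def _decoy_procedure(cause: CauseLabel, region: str) -> str:
    """What the contact is coded as when the correct procedure code is absent."""
    if cause is CauseLabel.INFECTION:
        return f"KQ{region}E10"  # debridement coded as plain skin surgery
    if cause is CauseLabel.SECONDARY_ARTHROPLASTY:
        return f"KN{region}B20"  # coded as a primary prosthesis insertion
    if cause is CauseLabel.WOUND_TREATMENT:
        return f"KN{region}W89"
    return f"KN{region}T99"  # nonspecific musculoskeletal revision


NONSPECIFIC_DIAGNOSIS = "DT798"


@dataclass
class SyntheticCohort:
    """Generated tables plus the per-fracture generation log."""

    index_surgeries: pd.DataFrame
    events: pd.DataFrame
    gold_labels: pd.DataFrame
    log: pd.DataFrame
    config: SyntheticConfig

    def to_csv(self, directory: str | Path) -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "index_surgeries": directory / "index_surgeries.csv",
            "events": directory / "events.csv",
            "gold_labels": directory / "gold_labels.csv",
        }
        registry_io.write_index_surgeries(self.index_surgeries, paths["index_surgeries"])
        registry_io.write_events(self.events, paths["events"])
        registry_io.write_gold_labels(self.gold_labels, paths["gold_labels"])
        return paths


def _draw_cause(rng, prevalences: dict[CauseLabel, float]) -> CauseLabel:
    u = rng.random()
    acc = 0.0
    for cause in REOPERATION_CAUSES:  # fixed order for reproducibility
        acc += prevalences.get(cause, 0.0)
        if u < acc:
            return cause
    return CauseLabel.NOT_REOPERATION


def generate(config: SyntheticConfig) -> SyntheticCohort:
    """Generate a cohort; bit-identical for a fixed config (seed included)."""
    rng = np.random.default_rng(config.seed)
    regions = sorted(config.region_mix)
    weights = np.array([config.region_mix[r] for r in regions], dtype=float)
    weights = weights / weights.sum()
    base_date = pd.Timestamp("2016-01-01")

    surgeries, events, gold, log = [], [], [], []
    contact_counter = 0

    def new_contact_id() -> str:
        nonlocal contact_counter
        contact_counter += 1
        return f"C{contact_counter:07d}"

    def emit_contact(pid, date, codes, side) -> str:
        cid = new_contact_id()
        for code in codes:
            events.append(
                {
                    "patient_id": pid,
                    "date": date,
                    "code": code,
                    "laterality": side,
                    "contact_id": cid,
                }
            )
        return cid

    def reop_contact_codes(cause: CauseLabel, region: str) -> tuple[list[str], bool, bool, bool]:
        model = config.coding[cause]
        u = rng.random()
        if u < model.p_both:
            proc_ok, diag_ok = True, True
        elif u < model.p_correct_procedure:
            proc_ok, diag_ok = True, False
        elif u < model.p_correct_procedure + model.p_correct_diagnosis - model.p_both:
            proc_ok, diag_ok = False, True
        else:
            proc_ok, diag_ok = False, False
        codes = []
        codes.append(
            _correct_procedure(cause, region, rng) if proc_ok else _decoy_procedure(cause, region)
        )
        if diag_ok:
            diag = _correct_diagnosis(cause, rng)
            if diag is not None:
                codes.append(diag)
        alt_used = False
        if not proc_ok and not diag_ok and model.p_alternative > 0:
            alt = _alternative_code(cause)
            if alt is not None and rng.random() < model.p_alternative:
                codes.append(alt)
                alt_used = True
        if rng.random() < config.p_nonspecific_diagnosis:
            codes.append(NONSPECIFIC_DIAGNOSIS)
        return codes, proc_ok, diag_ok, alt_used

    for i in range(config.n_fractures):
        fid = f"F{i:06d}"
        pid = f"P{i:06d}"
        region = regions[int(rng.choice(len(regions), p=weights))]
        side = "right" if rng.random() < 0.5 else "left"
        surgery_date = base_date + pd.Timedelta(days=int(rng.integers(0, 365)))
        index_proc = f"KN{region}J49"
        surgeries.append(
            {
                "fracture_id": fid,
                "patient_id": pid,
                "surgery_date": surgery_date,
                "procedure": index_proc,
                "region": region,
                "laterality": side,
            }
        )
        emit_contact(pid, surgery_date, [index_proc, "DS424"], side)

        censor_day = 366
        if config.censoring_rate > 0 and rng.random() < config.censoring_rate:
            censor_day = int(rng.integers(1, 365))

        cause = _draw_cause(rng, config.cause_prevalences)
        true_cause = CauseLabel.NOT_REOPERATION
        reop_day = None
        proc_ok = diag_ok = alt_used = None
        if cause is not CauseLabel.NOT_REOPERATION:
            lo, hi = CAUSE_DAY_WINDOWS[cause]
            day = int(rng.integers(lo, hi + 1))
            if day <= censor_day:
                true_cause = cause
                reop_day = day
                codes, proc_ok, diag_ok, alt_used = reop_contact_codes(cause, region)
                reop_side = (
                    "unspecified" if rng.random() < config.laterality_missing_rate else side
                )
                emit_contact(pid, surgery_date + pd.Timedelta(days=day), codes, reop_side)

                if config.p_second_reoperation > 0 and rng.random() < config.p_second_reoperation:
                    lesser = [
                        c
                        for c in REOPERATION_CAUSES
                        if severity_rank(c) > severity_rank(cause)
                    ]
                    if lesser:
                        second = lesser[int(rng.choice(len(lesser)))]
                        lo2, hi2 = CAUSE_DAY_WINDOWS[second]
                        day2 = int(rng.integers(lo2, hi2 + 1))
                        if day2 <= censor_day:
                            codes2, *_ = reop_contact_codes(second, region)
                            side2 = (
                                "unspecified"
                                if rng.random() < config.laterality_missing_rate
                                else side
                            )
                            emit_contact(
                                pid, surgery_date + pd.Timedelta(days=day2), codes2, side2
                            )

        noise_flags = {}
        nr = config.noise_rates
        other_regions = [r for r in regions if r != region]

        def noise_day(lo=1, hi=365) -> int | None:
            day = int(rng.integers(lo, hi + 1))
            return day if day <= censor_day else None

        if rng.random() < nr.get("er_visit", 0.0):
            day = noise_day()
            if day is not None:
                emit_contact(
                    pid, surgery_date + pd.Timedelta(days=day), [f"KN{region}X09"], side
                )
                noise_flags["er_visit"] = True
        if rng.random() < nr.get("new_fracture", 0.0) and other_regions:
            day = noise_day()
            if day is not None:
                r2 = other_regions[int(rng.choice(len(other_regions)))]
                emit_contact(
                    pid, surgery_date + pd.Timedelta(days=day), [f"KN{r2}J49", "DS424"], side
                )
                noise_flags["new_fracture"] = True
        if rng.random() < nr.get("chronic_wound", 0.0):
            day = noise_day()
            if day is not None:
                emit_contact(
                    pid, surgery_date + pd.Timedelta(days=day), [f"KQ{region}E10", "DL97"], side
                )
                noise_flags["chronic_wound"] = True
        if rng.random() < nr.get("kwire_removal", 0.0):
            day = noise_day(14, 120)
            if day is not None:
                emit_contact(
                    pid, surgery_date + pd.Timedelta(days=day), [f"KN{region}U19"], side
                )
                noise_flags["kwire_removal"] = True
        if rng.random() < nr.get("exfix_removal", 0.0):
            day = noise_day(14, 120)
            if day is not None:
                emit_contact(
                    pid, surgery_date + pd.Timedelta(days=day), [f"KN{region}U09"], side
                )
                noise_flags["exfix_removal"] = True
        if rng.random() < nr.get("contralateral", 0.0):
            day = noise_day()
            if day is not None:
                flipped = "left" if side == "right" else "right"
                emit_contact(
                    pid, surgery_date + pd.Timedelta(days=day), [f"KN{region}U29"], flipped
                )
                noise_flags["contralateral"] = True
        if rng.random() < nr.get("other_region", 0.0) and other_regions:
            day = noise_day()
            if day is not None:
                r2 = other_regions[int(rng.choice(len(other_regions)))]
                emit_contact(
                    pid, surgery_date + pd.Timedelta(days=day), [f"KN{r2}U29"], side
                )
                noise_flags["other_region"] = True

        gold.append({"fracture_id": fid, "true_cause": true_cause.value, "source": "synthetic"})
        log.append(
            {
                "fracture_id": fid,
                "region": region,
                "laterality": side,
                "true_cause": true_cause.value,
                "reop_day": reop_day,
                "proc_correct": proc_ok,
                "diag_correct": diag_ok,
                "alt_used": alt_used,
                "censor_day": censor_day if censor_day <= 365 else None,
                **{f"noise_{k}": True for k in noise_flags},
            }
        )

    events_frame = pd.DataFrame(events)
    events_frame["kind"] = [
        "procedure" if c.startswith("K") else "diagnosis" for c in events_frame["code"]
    ]
    log_frame = pd.DataFrame(log)
    for col in [c for c in log_frame.columns if c.startswith("noise_")]:
        log_frame[col] = log_frame[col].eq(True)
    return SyntheticCohort(
        index_surgeries=pd.DataFrame(surgeries),
        events=events_frame,
        gold_labels=pd.DataFrame(gold),
        log=log_frame,
        config=config,
    )


def summarize(cohort: SyntheticCohort) -> dict:
    """Generation report: cause counts, observed coding rates, noise counts."""
    log = cohort.log
    n = len(log)
    cause_counts = log["true_cause"].value_counts().to_dict()
    coding = {}
    for cause in REOPERATION_CAUSES:
        sub = log[log["true_cause"] == cause.value]
        if sub.empty:
            continue
        proc = sub["proc_correct"].astype(float)
        diag = sub["diag_correct"].astype(float)
        coding[cause.value] = {
            "n": int(len(sub)),
            "p_correct_procedure": float(proc.mean()),
            "p_correct_diagnosis": float(diag.mean()),
            "p_both": float((proc.astype(bool) & diag.astype(bool)).mean()),
            "p_either": float((proc.astype(bool) | diag.astype(bool)).mean()),
            "p_alternative_used": float(sub["alt_used"].astype(float).mean()),
        }
    noise = {
        col.removeprefix("noise_"): int(log[col].sum())
        for col in log.columns
        if col.startswith("noise_")
    }
    return {
        "n_fractures": n,
        "cause_counts": cause_counts,
        "coding_rates": coding,
        "noise_counts": noise,
        "seed": cohort.config.seed,
    }
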