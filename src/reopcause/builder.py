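"""Stepwise construction of cause-identification algorithms.

The construction mirrors how coded-data phenotyping algorithms are grown in
validation studies: candidate code families are ranked by the strength of
their univariate association with the gold label, then composed into
cumulative "or" steps — step k classifies a fracture positive when any of
the top-k families fires.  Adding families can only widen the positive set,
so sensitivity is non-decreasing across steps while PPV typically falls;
the deployed step is the one maximising Cohen's kappa (first occurrence on
ties, favouring parsimony).

The ranking statistic is the likelihood-ratio G^2 of the 2x2
pattern-fires x gold table — identical to the LR test of a single-predictor
logistic regression but finite and deterministic under complete separation
— signed by the direction of association.  Ties break by higher PPV, then
by group name.

:class:`StepwiseCauseModel` holds the per-fracture fire matrix and gold
labels; ``fit()`` returns a :class:`StepwiseResults` carrying the full
accuracy report of every step, the selected step, a ``summary()`` table and
a sensitivity/PPV trade-off ``plot()``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .causes import CauseLabel, MAJOR_CAUSES, MINOR_CAUSES
from .codesets import CauseAlgorithm, CodeSetConfig, PatternGroup, window_contains
from .classifier import algorithm_fires
from .codes import Code, matches
from .stats import AccuracyReport, ConfusionCounts, confusion, round_half_up


def _group_fires_for_fracture(group: PatternGroup, window, candidates: pd.DataFrame) -> bool:
    for row in candidates.itertuples():
        day = int(row.days_since_index)
        gwin = group.window if group.window is not None else window
        if not window_contains(gwin, day):
            continue
        codes = [Code.parse(c) for c in tuple(row.procedure_codes) + tuple(row.diagnosis_codes)]
        for pattern in group.patterns:
            if any(pattern.kind is c.kind and matches(pattern, c) for c in codes):
                return True
    return False


def fire_matrix(
    candidates: pd.DataFrame,
    index_surgeries: pd.DataFrame,
    groups: tuple[PatternGroup, ...],
    window=(None, None),
) -> pd.DataFrame:
    """Boolean fracture x pattern-group matrix of rule firings."""
    fracture_ids = list(index_surgeries["fracture_id"])
    by_fracture = (
        dict(tuple(candidates.groupby("fracture_id"))) if not candidates.empty else {}
    )
    data = {}
    empty = candidates.iloc[0:0]
    for group in groups:
        data[group.name] = [
            _group_fires_for_fracture(group, window, by_fracture.get(fid, empty))
            for fid in fracture_ids
        ]
    return pd.DataFrame(data, index=pd.Index(fracture_ids, name="fracture_id"))


def _signed_g2(tp: int, fp: int, fn: int, tn: int) -> float:
    """Likelihood-ratio statistic of the 2x2 table, signed by direction."""
    n = tp + fp + fn + tn
    g2 = 0.0
    for obs, row_tot, col_tot in (
        (tp, tp + fp, tp + fn),
        (fp, tp + fp, fp + tn),
        (fn, fn + tn, tp + fn),
        (tn, fn + tn, fp + tn),
    ):
        if obs > 0:
            exp = row_tot * col_tot / n
            g2 += 2.0 * obs * math.log(obs / exp)
    sign = 1.0 if tp * tn >= fp * fn else -1.0
    return sign * g2


class StepwiseCauseModel:
    """Stepwise "or"-composition model for one reoperation cause.

    Parameters
    ----------
    fires : DataFrame
        Boolean fracture x pattern-group matrix (which code family fired for
        which fracture, inside its admissible day window).
    gold : Series
        Boolean gold labels, indexed like ``fires``.
    cause : CauseLabel, optional
        The cause being modelled, for reporting.
    """

    def __init__(self, fires: pd.DataFrame, gold: pd.Series, cause: CauseLabel | None = None):
        if not fires.index.equals(gold.index):
            gold = gold.reindex(fires.index)
            if gold.isna().any():
                raise ValueError("gold labels missing for some fractures in the fire matrix")
        if fires.shape[1] == 0:
            raise ValueError("no candidate pattern groups")
        self.fires = fires.astype(bool)
        self.gold = gold.astype(bool)
        self.cause = CauseLabel(cause) if cause is not None else None
        if not self.gold.any() or self.gold.all():
            raise ValueError("gold labels must contain at least one positive and one negative")

    @classmethod
    def from_cohort(
        cls,
        candidates: pd.DataFrame,
        index_surgeries: pd.DataFrame,
        gold_labels: pd.DataFrame,
        cause: CauseLabel,
        pattern_pool: tuple[PatternGroup, ...],
        window=(None, None),
    ) -> "StepwiseCauseModel":
        """Build the fire matrix from candidate reoperations and gold labels."""
        cause = CauseLabel(cause)
        fires = fire_matrix(candidates, index_surgeries, pattern_pool, window)
        gold = (
            gold_labels.set_index("fracture_id")["true_cause"].reindex(fires.index)
            == cause.value
        )
        return cls(fires, gold, cause)

    def rank_patterns(self) -> list[str]:
        """Pattern groups ordered by decreasing association with the gold label."""
        scored = []
        for name in self.fires.columns:
            f = self.fires[name]
            tp = int((f & self.gold).sum())
            fp = int((f & ~self.gold).sum())
            fn = int((~f & self.gold).sum())
            tn = int((~f & ~self.gold).sum())
            score = _signed_g2(tp, fp, fn, tn) if f.any() else 0.0
            group_ppv = tp / (tp + fp) if (tp + fp) else -1.0
            scored.append((-score, -group_ppv, name))
        return [name for _, _, name in sorted(scored)]

    def fit(self, max_steps: int | None = None) -> "StepwiseResults":
        """Compose cumulative steps in rank order and select the kappa-best."""
        if max_steps is not None and max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        order = self.rank_patterns()
        if max_steps is not None:
            order = order[:max_steps]
        reports: list[AccuracyReport] = []
        union = pd.Series(False, index=self.fires.index)
        for name in order:
            union = union | self.fires[name]
            reports.append(AccuracyReport.from_counts(confusion(union, self.gold)))
        kappas = [r.kappa for r in reports]
        selected = int(np.argmax(kappas)) + 1  # first occurrence wins ties
        return StepwiseResults(self, tuple(order), tuple(reports), selected)


@dataclass(frozen=True)
class StepwiseResults:
    """Fitted step trace: per-step accuracy, selection, summary, plotting."""

    model: StepwiseCauseModel
    order: tuple[str, ...]
    reports: tuple[AccuracyReport, ...]
    selected_step: int

    @property
    def selected_report(self) -> AccuracyReport:
        return self.reports[self.selected_step - 1]

    def fires_at_step(self, step: int | None = None) -> pd.Series:
        """Boolean per-fracture prediction of the (selected) step."""
        step = self.selected_step if step is None else step
        cols = list(self.order[:step])
        return self.model.fires[cols].any(axis=1)

    @property
    def frame(self) -> pd.DataFrame:
        rows = []
        for k, (name, rep) in enumerate(zip(self.order, self.reports), start=1):
            row = {"step": k, "added_group": name, "selected": k == self.selected_step}
            row.update(rep.to_row())
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        cause = self.model.cause.value if self.model.cause else "cause"
        lines = [
            f"Stepwise algorithm construction: {cause}",
            f"fractures: {len(self.model.gold)}  positives: {int(self.model.gold.sum())}",
            f"selected step: {self.selected_step} (kappa-maximal)",
            "",
            f"{'step':>4} {'sens % (CI)':>16} {'PPV % (CI)':>16} {'spec %':>7} "
            f"{'kappa':>6} {'AUC':>5}  added group",
        ]
        for k, (name, rep) in enumerate(zip(self.order, self.reports), start=1):
            sens = rep.sensitivity.display() if rep.sensitivity else "--"
            ppv = rep.ppv.display() if rep.ppv else "--"
            spec = (
                f"{round_half_up(rep.specificity.estimate, 1):.1f}" if rep.specificity else "--"
            )
            auc = f"{rep.auc:.2f}" if rep.auc is not None else "--"
            mark = "*" if k == self.selected_step else " "
            lines.append(
                f"{k:>3}{mark} {sens:>16} {ppv:>16} {spec:>7} {rep.kappa:>6.2f} {auc:>5}  {name}"
            )
        lines.append("")
        lines.append("* kappa-maximal (deployed) step")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Sensitivity / PPV trade-off across steps (the classic staircase)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        steps = list(range(1, len(self.reports) + 1))
        sens = [r.sensitivity.estimate if r.sensitivity else float("nan") for r in self.reports]
        ppv = [r.ppv.estimate if r.ppv else float("nan") for r in self.reports]
        ax.plot(steps, sens, marker="o", label="sensitivity")
        ax.plot(steps, ppv, marker="s", label="PPV")
        ax.axvline(self.selected_step, linestyle="--", color="grey", label="selected step")
        ax.set_xlabel("step")
        ax.set_ylabel("%")
        ax.set_ylim(0, 105)
        if self.model.cause:
            ax.set_title(f"Stepwise trade-off: {self.model.cause.value}")
        ax.legend()
        return ax

    def to_algorithm(self, groups_by_name: dict[str, PatternGroup], window=(None, None)) -> CauseAlgorithm:
        """Freeze the fitted trace into a deployable CauseAlgorithm."""
        ordered = tuple(groups_by_name[name] for name in self.order)
        return CauseAlgorithm(self.model.cause, ordered, self.selected_step, window)


def combine_composite(
    results: dict[CauseLabel, StepwiseResults],
    gold_labels: pd.DataFrame,
    composite: str,
) -> AccuracyReport:
    """Score the union of selected-step algorithms against a composite label.

    ``composite`` is "major" (infection, nonunion, early re-osteosynthesis,
    secondary arthroplasty) or "minor" (hardware removal, wound treatment).
    """
    causes = MAJOR_CAUSES if composite == "major" else MINOR_CAUSES
    members = {CauseLabel(c): r for c, r in results.items() if CauseLabel(c) in causes}
    if not members:
        raise ValueError(f"no constituent results for composite {composite!r}")
    union = None
    for res in members.values():
        f = res.fires_at_step()
        union = f if union is None else (union | f)
    gold = gold_labels.set_index("fracture_id")["true_cause"].reindex(union.index)
    gold_bool = gold.isin([c.value for c in causes])
    return AccuracyReport.from_counts(confusion(union, gold_bool))


def build_all(
    candidates: pd.DataFrame,
    index_surgeries: pd.DataFrame,
    gold_labels: pd.DataFrame,
    pools: dict[CauseLabel, tuple[PatternGroup, ...]],
    config: CodeSetConfig | None = None,
    max_steps: int | None = None,
) -> dict[CauseLabel, StepwiseResults]:
    """Fit a stepwise model per cause; cause day windows come from config."""
    results = {}
    for cause, pool in pools.items():
        cause = CauseLabel(cause)
        window = config.algorithm(cause).window if config is not None else (None, None)
        model = StepwiseCauseModel.from_cohort(
            candidates, index_surgeries, gold_labels, cause, pool, window
        )
        results[cause] = model.fit(max_steps)
    return results
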