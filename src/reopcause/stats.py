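"""Diagnostic-accuracy statistics for 2x2 validation tables.

Sensitivity = 100*tp/(tp+fn), PPV = 100*tp/(tp+fp), specificity and NPV
analogously; 95% intervals are exact Clopper-Pearson; agreement is Cohen's
kappa; the AUC of a single deployed binary rule is its balanced accuracy
(sensitivity + specificity)/2.  Undefined metrics (zero denominators)
propagate as None, never as 0 and never as an exception.

Validation tables are often published as marginals plus the correct
diagonal (all test-positives TP with true positives TrP among them, all
test-negatives TN with true negatives TrN among them);
``ConfusionCounts.from_marginals`` rebuilds the four cells from that shape.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy.stats import beta


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Display rounding with .5 going away from zero, as printed tables do."""
    factor = 10.0 ** ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class ConfusionCounts:
    """The four cells of a test-vs-gold 2x2 table."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion cells must be non-negative")
        if self.total == 0:
            raise ValueError("empty confusion table")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_marginals(cls, test_pos: int, true_pos: int, test_neg: int, true_neg: int) -> "ConfusionCounts":
        """Rebuild cells from published marginals + diagonal.

        ``test_pos``/``test_neg`` are the column totals (all test-positive /
        test-negative), ``true_pos``/``true_neg`` the correctly classified
        counts within each column.
        """
        if true_pos > test_pos or true_neg > test_neg:
            raise ValueError("diagonal exceeds its marginal")
        return cls(tp=true_pos, fp=test_pos - true_pos, fn=test_neg - true_neg, tn=true_neg)


def confusion(predicted: pd.Series, gold: pd.Series) -> ConfusionCounts:
    """Cross-tabulate boolean predictions against boolean gold labels.

    Both series must be indexed by the same observation ids.
    """
    if len(predicted) != len(gold) or not predicted.index.sort_values().equals(
        gold.index.sort_values()
    ):
        raise ValueError("prediction and gold-label ids do not match")
    gold = gold.reindex(predicted.index)
    p = predicted.astype(bool)
    g = gold.astype(bool)
    return ConfusionCounts(
        tp=int((p & g).sum()),
        fp=int((p & ~g).sum()),
        fn=int((~p & g).sum()),
        tn=int((~p & ~g).sum()),
    )


def sensitivity(counts: ConfusionCounts) -> float | None:
    d = counts.tp + counts.fn
    return None if d == 0 else 100.0 * counts.tp / d


def ppv(counts: ConfusionCounts) -> float | None:
    d = counts.tp + counts.fp
    return None if d == 0 else 100.0 * counts.tp / d


def specificity_npv(counts: ConfusionCounts) -> tuple[float | None, float | None]:
    sd = counts.tn + counts.fp
    nd = counts.tn + counts.fn
    spec = None if sd == 0 else 100.0 * counts.tn / sd
    npv = None if nd == 0 else 100.0 * counts.tn / nd
    return spec, npv


@dataclass(frozen=True)
class ProportionCI:
    """A percentage with its exact binomial confidence interval."""

    estimate: float
    lower: float
    upper: float
    level: float = 0.95

    def __post_init__(self) -> None:
        if not 0 <= self.lower <= self.estimate <= self.upper <= 100:
            raise ValueError(
                f"inconsistent interval {self.lower}..{self.estimate}..{self.upper}"
            )

    def display(self) -> str:
        return (
            f"{round_half_up(self.estimate):.0f}"
            f" ({round_half_up(self.lower):.0f}-{round_half_up(self.upper):.0f})"
        )


def clopper_pearson(successes: int, n: int, level: float = 0.95) -> ProportionCI:
    """Exact binomial interval via the beta-quantile characterisation.

    Lower bound is 0 when successes = 0 and upper is 100 when successes = n,
    matching the inversion of the exact binomial test at alpha/2 per tail.
    """
    if n < 1 or not 0 <= successes <= n:
        raise ValueError(f"invalid counts {successes}/{n}")
    alpha = 1.0 - level
    lo = 0.0 if successes == 0 else float(beta.ppf(alpha / 2, successes, n - successes + 1))
    hi = 1.0 if successes == n else float(beta.ppf(1 - alpha / 2, successes + 1, n - successes))
    return ProportionCI(100.0 * successes / n, 100.0 * lo, 100.0 * hi, level)


def cohen_kappa(counts: ConfusionCounts) -> float:
    """Chance-corrected agreement of the 2x2 table; 1.0 at degenerate perfect agreement."""
    t = counts.total
    po = (counts.tp + counts.tn) / t
    pe = (
        (counts.tp + counts.fp) * (counts.tp + counts.fn)
        + (counts.fn + counts.tn) * (counts.fp + counts.tn)
    ) / (t * t)
    if pe == 1.0:
        return 1.0 if po == 1.0 else 0.0
    return (po - pe) / (1.0 - pe)


def binary_auc(counts: ConfusionCounts) -> float | None:
    """AUC of a single binary rule: balanced accuracy (sens + spec)/2, as fractions."""
    pos = counts.tp + counts.fn
    neg = counts.fp + counts.tn
    if pos == 0 or neg == 0:
        return None
    return (counts.tp / pos + counts.tn / neg) / 2.0


def cumulative_incidence(cases: int, at_risk: int) -> float:
    """Percent of the population at risk with the event during follow-up."""
    if at_risk <= 0:
        raise ValueError("at_risk must be positive")
    return 100.0 * cases / at_risk


@dataclass(frozen=True)
class AccuracyReport:
    """Full accuracy panel for one algorithm against the gold standard."""

    counts: ConfusionCounts
    sensitivity: ProportionCI | None
    ppv: ProportionCI | None
    specificity: ProportionCI | None
    npv: ProportionCI | None
    kappa: float
    auc: float | None

    @classmethod
    def from_counts(cls, counts: ConfusionCounts, level: float = 0.95) -> "AccuracyReport":
        def ci(k: int, n: int) -> ProportionCI | None:
            return None if n == 0 else clopper_pearson(k, n, level)

        return cls(
            counts=counts,
            sensitivity=ci(counts.tp, counts.tp + counts.fn),
            ppv=ci(counts.tp, counts.tp + counts.fp),
            specificity=ci(counts.tn, counts.tn + counts.fp),
            npv=ci(counts.tn, counts.tn + counts.fn),
            kappa=cohen_kappa(counts),
            auc=binary_auc(counts),
        )

    def to_row(self) -> dict:
        def est(ci: ProportionCI | None):
            return None if ci is None else ci.estimate

        def lo(ci: ProportionCI | None):
            return None if ci is None else ci.lower

        def hi(ci: ProportionCI | None):
            return None if ci is None else ci.upper

        return {
            "sensitivity_pct": est(self.sensitivity),
            "sensitivity_ci_low": lo(self.sensitivity),
            "sensitivity_ci_high": hi(self.sensitivity),
            "ppv_pct": est(self.ppv),
            "ppv_ci_low": lo(self.ppv),
            "ppv_ci_high": hi(self.ppv),
            "specificity_pct": est(self.specificity),
            "npv_pct": est(self.npv),
            "kappa": self.kappa,
            "auc": self.auc,
            "tp": self.counts.tp,
            "fp": self.counts.fp,
            "fn": self.counts.fn,
            "tn": self.counts.tn,
        }


def accuracy_table(reports: dict[str, AccuracyReport]) -> pd.DataFrame:
    """Validation-table-shaped frame: one row per algorithm/cause."""
    frame = pd.DataFrame({name: rep.to_row() for name, rep in reports.items()}).T
    frame.index.name = "cause"
    return frame


def write_accuracy_report(reports: dict[str, AccuracyReport], path: str | Path) -> None:
    """Write the accuracy panel as CSV or JSON depending on the suffix."""
    path = Path(path)
    table = accuracy_table(reports)
    if path.suffix.lower() == ".json":
        path.write_text(
            json.dumps({k: rep.to_row() for k, rep in reports.items()}, indent=2) + "\n",
            encoding="utf-8",
        )
    else:
        table.to_csv(path)
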