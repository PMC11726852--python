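"""Diagnostic-accuracy statistics against independent oracles.

The printed-table regressions use validation rows published as marginals
plus the correctly classified diagonal; cells are rebuilt with
``ConfusionCounts.from_marginals`` and every internally consistent metric
must round back to its printed value.
"""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import binom
from sklearn.metrics import cohen_kappa_score

from reopcause.stats import (
    AccuracyReport,
    ConfusionCounts,
    binary_auc,
    clopper_pearson,
    cohen_kappa,
    confusion,
    cumulative_incidence,
    ppv,
    round_half_up,
    sensitivity,
    specificity_npv,
)


def cells(tp, fp, fn, tn):
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


# Published validation rows: (test_pos, diag_tp, test_neg, diag_tn) and the
# printed integers they must reproduce after display rounding.
PRINTED_ROWS = {
    "infection": dict(marg=(103, 88, 2244, 2218), sens=77, ppv=85, kappa=0.80, auc=0.88),
    "nonunion": dict(marg=(138, 77, 2209, 2192), sens=82, ppv=56, kappa=0.65, auc=0.90),
    "re_osteosynthesis": dict(marg=(233, 175, 2114, 2094), sens=90, ppv=75, kappa=0.80, auc=0.94),
    "major": dict(marg=(570, 441, 1777, 1721), sens=89, ppv=77, kappa=None, auc=0.91),
    "minor": dict(marg=(1667, 1485, 680, 671), sens=99, ppv=89, kappa=0.82, auc=None),
    "hardware_removal": dict(marg=(917, 862, 1430, 1422), sens=99, ppv=94, kappa=None, auc=None),
    "wound_treatment": dict(marg=(753, 621, 1594, 1591), sens=None, ppv=None, kappa=0.86, auc=0.96),
}


class TestPrintedRowRegression:
    @pytest.mark.parametrize("name", sorted(PRINTED_ROWS))
    def test_metrics_round_to_printed_values(self, name):
        row = PRINTED_ROWS[name]
        c = ConfusionCounts.from_marginals(*row["marg"])
        if row["sens"] is not None:
            assert round_half_up(sensitivity(c)) == row["sens"]
        if row["ppv"] is not None:
            assert round_half_up(ppv(c)) == row["ppv"]
        if row["kappa"] is not None:
            assert round_half_up(cohen_kappa(c), 2) == row["kappa"]
        if row["auc"] is not None:
            assert round_half_up(binary_auc(c), 2) == row["auc"]

    def test_marginal_reconstruction_of_infection_row(self):
        c = ConfusionCounts.from_marginals(103, 88, 2244, 2218)
        assert (c.tp, c.fp, c.fn, c.tn) == (88, 15, 26, 2218)
        assert c.total == 2347

    def test_inconsistent_diagonal_rejected(self):
        # a diagonal exceeding its marginal is impossible
        with pytest.raises(ValueError):
            ConfusionCounts.from_marginals(104, 90, 2234, 2238)

    def test_overall_identification_ppv(self):
        assert round_half_up(ppv(cells(2212, 135, 0, 0))) == 94

    def test_specificity_from_reconstructed_cells(self):
        spec, _ = specificity_npv(cells(88, 15, 26, 2218))
        assert round_half_up(spec, 1) == 99.3
        spec_wound, _ = specificity_npv(cells(621, 132, 3, 1591))
        assert round_half_up(spec_wound, 1) == 92.3


class TestClopperPearson:
    def test_infection_sensitivity_interval(self):
        ci = clopper_pearson(88, 114)
        assert round_half_up(ci.lower) == 68
        assert round_half_up(ci.upper) == 85

    def test_degenerate_bounds(self):
        assert clopper_pearson(0, 10).lower == 0.0
        assert clopper_pearson(10, 10).upper == 100.0

    @pytest.mark.parametrize("n", [1, 2, 5, 13, 30])
    def test_matches_binomial_tail_inversion(self, n):
        """Bounds invert the exact binomial test at alpha/2 per tail."""
        alpha = 0.05
        grid = np.linspace(1e-9, 1 - 1e-9, 4001)
        for k in range(n + 1):
            ci = clopper_pearson(k, n)
            if k > 0:
                # lower bound: smallest p with P(X >= k) >= alpha/2
                upper_tail = 1 - binom.cdf(k - 1, n, grid)
                lo_oracle = grid[np.argmax(upper_tail >= alpha / 2)]
                assert math.isclose(ci.lower / 100, lo_oracle, abs_tol=5e-4)
            if k < n:
                # upper bound: largest p with P(X <= k) >= alpha/2
                lower_tail = binom.cdf(k, n, grid)
                hi_oracle = grid[len(grid) - 1 - np.argmax(lower_tail[::-1] >= alpha / 2)]
                assert math.isclose(ci.upper / 100, hi_oracle, abs_tol=5e-4)

    @settings(derandomize=True, max_examples=60)
    @given(k=st.integers(0, 40), n=st.integers(1, 40))
    def test_interval_contains_estimate(self, k, n):
        k = min(k, n)
        ci = clopper_pearson(k, n)
        assert ci.lower <= ci.estimate <= ci.upper

    def test_width_shrinks_with_n_at_fixed_proportion(self):
        widths = []
        for mult in (1, 2, 4, 8, 16):
            ci = clopper_pearson(3 * mult, 10 * mult)
            widths.append(ci.upper - ci.lower)
        assert widths == sorted(widths, reverse=True)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            clopper_pearson(5, 4)
        with pytest.raises(ValueError):
            clopper_pearson(0, 0)


class TestKappaAndAuc:
    def test_perfect_agreement(self):
        assert cohen_kappa(cells(10, 0, 0, 10)) == 1.0

    @settings(derandomize=True, max_examples=60)
    @given(
        tp=st.integers(0, 50), fp=st.integers(0, 50),
        fn=st.integers(0, 50), tn=st.integers(0, 50),
    )
    def test_matches_sklearn_and_bounded_by_po(self, tp, fp, fn, tn):
        if tp + fp + fn + tn == 0:
            return
        c = cells(tp, fp, fn, tn)
        pred = [1] * tp + [1] * fp + [0] * fn + [0] * tn
        gold = [1] * tp + [0] * fp + [1] * fn + [0] * tn
        expected = cohen_kappa_score(gold, pred) if len(set(gold)) > 1 and len(set(pred)) > 1 else None
        k = cohen_kappa(c)
        if expected is not None and not math.isnan(expected):
            assert math.isclose(k, expected, abs_tol=1e-12)
        po = (tp + tn) / c.total
        assert k <= po + 1e-12

    def test_zero_for_independent_labels(self):
        rng = np.random.default_rng(5)
        n = 20000
        gold = rng.random(n) < 0.3
        pred = rng.random(n) < 0.5
        c = confusion(pd.Series(pred), pd.Series(gold))
        assert abs(cohen_kappa(c)) < 0.02  # Monte-Carlo tolerance

    def test_auc_balanced_accuracy_and_scale_invariance(self):
        c = cells(88, 15, 26, 2218)
        assert round_half_up(binary_auc(c), 2) == 0.88
        scaled = cells(88 * 7, 15 * 7, 26 * 7, 2218 * 7)
        assert math.isclose(binary_auc(c), binary_auc(scaled))

    def test_chance_rule_has_auc_half(self):
        # sensitivity = 1 - specificity: 60% positive rate on both classes
        assert math.isclose(binary_auc(cells(60, 60, 40, 40)), 0.5)


class TestEdgeCasesAndHelpers:
    def test_undefined_metrics_propagate_as_none(self):
        c = cells(0, 0, 0, 5)
        assert sensitivity(c) is None
        assert ppv(c) is None
        rep = AccuracyReport.from_counts(c)
        assert rep.sensitivity is None and rep.ppv is None
        assert rep.specificity is not None

    def test_cumulative_incidence(self):
        assert round_half_up(cumulative_incidence(114, 11551), 1) == 1.0
        assert round_half_up(cumulative_incidence(870, 11551), 1) == 7.5
        assert cumulative_incidence(0, 100) == 0.0
        with pytest.raises(ValueError):
            cumulative_incidence(1, 0)

    def test_confusion_requires_matching_ids(self):
        pred = pd.Series([True, False], index=["a", "b"])
        gold = pd.Series([True, False], index=["a", "c"])
        with pytest.raises(ValueError, match="ids do not match"):
            confusion(pred, gold)

    def test_confusion_counts_examples(self):
        pred = pd.Series([True] * 4 + [False] * 6)
        c = confusion(pred, pred)
        assert (c.tp, c.fp, c.fn, c.tn) == (4, 0, 0, 6)
        gold = pd.Series([True] * 3 + [False] * 7)
        c2 = confusion(pd.Series([False] * 10), gold)
        assert (c2.tp, c2.fp, c2.fn, c2.tn) == (0, 0, 3, 7)

    def test_display_rounding_half_away_from_zero(self):
        assert round_half_up(84.5) == 85
        assert round_half_up(0.645, 2) == 0.65
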