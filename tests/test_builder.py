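"""Stepwise algorithm construction: ranking, step traces, kappa-maximal selection."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import cohen_kappa_score

from reopcause.builder import StepwiseCauseModel, combine_composite
from reopcause.causes import CauseLabel


def model_from_arrays(fires: dict, gold, cause=None) -> StepwiseCauseModel:
    frame = pd.DataFrame({k: np.asarray(v, dtype=bool) for k, v in fires.items()})
    return StepwiseCauseModel(frame, pd.Series(np.asarray(gold, dtype=bool)), cause)


def random_model(rng, n=120, k=5):
    gold = rng.random(n) < 0.3
    fires = {}
    for j in range(k):
        sens = rng.uniform(0.1, 0.9)
        fpr = rng.uniform(0.0, 0.3)
        fires[f"g{j}"] = np.where(gold, rng.random(n) < sens, rng.random(n) < fpr)
    return model_from_arrays(fires, gold)


class TestRanking:
    def test_dominant_pattern_ranked_first(self):
        rng = np.random.default_rng(0)
        n = 1000
        gold = np.arange(n) < 300
        a = np.where(gold, rng.random(n) < 0.9, rng.random(n) < 0.01)
        b = np.where(gold, rng.random(n) < 0.1, rng.random(n) < 0.05)
        model = model_from_arrays({"A": a, "B": b}, gold)
        assert model.rank_patterns() == ["A", "B"]

    def test_never_firing_pattern_ranked_last(self):
        gold = [True] * 5 + [False] * 15
        model = model_from_arrays(
            {"silent": [False] * 20, "useful": gold}, gold
        )
        assert model.rank_patterns()[-1] == "silent"

    def test_complete_separation_handled_deterministically(self):
        # fires exactly in the positives: top rank, no divergence
        gold = [True] * 4 + [False] * 16
        noisy = [True] * 2 + [False] * 10 + [True] * 8
        model = model_from_arrays({"perfect": gold, "noisy": noisy}, gold)
        assert model.rank_patterns()[0] == "perfect"
        assert model.fit().selected_step == 1

    def test_ties_break_by_ppv_then_name(self):
        gold = [True] * 4 + [False] * 4
        # b and a have identical 2x2 tables -> name breaks the tie
        same = [True, True, False, False, False, False, False, False]
        model = model_from_arrays({"b": same, "a": same}, gold)
        assert model.rank_patterns() == ["a", "b"]


class TestStepTrace:
    def test_perfect_single_pattern(self):
        gold = [True] * 6 + [False] * 14
        model = model_from_arrays({"exact": gold, "junk": [False] * 20}, gold)
        res = model.fit()
        assert res.selected_step == 1
        assert res.selected_report.kappa == 1.0
        assert res.selected_report.sensitivity.estimate == 100.0

    def test_negative_only_pattern_lowers_ppv_not_selection(self):
        gold = [True] * 10 + [False] * 30
        good = gold.copy()
        bad = [False] * 10 + [True] * 8 + [False] * 22  # fires only in negatives
        model = model_from_arrays({"good": good, "bad": bad}, gold)
        res = model.fit()
        assert res.order == ("good", "bad")
        assert res.selected_step == 1
        assert res.reports[1].kappa < res.reports[0].kappa
        assert res.reports[1].ppv.estimate < res.reports[0].ppv.estimate
        assert res.reports[1].sensitivity.estimate == res.reports[0].sensitivity.estimate

    @settings(derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10_000))
    def test_sensitivity_and_test_positives_non_decreasing(self, seed):
        model = random_model(np.random.default_rng(seed))
        res = model.fit()
        sens = [r.sensitivity.estimate for r in res.reports]
        npos = [r.counts.tp + r.counts.fp for r in res.reports]
        assert sens == sorted(sens)
        assert npos == sorted(npos)

    @settings(derandomize=True, max_examples=20)
    @given(seed=st.integers(0, 10_000), k=st.integers(2, 12))
    def test_selection_matches_exhaustive_search(self, seed, k):
        """Kappa-argmax over cumulative unions, recomputed independently."""
        model = random_model(np.random.default_rng(seed), n=150, k=k)
        res = model.fit()
        order = list(res.order)
        gold = model.gold.to_numpy()
        best_step, best_kappa = None, -np.inf
        union = np.zeros(len(gold), dtype=bool)
        for step, name in enumerate(order, start=1):
            union = union | model.fires[name].to_numpy()
            kappa = cohen_kappa_score(gold, union) if union.any() and not union.all() else (
                1.0 if (union == gold).all() else 0.0
            )
            if kappa > best_kappa + 1e-12:
                best_step, best_kappa = step, kappa
        assert res.selected_step == best_step
        assert res.selected_report.kappa == pytest.approx(best_kappa, abs=1e-9)

    def test_max_steps_contract(self):
        model = random_model(np.random.default_rng(1))
        with pytest.raises(ValueError):
            model.fit(max_steps=0)
        assert len(model.fit(max_steps=1).reports) == 1

    def test_degenerate_gold_rejected(self):
        with pytest.raises(ValueError, match="positive and one negative"):
            model_from_arrays({"a": [True, False]}, [True, True])

    def test_summary_mentions_selected_step(self):
        model = random_model(np.random.default_rng(2))
        res = model.fit()
        text = res.summary()
        assert f"selected step: {res.selected_step}" in text
        assert "kappa" in text


class TestParameterRecovery:
    def test_generative_informativeness_order_recovered(self):
        """Patterns generated with graded sensitivity rank in generative order."""
        rng = np.random.default_rng(77)
        n = 500
        gold = rng.random(n) < 0.25
        sens_by_pattern = {"strong": 0.85, "medium": 0.50, "weak": 0.15}
        fires = {
            name: np.where(gold, rng.random(n) < s, rng.random(n) < 0.02)
            for name, s in sens_by_pattern.items()
        }
        model = model_from_arrays(fires, gold)
        assert model.rank_patterns() == ["strong", "medium", "weak"]


class TestComposite:
    def _results(self, gold_causes, fires_by_cause):
        gold = pd.DataFrame(
            {"fracture_id": [f"F{i}" for i in range(len(gold_causes))], "true_cause": gold_causes}
        )
        results = {}
        for cause, fire in fires_by_cause.items():
            g = [c == cause.value for c in gold_causes]
            frame = pd.DataFrame(
                {"only": np.asarray(fire, dtype=bool)},
                index=pd.Index([f"F{i}" for i in range(len(fire))], name="fracture_id"),
            )
            results[cause] = StepwiseCauseModel(frame, pd.Series(g, index=frame.index), cause).fit()
        return results, gold

    def test_disjoint_constituents_sum_their_true_positives(self):
        causes = ["infection"] * 3 + ["nonunion"] * 4 + ["not_reoperation"] * 13
        inf_fire = [True] * 3 + [False] * 17
        non_fire = [False] * 3 + [True] * 4 + [False] * 13
        results, gold = self._results(
            causes, {CauseLabel.INFECTION: inf_fire, CauseLabel.NONUNION: non_fire}
        )
        rep = combine_composite(results, gold, "major")
        assert rep.counts.tp == 7  # 3 + 4, disjoint union
        assert rep.counts.fp == 0

    def test_composite_sensitivity_at_least_each_constituent(self):
        rng = np.random.default_rng(3)
        causes = (
            ["infection"] * 10 + ["nonunion"] * 10 + ["not_reoperation"] * 60
        )
        inf_fire = [bool(rng.random() < 0.7) if c == "infection" else False for c in causes]
        non_fire = [bool(rng.random() < 0.6) if c == "nonunion" else False for c in causes]
        results, gold = self._results(
            causes, {CauseLabel.INFECTION: inf_fire, CauseLabel.NONUNION: non_fire}
        )
        rep = combine_composite(results, gold, "major")
        # within each constituent's own positives the composite misses nothing more
        assert rep.counts.tp == sum(inf_fire) + sum(non_fire)

    def test_unknown_composite_without_members_rejected(self):
        causes = ["infection"] * 2 + ["not_reoperation"] * 8
        results, gold = self._results(causes, {CauseLabel.INFECTION: [True] * 2 + [False] * 8})
        with pytest.raises(ValueError):
            combine_composite(results, gold, "minor")
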