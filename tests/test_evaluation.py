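"""ROC/PR, variability-profile, enrichment and recall evaluation tests.

AUC values are checked against a brute-force pairwise-comparison oracle and
hypergeometric p-values against exact combinatorial summation.
"""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import exranges as ex
from exranges.containers import GoldStandard, ValidationError
from exranges.evaluation import (
    coefficient_of_variation,
    enrichment_score,
    pr_curve,
    recall_at_fraction,
    roc_auc,
    within_between_sd,
)


def brute_force_auc(scores, labels):
    """Oracle: P(random positive outranks random negative), ties = 1/2."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def gold(positives, universe):
    return GoldStandard({"TF": set(positives)}, universe=list(universe))


class TestRocAuc:
    def test_perfect_separation(self):
        g = gold(["t1", "t2"], ["t1", "t2", "t3", "t4"])
        s = {"t1": 0.9, "t2": 0.8, "t3": 0.1, "t4": 0.05}
        assert roc_auc(s, g).auc == 1.0

    def test_all_equal_scores_give_half(self):
        g = gold(["t1", "t2"], ["t1", "t2", "t3", "t4"])
        assert roc_auc({t: 0.5 for t in g.universe}, g).auc == 0.5

    def test_hand_worked_example(self):
        # positives are the 1st- and 3rd-ranked scores: 3 of 4 pairs ordered
        g = gold(["t1", "t2"], ["t1", "t2", "t3", "t4"])
        s = {"t1": 0.9, "t2": 0.3, "t3": 0.5, "t4": 0.1}
        assert roc_auc(s, g).auc == pytest.approx(0.75)
        assert brute_force_auc([0.9, 0.3, 0.5, 0.1], [1, 1, 0, 0]) == 0.75

    def test_reversed_ranking_gives_zero(self):
        g = gold(["t3", "t4"], ["t1", "t2", "t3", "t4"])
        s = {"t1": 0.9, "t2": 0.8, "t3": 0.2, "t4": 0.1}
        assert roc_auc(s, g).auc == 0.0

    @given(st.lists(st.integers(0, 5), min_size=2, max_size=50),
           st.randoms(use_true_random=False))
    def test_matches_pairwise_oracle(self, score_ints, rnd):
        labels = [rnd.random() < 0.5 for _ in score_ints]
        if not (any(labels) and not all(labels)):
            return
        universe = [f"t{i}" for i in range(len(score_ints))]
        g = gold([u for u, l in zip(universe, labels) if l], universe)
        s = {u: float(v) for u, v in zip(universe, score_ints)}
        assert roc_auc(s, g).auc == pytest.approx(
            brute_force_auc(score_ints, labels)
        )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        universe = [f"t{i}" for i in range(30)]
        g = gold(universe[:7], universe)
        s = rng.normal(size=30)
        a1 = roc_auc(dict(zip(universe, s)), g).auc
        a2 = roc_auc(dict(zip(universe, np.exp(3 * s))), g).auc
        assert a1 == pytest.approx(a2)

    def test_no_negatives_rejected(self):
        g = gold(["t1", "t2"], ["t1", "t2"])
        with pytest.raises(ValidationError, match="TF"):
            roc_auc({"t1": 1.0, "t2": 0.0}, g)


class TestPrCurve:
    def test_perfect_ranking_has_unit_precision_at_full_recall(self):
        g = gold(["t1", "t2"], ["t1", "t2", "t3", "t4"])
        s = {"t1": 0.9, "t2": 0.8, "t3": 0.1, "t4": 0.05}
        res = pr_curve(s, g)
        assert res.average_precision == 1.0
        assert res.precision[res.recall == 1.0].max() == 1.0

    def test_uninformative_scores_give_positive_rate(self):
        g = gold(["t1", "t2"], ["t1", "t2", "t3", "t4"])
        res = pr_curve({t: 0.5 for t in g.universe}, g)
        assert res.average_precision == pytest.approx(0.5)

    def test_hand_enumerated_average_precision(self):
        # positives at ranks 1 and 3: AP = (1/1 + 2/3)/2
        g = gold(["t1", "t3"], ["t1", "t2", "t3", "t4"])
        s = {"t1": 0.9, "t2": 0.5, "t3": 0.3, "t4": 0.1}
        assert pr_curve(s, g).average_precision == pytest.approx(5 / 6)


class TestVariabilityProfiles:
    def test_cv_examples(self, two_series_expr):
        v = pd.DataFrame(
            [[2.0, 2.0, 2.0], [1.0, 3.0, 1.0]],
            index=["flat", "vary"],
            columns=["a", "b", "c"],
        )
        d = pd.DataFrame({"series_id": "S", "time": [0.0, 1.0, 2.0]},
                         index=["a", "b", "c"])
        cv = coefficient_of_variation(ex.ExpressionMatrix(v, d))
        assert cv["flat"] == 0.0
        two_pt = np.std([1.0, 3.0], ddof=1) / 2.0
        assert two_pt == pytest.approx(math.sqrt(2) / 2)

    def test_cv_scale_invariance(self, two_series_expr):
        cv1 = coefficient_of_variation(two_series_expr)
        scaled = ex.ExpressionMatrix(two_series_expr.values * 10, two_series_expr.design)
        cv2 = coefficient_of_variation(scaled)
        pd.testing.assert_series_equal(cv1, cv2)

    def test_cv_zero_mean_excluded_with_warning(self):
        v = pd.DataFrame([[0.0, 0.0], [1.0, 2.0]], index=["z", "g"], columns=["a", "b"])
        d = pd.DataFrame({"series_id": "S", "time": [0.0, 1.0]}, index=["a", "b"])
        with pytest.warns(UserWarning, match="zero-mean"):
            cv = coefficient_of_variation(ex.ExpressionMatrix(v, d))
        assert "z" not in cv.index

    @staticmethod
    def _expr(series_a, series_b):
        vals = series_a + series_b
        samples = [f"s{i}" for i in range(len(vals))]
        v = pd.DataFrame([vals], index=["g"], columns=samples, dtype=float)
        d = pd.DataFrame(
            {"series_id": ["A"] * len(series_a) + ["B"] * len(series_b),
             "time": list(range(len(series_a))) + list(range(len(series_b)))},
            index=samples,
        )
        return ex.ExpressionMatrix(v, d)

    def test_pure_offset_series(self):
        res = within_between_sd(self._expr([1, 1, 1], [5, 5, 5]))
        assert res.loc["g", "within_sd"] == 0.0
        assert res.loc["g", "between_sd"] == pytest.approx(np.std([1, 5], ddof=1))

    def test_pure_oscillation_series(self):
        res = within_between_sd(self._expr([1, 3], [1, 3]))
        assert res.loc["g", "between_sd"] == 0.0
        assert res.loc["g", "within_sd"] == pytest.approx(math.sqrt(2))

    def test_series_shift_moves_only_between_component(self):
        base = self._expr([1, 4, 2], [3, 1, 5])
        shifted = self._expr([1, 4, 2], [3 + 7, 1 + 7, 5 + 7])
        r1, r2 = within_between_sd(base), within_between_sd(shifted)
        assert r1.loc["g", "within_sd"] == pytest.approx(r2.loc["g", "within_sd"])
        assert r2.loc["g", "between_sd"] > r1.loc["g", "between_sd"]

    def test_single_series_rejected(self):
        v = pd.DataFrame([[1.0, 2.0]], index=["g"], columns=["a", "b"])
        d = pd.DataFrame({"series_id": "S", "time": [0.0, 1.0]}, index=["a", "b"])
        with pytest.raises(ValidationError):
            within_between_sd(ex.ExpressionMatrix(v, d))


def exact_hypergeom_upper_tail(k, n_universe, n_category, n_draw):
    """Oracle: direct combinatorial summation of P(overlap >= k)."""
    total = 0
    for i in range(k, min(n_category, n_draw) + 1):
        total += math.comb(n_category, i) * math.comb(n_universe - n_category, n_draw - i)
    return total / math.comb(n_universe, n_draw)


class TestEnrichment:
    def test_whole_category_drawn(self):
        universe = [f"g{i}" for i in range(20)]
        ann = {g: {"cat"} for g in universe[:10]}
        res = enrichment_score(universe[:10], ann, universe)
        expected_p = 1 / math.comb(20, 10)
        assert res.pvalues["cat"] == pytest.approx(expected_p)
        assert res.score == pytest.approx(-math.log10(expected_p))
        assert res.score == pytest.approx(5.2667, abs=1e-3)

    def test_proportional_draw_is_unenriched(self):
        universe = [f"g{i}" for i in range(20)]
        ann = {g: {"cat"} for g in universe[:10]}
        # half the category, half the rest: overlap matches expectation
        targets = universe[:5] + universe[10:15]
        res = enrichment_score(targets, ann, universe)
        assert res.pvalues["cat"] > 0.5
        assert res.score < 0.3

    def test_score_sums_neglog10_over_categories(self):
        universe = [f"g{i}" for i in range(24)]
        ann = {}
        for g in universe[:6]:
            ann.setdefault(g, set()).add("c1")
        for g in universe[4:12]:
            ann.setdefault(g, set()).add("c2")
        res = enrichment_score(universe[:8], ann, universe)
        assert res.score == pytest.approx(float(-np.log10(res.pvalues).sum()))

    def test_matches_exact_combinatorial_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n_uni = int(rng.integers(5, 31))
            n_cat = int(rng.integers(1, n_uni))
            n_draw = int(rng.integers(1, n_uni))
            universe = [f"g{i}" for i in range(n_uni)]
            ann = {g: {"cat"} for g in universe[:n_cat]}
            targets = list(rng.choice(universe, size=n_draw, replace=False))
            k = len(set(targets) & set(universe[:n_cat]))
            res = enrichment_score(targets, ann, universe)
            if k == 0:
                assert "cat" not in res.pvalues.index
            else:
                assert res.pvalues["cat"] == pytest.approx(
                    exact_hypergeom_upper_tail(k, n_uni, n_cat, n_draw)
                )

    def test_empty_target_set_scores_zero_with_warning(self):
        with pytest.warns(UserWarning, match="empty"):
            res = enrichment_score([], {"g0": {"c"}}, ["g0", "g1"])
        assert res.score == 0.0


class TestRecallAtFraction:
    def ranked(self, pairs):
        return pd.DataFrame(pairs, columns=["regulator", "target"]).assign(score=0.0)

    def test_perfect_ranking_full_recall(self):
        g = GoldStandard({"A": {"t1", "t2"}}, universe=["t1", "t2", "t3", "t4"])
        edges = self.ranked([("A", "t1"), ("A", "t2"), ("A", "t3"), ("A", "t4")])
        assert recall_at_fraction(edges, g, 0.5) == 1.0

    def test_fraction_too_small_gives_zero(self):
        g = GoldStandard({"A": {"t4"}}, universe=["t1", "t2", "t3", "t4"])
        edges = self.ranked([("A", "t1"), ("A", "t2"), ("A", "t3"), ("A", "t4")])
        assert recall_at_fraction(edges, g, 0.25) == 0.0

    def test_monotone_in_fraction(self):
        rng = np.random.default_rng(2)
        universe = [f"t{i}" for i in range(40)]
        g = GoldStandard({"A": set(rng.choice(universe, 10, replace=False))},
                         universe=universe)
        order = list(rng.permutation(universe))
        edges = self.ranked([("A", t) for t in order])
        rec = [recall_at_fraction(edges, g, f) for f in np.linspace(0.05, 1.0, 20)]
        assert all(b >= a for a, b in zip(rec, rec[1:]))
        assert rec[-1] == 1.0

    def test_random_scores_recall_tracks_fraction(self):
        # uninformative ranking: expected recall ~ fraction retained
        rng = np.random.default_rng(3)
        universe = [f"t{i}" for i in range(50)]
        g = GoldStandard({"A": set(universe[:10])}, universe=universe)
        recalls = []
        for _ in range(200):
            order = list(rng.permutation(universe))
            recalls.append(recall_at_fraction(self.ranked([("A", t) for t in order]), g, 0.1))
        assert np.mean(recalls) == pytest.approx(0.1, abs=0.02)

    def test_invalid_fraction_rejected(self):
        g = GoldStandard({"A": {"t1"}}, universe=["t1", "t2"])
        edges = self.ranked([("A", "t1"), ("A", "t2")])
        with pytest.raises(ValueError):
            recall_at_fraction(edges, g, 0.0)
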