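"""Pair AUC ranking and the comparative statistics around it."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netsig.stratify import (auc_correlation, baseline_classifier_cv,
                             benjamini_hochberg, de_linear_model, pair_auc,
                             pca_scores, rank_auc, select_top_pairs,
                             wilcoxon_groups)

from .oracles import auc_exhaustive, wilcoxon_exact_two_sided


class TestRankAUC:
    @pytest.mark.parametrize("pos, neg, expected", [
        ([1, 2], [3, 4], 1.0),            # perfect separation
        ([2, 2], [2, 2], 0.5),            # all ties
        ([1, 2, 2], [2, 3], 5 / 6),       # 4 wins + 2 half-ties over 6 pairs
        ([3, 4], [1, 2], 0.0),            # reversed
    ])
    def test_fixtures(self, pos, neg, expected):
        assert rank_auc(pos, neg) == pytest.approx(expected)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.lists(st.integers(0, 8), min_size=1, max_size=10),
           st.lists(st.integers(0, 8), min_size=1, max_size=10))
    def test_rank_identity_equals_exhaustive_counting(self, pos, neg):
        assert rank_auc(pos, neg) == pytest.approx(auc_exhaustive(pos, neg))

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-5, 5, allow_nan=False), min_size=2, max_size=8),
           st.lists(st.floats(-5, 5, allow_nan=False), min_size=2, max_size=8))
    def test_orientation_symmetric_under_sign_flip(self, pos, neg):
        a = rank_auc(pos, neg)
        b = rank_auc([-x for x in pos], [-y for y in neg])
        assert max(a, 1 - a) == pytest.approx(max(b, 1 - b))


class TestSelectTopPairs:
    @pytest.fixture
    def table(self):
        return pd.DataFrame({
            "receptor": ["R1", "R1", "R2"],
            "tf": ["F1", "F2", "F1"],
            "auc_oriented": [0.95, 0.80, 0.95],
        })

    def test_threshold_filter(self, table):
        out = select_top_pairs(table, min_auc=0.9)
        assert len(out) == 2
        assert (out["auc_oriented"] >= 0.9).all()

    def test_k_larger_than_table_returns_all(self, table):
        assert len(select_top_pairs(table, k=10)) == 3

    def test_sorted_descending_with_lexicographic_ties(self, table):
        out = select_top_pairs(table)
        assert out[["receptor", "tf"]].iloc[0].tolist() == ["R1", "F1"]
        assert out["auc_oriented"].is_monotonic_decreasing


class TestWilcoxon:
    def test_identical_groups_give_p_near_one(self):
        assert wilcoxon_groups([1, 2, 3], [1, 2, 3]) >= 0.99

    def test_disjoint_groups_exact_p(self):
        p = wilcoxon_groups([1, 2, 3, 4], [10, 11, 12, 13])
        assert p == pytest.approx(2 / 70)
        assert p == pytest.approx(
            wilcoxon_exact_two_sided([1, 2, 3, 4], [10, 11, 12, 13]))

    def test_invariant_under_monotone_transform(self):
        x, y = [1.0, 2.5, 3.0], [2.0, 4.0, 5.5]
        assert wilcoxon_groups(x, y) == pytest.approx(
            wilcoxon_groups(np.exp(x), np.exp(y)))

    def test_constant_pooled_values_give_p_one(self):
        assert wilcoxon_groups([2, 2], [2, 2, 2]) == 1.0


class TestDELinearModel:
    def _cohort(self, rng, effect, n=20):
        labels = np.array(["a"] * n + ["b"] * n)
        base = rng.normal(5, 0.5, size=(3, 2 * n))
        base[0, n:] += np.log(effect) if effect > 1 else 0.0
        return pd.DataFrame(base, index=["hit", "null1", "null2"]), labels

    def test_planted_effect_detected_in_most_replicates(self):
        detected = 0
        for rep in range(50):
            rng = np.random.default_rng(rep)
            m, labels = self._cohort(rng, effect=2.0)
            out = de_linear_model(m, labels, ["hit", "null1", "null2"])
            detected += out.set_index("gene").loc["hit", "adjusted_p"] < 0.05
        assert detected >= 48  # >= 95% power

    def test_null_false_rejection_controlled(self):
        rejections = 0
        for rep in range(50):
            rng = np.random.default_rng(1000 + rep)
            m, labels = self._cohort(rng, effect=1.0)
            out = de_linear_model(m, labels, ["null1", "null2"])
            rejections += (out["adjusted_p"] < 0.05).any()
        assert rejections <= 8

    def test_bh_step_up_closed_form(self):
        """p = (.01, .02, .03, .04): step-up gives min_k(p_k * 4 / k) from
        each rank upward, i.e. all four adjust to .04."""
        adjusted = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adjusted, 0.04)

    def test_bh_monotone_in_rank(self):
        rng = np.random.default_rng(0)
        p = np.sort(rng.uniform(size=12))
        adjusted = benjamini_hochberg(p)
        assert np.all(np.diff(adjusted) >= -1e-12)
        assert np.all(adjusted >= p - 1e-12) and np.all(adjusted <= 1.0)

    def test_missing_gene_listed(self):
        m = pd.DataFrame(np.ones((1, 4)), index=["g"])
        with pytest.raises(KeyError, match="absent"):
            de_linear_model(m, ["a", "a", "b", "b"], ["g", "ghost"])


class TestPCA:
    def test_perfectly_correlated_features_load_on_pc1(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        scores, fractions = pca_scores(np.column_stack([x, 2 * x]), 2)
        assert fractions[0] == pytest.approx(1.0)

    def test_two_cluster_toy_separates_on_pc1(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 0.1, size=(10, 3))
        b = rng.normal(3, 0.1, size=(10, 3))
        scores, _ = pca_scores(np.vstack([a, b]), 1)
        assert scores.iloc[:10, 0].max() < scores.iloc[10:, 0].min()

    def test_variance_fractions_nonincreasing_and_bounded(self):
        rng = np.random.default_rng(2)
        _, fractions = pca_scores(rng.normal(size=(15, 6)), 4)
        assert fractions.sum() <= 1.0 + 1e-9
        assert np.all(np.diff(fractions) <= 1e-12)

    def test_constant_features_dropped_with_warning(self):
        rng = np.random.default_rng(3)
        m = np.column_stack([np.ones(10), rng.normal(size=10)])
        with pytest.warns(UserWarning, match="constant"):
            scores, _ = pca_scores(m, 1)
        assert scores.shape == (10, 1)


class TestBaselineClassifier:
    def test_label_shuffled_features_score_near_chance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(80, 4))
        y = np.array([0, 1] * 40)
        out = baseline_classifier_cv(x, y, folds=5, repeats=3, seed=0,
                                     hidden_sizes=(2,), max_iter=200)
        assert 0.40 <= out["mean_auc"] <= 0.60

    def test_separable_toy_scores_high(self):
        rng = np.random.default_rng(1)
        x = np.vstack([rng.normal(0, 0.3, size=(30, 3)),
                       rng.normal(3, 0.3, size=(30, 3))])
        y = np.array([0] * 30 + [1] * 30)
        out = baseline_classifier_cv(x, y, folds=5, repeats=2, seed=1,
                                     hidden_sizes=(2, 5), max_iter=300)
        assert out["mean_auc"] >= 0.95

    def test_same_seed_reproduces(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(40, 3))
        y = np.array([0, 1] * 20)
        a = baseline_classifier_cv(x, y, folds=4, repeats=2, seed=3,
                                   hidden_sizes=(2,), max_iter=100)
        b = baseline_classifier_cv(x, y, folds=4, repeats=2, seed=3,
                                   hidden_sizes=(2,), max_iter=100)
        assert a == b

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            baseline_classifier_cv(np.ones((6, 2)), np.zeros(6))


class TestAUCCorrelation:
    def _table(self, aucs):
        return pd.DataFrame({
            "receptor": [f"R{i}" for i in range(len(aucs))],
            "tf": [f"F{i}" for i in range(len(aucs))],
            "auc_oriented": aucs,
        })

    def test_identity_gives_r_one(self):
        a = self._table([0.6, 0.7, 0.8, 0.9])
        r, _ = auc_correlation(a, a)
        assert r == pytest.approx(1.0)

    def test_affine_reversal_gives_r_minus_one(self):
        a = self._table([0.6, 0.7, 0.8, 0.9])
        b = a.copy()
        b["auc_oriented"] = 1.5 - a["auc_oriented"]
        r, _ = auc_correlation(a, b)
        assert r == pytest.approx(-1.0)

    def test_hand_computed_r_on_five_pairs(self):
        a = self._table([0.5, 0.6, 0.7, 0.8, 0.9])
        b = self._table([0.55, 0.58, 0.75, 0.72, 0.95])
        r, _ = auc_correlation(a, b)
        x, y = np.array(a["auc_oriented"]), np.array(b["auc_oriented"])
        expected = (((x - x.mean()) * (y - y.mean())).sum()
                    / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()))
        assert r == pytest.approx(expected)

    def test_fewer_than_three_shared_pairs_rejected(self):
        a, b = self._table([0.6, 0.7]), self._table([0.6, 0.7])
        with pytest.raises(ValueError, match="shared"):
            auc_correlation(a, b)
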