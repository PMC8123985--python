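import numpy as np
import pytest

from _oracles import brute_ri_from_trees
from pscpred.riforest import (
    build_tree,
    entropy,
    info_gain,
    iter_internal_nodes,
    predict_tree,
    reaccumulate_ri,
    ri_scores,
    select_feature_subset,
    weighted_rate,
)
from pscpred.simulate import planted_matrix


class TestEntropy:
    def test_uniform_two_class(self):
        assert entropy(list("aabb")) == pytest.approx(1.0)

    def test_pure(self):
        assert entropy(list("aaaa")) == 0.0

    def test_uniform_four_class(self):
        assert entropy(list("abcd")) == pytest.approx(2.0)

    def test_three_one_split(self):
        assert entropy(list("aaab")) == pytest.approx(0.8112781244591328)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            entropy([])


class TestInfoGain:
    def test_perfect_split(self):
        assert info_gain(list("aabb"), list("aa"), list("bb")) == pytest.approx(1.0)

    def test_uninformative_split(self):
        assert info_gain(list("aabb"), list("ab"), list("ab")) == pytest.approx(0.0)

    def test_closed_form(self):
        got = info_gain(list("aaab"), list("aa"), list("ab"))
        assert got == pytest.approx(0.8112781244591328 - 0.5, abs=1e-12)

    def test_partition_mismatch_rejected(self):
        with pytest.raises(ValueError):
            info_gain(list("aabb"), list("aa"), list("ab"))


class TestBuildTree:
    def test_single_feature_perfect_split(self):
        X = np.array([[0.0], [0.0], [1.0], [1.0]])
        y = list("aabb")
        root = build_tree(X, y, ["f0"])
        assert root.feature == "f0"
        assert root.threshold == pytest.approx(0.5)
        assert root.info_gain == pytest.approx(1.0)
        assert predict_tree(root, X, ["f0"]) == list("aabb")

    def test_pure_labels_single_leaf(self):
        X = np.array([[0.0], [1.0], [2.0]])
        root = build_tree(X, list("aaa"), ["f0"])
        assert root.is_leaf and root.leaf_class == "a"

    def test_constant_features_single_leaf(self):
        X = np.zeros((4, 2))
        root = build_tree(X, list("aabb"), ["f0", "f1"])
        assert root.is_leaf

    def test_child_counts_sum_to_parent(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 3))
        y = [f"c{i % 3}" for i in range(30)]
        root = build_tree(X, y, ["f0", "f1", "f2"])
        for node in iter_internal_nodes(root):
            assert node.left.n_samples + node.right.n_samples == node.n_samples
            assert node.info_gain >= 0

    def test_determinism(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 4))
        y = [f"c{i % 2}" for i in range(40)]
        names = ["a", "b", "c", "d"]
        r1 = build_tree(X, y, names)
        r2 = build_tree(X, y, names)
        assert _tree_tuple(r1) == _tree_tuple(r2)

    def test_tie_prefers_lower_feature_name(self):
        # identical columns -> same IG; the lexicographically lower name wins
        X = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0], [1.0, 1.0]])
        root = build_tree(X, list("aabb"), ["zzz", "aaa"])
        assert root.feature == "aaa"


def _tree_tuple(node):
    if node.is_leaf:
        return ("leaf", node.leaf_class, node.n_samples)
    return (
        node.feature,
        node.threshold,
        node.info_gain,
        node.n_samples,
        _tree_tuple(node.left),
        _tree_tuple(node.right),
    )


class TestWeightedRate:
    def test_formula_arithmetic(self):
        assert weighted_rate(np.array([[3, 1], [0, 4]])) == pytest.approx(0.875)

    def test_diagonal(self):
        assert weighted_rate(np.diag([5, 2, 7])) == 1.0

    def test_zero_diagonal(self):
        assert weighted_rate(np.array([[0, 2], [3, 0]])) == 0.0

    def test_empty_true_class_rejected(self):
        with pytest.raises(ValueError):
            weighted_rate(np.array([[0, 0], [1, 1]]))


class TestRiScores:
    def test_constant_feature_has_zero_ri(self):
        rng = np.random.default_rng(0)
        fm, y, _ = planted_matrix(60, 5, 1, 3.0, 2, seed=0)
        fm.values[:, 2] = 7.0  # make one column constant
        ri = ri_scores(fm, y, s=2, t=5, seed=0)
        assert ri.scores[fm.names[2]] == 0.0

    def test_all_scores_non_negative(self):
        fm, y, _ = planted_matrix(60, 8, 2, 1.0, 4, seed=1)
        ri = ri_scores(fm, y, s=2, t=5, seed=1)
        assert all(v >= 0 for v in ri.scores.values())

    def test_determinism(self):
        fm, y, _ = planted_matrix(60, 8, 2, 1.0, 4, seed=2)
        r1 = ri_scores(fm, y, s=2, t=5, seed=9)
        r2 = ri_scores(fm, y, s=2, t=5, seed=9)
        assert r1.scores == r2.scores

    def test_planted_feature_wins_most_seeds(self):
        hits = 0
        for seed in range(20):
            fm, y, informative = planted_matrix(100, 10, 1, 3.0, 2, seed=seed)
            ri = ri_scores(fm, y, s=2, t=20, seed=seed)
            best = max(ri.scores, key=ri.scores.get)
            hits += best == fm.names[informative[0]]
        assert hits >= 18

    def test_additivity_against_tree_walk(self):
        fm, y, _ = planted_matrix(80, 10, 2, 2.0, 4, seed=5)
        ri = ri_scores(fm, y, s=2, t=5, seed=5, keep_trees=True)
        oracle = brute_ri_from_trees(ri.trees, fm.names)
        for name in fm.names:
            assert oracle[name] == pytest.approx(ri.scores[name], abs=0)
        assert reaccumulate_ri(ri) == oracle

    def test_too_few_samples_rejected(self):
        from pscpred.assembly import FeatureMatrix

        fm = FeatureMatrix(
            ids=("a", "b", "c"),
            names=("f0", "f1"),
            families=("SYN", "SYN"),
            values=np.zeros((3, 2)),
        )
        with pytest.raises(ValueError, match="4 samples"):
            ri_scores(fm, ["x", "x", "y"], s=1, t=1)


class TestSelectFeatureSubset:
    @staticmethod
    def _setup(seed=0):
        fm, y, informative = planted_matrix(80, 20, 4, 2.5, 4, seed=seed)
        ri = ri_scores(fm, y, s=2, t=10, seed=seed)
        return fm, y, ri, informative

    def test_single_candidate_grid_returns_top_q(self):
        fm, y, ri, _ = self._setup()
        sel = select_feature_subset(fm, y, ri, [10], lambda X, y: 0.5)
        assert sel.chosen == ri.ranking()[:10]
        assert sel.chosen_size == 10

    def test_tie_prefers_smaller_size(self):
        fm, y, ri, _ = self._setup()
        sel = select_feature_subset(fm, y, ri, [5, 10], lambda X, y: 0.7)
        assert sel.chosen_size == 5

    def test_empty_grid_rejected(self):
        fm, y, ri, _ = self._setup()
        with pytest.raises(ValueError):
            select_feature_subset(fm, y, ri, [], lambda X, y: 0.5)

    def test_oversized_grid_rejected(self):
        fm, y, ri, _ = self._setup()
        with pytest.raises(ValueError):
            select_feature_subset(fm, y, ri, [21], lambda X, y: 0.5)

    def test_eval_fn_sees_nested_prefixes(self):
        fm, y, ri, _ = self._setup()
        seen = []
        select_feature_subset(
            fm, y, ri, [5, 10], lambda X, y: seen.append(tuple(X.names)) or 0.0
        )
        assert len(seen[0]) == 5 and len(seen[1]) == 10
        assert seen[1][:5] == seen[0]
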