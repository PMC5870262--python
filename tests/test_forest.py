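"""Embedded random forest: block maps, Extra-trees, meta-variables,
meta-cutpoints, prediction routing, importance, and determinism."""

import numpy as np
import pytest

from ldtrees.data_io import ClusterMap
from ldtrees.forest import (
    ExtraTree,
    ForestParams,
    TTreesForest,
    fit_forest,
    grow_extra_tree,
    grow_meta_tree,
    make_block_map,
    meta_variable_values,
    optimal_meta_cutpoint,
    predict_proba,
    variable_importance,
)
from ldtrees.stats_core import discriminating_score
from conftest import make_dataset


class TestBlockMap:
    def test_sizes_with_short_tail(self):
        ds = make_dataset(np.zeros((45, 2), np.int8), [True, False])
        cmap = make_block_map(ds, B=20)
        assert [len(c) for c in cmap.clusters] == [20, 20, 5]
        assert cmap.provenance == "contiguous_blocks"

    def test_exact_fit_single_block(self):
        ds = make_dataset(np.zeros((20, 2), np.int8), [True, False])
        assert [len(c) for c in make_block_map(ds, B=20).clusters] == [20]

    def test_default_block_size_is_twenty(self):
        assert ForestParams().B == 20

    def test_invalid_block_size(self):
        ds = make_dataset(np.zeros((5, 2), np.int8), [True, False])
        with pytest.raises(ValueError):
            make_block_map(ds, B=0)


class TestGrowExtraTree:
    def test_pure_node_single_leaf(self):
        G = np.array([[0, 1, 2, 0]], dtype=np.int8)
        y = np.ones(4, bool)
        tree = grow_extra_tree(G, y, np.arange(4), np.array([0]),
                               rng=np.random.default_rng(0))
        assert tree.n_splits == 0
        assert tree.value[0] == 1.0

    def test_budget_one_gives_single_split(self):
        G = np.array([[0, 0, 2, 2]], dtype=np.int8)
        y = np.array([True, True, False, False])
        tree = grow_extra_tree(G, y, np.arange(4), np.array([0]), s_t=1,
                               rng=np.random.default_rng(1))
        assert tree.n_splits == 1

    def test_separating_variable_gives_perfect_training_accuracy(self):
        # values {0, 2} split classes: any theta in (0, 2) separates
        G = np.array([[0, 0, 0, 2, 2, 2]], dtype=np.int8)
        y = np.array([False, False, False, True, True, True])
        for seed in range(20):
            tree = grow_extra_tree(G, y, np.arange(6), np.array([0]),
                                   rng=np.random.default_rng(seed))
            nu = tree.route(G, np.arange(6))
            assert np.array_equal(nu, y.astype(float))

    def test_split_budget_respected(self):
        rng = np.random.default_rng(2)
        G = rng.integers(0, 3, size=(10, 200)).astype(np.int8)
        y = rng.random(200) < 0.5
        for s_t in (1, 3, 5):
            tree = grow_extra_tree(G, y, np.arange(200), np.arange(10), s_t=s_t,
                                   rng=np.random.default_rng(3))
            assert tree.n_splits <= s_t

    def test_empty_node_errors(self):
        G = np.zeros((1, 4), np.int8)
        with pytest.raises(ValueError):
            grow_extra_tree(G, np.ones(4, bool), np.array([], int), np.array([0]))

    def test_leaf_labels_are_case_fractions(self):
        rng = np.random.default_rng(4)
        G = rng.integers(0, 3, size=(5, 100)).astype(np.int8)
        y = rng.random(100) < 0.4
        tree = grow_extra_tree(G, y, np.arange(100), np.arange(5),
                               rng=np.random.default_rng(5))
        nu = tree.route(G, np.arange(100))
        for label in np.unique(nu):
            routed = nu == label
            assert y[routed].mean() == pytest.approx(label)


def manual_tree():
    """Hand-built 3-leaf tree: split snp0 @0.5 -> (leaf 0.2) / split snp1 @1.5
    -> (leaf 0.6)/(leaf 0.9)."""
    t = ExtraTree()
    t._add(0, 0.5, 0.5, 8, 0.1)       # root
    t._add(-1, 0.0, 0.2, 4, 0.0)      # left leaf
    t._add(1, 1.5, 0.5, 4, 0.05)      # right split
    t._add(-1, 0.0, 0.6, 2, 0.0)
    t._add(-1, 0.0, 0.9, 2, 0.0)
    t.left[0], t.right[0] = 1, 2
    t.left[2], t.right[2] = 3, 4
    return t


class TestMetaVariable:
    def test_single_leaf_tree(self):
        t = ExtraTree()
        t._add(-1, 0.0, 0.5, 3, 0.0)
        G = np.zeros((1, 3), np.int8)
        nu, dom = meta_variable_values(t, G, np.arange(3))
        assert np.all(nu == 0.5) and list(dom) == [0.5]

    def test_five_leaf_domain(self):
        labels = [0.0008, 0.040, 0.351, 0.635, 0.999]
        t = ExtraTree()
        # chain of 4 splits on snp0 with thresholds -0.5+k so each
        # genotype value reaches a distinct leaf (values 0..4)
        prev = None
        for k, lab in enumerate(labels[:-1]):
            node = t._add(0, k + 0.5, 0.5, 5 - k, 0.0)
            leaf = t._add(-1, 0.0, lab, 1, 0.0)
            t.left[node] = leaf
            if prev is not None:
                t.right[prev] = node
            prev = node
        t.right[prev] = t._add(-1, 0.0, labels[-1], 1, 0.0)
        G = np.arange(5, dtype=np.int8).reshape(1, 5)
        nu, dom = meta_variable_values(t, G, np.arange(5))
        assert sorted(dom) == sorted(labels)

    def test_routing_matches_manual_oracle(self):
        t = manual_tree()
        G = np.array(
            [[0, 0, 1, 1, 2, 2, 0, 1],
             [0, 2, 1, 2, 0, 2, 1, 0]], dtype=np.int8
        )
        expected = []
        for o in range(8):
            if G[0, o] <= 0.5:
                expected.append(0.2)
            elif G[1, o] <= 1.5:
                expected.append(0.6)
            else:
                expected.append(0.9)
        nu, _ = meta_variable_values(t, G, np.arange(8))
        assert np.array_equal(nu, expected)


class TestOptimalMetaCutpoint:
    def test_perfect_split(self):
        nu = np.array([0.1, 0.1, 0.9, 0.9])
        y = np.array([False, False, True, True])
        theta, score = optimal_meta_cutpoint(nu, y)
        assert theta == 0.1 and score == pytest.approx(1.0)

    def test_constant_nu_no_split(self):
        assert optimal_meta_cutpoint(np.full(4, 0.5), np.array([1, 0, 1, 0], bool)) is None

    def test_matches_exhaustive_oracle(self):
        nu = np.array([0.1, 0.3, 0.3, 0.8, 0.8, 0.8])
        y = np.array([False, True, False, True, True, False])
        best = None
        for theta in [0.1, 0.3]:
            left = nu <= theta
            score = discriminating_score(
                (int(y.sum()), int((~y).sum())),
                (int(y[left].sum()), int((~y)[left].sum())),
                (int(y[~left].sum()), int((~y)[~left].sum())),
            )
            if best is None or score > best[1]:
                best = (theta, score)
        assert optimal_meta_cutpoint(nu, y) == pytest.approx(best)

    def test_tie_prefers_smallest_theta(self):
        nu = np.array([0.2, 0.4, 0.6])
        y = np.array([True, False, True])
        theta, _ = optimal_meta_cutpoint(nu, y)
        assert theta == 0.2  # both candidates score equally here


class TestMetaTreeAndForest:
    def _toy_dataset(self, n=300, seed=0):
        rng = np.random.default_rng(seed)
        planted = np.r_[np.zeros(n // 2), np.full(n - n // 2, 2)].astype(np.int8)
        rows = [rng.integers(0, 3, n).astype(np.int8) for _ in range(9)]
        rows.insert(0, planted)
        pheno = np.r_[np.zeros(n // 2, bool), np.ones(n - n // 2, bool)]
        return make_dataset(rows, pheno)

    def test_small_node_is_single_meta_leaf(self):
        ds = self._toy_dataset()
        cmap = make_block_map(ds, B=5)
        params = ForestParams(T=1, S_n=2000, K=2)
        forest = fit_forest(ds, cmap, params, seed=0)
        from ldtrees.forest import MetaLeaf

        assert isinstance(forest.trees[0].root, MetaLeaf)

    def test_single_cluster_map_always_chosen(self):
        ds = self._toy_dataset()
        cmap = ClusterMap(clusters=[list(range(10))], n_snps=10)
        params = ForestParams(T=1, S_n=100, K=5)
        forest = fit_forest(ds, cmap, params, seed=1)
        for node in forest.trees[0].iter_nodes():
            assert node.cluster_id == 0

    def test_meta_thresholds_belong_to_domain(self):
        ds = self._toy_dataset()
        cmap = make_block_map(ds, B=5)
        params = ForestParams(T=5, S_n=100, K=2)
        forest = fit_forest(ds, cmap, params, seed=2)
        for tree in forest.trees:
            for node in tree.iter_nodes():
                # threshold must be one of the embedded tree's leaf labels
                assert node.threshold in set(node.tree.value)

    def test_forest_of_one_tree(self):
        ds = self._toy_dataset()
        cmap = make_block_map(ds, B=5)
        forest = fit_forest(ds, cmap, ForestParams(T=1, S_n=100, K=2), seed=3)
        assert forest.T == 1

    def test_planted_snp_dominates_importance(self):
        ds = self._toy_dataset()
        cmap = make_block_map(ds, B=5)
        forest = fit_forest(ds, cmap, ForestParams(T=20, S_n=100, K=2), seed=4)
        imp = variable_importance(forest, snp_ids=ds.snp_ids)
        assert imp.ranking()[0] == "snp0"

    def test_determinism_same_seed_bit_identical(self):
        ds = self._toy_dataset()
        cmap = make_block_map(ds, B=5)
        params = ForestParams(T=5, S_n=100, K=2)
        a = variable_importance(fit_forest(ds, cmap, params, seed=7)).scores
        b = variable_importance(fit_forest(ds, cmap, params, seed=7)).scores
        assert np.array_equal(a, b)

    def test_determinism_across_worker_counts(self):
        ds = self._toy_dataset()
        cmap = make_block_map(ds, B=5)
        params = ForestParams(T=4, S_n=100, K=2)
        serial = variable_importance(fit_forest(ds, cmap, params, seed=8, n_jobs=1)).scores
        parallel = variable_importance(fit_forest(ds, cmap, params, seed=8, n_jobs=2)).scores
        assert np.array_equal(serial, parallel)


class TestPredict:
    def test_all_meta_leaf_forest_predicts_label(self):
        ds = TestMetaTreeAndForest()._toy_dataset()
        cmap = make_block_map(ds, B=5)
        forest = fit_forest(ds, cmap, ForestParams(T=3, S_n=5000, K=2), seed=0)
        probs = predict_proba(forest, ds)
        from ldtrees.forest import MetaLeaf

        roots = [t.root for t in forest.trees]
        assert all(isinstance(r, MetaLeaf) for r in roots)
        assert np.allclose(probs, np.mean([r.probability for r in roots]))

    def test_mean_over_trees(self):
        # two single-meta-leaf trees with labels 0.2 and 0.8 average to 0.5
        from ldtrees.forest import MetaLeaf, MetaTree

        ds = TestMetaTreeAndForest()._toy_dataset()
        forest = fit_forest(ds, make_block_map(ds, B=5),
                            ForestParams(T=2, S_n=5000, K=1), seed=1)
        forest.trees = [MetaTree(MetaLeaf(0.2, 10), 10), MetaTree(MetaLeaf(0.8, 10), 10)]
        assert np.allclose(predict_proba(forest, ds), 0.5)

    def test_routing_matches_manual_oracle(self):
        ds = TestMetaTreeAndForest()._toy_dataset(seed=5)
        cmap = make_block_map(ds, B=5)
        forest = fit_forest(ds, cmap, ForestParams(T=1, S_n=100, K=2), seed=2)
        probs = predict_proba(forest, ds)

        def route_one(node, o):
            from ldtrees.forest import MetaLeaf

            while not isinstance(node, MetaLeaf):
                nu = node.tree.route(ds.genotypes, np.array([o]))[0]
                node = node.left if nu <= node.threshold else node.right
            return node.probability

        manual = [route_one(forest.trees[0].root, o) for o in range(ds.n_individuals)]
        assert np.allclose(probs, manual)

    def test_wrong_snp_count_errors(self):
        ds = TestMetaTreeAndForest()._toy_dataset()
        forest = fit_forest(ds, make_block_map(ds, B=5), ForestParams(T=1, S_n=100, K=2), seed=0)
        with pytest.raises(ValueError):
            predict_proba(forest, ds.subset_snps(range(5)))


class TestImportance:
    def test_unused_snps_score_zero_and_sum_normalization(self):
        ds = TestMetaTreeAndForest()._toy_dataset()
        cmap = make_block_map(ds, B=5)
        forest = fit_forest(ds, cmap, ForestParams(T=10, S_n=100, K=1), seed=3)
        imp = variable_importance(forest, snp_ids=ds.snp_ids)
        assert imp.scores.sum() == pytest.approx(1.0)
        used = set()
        for tree in forest.trees:
            for node in tree.iter_nodes():
                used |= {s for s, _, _ in node.tree.split_records()}
        unused = set(range(ds.n_snps)) - used
        assert all(imp.scores[i] == 0 for i in unused)

    def test_manual_accumulation_on_single_tree(self):
        ds = TestMetaTreeAndForest()._toy_dataset()
        cmap = make_block_map(ds, B=5)
        forest = fit_forest(ds, cmap, ForestParams(T=1, S_n=150, K=2), seed=6)
        imp = variable_importance(forest, normalize="none")
        expected = np.zeros(ds.n_snps)
        tree = forest.trees[0]
        for node in tree.iter_nodes():
            for snp, n_e, gain in node.tree.split_records():
                expected[snp] += (n_e / tree.n_boot) * gain
        assert np.allclose(imp.scores, expected)

    def test_max_normalization(self):
        ds = TestMetaTreeAndForest()._toy_dataset()
        forest = fit_forest(ds, make_block_map(ds, B=5),
                            ForestParams(T=5, S_n=100, K=2), seed=7)
        imp = variable_importance(forest, normalize="max")
        assert imp.scores.max() == pytest.approx(1.0)
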