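"""Latent-tree LD model: distance graph, DBSCAN, EM for latent class
models, latent validation, and the layer-1 cluster map."""

import itertools

import numpy as np
import pytest

from ldtrees.data_io import ClusterMap
from ldtrees.fltm import (
    DBSCANParams,
    DissimilarityGraph,
    FLTMParams,
    dbscan_cluster,
    fit_lcm,
    fltm_selection_criterion,
    impute_latent,
    latent_cardinality,
    layer1_map,
    ld_distance_graph,
    learn_fltm,
    select_R,
    validate_latent,
)
from conftest import make_dataset


class TestLDDistanceGraph:
    def test_identical_snps_weight_zero(self):
        rng = np.random.default_rng(0)
        col = rng.integers(0, 3, 500)
        ds = make_dataset([col, col.copy()], rng.random(500) < 0.5)
        g = ld_distance_graph(ds, delta_bp=50_000)
        nbrs = g._adj[0]
        assert len(nbrs) == 1
        assert nbrs[0][1] == pytest.approx(0.0, abs=1e-12)

    def test_distance_window_excludes_far_pairs(self):
        rng = np.random.default_rng(1)
        ds = make_dataset(
            [rng.integers(0, 3, 100), rng.integers(0, 3, 100)],
            rng.random(100) < 0.5,
            spacing=60_000,
        )
        g = ld_distance_graph(ds, delta_bp=50_000)
        assert g.degree(0) == 0 and g.degree(1) == 0

    def test_window_is_inclusive(self):
        rng = np.random.default_rng(2)
        ds = make_dataset(
            [rng.integers(0, 3, 100), rng.integers(0, 3, 100)],
            rng.random(100) < 0.5,
            spacing=50_000,
        )
        assert ld_distance_graph(ds, delta_bp=50_000).degree(0) == 1

    def test_independent_snps_weight_near_one(self):
        rng = np.random.default_rng(3)
        n = 10_000
        ds = make_dataset(
            [rng.integers(0, 3, n), rng.integers(0, 3, n)], rng.random(n) < 0.5
        )
        g = ld_distance_graph(ds)
        assert g._adj[0][0][1] == pytest.approx(1.0, abs=0.05)

    def test_constant_snp_is_isolated(self):
        rng = np.random.default_rng(4)
        ds = make_dataset(
            [np.zeros(100, dtype=np.int8), rng.integers(0, 3, 100)],
            rng.random(100) < 0.5,
        )
        g = ld_distance_graph(ds)
        assert g.degree(0) == 0


def dbscan_oracle(dist, R, N_min):
    """Brute-force density-reachability closure on a full distance matrix."""
    n = dist.shape[0]
    neigh = [{j for j in range(n) if j != i and dist[i, j] <= R} for i in range(n)]
    core = [len(neigh[i]) >= N_min for i in range(n)]
    label = [-1] * n
    cid = 0
    for i in range(n):
        if not core[i] or label[i] >= 0:
            continue
        frontier = {i}
        while frontier:
            u = frontier.pop()
            if label[u] >= 0:
                continue
            label[u] = cid
            frontier |= {v for v in neigh[u] if core[v] and label[v] < 0}
        cid += 1
    clusters = {c: [i for i in range(n) if core[i] and label[i] == c] for c in range(cid)}
    singles = []
    for i in range(n):
        if core[i]:
            continue
        core_nb = sorted(j for j in neigh[i] if core[j])
        if core_nb:
            clusters[label[core_nb[0]]].append(i)
        else:
            singles.append([i])
    out = [sorted(c) for c in clusters.values()] + singles
    out.sort(key=lambda c: c[0])
    return out


def graph_from_matrix(dist):
    g = DissimilarityGraph(dist.shape[0])
    for i in range(dist.shape[0]):
        for j in range(i + 1, dist.shape[0]):
            g.add_edge(i, j, float(dist[i, j]))
    return g


class TestDBSCAN:
    def test_all_far_gives_singletons(self):
        dist = np.ones((4, 4)) - np.eye(4)
        cmap = dbscan_cluster(graph_from_matrix(dist), DBSCANParams(R=0.3))
        assert cmap.clusters == [[0], [1], [2], [3]]

    def test_all_close_gives_one_cluster(self):
        dist = np.zeros((5, 5))
        cmap = dbscan_cluster(graph_from_matrix(dist), DBSCANParams(R=0.3))
        assert cmap.clusters == [[0, 1, 2, 3, 4]]

    def test_matches_reachability_oracle_on_random_matrices(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            n = 6
            d = rng.random((n, n))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0)
            got = dbscan_cluster(graph_from_matrix(d), DBSCANParams(R=0.3, N_min=2))
            assert got.clusters == dbscan_oracle(d, 0.3, 2)

    def test_result_is_partition(self):
        rng = np.random.default_rng(7)
        d = rng.random((10, 10))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        cmap = dbscan_cluster(graph_from_matrix(d), DBSCANParams(R=0.4))
        assert sorted(i for c in cmap.clusters for i in c) == list(range(10))


class TestLatentCardinality:
    @pytest.mark.parametrize("n_c,expected", [(2, 4), (3, 6), (4, 8), (5, 10), (100, 10)])
    def test_affine_formula_with_cap(self, n_c, expected):
        assert latent_cardinality(n_c) == expected

    def test_floor_two(self):
        assert latent_cardinality(2, FLTMParams(alpha=0.0, beta=0.1)) == 2

    def test_singleton_errors(self):
        with pytest.raises(ValueError):
            latent_cardinality(1)


def lcm_grid_oracle(patterns, counts, step=0.05):
    """Exhaustive grid search over a 2-child binary LCM with card 2."""
    grid = np.arange(step, 1.0, step)
    G = len(grid)
    best = -np.inf
    x1 = patterns[:, 0]
    x2 = patterns[:, 1]
    # vectorize the two child-2 parameters; loop the other three
    qa = np.where(x2[None, :] == 1, grid[:, None], 1 - grid[:, None])  # (G, m)
    qb = qa
    for p in grid:
        for a1 in grid:
            pa = np.where(x1 == 1, a1, 1 - a1)
            for b1 in grid:
                pb = np.where(x1 == 1, b1, 1 - b1)
                mix = (p * pa * qa)[:, None, :] + ((1 - p) * pb * qb)[None, :, :]
                ll = (counts * np.log(mix)).sum(axis=2).max()
                best = max(best, ll)
    return best


class TestFitLCM:
    def test_constant_children_reach_loglik_zero(self):
        X = np.zeros((2, 30), dtype=np.int16)
        lcm = fit_lcm(X, cardinality=2, nb_restarts=2, seed=0)
        assert lcm.loglik == pytest.approx(0.0, abs=1e-9)

    def test_loglik_trace_nondecreasing_on_random_data(self):
        rng = np.random.default_rng(11)
        for trial in range(100):
            n_children = int(rng.integers(2, 5))
            n = int(rng.integers(10, 60))
            X = rng.integers(0, 3, size=(n_children, n)).astype(np.int16)
            lcm = fit_lcm(X, cardinality=int(rng.integers(2, 5)),
                          nb_restarts=1, seed=trial)
            diffs = np.diff(lcm.loglik_trace)
            assert (diffs >= -1e-8).all()

    def test_reaches_grid_search_optimum_on_correlated_binary_children(self):
        rng = np.random.default_rng(12)
        z = rng.integers(0, 2, 200)
        X = np.stack([z, z]).astype(np.int16)  # perfectly correlated
        patterns, counts = np.unique(X.T, axis=0, return_counts=True)
        oracle = lcm_grid_oracle(patterns, counts.astype(float))
        lcm = fit_lcm(X, cardinality=2, arities=[2, 2], nb_restarts=10, seed=0)
        assert lcm.loglik >= oracle - 1e-3

    def test_cardinality_below_two_errors(self):
        with pytest.raises(ValueError):
            fit_lcm(np.zeros((2, 10), dtype=np.int16), cardinality=1)


class TestImputeValidate:
    def _fitted_identity_lcm(self):
        rng = np.random.default_rng(13)
        z = rng.integers(0, 2, 400)
        X = np.stack([z, z]).astype(np.int16)
        lcm = fit_lcm(X, cardinality=2, arities=[2, 2], nb_restarts=5, seed=1)
        return lcm, X

    def test_degenerate_posterior_is_deterministic(self):
        lcm, X = self._fitted_identity_lcm()
        a = impute_latent(lcm, X, seed=0)
        b = impute_latent(lcm, X, seed=999)
        # posterior is (near) degenerate for identical children
        assert np.array_equal(a, b)

    def test_same_seed_same_column(self):
        rng = np.random.default_rng(14)
        X = rng.integers(0, 3, size=(3, 100)).astype(np.int16)
        lcm = fit_lcm(X, cardinality=3, nb_restarts=2, seed=2)
        assert np.array_equal(impute_latent(lcm, X, seed=5), impute_latent(lcm, X, seed=5))

    def test_empirical_marginal_matches_analytic(self):
        rng = np.random.default_rng(15)
        z = rng.integers(0, 2, 10)
        X = np.stack([z, 1 - z]).astype(np.int16)
        lcm = fit_lcm(X, cardinality=2, arities=[2, 2], nb_restarts=5, seed=3)
        # replicate the 10 individuals 1000x to get 1e4 draws
        Xbig = np.tile(X, 1000)
        from ldtrees.fltm import _posterior

        analytic = _posterior(lcm, Xbig).mean(axis=0)
        draws = impute_latent(lcm, Xbig, seed=4)
        emp = np.bincount(draws, minlength=2) / draws.size
        assert np.abs(emp - analytic).sum() / 2 < 0.05  # total variation

    def test_latent_identical_to_children_scores_one(self):
        lcm, X = self._fitted_identity_lcm()
        valid, score = validate_latent(lcm, X[0], X, tau=0.3)
        assert valid and score == pytest.approx(1.0, abs=1e-9)

    def test_independent_latent_scores_near_zero(self):
        rng = np.random.default_rng(16)
        X = rng.integers(0, 3, size=(2, 10_000)).astype(np.int16)
        lcm = fit_lcm(X, cardinality=2, nb_restarts=1, seed=0)
        fake_latent = rng.integers(0, 2, 10_000).astype(np.int16)
        valid, score = validate_latent(lcm, fake_latent, X, tau=0.3)
        assert not valid and score < 0.05

    def test_threshold_is_inclusive(self):
        lcm, X = self._fitted_identity_lcm()
        _, score = validate_latent(lcm, X[0], X, tau=0.3)
        valid_at_score, _ = validate_latent(lcm, X[0], X, tau=score)
        assert valid_at_score

    def test_constant_latent_invalid(self):
        lcm, X = self._fitted_identity_lcm()
        valid, score = validate_latent(lcm, np.zeros(X.shape[1], np.int16), X)
        assert (valid, score) == (False, 0.0)


class TestLearnFLTM:
    def test_independent_snps_yield_no_latents(self):
        rng = np.random.default_rng(17)
        n = 2000
        rows = [rng.integers(0, 3, n) for _ in range(6)]
        ds = make_dataset(rows, rng.random(n) < 0.5)
        model = learn_fltm(ds, FLTMParams(nb_em_restarts=3), DBSCANParams(R=0.3), seed=0)
        assert model.n_latents == 0
        cmap = layer1_map(model)
        assert cmap.clusters == [[i] for i in range(6)]

    def test_ld_block_is_grouped(self, ld_block_dataset):
        model = learn_fltm(
            ld_block_dataset, FLTMParams(nb_em_restarts=3), DBSCANParams(R=0.5), seed=1
        )
        assert model.layers and len(model.layers[0]) >= 1
        block_latents = [v for v in model.layers[0] if set(v.snp_indices) <= set(range(5))]
        assert any(len(v.snp_indices) >= 4 for v in block_latents)

    def test_layer1_map_partitions(self, ld_block_dataset):
        model = learn_fltm(
            ld_block_dataset, FLTMParams(nb_em_restarts=2), DBSCANParams(R=0.5), seed=2
        )
        cmap = layer1_map(model)
        assert sorted(i for c in cmap.clusters for i in c) == list(range(8))
        assert cmap.provenance == "fltm_layer1"

    def test_validated_latents_meet_tau_on_recheck(self, ld_block_dataset):
        params = FLTMParams(nb_em_restarts=2)
        model = learn_fltm(ld_block_dataset, params, DBSCANParams(R=0.5), seed=3)
        for v in (model.layers[0] if model.layers else []):
            cols = np.stack(
                [ld_block_dataset.genotypes[i].astype(np.int16) for i in v.snp_indices]
            ) if len(v.children_ids) == len(v.snp_indices) else None
            assert v.validation_score >= params.tau

    def test_latent_count_within_structural_bound(self, ld_block_dataset):
        model = learn_fltm(ld_block_dataset, FLTMParams(nb_em_restarts=2),
                           DBSCANParams(R=0.6), seed=4)
        assert model.n_latents <= 3 * ld_block_dataset.n_snps

    def test_deterministic_given_seed(self, ld_block_dataset):
        kw = dict(params=FLTMParams(nb_em_restarts=2), dbscan=DBSCANParams(R=0.5))
        a = learn_fltm(ld_block_dataset, seed=7, **kw)
        b = learn_fltm(ld_block_dataset, seed=7, **kw)
        assert layer1_map(a) == layer1_map(b)
        assert [v.validation_score for l in a.layers for v in l] == [
            v.validation_score for l in b.layers for v in l
        ]


class TestSelectR:
    def test_single_value_grid(self, ld_block_dataset):
        r, model, crit = select_R(
            ld_block_dataset, FLTMParams(nb_em_restarts=2), r_grid=(0.4,), seed=0
        )
        assert r == 0.4 and 0.4 in crit

    def test_block_grouped_at_selected_r(self, ld_block_dataset):
        r, model, crit = select_R(
            ld_block_dataset, FLTMParams(nb_em_restarts=2),
            r_grid=(0.2, 0.4, 0.6), seed=1,
        )
        cmap = layer1_map(model)
        assert any(len(set(c) & set(range(5))) >= 4 for c in cmap.clusters)

    def test_reported_criterion_is_recomputable(self, ld_block_dataset):
        r, model, crit = select_R(
            ld_block_dataset, FLTMParams(nb_em_restarts=2), r_grid=(0.3, 0.5), seed=2
        )
        assert crit[r] == pytest.approx(fltm_selection_criterion(model))
        assert crit[r] == max(crit.values())
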