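"""Embedded random forest over SNP blocks or LD clusters (T-Trees).

Each *meta-tree* of the ensemble is grown on a bootstrap copy of the
individuals.  At a meta-node, K clusters are drawn from the cluster map;
one extremely randomized tree (Extra-tree) is grown per candidate
cluster on the node's observations; the tree's leaf labels (case
probabilities) define a numeric *meta-variable* nu, and the candidate
whose optimal threshold on nu best discriminates cases from controls
wins the split.  With a contiguous-block map this is the T-Trees
method; with the layer-1 cluster map of a latent-tree LD model it is
the hybrid method — the forest code is identical, parameterized by the
map.

SNP importance accumulates, over the winning Extra-trees of all
meta-nodes of all T meta-trees, each split's information gain weighted
by the fraction of the bootstrap sample reaching that split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from joblib import Parallel, delayed

from .data_io import MISSING, ClusterMap, GenotypeDataset
from .stats_core import discriminating_score_counts

__all__ = [
    "ForestParams",
    "ExtraTree",
    "MetaNode",
    "MetaLeaf",
    "MetaTree",
    "TTreesForest",
    "ImportanceVector",
    "make_block_map",
    "grow_extra_tree",
    "meta_variable_values",
    "optimal_meta_cutpoint",
    "grow_meta_tree",
    "fit_forest",
    "predict_proba",
    "variable_importance",
]


@dataclass(frozen=True)
class ForestParams:
    """Forest and embedded-tree hyper-parameters.

    Defaults follow the reference full-scale setting: T = 1000
    meta-trees, meta-leaf threshold S_n = 2000 observations, unbounded
    meta-node budget S_t, K = 1000 candidate clusters per meta-node,
    embedded leaf threshold s_n = 1, embedded split-node budget s_t = 5,
    k = the full block/cluster ("all"), contiguous block size B = 20.
    """

    T: int = 1000
    S_n: int = 2000
    S_t: int | None = None          # None = unbounded
    K: int = 1000
    s_n: int = 1
    s_t: int = 5
    k_policy: int | str = "all"     # "all" or a fixed integer
    B: int = 20

    def __post_init__(self) -> None:
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if self.S_n < 2:
            raise ValueError("S_n must be >= 2")
        if self.K < 1 or self.s_n < 1 or self.s_t < 1 or self.B < 1:
            raise ValueError("K, s_n, s_t, B must be >= 1")
        if isinstance(self.k_policy, int) and self.k_policy < 1:
            raise ValueError("fixed k must be >= 1")

    @classmethod
    def desk(cls, n_individuals: int | None = None, **overrides) -> "ForestParams":
        """Desk-scale preset: T = 50, K = 100, with the meta-leaf
        threshold scaled to half the sample size (the same S_n / n ratio
        as the full-scale setting, where S_n = 2000 for 4000 subjects)."""
        s_n = max(2, n_individuals // 2) if n_individuals else 500
        defaults = dict(T=50, K=100, S_n=s_n)
        defaults.update(overrides)
        return cls(**defaults)


class ExtraTree:
    """An extremely randomized tree stored as flat arrays.

    ``feature[i] >= 0`` marks a split node on that (global) SNP index
    with threshold ``threshold[i]`` (left child: value <= threshold);
    ``feature[i] == -1`` marks a leaf whose ``value[i]`` is the case
    probability of the training observations routed to it.
    """

    def __init__(self) -> None:
        self.feature: list[int] = []
        self.threshold: list[float] = []
        self.left: list[int] = []
        self.right: list[int] = []
        self.value: list[float] = []
        self.n_node: list[int] = []
        self.gain: list[float] = []

    def _add(self, feature: int, threshold: float, value: float, n: int, gain: float) -> int:
        self.feature.append(feature)
        self.threshold.append(threshold)
        self.left.append(-1)
        self.right.append(-1)
        self.value.append(value)
        self.n_node.append(n)
        self.gain.append(gain)
        return len(self.feature) - 1

    @property
    def n_splits(self) -> int:
        return sum(1 for f in self.feature if f >= 0)

    def route(self, genotypes: np.ndarray, sample_idx: np.ndarray) -> np.ndarray:
        """Leaf label reached by each observation in ``sample_idx``."""
        m = len(sample_idx)
        out = np.empty(m)
        stack = [(0, np.arange(m))]
        while stack:
            node, rows = stack.pop()
            f = self.feature[node]
            if f < 0:
                out[rows] = self.value[node]
                continue
            vals = genotypes[f, sample_idx[rows]]
            go_left = vals <= self.threshold[node]
            stack.append((self.left[node], rows[go_left]))
            stack.append((self.right[node], rows[~go_left]))
        return out

    def split_records(self) -> list[tuple[int, int, float]]:
        """(snp_index, n_at_node, gain) for every split node."""
        return [
            (self.feature[i], self.n_node[i], self.gain[i])
            for i in range(len(self.feature))
            if self.feature[i] >= 0
        ]


def make_block_map(ds: GenotypeDataset, B: int = 20) -> ClusterMap:
    """Partition the coordinate-sorted SNPs into contiguous blocks of B
    (the last block may be shorter)."""
    if B < 1:
        raise ValueError("B must be >= 1")
    n = ds.n_snps
    clusters = [list(range(i, min(i + B, n))) for i in range(0, n, B)]
    return ClusterMap(clusters=clusters, provenance="contiguous_blocks", n_snps=n)


def grow_extra_tree(
    genotypes: np.ndarray,
    y: np.ndarray,
    sample_idx: np.ndarray,
    cluster_vars: np.ndarray,
    k: int | str = "all",
    s_n: int = 1,
    s_t: int = 5,
    rng: np.random.Generator | None = None,
) -> ExtraTree:
    """Grow one Extra-tree on the observations ``sample_idx`` using the
    cluster's SNPs as candidate variables.

    At each node, k variables are drawn without replacement (all of them
    under the "all" policy); one threshold is drawn uniformly in the
    (min, max) of each non-constant variable's values at the node; the
    draw maximizing the discriminating score wins (ties -> first drawn).
    A node becomes a leaf when pure, smaller than ``s_n``, when the
    ``s_t`` split budget is exhausted (budget consumed in depth-first
    creation order, left child first) or when all candidates are
    constant.
    """
    if rng is None:
        rng = np.random.default_rng()
    sample_idx = np.asarray(sample_idx)
    if sample_idx.size == 0:
        raise ValueError("empty node data")
    cluster_vars = np.asarray(cluster_vars)
    sub = genotypes[np.ix_(cluster_vars, sample_idx)].astype(np.int8)
    ysub = y[sample_idx].astype(np.float64)
    n_vars = len(cluster_vars)
    tree = ExtraTree()
    budget = [s_t]

    def build(rows: np.ndarray) -> int:
        m = rows.size
        n_case = float(ysub[rows].sum())
        n_ctrl = m - n_case
        label = n_case / m
        if n_case == 0 or n_ctrl == 0 or m < s_n or budget[0] <= 0:
            return tree._add(-1, 0.0, label, m, 0.0)
        if isinstance(k, int) and k < n_vars:
            drawn = rng.choice(n_vars, size=k, replace=False)
        else:
            drawn = np.arange(n_vars)
        vals = sub[np.ix_(drawn, rows)]
        mins = vals.min(axis=1).astype(float)
        maxs = vals.max(axis=1).astype(float)
        cand = mins < maxs
        if not cand.any():
            return tree._add(-1, 0.0, label, m, 0.0)
        thetas = np.full(len(drawn), np.nan)
        thetas[cand] = rng.uniform(mins[cand], maxs[cand])
        left = vals <= thetas[:, None]
        case_left = left @ ysub[rows]
        scores = discriminating_score_counts(
            case_left, left.sum(axis=1) - case_left, n_case, n_ctrl
        )
        scores[~cand] = -1.0
        best = int(np.argmax(scores))  # first drawn wins ties
        budget[0] -= 1
        node = tree._add(
            int(cluster_vars[drawn[best]]), float(thetas[best]), label, m, float(scores[best])
        )
        go_left = sub[drawn[best], rows] <= thetas[best]
        tree.left[node] = build(rows[go_left])
        tree.right[node] = build(rows[~go_left])
        return node

    build(np.arange(sample_idx.size))
    return tree


def meta_variable_values(
    tree: ExtraTree, genotypes: np.ndarray, sample_idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Meta-variable nu(o) = leaf label reached by each observation, and
    its domain Dom(nu) = the distinct reached labels."""
    nu = tree.route(genotypes, np.asarray(sample_idx))
    return nu, np.unique(nu)


def optimal_meta_cutpoint(
    nu: np.ndarray, labels: np.ndarray
) -> tuple[float, float] | None:
    """Best threshold on the meta-variable over its value domain.

    Candidates are the sorted distinct nu values except the maximum
    (split: nu <= theta vs nu > theta); ties resolved toward the
    smallest theta.  Returns None when no split exists (single value).
    """
    nu = np.asarray(nu, dtype=float)
    y = np.asarray(labels, dtype=bool)
    distinct = np.unique(nu)
    if distinct.size < 2:
        return None
    order = np.argsort(nu, kind="stable")
    nu_sorted = nu[order]
    case_cum = np.cumsum(y[order].astype(float))
    n_case = float(case_cum[-1])
    n_ctrl = float(nu.size - n_case)
    # observations with nu <= theta for each candidate theta
    cuts = np.searchsorted(nu_sorted, distinct[:-1], side="right")
    case_left = case_cum[cuts - 1]
    n_left = cuts.astype(float)
    scores = discriminating_score_counts(case_left, n_left - case_left, n_case, n_ctrl)
    best = int(np.argmax(scores))  # argmax -> smallest theta on ties
    return float(distinct[best]), float(scores[best])


class MetaLeaf:
    __slots__ = ("probability", "n")

    def __init__(self, probability: float, n: int):
        self.probability = probability
        self.n = n


class MetaNode:
    __slots__ = ("cluster_id", "tree", "threshold", "score", "n", "left", "right")

    def __init__(self, cluster_id: int, tree: ExtraTree, threshold: float,
                 score: float, n: int):
        self.cluster_id = cluster_id
        self.tree = tree
        self.threshold = threshold
        self.score = score
        self.n = n
        self.left: "MetaNode | MetaLeaf | None" = None
        self.right: "MetaNode | MetaLeaf | None" = None


@dataclass
class MetaTree:
    root: MetaNode | MetaLeaf
    n_boot: int

    def iter_nodes(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            if isinstance(node, MetaNode):
                yield node
                stack.append(node.right)
                stack.append(node.left)

    def predict(self, genotypes: np.ndarray, sample_idx: np.ndarray) -> np.ndarray:
        out = np.empty(len(sample_idx))
        stack = [(self.root, np.arange(len(sample_idx)))]
        sample_idx = np.asarray(sample_idx)
        while stack:
            node, rows = stack.pop()
            if rows.size == 0:
                continue
            if isinstance(node, MetaLeaf):
                out[rows] = node.probability
                continue
            nu = node.tree.route(genotypes, sample_idx[rows])
            go_left = nu <= node.threshold
            stack.append((node.left, rows[go_left]))
            stack.append((node.right, rows[~go_left]))
        return out


def grow_meta_tree(
    genotypes: np.ndarray,
    y: np.ndarray,
    boot_idx: np.ndarray,
    cmap: ClusterMap,
    params: ForestParams,
    seed_parts: tuple[int, ...] = (0, 0),
) -> MetaTree:
    """Grow one meta-tree on a bootstrap sample.

    Every meta-node draws min(K, |map|) clusters without replacement,
    grows one Extra-tree per candidate and keeps the candidate whose
    optimal meta-cutpoint scores highest (ties -> first drawn).  A node
    with fewer than S_n observations, an exhausted S_t budget, or no
    positive-score candidate becomes a meta-leaf labeled with its case
    fraction.  Randomness is drawn from a counter-based stream keyed by
    (master seed, tree index, meta-node creation index), so results do
    not depend on execution parallelism.
    """
    boot_idx = np.asarray(boot_idx)
    if boot_idx.size == 0:
        raise ValueError("empty bootstrap sample")
    clusters = [np.asarray(c) for c in cmap.clusters]
    n_clusters = len(clusters)
    budget = [params.S_t if params.S_t is not None else np.inf]
    node_counter = [0]

    def node_rng() -> np.random.Generator:
        rng = np.random.default_rng(np.random.SeedSequence(seed_parts + (node_counter[0],)))
        node_counter[0] += 1
        return rng

    def build(idx: np.ndarray) -> MetaNode | MetaLeaf:
        m = idx.size
        case_frac = float(y[idx].mean())
        if m < params.S_n or budget[0] <= 0 or case_frac in (0.0, 1.0):
            return MetaLeaf(case_frac, m)
        rng = node_rng()
        n_draw = min(params.K, n_clusters)
        drawn = rng.choice(n_clusters, size=n_draw, replace=False)
        best = None  # (score, tree, theta, cluster_id, nu)
        for ci in drawn:
            cluster = clusters[ci]
            k = params.k_policy if isinstance(params.k_policy, int) else "all"
            et = grow_extra_tree(
                genotypes, y, idx, cluster,
                k=k, s_n=params.s_n, s_t=params.s_t, rng=rng,
            )
            nu, _dom = meta_variable_values(et, genotypes, idx)
            cut = optimal_meta_cutpoint(nu, y[idx])
            if cut is None:
                continue
            theta, score = cut
            if best is None or score > best[0]:
                best = (score, et, theta, int(ci), nu)
        if best is None or best[0] <= 0.0:
            return MetaLeaf(case_frac, m)
        score, et, theta, cid, nu = best
        budget[0] -= 1
        node = MetaNode(cid, et, theta, score, m)
        go_left = nu <= theta
        node.left = build(idx[go_left])
        node.right = build(idx[~go_left])
        return node

    return MetaTree(root=build(boot_idx), n_boot=boot_idx.size)


def _mode_impute(genotypes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Replace missing calls by the per-SNP modal genotype."""
    G = np.asarray(genotypes, dtype=np.int8).copy()
    modes = np.zeros(G.shape[0], dtype=np.int8)
    for i in range(G.shape[0]):
        row = G[i]
        miss = row == MISSING
        if not miss.any():
            counts = np.bincount(row, minlength=3)
            modes[i] = int(np.argmax(counts))
            continue
        obs = row[~miss]
        modes[i] = int(np.argmax(np.bincount(obs, minlength=3))) if obs.size else 0
        row[miss] = modes[i]
    return G, modes


@dataclass
class TTreesForest:
    """A fitted ensemble of T meta-trees sharing one cluster map."""

    trees: list[MetaTree]
    cmap: ClusterMap
    params: ForestParams
    seed: int
    n_snps: int
    impute_modes: np.ndarray

    @property
    def T(self) -> int:
        return len(self.trees)


@dataclass
class ImportanceVector:
    """Per-SNP importance scores; the GWAS ranking output."""

    scores: np.ndarray
    snp_ids: list[str]
    normalization: str = "sum"

    def ranking(self) -> list[str]:
        """snp_ids sorted by decreasing importance (ties: dataset order)."""
        order = np.argsort(-self.scores, kind="stable")
        return [self.snp_ids[i] for i in order]

    def ranks(self) -> np.ndarray:
        order = np.argsort(-self.scores, kind="stable")
        ranks = np.empty(len(self.scores), dtype=np.int64)
        ranks[order] = np.arange(1, len(self.scores) + 1)
        return ranks


def _grow_one(genotypes, y, n_ind, cmap, params, seed, t):
    boot_rng = np.random.default_rng(np.random.SeedSequence((seed, t)))
    boot = boot_rng.integers(0, n_ind, size=n_ind)
    return grow_meta_tree(genotypes, y, boot, cmap, params, seed_parts=(seed, t))


def fit_forest(
    ds: GenotypeDataset,
    cmap: ClusterMap,
    params: ForestParams = ForestParams(),
    seed: int = 0,
    n_jobs: int = 1,
) -> TTreesForest:
    """Fit T meta-trees, each on its own bootstrap of the individuals.

    Missing genotypes are mode-imputed per SNP once before learning.
    The result is deterministic given (dataset, map, params, seed),
    independent of ``n_jobs``.
    """
    if cmap.n_snps != ds.n_snps:
        raise ValueError("cluster map does not cover the dataset's SNPs")
    G, modes = _mode_impute(ds.genotypes)
    y = ds.phenotype
    n_ind = ds.n_individuals
    if n_jobs == 1:
        trees = [_grow_one(G, y, n_ind, cmap, params, seed, t) for t in range(params.T)]
    else:
        trees = Parallel(n_jobs=n_jobs)(
            delayed(_grow_one)(G, y, n_ind, cmap, params, seed, t)
            for t in range(params.T)
        )
    return TTreesForest(
        trees=trees, cmap=cmap, params=params, seed=seed,
        n_snps=ds.n_snps, impute_modes=modes,
    )


def predict_proba(forest: TTreesForest, ds: GenotypeDataset) -> np.ndarray:
    """Mean meta-leaf case probability over the T meta-trees."""
    if ds.n_snps != forest.n_snps:
        raise ValueError("dataset SNPs do not match the forest")
    G = np.asarray(ds.genotypes, dtype=np.int8).copy()
    miss = G == MISSING
    if miss.any():
        G[miss] = np.broadcast_to(forest.impute_modes[:, None], G.shape)[miss]
    idx = np.arange(ds.n_individuals)
    acc = np.zeros(ds.n_individuals)
    for tree in forest.trees:
        acc += tree.predict(G, idx)
    return acc / len(forest.trees)


def variable_importance(
    forest: TTreesForest, snp_ids: list[str] | None = None, normalize: str = "sum"
) -> ImportanceVector:
    """Accumulate split gains of the winning Extra-trees over the forest.

    raw(v) = sum over retained embedded split nodes e on SNP v of
    (|D_e| / |D_bootstrap|) * gain(e).  ``normalize`` is "sum" (scores
    sum to 1), "max" (max score 1) or "none".
    """
    if normalize not in ("sum", "max", "none"):
        raise ValueError(f"unknown normalization {normalize!r}")
    raw = np.zeros(forest.n_snps)
    for tree in forest.trees:
        for node in tree.iter_nodes():
            for snp, n_e, gain in node.tree.split_records():
                raw[snp] += (n_e / tree.n_boot) * gain
    if normalize == "sum" and raw.sum() > 0:
        raw = raw / raw.sum()
    elif normalize == "max" and raw.max() > 0:
        raw = raw / raw.max()
    ids = snp_ids if snp_ids is not None else [f"snp{i}" for i in range(forest.n_snps)]
    return ImportanceVector(scores=raw, snp_ids=ids, normalization=normalize)
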