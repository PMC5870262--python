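"""Forest of latent tree models (FLTM) for linkage-disequilibrium mapping.

The model is a forest of tree-shaped Bayesian networks whose leaves are
observed SNPs and whose internal nodes are discrete latent variables.
Learning proceeds bottom-up: active variables are clustered (DBSCAN on a
mutual-information dissimilarity, restricted to pairs within a physical
distance ``delta_bp``); for each cluster of size >= 2 a latent class
model (LCM) is fitted by EM; the latent variable is kept only if the
average normalized mutual information between it and its children
reaches the validity threshold ``tau``; validated latents replace their
children and the process iterates.

The child sets of the *validated layer-1 latents* form the LD cluster
map consumed by the hybrid tree-ensemble (:func:`layer1_map`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .data_io import MISSING, ClusterMap, GenotypeDataset

__all__ = [
    "FLTMParams",
    "DBSCANParams",
    "DissimilarityGraph",
    "LCM",
    "FLTMModel",
    "ld_distance_graph",
    "dbscan_cluster",
    "latent_cardinality",
    "fit_lcm",
    "validate_latent",
    "impute_latent",
    "learn_fltm",
    "layer1_map",
    "select_R",
    "fltm_selection_criterion",
]


@dataclass(frozen=True)
class FLTMParams:
    """Latent-tree learning parameters.

    ``alpha``/``beta``/``card_max`` define the cardinality heuristic
    card(L) = min(alpha + beta * n_children, card_max); ``tau`` is the
    latent validity threshold on the mean normalized mutual information;
    ``delta_bp`` is the maximal physical distance (base pairs, inclusive)
    for two variables to share a cluster.
    """

    alpha: float = 0.2
    beta: float = 2.0
    card_max: int = 10
    tau: float = 0.3
    nb_em_restarts: int = 10
    delta_bp: int = 50_000
    em_tol: float = 1e-4
    em_max_iter: int = 200

    def __post_init__(self) -> None:
        if self.card_max < 2:
            raise ValueError("card_max must be >= 2")
        if not (0 < self.tau < 1):
            raise ValueError("tau must be in (0,1)")
        if self.nb_em_restarts < 1:
            raise ValueError("nb_em_restarts must be >= 1")
        if self.delta_bp <= 0:
            raise ValueError("delta_bp must be > 0")


@dataclass(frozen=True)
class DBSCANParams:
    """DBSCAN radius ``R`` (on the 1 - NMI dissimilarity) and ``N_min``."""

    R: float = 0.3
    N_min: int = 2

    def __post_init__(self) -> None:
        if not (0 < self.R <= 1):
            raise ValueError("R must be in (0,1]")
        if self.N_min < 1:
            raise ValueError("N_min must be >= 1")


DEFAULT_R_GRID: tuple[float, ...] = tuple(round(0.05 * i, 2) for i in range(1, 19))


class DissimilarityGraph:
    """Sparse symmetric dissimilarity graph over n variables.

    Edges only exist between variables on the same chromosome within the
    physical-distance window; weights are 1 - NMI in [0, 1].
    """

    def __init__(self, n: int):
        self.n = n
        self._adj: list[list[tuple[int, float]]] = [[] for _ in range(n)]

    def add_edge(self, i: int, j: int, d: float) -> None:
        self._adj[i].append((j, d))
        self._adj[j].append((i, d))

    def neighbors_within(self, i: int, radius: float) -> list[int]:
        return [j for j, d in self._adj[i] if d <= radius]

    def degree(self, i: int) -> int:
        return len(self._adj[i])


def _pair_nmi(a: np.ndarray, b: np.ndarray, arity_a: int, arity_b: int) -> float | None:
    """Normalized MI of two discrete columns; None if a margin is constant."""
    if (a < 0).any() or (b < 0).any():
        ok = (a >= 0) & (b >= 0)
        if not ok.any():
            return None
        a, b = a[ok], b[ok]
    table = np.bincount(
        a.astype(np.intp) * arity_b + b, minlength=arity_a * arity_b
    ).reshape(arity_a, arity_b)
    total = table.sum()
    p = table / total
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    hx = -(px[px > 0] * np.log2(px[px > 0])).sum()
    hy = -(py[py > 0] * np.log2(py[py > 0])).sum()
    if min(hx, hy) == 0.0:
        return None
    pos = p > 0
    mi = (p[pos] * np.log2(p[pos] / np.outer(px, py)[pos])).sum()
    return float(min(max(mi, 0.0) / max(hx, hy), 1.0))


def _distance_graph(
    columns: list[np.ndarray],
    arities: list[int],
    positions: list[int],
    chromosomes: list[str],
    delta_bp: int,
) -> DissimilarityGraph:
    n = len(columns)
    graph = DissimilarityGraph(n)
    order = sorted(range(n), key=lambda i: (chromosomes[i], positions[i]))
    for a_idx in range(n):
        i = order[a_idx]
        for b_idx in range(a_idx + 1, n):
            j = order[b_idx]
            if chromosomes[j] != chromosomes[i]:
                break
            if abs(positions[j] - positions[i]) > delta_bp:
                break
            nmi = _pair_nmi(columns[i], columns[j], arities[i], arities[j])
            if nmi is None:
                continue
            graph.add_edge(i, j, 1.0 - nmi)
    return graph


def ld_distance_graph(ds: GenotypeDataset, delta_bp: int = 50_000) -> DissimilarityGraph:
    """Mutual-information dissimilarity graph over a dataset's SNPs.

    Edge (i, j) exists iff the SNPs share a chromosome and lie within
    ``delta_bp`` base pairs (inclusive); the weight is 1 - NMI.  Constant
    SNPs (zero entropy) get no edges.
    """
    if ds.n_snps < 2:
        raise ValueError("need at least 2 SNPs")
    cols = [ds.genotypes[i] for i in range(ds.n_snps)]
    return _distance_graph(
        cols,
        [3] * ds.n_snps,
        [s.position_bp for s in ds.snps],
        [s.chromosome for s in ds.snps],
        delta_bp,
    )


def dbscan_cluster(graph: DissimilarityGraph, params: DBSCANParams) -> ClusterMap:
    """Density-based clustering on the dissimilarity graph.

    Core points have >= ``N_min`` neighbors at distance <= R; clusters
    are the connected components of core points under <=R reachability;
    border points attach to the cluster of their smallest-index core
    neighbor; noise points become singletons so the result is always a
    partition.
    """
    n = graph.n
    if n == 0:
        return ClusterMap(clusters=[], provenance="fltm_layer1", n_snps=0)
    neigh = [graph.neighbors_within(i, params.R) for i in range(n)]
    core = np.array([len(neigh[i]) >= params.N_min for i in range(n)])

    label = np.full(n, -1, dtype=int)
    n_clusters = 0
    for i in range(n):
        if not core[i] or label[i] >= 0:
            continue
        # BFS over core points reachable within R
        label[i] = n_clusters
        stack = [i]
        while stack:
            u = stack.pop()
            for v in neigh[u]:
                if core[v] and label[v] < 0:
                    label[v] = n_clusters
                    stack.append(v)
        n_clusters += 1

    clusters: dict[int, list[int]] = {c: [] for c in range(n_clusters)}
    singles: list[list[int]] = []
    for i in range(n):
        if core[i]:
            clusters[label[i]].append(i)
            continue
        core_neigh = sorted(j for j in neigh[i] if core[j])
        if core_neigh:
            clusters[label[core_neigh[0]]].append(i)
        else:
            singles.append([i])
    ordered = [sorted(c) for c in clusters.values() if c] + singles
    ordered.sort(key=lambda c: c[0])
    return ClusterMap(clusters=ordered, provenance="fltm_layer1", n_snps=n)


def latent_cardinality(n_c: int, params: FLTMParams = FLTMParams()) -> int:
    """Affine cardinality heuristic: max(2, round(min(a + b*n_c, card_max)))."""
    if n_c < 2:
        raise ValueError("no latent class model for clusters of size < 2")
    value = min(params.alpha + params.beta * n_c, float(params.card_max))
    return max(2, int(np.floor(value + 0.5)))


@dataclass
class LCM:
    """A fitted latent class model: one latent, conditionally independent
    discrete children."""

    latent_id: str
    cardinality: int
    children: list[str]
    arities: list[int]
    prior: np.ndarray                 # (card,)
    cpts: list[np.ndarray]            # per child: (card, arity), rows sum to 1
    loglik: float                     # nats
    loglik_trace: list[float] = field(default_factory=list)


def _em_run(
    patterns: np.ndarray,
    weights: np.ndarray,
    arities: list[int],
    card: int,
    rng: np.random.Generator,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, list[np.ndarray], float, list[float]]:
    m, n_children = patterns.shape
    total_w = weights.sum()
    prior = rng.dirichlet(np.ones(card))
    cpts = [rng.dirichlet(np.ones(a), size=card) for a in arities]
    # stacked bookkeeping (constant across iterations): the CPTs of all
    # children are concatenated along the value axis so the E-step is a
    # single gather and the M-step a single matmul
    offsets = np.concatenate([[0], np.cumsum(arities)])
    total_arity = int(offsets[-1])
    flat_idx = np.empty((n_children, m), dtype=np.intp)
    onehot = np.zeros((m, total_arity))
    for c in range(n_children):
        v = patterns[:, c]
        obs = v >= 0
        # missing values point at a column whose log is forced to 0 below
        flat_idx[c] = np.where(obs, offsets[c] + v, 0)
        miss_rows = np.flatnonzero(~obs)
        rows = np.flatnonzero(obs)
        onehot[rows, offsets[c] + v[rows]] = 1.0
        if miss_rows.size:
            flat_idx[c, miss_rows] = -1  # sentinel
    missing_any = (flat_idx < 0).any()
    trace: list[float] = []
    prev_ll = -np.inf
    for _ in range(max_iter):
        flat_logcpt = np.log(np.maximum(np.concatenate(cpts, axis=1), 1e-300))  # (card, A)
        if missing_any:
            gathered = np.where(
                flat_idx[..., None] >= 0,
                flat_logcpt.T[np.maximum(flat_idx, 0)],
                0.0,
            )
        else:
            gathered = flat_logcpt.T[flat_idx]       # (n_children, m, card)
        logpost = gathered.sum(axis=0)
        logpost += np.log(np.maximum(prior, 1e-300))
        mx = logpost.max(axis=1)
        p = np.exp(logpost - mx[:, None])
        s = p.sum(axis=1)
        ll = float(weights @ (mx + np.log(s)))
        trace.append(ll)
        resp = (p / s[:, None]) * weights[:, None]
        # M-step
        prior = resp.sum(axis=0) / total_w
        num = resp.T @ onehot                        # (card, A)
        for c in range(n_children):
            blk = num[:, offsets[c]:offsets[c + 1]]
            denom = blk.sum(axis=1)
            cpts[c] = np.where(
                denom[:, None] > 0,
                blk / np.maximum(denom[:, None], 1e-300),
                1.0 / arities[c],
            )
        if ll - prev_ll < tol and np.isfinite(prev_ll):
            break
        prev_ll = ll
    return prior, cpts, trace[-1], trace


def fit_lcm(
    child_columns: np.ndarray,
    cardinality: int,
    arities: list[int] | None = None,
    nb_restarts: int = 10,
    tol: float = 1e-4,
    max_iter: int = 200,
    seed: int = 0,
    children: list[str] | None = None,
    latent_id: str = "L0",
) -> LCM:
    """Fit an LCM by EM; best of ``nb_restarts`` random initializations.

    ``child_columns`` is (n_children, n_individuals) with entries in
    {0..arity-1} or ``MISSING``; missing values are marginalized out of
    the E-step.  Log-likelihoods are in nats and non-decreasing within a
    run up to floating-point round-off.
    """
    X = np.asarray(child_columns)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 child columns")
    if cardinality < 2:
        raise ValueError("latent cardinality must be >= 2")
    if arities is None:
        arities = [max(int(X[c][X[c] >= 0].max(initial=0)) + 1, 2) for c in range(X.shape[0])]
    patterns, inverse, counts = np.unique(
        X.T, axis=0, return_inverse=True, return_counts=True
    )
    weights = counts.astype(float)
    best: tuple[np.ndarray, list[np.ndarray], float, list[float]] | None = None
    for r in range(nb_restarts):
        rng = np.random.default_rng(seed + r)
        run = _em_run(patterns, weights, arities, cardinality, rng, tol, max_iter)
        if best is None or run[2] > best[2]:
            best = run
    prior, cpts, ll, trace = best
    return LCM(
        latent_id=latent_id,
        cardinality=cardinality,
        children=children or [f"c{c}" for c in range(X.shape[0])],
        arities=list(arities),
        prior=prior,
        cpts=cpts,
        loglik=ll,
        loglik_trace=trace,
    )


def _posterior(lcm: LCM, child_columns: np.ndarray) -> np.ndarray:
    """P(L | observed children) per individual; shape (n, card)."""
    X = np.asarray(child_columns)
    n = X.shape[1]
    logpost = np.tile(np.log(np.maximum(lcm.prior, 1e-300)), (n, 1))
    for c in range(X.shape[0]):
        v = X[c]
        obs = v >= 0
        if obs.any():
            logcpt = np.log(np.maximum(lcm.cpts[c], 1e-300))
            logpost[obs] += logcpt[:, v[obs]].T
    logpost -= logsumexp(logpost, axis=1, keepdims=True)
    return np.exp(logpost)


def impute_latent(lcm: LCM, child_columns: np.ndarray, seed: int = 0) -> np.ndarray:
    """Sample each individual's latent state from P(L | children); seeded."""
    post = _posterior(lcm, child_columns)
    rng = np.random.default_rng(seed)
    u = rng.random(post.shape[0])
    cum = np.cumsum(post, axis=1)
    cum[:, -1] = 1.0 + 1e-12
    return (u[:, None] > cum).sum(axis=1).astype(np.int16)


def validate_latent(
    lcm: LCM,
    latent_column: np.ndarray,
    child_columns: np.ndarray,
    tau: float = 0.3,
) -> tuple[bool, float]:
    """Mean normalized MI between the imputed latent and each child.

    Valid iff score >= tau (inclusive).  A zero-entropy latent is invalid
    with score 0; a constant child contributes 0 to the mean.
    """
    lat = np.asarray(latent_column)
    card = int(lat.max(initial=0)) + 1
    vals, counts = np.unique(lat, return_counts=True)
    p = counts / counts.sum()
    h_lat = -(p * np.log2(p)).sum()
    if h_lat == 0.0:
        return False, 0.0
    scores = []
    X = np.asarray(child_columns)
    for c in range(X.shape[0]):
        nmi = _pair_nmi(lat, X[c], card, lcm.arities[c])
        scores.append(0.0 if nmi is None else nmi)
    score = float(np.mean(scores))
    return score >= tau, score


@dataclass
class ValidatedLatent:
    """A validated latent variable with its subtree bookkeeping."""

    latent_id: str
    lcm: LCM
    children_ids: list[str]
    snp_indices: list[int]     # all observed SNPs in the subtree
    validation_score: float
    imputed: np.ndarray
    position_bp: int
    chromosome: str


@dataclass
class FLTMModel:
    """Learned forest of latent trees: validated latents per layer."""

    n_snps: int
    layers: list[list[ValidatedLatent]]
    orphan_snps: list[int]
    params: FLTMParams
    dbscan: DBSCANParams
    seed: int

    @property
    def n_latents(self) -> int:
        return sum(len(layer) for layer in self.layers)

    @property
    def latent_data(self) -> dict[str, np.ndarray]:
        return {v.latent_id: v.imputed for layer in self.layers for v in layer}


def _derive_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(tuple(parts)).generate_state(1)[0] % (2**31))


def learn_fltm(
    ds: GenotypeDataset,
    params: FLTMParams = FLTMParams(),
    dbscan: DBSCANParams = DBSCANParams(),
    seed: int = 0,
) -> FLTMModel:
    """Iteratively cluster active variables and subsume them under
    validated latents until no new valid latent can be created."""
    n = ds.n_snps
    columns: list[np.ndarray] = [ds.genotypes[i].astype(np.int16) for i in range(n)]
    arities: list[int] = [3] * n
    positions: list[int] = [s.position_bp for s in ds.snps]
    chroms: list[str] = [s.chromosome for s in ds.snps]
    ids: list[str] = [s.snp_id for s in ds.snps]
    # SNPs in each active variable's subtree (observed vars: themselves)
    subtrees: list[list[int]] = [[i] for i in range(n)]

    layers: list[list[ValidatedLatent]] = []
    latent_counter = 0
    layer_no = 0
    rejected: set[frozenset[str]] = set()  # clusters already tried and invalid
    while len(columns) >= 2:
        layer_no += 1
        graph = _distance_graph(columns, arities, positions, chroms, params.delta_bp)
        cmap = dbscan_cluster(graph, dbscan)
        validated: list[ValidatedLatent] = []
        subsumed: set[int] = set()
        for ci, cluster in enumerate(cmap.clusters):
            if len(cluster) < 2:
                continue
            key = frozenset(ids[v] for v in cluster)
            if key in rejected:
                # identical cluster failed tau-validation in an earlier
                # iteration; re-fitting the same data cannot help
                continue
            card = latent_cardinality(len(cluster), params)
            X = np.stack([columns[v] for v in cluster])
            child_arities = [arities[v] for v in cluster]
            base = _derive_seed(seed, layer_no, ci)
            lcm = fit_lcm(
                X,
                cardinality=card,
                arities=child_arities,
                nb_restarts=params.nb_em_restarts,
                tol=params.em_tol,
                max_iter=params.em_max_iter,
                seed=base,
                children=[ids[v] for v in cluster],
                latent_id=f"L{latent_counter}",
            )
            lat_col = impute_latent(lcm, X, seed=base + 1)
            ok, score = validate_latent(lcm, lat_col, X, tau=params.tau)
            if not ok:
                continue
            snp_idx = sorted({s for v in cluster for s in subtrees[v]})
            validated.append(
                ValidatedLatent(
                    latent_id=f"L{latent_counter}",
                    lcm=lcm,
                    children_ids=[ids[v] for v in cluster],
                    snp_indices=snp_idx,
                    validation_score=score,
                    imputed=lat_col,
                    position_bp=int(np.mean([positions[v] for v in cluster])),
                    chromosome=chroms[cluster[0]],
                )
            )
            latent_counter += 1
            subsumed |= set(cluster)
        if not validated:
            break
        layers.append(validated)
        keep = [v for v in range(len(columns)) if v not in subsumed]
        columns = [columns[v] for v in keep] + [v.imputed for v in validated]
        arities = [arities[v] for v in keep] + [v.lcm.cardinality for v in validated]
        positions = [positions[v] for v in keep] + [v.position_bp for v in validated]
        chroms = [chroms[v] for v in keep] + [v.chromosome for v in validated]
        ids = [ids[v] for v in keep] + [v.latent_id for v in validated]
        subtrees = [subtrees[v] for v in keep] + [v.snp_indices for v in validated]
        if latent_counter > 3 * n:  # structural bound; should be unreachable
            raise RuntimeError("latent count exceeded 3 * n_snps")

    covered = {s for layer in layers for v in layer for s in v.snp_indices}
    orphans = sorted(set(range(n)) - covered)
    return FLTMModel(
        n_snps=n, layers=layers, orphan_snps=orphans,
        params=params, dbscan=dbscan, seed=seed,
    )


def layer1_map(model: FLTMModel, n_snps: int | None = None) -> ClusterMap:
    """Cluster map from validated layer-1 latents; uncovered SNPs are
    singletons.  This is the LD map the hybrid forest consumes."""
    n = n_snps if n_snps is not None else model.n_snps
    clusters: list[list[int]] = []
    covered: set[int] = set()
    if model.layers:
        for v in model.layers[0]:
            clusters.append(sorted(v.snp_indices))
            covered |= set(v.snp_indices)
    clusters += [[i] for i in range(n) if i not in covered]
    clusters.sort(key=lambda c: c[0])
    return ClusterMap(clusters=clusters, provenance="fltm_layer1", n_snps=n)


def fltm_selection_criterion(model: FLTMModel) -> float:
    """LD coverage captured by the layer-1 latents.

    The size-weighted validation score summed over validated layer-1
    latents, normalized by the total SNP count: equivalently the mean,
    over all SNPs, of the normalized mutual information its latent
    achieves (0 for SNPs left as singletons).  Normalizing only within
    validated clusters would make the criterion monotone toward tiny,
    tight clusters; dividing by n rewards both cluster quality and the
    fraction of the genome actually modeled.  Returns 0 for a model
    with no validated layer-1 latent.
    """
    if not model.layers or not model.layers[0]:
        return 0.0
    sizes = np.array([len(v.snp_indices) for v in model.layers[0]], dtype=float)
    scores = np.array([v.validation_score for v in model.layers[0]])
    return float((sizes * scores).sum() / model.n_snps)


def select_R(
    ds: GenotypeDataset,
    params: FLTMParams = FLTMParams(),
    r_grid: tuple[float, ...] = DEFAULT_R_GRID,
    n_min: int = 2,
    seed: int = 0,
) -> tuple[float, FLTMModel, dict[float, float]]:
    """Learn one FLTM per candidate radius R; keep the R maximizing the
    entropy-based selection criterion (ties -> smallest R)."""
    if not r_grid:
        raise ValueError("empty R grid")
    best_r, best_model, best_score = None, None, -1.0
    criteria: dict[float, float] = {}
    for r in r_grid:
        model = learn_fltm(ds, params, DBSCANParams(R=r, N_min=n_min), seed=seed)
        crit = fltm_selection_criterion(model)
        criteria[r] = crit
        if crit > best_score:
            best_r, best_model, best_score = r, model, crit
    return best_r, best_model, criteria
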