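"""Evaluation harness: causal recovery, predictive power, importance
distributions, and top-100 intersections.

Four analyses compare the single-SNP baseline, T-Trees and the hybrid
method: (1) the percentage of planted causal SNPs recovered in the top-k
of an importance ranking, aggregated over replicates; (2) 10-fold
cross-validated AUC of the forest's case-probability predictions (the LD
map is built once on the full dataset and shared across folds); (3) a
peer comparison of two importance distributions (Wilcoxon rank-sum,
Pearson correlation, quantile grid); (4) intersections of the top-100
SNP sets across methods, with top*m membership (SNPs jointly in every
method's top m).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.model_selection import StratifiedKFold

from .data_io import ClusterMap, GenotypeDataset
from .forest import ForestParams, fit_forest, predict_proba

__all__ = [
    "RecoveryReport",
    "CVResult",
    "DistributionComparison",
    "IntersectionReport",
    "topk_recovery",
    "roc_auc",
    "cross_validate",
    "compare_importances",
    "top_intersections",
]

DEFAULT_KS: tuple[int, ...] = (25, 50, 100, 200, 1000)


@dataclass
class RecoveryReport:
    """Percentage of causal SNPs found in the top-k, per k."""

    percentages: dict[int, float]
    n_replicates: int
    n_causal_total: int

    def __getitem__(self, k: int) -> float:
        return self.percentages[k]


def topk_recovery(
    rankings: list[list[str]],
    causal_ids: list[list[str]],
    ks: tuple[int, ...] = DEFAULT_KS,
) -> RecoveryReport:
    """Aggregate top-k causal recovery over replicates.

    ``rankings[r]`` is replicate r's SNP ids in rank order (best first);
    ``causal_ids[r]`` its planted causal SNPs.  The percentage for k is
    100 * sum_r |causal_r ∩ top-k_r| / sum_r |causal_r|.  k larger than
    a replicate's panel is capped at the panel size.
    """
    if len(rankings) != len(causal_ids):
        raise ValueError("rankings / causal_ids length mismatch")
    total_causal = sum(len(c) for c in causal_ids)
    if total_causal == 0:
        raise ValueError("no causal SNPs")
    pct: dict[int, float] = {}
    for k in ks:
        hits = 0
        for ranking, causal in zip(rankings, causal_ids):
            top = set(ranking[: min(k, len(ranking))])
            hits += len(top & set(causal))
        pct[int(k)] = 100.0 * hits / total_causal
    return RecoveryReport(
        percentages=pct, n_replicates=len(rankings), n_causal_total=total_causal
    )


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve, Mann-Whitney formulation (ties 0.5).

    The probability that a randomly chosen case receives a higher score
    than a randomly chosen control.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n_case = int(y.sum())
    n_ctrl = int((~y).sum())
    if n_case == 0 or n_ctrl == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(scores)  # average ranks handle ties
    u = ranks[y].sum() - n_case * (n_case + 1) / 2
    return float(u / (n_case * n_ctrl))


@dataclass
class CVResult:
    """Per-fold and mean cross-validated AUC."""

    fold_aucs: list[float]
    fold_assignment: np.ndarray  # fold index per individual

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_aucs))


def cross_validate(
    ds: GenotypeDataset,
    cmap: ClusterMap,
    params: ForestParams,
    n_folds: int = 10,
    seed: int = 0,
    n_jobs: int = 1,
) -> CVResult:
    """Stratified k-fold cross-validation of the forest's predictions.

    The cluster map is built once on the full dataset and reused for
    every fold; only the forest is refitted per fold.
    """
    y = ds.phenotype
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignment = np.empty(ds.n_individuals, dtype=int)
    aucs: list[float] = []
    for fold, (train, test) in enumerate(skf.split(np.zeros(len(y)), y)):
        assignment[test] = fold
        train_ds = ds.subset_individuals(train)
        test_ds = ds.subset_individuals(test)
        forest = fit_forest(train_ds, cmap, params, seed=seed + fold, n_jobs=n_jobs)
        probs = predict_proba(forest, test_ds)
        aucs.append(roc_auc(probs, test_ds.phenotype))
    return CVResult(fold_aucs=aucs, fold_assignment=assignment)


@dataclass
class DistributionComparison:
    """Peer comparison of two importance-score distributions."""

    wilcoxon_statistic: float
    wilcoxon_p: float
    pearson_r: float
    quantiles: dict[str, tuple[float, float]]  # label -> (v1 value, v2 value)


def _quantile_grid(n: int) -> list[tuple[str, float]]:
    grid: list[tuple[str, float]] = [("25%", 0.25), ("50%", 0.50), ("75%", 0.75)]
    for n_top in (300, 200, 100, 50, 20, 10):
        if n_top < n:
            grid.append((f"top{n_top}", 1.0 - n_top / n))
    grid.append(("max", 1.0))
    return grid


def compare_importances(
    v1: np.ndarray, v2: np.ndarray
) -> DistributionComparison:
    """Wilcoxon rank-sum, Pearson correlation and a quantile table.

    The rank-sum test uses the normal approximation with tie correction
    (exact when the combined sample is below 50 and tie-free); quantile
    labels include the positions of the top-300/200/100/50/20/10 scores.
    """
    a = np.asarray(v1, dtype=float)
    b = np.asarray(v2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("importance vectors must have the same length")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (a.size + b.size < 50 and not has_ties) else "asymptotic"
    mw = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    if np.all(a == a[0]) or np.all(b == b[0]):
        r = 0.0 if not np.array_equal(a, b) else 1.0
    else:
        r = float(sps.pearsonr(a, b).statistic)
    quantiles = {
        label: (float(np.quantile(a, q)), float(np.quantile(b, q)))
        for label, q in _quantile_grid(a.size)
    }
    return DistributionComparison(
        wilcoxon_statistic=float(mw.statistic),
        wilcoxon_p=float(mw.pvalue),
        pearson_r=r,
        quantiles=quantiles,
    )


@dataclass
class IntersectionReport:
    """Joint top-n membership across >= 2 ranked methods."""

    top_sets: dict[str, list[str]]
    pairwise: dict[tuple[str, str], list[str]]
    joint: list[str]                  # intersection over all methods
    max_rank: dict[str, int]          # per jointly-top-n SNP
    n: int

    def top_star(self, m: int) -> list[str]:
        """SNPs ranked within the top m by *every* method."""
        return sorted((s for s, r in self.max_rank.items() if r <= m),
                      key=lambda s: self.max_rank[s])


def top_intersections(
    rankings: dict[str, list[str]], n: int = 100
) -> IntersectionReport:
    """Pairwise and full intersections of the methods' top-n SNP sets.

    For each SNP in the full intersection, ``max_rank`` records its worst
    rank across methods; ``top_star(m)`` returns the SNPs jointly ranked
    within the top m by every method.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(rankings) < 2:
        raise ValueError("need at least two rankings")
    names = list(rankings)
    tops = {name: list(rankings[name][:n]) for name in names}
    rank_of = {
        name: {sid: i + 1 for i, sid in enumerate(rankings[name])} for name in names
    }
    pairwise: dict[tuple[str, str], list[str]] = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            pairwise[(a, b)] = sorted(set(tops[a]) & set(tops[b]))
    joint = set(tops[names[0]])
    for name in names[1:]:
        joint &= set(tops[name])
    max_rank = {
        sid: max(rank_of[name][sid] for name in names) for sid in joint
    }
    return IntersectionReport(
        top_sets=tops,
        pairwise=pairwise,
        joint=sorted(joint, key=lambda s: max_rank[s]),
        max_rank=max_rank,
        n=n,
    )
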