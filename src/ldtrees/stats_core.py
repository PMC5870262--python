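"""Entropy / mutual-information machinery and contingency-table tests.

All entropies and mutual informations are reported in bits (base-2
logarithms); normalized quantities are base-invariant.  The split
criterion used throughout the tree code is the class-entropy information
gain

    discriminatingScore = H(D) - w_l * H(D_l) - w_r * H(D_r),

where H is the binary entropy of the case/control composition of a
sample set and w_l, w_r are the relative child sizes.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

__all__ = [
    "class_entropy",
    "discriminating_score",
    "discriminating_score_counts",
    "mutual_information",
    "normalized_mi",
    "trend_test",
    "general_chi2_test",
    "hwe_exact_test",
]


def class_entropy(n_case: int, n_control: int) -> float:
    """Binary entropy (bits) of a case/control composition."""
    n = n_case + n_control
    if n <= 0:
        raise ValueError("empty class counts")
    if n_case < 0 or n_control < 0:
        raise ValueError("negative class counts")
    h = 0.0
    for k in (n_case, n_control):
        if k > 0:
            p = k / n
            h -= p * np.log2(p)
    return float(h)


def discriminating_score(
    parent: tuple[int, int], left: tuple[int, int], right: tuple[int, int]
) -> float:
    """Information gain of splitting ``parent`` into ``left`` + ``right``.

    An empty child contributes 0.  The result lies in [0, H(parent)].
    """
    if left[0] + right[0] != parent[0] or left[1] + right[1] != parent[1]:
        raise ValueError("left + right must equal parent componentwise")
    n = parent[0] + parent[1]
    if n == 0:
        raise ValueError("empty parent")
    score = class_entropy(*parent)
    for child in (left, right):
        m = child[0] + child[1]
        if m > 0:
            score -= (m / n) * class_entropy(*child)
    # clamp tiny negative float residue
    return float(max(score, 0.0))


def _entropy_from_counts(counts: np.ndarray) -> np.ndarray:
    """Vectorized binary entropy; ``counts`` has shape (..., 2)."""
    n = counts.sum(axis=-1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, counts / np.maximum(n, 1), 0.0)
        term = np.where(p > 0, -p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return term.sum(axis=-1)


def discriminating_score_counts(
    case_left: np.ndarray,
    ctrl_left: np.ndarray,
    n_case: float,
    n_ctrl: float,
) -> np.ndarray:
    """Vectorized discriminating score for many candidate splits at once.

    ``case_left``/``ctrl_left`` are arrays of left-child class counts for
    each candidate; the parent composition is (``n_case``, ``n_ctrl``).
    """
    case_left = np.asarray(case_left, dtype=float)
    ctrl_left = np.asarray(ctrl_left, dtype=float)
    n = n_case + n_ctrl
    parent = _entropy_from_counts(np.array([n_case, n_ctrl], dtype=float))
    left = np.stack([case_left, ctrl_left], axis=-1)
    right = np.stack([n_case - case_left, n_ctrl - ctrl_left], axis=-1)
    wl = left.sum(axis=-1) / n
    wr = right.sum(axis=-1) / n
    score = parent - wl * _entropy_from_counts(left) - wr * _entropy_from_counts(right)
    return np.maximum(score, 0.0)


def mutual_information(table: np.ndarray) -> float:
    """Mutual information (bits) of the joint count table of two variables."""
    t = np.asarray(table, dtype=float)
    total = t.sum()
    if total <= 0:
        raise ValueError("all-zero joint table")
    p = t / total
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(p > 0, p / (px * py), 1.0)
        mi = np.where(p > 0, p * np.log2(ratio), 0.0).sum()
    return float(max(mi, 0.0))


def _marginal_entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def normalized_mi(table: np.ndarray) -> float:
    """MI normalized by the larger marginal entropy; in [0, 1]."""
    t = np.asarray(table, dtype=float)
    total = t.sum()
    if total <= 0:
        raise ValueError("all-zero joint table")
    hx = _marginal_entropy(t.sum(axis=1) / total)
    hy = _marginal_entropy(t.sum(axis=0) / total)
    if min(hx, hy) == 0.0:
        raise ValueError("normalized MI undefined for a constant margin")
    return float(min(mutual_information(t) / max(hx, hy), 1.0))


def trend_test(table: np.ndarray) -> tuple[float, float]:
    """Cochran-Armitage trend test on a 2x3 genotype table.

    Rows are (cases, controls); columns are genotype dosages scored
    (0, 1, 2).  Returns the 1-df chi-square statistic and its p-value.
    No continuity correction is applied.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 3):
        raise ValueError("trend test expects a 2x3 table")
    if (t.sum(axis=1) <= 0).any() or t.sum() <= 0:
        raise ValueError("degenerate table: empty row")
    scores = np.array([0.0, 1.0, 2.0])
    n = t.sum()
    r = t[0].sum()          # cases
    c = t.sum(axis=0)       # genotype column totals
    a = t[0]                # case counts per genotype
    num = n * (n * (scores * a).sum() - r * (scores * c).sum()) ** 2
    den = r * (n - r) * (n * (scores**2 * c).sum() - ((scores * c).sum()) ** 2)
    if den <= 0:
        # no genotype variation: no trend to test
        return 0.0, 1.0
    stat = num / den
    p = float(sps.chi2.sf(stat, df=1))
    return float(stat), p


def general_chi2_test(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square genotypic test on a 2x3 table (2 df nominal).

    Genotype columns with no observations are dropped, collapsing the
    degrees of freedom accordingly (a single remaining column yields
    statistic 0, p = 1).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 3):
        raise ValueError("general test expects a 2x3 table")
    if (t.sum(axis=1) <= 0).any():
        raise ValueError("degenerate table: empty row")
    keep = t.sum(axis=0) > 0
    t = t[:, keep]
    if t.shape[1] < 2:
        return 0.0, 1.0
    res = sps.chi2_contingency(t, correction=False)
    return float(res.statistic), float(res.pvalue)


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided Hardy-Weinberg equilibrium test.

    Enumerates every heterozygote count compatible with the observed
    allele counts and sums the probabilities of all configurations no
    more probable than the observed one (the standard exact HWE test
    used in GWAS quality control).
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("negative genotype counts")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("empty genotype counts")
    n_a = 2 * n_aa + n_Aa  # minor allele count (by convention)
    n_A = 2 * n_AA + n_Aa
    if n_a > n_A:
        n_a, n_A = n_A, n_a
    if n_a == 0:
        return 1.0

    # log-probability of each possible het count, conditional on allele counts
    het_min = n_a % 2
    hets = np.arange(het_min, n_a + 1, 2)
    from scipy.special import gammaln

    def logfact(x):
        return gammaln(np.asarray(x, dtype=float) + 1.0)

    n_hom_rare = (n_a - hets) // 2
    n_hom_common = n - hets - n_hom_rare
    logp = (
        hets * np.log(2.0)
        + logfact(n)
        - logfact(hets)
        - logfact(n_hom_rare)
        - logfact(n_hom_common)
        - (logfact(2 * n) - logfact(n_a) - logfact(2 * n - n_a))
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = n_Aa
    if obs not in set(hets.tolist()):
        raise ValueError("observed heterozygote count incompatible with allele counts")
    p_obs = probs[hets == obs][0]
    return float(min(probs[probs <= p_obs * (1 + 1e-12)].sum(), 1.0))
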