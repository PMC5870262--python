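"""SNP quality control and the single-SNP association baseline.

Two QC presets are provided:

* ``simulated`` — remove SNPs with MAF < 0.05 or an exact HWE p-value
  below 0.001 (the rules applied to simulated panels);
* ``wtccc`` — remove SNPs with missingness > 5%, with missingness > 1%
  together with MAF < 5%, or with an exact HWE / trend / genotypic test
  p-value below 5.7e-7 (the consortium SNP-exclusion rules).

The single-SNP scan tests each marker's 2x3 case/control genotype table
and ranks SNPs by ascending p-value, ties broken by dataset order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import MISSING, GenotypeDataset
from .stats_core import general_chi2_test, hwe_exact_test, trend_test

__all__ = ["QCRuleSet", "AssocResult", "compute_maf", "apply_qc", "single_snp_scan"]


@dataclass(frozen=True)
class QCRuleSet:
    """Thresholds for SNP exclusion; ``None`` disables a rule."""

    name: str = "simulated"
    maf_min: float | None = 0.05
    hwe_p_min: float | None = 0.001
    miss_max: float | None = None
    miss_max_if_rare: tuple[float, float] | None = None  # (miss thr, maf thr)
    assoc_p_min_trend: float | None = None
    assoc_p_min_general: float | None = None

    @classmethod
    def simulated(cls) -> "QCRuleSet":
        return cls(name="simulated", maf_min=0.05, hwe_p_min=0.001)

    @classmethod
    def wtccc(cls) -> "QCRuleSet":
        thr = 5.7e-7
        return cls(
            name="wtccc",
            maf_min=None,
            hwe_p_min=thr,
            miss_max=0.05,
            miss_max_if_rare=(0.01, 0.05),
            assoc_p_min_trend=thr,
            assoc_p_min_general=thr,
        )


@dataclass
class AssocResult:
    """Per-SNP association statistics, ranked (rank 1 = most significant)."""

    snp_ids: list[str]
    statistics: np.ndarray
    p_values: np.ndarray
    ranks: np.ndarray  # permutation of 1..n

    def top(self, k: int) -> list[str]:
        """snp_ids of the k best-ranked SNPs, in rank order."""
        order = np.argsort(self.ranks)
        return [self.snp_ids[i] for i in order[:k]]


def compute_maf(genotype_row: np.ndarray) -> float:
    """Minor allele frequency over non-missing genotypes of one SNP."""
    g = np.asarray(genotype_row)
    g = g[g != MISSING]
    if g.size == 0:
        raise ValueError("all genotypes missing")
    f = g.sum() / (2 * g.size)
    return float(min(f, 1.0 - f))


def genotype_table(genotype_row: np.ndarray, phenotype: np.ndarray) -> np.ndarray:
    """2x3 (case/control x genotype 0/1/2) table over non-missing calls."""
    g = np.asarray(genotype_row)
    ok = g != MISSING
    g, y = g[ok], np.asarray(phenotype, bool)[ok]
    table = np.zeros((2, 3), dtype=np.int64)
    for row, mask in ((0, y), (1, ~y)):
        table[row] = np.bincount(g[mask], minlength=3)[:3]
    return table


def apply_qc(
    ds: GenotypeDataset, rules: QCRuleSet
) -> tuple[GenotypeDataset, list[tuple[str, list[str]]]]:
    """Filter SNPs violating any enabled rule.

    Returns the filtered dataset (original order preserved) and, per
    removed SNP, its id with the list of violated-rule names.
    """
    if ds.n_snps == 0 or ds.n_individuals == 0:
        raise ValueError("empty dataset")
    keep: list[int] = []
    removed: list[tuple[str, list[str]]] = []
    y = ds.phenotype
    for i in range(ds.n_snps):
        g = ds.genotypes[i]
        nonmiss = g != MISSING
        reasons: list[str] = []
        miss_rate = 1.0 - nonmiss.mean()
        maf = compute_maf(g) if nonmiss.any() else 0.0
        if rules.maf_min is not None and maf < rules.maf_min:
            reasons.append("maf")
        if rules.miss_max is not None and miss_rate > rules.miss_max:
            reasons.append("missingness")
        if rules.miss_max_if_rare is not None:
            m_thr, maf_thr = rules.miss_max_if_rare
            if miss_rate > m_thr and maf < maf_thr:
                reasons.append("missingness_rare")
        if rules.hwe_p_min is not None and nonmiss.any():
            gv = g[nonmiss]
            counts = np.bincount(gv, minlength=3)
            if hwe_exact_test(int(counts[0]), int(counts[1]), int(counts[2])) < rules.hwe_p_min:
                reasons.append("hwe")
        if (rules.assoc_p_min_trend is not None or rules.assoc_p_min_general is not None) and nonmiss.any():
            table = genotype_table(g, y)
            if table.sum(axis=1).min() > 0:
                if rules.assoc_p_min_trend is not None:
                    if trend_test(table)[1] < rules.assoc_p_min_trend:
                        reasons.append("trend")
                if rules.assoc_p_min_general is not None:
                    if general_chi2_test(table)[1] < rules.assoc_p_min_general:
                        reasons.append("general")
        if reasons:
            removed.append((ds.snps[i].snp_id, reasons))
        else:
            keep.append(i)
    return ds.subset_snps(keep), removed


def single_snp_scan(ds: GenotypeDataset, test: str = "general") -> AssocResult:
    """Test every SNP's case/control genotype table; rank by p ascending.

    ``test`` is ``"general"`` (2-df Pearson chi-square, the default) or
    ``"trend"`` (1-df Cochran-Armitage).  Monomorphic SNPs get p = 1.
    Ties in p are broken by dataset order, so ranks are reproducible.
    """
    if test not in ("general", "trend"):
        raise ValueError(f"unknown test {test!r}")
    y = ds.phenotype
    stats = np.zeros(ds.n_snps)
    ps = np.ones(ds.n_snps)
    for i in range(ds.n_snps):
        table = genotype_table(ds.genotypes[i], y)
        if (table.sum(axis=0) > 0).sum() < 2 or table.sum(axis=1).min() == 0:
            stats[i], ps[i] = 0.0, 1.0
            continue
        if test == "trend":
            stats[i], ps[i] = trend_test(table)
        else:
            stats[i], ps[i] = general_chi2_test(table)
    order = np.argsort(ps, kind="stable")
    ranks = np.empty(ds.n_snps, dtype=np.int64)
    ranks[order] = np.arange(1, ds.n_snps + 1)
    return AssocResult(snp_ids=ds.snp_ids, statistics=stats, p_values=ps, ranks=ranks)
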