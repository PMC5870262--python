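"""Case-control genotype simulator with haplotype-block LD structure.

The generator emulates the classic resampling-based GWAS simulation
protocol at desk scale: the genome is partitioned into haplotype blocks,
each block carries a small pool of distinct haplotypes (limited local
haplotype diversity, the property block- and cluster-based methods
exploit), and an individual is formed from two gametes whose block-level
haplotype choices follow a Markov chain along the chromosome (adjacent
blocks keep the same pool index with probability ``1 - recomb``).

Disease status is assigned through genotype penetrances parameterized by
a genetic model (additive / dominant / recessive), a genotype relative
risk (GRR) and the population prevalence; multiple causal SNPs combine
multiplicatively on the relative-risk scale, preserving each SNP's
marginal GRR.  Default sizes follow the reference simulation protocol:
20,000 SNPs, 2,000 cases + 2,000 controls, 10 causal SNPs, prevalence
0.01, GRR in {1.2, 1.5, 1.8}, causal MAF drawn from one of three
intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import GenotypeDataset, SNPInfo

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "HaplotypeBlockModel",
    "penetrances",
    "simulate_population",
    "simulate_case_control",
]

_MODELS = ("additive", "dominant", "recessive")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated case-control replicate."""

    n_snps: int = 20_000
    n_cases: int = 2_000
    n_controls: int = 2_000
    n_causal: int = 10
    genetic_model: str = "additive"
    grr: float = 1.5
    causal_maf_interval: tuple[float, float] = (0.15, 0.25)
    prevalence: float = 0.01
    block_size_range: tuple[int, int] = (5, 20)
    haplotypes_per_block: int = 8
    recomb_between_blocks: float = 0.5
    spacing_bp: int = 1_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genetic_model not in _MODELS:
            raise ValueError(f"genetic_model must be one of {_MODELS}")
        if not (0 < self.prevalence < 1):
            raise ValueError("prevalence must be in (0,1)")
        if self.grr < 1:
            raise ValueError("grr must be >= 1")
        if self.n_causal > self.n_snps:
            raise ValueError("n_causal exceeds n_snps")
        lo, hi = self.causal_maf_interval
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("causal_maf_interval must lie in (0, 0.5]")
        if self.haplotypes_per_block < 1:
            raise ValueError("haplotypes_per_block must be >= 1")


@dataclass
class SimulatedDataset:
    """A simulated replicate: the dataset plus causal-SNP ground truth.

    ``penetrances`` are the per-SNP marginal penetrances (f0, f1, f2) at
    the configured prevalence; ``risk_flip[sid]`` is True when the risk
    (minor) allele is the one *not* counted by the genotype codes, i.e.
    the risk dosage is ``2 - g``.  ``baseline_risk`` is the multi-locus
    baseline so that P(affected) = baseline_risk * prod_j gamma_j(dose_j).
    """

    dataset: GenotypeDataset
    causal_snp_ids: list[str]
    penetrances: dict[str, tuple[float, float, float]]
    causal_maf: dict[str, float]
    risk_flip: dict[str, bool]
    baseline_risk: float
    population: "HaplotypeBlockModel"


def penetrances(
    model: str, grr: float, risk_allele_freq: float, prevalence: float
) -> tuple[float, float, float]:
    """Penetrances (f0, f1, f2) for 0/1/2 copies of the risk allele.

    Relative risks per model: additive (g, 2g-1), dominant (g, g),
    recessive (1, g).  f0 is solved so the population prevalence under
    Hardy-Weinberg genotype frequencies equals ``prevalence``.
    """
    if model not in _MODELS:
        raise ValueError(f"unknown model {model!r}")
    q, K = risk_allele_freq, prevalence
    if not (0 < q < 1) or not (0 < K < 1) or grr < 1:
        raise ValueError("require 0<q<1, 0<K<1, grr>=1")
    if model == "additive":
        g1, g2 = grr, 2 * grr - 1
    elif model == "dominant":
        g1, g2 = grr, grr
    else:  # recessive
        g1, g2 = 1.0, grr
    p0, p1, p2 = (1 - q) ** 2, 2 * q * (1 - q), q**2
    f0 = K / (p0 + g1 * p1 + g2 * p2)
    f = (f0, g1 * f0, g2 * f0)
    if max(f) > 1:
        raise ValueError("infeasible configuration: penetrance exceeds 1")
    return f


class HaplotypeBlockModel:
    """Generative model of LD-structured gametes.

    Attributes
    ----------
    block_bounds
        ``(n_blocks, 2)`` start/stop SNP indices of each block.
    haplotypes
        Per block, an ``(H, block_len)`` 0/1 matrix of distinct haplotypes.
    frequencies
        Per block, haplotype frequencies (Dirichlet-distributed).
    allele_freq
        Population frequency of allele "1" at each SNP (marginal over the
        block-index Markov chain).
    """

    def __init__(self, config: SimulationConfig, rng: np.random.Generator):
        self.config = config
        lo, hi = config.block_size_range
        sizes: list[int] = []
        total = 0
        while total < config.n_snps:
            s = int(rng.integers(lo, hi + 1))
            s = min(s, config.n_snps - total)
            sizes.append(s)
            total += s
        if len(sizes) > 1 and sizes[-1] < lo:
            # fold a truncated tail block into its neighbour
            tail = sizes.pop()
            sizes[-1] += tail
        bounds = np.zeros((len(sizes), 2), dtype=int)
        bounds[:, 1] = np.cumsum(sizes)
        bounds[1:, 0] = bounds[:-1, 1]
        self.block_bounds = bounds

        H = config.haplotypes_per_block
        self.haplotypes: list[np.ndarray] = []
        self.frequencies: list[np.ndarray] = []
        for L in sizes:
            if H > 2**L:
                raise ValueError(f"haplotypes_per_block={H} exceeds 2^{L} for a block of {L} SNPs")
            p_col = rng.uniform(0.1, 0.9, size=L)
            if L <= 12:
                # enumerate all patterns, draw H distinct ones by probability
                grid = ((np.arange(2**L)[:, None] >> np.arange(L)) & 1).astype(np.int8)
                logp = (grid * np.log(p_col) + (1 - grid) * np.log(1 - p_col)).sum(axis=1)
                probs = np.exp(logp - logp.max())
                probs /= probs.sum()
                pick = rng.choice(2**L, size=H, replace=False, p=probs)
                hap = grid[pick]
            else:
                seen: dict[bytes, None] = {}
                rows: list[np.ndarray] = []
                for _ in range(200 * H):
                    h = (rng.random(L) < p_col).astype(np.int8)
                    key = h.tobytes()
                    if key not in seen:
                        seen[key] = None
                        rows.append(h)
                        if len(rows) == H:
                            break
                else:  # pragma: no cover
                    raise RuntimeError("could not draw distinct haplotypes")
                hap = np.stack(rows)
            self.haplotypes.append(hap)
            self.frequencies.append(rng.dirichlet(np.ones(H)))

        # marginal distribution of the block-index chain
        r = config.recomb_between_blocks
        pi = self.frequencies[0].copy()
        self._index_marginals = [pi]
        for b in range(1, len(sizes)):
            pi = (1 - r) * pi + r * self.frequencies[b]
            self._index_marginals.append(pi)
        freqs = np.empty(config.n_snps)
        for b, (start, stop) in enumerate(self.block_bounds):
            freqs[start:stop] = self._index_marginals[b] @ self.haplotypes[b]
        self.allele_freq = freqs

    @property
    def n_blocks(self) -> int:
        return len(self.haplotypes)

    @property
    def maf(self) -> np.ndarray:
        return np.minimum(self.allele_freq, 1 - self.allele_freq)

    def sample_gamete_indices(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Markov chain of block haplotype indices; shape (n, n_blocks)."""
        r = self.config.recomb_between_blocks
        idx = np.empty((n, self.n_blocks), dtype=np.int64)
        cum0 = np.cumsum(self.frequencies[0])
        idx[:, 0] = np.searchsorted(cum0, rng.random(n), side="right")
        for b in range(1, self.n_blocks):
            redraw = rng.random(n) < r
            fresh = np.searchsorted(np.cumsum(self.frequencies[b]), rng.random(n), side="right")
            idx[:, b] = np.where(redraw, fresh, idx[:, b - 1])
        np.clip(idx, 0, self.config.haplotypes_per_block - 1, out=idx)
        return idx

    def genotypes_from_indices(
        self, idx1: np.ndarray, idx2: np.ndarray, snp_sel: np.ndarray | None = None
    ) -> np.ndarray:
        """Genotype matrix (n_snps_selected, n_individuals) from index chains."""
        n = idx1.shape[0]
        if snp_sel is None:
            out = np.empty((self.config.n_snps, n), dtype=np.int8)
            for b, (start, stop) in enumerate(self.block_bounds):
                hap = self.haplotypes[b]
                out[start:stop] = (hap[idx1[:, b]] + hap[idx2[:, b]]).T
            return out
        snp_sel = np.asarray(snp_sel)
        out = np.empty((len(snp_sel), n), dtype=np.int8)
        starts = self.block_bounds[:, 0]
        for j, s in enumerate(snp_sel):
            b = int(np.searchsorted(self.block_bounds[:, 1], s, side="right"))
            off = s - starts[b]
            col = self.haplotypes[b][:, off]
            out[j] = col[idx1[:, b]] + col[idx2[:, b]]
        return out

    def sample_genotypes(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n unconditioned individuals; shape (n_snps, n)."""
        return self.genotypes_from_indices(
            self.sample_gamete_indices(n, rng), self.sample_gamete_indices(n, rng)
        )


def simulate_population(config: SimulationConfig) -> HaplotypeBlockModel:
    """Build the haplotype-block generative sampler for ``config``."""
    rng = np.random.default_rng(config.seed)
    return HaplotypeBlockModel(config, rng)


def _choose_causal(
    model: HaplotypeBlockModel, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    lo, hi = config.causal_maf_interval
    maf = model.maf
    eligible = np.flatnonzero((maf >= lo) & (maf <= hi))
    if len(eligible) < config.n_causal:
        raise ValueError(
            f"only {len(eligible)} SNPs have population MAF in [{lo}, {hi}]; "
            f"need {config.n_causal}"
        )
    # spread causal SNPs over distinct blocks when possible
    block_of = np.searchsorted(model.block_bounds[:, 1], eligible, side="right")
    chosen: list[int] = []
    used_blocks: set[int] = set()
    perm = rng.permutation(len(eligible))
    for j in perm:
        if block_of[j] not in used_blocks:
            chosen.append(int(eligible[j]))
            used_blocks.add(int(block_of[j]))
            if len(chosen) == config.n_causal:
                break
    for j in perm:  # fall back to sharing blocks if needed
        if len(chosen) == config.n_causal:
            break
        if int(eligible[j]) not in chosen:
            chosen.append(int(eligible[j]))
    return np.array(sorted(chosen))


def simulate_case_control(config: SimulationConfig) -> SimulatedDataset:
    """Simulate one replicate with exactly the configured case/control counts.

    Causal SNPs combine multiplicatively on the relative-risk scale:
    P(affected | genotypes) = f_base * prod_j gamma_j(dose_j), with the
    baseline f_base solved so the population prevalence equals the
    configured K.  This log-additive multi-locus model preserves each
    causal SNP's *marginal* genotype relative risk at the configured GRR
    (the convention of resampling-based GWAS simulators), unlike
    independent-attack combinations which dilute per-SNP effects.  The
    risk allele is the minor allele.  Individuals are rejection-sampled
    until the configured case and control counts are reached.
    """
    rng = np.random.default_rng(config.seed)
    for attempt in range(5):
        model = HaplotypeBlockModel(config, rng)
        try:
            causal = _choose_causal(model, config, rng) if config.n_causal else np.array([], int)
            break
        except ValueError:
            if attempt == 4:
                raise
    m = len(causal)
    K = config.prevalence

    pen: dict[str, tuple[float, float, float]] = {}
    causal_maf: dict[str, float] = {}
    gamma_tables = np.ones((m, 3))
    risk_flip = np.zeros(m, dtype=bool)  # risk dosage = 2 - g when allele "1" is major
    f_base = K
    for j, s in enumerate(causal):
        p1 = model.allele_freq[s]
        q = min(p1, 1 - p1)
        risk_flip[j] = p1 > 0.5
        f = penetrances(config.genetic_model, config.grr, q, K)
        gamma_tables[j] = np.array(f) / f[0]
        f_base *= f[0] / K  # K / E[gamma_j] accumulated over loci
        causal_maf[f"snp{s}"] = float(q)
        pen[f"snp{s}"] = tuple(float(x) for x in f)
    # joint risks of extreme multi-locus genotypes are clipped to 1 during
    # sampling; per-SNP feasibility is enforced inside penetrances()

    cases_idx: list[np.ndarray] = []
    ctrls_idx: list[np.ndarray] = []
    n_case = n_ctrl = 0
    need_cases, need_ctrls = config.n_cases, config.n_controls
    batch = max(2000, int(2 * need_cases / max(K, 1e-3) // 10))
    guard = 0
    while n_case < need_cases or n_ctrl < need_ctrls:
        guard += 1
        if guard > 10_000:
            raise RuntimeError("rejection sampling failed to converge")
        i1 = model.sample_gamete_indices(batch, rng)
        i2 = model.sample_gamete_indices(batch, rng)
        if m:
            g_causal = model.genotypes_from_indices(i1, i2, causal)
            p_aff = np.full(batch, f_base)
            for j in range(m):
                dose = g_causal[j].astype(int)
                if risk_flip[j]:
                    dose = 2 - dose
                p_aff *= gamma_tables[j, dose]
            np.clip(p_aff, 0.0, 1.0, out=p_aff)
        else:
            p_aff = np.full(batch, K)
        affected = rng.random(batch) < p_aff
        case_rows = np.flatnonzero(affected)[: need_cases - n_case]
        ctrl_rows = np.flatnonzero(~affected)[: need_ctrls - n_ctrl]
        for rows, store in ((case_rows, cases_idx), (ctrl_rows, ctrls_idx)):
            if len(rows):
                store.append(np.stack([i1[rows], i2[rows]], axis=0))
        n_case += len(case_rows)
        n_ctrl += len(ctrl_rows)

    all_pairs = cases_idx + ctrls_idx
    i1 = np.concatenate([p[0] for p in all_pairs], axis=0)
    i2 = np.concatenate([p[1] for p in all_pairs], axis=0)
    genotypes = model.genotypes_from_indices(i1, i2)
    phenotype = np.zeros(need_cases + need_ctrls, dtype=bool)
    phenotype[:need_cases] = True

    snps = [
        SNPInfo(snp_id=f"snp{i}", chromosome="1", position_bp=(i + 1) * config.spacing_bp)
        for i in range(config.n_snps)
    ]
    ds = GenotypeDataset(
        snps=snps,
        genotypes=genotypes,
        phenotype=phenotype,
        individual_ids=[f"ind{i}" for i in range(need_cases + need_ctrls)],
    )
    return SimulatedDataset(
        dataset=ds,
        causal_snp_ids=[f"snp{s}" for s in causal],
        penetrances=pen,
        causal_maf=causal_maf,
        risk_flip={f"snp{s}": bool(risk_flip[j]) for j, s in enumerate(causal)},
        baseline_risk=float(f_base),
        population=model,
    )
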