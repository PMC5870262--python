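"""Desk-scale reference experiments comparing the three GWAS strategies.

These runners wire the full pipeline — simulate, QC, LD-map learning,
forest fitting, ranking, evaluation — at a problem size a single CPU
handles in minutes: 2,000 SNPs, 500 cases + 500 controls, 10 causal
SNPs, forests of T = 50 meta-trees with K = 100 candidate clusters per
meta-node, and an R grid of {0.3, 0.5, 0.7}.  The full-scale reference
setting (20,000 SNPs, 2,000+2,000, T = 1000, R grid 0.05-0.90 step
0.05) uses the same code through the ordinary API.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluate import CVResult, RecoveryReport, cross_validate, topk_recovery
from .fltm import FLTMParams, layer1_map, select_R
from .forest import ForestParams, fit_forest, make_block_map, variable_importance
from .qc_assoc import QCRuleSet, apply_qc, single_snp_scan
from .simulate import SimulationConfig, simulate_case_control
from .stats_core import trend_test

__all__ = [
    "DESK_R_GRID",
    "desk_condition",
    "ReplicateRankings",
    "run_replicate",
    "run_recovery_experiment",
    "run_null_cv",
    "trend_type_i_error",
    "recovered_additive_grr",
]

#: Desk-scale DBSCAN radius grid (see docs/methods.md for the rationale).
DESK_R_GRID: tuple[float, ...] = (0.3, 0.5, 0.7)

DEFAULT_KS: tuple[int, ...] = (25, 50, 100, 200, 1000)


def desk_condition(seed: int, grr: float = 1.8,
                   maf_interval: tuple[float, float] = (0.25, 0.35),
                   genetic_model: str = "additive") -> SimulationConfig:
    """One desk-scale replicate condition (2,000 SNPs, 500+500, 10 causal)."""
    return SimulationConfig(
        n_snps=2000,
        n_cases=500,
        n_controls=500,
        n_causal=10,
        genetic_model=genetic_model,
        grr=grr,
        causal_maf_interval=maf_interval,
        prevalence=0.01,
        seed=seed,
    )


@dataclass
class ReplicateRankings:
    """Per-method SNP rankings (best first) for one replicate."""

    single_snp: list[str]
    ttrees: list[str]
    hybrid: list[str]
    causal_ids: list[str]
    n_snps_after_qc: int
    selected_R: float


def run_replicate(config: SimulationConfig, seed: int, n_jobs: int = 1) -> ReplicateRankings:
    """Simulate one replicate and rank its SNPs with all three methods.

    QC uses the simulated-data rules (MAF >= 0.05, HWE p >= 1e-3).  The
    T-Trees forest uses contiguous 20-SNP blocks; the hybrid forest uses
    the layer-1 cluster map of the FLTM model with R selected over the
    desk grid.  Both forests share the desk parameters (T = 50, K = 100,
    S_n = half the sample — the same S_n/n ratio as the reference
    full-scale setting).
    """
    sim = simulate_case_control(config)
    ds, _removed = apply_qc(sim.dataset, QCRuleSet.simulated())

    scan = single_snp_scan(ds, test="general")
    single_ranking = scan.top(ds.n_snps)

    params = ForestParams.desk(ds.n_individuals)

    block_map = make_block_map(ds, params.B)
    tt_forest = fit_forest(ds, block_map, params, seed=seed, n_jobs=n_jobs)
    tt_ranking = variable_importance(tt_forest, snp_ids=ds.snp_ids).ranking()

    best_r, model, _crit = select_R(
        ds, FLTMParams(), r_grid=DESK_R_GRID, seed=seed
    )
    ld_map = layer1_map(model)
    hy_forest = fit_forest(ds, ld_map, params, seed=seed, n_jobs=n_jobs)
    hy_ranking = variable_importance(hy_forest, snp_ids=ds.snp_ids).ranking()

    return ReplicateRankings(
        single_snp=single_ranking,
        ttrees=tt_ranking,
        hybrid=hy_ranking,
        causal_ids=list(sim.causal_snp_ids),
        n_snps_after_qc=ds.n_snps,
        selected_R=best_r,
    )


def run_recovery_experiment(
    seed: int,
    n_replicates: int = 5,
    ks: tuple[int, ...] = DEFAULT_KS,
    config_factory=desk_condition,
    n_jobs: int = 1,
) -> dict[str, RecoveryReport]:
    """Top-k causal recovery aggregated over replicates, per method."""
    reps = [
        run_replicate(config_factory(seed + 1000 * r), seed + r, n_jobs=n_jobs)
        for r in range(n_replicates)
    ]
    causal = [r.causal_ids for r in reps]
    return {
        "single_snp": topk_recovery([r.single_snp for r in reps], causal, ks),
        "ttrees": topk_recovery([r.ttrees for r in reps], causal, ks),
        "hybrid": topk_recovery([r.hybrid for r in reps], causal, ks),
    }


def run_null_cv(seed: int, n_folds: int = 10, n_jobs: int = 1) -> CVResult:
    """10-fold cross-validated AUC of the hybrid forest on GRR = 1 data.

    The LD map is learned once on the full dataset and shared by all
    folds, matching the evaluation protocol of the method comparison.
    """
    config = desk_condition(seed, grr=1.0)
    sim = simulate_case_control(config)
    ds, _ = apply_qc(sim.dataset, QCRuleSet.simulated())
    _r, model, _c = select_R(ds, FLTMParams(), r_grid=DESK_R_GRID, seed=seed)
    cmap = layer1_map(model)
    params = ForestParams.desk(ds.n_individuals)
    return cross_validate(ds, cmap, params, n_folds=n_folds, seed=seed, n_jobs=n_jobs)


def trend_type_i_error(
    seed: int,
    n_tables: int = 10_000,
    n_cases: int = 500,
    n_controls: int = 500,
    alpha: float = 0.05,
) -> float:
    """Empirical rejection rate of the trend test on null 2x3 tables.

    Each table draws both rows from the same Hardy-Weinberg genotype
    distribution with MAF ~ U(0.1, 0.5).
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    used = 0
    mafs = rng.uniform(0.1, 0.5, size=n_tables)
    for maf in mafs:
        p = np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2])
        table = np.stack([
            rng.multinomial(n_cases, p),
            rng.multinomial(n_controls, p),
        ])
        if (table.sum(axis=0) > 0).sum() < 2:
            continue
        used += 1
        rejections += trend_test(table)[1] < alpha
    return rejections / used


def recovered_additive_grr(
    seed: int,
    grr: float = 1.8,
    n_individuals: int = 20_000,
    maf_interval: tuple[float, float] = (0.25, 0.35),
) -> float:
    """Per-allele odds ratio recovered by logistic regression of disease
    status on the causal SNP's risk-allele dosage, in an unconditioned
    population sample (single causal SNP, additive model)."""
    import statsmodels.api as sm

    config = SimulationConfig(
        n_snps=500, n_cases=10, n_controls=10, n_causal=1,
        genetic_model="additive", grr=grr, causal_maf_interval=maf_interval,
        prevalence=0.01, seed=seed,
    )
    sim = simulate_case_control(config)
    model = sim.population
    rng = np.random.default_rng(seed)
    sid = sim.causal_snp_ids[0]
    snp_idx = np.array([int(sid[3:])])
    i1 = model.sample_gamete_indices(n_individuals, rng)
    i2 = model.sample_gamete_indices(n_individuals, rng)
    g = model.genotypes_from_indices(i1, i2, snp_idx)[0].astype(float)
    dose = 2 - g if sim.risk_flip[sid] else g
    f = np.array(sim.penetrances[sid])
    p_aff = sim.baseline_risk * (f[dose.astype(int)] / f[0])
    status = rng.random(n_individuals) < np.clip(p_aff, 0, 1)
    fit = sm.Logit(status.astype(float), sm.add_constant(dose)).fit(disp=0)
    return float(np.exp(fit.params[1]))
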