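import numpy as np
import pytest

from ldtrees.data_io import GenotypeDataset, SNPInfo
from ldtrees.simulate import SimulationConfig, simulate_case_control


def make_dataset(genotypes, phenotype, spacing=1000, chrom="1"):
    """Small helper: dataset from a raw matrix + boolean phenotype."""
    g = np.asarray(genotypes, dtype=np.int8)
    snps = [
        SNPInfo(snp_id=f"snp{i}", chromosome=chrom, position_bp=(i + 1) * spacing)
        for i in range(g.shape[0])
    ]
    return GenotypeDataset(
        snps=snps,
        genotypes=g,
        phenotype=np.asarray(phenotype, dtype=bool),
        individual_ids=[f"ind{j}" for j in range(g.shape[1])],
    )


@pytest.fixture(scope="session")
def strong_signal_sim():
    """One small replicate with a clearly detectable causal signal."""
    cfg = SimulationConfig(
        n_snps=400,
        n_cases=400,
        n_controls=400,
        n_causal=4,
        genetic_model="additive",
        grr=1.8,
        causal_maf_interval=(0.25, 0.35),
        seed=11,
    )
    return simulate_case_control(cfg)


@pytest.fixture(scope="session")
def ld_block_dataset():
    """Five near-identical SNPs (one LD block) plus three independent SNPs."""
    rng = np.random.default_rng(5)
    n = 400
    base = rng.integers(0, 3, size=n)
    block = []
    for _ in range(5):
        col = base.copy()
        flip = rng.random(n) < 0.03
        col[flip] = rng.integers(0, 3, size=flip.sum())
        block.append(col)
    indep = [rng.integers(0, 3, size=n) for _ in range(3)]
    genotypes = np.array(block + indep, dtype=np.int8)
    phenotype = rng.random(n) < 0.5
    return make_dataset(genotypes, phenotype)
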