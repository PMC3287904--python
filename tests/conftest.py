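import numpy as np
import pytest

from hcgene.data_io import GeneBlock, GenotypeMatrix
from hcgene.simulate import SimConfig, plan_causals, simulate_genotypes, simulate_traits


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_block(rng):
    """A clean 3-SNP gene block with moderately common variants."""
    X = rng.integers(0, 3, size=(60, 3)).astype(np.int16)
    from hcgene.data_io import compute_maf

    return GeneBlock(gene_id="G1", X=X, snp_ids=["s1", "s2", "s3"], maf=compute_maf(X))


@pytest.fixture(scope="session")
def tiny_panel():
    """A small simulated panel shared across tests (session-scoped for speed)."""
    cfg = SimConfig(n_individuals=200, n_genes=30, max_snps_per_gene=8,
                    n_replicates=6, n_causal_genes=3, seed=42)
    g, gene_map = simulate_genotypes(cfg)
    truth = plan_causals(g, cfg)
    reps = simulate_traits(g, truth, cfg)
    return cfg, g, gene_map, truth, reps
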