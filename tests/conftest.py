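import numpy as np
import pytest

from funprs import SimConfig, gen_gene_universe, gen_genotypes, gen_gwas_summary


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A compact but fully featured synthetic study."""
    return SimConfig(
        seed=11,
        n_snps=2000,
        n_genes=150,
        n_sets=25,
        n_planted_sets=3,
        genes_per_set=12,
        n_samples=120,
        frac_functional=0.4,
        n_proxy_pairs=10,
    )


@pytest.fixture
def small_universe(small_config):
    return gen_gene_universe(small_config)


@pytest.fixture
def small_stats(small_config, small_universe):
    return gen_gwas_summary(small_config, small_universe)


@pytest.fixture
def small_genotypes(small_config, small_universe):
    matrix, labels = gen_genotypes(small_config, small_universe)
    return matrix
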