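import numpy as np
import pytest

from eqtel.config import SimulationConfig
from eqtel.synthetic_data import simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Compact benchmark: 4 genes x 40 SNPs, informative epigenetic shifts."""
    cfg = SimulationConfig(
        n_samples=150,
        n_genes=4,
        snps_per_gene=40,
        block_size_mean=5.0,
        regulator_fraction=0.1,
        causal_count_lambda=1.5,
        enhancer_shift_sd=3.0,
    )
    g, e, f, truth = simulate_dataset(cfg, seed=11)
    return cfg, g, e, f, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
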