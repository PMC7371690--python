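import numpy as np
import pytest

from mitocompare.reference import load_gaur_gene_table
from mitocompare.synthetic_data import SimulationConfig, generate_genome


@pytest.fixture(scope="session")
def gaur_table():
    return load_gaur_gene_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(20230901)


@pytest.fixture(scope="session")
def synthetic_bovid():
    """A seeded synthetic genome on the bovid gene layout."""
    cfg = SimulationConfig(seed=42)
    genome, gt = generate_genome(cfg)
    return cfg, genome, gt
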