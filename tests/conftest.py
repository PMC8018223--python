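import numpy as np
import pytest

from oystermeth import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(
        n_scaffolds=1,
        scaffold_length=30_000,
        n_genes=6,
        gene_length_range=(1_000, 2_000),
        n_planted_dmcs=10,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
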