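import numpy as np
import pytest

from phipsinet import synthetic as syn


@pytest.fixture(scope="session")
def markov_chains():
    """A moderate batch of synthetic chains shared across tests."""
    return syn.generate_chains(
        syn.GeneratorSpec(n_chains=40, length_range=(40, 80), seed=7)
    )


@pytest.fixture(scope="session")
def toy_dataset_small():
    """A small deterministic lookup dataset (angles = f(centre residue))."""
    return syn.deterministic_toy_dataset(2000, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
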