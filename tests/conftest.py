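import pytest

from batchreg.simulate import SimConfig, simulate_dataset


SMALL_CONFIG = dict(
    n_scaffolds=2,
    scaffold_len=500_000,
    n_coding=60,
    n_lnc=90,
    n_planted_pairs=15,
)


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced synthetic dataset (with epigenome) shared across tests."""
    return simulate_dataset(SimConfig(seed=41, **SMALL_CONFIG))


@pytest.fixture(scope="session")
def default_dataset():
    """One full default-size dataset, generated once per session."""
    return simulate_dataset(SimConfig(seed=7))
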