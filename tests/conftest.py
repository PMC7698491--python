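import numpy as np
import pytest

from phagetu import make_dataset, run_landscape
from phagetu.synthetic_data import SimParams, noiseless


@pytest.fixture(scope="session")
def default_params():
    return SimParams()


@pytest.fixture(scope="session")
def noisy_dataset():
    """The reference synthetic experiment: 50 kb, 12 TUs, 3 timepoints,
    NB coverage noise, fixed seed."""
    return make_dataset(12, SimParams(), seed=11)


@pytest.fixture(scope="session")
def noisy_landscape(noisy_dataset):
    arch, genome, tracks, counts, lengths = noisy_dataset
    return arch, run_landscape(genome, arch.orfs, tracks)


@pytest.fixture(scope="session")
def noiseless_dataset():
    return make_dataset(12, noiseless(SimParams()), seed=11)


@pytest.fixture(scope="session")
def noiseless_landscape(noiseless_dataset):
    arch, genome, tracks, counts, lengths = noiseless_dataset
    return arch, run_landscape(genome, arch.orfs, tracks)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
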