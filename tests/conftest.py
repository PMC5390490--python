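import numpy as np
import pytest

from photolim import Species, default_study_config, for_species, generate_experiment


@pytest.fixture(scope="session")
def constants_rice():
    return for_species(Species.RICE)


@pytest.fixture(scope="session")
def constants_maize():
    return for_species(Species.MAIZE)


@pytest.fixture(scope="session")
def default_experiment():
    """One noisy study-like experiment, shared across read-only tests."""
    return generate_experiment(default_study_config(), seed=7)


@pytest.fixture(scope="session")
def noiseless_experiment():
    return generate_experiment(
        default_study_config(noise=False), seed=3
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
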