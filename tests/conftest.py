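import numpy as np
import pytest

from conthread import gen_features, gen_structure, native_contact_map


@pytest.fixture(scope="session")
def structure80():
    """A reproducible compact 80-residue trace shared across tests."""
    return gen_structure(80, seed=11)


@pytest.fixture(scope="session")
def features80(structure80):
    return gen_features(structure80, seed=12)


@pytest.fixture(scope="session")
def native80(structure80):
    return native_contact_map(structure80)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
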