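import numpy as np
import pytest

from dlocal.simulate import SimScenario, simulate_study
from dlocal.structure import build_model, load_exemplar


@pytest.fixture(scope="session")
def small_bundle():
    """A 300-gene, 16-cell synthetic study shared across tests."""
    return simulate_study(SimScenario(n_genes=300), seed=7)


@pytest.fixture(scope="session")
def b1():
    return load_exemplar("b1")


@pytest.fixture(scope="session")
def b2():
    return load_exemplar("b2")


@pytest.fixture(scope="session")
def b1_model(b1):
    return build_model(b1)


@pytest.fixture(scope="session")
def b2_model(b2):
    return build_model(b2)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
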