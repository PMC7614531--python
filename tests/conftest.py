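import numpy as np
import pytest

from neurocascade import inputs as inp
from neurocascade.kernels import KernelBank
from neurocascade.pipeline import make_fixtures


@pytest.fixture(scope="session")
def basis():
    return inp.build_basis()


@pytest.fixture(scope="session")
def template(basis):
    return inp.build_template(basis)


@pytest.fixture(scope="session")
def lap():
    """One 10 s lap of the default track at 1 ms resolution."""
    return inp.make_trajectory(10_000.0)


@pytest.fixture(scope="session")
def bank():
    return KernelBank()


@pytest.fixture(scope="session")
def fixture_dataset():
    """Tiny deterministic dataset (10 exc / 4 inh synapses, 2 s trials)."""
    return make_fixtures(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
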