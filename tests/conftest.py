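import numpy as np
import pytest

from neoqpt.synthetic import DoubleWellSpec, make_double_well_triple, make_random_neo


@pytest.fixture(scope="session")
def double_well_spec():
    return DoubleWellSpec()


@pytest.fixture(scope="session")
def double_well_triple(double_well_spec):
    return make_double_well_triple(double_well_spec)


@pytest.fixture(scope="session")
def random_ham():
    return make_random_neo(2, 2, 2, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_statevector(n_qubits: int, rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=1 << n_qubits) + 1j * rng.normal(size=1 << n_qubits)
    return v / np.linalg.norm(v)
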