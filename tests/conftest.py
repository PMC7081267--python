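import numpy as np
import pytest

from pocketseg import ToyComplexSpec, make_toy_complex


@pytest.fixture(scope="session")
def toy_complex():
    """One deterministic pseudo-protein with a single planted cavity."""
    return make_toy_complex(ToyComplexSpec(seed=7))


@pytest.fixture(scope="session")
def toy_protein(toy_complex):
    return toy_complex[0]


@pytest.fixture(scope="session")
def toy_pockets(toy_complex):
    return toy_complex[1]
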