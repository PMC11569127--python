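import numpy as np
import pytest

from loopstate.synth import ToyReceptorSpec, build_ideal_helix, build_toy_receptor


@pytest.fixture(scope="session")
def toy():
    """Default toy receptor: (frame, landmark map)."""
    return build_toy_receptor(ToyReceptorSpec())


@pytest.fixture(scope="session")
def toy_frame(toy):
    return toy[0]


@pytest.fixture(scope="session")
def toy_map(toy):
    return toy[1]


@pytest.fixture
def helix9():
    """Nine-residue ideal alpha-helix along +x."""
    return build_ideal_helix(9, start_res=110)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
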