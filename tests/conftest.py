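import numpy as np
import pytest

from longaxon.morphology import Morphology, Section
from longaxon.synthetic import SlabAtlasSpec, make_slab_atlas, make_toy_axon


@pytest.fixture(scope="session")
def slab_atlas():
    return make_slab_atlas(SlabAtlasSpec())


@pytest.fixture()
def toy_axon():
    return make_toy_axon(rng=np.random.default_rng(42))


@pytest.fixture()
def y_morphology():
    """Y-shaped axon: stem of 50 um, children of 30 and 20 um."""
    stem = Section(np.array([[0.0, 0.0, 0.0], [0.0, 50.0, 0.0]]), np.ones(2), None)
    left = Section(
        np.array([[0.0, 50.0, 0.0], [-15.0, 50.0 + np.sqrt(30.0**2 - 15.0**2), 0.0]]),
        np.ones(2),
        0,
    )
    right = Section(
        np.array([[0.0, 50.0, 0.0], [12.0, 50.0 + 16.0, 0.0]]), np.ones(2), 0
    )
    return Morphology(np.zeros(3), [stem, left, right])


def rng_stream(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
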