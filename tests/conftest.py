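import numpy as np
import pytest

from cultlink import PopulationState, SimulationParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params():
    """A small but otherwise typical parameterization for unit tests."""
    return SimulationParams(
        N=20, h=5, k=4, a=0.05, b=0.1, c=0.99, mu=0.01,
        burn_in_steps=10, post_steps=5,
    )


def state_from(variants, link_pairs=None):
    """Build a PopulationState from a variant matrix and per-individual link pairs."""
    variants = np.asarray(variants, dtype=np.int64)
    n, h = variants.shape
    links = np.zeros((n, h, h), dtype=np.bool_)
    for r, pairs in enumerate(link_pairs or [[]] * n):
        for i, j in pairs:
            links[r, i, j] = links[r, j, i] = True
    return PopulationState(variants, links)
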