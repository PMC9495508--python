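"""Shared fixtures: small synthetic benchmarks generated at test time."""

import numpy as np
import pytest

from hyperplace.simulate import (
    SimulationConfig,
    random_binary_tree,
    simulate_jc_alignment,
)


@pytest.fixture(scope="session")
def small_tree():
    """A 16-leaf random tree with exponential branch lengths."""
    return random_binary_tree(SimulationConfig(n_leaves=16, seed=11))


@pytest.fixture(scope="session")
def small_alignment(small_tree):
    """JC alignment (L=200) evolved on the 16-leaf tree."""
    return simulate_jc_alignment(small_tree, 200, seed=12)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
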