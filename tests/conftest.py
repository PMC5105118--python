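"""Shared fixtures: small synthetic worlds and toy alignment weights."""

import numpy as np
import pytest

from cranolex import synthetic
from cranolex.lexical import WeightMatrix, uniform_weights


@pytest.fixture(scope="session")
def small_params():
    return synthetic.SyntheticParams(
        n_pops=4, n_specimens_per_pop=6, n_landmarks=12, noise_sd=0.5
    )


@pytest.fixture(scope="session")
def small_world(small_params):
    return synthetic.simulate_tree(small_params, seed=42)


@pytest.fixture(scope="session")
def toy_weights():
    """3-symbol toy scheme with linear gaps, for exhaustive-oracle tests."""
    alphabet = "abc"
    w = {}
    for x in alphabet:
        for y in alphabet:
            w[(x, y)] = 2.0 if x == y else -1.0
    w[("a", "b")] = w[("b", "a")] = 0.5  # an off-diagonal 'common correspondence'
    return WeightMatrix(w, gap_open=-2.5, gap_extend=-2.5)


@pytest.fixture(scope="session")
def asjp_weights():
    return uniform_weights()


@pytest.fixture
def rng():
    return np.random.default_rng(7)
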