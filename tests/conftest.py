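"""Shared fixtures: small planted-morphotype datasets built at test time."""

import numpy as np
import pytest

from morphograph import (
    GAEConfig,
    SimulationConfig,
    knn_graph,
    preprocess,
    simulate_morphotypes,
    train,
)


@pytest.fixture(scope="session")
def small_sim():
    """120 specimens, 3 well-separated planted groups, 21 traits."""
    return simulate_morphotypes(
        SimulationConfig(n_specimens=120, n_groups=3, separation=4.0, seed=0)
    )


@pytest.fixture(scope="session")
def small_corrected(small_sim):
    return preprocess(small_sim.trait_table)


@pytest.fixture(scope="session")
def small_graph(small_corrected):
    return knn_graph(small_corrected, 4)


@pytest.fixture(scope="session")
def small_trained(small_corrected, small_graph):
    """A trained autoencoder on the small fixture (reduced epochs)."""
    emb, a_hat, trace = train(
        small_corrected, small_graph, GAEConfig(d=3, epochs=200, seed=0)
    )
    return emb, a_hat, trace


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
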