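"""Shared fixtures: small networks and short simulations reused across tests."""

import numpy as np
import pytest

from updownnet.network import NetworkConfig, build_network, simulate
from updownnet.synapses import SynapseParams


@pytest.fixture(scope="session")
def mixed_connectivity():
    """16% CH / 64% RS / 20% LTS network at the canonical size."""
    config = NetworkConfig(
        seed=101,
        exc_composition={"RS": 0.8, "CH": 0.2},
        inh_composition={"LTS": 1.0},
    )
    return build_network(config)


@pytest.fixture(scope="session")
def small_connectivity():
    """Small RS+LTS network for fast integration tests."""
    config = NetworkConfig(N=256, p=0.04, seed=7)
    return build_network(config)


@pytest.fixture(scope="session")
def weak_noise_sim(mixed_connectivity):
    """2.5-s weak-noise run (asynchronous irregular regime)."""
    return simulate(
        mixed_connectivity, SynapseParams(D=2.5e-6), 2500.0, seed=11
    )


@pytest.fixture(scope="session")
def intermittent_sim(mixed_connectivity):
    """6-s run in the intermittent regime (D = 1e-5)."""
    return simulate(mixed_connectivity, SynapseParams(D=1e-5), 6000.0, seed=13)
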