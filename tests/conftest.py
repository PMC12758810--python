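import numpy as np
import pytest

from microperf.network import Node, VascularNetwork, Vessel


def make_network(nodes, vessels, inlet, outlet, domain=None, centre=None):
    xs = [n[1] for n in nodes]
    ys = [n[2] for n in nodes]
    if domain is None:
        pad = 50.0
        domain = (min(xs) - pad, min(ys) - pad, max(xs) + pad, max(ys) + pad)
    if centre is None:
        centre = (0.5 * (domain[0] + domain[2]), 0.5 * (domain[1] + domain[3]))
    return VascularNetwork(
        nodes=[Node(*n) for n in nodes],
        vessels=[Vessel(id=i, node_a=a, node_b=b, diameter=d)
                 for i, (a, b, d) in enumerate(vessels)],
        inlet=inlet, outlet=outlet, domain=domain, centre=centre,
    )


@pytest.fixture
def single_path_network():
    """inlet -> 0 -> 1 -> outlet, one straight chain."""
    return make_network(
        nodes=[(0, 0, 0), (1, 100, 0), (2, 200, 0), (3, 300, 0)],
        vessels=[(0, 1, 40.0), (1, 2, 40.0), (2, 3, 40.0)],
        inlet=0, outlet=3,
    )


@pytest.fixture
def diamond_network():
    """Symmetric diamond: one split into two identical branches, then merge."""
    return make_network(
        nodes=[(0, 0, 0), (1, 100, 0), (2, 200, 100), (3, 200, -100),
               (4, 300, 0), (5, 400, 0)],
        vessels=[(0, 1, 50.0), (1, 2, 40.0), (1, 3, 40.0),
                 (2, 4, 40.0), (3, 4, 40.0), (4, 5, 50.0)],
        inlet=0, outlet=5,
    )


@pytest.fixture
def pendant_network():
    """Through-path with a pendant chain of 3 vessels hanging off it."""
    return make_network(
        nodes=[(0, 0, 0), (1, 100, 0), (2, 200, 0), (3, 300, 0),
               (10, 100, 100), (11, 100, 200), (12, 100, 300)],
        vessels=[(0, 1, 40.0), (1, 2, 40.0), (2, 3, 40.0),
                 (1, 10, 30.0), (10, 11, 30.0), (11, 12, 30.0)],
        inlet=0, outlet=3,
    )


@pytest.fixture(scope="session")
def small_generated_network():
    from microperf.generate import NetworkGenConfig, generate_network

    return generate_network(
        NetworkGenConfig(domain_size=3000.0, seed=11, lattice_pitch=300.0))


class UniformFlow:
    """Stub flow state: all vessels perfused at a uniform haematocrit."""

    def __init__(self, n_vessels, h=0.3):
        self.haematocrit = np.full(n_vessels, h)
        self.unperfused = np.zeros(n_vessels, dtype=bool)
        self.flow = np.ones(n_vessels)


@pytest.fixture
def uniform_flow():
    return UniformFlow
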