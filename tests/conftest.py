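import numpy as np
import pytest

import perfusim as pf
from perfusim.grid import TissueDomain, VoxelGrid
from perfusim.network import ROOT_TERMINAL, TERMINAL, VesselNetwork


@pytest.fixture(scope="session")
def frog_bundle():
    """Quasi-2D paired-tree scenario at the quasi-2D parameter preset."""
    return pf.make_paired_scenario(seed=1, base_shape=(96, 80, 1))


@pytest.fixture(scope="session")
def frog_solution(frog_bundle):
    return pf.simulate_flow(frog_bundle, method="direct")


@pytest.fixture(scope="session")
def frog_tracer(frog_bundle, frog_solution):
    run, maps = pf.simulate_tracer(frog_bundle, frog_solution)
    return run, maps


def box_domain(shape=(10, 10, 6), h=1.0, **kw):
    """Fully masked box domain for small hand-built networks."""
    grid = VoxelGrid(shape, (h, h, h))
    mask = np.ones(shape, bool)
    return TissueDomain(grid, mask, **kw)


def two_terminal_networks(domain, r_mm=0.5):
    """One arterial and one venous network, each a root->terminal edge
    entering from opposite faces of the domain."""
    grid = domain.grid
    fov = np.asarray(grid.fov)
    mid = 0.5 * fov
    net_a = VesselNetwork("a")
    a0 = net_a.add_node([0.0, mid[1], mid[2]], ROOT_TERMINAL)
    a1 = net_a.add_node([mid[0] * 0.8, mid[1], mid[2]], TERMINAL)
    net_a.add_edge(a0, a1, float(mid[0] * 0.8), r_mm)
    net_v = VesselNetwork("v")
    v0 = net_v.add_node([fov[0] - grid.voxel_size[0], mid[1], mid[2]], ROOT_TERMINAL)
    v1 = net_v.add_node([fov[0] * 0.6, mid[1], mid[2]], TERMINAL)
    net_v.add_edge(v0, v1, float(fov[0] * 0.4), r_mm)
    for net in (net_a, net_v):
        net.compute_node_volumes(None, domain)
    return net_a, net_v
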