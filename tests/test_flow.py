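"""Coupled pressure solver: TPFA, assembly structure, conservation, oracles."""

import numpy as np
import pytest

import perfusim as pf
from perfusim.coupling import build_kernels
from perfusim.flow import (assemble_coupled_system, solve_pressure,
                           tpfa_transmissibilities)
from perfusim.grid import MM, PERFUSION_UNIT, TissueDomain, VoxelGrid
from perfusim.network import ROOT_TERMINAL, TERMINAL, VesselNetwork

from conftest import box_domain, two_terminal_networks


class TestTPFA:
    def test_uniform_grid_closed_form(self):
        # homogeneous k on isotropic h-voxels: every interior face carries
        # t = (k/mu) * h
        dom = box_domain((6, 6, 6), h=2.0, k_a=4e-12, mu=2e-3)
        fi, fj, t = tpfa_transmissibilities(dom, "a")
        expected = (4e-12 / 2e-3) * (2.0 * MM)
        np.testing.assert_allclose(t, expected, rtol=1e-12)
        # 3 face orientations x 5 faces x 36 rows
        assert len(t) == 3 * 5 * 36

    def test_harmonic_mean_between_heterogeneous_cells(self):
        dom = box_domain((2, 1, 1), h=1.0)
        dom.k_a = np.array([[[1.0e-12]], [[3.0e-12]]])
        fi, fj, t = tpfa_transmissibilities(dom, "a")
        # harmonic mean of 1k and 3k half-cells: 2/(1/1+1/3) = 1.5k
        expected = (1.5e-12 / dom.mu) * (1.0 * MM)
        assert t[0] == pytest.approx(expected)

    def test_masked_faces_carry_no_flow(self):
        grid = VoxelGrid((4, 4, 4), (1, 1, 1))
        mask = np.ones((4, 4, 4), bool)
        mask[2:] = False  # only a 2x4x4 slab
        dom = TissueDomain(grid, mask)
        fi, fj, t = tpfa_transmissibilities(dom, "a")
        # faces: x: 1*16, y: 2*3*4, z: 2*4*3
        assert len(t) == 16 + 24 + 24


def _coupled_box(shape=(10, 10, 6), **domkw):
    dom = box_domain(shape, **domkw)
    net_a, net_v = two_terminal_networks(dom)
    ka = build_kernels(net_a, dom, 4.0)
    kv = build_kernels(net_v, dom, 4.0)
    sysm = assemble_coupled_system(dom, net_a, net_v, ka, kv,
                                   gamma_a=1e-14, gamma_v=1e-14,
                                   p_a0=10.6e3, p_v0=1.6e3)
    return dom, net_a, net_v, sysm


class TestAssembly:
    def test_cross_compartment_blocks_are_zero(self):
        # arterial Darcy rows may touch venous voxel pressures only through
        # the perfusion term; they never touch venous *node* unknowns, and
        # vice versa (the zero off-blocks of the coupled block matrix)
        dom, net_a, net_v, sysm = _coupled_box()
        n = sysm.n_masked
        A = sysm.A.tocsr()
        na = len(sysm.node_order["a"])
        nv = len(sysm.node_order["v"])
        blk = A[:n, sysm.node_offset["v"]:sysm.node_offset["v"] + nv]
        assert blk.nnz == 0
        blk = A[n:2 * n, sysm.node_offset["a"]:sysm.node_offset["a"] + na]
        assert blk.nnz == 0
        # arterial node rows never touch venous voxels
        blk = A[sysm.node_offset["a"]:sysm.node_offset["a"] + na, n:2 * n]
        assert blk.nnz == 0

    def test_alpha_zero_decouples_compartments(self):
        dom, net_a, net_v, sysm = _coupled_box(alpha=0.0)
        sol = solve_pressure(sysm)
        P = sol.perfusion_field()
        np.testing.assert_allclose(np.nan_to_num(P), 0.0, atol=1e-30)
        # each compartment equilibrates to its root pressure (no flow at all)
        m = dom.mask
        np.testing.assert_allclose(sol.p_a[m], 10.6e3, rtol=1e-8)
        np.testing.assert_allclose(sol.p_v[m], 1.6e3, rtol=1e-8)

    def test_floating_compartment_rejected(self):
        dom = box_domain((10, 10, 6), alpha=0.0)
        net_a, net_v = two_terminal_networks(dom)
        # strip the venous root: an alpha=0 venous compartment floats
        net_v.nodes[0].node_class = TERMINAL
        # (degree-1 so classification-wise legal, but unpressurised)
        ka = build_kernels(net_a, dom, 4.0)
        kv = build_kernels(net_v, dom, 4.0)
        with pytest.raises(ValueError, match="floating"):
            assemble_coupled_system(dom, net_a, net_v, ka, kv, 1e-14, 1e-14,
                                    10.6e3, 1.6e3)

    def test_mirror_symmetry_antisymmetric_pressures(self):
        # identical geometry for both compartments with swapped boundary
        # pressures: p_a + p_v must equal p_a0 + p_v0 everywhere
        dom = box_domain((10, 10, 6), k_a=2e-12, k_v=2e-12,
                         phi_a=0.08, phi_v=0.08)
        net_a, _ = two_terminal_networks(dom)
        net_v = VesselNetwork("v")
        for nid in sorted(net_a.nodes):
            n = net_a.nodes[nid]
            net_v.add_node(n.position, n.node_class, node_id=nid)
            net_v.nodes[nid].volume_m3 = n.volume_m3
        for e in net_a.edges:
            net_v.add_edge(e.j, e.k, e.length_mm, e.radius_mm)
        ka = build_kernels(net_a, dom, 4.0)
        kv = build_kernels(net_v, dom, 4.0)
        sysm = assemble_coupled_system(dom, net_a, net_v, ka, kv,
                                       1e-14, 1e-14, 10.6e3, 1.6e3)
        sol = solve_pressure(sysm)
        m = dom.mask
        np.testing.assert_allclose(sol.p_a[m] + sol.p_v[m], 10.6e3 + 1.6e3,
                                   rtol=1e-9)


class TestSolverOracles:
    def test_two_node_hagen_poiseuille(self):
        # with the closure relation substituted, the solved terminal flow of
        # a single root->terminal edge must satisfy q = kappa (p_root - p_t)
        dom, net_a, net_v, sysm = _coupled_box()
        sol = solve_pressure(sysm)
        e = net_a.edges[0]
        kappa = e.conductance(dom.mu)
        q = sol.terminal_flows["a"][1]
        dp = sol.node_pressures["a"][0] - sol.node_pressures["a"][1]
        assert q == pytest.approx(kappa * dp, rel=1e-10)

    def test_series_edges_equal_single_edge_of_summed_length(self):
        # kappa ~ 1/L so two collinear edges L1, L2 in series are exactly one
        # edge of length L1+L2: terminal flows must agree
        def run(split):
            dom = box_domain((12, 10, 6))
            net_a = VesselNetwork("a")
            r = net_a.add_node([0.0, 5.0, 3.0], ROOT_TERMINAL)
            if split:
                mid = net_a.add_node([3.0, 5.0, 3.0])
                t = net_a.add_node([6.0, 5.0, 3.0], TERMINAL)
                net_a.add_edge(r, mid, 3.0, 0.5)
                net_a.add_edge(mid, t, 3.0, 0.5)
            else:
                t = net_a.add_node([6.0, 5.0, 3.0], TERMINAL)
                net_a.add_edge(r, t, 6.0, 0.5)
            net_v = VesselNetwork("v")
            rv = net_v.add_node([12.0, 5.0, 3.0], ROOT_TERMINAL)
            tv = net_v.add_node([9.0, 5.0, 3.0], TERMINAL)
            net_v.add_edge(rv, tv, 3.0, 0.5)
            for net in (net_a, net_v):
                net.compute_node_volumes(None, dom)
            sol = pf.solve_coupled_flow(dom, net_a, net_v, epsilon_mm=4.0,
                                        gamma_a=1e-14, gamma_v=1e-14,
                                        p_a0=10.6e3, p_v0=1.6e3)
            return sol.terminal_flows["a"][max(net_a.terminals)]

        assert run(True) == pytest.approx(run(False), rel=1e-9)

    def test_parallel_edges_add_conductances(self):
        # a parallel pair of radius-R tubes between two junctions carries
        # the same flow as one tube whose conductance is the sum, i.e. a
        # tube of radius R * 2^(1/4) (terminals stay degree 1 by putting
        # the pair in the middle of a root-junction-junction-terminal chain)
        def run(parallel):
            dom = box_domain((12, 10, 6))
            net_a = VesselNetwork("a")
            r = net_a.add_node([0.0, 5.0, 3.0], ROOT_TERMINAL)
            n1 = net_a.add_node([2.0, 5.0, 3.0])
            n2 = net_a.add_node([5.0, 5.0, 3.0])
            t = net_a.add_node([7.0, 5.0, 3.0], TERMINAL)
            net_a.add_edge(r, n1, 2.0, 0.5)
            if parallel:
                net_a.add_edge(n1, n2, 3.0, 0.5)
                net_a.add_edge(n1, n2, 3.0, 0.5)
            else:
                net_a.add_edge(n1, n2, 3.0, 0.5 * 2 ** 0.25)
            net_a.add_edge(n2, t, 2.0, 0.5)
            net_v = VesselNetwork("v")
            rv = net_v.add_node([12.0, 5.0, 3.0], ROOT_TERMINAL)
            tv = net_v.add_node([9.0, 5.0, 3.0], TERMINAL)
            net_v.add_edge(rv, tv, 3.0, 0.5)
            for net in (net_a, net_v):
                net.compute_node_volumes(None, dom)
            sol = pf.solve_coupled_flow(dom, net_a, net_v, epsilon_mm=4.0,
                                        gamma_a=1e-14, gamma_v=1e-14,
                                        p_a0=10.6e3, p_v0=1.6e3)
            return sol.terminal_flows["a"][t]

        assert run(True) == pytest.approx(run(False), rel=1e-9)

    def test_dense_direct_matches_iterative_solver(self):
        # on a small grid the equilibrated system solved densely must agree
        # with the preconditioned GMRES solution to 1e-8 relative
        from perfusim.flow import equilibrate

        dom, net_a, net_v, sysm = _coupled_box(shape=(12, 12, 8))
        A2, b, Dr, Dc = equilibrate(sysm.A, sysm.d)
        x_dense = Dc @ np.linalg.solve(A2.toarray(), b)
        sol = solve_pressure(sysm, method="gmres", tol=1e-10)
        m = dom.mask
        x_it = np.concatenate([sol.p_a[m], sol.p_v[m]])
        rel = (np.linalg.norm(x_it - x_dense[:2 * sysm.n_masked])
               / np.linalg.norm(x_dense[:2 * sysm.n_masked]))
        assert rel < 1e-8


class TestConservation:
    def test_global_mass_balance(self, frog_solution):
        mb = frog_solution.mass_balance()
        assert mb["rel_err_inflow_outflow"] < 1e-6
        assert mb["rel_err_inflow_perfusion"] < 1e-6

    def test_interior_node_kirchhoff_balance(self, frog_solution):
        for comp, net in (("a", frog_solution.system.arterial),
                          ("v", frog_solution.system.venous)):
            scale = max(abs(e.flow) for e in net.edges)
            for nid, node in net.nodes.items():
                if node.node_class != "interior":
                    continue
                total = 0.0
                for ei in net.incident_edges(nid):
                    e = net.edges[ei]
                    total += e.flow if e.k == nid else -e.flow
                assert abs(total) < 1e-9 * scale

    def test_terminal_flows_satisfy_closure(self, frog_bundle, frog_solution):
        # the solved flows and pressures jointly satisfy the continuity
        # closure, i.e. the explicit-flow formulation is self-consistent
        from perfusim.coupling import continuity_closure

        sysm = frog_solution.system
        dom = sysm.domain
        rels = continuity_closure(sysm.arterial, sysm.kernels_a,
                                  sysm.gamma["a"], dom.mu,
                                  dom.grid.voxel_volume_m3)
        for nid, rel in rels.items():
            q_expect = rel.evaluate(frog_solution.node_pressures["a"][nid],
                                    np.nan_to_num(frog_solution.p_a))
            assert frog_solution.terminal_flows["a"][nid] == pytest.approx(
                q_expect, rel=1e-8)

    def test_raising_arterial_pressure_does_not_decrease_perfusion(self):
        dom, net_a, net_v, _ = _coupled_box()
        means = []
        for pa0 in (8.0e3, 10.6e3, 13.0e3):
            sol = pf.solve_coupled_flow(dom, net_a, net_v, epsilon_mm=4.0,
                                        gamma_a=1e-14, gamma_v=1e-14,
                                        p_a0=pa0, p_v0=1.6e3)
            means.append(sol.mean_perfusion_clinical())
        assert means[0] <= means[1] <= means[2]


class TestPerfusionMap:
    def test_unit_conversion_arithmetic(self):
        # alpha = 1e-6 m s/kg at 1000 Pa drop -> 1e-3 1/s = 6 ml/min/100ml
        assert 1e-6 * 1000.0 * PERFUSION_UNIT == pytest.approx(6.0)

    def test_pointwise_identity_and_linearity(self, frog_solution):
        dom = frog_solution.domain
        m = dom.mask
        P = frog_solution.perfusion_field()
        np.testing.assert_allclose(
            P[m], dom.alpha[m] * (frog_solution.p_a[m] - frog_solution.p_v[m]),
            rtol=1e-12)
        # sign of P follows the sign of the pressure difference
        assert np.all(np.sign(P[m]) == np.sign(frog_solution.p_a[m]
                                               - frog_solution.p_v[m]))
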