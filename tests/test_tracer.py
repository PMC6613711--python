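"""Indicator dilution: AIF, edge discretisation, transport, kinetics."""

import numpy as np
import pytest

from perfusim.tracer import (AIFModel, assemble_transport, backward_euler_run,
                             discretize_edges, observable_concentration,
                             timestep)


class TestAIF:
    def test_zero_before_delay(self):
        aif = AIFModel(C0=2.0, t0=7.5)
        t = np.linspace(0, 7.5, 20)
        np.testing.assert_array_equal(aif(t), 0.0)

    def test_peak_at_t0_plus_A_times_B(self):
        aif = AIFModel(C0=1.0, t0=7.5)  # A=3, B=1
        t = np.linspace(0, 40, 40001)
        assert t[np.argmax(aif(t))] == pytest.approx(10.5, abs=1e-2)
        assert aif.peak_time == 10.5

    def test_amplitude_scales_linearly(self):
        t = np.linspace(8, 30, 100)
        np.testing.assert_allclose(AIFModel(C0=3.0)(t), 3 * AIFModel(C0=1.0)(t))


class TestEdgeDiscretization:
    def test_one_subsegment_per_axis_voxel(self, frog_bundle, frog_solution):
        net = frog_bundle.arterial
        chains = discretize_edges(net, frog_bundle.domain,
                                  frog_bundle.vessel_mask_a)
        for ch in chains:
            assert len(ch.volumes_m3) == len(net.edges[ch.edge_index].medial_axis)

    def test_subsegment_volumes_partition_the_vessel_mask(self, frog_bundle,
                                                          frog_solution):
        dom = frog_bundle.domain
        net = frog_bundle.arterial
        chains = discretize_edges(net, dom, frog_bundle.vessel_mask_a)
        total = sum(ch.volumes_m3.sum() for ch in chains)
        n_seg = sum(len(ch.volumes_m3) for ch in chains)
        mask_vol = frog_bundle.vessel_mask_a.sum() * dom.grid.voxel_volume_m3
        # subsegments + node junction regions partition the mask, except
        # that every subsegment is floored at one voxel volume
        assert total <= mask_vol + n_seg * dom.grid.voxel_volume_m3
        assert total > 0.5 * mask_vol

    def test_downstream_ordering_follows_flow_sign(self, frog_bundle,
                                                   frog_solution):
        net = frog_bundle.arterial
        chains = discretize_edges(net, frog_bundle.domain,
                                  frog_bundle.vessel_mask_a)
        for ch in chains:
            e = net.edges[ch.edge_index]
            if e.flow > 0:
                assert (ch.up_node, ch.down_node) == (e.j, e.k)
            elif e.flow < 0:
                assert (ch.up_node, ch.down_node) == (e.k, e.j)

    def test_reversed_flow_reverses_subsegments(self, frog_bundle,
                                                frog_solution):
        import copy

        net = copy.deepcopy(frog_bundle.arterial)
        fwd = discretize_edges(net, frog_bundle.domain,
                               frog_bundle.vessel_mask_a)
        for e in net.edges:
            e.flow = -e.flow
        rev = discretize_edges(net, frog_bundle.domain,
                               frog_bundle.vessel_mask_a)
        for cf, cr in zip(fwd, rev):
            assert cf.up_node == cr.down_node
            np.testing.assert_allclose(cf.volumes_m3, cr.volumes_m3[::-1])


class TestTransport:
    def test_upwind_operator_sign_pattern(self, frog_bundle, frog_solution):
        # M-matrix structure of conservative upwinding: nonpositive
        # diagonal, nonnegative off-diagonal
        tr = assemble_transport(frog_solution, frog_bundle.vessel_mask_a,
                                frog_bundle.vessel_mask_v)
        B = tr.B.tocoo()
        off = B.row != B.col
        assert np.all(B.data[off] >= 0)
        assert np.all(tr.B.diagonal() <= 1e-30)

    def test_cfl_timestep_definition(self, frog_bundle, frog_solution):
        tr = assemble_transport(frog_solution, frog_bundle.vessel_mask_a,
                                frog_bundle.vessel_mask_v)
        dt, n = timestep(tr, factor=10.0, t_sim=120.0)
        outflux = -tr.B.diagonal() * tr.capacities
        act = outflux > 0
        cfl = np.min(tr.capacities[act] / outflux[act])
        assert dt == pytest.approx(10.0 * cfl)
        assert n == int(np.floor(120.0 / dt))

    def test_halving_flows_doubles_timestep(self, frog_bundle, frog_solution):
        import copy

        tr = assemble_transport(frog_solution, frog_bundle.vessel_mask_a,
                                frog_bundle.vessel_mask_v)
        dt1, _ = timestep(tr)
        tr2 = copy.copy(tr)
        tr2.B = tr.B * 0.5
        dt2, _ = timestep(tr2)
        assert dt2 == pytest.approx(2 * dt1)

    def test_floor_step_count_arithmetic(self, frog_bundle, frog_solution):
        tr = assemble_transport(frog_solution, frog_bundle.vessel_mask_a,
                                frog_bundle.vessel_mask_v)
        dt, n = timestep(tr, t_sim=120.0)
        # e.g. dt = 0.7 s over 120 s gives n = 171
        assert int(np.floor(120.0 / 0.7)) == 171
        assert n * dt <= 120.0 < (n + 1) * dt


class TestBackwardEuler:
    def test_zero_aif_keeps_concentrations_zero(self, frog_bundle,
                                                frog_solution):
        tr = assemble_transport(frog_solution, frog_bundle.vessel_mask_a,
                                frog_bundle.vessel_mask_v)
        run = backward_euler_run(tr, AIFModel(C0=0.0), t_sim=20.0,
                                 store_frames=False)
        assert np.all(run.mean_ca == 0)
        assert np.all(run.mean_cv == 0)
        assert run.mass_final == 0

    def test_concentrations_stay_nonnegative(self, frog_tracer):
        run, _ = frog_tracer
        assert np.all(run.mean_ca >= 0)
        assert np.all(run.mean_cv >= 0)
        for frame in run.frames:
            vals = frame[np.isfinite(frame)]
            assert np.all(vals >= -1e-15)

    def test_stepwise_tracer_mass_audit(self, frog_tracer):
        # at every step, inflow - outflow must equal the change of stored
        # mass to linear-solver precision (telescoping the implicit update)
        run, _ = frog_tracer
        assert run.mass_audit_max_rel < 1e-9
        assert run.mass_in_total - run.mass_out_total == pytest.approx(
            run.mass_final, rel=1e-9)

    def test_venous_curve_delayed_and_dispersed(self, frog_tracer):
        # the bolus reaches the arterial tissue compartment before the
        # venous one; the venous peak is later and lower
        run, _ = frog_tracer
        t_peak_a = run.times[np.argmax(run.mean_ca)]
        t_peak_v = run.times[np.argmax(run.mean_cv)]
        assert t_peak_v > t_peak_a
        assert run.mean_cv.max() < run.mean_ca.max()

    def test_plug_flow_delay_along_trunk(self, frog_bundle, frog_solution):
        # the subsegment chain of the arterial trunk transports the bolus
        # from the root to the first bifurcation with a delay close to the
        # plug-flow transit time (edge volume / flow)
        tr = assemble_transport(frog_solution, frog_bundle.vessel_mask_a,
                                frog_bundle.vessel_mask_v)
        net = frog_bundle.arterial
        root = net.root_terminals[0]
        (ei,) = net.incident_edges(root)
        chain = next(c for c in tr.chains["a"] if c.edge_index == ei)
        up = tr.node_dof["a"][chain.up_node]
        down = tr.node_dof["a"][chain.down_node]
        run = backward_euler_run(tr, AIFModel(C0=1.0, t0=2.0), t_sim=40.0,
                                 store_frames=False, probe_dofs=[up, down])

        def half_rise(series):
            half = 0.5 * series.max()
            return run.times[np.argmax(series >= half)]

        delay = half_rise(run.probes[:, 1]) - half_rise(run.probes[:, 0])
        transit = chain.volumes_m3.sum() / chain.flow_m3_s
        seg_transit = chain.volumes_m3.max() / chain.flow_m3_s
        # backward Euler disperses the front, so allow one subsegment
        # transit plus a couple of time steps of slack
        assert delay == pytest.approx(transit,
                                      abs=seg_transit + 3 * run.dt)


class TestKineticMaps:
    def test_observable_concentration_arithmetic(self):
        # c_a = c_v = 1, phi_a = 0.05, phi_v = 0.10, Hct = 0.40 -> C = 0.09
        assert observable_concentration(1.0, 1.0, 0.05, 0.10, 0.40) == \
            pytest.approx(0.09)

    def test_mtt_identity(self, frog_tracer, frog_bundle, frog_solution):
        _, maps = frog_tracer
        dom = frog_bundle.domain
        P = frog_solution.perfusion_field()
        m = dom.mask & (P > 0)
        np.testing.assert_allclose(
            maps["MTT"][m], (dom.phi_a[m] + dom.phi_v[m]) / P[m], rtol=1e-12)

    def test_mtt_ratio_example(self):
        # phi_a + phi_v = 0.15 at P = 0.005 1/s gives MTT = 30 s
        assert 0.15 / 0.005 == pytest.approx(30.0)

    def test_ttp_defined_inside_mask(self, frog_tracer, frog_bundle):
        run, maps = frog_tracer
        m = frog_bundle.domain.mask
        ttp = maps["TTP"][m]
        frac_defined = np.isfinite(ttp).mean()
        assert frac_defined > 0.95
        # TTP cannot precede the bolus delay
        assert np.nanmin(ttp) >= frog_bundle.config.t0_s
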