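"""Tissue transport: source projection, steady solvers, full drug model."""

import math

import numpy as np
import pytest
from scipy.linalg import expm

from microperf.generate import generate_single_vessel_fixture
from microperf.network import Node, VascularNetwork, Vessel
from microperf.pk import PKParams, effective_uptake_rate
from microperf.transport import (
    OxygenParams,
    ScalarField,
    TissueGrid,
    bound_from_free,
    project_line_sources,
    single_vessel_drug_profile,
    single_vessel_oxygen_profile,
    solve_drug_full,
    solve_drug_quasisteady,
    solve_oxygen,
)


def horizontal_vessel_net(length=200.0, y=50.0, diameter=20.0, domain=(0, 0, 200, 100)):
    return VascularNetwork(
        nodes=[Node(0, 0.0, y), Node(1, length, y)],
        vessels=[Vessel(id=0, node_a=0, node_b=1, diameter=diameter)],
        inlet=0, outlet=1, domain=domain,
        centre=(0.5 * (domain[0] + domain[2]), 0.5 * (domain[1] + domain[3])),
    )


class TestProjection:
    def test_axis_aligned_two_cell_split(self, uniform_flow):
        # segment along a cell-boundary-centred row, spanning 2 cells equally
        grid = TissueGrid((0.0, 0.0), 50.0, 4, 2)
        net = horizontal_vessel_net(length=100.0, y=25.0)
        src = project_line_sources(net, uniform_flow(1), grid, mode="line")
        per_cell = dict(zip(src.cell.tolist(), src.length.tolist()))
        assert per_cell == {0: pytest.approx(50.0), 1: pytest.approx(50.0)}

    def test_length_conserved_line_mode(self, small_generated_network, uniform_flow):
        net = small_generated_network
        grid = TissueGrid.from_network(net, 20.0)
        src = project_line_sources(net, uniform_flow(len(net.vessels)), grid,
                                   mode="line")
        totals = src.total_length_per_vessel()
        for i, v in enumerate(net.vessels):
            assert totals[i] == pytest.approx(net.vessel_length(v), rel=1e-9)

    def test_length_conserved_footprint_mode(self, uniform_flow):
        net, grid = generate_single_vessel_fixture(domain_size=1000, diameter=35)
        src = project_line_sources(net, uniform_flow(1), grid, mode="footprint")
        assert src.length.sum() == pytest.approx(1000.0, rel=1e-9)

    def test_diagonal_matches_supersampling_oracle(self, uniform_flow):
        # 45-degree segment; oracle: dense point sampling along the segment
        grid = TissueGrid((0.0, 0.0), 10.0, 10, 10)
        net = VascularNetwork(
            nodes=[Node(0, 5.0, 5.0), Node(1, 95.0, 95.0)],
            vessels=[Vessel(id=0, node_a=0, node_b=1, diameter=10.0)],
            inlet=0, outlet=1, domain=(0, 0, 100, 100), centre=(50, 50))
        src = project_line_sources(net, uniform_flow(1), grid, mode="line")
        n_mc = 400_000
        t = (np.arange(n_mc) + 0.5) / n_mc
        xs, ys = 5.0 + 90.0 * t, 5.0 + 90.0 * t
        flat = (np.minimum((ys / 10).astype(int), 9) * 10
                + np.minimum((xs / 10).astype(int), 9))
        seg_len = math.hypot(90, 90)
        oracle = np.bincount(flat, minlength=100) / n_mc * seg_len
        dense = np.zeros(100)
        np.add.at(dense, src.cell, src.length)
        assert np.allclose(dense, oracle, atol=1e-3 * seg_len)

    def test_unperfused_vessels_excluded(self, uniform_flow):
        grid = TissueGrid((0.0, 0.0), 50.0, 4, 2)
        net = horizontal_vessel_net(length=100.0, y=25.0)
        flow = uniform_flow(1)
        flow.unperfused[:] = True
        src = project_line_sources(net, flow, grid)
        assert len(src.cell) == 0

    def test_vessel_outside_grid_rejected(self, uniform_flow):
        grid = TissueGrid((0.0, 0.0), 50.0, 1, 1)
        net = horizontal_vessel_net(length=100.0, y=25.0)
        with pytest.raises(ValueError, match="outside"):
            project_line_sources(net, uniform_flow(1), grid)


class TestSteadyOxygen:
    def test_zero_haematocrit_zero_field(self, uniform_flow):
        net, grid = generate_single_vessel_fixture(domain_size=500, diameter=20)
        flow = uniform_flow(1, h=0.0)
        src = project_line_sources(net, flow, grid)
        field = solve_oxygen(grid, src)
        assert np.allclose(field.values, 0.0)

    def test_matches_exact_planar_solution(self, uniform_flow):
        params = OxygenParams()
        net, _ = generate_single_vessel_fixture(domain_size=1600, diameter=30)
        grid = TissueGrid((0.0, 0.0), 4.0, 400, 400)
        src = project_line_sources(net, uniform_flow(1, h=0.3), grid)
        field = solve_oxygen(grid, src, params)
        yc = (np.arange(400) + 0.5) * 4.0
        r = np.abs(yc - 800.0)
        band = (r >= 30) & (r <= 400)
        ana = single_vessel_oxygen_profile(r[band], 30.0, 0.3, params,
                                           half_domain=800.0)
        num = field.values[:, 200][band]
        assert np.max(np.abs(num - ana) / ana) < 0.01

    def test_linear_in_source_strength(self, uniform_flow):
        net, grid = generate_single_vessel_fixture(domain_size=500, diameter=20)
        src = project_line_sources(net, uniform_flow(1, h=0.3), grid)
        p1 = OxygenParams()
        p2 = OxygenParams(beta_ref=2 * p1.beta_ref)
        f1 = solve_oxygen(grid, src, p1)
        f2 = solve_oxygen(grid, src, p2)
        assert np.allclose(f2.values, 2 * f1.values, rtol=1e-10)

    def test_superposition_over_sources(self, uniform_flow):
        # linearity: with the operator fixed (same exchange geometry), the
        # response to both vessels' sources is the sum of the responses to
        # each vessel's source alone
        from microperf.transport import oxygen_operator

        grid = TissueGrid((0.0, 0.0), 10.0, 40, 40)
        both = VascularNetwork(
            nodes=[Node(0, 0.0, 120.0), Node(1, 400.0, 120.0),
                   Node(2, 0.0, 280.0), Node(3, 400.0, 280.0)],
            vessels=[Vessel(id=0, node_a=0, node_b=1, diameter=20.0),
                     Vessel(id=1, node_a=2, node_b=3, diameter=20.0)],
            inlet=0, outlet=3, domain=(0, 0, 400, 400), centre=(200, 200))
        src = project_line_sources(both, uniform_flow(2), grid)
        params = OxygenParams()
        op = oxygen_operator(grid, src, params)
        full = params.beta_ref * src.haematocrit / params.H_ref
        fa = op.solve(np.where(src.vessel_index == 0, full, 0.0))
        fb = op.solve(np.where(src.vessel_index == 1, full, 0.0))
        fab = op.solve(full)
        assert np.allclose(fab.values, fa.values + fb.values,
                           rtol=1e-8, atol=1e-12)

    def test_maximum_principle(self, small_generated_network):
        from microperf.hemodynamics import solve_coupled

        net = small_generated_network
        state = solve_coupled(net)
        grid = TissueGrid.from_network(net, 25.0)
        src = project_line_sources(net, state, grid)
        params = OxygenParams()
        field = solve_oxygen(grid, src, params)
        cap = params.beta_ref * src.haematocrit.max() / params.H_ref
        assert field.values.min() >= -1e-12
        assert field.values.max() <= cap + 1e-9

    def test_grid_refinement_converges(self, uniform_flow):
        # halving the cell size changes region-averaged oxygen by < 2%
        net, _ = generate_single_vessel_fixture(domain_size=800, diameter=30)
        means = []
        for h in (20.0, 10.0, 5.0):
            grid = TissueGrid((0.0, 0.0), h, int(800 / h), int(800 / h))
            src = project_line_sources(net, uniform_flow(1), grid)
            f = solve_oxygen(grid, src)
            xs, ys = grid.cell_centres()
            mask = np.hypot(xs - 400, ys - 400) <= 300
            means.append(f.values[mask].mean())
        assert abs(means[1] - means[0]) / means[0] < 0.02
        assert abs(means[2] - means[1]) / means[1] < 0.02


class TestSteadyDrug:
    def test_zero_plasma_zero_field(self, uniform_flow):
        net, grid = generate_single_vessel_fixture(domain_size=500, diameter=20)
        src = project_line_sources(net, uniform_flow(1), grid)
        field = solve_drug_quasisteady(grid, src, c_plasma=0.0)
        assert np.allclose(field.values, 0.0)

    def test_linear_in_plasma_concentration(self, uniform_flow):
        net, grid = generate_single_vessel_fixture(domain_size=500, diameter=20)
        src = project_line_sources(net, uniform_flow(1), grid)
        f1 = solve_drug_quasisteady(grid, src, c_plasma=100.0)
        f2 = solve_drug_quasisteady(grid, src, c_plasma=300.0)
        assert np.allclose(f2.values, 3 * f1.values, rtol=1e-10)

    def test_matches_exact_planar_solution(self, uniform_flow):
        # the drug penetration depth sqrt(D/k_eff) is only ~23 um, so this
        # comparison needs a fine grid (1 um) to resolve the lumen edge
        pk = PKParams()
        net, _ = generate_single_vessel_fixture(domain_size=400, diameter=30)
        grid = TissueGrid((0.0, 0.0), 1.0, 400, 400)
        src = project_line_sources(net, uniform_flow(1), grid)
        field = solve_drug_quasisteady(grid, src, pk, 810.0)
        yc = (np.arange(400) + 0.5) * 1.0
        r = np.abs(yc - 200.0)
        band = (r >= 25) & (r <= 120)
        ana = single_vessel_drug_profile(r[band], 30.0, 810.0, pk,
                                         half_domain=200.0)
        num = field.values[:, 200][band]
        assert np.max(np.abs(num - ana) / ana) < 0.01

    def test_maximum_principle(self, uniform_flow):
        pk = PKParams()
        net, grid = generate_single_vessel_fixture(domain_size=500, diameter=20)
        src = project_line_sources(net, uniform_flow(1), grid)
        field = solve_drug_quasisteady(grid, src, pk, 810.0)
        assert field.values.max() <= pk.epsilon * 810.0 + 1e-9
        assert field.values.min() >= -1e-12


class TestCylindricalProfile:
    def test_matches_independent_radial_finite_differences(self):
        # the K0 cross-section solution solved independently: radial ODE
        # D (C'' + C'/r) - k C = 0 on [r0, R] with a Robin wall condition
        # and a far Dirichlet value from the decay, discretised directly
        params = OxygenParams()
        d, h_l = 30.0, 0.3
        r0 = d / 2
        lam = math.sqrt(params.kappa / params.D_O2)
        c_v = params.beta_ref * h_l / params.H_ref
        rmax = 2000.0
        n = 8000
        r = np.linspace(r0, rmax, n)
        dr = r[1] - r[0]
        main = np.full(n, -2.0 * params.D_O2 / dr ** 2 - params.kappa)
        up = params.D_O2 / dr ** 2 + params.D_O2 / (2 * r[:-1] * dr)
        lo = params.D_O2 / dr ** 2 - params.D_O2 / (2 * r[1:] * dr)
        import scipy.sparse as sp
        import scipy.sparse.linalg as spla

        a = sp.diags([lo, main, up], [-1, 0, 1]).tolil()
        rhs = np.zeros(n)
        # Robin wall: -D C'(r0) = gamma (c_v - C(r0)) via ghost point
        a[0, 0] = -params.D_O2 / dr - params.gamma
        a[0, 1] = params.D_O2 / dr
        rhs[0] = -params.gamma * c_v
        a[-1, :] = 0.0
        a[-1, -1] = 1.0
        rhs[-1] = 0.0  # K0 has decayed by ~e^-9 here
        c_fd = spla.spsolve(a.tocsc(), rhs)
        band = (r > 20) & (r < 500)
        ana = single_vessel_oxygen_profile(
            r[band], d, h_l, params, geometry="cylindrical")
        assert np.max(np.abs(c_fd[band] - ana) / ana) < 0.01


class TestBoundFromFree:
    def test_zero_maps_to_zero_and_constant_ratio(self):
        pk = PKParams()
        grid = TissueGrid((0.0, 0.0), 10.0, 4, 4)
        c = ScalarField(grid, np.arange(16, dtype=float).reshape(4, 4), "nM")
        b = bound_from_free(c, pk)
        expected = pk.k_on * pk.C_r / (pk.epsilon * (pk.k_off + pk.k_int))
        assert b.values[0, 0] == 0.0
        nz = c.values > 0
        assert np.allclose(b.values[nz] / c.values[nz], expected)


class TestDrugFullModel:
    def test_no_binding_leaves_bound_and_internalised_zero(self, uniform_flow):
        pk = PKParams(k_on=1e-12)
        net, _ = generate_single_vessel_fixture(domain_size=200, diameter=20)
        grid = TissueGrid((0.0, 0.0), 20.0, 10, 10)
        src = project_line_sources(net, uniform_flow(1), grid)
        res = solve_drug_full(grid, src, pk, t_eval=[0.5], dt_max=0.01)
        assert res.fields[0].free.values.max() > 0
        assert res.fields[0].bound.values.max() < 1e-6
        assert res.fields[0].internalised.values.max() < 1e-6

    def test_well_mixed_matches_matrix_exponential(self, uniform_flow):
        # single-cell grid, no diffusion gradient: the PDE collapses to a
        # 3-compartment linear ODE with exponential forcing, solved exactly
        # by an (independent) matrix-exponential formula
        pk = PKParams()
        grid = TissueGrid((0.0, 0.0), 50.0, 1, 1)
        net = horizontal_vessel_net(length=50.0, y=25.0, diameter=20.0,
                                    domain=(0, 0, 50, 50))
        src = project_line_sources(net, uniform_flow(1), grid, mode="line")
        t_end = 0.2
        res = solve_drug_full(grid, src, pk, t_eval=[t_end],
                              dt_init=1e-6, dt_max=2e-4)
        e = src.length.sum() / 50.0 ** 2 * math.pi * 20.0 * pk.P
        kb = pk.k_on * pk.C_r / pk.epsilon
        m = np.array([
            [-e / pk.epsilon - kb, pk.k_off, 0.0],
            [kb, -(pk.k_off + pk.k_int), 0.0],
            [0.0, pk.k_int, 0.0],
        ])
        g = np.array([e * pk.C_plasma_initial, 0.0, 0.0])
        # particular solution for forcing g e^{-bt}: u_p = -(M + bI)^-1 g e^{-bt}
        up0 = -np.linalg.solve(m + pk.b * np.eye(3), g)
        u = expm(m * t_end) @ (-up0) + up0 * math.exp(-pk.b * t_end)
        got = np.array([res.fields[0].free.values[0, 0],
                        res.fields[0].bound.values[0, 0],
                        res.fields[0].internalised.values[0, 0]])
        assert np.allclose(got, u, rtol=2e-3)

    def test_mass_bookkeeping_closes(self, uniform_flow):
        pk = PKParams()
        net, _ = generate_single_vessel_fixture(domain_size=400, diameter=20)
        grid = TissueGrid((0.0, 0.0), 20.0, 20, 20)
        src = project_line_sources(net, uniform_flow(1), grid)
        res = solve_drug_full(grid, src, pk, t_eval=[1.0], dt_max=0.005)
        row = res.mass.iloc[-1]
        total = row["free"] + row["bound"] + row["internalised"]
        assert total == pytest.approx(row["cumulative_extravasated"], rel=0.02)

    def test_internalised_nondecreasing(self, uniform_flow):
        pk = PKParams()
        net, _ = generate_single_vessel_fixture(domain_size=200, diameter=20)
        grid = TissueGrid((0.0, 0.0), 20.0, 10, 10)
        src = project_line_sources(net, uniform_flow(1), grid)
        res = solve_drug_full(grid, src, pk, t_eval=[0.1, 0.5, 1.0, 2.0])
        totals = [f.internalised.values.sum() for f in res.fields]
        assert all(b >= a - 1e-9 for a, b in zip(totals, totals[1:]))

    def test_quasisteady_bound_ratio_reached(self, uniform_flow):
        # after the fast kinetics equilibrate, B/C matches the quasi-static
        # ratio everywhere the drug is present
        pk = PKParams()
        net, _ = generate_single_vessel_fixture(domain_size=200, diameter=20)
        grid = TissueGrid((0.0, 0.0), 20.0, 10, 10)
        src = project_line_sources(net, uniform_flow(1), grid)
        res = solve_drug_full(grid, src, pk, t_eval=[0.5])
        c = res.fields[0].free.values
        b = res.fields[0].bound.values
        expected = pk.k_on * pk.C_r / (pk.epsilon * (pk.k_off + pk.k_int))
        sel = c > 0.01 * c.max()
        assert np.allclose(b[sel] / c[sel], expected, rtol=1e-3)
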