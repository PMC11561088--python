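"""Finite-volume solver oracles: Poiseuille flow, species transport, coupling."""

import numpy as np
import pytest

from serpmix.chip_geometry import SegmentSpec, ChipSpec, build_chip, generate_mesh
from serpmix.flow_solver import (
    BoundaryConditions,
    ConvergenceError,
    MixtureModel,
    SolverSettings,
    W_PLGA,
    inlet_velocities,
    solve_coupled,
    solve_flow,
    solve_species,
)
from serpmix.lumped_model import ACN_PLGA, TRIS, OperatingPoint

CONST = SolverSettings(property_coupling="constant")


@pytest.fixture(scope="module")
def duct_flow(straight_duct):
    spec, chip, mesh = straight_duct
    bc = BoundaryConditions.from_operating_point(OperatingPoint(0.2), spec, mesh)
    flow = solve_flow(mesh, bc, 1000.0, 1e-3, CONST)
    return spec, mesh, bc, flow


class TestInletVelocities:
    @pytest.mark.parametrize(
        "frr, v1, v2",
        [
            ((1, 1), 8.33e-2, 8.33e-2),
            ((1, 3), 4.17e-2, 1.25e-1),
            # 1:5 from the definition v = Q*a/(a+b)/(d*h); the published
            # boundary-condition table prints 3.33e-2/1.33e-1 for this row,
            # which splits the flow 1:4 and contradicts its own FRR label.
            ((1, 5), 2.78e-2, 1.39e-1),
            ((1, 7), 2.08e-2, 1.46e-1),
        ],
    )
    def test_reference_operating_points(self, frr, v1, v2):
        got1, got2 = inlet_velocities(OperatingPoint(0.2, frr), 200.0, 100.0)
        assert got1 == pytest.approx(v1, rel=5e-3)
        assert got2 == pytest.approx(v2, rel=5e-3)

    @pytest.mark.parametrize("frr", [(1, 1), (1, 3), (1, 5), (1, 7)])
    def test_split_matches_frr_label(self, frr):
        v1, v2 = inlet_velocities(OperatingPoint(0.2, frr), 200.0, 100.0)
        assert v2 / v1 == pytest.approx(frr[1] / frr[0], rel=1e-12)

    def test_flows_sum_to_tfr(self):
        op = OperatingPoint(0.37, (2, 5))
        v1, v2 = inlet_velocities(op, 200.0, 100.0)
        assert (v1 + v2) * 2e-8 == pytest.approx(op.q_total, rel=1e-12)


class TestPlanePoiseuille:
    def test_max_over_mean_ratio(self, duct_flow):
        _, mesh, bc, flow = duct_flow
        prof = flow.u[-40]  # developed, away from the outlet
        # discrete parabola sampled at cell centers
        t = mesh.t_centers
        ana = 1.5 * bc.v_mean * (1 - (2 * t / mesh.width) ** 2)
        assert prof.max() / prof.mean() == pytest.approx(ana.max() / ana.mean(), rel=1e-2)
        assert prof.max() / prof.mean() == pytest.approx(1.5, rel=1.5e-2)

    def test_profile_matches_parabola(self, duct_flow):
        _, mesh, bc, flow = duct_flow
        t = mesh.t_centers
        ana = 1.5 * bc.v_mean * (1 - (2 * t / mesh.width) ** 2)
        assert np.abs(flow.u[-40] - ana).max() / ana.max() < 1e-2

    def test_pressure_gradient_within_1pct(self, duct_flow):
        _, mesh, bc, flow = duct_flow
        j0, j1 = 100, 300
        dpdx = (flow.p[j0].mean() - flow.p[j1].mean()) / (mesh.s_col[j1] - mesh.s_col[j0])
        assert dpdx == pytest.approx(12e-3 * bc.v_mean / mesh.width**2, rel=1e-2)

    def test_global_mass_balance(self, duct_flow):
        _, _, _, flow = duct_flow
        assert flow.mass_balance_error < 1e-6

    def test_transverse_velocity_negligible(self, duct_flow):
        _, _, bc, flow = duct_flow
        assert np.abs(flow.v[100:]).max() < 1e-3 * bc.v_mean


class TestSpecies:
    def test_large_diffusivity_perfect_mixing(self, duct_flow):
        spec, mesh, bc, flow = duct_flow
        sp = solve_species(mesh, flow, 1e-4, bc, CONST, rho=1000.0)
        assert np.abs(sp.Y[mesh.n_s // 2 :] - 0.5).max() < 1e-3

    @pytest.mark.parametrize("frr", [(1, 1), (1, 3), (1, 7)])
    def test_outlet_flow_weighted_mean_conserved(self, duct_flow, frr):
        spec, mesh, _, flow = duct_flow
        bc = BoundaryConditions.from_operating_point(OperatingPoint(0.2, frr), spec, mesh)
        sp = solve_species(mesh, flow, 3.5e-9, bc, CONST, rho=1000.0)
        assert sp.conservation_error < 1e-4

    def test_bounded_in_unit_interval(self, duct_flow):
        spec, mesh, _, flow = duct_flow
        bc = BoundaryConditions.from_operating_point(OperatingPoint(0.2, (1, 5)), spec, mesh)
        sp = solve_species(mesh, flow, 3.5e-9, bc, CONST, rho=1000.0)
        assert sp.Y.min() >= 0.0 and sp.Y.max() <= 1.0
        # bounded before clipping too, up to the deferred-loop residual
        assert sp.clip_excursion < 1e-6

    def test_antisymmetry_at_equal_split(self, duct_flow):
        _, mesh, bc, flow = duct_flow
        sp = solve_species(mesh, flow, 3.5e-9, bc, CONST, rho=1000.0)
        assert np.abs(sp.Y + sp.Y[:, ::-1] - 1.0).max() < 1e-6

    def test_transverse_profile_matches_marching_oracle(self, duct_flow):
        """Independent parabolized (space-marching FTCS) solution on a fine
        transverse grid, same parabolic velocity profile."""
        spec, mesh, bc, flow = duct_flow
        D = 2e-8  # resolved front
        w, vbar = mesh.width, bc.v_mean
        nt = 400
        dt = w / nt
        t = (np.arange(nt) + 0.5) * dt - w / 2
        u = 1.5 * vbar * (1 - (2 * t / w) ** 2)
        Y = (t < 0).astype(float)
        x, x_end = 0.0, 3.5e-3
        while x < x_end:
            d2 = np.empty_like(Y)
            d2[1:-1] = (Y[2:] - 2 * Y[1:-1] + Y[:-2]) / dt**2
            d2[0] = (Y[1] - Y[0]) / dt**2
            d2[-1] = (Y[-2] - Y[-1]) / dt**2
            dx = min(0.2 * dt**2 * u.min() / D, x_end - x)
            Y += dx * D / u * d2
            x += dx
        sp = solve_species(mesh, flow, D, bc, CONST, rho=1000.0)
        j = int(np.argmin(np.abs(mesh.s_col - x_end)))
        assert np.abs(sp.Y[j] - np.interp(mesh.t_centers, t, Y)).max() < 0.02

    def test_x_acn_accounts_for_plga_loading(self, duct_flow):
        spec, mesh, bc, flow = duct_flow
        sp = solve_species(mesh, flow, 3.5e-9, bc, CONST, rho=1000.0)
        assert np.allclose(sp.X_acn, sp.Y * (1 - W_PLGA))
        assert W_PLGA == pytest.approx(0.00878, rel=1e-2)


class TestCoupled:
    def test_constant_mode_reproduces_decoupled(self, straight_duct):
        spec, chip, mesh = straight_duct
        bc = BoundaryConditions.from_operating_point(OperatingPoint(0.2), spec, mesh)
        mix = MixtureModel()
        flow1, sp1 = solve_coupled(mesh, bc, mix, CONST)
        rho0 = float(mix.rho(0.5))
        mu0 = float(mix.mu(0.5))
        flow2 = solve_flow(mesh, bc, rho0, mu0, CONST)
        sp2 = solve_species(mesh, flow2, mix.D, bc, CONST, rho=rho0)
        assert flow1.content_hash() == flow2.content_hash()
        assert sp1.content_hash() == sp2.content_hash()

    def test_deterministic_repeat(self, straight_duct):
        spec, chip, mesh = straight_duct
        bc = BoundaryConditions.from_operating_point(OperatingPoint(0.2), spec, mesh)
        s = SolverSettings(property_coupling="coupled", picard_max=2)
        f1, y1 = solve_coupled(mesh, bc, MixtureModel(), s)
        f2, y2 = solve_coupled(mesh, bc, MixtureModel(), s)
        assert f1.content_hash() == f2.content_hash()
        assert y1.content_hash() == y2.content_hash()

    def test_mixture_model_endpoints(self):
        mix = MixtureModel()
        assert float(mix.rho(0.0)) == pytest.approx(TRIS.rho, rel=1e-12)
        assert float(mix.rho(1.0)) == pytest.approx(ACN_PLGA.rho, rel=1e-12)
        assert float(mix.mu(0.0)) == pytest.approx(TRIS.mu, rel=1e-12)
        assert float(mix.mu(1.0)) == pytest.approx(ACN_PLGA.mu, rel=1e-12)
        # continuous and bounded between the component values
        ys = np.linspace(0, 1, 11)
        assert np.all(mix.rho(ys) <= TRIS.rho) and np.all(mix.rho(ys) >= ACN_PLGA.rho)


class TestSolverContracts:
    def test_nonconvergence_raises_with_history(self, straight_duct):
        spec, chip, mesh = straight_duct
        bc = BoundaryConditions.from_operating_point(OperatingPoint(0.2), spec, mesh)
        s = SolverSettings(property_coupling="constant", tol=1e-14, max_outer=5)
        with pytest.raises(ConvergenceError) as exc:
            solve_flow(mesh, bc, 1000.0, 1e-3, s)
        assert len(exc.value.residual_history) == 5

    def test_stokes_mode_recovers_poiseuille(self, straight_duct):
        spec, chip, mesh = straight_duct
        bc = BoundaryConditions.from_operating_point(OperatingPoint(0.2), spec, mesh)
        s = SolverSettings(property_coupling="constant", momentum="stokes")
        flow = solve_flow(mesh, bc, 1000.0, 1e-3, s)
        t = mesh.t_centers
        ana = 1.5 * bc.v_mean * (1 - (2 * t / mesh.width) ** 2)
        assert np.abs(flow.u[-40] - ana).max() / ana.max() < 1e-2

    def test_regime_diagnostics_attached(self, duct_flow):
        # bulk Reynolds number on the channel-width scale rho*v_mean*w/mu
        _, mesh, bc, flow = duct_flow
        assert flow.reynolds == pytest.approx(1000.0 * bc.v_mean * mesh.width / 1e-3, rel=1e-6)

    def test_serpentine_small_chip_runs_and_conserves(self, small_chip_spec, small_mesh):
        bc = BoundaryConditions.from_operating_point(
            OperatingPoint(0.2), small_chip_spec, small_mesh
        )
        flow = solve_flow(small_mesh, bc, 1000.0, 1e-3, CONST)
        assert flow.mass_balance_error < 1e-6
        sp = solve_species(small_mesh, flow, 3.5e-9, bc, CONST, rho=1000.0)
        assert sp.conservation_error < 1e-4

    def test_grid_convergence_reported(self, small_chip):
        """Refining the mesh changes the section-mean Y by a decreasing amount."""
        from serpmix.chip_geometry import locate_sections

        means = {}
        for h in (40.0, 20.0, 10.0):
            mesh = generate_mesh(small_chip, h)
            bc = BoundaryConditions.from_operating_point(
                OperatingPoint(0.2), small_chip.spec, mesh
            )
            flow = solve_flow(mesh, bc, 1000.0, 1e-3, CONST)
            sp = solve_species(mesh, flow, 3.5e-9, bc, CONST, rho=1000.0)
            loc = locate_sections(small_chip, mesh, n=4)
            means[h] = np.array([sp.Y[j].mean() for j in loc.columns])
        d_coarse = np.abs(means[40.0] - means[20.0]).max()
        d_fine = np.abs(means[20.0] - means[10.0]).max()
        assert d_fine < d_coarse
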