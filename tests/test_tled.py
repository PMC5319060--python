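import numpy as np
import pytest

from hexreg import (BoundaryCondition, Config, HeterogeneousModel,
                    SimulationState, build_hex_mesh, critical_time_step,
                    internal_forces, lame_from_youngs, pk2_neo_hookean,
                    precompute_tled, run_to_equilibrium, strain_energy)
from hexreg.errors import (ConvergenceError, ElementInversionError,
                           ValidationError)
from hexreg.model import Scenario, scenario_boundary_condition
from hexreg.tled import advance_step

from conftest import block_volume
from _linear_fem import solve_linear_static

MATS = {1: (2e5, 0.49, 1000.0)}


class TestMaterial:
    def test_lame_closed_forms_at_study_values(self):
        E, nu = 2e5, 0.49
        mu, lam = lame_from_youngs(E, nu)
        assert mu == pytest.approx(E / (2 * 1.49), rel=1e-14)
        assert lam == pytest.approx(E * 0.49 / (1.49 * 0.02), rel=1e-14)

    def test_zero_poisson_gives_zero_lambda(self):
        _, lam = lame_from_youngs(1e6, 0.0)
        assert lam == 0.0

    def test_incompressible_limit_rejected(self):
        with pytest.raises(ValidationError, match="0.5"):
            lame_from_youngs(1e6, 0.5)

    def test_rest_state_is_stress_free(self):
        S = pk2_neo_hookean(np.eye(3), 1e5, 3e5)
        assert np.abs(S).max() == 0.0

    def test_uniaxial_stretch_matches_closed_form(self):
        mu = 7.0e4
        F = np.diag([1.2, 1.0, 1.0])
        S = pk2_neo_hookean(F, mu, 0.0)
        Cinv = np.diag([1 / 1.44, 1.0, 1.0])
        expect = mu * (np.eye(3) - Cinv)
        assert np.abs(S - expect).max() < 1e-12 * mu

    def test_inverted_gradient_rejected(self):
        with pytest.raises(ElementInversionError, match="inversion"):
            pk2_neo_hookean(np.diag([0.5, 0.5, -1.0]), 1e5, 1e5)


class TestPrecompute:
    def test_unit_cube_lumped_mass(self):
        mesh = build_hex_mesh(block_volume(1, 1, 1, spacing=1.0))
        pc = precompute_tled(mesh, MATS)
        assert np.allclose(pc.mass, 125.0)

    def test_shape_derivatives_sum_to_zero(self):
        mesh = build_hex_mesh(block_volume(1, 1, 1, spacing=3e-3))
        for quad in ("1pt", "8pt"):
            pc = precompute_tled(mesh, MATS, quadrature=quad)
            assert np.abs(pc.B.sum(axis=1)).max() < 1e-12

    def test_total_mass_conserved(self):
        mesh = build_hex_mesh(block_volume(2, 2, 2, spacing=4e-3))
        pc = precompute_tled(mesh, MATS)
        assert pc.mass.sum() == pytest.approx(
            1000.0 * mesh.n_elements * mesh.cell_volume, rel=1e-12)

    def test_missing_material_rejected(self):
        mesh = build_hex_mesh(block_volume(1, 1, 1, label=3))
        with pytest.raises(ValidationError, match="label"):
            precompute_tled(mesh, MATS)


class TestInternalForces:
    @pytest.mark.parametrize("quad", ["1pt", "8pt"])
    def test_rigid_translation_produces_no_force(self, quad):
        mesh = build_hex_mesh(block_volume(3, 2, 2))
        pc = precompute_tled(mesh, MATS, quadrature=quad)
        u = np.tile([1e-3, -2e-3, 5e-4], (mesh.n_nodes, 1))
        assert np.abs(internal_forces(pc, u)).max() < 1e-10

    def test_newtons_third_law(self):
        mesh = build_hex_mesh(block_volume(3, 2, 2))
        pc = precompute_tled(mesh, MATS)
        rng = np.random.default_rng(0)
        u = rng.normal(scale=2e-4, size=(mesh.n_nodes, 3))
        f = internal_forces(pc, u)
        assert np.abs(f.sum(axis=0)).max() < 1e-9

    def test_small_strain_bar_matches_linear_oracle(self):
        # 4x1x1 bar at 0.5% uniaxial strain: nonlinear TLED forces at the
        # linear-oracle equilibrium displacements are in balance within 1%
        # of the applied-force scale
        mesh = build_hex_mesh(block_volume(4, 1, 1))
        L = 4 * mesh.spacing[0]
        strain = 0.005
        base = np.flatnonzero(mesh.nodes[:, 0] < 1e-12)
        tip = np.flatnonzero(mesh.nodes[:, 0] > L - 1e-12)
        fixed_dofs, fixed_vals = [], []
        for n in base:
            fixed_dofs += [3 * n, 3 * n + 1, 3 * n + 2]
            fixed_vals += [0.0, 0.0, 0.0]
        for n in tip:
            # the driven face is glued to the actuator: full vector given
            fixed_dofs += [3 * n, 3 * n + 1, 3 * n + 2]
            fixed_vals += [strain * L, 0.0, 0.0]
        u_lin = solve_linear_static(
            mesh.nodes, mesh.elements,
            np.full(mesh.n_elements, 2e5), np.full(mesh.n_elements, 0.49),
            np.array(fixed_dofs), np.array(fixed_vals))
        pc = precompute_tled(mesh, MATS, quadrature="8pt")
        f = internal_forces(pc, u_lin)
        free = np.setdiff1d(np.arange(mesh.n_nodes), np.concatenate([base, tip]))
        scale = np.abs(f[tip]).sum()
        assert np.abs(f[free]).max() < 0.01 * scale

    def test_inversion_reports_element(self):
        mesh = build_hex_mesh(block_volume(2, 1, 1))
        pc = precompute_tled(mesh, MATS)
        u = np.zeros((mesh.n_nodes, 3))
        # collapse the second element along x
        second = mesh.elements[1]
        right = second[np.isin(second, mesh.elements[0], invert=True)]
        u[right, 0] = -1.2 * mesh.spacing[0]
        with pytest.raises(ElementInversionError) as err:
            internal_forces(pc, u)
        assert err.value.element == 1


class TestTimeStep:
    def test_closed_form_value(self):
        mesh = build_hex_mesh(block_volume(1, 1, 1, spacing=1.0))
        dt = critical_time_step(mesh, MATS, safety=0.8)
        mu, lam = lame_from_youngs(2e5, 0.49)
        assert dt == pytest.approx(0.8 / np.sqrt((lam + 2 * mu) / 1000.0),
                                   rel=1e-12)

    def test_stiffness_and_size_scalings(self):
        mesh1 = build_hex_mesh(block_volume(1, 1, 1, spacing=1.0))
        mesh2 = build_hex_mesh(block_volume(1, 1, 1, spacing=0.5))
        dt1 = critical_time_step(mesh1, MATS)
        assert critical_time_step(mesh2, MATS) == pytest.approx(dt1 / 2)
        stiffer = {1: (4e5, 0.49, 1000.0)}
        assert critical_time_step(mesh1, stiffer) == \
            pytest.approx(dt1 / np.sqrt(2))


class TestTimeStepping:
    def test_equilibrium_is_a_fixed_point(self):
        mesh = build_hex_mesh(block_volume(2, 2, 2))
        pc = precompute_tled(mesh, MATS)
        dt = critical_time_step(mesh, MATS)
        state = SimulationState.zeros(mesh.n_nodes)
        advance_step(pc, state, None, None, dt)
        assert np.abs(state.u).max() == 0.0

    def test_prescribed_node_is_exact_after_step(self):
        mesh = build_hex_mesh(block_volume(2, 2, 2))
        pc = precompute_tled(mesh, MATS)
        dt = critical_time_step(mesh, MATS)
        bc = BoundaryCondition(prescribed=np.array([0]),
                               prescribed_disp=np.array([[1e-4, 0, 0]]),
                               ramp_steps=0)
        state = SimulationState.zeros(mesh.n_nodes)
        advance_step(pc, state, None, bc, dt)
        assert state.u[0, 0] == 1e-4

    def test_damped_free_oscillation_dissipates_energy(self):
        mesh = build_hex_mesh(block_volume(2, 2, 2))
        pc = precompute_tled(mesh, MATS, alpha=200.0)
        # free boundaries concentrate stiffness on light corner nodes, so
        # stay well below the interior-element Courant estimate
        dt = 0.5 * critical_time_step(mesh, MATS)
        rng = np.random.default_rng(1)
        state = SimulationState.zeros(mesh.n_nodes)
        state.u = rng.normal(scale=1e-4, size=(mesh.n_nodes, 3))
        prev = None
        for n in range(400):
            advance_step(pc, state, None, None, dt)
            if n % 40 == 0:
                energy = strain_energy(pc, state.u) + \
                    0.5 * float(np.sum(pc.mass[:, None] * state.v ** 2))
                if prev is not None:
                    assert energy <= prev * (1 + 1e-6)
                prev = energy

    def test_momentum_conserved_without_damping(self):
        mesh = build_hex_mesh(block_volume(2, 2, 2))
        pc = precompute_tled(mesh, MATS, alpha=0.0)
        dt = critical_time_step(mesh, MATS)
        rng = np.random.default_rng(2)
        state = SimulationState.zeros(mesh.n_nodes)
        state.v = rng.normal(scale=1e-3, size=(mesh.n_nodes, 3))
        p0 = (pc.mass[:, None] * state.v).sum(axis=0)
        for _ in range(1000):
            advance_step(pc, state, None, None, dt)
        p1 = (pc.mass[:, None] * state.v).sum(axis=0)
        assert np.abs(p1 - p0).max() < 1e-9 * np.abs(p0).max()

    def test_zero_bc_converges_immediately(self):
        mesh = build_hex_mesh(block_volume(2, 2, 2))
        pc = precompute_tled(mesh, MATS, alpha=100.0)
        dt = critical_time_step(mesh, MATS)
        bc = BoundaryCondition(ramp_steps=0)
        state = run_to_equilibrium(pc, bc, dt, tol=1e-6, max_steps=1000)
        assert np.abs(state.u).max() == 0.0
        assert state.steps == 100  # just the settle window

    def test_unreachable_tolerance_reports_residual(self):
        mesh = build_hex_mesh(block_volume(2, 2, 2))
        pc = precompute_tled(mesh, MATS, alpha=5.0)
        dt = critical_time_step(mesh, MATS)
        bc = BoundaryCondition(
            fixed=np.flatnonzero(mesh.nodes[:, 0] < 1e-12),
            prescribed=np.flatnonzero(mesh.nodes[:, 0] > 9e-3),
            prescribed_disp=np.tile([1e-3, 0, 0],
                                    ((mesh.nodes[:, 0] > 9e-3).sum(), 1)),
            ramp_steps=10)
        with pytest.raises(ConvergenceError) as err:
            run_to_equilibrium(pc, bc, dt, tol=1e-15, max_steps=500)
        assert err.value.residual > 0

    def test_bar_equilibrium_matches_linear_static_oracle(self):
        # 8x2x2 bar, fixed base, 1% prescribed axial tip displacement
        mesh = build_hex_mesh(block_volume(8, 2, 2))
        L = 8 * mesh.spacing[0]
        base = np.flatnonzero(mesh.nodes[:, 0] < 1e-12)
        tip = np.flatnonzero(mesh.nodes[:, 0] > L - 1e-12)
        disp = 0.01 * L
        fixed_dofs, fixed_vals = [], []
        for n in base:
            fixed_dofs += [3 * n, 3 * n + 1, 3 * n + 2]
            fixed_vals += [0.0, 0.0, 0.0]
        for n in tip:
            fixed_dofs += [3 * n, 3 * n + 1, 3 * n + 2]
            fixed_vals += [disp, 0.0, 0.0]
        u_lin = solve_linear_static(
            mesh.nodes, mesh.elements,
            np.full(mesh.n_elements, 2e5), np.full(mesh.n_elements, 0.49),
            np.array(fixed_dofs), np.array(fixed_vals))
        pc = precompute_tled(mesh, MATS, quadrature="8pt", alpha=400.0)
        dt = 0.7 * critical_time_step(mesh, MATS)
        bc = BoundaryCondition(
            fixed=base, prescribed=tip,
            prescribed_disp=np.tile([disp, 0, 0], (len(tip), 1)),
            ramp_steps=200)
        state = run_to_equilibrium(pc, bc, dt, tol=2e-5, max_steps=60000)
        inner = np.setdiff1d(np.arange(mesh.n_nodes),
                             np.concatenate([base, tip]))
        err = np.abs(state.u[inner] - u_lin[inner]).max()
        assert err < 0.02 * np.abs(u_lin).max()


class TestScenarioBC:
    def test_plate_contact_tapers_with_depth(self, phantom_mesh):
        scn = Scenario(position_index=0,
                       patch_center=np.array([0.04, 0.02, 0.05]),
                       patch_half=np.array([0.015, 0.015, np.inf]),
                       direction=np.array([0.0, 0.0, -1.0]),
                       magnitude=6e-3)
        bc = scenario_boundary_condition(phantom_mesh, scn)
        assert len(bc.prescribed) > 0
        uz = bc.prescribed_disp[:, 2]
        # every contacted node moves down, none farther than the plate
        # travel, and the crown node moves the full magnitude
        assert uz.max() < 0
        assert uz.min() == pytest.approx(-6e-3, abs=1e-15)

    def test_zero_magnitude_prescribes_nothing(self, phantom_mesh):
        scn = Scenario(position_index=0,
                       patch_center=np.array([0.04, 0.02, 0.05]),
                       patch_half=np.array([0.015, 0.015, np.inf]),
                       direction=np.array([0.0, 0.0, -1.0]), magnitude=0.0)
        bc = scenario_boundary_condition(phantom_mesh, scn)
        assert len(bc.prescribed) == 0
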