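"""Explicit solver verification: mass lumping, element kinematics, CFL,
contact, patch test, wave-speed / energy / momentum oracles."""

import numpy as np
import pytest

from osseoimpact import fem, geometry, materials
from osseoimpact.fem import (
    Impactor,
    SolverError,
    TimeIntegrationParams,
    contact_force,
    element_stress,
    internal_forces,
    lumped_mass,
    stable_dt,
    total_strain_energy,
)

from conftest import bar_fixture, single_tet_mesh, uniform_library


def regular_tet_mesh(edge=1e-3):
    a = edge
    coords = np.array(
        [
            [0.0, 0.0, 0.0],
            [a, 0.0, 0.0],
            [a / 2.0, a * np.sqrt(3.0) / 2.0, 0.0],
            [a / 2.0, a * np.sqrt(3.0) / 6.0, a * np.sqrt(2.0 / 3.0)],
        ]
    )
    mesh = single_tet_mesh(coords)
    assert geometry.tet_volumes(mesh.node_coords, mesh.tets)[0] > 0
    return mesh


class TestLumpedMass:
    def test_single_tet_equal_split(self):
        # legs 2, 2, 6 mm -> V = 4e-9 m^3; rho = 1000 -> 1e-6 kg per node
        coords = np.array(
            [[0, 0, 0], [2e-3, 0, 0], [0, 2e-3, 0], [0, 0, 6e-3]], dtype=float
        )
        mesh = single_tet_mesh(coords)
        m = lumped_mass(mesh, uniform_library(rho=1000.0))
        assert np.allclose(m, 1e-6, rtol=1e-12)

    def test_total_mass_conserved(self, default_mesh):
        lib = uniform_library(rho=1700.0)
        m = lumped_mass(default_mesh, lib)
        # bone block plus the 24 exposed-head grid cells (12 per layer x 2)
        volume = 0.012 * 0.012 * 0.016 + 24 * (1e-3) ** 3
        assert m.sum() == pytest.approx(1700.0 * volume, rel=1e-12)

    def test_shared_node_additivity(self, tiny_mesh, default_lib):
        m = lumped_mass(tiny_mesh, default_lib)
        rho = np.empty(tiny_mesh.n_elements)
        for r in np.unique(tiny_mesh.region):
            rho[tiny_mesh.region == r] = default_lib.elastic[r].rho
        contrib = rho * tiny_mesh.volumes() / 4.0
        node = int(tiny_mesh.tets[0, 0])
        expected = contrib[(tiny_mesh.tets == node).any(axis=1)].sum()
        assert m[node] == pytest.approx(expected, rel=1e-12)


class TestElementStress:
    def test_uniaxial_stretch_nu_zero(self, tiny_mesh):
        lib = uniform_library(E=15e9, nu=0.0)
        alpha = 1e-4
        disp = np.zeros((tiny_mesh.n_nodes, 3))
        disp[:, 2] = alpha * tiny_mesh.node_coords[:, 2]
        sig = element_stress(tiny_mesh, 0, disp, lib)
        assert sig[2, 2] == pytest.approx(15e9 * alpha, rel=1e-12)
        off = sig.copy()
        off[2, 2] = 0.0
        assert np.abs(off).max() < 1e-6 * abs(sig[2, 2])

    def test_rigid_translation_stress_free(self, tiny_mesh, default_lib):
        disp = np.full((tiny_mesh.n_nodes, 3), 1e-3)
        sig = element_stress(tiny_mesh, 5, disp, default_lib)
        assert np.abs(sig).max() < 1e-3  # Pa, vs GPa-scale moduli

    def test_forces_are_energy_gradient(self, tiny_mesh, default_lib):
        rng = np.random.default_rng(7)
        disp = rng.normal(0.0, 1e-6, (tiny_mesh.n_nodes, 3))
        f = internal_forces(tiny_mesh, disp, default_lib)
        h = 1e-9
        for node, comp in [(10, 0), (40, 2), (100, 1)]:
            dp = disp.copy(); dp[node, comp] += h
            dm = disp.copy(); dm[node, comp] -= h
            grad = (
                total_strain_energy(tiny_mesh, dp, default_lib)
                - total_strain_energy(tiny_mesh, dm, default_lib)
            ) / (2 * h)
            assert -grad == pytest.approx(f[node, comp], rel=1e-6)

    def test_single_tet_internal_forces_balance(self):
        mesh = single_tet_mesh()
        lib = uniform_library()
        disp = np.zeros((4, 3))
        disp[3, 2] = 1e-5   # stretch one vertex
        f = internal_forces(mesh, disp, lib)
        assert np.allclose(f.sum(axis=0), 0.0, atol=1e-9 * np.abs(f).max())

    def test_zero_displacement_zero_forces(self, tiny_mesh, default_lib):
        f = internal_forces(tiny_mesh, np.zeros((tiny_mesh.n_nodes, 3)), default_lib)
        assert np.all(f == 0)


class TestPatchTest:
    def test_affine_field_exact_constant_stress(self, tiny_mesh):
        lib = uniform_library(E=10e9, nu=0.25)
        lam, mu = materials.lame_parameters(lib.elastic["CORTICAL"])
        A = np.array([[2e-4, 1e-4, 0.0], [0.0, -1e-4, 5e-5], [1e-4, 0.0, 3e-4]])
        disp = tiny_mesh.node_coords @ A.T
        eps_exact = 0.5 * (A + A.T)
        sig_exact = lam * np.trace(eps_exact) * np.eye(3) + 2 * mu * eps_exact
        for e in [0, 100, 777, tiny_mesh.n_elements - 1]:
            sig = element_stress(tiny_mesh, e, disp, lib)
            assert np.allclose(sig, sig_exact, rtol=1e-8)

    def test_interior_nodes_in_equilibrium(self, tiny_params):
        # flush implant so "interior" is unambiguous for a box
        from dataclasses import replace

        mesh = geometry.build_mesh(replace(tiny_params, implant_protrusion=0.0))
        lib = uniform_library(E=10e9, nu=0.25)
        A = np.array([[2e-4, 0, 0], [0, 1e-4, 0], [0, 0, -1e-4]])
        disp = mesh.node_coords @ A.T
        f = internal_forces(mesh, disp, lib)
        coords = mesh.node_coords
        lo, hi = coords.min(axis=0), coords.max(axis=0)
        interior = np.all((coords > lo + 1e-9) & (coords < hi - 1e-9), axis=1)
        scale = np.abs(f).max()
        assert np.abs(f[interior]).max() < 1e-8 * scale


class TestStableDt:
    def test_regular_tet_closed_form(self):
        mesh = regular_tet_mesh(edge=1e-3)
        lib = uniform_library(E=2.5e10, nu=0.0, rho=1000.0)   # c_d = 5000 m/s
        h = 1e-3 * np.sqrt(2.0 / 3.0)
        assert stable_dt(mesh, lib, cfl_factor=0.5) == pytest.approx(
            0.5 * h / 5000.0, rel=1e-9
        )

    def test_cfl_factor_linearity(self, tiny_mesh, default_lib):
        assert stable_dt(tiny_mesh, default_lib, cfl_factor=1.0) == pytest.approx(
            2.0 * stable_dt(tiny_mesh, default_lib, cfl_factor=0.5), rel=1e-12
        )

    def test_deactivating_element_cannot_decrease_dt(self, tiny_mesh, default_lib):
        full = stable_dt(tiny_mesh, default_lib)
        active = np.ones(tiny_mesh.n_elements, dtype=bool)
        # deactivate the governing element
        _, _, _, _, cd, h_min = fem._element_data(tiny_mesh, default_lib)
        active[np.argmin(h_min / cd)] = False
        assert stable_dt(tiny_mesh, default_lib, active=active) >= full

    def test_no_active_elements_rejected(self, tiny_mesh, default_lib):
        with pytest.raises(SolverError, match="active"):
            stable_dt(tiny_mesh, default_lib, active=np.zeros(tiny_mesh.n_elements, bool))


class TestContact:
    IMP = Impactor(center=[0, 0, 0], velocity=[0, 0, -1], radius=0.01,
                   mass=0.015, penalty_stiffness=1e6)

    def test_open_gap_zero_force(self):
        pos = np.array([[0.0, 0.0, -0.02], [0.011, 0.0, 0.0]])
        f, reaction, pen = contact_force(self.IMP, self.IMP.center, pos)
        assert np.all(f == 0) and np.all(reaction == 0) and np.all(pen <= 0)

    def test_south_pole_penetration(self):
        d = 1e-4
        pos = np.array([[0.0, 0.0, -(0.01 - d)]])
        f, reaction, pen = contact_force(self.IMP, self.IMP.center, pos)
        assert pen[0] == pytest.approx(d, rel=1e-12)
        assert f[0] == pytest.approx([0.0, 0.0, -1e6 * d], rel=1e-12)

    def test_action_reaction(self):
        rng = np.random.default_rng(3)
        pos = rng.normal(0.0, 0.006, (20, 3))
        f, reaction, _ = contact_force(self.IMP, self.IMP.center, pos)
        assert np.allclose(f.sum(axis=0) + reaction, 0.0, atol=1e-18)


class TestStepAndRun:
    def test_zero_state_remains_zero(self, tiny_mesh, default_lib):
        model = fem.build_model(tiny_mesh, default_lib)
        state = fem.initial_state(model)
        dt = stable_dt(tiny_mesh, default_lib)
        for _ in range(3):
            state = fem.step(model, state, dt)
        assert np.all(state.disp == 0) and np.all(state.vel == 0)
        assert np.all(state.stress == 0)

    def test_free_element_rigid_translation(self):
        mesh = single_tet_mesh()
        lib = uniform_library()
        model = fem.build_model(mesh, lib, fixed_set=None)
        state = fem.initial_state(model)
        v = np.array([1.0, -2.0, 0.5])
        state.vel[:] = v
        dt = stable_dt(mesh, lib)
        for _ in range(50):
            state = fem.step(model, state, dt)
        assert np.allclose(state.disp, v * state.time, rtol=1e-9)
        assert np.abs(state.stress).max() < 1e-3   # Pa

    def test_non_finite_state_reported(self, tiny_mesh, default_lib):
        model = fem.build_model(tiny_mesh, default_lib)
        state = fem.initial_state(model)
        interior = np.flatnonzero(
            np.all(
                (tiny_mesh.node_coords > 1e-9)
                & (tiny_mesh.node_coords < tiny_mesh.node_coords.max(axis=0) - 1e-9),
                axis=1,
            )
        )[0]
        state.disp[interior, 0] = np.nan
        with pytest.raises(SolverError, match="non-finite"):
            fem.step(model, state, stable_dt(tiny_mesh, default_lib))

    def test_run_t_end_zero_returns_initial_only(self, tiny_mesh, default_lib):
        model = fem.build_model(tiny_mesh, default_lib)
        hist = fem.run(model, TimeIntegrationParams(t_end=0.0))
        assert len(hist.times) == 1 and hist.times[0] == 0.0

    def test_no_impactor_rest_run_all_zero(self, tiny_mesh, default_lib):
        model = fem.build_model(tiny_mesh, default_lib)
        dt = stable_dt(tiny_mesh, default_lib)
        hist = fem.run(model, TimeIntegrationParams(t_end=20 * dt, output_every=5))
        for d in hist.disp:
            assert np.all(d == 0)


class TestWaveOracles:
    def test_wavefront_speed_matches_bar_theory(self):
        mesh, lib, model = bar_fixture()
        c = np.sqrt(15e9 / 1900.0)
        state = fem.initial_state(model)
        v0 = 1.0
        state.vel[mesh.node_coords[:, 2] < 0.008 - 1e-6, 2] = v0
        hist = fem.run(model, TimeIntegrationParams(t_end=1.0e-5, output_every=1),
                       state=state)
        times = np.asarray(hist.times)

        def arrival(z, frac=0.25):
            nodes = np.flatnonzero(np.abs(mesh.node_coords[:, 2] - z) < 1e-6)
            u = np.array([d[nodes, 2].mean() for d in hist.disp])
            v = np.gradient(u, times)
            i = np.flatnonzero(v > frac * v0)[0]
            w = (frac * v0 - v[i - 1]) / (v[i] - v[i - 1])
            return times[i - 1] + w * (times[i] - times[i - 1])

        t1, t2 = arrival(0.016), arrival(0.032)
        measured = 0.016 / (t2 - t1)
        assert abs(measured - c) / c < 0.02

    def test_energy_conservation_before_deletion(self):
        mesh, lib, model = bar_fixture()
        state = fem.initial_state(model)
        state.vel[mesh.node_coords[:, 2] < 0.008 - 1e-6, 2] = 1.0
        hist = fem.run(model, TimeIntegrationParams(t_end=1.0e-5, output_every=2),
                       state=state)
        e = hist.energy_frame()
        drift = np.abs(e["total_J"] - e["total_J"].iloc[0]).max()
        assert drift < 0.01 * e["kinetic_J"].max()

    def test_momentum_conserved_through_contact(self, tiny_mesh, default_lib):
        from osseoimpact import pipeline

        imp = pipeline.place_impactor(
            pipeline.LoadCondition(4.0, 0.0), tiny_mesh
        )
        model = fem.build_model(tiny_mesh, default_lib, impactor=imp,
                                fixed_set=None)
        hist = fem.run(model, TimeIntegrationParams(t_end=3e-4, output_every=100))
        s = hist.final_state
        assert s.impactor_touched
        p0 = imp.mass * imp.velocity
        p1 = (model.mass[:, None] * s.vel).sum(axis=0) + imp.mass * s.impactor_velocity
        assert np.linalg.norm(p1 - p0) < 0.005 * np.linalg.norm(p0)


class TestDeactivatedElements:
    def test_inactive_elements_silent(self, tiny_mesh, default_lib):
        rng = np.random.default_rng(11)
        disp = rng.normal(0, 1e-6, (tiny_mesh.n_nodes, 3))
        active = np.ones(tiny_mesh.n_elements, dtype=bool)
        dead = rng.choice(tiny_mesh.n_elements, 50, replace=False)
        active[dead] = False
        model = fem.build_model_nocontact(tiny_mesh, default_lib)
        f, sig, eps, vm, se, _ = fem._compute(
            model, disp, np.zeros_like(disp), active
        )
        assert np.all(sig[dead] == 0) and np.all(vm[dead] == 0)

    def test_kernel_matches_numpy_reference(self, tiny_mesh, default_lib):
        """Compiled hot-loop kernel agrees with the plain numpy assembly."""
        from osseoimpact import _kernel

        rng = np.random.default_rng(12)
        disp = rng.normal(0, 1e-6, (tiny_mesh.n_nodes, 3))
        vel = rng.normal(0, 1e-2, (tiny_mesh.n_nodes, 3))
        active = rng.random(tiny_mesh.n_elements) > 0.1
        model = fem.build_model_nocontact(tiny_mesh, default_lib)
        args = (
            tiny_mesh.tets, model.G, model.V, model.lam, model.mu, model.visc,
            disp, vel, active,
        )
        f_ref, sig_ref, _, vm_ref, se_ref, pv_ref = _kernel._compute_numpy(*args)
        f, sig, _, vm, se, pv = _kernel.compute(*args)
        assert np.allclose(f, f_ref, rtol=1e-12, atol=1e-20)
        assert np.allclose(sig, sig_ref, rtol=1e-12, atol=1e-6)
        assert np.allclose(vm, vm_ref, rtol=1e-12, atol=1e-6)
        assert se == pytest.approx(se_ref, rel=1e-12)
        assert pv == pytest.approx(pv_ref, rel=1e-10)
        assert pv >= 0.0
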