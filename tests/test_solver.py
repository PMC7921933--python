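import numpy as np
import pytest
from scipy.optimize import brentq

from punctfem import (
    DomainSpec,
    MaterialParams,
    ProbeSpec,
    SolverConfig,
    build_mesh,
    table_params,
)
from punctfem.material import bilinear_stress
from punctfem.solver import (
    FieldState,
    IPState,
    contact_update,
    erode_elements,
    radial_return,
    solve_explicit,
    solve_quasi_static,
    stable_time_step,
)

MICRO_SPEC = DomainSpec(radius=5.0, depth=6.0, skin_thickness=1.0, probe_radius=1.0)


def micro_mesh():
    return build_mesh(MICRO_SPEC, target_h=0.5, refinement_ratio=2.0)


@pytest.fixture(scope="module")
def avg_micro_run(avg_materials):
    """One quasi-static puncture of the micro model at average material levels."""
    res = solve_quasi_static(micro_mesh(), avg_materials,
                             ProbeSpec(velocity=1.5, max_insertion=2.0),
                             SolverConfig(increment=0.02))
    assert res.converged
    return res


def uniaxial_trace(p, axial_strains):
    """Strain-driven uniaxial tension: lateral strain iterated so lateral stress = 0."""
    state = IPState(eps=np.zeros(4), eps_p=np.zeros(4), ebar_p=0.0, stress=np.zeros(4))
    prev_ax = prev_lat = 0.0
    out = []
    for ez in axial_strains:
        def lat_resid(lat_total):
            deps = np.array([lat_total - prev_lat, ez - prev_ax, lat_total - prev_lat, 0.0])
            return radial_return(deps, state, p).stress[0]

        lat = brentq(lat_resid, -1.0, 0.5, xtol=1e-15)
        deps = np.array([lat - prev_lat, ez - prev_ax, lat - prev_lat, 0.0])
        state = radial_return(deps, state, p)
        out.append(state.stress[1])
        prev_ax, prev_lat = ez, lat
    return np.array(out), state


class TestRadialReturn:
    def test_uniaxial_trace_matches_bilinear_law(self):
        p = MaterialParams(E=6.0, sigma_y=2.5, Et=0.03, nu=0.3, rho=1100)
        eps = np.linspace(0, 0.8, 41)[1:]
        sig, _ = uniaxial_trace(p, eps)
        np.testing.assert_allclose(sig, bilinear_stress(eps, p), atol=1e-8)

    def test_perfect_plasticity_caps_at_yield(self):
        p = MaterialParams(E=6.0, sigma_y=2.5, Et=0.0, nu=0.3, rho=1100)
        sig, _ = uniaxial_trace(p, np.linspace(0.1, 0.8, 15))
        assert sig.max() <= 2.5 + 1e-8
        assert sig[-1] == pytest.approx(2.5, abs=1e-8)

    def test_elastic_degenerate_limit(self):
        # Et = E with a non-yielding sigma_y behaves exactly elastically
        p = MaterialParams(E=6.0, sigma_y=np.inf, Et=6.0, nu=0.3, rho=1100)
        pe = MaterialParams(E=6.0, sigma_y=1e12, Et=0.0, nu=0.3, rho=1100)
        eps = np.linspace(0.05, 0.6, 10)
        sig, state = uniaxial_trace(p, eps)
        np.testing.assert_allclose(sig, 6.0 * eps, rtol=1e-10)
        assert state.ebar_p == 0.0
        sig_e, _ = uniaxial_trace(pe, eps)
        np.testing.assert_allclose(sig, sig_e, rtol=1e-10)

    def test_zero_increment_is_identity(self):
        p = table_params("skin", "avg")
        state = IPState(eps=np.zeros(4), eps_p=np.zeros(4), ebar_p=0.0, stress=np.zeros(4))
        state = radial_return(np.array([0.0, 0.5, 0.0, 0.0]), state, p)
        again = radial_return(np.zeros(4), state, p)
        np.testing.assert_allclose(again.stress, state.stress, rtol=0, atol=1e-14)
        assert again.ebar_p == state.ebar_p

    def test_plastic_strain_monotone_and_isochoric(self):
        p = table_params("skin", "avg")
        state = IPState(eps=np.zeros(4), eps_p=np.zeros(4), ebar_p=0.0, stress=np.zeros(4))
        ebar_prev = 0.0
        for ez in np.linspace(0.1, 1.0, 10):
            state = radial_return(np.array([0.0, 0.1, 0.0, 0.0]), state, p)
            assert state.ebar_p >= ebar_prev
            ebar_prev = state.ebar_p
            assert abs(state.eps_p[:3].sum()) < 1e-12  # plastic flow is volume-preserving
        assert state.ebar_p > 0

    def test_nonfinite_increment_rejected(self):
        from punctfem.solver import NumericalStateError

        p = table_params("skin", "avg")
        state = IPState(eps=np.zeros(4), eps_p=np.zeros(4), ebar_p=0.0, stress=np.zeros(4))
        with pytest.raises(NumericalStateError):
            radial_return(np.array([np.nan, 0, 0, 0]), state, p)


class TestElasticOracles:
    def test_uniaxial_patch_test(self):
        # column under uniform compression: F = E*A*delta/L, exact for any mesh
        spec = DomainSpec(radius=2.0, depth=4.0, skin_thickness=1.0, probe_radius=1.0)
        mesh = build_mesh(spec, target_h=0.5, refinement_ratio=1.0)
        mat = MaterialParams(E=2.0, sigma_y=1e9, Et=0.0, nu=0.0, rho=1000)
        probe = ProbeSpec(radius=5.0, velocity=1.0, max_insertion=0.04)  # covers the whole face
        cfg = SolverConfig(penalty_scale=1e6, increment=0.01, newton_tol=1e-9,
                           bottom_fixed=False, outer_radial_fixed=False)
        res = solve_quasi_static(mesh, {"skin": mat, "flesh": mat}, probe, cfg)
        exact = mat.E * np.pi * spec.radius**2 * probe.max_insertion / spec.depth
        assert res.curve.forces[-1] == pytest.approx(exact, rel=1e-6)

    def test_sneddon_flat_punch_stiffness(self):
        # rigid flat punch on an elastic half-space: F = 2 E/(1-nu^2) a delta
        spec = DomainSpec(radius=30.0, depth=40.0, skin_thickness=1.0, probe_radius=1.0)
        mesh = build_mesh(spec, target_h=0.125, refinement_ratio=16.0)
        mat = MaterialParams(E=2.0, sigma_y=1e9, Et=0.0, nu=0.3, rho=1000)
        probe = ProbeSpec(radius=1.0, velocity=1.0, max_insertion=0.05)
        res = solve_quasi_static(mesh, {"skin": mat, "flesh": mat}, probe,
                                 SolverConfig(increment=0.025, newton_tol=1e-9))
        exact = 2.0 * mat.E / (1 - mat.nu**2) * probe.radius * probe.max_insertion
        assert res.curve.forces[-1] == pytest.approx(exact, rel=0.10)


class TestContact:
    def test_no_penetration_no_force(self, avg_materials):
        mesh = micro_mesh()
        state = FieldState.zero(mesh)
        f, nodes, pen, reaction = contact_update(0.0, mesh, state,
                                                 ProbeSpec(radius=1.0), penalty=100.0)
        assert nodes.size > 0
        assert reaction == 0.0
        assert np.all(f == 0.0)
        assert np.all(pen == 0.0)

    def test_uniform_penetration_reaction(self):
        mesh = micro_mesh()
        state = FieldState.zero(mesh)
        d = 0.1
        f, nodes, pen, reaction = contact_update(d, mesh, state,
                                                 ProbeSpec(radius=1.0), penalty=50.0)
        np.testing.assert_allclose(pen, d)
        assert reaction == pytest.approx(50.0 * d * nodes.size)
        # force acts downward on the z-dofs of the candidate nodes only
        np.testing.assert_allclose(f[2 * nodes + 1], -50.0 * d, rtol=1e-12)
        mask = np.ones(f.size, dtype=bool)
        mask[2 * nodes + 1] = False
        assert np.all(f[mask] == 0.0)

    def test_candidates_under_footprint_only(self):
        mesh = micro_mesh()
        state = FieldState.zero(mesh)
        _, nodes, _, _ = contact_update(0.0, mesh, state, ProbeSpec(radius=1.0), 1.0)
        assert np.all(mesh.nodes[nodes, 0] <= 1.0 + 1e-9)
        assert np.all(np.isclose(mesh.nodes[nodes, 1], MICRO_SPEC.depth))

    def test_erosion_exposes_lower_surface(self):
        mesh = micro_mesh()
        state = FieldState.zero(mesh)
        # erode the top element row under the footprint
        xy = mesh.nodes[mesh.elems]
        r_mid, z_mid = xy[..., 0].mean(axis=1), xy[..., 1].mean(axis=1)
        top_row = (z_mid > MICRO_SPEC.depth - 0.5) & (r_mid < 1.0)
        state.active[np.flatnonzero(top_row)] = False
        _, nodes, _, _ = contact_update(0.0, mesh, state, ProbeSpec(radius=1.0), 1.0)
        z = mesh.nodes[nodes, 1]
        # the exposed candidates now sit one element row down
        assert np.any(np.isclose(z, MICRO_SPEC.depth - 0.5))

    def test_negative_depth_rejected(self):
        mesh = micro_mesh()
        with pytest.raises(ValueError):
            contact_update(-0.1, mesh, FieldState.zero(mesh), ProbeSpec(radius=1.0), 1.0)


class TestErosion:
    def test_closed_threshold_and_permanence(self):
        mesh = micro_mesh()
        state = FieldState.zero(mesh)
        cfg = SolverConfig(eps_p_max=0.5)
        state.ebar_p[3, 0] = 0.5  # exactly at the threshold -> erodes
        state.ebar_p[5, 0] = 0.499
        state.stress[3] = 1.0
        newly = erode_elements(state, cfg)
        assert list(newly) == [3]
        assert not state.active[3]
        assert state.active[5]
        assert np.all(state.stress[3] == 0.0)
        # already-eroded elements are not reported again
        assert erode_elements(state, cfg).size == 0


class TestQuasiStaticDriver:
    def test_bioyield_with_erosion_on_micro_model(self, avg_micro_run):
        res = avg_micro_run
        f = res.curve.forces
        assert len(res.erosion_history) > 0
        peak = f.max()
        assert peak > 5.0
        assert f[-1] < peak  # post-rupture force drop
        assert res.curve.depths[0] == 0.0 and f[0] == 0.0

    def test_energy_bookkeeping(self, avg_micro_run):
        d = avg_micro_run.dissipated_energy
        assert d.min() >= -1e-9
        assert np.diff(d).min() >= -1e-5  # dissipation never decreases
        assert d[-1] > 0  # plasticity + erosion dissipated energy

    def test_deterministic(self, avg_materials):
        def run():
            return solve_quasi_static(micro_mesh(), avg_materials,
                                      ProbeSpec(velocity=1.5, max_insertion=1.0),
                                      SolverConfig(increment=0.05))
        a, b = run(), run()
        np.testing.assert_array_equal(a.curve.forces, b.curve.forces)

    def test_stop_after_drop_truncates(self, avg_materials):
        res = solve_quasi_static(micro_mesh(), avg_materials,
                                 ProbeSpec(velocity=1.5, max_insertion=6.0),
                                 SolverConfig(increment=0.02, stop_after_drop=0.3))
        assert res.curve.depths[-1] < 6.0
        assert res.curve.forces[-1] < 0.7 * res.curve.forces.max() + 1e-9

    def test_velocity_sets_time_axis_only(self, avg_materials):
        kw = dict(max_insertion=1.0)
        cfg = SolverConfig(increment=0.05)
        r1 = solve_quasi_static(micro_mesh(), avg_materials, ProbeSpec(velocity=1.5, **kw), cfg)
        r2 = solve_quasi_static(micro_mesh(), avg_materials, ProbeSpec(velocity=2.5, **kw), cfg)
        np.testing.assert_array_equal(r1.curve.forces, r2.curve.forces)
        np.testing.assert_allclose(r1.curve.times * 1.5, r2.curve.times * 2.5)

    def test_mesh_refinement_consistency(self, avg_materials):
        # pre-bioyield force at 1 mm within 5% between the shipped and a halved mesh
        forces = []
        for h, ratio in ((0.5, 4.0), (0.25, 8.0)):
            mesh = build_mesh(DomainSpec(), target_h=h, refinement_ratio=ratio)
            res = solve_quasi_static(mesh, avg_materials,
                                     ProbeSpec(velocity=1.5, max_insertion=1.0),
                                     SolverConfig(increment=0.02))
            forces.append(res.curve.forces[-1])
        assert abs(forces[1] - forces[0]) / forces[1] < 0.05


class TestExplicitDriver:
    def test_stable_time_step_formula(self):
        # 1 mm element of the mid-level skin: dt = 0.9 * h / sqrt(E/rho)
        dt = stable_time_step(1.0, 6.0, 1.1e-9)
        assert dt == pytest.approx(0.9 / np.sqrt(6.0 / 1.1e-9), rel=1e-12)
        assert dt == pytest.approx(1.22e-5, rel=0.01)
        # halving the element halves the step
        assert stable_time_step(0.5, 6.0, 1.1e-9) == pytest.approx(dt / 2)

    def test_zero_velocity_zero_force(self, avg_materials):
        res = solve_explicit(micro_mesh(), avg_materials,
                             ProbeSpec(velocity=0.0, max_insertion=1.0),
                             SolverConfig(mode="explicit", time_scale=500.0))
        assert res.curve.forces.max() == 0.0

    def test_explicit_matches_quasi_static_peak(self, avg_materials, avg_micro_run):
        res = solve_explicit(micro_mesh(), avg_materials,
                             ProbeSpec(velocity=1.5, max_insertion=2.0),
                             SolverConfig(mode="explicit", time_scale=500.0,
                                          damping=3000.0, filter_window=9, record_every=20))
        assert res.converged
        qs_peak = avg_micro_run.curve.forces.max()
        assert res.curve.forces.max() == pytest.approx(qs_peak, rel=0.15)

    def test_explicit_deterministic(self, avg_materials):
        def run():
            return solve_explicit(micro_mesh(), avg_materials,
                                  ProbeSpec(velocity=1.5, max_insertion=0.5),
                                  SolverConfig(mode="explicit", time_scale=500.0,
                                               damping=3000.0, record_every=20))
        a, b = run(), run()
        np.testing.assert_array_equal(a.curve.forces, b.curve.forces)
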