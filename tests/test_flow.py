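"""Transient ALE flow solver: exact solutions, invariants, determinism."""

import numpy as np
import pytest

from asciflow import flow as fl
from asciflow import geometry as geo
from asciflow import kinematics as kin
from asciflow._fem import Assembler


@pytest.fixture(scope="module")
def props():
    return fl.FluidProperties()


def _tiny_preset(amplitude=0.01, n_cycles=1):
    return kin.BreathingPreset(amplitude=amplitude, frequency=0.37,
                               n_cycles=n_cycles)


def _tiny_settings(**kw):
    defaults = dict(steps_per_cycle=20, snapshot_stride=2,
                    max_nonlinear_iterations=2)
    defaults.update(kw)
    return fl.SolverSettings(**defaults)


class TestDefaults:
    def test_ascitic_fluid_properties(self, props):
        assert props.density == pytest.approx(1017.5)
        assert props.dynamic_viscosity == pytest.approx(0.0012)

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            fl.SolverSettings(dt=-1.0)
        with pytest.raises(ValueError):
            fl.SolverSettings(element_pair="q2q1")
        with pytest.raises(ValueError):
            fl.FluidProperties(density=-1.0)


class TestQuiescent:
    def test_no_motion_stays_at_rest(self, coarse_mesh, props):
        solver = fl.FlowSolver(coarse_mesh, props, _tiny_settings())
        state = solver.initial_state()
        w = np.zeros((solver.nV, 2))
        for _ in range(3):
            state = solver.advance(state, coarse_mesh.points, w, 0.05)
            assert np.abs(state.velocity).max() == pytest.approx(0.0,
                                                                 abs=1e-14)
            assert np.ptp(state.pressure) == pytest.approx(0.0, abs=1e-10)

    def test_zero_amplitude_run_quiescent(self, coarse_mesh, coarse_spec,
                                          props):
        pre = _tiny_preset(amplitude=1e-30)
        hist = fl.run_cycles(coarse_mesh, pre, coarse_spec, props,
                             _tiny_settings())
        for s in hist.states:
            assert np.abs(s.velocity).max() < 1e-12


class TestDeterminism:
    def test_identical_configs_identical_histories(self, coarse_mesh,
                                                   coarse_spec, props):
        pre = _tiny_preset()
        h1 = fl.run_cycles(coarse_mesh, pre, coarse_spec, props,
                           _tiny_settings())
        h2 = fl.run_cycles(coarse_mesh, pre, coarse_spec, props,
                           _tiny_settings())
        for a, b in zip(h1.states, h2.states):
            assert np.array_equal(a.velocity, b.velocity)
            assert np.array_equal(a.pressure, b.pressure)


class TestStokesLinearity:
    def test_halving_amplitude_halves_speed(self, coarse_mesh, coarse_spec,
                                            props):
        """With convection disabled the problem is linear in the forcing."""
        settings = _tiny_settings(convection=False)
        h1 = fl.run_cycles(coarse_mesh, _tiny_preset(0.02), coarse_spec,
                           props, settings)
        h2 = fl.run_cycles(coarse_mesh, _tiny_preset(0.01), coarse_spec,
                           props, settings)
        m1 = max(np.abs(s.velocity).max() for s in h1.states)
        m2 = max(np.abs(s.velocity).max() for s in h2.states)
        assert m1 / m2 == pytest.approx(2.0, rel=0.005)


class TestMassCompatibility:
    def test_wall_flux_matches_volume_rate(self, cavity_mesh, cavity_spec):
        """Integral of w.n over the boundary must equal dV/dt, which the
        isovolumetric forcing keeps near zero."""
        pre = kin.preset("regular")
        mm = kin.MeshMotionSolver(cavity_mesh)
        dt = pre.period / 100
        d_prev = np.zeros_like(cavity_mesh.points)
        V = geo.compute_volume(cavity_mesh)
        f = pre.frequency
        for n in (3, 25, 50):
            fields = []
            for t in ((n - 1) * dt, n * dt):
                bf = kin.prescribed_boundary_motion(cavity_mesh, pre,
                                                    cavity_spec.z_ov, t)
                fields.append(mm.solve(bf))
            w = kin.mesh_velocity(fields, dt)
            # the swept-volume identity holds exactly on the mid-step
            # configuration for straight facets moving linearly in time
            mid = cavity_mesh.displaced(
                0.5 * (fields[0].values + fields[1].values))
            normals = mid.facet_normals()
            areas = mid.facet_areas()
            wf = w[mid.boundary_facets].mean(axis=1)
            flux = float((np.einsum("fi,fi->f", wf, normals) * areas).sum())
            assert abs(flux) <= 1e-3 * V * f


class TestDivergenceNorm:
    def test_zero_velocity_zero_by_convention(self, coarse_mesh):
        solver = fl.FlowSolver(coarse_mesh, fl.FluidProperties(),
                               _tiny_settings())
        state = solver.initial_state()
        assert fl.divergence_norm(state, coarse_mesh) == 0.0

    def test_rigid_rotation_divergence_free(self, coarse_mesh):
        solver = fl.FlowSolver(coarse_mesh, fl.FluidProperties(),
                               _tiny_settings())
        state = solver.initial_state()
        asm = Assembler(coarse_mesh, velocity_degree=2)
        vc = asm.vcoords
        state.velocity = np.stack([-vc[:, 1], vc[:, 0]], axis=1)
        assert fl.divergence_norm(state, coarse_mesh) < 1e-12


class TestPeriodicityResidual:
    def test_quiescent_history_zero(self, coarse_mesh):
        hist = fl.FlowHistory(mesh=coarse_mesh, snapshots_per_cycle=4)
        n = coarse_mesh.n_nodes
        for k in range(8):
            hist.states.append(fl.FlowState(
                velocity=np.zeros((n, 2)), pressure=np.zeros(n),
                mesh_displacement=np.zeros((n, 2)),
                mesh_velocity=np.zeros((n, 2)), time=0.1 * k))
        assert fl.periodicity_residual(hist) == 0.0

    def test_copied_cycle_exactly_periodic(self, coarse_mesh, coarse_spec,
                                           props):
        pre = _tiny_preset(n_cycles=1)
        hist = fl.run_cycles(coarse_mesh, pre, coarse_spec, props,
                             _tiny_settings())
        hist.states = hist.states + [
            fl.FlowState(s.velocity, s.pressure, s.mesh_displacement,
                         s.mesh_velocity, s.time + pre.period)
            for s in hist.states]
        assert fl.periodicity_residual(hist) == 0.0

    def test_single_cycle_rejected(self, coarse_mesh, coarse_spec, props):
        pre = _tiny_preset(n_cycles=1)
        hist = fl.run_cycles(coarse_mesh, pre, coarse_spec, props,
                             _tiny_settings())
        with pytest.raises(ValueError, match="2 full cycles"):
            fl.periodicity_residual(hist)


class TestDiagnostics:
    def test_reynolds_scales_with_amplitude(self, coarse_mesh, props):
        d1 = fl.diagnostics(coarse_mesh, _tiny_preset(0.02), props)
        d2 = fl.diagnostics(coarse_mesh, _tiny_preset(0.04), props)
        assert d2["reynolds"] == pytest.approx(2 * d1["reynolds"])
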