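"""Wall traction recovery, tangential projection, and cycle metrics."""

import json

import numpy as np
import pytest

from asciflow import flow as fl
from asciflow import geometry as geo
from asciflow import wss
from asciflow._fem import Assembler


@pytest.fixture(scope="module")
def props():
    return fl.FluidProperties()


@pytest.fixture(scope="module")
def channel():
    return geo.build_channel_mesh(0.004, 0.001, 16, 8)


def _fixture_state(mesh, velocity, pressure):
    """FlowState without solver reactions (exercises the assembly path)."""
    asm = Assembler(mesh, velocity_degree=2)
    n = mesh.n_nodes
    u = np.zeros((asm.V.ndof, 2))
    u[:] = velocity(asm.V.dof_coords(mesh.points))
    return fl.FlowState(
        velocity=u, pressure=pressure * np.ones(n),
        mesh_displacement=np.zeros((n, 2)),
        mesh_velocity=np.zeros((asm.V.ndof, 2)), time=0.0)


class TestWallTraction:
    @staticmethod
    def _interior(channel, asm_deg_coords, ids):
        """Mask excluding the patch-corner nodes, whose averaged normals mix
        two wall orientations."""
        L = channel.points[:, 0].max()
        x = asm_deg_coords[ids, 0]
        return (x > 0.05 * L) & (x < 0.95 * L)

    def test_hydrostatic_traction_is_minus_p_n(self, channel, props):
        p0 = 7.5
        state = _fixture_state(channel, lambda xy: 0.0, p0)
        ids, traction, normals = wss.wall_traction(state, channel, "floor",
                                                   props)
        vc = Assembler(channel, 2).vcoords
        sel = self._interior(channel, vc, ids)
        # floor normal is (0, -1): sigma.n = -p0 n = (0, p0)
        assert np.allclose(traction[sel, 0], 0.0, atol=1e-10 * p0)
        assert np.allclose(traction[sel, 1], p0, rtol=1e-8)

    def test_uniform_shear_wall_traction(self, channel, props):
        """u = (gdot y, 0): tangential traction mu*gdot; with the ascitic
        viscosity and gdot = 100/s this is 0.12 Pa = 1.2 dynes/cm^2."""
        gdot = 100.0
        state = _fixture_state(
            channel, lambda xy: np.stack(
                [gdot * xy[:, 1], np.zeros(len(xy))], axis=1), 0.0)
        field = wss.wss_field(state, channel, "floor", props)
        vc = Assembler(channel, 2).vcoords
        sel = self._interior(channel, vc, field.node_ids)
        assert np.allclose(field.magnitude_pa[sel], 0.12, rtol=1e-8)
        assert np.allclose(field.magnitude_dyn_cm2[sel], 1.2, rtol=1e-8)

    def test_absent_patch_rejected(self, channel, props):
        state = _fixture_state(channel, lambda xy: 0.0, 0.0)
        with pytest.raises(KeyError, match="ovary"):
            wss.wall_traction(state, channel, "ovary_left", props)

    def test_pressure_constant_leaves_wss_unchanged(self, channel, props):
        gdot = 50.0

        def vel(xy):
            return np.stack([gdot * xy[:, 1], np.zeros(len(xy))], axis=1)

        f1 = wss.wss_field(_fixture_state(channel, vel, 0.0), channel,
                           "floor", props)
        f2 = wss.wss_field(_fixture_state(channel, vel, 123.456), channel,
                           "floor", props)
        assert np.allclose(f1.tau, f2.tau, atol=1e-12)


class TestWallShear:
    def test_purely_normal_traction_no_shear(self):
        n = np.array([[0.0, 1.0], [1.0, 0.0]])
        t = 5.0 * n
        assert np.allclose(wss.wall_shear(t, n), 0.0)

    def test_tangency_invariant(self):
        rng = np.random.default_rng(11)
        t = rng.normal(size=(40, 2))
        ang = rng.uniform(0, 2 * np.pi, 40)
        n = np.stack([np.cos(ang), np.sin(ang)], axis=1)
        tau = wss.wall_shear(t, n)
        assert np.abs(np.einsum("ij,ij->i", tau, n)).max() < 1e-8 * (
            np.abs(tau).max() + 1e-30)

    def test_non_unit_normals_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            wss.wall_shear(np.ones((3, 2)), 2.0 * np.ones((3, 2)))


class TestPatchMetrics:
    def _field(self, channel, mag, t):
        ids = Assembler(channel, 2).V.boundary_dofs("floor")
        n = np.tile([0.0, -1.0], (len(ids), 1))
        tau = np.zeros((len(ids), 2))
        tau[:, 0] = mag / wss.PA_TO_DYN_CM2
        return wss.WSSField(ids, tau, n, t, "floor")

    def test_constant_field_mean_equals_peak(self, channel):
        fields = [self._field(channel, 2.5, t) for t in (0.0, 0.1, 0.2)]
        pm = wss.patch_metrics(fields, channel, "floor")
        assert pm.mean_fss == pytest.approx(2.5)
        assert pm.peak_fss == pytest.approx(2.5)

    def test_sin_squared_time_average(self, channel):
        c, f = 4.0, 1.0
        times = np.linspace(0, 1.0, 400, endpoint=False)
        fields = [self._field(channel, c * np.sin(2 * np.pi * f * t) ** 2, t)
                  for t in times]
        pm = wss.patch_metrics(fields, channel, "floor")
        assert pm.mean_fss == pytest.approx(c / 2, rel=1e-3)
        assert pm.peak_fss == pytest.approx(c, rel=1e-3)

    def test_peak_not_below_mean(self, channel):
        rng = np.random.default_rng(0)
        fields = [self._field(channel, rng.uniform(0, 5), t)
                  for t in np.linspace(0, 1, 7)]
        pm = wss.patch_metrics(fields, channel, "floor")
        assert pm.peak_fss >= pm.mean_fss >= 0.0

    def test_empty_patch_rejected(self, channel):
        with pytest.raises(ValueError):
            wss.patch_metrics([], channel, "floor")


class TestVelocityMetrics:
    def _history(self, mesh, states):
        return fl.FlowHistory(mesh=mesh, states=states,
                              snapshots_per_cycle=len(states))

    def test_quiescent_metrics_zero(self, coarse_mesh):
        asm = Assembler(coarse_mesh, 2)
        n = coarse_mesh.n_nodes
        states = [fl.FlowState(np.zeros((asm.V.ndof, 2)), np.zeros(n),
                               np.zeros((n, 2)), np.zeros((asm.V.ndof, 2)),
                               float(t)) for t in range(3)]
        mean, peak = wss.velocity_metrics(self._history(coarse_mesh, states),
                                          coarse_mesh)
        assert mean == 0.0 and peak == 0.0

    def test_uniform_speed_one_cm_s(self, coarse_mesh):
        asm = Assembler(coarse_mesh, 2)
        n = coarse_mesh.n_nodes
        u = np.zeros((asm.V.ndof, 2))
        u[:, 0] = 0.01  # 1 cm/s
        states = [fl.FlowState(u, np.zeros(n), np.zeros((n, 2)),
                               np.zeros((asm.V.ndof, 2)), float(t))
                  for t in range(2)]
        mean, peak = wss.velocity_metrics(self._history(coarse_mesh, states),
                                          coarse_mesh)
        assert mean == pytest.approx(1.0, rel=1e-10)
        assert peak == pytest.approx(1.0, rel=1e-10)


class TestSummary:
    def test_units_are_factor_ten(self):
        tau = np.array([[0.3, 0.0]])
        n = np.array([[0.0, 1.0]])
        f = wss.WSSField(np.array([0]), tau, n, 0.0, "x")
        assert f.magnitude_dyn_cm2 == pytest.approx(10 * f.magnitude_pa)

    def test_summary_json_roundtrip(self, coarse_mesh, coarse_spec, props):
        from asciflow import kinematics as kin
        pre = kin.BreathingPreset(amplitude=0.01, frequency=0.37, n_cycles=1)
        hist = fl.run_cycles(coarse_mesh, pre, coarse_spec, props,
                             fl.SolverSettings(steps_per_cycle=20,
                                               snapshot_stride=2))
        summary = wss.summarize(hist, coarse_mesh)
        blob = summary.to_json()
        back = json.loads(blob)
        assert back["mean_speed_cm_s"] == summary.mean_speed_cm_s
        assert set(back["patches"]) == {"ovary_left", "ovary_right"}
        for pm in summary.patches.values():
            assert pm.peak_fss >= pm.mean_fss >= 0.0

    def test_config_digest_changes_iff_content_changes(self):
        a = {"x": 1, "nested": {"b": 2, "a": 1}}
        b = {"nested": {"a": 1, "b": 2}, "x": 1}  # reordered only
        c = {"x": 1, "nested": {"b": 2, "a": 1.0001}}
        assert wss.config_digest(a) == wss.config_digest(b)
        assert wss.config_digest(a) != wss.config_digest(c)
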