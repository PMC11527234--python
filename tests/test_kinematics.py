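"""Breathing presets, boundary forcing, isovolumetry and mesh motion."""

import numpy as np
import pytest

from asciflow import geometry as geo
from asciflow import kinematics as kin


class TestPresets:
    def test_regular_parameters(self):
        p = kin.preset("regular")
        assert p.amplitude == pytest.approx(0.060)
        assert p.frequency == pytest.approx(0.37)

    def test_active_parameters(self):
        p = kin.preset("active")
        assert p.amplitude == pytest.approx(0.080)
        assert p.frequency == pytest.approx(1.0)

    def test_three_cycles_default(self):
        assert kin.preset("regular").n_cycles == 3
        assert kin.preset("active").n_cycles == 3

    def test_unknown_preset_lists_valid_names(self):
        with pytest.raises(ValueError, match="regular"):
            kin.preset("panting")

    def test_raised_cosine_starts_at_rest(self):
        p = kin.preset("regular")
        assert p.shape(0.0) == 0.0
        assert p.shape(0.5 * p.period) == pytest.approx(1.0)


class TestVerticalProfile:
    def test_endpoints_and_midpoint(self):
        assert kin.vertical_profile(0.4, 0.05, 0.4) == 1.0
        assert kin.vertical_profile(0.05, 0.05, 0.4) == 0.0
        assert kin.vertical_profile(0.225, 0.05, 0.4) == pytest.approx(0.5)

    def test_clamped_below_ovaries(self):
        assert kin.vertical_profile(-1.0, 0.05, 0.4) == 0.0
        assert kin.vertical_profile(0.02, 0.05, 0.4) == 0.0

    def test_degenerate_heights_rejected(self):
        with pytest.raises(ValueError):
            kin.vertical_profile(0.1, 0.4, 0.05)


class TestBoundaryDisplacement:
    def test_zero_at_start(self, cavity_mesh, cavity_spec):
        f = kin.boundary_displacement(cavity_mesh, kin.preset("regular"),
                                      cavity_spec.z_ov, 0.0)
        assert np.all(f.values == 0.0)

    def test_full_amplitude_at_half_period(self, cavity_mesh, cavity_spec):
        p = kin.preset("regular")
        f = kin.boundary_displacement(cavity_mesh, p, cavity_spec.z_ov,
                                      0.5 * p.period)
        top = cavity_mesh.points[f.node_ids, 1] > \
            cavity_mesh.points[:, 1].max() - 1e-12
        assert np.abs(f.values[top, 1]).max() == pytest.approx(0.060)

    def test_stationary_at_and_below_ovary_height(self, cavity_mesh,
                                                  cavity_spec):
        p = kin.preset("active")
        for t in (0.1, 0.3, 0.7):
            f = kin.prescribed_boundary_motion(cavity_mesh, p,
                                               cavity_spec.z_ov, t * p.period)
            low = cavity_mesh.points[f.node_ids, 1] <= cavity_spec.z_ov + 1e-12
            assert np.abs(f.values[low]).max() < 1e-14

    def test_periodicity(self, cavity_mesh, cavity_spec):
        p = kin.preset("regular")
        f1 = kin.boundary_displacement(cavity_mesh, p, cavity_spec.z_ov, 0.3)
        f2 = kin.boundary_displacement(cavity_mesh, p, cavity_spec.z_ov,
                                       0.3 + p.period)
        assert np.allclose(f1.values, f2.values, atol=1e-12)

    def test_amplitude_linearity_before_compensation(self, cavity_mesh,
                                                     cavity_spec):
        p1 = kin.BreathingPreset(amplitude=0.02, frequency=0.37)
        p2 = kin.BreathingPreset(amplitude=0.04, frequency=0.37)
        f1 = kin.boundary_displacement(cavity_mesh, p1, cavity_spec.z_ov, 0.4)
        f2 = kin.boundary_displacement(cavity_mesh, p2, cavity_spec.z_ov, 0.4)
        assert np.allclose(f2.values, 2.0 * f1.values, atol=1e-15)


class TestVolumeCompensation:
    def test_zero_vertical_gives_zero_compensation(self, cavity_mesh,
                                                   cavity_spec):
        zero = kin.DisplacementField(
            np.zeros((len(cavity_mesh.boundary_node_ids()), 2)), 0.0,
            cavity_mesh.boundary_node_ids())
        comp = kin.volume_compensation(cavity_mesh, zero, cavity_spec.z_ov)
        assert np.all(comp.values == 0.0)

    def test_piston_first_order_magnitude(self):
        """Small uniform piston displacement on a box: the compensation
        magnitude approaches deficit / effective lateral area."""
        x = np.linspace(-0.1, 0.1, 9)
        z = np.linspace(0.0, 0.2, 9)
        mesh = geo.structured_rectangle(x, z, patch_fn=_box_patches)
        ids = mesh.boundary_node_ids()
        delta = 1e-5
        vals = np.zeros((len(ids), 2))
        top = mesh.points[ids, 1] > 0.2 - 1e-12
        vals[top, 1] = -delta
        field = kin.DisplacementField(vals, 0.0, ids)
        comp = kin.volume_compensation(mesh, field, z_ov=1e-9)
        # deficit = delta * width; effective lateral area = 2 * height * <phi>
        expected = delta * 0.2 / (2 * 0.2 * 0.5)
        got = np.abs(comp.values[:, 0]).max()
        assert got == pytest.approx(expected, rel=0.05)

    def test_isovolumetry_through_full_cycle(self, cavity_mesh, cavity_spec):
        p = kin.preset("regular")
        mm = kin.MeshMotionSolver(cavity_mesh)
        V0 = geo.compute_volume(cavity_mesh)
        for t in np.linspace(0, p.period, 9):
            bf = kin.prescribed_boundary_motion(cavity_mesh, p,
                                                cavity_spec.z_ov, t)
            d = mm.solve(bf)
            V = geo.compute_volume(cavity_mesh.displaced(d.values))
            assert abs(V - V0) / V0 <= 1e-3


def _box_patches(side, mid):
    return {"floor": "floor", "top": "diaphragm", "left": "lateral",
            "right": "lateral"}[side]


class TestMeshMotion:
    def test_zero_boundary_zero_interior(self, coarse_mesh):
        ids = coarse_mesh.boundary_node_ids()
        f = kin.DisplacementField(np.zeros((len(ids), 2)), 0.0, ids)
        d = kin.solve_mesh_motion(coarse_mesh, f)
        assert np.abs(d.values).max() == 0.0

    def test_uniform_translation_propagates(self, coarse_mesh):
        ids = coarse_mesh.boundary_node_ids()
        shift = np.array([0.01, -0.02])
        f = kin.DisplacementField(np.tile(shift, (len(ids), 1)), 0.0, ids)
        d = kin.solve_mesh_motion(coarse_mesh, f)
        assert np.allclose(d.values, shift, atol=1e-10)

    def test_linear_field_reproduced(self, coarse_mesh):
        """Linear Dirichlet data has constant strain, hence satisfies the
        homogeneous equilibrium equations exactly (stiffening disabled)."""
        rng = np.random.default_rng(3)
        A = 0.05 * rng.normal(size=(2, 2))
        ids = coarse_mesh.boundary_node_ids()
        f = kin.DisplacementField(coarse_mesh.points[ids] @ A.T, 0.0, ids)
        settings = kin.MeshMotionSettings(stiffening_exponent=0.0)
        d = kin.solve_mesh_motion(coarse_mesh, f, settings)
        exact = coarse_mesh.points @ A.T
        assert np.abs(d.values - exact).max() < 1e-10

    def test_inversion_reported_with_advice(self, coarse_mesh):
        ids = coarse_mesh.boundary_node_ids()
        vals = np.zeros((len(ids), 2))
        top = coarse_mesh.points[ids, 1] > \
            coarse_mesh.points[:, 1].max() - 1e-9
        vals[top, 1] = -0.39  # push the diaphragm nearly to the floor
        f = kin.DisplacementField(vals, 0.0, ids)
        with pytest.raises(RuntimeError, match="stiffening_exponent"):
            kin.solve_mesh_motion(coarse_mesh, f)


class TestMeshVelocity:
    def test_constant_displacement_zero_velocity(self):
        d = [kin.DisplacementField(np.ones((5, 2)), t, None)
             for t in (0.0, 0.1)]
        w = kin.mesh_velocity(d, 0.1)
        assert np.all(w == 0.0)

    def test_bdf1_exact_for_linear(self):
        c = np.array([0.3, -0.2])
        d = [kin.DisplacementField(c * t, t, None) for t in (0.0, 0.1)]
        w = kin.mesh_velocity(d, 0.1, "backward_difference_1")
        assert np.allclose(w, c, atol=1e-14)

    def test_bdf2_exact_for_quadratic(self):
        c = np.array([[0.5, -1.0]])
        times = [0.0, 0.1, 0.2]
        d = [kin.DisplacementField(c * t * t, t, None) for t in times]
        w = kin.mesh_velocity(d, 0.1, "backward_difference_2")
        # d/dt (c t^2) at t = 0.2 is 0.4 c
        assert np.allclose(w, 0.4 * c, atol=1e-13)

    def test_insufficient_history_rejected(self):
        d = [kin.DisplacementField(np.zeros((3, 2)), 0.0, None)]
        with pytest.raises(ValueError, match="2 displacement levels"):
            kin.mesh_velocity(d, 0.1)
        with pytest.raises(ValueError, match="3 displacement levels"):
            kin.mesh_velocity(d * 2, 0.1, "backward_difference_2")
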