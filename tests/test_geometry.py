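"""Mesh generation, volume bookkeeping, refinement and quality checks."""

import numpy as np
import pytest

from asciflow import geometry as geo


class TestComputeVolume:
    def test_unit_cube_volume(self, unit_cube_mesh):
        assert geo.compute_volume(unit_cube_mesh) == pytest.approx(1.0,
                                                                   rel=1e-12)

    def test_unit_square_area(self, unit_square_mesh):
        assert geo.compute_volume(unit_square_mesh) == pytest.approx(1.0,
                                                                     rel=1e-12)

    def test_rigid_translation_invariance(self, unit_cube_mesh):
        v0 = geo.compute_volume(unit_cube_mesh)
        shift = np.array([1.3, -0.7, 2.1])
        moved = unit_cube_mesh.displaced(
            np.tile(shift, (unit_cube_mesh.n_nodes, 1)))
        assert geo.compute_volume(moved) == pytest.approx(v0, rel=1e-12)

    def test_scaling_law_3d(self, unit_cube_mesh):
        v0 = geo.compute_volume(unit_cube_mesh)
        scaled = geo.Mesh(2.0 * unit_cube_mesh.points, unit_cube_mesh.cells,
                          unit_cube_mesh.boundary_facets,
                          unit_cube_mesh.facet_patches, 3)
        assert geo.compute_volume(scaled) == pytest.approx(8.0 * v0,
                                                           rel=1e-10)

    def test_inverted_cell_reported(self, unit_square_mesh):
        cells = unit_square_mesh.cells.copy()
        cells[3, [0, 1]] = cells[3, [1, 0]]
        bad = geo.Mesh(unit_square_mesh.points, cells,
                       unit_square_mesh.boundary_facets,
                       unit_square_mesh.facet_patches, 2)
        with pytest.raises(ValueError, match="3"):
            geo.compute_volume(bad)

    def test_enclosed_volume_matches_cell_sum(self, cavity_mesh):
        v_cells = geo.compute_volume(cavity_mesh)
        v_bnd = geo.enclosed_volume(cavity_mesh.points,
                                    cavity_mesh.boundary_facets, 2)
        assert v_bnd == pytest.approx(v_cells, rel=1e-12)


class TestCavityGeneration:
    def test_all_patches_present(self, cavity_mesh):
        assert set(cavity_mesh.patch_names) == set(geo.CAVITY_PATCHES)

    @pytest.mark.parametrize("dim", [2, 3])
    def test_determinism(self, dim):
        spec = geo.CavitySpec(mesh_size=0.03, z_ov=0.05, dim=dim, seed=7,
                              jitter=0.1 if dim == 2 else 0.0)
        m1 = geo.build_cavity_mesh(spec)
        m2 = geo.build_cavity_mesh(spec)
        assert np.array_equal(m1.points, m2.points)
        assert np.array_equal(m1.cells, m2.cells)

    def test_target_volume_within_2pct(self):
        spec = geo.CavitySpec(dim=3, target_volume=2.5e-3, mesh_size=0.02)
        mesh = geo.build_cavity_mesh(spec)
        vol = geo.compute_volume(mesh)
        assert abs(vol - 2.5e-3) / 2.5e-3 < 0.02

    def test_refinement_level_increases_resolution(self):
        s0 = geo.CavitySpec(mesh_size=0.04, z_ov=0.05, refinement_level=0)
        s1 = geo.CavitySpec(mesh_size=0.04, z_ov=0.05, refinement_level=1)
        m0, m1 = geo.build_cavity_mesh(s0), geo.build_cavity_mesh(s1)
        assert m1.n_cells > m0.n_cells
        assert geo.min_cell_diameter(m1) < geo.min_cell_diameter(m0)

    def test_wall_grading_refines_near_floor_and_top(self):
        plain = geo.build_cavity_mesh(geo.CavitySpec(mesh_size=0.04,
                                                     z_ov=0.05))
        graded = geo.build_cavity_mesh(geo.CavitySpec(mesh_size=0.04,
                                                      z_ov=0.05,
                                                      wall_grading=2.0))

        def first_layer(mesh):
            z = np.unique(np.round(mesh.points[:, 1], 12))
            return z[1] - z[0]

        assert first_layer(graded) < first_layer(plain)
        assert graded.n_cells == plain.n_cells

    def test_mirror_symmetric_grid(self, cavity_mesh):
        xs = np.sort(np.unique(np.round(cavity_mesh.points[:, 0], 12)))
        assert np.allclose(xs, -xs[::-1])

    @pytest.mark.parametrize("kwargs,match", [
        ({"ovary_radius": -0.01}, "positive"),
        ({"z_ov": 1.0}, "z_ov"),
        ({"ovary_centers": ((-0.08, 0, 0.01), (0.08, 0, -0.005))},
         "protrude"),
        ({"ovary_centers": ((-0.08, 0, -0.05), (0.08, 0, -0.005))},
         "protrude"),
    ])
    def test_invalid_specs_rejected(self, kwargs, match):
        with pytest.raises(ValueError, match=match):
            geo.CavitySpec(**kwargs)


class TestRefine:
    def test_identity_at_level_zero(self, cavity_mesh):
        out = geo.refine(cavity_mesh, 0)
        assert out is cavity_mesh

    @pytest.mark.parametrize("fixture,factor",
                             [("unit_square_mesh", 4), ("unit_cube_mesh", 8)])
    def test_subdivision_factor(self, fixture, factor, request):
        mesh = request.getfixturevalue(fixture)
        fine = geo.refine(mesh, 1)
        assert fine.n_cells == factor * mesh.n_cells

    def test_volume_and_patch_areas_preserved(self, cavity_mesh):
        fine = geo.refine(cavity_mesh, 1)
        assert geo.compute_volume(fine) == pytest.approx(
            geo.compute_volume(cavity_mesh), rel=1e-10)
        qa = geo.quality_report(cavity_mesh).boundary_area_by_patch
        qb = geo.quality_report(fine).boundary_area_by_patch
        for patch in qa:
            assert qb[patch] == pytest.approx(qa[patch], rel=1e-10)

    def test_3d_volume_preserved(self, unit_cube_mesh):
        fine = geo.refine(unit_cube_mesh, 1)
        assert geo.compute_volume(fine) == pytest.approx(1.0, rel=1e-10)
        fine.validate()


class TestQualityReport:
    def test_cube_boundary_area(self, unit_cube_mesh):
        qr = geo.quality_report(unit_cube_mesh)
        assert qr.total_boundary_area() == pytest.approx(6.0, rel=1e-10)

    def test_patch_partition_sums_to_total(self, cavity_mesh):
        qr = geo.quality_report(cavity_mesh)
        total = geo._facet_areas(cavity_mesh.points,
                                 cavity_mesh.boundary_facets).sum()
        assert qr.total_boundary_area() == pytest.approx(total, rel=1e-10)
        assert qr.min_cell_volume > 0
        assert qr.n_cells == cavity_mesh.n_cells

    def test_collapsed_cell_rejected(self, unit_square_mesh):
        pts = unit_square_mesh.points.copy()
        cell = unit_square_mesh.cells[0]
        pts[cell[2]] = pts[cell[0]]  # degenerate triangle
        bad = geo.Mesh(pts, unit_square_mesh.cells,
                       unit_square_mesh.boundary_facets,
                       unit_square_mesh.facet_patches, 2)
        with pytest.raises(ValueError):
            geo.quality_report(bad)


class TestOrientation:
    def test_outward_normals(self, cavity_mesh):
        normals = cavity_mesh.facet_normals()
        centroids = cavity_mesh.facet_centroids()
        centre = cavity_mesh.points.mean(axis=0)
        # outward on the convex hull part of the boundary: diaphragm faces +z
        top = cavity_mesh.facets_of("diaphragm")
        assert np.all(normals[top, 1] > 0.99)
        lat = cavity_mesh.facets_of("lateral")
        assert np.all(normals[lat, 0] * (centroids[lat, 0] - centre[0]) > 0)
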