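"""Planes, signed distances, watertight cutting and the two volume routes."""

import numpy as np
import pytest
import trimesh
from hypothesis import given, settings
from hypothesis import strategies as st

from volceph.errors import (
    DegeneratePlaneError,
    MeshIntegrityError,
    OrientationError,
    VoxelBudgetError,
)
from volceph.geometry import (
    Plane,
    cut_mesh,
    mesh_volume,
    plane_fit,
    plane_from_points,
    signed_distance,
    voxel_volume_oracle,
)

from conftest import random_rigid_transform


class TestPlaneConstruction:
    def test_unit_axes(self):
        p = plane_from_points((0, 0, 0), (1, 0, 0), (0, 1, 0),
                              orient_toward=(0, 0, 1))
        assert np.allclose(p.normal, [0, 0, 1])
        assert p.offset == pytest.approx(0.0, abs=1e-12)

    def test_translated_plane(self):
        p = plane_from_points((0, 0, 5), (1, 0, 5), (0, 1, 5))
        assert abs(p.normal[2]) == pytest.approx(1.0)
        assert p.offset * p.normal[2] == pytest.approx(5.0)

    def test_collinear_raises_and_names_points(self):
        with pytest.raises(DegeneratePlaneError, match="2.0"):
            plane_from_points((0, 0, 0), (1, 0, 0), (2, 0, 0))

    def test_fit_coplanar_square(self):
        pts = [(0, 0, 2), (1, 0, 2), (1, 1, 2), (0, 1, 2)]
        p = plane_fit(pts)
        assert abs(p.normal @ [0, 0, 1]) == pytest.approx(1.0, abs=1e-12)
        assert max(abs(p.signed_distance(q)) for q in pts) < 1e-12

    def test_fit_alternating_noise_stays_near_horizontal(self):
        eps = 0.1
        pts = [(0, 0, eps), (1, 0, -eps), (0, 1, eps), (1, 1, -eps)]
        p = plane_fit(pts)
        angle = np.arccos(min(abs(p.normal @ [0, 0, 1]), 1.0))
        assert angle < 0.2

    def test_fit_three_points_reduces_to_exact(self):
        pts = [(0.3, 1.2, -0.7), (2.0, 0.1, 0.5), (-1.0, 0.8, 1.1)]
        a = plane_fit(pts, orient_toward=(0, 0, 10))
        b = plane_from_points(*pts, orient_toward=(0, 0, 10))
        assert np.allclose(a.normal, b.normal, atol=1e-9)
        assert a.offset == pytest.approx(b.offset, abs=1e-9)

    def test_fit_rejects_collinear(self):
        with pytest.raises(DegeneratePlaneError):
            plane_fit([(0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 0, 0)])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_plane_contains_its_points(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(-100, 100, size=(3, 3))
        area = 0.5 * np.linalg.norm(
            np.cross(pts[1] - pts[0], pts[2] - pts[0])
        )
        if area < 1e-6:
            return
        p = plane_from_points(*pts, orient_toward=(0, 0, 200))
        for q in pts:
            assert abs(p.signed_distance(q)) < 1e-9 * max(1.0, np.abs(pts).max())
        assert p.signed_distance((0, 0, 200)) >= 0


class TestSignedDistance:
    def test_above_on_below(self):
        z0 = Plane(np.array([0, 0, 1.0]), 0.0)
        assert signed_distance(z0, (0, 0, 5)) == pytest.approx(5.0)
        assert signed_distance(z0, (3, -2, 0)) == pytest.approx(0.0)
        z5 = Plane(np.array([0, 0, 1.0]), 5.0)
        assert signed_distance(z5, (0, 0, 1)) == pytest.approx(-4.0)


class TestMeshVolume:
    def test_unit_cube_exact(self, unit_cube):
        assert mesh_volume(unit_cube) == pytest.approx(1.0, abs=1e-12)

    def test_icosphere_close_to_analytic(self, icosphere):
        analytic = 4.0 / 3.0 * np.pi * 10.0**3
        assert mesh_volume(icosphere) == pytest.approx(analytic, rel=0.005)

    def test_agrees_with_independent_library_route(self, icosphere, unit_cube):
        for m in (icosphere, unit_cube):
            assert mesh_volume(m) == pytest.approx(float(m.volume), rel=1e-12)

    def test_flipped_face_is_rejected(self, unit_cube):
        faces = unit_cube.faces.copy()
        faces[0] = faces[0][::-1]
        broken = trimesh.Trimesh(
            vertices=unit_cube.vertices.copy(), faces=faces, process=False
        )
        with pytest.raises(MeshIntegrityError):
            mesh_volume(broken)

    def test_inward_mesh_is_rejected(self, unit_cube):
        inward = trimesh.Trimesh(
            vertices=unit_cube.vertices.copy(),
            faces=unit_cube.faces[:, ::-1].copy(),
            process=False,
        )
        with pytest.raises(OrientationError):
            mesh_volume(inward)

    def test_hole_reports_boundary_edges(self, unit_cube):
        holed = trimesh.Trimesh(
            vertices=unit_cube.vertices.copy(),
            faces=unit_cube.faces[1:].copy(),
            process=False,
        )
        with pytest.raises(MeshIntegrityError) as err:
            mesh_volume(holed)
        assert err.value.boundary_edges == 3

    def test_rigid_motion_invariance(self, icosphere):
        v0 = mesh_volume(icosphere)
        rng = np.random.default_rng(11)
        for _ in range(3):
            moved = icosphere.copy()
            moved.apply_transform(random_rigid_transform(rng))
            assert mesh_volume(moved) == pytest.approx(v0, rel=1e-9)


class TestCutMesh:
    def test_cube_cut_at_0_3(self, unit_cube):
        above, below = cut_mesh(unit_cube, Plane(np.array([0, 0, 1.0]), 0.3))
        assert mesh_volume(above) == pytest.approx(0.7, abs=1e-9)
        assert mesh_volume(below) == pytest.approx(0.3, abs=1e-9)

    def test_sphere_halves_analytic(self, icosphere):
        hemis = 0.5 * 4.0 / 3.0 * np.pi * 1000.0
        above, below = cut_mesh(icosphere, Plane(np.array([0, 0, 1.0]), 0.0))
        assert mesh_volume(above) == pytest.approx(hemis, rel=0.005)
        assert mesh_volume(below) == pytest.approx(hemis, rel=0.005)

    def test_plane_missing_mesh(self, unit_cube):
        above, below = cut_mesh(unit_cube, Plane(np.array([0, 0, 1.0]), 5.0))
        assert above is None
        assert mesh_volume(below) == pytest.approx(1.0)

    def test_cut_at_exact_boundary_face(self, unit_cube):
        above, below = cut_mesh(unit_cube, Plane(np.array([0, 0, 1.0]), 0.0))
        assert below is None
        assert mesh_volume(above) == pytest.approx(1.0)

    def test_non_watertight_input_rejected(self, unit_cube):
        holed = trimesh.Trimesh(
            vertices=unit_cube.vertices.copy(),
            faces=unit_cube.faces[1:].copy(),
            process=False,
        )
        with pytest.raises(MeshIntegrityError):
            cut_mesh(holed, Plane(np.array([0, 0, 1.0]), 0.5))

    @pytest.mark.parametrize("seed", range(5))
    def test_additivity_on_random_cuts(self, icosphere, unit_cube, seed):
        """Cut pieces' volumes sum to the original within 1e-6 relative,
        on convex and non-convex (torus) meshes."""
        torus = trimesh.creation.torus(major_radius=10, minor_radius=3)
        rng = np.random.default_rng(100 + seed)
        for mesh in (unit_cube, icosphere, torus):
            total = mesh_volume(mesh)
            extent = np.abs(mesh.bounds).max()
            n = rng.normal(size=3)
            n /= np.linalg.norm(n)
            plane = Plane(n, rng.uniform(-0.8, 0.8) * extent)
            above, below = cut_mesh(mesh, plane)
            va = mesh_volume(above) if above is not None else 0.0
            vb = mesh_volume(below) if below is not None else 0.0
            assert va + vb == pytest.approx(total, rel=1e-6)

    def test_cut_idempotence(self, icosphere):
        plane = Plane(np.array([1.0, 0, 0]), 2.0)
        above, _ = cut_mesh(icosphere, plane)
        again_above, again_below = cut_mesh(above, plane)
        assert again_below is None
        assert mesh_volume(again_above) == pytest.approx(
            mesh_volume(above), rel=1e-9
        )

    def test_torus_annulus_cap(self):
        """Cutting a torus mid-plane produces ring caps with interior holes."""
        torus = trimesh.creation.torus(major_radius=10, minor_radius=3)
        above, below = cut_mesh(torus, Plane(np.array([0, 0, 1.0]), 0.0))
        assert above.is_watertight and below.is_watertight
        total = mesh_volume(torus)
        assert mesh_volume(above) + mesh_volume(below) == pytest.approx(
            total, rel=1e-9
        )


class TestVoxelOracle:
    def test_cube_at_fine_voxel(self, unit_cube):
        assert voxel_volume_oracle(unit_cube, 0.05) == pytest.approx(1.0, rel=0.03)

    def test_sphere_agrees_with_mesh_volume(self, icosphere):
        v_mesh = mesh_volume(icosphere)
        v_vox = voxel_volume_oracle(icosphere, 0.5)
        assert v_vox == pytest.approx(v_mesh, rel=0.02)

    def test_refinement_improves_on_average(self, icosphere):
        v_mesh = mesh_volume(icosphere)
        errs = [
            abs(voxel_volume_oracle(icosphere, h) - v_mesh)
            for h in (2.0, 1.0, 0.5, 0.25)
        ]
        # monotone on average: strictly better end-to-end, at most one bump
        assert errs[-1] < errs[0]
        violations = sum(b >= a for a, b in zip(errs, errs[1:]))
        assert violations <= 1

    def test_cell_budget(self, icosphere):
        with pytest.raises(VoxelBudgetError, match="voxel"):
            voxel_volume_oracle(icosphere, 0.001)

    def test_oracle_vs_mesh_volume_on_random_meshes(self):
        """Two independent volume routes agree within the oracle bound on
        several convex and non-convex meshes."""
        rng = np.random.default_rng(5)
        meshes = [
            trimesh.creation.icosphere(subdivisions=3, radius=r)
            for r in (5.0, 12.0)
        ]
        meshes.append(trimesh.creation.torus(major_radius=8, minor_radius=2.5))
        box = trimesh.creation.box(extents=(7, 13, 5))
        meshes.append(box)
        cap = trimesh.creation.capsule(radius=4, height=10)
        meshes.append(trimesh.Trimesh(cap.vertices, cap.faces, process=False))
        h = 0.4
        for m in meshes:
            m = trimesh.Trimesh(m.vertices, m.faces, process=False)
            m.apply_transform(random_rigid_transform(rng))
            v_mesh = mesh_volume(m)
            v_vox = voxel_volume_oracle(m, h)
            bound = float(m.area) * h  # documented O(area * voxel) bound
            assert abs(v_vox - v_mesh) < bound
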