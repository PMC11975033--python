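import numpy as np
import pytest

from atlastrace.errors import (
    DegenerateGeometryError,
    GridMismatchError,
    UndefinedDenominatorError,
)
from atlastrace.synthetic import ellipsoid_voxel_oracle, ellipsoid_volume_mm3
from atlastrace.volume3d import (
    VoxelSolid,
    laplacian_smooth,
    percent_overlap,
    points_in_mesh,
    triangulate_boundary,
    voxelize,
)

CUBE = np.array([[x, y, z] for x in (0.0, 1000.0) for y in (0.0, 1000.0) for z in (0.0, 1000.0)])


def ellipsoid_surface(center, radii, n, seed):
    rng = np.random.default_rng(seed)
    d = rng.normal(size=(n, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    return np.asarray(center) + d * np.asarray(radii)


class TestTriangulateBoundary:
    def test_cube_hull(self):
        mesh = triangulate_boundary(CUBE)
        assert len(mesh.faces) == 12
        assert mesh.is_watertight
        assert mesh.volume == pytest.approx(1000.0**3)

    def test_ellipsoid_mesh_volume_near_analytic(self):
        pts = ellipsoid_surface((0, 0, 0), (800, 600, 500), 300, seed=2)
        mesh = triangulate_boundary(pts)
        analytic = 4 / 3 * np.pi * 800 * 600 * 500
        assert mesh.volume == pytest.approx(analytic, rel=0.05)

    @pytest.mark.parametrize("pts", [
        CUBE[:3],                                            # too few
        np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0.0]]),  # coplanar
    ], ids=["three-points", "coplanar"])
    def test_degenerate_clouds(self, pts):
        with pytest.raises(DegenerateGeometryError):
            triangulate_boundary(pts)

    def test_hull_volume_monotone_under_point_addition(self):
        rng = np.random.default_rng(31)
        pts = rng.uniform(0, 1000, size=(10, 3))
        vol = triangulate_boundary(pts).volume
        for _ in range(5):
            pts = np.vstack([pts, rng.uniform(0, 1000, size=(3, 3))])
            new_vol = triangulate_boundary(pts).volume
            assert new_vol >= vol - 1e-9
            vol = new_vol


class TestLaplacianSmooth:
    def test_zero_iterations_is_identity(self):
        mesh = triangulate_boundary(CUBE)
        out = laplacian_smooth(mesh, iterations=0, lam=0.5)
        np.testing.assert_array_equal(out.vertices, mesh.vertices)
        np.testing.assert_array_equal(out.faces, mesh.faces)

    def test_tetrahedron_single_full_step(self):
        """lam=1 sends each vertex to the centroid of the other three: volume ratio 1/27."""
        tetra = np.array([[0, 0, 0], [1000, 0, 0], [0, 1000, 0], [0, 0, 1000.0]])
        mesh = triangulate_boundary(tetra)
        sm = laplacian_smooth(mesh, iterations=1, lam=1.0)
        # direct evaluation of the update rule on the 4-vertex case
        V = mesh.vertices.view(np.ndarray)
        expected = (V.sum(axis=0) - V) / 3.0
        np.testing.assert_allclose(np.sort(sm.vertices, axis=0), np.sort(expected, axis=0),
                                   atol=1e-9)
        assert sm.volume == pytest.approx(mesh.volume / 27.0, rel=1e-9)

    def test_volume_decreases_monotonically_on_cube(self):
        mesh = triangulate_boundary(CUBE)
        vols = [mesh.volume]
        for _ in range(10):
            mesh = laplacian_smooth(mesh, iterations=1, lam=0.5)
            vols.append(mesh.volume)
        assert all(b < a for a, b in zip(vols, vols[1:]))

    def test_topology_unchanged(self):
        mesh = triangulate_boundary(ellipsoid_surface((0, 0, 0), (500, 500, 500), 100, 0))
        sm = laplacian_smooth(mesh, iterations=5, lam=0.7)
        np.testing.assert_array_equal(sm.faces, mesh.faces)
        assert sm.is_watertight

    @pytest.mark.parametrize("iters,lam", [(-1, 0.5), (1, 0.0), (1, 1.5)])
    def test_invalid_parameters(self, iters, lam):
        mesh = triangulate_boundary(CUBE)
        with pytest.raises(ValueError):
            laplacian_smooth(mesh, iterations=iters, lam=lam)


class TestVoxelize:
    def test_gridline_cube_is_exact(self):
        """1 mm cube with faces on gridlines: exactly 1000 voxels of 100 um."""
        solid = voxelize(triangulate_boundary(CUBE), 100.0)
        assert len(solid) == 1000
        assert solid.volume_mm3 == pytest.approx(1.0)
        assert solid.voxels == {(i, j, k) for i in range(10) for j in range(10) for k in range(10)}

    def test_ellipsoid_volume_convergence(self):
        """Radii (800, 600, 500) um: within 5% of 4/3 pi abc at 100 um, 2% at 50 um."""
        from atlastrace.synthetic import fibonacci_ellipsoid

        pts = fibonacci_ellipsoid((2000, 2000, 2000), (800, 600, 500), 1000)
        mesh = triangulate_boundary(pts)
        analytic = ellipsoid_volume_mm3((800, 600, 500))
        assert analytic == pytest.approx(1.0053, abs=1e-4)
        v100 = voxelize(mesh, 100.0).volume_mm3
        v50 = voxelize(mesh, 50.0).volume_mm3
        assert v100 == pytest.approx(analytic, rel=0.05)
        assert v50 == pytest.approx(analytic, rel=0.02)
        assert abs(v50 - mesh.volume / 1e9) <= abs(v100 - mesh.volume / 1e9) + 0.005

    def test_sub_voxel_mesh_is_empty_solid(self):
        tiny = triangulate_boundary(np.array([[1, 1, 1], [9, 1, 1], [1, 9, 1],
                                              [1, 1, 9], [9, 9, 9.0]]))
        solid = voxelize(tiny, 100.0)
        assert len(solid) == 0 and solid.volume_mm3 == 0.0

    def test_voxel_centers_match_containment(self):
        """Every retained voxel center is inside the mesh; every excluded neighbor is not."""
        pts = ellipsoid_surface((1000, 1000, 1000), (600, 500, 400), 400, seed=3)
        mesh = triangulate_boundary(pts)
        solid = voxelize(mesh, 100.0)
        centers = (np.array(sorted(solid.voxels)) + 0.5) * 100.0
        assert points_in_mesh(mesh, centers).all()


class TestPercentOverlap:
    def test_identical_solids(self):
        s = VoxelSolid(100.0, {(0, 0, 0), (1, 0, 0)}, "a")
        r = percent_overlap(s, s)
        assert r.percent == 100.0 and r.overlap_voxels == 2

    def test_disjoint_solids(self):
        a = VoxelSolid(100.0, {(0, 0, 0)}, "a")
        b = VoxelSolid(100.0, {(5, 5, 5)}, "b")
        assert percent_overlap(a, b).percent == 0.0

    def test_known_block_intersection(self):
        """Two overlapping blocks: percent equals brute-force set intersection."""
        a = {(i, j, k) for i in range(4) for j in range(4) for k in range(4)}
        b = {(i, j, k) for i in range(2, 6) for j in range(2, 6) for k in range(2, 6)}
        r = percent_overlap(VoxelSolid(100.0, a, "a"), VoxelSolid(100.0, b, "b"))
        assert r.overlap_voxels == len(a & b) == 8
        assert r.percent == pytest.approx(100 * 8 / 64)

    def test_intersection_symmetry(self):
        rng = np.random.default_rng(13)
        a = frozenset(map(tuple, rng.integers(0, 6, size=(40, 3)).tolist()))
        b = frozenset(map(tuple, rng.integers(0, 6, size=(40, 3)).tolist()))
        ra = percent_overlap(VoxelSolid(100.0, a), VoxelSolid(100.0, b))
        rb = percent_overlap(VoxelSolid(100.0, b), VoxelSolid(100.0, a))
        assert ra.overlap_voxels == rb.overlap_voxels
        assert ra.percent * len(b) == pytest.approx(rb.percent * len(a))

    def test_grid_mismatch(self):
        with pytest.raises(GridMismatchError):
            percent_overlap(VoxelSolid(100.0, {(0, 0, 0)}), VoxelSolid(50.0, {(0, 0, 0)}))

    def test_empty_target(self):
        with pytest.raises(UndefinedDenominatorError):
            percent_overlap(VoxelSolid(100.0, {(0, 0, 0)}), VoxelSolid(100.0, set()))

    def test_atlas_structure_overlap_matches_oracle(self, toy_atlas):
        """Ellipsoid solid vs nucleus block: equals the independent voxel-scan oracle."""
        atlas, manifest = toy_atlas
        mrn = manifest["nuclei"]["MRN"]
        center = (np.array(mrn["corner"]) + mrn["size"] / 2) * atlas.voxel_size_um
        radii = (500.0, 450.0, 400.0)
        mesh = triangulate_boundary(ellipsoid_surface(center, radii, 400, seed=5))
        solid = voxelize(mesh, atlas.voxel_size_um)
        target = atlas.region_voxels(mrn["region_id"])
        r = percent_overlap(solid, target, target_voxel_size_um=atlas.voxel_size_um)
        oracle_ell = ellipsoid_voxel_oracle(center, radii, atlas.voxel_size_um)
        # hull of finite surface samples is a subset of the analytic ellipsoid
        assert solid.voxels <= oracle_ell
        brute = len(solid.voxels & target)
        assert r.overlap_voxels == brute
        assert r.percent == pytest.approx(100 * brute / len(target))
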