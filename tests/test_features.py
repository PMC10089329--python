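"""Feature-extraction tests: hand-computed examples, conservation oracles,
invariance properties, and the surface-missing policy."""

import numpy as np
import pytest

import spheroidscore as s
from spheroidscore.features import (
    DegenerateCloudError,
    GaslikeMask,
    NoBulkCellsError,
    NoSurfaceError,
    PointCloud,
    SurfaceMesh,
)

from conftest import brute_force_gaslike


class TestCentroid:
    def test_single_point_identity(self):
        q = np.array([[3.0, -1.0, 7.0]])
        np.testing.assert_allclose(s.centroid(PointCloud(q)), q[0])

    def test_midpoint(self):
        cloud = PointCloud(np.array([[0.0, 0, 0], [2.0, 0, 0]]))
        np.testing.assert_allclose(s.centroid(cloud), [1.0, 0, 0])

    def test_translation_equivariance(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(40, 3)) * 30
        v = np.array([5.0, -17.0, 2.0])
        np.testing.assert_allclose(
            s.centroid(PointCloud(pts + v)), s.centroid(PointCloud(pts)) + v, atol=1e-12
        )


class TestCentralLocalDensity:
    def test_single_shell_degenerate(self):
        cloud = PointCloud(np.array([[0.0, 0, 0], [1.0, 0, 0], [0, 1.0, 0]]))
        profile = s.central_local_density(cloud, shell_thickness=100.0)
        np.testing.assert_allclose(profile.fractions, [1.0])

    def test_direct_count_two_shells(self):
        # four cells at centroid distances {5, 5, 15, 15}, thickness 10
        pts = np.array([[5.0, 0, 0], [-5.0, 0, 0], [0, 15.0, 0], [0, -15.0, 0]])
        profile = s.central_local_density(PointCloud(pts), shell_thickness=10.0)
        np.testing.assert_allclose(profile.fractions, [0.5, 0.5])
        np.testing.assert_allclose(profile.shell_edges, [0.0, 10.0, 20.0])

    def test_fractions_sum_to_one_and_match_shell_volumes(self):
        # Monte-Carlo against the analytic shell-volume ratio ((k+1)³−k³)/10³
        rng = np.random.default_rng(42)
        pts = rng.normal(size=(40000, 3))
        pts = pts / np.linalg.norm(pts, axis=1, keepdims=True)
        pts *= rng.uniform(0, 1, size=(40000, 1)) ** (1 / 3) * 100.0
        profile = s.central_local_density(PointCloud(pts), shell_thickness=10.0)
        assert np.isclose(profile.fractions.sum(), 1.0)
        k = np.arange(10)
        analytic = ((k + 1) ** 3 - k**3) / 1000.0
        np.testing.assert_allclose(profile.fractions[:10], analytic, atol=0.02)

    def test_invalid_thickness(self):
        with pytest.raises(ValueError):
            s.central_local_density(PointCloud(np.zeros((1, 3))), shell_thickness=0.0)


class TestClassifyGaslike:
    def test_published_defaults(self):
        mask = s.classify_gaslike(PointCloud(np.zeros((1, 3))))
        assert mask.D_crit == 125.0 and mask.d_crit == 19.0

    def test_two_far_cells_both_gaslike(self):
        cloud = PointCloud(np.array([[0.0, 0, 0], [300.0, 0, 0]]))
        mask = s.classify_gaslike(cloud)
        assert mask.is_gaslike.all()

    def test_dense_ball_inside_threshold(self):
        cloud = s.sample_ball(200, radius=100.0, min_separation=5.0, seed=1)
        assert s.classify_gaslike(cloud).n_gaslike == 0

    def test_lone_cell_never_gaslike(self):
        mask = s.classify_gaslike(PointCloud(np.array([[500.0, 0, 0]])))
        assert not mask.is_gaslike.any()

    def test_threshold_ties_are_bulk(self):
        # both inequalities are strict: exactly-at-threshold cells stay bulk
        pts = np.array([[-125.0, 0, 0], [125.0, 0, 0]])  # centroid at origin
        mask = s.classify_gaslike(PointCloud(pts), D_crit=125.0, d_crit=19.0)
        assert not mask.is_gaslike.any()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(-200, 200, size=(200, 3))
        mask = s.classify_gaslike(PointCloud(pts), D_crit=125.0, d_crit=19.0)
        expected = brute_force_gaslike(pts, 125.0, 19.0)
        np.testing.assert_array_equal(mask.is_gaslike, expected)


class TestGaslikeFeaturePoint:
    def _cloud_and_mask(self):
        # 9 bulk cells at centroid distances 10..90 and one gaslike at 200,
        # with the center fixed at the origin via an explicit mask
        radii = np.arange(10.0, 100.0, 10.0)
        pts = np.zeros((10, 3))
        pts[:9, 0] = radii
        pts[9, 1] = 200.0
        mask = GaslikeMask(
            is_gaslike=np.array([False] * 9 + [True]),
            D_crit=125.0,
            d_crit=19.0,
            center=np.zeros(3),
        )
        return PointCloud(pts), mask

    def test_hand_computed_point(self):
        cloud, mask = self._cloud_and_mask()
        p = s.gaslike_feature_point(cloud, mask)
        assert p.p95_bulk == pytest.approx(86.0)  # interpolated percentile
        assert p.p_x == pytest.approx(0.1)
        assert p.p_y == pytest.approx(200.0 / 86.0)

    def test_no_gaslikes_convention(self):
        cloud = s.sample_ball(50, radius=50.0, min_separation=2.0, seed=0)
        mask = s.classify_gaslike(cloud)
        p = s.gaslike_feature_point(cloud, mask)
        assert (p.p_x, p.p_y) == (0.0, 0.0)

    def test_empty_bulk_errors(self):
        cloud = PointCloud(np.array([[0.0, 0, 0], [300.0, 0, 0]]))
        mask = s.classify_gaslike(cloud)  # both gaslike
        with pytest.raises(NoBulkCellsError):
            s.gaslike_feature_point(cloud, mask)

    def test_scale_invariance_with_fixed_mask(self):
        cloud, mask = self._cloud_and_mask()
        p1 = s.gaslike_feature_point(cloud, mask)
        doubled = PointCloud(cloud.positions * 2.0)
        p2 = s.gaslike_feature_point(doubled, mask)
        assert p2.p_y == pytest.approx(p1.p_y)


class TestVoronoiVolumes:
    def test_cubic_lattice_equal_volumes(self):
        g = np.arange(3) * 10.0
        pts = np.stack(np.meshgrid(g, g, g, indexing="ij"), axis=-1).reshape(-1, 3)
        box = np.array([[-5.0, -5.0, -5.0], [25.0, 25.0, 25.0]])
        sample = s.voronoi_volumes(PointCloud(pts), box=box)
        np.testing.assert_allclose(sample.volumes, 1000.0, rtol=1e-9)
        assert sample.volumes.sum() == pytest.approx(27000.0)

    def test_single_point_gets_whole_box(self):
        box = np.array([[0.0, 0, 0], [10.0, 20.0, 5.0]])
        sample = s.voronoi_volumes(PointCloud(np.array([[5.0, 5.0, 2.0]])), box=box)
        assert sample.volumes[0] == pytest.approx(1000.0)

    @pytest.mark.parametrize("seed", [0, 3])
    def test_conservation(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 100, size=(50, 3))
        sample = s.voronoi_volumes(PointCloud(pts))
        lo, hi = sample.bounding_box
        assert sample.volumes.sum() == pytest.approx(np.prod(hi - lo), rel=1e-6)
        assert (sample.volumes > 0).all()

    def test_coplanar_cloud_rejected(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 100, size=(20, 3))
        pts[:, 2] = 1.5
        with pytest.raises(DegenerateCloudError):
            s.voronoi_volumes(PointCloud(pts))

    def test_point_outside_box_rejected(self):
        with pytest.raises(ValueError, match="box"):
            s.voronoi_volumes(
                PointCloud(np.array([[0.0, 0, 0], [50.0, 0, 0]])),
                box=np.array([[-1.0, -1, -1], [1.0, 1, 1]]),
            )


class TestVoxelize:
    def test_single_point_occupies_containing_voxel(self):
        grid, origin, h = s.voxelize(PointCloud(np.zeros((1, 3))), grid_spacing=5.0, reach=2.0)
        assert grid.sum() >= 1

    def test_occupied_count_matches_ball_volume(self):
        grid, origin, h = s.voxelize(PointCloud(np.zeros((1, 3))), grid_spacing=5.0, reach=15.0)
        expected = 4.0 / 3.0 * np.pi * 15.0**3 / 5.0**3
        assert grid.sum() == pytest.approx(expected, rel=0.15)

    def test_no_occupancy_on_grid_boundary(self):
        cloud = s.sample_ball(100, radius=50.0, min_separation=5.0, seed=2)
        grid, _, _ = s.voxelize(cloud, grid_spacing=5.0, reach=15.0)
        assert not grid[0].any() and not grid[-1].any()
        assert not grid[:, 0].any() and not grid[:, -1].any()
        assert not grid[:, :, 0].any() and not grid[:, :, -1].any()


@pytest.fixture(scope="module")
def ball_mesh():
    grid, origin, h = s.voxelize(PointCloud(np.zeros((1, 3))), grid_spacing=5.0, reach=100.0)
    return s.triangulate_surface(grid, origin, h)


class TestTriangulateSurface:

    def test_ball_area_matches_analytic_sphere(self, ball_mesh):
        assert s.surface_area(ball_mesh) == pytest.approx(4 * np.pi * 100.0**2, rel=0.05)

    def test_watertight(self, ball_mesh):
        edges = np.sort(
            np.vstack([ball_mesh.faces[:, [0, 1]], ball_mesh.faces[:, [1, 2]], ball_mesh.faces[:, [2, 0]]]),
            axis=1,
        )
        _, counts = np.unique(edges, axis=0, return_counts=True)
        assert (counts == 2).all()

    def test_normals_point_outward(self, ball_mesh):
        radial = ball_mesh.vertices / np.linalg.norm(ball_mesh.vertices, axis=1, keepdims=True)
        dots = np.einsum("ij,ij->i", ball_mesh.vertex_normals, radial)
        assert dots.mean() > 0.9

    def test_two_blobs_additive_area(self):
        pts = np.array([[0.0, 0, 0], [200.0, 0, 0]])
        grid, origin, h = s.voxelize(PointCloud(pts), grid_spacing=5.0, reach=20.0)
        both = s.surface_area(s.triangulate_surface(grid, origin, h))
        g1, o1, _ = s.voxelize(PointCloud(pts[:1]), grid_spacing=5.0, reach=20.0)
        single = s.surface_area(s.triangulate_surface(g1, o1, h))
        assert both == pytest.approx(2 * single, rel=0.01)

    def test_empty_and_full_grids_rejected(self):
        with pytest.raises(NoSurfaceError):
            s.triangulate_surface(np.zeros((4, 4, 4), dtype=bool), np.zeros(3), 1.0)
        with pytest.raises(NoSurfaceError):
            s.triangulate_surface(np.ones((4, 4, 4), dtype=bool), np.zeros(3), 1.0)


class TestSurfaceArea:
    def test_single_triangle(self):
        mesh = SurfaceMesh(
            vertices=np.array([[0.0, 0, 0], [1.0, 0, 0], [0, 1.0, 0]]),
            faces=np.array([[0, 1, 2]]),
            vertex_normals=np.tile([0.0, 0, 1.0], (3, 1)),
        )
        assert s.surface_area(mesh) == pytest.approx(0.5)

    def test_unit_cube(self):
        v = np.array(
            [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0], [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]],
            dtype=float,
        )
        f = np.array(
            [[0, 2, 1], [0, 3, 2], [4, 5, 6], [4, 6, 7], [0, 1, 5], [0, 5, 4],
             [1, 2, 6], [1, 6, 5], [2, 3, 7], [2, 7, 6], [3, 0, 4], [3, 4, 7]]
        )
        mesh = SurfaceMesh(vertices=v, faces=f, vertex_normals=np.zeros((8, 3)))
        assert s.surface_area(mesh) == pytest.approx(6.0)

    def test_degenerate_triangle_contributes_zero(self):
        mesh = SurfaceMesh(
            vertices=np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]]),
            faces=np.array([[0, 1, 2]]),
            vertex_normals=np.zeros((3, 3)),
        )
        assert s.surface_area(mesh) == 0.0


class TestSurfaceDeformation:
    def test_icosphere_all_ones(self):
        mesh = s.icosphere(radius=100.0, subdivisions=3)
        sample = s.surface_deformation(mesh, center=np.zeros(3))
        np.testing.assert_allclose(sample.scalar_products, 1.0, atol=1e-6)

    def test_inward_normals_give_minus_one(self):
        mesh = s.icosphere(radius=50.0, subdivisions=2)
        flipped = SurfaceMesh(mesh.vertices, mesh.faces, -mesh.vertex_normals)
        sample = s.surface_deformation(flipped, center=np.zeros(3))
        np.testing.assert_allclose(sample.scalar_products, -1.0, atol=1e-6)

    def test_values_bounded(self):
        grid, origin, h = s.voxelize(
            s.sample_ball(100, radius=60.0, min_separation=5.0, seed=4), 5.0, 15.0
        )
        mesh = s.triangulate_surface(grid, origin, h)
        sample = s.surface_deformation(mesh, np.zeros(3))
        assert sample.scalar_products.min() >= -1.0
        assert sample.scalar_products.max() <= 1.0


class TestExtractFeatures:
    def test_spherical_has_all_five_features(self, config):
        cloud = s.generate_phenotype(s.PhenotypeParams(phenotype_name="spherical", n_cells=500, seed=6))
        fs = s.extract_features(cloud, config=config)
        assert not fs.surface_missing
        assert fs.surface_area > 0
        assert fs.deformation.scalar_products.size > 0

    def test_destroyed_core_cuts_surface_features(self, config):
        cloud = s.generate_phenotype(s.PhenotypeParams(phenotype_name="spherical", seed=6))
        noised = s.jitter(cloud, alpha=1500.0, seed=5)
        fs = s.extract_features(noised, config=config)
        assert fs.surface_missing
        assert fs.density.fractions.sum() == pytest.approx(1.0)
        assert fs.voronoi.volumes.size == len(noised)

    def test_deterministic(self, config):
        cloud = s.generate_phenotype(s.PhenotypeParams(phenotype_name="deformed", n_cells=400, seed=7))
        a = s.extract_features(cloud, config=config)
        b = s.extract_features(cloud, config=config)
        np.testing.assert_array_equal(a.density.fractions, b.density.fractions)
        np.testing.assert_array_equal(a.voronoi.volumes, b.voronoi.volumes)
        assert a.surface_area == b.surface_area

    def test_translation_leaves_features_unchanged(self, config):
        cloud = s.generate_phenotype(s.PhenotypeParams(phenotype_name="spherical", n_cells=400, seed=8))
        moved = s.translate(cloud, [123.0, -45.0, 67.0])
        fa = s.extract_features(cloud, config=config)
        fb = s.extract_features(moved, config=config)
        for fid in s.FEATURE_IDS:
            fd = s.feature_distance(fa, fb, fid)
            assert fd is not None
            if fid in ("density", "gaslike", "voronoi"):
                assert fd.value <= 1e-9
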