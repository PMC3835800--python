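"""Grid triangulation, surface fitting, mesh distance and the ASD metric."""

import numpy as np
import pytest
import trimesh

from gridstereo import synthetic
from gridstereo._mesh import MeshDistance
from gridstereo.config import PipelineConfig
from gridstereo.errors import ConfigError, DegenerateGeometryError
from gridstereo.pipeline import reconstruct_pair
from gridstereo.surface import (
    GridSurface,
    average_surface_distance,
    fit_surface,
    reconstruct_grid,
)


def _plane_mesh(z=0.0, half=10.0, n=21):
    xs = np.linspace(-half, half, n)
    X, Y = np.meshgrid(xs, xs)
    verts = np.stack([X.reshape(-1), Y.reshape(-1), np.full(n * n, z)], axis=-1)
    idx = np.arange(n * n).reshape(n, n)
    a, b = idx[:-1, :-1].reshape(-1), idx[:-1, 1:].reshape(-1)
    c, d = idx[1:, :-1].reshape(-1), idx[1:, 1:].reshape(-1)
    faces = np.concatenate([np.stack([a, b, c], -1), np.stack([b, d, c], -1)])
    return trimesh.Trimesh(vertices=verts, faces=faces, process=False)


def _grid_from_fn(fn, rows=7, cols=11):
    pts = np.empty((rows, cols, 3))
    for r in range(rows):
        for c in range(cols):
            x, y = c * 2.0, r * 2.0
            pts[r, c] = [x, y, fn(x, y)]
    return GridSurface(points=pts, gaps=np.zeros((rows, cols)), n_dropped=0)


class TestReconstructGrid:
    def test_clean_scene_grid_close_to_truth(self, noise_free_scene, noise_free_render):
        left, right, truth = noise_free_render
        res = reconstruct_pair(left, right, noise_free_scene.rig, PipelineConfig())
        grid = res.grid
        assert grid.n_points == 77
        truth_grid = np.full_like(grid.points, np.nan)
        for k in range(len(truth.rows)):
            truth_grid[truth.rows[k], truth.cols[k]] = truth.points3d_left[k]
        err = np.linalg.norm(grid.points - truth_grid, axis=2)
        rmse = np.sqrt(np.nanmean(err**2))
        assert rmse < 0.05

    def test_gap_filter_drops_bad_pair(self, noise_free_scene, noise_free_render):
        from gridstereo.matching import MatchedGrid

        left, right, _ = noise_free_render
        res = reconstruct_pair(left, right, noise_free_scene.rig, PipelineConfig())
        m = res.matches
        # corrupt one right point vertically: big ray gap, epipolar-inconsistent
        right_pts = m.right.copy()
        right_pts[10, 1] += 80.0
        bad = MatchedGrid(left=m.left, right=right_pts, rows=m.rows, cols=m.cols,
                          residuals=m.residuals)
        grid = reconstruct_grid(bad, noise_free_scene.rig, max_gap=2.0)
        assert grid.n_points == 76
        assert grid.n_dropped == 1

    def test_depth_outlier_dropped(self, noise_free_scene, noise_free_render):
        from gridstereo.matching import MatchedGrid

        left, right, _ = noise_free_render
        res = reconstruct_pair(left, right, noise_free_scene.rig, PipelineConfig())
        m = res.matches
        # nearly identical pixels in both views: tiny gap, absurd depth
        left_pts, right_pts = m.left.copy(), m.right.copy()
        right_pts[5] = left_pts[5] + [0.05, 0.0]
        bad = MatchedGrid(left=left_pts, right=right_pts, rows=m.rows, cols=m.cols,
                          residuals=m.residuals)
        grid = reconstruct_grid(bad, noise_free_scene.rig, max_gap=2.0)
        assert grid.n_points == 76

    def test_too_few_matches_raise(self, noise_free_scene):
        from gridstereo.matching import MatchedGrid

        empty = MatchedGrid(left=np.zeros((2, 2)), right=np.zeros((2, 2)),
                            rows=np.array([0, 1]), cols=np.array([0, 1]),
                            residuals=np.zeros(2))
        with pytest.raises(DegenerateGeometryError):
            reconstruct_grid(empty, noise_free_scene.rig)


class TestFitSurface:
    def test_planar_grid_gives_coplanar_mesh(self):
        grid = _grid_from_fn(lambda x, y: 2.0 + 0.1 * x - 0.05 * y)
        mesh = fit_surface(grid, upsample=4)
        v = mesh.vertices
        residual = v[:, 2] - (2.0 + 0.1 * v[:, 0] - 0.05 * v[:, 1])
        assert np.max(np.abs(residual)) < 1e-9

    def test_upsample_one_returns_grid_points(self):
        grid = _grid_from_fn(lambda x, y: np.sin(x / 3) + y * 0.2)
        mesh = fit_surface(grid, upsample=1)
        assert np.allclose(mesh.vertices.reshape(7, 11, 3), grid.points, atol=1e-9)

    def test_interpolates_grid_nodes_exactly(self):
        grid = _grid_from_fn(lambda x, y: np.cos(x / 2) * np.sin(y / 3))
        mesh = fit_surface(grid, upsample=4)
        dense = mesh.vertices.reshape(25, 41, 3)
        assert np.max(np.abs(dense[::4, ::4] - grid.points)) < 1e-6

    def test_bump_grid_recovered_against_analytic_oracle(self):
        # grid sampled exactly from a Gaussian bump: the dense fitted mesh
        # must deviate from the analytic surface by < 0.1 mm at upsample 8
        amp, sig = 5.0, 6.0
        fn = lambda x, y: 30.0 - amp * np.exp(-((x - 10) ** 2 + (y - 6) ** 2) / (2 * sig**2))
        grid = _grid_from_fn(fn)
        mesh = fit_surface(grid, upsample=8)
        v = mesh.vertices
        assert np.max(np.abs(v[:, 2] - fn(v[:, 0], v[:, 1]))) < 0.1

    def test_missing_cell_filled_smoothly(self):
        grid = _grid_from_fn(lambda x, y: 5.0 + 0.3 * x + 0.1 * y)
        grid.points[3, 5] = np.nan
        mesh = fit_surface(grid, upsample=2)
        v = mesh.vertices
        residual = v[:, 2] - (5.0 + 0.3 * v[:, 0] + 0.1 * v[:, 1])
        assert np.max(np.abs(residual)) < 1e-6

    def test_tps_variant_also_interpolates(self):
        grid = _grid_from_fn(lambda x, y: np.cos(x / 2) + 0.2 * y)
        mesh = fit_surface(grid, upsample=2, method="tps")
        dense = mesh.vertices.reshape(13, 21, 3)
        assert np.max(np.abs(dense[::2, ::2] - grid.points)) < 1e-6

    def test_insufficient_support_raises(self):
        grid = _grid_from_fn(lambda x, y: 0.0, rows=2, cols=11)
        with pytest.raises(DegenerateGeometryError):
            fit_surface(grid)


class TestMeshDistance:
    def test_matches_brute_force_on_random_points(self, rng):
        # spatial-index contract: exact agreement with the all-triangles scan
        surf = synthetic.make_surface("liver_like", seed=3, resolution=1.2)
        md = MeshDistance(surf.mesh)
        assert md.n_triangles >= 500
        pts = rng.uniform([-18, -14, 20], [18, 14, 45], size=(200, 3))
        d_fast, c_fast = md.query(pts)
        d_brute, c_brute = md.query_brute_force(pts)
        assert np.allclose(d_fast, d_brute, atol=1e-12)
        assert np.allclose(c_fast, c_brute, atol=1e-9)

    def test_vertices_have_zero_distance(self):
        mesh = _plane_mesh()
        d, _ = MeshDistance(mesh).query(mesh.vertices)
        assert np.max(d) < 1e-12


class TestAverageSurfaceDistance:
    def test_identical_surfaces_give_zero(self):
        mesh = _plane_mesh()
        rep = average_surface_distance(mesh.vertices, mesh)
        assert rep.mean == 0.0

    def test_plane_translated_along_normal(self):
        # closed form: every point is exactly 1 mm from the reference plane
        ref = _plane_mesh(z=0.0, half=20.0)
        src = _plane_mesh(z=1.0, half=10.0)
        rep = average_surface_distance(src.vertices, ref)
        assert abs(rep.mean - 1.0) < 1e-12
        assert rep.std < 1e-12

    def test_symmetric_between_directional_means(self):
        ref = _plane_mesh(z=0.0, half=20.0)
        src = _plane_mesh(z=1.0, half=10.0)
        src = trimesh.Trimesh(vertices=src.vertices + [15.0, 0, 0], faces=src.faces,
                              process=False)
        fwd = average_surface_distance(src, ref, "forward").mean
        bwd = average_surface_distance(ref, src, "forward").mean
        sym = average_surface_distance(src, ref, "symmetric").mean
        assert min(fwd, bwd) <= sym <= max(fwd, bwd)

    def test_mean_not_above_max(self, rng):
        ref = _plane_mesh(z=0.0)
        pts = rng.uniform([-5, -5, 0.1], [5, 5, 3.0], size=(50, 3))
        rep = average_surface_distance(pts, ref)
        assert 0 <= rep.mean <= rep.distances.max()

    def test_empty_source_raises(self):
        with pytest.raises(ConfigError):
            average_surface_distance(np.zeros((0, 3)), _plane_mesh())
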