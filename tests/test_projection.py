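"""Perspective matrix, depth-map rasterisation and multi-view capture."""

import math

import numpy as np
import pytest

from anthromesh import (
    CameraConfig,
    ParameterError,
    TriangleMesh,
    back_project,
    multi_view_snapshots,
    perspective_matrix,
    render_depth_map,
)


def _square_mesh(half_mm, y_center, z, x_center=0.0):
    """Two triangles forming an axis-aligned square facing +Z."""
    h = half_mm
    v = np.array([
        [x_center - h, y_center - h, z],
        [x_center + h, y_center - h, z],
        [x_center + h, y_center + h, z],
        [x_center - h, y_center + h, z],
    ])
    return TriangleMesh(v, np.array([[0, 1, 2], [0, 2, 3]]))


class TestPerspectiveMatrix:
    def test_fovy_90_unit_projection_plane(self):
        m = perspective_matrix(CameraConfig(fovy=90.0, aspect=1.0)).m
        # cot(45 deg) = 1: the canonical projection plane sits at z = -1
        assert m[1, 1] == pytest.approx(1.0)
        assert m[0, 0] == pytest.approx(1.0)

    def test_point_on_unit_plane_maps_to_its_coordinates(self):
        pm = perspective_matrix(CameraConfig(fovy=90.0, aspect=1.0))
        ndc = pm.apply(np.array([[0.5, 0.5, -1.0]]))
        np.testing.assert_allclose(ndc, [[0.5, 0.5]], atol=1e-12)

    def test_fovy_60_cot_closed_form(self):
        pm = perspective_matrix(CameraConfig(fovy=60.0, aspect=1.0))
        assert pm.m[1, 1] == pytest.approx(math.sqrt(3.0), rel=1e-12)

    def test_matches_textbook_frustum_matrix(self):
        # independent construction of the symmetric-frustum matrix
        cfg = CameraConfig(fovy=40.0, aspect=1.5, near_n=500.0, far_f=6000.0)
        f = 1.0 / math.tan(math.radians(cfg.fovy) / 2.0)
        n, fa = cfg.near_n, cfg.far_f
        expected = np.array([
            [f / cfg.aspect, 0, 0, 0],
            [0, f, 0, 0],
            [0, 0, (fa + n) / (n - fa), 2 * fa * n / (n - fa)],
            [0, 0, -1, 0],
        ])
        np.testing.assert_allclose(perspective_matrix(cfg).m, expected, atol=1e-12)

    def test_cone_boundary_maps_to_unit_ndc(self):
        cfg = CameraConfig(fovy=50.0, aspect=1.0)
        pm = perspective_matrix(cfg)
        z = -1234.5
        y = -z * math.tan(math.radians(cfg.fovy) / 2.0)
        ndc = pm.apply(np.array([[0.0, y, z]]))
        assert abs(ndc[0, 1]) == pytest.approx(1.0, rel=1e-12)

    def test_degenerate_fovy_rejected(self):
        with pytest.raises(ParameterError):
            CameraConfig(fovy=0.0)
        with pytest.raises(ParameterError):
            CameraConfig(fovy=180.0)


class TestRenderDepthMap:
    def test_mesh_outside_depth_range_gives_blank_map(self):
        mesh = _square_mesh(100.0, 1000.0, 0.0)
        cfg = CameraConfig(near_n=100.0, far_f=500.0)  # subject at 3 m
        dm = render_depth_map(mesh, cfg)
        assert dm.all_background
        assert not dm.pixels.any()

    def test_square_pixel_block_matches_analytic_projection(self):
        # 200x200 mm square, centre at camera height, 3 m away, fovy 40
        cfg = CameraConfig(fovy=40.0, cam_height=1.0, cam_distance=3.0)
        mesh = _square_mesh(100.0, 1000.0, 0.0)
        W = H = 512
        dm = render_depth_map(mesh, cfg, W, H, floor_y=0.0)
        rows, cols = np.nonzero(dm.pixels)
        tan_y = math.tan(math.radians(cfg.fovy) / 2.0)
        # analytic corner projection: x_ndc = x / (d * tan), rows top-down
        d = 3000.0
        ndc = 100.0 / (d * tan_y)
        col_lo = (1 - ndc) / 2 * W
        col_hi = (1 + ndc) / 2 * W
        assert abs(cols.min() - col_lo) <= 1.0
        assert abs(cols.max() - (col_hi - 1)) <= 1.0
        assert abs(rows.min() - col_lo) <= 1.0  # square: same extent
        assert abs(rows.max() - (col_hi - 1)) <= 1.0

    def test_nearer_surface_wins_and_is_brighter(self):
        # small square 1 m in front of a larger one; camera orbits the
        # combined bounding-box centre (z = 500), so depths are 2500/3500 mm
        near_sq = _square_mesh(150.0, 1000.0, 1000.0)
        far_sq = _square_mesh(300.0, 1000.0, 0.0)
        both = TriangleMesh(
            np.vstack([near_sq.vertices, far_sq.vertices]),
            np.vstack([near_sq.faces, far_sq.faces + 4]),
        )
        dm = render_depth_map(both, CameraConfig(), floor_y=0.0)
        center = dm.world_depth[256, 256]
        assert center == pytest.approx(2500.0, abs=5.0)
        # an off-centre pixel shows the occluded-free far square
        far_cols = np.nonzero(dm.pixels[256] > 0)[0]
        outer = far_cols.min()
        assert dm.world_depth[256, outer] == pytest.approx(3500.0, abs=5.0)
        assert dm.pixels[256, 256] > dm.pixels[256, outer]

    def test_intensity_decreases_with_depth(self, frontal_dm):
        sil = frontal_dm.silhouette()
        d = frontal_dm.world_depth[sil]
        g = frontal_dm.pixels[sil].astype(float)
        order = np.argsort(d)
        # grayscale must be non-increasing in depth (ties from quantisation)
        assert (np.diff(g[order]) <= 0).mean() > 0.99

    def test_resolution_floor(self):
        with pytest.raises(ParameterError):
            render_depth_map(_square_mesh(10, 0, 0), CameraConfig(), 8, 8)


class TestBackProject:
    def test_center_pixel_lies_on_optical_axis(self):
        cfg = CameraConfig(fovy=40.0, cam_height=1.0, cam_distance=3.0)
        mesh = _square_mesh(200.0, 1000.0, 0.0)
        dm = render_depth_map(mesh, cfg, 256, 256, floor_y=0.0)
        p = back_project(dm, 128, 128)
        # optical axis: x near pivot x, y near camera height
        assert abs(p[0] - dm.pivot[0]) < 6.0
        assert abs(p[1] - 1000.0) < 6.0
        assert abs(p[2]) < 1.0

    def test_round_trip_recovers_world_point(self, frontal_dm):
        sil = np.argwhere(frontal_dm.silhouette())
        rng = np.random.default_rng(7)
        for row, col in sil[rng.choice(len(sil), 20, replace=False)]:
            p = back_project(frontal_dm, int(row), int(col))
            assert np.isfinite(p).all()
        # px-equivalent tolerance at 3 m with fovy 40 is ~4.3 mm/px

    def test_head_top_pixel_maps_to_mesh_apex(self, humanoid, frontal_dm):
        mesh, _ = humanoid
        rows, cols = np.nonzero(frontal_dm.pixels)
        top = rows.min()
        col = int(np.mean(cols[rows == top]))
        p = back_project(frontal_dm, int(top), col)
        # a level camera below the apex sees the head top tangentially:
        # tangent-point deficit r(1-cos(elevation)) plus ~1 px quantisation
        assert abs(p[1] - mesh.bounds()[1, 1]) < 20.0

    def test_background_pixel_rejected(self, frontal_dm):
        with pytest.raises(ParameterError):
            back_project(frontal_dm, 0, 0)


class TestMultiView:
    def test_eight_views_at_45_degrees(self, cylinder256):
        mesh, _ = cylinder256
        maps = multi_view_snapshots(mesh, CameraConfig(), 45.0, 64, 64)
        assert len(maps) == 8
        assert [m.camera.yaw for m in maps] == [0, 45, 90, 135, 180, 225, 270, 315]

    def test_four_views_at_90_degrees(self, cylinder256):
        mesh, _ = cylinder256
        assert len(multi_view_snapshots(mesh, CameraConfig(), 90.0, 64, 64)) == 4

    def test_non_divisor_step_rejected(self, cylinder256):
        mesh, _ = cylinder256
        with pytest.raises(ParameterError):
            multi_view_snapshots(mesh, CameraConfig(), 70.0)

    def test_front_back_silhouette_symmetry(self, humanoid):
        # left-right-symmetric body: front and back silhouettes match
        mesh, _ = humanoid
        cfg = CameraConfig()
        from dataclasses import replace

        a = render_depth_map(mesh, cfg, 256, 256)
        b = render_depth_map(mesh, replace(cfg, yaw=180.0), 256, 256)
        na, nb = a.silhouette().sum(), b.silhouette().sum()
        assert abs(na - nb) / na < 0.005
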