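"""Vertex normals, cross-sections, girths, volumes and the full report."""

import math

import numpy as np
import pytest
import trimesh

from anthromesh import (
    CameraConfig,
    MeasurementError,
    ParameterError,
    SeedPointSet,
    TriangleMesh,
    bmi,
    circumference,
    cross_section,
    locate_measurement_planes,
    measure_report,
    render_depth_map,
    detect_seed_points,
    slab_volume,
    vertex_normals,
    whtr,
)
from anthromesh.measure import CrossSection
from anthromesh.preprocess import resize_to_height
from anthromesh.synth_body import make_primitive


class TestVertexNormals:
    def test_flat_square_all_up(self):
        square = TriangleMesh(
            np.array([[-1.0, 0, -1], [1, 0, -1], [1, 0, 1], [-1, 0, 1]]),
            np.array([[0, 2, 1], [0, 3, 2]]),
        )
        vn = vertex_normals(square)
        np.testing.assert_allclose(vn.normals, [[0, 1, 0]] * 4, atol=1e-12)

    def test_single_triangle_normals_equal_face_normal(self):
        tri = TriangleMesh(np.array([[0.0, 0, 0], [1, 0, 0], [0, 0, 1]]),
                           np.array([[0, 2, 1]]))
        vn = vertex_normals(tri)
        np.testing.assert_allclose(vn.normals, [[0, 1, 0]] * 3, atol=1e-12)

    def test_icosphere_normals_are_radial_within_2_degrees(self):
        ico = trimesh.creation.icosphere(subdivisions=3, radius=100.0)
        mesh = TriangleMesh(np.asarray(ico.vertices), np.asarray(ico.faces))
        vn = vertex_normals(mesh)
        radial = mesh.vertices / np.linalg.norm(mesh.vertices, axis=1)[:, None]
        cosang = np.clip((vn.normals * radial).sum(axis=1), -1, 1)
        assert np.degrees(np.arccos(cosang)).max() < 2.0

    def test_unit_length_invariant(self):
        ico = trimesh.creation.icosphere(subdivisions=2, radius=50.0)
        vn = vertex_normals(TriangleMesh(np.asarray(ico.vertices),
                                         np.asarray(ico.faces)))
        np.testing.assert_allclose(np.linalg.norm(vn.normals, axis=1), 1.0,
                                   atol=1e-6)


class TestCrossSection:
    def test_cylinder_perimeter_closed_form(self, cylinder256):
        mesh, _ = cylinder256
        sec = cross_section(mesh, 150.0)
        assert len(sec.loops) == 1
        expected = 256 * 2 * 100.0 * math.sin(math.pi / 256)
        assert sec.perimeters[0] == pytest.approx(expected, rel=1e-9)

    def test_plane_above_mesh_is_empty(self, cylinder256):
        mesh, _ = cylinder256
        assert cross_section(mesh, 500.0).is_empty

    def test_humanoid_chest_level_has_three_loops(self, humanoid):
        mesh, gt = humanoid
        sec = cross_section(mesh, 0.70 * mesh.height_mm())
        assert len(sec.loops) == 3  # torso + two arms

    def test_circle_circumference_100cm(self):
        mesh, _ = make_primitive(
            "cylinder", dict(radius=159.1549, height=50.0), 512
        )
        sec = cross_section(mesh, 25.0)
        assert circumference(sec, "largest_area", "raw") == pytest.approx(
            100.0, rel=1e-4
        )

    def test_square_loop_raw_equals_convex(self):
        mesh, _ = make_primitive("box", dict(dx=80.0, dy=50.0, dz=120.0))
        sec = cross_section(mesh, 25.0)
        raw = circumference(sec, "largest_area", "raw")
        cvx = circumference(sec, "largest_area", "convex")
        assert raw == pytest.approx(2 * (80 + 120) / 10.0, rel=1e-9)
        assert cvx == pytest.approx(raw, rel=1e-9)

    def test_concave_star_convex_hull_shorter_than_raw(self):
        th = np.linspace(0, 2 * math.pi, 10, endpoint=False)
        r = np.where(np.arange(10) % 2 == 0, 100.0, 40.0)
        star = np.column_stack([r * np.cos(th), r * np.sin(th)])
        sec = CrossSection(plane_y=0.0, loops=[star])
        assert circumference(sec, "largest_area", "convex") < circumference(
            sec, "largest_area", "raw"
        )

    def test_empty_section_raises(self):
        with pytest.raises(MeasurementError):
            circumference(CrossSection(plane_y=0.0, loops=[]))


class TestSlabVolume:
    def test_cylinder_closed_form(self, cylinder256):
        mesh, gt = cylinder256
        v = slab_volume(mesh, 0.0, 300.0, 64)
        assert v == pytest.approx(math.pi * 100.0**2 * 300.0 / 1e6, rel=5e-3)
        assert v == pytest.approx(gt.volume_L, rel=1e-3)

    def test_zero_height_slab(self, cylinder256):
        mesh, _ = cylinder256
        assert slab_volume(mesh, 150.0, 150.0) == 0.0

    def test_sphere_segment_analytic(self):
        mesh, _ = make_primitive("ellipsoid", dict(a=100.0, b=100.0, c=100.0), 96)
        h, r = 50.0, 100.0
        analytic = math.pi * (r * r * 2 * h - 2 * h**3 / 3) / 1e6
        assert slab_volume(mesh, -h, h, 128) == pytest.approx(analytic, rel=0.01)

    def test_trapezoid_convergence_on_curved_sections(self):
        mesh, _ = make_primitive("ellipsoid", dict(a=100.0, b=100.0, c=100.0), 96)
        ref = slab_volume(mesh, -50.0, 50.0, 2048)
        errs = [abs(slab_volume(mesh, -50.0, 50.0, n) - ref) for n in (16, 32, 64)]
        assert errs[1] <= 0.6 * errs[0]
        assert errs[2] <= 0.6 * errs[1]


def _fake_seeds_for(mesh: TriangleMesh, armpit_frac=0.78, crotch_frac=0.30):
    """Plausible seed set for a phantom torso (cylinder/cone) without arms."""
    y0, y1 = mesh.bounds()[0, 1], mesh.bounds()[1, 1]
    H = y1 - y0

    def at(frac):
        return y0 + frac * H

    rows = {
        "head_top": 10, "neck": 40, "left_shoulder": 60, "right_shoulder": 60,
        "left_armpit": 70, "right_armpit": 70, "left_fingertip": 300,
        "right_fingertip": 300, "left_toe": 480, "right_toe": 480,
        "crotch": 350,
    }
    cols = {
        "head_top": 256, "neck": 256, "left_shoulder": 200,
        "right_shoulder": 312, "left_armpit": 205, "right_armpit": 307,
        "left_fingertip": 100, "right_fingertip": 412, "left_toe": 220,
        "right_toe": 292, "crotch": 256,
    }
    heights = {
        "head_top": at(1.0), "neck": at(0.88), "left_shoulder": at(0.82),
        "right_shoulder": at(0.82), "left_armpit": at(armpit_frac),
        "right_armpit": at(armpit_frac), "left_fingertip": at(0.42),
        "right_fingertip": at(0.42), "left_toe": at(0.0),
        "right_toe": at(0.0), "crotch": at(crotch_frac),
    }
    pts = {k: (rows[k], cols[k]) for k in rows}
    world = {k: np.array([0.0, heights[k], 0.0]) for k in heights}
    return SeedPointSet(points=pts, world_heights=heights, world_points=world)


class TestMeasurementPlanes:
    def test_chest_and_waist_found_at_construction_levels(self, humanoid, seeds):
        mesh, _ = humanoid
        H = mesh.height_mm()
        planes = locate_measurement_planes(mesh, seeds)
        assert abs(planes["chest"] - 0.72 * H) < 0.01 * H
        assert abs(planes["waist"] - 0.62 * H) < 0.01 * H
        assert abs(planes["hip"] - 0.54 * H) < 0.015 * H

    def test_constant_girth_phantom_equal_girths(self):
        mesh, _ = make_primitive("cylinder", dict(radius=140.0, height=1000.0), 256)
        fake = _fake_seeds_for(mesh)
        planes = locate_measurement_planes(mesh, fake)
        per = 256 * 2 * 140.0 * math.sin(math.pi / 256) / 10.0
        for name in ("chest", "waist", "hip"):
            sec = cross_section(mesh, planes[name])
            assert circumference(sec, "largest_area", "convex") == pytest.approx(
                per, rel=1e-6
            )

    def test_monotone_cone_falls_back_to_window_top(self):
        # radius shrinking upward: no interior girth maximum in the chest
        # window, so the search falls back to the armpit plane with a warning
        ys = np.linspace(0.0, 1000.0, 30)
        rings = []
        unit = np.column_stack([
            np.cos(np.linspace(0, 2 * math.pi, 64, endpoint=False)),
            np.sin(np.linspace(0, 2 * math.pi, 64, endpoint=False)),
        ])
        for y in ys:
            r = 200.0 - 0.15 * y
            rings.append(np.column_stack(
                [r * unit[:, 0], np.full(64, y), r * unit[:, 1]]
            ))
        from anthromesh.synth_body import _loft

        v, f = _loft(rings)
        mesh = TriangleMesh(v, f)
        fake = _fake_seeds_for(mesh)
        with pytest.warns(UserWarning, match="no interior girth maximum"):
            planes = locate_measurement_planes(mesh, fake)
        armpit_y = fake.world_heights["left_armpit"]
        assert planes["chest"] == pytest.approx(armpit_y, abs=1.0)


class TestMeasureReport:
    def test_humanoid_girth_recovery(self, humanoid, seeds):
        mesh, gt = humanoid
        rep = measure_report(mesh, seeds)
        for part in ("chest", "waist", "hip"):
            assert rep.circumferences[part] == pytest.approx(
                gt.circumferences[part], rel=0.02
            )
        assert rep.chest_volume == pytest.approx(gt.chest_volume_L, rel=0.05)
        assert rep.height == pytest.approx(mesh.height_mm() / 10.0, abs=1e-9)

    def test_similarity_scaling_of_all_quantities(self, humanoid, seeds):
        mesh, _ = humanoid
        rep = measure_report(mesh, seeds)
        s = 0.5
        small = resize_to_height(mesh, mesh.height_mm() / 10.0 * s)
        y0 = mesh.bounds()[0, 1]
        ys0 = small.bounds()[0, 1]

        def scale_h(h):
            return ys0 + (h - y0) * s

        heights = {k: scale_h(v) for k, v in seeds.world_heights.items()}
        world = {
            k: np.array([p[0] * s, scale_h(p[1]), p[2] * s])
            for k, p in seeds.world_points.items()
        }
        scaled_seeds = SeedPointSet(points=seeds.points,
                                    world_heights=heights, world_points=world)
        rep2 = measure_report(small, scaled_seeds)
        for part, v in rep.circumferences.items():
            assert rep2.circumferences[part] == pytest.approx(v * s, rel=1e-6)
        assert rep2.chest_volume == pytest.approx(rep.chest_volume * s**3,
                                                  rel=1e-6)

    def test_limb_girths_positive_and_plausible(self, humanoid, seeds):
        mesh, _ = humanoid
        rep = measure_report(mesh, seeds)
        for part in ("left_arm", "right_arm", "left_thigh", "right_thigh"):
            assert 10.0 < rep.circumferences[part] < 80.0
        assert rep.circumferences["left_arm"] == pytest.approx(
            rep.circumferences["right_arm"], rel=1e-6
        )


class TestObesityIndices:
    def test_bmi_formula(self):
        assert bmi(70.0, 175.0) == pytest.approx(22.857, abs=1e-3)

    def test_whtr_formula(self):
        assert whtr(80.0, 160.0) == 0.5

    def test_bmi_scale_invariance(self):
        # doubling weight while scaling height by sqrt(2) preserves BMI
        assert bmi(70.0, 175.0) == pytest.approx(
            bmi(140.0, 175.0 * math.sqrt(2.0)), rel=1e-12
        )

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ParameterError):
            bmi(0.0, 175.0)
        with pytest.raises(ParameterError):
            whtr(80.0, -1.0)
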