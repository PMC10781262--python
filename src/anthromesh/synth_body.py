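"""Parametric A-pose humanoid meshes and primitives with analytic ground truth.

The humanoid stands in an A-pose — arms abducted clear of the torso, legs
apart — because the silhouette landmark rules need a visible armpit gap and
crotch gap.  It is assembled from watertight parts:

* torso: a loft of elliptical cross-sections between control levels (pelvis
  bottom, hip, waist, chest, shoulder), monotone-cubic (PCHIP) interpolated
  so girth extrema sit exactly at the control levels;
* head: an ellipsoid on a neck cylinder whose radius creates the thinnest
  row in the top 30 % of the body;
* arms: tapered cylinders abducted from shoulder sockets, with a
  hemispherical shoulder cap so the upper arm overlaps the torso silhouette
  down to the intended armpit;
* legs: cylinders separated by a stance gap that closes exactly at the
  pelvis bottom (the crotch).

Cross-section profiles are true 256-gon polygons, so ground-truth girths are
exact polygon perimeter sums (no elliptic-integral approximation) and the
ground-truth chest slab volume is a quadrature of the exact polygon-area
function of the construction — both independent of any mesh slicing or
rendering downstream.

Body-level fractions of total height (pelvis 0.48, hip 0.54, waist 0.62,
chest 0.72, shoulder 0.82, head bottom 0.88) follow standard anthropometric
proportion tables for standing adults.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.integrate import quad
from scipy.optimize import brentq

from .errors import ParameterError
from .mesh_io import TriangleMesh, write_stl
from .projection import CameraConfig, multi_view_snapshots

# vertical placement of body levels, as fractions of total height
LEVEL_FRACTIONS = {
    "pelvis": 0.48,
    "hip": 0.54,
    "waist": 0.62,
    "chest": 0.72,
    "shoulder": 0.82,
}
NECK_BOTTOM_FRAC = 0.80
NECK_TOP_FRAC = 0.90
HEAD_CENTER_FRAC = 0.94
HEAD_RY_FRAC = 0.06
ARM_SOCKET_FRAC = 0.80
#: pelvis-bottom and shoulder girths relative to hip and chest girths
PELVIS_GIRTH_RATIO = 0.92
SHOULDER_GIRTH_RATIO = 0.92


@dataclass(frozen=True)
class BodyParams:
    """Construction parameters of a synthetic standing body.

    Girths are target circumferences (cm) of the torso profile polygon at
    the named levels; the torso ellipse keeps a fixed width/depth ratio
    ``torso_aspect``.  ``abduction_deg`` must exceed 10° and
    ``stance_half_gap_mm`` must be positive so the armpit and crotch gaps
    exist in the frontal silhouette.
    """

    height_mm: float = 1750.0
    chest_girth_cm: float = 100.0
    waist_girth_cm: float = 80.0
    hip_girth_cm: float = 96.0
    torso_aspect: float = 1.45
    head_radius_mm: float = 95.0
    neck_radius_mm: float = 55.0
    arm_radius_mm: float = 45.0
    arm_tip_radius_mm: float = 25.0
    arm_length_frac: float = 0.42
    abduction_deg: float = 25.0
    leg_radius_mm: float = 70.0
    stance_half_gap_mm: float = 25.0
    profile_sides: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height_mm <= 0:
            raise ParameterError("height must be positive")
        if not (self.waist_girth_cm < self.chest_girth_cm
                and self.waist_girth_cm < self.hip_girth_cm):
            raise ParameterError("body plan requires waist girth < chest and < hip")
        if self.abduction_deg <= 10.0:
            raise ParameterError("abduction must exceed 10 deg for an armpit gap")
        if self.stance_half_gap_mm <= 0:
            raise ParameterError("stance gap must be positive for a crotch gap")
        if self.profile_sides < 16:
            raise ParameterError("profile_sides must be at least 16")


@dataclass
class GroundTruth:
    """Analytic measurements of a constructed body or primitive.

    Girths are exact perimeters (cm) of the constructed profile polygons;
    ``chest_volume_L`` integrates the exact polygon-area function between
    the waist and chest levels; landmark heights (mm) come from the
    construction levels (the armpit from solving arm-silhouette edge =
    torso edge).
    """

    height_cm: float
    circumferences: dict[str, float] = field(default_factory=dict)
    chest_volume_L: float | None = None
    landmark_heights: dict[str, float] = field(default_factory=dict)
    volume_L: float | None = None


# ---------------------------------------------------------------------------
# mesh assembly helpers


def _polygon_unit(sides: int) -> np.ndarray:
    th = np.linspace(0.0, 2.0 * math.pi, sides, endpoint=False)
    return np.column_stack([np.cos(th), np.sin(th)])


def _polygon_perimeter_unit(sides: int, aspect: float) -> float:
    """Perimeter of the polygon inscribed in an ellipse with a=1, b=1/aspect."""
    ring = _polygon_unit(sides) * np.array([1.0, 1.0 / aspect])
    d = np.diff(np.vstack([ring, ring[:1]]), axis=0)
    return float(np.linalg.norm(d, axis=1).sum())


def _polygon_area_coeff(sides: int) -> float:
    """Area of the polygon inscribed in an ellipse = coeff * a * b."""
    return 0.5 * sides * math.sin(2.0 * math.pi / sides)


def _loft(rings: list[np.ndarray], close_bottom=True, close_top=True):
    """Triangulate a stack of rings (each (S, 3)) into a watertight tube."""
    S = len(rings[0])
    verts = [r for r in rings]
    faces = []
    for k in range(len(rings) - 1):
        base0, base1 = k * S, (k + 1) * S
        for i in range(S):
            j = (i + 1) % S
            faces.append([base0 + i, base1 + i, base1 + j])
            faces.append([base0 + i, base1 + j, base0 + j])
    verts = np.vstack(verts)
    extra = []
    if close_bottom:
        c = len(verts) + len(extra)
        extra.append(rings[0].mean(axis=0))
        for i in range(S):
            faces.append([c, (i + 1) % S, i])
    if close_top:
        c = len(verts) + len(extra)
        extra.append(rings[-1].mean(axis=0))
        base = (len(rings) - 1) * S
        for i in range(S):
            faces.append([c, base + i, base + (i + 1) % S])
    if extra:
        verts = np.vstack([verts] + [np.asarray(extra)])
    return verts, np.asarray(faces, dtype=np.int64)


def _merge(parts: list[tuple[np.ndarray, np.ndarray]]) -> TriangleMesh:
    verts, faces, off = [], [], 0
    for v, f in parts:
        verts.append(v)
        faces.append(f + off)
        off += len(v)
    return TriangleMesh(np.vstack(verts), np.vstack(faces))


def _cylinder_part(center_x: float, center_z: float, radius: float,
                   y0: float, y1: float, sides: int):
    ring = _polygon_unit(sides) * radius
    rings = [
        np.column_stack([ring[:, 0] + center_x, np.full(sides, y), ring[:, 1] + center_z])
        for y in (y0, y1)
    ]
    return _loft(rings)


def _ellipsoid_part(center: np.ndarray, semi: np.ndarray,
                    sectors: int = 48, stacks: int = 24):
    """Lat-long ellipsoid as a loft of circles with pole caps."""
    phis = np.linspace(-math.pi / 2, math.pi / 2, stacks + 1)[1:-1]
    rings = []
    for phi in phis:
        ring = _polygon_unit(sectors)
        x = semi[0] * math.cos(phi) * ring[:, 0] + center[0]
        z = semi[2] * math.cos(phi) * ring[:, 1] + center[2]
        y = np.full(sectors, semi[1] * math.sin(phi) + center[1])
        rings.append(np.column_stack([x, y, z]))
    verts, faces = _loft(rings, close_bottom=False, close_top=False)
    # pole caps
    S = sectors
    vb = np.array([center[0], center[1] - semi[1], center[2]])
    vt = np.array([center[0], center[1] + semi[1], center[2]])
    ib, it = len(verts), len(verts) + 1
    verts = np.vstack([verts, vb, vt])
    cap = []
    top_base = (len(rings) - 1) * S
    for i in range(S):
        j = (i + 1) % S
        cap.append([ib, j, i])
        cap.append([it, top_base + i, top_base + j])
    return verts, np.vstack([faces, np.asarray(cap, dtype=np.int64)])


def _arm_part(params: BodyParams, side: int, socket_x: float):
    """Tapered arm cone from the shoulder socket plus a hemispherical cap.

    ``side`` is +1 for the subject-left (+X) arm.
    """
    H = params.height_mm
    alpha = math.radians(params.abduction_deg)
    L = params.arm_length_frac * H
    y_s = ARM_SOCKET_FRAC * H
    socket = np.array([side * socket_x, y_s, 0.0])
    axis = np.array([side * math.sin(alpha), -math.cos(alpha), 0.0])
    # in-plane perpendicular and z form the tube frame
    perp = np.array([side * math.cos(alpha), math.sin(alpha), 0.0])
    ez = np.array([0.0, 0.0, 1.0])
    sides = 48
    unit = _polygon_unit(sides)
    n_rings = 10
    rings = []
    for t in np.linspace(0.0, 1.0, n_rings):
        r = params.arm_radius_mm + t * (params.arm_tip_radius_mm - params.arm_radius_mm)
        c = socket + t * L * axis
        rings.append(c + r * (unit[:, :1] * perp + unit[:, 1:] * ez))
    cone_v, cone_f = _loft(rings, close_bottom=False, close_top=True)

    # hemisphere over the socket, opening along -axis
    r0 = params.arm_radius_mm
    hemis = []
    for phi in np.linspace(0.0, math.pi / 2, 7)[:-1]:
        rr = r0 * math.cos(phi)
        c = socket - r0 * math.sin(phi) * axis
        hemis.append(c + rr * (unit[:, :1] * perp + unit[:, 1:] * ez))
    hemi_v, hemi_f = _loft(hemis[::-1], close_bottom=False, close_top=False)
    apex = socket - r0 * axis
    ia = len(hemi_v)
    hemi_v = np.vstack([hemi_v, apex])
    cap = []
    for i in range(sides):
        cap.append([ia, i, (i + 1) % sides])
    hemi_f = np.vstack([hemi_f, np.asarray(cap, dtype=np.int64)])
    return _merge([(cone_v, cone_f), (hemi_v, hemi_f)])


# ---------------------------------------------------------------------------
# torso profile


class _TorsoProfile:
    """PCHIP semi-axis functions a(y), b(y) through the control levels."""

    def __init__(self, params: BodyParams):
        H = params.height_mm
        p_unit = _polygon_perimeter_unit(params.profile_sides, params.torso_aspect)
        girths_mm = {
            "pelvis": PELVIS_GIRTH_RATIO * params.hip_girth_cm * 10.0,
            "hip": params.hip_girth_cm * 10.0,
            "waist": params.waist_girth_cm * 10.0,
            "chest": params.chest_girth_cm * 10.0,
            "shoulder": SHOULDER_GIRTH_RATIO * params.chest_girth_cm * 10.0,
        }
        ys = np.array([LEVEL_FRACTIONS[k] * H for k in girths_mm])
        a_vals = np.array([girths_mm[k] / p_unit for k in girths_mm])
        order = np.argsort(ys)
        self.y_knots = ys[order]
        self.a = PchipInterpolator(ys[order], a_vals[order])
        self.aspect = params.torso_aspect
        self.sides = params.profile_sides
        self.area_coeff = _polygon_area_coeff(params.profile_sides) / params.torso_aspect
        self.p_unit = p_unit

    def semi_a(self, y):
        return self.a(y)

    def perimeter_mm(self, y) -> float:
        return float(self.a(y)) * self.p_unit

    def area_mm2(self, y) -> float:
        a = float(self.a(y))
        return self.area_coeff * a * a  # coeff already folds in b = a/aspect

    @property
    def y_bottom(self) -> float:
        return float(self.y_knots[0])

    @property
    def y_top(self) -> float:
        return float(self.y_knots[-1])


def _torso_part(params: BodyParams, profile: _TorsoProfile):
    H = params.height_mm
    ys = np.unique(np.concatenate([
        np.linspace(profile.y_bottom, profile.y_top, 30), profile.y_knots
    ]))
    unit = _polygon_unit(params.profile_sides)
    rings = []
    for y in ys:
        a = float(profile.semi_a(y))
        b = a / params.torso_aspect
        rings.append(np.column_stack([a * unit[:, 0], np.full(len(unit), y), b * unit[:, 1]]))
    return _loft(rings)


def _arm_inner_edge_x(params: BodyParams, y: float, socket_x: float) -> float:
    """Frontal-silhouette inner edge of the arm cone at height y (mm)."""
    H = params.height_mm
    alpha = math.radians(params.abduction_deg)
    y_s = ARM_SOCKET_FRAC * H
    L = params.arm_length_frac * H
    s = (y_s - y) / math.cos(alpha)  # axial distance
    t = s / L
    r = params.arm_radius_mm + t * (params.arm_tip_radius_mm - params.arm_radius_mm)
    return socket_x + s * math.sin(alpha) - r / math.cos(alpha)


def _solve_armpit_y(params: BodyParams, profile: _TorsoProfile,
                    socket_x: float) -> float:
    """Height where the arm silhouette separates from the torso silhouette."""
    H = params.height_mm
    y_s = ARM_SOCKET_FRAC * H

    def gap(y):
        return _arm_inner_edge_x(params, y, socket_x) - float(profile.semi_a(y))

    lo, hi = profile.y_bottom + 1.0, y_s - 1.0
    if gap(hi) >= 0:
        raise ParameterError("arm already clear of torso at the shoulder; "
                             "abduction too large or torso too narrow")
    if gap(lo) <= 0:
        raise ParameterError("arm never separates from torso; abduction too small")
    return float(brentq(gap, lo, hi))


# ---------------------------------------------------------------------------
# public generators


def make_humanoid(params: BodyParams | None = None) -> tuple[TriangleMesh, GroundTruth]:
    """Build an A-pose humanoid mesh and its analytic ground truth.

    Raises :class:`ParameterError` if the arm placement cannot produce an
    armpit gap between the chest level and the shoulder.
    """
    if params is None:
        params = BodyParams()
    H = params.height_mm
    profile = _TorsoProfile(params)

    a_shoulder = float(profile.semi_a(profile.y_top))
    socket_x = a_shoulder + 0.5 * params.arm_radius_mm

    parts = [_torso_part(params, profile)]
    # head + neck
    head_center = np.array([0.0, HEAD_CENTER_FRAC * H, 0.0])
    head_semi = np.array([params.head_radius_mm, HEAD_RY_FRAC * H, params.head_radius_mm])
    parts.append(_ellipsoid_part(head_center, head_semi))
    parts.append(_cylinder_part(0.0, 0.0, params.neck_radius_mm,
                                NECK_BOTTOM_FRAC * H, NECK_TOP_FRAC * H, 48))
    # arms
    for side in (+1, -1):
        arm = _arm_part(params, side, socket_x)
        parts.append((arm.vertices, arm.faces))
    # legs
    leg_x = params.stance_half_gap_mm + params.leg_radius_mm
    for side in (+1, -1):
        parts.append(_cylinder_part(side * leg_x, 0.0, params.leg_radius_mm,
                                    0.0, (LEVEL_FRACTIONS["pelvis"] + 0.02) * H, 48))

    mesh = _merge(parts)

    # sanity: the armpit gap must open below the shoulder and above the chest
    armpit_y = _solve_armpit_y(params, profile, socket_x)
    if armpit_y <= LEVEL_FRACTIONS["chest"] * H:
        raise ParameterError(
            f"armpit gap opens at {armpit_y / H:.3f}H, below the chest level; "
            "adjust abduction or arm radius"
        )

    alpha = math.radians(params.abduction_deg)
    fingertip_y = ARM_SOCKET_FRAC * H - params.arm_length_frac * H * math.cos(alpha)

    chest_y = LEVEL_FRACTIONS["chest"] * H
    waist_y = LEVEL_FRACTIONS["waist"] * H
    vol_mm3, _ = quad(profile.area_mm2, waist_y, chest_y, limit=200)

    gt = GroundTruth(
        height_cm=H / 10.0,
        circumferences={
            "chest": params.chest_girth_cm,
            "waist": params.waist_girth_cm,
            "hip": params.hip_girth_cm,
        },
        chest_volume_L=vol_mm3 / 1e6,
        landmark_heights={
            "head_top": H,
            "neck": (HEAD_CENTER_FRAC - HEAD_RY_FRAC) * H,
            "armpit": armpit_y,
            "crotch": LEVEL_FRACTIONS["pelvis"] * H,
            "toes": 0.0,
            "fingertip": fingertip_y,
        },
    )
    return mesh, gt


def make_primitive(kind: str, dims: dict, profile_sides: int = 256
                   ) -> tuple[TriangleMesh, GroundTruth]:
    """Oracle fixtures: ``cylinder`` (radius, height), ``ellipsoid``
    (a, b, c), ``box`` (dx, dy, dz); all dimensions in mm, +Y up, base or
    centre at the origin as noted per kind."""
    if any(v <= 0 for v in dims.values()):
        raise ParameterError(f"{kind} dimensions must be positive: {dims}")
    if kind == "cylinder":
        r, h = dims["radius"], dims["height"]
        v, f = _cylinder_part(0.0, 0.0, r, 0.0, h, profile_sides)
        mesh = TriangleMesh(v, f)
        per = profile_sides * 2.0 * r * math.sin(math.pi / profile_sides)
        area = _polygon_area_coeff(profile_sides) * r * r
        gt = GroundTruth(
            height_cm=h / 10.0,
            circumferences={"mid": per / 10.0},
            volume_L=area * h / 1e6,
        )
        return mesh, gt
    if kind == "ellipsoid":
        a, b, c = dims["a"], dims["b"], dims["c"]
        v, f = _ellipsoid_part(np.array([0.0, 0.0, 0.0]), np.array([a, b, c]),
                               sectors=min(profile_sides, 96), stacks=48)
        mesh = TriangleMesh(v, f)
        gt = GroundTruth(
            height_cm=2 * b / 10.0,
            volume_L=4.0 / 3.0 * math.pi * a * b * c / 1e6,
        )
        return mesh, gt
    if kind == "box":
        dx, dy, dz = dims["dx"], dims["dy"], dims["dz"]
        x, y, z = dx / 2.0, dy, dz / 2.0
        verts = np.array([
            [-x, 0, -z], [x, 0, -z], [x, 0, z], [-x, 0, z],
            [-x, y, -z], [x, y, -z], [x, y, z], [-x, y, z],
        ], dtype=float)
        faces = np.array([
            [0, 1, 2], [0, 2, 3],          # bottom (-y outward)
            [4, 6, 5], [4, 7, 6],          # top (+y outward)
            [0, 5, 1], [0, 4, 5],          # -z
            [2, 7, 3], [2, 6, 7],          # +z
            [1, 6, 2], [1, 5, 6],          # +x
            [3, 4, 0], [3, 7, 4],          # -x
        ])
        mesh = TriangleMesh(verts, faces)
        gt = GroundTruth(
            height_cm=dy / 10.0,
            circumferences={"mid": 2.0 * (dx + dz) / 10.0},
            volume_L=dx * dy * dz / 1e6,
        )
        return mesh, gt
    raise ParameterError(f"unknown primitive kind {kind!r}")


def sample_population(n: int, seed: int = 0
                      ) -> list[tuple[TriangleMesh, GroundTruth]]:
    """Draw ``n`` random humanoids, deterministic in ``seed``.

    Heights are uniform on 1500–1900 mm and girths on chest 80–115, waist
    60–105, hip 80–115 cm, with rejection until the body plan (waist below
    chest and hip) holds.  All randomness flows through one seeded
    generator.
    """
    if n < 1:
        raise ParameterError("n must be at least 1")
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n:
        try:
            params = BodyParams(
                height_mm=rng.uniform(1500.0, 1900.0),
                chest_girth_cm=rng.uniform(80.0, 115.0),
                waist_girth_cm=rng.uniform(60.0, 105.0),
                hip_girth_cm=rng.uniform(80.0, 115.0),
                head_radius_mm=rng.uniform(85.0, 105.0),
                neck_radius_mm=rng.uniform(48.0, 62.0),
                arm_radius_mm=rng.uniform(40.0, 50.0),
                leg_radius_mm=rng.uniform(60.0, 80.0),
                stance_half_gap_mm=rng.uniform(20.0, 35.0),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            out.append(make_humanoid(params))
        except ParameterError:
            continue
    return out


def paired_dataset(mesh: TriangleMesh, out_dir: str | Path,
                   cfg: CameraConfig | None = None,
                   step_deg: float = 45.0,
                   size: int = 512) -> dict:
    """Write mesh + one orbit of depth maps + a JSON manifest pairing them."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if cfg is None:
        cfg = CameraConfig()
    stl_path = out_dir / "body.stl"
    write_stl(mesh, stl_path, dialect="binary")
    maps = multi_view_snapshots(mesh, cfg, step_deg, size, size)
    images = []
    for k, dm in enumerate(maps):
        angle = k * step_deg
        png = out_dir / f"view_{int(angle):03d}.png"
        dm.save_png(png)
        images.append({"angle_deg": angle, "path": png.name})
    manifest = {
        "mesh": stl_path.name,
        "images": images,
        "camera": {
            "fovy": cfg.fovy, "aspect": cfg.aspect,
            "cam_height_m": cfg.cam_height, "cam_distance_m": cfg.cam_distance,
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
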