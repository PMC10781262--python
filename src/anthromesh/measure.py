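"""Body measurements from a mesh: girths, lengths, volumes, vertex normals.

Circumferences come from horizontal cross-sections: every triangle is
intersected with the plane y = const, the resulting segments are chained into
closed loops, and a loop's perimeter is the girth.  ``convex`` tape mode
measures the convex-hull perimeter instead, emulating a tape measure spanning
concavities (used for torso girths); limb girths use the raw perimeter.

Volumes are slab integrals: cross-section area integrated over uniformly
spaced planes with the trapezoid rule.

Measurement planes are located relative to detected landmarks by searching
for perimeter extrema (widest torso section between waist and armpit = chest,
narrowest = waist, widest below = hip), which self-calibrates across body
shapes instead of hard-coding height fractions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon
from trimesh.intersections import mesh_plane

from .errors import MeasurementError, ParameterError
from .landmarks import SeedPointSet
from .mesh_io import TriangleMesh

#: segment endpoints closer than this (mm) are chained together
CHAIN_TOL_MM = 1e-6


# ---------------------------------------------------------------------------
# vertex normals


@dataclass
class VertexNormals:
    """Per-vertex unit normals; zero vector flags an isolated vertex."""

    normals: np.ndarray


def vertex_normals(mesh: TriangleMesh) -> VertexNormals:
    """Average the unit normals of the faces incident to each vertex.

    The mean is unweighted, as in classical smooth (Phong-style) shading;
    degenerate zero-area faces are skipped with a warning.
    """
    v, f = mesh.vertices, mesh.faces
    fn = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    norms = np.linalg.norm(fn, axis=1)
    good = norms > 1e-12
    if not good.all():
        warnings.warn(f"skipped {int((~good).sum())} degenerate face(s)")
    unit = np.zeros_like(fn)
    unit[good] = fn[good] / norms[good, None]

    acc = np.zeros_like(v)
    cnt = np.zeros(len(v))
    for k in range(3):
        np.add.at(acc, f[good, k], unit[good])
        np.add.at(cnt, f[good, k], 1.0)
    out = np.zeros_like(v)
    used = cnt > 0
    mean = acc[used] / cnt[used, None]
    length = np.linalg.norm(mean, axis=1)
    nz = length > 1e-12
    mean[nz] = mean[nz] / length[nz, None]
    out[used] = mean
    return VertexNormals(normals=out)


# ---------------------------------------------------------------------------
# cross sections


@dataclass
class CrossSection:
    """Closed loops of a horizontal section at ``plane_y`` (mm).

    Each loop is an (N, 2) array of (x, z) points in mm, implicitly closed.
    """

    plane_y: float
    loops: list[np.ndarray]
    perimeters: list[float] = field(default_factory=list)
    areas: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.perimeters:
            self.perimeters = [_loop_perimeter(lp) for lp in self.loops]
        if not self.areas:
            self.areas = [_loop_area(lp) for lp in self.loops]

    @property
    def is_empty(self) -> bool:
        return len(self.loops) == 0

    def total_area(self) -> float:
        return float(sum(self.areas))

    def total_perimeter(self) -> float:
        return float(sum(self.perimeters))


def _loop_perimeter(loop: np.ndarray) -> float:
    d = np.diff(np.vstack([loop, loop[:1]]), axis=0)
    return float(np.linalg.norm(d, axis=1).sum())


def _loop_area(loop: np.ndarray) -> float:
    x, z = loop[:, 0], loop[:, 1]
    return float(abs(np.dot(x, np.roll(z, -1)) - np.dot(z, np.roll(x, -1))) / 2.0)


def _chain_segments(segments: np.ndarray) -> list[np.ndarray]:
    """Chain unordered 2D segments into closed loops by endpoint matching.

    Endpoints are matched on coordinates rounded to ``CHAIN_TOL_MM``.  Open
    chains (non-watertight regions) are dropped with a warning.
    """
    decimals = max(0, -int(math.floor(math.log10(CHAIN_TOL_MM))))
    key = lambda p: (round(p[0], decimals), round(p[1], decimals))

    adj: dict[tuple, list[tuple[int, int]]] = {}
    for i, seg in enumerate(segments):
        for end in (0, 1):
            adj.setdefault(key(seg[end]), []).append((i, end))

    used = np.zeros(len(segments), dtype=bool)
    loops = []
    for start in range(len(segments)):
        if used[start]:
            continue
        used[start] = True
        chain = [segments[start][0], segments[start][1]]
        closed = False
        while True:
            k = key(chain[-1])
            nxt = next(((i, e) for i, e in adj.get(k, []) if not used[i]), None)
            if nxt is None:
                closed = key(chain[0]) == key(chain[-1])
                break
            i, e = nxt
            used[i] = True
            chain.append(segments[i][1 - e])
        if closed and len(chain) >= 4:
            loop = np.asarray(chain[:-1])
            if _loop_area(loop) > 1e-9:
                loops.append(loop)
        elif not closed and len(chain) > 2:
            warnings.warn(
                f"discarded open section chain of {len(chain)} points"
            )
    return loops


def cross_section(mesh: TriangleMesh, plane_y: float) -> CrossSection:
    """Intersect the mesh with the horizontal plane ``y = plane_y``.

    Returns the closed loops (x, z) found there; a plane outside the mesh
    yields an empty section.
    """
    tm = mesh.to_trimesh()
    segs3 = mesh_plane(tm, plane_normal=[0.0, 1.0, 0.0],
                       plane_origin=[0.0, plane_y, 0.0])
    if len(segs3) == 0:
        return CrossSection(plane_y=plane_y, loops=[])
    segs2 = segs3[:, :, [0, 2]]  # project to (x, z)
    loops = _chain_segments(segs2)
    return CrossSection(plane_y=plane_y, loops=loops)


def _select_loop(section: CrossSection, loop_select: str,
                 centroid_xz: tuple[float, float] | None = None) -> int:
    if section.is_empty:
        raise MeasurementError(f"empty section at y={section.plane_y}")
    if loop_select == "largest_area":
        return int(np.argmax(section.areas))
    if loop_select == "nearest_centroid":
        if centroid_xz is None:
            centroid_xz = (0.0, 0.0)
        c = np.asarray(centroid_xz)
        d = [np.linalg.norm(lp.mean(axis=0) - c) for lp in section.loops]
        return int(np.argmin(d))
    raise ParameterError(f"unknown loop_select {loop_select!r}")


def circumference(
    section: CrossSection,
    loop_select: str = "largest_area",
    tape_mode: str = "raw",
    centroid_xz: tuple[float, float] | None = None,
) -> float:
    """Girth of one loop of a section, in cm.

    ``raw`` returns the loop perimeter; ``convex`` the perimeter of its
    convex hull (a tape measure bridges concavities, so convex <= raw).
    """
    if tape_mode not in ("raw", "convex"):
        raise ParameterError(f"tape_mode must be 'raw' or 'convex', got {tape_mode!r}")
    i = _select_loop(section, loop_select, centroid_xz)
    if tape_mode == "raw":
        return section.perimeters[i] / 10.0
    hull = Polygon(section.loops[i]).convex_hull
    return float(hull.length) / 10.0


def slab_volume(
    mesh: TriangleMesh,
    y_low: float,
    y_high: float,
    n_slices: int = 64,
    loop_mode: str = "all",
) -> float:
    """Volume (litres) between two horizontal planes by slab integration.

    Section area is sampled on ``n_slices + 1`` uniform planes and integrated
    with the trapezoid rule.  ``loop_mode='largest'`` keeps only the
    largest-area loop per slice (e.g. the torso, excluding arm loops).
    """
    if y_low > y_high:
        raise ParameterError("require y_low <= y_high")
    if y_low == y_high:
        return 0.0
    ys = np.linspace(y_low, y_high, n_slices + 1)
    # the end planes are often tangent to caps (empty intersection); the
    # slice of the closed solid there is its limiting interior section
    eps = (y_high - y_low) * 1e-9
    ys[0] += eps
    ys[-1] -= eps
    areas = np.empty(len(ys))
    any_nonempty = False
    for i, y in enumerate(ys):
        sec = cross_section(mesh, y)
        if sec.is_empty:
            areas[i] = 0.0
            continue
        any_nonempty = True
        if loop_mode == "largest":
            areas[i] = sec.areas[int(np.argmax(sec.areas))]
        else:
            areas[i] = sec.total_area()
    if not any_nonempty:
        warnings.warn("all sections empty; slab volume is 0")
        return 0.0
    mm3 = np.trapezoid(areas, ys)
    return float(mm3) / 1e6


# ---------------------------------------------------------------------------
# measurement planes and report


@dataclass
class MeasurementReport:
    """Per-part body values: height (cm), girths (cm), lengths (cm), volume (L)."""

    height: float
    circumferences: dict[str, float]
    chest_volume: float
    lengths: dict[str, float]
    planes: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "height_cm": self.height,
            "circumferences_cm": dict(self.circumferences),
            "chest_volume_L": self.chest_volume,
            "lengths_cm": dict(self.lengths),
            "planes_mm": dict(self.planes),
        }


def _torso_perimeter_at(mesh: TriangleMesh, y: float, tape_mode: str = "convex") -> float:
    """Convex perimeter (mm) of the largest loop at height y; 0 if empty."""
    sec = cross_section(mesh, y)
    if sec.is_empty:
        return 0.0
    i = int(np.argmax(sec.areas))
    if tape_mode == "convex":
        return float(Polygon(sec.loops[i]).convex_hull.length)
    return sec.perimeters[i]


def locate_measurement_planes(
    mesh: TriangleMesh,
    seeds: SeedPointSet,
    n_search: int = 48,
) -> dict[str, float]:
    """Find the section heights (mm) for chest, waist, hip, thighs and arms.

    Chest = widest torso section between the waist-search floor and the
    armpit; waist = narrowest torso section in the upper 60 % of the
    crotch-to-armpit span; hip = widest section between crotch and waist.
    Thigh planes sit 5 % of body height below the crotch; upper-arm planes
    25 % of the shoulder-to-fingertip span below the armpit.  Extremum
    searches sample ``n_search`` planes per window; a window with no interior
    extremum falls back to its upper bound with a warning.
    """
    wh = seeds.world_heights
    armpit_y = min(wh["left_armpit"], wh["right_armpit"])
    crotch_y = wh["crotch"]
    shoulder_y = (wh["left_shoulder"] + wh["right_shoulder"]) / 2.0
    fingertip_y = (wh["left_fingertip"] + wh["right_fingertip"]) / 2.0
    body_h = mesh.height_mm()
    y0 = float(mesh.bounds()[0, 1])

    if not (crotch_y < armpit_y):
        raise MeasurementError("crotch landmark above armpit; cannot search planes")

    waist_floor = crotch_y + 0.4 * (armpit_y - crotch_y)

    def argext(lo: float, hi: float, mode: str) -> float:
        eps = (hi - lo) * 1e-3
        ys = np.linspace(lo + eps, hi - eps, n_search)
        per = np.array([_torso_perimeter_at(mesh, y) for y in ys])
        ok = per > 0
        if not ok.any():
            raise MeasurementError(f"no torso section in [{lo:.1f}, {hi:.1f}] mm")
        ys, per = ys[ok], per[ok]
        # prefer interior local extrema: the anatomical level is a girth
        # extremum of the torso, not a window-boundary artefact
        if mode == "max":
            interior = [
                i for i in range(1, len(per) - 1)
                if per[i] >= per[i - 1] and per[i] >= per[i + 1]
            ]
        else:
            interior = [
                i for i in range(1, len(per) - 1)
                if per[i] <= per[i - 1] and per[i] <= per[i + 1]
            ]
        if interior:
            best = max(interior, key=lambda i: per[i]) if mode == "max" else \
                min(interior, key=lambda i: per[i])
            return float(ys[best])
        if mode == "max":
            # monotone window (e.g. cone torso): fall back to the upper bound
            warnings.warn(
                f"no interior girth maximum in [{lo:.1f}, {hi:.1f}] mm; "
                "falling back to the window's upper bound"
            )
            return float(hi)
        return float(ys[int(np.argmin(per))])

    chest_y = argext(waist_floor, armpit_y, "max")
    waist_y = argext(waist_floor, armpit_y, "min")
    hip_y = argext(crotch_y, waist_y, "max")
    thigh_y = crotch_y - 0.05 * body_h
    arm_y = armpit_y - 0.25 * (shoulder_y - fingertip_y)

    return {
        "chest": chest_y,
        "waist": waist_y,
        "hip": hip_y,
        "thigh": max(thigh_y, y0 + 1e-3),
        "arm": arm_y,
    }


def _side_loop_circumference(
    mesh: TriangleMesh, y: float, side: str, exclude_central: bool
) -> float:
    """Raw girth (cm) of the left/right limb loop at height y.

    Picks the largest-area loop with centroid on the requested side of the
    body midline; with ``exclude_central`` the overall largest loop (the
    torso) is removed from consideration first.
    """
    sec = cross_section(mesh, y)
    if sec.is_empty:
        raise MeasurementError(f"empty section at y={y:.1f} for {side} limb")
    idxs = list(range(len(sec.loops)))
    if exclude_central and len(idxs) > 1:
        idxs.remove(int(np.argmax(sec.areas)))
    mid_x = float(np.mean([lp.mean(axis=0)[0] for lp in sec.loops]))
    sided = [
        i for i in idxs
        if (sec.loops[i].mean(axis=0)[0] < mid_x) == (side == "left")
    ]
    if not sided:
        raise MeasurementError(f"no {side}-side loop at y={y:.1f}")
    i = max(sided, key=lambda j: sec.areas[j])
    return sec.perimeters[i] / 10.0


def measure_report(mesh: TriangleMesh, seeds: SeedPointSet,
                   n_volume_slices: int = 64) -> MeasurementReport:
    """Full measurement report: height, seven girths, chest volume, lengths.

    Torso girths (chest/waist/hip) use convex tape mode on the largest loop;
    limb girths use raw perimeters of the side loops.  Chest volume is the
    torso-only slab between the chest and waist planes.  Lengths are
    landmark distances: shoulder-to-fingertip for arms, armpit-height to toe
    (vertical) for legs, neck-to-crotch (vertical) for the torso.
    """
    planes = locate_measurement_planes(mesh, seeds)
    circ: dict[str, float] = {}
    for name in ("chest", "waist", "hip"):
        sec = cross_section(mesh, planes[name])
        circ[name] = circumference(sec, "largest_area", "convex")
    for side in ("left", "right"):
        circ[f"{side}_arm"] = _side_loop_circumference(
            mesh, planes["arm"], side, exclude_central=True
        )
        circ[f"{side}_thigh"] = _side_loop_circumference(
            mesh, planes["thigh"], side, exclude_central=False
        )

    chest_volume = slab_volume(
        mesh, planes["waist"], planes["chest"], n_volume_slices, loop_mode="largest"
    )

    wp = seeds.world_points
    wh = seeds.world_heights
    lengths = {
        "arm_left": float(np.linalg.norm(wp["left_fingertip"] - wp["left_shoulder"])) / 10.0,
        "arm_right": float(np.linalg.norm(wp["right_fingertip"] - wp["right_shoulder"])) / 10.0,
        "leg_left": (wh["left_armpit"] - wh["left_toe"]) / 10.0,
        "leg_right": (wh["right_armpit"] - wh["right_toe"]) / 10.0,
        "torso": (wh["neck"] - wh["crotch"]) / 10.0,
    }

    return MeasurementReport(
        height=mesh.height_mm() / 10.0,
        circumferences=circ,
        chest_volume=chest_volume,
        lengths=lengths,
        planes=planes,
    )


# ---------------------------------------------------------------------------
# obesity indices


def bmi(weight_kg: float, height_cm: float) -> float:
    """Body-mass index, kg/m^2."""
    if weight_kg <= 0 or height_cm <= 0:
        raise ParameterError("weight and height must be positive")
    h = height_cm / 100.0
    return weight_kg / (h * h)


def whtr(waist_cm: float, height_cm: float) -> float:
    """Waist-to-height ratio (dimensionless)."""
    if waist_cm <= 0 or height_cm <= 0:
        raise ParameterError("waist and height must be positive")
    return waist_cm / height_cm
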