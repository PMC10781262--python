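"""Perspective camera model, CPU depth-map rendering and multi-view capture.

The capture geometry emulates a phone on a tripod: the camera sits at a given
height above the floor and horizontal distance from the subject, looking
horizontally along −Z at the subject's vertical axis.  A full orbit in fixed
angular steps (default 45°, eight views) produces the paired image sets used
to exercise the pipeline.

Depth is encoded near-bright: camera-space distance in ``[near_n, far_f]`` mm
maps linearly onto grayscale ``[255, 1]`` so the subject stands out against a
zero background.  The unquantised camera-space depth is kept alongside so any
silhouette pixel can be cast back to a 3D world point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import ParameterError
from .mesh_io import TriangleMesh


@dataclass(frozen=True)
class CameraConfig:
    """Perspective frustum plus physical placement.

    Parameters
    ----------
    fovy : float
        Vertical field of view, degrees (0 < fovy < 180).
    aspect : float
        Width/height ratio of the image plane.
    near_n, far_f : float
        Near/far clip distances, mm; also the ends of the grayscale ramp.
    cam_height : float
        Camera height above the floor, metres.
    cam_distance : float
        Horizontal camera-to-subject distance, metres.  The default (1 m, 3 m)
        placement is the error-minimising one found on the physical capture
        grid (see :mod:`anthromesh.evaluation`).
    yaw : float
        Orbit angle of the camera about the subject's vertical axis, degrees;
        0 is the frontal view.
    """

    fovy: float = 40.0
    aspect: float = 1.0
    near_n: float = 500.0
    far_f: float = 6000.0
    cam_height: float = 1.0
    cam_distance: float = 3.0
    yaw: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.fovy < 180.0):
            raise ParameterError(f"fovy must be in (0, 180), got {self.fovy}")
        if self.aspect <= 0:
            raise ParameterError("aspect must be positive")
        if not (0.0 < self.near_n < self.far_f):
            raise ParameterError("require 0 < near_n < far_f")
        if self.cam_distance <= 0:
            raise ParameterError("cam_distance must be positive")


@dataclass(frozen=True)
class ProjectionMatrix:
    """4x4 symmetric-frustum perspective matrix, camera frame -> clip space."""

    m: np.ndarray

    def apply(self, points_cam: np.ndarray) -> np.ndarray:
        """Project (N, 3) camera-frame points (mm, camera looks along −Z) to
        (N, 2) normalised device coordinates."""
        p = np.asarray(points_cam, dtype=np.float64)
        hom = np.column_stack([p, np.ones(len(p))])
        clip = hom @ self.m.T
        w = clip[:, 3]
        return clip[:, :2] / w[:, None]


def perspective_matrix(cfg: CameraConfig) -> ProjectionMatrix:
    """Build the perspective projection matrix for ``cfg``.

    With ``c = cot(fovy/2)`` the canonical projection plane sits at
    ``z = -c``: the matrix maps the frustum cone of half-angle fovy/2 about
    −Z onto |y_ndc| = 1.
    """
    half = math.radians(cfg.fovy) / 2.0
    c = 1.0 / math.tan(half)
    n, f = cfg.near_n, cfg.far_f
    m = np.array(
        [
            [c / cfg.aspect, 0.0, 0.0, 0.0],
            [0.0, c, 0.0, 0.0],
            [0.0, 0.0, -(f + n) / (f - n), -2.0 * f * n / (f - n)],
            [0.0, 0.0, -1.0, 0.0],
        ]
    )
    return ProjectionMatrix(m)


@dataclass
class DepthMap:
    """8-bit grayscale depth image with back-projection metadata.

    ``pixels[row, col]`` is 0 for background; nonzero values encode depth
    near-bright.  ``world_depth`` holds the unquantised camera-space distance
    (mm) per pixel (NaN on background).  ``pivot`` is the world (x, y, z)
    point on the subject's vertical axis the camera orbits about.
    """

    pixels: np.ndarray
    camera: CameraConfig
    world_depth: np.ndarray
    pivot: np.ndarray
    row0_is_top: bool = True
    all_background: bool = False

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def silhouette(self) -> np.ndarray:
        """Boolean H×W mask of nonzero pixels."""
        return self.pixels > 0

    def save_png(self, path: str | Path) -> None:
        import imageio.v3 as iio

        iio.imwrite(Path(path), self.pixels.astype(np.uint8))


def _camera_frame(cfg: CameraConfig, pivot: np.ndarray):
    """Camera origin and orthonormal axes (right, up, back) in world mm.

    The camera orbits the pivot's vertical axis at ``yaw`` degrees, stays
    level at ``cam_height`` m above the floor (world y = 0 is the subject's
    min-Y before rendering, handled by the caller) and looks horizontally
    toward the axis.
    """
    yaw = math.radians(cfg.yaw)
    d = cfg.cam_distance * 1000.0
    h = cfg.cam_height * 1000.0
    # yaw 0 puts the camera on the +Z side (frontal view)
    offset = np.array([math.sin(yaw) * d, 0.0, math.cos(yaw) * d])
    origin = np.array([pivot[0], 0.0, pivot[2]]) + offset
    origin[1] = h
    back = np.array([math.sin(yaw), 0.0, math.cos(yaw)])  # +Z_cam (away)
    up = np.array([0.0, 1.0, 0.0])
    right = np.cross(up, back)
    return origin, right, up, back


def _world_to_cam(points: np.ndarray, origin, right, up, back) -> np.ndarray:
    rel = points - origin
    return np.column_stack([rel @ right, rel @ up, rel @ back])


def render_depth_map(
    mesh: TriangleMesh,
    cfg: CameraConfig,
    width: int = 512,
    height: int = 512,
    floor_y: float | None = None,
) -> DepthMap:
    """Rasterise ``mesh`` into a z-buffered perspective depth map.

    The mesh is placed with its feet on the floor: the camera height is
    measured from ``floor_y`` (default: the mesh's min-Y).  Nearest surface
    wins per pixel; intensity ramps linearly from 255 at ``near_n`` to 1 at
    ``far_f``.  A mesh entirely outside the frustum yields an all-zero map
    with ``all_background`` set rather than an error.
    """
    if width < 16 or height < 16:
        raise ParameterError("resolution must be at least 16x16")
    if mesh.n_faces == 0:
        raise ParameterError("cannot render an empty mesh")

    b = mesh.bounds()
    if floor_y is None:
        floor_y = float(b[0, 1])
    cx, cz = (b[0, 0] + b[1, 0]) / 2.0, (b[0, 2] + b[1, 2]) / 2.0
    pivot = np.array([cx, floor_y, cz])

    # shift world so the floor is y=0 for the camera-height convention
    verts = mesh.vertices - np.array([0.0, floor_y, 0.0])
    origin, right, up, back = _camera_frame(cfg, pivot - np.array([0.0, floor_y, 0.0]))
    cam = _world_to_cam(verts, origin, right, up, back)

    half = math.radians(cfg.fovy) / 2.0
    tan_y = math.tan(half)
    tan_x = tan_y * cfg.aspect

    z = cam[:, 2]
    depth_buf = np.full((height, width), np.inf)
    front = z < -1e-9  # in front of the camera

    tris = mesh.faces
    any_drawn = False
    if front.any():
        # screen coordinates (float px) and inverse depth for all vertices
        with np.errstate(divide="ignore", invalid="ignore"):
            ndc_x = cam[:, 0] / (-z * tan_x)
            ndc_y = cam[:, 1] / (-z * tan_y)
        px = (ndc_x + 1.0) * 0.5 * width
        py = (1.0 - ndc_y) * 0.5 * height  # row 0 = top
        inv_d = np.where(front, 1.0 / (-z), 0.0)

        face_front = front[tris].all(axis=1)
        for fi in np.nonzero(face_front)[0]:
            i0, i1, i2 = tris[fi]
            x0, y0, x1, y1, x2, y2 = px[i0], py[i0], px[i1], py[i1], px[i2], py[i2]
            xmin = max(int(math.floor(min(x0, x1, x2))), 0)
            xmax = min(int(math.ceil(max(x0, x1, x2))), width - 1)
            ymin = max(int(math.floor(min(y0, y1, y2))), 0)
            ymax = min(int(math.ceil(max(y0, y1, y2))), height - 1)
            if xmin > xmax or ymin > ymax:
                continue
            area = (x1 - x0) * (y2 - y0) - (x2 - x0) * (y1 - y0)
            if abs(area) < 1e-12:
                continue
            xs = np.arange(xmin, xmax + 1) + 0.5
            ys = np.arange(ymin, ymax + 1) + 0.5
            gx, gy = np.meshgrid(xs, ys)
            w0 = ((x1 - gx) * (y2 - gy) - (x2 - gx) * (y1 - gy)) / area
            w1 = ((x2 - gx) * (y0 - gy) - (x0 - gx) * (y2 - gy)) / area
            w2 = 1.0 - w0 - w1
            inside = (w0 >= -1e-9) & (w1 >= -1e-9) & (w2 >= -1e-9)
            if not inside.any():
                continue
            # perspective-correct depth: 1/d interpolates linearly on screen
            inv = w0 * inv_d[i0] + w1 * inv_d[i1] + w2 * inv_d[i2]
            with np.errstate(divide="ignore"):
                d = 1.0 / inv
            sub = depth_buf[ymin : ymax + 1, xmin : xmax + 1]
            upd = inside & (d < sub)
            if upd.any():
                sub[upd] = d[upd]
                any_drawn = True

    visible = np.isfinite(depth_buf) & (depth_buf >= cfg.near_n) & (
        depth_buf <= cfg.far_f
    )
    pixels = np.zeros((height, width), dtype=np.uint8)
    if visible.any():
        d = depth_buf[visible]
        # linear ramp: near -> 255, far -> 1
        g = 255.0 + (d - cfg.near_n) * (1.0 - 255.0) / (cfg.far_f - cfg.near_n)
        pixels[visible] = np.clip(np.rint(g), 1, 255).astype(np.uint8)
    world_depth = np.where(visible, depth_buf, np.nan)

    return DepthMap(
        pixels=pixels,
        camera=cfg,
        world_depth=world_depth,
        pivot=pivot,
        all_background=not visible.any(),
    )


def back_project(dm: DepthMap, row: int, col: int) -> np.ndarray:
    """Cast a silhouette pixel back to its world point (mm).

    Uses the stored unquantised depth; re-projecting the returned point lands
    in the same pixel.  Raises on background pixels.
    """
    if dm.pixels[row, col] == 0 or not np.isfinite(dm.world_depth[row, col]):
        raise ParameterError(f"pixel ({row}, {col}) has no depth")
    cfg = dm.camera
    half = math.radians(cfg.fovy) / 2.0
    tan_y = math.tan(half)
    tan_x = tan_y * cfg.aspect
    ndc_x = (col + 0.5) / dm.width * 2.0 - 1.0
    ndc_y = 1.0 - (row + 0.5) / dm.height * 2.0
    d = float(dm.world_depth[row, col])
    x_cam = ndc_x * tan_x * d
    y_cam = ndc_y * tan_y * d
    z_cam = -d
    floor_y = 0.0  # camera frame was built with floor at y=0
    pivot0 = dm.pivot.copy()
    pivot0[1] = floor_y
    origin, right, up, back = _camera_frame(cfg, pivot0)
    world = origin + x_cam * right + y_cam * up + z_cam * back
    # undo the floor shift applied at render time
    world[1] += dm.pivot[1]
    return world


def multi_view_snapshots(
    mesh: TriangleMesh,
    cfg: CameraConfig,
    step_deg: float = 45.0,
    width: int = 512,
    height: int = 512,
) -> list[DepthMap]:
    """Render one full orbit of depth maps at ``step_deg`` yaw increments.

    View 0 is frontal; ``step_deg`` must divide 360 evenly (the standard
    45° step yields the eight-view pairing used for training sets).
    """
    if step_deg <= 0 or abs(360.0 / step_deg - round(360.0 / step_deg)) > 1e-9:
        raise ParameterError(f"step_deg must evenly divide 360, got {step_deg}")
    n = int(round(360.0 / step_deg))
    return [
        render_depth_map(mesh, replace(cfg, yaw=k * step_deg), width, height)
        for k in range(n)
    ]
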