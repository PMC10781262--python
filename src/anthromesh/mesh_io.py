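"""Triangle-mesh container and geometry-only STL/OBJ input/output.

Body scans are carried as bare triangle soup geometry: STL stores no colour or
texture channels at all, and on OBJ input every non-geometry record (``vt``,
``vn``, materials) is dropped.  Coordinates are millimetres in a world frame
with +Y up (body vertical), +X subject-left and +Z toward the default camera.

File parsing and welding are delegated to :mod:`trimesh`; this module owns the
validated container and the unit handling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from .errors import EmptyMeshError, MeshFormatError, ParameterError

#: vertices closer than this (mm) are merged into one on read
WELD_TOL_MM = 1e-6

_UNIT_TO_MM = {"mm": 1.0, "cm": 10.0, "m": 1000.0}


@dataclass
class TriangleMesh:
    """Indexed triangle mesh in millimetres.

    Attributes
    ----------
    vertices : (N, 3) float64 array
        Vertex positions, mm.
    faces : (M, 3) int array
        Vertex indices per triangle, counter-clockwise seen from outside.
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshFormatError("vertices must be an (N, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshFormatError("faces must be an (M, 3) array")
        if not np.all(np.isfinite(self.vertices)):
            raise MeshFormatError("non-finite vertex coordinate")
        if len(self.faces):
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise MeshFormatError("face index out of range")
            f = self.faces
            if np.any((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])):
                raise MeshFormatError("face repeats a vertex index")

    # -- basic queries -----------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def bounds(self) -> np.ndarray:
        """(2, 3) array of (min, max) corner coordinates, mm."""
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    def height_mm(self) -> float:
        """Vertical (Y) extent, mm."""
        b = self.bounds()
        return float(b[1, 1] - b[0, 1])

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy())

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )


def _from_trimesh(tm: trimesh.Trimesh) -> TriangleMesh:
    """Weld coincident vertices and wrap into a validated TriangleMesh."""
    tm = tm.copy()
    tm.merge_vertices(digits_vertex=6)  # 1e-6 mm weld
    tm.remove_unreferenced_vertices()
    if len(tm.faces) == 0:
        raise EmptyMeshError("mesh contains no faces")
    return TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


def _scale(mesh: TriangleMesh, unit: str) -> TriangleMesh:
    if unit not in _UNIT_TO_MM:
        raise ParameterError(f"unknown unit {unit!r}; expected mm, cm or m")
    k = _UNIT_TO_MM[unit]
    if k != 1.0:
        mesh = TriangleMesh(mesh.vertices * k, mesh.faces)
    return mesh


def read_stl(path: str | Path, unit: str = "mm") -> TriangleMesh:
    """Read an STL file (binary or ASCII dialect) as geometry only.

    STL stores an independent vertex triple per triangle; coincident vertices
    are welded (tolerance ``WELD_TOL_MM``) so downstream vertex-normal
    averaging sees shared vertices.  ``unit`` rescales to mm on load since the
    format carries no unit metadata.
    """
    path = Path(path)
    if not path.exists():
        raise MeshFormatError(f"no such file: {path}")
    try:
        tm = trimesh.load(str(path), file_type="stl", process=False)
    except Exception as exc:  # trimesh raises assorted types on bad files
        raise MeshFormatError(f"{path}: malformed STL ({exc})") from exc
    if not isinstance(tm, trimesh.Trimesh):
        raise MeshFormatError(f"{path}: STL did not contain triangle geometry")
    return _scale(_from_trimesh(tm), unit)


def read_obj(path: str | Path, unit: str = "mm") -> TriangleMesh:
    """Read a Wavefront OBJ, keeping only ``v``/``f`` geometry.

    Texture coordinates, normals, materials and colours are discarded.
    Polygonal faces are fan-triangulated; negative (relative) indices follow
    the OBJ convention.
    """
    path = Path(path)
    if not path.exists():
        raise MeshFormatError(f"no such file: {path}")
    try:
        tm = trimesh.load(
            str(path), file_type="obj", process=False, skip_materials=True
        )
    except Exception as exc:
        raise MeshFormatError(f"{path}: malformed OBJ ({exc})") from exc
    if isinstance(tm, trimesh.Scene):
        geoms = list(tm.geometry.values())
        if not geoms:
            raise EmptyMeshError(f"{path}: OBJ contains no faces")
        tm = trimesh.util.concatenate(geoms)
    if not isinstance(tm, trimesh.Trimesh) or len(tm.faces) == 0:
        raise EmptyMeshError(f"{path}: OBJ contains no faces")
    return _scale(_from_trimesh(tm), unit)


def read_mesh(path: str | Path, unit: str = "mm") -> TriangleMesh:
    """Dispatch on file extension (.stl / .obj)."""
    suffix = Path(path).suffix.lower()
    if suffix == ".stl":
        return read_stl(path, unit)
    if suffix == ".obj":
        return read_obj(path, unit)
    raise MeshFormatError(f"unsupported mesh format: {suffix!r}")


def write_stl(
    mesh: TriangleMesh, path: str | Path, dialect: str = "binary"
) -> None:
    """Write ``mesh`` as STL; binary (32-bit floats, 50 bytes/triangle) or ascii."""
    if dialect not in ("binary", "ascii"):
        raise ParameterError(f"dialect must be 'binary' or 'ascii', got {dialect!r}")
    tm = mesh.to_trimesh()
    path = Path(path)
    if dialect == "binary":
        data = trimesh.exchange.stl.export_stl(tm)
        path.write_bytes(data)
    else:
        text = trimesh.exchange.stl.export_stl_ascii(tm)
        path.write_text(text)


def write_obj(mesh: TriangleMesh, path: str | Path) -> None:
    """Write ``mesh`` as a geometry-only OBJ (``v`` and ``f`` records)."""
    path = Path(path)
    with path.open("w") as fh:
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for f in mesh.faces:
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")
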