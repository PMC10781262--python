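"""Vertex reduction with an information-loss guard, and height calibration.

Raw body scans carry ~250k vertices; downstream work needs far fewer.  The
reducer collapses the shortest edge repeatedly (midpoint placement) and the
stepwise driver removes a fixed number of vertices per step — stopping before
a floor (body information is empirically lost below ~60k vertices on
full-resolution scans) or before a step whose measured loss exceeds a budget.

"Information" here means measurable body dimensions, not visual fidelity:
the loss metric compares girths on a fixed set of probe planes between the
reduced mesh and the reference.

Height calibration uniformly rescales a mesh about its floor point so the
vertical extent matches the subject's known stature; girths scale linearly
and volumes cubically with the same factor.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, UndefinedLossError
from .mesh_io import TriangleMesh

#: probe-plane heights for the loss metric, as fractions of body height
LOSS_PROBE_FRACTIONS = (0.10, 0.30, 0.45, 0.55, 0.72)


@dataclass
class DecimationTrace:
    """Accepted reduction steps: (vertex_count, loss) pairs plus the result."""

    steps: list[tuple[int, float]]
    final_mesh: TriangleMesh


def decimate_to(mesh: TriangleMesh, target_vertices: int) -> TriangleMesh:
    """Reduce the mesh to at most ``target_vertices`` vertices.

    Iterative shortest-edge collapse with midpoint placement: the globally
    shortest edge is contracted to its midpoint until the target is reached.
    A mesh already at or below the target is returned unchanged.
    """
    if target_vertices < 4:
        raise ParameterError("target_vertices must be at least 4")
    if mesh.n_vertices <= target_vertices:
        return mesh

    verts = mesh.vertices.copy()
    # union-find over vertices; faces re-indexed at the end
    parent = np.arange(len(verts))

    def find(i: int) -> int:
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:
            parent[i], i = root, parent[i]
        return root

    edges = set()
    for tri in mesh.faces:
        a, b, c = int(tri[0]), int(tri[1]), int(tri[2])
        edges.update({tuple(sorted((a, b))), tuple(sorted((b, c))),
                      tuple(sorted((a, c)))})
    heap = [
        (float(np.linalg.norm(verts[a] - verts[b])), a, b) for a, b in edges
    ]
    heapq.heapify(heap)

    alive = len(verts)
    while alive > target_vertices and heap:
        d, a, b = heapq.heappop(heap)
        ra, rb = find(a), find(b)
        if ra == rb:
            continue
        true_d = float(np.linalg.norm(verts[ra] - verts[rb]))
        if true_d > d + 1e-12:
            # stale entry: endpoints have moved, re-queue with current length
            heapq.heappush(heap, (true_d, ra, rb))
            continue
        mid = (verts[ra] + verts[rb]) / 2.0
        parent[rb] = ra
        verts[ra] = mid
        alive -= 1

    root = np.array([find(i) for i in range(len(verts))])
    keep = np.unique(root)
    remap = np.full(len(verts), -1)
    remap[keep] = np.arange(len(keep))
    new_faces = remap[root[mesh.faces]]
    f = new_faces
    ok = (f[:, 0] != f[:, 1]) & (f[:, 1] != f[:, 2]) & (f[:, 0] != f[:, 2])
    return TriangleMesh(verts[keep], f[ok])


def information_loss(mesh: TriangleMesh, reference: TriangleMesh) -> float:
    """Worst relative girth change over the probe planes, in [0, 1+).

    For each probe plane (fixed fractions of the reference's height) the
    total cross-section perimeter of ``mesh`` is compared with that of
    ``reference``; the maximum of |Δp|/p_ref is returned.  Planes missing
    both meshes are skipped; if every plane misses, the loss is undefined.
    """
    from .measure import cross_section  # deferred: measure imports landmarks

    b = reference.bounds()
    y0, y1 = b[0, 1], b[1, 1]
    worst = None
    for frac in LOSS_PROBE_FRACTIONS:
        y = y0 + frac * (y1 - y0)
        p_ref = cross_section(reference, y).total_perimeter()
        p_new = cross_section(mesh, y).total_perimeter()
        if p_ref <= 0 and p_new <= 0:
            continue
        if p_ref <= 0:
            worst = max(worst or 0.0, 1.0)
            continue
        worst = max(worst or 0.0, abs(p_new - p_ref) / p_ref)
    if worst is None:
        raise UndefinedLossError("no probe plane intersected either mesh")
    return float(worst)


def reduce_stepwise(
    mesh: TriangleMesh,
    step: int = 10_000,
    floor: int = 60_000,
    max_loss: float = 0.05,
) -> DecimationTrace:
    """Repeatedly remove ``step`` vertices, guarding floor and loss budget.

    Stops before the first step that would drop below ``floor`` vertices or
    whose measured information loss (vs. the original mesh) would exceed
    ``max_loss``, whichever comes first.  The trace records every accepted
    step; the scan-preprocessing defaults (10k step, 60k floor) reflect the
    point where body dimensions begin to degrade on full-body scans.
    """
    if step <= 0:
        raise ParameterError("step must be positive")
    if floor < 4:
        raise ParameterError("floor must be at least 4")

    current = mesh
    steps: list[tuple[int, float]] = []
    while current.n_vertices - step >= floor:
        candidate = decimate_to(current, current.n_vertices - step)
        loss = information_loss(candidate, mesh)
        if loss > max_loss:
            break
        current = candidate
        steps.append((current.n_vertices, loss))
    return DecimationTrace(steps=steps, final_mesh=current)


def resize_to_height(mesh: TriangleMesh, actual_height_cm: float) -> TriangleMesh:
    """Uniformly scale the mesh about its floor point to the stated stature.

    The scale factor is (target height)/(current height); girths scale by
    the same factor, volumes by its cube.  The floor point (bounding-box
    centre at min-Y) is the fixed point of the scaling.
    """
    if actual_height_cm <= 0:
        raise ParameterError("actual_height_cm must be positive")
    h = mesh.height_mm()
    if h <= 0:
        raise ParameterError("mesh has zero vertical extent")
    s = (actual_height_cm * 10.0) / h
    b = mesh.bounds()
    pivot = np.array([(b[0, 0] + b[1, 0]) / 2.0, b[0, 1], (b[0, 2] + b[1, 2]) / 2.0])
    return TriangleMesh(pivot + (mesh.vertices - pivot) * s, mesh.faces)
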