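"""Anatomical feature points by quadric-error-metric mesh simplification.

Cusps, ridges and groove landmarks of an occlusal surface concentrate the
mesh's shape information. Simplifying the tooth mesh with Garland-Heckbert
quadric edge collapse down to a small vertex budget leaves exactly those
vertices standing; each surviving vertex, mapped back to the nearest vertex
of the full-resolution mesh, is treated as a feature point.

The collapse ordering is deterministic: equal costs are broken by the
lexicographically smallest (i, j) vertex-index pair. Boundary shape is
preserved through perpendicular constraint-plane quadrics on boundary
edges, so open patches keep their rims while collinear rim segments remain
collapsible.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .mesh import TriangleMesh

log = logging.getLogger(__name__)

__all__ = ["FeaturePointSet", "simplify_qem", "extract_feature_points"]

_BOUNDARY_PENALTY = 1e3


@dataclass
class FeaturePointSet:
    """Feature points living exactly on vertices of the source mesh."""

    source_indices: np.ndarray  # indices into the originating mesh
    positions: np.ndarray  # (n, 3); equal to mesh.vertices[source_indices]

    @property
    def count(self) -> int:
        return len(self.source_indices)


def _plane_quadric(normal: np.ndarray, point: np.ndarray) -> np.ndarray:
    d = -float(normal @ point)
    p = np.append(normal, d)
    return np.outer(p, p)


def _quadric_cost(q: np.ndarray, v: np.ndarray) -> float:
    h = (v[0], v[1], v[2], 1.0)
    return float(sum(h[i] * sum(q[i, j] * h[j] for j in range(4)) for i in range(4)))


def _collapse_position(q: np.ndarray, vi: np.ndarray, vj: np.ndarray):
    """Optimal contraction position for combined quadric q, with fallback.

    Returns (position, cost). Falls back to the best of the endpoints and
    the midpoint when the quadric's 3x3 block is (near-)singular.
    """
    a = q[:3, :3]
    # explicit 3x3 solve via the adjugate; cheap and allocation-free
    (a00, a01, a02), (a10, a11, a12), (a20, a21, a22) = a
    det = (
        a00 * (a11 * a22 - a12 * a21)
        - a01 * (a10 * a22 - a12 * a20)
        + a02 * (a10 * a21 - a11 * a20)
    )
    scale = float(np.abs(a).max())
    if scale > 0 and abs(det) > 1e-9 * scale**3:
        b0, b1, b2 = -q[0, 3], -q[1, 3], -q[2, 3]
        x = (
            b0 * (a11 * a22 - a12 * a21)
            - a01 * (b1 * a22 - a12 * b2)
            + a02 * (b1 * a21 - a11 * b2)
        ) / det
        y = (
            a00 * (b1 * a22 - a12 * b2)
            - b0 * (a10 * a22 - a12 * a20)
            + a02 * (a10 * b2 - b1 * a20)
        ) / det
        z = (
            a00 * (a11 * b2 - b1 * a21)
            - a01 * (a10 * b2 - b1 * a20)
            + b0 * (a10 * a21 - a11 * a20)
        ) / det
        v = np.array([x, y, z])
        return v, _quadric_cost(q, v)
    best_v, best_c = None, np.inf
    for v in (vi, vj, 0.5 * (vi + vj)):
        c = _quadric_cost(q, v)
        if c < best_c:
            best_v, best_c = v, c
    return best_v, best_c


def simplify_qem(
    mesh: TriangleMesh, target_vertex_count: int
) -> tuple[TriangleMesh, np.ndarray]:
    """Quadric-error edge-collapse simplification to a vertex budget.

    Returns the simplified mesh and, for each simplified vertex, the index
    of the Euclidean-nearest vertex of the original mesh. Collapses that
    would break edge-manifoldness (link condition) or fold a triangle over
    are skipped; if no legal collapse remains before the budget is reached,
    the achieved count is returned with a logged note.
    """
    m = mesh.n_vertices
    if not (4 <= target_vertex_count <= m):
        raise ValueError(f"target_vertex_count must be in [4, {m}]")
    if target_vertex_count == m:
        return mesh.copy(), np.arange(m)

    verts = mesh.vertices.copy()
    faces = [tuple(f) for f in mesh.faces.tolist()]
    face_alive = [True] * len(faces)
    vert_faces: list[set[int]] = [set() for _ in range(m)]
    for fi, f in enumerate(faces):
        for v in f:
            vert_faces[v].add(fi)

    # vertex quadrics from incident face planes
    quadrics = [np.zeros((4, 4)) for _ in range(m)]
    for f in faces:
        p0, p1, p2 = verts[f[0]], verts[f[1]], verts[f[2]]
        n = np.cross(p1 - p0, p2 - p0)
        nn = np.linalg.norm(n)
        if nn < 1e-300:
            continue
        q = _plane_quadric(n / nn, p0)
        for v in f:
            quadrics[v] += q

    # boundary constraint planes: perpendicular to the face through the edge
    edge_faces: dict[tuple[int, int], list[int]] = {}
    for fi, f in enumerate(faces):
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            edge_faces.setdefault((min(a, b), max(a, b)), []).append(fi)
    for (a, b), efs in edge_faces.items():
        if len(efs) != 1:
            continue
        f = faces[efs[0]]
        p0, p1, p2 = verts[f[0]], verts[f[1]], verts[f[2]]
        fn = np.cross(p1 - p0, p2 - p0)
        e = verts[b] - verts[a]
        n = np.cross(e, fn)
        nn = np.linalg.norm(n)
        if nn < 1e-300:
            continue
        q = _BOUNDARY_PENALTY * float(e @ e) * _plane_quadric(n / nn, verts[a])
        quadrics[a] += q
        quadrics[b] += q

    neighbors: list[set[int]] = [set() for _ in range(m)]
    for a, b in edge_faces:
        neighbors[a].add(b)
        neighbors[b].add(a)

    alive = np.ones(m, dtype=bool)
    n_alive = m
    stamp = [0] * m  # bumped on every change touching a vertex

    heap: list[tuple[float, int, int, int, int, int, np.ndarray]] = []
    counter = 0  # tie-breaker so heap never compares ndarray payloads

    def push_edge(i: int, j: int) -> None:
        nonlocal counter
        i, j = (i, j) if i < j else (j, i)
        pos, cost = _collapse_position(quadrics[i] + quadrics[j], verts[i], verts[j])
        counter += 1
        heapq.heappush(heap, (cost, i, j, stamp[i], stamp[j], counter, pos))

    for a, b in edge_faces:
        push_edge(a, b)

    def link_ok(i: int, j: int) -> bool:
        shared_faces = vert_faces[i] & vert_faces[j]
        opposite = set()
        for fi in shared_faces:
            opposite.update(v for v in faces[fi] if v not in (i, j))
        return neighbors[i] & neighbors[j] == opposite and len(shared_faces) <= 2

    def folds(i: int, j: int, pos: np.ndarray) -> bool:
        # would moving i/j to pos flip any surviving incident face?
        for v in (i, j):
            for fi in vert_faces[v]:
                f = faces[fi]
                if i in f and j in f:
                    continue  # face disappears
                pts_old = [verts[x] for x in f]
                pts_new = [pos if x in (i, j) else verts[x] for x in f]
                n_old = np.cross(pts_old[1] - pts_old[0], pts_old[2] - pts_old[0])
                n_new = np.cross(pts_new[1] - pts_new[0], pts_new[2] - pts_new[0])
                if n_old @ n_new <= 0:
                    return True
        return False

    while n_alive > target_vertex_count and heap:
        cost, i, j, si, sj, _, pos = heapq.heappop(heap)
        if not (alive[i] and alive[j]) or stamp[i] != si or stamp[j] != sj:
            continue
        if j not in neighbors[i]:
            continue
        if not link_ok(i, j) or folds(i, j, pos):
            continue
        # collapse j into i at pos
        verts[i] = pos
        quadrics[i] = quadrics[i] + quadrics[j]
        alive[j] = False
        n_alive -= 1
        dead_faces = vert_faces[i] & vert_faces[j]
        for fi in dead_faces:
            face_alive[fi] = False
            for v in faces[fi]:
                vert_faces[v].discard(fi)
        for fi in list(vert_faces[j]):
            f = faces[fi]
            faces[fi] = tuple(i if v == j else v for v in f)
            vert_faces[j].discard(fi)
            vert_faces[i].add(fi)
        for nb in list(neighbors[j]):
            neighbors[nb].discard(j)
            if nb != i:
                neighbors[nb].add(i)
                neighbors[i].add(nb)
        neighbors[i].discard(j)
        neighbors[j].clear()
        stamp[i] += 1
        stamp[j] += 1
        # only edges incident to i change (its quadric and position moved)
        for nb in neighbors[i]:
            push_edge(i, nb)

    if n_alive > target_vertex_count:
        log.warning(
            "no legal collapse left: achieved %d vertices (target %d)",
            n_alive, target_vertex_count,
        )

    keep = np.flatnonzero(alive)
    remap = -np.ones(m, dtype=np.int64)
    remap[keep] = np.arange(len(keep))
    new_faces = np.array(
        [
            [remap[v] for v in faces[fi]]
            for fi in range(len(faces))
            if face_alive[fi]
        ],
        dtype=np.int64,
    ).reshape(-1, 3)
    simplified = TriangleMesh(verts[keep], new_faces)
    _, nearest = cKDTree(mesh.vertices).query(simplified.vertices)
    return simplified, np.asarray(nearest, dtype=np.int64)


def extract_feature_points(mesh: TriangleMesh, n_features: int) -> FeaturePointSet:
    """QEM-derived anatomical feature points of a tooth mesh.

    Simplifies to ``n_features`` vertices and maps each surviving vertex
    back to the nearest original vertex, so feature positions are an exact
    subset of the input's vertex positions. Deterministic for fixed input.
    """
    _, source = simplify_qem(mesh, n_features)
    source = np.unique(source)
    return FeaturePointSet(source, mesh.vertices[source].copy())
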