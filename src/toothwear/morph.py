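"""In-between wear morphologies by interpolating Laplacian coordinates.

With S0 and the homogeneous surface S_h in one-to-one vertex
correspondence, intermediate wear states are generated in the differential
domain rather than by blending positions: the Laplacian (umbrella)
coordinates delta encode local surface detail and are translation
invariant, so interpolating them preserves anatomical features that plain
linear vertex blending would smear.

Direction and magnitude are interpolated separately ("bilinear"):

    delta_MU = (1-u) delta_S/|delta_S| + u delta_T/|delta_T|
    |delta_M| = (1-u) |delta_S| + u |delta_T|
    delta_M  = |delta_M| * delta_MU

and positions are recovered by solving the sparse system L V = delta_M in
least squares, made well-posed by soft positional anchors on the axial
region (which wear never moves). By default delta_MU is used exactly as
the convex combination above; ``renormalize_direction=True`` rescales it
to unit length first, the common variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

from .mesh import LaplacianMatrix, TriangleMesh, build_laplacian

__all__ = [
    "LaplacianCoords",
    "AnchorSet",
    "MorphFrame",
    "laplacian_coords",
    "interpolate_delta",
    "reconstruct",
    "morph_sequence",
    "wear_map",
]

_ZERO_MAG = 1e-12


@dataclass
class LaplacianCoords:
    """Per-vertex differential vectors with split magnitude/direction."""

    deltas: np.ndarray  # (m, 3)
    magnitudes: np.ndarray  # (m,)
    directions: np.ndarray  # (m, 3); zero rows where undefined
    defined: np.ndarray  # (m,) bool, magnitude > 1e-12

    @classmethod
    def from_deltas(cls, deltas: np.ndarray) -> "LaplacianCoords":
        deltas = np.asarray(deltas, dtype=np.float64)
        mags = np.linalg.norm(deltas, axis=1)
        defined = mags > _ZERO_MAG
        dirs = np.zeros_like(deltas)
        dirs[defined] = deltas[defined] / mags[defined, None]
        return cls(deltas, mags, dirs, defined)


@dataclass
class AnchorSet:
    """Positional constraints pinning the reconstruction in space.

    With ``weight=inf`` (the default) anchors are enforced exactly by
    eliminating the anchored coordinates from the system; a finite weight
    adds soft penalty rows instead.
    """

    indices: np.ndarray
    positions: np.ndarray
    weight: float = np.inf

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if len(self.indices) == 0:
            raise ValueError("anchor set must be non-empty (the Laplacian system "
                             "is singular without positional constraints)")


@dataclass
class MorphFrame:
    """One intermediate wear state of the morph sequence."""

    mesh: TriangleMesh
    u: float
    wear_depth: np.ndarray  # (m,) >= 0, mm


def laplacian_coords(mesh: TriangleMesh, lap: LaplacianMatrix | None = None) -> LaplacianCoords:
    """Uniform-weight differential coordinates delta = L V of a mesh."""
    lap = lap or build_laplacian(mesh)
    return LaplacianCoords.from_deltas(lap.apply(mesh.vertices))


def interpolate_delta(
    delta_s: LaplacianCoords,
    delta_t: LaplacianCoords,
    u: float,
    renormalize_direction: bool = False,
) -> LaplacianCoords:
    """Bilinear (direction + magnitude) interpolation of differential coords.

    Where either endpoint's magnitude vanishes the split is undefined and
    the vertex degrades to plain linear interpolation of the raw vectors.
    """
    if delta_s.deltas.shape != delta_t.deltas.shape:
        raise ValueError("Laplacian coordinate sets differ in size (connectivity mismatch)")
    if not 0.0 <= u <= 1.0:
        raise ValueError("u must lie in [0, 1]")
    both = delta_s.defined & delta_t.defined
    dir_m = (1.0 - u) * delta_s.directions + u * delta_t.directions
    if renormalize_direction:
        n = np.linalg.norm(dir_m, axis=1)
        ok = n > _ZERO_MAG
        dir_m[ok] /= n[ok, None]
    mag_m = (1.0 - u) * delta_s.magnitudes + u * delta_t.magnitudes
    deltas = mag_m[:, None] * dir_m
    lin = (1.0 - u) * delta_s.deltas + u * delta_t.deltas
    deltas[~both] = lin[~both]
    return LaplacianCoords.from_deltas(deltas)


def reconstruct(
    delta_m: LaplacianCoords,
    laplacian: LaplacianMatrix,
    anchors: AnchorSet,
    faces: np.ndarray,
) -> TriangleMesh:
    """Recover world coordinates from differential coordinates.

    Solves ``min || L V - delta ||^2`` with the anchored vertices either
    eliminated (hard anchors, ``weight=inf``) or added as penalty rows
    ``weight * (V[anchors] - targets)``; exact whenever delta and anchors
    are consistent (e.g. at the endpoints of a morph).
    """
    lap = laplacian.matrix
    m = lap.shape[0]
    if np.isinf(anchors.weight):
        fixed = np.zeros(m, dtype=bool)
        fixed[anchors.indices] = True
        free = np.flatnonzero(~fixed)
        x = np.zeros((m, 3))
        x[anchors.indices] = anchors.positions
        a = lap.tocsc()[:, free]
        rhs = delta_m.deltas - lap.tocsc()[:, fixed] @ x[fixed]
        ata = (a.T @ a).tocsc()
        solve = splu(ata).solve
        atb = a.T @ rhs
        x[free] = np.column_stack([solve(atb[:, d]) for d in range(3)])
        return TriangleMesh(x, np.asarray(faces).copy())
    k = len(anchors.indices)
    rows = sparse.coo_matrix(
        (np.full(k, anchors.weight), (np.arange(k), anchors.indices)), shape=(k, m)
    )
    a = sparse.vstack([lap, rows]).tocsc()
    rhs = np.vstack([delta_m.deltas, anchors.weight * anchors.positions])
    ata = (a.T @ a).tocsc()
    solve = splu(ata).solve
    atb = a.T @ rhs
    v = np.column_stack([solve(atb[:, d]) for d in range(3)])
    return TriangleMesh(v, np.asarray(faces).copy())


def morph_sequence(
    s0: TriangleMesh,
    sh: TriangleMesh,
    u_values,
    renormalize_direction: bool = False,
) -> list[MorphFrame]:
    """Morph frames between the intact surface and the homogeneous surface.

    Anchors are the axial vertices, linearly interpolated between their S0
    and S_h positions (identical when the axial region is untouched, the
    normal case). On meshes without a region mask the boundary vertices
    anchor the solve; a closed unmasked mesh falls back to anchoring every
    vertex, which reduces to constrained linear blending.
    """
    u_values = list(u_values)
    if any(not 0.0 <= u <= 1.0 for u in u_values):
        raise ValueError("u values must lie in [0, 1]")
    if sorted(u_values) != u_values:
        raise ValueError("u values must be sorted ascending")
    if s0.vertices.shape != sh.vertices.shape or not np.array_equal(s0.faces, sh.faces):
        raise ValueError("S0 and S_h must share connectivity")
    lap = build_laplacian(s0)
    d_s = laplacian_coords(s0, lap)
    d_t = LaplacianCoords.from_deltas(lap.apply(sh.vertices))
    anchor_idx = s0.axial_indices()
    if len(anchor_idx) == 0:
        anchor_idx = s0.boundary_vertices()
    if len(anchor_idx) == 0:
        anchor_idx = np.arange(s0.n_vertices)
    frames: list[MorphFrame] = []
    for u in u_values:
        d_m = interpolate_delta(d_s, d_t, u, renormalize_direction)
        targets = (1.0 - u) * s0.vertices[anchor_idx] + u * sh.vertices[anchor_idx]
        anchors = AnchorSet(anchor_idx, targets)
        mesh = reconstruct(d_m, lap, anchors, s0.faces)
        mesh.region_mask = None if s0.region_mask is None else s0.region_mask.copy()
        depth, _ = wear_map(s0, mesh)
        mesh.scalars["wear_depth"] = depth
        frames.append(MorphFrame(mesh, float(u), depth))
    return frames


def wear_map(s0: TriangleMesh, frame: TriangleMesh) -> tuple[np.ndarray, np.ndarray]:
    """Per-vertex wear depth of a frame and its yellow-to-red colouring.

    Depth is the Euclidean distance each vertex has moved from its intact
    position; colours map [0, max depth] linearly from yellow (255,255,0)
    to red (255,0,0), with unworn vertices in a neutral base colour.
    """
    from .mesh import wear_colors

    if s0.vertices.shape != frame.vertices.shape:
        raise ValueError("meshes must share connectivity")
    depth = np.linalg.norm(frame.vertices - s0.vertices, axis=1)
    return depth, wear_colors(depth)
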