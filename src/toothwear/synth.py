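"""Synthetic intact/worn molar-like mesh pairs with known ground truth.

No scan archive accompanies the method, so every pipeline stage is
exercised on a parametric stand-in: a cusp-and-fossa occlusal cap (sum of
Gaussian bumps minus a central fossa over a gently domed disk) with a
vertical axial skirt. Wear is applied as a known smooth depth field along
the vertex normals, and the worn counterpart can be independently
retessellated (midpoint subdivision plus seeded random edge flips) so the
two meshes share no vertex correspondence — mimicking two independent
scans. The generator is fully deterministic per seed.

All synthetic fixtures in this package are synthetic stand-ins for scanner
data; dimensions are millimetres and sized like a lower first molar.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .mesh import AXIAL, OCCLUSAL, TriangleMesh, vertex_normals

log = logging.getLogger(__name__)

__all__ = ["SyntheticToothSpec", "WearFieldSpec", "generate_tooth", "apply_wear"]


@dataclass
class SyntheticToothSpec:
    """Parameters of the parametric tooth surface.

    ``resolution`` targets the occlusal-cap vertex count; cusp apices sit
    on a ring at 55% of the base radius at equal angles.
    """

    n_cusps: int = 5
    cusp_height: float = 1.5  # mm
    base_radius: float = 5.0  # mm
    skirt_depth: float = 3.0  # mm of axial wall below the cap rim
    resolution: int = 2000  # target cap vertex count
    seed: int = 0
    cusp_sigma: float = 0.9  # mm, bump width
    fossa_depth: float = 0.6  # mm, central depression
    jitter: float = 0.015  # in-plane vertex jitter, fraction of base radius

    def cusp_centers(self) -> np.ndarray:
        """Analytic (x, y) cusp apex locations."""
        if self.n_cusps == 0:
            return np.empty((0, 2))
        ang = 2.0 * np.pi * np.arange(self.n_cusps) / self.n_cusps + np.pi / 7.0
        r = 0.55 * self.base_radius
        return np.column_stack([r * np.cos(ang), r * np.sin(ang)])

    def height(self, xy: np.ndarray) -> np.ndarray:
        """Occlusal height field z(x, y) over the cap."""
        xy = np.atleast_2d(xy)
        r2 = (xy**2).sum(1)
        rr = self.base_radius**2
        z = 0.25 * self.cusp_height * np.clip(1.0 - r2 / rr, 0.0, None)  # dome
        for c in self.cusp_centers():
            d2 = ((xy - c) ** 2).sum(1)
            z = z + self.cusp_height * np.exp(-d2 / (2.0 * self.cusp_sigma**2))
        z = z - self.fossa_depth * np.exp(-r2 / (2.0 * (0.35 * self.base_radius) ** 2))
        # taper so the rim joins the skirt at z = 0
        taper = np.clip(1.0 - (np.sqrt(r2) / self.base_radius) ** 6, 0.0, 1.0)
        return z * taper


@dataclass
class WearFieldSpec:
    """Known smooth wear-depth field applied to the occlusal region."""

    max_depth: float = 0.5  # mm
    pattern: str = "per-cusp"  # "uniform-occlusal" | "per-cusp"
    sigma: float = 1.4  # mm, width of per-cusp wear lobes
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pattern not in ("uniform-occlusal", "per-cusp"):
            raise ValueError("pattern must be 'uniform-occlusal' or 'per-cusp'")
        if self.max_depth < 0:
            raise ValueError("max_depth must be non-negative")

    def depth(self, xy: np.ndarray, cusp_centers: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(xy)
        if self.pattern == "uniform-occlusal":
            return np.full(len(xy), self.max_depth)
        if len(cusp_centers) == 0:
            return np.full(len(xy), self.max_depth)
        acc = np.zeros(len(xy))
        for c in cusp_centers:
            d2 = ((xy - c) ** 2).sum(1)
            acc += np.exp(-d2 / (2.0 * self.sigma**2))
        return self.max_depth * np.minimum(acc, 1.0)


def generate_tooth(spec: SyntheticToothSpec) -> TriangleMesh:
    """Build the intact synthetic tooth: occlusal cap plus axial skirt.

    The cap is a concentric-ring triangulated disk carrying the analytic
    height field; the rim ring and the extruded skirt are labelled axial,
    everything inside the rim occlusal. Same spec (and seed) twice gives
    bit-identical meshes.
    """
    if spec.resolution < 50:
        raise ValueError("resolution must be at least 50 vertices")
    rng = np.random.default_rng(spec.seed)
    # rings: ring k has 6k vertices; 3K(K+1)+1 cap vertices total
    n_rings = max(3, round((-3 + np.sqrt(9 + 12 * (spec.resolution - 1))) / 6))
    pts = [(0.0, 0.0)]
    ring_start = [0]
    for k in range(1, n_rings + 1):
        nk = 6 * k
        ring_start.append(len(pts))
        ang = 2.0 * np.pi * np.arange(nk) / nk + (0.5 * np.pi * k / n_rings)
        r = spec.base_radius * k / n_rings
        pts.extend(zip(r * np.cos(ang), r * np.sin(ang)))
    xy = np.array(pts)
    # seeded in-plane jitter, fading to zero at the rim so the skirt stays clean
    fade = 1.0 - (np.linalg.norm(xy, axis=1) / spec.base_radius) ** 2
    xy += (
        spec.jitter
        * spec.base_radius
        * np.clip(fade, 0.0, None)[:, None]
        * rng.uniform(-1.0, 1.0, xy.shape)
    )
    # ovoid crown outline (molar cross-sections are not circular); this also
    # makes the axial wall rotationally asymmetric, as selective ICP requires
    theta = np.arctan2(xy[:, 1], xy[:, 0])
    shape = 1.0 + 0.06 * np.cos(2.0 * theta + 0.7) + 0.025 * np.sin(3.0 * theta - 0.4)
    xy *= shape[:, None]

    # Delaunay triangulation of the jittered disk (deterministic, manifold);
    # orient every face counter-clockwise seen from +z
    from scipy.spatial import Delaunay

    tri = Delaunay(xy)
    cap = tri.simplices.copy()
    p = xy[cap]
    area2 = (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1]) - (
        p[:, 2, 0] - p[:, 0, 0]
    ) * (p[:, 1, 1] - p[:, 0, 1])
    cap[area2 < 0] = cap[area2 < 0][:, ::-1]
    faces: list[tuple[int, int, int]] = [tuple(x) for x in cap.tolist()]

    z = spec.height(xy)
    verts = np.column_stack([xy, z])
    mask = np.zeros(len(verts), dtype=np.int64)
    mask[: ring_start[n_rings]] = OCCLUSAL  # inner rings
    mask[ring_start[n_rings] :] = AXIAL  # rim ring joins the skirt

    # vertical axial skirt extruded from the rim ring
    rim = np.arange(ring_start[n_rings], len(verts))
    n_rim = len(rim)
    n_rows = 3
    all_verts = [verts]
    all_mask = [mask]
    prev = rim
    for s in range(1, n_rows + 1):
        t = s / n_rows
        ring = verts[rim].copy()
        # barrel-shaped wall (height of contour): keeps the rigid fit of the
        # axial region fully constrained in every direction
        ring[:, :2] *= 1.0 + 0.06 * np.sin(np.pi * t)
        ring[:, 2] -= spec.skirt_depth * t
        start = sum(len(v) for v in all_verts)
        all_verts.append(ring)
        all_mask.append(np.full(n_rim, AXIAL, dtype=np.int64))
        cur = np.arange(start, start + n_rim)
        for j in range(n_rim):
            a, b = prev[j], prev[(j + 1) % n_rim]
            c, d = cur[j], cur[(j + 1) % n_rim]
            # outward-facing skirt quads (cap faces are CCW from +z)
            faces.append((a, c, b))
            faces.append((b, c, d))
        prev = cur

    mesh = TriangleMesh(
        np.vstack(all_verts), np.array(faces, dtype=np.int64), np.concatenate(all_mask)
    )
    mesh.validate()
    return mesh


def apply_wear(
    mesh: TriangleMesh, wear: WearFieldSpec, retessellate: bool = False
) -> tuple[TriangleMesh, np.ndarray]:
    """Wear a tooth by its depth field; optionally break the tessellation.

    Occlusal vertices move inward along their normals by the depth field
    evaluated at their (x, y); the axial skirt never moves. With
    ``retessellate`` the worn surface is midpoint-subdivided and a seeded
    fraction of its interior edges flipped, yielding an independent
    tessellation with a different vertex count. The returned ground-truth
    depth always lives on the ORIGINAL tessellation.
    """
    if mesh.region_mask is None:
        raise ValueError("apply_wear needs a region mask")
    centers = _infer_cusp_centers(mesh)
    depth = wear.depth(mesh.vertices[:, :2], centers)
    depth[mesh.region_mask == AXIAL] = 0.0
    zmax = mesh.vertices[:, 2].max() - mesh.vertices[:, 2].min()
    if wear.max_depth >= zmax:
        log.warning("max_depth %.3g exceeds crown relief %.3g: cusps obliterated",
                    wear.max_depth, zmax)
    normals = vertex_normals(mesh)
    worn = mesh.copy()
    worn.vertices = mesh.vertices - depth[:, None] * normals
    truth = depth.copy()
    if retessellate:
        worn = _retessellate(worn, wear.seed)
    worn.validate()
    return worn, truth


def _infer_cusp_centers(mesh: TriangleMesh) -> np.ndarray:
    """Occlusal local height maxima (x, y); the wear lobes centre on these."""
    occ = set(mesh.occlusal_indices().tolist())
    nbrs: dict[int, set[int]] = {}
    for f in mesh.faces:
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            nbrs.setdefault(int(a), set()).add(int(b))
            nbrs.setdefault(int(b), set()).add(int(a))
    z = mesh.vertices[:, 2]
    peaks = [
        i for i in occ
        if all(z[i] > z[j] for j in nbrs.get(i, ()))
    ]
    return mesh.vertices[np.array(peaks, dtype=np.int64), :2] if peaks else np.empty((0, 2))


def _retessellate(mesh: TriangleMesh, seed: int, flip_fraction: float = 0.15) -> TriangleMesh:
    """Midpoint-subdivide, then flip a seeded sample of interior edges."""
    v, f = mesh.vertices, mesh.faces
    edge_id: dict[tuple[int, int], int] = {}
    mids: list[np.ndarray] = []
    mid_label: list[int] = []

    def midpoint(a: int, b: int) -> int:
        key = (min(a, b), max(a, b))
        if key not in edge_id:
            edge_id[key] = len(v) + len(mids)
            mids.append(0.5 * (v[a] + v[b]))
            if mesh.region_mask is not None:
                lab = (
                    AXIAL
                    if mesh.region_mask[a] == AXIAL and mesh.region_mask[b] == AXIAL
                    else OCCLUSAL
                )
                mid_label.append(lab)
        return edge_id[key]

    new_faces: list[tuple[int, int, int]] = []
    for a, b, c in f:
        ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
        new_faces += [(a, ab, ca), (ab, b, bc), (ca, bc, c), (ab, bc, ca)]
    verts = np.vstack([v, np.array(mids)])
    faces = np.array(new_faces, dtype=np.int64)
    mask = None
    if mesh.region_mask is not None:
        mask = np.concatenate([mesh.region_mask, np.array(mid_label, dtype=np.int64)])

    faces = _random_edge_flips(verts, faces, seed, flip_fraction)
    return TriangleMesh(verts, faces, mask)


def _random_edge_flips(verts, faces, seed, fraction):
    rng = np.random.default_rng(seed)
    face_list = [tuple(x) for x in faces.tolist()]
    edge_faces: dict[tuple[int, int], list[int]] = {}
    for fi, (a, b, c) in enumerate(face_list):
        for e in ((a, b), (b, c), (c, a)):
            edge_faces.setdefault((min(e), max(e)), []).append(fi)
    interior = [e for e, fs in edge_faces.items() if len(fs) == 2]
    rng.shuffle(interior)
    n_try = int(fraction * len(interior))
    adjacency = {e for e in edge_faces}
    touched: set[int] = set()
    for a, b in interior[:n_try]:
        f1, f2 = edge_faces[(a, b)]
        if f1 in touched or f2 in touched:
            continue
        t1, t2 = face_list[f1], face_list[f2]
        c = next(x for x in t1 if x not in (a, b))
        d = next(x for x in t2 if x not in (a, b))
        if (min(c, d), max(c, d)) in adjacency:
            continue
        # orientation-preserving flip: keep winding of the containing faces
        i1 = t1.index(c)
        na1, nb1 = t1[(i1 + 1) % 3], t1[(i1 + 2) % 3]  # c, na1, nb1 == c, a, b order
        new1 = (c, na1, d)
        new2 = (c, d, nb1)
        # reject flips that fold either new triangle against the old pair
        n_old = np.cross(verts[t1[1]] - verts[t1[0]], verts[t1[2]] - verts[t1[0]])
        ok = True
        for tri in (new1, new2):
            n_new = np.cross(verts[tri[1]] - verts[tri[0]], verts[tri[2]] - verts[tri[0]])
            if n_old @ n_new <= 1e-12:
                ok = False
                break
        if not ok:
            continue
        face_list[f1], face_list[f2] = new1, new2
        touched.update((f1, f2))
        adjacency.discard((min(a, b), max(a, b)))
        adjacency.add((min(c, d), max(c, d)))
    return np.array(face_list, dtype=np.int64)
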