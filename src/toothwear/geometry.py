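"""Low-level geometric queries shared by registration, projection and QC.

All routines are vectorised numpy over (chunked) point-by-triangle blocks;
meshes in this pipeline are small (10^3..10^4 faces), so brute candidate
sets pruned by a KD-tree are both simple and fast enough.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

_EPS = 1e-12


def ray_mesh_intersections(
    origins: np.ndarray,
    directions: np.ndarray,
    triangles: np.ndarray,
    chunk: int = 256,
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest intersection of each ray with a triangle soup (Moller-Trumbore).

    Parameters
    ----------
    origins, directions : (n, 3) arrays; directions need not be unit length
        (returned t is in units of the direction vector).
    triangles : (F, 3, 3) vertex coordinates.

    Returns
    -------
    t : (n,) smallest non-negative ray parameter, ``inf`` where the ray
        misses every triangle.
    tri_index : (n,) index of the hit triangle, -1 on a miss.
    """
    origins = np.asarray(origins, dtype=np.float64)
    directions = np.asarray(directions, dtype=np.float64)
    v0 = triangles[:, 0]
    e1 = triangles[:, 1] - v0
    e2 = triangles[:, 2] - v0
    n = len(origins)
    t_best = np.full(n, np.inf)
    idx_best = np.full(n, -1, dtype=np.int64)
    for s in range(0, n, chunk):
        o = origins[s : s + chunk, None, :]
        d = directions[s : s + chunk, None, :]
        pvec = np.cross(d, e2[None, :, :])
        det = np.einsum("rfk,fk->rf", pvec, e1)
        inv = np.where(np.abs(det) > _EPS, 1.0 / np.where(det == 0, 1.0, det), np.nan)
        tvec = o - v0[None, :, :]
        u = np.einsum("rfk,rfk->rf", tvec, pvec) * inv
        qvec = np.cross(tvec, e1[None, :, :])
        v = np.einsum("rfk,rfk->rf", qvec, d) * inv
        t = np.einsum("rfk,fk->rf", qvec, e2) * inv
        ok = (
            np.isfinite(t)
            & (u >= -1e-10)
            & (v >= -1e-10)
            & (u + v <= 1.0 + 1e-10)
            & (t >= -1e-10)
        )
        t = np.where(ok, np.maximum(t, 0.0), np.inf)
        j = np.argmin(t, axis=1)
        rows = np.arange(t.shape[0])
        tmin = t[rows, j]
        hit = np.isfinite(tmin)
        t_best[s : s + chunk][hit] = tmin[hit]
        idx_best[s : s + chunk][hit] = j[hit]
    return t_best, idx_best


def closest_point_on_triangles(points: np.ndarray, triangles: np.ndarray):
    """Closest point of each point on its own candidate triangle (paired).

    ``points``: (k, 3); ``triangles``: (k, 3, 3). Returns (k, 3) closest
    points and (k,) squared distances. Standard region-walk formulation.
    """
    p = np.asarray(points, dtype=np.float64)
    a, b, c = triangles[:, 0], triangles[:, 1], triangles[:, 2]
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    def settle(mask, value):
        m = mask & ~done
        out[m] = value[m]
        done[m] = True

    settle((d1 <= 0) & (d2 <= 0), a)
    settle((d3 >= 0) & (d4 <= d3), b)
    settle((d6 >= 0) & (d5 <= d6), c)
    vc = d1 * d4 - d3 * d2
    with np.errstate(divide="ignore", invalid="ignore"):
        v = d1 / (d1 - d3)
    settle((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + np.nan_to_num(v)[:, None] * ab)
    vb = d5 * d2 - d1 * d6
    with np.errstate(divide="ignore", invalid="ignore"):
        w = d2 / (d2 - d6)
    settle((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + np.nan_to_num(w)[:, None] * ac)
    va = d3 * d6 - d5 * d4
    with np.errstate(divide="ignore", invalid="ignore"):
        w2 = (d4 - d3) / ((d4 - d3) + (d5 - d6))
    settle((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0), b + np.nan_to_num(w2)[:, None] * (c - b))
    denom = np.where(va + vb + vc == 0, 1.0, va + vb + vc)
    v3 = (vb / denom)[:, None]
    w3 = (vc / denom)[:, None]
    settle(np.ones(len(p), dtype=bool), a + v3 * ab + w3 * ac)
    d2_out = np.einsum("ij,ij->i", out - p, out - p)
    return out, d2_out


class MeshProximity:
    """Approximate-exact closest-point queries on a triangle mesh.

    A KD-tree over triangle centroids proposes ``k`` candidate triangles per
    query; the exact closest point is then taken over the candidates. With
    k of a few dozen on meshes of this pipeline's density the result is the
    true closest point for all practical queries.
    """

    def __init__(self, vertices: np.ndarray, faces: np.ndarray, k: int = 32):
        self.triangles = np.asarray(vertices, dtype=np.float64)[np.asarray(faces)]
        self.centroids = self.triangles.mean(axis=1)
        self.tree = cKDTree(self.centroids)
        self.k = min(k, len(self.centroids))

    def query(self, points: np.ndarray):
        """Closest surface points: returns (points, distances, triangle ids)."""
        points = np.asarray(points, dtype=np.float64)
        _, cand = self.tree.query(points, k=self.k)
        cand = np.atleast_2d(cand)
        n, k = cand.shape
        flat_pts = np.repeat(points, k, axis=0)
        flat_tri = self.triangles[cand.ravel()]
        cp, d2 = closest_point_on_triangles(flat_pts, flat_tri)
        d2 = d2.reshape(n, k)
        j = np.argmin(d2, axis=1)
        rows = np.arange(n)
        best = cp.reshape(n, k, 3)[rows, j]
        return best, np.sqrt(d2[rows, j]), cand[rows, j]


def _moller_paired(origins, directions, triangles):
    """Ray parameter of each ray against its own paired triangle; inf on miss."""
    v0 = triangles[:, 0]
    e1 = triangles[:, 1] - v0
    e2 = triangles[:, 2] - v0
    pvec = np.cross(directions, e2)
    det = np.einsum("ij,ij->i", pvec, e1)
    ok = np.abs(det) > _EPS
    inv = np.where(ok, 1.0 / np.where(det == 0, 1.0, det), np.nan)
    tvec = origins - v0
    u = np.einsum("ij,ij->i", tvec, pvec) * inv
    qvec = np.cross(tvec, e1)
    v = np.einsum("ij,ij->i", qvec, directions) * inv
    t = np.einsum("ij,ij->i", qvec, e2) * inv
    good = (
        np.isfinite(t)
        & (u >= -1e-10)
        & (v >= -1e-10)
        & (u + v <= 1.0 + 1e-10)
        & (t >= -1e-10)
    )
    return np.where(good, np.maximum(t, 0.0), np.inf)


class RayProjector:
    """Accelerated nearest +/- ray-mesh intersection for locally short rays.

    Triangles are split by circumradius: *small* ones are searched through a
    centroid KD-tree (k nearest candidates per origin), while the few
    *large* ones (e.g. coarse side walls) are pruned per ray by
    line-to-centroid distance and tested directly. A candidate result is
    trusted only when it provably precedes every untested small triangle
    (|t| + max small radius <= distance to the k-th candidate centroid);
    the remaining rays are resolved by the exact brute-force pass, so the
    result is exact in all cases and fast when hits are local — which they
    are throughout the contraction iterations.
    """

    def __init__(self, vertices: np.ndarray, faces: np.ndarray, k: int = 48):
        tris = np.asarray(vertices, dtype=np.float64)[np.asarray(faces)]
        cent = tris.mean(axis=1)
        rad = np.sqrt(((tris - cent[:, None, :]) ** 2).sum(-1).max(-1))
        self.triangles = tris
        if len(rad):
            cutoff = 1.5 * np.median(rad)
            large = rad > cutoff
        else:
            large = np.zeros(0, dtype=bool)
        self.small_tris = tris[~large]
        self.small_cent = cent[~large]
        self.small_rmax = float(rad[~large].max()) if (~large).any() else 0.0
        self.large_tris = tris[large]
        self.large_cent = cent[large]
        self.large_rad = rad[large]
        self.tree = cKDTree(self.small_cent) if len(self.small_cent) else None
        self.k = min(k, len(self.small_cent))

    def _large_best(self, origins, directions):
        """Signed nearest hit among the large triangles (line-distance pruned)."""
        n = len(origins)
        best = np.full(n, np.inf)
        if len(self.large_tris) == 0:
            return best
        rel = self.large_cent[None, :, :] - origins[:, None, :]  # (n, L, 3)
        proj = np.einsum("nlk,nk->nl", rel, directions)
        perp2 = np.einsum("nlk,nlk->nl", rel, rel) - proj**2
        hit_possible = perp2 <= (self.large_rad[None, :] + 1e-12) ** 2
        ri, li = np.nonzero(hit_possible)
        if len(ri) == 0:
            return best
        for sign in (1.0, -1.0):
            t = _moller_paired(
                origins[ri], sign * directions[ri], self.large_tris[li]
            )
            signed = sign * t
            finite = np.isfinite(t)
            if finite.any():
                order = np.argsort(np.abs(signed[finite]), kind="stable")
                rows = ri[finite][order]
                vals = signed[finite][order]
                first = np.unique(rows, return_index=True)[1]
                better = np.abs(vals[first]) < np.abs(best[rows[first]])
                best[rows[first][better]] = vals[first][better]
        return best

    def cast_signed(self, origins: np.ndarray, normals: np.ndarray):
        """Signed distance along +/-normal to the nearest intersection.

        Positive = hit along +normal. ``inf`` where both rays miss. Exact.
        """
        origins = np.asarray(origins, dtype=np.float64)
        normals = np.asarray(normals, dtype=np.float64)
        n = len(origins)
        best = self._large_best(origins, normals)
        if self.tree is None:
            return best
        dk, cand = self.tree.query(origins, k=self.k)
        dk = np.atleast_2d(dk)[:, -1]
        cand = np.atleast_2d(cand)
        k = cand.shape[1]
        o_rep = np.repeat(origins, k, axis=0)
        d_rep = np.repeat(normals, k, axis=0)
        tris = self.small_tris[cand.ravel()]
        t_plus = _moller_paired(o_rep, d_rep, tris).reshape(n, k).min(axis=1)
        t_minus = _moller_paired(o_rep, -d_rep, tris).reshape(n, k).min(axis=1)
        small_best = np.where(t_plus <= t_minus, t_plus, -t_minus)
        cand_best = np.where(np.abs(small_best) <= np.abs(best), small_best, best)
        # sound only if no untested small triangle could intersect nearer
        trusted = np.abs(cand_best) + self.small_rmax <= dk
        if k == len(self.small_cent):
            trusted[:] = True
        if not trusted.all():
            rest = ~trusted
            tp = ray_mesh_intersections(origins[rest], normals[rest], self.small_tris)[0]
            tm = ray_mesh_intersections(origins[rest], -normals[rest], self.small_tris)[0]
            sb = np.where(tp <= tm, tp, -tm)
            cand_best[rest] = np.where(
                np.abs(sb) <= np.abs(best[rest]), sb, best[rest]
            )
        return cand_best


def count_self_intersections(vertices: np.ndarray, faces: np.ndarray) -> int:
    """Number of intersecting non-adjacent triangle pairs (brute force + pruning).

    Two triangles intersect iff an edge of one properly crosses the interior
    of the other (coplanar overlaps are not counted). Intended for QC on
    meshes up to a few thousand faces.
    """
    v = np.asarray(vertices, dtype=np.float64)
    f = np.asarray(faces)
    tris = v[f]
    cent = tris.mean(axis=1)
    rad = np.sqrt(((tris - cent[:, None, :]) ** 2).sum(-1).max(-1))
    tree = cKDTree(cent)
    rmax = rad.max()
    pairs = tree.query_pairs(2.0 * rmax, output_type="ndarray")
    if len(pairs) == 0:
        return 0
    # drop pairs sharing a vertex and pairs whose bounding spheres don't touch
    share = np.array(
        [len(set(f[i]) & set(f[j])) > 0 for i, j in pairs]
    )
    d = np.linalg.norm(cent[pairs[:, 0]] - cent[pairs[:, 1]], axis=1)
    close = d <= rad[pairs[:, 0]] + rad[pairs[:, 1]]
    pairs = pairs[~share & close]
    count = 0
    for i, j in pairs:
        if _tri_tri_intersect(tris[i], tris[j]):
            count += 1
    return count


def _segments_cross_triangle(segs_a, segs_b, tri) -> bool:
    """Does any segment (a->b) properly cross triangle tri?"""
    a = segs_a
    d = segs_b - segs_a
    v0, e1, e2 = tri[0], tri[1] - tri[0], tri[2] - tri[0]
    pvec = np.cross(d, e2)
    det = pvec @ e1
    ok = np.abs(det) > _EPS
    if not ok.any():
        return False
    inv = np.where(ok, 1.0 / np.where(det == 0, 1.0, det), 0.0)
    tvec = a - v0
    u = np.einsum("ij,ij->i", tvec, pvec) * inv
    qvec = np.cross(tvec, np.broadcast_to(e1, a.shape))
    vv = np.einsum("ij,ij->i", qvec, d) * inv
    t = (qvec @ e2) * inv
    hit = ok & (u > 1e-10) & (vv > 1e-10) & (u + vv < 1 - 1e-10) & (t > 1e-10) & (t < 1 - 1e-10)
    return bool(hit.any())


def _tri_tri_intersect(t1: np.ndarray, t2: np.ndarray) -> bool:
    e = np.array([[0, 1], [1, 2], [2, 0]])
    return _segments_cross_triangle(t1[e[:, 0]], t1[e[:, 1]], t2) or _segments_cross_triangle(
        t2[e[:, 0]], t2[e[:, 1]], t1
    )
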