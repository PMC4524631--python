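"""Construction of the homogeneous wear surface S_h.

The worn scan S1 has no vertex correspondence with the intact scan S0. The
homogeneous surface S_h fixes that: it keeps S0's connectivity while its
geometry converges onto S1, giving every intact vertex a worn counterpart.

Two stages:

1. *Initialization by an RBF distance field.* Each feature point of S0 is
   projected along its normal onto S1; the signed projection distances
   D_i (negative = material loss, inward) are interpolated over space with
   a cubic-kernel radial basis field phi(x) = x^3 plus a first-order
   polynomial, subject to the four orthogonality side conditions that make
   the interpolant affine-reproducing. Evaluating the field at every S0
   vertex and offsetting along the vertex normal yields the initial S_h.

2. *Contraction and bounding.* The residual between the initial S_h and S1
   is removed iteratively: project every occlusal vertex P_i along its
   normal to Q_i on S1, move it a fraction lambda of the way
   (P_i' = P_i + lambda (Q_i - P_i), lambda = 0.4 by default — the partial
   step keeps self-intersections down), regularize with a 1-ring weighted
   smoothing pass, and repeat until the summed error E = sum |P_i - Q_i|
   drops below epsilon (default 0.001).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .features import FeaturePointSet
from .geometry import MeshProximity, RayProjector
from .mesh import TriangleMesh, vertex_normals

log = logging.getLogger(__name__)

__all__ = [
    "RBFField",
    "ContractionParams",
    "ProjectionResult",
    "ConvergenceError",
    "project_along_normal",
    "fit_rbf",
    "evaluate_rbf",
    "build_initial_homogeneous",
    "contract_and_bound",
]


class ConvergenceError(RuntimeError):
    """Contraction-and-bounding stalled (error not decreasing)."""


@dataclass
class RBFField:
    """Cubic-kernel radial basis interpolant of a scalar over 3-space.

    ``f(x) = sum_j lambda_j |x - V_j|^3 + c0 + c1 x + c2 y + c3 z``

    The weights satisfy the orthogonality conditions
    ``sum lambda_j = sum lambda_j V_j = 0``, which make the interpolant
    reproduce affine data exactly.
    """

    centers: np.ndarray  # (n, 3)
    weights: np.ndarray  # (n,)
    poly: np.ndarray  # (4,) c0..c3

    def __call__(self, query: np.ndarray) -> np.ndarray:
        return evaluate_rbf(self, query)


@dataclass
class ContractionParams:
    """Knobs of the contraction-and-bounding iteration (defaults as published)."""

    contraction_factor: float = 0.4  # lambda in [0, 1]
    epsilon: float = 0.001  # stop when E = sum |P_i - Q_i| < epsilon (mm)
    max_iterations: int = 200
    smoothing_weight: float = 0.5  # w in [0, 1]
    smoothing: str = "displacement"  # "displacement" | "position" | "none"
    mean_error: bool = False  # stop on E/m instead of the summed E

    def __post_init__(self) -> None:
        if not 0.0 <= self.contraction_factor <= 1.0:
            raise ValueError("contraction_factor must be in [0, 1]")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if not 0.0 <= self.smoothing_weight <= 1.0:
            raise ValueError("smoothing_weight must be in [0, 1]")
        if self.smoothing not in ("displacement", "position", "none"):
            raise ValueError("smoothing must be displacement|position|none")


@dataclass
class ProjectionResult:
    """Normal-ray projections of points onto a target surface."""

    projected_points: np.ndarray  # (n, 3), on the target surface
    signed_distances: np.ndarray  # (n,), + along the outward normal (mm)
    hit_flags: np.ndarray  # (n,) bool; False = closest-point fallback


def project_along_normal(
    points: np.ndarray,
    normals: np.ndarray,
    target: TriangleMesh,
    max_distance: float | None = None,
) -> ProjectionResult:
    """Project points along their +/- normal rays onto a target mesh.

    The nearer of the two ray hits wins; its distance is signed positive
    when the hit lies along the outward normal. Points whose rays miss the
    target entirely — or whose nearest hit is farther than ``max_distance``,
    i.e. the ray sailed past the nearby surface onto a distant sheet — fall
    back to the closest surface point (flagged False, sign from the normal
    side of the offset).
    """
    points = np.asarray(points, dtype=np.float64)
    normals = np.asarray(normals, dtype=np.float64)
    if target.n_faces == 0:
        raise ValueError("target mesh has no faces")
    norms = np.linalg.norm(normals, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-6):
        raise ValueError("normals must be unit length")
    projector = getattr(target, "_ray_projector", None)
    if projector is None:
        projector = RayProjector(target.vertices, target.faces)
        target._ray_projector = projector  # cached; geometry is never mutated in place
    signed = projector.cast_signed(points, normals)
    hit = np.isfinite(signed)
    if max_distance is not None:
        hit &= np.abs(signed) <= max_distance
    q = points + np.where(hit, signed, 0.0)[:, None] * normals
    if not hit.all():
        miss = ~hit
        prox = MeshProximity(target.vertices, target.faces)
        cp, dist, _ = prox.query(points[miss])
        side = np.sign(np.einsum("ij,ij->i", cp - points[miss], normals[miss]))
        side[side == 0] = 1.0
        q[miss] = cp
        signed[miss] = side * dist
    return ProjectionResult(q, signed, hit)


def fit_rbf(centers: np.ndarray, distances: np.ndarray) -> RBFField:
    """Solve the dense symmetric (n+4)x(n+4) interpolation system.

    ``[[A, P], [P^T, 0]] [lambda, c] = [D, 0]`` with
    ``A_ij = |V_i - V_j|^3`` and ``P = [1, V^x, V^y, V^z]``.
    """
    centers = np.asarray(centers, dtype=np.float64)
    distances = np.asarray(distances, dtype=np.float64)
    n = len(centers)
    if n < 4:
        raise ValueError("need at least 4 RBF centers")
    diff = centers[:, None, :] - centers[None, :, :]
    r = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    dup = np.argwhere((r < 1e-12) & ~np.eye(n, dtype=bool))
    if len(dup):
        i, j = dup[0]
        raise ValueError(f"duplicate RBF centers {i} and {j} make the system singular")
    a = r**3
    p = np.column_stack([np.ones(n), centers])
    sys = np.zeros((n + 4, n + 4))
    sys[:n, :n] = a
    sys[:n, n:] = p
    sys[n:, :n] = p.T
    rhs = np.concatenate([distances, np.zeros(4)])
    try:
        sol = scipy.linalg.solve(sys, rhs, assume_a="sym")
        residual = np.abs(sys @ sol - rhs).max()
    except (scipy.linalg.LinAlgError, ValueError):
        sol, residual = None, np.inf
    scale = max(np.abs(distances).max(), 1.0)
    if sol is None or residual > 1e-8 * scale:
        # coplanar centers leave one polynomial coefficient free; take the
        # minimum-norm interpolant instead
        sol, *_ = scipy.linalg.lstsq(sys, rhs, lapack_driver="gelsd")
        residual = np.abs(sys @ sol - rhs).max()
        if residual > 1e-6 * scale:
            raise ValueError(
                f"RBF system is numerically singular (residual {residual:.3g})"
            )
    return RBFField(centers.copy(), sol[:n], sol[n:])


def evaluate_rbf(field: RBFField, query: np.ndarray) -> np.ndarray:
    """Evaluate the field at one point (returns a scalar) or many (array)."""
    q = np.atleast_2d(np.asarray(query, dtype=np.float64))
    diff = q[:, None, :] - field.centers[None, :, :]
    r = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    vals = (r**3) @ field.weights + field.poly[0] + q @ field.poly[1:]
    return vals[0] if np.asarray(query).ndim == 1 else vals


def build_initial_homogeneous(
    s0: TriangleMesh,
    features: FeaturePointSet,
    s1: TriangleMesh,
    vector_field: bool = False,
) -> TriangleMesh:
    """Initial S_h: RBF-interpolated signed wear offsets along S0 normals.

    Feature points of S0 are projected along their normals onto S1; an
    RBF field fitted to their signed distances is evaluated at every S0
    vertex and applied as an offset along the vertex normal. Axial vertices
    (unchanged by wear) get zero offset. Output keeps S0's connectivity.

    With ``vector_field=True`` the three components of the feature
    displacements (Q_i - V_i) are interpolated by independent RBF fields
    instead of the scalar normal-offset field.
    """
    normals = vertex_normals(s0)
    proj = project_along_normal(
        features.positions, normals[features.source_indices], s1
    )
    out = s0.copy()
    free = s0.occlusal_indices()
    if vector_field:
        disp = proj.projected_points - features.positions
        moves = np.column_stack([
            evaluate_rbf(fit_rbf(features.positions, disp[:, d]), s0.vertices)
            for d in range(3)
        ])
        out.vertices[free] += moves[free]
    else:
        field = fit_rbf(features.positions, proj.signed_distances)
        offsets = evaluate_rbf(field, s0.vertices)
        out.vertices[free] += offsets[free, None] * normals[free]
    return out


def _one_ring_averaging(mesh: TriangleMesh):
    """Averaging operator A = I - L whose rows are 1-ring centroid weights."""
    from scipy import sparse

    from .mesh import build_laplacian

    lap = build_laplacian(mesh).matrix
    return sparse.identity(lap.shape[0], format="csr") - lap


def contract_and_bound(
    sh: TriangleMesh,
    s1: TriangleMesh,
    params: ContractionParams | None = None,
) -> tuple[TriangleMesh, list[float]]:
    """Converge S_h onto S1 by contraction and bounding; returns (mesh, E trace).

    Per iteration: recompute S_h normals; project every occlusal vertex P_i
    along its normal to Q_i on S1; evaluate E = sum |P_i - Q_i| (stop if
    E < epsilon); step P_i' = P_i + lambda (Q_i - P_i); smooth over the
    1-ring. Axial vertices are pinned throughout. The default smoothing
    regularizes the per-iteration displacement field; ``smoothing="position"``
    blends positions with the 1-ring centroid as a classic umbrella pass.

    Raises :class:`ConvergenceError` if E fails to decrease for five
    consecutive iterations.
    """
    params = params or ContractionParams()
    out = sh.copy()
    free = out.occlusal_indices()
    if len(free) == 0:
        return out, [0.0]
    averaging = _one_ring_averaging(out)
    trace: list[float] = []
    stalls = 0
    cap = None  # adaptive ray-length cap keeps vertices off distant sheets
    for _ in range(params.max_iterations + 1):
        normals = vertex_normals(out)
        proj = project_along_normal(out.vertices[free], normals[free], s1, max_distance=cap)
        cap = 5.0 * max(float(np.quantile(np.abs(proj.signed_distances), 0.99)), 1e-9)
        err = np.abs(proj.signed_distances)
        e = float(err.sum())
        trace.append(e)
        stop = (e / len(free)) < params.epsilon if params.mean_error else e < params.epsilon
        if stop:
            break
        if len(trace) >= 2 and trace[-1] >= trace[-2]:
            stalls += 1
            if stalls >= 5:
                raise ConvergenceError(
                    f"error non-decreasing for 5 consecutive iterations "
                    f"(E trace tail: {[round(t, 6) for t in trace[-6:]]})"
                )
        else:
            stalls = 0
        if len(trace) > params.max_iterations:
            log.warning("contraction stopped at max_iterations with E=%.3g", e)
            break
        step = np.zeros_like(out.vertices)
        step[free] = params.contraction_factor * (proj.projected_points - out.vertices[free])
        w = params.smoothing_weight
        if params.smoothing == "displacement":
            smoothed = (1.0 - w) * step + w * (averaging @ step)
            smoothed[out.axial_indices()] = 0.0
            out.vertices = out.vertices + smoothed
        elif params.smoothing == "position":
            moved = out.vertices + step
            blended = (1.0 - w) * moved + w * (averaging @ moved)
            blended[out.axial_indices()] = out.vertices[out.axial_indices()]
            out.vertices = blended
        else:
            out.vertices = out.vertices + step
    return out, trace
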