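"""Selective rigid alignment of intact and worn tooth meshes.

Occlusal wear leaves the axial walls of the crown untouched, so the two
scans are registered on the axial region only: classic point-to-point ICP,
pairing each axial source vertex with its closest point on the target's
axial surface (point-to-triangle, so the fit is independent of the target's
tessellation density) and solving each round's rigid fit in closed form
(Kabsch/SVD). The recovered transform is then applied to the whole mesh.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .geometry import MeshProximity
from .mesh import TriangleMesh

log = logging.getLogger(__name__)

__all__ = ["RigidTransform", "icp_align", "apply_transform", "kabsch"]


@dataclass
class RigidTransform:
    """Proper rigid motion x -> R x + t."""

    rotation: np.ndarray  # (3, 3) orthonormal, det +1
    translation: np.ndarray  # (3,)
    converged: bool = True
    rms_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=np.float64)
        self.translation = np.asarray(self.translation, dtype=np.float64)
        r = self.rotation
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-9) or not np.isclose(
            np.linalg.det(r), 1.0, atol=1e-9
        ):
            raise ValueError("rotation must be orthonormal with determinant +1")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=np.float64) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: x -> self(other(x))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def matrix(self) -> np.ndarray:
        """Homogeneous 4x4 row form."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m


def kabsch(source: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Least-squares rigid fit mapping paired source points onto target points."""
    source = np.asarray(source, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    cs, ct = source.mean(0), target.mean(0)
    h = (source - cs).T @ (target - ct)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform(r, ct - r @ cs)


def _check_nondegenerate(points: np.ndarray) -> None:
    if len(points) < 3:
        raise ValueError("ICP needs at least 3 source points")
    c = points - points.mean(0)
    s = np.linalg.svd(c, compute_uv=False)
    if s[1] <= 1e-12 * max(s[0], 1.0):
        raise ValueError("source points are collinear or coincident; ICP is degenerate")


def icp_align(
    source_points: np.ndarray,
    target_mesh: TriangleMesh,
    max_iterations: int = 50,
    tolerance: float = 1e-10,
) -> RigidTransform:
    """Point-to-surface ICP of source points onto a target mesh region.

    Iterates closest-point pairing against the target surface with a Kabsch
    rigid fit until the RMS closest-point distance changes by less than
    ``tolerance`` or ``max_iterations`` is hit (then the best transform so
    far is returned with ``converged=False`` and a logged warning). The RMS
    trace is recorded on the returned transform.
    """
    source_points = np.asarray(source_points, dtype=np.float64)
    _check_nondegenerate(source_points)
    if target_mesh.n_faces == 0:
        raise ValueError("target region has no faces")
    prox = MeshProximity(target_mesh.vertices, target_mesh.faces)

    current = RigidTransform.identity()
    moved = source_points.copy()
    trace: list[float] = []
    converged = False
    for _ in range(max_iterations):
        closest, dists, _ = prox.query(moved)
        rms = float(np.sqrt(np.mean(dists**2)))
        if trace and abs(trace[-1] - rms) < tolerance:
            trace.append(rms)
            converged = True
            break
        trace.append(rms)
        step = kabsch(moved, closest)
        moved = step.apply(moved)
        current = step.compose(current)
    if not converged:
        log.warning("ICP did not converge in %d iterations (last RMS %.3g)",
                    max_iterations, trace[-1] if trace else float("nan"))
    current.converged = converged
    current.rms_trace = trace
    return current


def apply_transform(mesh: TriangleMesh, transform: RigidTransform) -> TriangleMesh:
    """Rigidly move a mesh; topology, masks and scalars are untouched."""
    out = mesh.copy()
    out.vertices = transform.apply(mesh.vertices)
    return out
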