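"""Triangle-mesh container, I/O and the uniform-weight Laplacian.

A tooth surface is represented as an indexed triangle mesh ``M = (V, K)``:
``V`` the vertex positions (millimetres) and ``K`` the triangulation. The
mesh optionally carries a region mask splitting it into the *occlusal*
surface (the chewing surface, where wear happens) and the *axial* surface
(the crown walls, unchanged by wear), plus named per-vertex scalar fields
such as wear depth.

Meshes are required to be edge-manifold and consistently oriented at load
time; open boundaries are allowed (an occlusal patch may be an open cap).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy import sparse

log = logging.getLogger(__name__)

AXIAL = 0
OCCLUSAL = 1

__all__ = [
    "AXIAL",
    "OCCLUSAL",
    "TriangleMesh",
    "LaplacianMatrix",
    "MeshValidationError",
    "load_mesh",
    "save_mesh",
    "vertex_normals",
    "build_laplacian",
    "wear_colors",
]


class MeshValidationError(ValueError):
    """A mesh violates a structural requirement (indices, manifoldness, orientation)."""


@dataclass
class TriangleMesh:
    """Indexed triangle mesh with optional region mask and per-vertex scalars.

    Parameters
    ----------
    vertices : (m, 3) float array, model units (mm)
    faces : (f, 3) int array of 0-based vertex indices, counter-clockwise
        as seen from outside.
    region_mask : optional (m,) int array, ``AXIAL`` (0) or ``OCCLUSAL`` (1).
    scalars : dict of named per-vertex float arrays.
    """

    vertices: np.ndarray
    faces: np.ndarray
    region_mask: np.ndarray | None = None
    scalars: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshValidationError("vertices must be an (m, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshValidationError("faces must be an (f, 3) array")
        if self.region_mask is not None:
            self.region_mask = np.asarray(self.region_mask, dtype=np.int64)
            if self.region_mask.shape != (len(self.vertices),):
                raise MeshValidationError("region_mask must have one label per vertex")

    # -- basic accessors -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def occlusal_indices(self) -> np.ndarray:
        """Indices of occlusal vertices (all vertices if no mask is set)."""
        if self.region_mask is None:
            return np.arange(self.n_vertices)
        return np.flatnonzero(self.region_mask == OCCLUSAL)

    def axial_indices(self) -> np.ndarray:
        if self.region_mask is None:
            return np.empty(0, dtype=np.int64)
        return np.flatnonzero(self.region_mask == AXIAL)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(
            self.vertices.copy(),
            self.faces.copy(),
            None if self.region_mask is None else self.region_mask.copy(),
            {k: v.copy() for k, v in self.scalars.items()},
        )

    def bbox_diagonal(self) -> float:
        return float(np.linalg.norm(self.vertices.max(0) - self.vertices.min(0)))

    # -- structure -------------------------------------------------------

    def validate(self) -> None:
        """Check index validity, degeneracy, edge-manifoldness and orientation.

        Raises :class:`MeshValidationError` naming the first offending face.
        """
        m = self.n_vertices
        if self.faces.size:
            bad = np.flatnonzero((self.faces < 0).any(1) | (self.faces >= m).any(1))
            if bad.size:
                raise MeshValidationError(
                    f"face {bad[0]} references an out-of-range vertex index: "
                    f"{self.faces[bad[0]].tolist()} (mesh has {m} vertices)"
                )
            f = self.faces
            degen = np.flatnonzero(
                (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
            )
            if degen.size:
                raise MeshValidationError(
                    f"face {degen[0]} is degenerate (repeated vertex index): "
                    f"{f[degen[0]].tolist()}"
                )
            di = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
            face_of = np.tile(np.arange(len(f)), 3)
            # Edge-manifold <=> each undirected edge is used by at most 2 faces.
            ukeys = np.minimum(di[:, 0], di[:, 1]) * m + np.maximum(di[:, 0], di[:, 1])
            uniq, inv, counts = np.unique(ukeys, return_inverse=True, return_counts=True)
            if counts.max(initial=0) > 2:
                bad_key = np.flatnonzero(counts > 2)[0]
                j = np.flatnonzero(inv == bad_key)
                culprit = int(face_of[j].max())
                raise MeshValidationError(
                    f"face {culprit} makes undirected edge "
                    f"{tuple(di[j[0]].tolist())} non-manifold (>2 incident faces)"
                )
            # Consistent orientation <=> no directed edge appears twice.
            keys = di[:, 0] * m + di[:, 1]
            order = np.argsort(keys, kind="stable")
            dup = np.flatnonzero(np.diff(keys[order]) == 0)
            if dup.size:
                j = order[dup[0] + 1]
                raise MeshValidationError(
                    f"face {face_of[j]} repeats directed edge "
                    f"{tuple(di[j].tolist())}: mesh is not consistently oriented"
                )

    def edges_unique(self) -> np.ndarray:
        """Undirected edges as an (e, 2) array with i < j, sorted."""
        f = self.faces
        e = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def boundary_vertices(self) -> np.ndarray:
        """Vertices on open boundary edges (edges with a single incident face)."""
        f = self.faces
        e = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        e = np.sort(e, axis=1)
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        return np.unique(uniq[counts == 1])

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)


@dataclass
class LaplacianMatrix:
    """Sparse uniform-weight (umbrella) Laplacian of a mesh.

    Row i encodes ``L(v_i) = v_i - (1/d_i) * sum_{j in N(i)} v_j`` where
    ``d_i`` is the vertex degree: diagonal 1, off-diagonals ``-w_ij`` with
    ``sum_j w_ij = 1``, so every row sums to zero and constants are
    annihilated (the operator is translation invariant).
    """

    matrix: sparse.csr_matrix
    weighting: str = "uniform"

    def apply(self, vertices: np.ndarray) -> np.ndarray:
        """Differential (delta) coordinates of a vertex array."""
        return self.matrix @ np.asarray(vertices, dtype=np.float64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape


def build_laplacian(mesh: TriangleMesh, weighting: str = "uniform") -> LaplacianMatrix:
    """Uniform-weight Laplacian ``I - D^{-1} A`` of the mesh graph.

    ``weighting="cotangent"`` switches to cotangent weights (normalised so
    each row still sums to zero); uniform weights are the default used
    throughout the wear pipeline.
    """
    m = mesh.n_vertices
    if m < 4:
        raise MeshValidationError("need at least 4 vertices to build a Laplacian")
    e = mesh.edges_unique()
    if weighting == "uniform":
        rows = np.concatenate([e[:, 0], e[:, 1]])
        cols = np.concatenate([e[:, 1], e[:, 0]])
        w = np.ones(len(rows))
    elif weighting == "cotangent":
        rows, cols, w = _cotangent_entries(mesh)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    adj = sparse.coo_matrix((w, (rows, cols)), shape=(m, m)).tocsr()
    deg = np.asarray(adj.sum(axis=1)).ravel()
    if np.any(deg == 0):
        i = int(np.flatnonzero(deg == 0)[0])
        raise MeshValidationError(f"vertex {i} has no neighbours (degree 0)")
    dinv = sparse.diags(1.0 / deg)
    lap = (sparse.identity(m, format="csr") - dinv @ adj).tocsr()
    return LaplacianMatrix(lap, weighting)


def _cotangent_entries(mesh: TriangleMesh):
    v, f = mesh.vertices, mesh.faces
    rows, cols, vals = [], [], []
    for a, b, c in ((0, 1, 2), (1, 2, 0), (2, 0, 1)):
        # cotangent at corner c weights edge (a, b)
        u1 = v[f[:, a]] - v[f[:, c]]
        u2 = v[f[:, b]] - v[f[:, c]]
        cross = np.linalg.norm(np.cross(u1, u2), axis=1)
        cot = np.einsum("ij,ij->i", u1, u2) / np.maximum(cross, 1e-300)
        cot = np.clip(cot, 1e-6, None)  # keep weights positive for row normalisation
        rows += [f[:, a], f[:, b]]
        cols += [f[:, b], f[:, a]]
        vals += [cot, cot]
    return np.concatenate(rows), np.concatenate(cols), np.concatenate(vals)


def vertex_normals(mesh: TriangleMesh) -> np.ndarray:
    """Outward unit vertex normals, area-weighted over incident faces."""
    v, f = mesh.vertices, mesh.faces
    fn = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])  # 2*area*n
    vn = np.zeros_like(v)
    for k in range(3):
        np.add.at(vn, f[:, k], fn)
    norms = np.linalg.norm(vn, axis=1)
    isolated = np.flatnonzero(norms == 0)
    if isolated.size:
        raise MeshValidationError(
            f"vertex {isolated[0]} has no incident face (or zero normal sum)"
        )
    return vn / norms[:, None]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_FORMATS = {".ply": "ply", ".obj": "obj", ".stl": "stl"}


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in ("ply", "obj", "stl"):
            raise ValueError(f"unsupported mesh format {fmt!r}")
        return fmt
    try:
        return _FORMATS[path.suffix.lower()]
    except KeyError:
        raise ValueError(f"cannot infer mesh format from suffix {path.suffix!r}") from None


def load_mesh(path: str | Path, fmt: str | None = None) -> TriangleMesh:
    """Load and validate a PLY/OBJ/STL mesh, preserving vertex order and units.

    PLY files may carry extra per-vertex float properties, restored into
    ``scalars``, and an integer ``region`` property restored as the region
    mask (0=axial, 1=occlusal).
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        tm = trimesh.load(str(path), file_type=fmt, process=False, force="mesh")
    except Exception as err:  # trimesh raises parser-specific errors
        raise MeshValidationError(
            f"{path}: unreadable {fmt} (malformed or out-of-range face data): {err}"
        ) from err
    mesh = TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces))
    if fmt == "ply":
        props = _read_ply_vertex_properties(path)
        for name, arr in props.items():
            if name == "region":
                mesh.region_mask = arr.astype(np.int64)
            else:
                mesh.scalars[name] = arr.astype(np.float64)
    mesh.validate()
    return mesh


def save_mesh(
    mesh: TriangleMesh,
    path: str | Path,
    scalar_name: str | None = None,
    fmt: str | None = None,
) -> None:
    """Write a mesh; PLY embeds scalars, region mask and wear colouring.

    With ``scalar_name`` given, the PLY output carries that field both as a
    per-vertex float property and as an RGB vertex colour through the
    yellow-to-red wear map. STL cannot carry attributes: a warning is logged
    and they are dropped.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if scalar_name is not None and scalar_name not in mesh.scalars:
        raise KeyError(f"mesh has no scalar field {scalar_name!r}")
    tm = mesh.to_trimesh()
    if fmt == "ply":
        for name, arr in mesh.scalars.items():
            tm.vertex_attributes[name] = np.asarray(arr, dtype=np.float64)
        if mesh.region_mask is not None:
            tm.vertex_attributes["region"] = mesh.region_mask.astype(np.int32)
        if scalar_name is not None:
            tm.visual.vertex_colors = wear_colors(mesh.scalars[scalar_name])
        data = trimesh.exchange.ply.export_ply(
            tm, encoding="binary_little_endian", include_attributes=True
        )
        path.write_bytes(data)
    else:
        if fmt == "stl" and (scalar_name or mesh.scalars or mesh.region_mask is not None):
            log.warning("STL has no per-vertex attributes; scalars/region dropped")
        tm.export(str(path), file_type=fmt)


def wear_colors(depth: np.ndarray, base: tuple[int, int, int] = (225, 225, 225)) -> np.ndarray:
    """RGBA colours for a wear-depth field: yellow (shallow) to red (deep).

    Depths are mapped linearly from ``[0, max depth]`` onto
    yellow ``(255, 255, 0)`` -> red ``(255, 0, 0)``; vertices with zero wear
    get the neutral base colour.
    """
    depth = np.asarray(depth, dtype=np.float64)
    rgba = np.empty((len(depth), 4), dtype=np.uint8)
    rgba[:] = (*base, 255)
    dmax = depth.max() if len(depth) else 0.0
    if dmax > 0:
        worn = depth > 1e-12 * max(dmax, 1.0)
        t = depth[worn] / dmax
        rgba[worn, 0] = 255
        rgba[worn, 1] = np.round(255 * (1.0 - t)).astype(np.uint8)
        rgba[worn, 2] = 0
    return rgba


# trimesh's PLY loader discards unknown vertex properties, so scalar fields
# ("wear_depth", "region", ...) are recovered with this header-driven reader.
_PLY_DTYPES = {
    "char": "i1", "int8": "i1", "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2", "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4", "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4", "double": "f8", "float64": "f8",
}
_STANDARD = {"x", "y", "z", "nx", "ny", "nz", "red", "green", "blue", "alpha", "s", "t"}


def _read_ply_vertex_properties(path: Path) -> dict[str, np.ndarray]:
    with open(path, "rb") as fh:
        if fh.readline().strip() != b"ply":
            return {}
        encoding = None
        n_vertex = 0
        props: list[tuple[str, str]] = []
        element = None
        while True:
            line = fh.readline()
            if not line:
                return {}
            tok = line.decode("ascii", "replace").split()
            if not tok:
                continue
            if tok[0] == "format":
                encoding = tok[1]
            elif tok[0] == "element":
                element = tok[1]
                if element == "vertex":
                    n_vertex = int(tok[2])
            elif tok[0] == "property" and element == "vertex":
                if tok[1] == "list":
                    return {}  # list property on vertices: bail out
                props.append((tok[2], _PLY_DTYPES[tok[1]]))
            elif tok[0] == "end_header":
                break
        extra = [name for name, _ in props if name not in _STANDARD]
        if not extra:
            return {}
        if encoding == "ascii":
            rows = [fh.readline().split() for _ in range(n_vertex)]
            arr = np.array(rows, dtype=np.float64)
            return {name: arr[:, i] for i, (name, _) in enumerate(props) if name in extra}
        endian = "<" if encoding == "binary_little_endian" else ">"
        dtype = np.dtype([(name, endian + dt) for name, dt in props])
        arr = np.frombuffer(fh.read(dtype.itemsize * n_vertex), dtype=dtype)
        return {name: np.asarray(arr[name]) for name in extra}
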