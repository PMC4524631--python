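"""Shared synthetic fixtures; everything is generated in memory per session."""

import numpy as np
import pytest

from toothwear.mesh import AXIAL, OCCLUSAL, TriangleMesh
from toothwear.synth import SyntheticToothSpec, WearFieldSpec, apply_wear, generate_tooth


@pytest.fixture(scope="session")
def tetra():
    """Regular tetrahedron with unit circumradius, outward-oriented."""
    v = np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
    ) / np.sqrt(3.0)
    f = np.array([[0, 1, 2], [0, 3, 1], [0, 2, 3], [1, 3, 2]])
    mesh = TriangleMesh(v, f)
    mesh.validate()
    return mesh


@pytest.fixture(scope="session")
def icosphere():
    import trimesh

    tm = trimesh.creation.icosphere(subdivisions=2)
    return TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


def make_grid(n=6, z=0.0, spacing=1.0):
    """Triangulated square grid in the z-plane, faces CCW from +z."""
    xs = np.arange(n) * spacing
    xx, yy = np.meshgrid(xs, xs, indexing="ij")
    v = np.column_stack([xx.ravel(), yy.ravel(), np.full(n * n, z)])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            b = a + 1
            c = a + n
            d = c + 1
            faces.append([a, d, b])
            faces.append([a, c, d])
    return TriangleMesh(v, np.array(faces))


@pytest.fixture(scope="session")
def grid():
    return make_grid()


@pytest.fixture(scope="session")
def small_tooth():
    """~700-vertex synthetic tooth, enough structure for every stage."""
    return generate_tooth(SyntheticToothSpec(resolution=500, seed=1))


@pytest.fixture(scope="session")
def small_worn_pair(small_tooth):
    """(s0, s1 retessellated, ground-truth depth) at test scale."""
    s1, truth = apply_wear(
        small_tooth, WearFieldSpec(max_depth=0.4, pattern="per-cusp", seed=1),
        retessellate=True,
    )
    return small_tooth, s1, truth


@pytest.fixture(scope="session")
def analytic_sh(small_tooth):
    """Homogeneous-surface stand-in: s0 worn in place (same connectivity)."""
    sh, truth = apply_wear(
        small_tooth, WearFieldSpec(max_depth=0.4, pattern="per-cusp", seed=1),
        retessellate=False,
    )
    return sh, truth


@pytest.fixture()
def pyramid():
    """Square base (axial, pinned) with an occlusal apex at the origin."""
    v = np.array(
        [[-1, -1, 0], [1, -1, 0], [1, 1, 0], [-1, 1, 0], [0, 0, 0]], dtype=float
    )
    f = np.array([[0, 1, 4], [1, 2, 4], [2, 3, 4], [3, 0, 4]])
    mask = np.array([AXIAL, AXIAL, AXIAL, AXIAL, OCCLUSAL])
    return TriangleMesh(v, f, region_mask=mask)
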