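"""RBF distance field, normal projection and contraction-and-bounding."""

import numpy as np
import pytest

from toothwear.homogenize import (
    ContractionParams,
    build_initial_homogeneous,
    contract_and_bound,
    evaluate_rbf,
    fit_rbf,
    project_along_normal,
)
from toothwear.features import FeaturePointSet

from .conftest import make_grid


def plane_patch(z=0.0, n=8, spacing=1.0):
    return make_grid(n=n, z=z, spacing=spacing)


class TestProjection:
    def test_point_above_plane_projects_down(self):
        patch = plane_patch(z=0.0, n=8)
        res = project_along_normal(
            np.array([[3.0, 3.0, 1.0]]), np.array([[0.0, 0.0, 1.0]]), patch
        )
        np.testing.assert_allclose(res.projected_points[0], [3.0, 3.0, 0.0], atol=1e-12)
        assert res.signed_distances[0] == pytest.approx(-1.0)
        assert res.hit_flags[0]

    def test_point_on_surface_has_zero_distance(self):
        patch = plane_patch()
        res = project_along_normal(
            np.array([[2.5, 2.5, 0.0]]), np.array([[0.0, 0.0, 1.0]]), patch
        )
        assert abs(res.signed_distances[0]) < 1e-9

    def test_ray_past_patch_boundary_falls_back_to_closest_point(self):
        patch = plane_patch(n=5)  # spans [0,4]^2
        res = project_along_normal(
            np.array([[10.0, 2.0, 0.5]]), np.array([[0.0, 0.0, 1.0]]), patch
        )
        assert not res.hit_flags[0]
        np.testing.assert_allclose(res.projected_points[0], [4.0, 2.0, 0.0], atol=1e-9)

    def test_projected_points_lie_on_target_triangles(self, small_worn_pair):
        from toothwear.mesh import vertex_normals

        s0, s1, _ = small_worn_pair
        occ = s0.occlusal_indices()
        res = project_along_normal(
            s0.vertices[occ], vertex_normals(s0)[occ], s1
        )
        from toothwear.geometry import MeshProximity

        prox = MeshProximity(s1.vertices, s1.faces)
        _, d, _ = prox.query(res.projected_points)
        assert d.max() < 1e-9

    def test_non_unit_normals_rejected(self):
        patch = plane_patch()
        with pytest.raises(ValueError, match="unit"):
            project_along_normal(
                np.array([[0.0, 0.0, 1.0]]), np.array([[0.0, 0.0, 2.0]]), patch
            )


class TestRBF:
    def test_affine_data_reproduced_by_polynomial_only(self):
        rng = np.random.default_rng(5)
        centers = rng.normal(size=(12, 3))
        d = 2.0 + 3.0 * centers[:, 0]
        field = fit_rbf(centers, d)
        np.testing.assert_allclose(field.weights, 0.0, atol=1e-8)
        np.testing.assert_allclose(field.poly, [2.0, 3.0, 0.0, 0.0], atol=1e-8)
        assert evaluate_rbf(field, np.array([1.0, 1.0, 1.0])) == pytest.approx(5.0)

    def test_zero_data_gives_zero_field(self):
        rng = np.random.default_rng(6)
        centers = rng.normal(size=(8, 3))
        field = fit_rbf(centers, np.zeros(8))
        q = rng.normal(size=(20, 3))
        np.testing.assert_allclose(evaluate_rbf(field, q), 0.0, atol=1e-9)

    def test_interpolation_exact_at_centers_and_matches_dense_oracle(self):
        rng = np.random.default_rng(7)
        centers = rng.normal(size=(10, 3))
        d = rng.normal(size=10)
        field = fit_rbf(centers, d)
        np.testing.assert_allclose(evaluate_rbf(field, centers), d, atol=1e-8)
        # independent oracle: generic lstsq on the same augmented system
        r = np.linalg.norm(centers[:, None] - centers[None], axis=2)
        a = np.block([[r**3, np.column_stack([np.ones(10), centers])],
                      [np.column_stack([np.ones(10), centers]).T, np.zeros((4, 4))]])
        sol, *_ = np.linalg.lstsq(a, np.concatenate([d, np.zeros(4)]), rcond=None)
        np.testing.assert_allclose(field.weights, sol[:10], atol=1e-7)

    def test_orthogonality_side_conditions(self):
        rng = np.random.default_rng(8)
        centers = rng.normal(size=(15, 3))
        field = fit_rbf(centers, rng.normal(size=15))
        lam = field.weights
        assert abs(lam.sum()) < 1e-8
        np.testing.assert_allclose(lam @ field.centers, 0.0, atol=1e-8)

    def test_radial_part_commutes_with_rigid_motion(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(9)
        centers = rng.normal(size=(10, 3))
        lam = rng.normal(size=10)
        lam -= lam.mean()  # irrelevant for this check
        q = rng.normal(size=3)
        r = Rotation.random(random_state=1).as_matrix()
        t = np.array([1.0, -2.0, 0.5])
        radial = lambda c, p: ((np.linalg.norm(p - c, axis=1) ** 3) * lam).sum()
        assert radial(centers, q) == pytest.approx(radial(centers @ r.T + t, r @ q + t))

    def test_duplicate_centers_named_in_error(self):
        centers = np.array([[0, 0, 0], [1, 0, 0], [1, 0, 0], [0, 1, 0.0], [0, 0, 1.0]])
        with pytest.raises(ValueError, match="duplicate"):
            fit_rbf(centers, np.arange(5.0))

    def test_too_few_centers_rejected(self):
        with pytest.raises(ValueError):
            fit_rbf(np.eye(3), np.zeros(3))


class TestInitialSurface:
    def test_identical_pair_returns_s0(self, small_tooth):
        fps_idx = np.arange(0, small_tooth.n_vertices, 29)
        fps = FeaturePointSet(fps_idx, small_tooth.vertices[fps_idx].copy())
        sh = build_initial_homogeneous(small_tooth, fps, small_tooth)
        np.testing.assert_allclose(sh.vertices, small_tooth.vertices, atol=1e-6)

    def test_constant_offset_reproduced_exactly(self):
        s0 = plane_patch(z=0.0, n=9)
        s1 = plane_patch(z=-0.5, n=11)  # larger so every ray hits
        s1.vertices[:, :2] = (s1.vertices[:, :2] - 1.0) * 1.2 + 1.0
        idx = np.array([0, 8, 72, 80, 40, 4, 36])
        fps = FeaturePointSet(idx, s0.vertices[idx].copy())
        sh = build_initial_homogeneous(s0, fps, s1)
        np.testing.assert_allclose(sh.vertices[:, 2], -0.5, atol=1e-6)

    def test_vector_field_variant_also_lands_near_the_worn_surface(self, small_worn_pair):
        """The component-wise vector-RBF initialization is a valid starting
        point: its occlusal vertices sit close to S1, like the scalar field's."""
        from toothwear.features import extract_feature_points
        from toothwear.geometry import MeshProximity

        s0, s1, _ = small_worn_pair
        fps = extract_feature_points(s0, 60)
        occ = s0.occlusal_indices()
        prox = MeshProximity(s1.vertices, s1.faces)
        for flag in (False, True):
            sh = build_initial_homogeneous(s0, fps, s1, vector_field=flag)
            np.testing.assert_array_equal(sh.faces, s0.faces)
            _, dist, _ = prox.query(sh.vertices[occ])
            assert dist.mean() < 0.05

    def test_initial_surface_keeps_connectivity_and_axial(self, small_worn_pair):
        from toothwear.features import extract_feature_points

        s0, s1, _ = small_worn_pair
        fps = extract_feature_points(s0, 60)
        sh = build_initial_homogeneous(s0, fps, s1)
        np.testing.assert_array_equal(sh.faces, s0.faces)
        ax = s0.axial_indices()
        np.testing.assert_array_equal(sh.vertices[ax], s0.vertices[ax])


class TestContraction:
    def test_single_free_vertex_moves_lambda_fraction(self, pyramid):
        target = plane_patch(z=1.0, n=5)
        target.vertices[:, :2] -= 2.0  # center the patch over the apex
        params = ContractionParams(
            contraction_factor=0.4, smoothing="none", max_iterations=1, epsilon=1e-12
        )
        out, trace = contract_and_bound(pyramid, target, params)
        assert trace[0] == pytest.approx(1.0)
        np.testing.assert_allclose(out.vertices[4], [0.0, 0.0, 0.4], atol=1e-9)
        np.testing.assert_array_equal(out.vertices[:4], pyramid.vertices[:4])

    def test_already_converged_runs_zero_iterations(self, small_worn_pair):
        s0, _, _ = small_worn_pair
        out, trace = contract_and_bound(s0, s0, ContractionParams())
        assert len(trace) == 1 and trace[0] < 0.001
        np.testing.assert_array_equal(out.vertices, s0.vertices)

    def test_converges_on_synthetic_pair_with_decreasing_error(self, converged_small):
        _, trace, _ = converged_small
        trace = np.asarray(trace)
        assert trace[-1] < 0.001
        assert (np.diff(trace) < 0).all()  # strictly decreasing E

    def test_connectivity_and_axial_positions_preserved(self, converged_small, small_worn_pair):
        s0, _, _ = small_worn_pair
        sh, _, _ = converged_small
        np.testing.assert_array_equal(sh.faces, s0.faces)
        ax = s0.axial_indices()
        np.testing.assert_array_equal(sh.vertices[ax], s0.vertices[ax])

    def test_mean_error_bound_at_convergence(self, converged_small, small_worn_pair):
        s0, _, _ = small_worn_pair
        _, trace, _ = converged_small
        m = len(s0.occlusal_indices())
        assert trace[-1] / m < 1e-5

    def test_self_intersections_not_increased(self, converged_small, small_worn_pair):
        from toothwear.geometry import count_self_intersections

        s0, s1, _ = small_worn_pair
        sh0 = converged_small[2]
        sh = converged_small[0]
        before = count_self_intersections(sh0.vertices, sh0.faces)
        after = count_self_intersections(sh.vertices, sh.faces)
        assert after <= before


@pytest.fixture(scope="module")
def converged_small(small_worn_pair):
    """(converged S_h, E trace, initial S_h) on the small synthetic pair."""
    from toothwear.features import extract_feature_points

    s0, s1, _ = small_worn_pair
    fps = extract_feature_points(s0, 60)
    sh0 = build_initial_homogeneous(s0, fps, s1)
    sh, trace = contract_and_bound(sh0, s1, ContractionParams(max_iterations=200))
    return sh, trace, sh0
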