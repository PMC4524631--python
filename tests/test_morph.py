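"""Laplacian-coordinate interpolation, reconstruction and wear maps."""

import numpy as np
import pytest

from toothwear.mesh import TriangleMesh, build_laplacian
from toothwear.morph import (
    AnchorSet,
    LaplacianCoords,
    interpolate_delta,
    laplacian_coords,
    morph_sequence,
    reconstruct,
    wear_map,
)


class TestCoords:
    def test_centroid_vertex_has_zero_delta(self, pyramid):
        # apex sits exactly at the centroid of its 1-ring (the square base)
        coords = laplacian_coords(pyramid)
        np.testing.assert_allclose(coords.deltas[4], 0.0, atol=1e-12)
        assert not coords.defined[4]

    def test_translation_invariance(self, small_tooth):
        a = laplacian_coords(small_tooth)
        shifted = TriangleMesh(small_tooth.vertices + [5.0, 6.0, -7.0],
                               small_tooth.faces.copy())
        b = laplacian_coords(shifted)
        np.testing.assert_allclose(a.deltas, b.deltas, atol=1e-9)

    def test_matches_brute_force(self, tetra):
        coords = laplacian_coords(tetra)
        for i in range(4):
            others = [j for j in range(4) if j != i]
            expected = tetra.vertices[i] - tetra.vertices[others].mean(0)
            np.testing.assert_allclose(coords.deltas[i], expected, atol=1e-12)


class TestInterpolation:
    @staticmethod
    def _coords(arrs):
        return LaplacianCoords.from_deltas(np.asarray(arrs, dtype=float))

    def test_endpoints_are_exact(self, small_tooth, analytic_sh):
        sh, _ = analytic_sh
        lap = build_laplacian(small_tooth)
        d_s = laplacian_coords(small_tooth, lap)
        d_t = LaplacianCoords.from_deltas(lap.apply(sh.vertices))
        np.testing.assert_allclose(
            interpolate_delta(d_s, d_t, 0.0).deltas, d_s.deltas, atol=1e-12
        )
        np.testing.assert_allclose(
            interpolate_delta(d_s, d_t, 1.0).deltas, d_t.deltas, atol=1e-12
        )

    def test_hand_worked_half_step(self):
        d_s = self._coords([[2.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        d_t = self._coords([[0, 4.0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        out = interpolate_delta(d_s, d_t, 0.5)
        # direction (0.5, 0.5, 0), magnitude (1-u)*2 + u*4 = 3 -> (1.5, 1.5, 0)
        np.testing.assert_allclose(out.deltas[0], [1.5, 1.5, 0.0], atol=1e-12)

    def test_magnitude_linearity_to_machine_precision(self, small_tooth, analytic_sh):
        sh, _ = analytic_sh
        lap = build_laplacian(small_tooth)
        d_s = laplacian_coords(small_tooth, lap)
        d_t = LaplacianCoords.from_deltas(lap.apply(sh.vertices))
        for u in (0.25, 0.5, 0.9):
            out = interpolate_delta(d_s, d_t, u)
            both = d_s.defined & d_t.defined
            expected = (1 - u) * d_s.magnitudes + u * d_t.magnitudes
            # |delta_M| = |mag * dir| where dir is the (unnormalized) blend;
            # the magnitude written into the blend is exactly the linear one
            blend = (1 - u) * d_s.directions[both] + u * d_t.directions[both]
            np.testing.assert_allclose(
                np.linalg.norm(out.deltas[both], axis=1),
                expected[both] * np.linalg.norm(blend, axis=1),
                rtol=1e-12,
            )

    def test_zero_magnitude_degrades_to_linear(self):
        d_s = self._coords([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        d_t = self._coords([[2.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        out = interpolate_delta(d_s, d_t, 0.5)
        np.testing.assert_allclose(out.deltas[0], [1.0, 0, 0], atol=1e-12)

    def test_connectivity_mismatch_rejected(self):
        d4 = self._coords(np.eye(4, 3))
        d5 = self._coords(np.eye(5, 3))
        with pytest.raises(ValueError, match="mismatch"):
            interpolate_delta(d4, d5, 0.5)


class TestReconstruct:
    def test_identity_with_axial_anchors(self, small_tooth):
        lap = build_laplacian(small_tooth)
        coords = laplacian_coords(small_tooth, lap)
        ax = small_tooth.axial_indices()
        anchors = AnchorSet(ax, small_tooth.vertices[ax])
        rec = reconstruct(coords, lap, anchors, small_tooth.faces)
        tol = 1e-6 * small_tooth.bbox_diagonal()
        assert np.abs(rec.vertices - small_tooth.vertices).max() < tol

    def test_translated_anchors_translate_everything(self, small_tooth):
        lap = build_laplacian(small_tooth)
        coords = laplacian_coords(small_tooth, lap)
        ax = small_tooth.axial_indices()
        shift = np.array([1.0, 2.0, 3.0])
        rec = reconstruct(coords, lap, AnchorSet(ax, small_tooth.vertices[ax] + shift),
                          small_tooth.faces)
        np.testing.assert_allclose(
            rec.vertices, small_tooth.vertices + shift,
            atol=1e-6 * small_tooth.bbox_diagonal(),
        )

    def test_tetrahedron_matches_dense_solve(self, tetra):
        lap = build_laplacian(tetra)
        coords = laplacian_coords(tetra, lap)
        anchors = AnchorSet(np.array([0]), tetra.vertices[[0]], weight=1.0)
        rec = reconstruct(coords, lap, anchors, tetra.faces)
        dense = np.vstack([lap.matrix.toarray(), np.eye(4)[[0]]])
        rhs = np.vstack([coords.deltas, tetra.vertices[[0]]])
        oracle, *_ = np.linalg.lstsq(dense, rhs, rcond=None)
        np.testing.assert_allclose(rec.vertices, oracle, atol=1e-9)

    def test_empty_anchor_set_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            AnchorSet(np.array([], dtype=int), np.empty((0, 3)))


class TestMorphSequence:
    def test_endpoint_frames_reproduce_inputs(self, small_tooth, analytic_sh):
        sh, _ = analytic_sh
        frames = morph_sequence(small_tooth, sh, [0.0, 1.0])
        tol = 1e-6 * small_tooth.bbox_diagonal()
        assert np.abs(frames[0].mesh.vertices - small_tooth.vertices).max() < tol
        assert np.abs(frames[1].mesh.vertices - sh.vertices).max() < tol

    def test_degenerate_morph_keeps_s0(self, small_tooth):
        frames = morph_sequence(small_tooth, small_tooth.copy(), [0.0, 0.5, 1.0])
        tol = 1e-6 * small_tooth.bbox_diagonal()
        for fr in frames:
            assert np.abs(fr.mesh.vertices - small_tooth.vertices).max() < tol
            assert fr.wear_depth.max() < tol

    def test_axial_region_is_stationary(self, small_tooth, analytic_sh):
        sh, _ = analytic_sh
        ax = small_tooth.axial_indices()
        for fr in morph_sequence(small_tooth, sh, [0.0, 0.3, 0.7, 1.0]):
            assert np.abs(fr.mesh.vertices[ax] - small_tooth.vertices[ax]).max() < 1e-9

    def test_wear_depth_monotone_in_u(self, small_tooth, analytic_sh):
        sh, _ = analytic_sh
        frames = morph_sequence(small_tooth, sh, [0.2, 0.4, 0.6, 0.8, 1.0])
        depths = np.stack([fr.wear_depth for fr in frames])
        worn = depths[-1] > 1e-3  # vertices that actually wear
        assert (np.diff(depths[:, worn], axis=0) > -1e-9).all()

    def test_frame_continuity_under_grid_refinement(self, small_tooth, analytic_sh):
        sh, _ = analytic_sh

        def max_step(n):
            frames = morph_sequence(small_tooth, sh, np.linspace(0, 1, n))
            return max(
                np.abs(b.mesh.vertices - a.mesh.vertices).max()
                for a, b in zip(frames, frames[1:])
            )

        coarse, fine = max_step(4), max_step(7)
        assert fine < coarse

    def test_unsorted_u_rejected(self, small_tooth):
        with pytest.raises(ValueError, match="sorted"):
            morph_sequence(small_tooth, small_tooth.copy(), [0.5, 0.2])


class TestWearMap:
    def test_identical_meshes_have_zero_depth(self, small_tooth):
        depth, rgba = wear_map(small_tooth, small_tooth)
        assert depth.max() == 0.0
        assert (rgba[:, :3] == rgba[0, :3]).all()

    def test_single_displaced_vertex(self, small_tooth):
        moved = small_tooth.copy()
        moved.vertices[10] += [0.0, 0.0, -0.3]
        depth, rgba = wear_map(small_tooth, moved)
        assert depth.argmax() == 10
        assert depth[10] == pytest.approx(0.3)
        assert tuple(rgba[10, :3]) == (255, 0, 0)
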