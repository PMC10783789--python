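"""Embedding, trajectory statistics, templates, and Procrustes alignment."""

import numpy as np
import pytest
from scipy.linalg import orthogonal_procrustes
from scipy.stats import kstest, special_ortho_group

from copingmanifold.manifold import (AlignmentResult, apply_alignment,
                                     build_template, center_scale_manifold,
                                     circular_pairing, embed, epoch_digits,
                                     flow_field, haar_rotations, procrustes_align,
                                     select_plane, turn_angles)
from copingmanifold.session import IMMOBILITY, STRUGGLE


def _ring(n=800, noise=0.0, rng=None, clockwise=False, revolutions=1):
    t = np.linspace(0, revolutions * 2 * np.pi, n, endpoint=False)
    if clockwise:
        t = -t
    xy = np.column_stack([np.cos(t), np.sin(t)])
    if noise and rng is not None:
        xy += noise * rng.standard_normal(xy.shape)
    return xy


class TestEmbed:
    def test_pca_recovers_planted_linear_subspace(self, rng):
        latent = rng.standard_normal((500, 2))
        basis = np.linalg.qr(rng.standard_normal((20, 2)))[0]
        X = latent @ basis.T            # frames x neurons, rank 2
        X -= X.mean(axis=0)
        emb = embed(X.T, method="pca", d=5)
        recon_err = np.linalg.norm(
            emb.coords[:, :2] @ np.linalg.pinv(emb.coords[:, :2]) @ X - X)
        assert recon_err < 1e-8
        assert np.abs(emb.coords[:, 2:]).max() < 1e-8

    def test_isomap_deterministic(self, rng):
        X = rng.random((40, 700))
        a = embed(X, method="isomap", d=3, n_neighbors=50)
        b = embed(X, method="isomap", d=3, n_neighbors=50)
        np.testing.assert_allclose(a.coords, b.coords, atol=1e-10)

    def test_too_few_frames_for_isomap_rejected(self, rng):
        with pytest.raises(ValueError):
            embed(rng.random((10, 100)), method="isomap", n_neighbors=500)


class TestPlaneSelection:
    def test_planted_ring_found_in_higher_axes(self, rng):
        """Ring planted in axes (1, 3) of 5 is selected over noise pairs."""
        n = 1600
        coords = 0.02 * rng.standard_normal((n, 5))
        ring = _ring(n, revolutions=6)
        coords[:, 1] += ring[:, 0]
        coords[:, 3] += ring[:, 1]
        assert select_plane(coords) == (1, 3)

    def test_planted_pair_criterion_dominates(self, rng):
        from copingmanifold.manifold import plane_rotation_criterion
        n = 1600
        coords = 0.02 * rng.standard_normal((n, 4))
        coords[:, [0, 2]] += _ring(n, revolutions=6)
        planted = plane_rotation_criterion(coords[:, [0, 2]])
        for pair in [(0, 1), (0, 3), (1, 2), (1, 3), (2, 3)]:
            assert planted >= 2 * plane_rotation_criterion(coords[:, list(pair)])

    def test_degenerate_trajectory_tie_breaks_to_first_axes(self):
        line = np.column_stack([np.arange(100.0)] * 4)  # no rotation anywhere
        assert select_plane(line) == (0, 1)


class TestFlowField:
    def test_uniform_motion_gives_constant_vectors(self):
        step = np.array([0.3, -0.2])
        plane = np.arange(200)[:, None] * step[None, :]
        ff = flow_field(plane, bins=5)
        occupied = ff.occupancy > 0
        for v in ff.mean_velocity[occupied]:
            np.testing.assert_allclose(v, step, atol=1e-12)

    def test_circle_vectors_tangent(self):
        ff = flow_field(_ring(800), bins=15)
        occ = ff.occupancy > 0
        v = ff.mean_velocity[occ]
        p = ff.mean_position[occ]
        dots = np.abs((v * p).sum(axis=1))
        mags = np.linalg.norm(v, axis=1) * np.linalg.norm(p, axis=1)
        assert np.all(dots / mags < 1e-6)

    def test_occupancy_conserved(self, rng):
        plane = rng.standard_normal((321, 2))
        ff = flow_field(plane)
        assert ff.occupancy.sum() == 320


class TestTurnAngles:
    def test_counterclockwise_circle_fully_leftward(self):
        _, leftward, _ = turn_angles(_ring(800), n_bins=800)
        assert leftward == 1.0

    def test_clockwise_circle_never_leftward(self):
        _, leftward, _ = turn_angles(_ring(800, clockwise=True), n_bins=800)
        assert leftward == 0.0

    def test_straight_line_has_zero_turns(self):
        line = np.column_stack([np.arange(100.0), 2 * np.arange(100.0)])
        angles, leftward, _ = turn_angles(line, n_bins=50)
        np.testing.assert_allclose(np.minimum(angles, 2 * np.pi - angles), 0,
                                   atol=1e-9)
        assert leftward == 0.0

    def test_direction_statistic_rotation_invariant_reflection_flips(self, rng):
        ring = _ring(800, noise=0.02, rng=rng)
        _, leftward, _ = turn_angles(ring, n_bins=200)
        theta = 1.1
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        _, rotated, _ = turn_angles(ring @ R, n_bins=200)
        _, reflected, _ = turn_angles(ring * [1, -1], n_bins=200)
        assert rotated == pytest.approx(leftward)
        assert reflected == pytest.approx(1 - leftward, abs=1e-12)


class TestCenterScale:
    def test_centered_and_unit_norm(self, rng):
        out = center_scale_manifold(rng.standard_normal((50, 5)) + 3)
        np.testing.assert_allclose(out.mean(axis=0), 0, atol=1e-10)
        assert np.linalg.norm(out) == pytest.approx(1.0, abs=1e-10)

    def test_idempotent(self, rng):
        x = rng.standard_normal((30, 3))
        once = center_scale_manifold(x)
        np.testing.assert_allclose(center_scale_manifold(once), once, atol=1e-12)

    def test_degenerate_cluster_rejected(self):
        with pytest.raises(ValueError):
            center_scale_manifold(np.tile([3.0, 4.0], (10, 1)))


class TestTemplate:
    def test_default_shape_five_by_forty(self, rng):
        coping = np.int8([STRUGGLE] * 60 + [IMMOBILITY] * 40 +
                         [STRUGGLE] * 30 + [IMMOBILITY] * 50)
        coords = rng.standard_normal((180, 5))
        tpl = build_template(coords, coping)
        assert tpl.matrix.shape == (5, 40)

    def test_two_ramp_epochs_average_per_digit(self):
        """Epochs 0..19 and 20..39 over 20 frames: digit k -> mean k + 9."""
        coping = np.int8([STRUGGLE] * 20 + [IMMOBILITY] * 20 +
                         [STRUGGLE] * 20 + [IMMOBILITY] * 20)
        coords = np.r_[np.arange(0., 20), np.zeros(20),
                       np.arange(20., 40), np.zeros(20)][:, None]
        coords = np.column_stack([coords, np.zeros(80)])  # d = 2
        tpl = build_template(coords, coping, n_digits=20)
        np.testing.assert_allclose(tpl.matrix[0, :20], np.arange(20) + 10)

    def test_constant_epoch_gives_constant_row(self):
        coping = np.int8([STRUGGLE] * 30 + [IMMOBILITY] * 30)
        coords = np.column_stack([np.full(60, 2.5), np.r_[np.zeros(30), np.ones(30)]])
        tpl = build_template(coords, coping, n_digits=10)
        np.testing.assert_allclose(tpl.matrix[0], 2.5)

    def test_missing_coping_class_rejected(self, rng):
        coping = np.int8([STRUGGLE] * 50)
        with pytest.raises(ValueError, match="immobility"):
            build_template(rng.standard_normal((50, 3)), coping)

    def test_short_epochs_reuse_digits(self):
        frames, digits = epoch_digits(np.int8([STRUGGLE] * 5), STRUGGLE, 20)
        assert len(frames) == 5
        assert digits[0] == 1 and digits[-1] == 20


class TestProcrustes:
    def test_identity_when_already_aligned(self, rng):
        A = rng.standard_normal((40, 5))
        res = procrustes_align(A, A)
        np.testing.assert_allclose(res.Q, np.eye(5), atol=1e-10)
        assert res.residual < 1e-10

    def test_exact_rotation_recovery(self, rng):
        A = rng.standard_normal((40, 5))
        R = special_ortho_group.rvs(5, random_state=rng)
        res = procrustes_align(A, A @ R)
        assert np.linalg.norm(A @ res.Q - A @ R) < 1e-8
        assert np.max(np.abs(res.Q - R)) < 1e-6

    def test_matches_scipy_reference(self, rng):
        A, B = rng.standard_normal((40, 5)), rng.standard_normal((40, 5))
        res = procrustes_align(A, B)
        Q_ref, _ = orthogonal_procrustes(A, B)
        np.testing.assert_allclose(res.Q, Q_ref, atol=1e-10)

    def test_two_dim_angle_grid_brute_force(self, rng):
        """Closed form matches the best over a fine rotation/reflection grid."""
        A, B = rng.standard_normal((40, 2)), rng.standard_normal((40, 2))
        res = procrustes_align(A, B)
        angles = np.arange(0, 2 * np.pi, 1e-4)
        c, s = np.cos(angles), np.sin(angles)
        rots = np.stack([np.stack([c, -s], -1), np.stack([s, c], -1)], 1)
        refls = rots.copy()
        refls[:, :, 1] *= -1
        best = np.inf
        for mats in (rots, refls):
            r = np.linalg.norm(np.einsum("ij,njk->nik", A, mats) - B, axis=(1, 2))
            best = min(best, r.min())
        assert res.residual <= best + 1e-6

    def test_never_worse_than_identity(self, rng):
        A, B = rng.standard_normal((40, 5)), rng.standard_normal((40, 5))
        res = procrustes_align(A, B)
        assert res.residual <= res.identity_residual

    def test_rank_deficiency_flagged(self):
        A = np.zeros((40, 3))
        A[:, 0] = np.arange(40.0)
        res = procrustes_align(A, A)
        assert res.degenerate

    def test_result_validates_orthogonality(self):
        with pytest.raises(ValueError):
            AlignmentResult(Q=np.array([[1.0, 0.5], [0.0, 1.0]]),
                            residual=0.0, identity_residual=0.0)


class TestApplyAlignment:
    def test_identity_leaves_manifold_unchanged(self, rng):
        M = rng.standard_normal((100, 4))
        np.testing.assert_array_equal(apply_alignment(M, np.eye(4)), M)

    def test_pairwise_distances_preserved(self, rng):
        from scipy.spatial.distance import pdist
        M = rng.standard_normal((60, 5))
        Q = special_ortho_group.rvs(5, random_state=rng)
        np.testing.assert_allclose(pdist(apply_alignment(M, Q)), pdist(M),
                                   atol=1e-10)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            apply_alignment(rng.standard_normal((10, 3)), np.eye(4))


class TestRotationNull:
    def test_matrices_are_special_orthogonal(self, rng):
        mats = haar_rotations(5, 50, rng)
        for Q in mats:
            np.testing.assert_allclose(Q.T @ Q, np.eye(5), atol=1e-10)
            assert np.linalg.det(Q) == pytest.approx(1.0, abs=1e-10)

    def test_two_dim_angles_uniform(self, rng):
        mats = haar_rotations(2, 10000, rng)
        angles = np.arctan2(mats[:, 1, 0], mats[:, 0, 0])
        stat = kstest((angles + np.pi) / (2 * np.pi), "uniform")
        assert stat.pvalue > 0.01


class TestCircularPairing:
    def test_three_animals(self):
        assert circular_pairing(["a", "b", "c"]) == [("c", "a"), ("a", "b"),
                                                     ("b", "c")]

    def test_two_animals(self):
        assert circular_pairing(["a", "b"]) == [("b", "a"), ("a", "b")]

    def test_six_animals_give_six_pairs(self):
        assert len(circular_pairing(list("abcdef"))) == 6

    def test_single_animal_rejected(self):
        with pytest.raises(ValueError):
            circular_pairing(["a"])
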