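"""Spatially penalized FCM: neighbor prior, penalized updates, segmentation."""

import numpy as np
import pytest

from gapfcm.fcm import run_fcm, update_memberships_fcm
from gapfcm.phantoms import halves_phantom, misclassification_rate
from gapfcm.spatial import (
    neighbor_prior,
    pfcm_objective,
    run_pfcm,
    update_memberships_pfcm,
)

from _oracles import (
    naive_neighbor_prior,
    naive_pfcm_objective,
    random_membership,
)


class TestNeighborPrior:
    def test_constant_field_is_preserved(self):
        u = np.tile(np.array([[0.3], [0.7]]), (1, 12))
        P = neighbor_prior(u, 3, 4, connectivity=8)
        np.testing.assert_allclose(P[0], 0.3, atol=1e-12)
        np.testing.assert_allclose(P[1], 0.7, atol=1e-12)

    def test_interior_pixel_of_crisp_half_sees_own_class(self):
        H, W = 6, 8
        labels = (np.arange(W) >= W // 2)[None, :].repeat(H, axis=0)
        u = np.stack([(~labels).ravel(), labels.ravel()]).astype(float)
        P = neighbor_prior(u, H, W, connectivity=4)
        # pixel one column inside the left half, away from the midline
        k = 2 * W + 1
        np.testing.assert_allclose(P[:, k], [1.0, 0.0], atol=1e-12)

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_naive_neighbor_loop(self, rng, connectivity):
        u = random_membership(rng, 3, 9)
        P = neighbor_prior(u, 3, 3, connectivity=connectivity)
        np.testing.assert_allclose(
            P, naive_neighbor_prior(u, 3, 3, connectivity), atol=1e-12
        )

    def test_columns_sum_to_one(self, rng):
        u = random_membership(rng, 4, 5 * 7)
        P = neighbor_prior(u, 5, 7)
        np.testing.assert_allclose(P.sum(axis=0), 1.0, atol=1e-9)

    def test_geometry_mismatch_raises(self):
        with pytest.raises(ValueError, match="pixels"):
            neighbor_prior(np.ones((2, 10)) / 2, 3, 4)


class TestPfcmObjective:
    def test_sigma_zero_reduces_to_fcm(self, rng):
        from gapfcm.fcm import fcm_objective

        d2 = rng.random((2, 9))
        u = random_membership(rng, 2, 9)
        P = random_membership(rng, 2, 9)
        assert pfcm_objective(d2, u, P, 2.0, 0.0) == fcm_objective(d2, u, 2.0)

    def test_uniform_crisp_labeling_on_centers_is_zero(self):
        # all pixels of one class sitting exactly on its center: d2 = 0
        # where u = 1, and P = 1 there, so both terms vanish
        d2 = np.array([[0.0] * 9, [4.0] * 9])
        u = np.array([[1.0] * 9, [0.0] * 9])
        P = neighbor_prior(u, 3, 3)
        assert pfcm_objective(d2, u, P, 2.0, 1.0) == 0.0

    def test_matches_naive_oracle(self, rng):
        d2 = rng.random((3, 12))
        u = random_membership(rng, 3, 12)
        P = random_membership(rng, 3, 12)
        np.testing.assert_allclose(
            pfcm_objective(d2, u, P, 2.0, 1.7),
            naive_pfcm_objective(d2, u, P, 2.0, 1.7),
            atol=1e-12,
        )


class TestPfcmMembershipUpdate:
    def test_sigma_zero_equals_fcm_update(self, rng):
        d2 = rng.random((3, 10))
        P = random_membership(rng, 3, 10)
        np.testing.assert_array_equal(
            update_memberships_pfcm(d2, P, 2.0, 0.0),
            update_memberships_fcm(d2, 2.0),
        )

    def test_symmetric_point_splits_evenly(self):
        u = update_memberships_pfcm(
            np.array([[1.0], [1.0]]), np.array([[0.4], [0.4]]), 2.0, 1.0
        )
        np.testing.assert_allclose(u.ravel(), [0.5, 0.5])

    def test_hand_example_and_improvement(self):
        # w=2, d2=(1,1), sigma=1, P=(1,0): g=(1,2) so u=(2/3,1/3)
        d2 = np.array([[1.0], [1.0]])
        P = np.array([[1.0], [0.0]])
        u = update_memberships_pfcm(d2, P, 2.0, 1.0)
        np.testing.assert_allclose(u.ravel(), [2 / 3, 1 / 3])
        uniform = np.array([[0.5], [0.5]])
        assert pfcm_objective(d2, u, P, 2.0, 1.0) < pfcm_objective(
            d2, uniform, P, 2.0, 1.0
        )

    def test_update_minimizes_objective_among_random_rivals(self, rng):
        d2 = rng.random((3, 8))
        P = random_membership(rng, 3, 8)
        u = update_memberships_pfcm(d2, P, 2.0, 1.5)
        best = pfcm_objective(d2, u, P, 2.0, 1.5)
        for _ in range(20):
            rival = random_membership(rng, 3, 8)
            assert best <= pfcm_objective(d2, rival, P, 2.0, 1.5) + 1e-12


class TestRunPfcm:
    def test_noiseless_two_region_phantom_is_perfect(self):
        # center tolerance needs a boundary fraction small enough that the
        # spatial penalty's boundary-pixel pull stays below 1e-3
        ph = halves_phantom(32, 32, noise_sd=0.0)
        res = run_pfcm(ph.image, 2, sigma=1.0, seed=0)
        assert misclassification_rate(res.labels, ph.truth) == 0.0
        got = np.sort(res.centers.ravel())
        np.testing.assert_allclose(got, [0.2, 0.8], atol=1e-3)

    def test_sigma_zero_is_bit_identical_to_fcm(self):
        ph = halves_phantom(16, 16, noise_sd=0.08, seed=9)
        init = np.array([[0.3], [0.6]])
        res_p = run_pfcm(ph.image, 2, sigma=0.0, init_centers=init)
        res_f = run_fcm(ph.image.reshape(-1, 1), 2, init_centers=init)
        np.testing.assert_array_equal(res_p.centers, res_f.centers)
        np.testing.assert_array_equal(res_p.memberships, res_f.memberships)
        assert res_p.objective_trace == res_f.objective_trace

    def test_objective_trace_non_increasing(self):
        ph = halves_phantom(20, 20, noise_sd=0.1, seed=4)
        res = run_pfcm(ph.image, 2, sigma=1.0, seed=4)
        assert np.all(np.diff(res.objective_trace) <= 1e-8)

    def test_spatial_penalty_reduces_outlier_errors(self):
        # aggregate over seeds: sigma>0 never does worse than sigma=0
        # on phantoms with impulsive outliers, same init
        errs0, errs2 = 0.0, 0.0
        init = np.array([[0.35], [0.65]])
        for seed in range(10):
            ph = halves_phantom(24, 24, noise_sd=0.05, outlier_frac=0.05, seed=seed)
            r0 = run_pfcm(ph.image, 2, sigma=0.0, init_centers=init)
            r2 = run_pfcm(ph.image, 2, sigma=2.0, init_centers=init)
            errs0 += misclassification_rate(r0.labels, ph.truth)
            errs2 += misclassification_rate(r2.labels, ph.truth)
        assert errs2 <= errs0

    def test_membership_columns_sum_to_one(self):
        ph = halves_phantom(12, 12, noise_sd=0.1, seed=2)
        res = run_pfcm(ph.image, 2, sigma=1.0, seed=2)
        np.testing.assert_allclose(res.memberships.sum(axis=0), 1.0, atol=1e-9)

    def test_penalty_exponent_one_mode_runs(self):
        ph = halves_phantom(12, 12, noise_sd=0.05, seed=3)
        res = run_pfcm(ph.image, 2, sigma=1.0, penalty_exponent=1.0, seed=3)
        assert misclassification_rate(res.labels, ph.truth) < 0.1
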