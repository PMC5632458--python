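"""Patch sampling, features, fuzzy c-means and seeded cluster selection."""

import numpy as np
import pytest

from epifat.clustering import (
    FuzzyClustering,
    PatchSet,
    fuzzy_c_means,
    patch_features,
    pixelwise_membership,
    pondered_cluster_means,
    sample_patches,
    select_cluster,
    standardize_features,
)
from epifat.errors import InsufficientDataError, NoPatchesError


class TestSamplePatches:
    def test_full_roi_count(self):
        """A 9x9 image with full ROI, R=3, stride=1 hosts a 7x7 grid of
        valid centers."""
        img = np.arange(81, dtype=float).reshape(9, 9)
        ps = sample_patches(img, np.ones((9, 9)), R=3, stride=1)
        assert len(ps) == 49

    def test_single_pixel_roi(self):
        roi = np.zeros((5, 5))
        roi[2, 2] = 1
        ps = sample_patches(np.ones((5, 5)), roi, R=3, stride=1)
        assert len(ps) == 1 and tuple(ps.centers[0]) == (2, 2)

    def test_roi_pixel_off_grid_raises(self):
        roi = np.zeros((5, 5))
        roi[0, 0] = 1  # window cannot fit around a border pixel
        with pytest.raises(NoPatchesError):
            sample_patches(np.ones((5, 5)), roi, R=3, stride=1)

    def test_matches_exhaustive_enumeration(self):
        """Center set equals brute-force enumeration of stride-grid points
        passing the window-fits and center-in-ROI tests."""
        rng = np.random.default_rng(0)
        img = rng.uniform(size=(40, 37))
        roi = rng.uniform(size=(40, 37)) > 0.4
        R, stride, h = 5, 2, 2
        ps = sample_patches(img, roi, R=R, stride=stride)
        expected = sorted(
            (i, j)
            for i in range(h, 40 - h, stride)
            for j in range(h, 37 - h, stride)
            if roi[i, j]
        )
        assert sorted(map(tuple, ps.centers)) == expected
        # features match a per-window two-pass computation
        for (i, j), (u1, u2) in zip(ps.centers, ps.features):
            win = img[i - h : i + h + 1, j - h : j + h + 1]
            m = win.sum() / R**2
            v = ((win - m) ** 2).sum() / R**2
            assert abs(u1 - m) < 1e-12 and abs(u2 - v) < 1e-12


class TestPatchFeatures:
    @pytest.mark.parametrize(
        "window,expected",
        [
            (np.full((3, 3), 4.2), (4.2, 0.0)),
            (np.array([[0.0, 0.0], [1.0, 1.0]]), (0.5, 0.25)),
        ],
    )
    def test_closed_forms(self, window, expected):
        u1, u2 = patch_features(window)
        assert u1 == pytest.approx(expected[0])
        assert u2 == pytest.approx(expected[1])

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(1)
        win = rng.uniform(size=(5, 5))
        u1, u2 = patch_features(win)
        mean = sum(win.ravel()) / 25
        var = sum((x - mean) ** 2 for x in win.ravel()) / 25
        assert u1 == pytest.approx(mean, abs=1e-12)
        assert u2 == pytest.approx(var, abs=1e-12)


def _naive_fcm(X, C, m, tol, max_iter, seed):
    """Independent loop-based FCM oracle sharing only the initialization
    convention (centers drawn from the data with a seeded generator)."""
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(X), size=C, replace=False)
    centers = X[idx].copy()
    scale = X.std(axis=0)
    centers += 1e-9 * np.maximum(scale, 1e-12) * rng.standard_normal(centers.shape)
    Q = len(X)
    mu = np.zeros((Q, C))
    for _ in range(max_iter):
        for k in range(Q):
            d2 = [float(((X[k] - centers[c]) ** 2).sum()) for c in range(C)]
            if min(d2) <= 1e-300:
                for c in range(C):
                    mu[k, c] = 1.0 if d2[c] <= 1e-300 else 0.0
                mu[k] /= mu[k].sum()
            else:
                for c in range(C):
                    mu[k, c] = 1.0 / sum((d2[c] / d2[l]) ** (1 / (m - 1)) for l in range(C))
        new_centers = np.zeros_like(centers)
        for c in range(C):
            w = mu[:, c] ** m
            new_centers[c] = (w[:, None] * X).sum(axis=0) / w.sum()
        if np.abs(new_centers - centers).max() < tol:
            centers = new_centers
            break
        centers = new_centers
    return mu, centers


class TestFuzzyCMeans:
    def test_two_blob_separation_and_oracle_agreement(self):
        rng = np.random.default_rng(2)
        X = np.concatenate(
            [rng.normal(0, 0.05, (100, 2)), rng.normal(3, 0.05, (100, 2))]
        )
        fcm = fuzzy_c_means(X, C=2, seed=7)
        assert fcm.converged
        assert np.all(fcm.memberships.max(axis=1) >= 0.99)
        mu_ref, cen_ref = _naive_fcm(X, 2, 2.0, 1e-5, 300, 7)
        np.testing.assert_allclose(fcm.memberships, mu_ref, atol=1e-6)
        np.testing.assert_allclose(fcm.centers, cen_ref, atol=1e-6)

    def test_membership_normalization_every_iteration(self):
        rng = np.random.default_rng(3)
        fcm = fuzzy_c_means(rng.uniform(size=(200, 2)), C=4, seed=0)
        assert fcm.max_sum_error_history.max() <= 1e-9

    def test_objective_monotone_nonincreasing(self):
        rng = np.random.default_rng(4)
        fcm = fuzzy_c_means(rng.uniform(size=(300, 2)), C=3, seed=1)
        assert np.all(np.diff(fcm.objective_history) <= 1e-9)

    def test_bit_reproducible_with_fixed_seed(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(size=(150, 2))
        a = fuzzy_c_means(X, C=3, seed=42)
        b = fuzzy_c_means(X, C=3, seed=42)
        assert np.array_equal(a.memberships, b.memberships)
        assert np.array_equal(a.centers, b.centers)

    def test_point_on_center_gets_full_membership(self):
        """Zero-distance limit: a feature point coincident with a cluster
        center has membership 1 there, 0 elsewhere."""
        X = np.array([[0.0, 0.0]] * 50 + [[5.0, 5.0]] * 50)
        fcm = fuzzy_c_means(X, C=2, seed=0, tol=1e-12)
        k = 0  # lies exactly on its converged center
        assert fcm.memberships[k].max() == pytest.approx(1.0, abs=1e-9)

    def test_too_few_points_raises(self):
        with pytest.raises(InsufficientDataError):
            fuzzy_c_means(np.zeros((2, 2)), C=3)


def _clustering_with(memberships):
    mu = np.asarray(memberships, dtype=float)
    return FuzzyClustering(
        memberships=mu,
        centers=np.zeros((mu.shape[1], 2)),
        fuzzifier=2.0,
        objective_history=np.array([]),
        max_sum_error_history=np.array([]),
        n_iter=0,
        converged=True,
    )


class TestSelectCluster:
    def test_exact_match_zero_distance(self):
        features = np.array([[0.0, 0.0], [2.0, 2.0]])
        fcm = _clustering_with([[1, 0], [0, 1]])
        # printed normalization: u_hat = ((0,0)/2, (1,1))
        assert select_cluster(fcm, features, np.array([1.0, 1.0]), mode="as_printed") == 1

    def test_nearer_cluster_wins(self):
        features = np.array([[0.0, 0.0], [2.0, 2.0]])
        fcm = _clustering_with([[1, 0], [0, 1]])
        # pondered means (0,0) and (1,1); u* = (0.1, 0.1) is nearer to 0
        assert select_cluster(fcm, features, np.array([0.1, 0.1]), mode="as_printed") == 0

    def test_tie_breaks_to_lowest_index(self):
        features = np.array([[1.0, 0.0], [-1.0, 0.0]])
        fcm = _clustering_with([[1, 0], [0, 1]])
        assert select_cluster(fcm, features, np.array([0.0, 0.0]), mode="normalized") == 0

    def test_pondered_mean_modes(self):
        features = np.array([[2.0, 0.0], [4.0, 0.0], [0.0, 0.0]])
        fcm = _clustering_with([[0.5, 0.5], [0.5, 0.5], [0.0, 1.0]])
        printed = pondered_cluster_means(fcm, features, "as_printed")
        normalized = pondered_cluster_means(fcm, features, "normalized")
        np.testing.assert_allclose(printed[0], [1.0, 0.0])  # (0.5*2+0.5*4)/3
        np.testing.assert_allclose(normalized[0], [3.0, 0.0])  # /1.0

    def test_relabel_invariance(self, stage0):
        """Permuting cluster labels selects the same cluster's memberships."""
        fcm, z, u_star = stage0["fcm"], stage0["z"], stage0["u_star"]
        c0 = select_cluster(fcm, z, u_star, mode="normalized")
        perm = np.array([2, 0, 4, 1, 3])
        permuted = _clustering_with(fcm.memberships[:, perm])
        c1 = select_cluster(permuted, z, u_star, mode="normalized")
        np.testing.assert_array_equal(
            fcm.memberships[:, c0], permuted.memberships[:, c1]
        )

    def test_phantom_selected_cluster_best_overlaps_fat(self, stage0):
        """The seeded selection picks the cluster whose pixel support
        overlaps the ground-truth fat at least as well as any other."""
        from epifat.clustering import pixelwise_membership

        fat = stage0["fat"] > 0
        patches, fcm, roi = stage0["patches"], stage0["fcm"], stage0["roi"]
        overlaps = []
        for c in range(fcm.n_clusters):
            f = pixelwise_membership(fcm.memberships[:, c], patches, fat.shape) * roi
            overlaps.append((f >= 0.5)[fat].sum())
        assert overlaps[stage0["c_res"]] == max(overlaps)


class TestPixelwiseMembership:
    def _patchset(self, centers, R):
        n = len(centers)
        return PatchSet(
            centers=np.asarray(centers), features=np.zeros((n, 2)), patch_size=R
        )

    def test_single_cover(self):
        ps = self._patchset([(2, 2)], 3)
        out = pixelwise_membership(np.array([0.8]), ps, (6, 6))
        assert out[2, 2] == pytest.approx(0.8)
        assert out[5, 5] == 0.0

    def test_mean_of_two_covers(self):
        ps = self._patchset([(2, 2), (3, 3)], 3)
        out = pixelwise_membership(np.array([0.2, 0.6]), ps, (8, 8))
        assert out[1, 1] == pytest.approx(0.2)  # only first patch
        assert out[3, 3] == pytest.approx(0.4)  # covered by both

    def test_matches_bruteforce_accumulation(self):
        rng = np.random.default_rng(6)
        img = rng.uniform(size=(64, 64))
        roi = rng.uniform(size=(64, 64)) > 0.3
        ps = sample_patches(img, roi, R=5, stride=2)
        mu = rng.uniform(size=len(ps))
        out = pixelwise_membership(mu, ps, (64, 64))

        acc = np.zeros((64, 64))
        cnt = np.zeros((64, 64))
        for (ci, cj), m in zip(ps.centers, mu):
            acc[ci - 2 : ci + 3, cj - 2 : cj + 3] += m
            cnt[ci - 2 : ci + 3, cj - 2 : cj + 3] += 1
        expected = np.divide(acc, cnt, out=np.zeros_like(acc), where=cnt > 0)
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_values_bounded_by_contributing_memberships(self):
        rng = np.random.default_rng(7)
        ps = self._patchset([(3, 3), (4, 4), (5, 5)], 3)
        mu = rng.uniform(size=3)
        out = pixelwise_membership(mu, ps, (10, 10))
        covered = out > 0
        assert out[covered].min() >= mu.min() - 1e-12
        assert out[covered].max() <= mu.max() + 1e-12


def test_standardize_features_round_trip():
    rng = np.random.default_rng(8)
    f = rng.normal([5, 100], [2, 30], size=(500, 2))
    z, mean, std = standardize_features(f)
    np.testing.assert_allclose(z.mean(axis=0), 0, atol=1e-12)
    np.testing.assert_allclose(z.std(axis=0), 1, atol=1e-12)
    np.testing.assert_allclose(z * std + mean, f, atol=1e-10)
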