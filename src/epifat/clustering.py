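"""Seeded patch-based fuzzy c-means clustering inside the heart ROI.

Square R x R luminance patches are sampled on a regular stride grid inside
the ROI.  Each patch is summarized by a two-dimensional texture feature
``u = (u1, u2)``: the patch mean and the biased (1/R^2) patch variance.
Fuzzy c-means (FCM) partitions the z-scored feature set into C soft
clusters; the epicardial-fat cluster is selected as the one whose pondered
(membership-weighted) mean feature lies closest to the feature of a single
user-marked reference patch.  The selected cluster's patch memberships are
finally projected back onto the pixel grid by averaging, over each pixel,
the memberships of all patches covering it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, NoPatchesError

__all__ = [
    "PatchSet",
    "FuzzyClustering",
    "SeedPoint",
    "patch_features",
    "sample_patches",
    "standardize_features",
    "fuzzy_c_means",
    "select_cluster",
    "pixelwise_membership",
]


@dataclass(frozen=True)
class SeedPoint:
    """User-provided seed: slice index and (row, col) center of the
    reference epicardial-fat patch."""

    slice_index: int
    center: tuple[int, int]


@dataclass(frozen=True)
class PatchSet:
    """Q patches sampled from one slice.

    ``centers`` is a (Q, 2) int array of (row, col) patch centers,
    ``features`` a (Q, 2) float array of (mean, variance) per patch,
    ``patch_size`` the odd window side R.
    """

    centers: np.ndarray
    features: np.ndarray
    patch_size: int

    def __post_init__(self):
        if len(self.centers) != len(self.features):
            raise ValueError("centers and features must have equal length")

    def __len__(self) -> int:
        return len(self.centers)


@dataclass(frozen=True)
class FuzzyClustering:
    """Result of an FCM run on a patch feature set.

    ``memberships`` is (Q, C) with rows summing to 1; ``centers`` the C
    cluster centers in (standardized) feature space; ``objective_history``
    the value of the FCM objective J_m after each iteration;
    ``max_sum_error_history`` the per-iteration worst deviation of a
    membership row sum from 1 (a numerical self-check).
    """

    memberships: np.ndarray
    centers: np.ndarray
    fuzzifier: float
    objective_history: np.ndarray
    max_sum_error_history: np.ndarray
    n_iter: int
    converged: bool

    @property
    def n_clusters(self) -> int:
        return self.centers.shape[0]


def patch_features(window: np.ndarray) -> tuple[float, float]:
    """Mean and biased variance of one R x R luminance window.

    ``u1 = (1/R^2) sum U(i,j)``; ``u2 = (1/R^2) sum (U(i,j) - u1)^2``.
    """
    w = np.asarray(window, dtype=np.float64)
    u1 = float(w.mean())
    u2 = float(((w - u1) ** 2).mean())
    return u1, u2


def sample_patches(
    image: np.ndarray,
    roi: np.ndarray,
    R: int = 5,
    stride: int = 2,
) -> PatchSet:
    """Sample patch centers on a stride grid restricted to the ROI.

    A candidate center is kept iff its R x R window lies fully inside the
    image and the center pixel is inside the ROI mask.  Features are
    computed for every retained patch.

    Raises :class:`NoPatchesError` if no candidate survives.
    """
    if R % 2 != 1 or R < 1:
        raise ValueError("patch size R must be a positive odd integer")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    image = np.asarray(image, dtype=np.float64)
    roi = np.asarray(roi).astype(bool)
    if image.shape != roi.shape:
        raise ValueError("image and roi shapes differ")
    M, N = image.shape
    h = R // 2
    rows = np.arange(h, M - h, stride)
    cols = np.arange(h, N - h, stride)
    if rows.size == 0 or cols.size == 0:
        raise NoPatchesError(f"image {image.shape} too small for R={R} patches")
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    keep = roi[rr, cc]
    centers = np.stack([rr[keep], cc[keep]], axis=1)
    if centers.shape[0] == 0:
        raise NoPatchesError("ROI hosts no patch center on the sampling grid")
    # all windows at once via a sliding view indexed at the kept corners
    win = np.lib.stride_tricks.sliding_window_view(image, (R, R))
    blocks = win[centers[:, 0] - h, centers[:, 1] - h]  # (Q, R, R)
    u1 = blocks.mean(axis=(1, 2))
    u2 = ((blocks - u1[:, None, None]) ** 2).mean(axis=(1, 2))
    return PatchSet(centers=centers, features=np.stack([u1, u2], axis=1), patch_size=R)


def standardize_features(
    features: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Z-score each feature dimension; returns ``(z, mean, std)``.

    Constant dimensions get std 1 so they map to zero rather than NaN.
    The same ``(mean, std)`` must be applied to the reference-patch
    feature before cluster selection.
    """
    f = np.asarray(features, dtype=np.float64)
    mean = f.mean(axis=0)
    std = f.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    return (f - mean) / std, mean, std


def fuzzy_c_means(
    features: np.ndarray,
    C: int = 5,
    m: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 300,
    seed: int | list[int] = 0,
) -> FuzzyClustering:
    """Fuzzy c-means on a (Q, d) feature array.

    Cluster centers are initialized from C distinct data points drawn with
    a seeded generator, so a fixed seed makes the run bit-reproducible.
    Each iteration performs the standard alternating updates

        mu_c(k) = 1 / sum_l (d_ck / d_lk)^(2/(m-1)),
        v_c     = sum_k mu_c(k)^m u_k / sum_k mu_c(k)^m,

    and stops when the largest center displacement falls below ``tol``.
    The objective J_m = sum_{c,k} mu_c(k)^m d_ck^2 is recorded after every
    iteration and is non-increasing.

    Raises :class:`InsufficientDataError` when Q < C.
    """
    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("features must be 2D (Q, d)")
    Q = X.shape[0]
    if C < 2:
        raise ValueError("C must be >= 2")
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    if Q < C:
        raise InsufficientDataError(f"need at least C={C} points, got Q={Q}")

    rng = np.random.default_rng(seed)
    # distinct initial centers drawn from the data, tiny jitter to break
    # exact duplicates in the data itself
    idx = rng.choice(Q, size=C, replace=False)
    centers = X[idx].copy()
    scale = X.std(axis=0)
    centers += 1e-9 * np.maximum(scale, 1e-12) * rng.standard_normal(centers.shape)

    obj_hist: list[float] = []
    sum_err_hist: list[float] = []
    converged = False
    memberships = np.full((Q, C), 1.0 / C)
    it = 0
    for it in range(1, max_iter + 1):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)  # (Q, C)
        d2 = np.maximum(d2, 0.0)
        # mu_ck = d_ck^{-2/(m-1)} / sum_l d_lk^{-2/(m-1)}; a point sitting
        # exactly on a center gets full membership there (zero-distance limit)
        zero = d2 <= 1e-300
        inv = np.zeros_like(d2)
        np.power(d2, -1.0 / (m - 1.0), out=inv, where=~zero)
        sums = inv.sum(axis=1, keepdims=True)
        memberships = np.divide(inv, sums, out=np.zeros_like(inv), where=sums > 0)
        any_zero = zero.any(axis=1)
        if any_zero.any():
            z = zero[any_zero].astype(np.float64)
            memberships[any_zero] = z / z.sum(axis=1, keepdims=True)
        sum_err_hist.append(float(np.abs(memberships.sum(axis=1) - 1.0).max()))
        w = memberships**m
        new_centers = (w.T @ X) / w.sum(axis=0)[:, None]
        obj_hist.append(float((w * d2).sum()))
        shift = float(np.abs(new_centers - centers).max())
        centers = new_centers
        if shift < tol:
            converged = True
            break

    return FuzzyClustering(
        memberships=memberships,
        centers=centers,
        fuzzifier=float(m),
        objective_history=np.asarray(obj_hist),
        max_sum_error_history=np.asarray(sum_err_hist),
        n_iter=it,
        converged=converged,
    )


def pondered_cluster_means(
    clustering: FuzzyClustering,
    features: np.ndarray,
    mode: str = "as_printed",
) -> np.ndarray:
    """Membership-pondered mean feature of every cluster, (C, d).

    ``mode="as_printed"`` normalizes by the patch count Q,
    ``u_hat_c = (1/Q) sum_k mu_c(k) u_k``; ``mode="normalized"`` uses the
    conventional weighted mean ``sum_k mu_c(k) u_k / sum_k mu_c(k)``.
    """
    U = np.asarray(features, dtype=np.float64)
    mu = clustering.memberships
    num = mu.T @ U  # (C, d)
    if mode == "as_printed":
        return num / U.shape[0]
    if mode == "normalized":
        return num / mu.sum(axis=0)[:, None]
    raise ValueError(f"unknown pondered-mean mode {mode!r}")


def select_cluster(
    clustering: FuzzyClustering,
    features: np.ndarray,
    u_star: np.ndarray,
    mode: str = "as_printed",
) -> int:
    """Index of the cluster closest to the reference-patch feature.

    Distance is the squared Euclidean norm between ``u_star`` and each
    cluster's pondered mean; ties break toward the lowest cluster index.
    ``u_star`` must live in the same (standardized) feature space as
    ``features``.
    """
    u_hat = pondered_cluster_means(clustering, features, mode=mode)
    d = ((np.asarray(u_star, dtype=np.float64) - u_hat) ** 2).sum(axis=1)
    return int(np.argmin(d))


def pixelwise_membership(
    memberships: np.ndarray,
    patches: PatchSet,
    image_shape: tuple[int, int],
) -> np.ndarray:
    """Project per-patch memberships of the selected cluster onto pixels.

    Every pixel receives the mean membership of all patches whose R x R
    window covers it; pixels covered by no patch get 0.  ``memberships``
    is the (Q,) membership column of the selected cluster.
    """
    mu = np.asarray(memberships, dtype=np.float64)
    if mu.shape != (len(patches),):
        raise ValueError("memberships must be a (Q,) column for the selected cluster")
    R = patches.patch_size
    h = R // 2
    acc = np.zeros(image_shape, dtype=np.float64)
    cnt = np.zeros(image_shape, dtype=np.int64)
    off = np.arange(-h, h + 1)
    di, dj = np.meshgrid(off, off, indexing="ij")
    rows = (patches.centers[:, 0, None, None] + di[None]).ravel()
    cols = (patches.centers[:, 1, None, None] + dj[None]).ravel()
    vals = np.repeat(mu, R * R)
    np.add.at(acc, (rows, cols), vals)
    np.add.at(cnt, (rows, cols), 1)
    out = np.zeros(image_shape, dtype=np.float64)
    covered = cnt > 0
    out[covered] = acc[covered] / cnt[covered]
    return out
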