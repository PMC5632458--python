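"""Referent-ellipse estimation from the soft fuzzy-cluster point cloud.

The epicardial fat rim is modelled by a *referent ellipse* (RE) with center
``(x_c, y_c)``, orientation ``phi0`` and characteristic semi-axes ``a, b``.
Estimation proceeds in three moment/PCA/least-squares stages:

1. the center is the luminance-and-membership weighted center of gravity,
   ``x_c = M(1,0)/M(0,0)``, ``y_c = M(0,1)/M(0,0)``, with weighted image
   moments ``M(p,q) = sum_ij i^p j^q X(i,j) mu(i,j)``;
2. the orientation is the principal direction of the soft point cloud:
   PCA of the (diagonally loaded) covariance of the membership-scaled
   coordinate observations;
3. the axes minimize the weighted parametric residual

       sum_ij X(i,j) mu(i,j) [(a cos phi_ij - x~)^2 + (b sin phi_ij - y~)^2]

   over ``B_l < a, b < B_u`` in the frame translated to the center and
   rotated by ``-phi0``, where each point's angle ``phi_ij`` is its own
   ellipse parameter angle (see :func:`fit_axes`).

Coordinates are (row, col) = (i, j); the ``x`` axis is the row axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyClusterError

__all__ = [
    "ReferentEllipse",
    "AxisBounds",
    "weighted_moment",
    "estimate_center",
    "orientation_from_points",
    "estimate_orientation",
    "transform_coords",
    "axis_objective",
    "fit_axes",
    "fit_referent_ellipse",
]

#: matrix size the default axis bounds were calibrated on
REFERENCE_GRID = 512


@dataclass(frozen=True)
class ReferentEllipse:
    """Fitted geometric prior: center (pixels, (row, col) axes), orientation
    ``phi0`` in radians in [0, pi), and semi-axes ``a`` (along the rotated
    x/row axis) and ``b``."""

    center: tuple[float, float]
    phi0: float
    a: float
    b: float

    def __post_init__(self):
        if not (self.a > 0 and self.b > 0):
            raise ValueError("semi-axes must be positive")
        if not np.isfinite(self.phi0):
            raise ValueError("phi0 must be finite")


@dataclass(frozen=True)
class AxisBounds:
    """Admissible range (pixels) for both semi-axes; defaults are the
    study values for a 512-wide grid and should be rescaled for other
    matrix sizes via :meth:`scaled_to`."""

    lower: float = 200.0
    upper: float = 450.0

    def __post_init__(self):
        if not (0 < self.lower < self.upper):
            raise ValueError("bounds must satisfy 0 < lower < upper")

    def scaled_to(self, image_width: int) -> "AxisBounds":
        f = image_width / REFERENCE_GRID
        return AxisBounds(self.lower * f, self.upper * f)


def weighted_moment(image: np.ndarray, field: np.ndarray, p: int, q: int) -> float:
    """Weighted image moment ``M(p,q) = sum_ij i^p j^q X(i,j) mu(i,j)``
    where ``X`` is pixel luminance and ``mu`` the membership field."""
    X = np.asarray(image, dtype=np.float64)
    mu = np.asarray(field, dtype=np.float64)
    if X.shape != mu.shape:
        raise ValueError("image and field shapes differ")
    i = np.arange(X.shape[0], dtype=np.float64)
    j = np.arange(X.shape[1], dtype=np.float64)
    W = X * mu
    return float((i**p) @ W @ (j**q))


def estimate_center(image: np.ndarray, field: np.ndarray) -> tuple[float, float]:
    """Center of gravity of the weighted cloud, ``(M(1,0)/M(0,0),
    M(0,1)/M(0,0))``.  Raises :class:`EmptyClusterError` if the total
    weight M(0,0) vanishes."""
    m00 = weighted_moment(image, field, 0, 0)
    if m00 <= 0:
        raise EmptyClusterError("selected cluster carries no weight; center undefined")
    return (
        weighted_moment(image, field, 1, 0) / m00,
        weighted_moment(image, field, 0, 1) / m00,
    )


def orientation_from_points(
    coords: np.ndarray,
    weights: np.ndarray,
    loading: float | None = None,
    mode: str = "weighted_coords",
) -> float:
    """Principal direction of a soft point cloud, in [0, pi).

    ``mode="weighted_coords"`` builds the observations ``p_k = mu_k [i, j]``
    (membership-scaled coordinates) and takes the PCA of their covariance;
    ``mode="weighted_average"`` computes the membership-weighted covariance
    of the raw coordinates.  The covariance is regularized by diagonal
    loading ``+ eps I`` (default ``1e-6 * trace/2``) before the
    eigendecomposition; the orientation is the angle of the dominant
    eigenvector folded into [0, pi), measured from the row (x) axis.
    """
    P = np.asarray(coords, dtype=np.float64)
    w = np.asarray(weights, dtype=np.float64)
    if P.ndim != 2 or P.shape[1] != 2:
        raise ValueError("coords must be (n, 2)")
    if w.shape != (P.shape[0],):
        raise ValueError("weights must be (n,)")
    if P.shape[0] < 2:
        raise EmptyClusterError("need at least 2 points for an orientation")

    if mode == "weighted_coords":
        obs = w[:, None] * P
        mean = obs.mean(axis=0)
        d = obs - mean
        cov = (d.T @ d) / obs.shape[0]
    elif mode == "weighted_average":
        tot = w.sum()
        if tot <= 0:
            raise EmptyClusterError("all weights zero; orientation undefined")
        mean = (w[:, None] * P).sum(axis=0) / tot
        d = P - mean
        cov = (w[:, None] * d).T @ d / tot
    else:
        raise ValueError(f"unknown orientation mode {mode!r}")

    if loading is None:
        loading = 1e-6 * np.trace(cov) / 2.0
    cov = cov + loading * np.eye(2)
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, int(np.argmax(evals))]
    phi0 = float(np.arctan2(v[1], v[0])) % np.pi
    return phi0


def estimate_orientation(
    field: np.ndarray,
    roi: np.ndarray,
    loading: float | None = None,
    mode: str = "weighted_coords",
) -> float:
    """Orientation of the referent ellipse from the membership field over
    the ROI (see :func:`orientation_from_points`)."""
    roi = np.asarray(roi).astype(bool)
    mu = np.asarray(field, dtype=np.float64)
    if mu.shape != roi.shape:
        raise ValueError("field and roi shapes differ")
    coords = np.argwhere(roi).astype(np.float64)
    return orientation_from_points(coords, mu[roi], loading=loading, mode=mode)


def transform_coords(
    points: np.ndarray,
    phi0: float,
    center: tuple[float, float],
) -> np.ndarray:
    """Map image points into the ellipse frame: translate by the center,
    rotate by ``-phi0``.  The rotation is orthonormal with det = +1, so
    pairwise distances are preserved."""
    p = np.atleast_2d(np.asarray(points, dtype=np.float64))
    c, s = np.cos(phi0), np.sin(phi0)
    Rm = np.array([[c, s], [-s, c]])
    return (p - np.asarray(center, dtype=np.float64)) @ Rm.T


def _point_angles(tx, ty, a, b, theta0, newton_iters=3):
    """Refine per-point ellipse parameter angles toward the projection of
    each point on the (a, b) ellipse, by safeguarded Newton steps on the
    squared-residual derivative.  A step is kept only if it does not
    increase the point's residual."""
    theta = theta0.copy()
    res = (a * np.cos(theta) - tx) ** 2 + (b * np.sin(theta) - ty) ** 2
    for _ in range(newton_iters):
        st, ct = np.sin(theta), np.cos(theta)
        g = (b * b - a * a) * st * ct + a * tx * st - b * ty * ct
        gp = (b * b - a * a) * (ct * ct - st * st) + a * tx * ct + b * ty * st
        step = np.where(np.abs(gp) > 1e-12, g / np.where(gp == 0, 1.0, gp), 0.0)
        cand = theta - np.clip(step, -0.5, 0.5)
        cres = (a * np.cos(cand) - tx) ** 2 + (b * np.sin(cand) - ty) ** 2
        better = cres < res
        theta = np.where(better, cand, theta)
        res = np.where(better, cres, res)
    return theta, res


def axis_objective(
    a: float,
    b: float,
    tpoints: np.ndarray,
    weights: np.ndarray,
    newton_iters: int = 8,
) -> float:
    """Weighted parametric residual of the (a, b) ellipse against the
    transformed points, with each point evaluated at its own parameter
    angle (initialized at the scaled polar angle, Newton-refined).  Zero
    iff every positively weighted point lies on the ellipse."""
    t = np.atleast_2d(np.asarray(tpoints, dtype=np.float64))
    w = np.asarray(weights, dtype=np.float64)
    tx, ty = t[:, 0], t[:, 1]
    theta0 = np.arctan2(ty / b, tx / a)
    _, res = _point_angles(tx, ty, a, b, theta0, newton_iters=newton_iters)
    return float((w * res).sum())


def fit_axes(
    tpoints: np.ndarray,
    weights: np.ndarray,
    bounds: AxisBounds,
    max_iter: int = 200,
    tol: float = 1e-12,
) -> tuple[float, float]:
    """Estimate the semi-axes (a, b) by bounded block-coordinate descent.

    The objective couples (a, b) with per-point parameter angles.  Fixing
    the angles, each axis has a closed-form bounded minimizer (the problem
    is separable and quadratic); fixing (a, b), each angle is refined
    toward the point's projection on the current ellipse by safeguarded
    Newton steps that never increase the point's residual.  Angles start
    at the raw polar angle ``atan2(y~, x~)`` (the circle case, where the
    polar and parameter angles coincide); the deterministic axis start is
    the clipped second-moment radius of the cloud along each axis.  The
    objective is therefore non-increasing, and noise-free data generated
    on an in-bounds ellipse is recovered exactly (zero objective).

    Raises :class:`EmptyClusterError` when all weights vanish.
    """
    t = np.atleast_2d(np.asarray(tpoints, dtype=np.float64))
    w = np.asarray(weights, dtype=np.float64)
    if w.shape != (t.shape[0],):
        raise ValueError("weights must be (n,)")
    if not (w > 0).any():
        raise EmptyClusterError("all weights zero; axis fit undefined")
    keep = w > 0
    tx, ty, w = t[keep, 0], t[keep, 1], w[keep]
    wsum = w.sum()

    lo = np.nextafter(bounds.lower, bounds.upper)
    hi = np.nextafter(bounds.upper, bounds.lower)

    def clip(v):
        return float(np.clip(v, lo, hi))

    # second-moment radii: for points on an ellipse, E[x~^2] ~ a^2/2
    a = clip(np.sqrt(2.0 * (w * tx**2).sum() / wsum))
    b = clip(np.sqrt(2.0 * (w * ty**2).sum() / wsum))
    theta = np.arctan2(ty, tx)

    prev = np.inf
    for _ in range(max_iter):
        ct, st = np.cos(theta), np.sin(theta)
        denom_a = (w * ct * ct).sum()
        denom_b = (w * st * st).sum()
        if denom_a > 0:
            a = clip((w * tx * ct).sum() / denom_a)
        if denom_b > 0:
            b = clip((w * ty * st).sum() / denom_b)
        theta, res = _point_angles(tx, ty, a, b, theta, newton_iters=3)
        obj = float((w * res).sum())
        if prev - obj <= tol * max(1.0, obj):
            break
        prev = obj
    return a, b


def fit_referent_ellipse(
    image: np.ndarray,
    field: np.ndarray,
    roi: np.ndarray,
    bounds: AxisBounds | None = None,
    loading: float | None = None,
    orientation_mode: str = "weighted_coords",
) -> ReferentEllipse:
    """Full referent-ellipse fit: weighted center of gravity, PCA
    orientation, then the bounded axis fit on the luminance-and-membership
    weighted cloud in the transformed frame.  ``bounds`` defaults to the
    study values rescaled to the image width."""
    X = np.asarray(image, dtype=np.float64)
    mu = np.asarray(field, dtype=np.float64)
    if bounds is None:
        bounds = AxisBounds().scaled_to(X.shape[1])
    center = estimate_center(X, mu)
    phi0 = estimate_orientation(mu, roi, loading=loading, mode=orientation_mode)
    w = (X * mu)[np.asarray(roi).astype(bool)]
    coords = np.argwhere(np.asarray(roi).astype(bool)).astype(np.float64)
    t = transform_coords(coords, phi0, center)
    a, b = fit_axes(t, w, bounds)
    return ReferentEllipse(center=center, phi0=phi0, a=a, b=b)
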