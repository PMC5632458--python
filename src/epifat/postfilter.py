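"""Arc/ring-constrained postfiltering of the defuzzified fat cluster.

The selected fuzzy cluster is first made crisp by an alpha-cut.  Guided by
the geometric ellipse prior, a pixel of the crisp cluster is then retained
only if (i) its polar angle in the referent-ellipse frame lies inside the
per-slice control arc ``[phi1, phi2]`` and (ii) its radial distance to the
referent ellipse is at most ``epsilon`` pixels.  A morphological closing
with a disk structuring element finally regularizes the retained region.

Control arcs are marked by an expert on a few equidistant slices and
linearly interpolated (clamped outside the covered range) for the rest.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi

from .ellipse import ReferentEllipse, transform_coords
from .errors import MissingControlsError
from .preprocess import disk_footprint

__all__ = [
    "ArcConstraint",
    "FilterParams",
    "alpha_cut",
    "ellipse_ring_distance",
    "interpolate_control_angles",
    "filter_desirable",
    "close_mask",
]

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class ArcConstraint:
    """Per-slice angular window ``[phi1, phi2]`` (radians) in the
    referent-ellipse frame; ``phi1 <= phi2``, and windows crossing the
    2*pi wrap are expressed by letting ``phi2`` exceed 2*pi."""

    phi1: float
    phi2: float

    def __post_init__(self):
        if not (self.phi1 <= self.phi2):
            raise ValueError("arc requires phi1 <= phi2")

    @property
    def width(self) -> float:
        return self.phi2 - self.phi1


@dataclass(frozen=True)
class FilterParams:
    """Alpha-cut level and ring half-width (pixels); defaults are the
    cross-validated optima."""

    alpha: float = 0.7
    epsilon: float = 20.0

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if not self.epsilon > 0:
            raise ValueError("epsilon must be positive")


def alpha_cut(field: np.ndarray, alpha: float) -> np.ndarray:
    """Crisp mask ``{(i,j) | mu(i,j) >= alpha}`` (inclusive at mu = alpha).

    Antitone in alpha: a higher cut level is a subset of a lower one.
    An empty result is allowed.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    return (np.asarray(field, dtype=np.float64) >= alpha).astype(np.uint8)


def _polar_in_frame(points: np.ndarray, ellipse: ReferentEllipse):
    """Polar radius and angle (in [0, 2*pi)) of points in the ellipse
    frame (translated to the center, rotated by -phi0)."""
    t = transform_coords(points, ellipse.phi0, ellipse.center)
    rho = np.hypot(t[:, 0], t[:, 1])
    phi = np.arctan2(t[:, 1], t[:, 0]) % TWO_PI
    return t, rho, phi


def _ellipse_polar_radius(ellipse: ReferentEllipse, phi: np.ndarray) -> np.ndarray:
    """Polar radius of the ellipse boundary at polar angle phi in its own
    frame: ``a b / sqrt(b^2 cos^2 + a^2 sin^2)``."""
    a, b = ellipse.a, ellipse.b
    return a * b / np.sqrt((b * np.cos(phi)) ** 2 + (a * np.sin(phi)) ** 2)


def ellipse_ring_distance(
    points: np.ndarray,
    ellipse: ReferentEllipse,
    mode: str = "corrected",
) -> np.ndarray:
    """Radial distance (pixels) of image points to the referent ellipse.

    ``mode="corrected"`` (default) uses the true polar radius of the point
    and of the ellipse at the same polar angle, ``d = |rho - rho_RE(phi)|``.
    ``mode="as_printed"`` reproduces the literal study formulas
    ``rho = x~^2 cos^2 phi + y~^2 sin^2 phi`` and
    ``rho_RE = a^2 cos^2 phi + b^2 sin^2 phi`` (no square roots), kept only
    for comparison; its output is not a length.

    A point at the ellipse center (undefined angle) gets ``d = min(a, b)``
    by convention.
    """
    p = np.atleast_2d(np.asarray(points, dtype=np.float64))
    t, rho, phi = _polar_in_frame(p, ellipse)
    at_center = rho == 0.0
    if mode == "corrected":
        d = np.abs(rho - _ellipse_polar_radius(ellipse, phi))
    elif mode == "as_printed":
        c2, s2 = np.cos(phi) ** 2, np.sin(phi) ** 2
        rho_p = t[:, 0] ** 2 * c2 + t[:, 1] ** 2 * s2
        rho_re = ellipse.a**2 * c2 + ellipse.b**2 * s2
        d = np.abs(rho_p - rho_re)
    else:
        raise ValueError(f"unknown distance mode {mode!r}")
    d[at_center] = min(ellipse.a, ellipse.b)
    return d


def interpolate_control_angles(
    controls: Sequence[tuple[int, float, float]],
    slice_index: int,
) -> ArcConstraint:
    """Linearly interpolate the control arcs at a slice index.

    ``controls`` is a sequence of ``(slice_index, phi1, phi2)`` with
    strictly increasing slice indices (radians, already unwrapped so that
    interpolation across the 2*pi wrap is meaningful).  Queries outside
    the covered range clamp to the nearest control.
    """
    if len(controls) == 0:
        raise MissingControlsError("no control angles supplied")
    ctrl = sorted(controls, key=lambda c: c[0])
    idx = np.array([c[0] for c in ctrl], dtype=np.float64)
    if np.any(np.diff(idx) <= 0):
        raise ValueError("control slice indices must be strictly increasing")
    p1 = np.array([c[1] for c in ctrl], dtype=np.float64)
    p2 = np.array([c[2] for c in ctrl], dtype=np.float64)
    return ArcConstraint(
        phi1=float(np.interp(slice_index, idx, p1)),
        phi2=float(np.interp(slice_index, idx, p2)),
    )


def _in_arc(phi: np.ndarray, arc: ArcConstraint) -> np.ndarray:
    """Inclusive membership of polar angles in the arc, handling windows
    that cross the 2*pi wrap (phi2 > 2*pi)."""
    if arc.width >= TWO_PI:
        return np.ones_like(phi, dtype=bool)
    rel = (phi - arc.phi1) % TWO_PI
    return rel <= arc.width


def filter_desirable(
    crisp: np.ndarray,
    ellipse: ReferentEllipse,
    arc: ArcConstraint,
    epsilon: float,
    distance_mode: str = "corrected",
) -> np.ndarray:
    """Retain crisp-cluster pixels inside the control arc and within the
    epsilon-ring of the referent ellipse (both predicates inclusive).

    Output is always a subset of the input mask, and is monotone in both
    ``epsilon`` and the arc width.
    """
    crisp = np.asarray(crisp)
    out = np.zeros(crisp.shape, dtype=np.uint8)
    pts = np.argwhere(crisp > 0)
    if pts.size == 0:
        return out
    _, _, phi = _polar_in_frame(pts.astype(np.float64), ellipse)
    d = ellipse_ring_distance(pts.astype(np.float64), ellipse, mode=distance_mode)
    keep = _in_arc(phi, arc) & (d <= epsilon)
    out[pts[keep, 0], pts[keep, 1]] = 1
    return out


def close_mask(mask: np.ndarray, se_diameter: int = 20) -> np.ndarray:
    """Morphological closing with a disk structuring element (diameter in
    pixels).  Idempotent; fills gaps narrower than the element."""
    m = np.asarray(mask) > 0
    if not m.any():
        return np.zeros_like(m, dtype=np.uint8)
    se = disk_footprint(se_diameter)
    r = se.shape[0] // 2
    # pad so the erosion half of the closing cannot eat border pixels
    padded = np.pad(m, r)
    closed = ndi.binary_closing(padded, structure=se)[r:-r, r:-r]
    return closed.astype(np.uint8)
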