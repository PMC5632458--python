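"""Synthetic cardiac CT phantom with exact ground truth.

Each slice emulates the statistical structure of a contrast chest CT at
cardiac zoom: dark lung fields, a bright elliptical heart (myocardium with
brighter contrast-filled blood-pool blobs so clustering sees several
tissue textures), a darker epicardial fat arc hugging the heart boundary
over a limited angular range, and bright bone distractors near the image
border.  Luminances live on the native 12-bit scale (0..4095) and are
chosen to mimic contrast-CT ordering (lung << fat < myocardium < blood <
bone); they are not claimed to match Hounsfield units.

The fat arc is defined in the heart ellipse's own frame: a pixel with
polar angle ``phi`` and radius ``rho`` belongs to the fat ring iff
``rho_heart(phi) < rho <= rho_heart(phi) + thickness`` and ``phi`` lies in
the arc ``[theta1, theta2]``.  The generating "referent ellipse" of the
fat layer is therefore the heart ellipse grown by half the ring thickness.

Default geometry mirrors the study's acquisition: the heart nearly fills
a 512 x 512 grid (effective in-plane resolution ~0.25 mm/px), and the fat
pad is 40 px (~10 mm) thick.  Default additive noise s.d. is 80, ~2% of
the 12-bit range.  A fixed seed makes every output bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ellipse import ReferentEllipse
from .errors import InvalidSpecError
from .preprocess import CTSlice

__all__ = ["PhantomSpec", "PhantomVolume", "generate_slice", "generate_volume"]

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic cardiac slice generator."""

    image_size: tuple[int, int] = (512, 512)
    heart_center: tuple[float, float] = (256.0, 256.0)
    heart_axes: tuple[float, float] = (210.0, 185.0)
    heart_orientation: float = 0.3  # radians from the row axis, in [0, pi)
    fat_arc: tuple[float, float] = (0.5, 3.8)  # polar angles, heart frame
    fat_thickness: float = 40.0  # radial thickness, px (~10 mm at 0.25 mm/px)
    # luminances follow the CT-number = HU + 1024 convention: fat (~-100 HU)
    # lies just below soft tissue and far above lung, so adaptive
    # thresholding keeps the fat rim inside the heart ROI
    fat_luminance: float = 920.0
    fat_luminance_sd: float = 0.0  # extra texture inside the fat ring
    # render fat-luminance tissue on the full ring around the heart
    # (pericardial/mediastinal fat-like distractors); only the arc portion
    # is true epicardial fat, so the arc filter has real work to do
    full_fat_ring: bool = True
    myocardium_luminance: float = 1080.0
    blood_luminance: float = 1330.0
    lung_luminance: float = 120.0
    bone_luminance: float = 1930.0
    # blood-pool blobs in the heart frame: (cx, cy, semi_x, semi_y)
    blood_blobs: tuple[tuple[float, float, float, float], ...] = (
        (-55.0, -35.0, 75.0, 48.0),
        (55.0, 45.0, 62.0, 52.0),
    )
    # bone distractors as (row, col, radius); all well below the opening
    # structuring-element diameter so morphology removes them
    bone_disks: tuple[tuple[float, float, float], ...] = (
        (70.0, 70.0, 14.0),
        (440.0, 75.0, 12.0),
        (80.0, 445.0, 13.0),
    )
    noise_sd: float = 80.0
    seed: int = 0
    n_slices: int = 8
    # per-slice geometric drift
    center_drift: tuple[float, float] = (0.8, -0.5)  # px / slice
    arc_drift: tuple[float, float] = (0.012, 0.012)  # rad / slice
    pixel_spacing: tuple[float, float] = (0.25, 0.25)  # mm
    slice_thickness: float = 2.0  # mm

    def slice_geometry(self, slice_index: int):
        """Heart center and fat arc for a slice after linear drift."""
        l = slice_index
        center = (
            self.heart_center[0] + l * self.center_drift[0],
            self.heart_center[1] + l * self.center_drift[1],
        )
        arc = (
            self.fat_arc[0] + l * self.arc_drift[0],
            self.fat_arc[1] + l * self.arc_drift[1],
        )
        return center, arc

    def fat_ellipse(self, slice_index: int = 0) -> ReferentEllipse:
        """Ground-truth referent ellipse of the fat layer mid-line."""
        center, _ = self.slice_geometry(slice_index)
        return ReferentEllipse(
            center=center,
            phi0=self.heart_orientation % np.pi,
            a=self.heart_axes[0] + self.fat_thickness / 2.0,
            b=self.heart_axes[1] + self.fat_thickness / 2.0,
        )

    def seed_point(self, slice_index: int = 0) -> tuple[int, int]:
        """A (row, col) pixel at the angular and radial middle of the fat
        arc — the canonical user seed for pipeline runs on this phantom."""
        center, arc = self.slice_geometry(slice_index)
        a, b = self.heart_axes
        phi = 0.5 * (arc[0] + arc[1])
        rho_h = a * b / np.hypot(b * np.cos(phi), a * np.sin(phi))
        rho = rho_h + self.fat_thickness / 2.0
        p0 = self.heart_orientation
        i = center[0] + rho * (np.cos(phi) * np.cos(p0) - np.sin(phi) * np.sin(p0))
        j = center[1] + rho * (np.cos(phi) * np.sin(p0) + np.sin(phi) * np.cos(p0))
        return int(round(i)), int(round(j))


@dataclass(frozen=True)
class PhantomVolume:
    """A generated stack: slices, exact masks and per-slice geometry."""

    slices: list[CTSlice]
    fat_masks: np.ndarray  # (n, M, N) uint8
    heart_masks: np.ndarray  # (n, M, N) uint8
    ellipses: list[ReferentEllipse]
    arcs: list[tuple[float, float]]
    spec: PhantomSpec

    def control_angles(self, L: int = 5) -> list[tuple[int, float, float]]:
        """Ground-truth control arcs on L equidistant slices (the expert
        annotation a real run would receive)."""
        n = len(self.slices)
        idx = np.unique(np.linspace(0, n - 1, min(L, n)).round().astype(int))
        return [(int(l), *self.arcs[l]) for l in idx]


def _validate(spec: PhantomSpec, slice_index: int) -> None:
    M, N = spec.image_size
    center, _ = spec.slice_geometry(slice_index)
    ao = spec.heart_axes[0] + spec.fat_thickness
    bo = spec.heart_axes[1] + spec.fat_thickness
    c, s = np.cos(spec.heart_orientation), np.sin(spec.heart_orientation)
    # exact bounding half-widths of the rotated outer ellipse
    ext_i = np.hypot(ao * c, bo * s)
    ext_j = np.hypot(ao * s, bo * c)
    if (
        center[0] - ext_i < 0
        or center[1] - ext_j < 0
        or center[0] + ext_i > M - 1
        or center[1] + ext_j > N - 1
    ):
        raise InvalidSpecError(
            f"fat ring exceeds the image on slice {slice_index}: "
            f"center {center}, extent ({ext_i:.1f}, {ext_j:.1f}), image {spec.image_size}"
        )
    if not 0 < spec.fat_thickness:
        raise InvalidSpecError("fat_thickness must be positive")
    if not spec.fat_arc[0] < spec.fat_arc[1]:
        raise InvalidSpecError("fat arc requires theta1 < theta2")
    for lum in (
        spec.fat_luminance,
        spec.myocardium_luminance,
        spec.blood_luminance,
        spec.lung_luminance,
        spec.bone_luminance,
    ):
        if not 0 <= lum <= 4095:
            raise InvalidSpecError(f"luminance {lum} outside the 12-bit range")


def generate_slice(
    spec: PhantomSpec, slice_index: int = 0
) -> tuple[CTSlice, np.ndarray, np.ndarray, ReferentEllipse]:
    """Render one phantom slice.

    Returns ``(ct_slice, fat_mask, heart_mask, fat_ellipse)`` where the
    masks are exact ground truth and ``fat_ellipse`` is the generating
    referent ellipse of the fat layer.  Reproducible: the noise stream is
    derived from ``(spec.seed, slice_index)``.
    """
    _validate(spec, slice_index)
    M, N = spec.image_size
    center, arc = spec.slice_geometry(slice_index)
    a, b = spec.heart_axes
    p0 = spec.heart_orientation

    ii, jj = np.meshgrid(np.arange(M), np.arange(N), indexing="ij")
    di = ii - center[0]
    dj = jj - center[1]
    c, s = np.cos(p0), np.sin(p0)
    x = c * di + s * dj  # heart-frame coordinates
    y = -s * di + c * dj
    rho = np.hypot(x, y)
    phi = np.arctan2(y, x) % TWO_PI
    rho_h = a * b / np.sqrt((b * np.cos(phi)) ** 2 + (a * np.sin(phi)) ** 2)

    heart = rho <= rho_h
    width = arc[1] - arc[0]
    in_arc = ((phi - arc[0]) % TWO_PI) <= width if width < TWO_PI else np.ones_like(phi, bool)
    ring = (~heart) & (rho <= rho_h + spec.fat_thickness)
    fat = ring & in_arc  # ground truth: the epicardial (arc) portion only
    fatty = ring if spec.full_fat_ring else fat

    img = np.full((M, N), spec.lung_luminance, dtype=np.float64)
    img[heart] = spec.myocardium_luminance
    for cx, cy, ax, ay in spec.blood_blobs:
        blob = ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 <= 1.0
        img[blob & heart] = spec.blood_luminance
    img[fatty] = spec.fat_luminance
    for br, bc, rad in spec.bone_disks:
        bone = (ii - br) ** 2 + (jj - bc) ** 2 <= rad**2
        img[bone] = spec.bone_luminance

    rng = np.random.default_rng([spec.seed, slice_index])
    if spec.fat_luminance_sd > 0:
        img[fatty] += spec.fat_luminance_sd * rng.standard_normal(int(fatty.sum()))
    if spec.noise_sd > 0:
        img += spec.noise_sd * rng.standard_normal((M, N))
    np.clip(img, 0.0, 4095.0, out=img)

    ct = CTSlice(
        pixels=img,
        pixel_spacing=spec.pixel_spacing,
        slice_index=slice_index,
        slice_thickness=spec.slice_thickness,
    )
    return ct, fat.astype(np.uint8), heart.astype(np.uint8), spec.fat_ellipse(slice_index)


def generate_volume(spec: PhantomSpec, n_slices: int | None = None) -> PhantomVolume:
    """Render a drifting stack of phantom slices (geometry drifts linearly
    across slices to exercise control-angle interpolation)."""
    n = spec.n_slices if n_slices is None else n_slices
    if n < 1:
        raise InvalidSpecError("n_slices must be >= 1")
    slices, fats, hearts, ellipses, arcs = [], [], [], [], []
    for l in range(n):
        ct, fat, heart, ell = generate_slice(spec, l)
        slices.append(ct)
        fats.append(fat)
        hearts.append(heart)
        ellipses.append(ell)
        arcs.append(spec.slice_geometry(l)[1])
    return PhantomVolume(
        slices=slices,
        fat_masks=np.stack(fats),
        heart_masks=np.stack(hearts),
        ellipses=ellipses,
        arcs=arcs,
        spec=spec,
    )
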