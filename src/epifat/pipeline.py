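"""End-to-end slice-by-slice segmentation driver.

For every slice: tone map -> ROI extraction -> patch sampling -> fuzzy
c-means -> seeded cluster selection -> pixel-wise membership -> referent
ellipse fit -> alpha-cut -> arc/ring filter -> closing.  The seed point is
placed once per patient on a representative slice; its reference feature
is reused on every slice (re-standardized per slice) to re-select the fat
cluster, so the whole 3D run needs a single user interaction.

Per-slice failures (empty ROI, empty selected cluster) log a warning and
yield an empty slice mask so 3D aggregation never aborts.  Output depends
only on the input pixels, the configuration, the seed point, the control
angles and the clustering RNG seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import clustering as cl
from . import postfilter as pf
from .config import PipelineConfig
from .ellipse import AxisBounds, ReferentEllipse, fit_referent_ellipse
from .errors import EpifatError
from .metrics import VolumeReport, fat_volume
from .preprocess import CTSlice, MorphologyParams, extract_roi, tone_map

logger = logging.getLogger("epifat")

__all__ = ["SliceReport", "PipelineResult", "reference_feature", "segment_slice", "run_pipeline"]


@dataclass
class SliceReport:
    """Per-slice audit record."""

    slice_index: int
    ok: bool
    message: str = ""
    selected_cluster: int | None = None
    n_patches: int = 0
    roi_pixels: int = 0
    ellipse: ReferentEllipse | None = None
    arc: tuple[float, float] | None = None
    mask_pixels: int = 0


@dataclass
class PipelineResult:
    """Aggregated output of a 3D run."""

    mask3d: np.ndarray  # (n_slices, M, N) uint8
    reports: list[SliceReport]
    volume: VolumeReport
    membership_fields: list[np.ndarray] | None = None
    roi_masks: list[np.ndarray] | None = None


def reference_feature(
    ct_enhanced: CTSlice, center: tuple[int, int], R: int
) -> np.ndarray:
    """Raw (mean, variance) feature of the R x R reference patch around
    the user seed on the enhanced seed slice."""
    h = R // 2
    i, j = center
    M, N = ct_enhanced.shape
    if not (h <= i < M - h and h <= j < N - h):
        raise ValueError(f"seed patch at {center} does not fit inside the image")
    window = ct_enhanced.pixels[i - h : i + h + 1, j - h : j + h + 1]
    return np.array(cl.patch_features(window))


def segment_slice(
    ct: CTSlice,
    u_star_raw: np.ndarray,
    arc: pf.ArcConstraint,
    config: PipelineConfig,
    keep_artifacts: bool = False,
):
    """Segment one slice; returns ``(mask, report[, field, roi])``.

    ``u_star_raw`` is the un-standardized reference feature (it is mapped
    with this slice's own z-score transform before cluster selection).
    """
    ccfg, pcfg, ecfg, fcfg = (
        config.clustering,
        config.preprocess,
        config.ellipse,
        config.postfilter,
    )
    report = SliceReport(slice_index=ct.slice_index, ok=False)
    empty = np.zeros(ct.shape, dtype=np.uint8)
    try:
        enhanced = tone_map(ct, pcfg.clip_percentiles, method=pcfg.tone_method)
        roi = extract_roi(
            enhanced, MorphologyParams(ms1=pcfg.ms1, ms2=pcfg.ms2, closure_size=fcfg.closure_size)
        )
        report.roi_pixels = int(roi.sum())
        patches = cl.sample_patches(enhanced.pixels, roi, R=ccfg.R, stride=ccfg.stride)
        report.n_patches = len(patches)
        z, mean, std = cl.standardize_features(patches.features)
        fcm = cl.fuzzy_c_means(
            z,
            C=ccfg.C,
            m=ccfg.m,
            tol=ccfg.tol,
            max_iter=ccfg.max_iter,
            seed=[ccfg.rng_seed, ct.slice_index],
        )
        u_star = (np.asarray(u_star_raw) - mean) / std
        c_res = cl.select_cluster(fcm, z, u_star, mode=ccfg.pondered_mean)
        report.selected_cluster = c_res
        field = cl.pixelwise_membership(fcm.memberships[:, c_res], patches, ct.shape)
        field *= roi  # membership support stays inside the ROI
        ellipse = fit_referent_ellipse(
            enhanced.pixels,
            field,
            roi,
            bounds=AxisBounds(ecfg.B_l, ecfg.B_u),
            loading=ecfg.loading,
            orientation_mode=ecfg.orientation_mode,
        )
        report.ellipse = ellipse
        report.arc = (arc.phi1, arc.phi2)
        crisp = pf.alpha_cut(field, fcfg.alpha)
        filtered = pf.filter_desirable(
            crisp, ellipse, arc, fcfg.epsilon, distance_mode=fcfg.distance_mode
        )
        mask = pf.close_mask(filtered, fcfg.closure_size)
        report.mask_pixels = int(mask.sum())
        report.ok = True
        if keep_artifacts:
            return mask, report, field, roi
        return mask, report
    except EpifatError as exc:
        report.message = f"{type(exc).__name__}: {exc}"
        logger.warning("slice %d skipped: %s", ct.slice_index, report.message)
        if keep_artifacts:
            return empty, report, np.zeros(ct.shape), np.zeros(ct.shape, dtype=np.uint8)
        return empty, report


def run_pipeline(
    config: PipelineConfig,
    slices: list[CTSlice],
    seed_point: cl.SeedPoint,
    control_angles: list[tuple[int, float, float]],
    keep_artifacts: bool = False,
) -> PipelineResult:
    """Run the full segmentation on a CT series.

    ``control_angles`` is a list of ``(slice_index, phi1, phi2)`` in
    radians; arcs on unlabeled slices are linearly interpolated.
    """
    if not slices:
        raise ValueError("empty series")
    width = slices[0].shape[1]
    cfg = config.scaled_for_width(width)

    # reference feature from the enhanced seed slice, once per patient
    by_index = {s.slice_index: s for s in slices}
    seed_slice = by_index.get(seed_point.slice_index)
    if seed_slice is None:
        raise ValueError(f"seed slice {seed_point.slice_index} not in series")
    enhanced_seed = tone_map(
        seed_slice, cfg.preprocess.clip_percentiles, method=cfg.preprocess.tone_method
    )
    u_star_raw = reference_feature(enhanced_seed, seed_point.center, cfg.clustering.R)

    masks, reports = [], []
    fields = [] if keep_artifacts else None
    rois = [] if keep_artifacts else None
    for ct in slices:
        arc = pf.interpolate_control_angles(control_angles, ct.slice_index)
        out = segment_slice(ct, u_star_raw, arc, cfg, keep_artifacts=keep_artifacts)
        masks.append(out[0])
        reports.append(out[1])
        if keep_artifacts:
            fields.append(out[2])
            rois.append(out[3])

    mask3d = np.stack(masks)
    volume = fat_volume(
        mask3d, slices[0].pixel_spacing, slices[0].slice_thickness
    )
    return PipelineResult(
        mask3d=mask3d,
        reports=reports,
        volume=volume,
        membership_fields=fields,
        roi_masks=rois,
    )
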