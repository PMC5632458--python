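"""Shared fixtures: phantom slices and cached pipeline stages.

The heavier end-to-end artifacts (a segmented phantom slice, multi-seed
Dice sweeps across noise levels) are computed once per session and reused
by several test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from epifat import (
    PhantomSpec,
    PipelineConfig,
    SeedPoint,
    dice,
    generate_slice,
    generate_volume,
    run_pipeline,
)
from epifat import clustering as cl
from epifat.pipeline import reference_feature
from epifat.preprocess import extract_roi, tone_map


@pytest.fixture(scope="session")
def default_spec() -> PhantomSpec:
    return PhantomSpec()


@pytest.fixture(scope="session")
def phantom_slice0(default_spec):
    """(ct, fat_mask, heart_mask, generating ellipse) of slice 0."""
    return generate_slice(default_spec, 0)


@pytest.fixture(scope="session")
def stage0(default_spec, phantom_slice0):
    """All intermediate artifacts of the segmentation of phantom slice 0."""
    ct, fat, heart, ell = phantom_slice0
    enh = tone_map(ct)
    roi = extract_roi(enh)
    patches = cl.sample_patches(enh.pixels, roi, R=5, stride=2)
    z, mean, std = cl.standardize_features(patches.features)
    fcm = cl.fuzzy_c_means(z, C=5, seed=[0, 0])
    u_star = (reference_feature(enh, default_spec.seed_point(0), 5) - mean) / std
    c_res = cl.select_cluster(fcm, z, u_star, mode="normalized")
    field = cl.pixelwise_membership(fcm.memberships[:, c_res], patches, ct.shape) * roi
    return {
        "ct": ct,
        "fat": fat,
        "heart": heart,
        "ellipse_true": ell,
        "enhanced": enh,
        "roi": roi,
        "patches": patches,
        "z": z,
        "fcm": fcm,
        "u_star": u_star,
        "c_res": c_res,
        "field": field,
    }


def single_slice_dice(noise_sd: float, seed: int) -> float:
    """End-to-end Dice of one phantom slice at the given noise level;
    ``seed`` drives both the phantom noise and the FCM initialization."""
    spec = PhantomSpec(n_slices=1, noise_sd=noise_sd, seed=seed)
    vol = generate_volume(spec)
    cfg = PipelineConfig()
    cfg.clustering.rng_seed = seed
    res = run_pipeline(
        cfg, vol.slices, SeedPoint(0, spec.seed_point(0)), vol.control_angles()
    )
    return dice(res.mask3d[0], vol.fat_masks[0])


@pytest.fixture(scope="session")
def dice_by_noise():
    """Per-seed end-to-end Dice at three phantom noise levels."""
    levels = (0.0, 80.0, 200.0)
    seeds = range(10)
    return {
        sd: np.array([single_slice_dice(sd, s) for s in seeds]) for sd in levels
    }
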