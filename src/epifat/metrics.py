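"""Segmentation evaluation: Dice overlap, fat volume, normalized volume.

The Dice similarity coefficient between voxel sets A and B is
``D(A, B) = 2|A ∩ B| / (|A| + |B|)``.  Fat volume is the voxel count times
the physical voxel volume; the *normalized volume* (NV) divides the fat
volume by the patient's body weight, so patients of different habitus are
comparable.  NV is reported both in mm^3/kg and in raw voxels/kg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import MetadataError, UndefinedMetricError

__all__ = [
    "VolumeReport",
    "dice",
    "fat_volume",
    "normalized_volume",
    "relative_error",
]


@dataclass(frozen=True)
class VolumeReport:
    """Physical summary of a 3D binary segmentation."""

    voxel_count: int
    voxel_volume_mm3: float
    volume_mm3: float

    def normalized(self, patient_weight_kg: float) -> dict[str, float]:
        """NV in mm^3/kg plus the raw voxels-per-kg ratio."""
        return {
            "nv_mm3_per_kg": normalized_volume(self.volume_mm3, patient_weight_kg),
            "nv_voxels_per_kg": normalized_volume(
                float(self.voxel_count), patient_weight_kg
            ),
        }


def dice(A: np.ndarray, B: np.ndarray) -> float:
    """Dice similarity coefficient of two same-shaped binary masks.

    Raises :class:`UndefinedMetricError` when both masks are empty (the
    0/0 case), which callers should report as missing rather than 1.0.
    """
    A = np.asarray(A) > 0
    B = np.asarray(B) > 0
    if A.shape != B.shape:
        raise ValueError(f"mask shapes differ: {A.shape} vs {B.shape}")
    sa, sb = int(A.sum()), int(B.sum())
    if sa + sb == 0:
        raise UndefinedMetricError("Dice undefined for two empty masks (0/0)")
    return 2.0 * int((A & B).sum()) / (sa + sb)


def fat_volume(
    mask3d: np.ndarray,
    spacing: tuple[float, float],
    thickness: float,
) -> VolumeReport:
    """Physical volume of a stacked (n_slices, M, N) binary mask.

    ``spacing`` is the in-plane (row, col) pixel size in mm and
    ``thickness`` the slice thickness in mm; uniform across the stack.
    """
    if spacing is None or thickness is None:
        raise MetadataError("pixel spacing and slice thickness are required")
    sr, sc = float(spacing[0]), float(spacing[1])
    th = float(thickness)
    if sr <= 0 or sc <= 0 or th <= 0:
        raise MetadataError("spacing and thickness must be positive")
    count = int((np.asarray(mask3d) > 0).sum())
    voxvol = sr * sc * th
    return VolumeReport(
        voxel_count=count, voxel_volume_mm3=voxvol, volume_mm3=count * voxvol
    )


def normalized_volume(volume: float, patient_weight: float) -> float:
    """Fat volume divided by patient weight (kg)."""
    if not patient_weight > 0:
        raise ValueError(f"patient weight must be positive, got {patient_weight}")
    return float(volume) / float(patient_weight)


def relative_error(seg_volume: float, ref_volume: float) -> float:
    """Absolute relative volume error in percent, ``100 |seg - ref| / ref``."""
    if ref_volume <= 0:
        raise UndefinedMetricError("relative error undefined for ref volume <= 0")
    return 100.0 * abs(float(seg_volume) - float(ref_volume)) / float(ref_volume)
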