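"""Readers and writers for the standard formats the pipeline touches.

DICOM series (one file per slice) are read with pydicom and sorted by
position along the slice axis; NIfTI volumes with nibabel.  Masks and
membership fields can be written as NIfTI volumes and per-slice PNGs,
phantom stacks as DICOM-like series.  Pixel data stay on the native
12-bit scale.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, UID

from .errors import MetadataError
from .preprocess import CTSlice

__all__ = [
    "read_ct_series",
    "read_dicom_series",
    "read_nifti_volume",
    "write_dicom_series",
    "write_nifti_volume",
    "write_mask_png",
    "write_overlay_png",
]

# deterministic UID root for phantom series (test data, never clinical)
_UID_PREFIX = "1.2.826.0.1.3680043.10.1465."


def read_ct_series(path: str | Path) -> list[CTSlice]:
    """Read a CT series from a DICOM directory or a NIfTI file."""
    path = Path(path)
    if path.is_dir():
        return read_dicom_series(path)
    return read_nifti_volume(path)


def read_dicom_series(directory: str | Path) -> list[CTSlice]:
    """Read one-file-per-slice DICOM, sorted by slice position.

    Slices are ordered by the z component of ImagePositionPatient when
    present, otherwise by InstanceNumber.  Raises
    :class:`MetadataError` for mixed series UIDs or missing pixel spacing.
    """
    files = sorted(Path(directory).glob("*.dcm"))
    if not files:
        raise FileNotFoundError(f"no .dcm files in {directory}")
    datasets = [pydicom.dcmread(str(f)) for f in files]
    uids = {str(getattr(ds, "SeriesInstanceUID", "")) for ds in datasets}
    if len(uids) > 1:
        raise MetadataError(f"directory mixes {len(uids)} series UIDs")

    def sort_key(ds):
        pos = getattr(ds, "ImagePositionPatient", None)
        if pos is not None and len(pos) == 3:
            return float(pos[2])
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=sort_key)
    out = []
    for idx, ds in enumerate(datasets):
        spacing = getattr(ds, "PixelSpacing", None)
        if spacing is None:
            raise MetadataError(f"slice {idx} lacks PixelSpacing")
        thickness = float(getattr(ds, "SliceThickness", 1.0))
        px = ds.pixel_array.astype(np.float64)
        out.append(
            CTSlice(
                pixels=px,
                pixel_spacing=(float(spacing[0]), float(spacing[1])),
                slice_index=idx,
                slice_thickness=thickness,
            )
        )
    return out


def read_nifti_volume(path: str | Path) -> list[CTSlice]:
    """Read a NIfTI volume as a list of slices (last axis = slice)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise MetadataError(f"expected a 3D NIfTI volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise MetadataError(f"non-positive voxel sizes in NIfTI header: {zooms}")
    return [
        CTSlice(
            pixels=data[:, :, k],
            pixel_spacing=(float(zooms[0]), float(zooms[1])),
            slice_index=k,
            slice_thickness=float(zooms[2]),
        )
        for k in range(data.shape[2])
    ]


def write_dicom_series(slices: list[CTSlice], directory: str | Path, series_number: int = 1) -> list[Path]:
    """Write slices as a 16-bit monochrome DICOM series (secondary
    capture), with deterministic UIDs so phantom round trips are stable."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = UID(f"{_UID_PREFIX}{series_number}.0")
    paths = []
    for k, ct in enumerate(slices):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
        meta.MediaStorageSOPInstanceUID = UID(f"{_UID_PREFIX}{series_number}.{k + 1}")
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\x00" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = UID(f"{_UID_PREFIX}{series_number}")
        ds.Modality = "OT"
        ds.SeriesNumber = series_number
        ds.InstanceNumber = k + 1
        ds.ImagePositionPatient = [0.0, 0.0, float(k) * ct.slice_thickness]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [ct.pixel_spacing[0], ct.pixel_spacing[1]]
        ds.SliceThickness = ct.slice_thickness
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.Rows, ds.Columns = ct.shape
        ds.BitsAllocated = 16
        ds.BitsStored = 12
        ds.HighBit = 11
        ds.PixelRepresentation = 0
        px = np.clip(np.round(ct.pixels), 0, 4095).astype(np.uint16)
        ds.PixelData = px.tobytes()
        path = directory / f"slice_{k:04d}.dcm"
        ds.save_as(str(path), enforce_file_format=True)
        paths.append(path)
    return paths


def write_nifti_volume(
    volume: np.ndarray,
    path: str | Path,
    spacing: tuple[float, float] = (1.0, 1.0),
    thickness: float = 1.0,
) -> None:
    """Write a (M, N, n_slices) or (n_slices, M, N) array as NIfTI.

    Stacked-first arrays are transposed so the slice axis is last.
    """
    vol = np.asarray(volume)
    if vol.ndim != 3:
        raise ValueError("expected a 3D array")
    if vol.shape[0] < vol.shape[2]:  # (n, M, N) -> (M, N, n)
        vol = np.transpose(vol, (1, 2, 0))
    affine = np.diag([spacing[0], spacing[1], thickness, 1.0])
    nib.save(nib.Nifti1Image(vol.astype(np.float32), affine), str(path))


def write_mask_png(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask (or [0,1] membership field) as an 8-bit PNG."""
    arr = np.asarray(mask, dtype=np.float64)
    iio.imwrite(str(path), np.clip(arr * 255.0, 0, 255).astype(np.uint8))


def write_overlay_png(image: np.ndarray, mask: np.ndarray, path: str | Path) -> None:
    """QC overlay: the grayscale slice with the mask blended in red."""
    img = np.asarray(image, dtype=np.float64)
    rng = img.max() - img.min()
    gray = (img - img.min()) / rng if rng > 0 else np.zeros_like(img)
    rgb = np.stack([gray] * 3, axis=-1)
    m = np.asarray(mask) > 0
    rgb[m, 0] = 0.6 * rgb[m, 0] + 0.4
    rgb[m, 1] *= 0.6
    rgb[m, 2] *= 0.6
    iio.imwrite(str(path), (rgb * 255).astype(np.uint8))


def write_json(data: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2, default=float)
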