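"""NIfTI-1 reading and writing for MR volumes and segmentation masks.

Only single-file NIfTI-1 (``.nii`` / ``.nii.gz``) is supported. Masks are
stored as unsigned 8-bit with values {0, 1}; any nonzero on-disk value is
binarized to 1 on read. Spacing is taken from the header zooms (mm). The
on-disk affine is preserved on write, but all processing in this package
happens in voxel index space.
"""

from __future__ import annotations

import os

import nibabel as nib
import numpy as np

from .core import BinaryMask, VoxelVolume

__all__ = ["read_volume", "read_mask", "write_volume", "write_mask"]


def _load(path):
    if not os.path.exists(path):
        raise FileNotFoundError(f"NIfTI file not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D image, got {data.ndim}-D")
    zooms = img.header.get_zooms()[:3]
    return data, tuple(float(z) for z in zooms), img.affine


def read_volume(path, case_id: str | None = None, fat_saturated: bool = True) -> VoxelVolume:
    """Read a 3-D MR volume; spacing comes from the header in mm."""
    data, spacing, _ = _load(path)
    data = data.astype(np.float32)
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: volume contains non-finite voxel values")
    if case_id is None:
        case_id = os.path.basename(str(path)).split(".nii")[0]
    return VoxelVolume(data, spacing, case_id=case_id, fat_saturated=fat_saturated)


def read_mask(path, role: str = "cyst") -> BinaryMask:
    """Read a segmentation mask, binarizing any nonzero value to 1."""
    data, spacing, _ = _load(path)
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: mask contains non-finite voxel values")
    return BinaryMask((data != 0).astype(np.uint8), spacing, label_role=role)


def _affine(spacing):
    return np.diag([spacing[0], spacing[1], spacing[2], 1.0])


def write_volume(volume: VoxelVolume, path) -> None:
    img = nib.Nifti1Image(volume.voxels.astype(np.float32), _affine(volume.spacing))
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def write_mask(mask: BinaryMask, path) -> None:
    """Write a binary mask as uint8 {0,1}; round-trips through read_mask."""
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), _affine(mask.spacing))
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))
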