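"""Slice extraction, resampling and intensity normalization.

Each MR scan is normalized as a whole volume: intensities are first rescaled
so that the 95th percentile over all voxels equals a common level, then
standard scalar normalization is applied (zero mean, unit standard
deviation). The subsequent standardization makes the common percentile level
immaterial — normalization is invariant to positive rescaling of the input —
so the default level of 1000 arbitrary units is a free choice.

The network consumes 2-D two-channel samples: the normalized image slice in
one channel and the kidney mask slice in the other, both resampled to the
processing matrix (cubic interpolation for the image, nearest neighbor for
masks). In training mode only slices intersecting the kidney are retained —
all-background slices carry no gradient signal for a cyst target confined to
the kidneys — while inference keeps every slice so volumes reassemble
completely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import StudyCase, VoxelVolume

__all__ = ["SliceSample", "resample_slice", "normalize_intensity", "assemble_samples"]

DEFAULT_TARGET_P95 = 1000.0


@dataclass
class SliceSample:
    """One two-channel network sample (image + kidney), optional cyst target."""

    input_image: np.ndarray
    input_kidney: np.ndarray
    target_cyst: np.ndarray | None
    case_id: str
    slice_index: int


def resample_slice(slice_2d: np.ndarray, out_shape: tuple[int, int], method: str) -> np.ndarray:
    """Resample a 2-D grid to ``out_shape``.

    ``method`` is ``"cubic"`` for intensity slices (values are not clipped to
    the input range) and ``"nearest"`` for mask slices (preserves binarity).
    """
    if method not in ("cubic", "nearest"):
        raise ValueError(f"method must be 'cubic' or 'nearest', got {method!r}")
    out_shape = (int(out_shape[0]), int(out_shape[1]))
    if out_shape[0] <= 0 or out_shape[1] <= 0:
        raise ValueError(f"out_shape must be positive, got {out_shape}")
    slice_2d = np.asarray(slice_2d)
    if slice_2d.ndim != 2:
        raise ValueError("resample_slice expects a 2-D grid")
    if slice_2d.shape == out_shape:
        return slice_2d.copy()
    factors = (out_shape[0] / slice_2d.shape[0], out_shape[1] / slice_2d.shape[1])
    order = 3 if method == "cubic" else 0
    out = ndimage.zoom(
        slice_2d.astype(np.float32 if method == "cubic" else slice_2d.dtype),
        factors,
        order=order,
        mode="nearest",
        grid_mode=True,
    )
    # zoom can be off by one under rounding; enforce the contract exactly
    if out.shape != out_shape:  # pragma: no cover
        out = out[: out_shape[0], : out_shape[1]]
    return out


def normalize_intensity(volume: VoxelVolume, target_p95: float = DEFAULT_TARGET_P95) -> VoxelVolume:
    """Match the volume-wide 95th percentile, then standardize to z-scores.

    Raises on constant volumes (degenerate variance) and on volumes whose
    95th percentile is non-positive, where percentile matching by positive
    rescaling is undefined.
    """
    if target_p95 <= 0:
        raise ValueError("target_p95 must be positive")
    vox = volume.voxels.astype(np.float64)
    sd = vox.std()
    if sd == 0:
        raise ValueError(f"case {volume.case_id!r}: constant volume has degenerate variance")
    p95 = np.percentile(vox, 95)
    if p95 <= 0:
        raise ValueError(f"case {volume.case_id!r}: non-positive 95th percentile ({p95:g})")
    vox = vox * (target_p95 / p95)
    vox = (vox - vox.mean()) / vox.std()
    return VoxelVolume(
        vox.astype(np.float32),
        volume.spacing,
        case_id=volume.case_id,
        fat_saturated=volume.fat_saturated,
    )


def assemble_samples(
    case: StudyCase,
    with_targets: bool,
    truth_source: str = "truth",
    out_shape: tuple[int, int] = (256, 256),
) -> list[SliceSample]:
    """Cut a case into per-slice two-channel samples.

    The image volume is expected to be normalized already. With
    ``with_targets`` (training mode) only slices containing at least one
    kidney voxel are retained and each sample carries its cyst target from
    ``truth_source``; without targets (inference mode) every slice is
    retained and targets are absent.
    """
    img = case.image.voxels
    kid = case.kidney.voxels
    cyst = case.cyst(truth_source).voxels if with_targets else None
    samples: list[SliceSample] = []
    for k in range(img.shape[2]):
        kid_slice = kid[:, :, k]
        if with_targets and not kid_slice.any():
            continue
        samples.append(
            SliceSample(
                input_image=resample_slice(img[:, :, k], out_shape, "cubic").astype(np.float32),
                input_kidney=resample_slice(kid_slice, out_shape, "nearest").astype(np.uint8),
                target_cyst=(
                    resample_slice(cyst[:, :, k], out_shape, "nearest").astype(np.uint8)
                    if with_targets
                    else None
                ),
                case_id=case.case_id,
                slice_index=k,
            )
        )
    return samples
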