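"""Core domain containers shared by every stage of the pipeline.

The unit of study input is a 3-D T2-weighted MR volume of an ADPKD patient
together with binary segmentation masks for the kidneys and for the cysts.
All grids use one axis convention throughout the package:
``(row, column, slice)`` with coronal slices stacked along the third axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "VoxelVolume",
    "BinaryMask",
    "StudyCase",
    "MASK_ROLES",
    "FeasibilityError",
]

MASK_ROLES = ("kidney", "cyst")


class FeasibilityError(ValueError):
    """A phantom request is geometrically impossible (names the constraint)."""


def _check_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be three positive lengths in mm, got {spacing}")
    return spacing


@dataclass
class VoxelVolume:
    """3-D scalar intensity grid with per-axis physical spacing in mm."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    case_id: str = ""
    fat_saturated: bool = True

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"volume must be 3-D, got {self.voxels.ndim}-D")
        if self.voxels.shape[2] < 1:
            raise ValueError("volume must contain at least one slice")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("volume contains non-finite intensities")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class BinaryMask:
    """{0,1} grid congruent to a :class:`VoxelVolume`."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    label_role: str = "cyst"

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"mask must be 3-D, got {self.voxels.ndim}-D")
        vals = np.unique(self.voxels)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"mask voxels must be exactly 0 or 1, found values {vals[:5]}")
        self.voxels = self.voxels.astype(np.uint8)
        self.spacing = _check_spacing(self.spacing)
        if self.label_role not in MASK_ROLES:
            raise ValueError(f"label_role must be one of {MASK_ROLES}, got {self.label_role!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def count(self) -> int:
        return int(self.voxels.sum())

    def congruent_with(self, other) -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)


@dataclass
class StudyCase:
    """One case: MR image, kidney mask, and cyst masks keyed by source.

    Sources are free-form names such as ``truth`` (phantom ground truth),
    ``reader-1``/``reader-2`` (manual tracings) or ``auto`` (the ensemble
    prediction).
    """

    image: VoxelVolume
    kidney: BinaryMask
    cyst_by_source: Mapping[str, BinaryMask] = field(default_factory=dict)

    def __post_init__(self):
        self.cyst_by_source = dict(self.cyst_by_source)
        if not self.kidney.congruent_with(self.image):
            raise ValueError("kidney mask is not congruent with the image volume")
        for name, mask in self.cyst_by_source.items():
            if not mask.congruent_with(self.image):
                raise ValueError(f"cyst mask {name!r} is not congruent with the image volume")

    @property
    def case_id(self) -> str:
        return self.image.case_id

    def cyst(self, source: str) -> BinaryMask:
        try:
            return self.cyst_by_source[source]
        except KeyError:
            raise KeyError(
                f"case {self.case_id!r} has no cyst mask from source {source!r}; "
                f"available: {sorted(self.cyst_by_source)}"
            ) from None
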