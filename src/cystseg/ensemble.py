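"""Majority-vote fusion of the cross-validation fold models.

Each trained fold model predicts binary per-slice cyst masks for a case; a
voxel is positive in the ensemble output iff at least ``vote_threshold``
members (default: a strict majority of an odd member count) vote for it.
Votes are taken on binarized member outputs, not averaged probabilities.

Multiplying the prediction by the kidney mask is offered as opt-in
post-processing (``apply_kidney_mask``) and is off by default: the
two-channel input already teaches the network to confine cysts to the
kidneys, and residual false positives outside them are part of what the
evaluation should see.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import BinaryMask, StudyCase
from .network import NetworkConfig, SegmentationNetwork, predict_slices
from .preprocessing import assemble_samples, normalize_intensity, resample_slice

__all__ = ["EnsembleModel", "predict_case", "majority_vote"]


def majority_vote(masks: list[np.ndarray], vote_threshold: int) -> np.ndarray:
    """Per-voxel vote fusion: 1 where at least ``vote_threshold`` masks are 1."""
    if not masks:
        raise ValueError("majority_vote needs at least one mask")
    shapes = {np.asarray(m).shape for m in masks}
    if len(shapes) != 1:
        raise ValueError(f"masks disagree in shape: {shapes}")
    votes = np.zeros(next(iter(shapes)), dtype=np.int16)
    for m in masks:
        votes += np.asarray(m, dtype=np.int16)
    return (votes >= vote_threshold).astype(np.uint8)


@dataclass
class EnsembleModel:
    members: list[SegmentationNetwork]
    member_threshold: float = 0.5
    vote_threshold: int | None = None
    config: NetworkConfig = field(init=False)

    def __post_init__(self):
        if len(self.members) < 3 or len(self.members) % 2 == 0:
            raise ValueError(
                f"ensemble needs an odd member count >= 3, got {len(self.members)}"
            )
        shapes = {tuple(m.config.input_shape) for m in self.members}
        if len(shapes) != 1:
            raise ValueError(f"member configs disagree on input shape: {shapes}")
        self.config = self.members[0].config
        if self.vote_threshold is None:
            self.vote_threshold = len(self.members) // 2 + 1
        if not 1 <= self.vote_threshold <= len(self.members):
            raise ValueError("vote_threshold must be in [1, member count]")


def predict_case(
    ensemble: EnsembleModel,
    case: StudyCase,
    apply_kidney_mask: bool = False,
    normalized: bool = False,
) -> BinaryMask:
    """Predict a 3-D cyst mask congruent with the case's image volume.

    The image is normalized (unless ``normalized`` says the caller already
    did), cut into two-channel slices at the processing matrix, predicted by
    every member, fused per voxel by vote count, and the fused slices are
    mapped back to the native grid by nearest-neighbor resampling.
    """
    work = case if normalized else StudyCase(
        normalize_intensity(case.image), case.kidney, case.cyst_by_source
    )
    shape = tuple(ensemble.config.input_shape)
    samples = assemble_samples(work, with_targets=False, out_shape=shape)
    member_preds = [
        np.stack(predict_slices(m, samples, threshold=ensemble.member_threshold), axis=-1)
        for m in ensemble.members
    ]
    fused = majority_vote(member_preds, ensemble.vote_threshold).astype(bool)

    native = case.image.shape
    if (native[0], native[1]) != shape:
        out = np.zeros(native, dtype=np.uint8)
        for k in range(native[2]):
            out[:, :, k] = resample_slice(
                fused[:, :, k].astype(np.uint8), (native[0], native[1]), "nearest"
            )
    else:
        out = fused.astype(np.uint8)
    if apply_kidney_mask:
        out = out * case.kidney.voxels
    return BinaryMask(out, case.image.spacing, label_role="cyst")
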