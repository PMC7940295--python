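"""Agreement statistics and volume measures for cyst segmentations.

Overlap agreement between a test and a reference mask is summarized by Dice,
Jaccard, sensitivity and precision from voxel-wise TP/FP/FN counts, plus the
exact symmetric Hausdorff distance in 3-D voxel-index units (anisotropic
spacing deliberately ignored: the distance is reported in voxels). Volumes
(TKV, TCV) are voxel count x voxel volume; cystic index is TCV/TKV. Method
agreement on volumes uses signed percent difference, ordinary least-squares
regression with a 95% confidence band, and Bland-Altman bias / limits of
agreement.

Metrics with an undefined denominator (empty masks) propagate as NaN — not
as zero — and are excluded from cohort means with a logged count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .core import BinaryMask, StudyCase, VoxelVolume

__all__ = [
    "SegmentationMetrics",
    "VolumeStats",
    "BlandAltmanResult",
    "RegressionResult",
    "overlap_metrics",
    "hausdorff_vox",
    "volume_stats",
    "percent_difference",
    "bland_altman",
    "linear_fit",
    "evaluate_test_set",
    "EvaluationReport",
    "render_overlay",
]

logger = logging.getLogger(__name__)

METRIC_COLUMNS = [
    "jaccard",
    "dice",
    "sensitivity",
    "precision",
    "hausdorff_vox",
    "tcv_percent_difference",
]


@dataclass
class SegmentationMetrics:
    dice: float
    jaccard: float
    sensitivity: float
    precision: float
    hausdorff_vox: float = math.nan
    tcv_percent_difference: float = math.nan


@dataclass
class VolumeStats:
    tkv_ml: float
    tcv_ml: float
    cystic_index: float


@dataclass
class BlandAltmanResult:
    bias: float
    loa_low: float
    loa_high: float
    points: list[tuple[float, float]]  # (pair mean, difference a - b)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    # pointwise 95% confidence band of the mean response, at the observed x
    band_x: np.ndarray = field(repr=False, default=None)
    band_low: np.ndarray = field(repr=False, default=None)
    band_high: np.ndarray = field(repr=False, default=None)


def _congruent(test: BinaryMask, reference: BinaryMask):
    if test.shape != reference.shape:
        raise ValueError(f"shape mismatch: {test.shape} vs {reference.shape}")
    if not np.allclose(test.spacing, reference.spacing):
        raise ValueError(f"spacing mismatch: {test.spacing} vs {reference.spacing}")


def overlap_metrics(test: BinaryMask, reference: BinaryMask) -> SegmentationMetrics:
    """Dice, Jaccard, sensitivity and precision from voxel counts.

    Undefined ratios (all-empty denominators) come back as NaN.
    """
    _congruent(test, reference)
    t = test.voxels.astype(bool)
    r = reference.voxels.astype(bool)
    tp = int((t & r).sum())
    fp = int((t & ~r).sum())
    fn = int((~t & r).sum())
    div = lambda a, b: a / b if b else math.nan
    return SegmentationMetrics(
        dice=div(2 * tp, 2 * tp + fp + fn),
        jaccard=div(tp, tp + fp + fn),
        sensitivity=div(tp, tp + fn),
        precision=div(tp, tp + fp),
    )


def hausdorff_vox(test: BinaryMask, reference: BinaryMask) -> float:
    """Exact symmetric Hausdorff distance in 3-D voxel-index units."""
    _congruent(test, reference)
    a = np.argwhere(test.voxels)
    b = np.argwhere(reference.voxels)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("Hausdorff distance is undefined for an empty mask")
    ta, tb = cKDTree(a), cKDTree(b)
    h_ab = tb.query(a)[0].max()
    h_ba = ta.query(b)[0].max()
    return float(max(h_ab, h_ba))


def volume_stats(kidney: BinaryMask, cyst: BinaryMask) -> VolumeStats:
    """TKV and TCV in mL (voxel count x voxel volume), and cystic index."""
    _congruent(kidney, cyst)
    vox_ml = float(np.prod(kidney.spacing)) / 1000.0
    tkv = kidney.count() * vox_ml
    tcv = cyst.count() * vox_ml
    return VolumeStats(tkv_ml=tkv, tcv_ml=tcv, cystic_index=tcv / tkv if tkv > 0 else math.nan)


def percent_difference(test_volume: float, reference_volume: float) -> float:
    """Signed percent difference, reference-denominated."""
    if reference_volume <= 0:
        raise ValueError("percent difference is undefined for a non-positive reference volume")
    return 100.0 * (test_volume - reference_volume) / reference_volume


def bland_altman(pairs) -> BlandAltmanResult:
    """Bias and 1.96-sd limits of agreement of pairwise differences a - b."""
    pairs = [(float(a), float(b)) for a, b in pairs]
    if len(pairs) < 2:
        raise ValueError("Bland-Altman analysis needs at least 2 pairs")
    d = np.array([a - b for a, b in pairs])
    m = np.array([(a + b) / 2 for a, b in pairs])
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        points=list(zip(m.tolist(), d.tolist())),
    )


def linear_fit(pairs) -> RegressionResult:
    """OLS fit y = m*x + b with r^2 and a pointwise 95% mean-response band."""
    pairs = [(float(x), float(y)) for x, y in pairs]
    if len(pairs) < 3:
        raise ValueError("linear fit needs at least 3 pairs")
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    if np.var(x) == 0:
        raise ValueError("linear fit is undefined with zero x-variance")
    n = len(x)
    res = stats.linregress(x, y)
    slope, intercept = float(res.slope), float(res.intercept)
    yhat = slope * x + intercept
    sse = float(((y - yhat) ** 2).sum())
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    order = np.argsort(x)
    xs = x[order]
    if n > 2:
        mse = sse / (n - 2)
        sxx = float(((x - x.mean()) ** 2).sum())
        se_mean = np.sqrt(mse * (1.0 / n + (xs - x.mean()) ** 2 / sxx))
        tcrit = stats.t.ppf(0.975, n - 2)
    else:  # pragma: no cover - n >= 3 enforced above
        se_mean = np.zeros_like(xs)
        tcrit = 0.0
    fit = slope * xs + intercept
    return RegressionResult(
        slope=slope,
        intercept=intercept,
        r_squared=float(np.clip(r2, 0.0, 1.0)),
        band_x=xs,
        band_low=fit - tcrit * se_mean,
        band_high=fit + tcrit * se_mean,
    )


# ---------------------------------------------------------------------------
# cohort evaluation
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    per_case: pd.DataFrame
    summary: pd.DataFrame  # mean, sd, n per metric
    bland_altman_cystic_index: BlandAltmanResult
    regression_tcv: RegressionResult | None
    regression_cystic_index: RegressionResult | None

    def summary_text(self) -> str:
        lines = []
        for metric, row in self.summary.iterrows():
            lines.append(f"{metric}: {row['mean']:.2f} ± {row['sd']:.2f} (n={int(row['n'])})")
        return "\n".join(lines)


def evaluate_test_set(
    cases: list[StudyCase], test_source: str, reference_source: str
) -> EvaluationReport:
    """Per-case agreement metrics plus cohort summaries and volume agreement.

    ``test_source`` is compared against ``reference_source`` on every case
    (the reference denominates percent differences). Undefined entries are
    NaN and excluded from the cohort mean +- sd with a logged count.
    """
    rows = []
    ba_pairs = []
    tcv_pairs = []
    ci_pairs = []
    for case in cases:
        t = case.cyst(test_source)
        r = case.cyst(reference_source)
        m = overlap_metrics(t, r)
        try:
            hd = hausdorff_vox(t, r)
        except ValueError:
            hd = math.nan
        vt = volume_stats(case.kidney, t)
        vr = volume_stats(case.kidney, r)
        pdiff = percent_difference(vt.tcv_ml, vr.tcv_ml) if vr.tcv_ml > 0 else math.nan
        rows.append(
            {
                "case_id": case.case_id,
                "jaccard": m.jaccard,
                "dice": m.dice,
                "sensitivity": m.sensitivity,
                "precision": m.precision,
                "hausdorff_vox": hd,
                "tcv_percent_difference": pdiff,
                "tcv_test_ml": vt.tcv_ml,
                "tcv_reference_ml": vr.tcv_ml,
                "cystic_index_test": vt.cystic_index,
                "cystic_index_reference": vr.cystic_index,
            }
        )
        ba_pairs.append((vt.cystic_index, vr.cystic_index))
        tcv_pairs.append((vr.tcv_ml, vt.tcv_ml))
        ci_pairs.append((vr.cystic_index, vt.cystic_index))

    per_case = pd.DataFrame(rows).set_index("case_id")
    summary_rows = {}
    for col in METRIC_COLUMNS:
        vals = per_case[col].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        if (~ok).sum():
            logger.info("metric %s: %d undefined case(s) excluded from summary", col, int((~ok).sum()))
        summary_rows[col] = {
            "mean": float(np.mean(vals[ok])) if ok.any() else math.nan,
            "sd": float(np.std(vals[ok], ddof=1)) if ok.sum() > 1 else math.nan,
            "n": int(ok.sum()),
        }
    summary = pd.DataFrame(summary_rows).T[["mean", "sd", "n"]]

    ba = bland_altman(ba_pairs) if len(ba_pairs) >= 2 else None
    reg_tcv = linear_fit(tcv_pairs) if len(tcv_pairs) >= 3 else None
    reg_ci = linear_fit(ci_pairs) if len(ci_pairs) >= 3 else None
    return EvaluationReport(
        per_case=per_case,
        summary=summary,
        bland_altman_cystic_index=ba,
        regression_tcv=reg_tcv,
        regression_cystic_index=reg_ci,
    )


# ---------------------------------------------------------------------------
# qualitative overlay
# ---------------------------------------------------------------------------


def render_overlay(
    image: VoxelVolume,
    mask_a: BinaryMask,
    mask_b: BinaryMask,
    slice_index: int,
    path=None,
):
    """Render one slice with mask agreement/disagreement regions colored.

    Voxels only in ``mask_a`` are violet, only in ``mask_b`` green, and the
    agreement region dark gray over a darkened background slice. Returns the
    RGB array; writes a PNG when ``path`` is given.
    """
    if not 0 <= slice_index < image.shape[2]:
        raise ValueError(f"slice_index {slice_index} out of range [0, {image.shape[2]})")
    sl = image.voxels[:, :, slice_index].astype(np.float64)
    lo, hi = sl.min(), sl.max()
    gray = (sl - lo) / (hi - lo) if hi > lo else np.zeros_like(sl)
    gray *= 0.5  # darkened background for overlay visibility
    rgb = np.stack([gray, gray, gray], axis=-1)
    a = mask_a.voxels[:, :, slice_index].astype(bool)
    b = mask_b.voxels[:, :, slice_index].astype(bool)
    rgb[a & ~b] = (0.58, 0.0, 0.83)  # violet: a only
    rgb[b & ~a] = (0.0, 0.8, 0.2)  # green: b only
    rgb[a & b] = (0.35, 0.35, 0.35)  # dark gray: agreement
    if path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 4))
        ax.imshow(rgb, interpolation="nearest")
        ax.axis("off")
        fig.tight_layout(pad=0)
        fig.savefig(path, dpi=100)
        plt.close(fig)
    return rgb
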