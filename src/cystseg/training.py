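"""Stratified splitting, soft-Dice loss, and the per-fold training loop.

The cohort is split into a hold-out test set and cross-validation folds so
that disease severity (TKV) is balanced across all partitions: cases are
stratified by fat-saturation, ranked by TKV within each stratum, and spread
over the partitions by systematic (strided) allocation with seeded jitter.
A rank test between any partition and the remainder should then show no
severity difference.

Training minimizes the soft Dice loss 1 - (2*sum(p*t)+s)/(sum(p)+sum(t)+s)
over each batch of slice samples with Adam (lr 1e-3, decay 1e-5, batch 8).
After every epoch the model is evaluated on the validation cases as
reassembled volumes (hard Dice at threshold 0.5, averaged per case) and the
weights of the best validation epoch are kept.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import StudyCase
from .network import Adam, NetworkConfig, SegmentationNetwork, build_network
from .preprocessing import assemble_samples

__all__ = [
    "SplitPlan",
    "TrainConfig",
    "LearningCurve",
    "stratify_cases",
    "soft_dice_loss",
    "soft_dice_grad",
    "hard_dice",
    "train_fold",
    "run_cross_validation",
    "case_tkv_ml",
]


# ---------------------------------------------------------------------------
# stratified splitting
# ---------------------------------------------------------------------------


@dataclass
class SplitPlan:
    test_ids: list[str]
    folds: list[tuple[list[str], list[str]]]  # (train_ids, val_ids) per fold

    def __post_init__(self):
        test = set(self.test_ids)
        seen_val: set[str] = set()
        for train, val in self.folds:
            if test & set(train) or test & set(val):
                raise ValueError("test set overlaps a fold")
            if set(train) & set(val):
                raise ValueError("train and validation overlap within a fold")
            if seen_val & set(val):
                raise ValueError("a case appears in more than one fold's validation set")
            seen_val |= set(val)

    def to_dict(self) -> dict:
        return {"test_ids": self.test_ids, "folds": [list(map(list, f)) for f in self.folds]}

    @classmethod
    def from_dict(cls, d: dict) -> "SplitPlan":
        return cls(
            test_ids=list(d["test_ids"]),
            folds=[(list(t), list(v)) for t, v in d["folds"]],
        )


def case_tkv_ml(case: StudyCase) -> float:
    """Total kidney volume in mL: voxel count x voxel volume."""
    return case.kidney.count() * case.image.voxel_volume_mm3 / 1000.0


def _quotas(m: int, fractions: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of m items to groups."""
    raw = fractions * m
    base = np.floor(raw).astype(int)
    rem = m - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:rem]] += 1
    return base


def stratify_cases(
    cases: list[StudyCase],
    n_test: int,
    n_folds: int = 3,
    seed: int = 0,
    stratify_fat_sat: bool = True,
) -> SplitPlan:
    """TKV-balanced allocation into a hold-out set and validation folds.

    Within each fat-saturation stratum cases are sorted by TKV and spread
    across the groups (test, val-fold 0..n_folds-1) by systematic striding:
    each group's members sit at evenly spaced ranks, with seeded jitter
    breaking ties. Each non-test case lands in exactly one fold's validation
    set; that fold's training set is the rest of the non-test cases.
    """
    ids = [c.case_id for c in cases]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate case ids in cohort")
    n = len(cases)
    if not 0 < n_test < n:
        raise ValueError(f"n_test must be in (0, {n}), got {n_test}")
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")

    rng = np.random.default_rng(seed)
    n_groups = 1 + n_folds  # group 0 = test, groups 1.. = val folds
    global_quota = np.concatenate([[n_test], _quotas(n - n_test, np.full(n_folds, 1 / n_folds))])
    fractions = global_quota / n

    if stratify_fat_sat:
        strata_keys = sorted({c.image.fat_saturated for c in cases}, reverse=True)
        strata = [[c for c in cases if c.image.fat_saturated == key] for key in strata_keys]
    else:
        strata = [list(cases)]

    # per-stratum quotas via largest remainder, then fix up global totals
    per = np.array([_quotas(len(s), fractions) for s in strata])
    for g in range(n_groups):
        while per[:, g].sum() > global_quota[g]:
            i = int(np.argmax(per[:, g]))
            per[i, g] -= 1
            deficit = np.where(per.sum(axis=0) < global_quota)[0][0]
            per[i, deficit] += 1

    groups: list[list[str]] = [[] for _ in range(n_groups)]
    for stratum, quota in zip(strata, per):
        stratum = sorted(stratum, key=case_tkv_ml)
        m = len(stratum)
        # systematic spread: group g's j-th member targets rank (j + u)/q
        keys = []
        for g in range(n_groups):
            for j in range(int(quota[g])):
                keys.append(((j + rng.uniform(0.25, 0.75)) / max(quota[g], 1), g))
        order = sorted(range(m), key=lambda i: (keys[i][0], rng.random()))
        for rank, i in enumerate(order):
            groups[keys[i][1]].append(stratum[rank].case_id)

    test_ids = sorted(groups[0])
    non_test = [cid for cid in ids if cid not in set(test_ids)]
    folds = []
    for g in range(1, n_groups):
        val = sorted(groups[g])
        train = [cid for cid in non_test if cid not in set(val)]
        folds.append((train, val))
    return SplitPlan(test_ids=test_ids, folds=folds)


def split_balance_pvalues(cases: list[StudyCase], plan: SplitPlan) -> dict[str, float]:
    """Rank-test p-value of TKV for each partition vs the remaining cases."""
    tkv = {c.case_id: case_tkv_ml(c) for c in cases}
    out = {}
    partitions = {"test": plan.test_ids}
    for i, (_, val) in enumerate(plan.folds):
        partitions[f"fold{i}_val"] = val
    for name, ids in partitions.items():
        a = [tkv[c] for c in ids]
        b = [tkv[c] for c in tkv if c not in set(ids)]
        out[name] = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return out


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------


def soft_dice_loss(pred: np.ndarray, target: np.ndarray, smooth: float = 1.0) -> float:
    """1 - (2*sum(p*t)+s) / (sum(p)+sum(t)+s), summed over all batch pixels."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs target {target.shape}")
    if smooth <= 0:
        raise ValueError("smooth must be positive")
    num = 2.0 * float((pred * target).sum()) + smooth
    den = float(pred.sum()) + float(target.sum()) + smooth
    return 1.0 - num / den


def soft_dice_grad(pred: np.ndarray, target: np.ndarray, smooth: float = 1.0) -> np.ndarray:
    """d(soft_dice_loss)/d(pred)."""
    pred = np.asarray(pred, dtype=np.float32)
    target = np.asarray(target, dtype=np.float32)
    num = 2.0 * float((pred * target).sum()) + smooth
    den = float(pred.sum()) + float(target.sum()) + smooth
    return ((num - 2.0 * target * den) / den**2).astype(np.float32)


def hard_dice(a: np.ndarray, b: np.ndarray) -> float:
    """Binary Dice; 1.0 when both sets are empty (full agreement)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (sa + sb)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    lr_decay: float = 1e-5
    epochs: int = 200
    batch_size: int = 8
    dice_smooth: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if min(self.learning_rate, self.lr_decay, self.dice_smooth) <= 0:
            raise ValueError("learning_rate, lr_decay and dice_smooth must be positive")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")


@dataclass
class LearningCurve:
    train_dice: list[float] = field(default_factory=list)
    val_dice: list[float] = field(default_factory=list)
    best_epoch: int = 0  # index into the series

    def write_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["epoch", "train_dice", "val_dice"])
            for e, (tr, va) in enumerate(zip(self.train_dice, self.val_dice), start=1):
                w.writerow([e, f"{tr:.6f}", f"{va:.6f}"])

    def plot(self, path, title: str = "") -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        epochs = np.arange(1, len(self.train_dice) + 1)
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.plot(epochs, self.train_dice, label="training Dice")
        ax.plot(epochs, self.val_dice, label="validation Dice")
        ax.axvline(self.best_epoch + 1, ls=":", color="gray", label="best epoch")
        ax.set_xlabel("epoch")
        ax.set_ylabel("Dice")
        ax.set_ylim(0, 1)
        if title:
            ax.set_title(title)
        ax.legend()
        fig.tight_layout()
        fig.savefig(path, dpi=100)
        plt.close(fig)


def _validation_dice(model: SegmentationNetwork, val_data, batch_size: int) -> float:
    """Mean per-case volume Dice (threshold 0.5) on reassembled predictions."""
    from .network import predict_slices

    dices = []
    for case, samples in val_data:
        preds = predict_slices(model, samples, threshold=0.5, batch_size=batch_size)
        pred_vol = np.stack(preds, axis=-1)
        truth_vol = np.stack([s.target_cyst for s in samples], axis=-1)
        dices.append(hard_dice(pred_vol, truth_vol))
    return float(np.mean(dices))


def train_fold(
    fold: tuple[list[str], list[str]],
    cases: list[StudyCase],
    net_config: NetworkConfig,
    train_config: TrainConfig,
    truth_source: str = "truth",
    verbose: bool = False,
) -> tuple[dict[str, np.ndarray], LearningCurve]:
    """Train one fold; returns (best-validation weights, learning curve)."""
    train_ids, val_ids = fold
    if not train_ids or not val_ids:
        raise ValueError("train and validation sets must be non-empty")
    by_id = {c.case_id: c for c in cases}
    shape = net_config.input_shape

    train_samples = []
    for cid in train_ids:
        train_samples += assemble_samples(by_id[cid], with_targets=True,
                                          truth_source=truth_source, out_shape=shape)
    # validation volumes are reassembled from every slice (inference mode
    # keeps all slices), with targets attached for scoring
    val_data = []
    for cid in val_ids:
        case = by_id[cid]
        samples = assemble_samples(case, with_targets=False, out_shape=shape)
        cyst = case.cyst(truth_source).voxels
        for s in samples:
            s.target_cyst = (
                np.rint(
                    np.asarray(
                        _nearest(cyst[:, :, s.slice_index], shape)
                    )
                ).astype(np.uint8)
            )
        val_data.append((case, samples))

    if not any(s.target_cyst.any() for s in train_samples):
        import warnings

        warnings.warn("all training cyst targets are empty; loss is defined via smoothing")

    rng = np.random.default_rng(train_config.seed)
    model = build_network(net_config, seed=int(rng.integers(2**31 - 1)))
    opt = Adam(model.parameters(), lr=train_config.learning_rate, decay=train_config.lr_decay)
    smooth = train_config.dice_smooth
    bs = train_config.batch_size

    curve = LearningCurve()
    best_state = model.copy_state()
    best_val = -np.inf
    n_samples = len(train_samples)
    for epoch in range(train_config.epochs):
        order = rng.permutation(n_samples)
        inter = union = 0.0
        for start in range(0, n_samples, bs):
            chunk = [train_samples[i] for i in order[start : start + bs]]
            x = np.stack(
                [np.stack([s.input_image, s.input_kidney.astype(np.float32)]) for s in chunk]
            )
            t = np.stack([s.target_cyst for s in chunk]).astype(np.float32)
            model.zero_grad()
            p = model.forward(x, training=True)
            model.backward(soft_dice_grad(p, t, smooth))
            opt.step()
            hard = p >= 0.5
            inter += float((hard & (t > 0.5)).sum())
            union += float(hard.sum() + t.sum())
        train_dice = 2.0 * inter / union if union else 1.0
        val_dice = _validation_dice(model, val_data, bs)
        curve.train_dice.append(train_dice)
        curve.val_dice.append(val_dice)
        if val_dice > best_val:
            best_val = val_dice
            curve.best_epoch = epoch
            best_state = model.copy_state()
        if verbose:
            print(f"  epoch {epoch + 1:3d}: train Dice {train_dice:.3f}, val Dice {val_dice:.3f}")
    return best_state, curve


def _nearest(slice_2d, shape):
    from .preprocessing import resample_slice

    return resample_slice(slice_2d, shape, "nearest")


def run_cross_validation(
    plan: SplitPlan,
    cases: list[StudyCase],
    net_config: NetworkConfig,
    train_config: TrainConfig,
    truth_source: str = "truth",
    verbose: bool = False,
) -> list[tuple[dict[str, np.ndarray], LearningCurve]]:
    """Train one model per fold; the ensemble needs an odd count >= 3."""
    if len(plan.folds) < 3 or len(plan.folds) % 2 == 0:
        raise ValueError(
            f"majority-vote ensembling needs an odd number of folds >= 3, got {len(plan.folds)}"
        )
    results = []
    seeds = np.random.SeedSequence(train_config.seed).generate_state(len(plan.folds)) % (2**31)
    for i, fold in enumerate(plan.folds):
        if verbose:
            print(f"fold {i + 1}/{len(plan.folds)}: {len(fold[0])} train, {len(fold[1])} val")
        fold_cfg = TrainConfig(
            learning_rate=train_config.learning_rate,
            lr_decay=train_config.lr_decay,
            epochs=train_config.epochs,
            batch_size=train_config.batch_size,
            dice_smooth=train_config.dice_smooth,
            seed=int(seeds[i]),
        )
        results.append(
            train_fold(fold, cases, net_config, fold_cfg, truth_source=truth_source, verbose=verbose)
        )
    return results
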