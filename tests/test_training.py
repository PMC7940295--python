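import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cystseg.core import StudyCase
from cystseg.network import NetworkConfig, build_network
from cystseg.phantom import generate_cohort
from cystseg.preprocessing import normalize_intensity
from cystseg.training import (
    SplitPlan,
    TrainConfig,
    run_cross_validation,
    soft_dice_loss,
    split_balance_pvalues,
    stratify_cases,
    train_fold,
)


class TestSoftDice:
    def test_perfect_overlap_loss_vanishes_with_smooth(self):
        t = np.ones((4, 4))
        assert soft_dice_loss(t, t, smooth=1e-9) < 1e-8

    def test_empty_empty_convention(self):
        z = np.zeros((3, 3))
        assert soft_dice_loss(z, z, smooth=1.0) == 0.0

    def test_half_probability_on_half_target(self):
        # pred all 0.5 over N pixels, target half ones:
        # loss = 1 - (2*0.25N + s) / (0.5N + 0.5N + s) ~ 0.5
        n = 10000
        pred = np.full(n, 0.5)
        target = np.zeros(n)
        target[: n // 2] = 1.0
        assert soft_dice_loss(pred, target, smooth=1.0) == pytest.approx(0.5, abs=1e-3)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            soft_dice_loss(np.zeros((2, 2)), np.zeros((3, 3)))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_loss_bounded_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        pred = rng.random((4, 8))
        target = (rng.random((4, 8)) < 0.5).astype(float)
        loss = soft_dice_loss(pred, target, smooth=1.0)
        assert 0.0 <= loss <= 1.0


def _cohort(n, seed=11):
    return [
        StudyCase(normalize_intensity(c.image), c.kidney, dict(c.cyst_by_source))
        for c in generate_cohort(n, seed=seed, grid_shape=(32, 32, 8), noise_sigma=10.0)
    ]


class TestStratify:
    def test_partition_sizes_sixty_case_cohort(self):
        cases = _cohort(60)
        plan = stratify_cases(cases, n_test=20, n_folds=3, seed=0)
        assert len(plan.test_ids) == 20
        val_sizes = sorted(len(v) for _, v in plan.folds)
        assert val_sizes in ([13, 13, 14], [13, 14, 13], [14, 13, 13]) or val_sizes == [13, 13, 14]
        for train, val in plan.folds:
            assert len(train) + len(val) == 40

    def test_fat_saturation_proportions_preserved(self):
        cases = _cohort(60)
        by_id = {c.case_id: c for c in cases}
        plan = stratify_cases(cases, n_test=20, n_folds=3, seed=0)
        n_fat_test = sum(by_id[c].image.fat_saturated for c in plan.test_ids)
        assert n_fat_test == 14  # 70% of 20

    def test_deterministic(self):
        cases = _cohort(30)
        a = stratify_cases(cases, n_test=10, n_folds=3, seed=4)
        b = stratify_cases(cases, n_test=10, n_folds=3, seed=4)
        assert a.to_dict() == b.to_dict()

    def test_duplicate_ids_rejected(self):
        cases = _cohort(6)
        cases.append(cases[0])
        with pytest.raises(ValueError, match="duplicate"):
            stratify_cases(cases, n_test=2, n_folds=3, seed=0)

    def test_every_non_test_case_in_exactly_one_val_set(self):
        cases = _cohort(30)
        plan = stratify_cases(cases, n_test=10, n_folds=3, seed=4)
        all_val = [cid for _, val in plan.folds for cid in val]
        assert sorted(all_val) == sorted(
            set(c.case_id for c in cases) - set(plan.test_ids)
        )

    def test_tkv_balance_monotone_cohort(self):
        # strictly increasing TKV: each partition's mean stays near global
        from cystseg.training import case_tkv_ml

        cases = _cohort(60)
        plan = stratify_cases(cases, n_test=20, n_folds=3, seed=0)
        tkv = {c.case_id: case_tkv_ml(c) for c in cases}
        global_mean = np.mean(list(tkv.values()))
        for ids in [plan.test_ids] + [v for _, v in plan.folds]:
            part_mean = np.mean([tkv[c] for c in ids])
            assert abs(part_mean - global_mean) / global_mean < 0.15

    def test_split_plan_overlap_validation(self):
        with pytest.raises(ValueError):
            SplitPlan(test_ids=["a"], folds=[(["b"], ["a"])])


def _tiny_train(epochs=3, seed=5, n=6):
    cases = _cohort(n, seed=21)
    ids = [c.case_id for c in cases]
    fold = (ids[: n - 2], ids[n - 2 :])
    cfg = NetworkConfig(kernel_schedule=[3, 3], base_filters=4, input_shape=(32, 32))
    return train_fold(fold, cases, cfg, TrainConfig(epochs=epochs, seed=seed))


class TestTrainFold:
    def test_best_epoch_attains_max_validation_dice(self):
        _, curve = _tiny_train()
        assert curve.val_dice[curve.best_epoch] == max(curve.val_dice)
        assert len(curve.train_dice) == len(curve.val_dice) == 3

    def test_same_seed_reproduces_curves(self):
        _, a = _tiny_train(seed=5)
        _, b = _tiny_train(seed=5)
        assert a.train_dice == b.train_dice
        assert a.val_dice == b.val_dice

    def test_checkpoint_reproduces_recorded_best_validation_dice(self):
        cases = _cohort(6, seed=21)
        ids = [c.case_id for c in cases]
        fold = (ids[:4], ids[4:])
        cfg = NetworkConfig(kernel_schedule=[3, 3], base_filters=4, input_shape=(32, 32))
        state, curve = train_fold(fold, cases, cfg, TrainConfig(epochs=3, seed=5))
        from cystseg.preprocessing import assemble_samples, resample_slice
        from cystseg.training import _validation_dice

        model = build_network(cfg, seed=0)
        model.load_state_dict(state)
        by_id = {c.case_id: c for c in cases}
        val_data = []
        for cid in fold[1]:
            case = by_id[cid]
            samples = assemble_samples(case, with_targets=False, out_shape=(32, 32))
            cyst = case.cyst("truth").voxels
            for s in samples:
                s.target_cyst = resample_slice(
                    cyst[:, :, s.slice_index], (32, 32), "nearest"
                ).astype(np.uint8)
            val_data.append((case, samples))
        redone = _validation_dice(model, val_data, 8)
        assert abs(redone - curve.val_dice[curve.best_epoch]) < 1e-5

    def test_empty_train_set_rejected(self):
        cases = _cohort(4, seed=21)
        cfg = NetworkConfig(kernel_schedule=[3, 3], base_filters=4, input_shape=(32, 32))
        with pytest.raises(ValueError):
            train_fold(([], [cases[0].case_id]), cases, cfg, TrainConfig(epochs=1))


class TestCrossValidation:
    def test_single_fold_plan_rejected(self):
        cases = _cohort(8)
        plan = SplitPlan(
            test_ids=[cases[-1].case_id],
            folds=[([c.case_id for c in cases[:5]], [c.case_id for c in cases[5:7]])],
        )
        cfg = NetworkConfig(kernel_schedule=[3, 3], base_filters=4, input_shape=(32, 32))
        with pytest.raises(ValueError, match="odd"):
            run_cross_validation(plan, cases, cfg, TrainConfig(epochs=1))


def test_balance_pvalues_above_threshold_on_sixty_cases():
    cases = _cohort(60)
    plan = stratify_cases(cases, n_test=20, n_folds=3, seed=0)
    pvals = split_balance_pvalues(cases, plan)
    assert all(p > 0.05 for p in pvals.values()), pvals
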