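import math

import numpy as np
import pytest

from cystseg.core import BinaryMask, StudyCase, VoxelVolume
from cystseg.metrics import (
    bland_altman,
    evaluate_test_set,
    hausdorff_vox,
    linear_fit,
    overlap_metrics,
    percent_difference,
    render_overlay,
    volume_stats,
)
from cystseg.phantom import generate_case, PhantomSpec, simulate_second_reader

from oracles import brute_hausdorff, brute_overlap, brute_volume_ml

SPACING = (1.5, 1.5, 3.0)


def _mask(vox):
    return BinaryMask(np.asarray(vox, dtype=np.uint8), SPACING)


def _random_mask(rng, shape=(8, 8, 4), p=0.3):
    return _mask(rng.random(shape) < p)


class TestOverlap:
    def test_identical_masks(self, rng):
        m = _random_mask(rng)
        r = overlap_metrics(m, m)
        assert (r.dice, r.jaccard, r.sensitivity, r.precision) == (1, 1, 1, 1)

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 2))
        b = np.zeros((4, 4, 2))
        a[0, 0, 0] = 1
        b[1, 1, 1] = 1
        r = overlap_metrics(_mask(a), _mask(b))
        assert (r.dice, r.jaccard, r.sensitivity, r.precision) == (0, 0, 0, 0)

    def test_hand_counted_example(self):
        # |test| = 4, |reference| = 6, overlap 3
        test = np.zeros((4, 4, 2))
        ref = np.zeros((4, 4, 2))
        test.flat[[0, 1, 2, 10]] = 1
        ref.flat[[0, 1, 2, 20, 21, 22]] = 1
        r = overlap_metrics(_mask(test), _mask(ref))
        assert r.dice == pytest.approx(0.6)
        assert r.jaccard == pytest.approx(3 / 7)
        assert r.sensitivity == pytest.approx(0.5)
        assert r.precision == pytest.approx(0.75)

    def test_empty_masks_give_nan_not_zero(self):
        z = _mask(np.zeros((3, 3, 2)))
        r = overlap_metrics(z, z)
        assert math.isnan(r.dice) and math.isnan(r.precision)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            overlap_metrics(_mask(np.zeros((3, 3, 2))), _mask(np.zeros((4, 4, 2))))


class TestHausdorff:
    def test_identical_masks_zero(self, rng):
        m = _random_mask(rng)
        assert hausdorff_vox(m, m) == 0.0

    def test_three_four_five_triangle(self):
        a = np.zeros((8, 8, 2))
        b = np.zeros((8, 8, 2))
        a[0, 0, 0] = 1
        b[3, 4, 0] = 1
        assert hausdorff_vox(_mask(a), _mask(b)) == 5.0

    def test_concentric_spheres_directed_asymmetry(self):
        grid = np.indices((16, 16, 16))
        d2 = ((grid - 8) ** 2).sum(axis=0)
        inner = _mask(d2 <= 9)
        outer = _mask(d2 <= 25)
        # inner is a subset: its directed distance to outer is 0
        assert hausdorff_vox(inner, outer) > 0
        assert hausdorff_vox(inner, outer) == pytest.approx(brute_hausdorff(
            inner.voxels, outer.voxels), abs=1e-6)

    def test_empty_mask_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            hausdorff_vox(_random_mask(rng), _mask(np.zeros((8, 8, 4))))


class TestVolumes:
    def test_thousand_voxels_at_nominal_spacing(self):
        vox = np.zeros((20, 20, 4), np.uint8)
        vox.flat[:1000] = 1
        kidney = BinaryMask(vox, SPACING, label_role="kidney")
        cyst = _mask(np.zeros((20, 20, 4)))
        vs = volume_stats(kidney, cyst)
        assert vs.tkv_ml == pytest.approx(6.75)  # 1000 * 6.75 mm^3
        assert vs.tcv_ml == 0.0 and vs.cystic_index == 0.0

    def test_cyst_equals_kidney_gives_index_one(self, rng):
        vox = (rng.random((8, 8, 4)) < 0.4).astype(np.uint8)
        kidney = BinaryMask(vox, SPACING, label_role="kidney")
        cyst = BinaryMask(vox.copy(), SPACING)
        assert volume_stats(kidney, cyst).cystic_index == 1.0

    @pytest.mark.parametrize(
        "test,ref,expected", [(100, 100, 0.0), (110, 100, 10.0), (80, 100, -20.0)]
    )
    def test_percent_difference(self, test, ref, expected):
        assert percent_difference(test, ref) == pytest.approx(expected)

    def test_percent_difference_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_difference(10, 0)


class TestBlandAltman:
    def test_equal_pairs(self):
        r = bland_altman([(1, 1), (2, 2), (3, 3)])
        assert r.bias == 0 and r.loa_low == 0 and r.loa_high == 0

    def test_hand_computed_limits(self):
        r = bland_altman([(1, 0), (3, 0)])
        sd = math.sqrt(2)
        assert r.bias == pytest.approx(2.0)
        assert r.loa_low == pytest.approx(2 - 1.96 * sd)
        assert r.loa_high == pytest.approx(2 + 1.96 * sd)
        assert r.points == [(0.5, 1.0), (1.5, 3.0)]

    def test_antisymmetry(self, rng):
        pairs = [(float(a), float(b)) for a, b in rng.random((6, 2))]
        fwd = bland_altman(pairs)
        rev = bland_altman([(b, a) for a, b in pairs])
        assert fwd.bias == pytest.approx(-rev.bias)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([(1, 2)])


class TestLinearFit:
    def test_collinear_points(self):
        r = linear_fit([(x, 2 * x + 1) for x in range(5)])
        assert r.slope == pytest.approx(2.0)
        assert r.intercept == pytest.approx(1.0)
        assert r.r_squared == pytest.approx(1.0)

    def test_symmetric_points_give_zero_slope(self):
        r = linear_fit([(0, 1), (1, 2), (2, 2), (3, 1)])
        assert r.slope == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_ols(self):
        r = linear_fit([(0, 0), (1, 1), (2, 1), (3, 2)])
        assert r.slope == pytest.approx(0.6)
        assert r.intercept == pytest.approx(0.1)

    def test_zero_x_variance_rejected(self):
        with pytest.raises(ValueError):
            linear_fit([(1, 0), (1, 1), (1, 2)])

    def test_confidence_band_brackets_fit(self):
        r = linear_fit([(x, 2 * x + 0.5 * ((-1) ** x)) for x in range(8)])
        fit = r.slope * r.band_x + r.intercept
        assert np.all(r.band_low <= fit + 1e-12)
        assert np.all(r.band_high >= fit - 1e-12)


class TestIdentities:
    """Relations that must hold between the overlap metrics."""

    @pytest.mark.parametrize("seed", range(5))
    def test_jaccard_dice_relation_and_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        a, b = _random_mask(rng), _random_mask(rng)
        fwd = overlap_metrics(a, b)
        rev = overlap_metrics(b, a)
        assert fwd.jaccard == pytest.approx(fwd.dice / (2 - fwd.dice), abs=1e-9)
        assert fwd.dice == pytest.approx(rev.dice, abs=1e-12)
        assert fwd.jaccard == pytest.approx(rev.jaccard, abs=1e-12)
        assert fwd.sensitivity == pytest.approx(rev.precision, abs=1e-12)
        if a.count() and b.count():
            assert hausdorff_vox(a, b) == pytest.approx(hausdorff_vox(b, a), abs=1e-12)


def test_metrics_match_brute_force_on_random_pairs():
    """Oracle equivalence on 50 random small mask pairs."""
    rng = np.random.default_rng(77)
    for trial in range(50):
        shape = tuple(rng.integers(3, 17, size=3))
        a = _mask(rng.random(shape) < 0.35)
        b = _mask(rng.random(shape) < 0.35)
        got = overlap_metrics(a, b)
        want = brute_overlap(a.voxels, b.voxels)
        for name in ("dice", "jaccard", "sensitivity", "precision"):
            g, w = getattr(got, name), want[name]
            assert (math.isnan(g) and math.isnan(w)) or g == pytest.approx(w, abs=1e-9)
        if a.count() and b.count():
            assert hausdorff_vox(a, b) == pytest.approx(
                brute_hausdorff(a.voxels, b.voxels), abs=1e-6
            )
        assert volume_stats(a, b).tkv_ml == pytest.approx(
            brute_volume_ml(a.voxels, SPACING), abs=1e-9
        )


class TestEvaluateTestSet:
    def _cases(self, n=4, level=2.0):
        cases = []
        for i in range(n):
            case = generate_case(
                PhantomSpec(grid_shape=(32, 32, 8), target_cystic_index=0.3, seed=200 + i,
                            case_id=f"c{i}")
            )
            truth = case.cyst("truth")
            case.cyst_by_source["reader-2"] = simulate_second_reader(truth, level, seed=i)
            cases.append(case)
        return cases

    def test_self_comparison_is_perfect(self):
        cases = self._cases(level=0.0)
        rep = evaluate_test_set(cases, "reader-2", "truth")
        assert (rep.per_case["dice"] == 1.0).all()
        assert (rep.per_case["tcv_percent_difference"] == 0.0).all()

    def test_summary_mean_matches_brute_force_per_case(self):
        cases = self._cases(n=5)
        rep = evaluate_test_set(cases, "reader-2", "truth")
        brute = [
            brute_overlap(c.cyst("reader-2").voxels, c.cyst("truth").voxels)["dice"]
            for c in cases
        ]
        assert rep.summary.loc["dice", "mean"] == pytest.approx(np.mean(brute), abs=1e-9)

    def test_missing_source_names_case(self):
        cases = self._cases(n=2)
        del cases[1].cyst_by_source["reader-2"]
        with pytest.raises(KeyError, match="c1"):
            evaluate_test_set(cases, "reader-2", "truth")


class TestOverlay:
    def test_identical_masks_show_only_agreement_color(self, phantom_case):
        truth = phantom_case.cyst("truth")
        k = int(np.argmax(truth.voxels.sum(axis=(0, 1))))
        rgb = render_overlay(phantom_case.image, truth, truth, k)
        # no pure violet or green pixels
        assert not ((rgb == (0.58, 0.0, 0.83)).all(axis=-1)).any()
        assert not ((rgb == (0.0, 0.8, 0.2)).all(axis=-1)).any()
        assert ((rgb == (0.35, 0.35, 0.35)).all(axis=-1)).any()

    def test_disjoint_masks_show_no_agreement_color(self):
        img = VoxelVolume(np.random.default_rng(0).random((8, 8, 2)).astype(np.float32), SPACING)
        a = np.zeros((8, 8, 2)); a[1, 1, 0] = 1
        b = np.zeros((8, 8, 2)); b[5, 5, 0] = 1
        rgb = render_overlay(img, _mask(a), _mask(b), 0)
        assert not ((rgb == (0.35, 0.35, 0.35)).all(axis=-1)).any()

    def test_out_of_range_slice_rejected(self, phantom_case):
        with pytest.raises(ValueError):
            render_overlay(
                phantom_case.image, phantom_case.cyst("truth"), phantom_case.kidney, 99
            )

    def test_png_written(self, tmp_path, phantom_case):
        truth = phantom_case.cyst("truth")
        render_overlay(phantom_case.image, truth, phantom_case.kidney, 6,
                       path=tmp_path / "o.png")
        assert (tmp_path / "o.png").stat().st_size > 0
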