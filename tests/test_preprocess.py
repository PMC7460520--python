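import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from myoinvade import preprocess as pp


def _grid(values):
    """Tile a short pixel list into a valid 8x8 image."""
    v = np.asarray(values, dtype=np.float64)
    return np.resize(v, (8, 8))


class TestStandardize:
    def test_zero_mean_unit_std(self):
        rng = np.random.default_rng(0)
        out = pp.standardize(rng.uniform(0, 500, size=(32, 32)))
        assert abs(out.pixels.mean()) < 1e-6
        assert abs(out.pixels.std() - 1.0) < 1e-6

    def test_four_level_image_hand_computed(self):
        out = pp.standardize(_grid([0, 1, 2, 3]))
        assert out.source_mean == pytest.approx(1.5)
        assert out.source_std == pytest.approx(np.sqrt(1.25))
        expected = [-1.3416, -0.4472, 0.4472, 1.3416]
        np.testing.assert_allclose(out.pixels[0, :4], expected, atol=1e-4)

    def test_population_not_sample_std(self):
        img = _grid([0, 1, 2, 3])
        # the sample (n-1) convention would give a different spread
        assert pp.standardize(img).source_std != pytest.approx(
            img.std(ddof=1))

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pp.standardize(np.full((16, 16), 7.0))

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(hst.integers(0, 2**31 - 1))
    def test_idempotent(self, seed):
        img = np.random.default_rng(seed).normal(50, 9, size=(16, 16))
        once = pp.standardize(img).pixels
        twice = pp.standardize(once).pixels
        np.testing.assert_allclose(once, twice, atol=1e-6)


class TestCropResize:
    def test_identity_when_already_square_target(self):
        img = np.random.default_rng(1).uniform(size=(96, 96))
        np.testing.assert_array_equal(pp.crop_resize(img, 96), img)

    def test_center_crop_window(self):
        img = np.arange(1024 * 896, dtype=np.float64).reshape(1024, 896)
        out = pp.crop_resize(img, 896)
        np.testing.assert_array_equal(out, img[64:960, :])

    def test_mask_stays_binary_after_resize(self):
        mask = np.zeros((100, 100), dtype=bool)
        mask[30:70, 20:80] = True
        out = pp.crop_resize(mask, 64, is_mask=True)
        assert out.dtype == bool
        assert set(np.unique(out)) <= {False, True}

    def test_invalid_target(self):
        with pytest.raises(ValueError):
            pp.crop_resize(np.zeros((32, 32)), 4)


class TestAugment:
    @pytest.fixture()
    def pair(self):
        rng = np.random.default_rng(2)
        img = rng.uniform(size=(32, 32))
        mask = np.zeros((32, 32), dtype=bool)
        mask[8:20, 10:25] = True
        return img, mask

    def test_flips_are_involutions(self, pair):
        img, mask = pair
        plan = pp.AugmentPlan(affine=False, multiply=False)
        out = pp.augment(img, mask, plan, seed=0)
        assert len(out) == 3  # original + 2 flips
        np.testing.assert_array_equal(out[1][0][:, ::-1], img)
        np.testing.assert_array_equal(out[2][0][::-1, :], img)
        for _, m in out:
            assert m.dtype == bool and m.sum() == mask.sum()

    def test_geometric_ops_applied_identically_and_mask_binary(self, pair):
        img, mask = pair
        out = pp.augment(img, mask, pp.AugmentPlan(), seed=5)
        # original + hflip + vflip + affine + multiply
        assert len(out) == 5
        aff_img, aff_mask = out[3]
        assert aff_mask.dtype == bool
        assert 0 < aff_mask.sum() < mask.size
        # intensity multiplication leaves geometry untouched
        mul_img, mul_mask = out[4]
        np.testing.assert_array_equal(mul_mask, mask)
        ratio = mul_img[img != 0] / img[img != 0]
        assert np.allclose(ratio, ratio[0])
        assert 0.8 <= ratio[0] <= 1.2

    def test_deterministic_by_seed(self, pair):
        img, mask = pair
        a = pp.augment(img, mask, seed=7)
        b = pp.augment(img, mask, seed=7)
        for (ia, ma), (ib, mb) in zip(a, b):
            np.testing.assert_array_equal(ia, ib)
            np.testing.assert_array_equal(ma, mb)

    def test_shape_mismatch_raises(self, pair):
        img, mask = pair
        with pytest.raises(ValueError, match="differ"):
            pp.augment(img, mask[:16], seed=0)


class TestSplitCohort:
    def test_study_shaped_split(self):
        ids = [f"c{i}" for i in range(72)]
        split = pp.split_cohort(ids, seed=0)
        sizes = tuple(len(split.cases(s)) for s in ("train", "validation", "test"))
        assert sizes == (24, 6, 42)
        assert len(split.evaluation_group) == 48
        assert len(pp.SplitAssignment(split.labels, strict=True)
                   .evaluation_group) == 42

    def test_small_cohort_arithmetic(self):
        split = pp.split_cohort([str(i) for i in range(9)],
                                train_fraction=1 / 3, val_count=1, seed=1)
        assert tuple(len(split.cases(s))
                     for s in ("train", "validation", "test")) == (3, 1, 5)

    def test_stratified_split_preserves_stage_proportions(self):
        ids = [f"c{i}" for i in range(72)]
        stages = {cid: ("IB" if i < 19 else "IA") for i, cid in enumerate(ids)}
        split = pp.split_cohort(ids, seed=3, stratify_by_stage=stages)
        for part, n_part in (("train", 24), ("validation", 6), ("test", 42)):
            members = split.cases(part)
            assert len(members) == n_part
            n_ib = sum(stages[c] == "IB" for c in members)
            expected = n_part * 19 / 72
            assert abs(n_ib - expected) <= 1.0

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValueError):
            pp.split_cohort(["a", "b"], train_fraction=0.5, val_count=6, seed=0)
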