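import numpy as np
import pytest

from myoinvade import phantom as ph
from myoinvade import preprocess as pp
from myoinvade import segmentation as seg
from myoinvade.segmentation import _batch_dice_loss_grad


def _disc(center, radius, shape=(64, 64)):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return np.hypot(yy - center[0], xx - center[1]) <= radius


class TestMetrics:
    def test_dice_loss_identity_case(self):
        m = _disc((32, 32), 10).astype(float)
        area = m.sum()
        assert seg.dice_loss(m, m) <= 1.0 / (2 * area + 1)

    def test_dice_loss_disjoint_and_half_overlap(self):
        a = np.zeros((40, 40))
        b = np.zeros((40, 40))
        a[:5, :20] = 1  # area 100
        b[20:25, :20] = 1  # area 100, disjoint
        assert seg.dice_loss(a, b) == pytest.approx(1 - 1 / 201)
        c = np.zeros((40, 40))
        c[:5, 10:30] = 1  # area 100, overlap 50 with a
        assert seg.dice_loss(a, c) == pytest.approx(1 - 101 / 201)

    def test_iou_examples(self):
        a = np.zeros((40, 40), bool)
        b = np.zeros((40, 40), bool)
        a[:5, :20] = True
        c = a.copy()
        assert seg.iou(a, c) == 1.0
        assert seg.iou(a, b[::-1]) == 0.0  # empty vs a -> 0? b is empty
        b[:5, 10:30] = True
        assert seg.iou(a, b) == pytest.approx(50 / 150)
        empty = np.zeros((8, 8), bool)
        assert seg.iou(empty, empty) == 1.0

    def test_iou_dice_algebraic_identity_on_random_masks(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            a = rng.uniform(size=(24, 24)) < rng.uniform(0.1, 0.9)
            b = rng.uniform(size=(24, 24)) < rng.uniform(0.1, 0.9)
            if not (a.any() or b.any()):
                continue
            d = seg.dice_coefficient(a.astype(float), b.astype(float), eps=0.0)
            assert seg.iou(a, b) == pytest.approx(d / (2 - d))
            # symmetry and bounds
            assert seg.iou(a, b) == seg.iou(b, a)
            assert 0.0 <= seg.dice_loss(a.astype(float), b.astype(float)) < 1.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            seg.iou(np.zeros((4, 4), bool), np.zeros((5, 5), bool))
        with pytest.raises(ValueError):
            seg.dice_loss(np.zeros((4, 4)), np.zeros((5, 5)))


class TestModelConstruction:
    def test_tiny_output_shape_contract(self):
        model = seg.build_model(seg.ModelSpec("tiny"), seed=0)
        out = model.forward(np.zeros((1, 1, 128, 128), np.float32))
        assert out.shape == (1, 2, 128, 128)
        assert np.all((out >= 0) & (out <= 1))
        assert model.n_parameters() <= 500_000

    @pytest.mark.parametrize("family", ["vgg11-like", "vgg16-like",
                                        "resnet34-like"])
    def test_study_encoder_families_constructible(self, family):
        model = seg.build_model(seg.ModelSpec(family, base_channels=4), seed=1)
        out = model.forward(np.zeros((1, 1, 64, 64), np.float32))
        assert out.shape == (1, 2, 64, 64)

    def test_seeded_init_reproducible(self):
        a = seg.build_model(seg.ModelSpec("tiny"), seed=3)
        b = seg.build_model(seg.ModelSpec("tiny"), seed=3)
        for (wa, _), (wb, _) in zip(a.params(), b.params()):
            np.testing.assert_array_equal(wa, wb)

    def test_unknown_family_and_pretrained_rejected(self):
        with pytest.raises(ValueError, match="unsupported"):
            seg.build_model(seg.ModelSpec("alexnet-like"))
        with pytest.raises(ValueError, match="pretrained"):
            seg.build_model(seg.ModelSpec("tiny", pretrained=True))


class TestBackprop:
    def test_analytic_gradients_match_numeric(self):
        rng = np.random.default_rng(0)
        model = seg.build_model(seg.ModelSpec("tiny", base_channels=3), seed=2)
        x = rng.normal(size=(2, 1, 16, 16)).astype(np.float32)
        y = (rng.uniform(size=(2, 2, 16, 16)) > 0.6).astype(np.float32)
        probs = model.forward(x)
        _, grad = _batch_dice_loss_grad(probs, y)
        model.zero_grad()
        model.backward(grad)
        params = model.params()
        checked = 0
        for w, gw in params[::3]:
            idx = tuple(rng.integers(0, s) for s in w.shape)
            eps = 1e-3
            orig = w[idx]
            w[idx] = orig + eps
            lp, _ = _batch_dice_loss_grad(model.forward(x), y)
            w[idx] = orig - eps
            lm, _ = _batch_dice_loss_grad(model.forward(x), y)
            w[idx] = orig
            numeric = (lp - lm) / (2 * eps)
            assert gw[idx] == pytest.approx(numeric, abs=2e-4, rel=0.05)
            checked += 1
        assert checked >= 4


@pytest.fixture(scope="module")
def small_data():
    cases = ph.generate_cohort(ph.CohortSpec(n_cases=10, canvas_size=64,
                                             seed=8))
    xs, ys = [], []
    for c in cases:
        xs.append(pp.standardize(c.images["t1c"]).pixels[None])
        ys.append(np.stack([c.uterus_mask, c.lesion_mask]))
    return (np.stack(xs).astype(np.float32),
            np.stack(ys).astype(np.float32))


class TestTraining:
    def test_zero_epochs_returns_model_unchanged(self, small_data):
        x, y = small_data
        model = seg.build_model(seg.ModelSpec("tiny"), seed=0)
        before = model.state()
        rec = seg.train(model, x[:8], y[:8], x[8:], y[8:],
                        seg.TrainConfig(epochs=0, seed=0))
        for w_before, (w_after, _) in zip(before, model.params()):
            np.testing.assert_array_equal(w_before, w_after)
        assert rec.best_epoch is None

    def test_loss_decreases_and_best_epoch_selected(self, small_data):
        x, y = small_data
        model = seg.build_model(seg.ModelSpec("tiny"), seed=1)
        cfg = seg.TrainConfig(batch_size=4, learning_rate=0.02, epochs=8,
                              seed=0)
        rec = seg.train(model, x[:8], y[:8], x[8:], y[8:], cfg)
        assert rec.curves.train_loss.iloc[-1] < rec.curves.train_loss.iloc[0]
        assert rec.best_epoch == int(rec.curves.val_loss.idxmin())

    def test_overfit_single_phantom_recovers_uterus(self, small_data):
        x, y = small_data
        model = seg.build_model(seg.ModelSpec("tiny"), seed=2)
        cfg = seg.TrainConfig(batch_size=1, learning_rate=0.03, epochs=60,
                              seed=0)
        seg.train(model, x[:1], y[:1], x[:1], y[:1], cfg)
        out = seg.predict_masks(model, x[0], case_id="p0")
        assert seg.iou(out.masks["uterus"], y[0, 0] >= 0.5) > 0.9

    def test_predict_masks_contract(self, small_data):
        x, y = small_data
        model = seg.build_model(seg.ModelSpec("tiny"), seed=3)
        out = seg.predict_masks(model, x[0], case_id="c")
        assert set(out.masks) == {"uterus", "lesion"}
        for s, prob in out.probabilities.items():
            assert prob.shape == x[0, 0].shape
            assert np.all((prob >= 0) & (prob <= 1))
        # containment enforced post hoc
        assert not np.any(out.masks["lesion"] & ~out.masks["uterus"])

    def test_resolution_mismatch_rejected(self, small_data):
        x, _ = small_data
        model = seg.build_model(seg.ModelSpec("tiny"), seed=0)
        with pytest.raises(ValueError, match="channel"):
            seg.predict_masks(model, np.zeros((3, 64, 64), np.float32))
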