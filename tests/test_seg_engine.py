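"""ComboLoss correctness, training-loop contracts, and tile/slide inference."""

import numpy as np
import pytest

from lvipathnet.seg_engine import (
    LossWeights,
    SegModelSpec,
    TinySegNet,
    TrainConfig,
    binary_iou,
    combo_loss,
    combo_loss_grad,
    dice_loss,
    predict_slide,
    predict_tile,
    train_segmenter,
    wce,
)
from lvipathnet.types import SlidePlane


def brute_force_wce(p, y, w_fg, w_bg):
    p = np.clip(p, 1e-7, 1 - 1e-7)
    total = 0.0
    for pi, yi in zip(p.ravel(), y.ravel()):
        total += w_fg * yi * np.log(pi) + w_bg * (1 - yi) * np.log(1 - pi)
    return -total / p.size


def brute_force_dice(p, y, smooth, background=False):
    p = np.clip(p, 1e-7, 1 - 1e-7)
    if background:
        p, y = 1 - p, 1 - y
    num = 2 * float(np.sum(p * y)) + smooth
    den = float(np.sum(p) + np.sum(y)) + smooth
    return 1 - num / den


class TestWce:
    def test_perfect_prediction_is_zero(self):
        y = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert wce(y, y) == pytest.approx(0.0, abs=1e-5)

    def test_uniform_half_is_ln2(self):
        p = np.full((8, 8), 0.5)
        y = (np.arange(64).reshape(8, 8) % 2).astype(float)
        assert wce(p, y) == pytest.approx(np.log(2), rel=1e-9)

    def test_weighted_3x3_matches_hand_oracle(self, rng):
        p = rng.uniform(0.1, 0.9, (3, 3))
        y = (rng.random((3, 3)) > 0.5).astype(float)
        assert wce(p, y, (2.0, 1.0)) == pytest.approx(
            brute_force_wce(p, y, 2.0, 1.0), rel=1e-12)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            wce(np.zeros((2, 2)), np.zeros((3, 3)))


class TestDiceLoss:
    def test_perfect_prediction_near_zero(self):
        y = np.array([[1.0, 1.0], [0.0, 0.0]])
        assert dice_loss(y, y) == pytest.approx(0.0, abs=1e-5)

    def test_total_miss_approaches_one(self):
        n = 64
        p = np.ones((n, n))
        y = np.zeros((n, n))
        loss = dice_loss(p, y, "foreground", smooth=1.0)
        assert loss == pytest.approx(1 - 1 / (n * n + 1), rel=1e-4)

    @pytest.mark.parametrize("target", ["foreground", "background"])
    def test_random_8x8_matches_brute_force(self, rng, target):
        p = rng.uniform(0, 1, (8, 8))
        y = (rng.random((8, 8)) > 0.5).astype(float)
        assert dice_loss(p, y, target, smooth=1.0) == pytest.approx(
            brute_force_dice(p, y, 1.0, background=target == "background"),
            rel=1e-9)


class TestComboLoss:
    def test_perfect_prediction_is_zero(self):
        y = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert combo_loss(y, y) == pytest.approx(0.0, abs=1e-4)

    def test_printed_weights_sum_unit_components(self):
        w = LossWeights()
        assert (w.alpha, w.beta, w.gamma) == (0.5, 0.2, 0.3)
        # if each component were exactly 1, the combination would be 1.0
        assert w.alpha * 1 + w.beta * 1 + w.gamma * 1 == pytest.approx(1.0)

    def test_random_instance_composes_component_oracles(self, rng):
        p = rng.uniform(0.05, 0.95, (8, 8))
        y = (rng.random((8, 8)) > 0.6).astype(float)
        w = LossWeights(wce_class_weights=(1.5, 0.75))
        expected = (0.5 * brute_force_wce(p, y, 1.5, 0.75)
                    + 0.2 * brute_force_dice(p, y, 1.0)
                    + 0.3 * brute_force_dice(p, y, 1.0, background=True))
        assert combo_loss(p, y, w) == pytest.approx(expected, rel=1e-9)

    def test_degenerates_to_wce_and_dice(self, rng):
        p = rng.uniform(0.05, 0.95, (6, 6))
        y = (rng.random((6, 6)) > 0.5).astype(float)
        only_wce = LossWeights(alpha=1, beta=0, gamma=0)
        assert combo_loss(p, y, only_wce) == pytest.approx(wce(p, y), rel=1e-12)
        only_fg = LossWeights(alpha=0, beta=1, gamma=0)
        assert combo_loss(p, y, only_fg) == pytest.approx(
            dice_loss(p, y, "foreground"), rel=1e-12)

    def test_nonnegative_and_corruption_monotone(self, rng):
        y = (rng.random((64, 64)) > 0.7).astype(float)
        p = y.copy()
        losses = [combo_loss(p, y)]
        flat = rng.permutation(y.size)
        for k in range(10):
            p.ravel()[flat[k]] = 1.0 - p.ravel()[flat[k]]
            losses.append(combo_loss(p, y))
        assert losses[0] >= 0
        assert all(b > a for a, b in zip(losses, losses[1:]))

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(alpha=-0.1)

    def test_gradient_matches_finite_differences(self, rng):
        p = rng.uniform(0.1, 0.9, (5, 5))
        y = (rng.random((5, 5)) > 0.5).astype(float)
        w = LossWeights(wce_class_weights=(2.0, 0.5))
        g = combo_loss_grad(p, y, w)
        eps = 1e-6
        for idx in [(0, 0), (2, 3), (4, 4)]:
            p2 = p.copy()
            p2[idx] += eps
            fd = (combo_loss(p2, y, w) - combo_loss(p, y, w)) / eps
            assert g[idx] == pytest.approx(fd, rel=1e-3)


def make_disk_tile(seed, side=48):
    r = np.random.default_rng(seed)
    img = np.full((side, side, 3), 230, np.uint8)
    yy, xx = np.mgrid[0:side, 0:side]
    cy, cx = r.integers(side // 4, 3 * side // 4, 2)
    rad = r.integers(side // 8, side // 4)
    m = (yy - cy) ** 2 + (xx - cx) ** 2 <= rad**2
    img[m] = [200, 90, 140]
    return img, m.astype(float)


@pytest.fixture(scope="module")
def trained_disk_model():
    tiles = [make_disk_tile(i) for i in range(40)]
    model, history = train_segmenter(
        tiles[:30], tiles[30:], SegModelSpec(base_channels=6),
        TrainConfig(learning_rate=3e-3, max_epochs=25, lr_decay_epoch=20,
                    early_stop_patience=10, seed=1),
    )
    return model, history


class TestTrainSegmenter:
    def test_learns_high_contrast_disks(self, trained_disk_model):
        _, history = trained_disk_model
        assert max(h["val_iou"] for h in history) > 0.7

    def test_lr_decays_by_factor_at_decay_epoch(self, trained_disk_model):
        _, history = trained_disk_model
        by_epoch = {h["epoch"]: h["lr"] for h in history}
        assert by_epoch[20] == pytest.approx(0.3 * by_epoch[19])
        assert by_epoch[19] == pytest.approx(by_epoch[1])

    def test_same_seed_reproduces_first_epoch_loss(self):
        tiles = [make_disk_tile(i, side=16) for i in range(8)]
        cfg = TrainConfig(learning_rate=1e-3, max_epochs=2, lr_decay_epoch=1,
                          early_stop_patience=1, seed=3)
        _, h1 = train_segmenter(tiles[:6], tiles[6:], SegModelSpec(4), cfg)
        _, h2 = train_segmenter(tiles[:6], tiles[6:], SegModelSpec(4), cfg)
        assert h1[0]["train_loss"] == h2[0]["train_loss"]

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train_segmenter([], [], SegModelSpec(4), TrainConfig(seed=0))

    def test_default_config_matches_training_protocol(self):
        cfg = TrainConfig()
        assert cfg.learning_rate == 1e-4
        assert cfg.batch_size == 16
        assert cfg.max_epochs == 250
        assert cfg.lr_decay_factor == 0.3
        assert cfg.lr_decay_epoch == 12


class TestPredictTile:
    def test_constant_stub_unchanged_by_tta(self, rng):
        img = rng.integers(0, 256, (32, 32, 3), dtype=np.uint8)

        def stub(image):
            return np.full(image.shape[:2], 0.7)

        out_tta = predict_tile(stub, img, use_tta=True, use_reflect_pad=False)
        out_plain = predict_tile(stub, img, use_tta=False, use_reflect_pad=False)
        np.testing.assert_allclose(out_tta, out_plain)

    def test_d4_equivariant_oracle_tta_equals_plain(self, rng):
        def oracle(image):
            g = image.astype(float).mean(axis=-1)
            return g / (g.max() + 1e-9)

        img = rng.integers(0, 256, (24, 24, 3), dtype=np.uint8)
        out_tta = predict_tile(oracle, img, use_tta=True, use_reflect_pad=False)
        np.testing.assert_allclose(out_tta, oracle(img), atol=1e-12)

    def test_reflect_pad_path_returns_original_footprint(self, rng):
        img = rng.integers(0, 256, (20, 30, 3), dtype=np.uint8)

        def stub(image):
            return np.zeros(image.shape[:2])

        out = predict_tile(stub, img, use_tta=False, use_reflect_pad=True)
        assert out.shape == (20, 30)

    def test_output_in_unit_interval_from_real_model(self, rng):
        model = TinySegNet(SegModelSpec(base_channels=4), seed=0)
        img = rng.integers(0, 256, (16, 16, 3), dtype=np.uint8)
        out = predict_tile(model, img, use_tta=True, use_reflect_pad=True)
        assert out.shape == (16, 16)
        assert (out >= 0).all() and (out <= 1).all()


class TestPredictSlide:
    def test_disk_stub_recovers_disk(self):
        yy, xx = np.mgrid[0:100, 0:100]
        disk = (yy - 50) ** 2 + (xx - 50) ** 2 <= 30**2
        plane = SlidePlane(np.zeros((100, 100, 3), dtype=np.uint8), 1.0, "p")
        plane.pixels[disk] = 255

        def stub(image):
            return (image.astype(float).mean(axis=-1) > 128).astype(float)

        prob, binary = predict_slide(stub, plane, tile_size=40, overlap=0.5,
                                     use_tta=False, use_reflect_pad=False)
        assert binary_iou(binary, disk) > 0.98

    def test_overlap_irrelevant_for_constant_stub(self):
        plane = SlidePlane(np.zeros((64, 64, 3), dtype=np.uint8), 1.0, "p")

        def stub(image):
            return np.full(image.shape[:2], 0.9)

        _, m0 = predict_slide(stub, plane, 32, overlap=0.0, use_tta=False,
                              use_reflect_pad=False)
        _, m5 = predict_slide(stub, plane, 32, overlap=0.5, use_tta=False,
                              use_reflect_pad=False)
        np.testing.assert_array_equal(m0, m5)

    def test_tile_larger_than_plane_is_single_clamped_tile(self):
        plane = SlidePlane(np.zeros((30, 40, 3), dtype=np.uint8), 1.0, "p")

        def stub(image):
            return np.zeros(image.shape[:2])

        prob, binary = predict_slide(stub, plane, tile_size=64, use_tta=False,
                                     use_reflect_pad=True)
        assert prob.shape == (30, 40)
        assert not binary.any()


class TestCheckpointRoundTrip:
    def test_segnet_save_load_preserves_predictions(self, tmp_path, rng):
        model = TinySegNet(SegModelSpec(base_channels=4), seed=3)
        path = tmp_path / "seg.npz"
        model.save(path)
        loaded = TinySegNet.load(path)
        img = rng.integers(0, 256, (16, 16, 3), dtype=np.uint8)
        np.testing.assert_array_equal(model.predict_proba(img),
                                      loaded.predict_proba(img))
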