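"""Instance extraction, classifier tile preparation, ensemble, flagging."""

import numpy as np
import pytest

from lvipathnet.invasion_classifier import (
    ClsMemberSpec,
    TileVerdict,
    class_weights,
    default_min_area_px,
    ensemble_predict,
    extract_instances,
    flag_invasion,
    make_classifier_inputs,
    train_classifier_member,
)
from lvipathnet.types import SlidePlane, TileSpec


def flood_fill_count(mask):
    """Independent 8-connected component counter (iterative flood fill)."""
    mask = mask.astype(bool).copy()
    H, W = mask.shape
    count = 0
    for sy in range(H):
        for sx in range(W):
            if not mask[sy, sx]:
                continue
            count += 1
            stack = [(sy, sx)]
            mask[sy, sx] = False
            while stack:
                y, x = stack.pop()
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < H and 0 <= nx < W and mask[ny, nx]:
                            mask[ny, nx] = False
                            stack.append((ny, nx))
    return count


class TestExtractInstances:
    def test_two_disjoint_disks(self):
        mask = np.zeros((50, 50), dtype=bool)
        yy, xx = np.mgrid[0:50, 0:50]
        mask |= (yy - 12) ** 2 + (xx - 12) ** 2 <= 36
        mask |= (yy - 38) ** 2 + (xx - 38) ** 2 <= 36
        instances = extract_instances(mask)
        assert len(instances) == 2
        assert instances[0].id == 0 and instances[1].id == 1

    def test_min_area_filter_drops_small_component(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[2:6, 2:7] = True  # 20 px
        assert extract_instances(mask, min_area_px=50) == []
        assert len(extract_instances(mask, min_area_px=20)) == 1

    def test_empty_mask_empty_list(self):
        assert extract_instances(np.zeros((8, 8), dtype=bool)) == []

    def test_count_matches_flood_fill_oracle(self, rng):
        mask = rng.random((40, 40)) > 0.72
        assert len(extract_instances(mask)) == flood_fill_count(mask)

    def test_diagonal_pixels_are_connected(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, 0] = mask[1, 1] = mask[2, 2] = True
        assert len(extract_instances(mask)) == 1

    def test_ids_row_major_by_first_pixel(self, rng):
        mask = rng.random((30, 30)) > 0.8
        instances = extract_instances(mask)
        firsts = []
        for inst in instances:
            x, y, w, h = inst.bbox
            ys, xs = np.nonzero(inst.mask)
            order = np.lexsort((xs, ys))
            firsts.append(((ys[order[0]] + y) * 30 + xs[order[0]] + x))
        assert firsts == sorted(firsts)


def one_instance(mask):
    (inst,) = extract_instances(mask)
    return inst


class TestMakeClassifierInputs:
    def plane(self, side=600, mpp=0.5):
        return SlidePlane(
            np.random.default_rng(0).integers(0, 256, (side, side, 3), dtype=np.uint8),
            mpp=mpp, name="p")

    def test_capillary_single_tile_resized(self):
        plane = self.plane(mpp=0.5)  # tile = 256 px
        mask = np.zeros((600, 600), dtype=bool)
        yy, xx = np.mgrid[0:600, 0:600]
        mask |= (yy - 300) ** 2 + (xx - 300) ** 2 <= 30**2
        tiles = make_classifier_inputs(one_instance(mask), plane)
        assert len(tiles) == 1
        spec, img = tiles[0]
        assert (spec.w, spec.h) == (256, 256)
        assert img.shape == (224, 224, 3)
        assert img.dtype == np.uint8

    def test_candidate_grid_is_bbox_ceil_division(self):
        plane = self.plane(side=900, mpp=0.5)  # cell 256
        mask = np.zeros((900, 900), dtype=bool)
        mask[100:400, 100:800] = True  # bbox 700 x 300 -> 3 x 2 grid
        tiles = make_classifier_inputs(one_instance(mask), plane,
                                       min_mask_fraction=1e-9)
        assert len(tiles) == 6

    def test_kept_tiles_superset_of_center_in_mask(self):
        plane = self.plane(side=520, mpp=1.0)  # cell 128
        yy, xx = np.mgrid[0:520, 0:520]
        mask = ((yy - 250) ** 2 / 4 + (xx - 250) ** 2) <= 120**2
        inst = one_instance(mask)
        kept = {(s.x, s.y) for s, _ in
                make_classifier_inputs(inst, plane, min_mask_fraction=1e-9)}
        x0, y0, w, h = inst.bbox
        cell = 128
        for gy in range((h + cell - 1) // cell):
            for gx in range((w + cell - 1) // cell):
                cy, cx = y0 + gy * cell + cell // 2, x0 + gx * cell + cell // 2
                if 0 <= cy < 520 and 0 <= cx < 520 and mask[cy, cx]:
                    tx = min(max(x0 + gx * cell, 0), 520 - cell)
                    ty = min(max(y0 + gy * cell, 0), 520 - cell)
                    assert (tx, ty) in kept

    def test_tiles_cover_instance_mask(self):
        plane = self.plane(side=520, mpp=1.0)
        yy, xx = np.mgrid[0:520, 0:520]
        mask = ((yy - 250) ** 2 / 4 + (xx - 250) ** 2) <= 110**2
        inst = one_instance(mask)
        tiles = make_classifier_inputs(inst, plane, min_mask_fraction=1e-9)
        cover = np.zeros((520, 520), dtype=bool)
        for s, _ in tiles:
            cover[s.y : s.y + s.h, s.x : s.x + s.w] = True
        assert (cover | ~mask).all()

    def test_background_masked_to_white(self):
        plane = SlidePlane(np.zeros((300, 300, 3), dtype=np.uint8), 1.0, "p")
        mask = np.zeros((300, 300), dtype=bool)
        mask[100:140, 100:140] = True
        (spec, img), = make_classifier_inputs(one_instance(mask), plane)
        # plane is black; masked background must be white, vessel black
        assert img.max() == 255 and img.min() == 0

    def test_missing_mpp_rejected(self):
        plane = self.plane()
        plane.mpp = 0
        mask = np.zeros((600, 600), dtype=bool)
        mask[10:20, 10:20] = True
        with pytest.raises(ValueError):
            make_classifier_inputs(one_instance(mask), plane)

    def test_default_min_area_is_smallest_caliber_disk(self):
        assert default_min_area_px(0.5) == round(np.pi * 10**2)
        assert default_min_area_px(2.0) == round(np.pi * 2.5**2)


class TestClassWeights:
    def test_study_tile_counts_inverse_frequency(self):
        labels = [1] * 493 + [0] * 1029
        w0, w1 = class_weights(labels)
        assert w0 + w1 == pytest.approx(1.0)
        assert w1 / w0 == pytest.approx(1029 / 493, rel=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            class_weights([1, 1, 1])


def blob_tile(positive, seed, side=32):
    r = np.random.default_rng(seed)
    img = np.full((side, side, 3), 235, np.uint8)
    img += r.integers(0, 8, img.shape).astype(np.uint8)
    if positive:
        cy, cx = r.integers(side // 4, 3 * side // 4, 2)
        img[cy - 3 : cy + 3, cx - 3 : cx + 3] = [80, 50, 120]
    return img


class TestTrainClassifierMember:
    def test_learns_linearly_separable_blobs(self):
        tiles = [blob_tile(i % 2 == 0, i) for i in range(60)]
        labels = [int(i % 2 == 0) for i in range(60)]
        spec = ClsMemberSpec("t", base_channels=6, depth=2, input_px=32)
        model = train_classifier_member(tiles[:40], labels[:40], spec,
                                        epochs=20, seed=0,
                                        val_tiles=tiles[40:], val_labels=labels[40:])
        preds = [model.predict_proba(t) >= 0.5 for t in tiles[40:]]
        acc = np.mean([p == l for p, l in zip(preds, labels[40:])])
        assert acc > 0.95

    def test_single_class_rejected(self):
        tiles = [blob_tile(True, i) for i in range(4)]
        with pytest.raises(ValueError):
            train_classifier_member(tiles, [1, 1, 1, 1], epochs=1)

    def test_seeded_determinism(self):
        tiles = [blob_tile(i % 2 == 0, i, side=16) for i in range(8)]
        labels = [int(i % 2 == 0) for i in range(8)]
        spec = ClsMemberSpec("t", base_channels=4, depth=2, input_px=16)
        m1 = train_classifier_member(tiles, labels, spec, epochs=2, seed=5)
        m2 = train_classifier_member(tiles, labels, spec, epochs=2, seed=5)
        for a, b in zip(m1.get_state(), m2.get_state()):
            np.testing.assert_array_equal(a, b)


class TestEnsemblePredict:
    def test_mean_of_member_probabilities(self):
        members = [lambda img: 0.2, lambda img: 0.4, lambda img: 0.9]
        assert ensemble_predict(members, None) == pytest.approx(0.5)

    def test_single_member_identity(self):
        assert ensemble_predict([lambda img: 0.73], None) == pytest.approx(0.73)

    def test_permutation_invariant_and_bounded(self, rng):
        vals = rng.random(5)
        members = [(lambda v: lambda img: float(v))(v) for v in vals]
        p1 = ensemble_predict(members, None)
        p2 = ensemble_predict(members[::-1], None)
        assert p1 == pytest.approx(p2)
        assert vals.min() <= p1 <= vals.max()

    def test_ensemble_beats_worst_member_on_noisy_stubs(self, rng):
        # stubs around truth 0.5 +/- noise: mean has lower error than members
        truth = 0.5
        n = 1000
        noises = [rng.normal(0, 0.2, n), rng.normal(0, 0.2, n), rng.normal(0, 0.2, n)]
        preds = [np.clip(truth + e, 0, 1) for e in noises]
        ens = np.mean(preds, axis=0)
        ens_err = np.mean((ens - truth) ** 2)
        member_errs = [np.mean((p - truth) ** 2) for p in preds]
        assert ens_err <= min(member_errs)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            ensemble_predict([], None)


class TestFlagInvasion:
    def make_instances(self, n):
        out = []
        for i in range(n):
            mask = np.ones((3, 3), dtype=bool)
            from lvipathnet.invasion_classifier import VesselInstance

            out.append(VesselInstance(id=i, bbox=(i * 10, 0, 3, 3),
                                      area_px=9, mask=mask))
        return out

    def verdict(self, iid, prob):
        return TileVerdict(iid, TileSpec(0, 0, 4, 4), (prob,), prob)

    def test_all_below_threshold_zero_invasive(self):
        insts = self.make_instances(2)
        verdicts = [self.verdict(0, 0.2), self.verdict(1, 0.4)]
        _, summary = flag_invasion(insts, verdicts)
        assert summary["n_invasive"] == 0

    def test_any_tile_rule(self):
        insts = self.make_instances(1)
        verdicts = [self.verdict(0, 0.1)] * 10 + [self.verdict(0, 0.99)]
        flagged, summary = flag_invasion(insts, verdicts)
        assert flagged[0].verdict == "invasive"
        assert summary["n_invasive"] == 1
        assert summary["max_prob_by_instance"][0] == pytest.approx(0.99)

    def test_orphan_verdict_rejected(self):
        insts = self.make_instances(1)
        with pytest.raises(ValueError):
            flag_invasion(insts, [self.verdict(7, 0.5)])

    def test_verdict_label_follows_threshold(self):
        v = TileVerdict(0, TileSpec(0, 0, 4, 4), (0.6,), 0.6, threshold=0.5)
        assert v.label == "invasive_or_displacement"
        v2 = TileVerdict(0, TileSpec(0, 0, 4, 4), (0.4,), 0.4, threshold=0.5)
        assert v2.label == "clean"


class TestMemberCheckpointRoundTrip:
    def test_save_load_preserves_probability(self, tmp_path, rng):
        from lvipathnet.invasion_classifier import TinyClassifier

        spec = ClsMemberSpec("rt", base_channels=4, depth=2, input_px=16)
        model = TinyClassifier(spec, seed=2)
        path = tmp_path / "member.npz"
        model.save(path)
        loaded = TinyClassifier.load(path)
        img = rng.integers(0, 256, (16, 16, 3), dtype=np.uint8)
        assert loaded.predict_proba(img) == model.predict_proba(img)
        assert loaded.spec == spec
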