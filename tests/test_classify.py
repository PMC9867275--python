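"""Classification tests: preprocessing stage contracts, augmentation
semantics, CNN training/prediction, and the HOG+SVM auto-labeler."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skimage import color as skcolor
from skimage import transform as sktransform

import segdigit as sd
from segdigit.classify import _extract_crops

RNG = np.random.default_rng(77)


class TestPadSquare:
    def test_landscape_margins(self):
        out = sd.pad_square(np.ones((20, 30)))
        assert out.shape == (30, 30)
        assert not out[:5].any() and not out[-5:].any()
        assert out[5:25].all()

    def test_square_unchanged(self):
        img = RNG.random((7, 7))
        assert np.array_equal(sd.pad_square(img), img)

    def test_odd_remainder_goes_bottom(self):
        out = sd.pad_square(np.ones((3, 6)))
        assert out.shape == (6, 6)
        assert not out[0].any()          # 1 row on top
        assert out[1:4].all()
        assert not out[4:].any()         # 2 rows on bottom

    @pytest.mark.parametrize("i,j", [(1, 9), (9, 1), (4, 4), (5, 8)])
    def test_source_pixels_preserved(self, i, j):
        img = RNG.random((i, j))
        out = sd.pad_square(img)
        side = max(i, j)
        top, left = (side - i) // 2, (side - j) // 2
        assert np.array_equal(out[top : top + i, left : left + j], img)
        assert out.sum() == pytest.approx(img.sum())

    def test_empty_crop_rejected(self):
        with pytest.raises(ValueError):
            sd.pad_square(np.zeros((0, 3)))


class TestComplementBinary:
    def test_all_ones_to_zeros(self):
        assert not sd.complement_binary(np.ones((3, 3))).any()

    def test_elementwise_example(self):
        out = sd.complement_binary(np.array([[0, 1], [1, 0]]))
        assert out.tolist() == [[1, 0], [0, 1]]

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_involution(self, seed):
        img = (np.random.default_rng(seed).random((6, 6)) < 0.5).astype(int)
        assert np.array_equal(sd.complement_binary(sd.complement_binary(img)), img)

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            sd.complement_binary(np.array([[0.5]]))


class TestToModelInput:
    def test_no_op_resize_channels_equal_input(self):
        img = RNG.random((8, 8))
        out = sd.to_model_input(img, 8)
        for c in range(3):
            assert np.array_equal(out[..., c], img)

    def test_three_identical_channels(self):
        out = sd.to_model_input(RNG.random((5, 5)), 12)
        assert np.array_equal(out[..., 0], out[..., 1])
        assert np.array_equal(out[..., 1], out[..., 2])

    def test_nearest_neighbor_block_replication(self):
        checker = np.array([[1.0, 0.0], [0.0, 1.0]])
        out = sd.to_model_input(checker, 4, order=0)
        expected = np.kron(checker, np.ones((2, 2)))
        assert np.array_equal(out[..., 0], expected)

    def test_invalid_side_rejected(self):
        with pytest.raises(ValueError):
            sd.to_model_input(np.ones((4, 4)), 0)
        with pytest.raises(ValueError):
            sd.to_model_input(np.ones((4, 5)), 8)


class TestPreprocessROI:
    def test_bright_glyph_is_complemented(self):
        # bright glyph on dark field -> after complement: dark glyph, bright field
        frame = np.zeros((20, 20, 3), dtype=np.uint8)
        frame[5:15, 8:12] = 255
        out = sd.preprocess_roi(frame, sd.BBox(6, 3, 10, 14), 16)
        assert out[..., 0].max() == 1.0
        # glyph interior became 0, surrounding field became 1
        assert out[8, 8, 0] < 0.5

    def test_degenerate_single_pixel_box(self):
        frame = np.full((10, 10, 3), 200, dtype=np.uint8)
        out = sd.preprocess_roi(frame, sd.BBox(4, 4, 1, 1), 8)
        assert out.shape == (8, 8, 3)
        assert np.unique(out).tolist() == [0.0]

    def test_out_of_frame_box_rejected(self):
        frame = np.zeros((10, 10, 3), dtype=np.uint8)
        with pytest.raises(ValueError):
            sd.preprocess_roi(frame, sd.BBox(8, 8, 4, 4), 8)

    def test_equals_stage_composition(self, clean_frame):
        """The fused path must equal composing the stages independently."""
        frame, gt = clean_frame
        box = gt.boxes[0].bbox
        crop = frame[box.y : box.y + box.height, box.x : box.x + box.width]
        gray = skcolor.rgb2gray(crop)
        binary = (gray > 0.5).astype(float)
        comp = np.abs(binary - 1)
        i, j = comp.shape
        side = max(i, j)
        sq = np.zeros((side, side))
        top, left = (side - i) // 2, (side - j) // 2
        sq[top : top + i, left : left + j] = comp
        res = sktransform.resize(sq, (32, 32), order=1, anti_aliasing=True, preserve_range=True)
        expected = np.stack([res] * 3, axis=-1)
        assert np.allclose(sd.preprocess_roi(frame, box, 32), expected)


class TestAugmentation:
    def test_replication_factor_multiplies_crops(self, clean_scene):
        train, _ = sd.make_dataset(5, 0, clean_scene, seed=1)
        out = sd.augment_dataset(train, sd.AugmentationConfig(replication_factor=10))
        assert len(out) == 50
        assert sum(out.label_histogram().values()) == 10 * sum(train.label_histogram().values())

    def test_identity_scaling_is_pixel_identical(self, clean_scene):
        train, _ = sd.make_dataset(3, 0, clean_scene, seed=1)
        out = sd.augment_dataset(train, sd.AugmentationConfig(2, (1.0, 1.0)), seed=4)
        for k, (frame, gt) in enumerate(out.frames):
            src_frame, src_gt = train.frames[k % 3]
            assert np.array_equal(frame, src_frame)
            assert [b.bbox for b in gt.boxes] == [b.bbox for b in src_gt.boxes]

    def test_seeded_determinism(self, clean_scene):
        train, _ = sd.make_dataset(3, 0, clean_scene, seed=1)
        cfg = sd.AugmentationConfig(3, (0.9, 1.0))
        a = sd.augment_dataset(train, cfg, seed=9)
        b = sd.augment_dataset(train, cfg, seed=9)
        for (fa, _), (fb, _) in zip(a.frames, b.frames):
            assert np.array_equal(fa, fb)

    def test_labels_preserved_boxes_shrunk(self, clean_scene):
        train, _ = sd.make_dataset(3, 0, clean_scene, seed=1)
        out = sd.augment_dataset(train, sd.AugmentationConfig(1, (0.9, 0.9)), seed=0)
        for (frame, gt), (_, src_gt) in zip(out.frames, train.frames):
            for new, old in zip(gt.boxes, src_gt.boxes):
                assert new.label == old.label
                assert new.bbox.area < old.bbox.area
                assert old.bbox.contains(new.bbox)

    def test_bad_factor_rejected(self):
        with pytest.raises(ValueError):
            sd.AugmentationConfig(replication_factor=0)


@pytest.fixture(scope="module")
def crop_model():
    """CNN trained on 10 noise-free crops per class (10 snapshots of a
    10-digit display), augmented x10."""
    tmpl = sd.default_scene(n_digits=10, glyph_height=48, spacing=60)
    train, _ = sd.make_dataset(10, 0, tmpl, seed=13)
    assert all(v == 10 for v in train.label_histogram().values())
    model = sd.train_classifier(
        train, aug=sd.AugmentationConfig(10, (0.9, 1.0)), tc=sd.TrainConfig(seed=13)
    )
    return train, model


class TestTrainPredict:
    def test_heldout_crop_accuracy(self, crop_model):
        _, model = crop_model
        tmpl = sd.default_scene(n_digits=10, glyph_height=48, spacing=60,
                                scale_jitter=(0.95, 1.05))
        _, test = sd.make_dataset(0, 20, tmpl, seed=99)
        ok = tot = 0
        for frame, gt in test.frames:
            for box in gt.boxes:
                label, _ = sd.predict_digit(model, sd.preprocess_roi(frame, box.bbox, 32))
                ok += label == box.label
                tot += 1
        assert tot == 200
        assert ok / tot >= 0.99

    def test_scores_are_probabilities(self, crop_model):
        _, model = crop_model
        x = RNG.random((4, 3, 32, 32))
        probs = model.predict_proba(x)
        assert probs.shape == (4, 10)
        assert (probs >= 0).all()
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_constant_input_has_pigeonhole_score(self, crop_model):
        _, model = crop_model
        label, score = sd.predict_digit(model, np.zeros((32, 32, 3)))
        assert 0 <= label <= 9
        assert score >= 0.1

    def test_score_is_max_probability(self, crop_model):
        _, model = crop_model
        x = RNG.random((32, 32, 1)).repeat(3, axis=2)
        label, score = sd.predict_digit(model, x)
        probs = model.predict_proba(x.transpose(2, 0, 1)[None])[0]
        assert label == probs.argmax()
        assert score == pytest.approx(probs.max())

    def test_seeded_training_is_deterministic(self, clean_scene):
        train, _ = sd.make_dataset(10, 0, clean_scene, seed=3)
        tc = sd.TrainConfig(seed=5, max_epochs=4)
        m1 = sd.train_classifier(train, aug=None, tc=tc)
        m2 = sd.train_classifier(train, aug=None, tc=tc)
        x = np.random.default_rng(0).random((8, 3, 32, 32))
        assert np.array_equal(m1.forward(x).argmax(axis=1), m2.forward(x).argmax(axis=1))

    def test_missing_class_rejected(self, clean_scene):
        train, _ = sd.make_dataset(2, 0, clean_scene, seed=3)  # only 8 crops
        with pytest.raises(ValueError, match="misses"):
            sd.train_classifier(train, aug=None, tc=sd.TrainConfig(max_epochs=1))

    def test_wrong_input_size_rejected(self, crop_model):
        _, model = crop_model
        with pytest.raises(ValueError):
            sd.predict_digit(model, np.zeros((16, 16, 3)))

    def test_checkpoint_roundtrip(self, crop_model, tmp_path):
        _, model = crop_model
        model.save(tmp_path / "model.npz")
        loaded = sd.CompactCNN.load(tmp_path / "model.npz")
        x = np.random.default_rng(1).random((4, 3, 32, 32))
        assert np.allclose(model.predict_proba(x), loaded.predict_proba(x))


class TestAutoLabeler:
    def test_training_set_accuracy_perfect(self, crop_model):
        train, _ = crop_model
        labeler = sd.train_autolabeler(train)
        X, y = _extract_crops(train, 32)
        preds = [labeler.predict(x.transpose(1, 2, 0)) for x in X]
        assert (np.asarray(preds) == y).all()

    def test_descriptor_deterministic(self, crop_model):
        train, _ = crop_model
        labeler = sd.train_autolabeler(train)
        x = RNG.random((32, 32, 3))
        assert np.array_equal(labeler.describe(x), labeler.describe(x.copy()))

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            sd.train_autolabeler(sd.Dataset([]))

    def test_auto_label_stream(self, crop_model, clean_scene):
        train, _ = crop_model
        labeler = sd.train_autolabeler(train)
        anchors = sd.derive_anchors(train, per_class=True)
        cfg = sd.LocalizationConfig(hsv=sd.DEFAULT_FG_HSV_RANGE, anchors=anchors)

        # a digit-free frame yields zero proposals
        blank = sd.render_frame(sd.SceneSpec(frame_size=(60, 80), digits=[]))[0]
        (empty,) = sd.auto_label(labeler, [blank], cfg)
        assert empty.boxes == [] and not empty.validated

        # clean synthetic stream: proposed labels match ground truth >= 95%
        tmpl = sd.default_scene(n_digits=10, glyph_height=48, spacing=60)
        _, test = sd.make_dataset(0, 10, tmpl, seed=21)
        proposals = sd.auto_label(labeler, [f for f, _ in test.frames], cfg)
        ok = tot = 0
        for prop, (_, gt) in zip(proposals, test.frames):
            assert not prop.validated
            for pbox in prop.boxes:
                match = max(gt.boxes, key=lambda g: sd.iou(g.bbox, pbox.bbox))
                ok += pbox.label == match.label
                tot += 1
        assert tot >= 90
        assert ok / tot >= 0.95
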