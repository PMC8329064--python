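"""Segmentation: preprocessing, model contracts, training, evaluation."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gbmregio as g
from gbmregio.segmentation import (_T, _backward, _concat, _conv2d, _maxpool2,
                                   _relu, _softmax_ce, _upsample2,
                                   ConfusionCounts)


def _slide(size=64, seed=0, labels=4):
    p = g.SlideLayoutParams(image_size=size, seed=seed,
                            necrosis_blob_count=0 if labels <= 4 else 2,
                            mvp_blob_count=0 if labels <= 4 else 2)
    return g.generate_tissue_slide(p)


class TestResizePair:
    def test_identity_size_is_byte_identical(self):
        sl = _slide(64)
        out = g.resize_pair(sl, 64)
        assert np.array_equal(out.mask, sl.mask)
        assert np.array_equal(out.image, sl.image)

    def test_mask_labels_never_blended(self):
        sl = _slide(128, labels=8)
        src_labels = set(np.unique(sl.mask))
        out = g.resize_pair(sl, 64)
        assert set(np.unique(out.mask)) <= src_labels

    def test_checkerboard_downsize_picks_source_block_labels(self):
        # checkerboard of 2x2 blocks with labels {0, 3}
        mask = (((np.arange(64)[:, None] // 2) +
                 (np.arange(64)[None, :] // 2)) % 2 * 3).astype(np.uint8)
        sl = g.LabeledSlide(np.zeros((64, 64, 3), dtype=np.uint8), mask)
        out = g.resize_pair(sl, 32)
        # each output pixel maps to a 2x2 source block of a single label
        for y in range(0, 32, 7):
            for x in range(0, 32, 7):
                src_block = mask[2 * y:2 * y + 2, 2 * x:2 * x + 2]
                assert out.mask[y, x] in src_block

    def test_non_square_target_rejected(self):
        with pytest.raises(ValueError):
            g.resize_pair(_slide(64), (64, 32))


class TestPatches:
    def test_even_tiling_grid(self):
        sl = _slide(64)
        pset = g.extract_patches(sl, 32)
        assert len(pset) == 4
        assert [(r, c) for _, _, r, c in pset.patches] == [
            (0, 0), (0, 1), (1, 0), (1, 1)]
        assert pset.padding_mode == "none"

    def test_uneven_size_reflection_padded(self):
        img = np.random.default_rng(0).integers(
            0, 255, size=(100, 100, 3)).astype(np.uint8)
        pset = g.extract_patches(img, 64)
        assert pset.padded_size == (128, 128)
        assert len(pset) == 4
        assert pset.padding_mode == "reflect"

    def test_round_trip_is_pixel_exact(self):
        sl = _slide(96, labels=8)
        img, msk = g.stitch_patches(g.extract_patches(sl, 32))
        assert np.array_equal(img, sl.image)
        assert np.array_equal(msk, sl.mask)

    @settings(max_examples=40, deadline=None)
    @given(size=st.integers(33, 120), patch=st.integers(16, 64),
           stride_frac=st.integers(1, 4))
    def test_round_trip_property_random_sizes_and_strides(self, size, patch,
                                                          stride_frac):
        if patch > 2 * size - 2:
            return
        stride = max(1, patch // stride_frac)
        rng = np.random.default_rng(size * 1000 + patch)
        img = rng.integers(0, 255, size=(size, size, 3)).astype(np.uint8)
        msk = rng.integers(0, 8, size=(size, size)).astype(np.uint8)
        sl = g.LabeledSlide(img, msk)
        out_img, out_msk = g.stitch_patches(
            g.extract_patches(sl, patch, stride))
        assert np.array_equal(out_img, img)
        assert np.array_equal(out_msk, msk)

    @pytest.mark.parametrize("value,expected",
                             [(255, 1.0), (0, 0.0), (128, 128 / 255)])
    def test_normalization_maps_8bit_to_unit_interval(self, value, expected):
        img = np.full((32, 32, 3), value, dtype=np.uint8)
        pset = g.extract_patches(g.LabeledSlide(
            img, np.zeros((32, 32), dtype=np.uint8)), 32)
        out = g.normalize_patches(pset)
        assert out.patches[0][0].max() == pytest.approx(expected)
        assert out.patches[0][0].min() == pytest.approx(expected)


class TestAugment:
    def test_no_flip_full_crop_is_identity(self):
        sl = _slide(64)
        it, mt = g.augment(sl.image, sl.mask, seed=1, flip_prob=0.0)
        assert np.array_equal(it, sl.image)
        assert np.array_equal(mt, sl.mask)

    def test_vertical_flip_is_involution(self):
        sl = _slide(64)
        flipped_i, flipped_m = sl.image[::-1], sl.mask[::-1]
        it, mt = g.augment(flipped_i, flipped_m, seed=0, flip_prob=1.0)
        it2, mt2 = g.augment(it, mt, seed=0, flip_prob=1.0)
        assert np.array_equal(it2, flipped_i)
        assert np.array_equal(mt2, flipped_m)

    def test_seeded_determinism(self):
        sl = _slide(64)
        a = g.augment(sl.image, sl.mask, seed=7, crop_size=32)
        b = g.augment(sl.image, sl.mask, seed=7, crop_size=32)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_image_and_mask_get_same_transform(self):
        # encode position in both image and mask; they must stay aligned
        coord = np.arange(64 * 64).reshape(64, 64)
        img = np.stack([coord % 251] * 3, axis=-1).astype(np.uint8)
        msk = (coord % 251).astype(np.uint8)
        it, mt = g.augment(img, msk, seed=3, crop_size=32, flip_prob=1.0)
        assert np.array_equal(it[..., 0], mt)


class TestModel:
    def test_probabilities_sum_to_one(self):
        model = g.build_model(dataclasses.replace(g.DESK_PRESET, seed=1))
        x = np.random.default_rng(0).random((1, 16, 16, 3), dtype=np.float32)
        proba = model.predict_proba(x)
        assert proba.shape == (1, 16, 16, 8)
        assert np.allclose(proba.sum(-1), 1.0, atol=1e-6)

    def test_doubling_growth_rate_increases_parameter_count(self):
        small = g.build_model(dataclasses.replace(g.DESK_PRESET, growth_rate=8))
        big = g.build_model(dataclasses.replace(g.DESK_PRESET, growth_rate=16))
        assert big.param_count > small.param_count

    def test_desk_preset_parameter_count_matches_closed_form(self):
        # hand-derived from the layout rules: first conv 3->16; two down
        # blocks of two 3x3 convs emitting 8 channels each; 1x1 transitions;
        # bottleneck of two layers; up path with 3x3 compression to 32 and
        # two-layer blocks; final 1x1 conv to 8 classes
        def conv(k, cin, cout):
            return k * k * cin * cout + cout

        expected = conv(3, 3, 16)
        c = 16
        skips = []
        for _ in range(2):                      # down blocks
            for j in range(2):
                expected += conv(3, c + j * 8, 8)
            c += 16
            skips.append(c)
            expected += conv(1, c, c)           # transition down
        for j in range(2):                      # bottleneck
            expected += conv(3, c + j * 8, 8)
        c += 16
        for skip in reversed(skips):            # up path
            expected += conv(3, c + skip, 32)
            for j in range(2):
                expected += conv(3, 32 + j * 8, 8)
            c = 32 + 16
        expected += conv(1, c, 8)
        model = g.build_model(g.DESK_PRESET)
        assert model.param_count == expected

    def test_paper_scale_layout_is_expressible(self):
        model = g.build_model(g.PAPER_PRESET)
        # 103-layer layout: large but finite; forward shape check at min size
        x = np.zeros((1, 32, 32, 3), dtype=np.float32)
        assert model.predict_proba(x).shape == (1, 32, 32, 8)

    def test_spatial_collapse_raises(self):
        cfg = dataclasses.replace(g.DESK_PRESET, dense_blocks_down=5)
        model = g.build_model(cfg)
        with pytest.raises(ValueError):
            model.forward(np.zeros((1, 16, 16, 3), dtype=np.float32))

    def test_save_load_round_trip(self, tmp_path):
        model = g.build_model(dataclasses.replace(g.DESK_PRESET, seed=3))
        x = np.random.default_rng(1).random((1, 16, 16, 3), dtype=np.float32)
        before = model.predict_proba(x)
        model.save(tmp_path / "m.zip")
        loaded = g.SegModel.load(tmp_path / "m.zip")
        assert np.array_equal(loaded.predict_proba(x), before)


class TestAutodiff:
    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(1, 8, 8, 3))
        w1 = rng.normal(size=(3, 3, 3, 4)) * 0.3
        b1 = np.zeros(4)
        w2 = rng.normal(size=(1, 1, 7, 5)) * 0.3
        b2 = np.zeros(5)
        labels = rng.integers(0, 5, size=(1, 8, 8))

        def loss(w1v, b1v, w2v, b2v, xv):
            t = [_T(a) for a in (xv, w1v, b1v, w2v, b2v)]
            h = _relu(_conv2d(t[0], t[1], t[2]))
            z = _conv2d(_upsample2(_maxpool2(_concat([t[0], h]))), t[3], t[4])
            return _softmax_ce(z, labels), t

        L, tensors = loss(w1, b1, w2, b2, x)
        _backward(L)
        eps = 1e-6
        args = {"x": x, "w1": w1, "b1": b1, "w2": w2, "b2": b2}
        for name, t in zip(args, tensors):
            for _ in range(3):
                idx = tuple(rng.integers(0, s) for s in args[name].shape)
                pert = {k: v.copy() for k, v in args.items()}
                pert[name][idx] += eps
                Lp, _ = loss(pert["w1"], pert["b1"], pert["w2"], pert["b2"],
                             pert["x"])
                pert[name][idx] -= 2 * eps
                Lm, _ = loss(pert["w1"], pert["b1"], pert["w2"], pert["b2"],
                             pert["x"])
                fd = (float(Lp.data) - float(Lm.data)) / (2 * eps)
                assert t.grad[idx] == pytest.approx(fd, abs=1e-7, rel=1e-4)


class TestTraining:
    def test_single_class_dataset_reaches_perfect_accuracy(self):
        rng = np.random.default_rng(0)
        tiles = [(rng.random((16, 16, 3), dtype=np.float32),
                  np.full((16, 16), 3, dtype=np.int64)) for _ in range(4)]
        cfg = dataclasses.replace(g.DESK_PRESET, epochs=5, seed=0)
        model = g.build_model(cfg)
        _, hist = g.train(model, tiles, tiles, cfg)
        assert hist["val_accuracy"][-1] == 1.0

    def test_zero_learning_rate_freezes_parameters(self):
        rng = np.random.default_rng(0)
        tiles = [(rng.random((16, 16, 3), dtype=np.float32),
                  rng.integers(0, 8, (16, 16))) for _ in range(2)]
        cfg = dataclasses.replace(g.DESK_PRESET, epochs=3, learning_rate=0.0,
                                  seed=0)
        model = g.build_model(cfg)
        before = {k: t.data.copy() for k, t in model.params.items()}
        _, hist = g.train(model, tiles, tiles, cfg)
        for k, t in model.params.items():
            assert np.array_equal(t.data, before[k])
        assert len(set(np.round(hist["train_loss"], 10))) == 1

    def test_empty_training_set_rejected(self):
        model = g.build_model(g.DESK_PRESET)
        with pytest.raises(ValueError):
            g.train(model, [], [], g.DESK_PRESET)

    def test_training_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        tiles = [(rng.random((16, 16, 3), dtype=np.float32),
                  rng.integers(0, 4, (16, 16))) for _ in range(4)]
        cfg = dataclasses.replace(g.DESK_PRESET, epochs=3, seed=9)
        hists = []
        for _ in range(2):
            model = g.build_model(cfg)
            _, hist = g.train(model, tiles[:3], tiles[3:], cfg)
            hists.append(hist)
        assert hists[0] == hists[1]

    def test_search_ranks_fitting_config_first(self, texture_tiles):
        tiles = [(it[:32, :32], mt[:32, :32]) for it, mt in texture_tiles[:6]]
        table = g.hyperparameter_search(
            {"learning_rate": [0.0, 1.5e-3]}, n_trials=2, seed=4,
            train_set=tiles[:4], val_set=tiles[4:],
            base_config=dataclasses.replace(g.DESK_PRESET, epochs=3))
        assert len(table) == 2
        assert table.loc[0, "learning_rate"] == 1.5e-3

    def test_search_validates_inputs(self):
        with pytest.raises(ValueError):
            g.hyperparameter_search({}, 1, 0)
        with pytest.raises(ValueError):
            g.hyperparameter_search({"epochs": [2]}, 0, 0)


class TestEvaluation:
    def test_perfect_and_half_agreement(self):
        m = np.zeros((10, 10), dtype=np.uint8)
        acc, _ = g.pixel_accuracy(m, m)
        assert acc == 1.0
        m2 = m.copy()
        m2[:5] = 1
        acc, _ = g.pixel_accuracy(m2, m)
        assert acc == 0.5

    def test_hand_counted_toy_masks(self):
        gt = np.array([[0, 1, 2, 3]] * 4, dtype=np.uint8)
        pred = gt.copy()
        pred[0, 0], pred[1, 1], pred[2, 2] = 5, 6, 7
        acc, counts = g.pixel_accuracy(pred, gt)
        assert acc == pytest.approx(13 / 16)
        tp, tn, fp, fn = counts.pooled
        assert tp + tn + fp + fn == 8 * 16
        assert (tp + tn) / (tp + tn + fp + fn) == pytest.approx(
            1 - 2 * 3 / (8 * 16))  # each error hits one FP and one FN class

    def test_micro_pooled_counts_equal_global_accuracy(self):
        rng = np.random.default_rng(3)
        pred = rng.integers(0, 8, (32, 32))
        gt = rng.integers(0, 8, (32, 32))
        acc, counts = g.pixel_accuracy(pred, gt)
        # accuracy from pooled counts differs from the plain fraction: the
        # pooled ratio counts every correct pixel once as TP and 7x as TN
        tp = counts.tp.sum()
        assert tp / gt.size == pytest.approx(acc)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            g.pixel_accuracy(np.zeros((4, 4)), np.zeros((5, 5)))

    def test_predict_mask_constant_model_and_determinism(self, texture_tiles):
        cfg = dataclasses.replace(g.DESK_PRESET, epochs=1, seed=2)
        model = g.build_model(cfg)
        sl = _slide(64)
        a = g.predict_mask(model, sl, patch_size=32)
        b = g.predict_mask(model, sl, patch_size=32)
        assert a.shape == sl.mask.shape
        assert np.array_equal(a, b)
        assert a.max() <= 7

    def test_review_report_flags_the_aberrant_mask(self):
        rng = np.random.default_rng(0)
        priors = {"CT": (0.5, 0.02), "BG": (0.5, 0.02)}
        masks = {}
        for i in range(10):
            m = np.zeros((20, 20), dtype=np.uint8)
            m[:10] = 3                       # half CT, half BG
            masks[f"m{i}"] = m
        bad = np.full((20, 20), 4, dtype=np.uint8)   # 5-sigma CTmvp excess
        bad[:10] = 3
        masks["bad"] = bad
        table, text = g.review_report(masks, priors, z_threshold=3.0)
        flagged = set(table.loc[table.flagged, "mask"])
        assert flagged == {"bad"}
        assert "bad" in text

    def test_review_report_matching_priors_no_flags(self):
        m = np.zeros((10, 10), dtype=np.uint8)
        m[:5] = 3
        table, _ = g.review_report([m], {"CT": (0.5, 0.1), "BG": (0.5, 0.1)})
        assert not table.flagged.any()
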