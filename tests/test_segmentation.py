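"""U-Net construction, metrics, losses, training semantics and masking."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from woundkit.phantom import generate_dataset
from woundkit.segmentation import (SegConfig, TissueMap, build_unet, dice,
                                   iou, presence_call, segment_tissue,
                                   segment_wound, stage2_config,
                                   tissue_fractions, train)
from woundkit.segmentation._nn import Adam, ce_dice_loss
from woundkit.segmentation.train import stage_inputs


class TestBuildUnet:
    def test_output_shape_contract(self):
        net = build_unet(SegConfig(input_size=(64, 64), depth_levels=3,
                                   base_filters=4, seed=0))
        x = np.zeros((2, 3, 64, 64), np.float32)
        assert net.forward(x, train=False).shape == (2, 2, 64, 64)

    def test_indivisible_input_rejected(self):
        with pytest.raises(ValueError):
            SegConfig(input_size=(100, 100), depth_levels=3)

    def test_parameter_count_grows_with_base_filters(self):
        counts = [build_unet(SegConfig(base_filters=f, seed=0)).n_parameters()
                  for f in (4, 8, 16)]
        assert counts[0] < counts[1] < counts[2]

    def test_save_load_round_trip(self, tmp_path):
        net = build_unet(SegConfig(input_size=(32, 32), base_filters=4,
                                   seed=3))
        x = np.random.default_rng(0).random((1, 3, 32, 32), dtype=np.float32)
        before = net.forward(x, train=False)
        net.save(str(tmp_path / "m"))
        from woundkit.segmentation.unet import UNet
        loaded = UNet.load(str(tmp_path / "m"))
        assert np.array_equal(loaded.forward(x, train=False), before)


class TestLoss:
    def test_gradient_matches_finite_differences(self):
        cfg = SegConfig(input_size=(8, 8), in_channels=2, depth_levels=2,
                        base_filters=2, seed=3)
        net = build_unet(cfg)
        rng = np.random.default_rng(0)
        x = rng.random((2, 2, 8, 8)).astype(np.float32)
        y = (rng.random((2, 8, 8)) > 0.5).astype(np.uint8)

        def loss_of():
            return ce_dice_loss(net.forward(x, train=True), y)

        _, dlog, _ = loss_of()
        for _, g in net.params:
            g[...] = 0
        net.backward(dlog)
        eps = 1e-3
        params = net.params
        for pi in (0, len(params) // 2, len(params) - 2):
            p, g = params[pi]
            flat = p.reshape(-1)
            for k in rng.integers(0, flat.size, 2):
                old = flat[k]
                flat[k] = old + eps
                lp, _, _ = loss_of()
                flat[k] = old - eps
                lm, _, _ = loss_of()
                flat[k] = old
                num = (lp - lm) / (2 * eps)
                ana = g.reshape(-1)[k]
                assert abs(num - ana) < 2e-2 * max(1.0, abs(num))

    def test_masked_loss_ignores_outside_pixels(self):
        rng = np.random.default_rng(1)
        logits = rng.normal(size=(1, 3, 8, 8))
        y = rng.integers(0, 3, (1, 8, 8)).astype(np.uint8)
        m = np.zeros((1, 8, 8), bool)
        m[0, 2:5, 2:5] = True
        l1, d1, _ = ce_dice_loss(logits, y, pixel_mask=m)
        logits2 = logits.copy()
        logits2[0, :, 0, 0] = 99.0       # outside the mask
        l2, d2, _ = ce_dice_loss(logits2, y, pixel_mask=m)
        assert np.isclose(l1, l2)
        assert np.allclose(d1[0, :, 2:5, 2:5], d2[0, :, 2:5, 2:5])
        assert np.allclose(d1[0, :, 0, 0], 0.0)


class TestOverlapMetrics:
    def test_reference_values(self):
        a = np.zeros((10, 20), bool)
        b = np.zeros((10, 20), bool)
        a[:5, :10], b[:5, 5:15] = True, True     # 100 px each, 50 overlap
        assert dice(a, b) == 0.5
        assert iou(a, b) == pytest.approx(1 / 3)
        assert dice(a, a) == iou(a, a) == 1.0
        assert dice(a, ~a) == iou(a, ~a) == 0.0
        empty = np.zeros_like(a)
        assert dice(empty, empty) == iou(empty, empty) == 1.0

    @settings(max_examples=60, derandomize=True)
    @given(st.integers(0, 2 ** 16 - 1), st.integers(0, 2 ** 16 - 1))
    def test_dice_bounds_symmetry_and_iou_ordering(self, bits_a, bits_b):
        a = np.array([(bits_a >> i) & 1 for i in range(16)], bool)
        b = np.array([(bits_b >> i) & 1 for i in range(16)], bool)
        d, j = dice(a, b), iou(a, b)
        assert 0.0 <= j <= d <= 1.0
        assert d == dice(b, a) and j == iou(b, a)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice(np.zeros((2, 2), bool), np.zeros((3, 3), bool))


class TestTissueFractions:
    def test_reference_fractions(self):
        mask = np.ones((4, 8), bool)
        labels = np.zeros((4, 8), np.uint8)
        labels[0] = 1                      # 8/32 slough
        labels[1, :4] = 2                  # 4/32 necrosis
        f = tissue_fractions(TissueMap(labels=labels, wound_mask=mask))
        assert (f.slough_pct, f.necrosis_pct) == (25.0, 12.5)
        all_slough = tissue_fractions(TissueMap(
            labels=np.ones((4, 8), np.uint8), wound_mask=mask))
        assert (all_slough.slough_pct, all_slough.necrosis_pct) == (100.0, 0.0)

    def test_empty_mask(self):
        f = tissue_fractions(TissueMap(labels=np.zeros((4, 4), np.uint8),
                                       wound_mask=np.zeros((4, 4), bool)))
        assert f.wound_pixels == 0 and f.slough_pct == 0.0

    def test_labels_outside_mask_forced_to_other(self):
        labels = np.full((4, 4), 2, np.uint8)
        mask = np.zeros((4, 4), bool)
        mask[0, 0] = True
        t = TissueMap(labels=labels, wound_mask=mask)
        assert t.labels.sum() == 2 and t.labels[0, 0] == 2

    def test_presence_thresholding(self):
        from woundkit.segmentation.maps import TissueFractions
        assert presence_call(TissueFractions(0, 0, 10)) == {
            "slough_present": False, "necrosis_present": False}
        # trace slough with clear necrosis (default 1% threshold)
        flags = presence_call(TissueFractions(0.03, 8.17, 1000))
        assert not flags["slough_present"] and flags["necrosis_present"]
        flags0 = presence_call(TissueFractions(0.03, 8.17, 1000),
                               threshold_pct=0.0)
        assert flags0["slough_present"]


@pytest.fixture(scope="module")
def tiny_dataset():
    return generate_dataset(20, seed=21, image_size=64)


class TestTraining:
    def test_history_and_running_best(self, tiny_dataset):
        cfg = SegConfig(input_size=(64, 64), base_filters=4, max_epochs=2,
                        seed=0)
        net = build_unet(cfg)
        net, hist = train(net, tiny_dataset, stage=1)
        assert hist.n_epochs == 2
        assert len(hist.train_loss) == len(hist.val_dice) == 2
        best = np.maximum.accumulate(hist.val_dice)
        assert (np.diff(best) >= 0).all()
        assert 1 <= hist.best_epoch <= 2

    def test_early_stop_fires_on_plateau(self, tiny_dataset):
        # lr = 0 freezes the network: no epoch can improve, so training
        # stops after 1 + patience epochs
        cfg = SegConfig(input_size=(64, 64), base_filters=4, max_epochs=40,
                        learning_rate=0.0, seed=0)
        net = build_unet(cfg)
        net, hist = train(net, tiny_dataset, stage=1)
        assert hist.n_epochs <= 11

    def test_training_reproducible_for_seed(self, tiny_dataset):
        weights = []
        for _ in range(2):
            cfg = SegConfig(input_size=(64, 64), base_filters=4,
                            max_epochs=1, seed=5)
            net = build_unet(cfg)
            net, _ = train(net, tiny_dataset, stage=1)
            weights.append(net.get_weights())
        assert all(np.array_equal(a, b)
                   for a, b in zip(weights[0], weights[1]))

    def test_empty_split_rejected(self, tiny_dataset):
        import pandas as pd
        from woundkit.phantom import Dataset
        man = tiny_dataset.manifest.copy()
        man["split"] = "train"
        bad = Dataset(images=tiny_dataset.images,
                      wound_masks=tiny_dataset.wound_masks,
                      tissue=tiny_dataset.tissue, manifest=man)
        net = build_unet(SegConfig(input_size=(64, 64), base_filters=4,
                                   max_epochs=1, seed=0))
        with pytest.raises(ValueError):
            train(net, bad, stage=1)


class TestInferenceMasking:
    def test_empty_mask_yields_empty_tissue_map(self):
        net2 = build_unet(stage2_config(base_filters=4, seed=0))
        rgb = np.zeros((64, 64, 3), np.uint8)
        t = segment_tissue(net2, rgb, np.zeros((64, 64), bool))
        assert t.labels.sum() == 0

    def test_predictions_never_leak_outside_mask(self):
        # even an untrained network must respect the masking contract
        net2 = build_unet(stage2_config(input_size=(32, 32), base_filters=4,
                                        seed=1))
        rng = np.random.default_rng(0)
        rgb = rng.integers(0, 255, (64, 64, 3), np.uint8)
        mask = np.zeros((64, 64), bool)
        mask[20:40, 25:45] = True
        t = segment_tissue(net2, rgb, mask)
        assert not np.isin(t.labels[~mask], [1, 2]).any()

    def test_stage2_inputs_zeroed_outside_mask(self):
        rgb = np.full((1, 16, 16, 3), 200, np.uint8)
        mask = np.zeros((1, 16, 16), bool)
        mask[0, 4:8, 4:8] = True
        x = stage_inputs(2, rgb, mask)
        assert x.shape == (1, 4, 16, 16)
        assert x[0, :3, 0, 0].sum() == 0.0
        assert x[0, 3, 5, 5] == 1.0

    def test_wound_speckle_filtered(self):
        net1 = build_unet(SegConfig(input_size=(64, 64), base_filters=4,
                                    seed=2))
        rgb = np.random.default_rng(3).integers(0, 255, (64, 64, 3),
                                                np.uint8)
        mask = segment_wound(net1, rgb, min_area_px=10 ** 6)
        assert not mask.any()      # everything is sub-threshold speckle
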