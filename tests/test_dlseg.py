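"""Thumbnail segmentation harness: splits, training mechanics, contract."""

import numpy as np
import pytest

from ctcscope import nn
from ctcscope.dlseg import (
    Segmenter,
    TrainingConfig,
    dice_score,
    prepare_training_pairs,
    segment_thumbnail,
    train_segmenter,
)


def make_disk_pairs(n, rng, noise=5.0):
    """Bright disks on a dark background: the easy training instance."""
    images, masks = [], []
    yy, xx = np.mgrid[0:80, 0:80]
    for _ in range(n):
        r = rng.uniform(6, 12)
        cy, cx = rng.uniform(20, 60, size=2)
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
        img = 20.0 + mask * rng.uniform(150, 230) + rng.normal(0, noise, (80, 80))
        images.append(np.clip(img, 0, 255).astype(np.uint8))
        masks.append(mask)
    return images, masks


@pytest.fixture(scope="module")
def disk_pairs():
    return make_disk_pairs(100, np.random.default_rng(42))


@pytest.fixture(scope="module")
def quick_segmenter(disk_pairs):
    config = TrainingConfig(epochs=12, seed=0)
    split = prepare_training_pairs(*disk_pairs, config)
    return train_segmenter(split, config), split


class TestPrepareTrainingPairs:
    def test_eighty_twenty_split(self):
        images, masks = make_disk_pairs(100, np.random.default_rng(0))
        split = prepare_training_pairs(images, masks)
        assert len(split.train_images) == 80
        assert len(split.val_images) == 20

    def test_same_seed_same_split(self, disk_pairs):
        a = prepare_training_pairs(*disk_pairs, TrainingConfig(seed=5))
        b = prepare_training_pairs(*disk_pairs, TrainingConfig(seed=5))
        assert np.array_equal(a.train_indices, b.train_indices)

    def test_split_partitions_input(self, disk_pairs):
        split = prepare_training_pairs(*disk_pairs)
        merged = sorted(np.concatenate([split.train_indices, split.val_indices]))
        assert merged == list(range(len(disk_pairs[0])))
        assert not set(split.train_indices) & set(split.val_indices)

    def test_too_few_pairs_rejected(self, rng):
        images, masks = make_disk_pairs(5, rng)
        with pytest.raises(ValueError, match="at least 10"):
            prepare_training_pairs(images, masks)

    def test_shape_mismatch_rejected(self, disk_pairs):
        images, masks = disk_pairs
        bad_masks = [m[:40, :40] for m in masks]
        with pytest.raises(ValueError):
            prepare_training_pairs(images, bad_masks)


class TestGradients:
    def test_backward_matches_numerical_gradient(self):
        net = nn.TinyUNet(base_filters=3, seed=1)
        # layers are dtype-generic: check in float64 where central differences
        # are meaningful
        net.params = {k: v.astype(np.float64) for k, v in net.params.items()}
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 1, size=(2, 1, 8, 8))
        y = (rng.uniform(size=(2, 1, 8, 8)) > 0.5).astype(np.float64)
        logits = net.forward(x, keep_cache=True)
        _, dlogits = nn.bce_with_logits(logits, y)
        grads = net.backward(dlogits)
        for key, param in net.params.items():
            idx = tuple(rng.integers(0, s) for s in param.shape)
            eps = 1e-6
            original = param[idx]
            param[idx] = original + eps
            up, _ = nn.bce_with_logits(net.forward(x), y)
            param[idx] = original - eps
            down, _ = nn.bce_with_logits(net.forward(x), y)
            param[idx] = original
            numeric = (up - down) / (2 * eps)
            assert grads[key][idx] == pytest.approx(numeric, rel=0.05, abs=1e-6)


class TestTraining:
    def test_loss_decreases(self, quick_segmenter):
        seg, _split = quick_segmenter
        assert seg.epoch_losses[-1] < seg.epoch_losses[0]

    def test_easy_instance_reaches_good_dice(self, quick_segmenter):
        seg, _split = quick_segmenter
        assert seg.validation_dice >= 0.8

    def test_deterministic_given_seed(self, disk_pairs):
        config = TrainingConfig(epochs=1, seed=9)
        split = prepare_training_pairs(*disk_pairs, config)
        a = train_segmenter(split, config)
        b = train_segmenter(split, config)
        for key in a.net.params:
            assert np.array_equal(a.net.params[key], b.net.params[key])

    def test_zero_epoch_baseline(self, disk_pairs):
        config = TrainingConfig(epochs=0, seed=0)
        split = prepare_training_pairs(*disk_pairs, config)
        seg = train_segmenter(split, config)
        assert seg.epoch_losses == []
        assert seg.validation_dice is not None  # reported, no pass requirement


class TestSegmenterContract:
    def test_output_shape_and_dtype(self, quick_segmenter, disk_pairs):
        seg, _ = quick_segmenter
        mask = segment_thumbnail(seg, disk_pairs[0][0])
        assert mask.shape == (80, 80)
        assert mask.dtype == bool

    def test_wrong_shape_rejected(self, quick_segmenter):
        seg, _ = quick_segmenter
        with pytest.raises(ValueError, match="80x80"):
            seg.segment(np.zeros((40, 40), dtype=np.uint8))

    def test_blank_thumbnail_yields_near_empty_mask(self, quick_segmenter):
        seg, _ = quick_segmenter
        mask = seg.segment(np.zeros((80, 80), dtype=np.uint8))
        assert mask.mean() <= 0.05

    def test_high_snr_nucleus_recovered(self, quick_segmenter):
        seg, split = quick_segmenter
        pred = seg.segment(split.val_images[0])
        truth = split.val_masks[0]
        iou = np.logical_and(pred, truth).sum() / max(1, np.logical_or(pred, truth).sum())
        assert iou >= 0.7

    def test_serialization_round_trip(self, quick_segmenter, tmp_path, disk_pairs):
        seg, _ = quick_segmenter
        path = tmp_path / "model.npz"
        seg.save(path)
        loaded = Segmenter.load(path)
        batch = np.stack(disk_pairs[0][:8])
        assert np.array_equal(seg.segment_batch(batch), loaded.segment_batch(batch))
        assert loaded.config == seg.config
        assert loaded.validation_dice == seg.validation_dice


class TestDice:
    def test_both_empty_is_one(self):
        z = np.zeros((4, 4), dtype=bool)
        assert dice_score(z, z) == 1.0

    def test_identical_masks(self, rng):
        m = rng.uniform(size=(10, 10)) > 0.5
        assert dice_score(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4), dtype=bool)
        b = np.zeros((4, 4), dtype=bool)
        a[0, 0], b[3, 3] = True, True
        assert dice_score(a, b) == 0.0
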