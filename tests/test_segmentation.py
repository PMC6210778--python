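"""Segmentation, thumbnails, 8-bit casting, percentile normalization, TIFF IO."""

import numpy as np
import pytest

import ctcscope as cs
from ctcscope.filtering import fourier_background_filter
from ctcscope.pipeline import evaluate_against_truth
from ctcscope.segmentation import (
    EventMask,
    ThresholdPolicy,
    cast_celltracks_to_8bit,
    make_thumbnail,
    normalize_led_percentile,
    segment_events,
)
from .conftest import disk_mask


class TestSegmentEvents:
    def test_blank_image_has_no_events(self, rng):
        blank = rng.normal(100.0, 10.0, size=(256, 256)).clip(0, 4095)
        filtered = {"DAPI": fourier_background_filter(blank)}
        assert segment_events(filtered) == []

    def test_sparse_high_snr_detection(self, clean_sample):
        scores = evaluate_against_truth(
            clean_sample["events"], clean_sample["classified"], clean_sample["truth"]
        )
        assert scores["recall"] >= 0.98
        assert scores["precision"] >= 0.98

    def test_tangent_disks_become_one_event(self):
        image = np.full((128, 128), 0.0)
        pair = disk_mask(10, [(0, 0), (0, 20)])
        image[40 : 40 + pair.shape[0], 40 : 40 + pair.shape[1]] = pair * 1000.0
        events = segment_events({"DAPI": image})
        assert len(events) == 1

    def test_labels_partition_pixels(self, clean_sample):
        events = clean_sample["events"]
        shape = clean_sample["stack"].shape
        coverage = np.zeros(shape, dtype=int)
        for ev in events:
            r0, c0, r1, c1 = ev.bbox
            coverage[r0:r1, c0:c1] += ev.nucleus
        assert coverage.max() == 1

    def test_event_ids_dense(self, clean_sample):
        ids = [e.event_id for e in clean_sample["events"]]
        assert ids == list(range(len(ids)))

    def test_min_size_enforced(self, clean_sample):
        assert all(e.nucleus.sum() >= 4 for e in clean_sample["events"])

    def test_missing_dapi_rejected(self):
        with pytest.raises(KeyError):
            segment_events({"CK": np.zeros((32, 32))})


class TestMakeThumbnail:
    @staticmethod
    def _event(bbox, shape=(200, 200)):
        h, w = bbox[2] - bbox[0], bbox[3] - bbox[1]
        nucleus = np.ones((h, w), dtype=bool)
        return EventMask(event_id=0, bbox=bbox, masks={"DAPI": nucleus},
                         centroid=((bbox[0] + bbox[2]) / 2, (bbox[1] + bbox[3]) / 2))

    def test_constant_crop_pads_with_same_value(self):
        image = np.full((200, 200), 7.0)
        thumb = make_thumbnail(self._event((10, 20, 60, 80)), {"DAPI": image})
        assert thumb.channels["DAPI"].shape == (80, 80)
        assert np.all(thumb.channels["DAPI"] == 7.0)

    def test_padding_uses_boundary_median(self):
        image = np.zeros((100, 100))
        # crop whose boundary holds values {1, 1, 3, ...}: median must win
        image[10:13, 10:13] = [[1, 1, 3], [1, 9, 3], [1, 1, 3]]
        thumb = make_thumbnail(self._event((10, 10, 13, 13), (100, 100)), {"DAPI": image})
        pad_value = thumb.channels["DAPI"][0, 0]
        boundary = [1, 1, 3, 1, 3, 1, 1, 3]
        assert pad_value == np.median(boundary)

    def test_padded_region_is_point_mass(self, rng):
        # property: outside the crop the histogram is a single value
        for _ in range(5):
            h, w = rng.integers(5, 60, size=2)
            image = rng.uniform(0, 4095, size=(200, 200))
            thumb = make_thumbnail(self._event((50, 50, 50 + h, 50 + w)), {"DAPI": image})
            canvas = thumb.channels["DAPI"]
            pad_values = canvas[~thumb.valid_mask]
            if pad_values.size:
                assert np.unique(pad_values).size == 1

    def test_idempotent_on_full_size_crop(self):
        image = np.arange(200 * 200, dtype=float).reshape(200, 200)
        thumb = make_thumbnail(self._event((10, 10, 90, 90)), {"DAPI": image})
        assert np.array_equal(thumb.channels["DAPI"], image[10:90, 10:90])

    def test_oversized_event_center_cropped(self):
        image = np.arange(300 * 300, dtype=float).reshape(300, 300)
        thumb = make_thumbnail(self._event((10, 10, 150, 150), (300, 300)), {"DAPI": image})
        assert thumb.channels["DAPI"].shape == (80, 80)
        assert thumb.crop_shape == (80, 80)


class TestEightBitCasting:
    def _thumb(self, value):
        canvas = np.full((80, 80), float(value))
        return cs.Thumbnail(event_id=0, channels={"DAPI": canvas},
                            crop_origin=(0, 0), crop_shape=(80, 80),
                            canvas_offset=(0, 0))

    @pytest.mark.parametrize("value,expected", [(4095, 255), (0, 0), (2048, 128)])
    def test_celltracks_casting_rule(self, value, expected):
        out = cast_celltracks_to_8bit(self._thumb(value))
        assert out.channels["DAPI"].dtype == np.uint8
        assert int(out.channels["DAPI"][0, 0]) == expected

    def test_overflow_clipped(self):
        out = cast_celltracks_to_8bit(self._thumb(5000))
        assert int(out.channels["DAPI"][0, 0]) == 255

    def test_percentile_value_maps_to_255(self, rng):
        thumbs = []
        for _ in range(4):
            canvas = rng.uniform(0, 1000, size=(80, 80))
            thumbs.append(cs.Thumbnail(event_id=0, channels={"DAPI": canvas},
                                       crop_origin=(0, 0), crop_shape=(80, 80),
                                       canvas_offset=(0, 0), source="led"))
        normalized, divisors = normalize_led_percentile(thumbs)
        pixels = np.concatenate([t.channels["DAPI"].ravel() for t in thumbs])
        expected = float(np.percentile(pixels, 99.9))  # sorting oracle
        assert divisors["DAPI"] == pytest.approx(expected)
        value = np.round(expected / divisors["DAPI"] * 255)
        assert value == 255

    def test_constant_thumbnail_saturates(self):
        thumbs = [self._thumb(123.0)]
        normalized, _ = normalize_led_percentile(thumbs)
        assert np.all(normalized[0].channels["DAPI"] == 255)

    def test_hot_pixel_clipped_but_bulk_preserved(self, rng):
        canvas = rng.uniform(900, 1000, size=(80, 80))
        canvas[3, 3] = 65535.0
        thumbs = [cs.Thumbnail(event_id=0, channels={"DAPI": canvas},
                               crop_origin=(0, 0), crop_shape=(80, 80),
                               canvas_offset=(0, 0), source="led")]
        normalized, divisors = normalize_led_percentile(thumbs)
        out = normalized[0].channels["DAPI"]
        assert out[3, 3] == 255  # saturated pixel clips
        assert divisors["DAPI"] < 2000  # percentile ignored the hot pixel
        assert out[out < 255].max() >= 230  # bulk lands near the top of the range


class TestStackIO:
    def test_round_trip_12bit(self, tmp_path, rng):
        channels = {ch: rng.integers(0, 4096, size=(64, 64)).astype(np.uint16)
                    for ch in ("DAPI", "CK", "CD45")}
        stack = cs.ImageStack(channels=channels)
        cs.write_stack(stack, tmp_path / "s.tiff")
        loaded = cs.read_stack(tmp_path / "s.tiff")
        for ch in channels:
            assert np.array_equal(loaded.channels[ch], channels[ch])
        assert loaded.pixel_pitch == stack.pixel_pitch

    def test_led_bit_depth_tag_preserved(self, tmp_path, rng):
        channels = {"DAPI": rng.integers(0, 65536, size=(32, 32)).astype(np.uint16)}
        stack = cs.ImageStack(channels=channels, bit_depth=16, source="led")
        cs.write_stack(stack, tmp_path / "led.tiff")
        loaded = cs.read_stack(tmp_path / "led.tiff")
        assert loaded.bit_depth == 16
        assert loaded.source == "led"

    def test_missing_required_channel(self, tmp_path, rng):
        channels = {"CK": rng.integers(0, 4096, size=(32, 32)).astype(np.uint16)}
        stack = cs.ImageStack(channels=channels)
        cs.write_stack(stack, tmp_path / "nodapi.tiff")
        with pytest.raises(KeyError, match="DAPI"):
            cs.read_stack(tmp_path / "nodapi.tiff")

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            cs.ImageStack(channels={"DAPI": np.zeros((4, 4), dtype=np.uint16),
                                    "CK": np.zeros((5, 5), dtype=np.uint16)})
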