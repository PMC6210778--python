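"""Event segmentation and thumbnail extraction.

Events are connected components of supra-threshold pixels in the
background-filtered DAPI channel (8-connectivity, minimum 4 pixels); the
threshold is a multiple of the filtered image's standard deviation.  Touching
cells are deliberately left as one event — they are split logically downstream
by the perimeter-to-area score, not pixel-wise.  Marker masks are computed per
event by thresholding each marker channel inside a dilated bounding box and
keeping only stain near the nucleus.

Each event can be exported as an 80x80 per-channel thumbnail: the crop is
padded on all four sides with the median intensity of its boundary pixels,
then cast to 8 bits either by the fixed 12-bit CellTracks rule (divide by
4095, multiply by 255) or, for 16-bit LED scans, by a per-channel 99.9th
percentile computed over all thumbnails of the sample, which ignores isolated
saturated pixels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

logger = logging.getLogger(__name__)

THUMBNAIL_SIZE = 80
CELLTRACKS_MAX = 4095


@dataclass(frozen=True)
class ThresholdPolicy:
    """How supra-threshold pixels are selected on filtered channels.

    ``k`` scales the standard deviation of each filtered channel;
    ``min_size`` drops connected components smaller than that many pixels;
    ``dilation`` grows the nucleus bounding box (and the allowed distance of
    marker stain from the nucleus) by that many pixels.  With ``robust`` the
    standard deviation is estimated from the median absolute deviation, so
    bright cells do not inflate their own detection threshold; the plain
    standard deviation is only appropriate for near-empty images.  ``floor``
    is an absolute lower bound on the threshold (12-bit filtered scale): in a
    noise-free image the scaled deviation collapses to filter ringing, and
    nothing dimmer than the floor could pass the downstream intensity gates
    anyway.
    """

    k: float = 3.0
    min_size: int = 4
    dilation: int = 5
    robust: bool = True
    floor: float = 20.0

    def threshold(self, image: np.ndarray) -> float:
        image = np.asarray(image, dtype=float)
        if self.robust:
            sigma = 1.4826 * float(np.median(np.abs(image - np.median(image))))
        else:
            sigma = float(image.std())
        return max(self.k * sigma, self.floor)


@dataclass
class EventMask:
    """One segmented object: per-channel binary masks in a common crop frame.

    ``bbox`` is the 0-based, half-open ``(r0, c0, r1, c1)`` window (already
    dilated) that all masks share.  The DAPI (nucleus) mask is mandatory and
    non-empty.
    """

    event_id: int
    bbox: Tuple[int, int, int, int]
    masks: Dict[str, np.ndarray]
    centroid: Tuple[float, float]

    def __post_init__(self) -> None:
        if "DAPI" not in self.masks or not self.masks["DAPI"].any():
            raise ValueError("EventMask requires a non-empty DAPI mask")
        r0, c0, r1, c1 = self.bbox
        shape = (r1 - r0, c1 - c0)
        for ch, m in self.masks.items():
            if m.shape != shape:
                raise ValueError(f"mask {ch!r} does not fit the bounding box")

    @property
    def nucleus(self) -> np.ndarray:
        return self.masks["DAPI"]

    def crop(self, image: np.ndarray) -> np.ndarray:
        r0, c0, r1, c1 = self.bbox
        return image[r0:r1, c0:c1]


@dataclass
class Thumbnail:
    """Per-channel 80x80 crops of one event, with provenance.

    ``crop_origin``/``crop_shape`` locate the source window in the full image
    and ``canvas_offset`` places it inside the 80x80 canvas; the remainder of
    the canvas is padding.
    """

    event_id: int
    channels: Dict[str, np.ndarray]
    crop_origin: Tuple[int, int]
    crop_shape: Tuple[int, int]
    canvas_offset: Tuple[int, int]
    source: str = "celltracks"
    normalization: Optional[str] = None

    def __post_init__(self) -> None:
        for ch, img in self.channels.items():
            if img.shape != (THUMBNAIL_SIZE, THUMBNAIL_SIZE):
                raise ValueError(f"thumbnail channel {ch!r} is not 80x80")

    @property
    def valid_mask(self) -> np.ndarray:
        """True over the source crop, False over the padding."""
        m = np.zeros((THUMBNAIL_SIZE, THUMBNAIL_SIZE), dtype=bool)
        r, c = self.canvas_offset
        h, w = self.crop_shape
        m[r : r + h, c : c + w] = True
        return m


def segment_events(
    filtered: Mapping[str, np.ndarray],
    policy: ThresholdPolicy | None = None,
) -> List[EventMask]:
    """Segment the filtered DAPI channel and attach per-event marker masks.

    Returns events with dense ids ``0..K-1``.  An image with no
    supra-threshold component of at least ``min_size`` pixels yields an empty
    list (not an error).
    """
    policy = policy or ThresholdPolicy()
    if "DAPI" not in filtered:
        raise KeyError("filtered stack has no DAPI channel")
    dapi = np.asarray(filtered["DAPI"], dtype=float)
    binary = dapi > policy.threshold(dapi)
    if policy.min_size > 1:
        binary = morphology.remove_small_objects(binary, max_size=policy.min_size - 1)
    labels, n_events = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    if n_events == 0:
        return []

    marker_thresholds = {
        ch: policy.threshold(np.asarray(img, dtype=float))
        for ch, img in filtered.items()
        if ch != "DAPI"
    }

    events: List[EventMask] = []
    h, w = dapi.shape
    selem = morphology.disk(policy.dilation)
    objects = ndimage.find_objects(labels)
    for idx, slc in enumerate(objects, start=1):
        r0 = max(slc[0].start - policy.dilation, 0)
        r1 = min(slc[0].stop + policy.dilation, h)
        c0 = max(slc[1].start - policy.dilation, 0)
        c1 = min(slc[1].stop + policy.dilation, w)
        nucleus = labels[r0:r1, c0:c1] == idx
        near_nucleus = morphology.dilation(nucleus, selem)
        masks: Dict[str, np.ndarray] = {"DAPI": nucleus}
        for ch, thr in marker_thresholds.items():
            crop = np.asarray(filtered[ch], dtype=float)[r0:r1, c0:c1]
            stain = crop > thr
            if stain.any():
                stain = _components_touching(stain, near_nucleus, policy.min_size)
            masks[ch] = stain
        rows, cols = np.nonzero(nucleus)
        centroid = (float(rows.mean()) + r0, float(cols.mean()) + c0)
        events.append(
            EventMask(event_id=idx - 1, bbox=(r0, c0, r1, c1), masks=masks, centroid=centroid)
        )
    return events


def _components_touching(
    stain: np.ndarray, anchor: np.ndarray, min_size: int
) -> np.ndarray:
    """Keep stain components of >= min_size pixels that touch the anchor region."""
    lab, n = ndimage.label(stain, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return stain
    keep = np.zeros(n + 1, dtype=bool)
    counts = np.bincount(lab.ravel(), minlength=n + 1)
    touching = np.unique(lab[anchor & stain])
    keep[touching] = True
    keep[counts < min_size] = False
    keep[0] = False
    return keep[lab]


def _boundary_median(crop: np.ndarray) -> float:
    if crop.shape[0] <= 2 or crop.shape[1] <= 2:
        return float(np.median(crop))
    border = np.concatenate(
        [crop[0, :], crop[-1, :], crop[1:-1, 0], crop[1:-1, -1]]
    )
    return float(np.median(border))


def make_thumbnail(
    event: EventMask,
    channels: Mapping[str, np.ndarray],
    size: int = THUMBNAIL_SIZE,
    source: str = "celltracks",
) -> Thumbnail:
    """Crop each channel around the event and pad to ``size`` x ``size``.

    The padding value is the median intensity of the crop's boundary pixels,
    computed per channel.  Events larger than the thumbnail in a dimension
    are center-cropped (features are computed on the full mask elsewhere, so
    nothing is lost for gating).
    """
    r0, c0, r1, c1 = event.bbox
    img_shape = next(iter(channels.values())).shape
    # center-crop the window to at most `size` per dimension
    if r1 - r0 > size:
        mid = (r0 + r1) // 2
        r0, r1 = mid - size // 2, mid + size - size // 2
        r0, r1 = max(r0, 0), min(r1, img_shape[0])
    if c1 - c0 > size:
        mid = (c0 + c1) // 2
        c0, c1 = mid - size // 2, mid + size - size // 2
        c0, c1 = max(c0, 0), min(c1, img_shape[1])
    ch_h, ch_w = r1 - r0, c1 - c0
    off_r = (size - ch_h) // 2
    off_c = (size - ch_w) // 2

    thumbs: Dict[str, np.ndarray] = {}
    for ch, img in channels.items():
        crop = np.asarray(img)[r0:r1, c0:c1]
        canvas = np.full((size, size), _boundary_median(crop), dtype=float)
        canvas[off_r : off_r + ch_h, off_c : off_c + ch_w] = crop
        thumbs[ch] = canvas
    return Thumbnail(
        event_id=event.event_id,
        channels=thumbs,
        crop_origin=(r0, c0),
        crop_shape=(ch_h, ch_w),
        canvas_offset=(off_r, off_c),
        source=source,
    )


def cast_celltracks_to_8bit(
    thumbnail: Thumbnail, max_value: int = CELLTRACKS_MAX
) -> Thumbnail:
    """12-bit CellTracks casting: ``v -> round(v / 4095 * 255)``, clipped."""
    out: Dict[str, np.ndarray] = {}
    for ch, img in thumbnail.channels.items():
        img = np.asarray(img, dtype=float)
        if img.max() > max_value:
            logger.warning(
                "thumbnail %s channel %s exceeds %d; clipping",
                thumbnail.event_id, ch, max_value,
            )
        out[ch] = np.clip(np.round(img / max_value * 255.0), 0, 255).astype(np.uint8)
    return Thumbnail(
        event_id=thumbnail.event_id,
        channels=out,
        crop_origin=thumbnail.crop_origin,
        crop_shape=thumbnail.crop_shape,
        canvas_offset=thumbnail.canvas_offset,
        source=thumbnail.source,
        normalization=f"celltracks/{max_value}",
    )


def normalize_led_percentile(
    thumbnails: Sequence[Thumbnail], q: float = 99.9
) -> Tuple[List[Thumbnail], Dict[str, float]]:
    """Per-channel percentile normalization of all thumbnails of a sample.

    For each channel, the ``q``-th percentile over all pixels of all
    thumbnails is mapped to 255; values above (isolated saturated pixels)
    clip at 255.  Returns the normalized thumbnails and the divisors used.
    """
    if not thumbnails:
        raise ValueError("need at least one thumbnail")
    channel_names = list(thumbnails[0].channels)
    divisors: Dict[str, float] = {}
    for ch in channel_names:
        pixels = np.concatenate([t.channels[ch].ravel() for t in thumbnails])
        p = float(np.percentile(pixels, q))
        if p <= 0:
            logger.warning("channel %s is all zero; normalization divisor set to 1", ch)
            p = 1.0
        divisors[ch] = p
    out: List[Thumbnail] = []
    for t in thumbnails:
        channels = {
            ch: np.clip(
                np.round(np.asarray(img, dtype=float) / divisors[ch] * 255.0), 0, 255
            ).astype(np.uint8)
            for ch, img in t.channels.items()
        }
        out.append(
            Thumbnail(
                event_id=t.event_id,
                channels=channels,
                crop_origin=t.crop_origin,
                crop_shape=t.crop_shape,
                canvas_offset=t.canvas_offset,
                source=t.source,
                normalization=f"led/p{q}",
            )
        )
    return out, divisors
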