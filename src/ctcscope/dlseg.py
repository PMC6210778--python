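"""Learning-based thumbnail segmentation harness.

This reproduces the thumbnail learning loop at desk scale: 80x80 single-
channel 8-bit thumbnails paired with binary masks are split 80/20 into
training and validation sets, a small U-net is trained for ten epochs with
batch size 16, and the resulting segmenter maps a thumbnail to a binary mask
that feeds back into the same feature and lineage machinery as the
threshold path.  Masks from the threshold segmentation of clean, sparse
samples serve as training labels, mirroring how satisfactory classic
segmentations were used to supervise the network.

The segmenter is a plain function contract: 80x80 8-bit image in, 80x80
boolean mask out, serializable with its configuration and training history.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .classify import (
    ClassifiedEvent,
    ClassRuleSet,
    ClusterBands,
    GatingConfig,
    classify_cluster,
    classify_lineage,
    gate_nucleated,
)
from .features import (
    ChannelStats,
    FeatureVector,
    area_um2,
    intensity_stats,
    overlay_fraction,
    p2a,
    perimeter_um,
    roundness,
)
from .io import ImageStack
from .segmentation import (
    EventMask,
    Thumbnail,
    cast_celltracks_to_8bit,
    make_thumbnail,
    normalize_led_percentile,
    THUMBNAIL_SIZE,
)

__all__ = [
    "TrainingConfig", "TrainValSplit", "Segmenter", "prepare_training_pairs",
    "train_segmenter", "segment_thumbnail", "dice_score",
    "training_pairs_from_events", "classify_events_dl",
]


@dataclass(frozen=True)
class TrainingConfig:
    """Training hyperparameters; defaults match the desk-scale harness."""

    batch_size: int = 16
    epochs: int = 10
    val_fraction: float = 0.2
    seed: int = 0
    base_filters: int = 8
    learning_rate: float = 1e-3

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must be in (0, 1)")
        if self.epochs < 0:
            raise ValueError("epochs must be non-negative")


@dataclass
class TrainValSplit:
    train_images: np.ndarray  # (n, 80, 80) uint8
    train_masks: np.ndarray   # (n, 80, 80) bool
    val_images: np.ndarray
    val_masks: np.ndarray
    train_indices: np.ndarray
    val_indices: np.ndarray


def prepare_training_pairs(
    images: Sequence[np.ndarray],
    masks: Sequence[np.ndarray],
    config: TrainingConfig | None = None,
) -> TrainValSplit:
    """Seeded train/validation split of (thumbnail, mask) pairs.

    Requires at least 10 pairs; images and masks must be 80x80 and aligned.
    The two sets are disjoint and their union is the input set.
    """
    config = config or TrainingConfig()
    if len(images) != len(masks):
        raise ValueError("images and masks must be parallel lists")
    if len(images) < 10:
        raise ValueError("need at least 10 training pairs")
    imgs = np.stack([np.asarray(im) for im in images])
    msks = np.stack([np.asarray(m, dtype=bool) for m in masks])
    if imgs.shape[1:] != (THUMBNAIL_SIZE, THUMBNAIL_SIZE):
        raise ValueError("thumbnails must be 80x80")
    if msks.shape != imgs.shape:
        raise ValueError("mask shape does not match image shape")

    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(imgs))
    n_val = max(1, int(round(config.val_fraction * len(imgs))))
    val_idx, train_idx = order[:n_val], order[n_val:]
    return TrainValSplit(
        train_images=imgs[train_idx],
        train_masks=msks[train_idx],
        val_images=imgs[val_idx],
        val_masks=msks[val_idx],
        train_indices=train_idx,
        val_indices=val_idx,
    )


def dice_score(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A&B|/(|A|+|B|); 1.0 when both masks are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


@dataclass
class Segmenter:
    """A trained thumbnail segmenter with its configuration and history."""

    net: nn.TinyUNet
    config: TrainingConfig
    epoch_losses: List[float] = field(default_factory=list)
    validation_dice: Optional[float] = None

    def segment(self, thumbnail: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        """80x80 8-bit image -> 80x80 boolean mask."""
        img = np.asarray(thumbnail)
        if img.shape != (THUMBNAIL_SIZE, THUMBNAIL_SIZE):
            raise ValueError("segmenter input must be 80x80")
        x = img.astype(float)[None, None] / 255.0
        return self.net.predict_proba(x)[0, 0] > threshold

    def segment_batch(self, thumbnails: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        x = np.asarray(thumbnails, dtype=float)[:, None] / 255.0
        return self.net.predict_proba(x)[:, 0] > threshold

    def save(self, path: str | Path) -> None:
        meta = {
            "config": {
                "batch_size": self.config.batch_size,
                "epochs": self.config.epochs,
                "val_fraction": self.config.val_fraction,
                "seed": self.config.seed,
                "base_filters": self.config.base_filters,
                "learning_rate": self.config.learning_rate,
            },
            "epoch_losses": self.epoch_losses,
            "validation_dice": self.validation_dice,
        }
        np.savez(
            path,
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            **self.net.state_dict(),
        )

    @classmethod
    def load(cls, path: str | Path) -> "Segmenter":
        data = np.load(path)
        meta = json.loads(bytes(data["meta"]).decode())
        config = TrainingConfig(**meta["config"])
        net = nn.TinyUNet(base_filters=config.base_filters, seed=config.seed)
        net.load_state_dict({k: data[k] for k in net.params})
        return cls(
            net=net,
            config=config,
            epoch_losses=list(meta["epoch_losses"]),
            validation_dice=meta["validation_dice"],
        )


def train_segmenter(
    split: TrainValSplit, config: TrainingConfig | None = None
) -> Segmenter:
    """Train the small U-net on a prepared split.

    Deterministic for a fixed seed.  With ``epochs=0`` the untrained baseline
    is returned (its validation Dice is still reported).  A non-finite loss
    raises ``RuntimeError`` with the configuration echoed.
    """
    config = config or TrainingConfig()
    net = nn.TinyUNet(base_filters=config.base_filters, seed=config.seed)
    x = split.train_images.astype(float)[:, None] / 255.0
    y = split.train_masks.astype(float)[:, None]
    try:
        losses = nn.train(
            net, x, y,
            epochs=config.epochs,
            batch_size=config.batch_size,
            learning_rate=config.learning_rate,
            seed=config.seed,
        )
    except RuntimeError as err:
        raise RuntimeError(f"{err} (config: {config})") from err
    seg = Segmenter(net=net, config=config, epoch_losses=losses)
    pred = seg.segment_batch(split.val_images)
    seg.validation_dice = float(
        np.mean([dice_score(p, t) for p, t in zip(pred, split.val_masks)])
    )
    return seg


def segment_thumbnail(segmenter: Segmenter, thumbnail: np.ndarray) -> np.ndarray:
    """Apply the contract: one 80x80 8-bit channel image -> binary mask."""
    return segmenter.segment(thumbnail)


def _place_in_canvas(thumb: Thumbnail, image: np.ndarray) -> np.ndarray:
    """Crop ``image`` with the thumbnail's window and place it in an 80x80 canvas."""
    canvas = np.zeros((THUMBNAIL_SIZE, THUMBNAIL_SIZE), dtype=float)
    r0, c0 = thumb.crop_origin
    h, w = thumb.crop_shape
    orr, occ = thumb.canvas_offset
    canvas[orr : orr + h, occ : occ + w] = image[r0 : r0 + h, c0 : c0 + w]
    return canvas


def _mask_in_canvas(thumb: Thumbnail, event: EventMask, channel: str) -> np.ndarray:
    """Place an event's threshold mask into the thumbnail canvas frame."""
    canvas = np.zeros((THUMBNAIL_SIZE, THUMBNAIL_SIZE), dtype=bool)
    mask = event.masks.get(channel)
    if mask is None:
        return canvas
    er0, ec0 = event.bbox[0], event.bbox[1]
    tr0, tc0 = thumb.crop_origin
    h, w = thumb.crop_shape
    orr, occ = thumb.canvas_offset
    # overlap between the thumbnail window and the event box, in mask coords
    sub = np.zeros((h, w), dtype=bool)
    mr0, mc0 = tr0 - er0, tc0 - ec0
    src = mask[max(mr0, 0) : mr0 + h, max(mc0, 0) : mc0 + w]
    dst_r = max(-mr0, 0)
    dst_c = max(-mc0, 0)
    sub[dst_r : dst_r + src.shape[0], dst_c : dst_c + src.shape[1]] = src
    canvas[orr : orr + h, occ : occ + w] = sub
    return canvas


def _to_8bit(thumbs: List[Thumbnail], source: str) -> List[Thumbnail]:
    if source == "celltracks":
        return [cast_celltracks_to_8bit(t) for t in thumbs]
    normalized, _ = normalize_led_percentile(thumbs)
    return normalized


def training_pairs_from_events(
    stack: ImageStack,
    events: Sequence[EventMask],
    channels: Optional[Sequence[str]] = None,
) -> Tuple[List[np.ndarray], List[np.ndarray]]:
    """Build (8-bit thumbnail, threshold mask) pairs, channels separated.

    This is the supervision source: thumbnails of events whose threshold
    segmentation is trusted, one training pair per channel per event.
    """
    channels = list(channels) if channels is not None else list(stack.channels)
    thumbs = [make_thumbnail(ev, stack.channels, source=stack.source) for ev in events]
    thumbs8 = _to_8bit(thumbs, stack.source)
    images: List[np.ndarray] = []
    masks: List[np.ndarray] = []
    for ev, t8 in zip(events, thumbs8):
        for ch in channels:
            if ch not in t8.channels:
                continue
            images.append(t8.channels[ch])
            masks.append(_mask_in_canvas(t8, ev, ch))
    return images, masks


def classify_events_dl(
    stack: ImageStack,
    events: Sequence[EventMask],
    filtered: Dict[str, np.ndarray],
    segmenter: Segmenter,
    *,
    gating: GatingConfig | None = None,
    bands: ClusterBands | None = None,
    rules: ClassRuleSet | None = None,
    panel: Optional[Sequence[str]] = None,
) -> List[ClassifiedEvent]:
    """Classify events using network masks instead of threshold masks.

    Each event's per-channel thumbnails are segmented by the network; the
    resulting masks are measured on the background-filtered intensities with
    exactly the same feature and gating code as the threshold path.
    """
    panel = tuple(panel) if panel is not None else tuple(stack.channels)
    thumbs = [make_thumbnail(ev, stack.channels, source=stack.source) for ev in events]
    thumbs8 = _to_8bit(thumbs, stack.source)

    out: List[ClassifiedEvent] = []
    for ev, t8 in zip(events, thumbs8):
        valid = t8.valid_mask
        dl_masks = {
            ch: segmenter.segment(t8.channels[ch]) & valid
            for ch in panel
            if ch in t8.channels
        }
        nucleus = dl_masks.get("DAPI", np.zeros_like(valid))
        feats = _features_from_canvas(t8, dl_masks, filtered, stack.pixel_pitch)
        nucleated = nucleus.any() and gate_nucleated(feats, gating)
        out.append(
            ClassifiedEvent(
                event_id=ev.event_id,
                is_nucleated=bool(nucleated),
                cluster_kind=classify_cluster(feats.p2a, bands) if nucleated else None,
                label=classify_lineage(feats, rules, panel) if nucleated else None,
                features=feats,
            )
        )
    return out


def _features_from_canvas(
    thumb: Thumbnail,
    masks: Dict[str, np.ndarray],
    filtered: Dict[str, np.ndarray],
    pixel_pitch: float,
) -> FeatureVector:
    nucleus = masks.get("DAPI", np.zeros((THUMBNAIL_SIZE, THUMBNAIL_SIZE), dtype=bool))
    channels: Dict[str, ChannelStats] = {}
    for ch, mask in masks.items():
        if not mask.any():
            channels[ch] = ChannelStats()
            continue
        intensities = _place_in_canvas(thumb, np.asarray(filtered[ch], dtype=float))
        mean, sd = intensity_stats(mask, intensities)
        channels[ch] = ChannelStats(
            mean=mean,
            sd=sd,
            area_um2=area_um2(mask, pixel_pitch),
            overlay=overlay_fraction(nucleus, mask) if nucleus.any() else 0.0,
        )
    channels.setdefault("DAPI", ChannelStats())
    n_px = int(nucleus.sum())
    if n_px < 4:
        return FeatureVector(
            channels=channels,
            dapi_area_um2=area_um2(nucleus, pixel_pitch),
            perimeter_um=0.0,
            roundness=1.0,
            p2a=float("inf"),
            degenerate=True,
        )
    return FeatureVector(
        channels=channels,
        dapi_area_um2=area_um2(nucleus, pixel_pitch),
        perimeter_um=perimeter_um(nucleus, pixel_pitch),
        roundness=roundness(nucleus),
        p2a=p2a(nucleus),
    )
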