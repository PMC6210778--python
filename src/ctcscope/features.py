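"""Per-event intensity and shape measurements.

These are the quantities the nucleated-cell gate and the lineage table
consume: background-subtracted mean/sd intensity per channel, marker area,
the fraction of the nucleus covered by each marker, and two shape scores of
the nucleus mask,

    roundness = 1 - 4*pi*A / P^2        (0 for a perfect circle)
    P2A       = P^2 / (4*pi*A)          (1 for a perfect circle)

where ``P`` is a sub-pixel contour length and ``A`` the pixel area.  The P2A
score separates single cells (<1.5), doublets ([1.5, 2.5)), small clusters
([2.5, 4)) and large clusters (>=4): two tangent equal disks score ~2
analytically and a tangent chain of k disks scores ~k.

Perimeter estimation matters here.  A raw marching-squares polygon on a
digital disk overestimates 2*pi*r by ~7-9% and a crack (boundary-pixel)
perimeter by ~27%, which would push single cells toward the doublet band.
``perimeter_um`` therefore measures the marching-squares contour after one
pass of closed-polygon vertex smoothing (kernel 0.18/0.64/0.18), calibrated
so a digital disk scores P2A ~ 1.05-1.08 while a 1-pixel-wide bar keeps its
crack length within 10%.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict

import numpy as np
from skimage import measure

#: discretization tolerance on the shape-score invariants
SHAPE_EPS = 0.05

#: weight of each neighbour vertex in the one smoothing pass of the contour
_SMOOTH_W = 0.18

#: masks smaller than this many pixels have no meaningful contour
DEGENERATE_AREA_PX = 4


@dataclass(frozen=True)
class ChannelStats:
    """Background-subtracted intensity statistics of one marker channel."""

    mean: float = 0.0
    sd: float = 0.0
    area_um2: float = 0.0
    overlay: float = 0.0  # fraction of the nucleus covered by this marker


@dataclass
class FeatureVector:
    """All measurements of one segmented event.

    ``channels`` must contain a ``"DAPI"`` entry; shape descriptors refer to
    the DAPI (nucleus) mask.
    """

    channels: Dict[str, ChannelStats]
    dapi_area_um2: float = 0.0
    perimeter_um: float = 0.0
    roundness: float = 0.0
    p2a: float = 1.0
    degenerate: bool = False

    def __post_init__(self) -> None:
        if "DAPI" not in self.channels:
            raise KeyError("FeatureVector requires DAPI channel statistics")

    @property
    def dapi_mean(self) -> float:
        return self.channels["DAPI"].mean

    @property
    def dapi_sd(self) -> float:
        return self.channels["DAPI"].sd

    def mean(self, channel: str) -> float:
        st = self.channels.get(channel)
        return 0.0 if st is None else st.mean

    def overlay(self, channel: str) -> float:
        st = self.channels.get(channel)
        return 0.0 if st is None else st.overlay

    def area(self, channel: str) -> float:
        st = self.channels.get(channel)
        return 0.0 if st is None else st.area_um2


def intensity_stats(mask: np.ndarray, channel_image: np.ndarray) -> tuple:
    """Mean and population standard deviation of in-mask pixel values.

    The channel image is expected to be background-filtered, so the mean is
    relative to a zero background.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("intensity_stats of an empty mask")
    values = np.asarray(channel_image, dtype=float)[mask]
    return float(values.mean()), float(values.std(ddof=0))


def area_um2(mask: np.ndarray, pixel_pitch: float) -> float:
    """Pixel count times squared pixel pitch."""
    if pixel_pitch <= 0:
        raise ValueError("pixel_pitch must be positive")
    return float(np.count_nonzero(mask)) * pixel_pitch**2


def _contours(mask: np.ndarray):
    padded = np.pad(np.asarray(mask, dtype=float), 2)
    return measure.find_contours(padded, 0.5, fully_connected="high")


def _smoothed_length(contour: np.ndarray) -> float:
    closed = bool(np.allclose(contour[0], contour[-1]))
    pts = contour[:-1] if closed else contour
    if len(pts) >= 3:
        w = _SMOOTH_W
        pts = (1 - 2 * w) * pts + w * (np.roll(pts, 1, axis=0) + np.roll(pts, -1, axis=0))
    if closed:
        pts = np.vstack([pts, pts[:1]])
    steps = np.diff(pts, axis=0)
    return float(np.hypot(steps[:, 0], steps[:, 1]).sum())


def perimeter_px(mask: np.ndarray) -> float:
    """Sub-pixel contour length of a binary mask, in pixels."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("perimeter of an empty mask")
    contours = _contours(mask)
    if measure.label(mask, connectivity=2).max() > 1:
        warnings.warn(
            "perimeter of a disconnected mask: summing contour lengths",
            stacklevel=2,
        )
    return float(sum(_smoothed_length(c) for c in contours))


def perimeter_um(mask: np.ndarray, pixel_pitch: float) -> float:
    """Contour length in micrometer."""
    if pixel_pitch <= 0:
        raise ValueError("pixel_pitch must be positive")
    return perimeter_px(mask) * pixel_pitch


def roundness(mask: np.ndarray) -> float:
    """``1 - 4*pi*A/P^2``, clipped at 0; degenerate masks (<4 px) return 1."""
    mask = np.asarray(mask, dtype=bool)
    area = int(np.count_nonzero(mask))
    if area == 0:
        raise ValueError("roundness of an empty mask")
    if area < DEGENERATE_AREA_PX:
        return 1.0
    perim = perimeter_px(mask)
    return max(0.0, 1.0 - 4.0 * math.pi * area / perim**2)


def p2a(mask: np.ndarray) -> float:
    """``P^2/(4*pi*A)``; 1 for a perfect disk, grows with boundary complexity.

    Degenerate masks (<4 px) return ``inf``, the counterpart of roundness 1.
    """
    mask = np.asarray(mask, dtype=bool)
    area = int(np.count_nonzero(mask))
    if area == 0:
        raise ValueError("p2a of an empty mask")
    if area < DEGENERATE_AREA_PX:
        return math.inf
    perim = perimeter_px(mask)
    return perim**2 / (4.0 * math.pi * area)


def overlay_fraction(nucleus_mask: np.ndarray, marker_mask: np.ndarray) -> float:
    """Fraction of the nucleus covered by the marker: |n & m| / |n|."""
    nucleus = np.asarray(nucleus_mask, dtype=bool)
    marker = np.asarray(marker_mask, dtype=bool)
    n = int(np.count_nonzero(nucleus))
    if n == 0:
        raise ValueError("overlay_fraction with an empty nucleus mask")
    return float(np.count_nonzero(nucleus & marker)) / n
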