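"""Multi-channel image stack container and TIFF round-trip.

A cartridge scan is stored as one 2-D intensity grid per fluorescence channel
on a shared pixel grid.  Stacks are written as multi-page TIFF with one page
per channel; the channel name and acquisition metadata travel in the page
description so a stack survives a round trip bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Mapping

import numpy as np
import tifffile

#: canonical channel names, in conventional acquisition order
CHANNEL_ORDER = ("DAPI", "CK", "CD45", "CD16", "WGA")

#: bit depth per image source: 12-bit CellTracks scanner, 16-bit LED microscope
SOURCE_BIT_DEPTH = {"celltracks": 12, "led": 16}


@dataclass
class ImageStack:
    """Named fluorescence channels on a common pixel grid.

    Parameters
    ----------
    channels
        Mapping channel name -> 2-D intensity array.  All channels must share
        one shape; intensities must lie in ``[0, 2**bit_depth - 1]``.
    pixel_pitch
        Pixel pitch in micrometer per pixel (0.64 for the CellTracks scanner).
    bit_depth
        Acquisition bit depth (12 for CellTracks, 16 for the LED microscope).
    source
        ``"celltracks"`` or ``"led"``; selects the 8-bit casting rule used for
        thumbnails downstream.
    """

    channels: Dict[str, np.ndarray]
    pixel_pitch: float = 0.64
    bit_depth: int = 12
    source: str = "celltracks"

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("ImageStack needs at least one channel")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        if self.source not in SOURCE_BIT_DEPTH:
            raise ValueError(f"unknown source {self.source!r}")
        shapes = {ch: np.asarray(img).shape for ch, img in self.channels.items()}
        first = next(iter(shapes.values()))
        if any(s != first for s in shapes.values()):
            raise ValueError(f"channel shapes differ: {shapes}")
        vmax = 2 ** self.bit_depth - 1
        for ch, img in self.channels.items():
            img = np.asarray(img)
            if img.ndim != 2:
                raise ValueError(f"channel {ch!r} is not a 2-D image")
            if img.min() < 0 or img.max() > vmax:
                raise ValueError(
                    f"channel {ch!r} exceeds the {self.bit_depth}-bit range [0, {vmax}]"
                )

    @property
    def shape(self) -> tuple:
        return next(iter(self.channels.values())).shape

    @property
    def max_value(self) -> int:
        return 2 ** self.bit_depth - 1


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write one TIFF page per channel; metadata goes in the page description."""
    path = Path(path)
    with tifffile.TiffWriter(path) as tif:
        for name, img in stack.channels.items():
            desc = json.dumps(
                {
                    "channel": name,
                    "pixel_pitch": stack.pixel_pitch,
                    "bit_depth": stack.bit_depth,
                    "source": stack.source,
                }
            )
            tif.write(np.asarray(img), description=desc, contiguous=False)


def read_stack(path: str | Path, required: Iterable[str] = ("DAPI",)) -> ImageStack:
    """Read a multi-page TIFF written by :func:`write_stack`.

    Raises
    ------
    KeyError
        If a channel listed in ``required`` is missing from the file.
    """
    path = Path(path)
    channels: Dict[str, np.ndarray] = {}
    meta: Mapping = {}
    with tifffile.TiffFile(path) as tif:
        for i, page in enumerate(tif.pages):
            desc = page.tags.get("ImageDescription")
            try:
                info = json.loads(desc.value) if desc is not None else {}
            except (TypeError, json.JSONDecodeError):
                info = {}
            name = info.get("channel", f"page{i}")
            channels[name] = page.asarray()
            if info:
                meta = info
    for name in required:
        if name not in channels:
            raise KeyError(f"stack {path} has no channel named {name!r}")
    return ImageStack(
        channels=channels,
        pixel_pitch=float(meta.get("pixel_pitch", 0.64)),
        bit_depth=int(meta.get("bit_depth", 12)),
        source=str(meta.get("source", "celltracks")),
    )
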