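"""Synthetic cartridge images with per-cell ground truth.

The simulator emulates what an EpCAM-enriched cartridge scan looks like to
the analysis code: 12-bit multi-channel images in which every nucleated cell
is a DAPI blob (a Gaussian-smoothed disk, or a chain of tangent disks for
doublets and clusters), membrane markers (CD45, CD16, wheat germ agglutinin)
are rings straddling the nucleus edge, and cytokeratin is a filled
cytoplasmic disk.  On top of the clean signal it renders the artifacts that
drove the analysis design: a smooth multiplicative illumination bias,
Poisson-Gaussian camera noise, fragmented marker staining, and cell densities
from near-empty cartridges to crowded fields where footprints merge.

Every rendered cell is recorded in a :class:`GroundTruthTable` with its
centroid, lineage class, cluster kind and rendered amplitudes, so detection,
gating and classification can be scored exactly.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter
from skimage import measure

from .io import ImageStack, write_stack

# lineage labels (the classifier owns the full set; the simulator renders these)
CTC = "CTC"
LEUK_CD45 = "LEUK_CD45"
LEUK_CD45_CD16 = "LEUK_CD45_CD16"
LEUK_CD16 = "LEUK_CD16"
BARE_NUCLEUS = "BARE_NUCLEUS"
UNSTAINED_CELL = "UNSTAINED_CELL"
NONSPECIFIC = "NONSPECIFIC"

#: channels required to render each class, beyond DAPI
_CLASS_CHANNELS = {
    CTC: ("CK",),
    LEUK_CD45: ("CD45",),
    LEUK_CD45_CD16: ("CD45", "CD16"),
    LEUK_CD16: ("CD16",),
    BARE_NUCLEUS: (),
    UNSTAINED_CELL: ("WGA",),
    NONSPECIFIC: ("CK", "CD45"),
}

CLUSTER_KINDS = ("single", "doublet", "small_cluster", "large_cluster")

#: number of nuclei per cluster kind (inclusive ranges)
_CLUSTER_SIZES = {
    "single": (1, 1),
    "doublet": (2, 2),
    "small_cluster": (3, 5),
    "large_cluster": (6, 8),
}

#: center-to-center spacing between chained nuclei, in nucleus radii
_CHAIN_SPACING = 1.95

#: marker geometry relative to the nucleus radius
_RING_INNER, _RING_OUTER = 0.8, 1.3  # membrane markers straddle the nucleus edge
_CK_RADIUS = 1.4                      # cytokeratin fills the cytoplasm


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


def _default_class_mix() -> Dict[str, float]:
    # granulocyte-dominated composition typical of an enriched patient sample
    return {
        CTC: 0.05,
        LEUK_CD45: 0.15,
        LEUK_CD45_CD16: 0.10,
        LEUK_CD16: 0.45,
        BARE_NUCLEUS: 0.15,
        UNSTAINED_CELL: 0.10,
    }


def _default_cluster_mix() -> Dict[str, float]:
    return {"single": 0.8, "doublet": 0.1, "small_cluster": 0.07, "large_cluster": 0.03}


def _default_gains() -> Dict[str, float]:
    return {"DAPI": 1500.0, "CK": 1200.0, "CD45": 1000.0, "CD16": 1000.0, "WGA": 800.0}


@dataclass
class SimulationConfig:
    """Study conditions of one simulated cartridge.

    Defaults describe a moderately crowded 12-bit CellTracks-style scan:
    0.64 um/pixel pitch, nuclei of 5 +- 0.8 um radius, background level 100
    with read noise sd 10 and Poisson shot noise, a 20% illumination bias on
    a 100 px spatial scale, and occasional fragmented marker staining.
    """

    image_size: Tuple[int, int] = (1024, 1024)
    pixel_pitch: float = 0.64
    n_cells: int = 500
    class_mix: Dict[str, float] = field(default_factory=_default_class_mix)
    cluster_mix: Dict[str, float] = field(default_factory=_default_cluster_mix)
    nucleus_radius_um: Tuple[float, float] = (5.0, 0.8)  # mean, sd
    channel_gains: Dict[str, float] = field(default_factory=_default_gains)
    illumination_bias: Tuple[float, float] = (0.2, 100.0)  # amplitude, scale px
    background: float = 100.0
    read_noise_sd: float = 10.0
    shot_noise: bool = True
    fragmentation_prob: float = 0.1
    panel: Tuple[str, ...] = ("DAPI", "CK", "CD45", "CD16", "WGA")
    min_distance_um: Optional[float] = None
    edge_policy: str = "replace"  # or "clip"
    bit_depth: int = 12
    source: str = "celltracks"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_pitch <= 0:
            raise ConfigurationError("pixel_pitch must be positive")
        if self.n_cells < 0:
            raise ConfigurationError("n_cells must be non-negative")
        for name, mix in (("class_mix", self.class_mix), ("cluster_mix", self.cluster_mix)):
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} probabilities sum to {total}, not 1")
            if any(p < 0 for p in mix.values()):
                raise ConfigurationError(f"{name} has negative probabilities")
        vmax = 2 ** self.bit_depth - 1
        for ch, g in self.channel_gains.items():
            if not 0 <= g <= vmax:
                raise ConfigurationError(f"gain for {ch} outside [0, {vmax}]")
        amp, _scale = self.illumination_bias
        if not 0 <= amp < 1:
            raise ConfigurationError("illumination bias amplitude must be in [0, 1)")
        if "DAPI" not in self.panel:
            raise ConfigurationError("panel must include DAPI")
        if self.edge_policy not in ("replace", "clip"):
            raise ConfigurationError("edge_policy must be 'replace' or 'clip'")
        for cls, prob in self.class_mix.items():
            if cls not in _CLASS_CHANNELS:
                raise ConfigurationError(f"unknown class {cls!r}")
            if prob > 0:
                missing = [c for c in _CLASS_CHANNELS[cls] if c not in self.panel]
                if missing:
                    raise ConfigurationError(
                        f"class {cls} needs channel(s) {missing} absent from panel"
                    )
        for kind in self.cluster_mix:
            if kind not in _CLUSTER_SIZES:
                raise ConfigurationError(f"unknown cluster kind {kind!r}")

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["image_size"] = list(self.image_size)
        data["nucleus_radius_um"] = list(self.nucleus_radius_um)
        data["illumination_bias"] = list(self.illumination_bias)
        data["panel"] = list(self.panel)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text())
        for key in ("image_size", "nucleus_radius_um", "illumination_bias", "panel"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class GroundTruthCell:
    cell_id: int
    centroid: Tuple[float, float]  # (row, col) pixels
    true_class: str
    cluster_kind: str
    rendered_amplitudes: Dict[str, float]
    nucleus_area_um2: float

    def __post_init__(self) -> None:
        if self.true_class not in _CLASS_CHANNELS:
            raise ValueError(f"unknown class {self.true_class!r}")
        if self.nucleus_area_um2 <= 0:
            raise ValueError("nucleus_area_um2 must be positive")


@dataclass
class GroundTruthTable:
    cells: List[GroundTruthCell]
    config: SimulationConfig

    def __post_init__(self) -> None:
        ids = [c.cell_id for c in self.cells]
        if len(ids) != len(set(ids)):
            raise ValueError("cell_ids must be unique")

    def __len__(self) -> int:
        return len(self.cells)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            row = {
                "cell_id": c.cell_id,
                "y": c.centroid[0],
                "x": c.centroid[1],
                "class": c.true_class,
                "cluster_kind": c.cluster_kind,
                "area_um2": c.nucleus_area_um2,
            }
            for ch, amp in c.rendered_amplitudes.items():
                row[f"amp_{ch}"] = amp
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def render_cluster(
    kind: str,
    radius_px: float,
    centroid: Tuple[float, float],
    rng: Optional[np.random.Generator] = None,
) -> Tuple[np.ndarray, Tuple[int, int], List[Tuple[float, float]]]:
    """Rasterize the nucleus footprint of one single/doublet/cluster.

    Nuclei in a multi-cell event are chained tangent disks (spacing 1.95 r)
    along a gently turning random walk, which keeps the footprint connected
    and gives the analytic P2A signature: ~1 for a single, ~2 for a doublet,
    ~k for a k-chain.

    Returns
    -------
    footprint : bool array
        Connected binary mask in a local frame.
    origin : (int, int)
        Full-image coordinates of the footprint's ``[0, 0]`` pixel.
    centers : list of (row, col)
        Disk centers in full-image coordinates.
    """
    if radius_px <= 0:
        raise ValueError("radius must be positive")
    if kind not in _CLUSTER_SIZES:
        raise ValueError(f"unknown cluster kind {kind!r}")
    rng = rng or np.random.default_rng()
    lo, hi = _CLUSTER_SIZES[kind]
    n_disks = int(rng.integers(lo, hi + 1))

    spacing = _CHAIN_SPACING * radius_px
    while True:
        centers = [np.zeros(2)]
        angle = rng.uniform(0.0, 2.0 * math.pi)
        for _ in range(n_disks - 1):
            angle += rng.uniform(-0.7, 0.7)
            centers.append(centers[-1] + spacing * np.array([math.sin(angle), math.cos(angle)]))
        centers = np.array(centers)
        centers -= centers.mean(axis=0)
        footprint = _rasterize_disks(centers, radius_px)
        if measure.label(footprint, connectivity=2).max() == 1:
            break
        spacing *= 0.95  # random walk folded onto itself; tighten and retry

    pad = int(math.ceil(radius_px)) + 1
    origin = (
        int(round(centroid[0])) - footprint.shape[0] // 2,
        int(round(centroid[1])) - footprint.shape[1] // 2,
    )
    local_off = np.array([pad, pad]) - centers.min(axis=0)
    abs_centers = [
        (float(c[0] + local_off[0] + origin[0]), float(c[1] + local_off[1] + origin[1]))
        for c in centers
    ]
    return footprint, origin, abs_centers


def _rasterize_disks(centers: np.ndarray, radius: float) -> np.ndarray:
    pad = int(math.ceil(radius)) + 1
    mins = centers.min(axis=0)
    span = centers.max(axis=0) - mins
    h = int(math.ceil(span[0])) + 2 * pad + 1
    w = int(math.ceil(span[1])) + 2 * pad + 1
    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.zeros((h, w), dtype=bool)
    for c in centers:
        cy, cx = c - mins + pad
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= radius * radius
    return mask


def make_bias_field(
    shape: Tuple[int, int],
    amplitude: float,
    scale: float,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Smooth multiplicative illumination field with mean exactly 1.

    The field is low-pass filtered white noise rescaled so its excursion from
    1 is at most ``amplitude``; ``scale`` is the correlation length in pixels.
    """
    if not 0 <= amplitude < 1:
        raise ValueError("bias amplitude must be in [0, 1)")
    if amplitude == 0:
        return np.ones(shape)
    rng = rng or np.random.default_rng()
    rough = rng.standard_normal(shape)
    smooth = gaussian_filter(rough, sigma=scale, mode="reflect")
    smooth -= smooth.mean()
    peak = np.abs(smooth).max()
    if peak > 0:
        smooth /= peak
    return 1.0 + amplitude * smooth


def apply_illumination_bias(
    image: np.ndarray,
    bias_amplitude: float,
    bias_scale: float,
    rng: Optional[np.random.Generator] = None,
    max_value: float = 4095.0,
    field: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Multiply an image by a smooth mean-1 bias field, clipped to bit depth.

    Pass ``field`` to reuse one field across channels (illumination is a
    property of the optics, not of the fluorophore).
    """
    image = np.asarray(image, dtype=float)
    if bias_amplitude == 0 and field is None:
        return image.copy()
    if field is None:
        field = make_bias_field(image.shape, bias_amplitude, bias_scale, rng)
    return np.clip(image * field, 0.0, max_value)


def _fragment_mask(shape: Tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Random binary patch mask with ~50% coverage, used to break up a stain."""
    noise = gaussian_filter(rng.standard_normal(shape), sigma=2.0, mode="reflect")
    return noise > np.median(noise)


def _paint(canvas: np.ndarray, origin: Tuple[int, int], patch: np.ndarray) -> None:
    """Add ``patch`` into ``canvas`` at ``origin``, clipping at the borders."""
    h, w = canvas.shape
    ph, pw = patch.shape
    r0, c0 = origin
    rr0, cc0 = max(r0, 0), max(c0, 0)
    rr1, cc1 = min(r0 + ph, h), min(c0 + pw, w)
    if rr0 >= rr1 or cc0 >= cc1:
        return
    canvas[rr0:rr1, cc0:cc1] += patch[rr0 - r0 : rr1 - r0, cc0 - c0 : cc1 - c0]


def _annulus(radius: float, inner: float, outer: float) -> np.ndarray:
    r_out = outer * radius
    size = 2 * int(math.ceil(r_out)) + 3
    c = size // 2
    yy, xx = np.mgrid[0:size, 0:size]
    d2 = (yy - c) ** 2 + (xx - c) ** 2
    return (d2 >= (inner * radius) ** 2) & (d2 <= r_out**2)


def _disk(radius: float) -> np.ndarray:
    size = 2 * int(math.ceil(radius)) + 3
    c = size // 2
    yy, xx = np.mgrid[0:size, 0:size]
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius * radius


def generate_sample(config: SimulationConfig) -> Tuple[ImageStack, GroundTruthTable]:
    """Render one cartridge and its ground truth; deterministic in the seed."""
    rng = np.random.default_rng(config.seed)
    h, w = config.image_size
    vmax = 2 ** config.bit_depth - 1
    canvases = {ch: np.zeros((h, w), dtype=float) for ch in config.panel}

    classes = list(config.class_mix)
    class_p = np.array([config.class_mix[c] for c in classes])
    kinds = list(config.cluster_mix)
    kind_p = np.array([config.cluster_mix[k] for k in kinds])
    mean_r, sd_r = config.nucleus_radius_um
    min_dist_px = (
        config.min_distance_um / config.pixel_pitch if config.min_distance_um else None
    )

    cells: List[GroundTruthCell] = []
    placed: List[np.ndarray] = []
    for cell_id in range(config.n_cells):
        true_class = classes[int(rng.choice(len(classes), p=class_p))]
        kind = kinds[int(rng.choice(len(kinds), p=kind_p))]
        radius_um = max(2.0, rng.normal(mean_r, sd_r))
        radius_px = radius_um / config.pixel_pitch

        footprint = origin = centers = None
        for _attempt in range(200):
            centroid = (rng.uniform(0, h), rng.uniform(0, w))
            fp, og, cs = render_cluster(kind, radius_px, centroid, rng)
            # the spacing constraint applies between individual nuclei, so a
            # long chain cannot brush against a neighbouring cell
            if min_dist_px is not None and placed:
                d = np.linalg.norm(
                    np.asarray(placed)[:, None, :] - np.asarray(cs)[None, :, :], axis=-1
                )
                if d.min() < min_dist_px:
                    continue
            in_bounds = (
                og[0] >= 0
                and og[1] >= 0
                and og[0] + fp.shape[0] <= h
                and og[1] + fp.shape[1] <= w
            )
            if in_bounds or config.edge_policy == "clip":
                footprint, origin, centers = fp, og, cs
                break
        if footprint is None:
            # spacing constraint unsatisfiable (placement near saturation):
            # fall back to an unconstrained in-bounds position
            warnings.warn(
                f"cell {cell_id}: min-distance placement failed; placing unconstrained",
                stacklevel=2,
            )
            for _attempt in range(200):
                centroid = (rng.uniform(0, h), rng.uniform(0, w))
                fp, og, cs = render_cluster(kind, radius_px, centroid, rng)
                if (og[0] >= 0 and og[1] >= 0 and og[0] + fp.shape[0] <= h
                        and og[1] + fp.shape[1] <= w):
                    break
            footprint, origin, centers = fp, og, cs
        placed.extend(np.asarray(c) for c in centers)

        amplitudes: Dict[str, float] = {}
        amp_jitter = rng.uniform(0.85, 1.15)
        dapi_amp = config.channel_gains.get("DAPI", 1500.0) * amp_jitter
        amplitudes["DAPI"] = dapi_amp
        _paint(canvases["DAPI"], origin, footprint.astype(float) * dapi_amp)

        marker_channels = _CLASS_CHANNELS[true_class]
        wants_wga = true_class != BARE_NUCLEUS and "WGA" in config.panel
        render_channels = set(marker_channels) | ({"WGA"} if wants_wga else set())
        for ch in sorted(render_channels):
            if ch not in config.panel:
                continue
            amp = config.channel_gains.get(ch, 800.0) * rng.uniform(0.85, 1.15)
            amplitudes[ch] = amp
            stamp = _disk(_CK_RADIUS * radius_px) if ch == "CK" else _annulus(
                radius_px, _RING_INNER, _RING_OUTER
            )
            for center in centers:
                blob = stamp.astype(float)
                if rng.uniform() < config.fragmentation_prob:
                    blob = blob * _fragment_mask(blob.shape, rng)
                blob_origin = (
                    int(round(center[0])) - stamp.shape[0] // 2,
                    int(round(center[1])) - stamp.shape[1] // 2,
                )
                _paint(canvases[ch], blob_origin, blob * amp)

        centroid_rc = (
            float(np.mean([c[0] for c in centers])),
            float(np.mean([c[1] for c in centers])),
        )
        # area of the un-clipped footprint; clipping at the edge is a render detail
        cells.append(
            GroundTruthCell(
                cell_id=cell_id,
                centroid=centroid_rc,
                true_class=true_class,
                cluster_kind=kind,
                rendered_amplitudes=amplitudes,
                nucleus_area_um2=float(footprint.sum()) * config.pixel_pitch**2,
            )
        )

    bias_amp, bias_scale = config.illumination_bias
    bias = make_bias_field((h, w), bias_amp, bias_scale, rng) if bias_amp > 0 else None

    channels: Dict[str, np.ndarray] = {}
    for ch in config.panel:
        img = gaussian_filter(canvases[ch], sigma=1.0, mode="reflect")
        img += config.background
        if bias is not None:
            img = img * bias
        if config.shot_noise:
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
        if config.read_noise_sd > 0:
            img = img + rng.normal(0.0, config.read_noise_sd, size=img.shape)
        channels[ch] = np.clip(np.round(img), 0, vmax).astype(np.uint16)

    stack = ImageStack(
        channels=channels,
        pixel_pitch=config.pixel_pitch,
        bit_depth=config.bit_depth,
        source=config.source,
    )
    return stack, GroundTruthTable(cells=cells, config=config)


def write_sample(
    stack: ImageStack, truth: GroundTruthTable, out_dir: str | Path
) -> None:
    """Write TIFF stack, ground-truth CSV and config echo YAML into a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_stack(stack, out / "cartridge.tiff")
    truth.to_csv(out / "ground_truth.csv")
    truth.config.to_yaml(out / "config.yaml")
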