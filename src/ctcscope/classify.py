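"""Nucleated-cell gating, cluster typing, lineage assignment, enumeration.

The gate keeps events whose DAPI signal looks like DNA staining: mean
fluorescence intensity >= 50 and standard deviation >= 20 (on the
background-filtered scale), nucleus size < 500 um^2 and roundness < 0.95.
Gated events are typed by the perimeter-to-area score (single < 1.5 <=
doublet < 2.5 <= small cluster < 4 <= large cluster) and counted as one event
each, regardless of how many nuclei they merge.

Lineage follows the marker-expression table: a marker is "present" when its
background-filtered mean intensity exceeds a small presence threshold
(an idealized "0 vs >0" column never holds exactly in noisy images).  A CTC
is cytokeratin-positive (mean >= 50, overlay with the nucleus > 0.4, stain
area > 9 um^2) without CD45 or CD16; leukocyte classes are the three CD45/CD16
combinations without cytokeratin; cytokeratin together with a leukocyte
marker means non-specific antibody binding.  When wheat germ agglutinin is in
the panel, marker-free events split into bare nuclei (no membrane) and
unstained cells (membrane present).

Population counts use the subsample-and-extrapolate rule: classify a random
10% of the gated events (at least 1000, at most 5000) and scale the per-class
counts back to the full total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .features import FeatureVector

CTC = "CTC"
LEUK_CD45 = "LEUK_CD45"
LEUK_CD45_CD16 = "LEUK_CD45_CD16"
LEUK_CD16 = "LEUK_CD16"
BARE_NUCLEUS = "BARE_NUCLEUS"
UNSTAINED_CELL = "UNSTAINED_CELL"
NONSPECIFIC = "NONSPECIFIC"
UNIDENTIFIED = "UNIDENTIFIED"

CLASS_LABELS = (
    CTC,
    LEUK_CD45,
    LEUK_CD45_CD16,
    LEUK_CD16,
    BARE_NUCLEUS,
    UNSTAINED_CELL,
    NONSPECIFIC,
    UNIDENTIFIED,
)

CLUSTER_KINDS = ("single", "doublet", "small_cluster", "large_cluster")


@dataclass(frozen=True)
class GatingConfig:
    """DNA-staining criteria selecting nucleated cells."""

    dapi_mean_min: float = 50.0
    dapi_sd_min: float = 20.0
    size_max_um2: float = 500.0
    roundness_max: float = 0.95

    def __post_init__(self) -> None:
        if min(self.dapi_mean_min, self.dapi_sd_min, self.size_max_um2, self.roundness_max) <= 0:
            raise ValueError("gating thresholds must be positive")


@dataclass(frozen=True)
class ClusterBands:
    """P2A band edges; left-closed as printed: [1.5, 2.5) is a doublet."""

    single_max: float = 1.5
    doublet_max: float = 2.5
    small_cluster_max: float = 4.0

    def __post_init__(self) -> None:
        if not self.single_max < self.doublet_max < self.small_cluster_max:
            raise ValueError("cluster bands must be strictly increasing")


@dataclass(frozen=True)
class ClassRuleSet:
    """Machine form of the marker-expression table.

    ``presence_threshold`` separates "0" from ">0" columns on the filtered
    intensity scale.  ``strict_wga`` additionally requires membrane staining
    for CTC and leukocyte rows (the table reads that way literally, but many
    genuine leukocytes lack detectable membrane stain, so it is off by
    default and the membrane column only drives the bare/unstained split).
    """

    presence_threshold: float = 5.0
    ctc_ck_mean_min: float = 50.0
    ctc_overlay_ck_min: float = 0.4
    ctc_ck_area_min_um2: float = 9.0
    strict_wga: bool = False

    def __post_init__(self) -> None:
        for v in (
            self.presence_threshold,
            self.ctc_ck_mean_min,
            self.ctc_overlay_ck_min,
            self.ctc_ck_area_min_um2,
        ):
            if v < 0:
                raise ValueError("rule thresholds must be non-negative")


@dataclass(frozen=True)
class SubsampleConfig:
    """Fraction and caps of the classification subsample."""

    fraction: float = 0.10
    min_events: int = 1000
    max_events: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        if self.min_events > self.max_events:
            raise ValueError("min_events must not exceed max_events")


@dataclass
class ClassifiedEvent:
    """Gate/cluster/lineage decision for one event."""

    event_id: int
    is_nucleated: bool
    cluster_kind: Optional[str]
    label: Optional[str]
    features: FeatureVector

    def __post_init__(self) -> None:
        if self.is_nucleated != (self.label is not None):
            raise ValueError("lineage label is assigned iff the event is nucleated")


def gate_nucleated(f: FeatureVector, g: GatingConfig | None = None) -> bool:
    """True iff the event passes all four DNA-staining criteria.

    Boundary semantics follow the printed thresholds: means and sds at the
    threshold pass (>=), sizes and roundness at the threshold fail (<).
    """
    g = g or GatingConfig()
    if "DAPI" not in f.channels:
        raise KeyError("feature vector has no DAPI statistics")
    return (
        f.dapi_mean >= g.dapi_mean_min
        and f.dapi_sd >= g.dapi_sd_min
        and f.dapi_area_um2 < g.size_max_um2
        and f.roundness < g.roundness_max
    )


def classify_cluster(p2a_value: float, bands: ClusterBands | None = None) -> str:
    """Map a P2A score to single/doublet/small_cluster/large_cluster."""
    if p2a_value < 0:
        raise ValueError("p2a must be non-negative")
    bands = bands or ClusterBands()
    if p2a_value < bands.single_max:
        return "single"
    if p2a_value < bands.doublet_max:
        return "doublet"
    if p2a_value < bands.small_cluster_max:
        return "small_cluster"
    return "large_cluster"


def count_nucleated(events: Sequence[ClassifiedEvent]) -> int:
    """Number of gated events; doublets and clusters count as one."""
    return sum(1 for e in events if e.is_nucleated)


def classify_lineage(
    f: FeatureVector,
    rules: ClassRuleSet | None = None,
    panel: Sequence[str] = ("DAPI", "CK", "CD45", "CD16", "WGA"),
) -> str:
    """Assign a gated event to one lineage label.

    Channels absent from the panel are treated as not present, so the CD16
    rules are inert on the base panel and the bare/unstained split only
    exists when the membrane stain was acquired.  The rules are mutually
    exclusive by construction; evaluation order (CTC, leukocytes,
    non-specific, bare/unstained) only breaks threshold-boundary ties.
    """
    rules = rules or ClassRuleSet()
    has_wga = "WGA" in panel

    def present(ch: str) -> bool:
        return ch in panel and f.mean(ch) > rules.presence_threshold

    ck, cd45, cd16, wga = (present(c) for c in ("CK", "CD45", "CD16", "WGA"))
    wga_ok = wga or not (rules.strict_wga and has_wga)

    if (
        ck
        and f.mean("CK") >= rules.ctc_ck_mean_min
        and not cd45
        and not cd16
        and f.overlay("CK") > rules.ctc_overlay_ck_min
        and f.area("CK") > rules.ctc_ck_area_min_um2
        and wga_ok
    ):
        return CTC
    if cd45 and not ck and not cd16 and f.overlay("CD45") > 0 and wga_ok:
        return LEUK_CD45
    if cd45 and cd16 and not ck and f.overlay("CD45") > 0 and f.overlay("CD16") > 0 and wga_ok:
        return LEUK_CD45_CD16
    if cd16 and not cd45 and not ck and f.overlay("CD16") > 0 and wga_ok:
        return LEUK_CD16
    if ck and (cd45 or cd16):
        return NONSPECIFIC
    if has_wga and not ck and not cd45 and not cd16:
        return UNSTAINED_CELL if wga else BARE_NUCLEUS
    return UNIDENTIFIED


def subsample_and_extrapolate(
    events: Sequence,
    config: SubsampleConfig | None = None,
    labeler: Optional[Callable[[object], str]] = None,
) -> Tuple[Dict[str, int], Dict[str, object]]:
    """Estimate per-class counts from a classified random subsample.

    Draws ``n = clamp(round(fraction * N), min(min_events, N), max_events)``
    events uniformly without replacement, labels them (``labeler`` defaults
    to the ``label`` attribute, or identity for plain strings) and scales the
    subsample counts back to ``N``.  Largest-remainder rounding guarantees
    the estimates sum to ``N`` exactly.

    Returns the per-class estimates and a provenance record
    (``n``, ``total``, ``fraction``, ``seed``, ``extrapolation_factor``).
    """
    config = config or SubsampleConfig()
    n_total = len(events)
    provenance: Dict[str, object] = {
        "total": n_total,
        "fraction": config.fraction,
        "seed": config.seed,
    }
    if n_total == 0:
        provenance.update(n=0, extrapolation_factor=0.0)
        return {}, provenance

    if labeler is None:
        labeler = lambda e: e if isinstance(e, str) else e.label

    n = int(round(config.fraction * n_total))
    n = max(n, min(config.min_events, n_total))
    n = min(n, config.max_events, n_total)
    rng = np.random.default_rng(config.seed)
    chosen = rng.choice(n_total, size=n, replace=False)

    counts: Dict[str, int] = {}
    for i in chosen:
        lbl = labeler(events[i])
        counts[lbl] = counts.get(lbl, 0) + 1

    estimates = _largest_remainder(
        {lbl: n_total * c / n for lbl, c in counts.items()}, n_total
    )
    provenance.update(n=n, extrapolation_factor=n_total / n)
    return estimates, provenance


def _largest_remainder(raw: Mapping[str, float], total: int) -> Dict[str, int]:
    """Round fractional counts to integers that sum exactly to ``total``."""
    floors = {k: int(math.floor(v)) for k, v in raw.items()}
    remainder = total - sum(floors.values())
    order = sorted(raw, key=lambda k: (-(raw[k] - floors[k]), k))
    for k in order[:remainder]:
        floors[k] += 1
    return floors
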