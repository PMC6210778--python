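"""End-to-end sample analysis: filter, segment, gate, classify, enumerate.

``analyze_sample`` runs the whole chain on an :class:`~ctcscope.io.ImageStack`
and returns a :class:`SampleReport` (totals, per-class counts and fractions,
subsampling provenance) together with the per-event decisions.  Helpers score
a run against simulator ground truth and export the event table as CSV.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .classify import (
    ClassifiedEvent,
    ClassRuleSet,
    ClusterBands,
    GatingConfig,
    SubsampleConfig,
    classify_cluster,
    classify_lineage,
    count_nucleated,
    gate_nucleated,
    subsample_and_extrapolate,
)
from .features import ChannelStats, FeatureVector, intensity_stats, overlay_fraction
from .features import area_um2 as _area_um2
from .features import p2a as _p2a
from .features import perimeter_um as _perimeter_um
from .features import roundness as _roundness
from .filtering import FilterConfig, fourier_background_filter
from .io import ImageStack
from .segmentation import EventMask, ThresholdPolicy, segment_events
from .simulate import GroundTruthTable


def compute_event_features(
    event: EventMask,
    filtered: Mapping[str, np.ndarray],
    pixel_pitch: float,
) -> FeatureVector:
    """Measure one segmented event on the background-filtered channels."""
    nucleus = event.nucleus
    channels: Dict[str, ChannelStats] = {}
    for ch in filtered:
        mask = event.masks.get(ch)
        if ch == "DAPI":
            mask = nucleus
        if mask is None or not mask.any():
            channels[ch] = ChannelStats()
            continue
        mean, sd = intensity_stats(mask, event.crop(np.asarray(filtered[ch], dtype=float)))
        channels[ch] = ChannelStats(
            mean=mean,
            sd=sd,
            area_um2=_area_um2(mask, pixel_pitch),
            overlay=overlay_fraction(nucleus, mask),
        )
    area = _area_um2(nucleus, pixel_pitch)
    degenerate = int(nucleus.sum()) < 4
    if degenerate:
        rnd, shape_p2a, perim = 1.0, math.inf, 0.0
    else:
        perim = _perimeter_um(nucleus, pixel_pitch)
        rnd = _roundness(nucleus)
        shape_p2a = _p2a(nucleus)
    return FeatureVector(
        channels=channels,
        dapi_area_um2=area,
        perimeter_um=perim,
        roundness=rnd,
        p2a=shape_p2a,
        degenerate=degenerate,
    )


def classify_events(
    events: Sequence[EventMask],
    filtered: Mapping[str, np.ndarray],
    pixel_pitch: float,
    *,
    gating: GatingConfig | None = None,
    bands: ClusterBands | None = None,
    rules: ClassRuleSet | None = None,
    panel: Optional[Sequence[str]] = None,
) -> List[ClassifiedEvent]:
    """Gate and classify a list of segmented events."""
    panel = tuple(panel) if panel is not None else tuple(filtered)
    out: List[ClassifiedEvent] = []
    for ev in events:
        f = compute_event_features(ev, filtered, pixel_pitch)
        nucleated = gate_nucleated(f, gating)
        out.append(
            ClassifiedEvent(
                event_id=ev.event_id,
                is_nucleated=nucleated,
                cluster_kind=classify_cluster(f.p2a, bands) if nucleated else None,
                label=classify_lineage(f, rules, panel) if nucleated else None,
                features=f,
            )
        )
    return out


@dataclass
class SampleReport:
    """Per-sample totals, per-class counts/fractions, subsample provenance."""

    sample_id: str
    cohort: Optional[str] = None
    total_events: int = 0
    total_nucleated: int = 0
    class_counts: Dict[str, int] = field(default_factory=dict)
    extrapolated_counts: Optional[Dict[str, int]] = None
    subsample: Optional[Dict[str, object]] = None

    @property
    def class_fractions(self) -> Dict[str, float]:
        if self.total_nucleated == 0:
            return {k: 0.0 for k in self.class_counts}
        return {k: v / self.total_nucleated for k, v in self.class_counts.items()}

    def to_json(self, path: str | Path) -> None:
        data = {
            "sample_id": self.sample_id,
            "cohort": self.cohort,
            "total_events": self.total_events,
            "total_nucleated": self.total_nucleated,
            "class_counts": self.class_counts,
            "class_fractions": self.class_fractions,
            "extrapolated_counts": self.extrapolated_counts,
            "subsample": self.subsample,
        }
        Path(path).write_text(json.dumps(data, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SampleReport":
        data = json.loads(Path(path).read_text())
        return cls(
            sample_id=data["sample_id"],
            cohort=data.get("cohort"),
            total_events=data["total_events"],
            total_nucleated=data["total_nucleated"],
            class_counts=data.get("class_counts", {}),
            extrapolated_counts=data.get("extrapolated_counts"),
            subsample=data.get("subsample"),
        )


def analyze_sample(
    stack: ImageStack,
    *,
    sample_id: str = "sample",
    cohort: Optional[str] = None,
    filter_config: FilterConfig | None = None,
    policy: ThresholdPolicy | None = None,
    gating: GatingConfig | None = None,
    bands: ClusterBands | None = None,
    rules: ClassRuleSet | None = None,
    subsample: SubsampleConfig | None = None,
    panel: Optional[Sequence[str]] = None,
) -> Tuple[SampleReport, List[ClassifiedEvent]]:
    """Run the full pipeline on one stack.

    When ``subsample`` is given, the reported ``extrapolated_counts`` come
    from classifying only the subsample; ``class_counts`` always reflect the
    full classification (useful for validation).
    """
    filtered = {
        ch: fourier_background_filter(img, filter_config)
        for ch, img in stack.channels.items()
    }
    events = segment_events(filtered, policy)
    classified = classify_events(
        events, filtered, stack.pixel_pitch,
        gating=gating, bands=bands, rules=rules, panel=panel,
    )
    gated = [e for e in classified if e.is_nucleated]
    counts: Dict[str, int] = {}
    for e in gated:
        counts[e.label] = counts.get(e.label, 0) + 1

    extrapolated = provenance = None
    if subsample is not None:
        extrapolated, provenance = subsample_and_extrapolate(gated, subsample)

    report = SampleReport(
        sample_id=sample_id,
        cohort=cohort,
        total_events=len(classified),
        total_nucleated=count_nucleated(classified),
        class_counts=counts,
        extrapolated_counts=extrapolated,
        subsample=provenance,
    )
    return report, classified


def events_to_frame(events: Sequence[ClassifiedEvent]) -> pd.DataFrame:
    """Feature table: one row per event, lineage and cluster decisions included."""
    rows = []
    for e in events:
        row: Dict[str, object] = {
            "event_id": e.event_id,
            "is_nucleated": e.is_nucleated,
            "cluster_kind": e.cluster_kind,
            "label": e.label,
            "dapi_area_um2": e.features.dapi_area_um2,
            "roundness": e.features.roundness,
            "p2a": e.features.p2a,
        }
        for ch, st in e.features.channels.items():
            key = ch.lower()
            row[f"{key}_mean"] = st.mean
            row[f"{key}_sd"] = st.sd
            row[f"{key}_area_um2"] = st.area_um2
            row[f"{key}_overlay"] = st.overlay
        rows.append(row)
    return pd.DataFrame(rows)


def events_to_csv(events: Sequence[ClassifiedEvent], path: str | Path) -> None:
    events_to_frame(events).to_csv(path, index=False)


def evaluate_against_truth(
    events: Sequence[EventMask],
    classified: Sequence[ClassifiedEvent],
    truth: GroundTruthTable,
) -> Dict[str, object]:
    """Score detection and classification against simulator ground truth.

    A ground-truth cell is detected when its centroid falls inside an event's
    nucleus mask; an event merging several cells inherits the majority class
    (ties broken by cell order).  Returns detection recall/precision and, per
    true class, the fraction of matched gated events whose assigned label is
    correct, plus a confusion table.
    """
    by_id = {e.event_id: e for e in classified}
    h = w = 0
    owner: Dict[Tuple[int, int], int] = {}
    label_img = None
    if events:
        shape = _full_shape(events)
        label_img = np.full(shape, -1, dtype=int)
        for ev in events:
            r0, c0, r1, c1 = ev.bbox
            sub = label_img[r0:r1, c0:c1]
            sub[ev.nucleus] = ev.event_id

    matches: Dict[int, List[str]] = {}
    n_detected = 0
    for cell in truth.cells:
        if label_img is None:
            continue
        r = min(max(int(round(cell.centroid[0])), 0), label_img.shape[0] - 1)
        c = min(max(int(round(cell.centroid[1])), 0), label_img.shape[1] - 1)
        ev_id = int(label_img[r, c])
        if ev_id >= 0:
            n_detected += 1
            matches.setdefault(ev_id, []).append(cell.true_class)

    confusion: Dict[Tuple[str, str], int] = {}
    per_class_total: Dict[str, int] = {}
    per_class_correct: Dict[str, int] = {}
    for ev_id, true_classes in matches.items():
        ev = by_id.get(ev_id)
        if ev is None or not ev.is_nucleated:
            continue
        majority = max(set(true_classes), key=true_classes.count)
        confusion[(majority, ev.label)] = confusion.get((majority, ev.label), 0) + 1
        per_class_total[majority] = per_class_total.get(majority, 0) + 1
        if ev.label == majority:
            per_class_correct[majority] = per_class_correct.get(majority, 0) + 1

    n_truth = len(truth.cells)
    n_events = len(events)
    return {
        "recall": n_detected / n_truth if n_truth else float("nan"),
        "precision": len(matches) / n_events if n_events else float("nan"),
        "per_class_accuracy": {
            cls: per_class_correct.get(cls, 0) / tot
            for cls, tot in per_class_total.items()
        },
        "confusion": confusion,
        "n_matched_gated": sum(per_class_total.values()),
    }


def _full_shape(events: Sequence[EventMask]) -> Tuple[int, int]:
    return (
        max(e.bbox[2] for e in events),
        max(e.bbox[3] for e in events),
    )
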