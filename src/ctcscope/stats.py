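"""Cohort-level summaries and nonparametric comparisons.

Nucleated-cell counts are heavily right-skewed across samples, so cohort
comparisons use the two-sided Mann-Whitney U test on log10(count + 1)
transformed totals.  For small groups (smaller group <= 8 and at most 25
observations in total) the p-value is exact, computed by enumerating every
assignment of the pooled observations to the two groups; larger problems use
the normal approximation with tie correction.  No multiple-testing adjustment
is applied by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import json
import numpy as np
import pandas as pd
from scipy import stats as sps

from .pipeline import SampleReport

EXACT_MIN_GROUP = 8
EXACT_MAX_TOTAL = 25


def mann_whitney(counts_a: Sequence[float], counts_b: Sequence[float]) -> Tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of the first group, p).

    Exact when ``min(n1, n2) <= 8`` and ``n1 + n2 <= 25``: the null
    distribution of U is enumerated over all C(n1+n2, n1) group assignments
    (midranks handle ties), and p is the probability of a U at least as far
    from its mean as observed.  Otherwise the normal approximation with tie
    correction is used.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)

    if min(n1, n2) <= EXACT_MIN_GROUP and n1 + n2 <= EXACT_MAX_TOTAL:
        mu = n1 * n2 / 2.0
        observed_dev = abs(u1 - mu)
        n_extreme = 0
        n_total = 0
        base = n1 * (n1 + 1) / 2.0
        for combo in combinations(range(n1 + n2), n1):
            u = ranks[list(combo)].sum() - base
            n_total += 1
            if abs(u - mu) >= observed_dev - 1e-9:
                n_extreme += 1
        return u1, n_extreme / n_total

    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return u1, float(res.pvalue)


def log_transform_counts(counts: Sequence[float]) -> np.ndarray:
    """``log10(count + 1)``; the +1 offset accommodates zero counts."""
    x = np.asarray(counts, dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    return np.log10(x + 1.0)


def replicate_cv(replicate_counts: Sequence[float]) -> float:
    """Coefficient of variation in percent: 100 * sample sd / mean."""
    x = np.asarray(replicate_counts, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two replicates")
    mean = x.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(100.0 * x.std(ddof=1) / mean)


@dataclass
class CohortSummary:
    """Per-class location/spread per cohort plus the cohort comparison."""

    cohorts: Tuple[str, str]
    per_class: Dict[str, Dict[str, Dict[str, float]]]  # cohort -> class -> stats
    totals: Dict[str, Dict[str, float]]  # cohort -> stats of total nucleated
    u_statistic: float
    p_value: float
    degenerate_sd: bool = False  # some cohort had a single sample

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "cohorts": list(self.cohorts),
            "per_class": self.per_class,
            "totals": self.totals,
            "u_statistic": self.u_statistic,
            "p_value": self.p_value,
            "degenerate_sd": self.degenerate_sd,
        }, indent=2))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cohort, classes in self.per_class.items():
            for cls, st in classes.items():
                rows.append({"cohort": cohort, "class": cls, **st})
        return pd.DataFrame(rows)


def _column_stats(values: np.ndarray) -> Dict[str, float]:
    degenerate = values.size < 2
    return {
        "mean": float(values.mean()),
        "sd": 0.0 if degenerate else float(values.std(ddof=1)),
        "median": float(np.median(values)),
        "min": float(values.min()),
        "max": float(values.max()),
        "n": int(values.size),
    }


def summarize_cohort(
    reports: Sequence[SampleReport],
    cohorts: Tuple[str, str] = ("patient", "control"),
) -> CohortSummary:
    """Summarize per-class counts per cohort and compare log totals.

    Raises on an unknown cohort label or an empty cohort.  With one sample in
    a cohort the sd is reported as 0 and flagged ``degenerate_sd``.
    """
    available = {r.cohort for r in reports}
    for c in cohorts:
        if c not in available:
            raise ValueError(f"no reports labeled cohort {c!r}")

    class_names = sorted({cls for r in reports for cls in r.class_counts})
    per_class: Dict[str, Dict[str, Dict[str, float]]] = {}
    totals: Dict[str, Dict[str, float]] = {}
    degenerate = False
    grouped = {c: [r for r in reports if r.cohort == c] for c in cohorts}
    for cohort, rs in grouped.items():
        per_class[cohort] = {}
        for cls in class_names:
            vals = np.array([r.class_counts.get(cls, 0) for r in rs], dtype=float)
            st = _column_stats(vals)
            degenerate |= st["n"] < 2
            per_class[cohort][cls] = st
        tot = np.array([r.total_nucleated for r in rs], dtype=float)
        totals[cohort] = _column_stats(tot)

    log_a = log_transform_counts([r.total_nucleated for r in grouped[cohorts[0]]])
    log_b = log_transform_counts([r.total_nucleated for r in grouped[cohorts[1]]])
    u, p = mann_whitney(log_a, log_b)
    return CohortSummary(
        cohorts=cohorts,
        per_class=per_class,
        totals=totals,
        u_statistic=u,
        p_value=p,
        degenerate_sd=degenerate,
    )
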