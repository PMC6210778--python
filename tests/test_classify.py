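"""Gating boundaries, cluster bands, lineage table, subsample-extrapolation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctcscope.classify import (
    CLASS_LABELS,
    ClassRuleSet,
    ClusterBands,
    GatingConfig,
    SubsampleConfig,
    classify_cluster,
    classify_lineage,
    count_nucleated,
    gate_nucleated,
    subsample_and_extrapolate,
    ClassifiedEvent,
)
from .conftest import LINEAGE_ARCHETYPES, make_feature_vector as fv


class TestGateBoundaries:
    def test_typical_cell_passes(self):
        assert gate_nucleated(fv(dapi_mean=100, dapi_sd=30, area=80, rnd=0.3))

    @pytest.mark.parametrize(
        "kwargs,expected",
        [
            (dict(dapi_mean=49.999), False),   # mean below threshold fails
            (dict(dapi_mean=50.0), True),      # >= 50 passes at the boundary
            (dict(dapi_sd=19.999), False),
            (dict(dapi_sd=20.0), True),        # >= 20 passes at the boundary
            (dict(area=500.0), False),         # < 500 um^2: boundary fails
            (dict(area=499.9), True),
            (dict(rnd=0.95), False),           # < 0.95: boundary fails
            (dict(rnd=0.949), True),
        ],
    )
    def test_printed_boundary_semantics(self, kwargs, expected):
        assert gate_nucleated(fv(**kwargs)) is expected

    def test_missing_dapi_rejected(self):
        f = fv()
        del f.channels["DAPI"]
        with pytest.raises(KeyError):
            gate_nucleated(f)

    def test_gate_monotone_in_mean_threshold(self, rng):
        vectors = [
            fv(dapi_mean=m, dapi_sd=s, area=a, rnd=r)
            for m, s, a, r in zip(
                rng.uniform(0, 200, 200), rng.uniform(0, 60, 200),
                rng.uniform(1, 600, 200), rng.uniform(0, 1, 200),
            )
        ]
        counts = []
        for mean_min in (10.0, 50.0, 90.0):
            g = GatingConfig(dapi_mean_min=mean_min)
            counts.append(sum(gate_nucleated(f, g) for f in vectors))
        assert counts == sorted(counts, reverse=True)


class TestClusterBands:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (1.0, "single"),
            (0.97, "single"),        # discretization undershoot stays single
            (1.5, "doublet"),        # band edges are left-closed
            (2.49, "doublet"),
            (2.5, "small_cluster"),
            (4.0, "large_cluster"),
            (8.0, "large_cluster"),
        ],
    )
    def test_band_assignment(self, value, expected):
        assert classify_cluster(value) == expected

    def test_bands_must_increase(self):
        with pytest.raises(ValueError):
            ClusterBands(single_max=3.0, doublet_max=2.5)

    def test_negative_p2a_rejected(self):
        with pytest.raises(ValueError):
            classify_cluster(-0.1)


class TestCounting:
    def test_clusters_count_as_one(self):
        events = []
        for i, kind in enumerate(["single"] * 3 + ["doublet"] * 2 + ["large_cluster"]):
            events.append(ClassifiedEvent(
                event_id=i, is_nucleated=True, cluster_kind=kind,
                label="BARE_NUCLEUS", features=fv(),
            ))
        assert count_nucleated(events) == 6

    def test_empty_list(self):
        assert count_nucleated([]) == 0


class TestLineageTable:
    @pytest.mark.parametrize("label", sorted(LINEAGE_ARCHETYPES))
    def test_archetype_maps_to_its_row(self, label):
        assert classify_lineage(fv(**LINEAGE_ARCHETYPES[label])) == label

    def test_dim_cytokeratin_is_not_a_ctc(self):
        # present but below the CTC intensity rule -> no other row matches
        f = fv(ck=30.0, ck_overlay=0.5, ck_area=12.0, wga=50.0)
        assert classify_lineage(f) == "UNIDENTIFIED"

    def test_ck_with_either_leukocyte_marker_is_nonspecific(self):
        f = fv(ck=60.0, ck_overlay=0.5, ck_area=12.0, cd16=35.0, cd16_overlay=0.3)
        assert classify_lineage(f) == "NONSPECIFIC"

    def test_cd16_rules_inert_without_cd16_channel(self):
        panel = ("DAPI", "CK", "CD45")
        f = fv(cd45=40.0, cd45_overlay=0.3, cd16=35.0, cd16_overlay=0.3)
        assert classify_lineage(f, panel=panel) == "LEUK_CD45"

    def test_no_bare_unstained_split_without_membrane_channel(self):
        panel = ("DAPI", "CK", "CD45", "CD16")
        assert classify_lineage(fv(), panel=panel) == "UNIDENTIFIED"

    def test_strict_wga_demotes_unstained_leukocyte(self):
        rules = ClassRuleSet(strict_wga=True)
        f = fv(cd45=40.0, cd45_overlay=0.3, wga=0.0)
        assert classify_lineage(f, rules) == "UNIDENTIFIED"
        assert classify_lineage(fv(cd45=40.0, cd45_overlay=0.3, wga=50.0), rules) == "LEUK_CD45"

    def test_exhaustive_and_exclusive_over_random_vectors(self, rng):
        # every gated vector receives exactly one label from the label set
        for _ in range(10_000):
            f = fv(
                ck=rng.uniform(0, 120), cd45=rng.uniform(0, 80),
                cd16=rng.uniform(0, 80), wga=rng.uniform(0, 80),
                ck_overlay=rng.uniform(0, 1), cd45_overlay=rng.uniform(0, 1),
                cd16_overlay=rng.uniform(0, 1), ck_area=rng.uniform(0, 30),
            )
            label = classify_lineage(f)
            assert label in CLASS_LABELS


class TestSubsample:
    @staticmethod
    def _labels(rng, n, p_ctc=0.1):
        return list(rng.choice(["CTC", "LEUK_CD45"], size=n, p=[p_ctc, 1 - p_ctc]))

    def test_small_sample_is_exact(self, rng):
        labels = self._labels(rng, 400)
        estimates, prov = subsample_and_extrapolate(labels, SubsampleConfig(seed=3))
        assert prov["n"] == 400  # below the floor: everything is used
        truth = {lbl: labels.count(lbl) for lbl in set(labels)}
        assert estimates == truth

    def test_caps_enforced(self):
        labels = ["LEUK_CD45"] * 100_000
        _, prov = subsample_and_extrapolate(labels, SubsampleConfig(seed=0))
        assert prov["n"] == 5000
        labels = ["LEUK_CD45"] * 4000
        _, prov = subsample_and_extrapolate(labels, SubsampleConfig(seed=0))
        assert prov["n"] == 1000  # floor when 10% < 1000

    def test_estimates_sum_to_total(self, rng):
        for n in (1500, 20_000):
            labels = list(rng.choice(list("abcde"), size=n))
            estimates, _ = subsample_and_extrapolate(labels, SubsampleConfig(seed=1))
            assert sum(estimates.values()) == n

    def test_empty_sample(self):
        estimates, prov = subsample_and_extrapolate([], SubsampleConfig())
        assert estimates == {}
        assert prov["n"] == 0

    def test_deterministic_in_seed(self, rng):
        labels = self._labels(rng, 30_000)
        a, _ = subsample_and_extrapolate(labels, SubsampleConfig(seed=7))
        b, _ = subsample_and_extrapolate(labels, SubsampleConfig(seed=7))
        assert a == b

    def test_unbiased_over_seeds(self, rng):
        # smaller companion of the full Monte-Carlo check in the acceptance suite
        labels = self._labels(rng, 12_000, p_ctc=0.2)
        truth = labels.count("CTC")
        estimates = [
            subsample_and_extrapolate(labels, SubsampleConfig(seed=s))[0].get("CTC", 0)
            for s in range(50)
        ]
        n = 1200
        sd_mean = 12_000 * np.sqrt(0.2 * 0.8 / n) / np.sqrt(len(estimates))
        assert abs(np.mean(estimates) - truth) <= 3 * sd_mean


class TestProperties:
    @settings(derandomize=True, max_examples=80, deadline=None)
    @given(
        labels=st.lists(st.sampled_from(["a", "b", "c"]), min_size=1, max_size=400),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_extrapolation_conserves_total(self, labels, seed):
        config = SubsampleConfig(fraction=0.3, min_events=5, max_events=50, seed=seed)
        estimates, _ = subsample_and_extrapolate(labels, config)
        assert sum(estimates.values()) == len(labels)
        assert all(v >= 0 for v in estimates.values())

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(value=st.floats(min_value=0.0, max_value=50.0, allow_nan=False))
    def test_cluster_bands_partition_the_axis(self, value):
        kind = classify_cluster(value)
        bands = ClusterBands()
        expected = (
            "single" if value < bands.single_max
            else "doublet" if value < bands.doublet_max
            else "small_cluster" if value < bands.small_cluster_max
            else "large_cluster"
        )
        assert kind == expected
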