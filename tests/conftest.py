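"""Shared fixtures: geometric masks and simulated cartridges with truth."""

from __future__ import annotations

import numpy as np
import pytest

import ctcscope as cs
from ctcscope.filtering import fourier_background_filter
from ctcscope.pipeline import classify_events
from ctcscope.segmentation import segment_events


def make_feature_vector(
    dapi_mean=100.0, dapi_sd=30.0, area=80.0, rnd=0.3, p2a_value=1.1,
    ck=0.0, cd45=0.0, cd16=0.0, wga=0.0,
    ck_overlay=0.0, cd45_overlay=0.0, cd16_overlay=0.0, ck_area=0.0,
):
    """Hand-built per-event measurements; defaults pass the nucleated gate."""
    from ctcscope.features import ChannelStats, FeatureVector

    channels = {
        "DAPI": ChannelStats(mean=dapi_mean, sd=dapi_sd, area_um2=area, overlay=1.0),
        "CK": ChannelStats(mean=ck, overlay=ck_overlay, area_um2=ck_area),
        "CD45": ChannelStats(mean=cd45, overlay=cd45_overlay),
        "CD16": ChannelStats(mean=cd16, overlay=cd16_overlay),
        "WGA": ChannelStats(mean=wga, overlay=0.5 if wga > 0 else 0.0),
    }
    return FeatureVector(channels=channels, dapi_area_um2=area,
                         roundness=rnd, p2a=p2a_value)


#: one marker-expression archetype per population of the lineage table
LINEAGE_ARCHETYPES = {
    "CTC": dict(ck=60.0, ck_overlay=0.5, ck_area=12.0, wga=50.0),
    "LEUK_CD45": dict(cd45=40.0, cd45_overlay=0.3, wga=50.0),
    "LEUK_CD45_CD16": dict(cd45=40.0, cd45_overlay=0.3, cd16=35.0,
                           cd16_overlay=0.3, wga=50.0),
    "LEUK_CD16": dict(cd16=35.0, cd16_overlay=0.3, wga=50.0),
    "BARE_NUCLEUS": dict(),
    "UNSTAINED_CELL": dict(wga=50.0),
    "NONSPECIFIC": dict(ck=60.0, ck_overlay=0.5, ck_area=12.0,
                        cd45=40.0, cd45_overlay=0.3, wga=50.0),
}


def disk_mask(radius: float, centers=((0.0, 0.0),)) -> np.ndarray:
    """Rasterize one or more disks (dist <= r) on a tight canvas."""
    pad = int(np.ceil(radius)) + 2
    cs_ = np.array(centers, dtype=float)
    h = int(cs_[:, 0].max() - cs_[:, 0].min() + 2 * pad + 3)
    w = int(cs_[:, 1].max() - cs_[:, 1].min() + 2 * pad + 3)
    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.zeros((h, w), dtype=bool)
    offset = np.array([pad + 1, pad + 1]) - cs_.min(axis=0)
    for c in cs_:
        cy, cx = c + offset
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= radius * radius
    return mask


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


def make_clean_config(seed: int = 11, n_cells: int = 110) -> cs.SimulationConfig:
    """Noise-free, bias-free, unfragmented sparse cartridge with all classes."""
    return cs.SimulationConfig(
        image_size=(1024, 1024),
        n_cells=n_cells,
        min_distance_um=42.0,
        illumination_bias=(0.0, 100.0),
        read_noise_sd=0.0,
        shot_noise=False,
        fragmentation_prob=0.0,
        cluster_mix={"single": 0.85, "doublet": 0.09, "small_cluster": 0.04,
                     "large_cluster": 0.02},
        class_mix={
            "CTC": 0.15, "LEUK_CD45": 0.17, "LEUK_CD45_CD16": 0.17,
            "LEUK_CD16": 0.17, "BARE_NUCLEUS": 0.17, "UNSTAINED_CELL": 0.17,
        },
        seed=seed,
    )


@pytest.fixture(scope="session")
def clean_sample():
    """Simulated sample plus every intermediate the pipeline produces."""
    config = make_clean_config()
    stack, truth = cs.generate_sample(config)
    filtered = {
        ch: fourier_background_filter(img) for ch, img in stack.channels.items()
    }
    events = segment_events(filtered)
    classified = classify_events(events, filtered, stack.pixel_pitch)
    return {
        "config": config,
        "stack": stack,
        "truth": truth,
        "filtered": filtered,
        "events": events,
        "classified": classified,
    }


@pytest.fixture(scope="session")
def noisy_sample():
    """Default-artifact sample (bias, noise, fragmentation) at moderate density."""
    config = cs.SimulationConfig(
        image_size=(512, 512), n_cells=60, min_distance_um=30.0, seed=1
    )
    stack, truth = cs.generate_sample(config)
    filtered = {
        ch: fourier_background_filter(img) for ch, img in stack.channels.items()
    }
    events = segment_events(filtered)
    classified = classify_events(events, filtered, stack.pixel_pitch)
    return {
        "config": config,
        "stack": stack,
        "truth": truth,
        "filtered": filtered,
        "events": events,
        "classified": classified,
    }
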