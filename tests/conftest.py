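"""Shared fixtures: a small synthetic study reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest
import shapely.geometry as sg

from telemax import lifehistory as lh
from telemax import telemetry as tm
from telemax.synthio import SimConfig, simulate


@pytest.fixture(scope="session")
def small_sim():
    """A compact multi-group study: 14 individuals on a 120-km grid."""
    cfg = SimConfig(
        nrows=120,
        ncols=120,
        resolution=1000.0,
        group_counts={
            "adult_migrant": 2,
            "adult_resident_breeder": 3,
            "adult_resident_floater": 3,
            "nonadult_resident": 4,
            "nonadult_migrant": 2,
        },
        n_winter_patches=2,
        min_patch_separation_m=40_000.0,
        seed=3,
    )
    stack, truth, fixes, meta = simulate(cfg)
    return {"cfg": cfg, "stack": stack, "truth": truth, "fixes": fixes, "meta": meta}


@pytest.fixture(scope="session")
def filtered_sim(small_sim):
    """The small study taken through proofing + season/daytime filtering."""
    fixes = small_sim["fixes"]
    f1, _ = tm.argos_class_filter(fixes)
    f2, _ = tm.spike_filter(f1)
    f3, _ = tm.velocity_filter(f2)
    f4, _ = tm.hourly_subsample(f3)
    winter, summer, _ = tm.season_daytime_filter(f4)
    return {**small_sim, "winter": winter, "summer": summer, "hourly": f4}


@pytest.fixture(scope="session")
def classified_sim(filtered_sim):
    grid = filtered_sim["stack"].grid
    study_area = sg.box(*grid.extent)
    labels, retained = lh.classify_all(
        filtered_sim["winter"],
        filtered_sim["summer"],
        filtered_sim["meta"],
        study_area,
        grid.crs,
    )
    return {**filtered_sim, "labels": labels, "retained": retained, "study_area": study_area}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
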