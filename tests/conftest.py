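"""Shared fixtures: small geometries and seeded synthetic populations."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import gazesat as gs


@pytest.fixture(scope="session")
def small_geometry() -> gs.StimulusGeometry:
    return gs.StimulusGeometry(width_px=200, height_px=150, px_per_deg=10.0)


@pytest.fixture(scope="session")
def dataset1_small():
    """30 participants from the single-image profile, 5-s window, downscaled use."""
    cfg = gs.dataset1_profile(n_participants=30, seed=11)
    seqs = gs.generate_fixations(cfg)
    recs = [gs.truncate_window(r, 0.0, 5.0) for r in gs.generate_gaze_samples(seqs, cfg)]
    return cfg, seqs, recs


@pytest.fixture(scope="session")
def dataset1_medium():
    """200-participant single-image population for saturation properties."""
    cfg = gs.dataset1_profile(n_participants=200, seed=7)
    seqs = gs.generate_fixations(cfg)
    recs = [gs.truncate_window(r, 0.0, 5.0) for r in gs.generate_gaze_samples(seqs, cfg)]
    return cfg, recs


@pytest.fixture(scope="session")
def dataset1_fixations_1000():
    """1000 fixation sequences (first 5 s) for AOI variance scaling checks."""
    cfg = gs.dataset1_profile(n_participants=1000, seed=13)
    seqs = [gs.truncate_window(s, 0.0, 5.0) for s in gs.generate_fixations(cfg)]
    return cfg, seqs


@pytest.fixture(scope="session")
def medium_auc_result(dataset1_medium):
    """AUC saturation fit on the 200-participant population (shared: slow)."""
    cfg, recs = dataset1_medium
    model = gs.SaturationAnalysis.from_recordings(
        recs,
        metrics=("AUC",),
        n_grid=[1, 2, 4, 8, 16, 32, 64],
        n_bootstrap=200,
        downscale=10,
    )
    return model.fit(seed=3)


@pytest.fixture
def square_aoi() -> gs.AOI:
    return gs.AOI(name="box", vertices=[(50, 40), (150, 40), (150, 110), (50, 110)])


def make_fixseq(participant_id, xy, durations=None, geometry=None):
    """Fixation sequence with back-to-back fixations at the given locations."""
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    durations = np.full(n, 0.2) if durations is None else np.asarray(durations, float)
    onsets = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    return gs.FixationSequence(
        participant_id=str(participant_id),
        onsets_s=onsets,
        durations_s=durations,
        xs_px=xy[:, 0],
        ys_px=xy[:, 1],
        geometry=geometry,
    )


def replace_cfg(cfg, **kwargs):
    return dataclasses.replace(cfg, **kwargs)
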