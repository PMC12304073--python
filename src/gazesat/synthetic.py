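"""Synthetic multi-observer gaze generator.

Generates fixation sequences and raw gaze-sample recordings with the
statistical structure that scene-viewing saturation analyses assume:

* a *shared* mixture of Gaussian hotspots that all observers are drawn to
  (image-driven attention),
* *idiosyncratic* per-observer hotspots drawn once per participant
  (observer-specific interests — the source of inter-observer variability),
* a Gaussian *centre bias*,
* isotropic measurement jitter calibrated so the sample-to-sample
  root-median-squared displacement (RMS-S2S) of within-fixation samples
  matches a target precision in degrees.

Two ready-made profiles emulate the contrasting data-collection styles the
analysis is designed for: a single-image, 60 Hz, moderate-precision setup
with high inter-observer variability (``dataset1_profile``) and a
multi-image, 500 Hz, high-precision laboratory setup
(``dataset2_profile``).

Noise calibration
-----------------
Within a fixation each sample is the fixation location plus iid isotropic
Gaussian jitter with per-axis standard deviation ``s``.  The displacement
between consecutive samples then has independent N(0, 2 s^2) components, so
the squared displacement is distributed as ``2 s^2 * chi2(2)`` whose median
is ``2 s^2 * 2 ln 2``.  Hence RMS-S2S = ``2 s sqrt(ln 2)`` and the jitter
scale that realises a target RMS-S2S of ``r`` degrees is
``s = r * px_per_deg / (2 sqrt(ln 2))`` pixels (calibration constant
``1 / (2 sqrt(ln 2)) ~= 0.6006``), verified numerically in the test suite.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .data import FixationSequence, GazeRecording
from .geometry import StimulusGeometry

__all__ = [
    "Hotspot",
    "SyntheticConfig",
    "dataset1_profile",
    "dataset2_profile",
    "generate_fixations",
    "generate_gaze_samples",
    "generate_image_set",
    "randomize_hotspots",
    "JITTER_CALIBRATION",
]

#: per-axis jitter sd = RMS-S2S * JITTER_CALIBRATION (see module docstring)
JITTER_CALIBRATION = 1.0 / (2.0 * math.sqrt(math.log(2.0)))

#: idiosyncratic hotspots: sd in degrees, drawn uniformly over the central
#: fraction of the stimulus (avoids edge artefacts)
IDIO_SD_DEG = 2.0
IDIO_REGION_FRAC = 0.8

#: fixation durations are normal truncated at this floor (seconds)
MIN_FIXATION_S = 0.05

# private stream tags for hierarchical seeding
_FIX_STREAM = 11
_GAZE_STREAM = 22
_IMAGE_STREAM = 33


@dataclass(frozen=True)
class Hotspot:
    """A shared attention attractor: centre (px), isotropic sd (deg), weight."""

    center_px: tuple[float, float]
    sd_deg: float
    weight: float


@dataclass
class SyntheticConfig:
    """Full parameterisation of one synthetic population.

    ``w_shared + w_idio + w_center`` must equal 1 (within 1e-12); hotspot
    weights must sum to 1.  A single global ``seed`` feeds hierarchical
    per-participant streams, so increasing ``n_participants`` never changes
    earlier participants' data.
    """

    n_participants: int
    geometry: StimulusGeometry
    hotspots: list[Hotspot]
    w_shared: float
    w_idio: float
    w_center: float
    n_idio_hotspots: int = 3
    fixation_duration_mean_s: float = 0.25
    fixation_duration_sd_s: float = 0.10
    fixations_per_view: int | None = None
    noise_rms_deg: float = 0.0
    sampling_rate_hz: float = 60.0
    view_duration_s: float = 10.0
    center_bias_sd_deg: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        w = self.w_shared + self.w_idio + self.w_center
        if abs(w - 1.0) > 1e-12:
            raise ValueError(f"w_shared + w_idio + w_center must equal 1, got {w!r}")
        if min(self.w_shared, self.w_idio, self.w_center) < 0:
            raise ValueError("mixture weights must be nonnegative")
        if self.hotspots:
            hw = sum(h.weight for h in self.hotspots)
            if abs(hw - 1.0) > 1e-9:
                raise ValueError(f"hotspot weights must sum to 1, got {hw!r}")
        elif self.w_shared > 0:
            raise ValueError("w_shared > 0 requires at least one hotspot")
        if self.noise_rms_deg < 0:
            raise ValueError("noise_rms_deg must be nonnegative")
        if self.sampling_rate_hz <= 0 or self.view_duration_s <= 0:
            raise ValueError("sampling_rate_hz and view_duration_s must be positive")
        if self.seed < 0:
            raise ValueError("seed must be a nonnegative integer")

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["geometry"] = dataclasses.asdict(self.geometry)
        d["hotspots"] = [
            {"center_px": list(h.center_px), "sd_deg": h.sd_deg, "weight": h.weight}
            for h in self.hotspots
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        d["geometry"] = StimulusGeometry(**d["geometry"])
        d["hotspots"] = [
            Hotspot(tuple(h["center_px"]), h["sd_deg"], h["weight"])
            for h in d["hotspots"]
        ]
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


_DATASET1_HOTSPOTS = [
    Hotspot((480.0, 340.0), 1.5, 0.30),
    Hotspot((960.0, 620.0), 1.5, 0.25),
    Hotspot((1450.0, 380.0), 1.5, 0.20),
    Hotspot((700.0, 820.0), 2.0, 0.15),
    Hotspot((1300.0, 860.0), 2.0, 0.10),
]

_DATASET2_HOTSPOTS = [
    Hotspot((320.0, 300.0), 1.2, 0.30),
    Hotspot((640.0, 520.0), 1.2, 0.25),
    Hotspot((980.0, 330.0), 1.2, 0.20),
    Hotspot((460.0, 720.0), 1.5, 0.15),
    Hotspot((900.0, 760.0), 1.5, 0.10),
]


def dataset1_profile(n_participants: int = 1248, seed: int = 0) -> SyntheticConfig:
    """Single-image, unsupervised, moderate-precision profile.

    1920x1080 stimulus spanning ~50 degrees horizontally (38.4 px/deg),
    60 Hz sampling for a 10 s view, RMS-S2S 0.41 deg, and a high
    idiosyncratic mixture weight reflecting a diverse observer pool.
    """
    return SyntheticConfig(
        n_participants=n_participants,
        geometry=StimulusGeometry(1920, 1080, 1920 / 50.0),
        hotspots=list(_DATASET1_HOTSPOTS),
        w_shared=0.45,
        w_idio=0.40,
        w_center=0.15,
        n_idio_hotspots=3,
        noise_rms_deg=0.41,
        sampling_rate_hz=60.0,
        view_duration_s=10.0,
        seed=seed,
    )


def dataset2_profile(n_participants: int = 115, seed: int = 0) -> SyntheticConfig:
    """Multi-image, supervised, high-precision laboratory profile.

    1280x960 stimuli spanning ~28 degrees horizontally (~45.7 px/deg),
    500 Hz sampling for a 5 s view, RMS-S2S 0.006 deg, and a lower
    idiosyncratic weight (homogeneous, well-monitored observers).
    """
    return SyntheticConfig(
        n_participants=n_participants,
        geometry=StimulusGeometry(1280, 960, 1280 / 28.0),
        hotspots=list(_DATASET2_HOTSPOTS),
        w_shared=0.60,
        w_idio=0.20,
        w_center=0.20,
        n_idio_hotspots=2,
        noise_rms_deg=0.006,
        sampling_rate_hz=500.0,
        view_duration_s=5.0,
        seed=seed,
    )


_PROFILES = {"dataset1": dataset1_profile, "dataset2": dataset2_profile}


def named_profile(name: str, n_participants: int | None = None, seed: int = 0) -> SyntheticConfig:
    """Look up a profile by name ('dataset1' or 'dataset2')."""
    from .exceptions import UnknownProfileError

    try:
        factory = _PROFILES[name]
    except KeyError:
        raise UnknownProfileError(
            f"unknown profile {name!r}; available: {sorted(_PROFILES)}"
        ) from None
    if n_participants is None:
        return factory(seed=seed)
    return factory(n_participants=n_participants, seed=seed)


def _clip_into(geometry: StimulusGeometry, xs: np.ndarray, ys: np.ndarray):
    """Clip coordinates into [0, width) x [0, height)."""
    xs = np.clip(xs, 0.0, np.nextafter(float(geometry.width_px), 0.0))
    ys = np.clip(ys, 0.0, np.nextafter(float(geometry.height_px), 0.0))
    return xs, ys


def _participant_rng(seed: int, stream: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stream, index]))


def _draw_durations(rng: np.random.Generator, config: SyntheticConfig) -> np.ndarray:
    """Durations filling the view exactly (last fixation clipped)."""
    mean, sd = config.fixation_duration_mean_s, config.fixation_duration_sd_s
    a = (MIN_FIXATION_S - mean) / sd
    expect = max(4, int(math.ceil(config.view_duration_s / mean)))
    durations: list[float] = []
    total = 0.0
    while total < config.view_duration_s:
        batch = stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=expect, random_state=rng)
        for d in batch:
            durations.append(float(d))
            total += float(d)
            if total >= config.view_duration_s:
                break
    # clip the final fixation so the cumulative duration fills the view
    overshoot = total - config.view_duration_s
    durations[-1] -= overshoot
    if durations[-1] <= 0:  # numerically impossible, but stay safe
        durations.pop()
    if config.fixations_per_view is not None:
        durations = durations[: config.fixations_per_view]
    return np.asarray(durations)


def _draw_locations(rng: np.random.Generator, config: SyntheticConfig, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Fixation locations from the shared/idiosyncratic/centre mixture."""
    geom = config.geometry
    ppd = geom.px_per_deg
    w, h = float(geom.width_px), float(geom.height_px)

    # idiosyncratic hotspots: drawn once per participant over the central region
    lo_x, hi_x = (1 - IDIO_REGION_FRAC) / 2 * w, (1 + IDIO_REGION_FRAC) / 2 * w
    lo_y, hi_y = (1 - IDIO_REGION_FRAC) / 2 * h, (1 + IDIO_REGION_FRAC) / 2 * h
    idio_centers = np.column_stack(
        [
            rng.uniform(lo_x, hi_x, size=config.n_idio_hotspots),
            rng.uniform(lo_y, hi_y, size=config.n_idio_hotspots),
        ]
    )

    comp = rng.choice(3, size=k, p=[config.w_shared, config.w_idio, config.w_center])
    xs = np.empty(k)
    ys = np.empty(k)

    shared = comp == 0
    if shared.any():
        weights = np.array([hs.weight for hs in config.hotspots])
        centers = np.array([hs.center_px for hs in config.hotspots])
        sds = np.array([hs.sd_deg for hs in config.hotspots]) * ppd
        which = rng.choice(len(config.hotspots), size=int(shared.sum()), p=weights)
        xs[shared] = centers[which, 0] + rng.normal(0, 1, which.size) * sds[which]
        ys[shared] = centers[which, 1] + rng.normal(0, 1, which.size) * sds[which]

    idio = comp == 1
    if idio.any():
        which = rng.integers(config.n_idio_hotspots, size=int(idio.sum()))
        sd_px = IDIO_SD_DEG * ppd
        xs[idio] = idio_centers[which, 0] + rng.normal(0, sd_px, which.size)
        ys[idio] = idio_centers[which, 1] + rng.normal(0, sd_px, which.size)

    center = comp == 2
    if center.any():
        cx, cy = geom.center_px
        sd_px = config.center_bias_sd_deg * ppd
        n = int(center.sum())
        xs[center] = cx + rng.normal(0, sd_px, n)
        ys[center] = cy + rng.normal(0, sd_px, n)

    return _clip_into(geom, xs, ys)


def generate_fixations(config: SyntheticConfig) -> list[FixationSequence]:
    """Generate one fixation sequence per participant.

    Fixation durations are drawn from a normal distribution truncated at
    50 ms and fill the view duration exactly (the final fixation is
    clipped); onsets are the cumulative durations.  Locations are drawn
    from the shared/idiosyncratic/centre mixture and clipped inside the
    stimulus.  Fully reproducible from ``config.seed``; participant ``i``
    depends only on ``(seed, i)``.
    """
    sequences = []
    for i in range(config.n_participants):
        rng = _participant_rng(config.seed, _FIX_STREAM, i)
        durations = _draw_durations(rng, config)
        onsets = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
        xs, ys = _draw_locations(rng, config, len(durations))
        sequences.append(
            FixationSequence(
                participant_id=f"p{i:04d}",
                onsets_s=onsets,
                durations_s=durations,
                xs_px=xs,
                ys_px=ys,
                geometry=config.geometry,
            )
        )
    return sequences


def generate_gaze_samples(
    fixation_sequences: list[FixationSequence], config: SyntheticConfig
) -> list[GazeRecording]:
    """Expand fixations to raw samples at the configured sampling rate.

    Sample ``k`` of a recording is taken at ``t = k / rate`` and lies on
    the fixation active at that time, plus isotropic Gaussian jitter whose
    per-axis sd is ``noise_rms_deg * px_per_deg * JITTER_CALIBRATION`` so
    that the within-fixation RMS-S2S matches ``config.noise_rms_deg``.
    """
    rate = config.sampling_rate_hz
    ppd = config.geometry.px_per_deg
    jitter_px = config.noise_rms_deg * ppd * JITTER_CALIBRATION
    recordings = []
    for i, seq in enumerate(fixation_sequences):
        rng = _participant_rng(config.seed, _GAZE_STREAM, i)
        total = float(seq.onsets_s[-1] + seq.durations_s[-1]) if len(seq) else 0.0
        n_samples = int(round(total * rate))
        t = np.arange(n_samples) / rate
        idx = np.clip(np.searchsorted(seq.onsets_s, t, side="right") - 1, 0, None)
        xs = seq.xs_px[idx].astype(float)
        ys = seq.ys_px[idx].astype(float)
        if jitter_px > 0:
            xs = xs + rng.normal(0.0, jitter_px, n_samples)
            ys = ys + rng.normal(0.0, jitter_px, n_samples)
        xs, ys = _clip_into(config.geometry, xs, ys)
        recordings.append(
            GazeRecording(
                participant_id=seq.participant_id,
                times_s=t,
                xs_px=xs,
                ys_px=ys,
                geometry=config.geometry,
            )
        )
    return recordings


def randomize_hotspots(
    geometry: StimulusGeometry, n: int, rng: np.random.Generator
) -> list[Hotspot]:
    """Random shared-hotspot set for one image (centres over the central 80%)."""
    w, h = float(geometry.width_px), float(geometry.height_px)
    cx = rng.uniform(0.1 * w, 0.9 * w, n)
    cy = rng.uniform(0.1 * h, 0.9 * h, n)
    sds = rng.uniform(1.0, 2.0, n)
    raw_w = rng.uniform(0.5, 1.0, n)
    weights = raw_w / raw_w.sum()
    return [Hotspot((float(x), float(y)), float(s), float(wt)) for x, y, s, wt in zip(cx, cy, sds, weights)]


def generate_image_set(
    config: SyntheticConfig, n_images: int, image_prefix: str = "img"
) -> dict[str, list[FixationSequence]]:
    """Generate fixations for the same participants viewing several images.

    Each image gets its own random shared-hotspot set (a different scene)
    while participant identities — and hence idiosyncratic behaviour
    streams — are shared across images.
    """
    out: dict[str, list[FixationSequence]] = {}
    for j in range(n_images):
        img_rng = np.random.default_rng(np.random.SeedSequence([config.seed, _IMAGE_STREAM, j]))
        child_seed = int(img_rng.integers(0, 2**31 - 1))
        cfg_j = replace(
            config,
            hotspots=randomize_hotspots(config.geometry, max(3, len(config.hotspots)), img_rng),
            seed=child_seed,
        )
        out[f"{image_prefix}{j:03d}"] = generate_fixations(cfg_j)
    return out
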