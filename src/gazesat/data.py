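"""Core per-participant gaze containers.

``GazeRecording`` holds a participant's raw timestamped gaze samples and is
the input to sample-based distribution maps and to the RMS-S2S precision
statistic.  ``FixationSequence`` holds ordered fixation events (onset,
duration, location) and is the input to fixation-based maps and to all
area-of-interest metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import StimulusGeometry


@dataclass
class GazeRecording:
    """Timestamped gaze samples of one participant on one stimulus.

    times_s must be strictly increasing; times/xs/ys have equal length.
    """

    participant_id: str
    times_s: np.ndarray
    xs_px: np.ndarray
    ys_px: np.ndarray
    geometry: StimulusGeometry

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.xs_px = np.asarray(self.xs_px, dtype=float)
        self.ys_px = np.asarray(self.ys_px, dtype=float)
        n = len(self.times_s)
        if len(self.xs_px) != n or len(self.ys_px) != n:
            raise ValueError("times_s, xs_px and ys_px must have equal length")
        if n and np.any(self.times_s < 0):
            raise ValueError("times_s must be nonnegative")
        if n > 1 and not np.all(np.diff(self.times_s) > 0):
            raise ValueError("times_s must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times_s)

    @property
    def points(self) -> np.ndarray:
        """Sample locations as an (n, 2) array of (x, y) pixels."""
        return np.column_stack([self.xs_px, self.ys_px])


@dataclass
class FixationSequence:
    """Ordered fixation events of one participant.

    Onsets are nondecreasing; durations strictly positive.
    """

    participant_id: str
    onsets_s: np.ndarray
    durations_s: np.ndarray
    xs_px: np.ndarray
    ys_px: np.ndarray
    geometry: StimulusGeometry | None = field(default=None)

    def __post_init__(self) -> None:
        self.onsets_s = np.asarray(self.onsets_s, dtype=float)
        self.durations_s = np.asarray(self.durations_s, dtype=float)
        self.xs_px = np.asarray(self.xs_px, dtype=float)
        self.ys_px = np.asarray(self.ys_px, dtype=float)
        n = len(self.onsets_s)
        if any(len(a) != n for a in (self.durations_s, self.xs_px, self.ys_px)):
            raise ValueError("onset/duration/x/y arrays must have equal length")
        if n and np.any(self.durations_s <= 0):
            raise ValueError("fixation durations must be positive")
        if n > 1 and np.any(np.diff(self.onsets_s) < 0):
            raise ValueError("fixation onsets must be nondecreasing")

    def __len__(self) -> int:
        return len(self.onsets_s)

    @property
    def points(self) -> np.ndarray:
        """Fixation locations as an (n, 2) array of (x, y) pixels."""
        return np.column_stack([self.xs_px, self.ys_px])
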