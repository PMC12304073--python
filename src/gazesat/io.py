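"""Reading/writing gaze, fixation and AOI files; preprocessing; data quality.

File dialects (all plain UTF-8):

* gaze CSV — header ``participant,t,x,y``
* fixation CSV — header ``participant,onset,duration,x,y``
* AOI file — JSON list of ``{"name": ..., "vertices": [[x, y], ...]}``
  with vertices in pixel coordinates, origin top-left.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from .data import FixationSequence, GazeRecording
from .exceptions import EmptyInputError, InsufficientDataError, SchemaError
from .geometry import StimulusGeometry

logger = logging.getLogger(__name__)

#: recommended minimum AOI minor axis in degrees of visual angle
MIN_AOI_AXIS_DEG = 2.2


@dataclass
class AOI:
    """Named polygonal area of interest, vertices in pixels (origin top-left)."""

    name: str
    vertices: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise ValueError(f"AOI {self.name!r} needs >= 3 vertices, got {len(self.vertices)}")
        self.vertices = [(float(x), float(y)) for x, y in self.vertices]
        poly = Polygon(self.vertices)
        if not poly.is_simple or poly.area == 0:
            raise ValueError(f"AOI {self.name!r} polygon must be simple with nonzero area")
        self._polygon = poly

    @property
    def polygon(self) -> Polygon:
        return self._polygon

    def contains(self, x: float, y: float) -> bool:
        """Point-in-polygon test; boundary points count as inside."""
        return bool(self._polygon.covers(Point(x, y)))

    def minor_axis_deg(self, geometry: StimulusGeometry) -> float:
        """Shorter side of the minimum rotated bounding rectangle, in degrees."""
        rect = self._polygon.minimum_rotated_rectangle
        coords = np.asarray(rect.exterior.coords[:4])
        sides = np.linalg.norm(np.diff(np.vstack([coords, coords[:1]]), axis=0), axis=1)
        return float(sides.min()) / geometry.px_per_deg

    def check_min_size(self, geometry: StimulusGeometry, min_deg: float = MIN_AOI_AXIS_DEG) -> float:
        """Warn when the minor axis falls below the recommended minimum."""
        minor = self.minor_axis_deg(geometry)
        if minor < min_deg:
            warnings.warn(
                f"AOI {self.name!r} minor axis {minor:.2f} deg is below the "
                f"recommended minimum of {min_deg} deg",
                UserWarning,
                stacklevel=2,
            )
        return minor


@dataclass
class QualityReport:
    """Per-participant spatial precision summary."""

    participant_id: str
    rms_s2s_deg: float
    n_samples: int


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")


def read_gaze_csv(path, geometry: StimulusGeometry) -> list[GazeRecording]:
    """Read a ``participant,t,x,y`` CSV into one recording per participant.

    Rows with non-finite coordinates or timestamps are dropped (count
    logged); samples are sorted by time within participant.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise EmptyInputError(f"{path}: no data rows")
    _require_columns(df, ["participant", "t", "x", "y"], path)
    finite = np.isfinite(df[["t", "x", "y"]].to_numpy(dtype=float)).all(axis=1)
    dropped = int((~finite).sum())
    if dropped:
        logger.info("read_gaze_csv(%s): dropped %d rows with non-finite values", path, dropped)
    df = df[finite]
    recordings = []
    for pid, grp in df.groupby("participant", sort=True):
        grp = grp.sort_values("t")
        recordings.append(
            GazeRecording(
                participant_id=str(pid),
                times_s=grp["t"].to_numpy(dtype=float),
                xs_px=grp["x"].to_numpy(dtype=float),
                ys_px=grp["y"].to_numpy(dtype=float),
                geometry=geometry,
            )
        )
    return recordings


def write_gaze_csv(recordings: list[GazeRecording], path) -> None:
    frames = [
        pd.DataFrame(
            {"participant": r.participant_id, "t": r.times_s, "x": r.xs_px, "y": r.ys_px}
        )
        for r in recordings
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_fixation_csv(path, geometry: StimulusGeometry | None = None) -> list[FixationSequence]:
    """Read a ``participant,onset,duration,x,y`` CSV into fixation sequences."""
    df = pd.read_csv(path)
    if df.empty:
        raise EmptyInputError(f"{path}: no data rows")
    _require_columns(df, ["participant", "onset", "duration", "x", "y"], path)
    finite = np.isfinite(df[["onset", "duration", "x", "y"]].to_numpy(dtype=float)).all(axis=1)
    dropped = int((~finite).sum())
    if dropped:
        logger.info("read_fixation_csv(%s): dropped %d rows with non-finite values", path, dropped)
    df = df[finite]
    sequences = []
    for pid, grp in df.groupby("participant", sort=True):
        grp = grp.sort_values("onset")
        sequences.append(
            FixationSequence(
                participant_id=str(pid),
                onsets_s=grp["onset"].to_numpy(dtype=float),
                durations_s=grp["duration"].to_numpy(dtype=float),
                xs_px=grp["x"].to_numpy(dtype=float),
                ys_px=grp["y"].to_numpy(dtype=float),
                geometry=geometry,
            )
        )
    return sequences


def write_fixation_csv(sequences: list[FixationSequence], path) -> None:
    frames = [
        pd.DataFrame(
            {
                "participant": s.participant_id,
                "onset": s.onsets_s,
                "duration": s.durations_s,
                "x": s.xs_px,
                "y": s.ys_px,
            }
        )
        for s in sequences
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_aoi_file(path, geometry: StimulusGeometry | None = None) -> list[AOI]:
    """Read a JSON AOI file; size warnings are emitted when geometry is given."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    aois = [AOI(name=entry["name"], vertices=[tuple(v) for v in entry["vertices"]]) for entry in doc]
    if geometry is not None:
        for aoi in aois:
            aoi.check_min_size(geometry)
    return aois


def write_aoi_file(aois: list[AOI], path) -> None:
    doc = [{"name": a.name, "vertices": [list(v) for v in a.vertices]} for a in aois]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2)


def truncate_window(obj, t_start_s: float, t_end_s: float):
    """Restrict a recording or fixation sequence to the window [t_start, t_end).

    Samples are kept when their timestamp falls in the window.  Fixations
    are kept when their *onset* falls in the window; a retained fixation
    extending past ``t_end_s`` has its duration clipped at the window end.
    Idempotent.
    """
    if not t_start_s < t_end_s:
        raise ValueError("t_start_s must be < t_end_s")
    if isinstance(obj, GazeRecording):
        keep = (obj.times_s >= t_start_s) & (obj.times_s < t_end_s)
        return GazeRecording(
            participant_id=obj.participant_id,
            times_s=obj.times_s[keep],
            xs_px=obj.xs_px[keep],
            ys_px=obj.ys_px[keep],
            geometry=obj.geometry,
        )
    if isinstance(obj, FixationSequence):
        keep = (obj.onsets_s >= t_start_s) & (obj.onsets_s < t_end_s)
        onsets = obj.onsets_s[keep]
        durations = np.minimum(obj.durations_s[keep], t_end_s - onsets)
        return FixationSequence(
            participant_id=obj.participant_id,
            onsets_s=onsets,
            durations_s=durations,
            xs_px=obj.xs_px[keep],
            ys_px=obj.ys_px[keep],
            geometry=obj.geometry,
        )
    raise TypeError(f"unsupported type for truncate_window: {type(obj)!r}")


def rms_s2s(recording: GazeRecording) -> float:
    """Sample-to-sample root *median* squared displacement, in degrees.

    sqrt(median over consecutive sample pairs of the squared Euclidean
    pixel displacement) divided by px_per_deg.  The median (rather than
    the mean) keeps occasional saccadic jumps from dominating the
    precision estimate.
    """
    if len(recording) < 2:
        raise InsufficientDataError(
            f"rms_s2s needs >= 2 samples, got {len(recording)} "
            f"for participant {recording.participant_id!r}"
        )
    dx = np.diff(recording.xs_px)
    dy = np.diff(recording.ys_px)
    med = float(np.median(dx * dx + dy * dy))
    return float(np.sqrt(med)) / recording.geometry.px_per_deg


def quality_report(recording: GazeRecording) -> QualityReport:
    return QualityReport(
        participant_id=recording.participant_id,
        rms_s2s_deg=rms_s2s(recording),
        n_samples=len(recording),
    )
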