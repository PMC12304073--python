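"""Stimulus geometry: screen size in pixels and the pixel/degree conversion.

All coordinates in this package are 0-based pixels with the origin at the
top-left of the stimulus and y increasing downward, matching the convention
of screen-based eye trackers.  ``px_per_deg`` is the (assumed isotropic)
number of pixels subtending one degree of visual angle; it fixes the scale
of Gaussian blur kernels, measurement-noise calibration and AOI size checks.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class StimulusGeometry:
    """Screen geometry of a single stimulus.

    Parameters
    ----------
    width_px, height_px
        Stimulus size in pixels (>= 1).
    px_per_deg
        Isotropic pixels per degree of visual angle (> 0).
    """

    width_px: int
    height_px: int
    px_per_deg: float

    def __post_init__(self) -> None:
        if self.width_px < 1 or self.height_px < 1:
            raise ValueError("width_px and height_px must be >= 1")
        if not self.px_per_deg > 0:
            raise ValueError("px_per_deg must be positive")

    @property
    def center_px(self) -> tuple[float, float]:
        """Screen centre as (x, y) in pixels."""
        return (self.width_px / 2.0, self.height_px / 2.0)

    def deg_to_px(self, deg: float) -> float:
        return deg * self.px_per_deg

    def px_to_deg(self, px: float) -> float:
        return px / self.px_per_deg
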