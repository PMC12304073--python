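"""Gaze distribution maps and their transforms.

A distribution map is a pixel grid in which each cell counts the gaze
samples (or fixations) recorded at that location.  The analysis pipeline
applies three transforms:

* ``gaussian_blur`` — isotropic Gaussian smoothing with a sigma expressed
  in degrees of visual angle (converted to pixels via the stimulus
  geometry, accounting for any downscale factor);
* ``standardize`` — z-scoring over all pixels (population sd);
* ``minmax_scale`` — affine rescaling of the pixel values to [0, 1].

A ``downscale`` factor bins the stimulus into coarser cells
(``floor(x / downscale)``), trading spatial resolution for speed; all
degree-to-pixel conversions account for it.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .exceptions import GeometryMismatchError
from .geometry import StimulusGeometry

logger = logging.getLogger(__name__)

#: blur kernels are truncated at this many standard deviations
BLUR_TRUNCATE_SD = 4.0


@dataclass
class DistributionMap:
    """A (possibly transformed) gaze distribution map.

    ``grid`` has shape ``(ceil(height/downscale), ceil(width/downscale))``
    and row index = y cell, column index = x cell.  State flags record
    which transforms have been applied.
    """

    grid: np.ndarray
    geometry: StimulusGeometry
    downscale: int = 1
    blurred_sigma_deg: float | None = None
    standardized: bool = False
    scaled01: bool = False

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise ValueError("grid must be 2-D")
        if self.downscale < 1:
            raise ValueError("downscale must be a positive integer")

    @property
    def sigma_px(self) -> float | None:
        """Blur sigma in (downscaled) grid pixels, if blurred."""
        if self.blurred_sigma_deg is None:
            return None
        return self.blurred_sigma_deg * self.geometry.px_per_deg / self.downscale

    def same_frame(self, other: "DistributionMap") -> bool:
        return (
            self.geometry == other.geometry
            and self.downscale == other.downscale
            and self.grid.shape == other.grid.shape
        )

    # -- serialisation ----------------------------------------------------
    def save(self, basepath: str) -> None:
        """Write ``<basepath>.txt`` (dense matrix) + ``<basepath>.json`` sidecar."""
        np.savetxt(f"{basepath}.txt", self.grid)
        meta = {
            "geometry": {
                "width_px": self.geometry.width_px,
                "height_px": self.geometry.height_px,
                "px_per_deg": self.geometry.px_per_deg,
            },
            "downscale": self.downscale,
            "blurred_sigma_deg": self.blurred_sigma_deg,
            "standardized": self.standardized,
            "scaled01": self.scaled01,
        }
        with open(f"{basepath}.json", "w", encoding="utf-8") as fh:
            json.dump(meta, fh, indent=2)

    @classmethod
    def load(cls, basepath: str) -> "DistributionMap":
        grid = np.loadtxt(f"{basepath}.txt")
        with open(f"{basepath}.json", "r", encoding="utf-8") as fh:
            meta = json.load(fh)
        return cls(
            grid=np.atleast_2d(grid),
            geometry=StimulusGeometry(**meta["geometry"]),
            downscale=meta["downscale"],
            blurred_sigma_deg=meta["blurred_sigma_deg"],
            standardized=meta["standardized"],
            scaled01=meta["scaled01"],
        )

    def to_image(self, path, cmap: str = "inferno") -> None:
        """Render the map to an image file for visual inspection."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 6 * self.grid.shape[0] / self.grid.shape[1]))
        ax.imshow(self.grid, cmap=cmap, interpolation="nearest")
        ax.set_axis_off()
        fig.savefig(path, bbox_inches="tight", dpi=150)
        plt.close(fig)


def grid_shape(geometry: StimulusGeometry, downscale: int = 1) -> tuple[int, int]:
    """Grid shape (rows, cols) of a map at the given downscale."""
    return (
        int(np.ceil(geometry.height_px / downscale)),
        int(np.ceil(geometry.width_px / downscale)),
    )


def accumulate(
    points, geometry: StimulusGeometry, downscale: int = 1
) -> DistributionMap:
    """Accumulate (x, y) pixel locations into a count map.

    Points outside ``[0, width) x [0, height)`` are dropped (count logged).
    The grid sum equals the number of retained points.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    shape = grid_shape(geometry, downscale)
    grid = np.zeros(shape)
    if len(pts):
        inside = (
            (pts[:, 0] >= 0)
            & (pts[:, 0] < geometry.width_px)
            & (pts[:, 1] >= 0)
            & (pts[:, 1] < geometry.height_px)
        )
        dropped = int((~inside).sum())
        if dropped:
            logger.info("accumulate: dropped %d points outside the stimulus", dropped)
        pts = pts[inside]
        cols = (pts[:, 0] // downscale).astype(int)
        rows = (pts[:, 1] // downscale).astype(int)
        np.add.at(grid, (rows, cols), 1.0)
    return DistributionMap(grid=grid, geometry=geometry, downscale=downscale)


def gaussian_blur(dmap: DistributionMap, sigma_deg: float = 1.0) -> DistributionMap:
    """Blur with an isotropic Gaussian of ``sigma_deg`` degrees.

    The kernel sd in grid pixels is ``sigma_deg * px_per_deg / downscale``,
    truncated at 4 sd, with nearest-edge padding (no mass leaks off the
    grid edges, so border gaze is not penalised).  Must be applied before
    standardisation.
    """
    if dmap.standardized:
        raise ValueError("gaussian_blur must be applied before standardize")
    sigma_px = sigma_deg * dmap.geometry.px_per_deg / dmap.downscale
    blurred = ndimage.gaussian_filter(dmap.grid, sigma=sigma_px, mode="nearest", truncate=BLUR_TRUNCATE_SD)
    return replace(dmap, grid=blurred, blurred_sigma_deg=sigma_deg)


def standardize(dmap: DistributionMap) -> DistributionMap:
    """Z-score the grid over all pixels (population standard deviation).

    A constant grid (sd = 0) maps to the all-zero grid with a warning.
    Idempotent.
    """
    sd = float(dmap.grid.std())
    if sd == 0.0:
        warnings.warn(
            "standardize: constant map has zero variance; returning all-zero z-map",
            UserWarning,
            stacklevel=2,
        )
        z = np.zeros_like(dmap.grid)
    else:
        z = (dmap.grid - dmap.grid.mean()) / sd
    return replace(dmap, grid=z, standardized=True)


def minmax_scale(dmap: DistributionMap) -> DistributionMap:
    """Rescale pixel values to [0, 1]; a constant grid maps to all 0.5."""
    lo = float(dmap.grid.min())
    hi = float(dmap.grid.max())
    if hi == lo:
        warnings.warn(
            "minmax_scale: constant map; returning all-0.5 grid",
            UserWarning,
            stacklevel=2,
        )
        scaled = np.full_like(dmap.grid, 0.5)
    else:
        scaled = (dmap.grid - lo) / (hi - lo)
    return replace(dmap, grid=scaled, scaled01=True)


def check_same_frame(a: DistributionMap, b: DistributionMap) -> None:
    if not a.same_frame(b):
        raise GeometryMismatchError(
            "maps must share geometry, downscale and grid shape: "
            f"{a.grid.shape}@{a.downscale} vs {b.grid.shape}@{b.downscale}"
        )
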