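"""Distribution-map similarity metrics: NSS and AUC.

Both metrics compare a *comparison* map (built from a participant sample)
against a *benchmark* map (built from a larger, disjoint set of
participants), starting from raw count maps on the same geometry:

NSS
    The comparison map is Gaussian-blurred then z-scored; the benchmark
    map is z-scored but *not* blurred.  The benchmark acts as a mask: NSS
    is the mean of the comparison z-values over all pixels where the
    benchmark received at least an average amount of gaze (z >= 0,
    inclusive).  Unbounded above; 0 means chance-level correspondence.

AUC
    The z-scored benchmark is thresholded at z >= 0 into binary labels;
    the comparison map is blurred and min-max scaled to [0, 1] and treated
    as predictions.  The value is the rank-based (Mann-Whitney, average
    ranks for ties) area under the ROC curve over *all* grid pixels.
    1 = perfect correspondence, 0.5 = chance.

The z >= 0 threshold is inclusive on both metrics: pixels exactly at the
mean belong to the mask / positive labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import UndefinedAUCError
from .maps import DistributionMap, check_same_frame, gaussian_blur, minmax_scale, standardize

__all__ = ["SimilarityResult", "nss", "auc", "rank_auc"]


@dataclass
class SimilarityResult:
    """Outcome of one map comparison.

    ``mask_fraction`` is the fraction of pixels with benchmark z >= 0.
    """

    metric: str
    value: float
    n_comparison_points: int
    n_benchmark_points: int
    mask_fraction: float


def rank_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney AUC with average ranks for tied scores.

    ``labels`` are booleans; ``scores`` real-valued predictions.  Raises
    when labels are all-true or all-false (AUC undefined).
    """
    labels = np.asarray(labels, dtype=bool).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have the same size")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        side = "positive" if n_pos == 0 else "negative"
        raise UndefinedAUCError(f"AUC undefined: no {side} labels in the benchmark mask")
    ranks = stats.rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _prepare(comparison_raw: DistributionMap, benchmark_raw: DistributionMap, sigma_deg: float):
    check_same_frame(comparison_raw, benchmark_raw)
    comp_blurred = gaussian_blur(comparison_raw, sigma_deg=sigma_deg)
    bench_z = standardize(benchmark_raw)
    return comp_blurred, bench_z


def nss(
    comparison_raw: DistributionMap,
    benchmark_raw: DistributionMap,
    sigma_deg: float = 1.0,
) -> SimilarityResult:
    """Normalized scanpath saliency of a comparison map against a benchmark.

    Both inputs are raw count maps on the same geometry/downscale.  If the
    benchmark is constant its z-map is all zeros, the mask covers every
    pixel, and NSS is exactly 0 (a z-scored map has mean 0).
    """
    comp_blurred, bench_z = _prepare(comparison_raw, benchmark_raw, sigma_deg)
    comp_z = standardize(comp_blurred)
    mask = bench_z.grid >= 0.0
    value = float(comp_z.grid[mask].mean())
    return SimilarityResult(
        metric="NSS",
        value=value,
        n_comparison_points=int(round(comparison_raw.grid.sum())),
        n_benchmark_points=int(round(benchmark_raw.grid.sum())),
        mask_fraction=float(mask.mean()),
    )


def auc(
    comparison_raw: DistributionMap,
    benchmark_raw: DistributionMap,
    sigma_deg: float = 1.0,
) -> SimilarityResult:
    """Rank-based ROC area of a comparison map against a benchmark.

    Labels: benchmark z >= 0.  Predictions: min-max scaled blur of the
    comparison map.  Computed over every pixel of the grid; raises
    ``UndefinedAUCError`` when the labels are one-sided.
    """
    comp_blurred, bench_z = _prepare(comparison_raw, benchmark_raw, sigma_deg)
    predictions = minmax_scale(comp_blurred)
    labels = bench_z.grid >= 0.0
    value = rank_auc(labels, predictions.grid)
    return SimilarityResult(
        metric="AUC",
        value=value,
        n_comparison_points=int(round(comparison_raw.grid.sum())),
        n_benchmark_points=int(round(benchmark_raw.grid.sum())),
        mask_fraction=float(labels.mean()),
    )
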