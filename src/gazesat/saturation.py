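"""Leave-n-out bootstrap saturation curves and sample-size guideline tables.

The engine answers the question "how many observers does a scene-viewing
study need?" empirically.  For each candidate sample size ``n`` it
repeatedly (bootstrap) draws ``n`` participants without replacement,
pools their gaze into a comparison distribution map, pools a *half-sized
benchmark* — ``ceil(N / 2)`` participants drawn from the non-sampled
remainder — and scores the pair with NSS and/or AUC.  Across iterations
it reports the mean and the 2.5th/97.5th percentiles (the 95% range).
Holding the benchmark size constant across ``n`` keeps the reference
standard equally informative at every sample size, so the curve isolates
the effect of the sample; at the largest admissible ``n = floor(N / 2)``
the benchmark is exactly the remaining half.  The ``floor(N / 2)`` cap
guarantees a disjoint half is always available.

As ``n`` grows the similarity to the benchmark saturates (law of
diminishing returns); the guideline tables read the curve backwards:
``threshold_table`` lists the successive sample sizes at which the mean
metric first clears a relative improvement (default +5%) over the
previous row, and ``cross_reference`` tabulates the relative change
between arbitrary sample-size pairs.

Two presentation layers are provided: plain functions
(``bootstrap_curve``, ``multi_image_curve``, ``pct_change``,
``threshold_table``, ``cross_reference``) and a model/results pair
(``SaturationAnalysis`` / ``SaturationResult``) that computes both
metrics on shared bootstrap draws and carries summaries, tables and
plots.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import LeaveNOutError, MissingSampleSizeError, UndefinedChangeError
from .geometry import StimulusGeometry
from .maps import BLUR_TRUNCATE_SD, accumulate, grid_shape
from .similarity import rank_auc

__all__ = [
    "SaturationCurve",
    "GuidelineTable",
    "bootstrap_curve",
    "multi_image_curve",
    "pct_change",
    "threshold_table",
    "cross_reference",
    "default_sample_grid",
    "SaturationAnalysis",
    "SaturationResult",
]

METRICS = ("NSS", "AUC")


# ---------------------------------------------------------------------------
# result containers


@dataclass
class SaturationCurve:
    """Bootstrap mean and 95% range of a similarity metric per sample size."""

    metric: str
    sample_sizes: np.ndarray
    mean: np.ndarray
    lo_2_5: np.ndarray
    hi_97_5: np.ndarray
    n_bootstrap: int
    stratum: str | None = None

    def __post_init__(self) -> None:
        self.sample_sizes = np.asarray(self.sample_sizes, dtype=int)
        self.mean = np.asarray(self.mean, dtype=float)
        self.lo_2_5 = np.asarray(self.lo_2_5, dtype=float)
        self.hi_97_5 = np.asarray(self.hi_97_5, dtype=float)
        order = np.argsort(self.sample_sizes)
        for name in ("sample_sizes", "mean", "lo_2_5", "hi_97_5"):
            setattr(self, name, getattr(self, name)[order])

    def mean_at(self, n: int) -> float:
        idx = np.flatnonzero(self.sample_sizes == n)
        if idx.size == 0:
            raise MissingSampleSizeError(f"sample size n={n} not in curve")
        return float(self.mean[idx[0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": self.metric,
                "stratum": self.stratum if self.stratum is not None else "",
                "n": self.sample_sizes,
                "mean": self.mean,
                "lo": self.lo_2_5,
                "hi": self.hi_97_5,
                "n_boot": self.n_bootstrap,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SaturationCurve":
        metric = str(df["metric"].iloc[0])
        stratum = df["stratum"].iloc[0] if "stratum" in df else None
        if isinstance(stratum, float) and np.isnan(stratum):
            stratum = None
        return cls(
            metric=metric,
            sample_sizes=df["n"].to_numpy(int),
            mean=df["mean"].to_numpy(float),
            lo_2_5=df["lo"].to_numpy(float),
            hi_97_5=df["hi"].to_numpy(float),
            n_bootstrap=int(df["n_boot"].iloc[0]),
            stratum=stratum if stratum not in ("", None) else None,
        )


@dataclass
class GuidelineTable:
    """Successive sample sizes achieving a relative metric increase.

    Each row's value is at least ``(1 + rel_increase)`` times the previous
    row's.  ``exhausted`` records that the scan ran past the largest
    sample size in the curve (reported as "> n_max").
    """

    rows: list[tuple[int, float]]
    rel_increase: float
    n_max: int
    exhausted: bool
    metric: str = ""

    def to_frame(self) -> pd.DataFrame:
        ns: list[object] = [n for n, _ in self.rows]
        vals: list[float] = [v for _, v in self.rows]
        if self.exhausted:
            ns.append(f"> {self.n_max}")
            vals.append(np.nan)
        return pd.DataFrame({"metric": self.metric, "n": ns, "value": np.round(vals, 2)})


# ---------------------------------------------------------------------------
# participant stacks (pooled-map algebra)


def _as_point_sets(participants, geometry: StimulusGeometry | None):
    """Normalise input to (dict id -> (k, 2) array, geometry)."""
    if isinstance(participants, Mapping):
        if geometry is None:
            raise ValueError("geometry is required when passing raw point sets")
        return {str(k): np.asarray(v, float).reshape(-1, 2) for k, v in participants.items()}, geometry
    point_sets = {}
    for obj in participants:
        point_sets[str(obj.participant_id)] = obj.points
        if geometry is None:
            geometry = obj.geometry
    if geometry is None:
        raise ValueError("geometry could not be inferred from the inputs")
    return point_sets, geometry


class _ParticipantStack:
    """Per-participant raw and pre-blurred maps, in sorted-id order.

    The Gaussian blur is linear, so the blurred pooled map of any subset
    equals the sum of the pre-blurred per-participant maps — each
    bootstrap iteration then costs only array sums, never a convolution.
    Sorting by participant id makes every curve statistic invariant to the
    order in which participants are supplied.
    """

    def __init__(self, point_sets, geometry, downscale, sigma_deg):
        self.ids = sorted(point_sets)
        self.geometry = geometry
        self.downscale = downscale
        self.sigma_deg = sigma_deg
        shape = grid_shape(geometry, downscale)
        n = len(self.ids)
        self.raw = np.empty((n, *shape))
        for i, pid in enumerate(self.ids):
            self.raw[i] = accumulate(point_sets[pid], geometry, downscale).grid
        sigma_px = sigma_deg * geometry.px_per_deg / downscale
        self.blur = np.empty_like(self.raw)
        for i in range(n):
            self.blur[i] = ndimage.gaussian_filter(
                self.raw[i], sigma=sigma_px, mode="nearest", truncate=BLUR_TRUNCATE_SD
            )
        self.total_raw = self.raw.sum(axis=0)
        self.total_blur = self.blur.sum(axis=0)

    def __len__(self) -> int:
        return len(self.ids)

    def sample_maps(self, idx: np.ndarray, bench_idx: np.ndarray):
        """(comparison blurred map, benchmark raw map) for index draws."""
        comp_blur = self.blur[idx].sum(axis=0)
        bench_raw = self.raw[bench_idx].sum(axis=0)
        return comp_blur, bench_raw


def _zscore(a: np.ndarray) -> np.ndarray:
    sd = a.std()
    if sd == 0.0:
        return np.zeros_like(a)
    return (a - a.mean()) / sd


def _metric_values(metrics, comp_blur: np.ndarray, bench_raw: np.ndarray) -> dict[str, float]:
    """Score one comparison/benchmark pair; maps are already blurred/raw."""
    bench_z = _zscore(bench_raw)
    labels = bench_z >= 0.0
    out = {}
    for metric in metrics:
        if metric == "NSS":
            out[metric] = float(_zscore(comp_blur)[labels].mean())
        elif metric == "AUC":
            lo, hi = comp_blur.min(), comp_blur.max()
            preds = np.full_like(comp_blur, 0.5) if hi == lo else (comp_blur - lo) / (hi - lo)
            out[metric] = rank_auc(labels, preds)
        else:
            raise ValueError(f"unknown metric {metric!r}")
    return out


def _validate_grid(n_grid, n_participants: int) -> np.ndarray:
    grid = np.asarray(sorted(set(int(n) for n in n_grid)), dtype=int)
    if grid.size == 0 or grid[0] < 1:
        raise ValueError("n_grid must contain positive sample sizes")
    cap = n_participants // 2
    if grid[-1] > cap:
        raise LeaveNOutError(
            f"sample size {grid[-1]} exceeds floor(N/2) = {cap}: the leave-n-out "
            "design needs a disjoint half-sized benchmark for every sample"
        )
    return grid


def _bootstrap_matrices(stacks, n_grid, n_bootstrap, metrics, seed):
    """Bootstrap value matrices {metric: (n_bootstrap, len(n_grid))}.

    ``stacks`` is a list of `_ParticipantStack`s sharing the same sampled
    indices (one per image); values are averaged over stacks.
    """
    n_common = min(len(s) for s in stacks)
    bench_size = n_common - n_common // 2  # the "remaining half"
    values = {m: np.empty((n_bootstrap, len(n_grid))) for m in metrics}
    rng = np.random.default_rng(np.random.SeedSequence([seed]))
    everyone = np.arange(n_common)
    for it in range(n_bootstrap):
        for j, n in enumerate(n_grid):
            idx = rng.choice(n_common, size=int(n), replace=False)
            rest = np.setdiff1d(everyone, idx, assume_unique=True)
            bench_idx = rng.choice(rest, size=bench_size, replace=False)
            acc = {m: 0.0 for m in metrics}
            for stack in stacks:
                comp_blur, bench_raw = stack.sample_maps(idx, bench_idx)
                for m, v in _metric_values(metrics, comp_blur, bench_raw).items():
                    acc[m] += v
            for m in metrics:
                values[m][it, j] = acc[m] / len(stacks)
    return values


def _curve_from_values(metric, n_grid, values, n_bootstrap, stratum=None) -> SaturationCurve:
    return SaturationCurve(
        metric=metric,
        sample_sizes=n_grid,
        mean=values.mean(axis=0),
        lo_2_5=np.percentile(values, 2.5, axis=0),
        hi_97_5=np.percentile(values, 97.5, axis=0),
        n_bootstrap=n_bootstrap,
        stratum=stratum,
    )


# ---------------------------------------------------------------------------
# public functions


def bootstrap_curve(
    participants,
    metric: str = "AUC",
    n_grid: Sequence[int] | None = None,
    n_bootstrap: int = 1000,
    sigma_deg: float = 1.0,
    seed: int = 0,
    *,
    geometry: StimulusGeometry | None = None,
    downscale: int = 1,
    stratum: str | None = None,
) -> SaturationCurve:
    """Leave-n-out bootstrap saturation curve for one participant pool.

    ``participants`` is either a mapping ``id -> (k, 2) point array``
    (requires ``geometry``) or a list of recordings / fixation sequences.
    Per iteration and sample size, ``n`` participants are drawn uniformly
    without replacement; the comparison map pools their points and the
    benchmark map pools a half-sized (``ceil(N/2)``) subset of the
    non-sampled participants.
    """
    point_sets, geometry = _as_point_sets(participants, geometry)
    n_grid = _validate_grid(
        n_grid if n_grid is not None else default_sample_grid(len(point_sets)),
        len(point_sets),
    )
    stack = _ParticipantStack(point_sets, geometry, downscale, sigma_deg)
    values = _bootstrap_matrices([stack], n_grid, n_bootstrap, (metric,), seed)
    return _curve_from_values(metric, n_grid, values[metric], n_bootstrap, stratum)


def multi_image_curve(
    per_image_participants: Mapping[str, object],
    metric: str = "AUC",
    n_grid: Sequence[int] | None = None,
    n_bootstrap: int = 10,
    sigma_deg: float = 1.0,
    seed: int = 0,
    *,
    geometry: StimulusGeometry | None = None,
    downscale: int = 1,
    categories: Mapping[str, str] | None = None,
    stratum: str | None = None,
) -> SaturationCurve:
    """Saturation curve averaged over images viewed by the same observers.

    Per iteration, the *same* sampled participant ids score every image
    (against that image's own leave-n-out benchmark) and the metric is the
    across-image average.  ``stratum`` restricts the image set to one
    category label when ``categories`` is given.
    """
    images = sorted(per_image_participants)
    if stratum is not None:
        if categories is None:
            raise ValueError("stratum filtering requires a categories mapping")
        images = [im for im in images if categories.get(im) == stratum]
    if len(images) < 2:
        raise ValueError("multi_image_curve needs at least 2 images")

    per_image_sets = {}
    geom = geometry
    for im in images:
        per_image_sets[im], geom = _as_point_sets(per_image_participants[im], geom)

    common_ids = sorted(set.intersection(*(set(s) for s in per_image_sets.values())))
    n_grid_arr = np.asarray(
        sorted(set(int(n) for n in (n_grid if n_grid is not None else default_sample_grid(len(common_ids))))),
        dtype=int,
    )
    for im in images:
        if len(per_image_sets[im]) < 2 * n_grid_arr[-1]:
            raise LeaveNOutError(
                f"image {im!r} has {len(per_image_sets[im])} participants; "
                f"needs >= {2 * n_grid_arr[-1]} for max sample size {n_grid_arr[-1]}"
            )
    n_grid_arr = _validate_grid(n_grid_arr, len(common_ids))

    stacks = [
        _ParticipantStack({pid: per_image_sets[im][pid] for pid in common_ids}, geom, downscale, sigma_deg)
        for im in images
    ]
    values = _bootstrap_matrices(stacks, n_grid_arr, n_bootstrap, (metric,), seed)
    return _curve_from_values(metric, n_grid_arr, values[metric], n_bootstrap, stratum)


def pct_change(curve: SaturationCurve) -> pd.DataFrame:
    """Percentage change in the mean metric from n-1 to n.

    Reported for every sample size whose predecessor n-1 is also in the
    curve: ``100 * (mean(n) - mean(n-1)) / mean(n-1)``.
    """
    rows = []
    sizes = set(curve.sample_sizes.tolist())
    for n in curve.sample_sizes:
        n = int(n)
        if n - 1 not in sizes:
            continue
        prev = curve.mean_at(n - 1)
        if prev == 0.0:
            raise UndefinedChangeError(f"mean at n={n - 1} is zero; percentage change undefined")
        rows.append({"n": n, "pct_change": 100.0 * (curve.mean_at(n) - prev) / prev})
    return pd.DataFrame(rows, columns=["n", "pct_change"])


def threshold_table(curve: SaturationCurve, rel_increase: float = 0.05) -> GuidelineTable:
    """Greedy scan for sample sizes achieving successive relative increases.

    Starting from the smallest sample size in the curve (nominally n = 1),
    each subsequent row is the smallest n whose bootstrap mean is at least
    ``(1 + rel_increase)`` times the previous row's mean.  When no such n
    remains the table records "> n_max".
    """
    ns = curve.sample_sizes
    means = curve.mean
    rows = [(int(ns[0]), float(means[0]))]
    current = float(means[0])
    i = 0
    exhausted = False
    while True:
        # tiny relative slack keeps exact-arithmetic boundary cases stable
        target = (1.0 + rel_increase) * current * (1.0 - 1e-12)
        nxt = None
        for j in range(i + 1, len(ns)):
            if means[j] >= target:
                nxt = j
                break
        if nxt is None:
            exhausted = True
            break
        rows.append((int(ns[nxt]), float(means[nxt])))
        current = float(means[nxt])
        i = nxt
    return GuidelineTable(
        rows=rows,
        rel_increase=rel_increase,
        n_max=int(ns[-1]),
        exhausted=exhausted,
        metric=curve.metric,
    )


def cross_reference(
    curve: SaturationCurve, from_ns: Sequence[int], to_ns: Sequence[int]
) -> pd.DataFrame:
    """Matrix of percentage changes in the mean metric between sample sizes.

    Cell (i, j) = ``100 * (mean(to_ns[j]) - mean(from_ns[i])) / mean(from_ns[i])``.
    """
    data = np.empty((len(from_ns), len(to_ns)))
    for i, nf in enumerate(from_ns):
        mf = curve.mean_at(int(nf))
        if mf == 0.0:
            raise UndefinedChangeError(f"mean at n={nf} is zero; percentage change undefined")
        for j, nt in enumerate(to_ns):
            data[i, j] = 100.0 * (curve.mean_at(int(nt)) - mf) / mf
    return pd.DataFrame(data, index=list(from_ns), columns=list(to_ns))


def default_sample_grid(n_participants: int) -> list[int]:
    """Default sample-size grid: dense below 50, century steps above."""
    cap = n_participants // 2
    base = [1, 2, 3, 4, 5, 6, 8, 10, 13, 16, 20, 25, 32, 40, 50]
    grid = [n for n in base if n <= cap]
    n = 100
    while n <= cap:
        grid.append(n)
        n += 100
    if cap >= 1 and cap not in grid:
        grid.append(cap)
    return sorted(set(grid))


# ---------------------------------------------------------------------------
# model / results


class SaturationAnalysis:
    """Leave-n-out bootstrap saturation model for a participant pool.

    Parameters
    ----------
    participants
        Mapping ``id -> (k, 2) point array`` (with ``geometry``), a list
        of recordings / fixation sequences, or — for a multi-image study —
        a mapping ``image -> participants`` (any of the former per image).
    metrics
        Metrics to bootstrap; both share the same participant draws.
    n_grid
        Sample sizes; defaults to a dense-then-century grid capped at N/2.
    n_bootstrap, sigma_deg, downscale
        Bootstrap repetitions, blur scale (degrees), and grid downscale.
    categories
        Optional image -> category mapping for stratified multi-image fits.

    ``fit(seed)`` returns a :class:`SaturationResult`.
    """

    def __init__(
        self,
        participants,
        *,
        geometry: StimulusGeometry | None = None,
        metrics: Sequence[str] = METRICS,
        n_grid: Sequence[int] | None = None,
        n_bootstrap: int = 1000,
        sigma_deg: float = 1.0,
        downscale: int = 1,
        categories: Mapping[str, str] | None = None,
        stratum: str | None = None,
    ):
        self.metrics = tuple(metrics)
        for m in self.metrics:
            if m not in METRICS:
                raise ValueError(f"unknown metric {m!r}; choose from {METRICS}")
        self.n_bootstrap = int(n_bootstrap)
        self.sigma_deg = float(sigma_deg)
        self.downscale = int(downscale)
        self.categories = dict(categories) if categories else None
        self.stratum = stratum

        self._multi_image = isinstance(participants, Mapping) and participants and all(
            not _looks_like_points(v) for v in participants.values()
        )
        if self._multi_image:
            images = sorted(participants)
            if stratum is not None:
                if self.categories is None:
                    raise ValueError("stratum filtering requires a categories mapping")
                images = [im for im in images if self.categories.get(im) == stratum]
            if len(images) < 2:
                raise ValueError("multi-image analysis needs at least 2 images")
            self._images = images
            self._per_image_sets = {}
            geom = geometry
            for im in images:
                self._per_image_sets[im], geom = _as_point_sets(participants[im], geom)
            self.geometry = geom
            self._ids = sorted(
                set.intersection(*(set(s) for s in self._per_image_sets.values()))
            )
        else:
            self._point_sets, self.geometry = _as_point_sets(participants, geometry)
            self._ids = sorted(self._point_sets)

        self.n_participants = len(self._ids)
        self.n_grid = _validate_grid(
            n_grid if n_grid is not None else default_sample_grid(self.n_participants),
            self.n_participants,
        )
        if self._multi_image:
            for im in self._images:
                if len(self._per_image_sets[im]) < 2 * int(self.n_grid[-1]):
                    raise LeaveNOutError(
                        f"image {im!r} has {len(self._per_image_sets[im])} participants; "
                        f"needs >= {2 * int(self.n_grid[-1])}"
                    )

    @classmethod
    def from_recordings(cls, recordings, **kwargs) -> "SaturationAnalysis":
        """Build from GazeRecording objects (sample-based maps)."""
        return cls(recordings, **kwargs)

    @classmethod
    def from_fixations(cls, sequences, geometry=None, **kwargs) -> "SaturationAnalysis":
        """Build from FixationSequence objects (fixation-based maps)."""
        return cls(sequences, geometry=geometry, **kwargs)

    @classmethod
    def from_images(cls, per_image_participants, **kwargs) -> "SaturationAnalysis":
        """Build a multi-image (per-image-then-average) analysis."""
        return cls(per_image_participants, **kwargs)

    def fit(self, seed: int = 0) -> "SaturationResult":
        """Run the bootstrap and return the fitted curves."""
        if self._multi_image:
            stacks = [
                _ParticipantStack(
                    {pid: self._per_image_sets[im][pid] for pid in self._ids},
                    self.geometry,
                    self.downscale,
                    self.sigma_deg,
                )
                for im in self._images
            ]
        else:
            stacks = [
                _ParticipantStack(self._point_sets, self.geometry, self.downscale, self.sigma_deg)
            ]
        values = _bootstrap_matrices(stacks, self.n_grid, self.n_bootstrap, self.metrics, seed)
        curves = {
            m: _curve_from_values(m, self.n_grid, values[m], self.n_bootstrap, self.stratum)
            for m in self.metrics
        }
        return SaturationResult(model=self, curves=curves, seed=seed)


def _looks_like_points(v) -> bool:
    """True when v is a point array rather than a nested participant set."""
    try:
        arr = np.asarray(v, dtype=float)
    except (TypeError, ValueError):
        return False
    return arr.ndim == 2 and arr.shape[1] == 2


@dataclass
class SaturationResult:
    """Fitted saturation curves plus derived tables and plots."""

    model: SaturationAnalysis
    curves: dict[str, SaturationCurve]
    seed: int = 0

    def curve(self, metric: str) -> SaturationCurve:
        return self.curves[metric]

    def curve_frame(self) -> pd.DataFrame:
        return pd.concat([c.to_frame() for c in self.curves.values()], ignore_index=True)

    def pct_change(self, metric: str) -> pd.DataFrame:
        return pct_change(self.curves[metric])

    def threshold_table(self, metric: str, rel_increase: float = 0.05) -> GuidelineTable:
        return threshold_table(self.curves[metric], rel_increase)

    def cross_reference(self, metric: str, from_ns, to_ns) -> pd.DataFrame:
        return cross_reference(self.curves[metric], from_ns, to_ns)

    def summary(self) -> str:
        """Plain-text summary in the spirit of a regression results table."""
        lines = [
            "Leave-n-out bootstrap saturation analysis",
            "=" * 57,
            f"participants: {self.model.n_participants:>6d}    bootstrap iterations: {self.model.n_bootstrap}",
            f"blur sigma:   {self.model.sigma_deg:>6.2f} deg  downscale: {self.model.downscale}   seed: {self.seed}",
        ]
        if self.model.stratum:
            lines.append(f"stratum:      {self.model.stratum}")
        for metric, curve in self.curves.items():
            lines.append("")
            lines.append(f"{metric} (mean [2.5%, 97.5%] per sample size n)")
            lines.append("-" * 57)
            df = curve.to_frame()[["n", "mean", "lo", "hi"]]
            lines.append(df.to_string(index=False, float_format=lambda v: f"{v:8.4f}"))
        return "\n".join(lines)

    def plot(self, ax=None):
        """Curve plot with shaded 95% range, one panel per metric."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if ax is None:
            fig, axes = plt.subplots(1, len(self.curves), figsize=(5 * len(self.curves), 4))
            axes = np.atleast_1d(axes)
        else:
            axes = np.atleast_1d(ax)
            fig = axes[0].figure
        for a, (metric, c) in zip(axes, self.curves.items()):
            a.fill_between(c.sample_sizes, c.lo_2_5, c.hi_97_5, alpha=0.3, label="95% range")
            a.plot(c.sample_sizes, c.mean, marker="o", label="bootstrap mean")
            a.set_xscale("log")
            a.set_xlabel("sample size n")
            a.set_ylabel(metric)
            a.legend()
        fig.tight_layout()
        return fig

    def to_csv(self, outdir, from_ns=None, to_ns=None) -> None:
        """Write curve.csv, pct_change.csv, threshold_table.csv, crossref.csv."""
        import os

        os.makedirs(outdir, exist_ok=True)
        self.curve_frame().to_csv(os.path.join(outdir, "curve.csv"), index=False)
        pd.concat(
            [self.pct_change(m).assign(metric=m) for m in self.curves],
            ignore_index=True,
        ).to_csv(os.path.join(outdir, "pct_change.csv"), index=False)
        pd.concat(
            [self.threshold_table(m).to_frame() for m in self.curves],
            ignore_index=True,
        ).to_csv(os.path.join(outdir, "threshold_table.csv"), index=False)
        ns = list(self.model.n_grid)
        from_ns = from_ns if from_ns is not None else ns
        to_ns = to_ns if to_ns is not None else ns
        frames = []
        for m in self.curves:
            xr = self.cross_reference(m, from_ns, to_ns)
            xr.insert(0, "metric", m)
            xr.insert(1, "from_n", from_ns)
            frames.append(xr)
        pd.concat(frames, ignore_index=True).to_csv(
            os.path.join(outdir, "crossref.csv"), index=False
        )
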