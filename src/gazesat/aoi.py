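"""Area-of-interest fixation metrics and their bootstrap variance curves.

Five per-participant metrics are computed for each named polygonal AOI:

1. ``n_visits`` — number of visits, a visit being a maximal run of
   consecutive fixations inside the AOI separated by at least one
   fixation outside it;
2. ``pct_fixated`` — in-AOI fixations as a percentage of all fixations;
3. ``ttff_s`` — time to first fixation within the AOI (missing when the
   AOI is never fixated);
4. ``dwell_per_visit_s`` — total in-AOI fixation duration divided by the
   number of visits (missing when there are no visits);
5. ``total_dwell_s`` — sum of in-AOI fixation durations.

The variance analysis subsamples participants at each candidate sample
size, takes the across-participant mean of a metric per draw (pairwise
exclusion of missing values), and summarises the spread of those means as
the 95% range — 97.5th minus 2.5th percentile over bootstrap iterations.
The guideline tables read the variance curve the same way the similarity
tables read the saturation curve, but downward: ``variance_reduction_table``
lists sample sizes at which the 95% range first drops by a relative
fraction (default 25%).
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import FixationSequence
from .exceptions import MissingSampleSizeError, UndefinedChangeError
from .io import AOI

__all__ = [
    "AOI_METRICS",
    "AOIMetricsRecord",
    "VarianceCurve",
    "fixation_in_aoi",
    "aoi_metrics",
    "aoi_metrics_table",
    "variance_curve",
    "variance_reduction_table",
    "variance_cross_reference",
    "AOIVarianceAnalysis",
    "AOIVarianceResult",
]

AOI_METRICS = ("n_visits", "pct_fixated", "ttff_s", "dwell_per_visit_s", "total_dwell_s")


@dataclass
class AOIMetricsRecord:
    """The five AOI metrics for one participant and one AOI.

    ``ttff_s`` and ``dwell_per_visit_s`` are NaN when the AOI was never
    fixated.
    """

    participant_id: str
    aoi_name: str
    n_visits: int
    pct_fixated: float
    ttff_s: float
    dwell_per_visit_s: float
    total_dwell_s: float


def fixation_in_aoi(x: float, y: float, aoi: AOI) -> bool:
    """Point-in-polygon hit test; boundary points count as inside."""
    return aoi.contains(x, y)


def _hits(seq: FixationSequence, aoi: AOI) -> np.ndarray:
    return np.array([aoi.contains(x, y) for x, y in zip(seq.xs_px, seq.ys_px)], dtype=bool)


def aoi_metrics(seq: FixationSequence, aoi: AOI) -> AOIMetricsRecord:
    """Compute the five AOI metrics for one fixation sequence.

    An empty sequence yields the all-zero record with missing ttff and
    dwell-per-visit.
    """
    hits = _hits(seq, aoi)
    n_total = len(hits)
    n_in = int(hits.sum())
    if n_in == 0:
        return AOIMetricsRecord(
            participant_id=seq.participant_id,
            aoi_name=aoi.name,
            n_visits=0,
            pct_fixated=0.0,
            ttff_s=np.nan,
            dwell_per_visit_s=np.nan,
            total_dwell_s=0.0,
        )
    # visits = maximal runs of consecutive in-AOI fixations
    starts = hits & ~np.concatenate([[False], hits[:-1]])
    n_visits = int(starts.sum())
    total_dwell = float(seq.durations_s[hits].sum())
    return AOIMetricsRecord(
        participant_id=seq.participant_id,
        aoi_name=aoi.name,
        n_visits=n_visits,
        pct_fixated=100.0 * n_in / n_total,
        ttff_s=float(seq.onsets_s[hits][0]),
        dwell_per_visit_s=total_dwell / n_visits,
        total_dwell_s=total_dwell,
    )


def aoi_metrics_table(sequences: Sequence[FixationSequence], aois: Sequence[AOI]) -> pd.DataFrame:
    """Long table of all metrics: one row per (participant, AOI)."""
    rows = []
    for seq in sequences:
        for aoi in aois:
            rec = aoi_metrics(seq, aoi)
            rows.append(
                {
                    "participant": rec.participant_id,
                    "aoi": rec.aoi_name,
                    "n_visits": rec.n_visits,
                    "pct_fixated": rec.pct_fixated,
                    "ttff_s": rec.ttff_s,
                    "dwell_per_visit_s": rec.dwell_per_visit_s,
                    "total_dwell_s": rec.total_dwell_s,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class VarianceCurve:
    """Bootstrap mean and 95% range of an AOI metric's sample mean per n."""

    aoi_name: str
    metric: str
    sample_sizes: np.ndarray
    mean: np.ndarray
    range95: np.ndarray
    lo_2_5: np.ndarray
    hi_97_5: np.ndarray
    n_bootstrap: int
    n_missing: int = 0

    def __post_init__(self) -> None:
        self.sample_sizes = np.asarray(self.sample_sizes, dtype=int)
        for name in ("mean", "range95", "lo_2_5", "hi_97_5"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        order = np.argsort(self.sample_sizes)
        for name in ("sample_sizes", "mean", "range95", "lo_2_5", "hi_97_5"):
            setattr(self, name, getattr(self, name)[order])

    def range95_at(self, n: int) -> float:
        idx = np.flatnonzero(self.sample_sizes == n)
        if idx.size == 0:
            raise MissingSampleSizeError(f"sample size n={n} not in curve")
        return float(self.range95[idx[0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "aoi": self.aoi_name,
                "metric": self.metric,
                "n": self.sample_sizes,
                "mean": self.mean,
                "lo": self.lo_2_5,
                "hi": self.hi_97_5,
                "range95": self.range95,
                "n_boot": self.n_bootstrap,
            }
        )


def variance_curve(
    fixation_sets: Sequence[FixationSequence],
    aoi: AOI,
    metric: str,
    n_grid: Sequence[int],
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> VarianceCurve:
    """Bootstrap variance-vs-sample-size curve for one AOI metric.

    Per iteration and sample size, ``n`` participants are drawn without
    replacement and the across-participant mean of the metric is taken
    (participants with a missing value are excluded from that mean; the
    total number of missing participants is recorded on the curve).
    Participant draws are keyed to sorted participant ids, so input order
    does not matter.
    """
    if metric not in AOI_METRICS:
        raise ValueError(f"unknown AOI metric {metric!r}; choose from {AOI_METRICS}")
    seqs = sorted(fixation_sets, key=lambda s: str(s.participant_id))
    values = np.array([getattr(aoi_metrics(s, aoi), metric) for s in seqs], dtype=float)
    n_participants = len(values)
    grid = np.asarray(sorted(set(int(n) for n in n_grid)), dtype=int)
    if grid[0] < 1 or grid[-1] > n_participants:
        raise ValueError(f"n_grid must lie in [1, {n_participants}]")
    n_missing = int(np.isnan(values).sum())

    rng = np.random.default_rng(np.random.SeedSequence([seed]))
    boot = np.empty((n_bootstrap, len(grid)))
    with np.errstate(invalid="ignore"):  # all-NaN draws yield NaN means
        for it in range(n_bootstrap):
            for j, n in enumerate(grid):
                idx = rng.choice(n_participants, size=int(n), replace=False)
                sample = values[idx]
                finite = sample[~np.isnan(sample)]
                boot[it, j] = finite.mean() if finite.size else np.nan

    lo = np.nanpercentile(boot, 2.5, axis=0)
    hi = np.nanpercentile(boot, 97.5, axis=0)
    return VarianceCurve(
        aoi_name=aoi.name,
        metric=metric,
        sample_sizes=grid,
        mean=np.nanmean(boot, axis=0),
        range95=hi - lo,
        lo_2_5=lo,
        hi_97_5=hi,
        n_bootstrap=n_bootstrap,
        n_missing=n_missing,
    )


def variance_reduction_table(curve: VarianceCurve, rel_decrease: float = 0.25) -> pd.DataFrame:
    """Sample sizes achieving successive relative decreases in the 95% range.

    Greedy scan starting at the smallest n: each subsequent row is the
    smallest n whose range95 is at most ``(1 - rel_decrease)`` times the
    previous row's.  A final "> n_max" row marks exhaustion of the grid.
    """
    ns = curve.sample_sizes
    r = curve.range95
    rows: list[dict] = [{"n": int(ns[0]), "range95": float(r[0])}]
    current = float(r[0])
    i = 0
    exhausted = False
    while True:
        # tiny relative slack keeps exact-arithmetic boundary cases stable
        target = (1.0 - rel_decrease) * current * (1.0 + 1e-12)
        nxt = None
        for j in range(i + 1, len(ns)):
            if r[j] <= target:
                nxt = j
                break
        if nxt is None:
            exhausted = True
            break
        rows.append({"n": int(ns[nxt]), "range95": float(r[nxt])})
        current = float(r[nxt])
        i = nxt
    if exhausted:
        rows.append({"n": f"> {int(ns[-1])}", "range95": np.nan})
    df = pd.DataFrame(rows)
    df.insert(0, "metric", curve.metric)
    df.insert(0, "aoi", curve.aoi_name)
    return df


def variance_cross_reference(
    curve: VarianceCurve, from_ns: Sequence[int], to_ns: Sequence[int]
) -> pd.DataFrame:
    """Matrix of percentage changes in the 95% range between sample sizes."""
    data = np.empty((len(from_ns), len(to_ns)))
    for i, nf in enumerate(from_ns):
        rf = curve.range95_at(int(nf))
        if rf == 0.0:
            raise UndefinedChangeError(f"range95 at n={nf} is zero; percentage change undefined")
        for j, nt in enumerate(to_ns):
            data[i, j] = 100.0 * (curve.range95_at(int(nt)) - rf) / rf
    return pd.DataFrame(data, index=list(from_ns), columns=list(to_ns))


class AOIVarianceAnalysis:
    """Bootstrap variance model for AOI metrics across sample sizes.

    Computes, for every (AOI, metric) pair, the dispersion of the sample
    mean at each candidate sample size.  ``fit(seed)`` returns an
    :class:`AOIVarianceResult`.
    """

    def __init__(
        self,
        fixation_sets: Sequence[FixationSequence],
        aois: Sequence[AOI],
        *,
        metrics: Sequence[str] = AOI_METRICS,
        n_grid: Sequence[int] | None = None,
        n_bootstrap: int = 1000,
    ):
        self.fixation_sets = sorted(fixation_sets, key=lambda s: str(s.participant_id))
        self.aois = list(aois)
        self.metrics = tuple(metrics)
        for m in self.metrics:
            if m not in AOI_METRICS:
                raise ValueError(f"unknown AOI metric {m!r}")
        self.n_participants = len(self.fixation_sets)
        if n_grid is None:
            base = [1, 2, 3, 5, 7, 10, 15, 25, 40, 65, 100, 160, 250, 400, 650, 1000]
            n_grid = [n for n in base if n <= self.n_participants]
            if self.n_participants not in n_grid:
                n_grid.append(self.n_participants)
        self.n_grid = sorted(set(int(n) for n in n_grid))
        self.n_bootstrap = int(n_bootstrap)

    def fit(self, seed: int = 0) -> "AOIVarianceResult":
        curves: dict[tuple[str, str], VarianceCurve] = {}
        for k, aoi in enumerate(self.aois):
            for m, metric in enumerate(self.metrics):
                # independent but reproducible stream per (aoi, metric)
                sub_seed = int(
                    np.random.default_rng(
                        np.random.SeedSequence([seed, k, m])
                    ).integers(0, 2**31 - 1)
                )
                curves[(aoi.name, metric)] = variance_curve(
                    self.fixation_sets,
                    aoi,
                    metric,
                    self.n_grid,
                    n_bootstrap=self.n_bootstrap,
                    seed=sub_seed,
                )
        table = aoi_metrics_table(self.fixation_sets, self.aois)
        return AOIVarianceResult(model=self, curves=curves, metrics_table=table, seed=seed)


@dataclass
class AOIVarianceResult:
    """Fitted AOI variance curves plus derived tables and plots."""

    model: AOIVarianceAnalysis
    curves: dict[tuple[str, str], VarianceCurve]
    metrics_table: pd.DataFrame
    seed: int = 0

    def curve(self, aoi_name: str, metric: str) -> VarianceCurve:
        return self.curves[(aoi_name, metric)]

    def curve_frame(self) -> pd.DataFrame:
        return pd.concat([c.to_frame() for c in self.curves.values()], ignore_index=True)

    def variance_reduction_table(
        self, aoi_name: str, metric: str, rel_decrease: float = 0.25
    ) -> pd.DataFrame:
        return variance_reduction_table(self.curves[(aoi_name, metric)], rel_decrease)

    def cross_reference(self, aoi_name: str, metric: str, from_ns, to_ns) -> pd.DataFrame:
        return variance_cross_reference(self.curves[(aoi_name, metric)], from_ns, to_ns)

    def summary(self) -> str:
        lines = [
            "AOI-metric bootstrap variance analysis",
            "=" * 57,
            f"participants: {self.model.n_participants}    AOIs: {len(self.model.aois)}    "
            f"bootstrap iterations: {self.model.n_bootstrap}    seed: {self.seed}",
        ]
        for (aoi_name, metric), c in self.curves.items():
            lines.append("")
            lines.append(f"{aoi_name} / {metric} (mean and 95% range per n)")
            lines.append("-" * 57)
            df = c.to_frame()[["n", "mean", "range95"]]
            lines.append(df.to_string(index=False, float_format=lambda v: f"{v:9.4f}"))
        return "\n".join(lines)

    def plot(self, metric: str | None = None):
        """95% range vs sample size (log x), one line per AOI."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        metrics = [metric] if metric else list(self.model.metrics)
        fig, axes = plt.subplots(1, len(metrics), figsize=(5 * len(metrics), 4))
        axes = np.atleast_1d(axes)
        for a, m in zip(axes, metrics):
            for aoi in self.model.aois:
                c = self.curves[(aoi.name, m)]
                a.plot(c.sample_sizes, c.range95, marker="o", label=aoi.name)
            a.set_xscale("log")
            a.set_xlabel("sample size n")
            a.set_ylabel(f"95% range of mean {m}")
            a.legend(fontsize=8)
        fig.tight_layout()
        return fig

    def to_csv(self, outdir) -> None:
        """Write aoi_metrics.csv, aoi_variance_curve.csv, aoi_tables.csv."""
        import os

        os.makedirs(outdir, exist_ok=True)
        self.metrics_table.to_csv(os.path.join(outdir, "aoi_metrics.csv"), index=False)
        self.curve_frame().to_csv(os.path.join(outdir, "aoi_variance_curve.csv"), index=False)
        pd.concat(
            [
                self.variance_reduction_table(aoi.name, m)
                for aoi in self.model.aois
                for m in self.model.metrics
            ],
            ignore_index=True,
        ).to_csv(os.path.join(outdir, "aoi_tables.csv"), index=False)
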