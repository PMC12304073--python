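"""AOI hit testing, the five fixation metrics, and variance curves."""

import numpy as np
import pandas as pd
import pytest

import gazesat as gs
from tests.conftest import make_fixseq


def winding_number_inside(px, py, vertices):
    """Independent point-in-polygon oracle (winding number)."""
    wn = 0
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        if y1 <= py:
            if y2 > py and (x2 - x1) * (py - y1) - (px - x1) * (y2 - y1) > 0:
                wn += 1
        elif y2 <= py and (x2 - x1) * (py - y1) - (px - x1) * (y2 - y1) < 0:
            wn -= 1
    return wn != 0


class TestHitTesting:
    def test_centroid_of_convex_polygon_inside(self, square_aoi):
        assert gs.fixation_in_aoi(100, 75, square_aoi)

    def test_point_outside_bounding_box(self, square_aoi):
        assert not gs.fixation_in_aoi(10, 10, square_aoi)

    def test_boundary_point_counts_as_inside(self, square_aoi):
        assert gs.fixation_in_aoi(50, 40, square_aoi)
        assert gs.fixation_in_aoi(100, 40, square_aoi)

    def test_thousand_random_points_match_winding_oracle(self):
        verts = [(20, 10), (180, 40), (150, 140), (90, 90), (30, 120)]
        aoi = gs.AOI("blob", verts)
        rng = np.random.default_rng(0)
        pts = np.column_stack([rng.uniform(0, 200, 1000), rng.uniform(0, 150, 1000)])
        got = [gs.fixation_in_aoi(x, y, aoi) for x, y in pts]
        expected = [winding_number_inside(x, y, verts) for x, y in pts]
        assert got == expected


class TestAOIMetrics:
    def test_hand_traced_visit_pattern(self, square_aoi):
        # in/out pattern [out, in, in, out, in]; onsets 0,0.2,...; durations 0.2
        xy = [(10, 10), (100, 75), (110, 80), (10, 10), (100, 75)]
        rec = gs.aoi_metrics(make_fixseq("a", xy), square_aoi)
        assert rec.n_visits == 2
        assert rec.pct_fixated == pytest.approx(60.0)
        assert rec.ttff_s == pytest.approx(0.2)
        assert rec.total_dwell_s == pytest.approx(0.6)
        assert rec.dwell_per_visit_s == pytest.approx(0.3)

    def test_never_fixated(self, square_aoi):
        rec = gs.aoi_metrics(make_fixseq("a", [(10, 10), (20, 20)]), square_aoi)
        assert rec.n_visits == 0
        assert rec.pct_fixated == 0.0
        assert np.isnan(rec.ttff_s)
        assert np.isnan(rec.dwell_per_visit_s)
        assert rec.total_dwell_s == 0.0

    def test_all_inside_single_visit(self, square_aoi):
        xy = [(100, 75)] * 5
        rec = gs.aoi_metrics(make_fixseq("a", xy), square_aoi)
        assert rec.n_visits == 1
        assert rec.pct_fixated == 100.0
        assert rec.dwell_per_visit_s == pytest.approx(rec.total_dwell_s)

    def test_empty_sequence(self, square_aoi):
        empty = gs.FixationSequence("a", [], [], [], [])
        rec = gs.aoi_metrics(empty, square_aoi)
        assert rec.n_visits == 0 and rec.total_dwell_s == 0.0
        assert np.isnan(rec.ttff_s)

    def test_internal_consistency_on_randomized_sequences(self, square_aoi):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            k = rng.integers(1, 12)
            xy = np.column_stack([rng.uniform(0, 200, k), rng.uniform(0, 150, k)])
            rec = gs.aoi_metrics(make_fixseq("a", xy), square_aoi)
            zero = rec.n_visits == 0
            assert zero == (rec.total_dwell_s == 0.0)
            assert zero == (rec.pct_fixated == 0.0)
            assert zero == np.isnan(rec.ttff_s)
            if not zero:
                assert rec.dwell_per_visit_s == pytest.approx(rec.total_dwell_s / rec.n_visits)

    def test_n_visits_matches_run_length_oracle(self, square_aoi):
        """Visit counting equals run-length encoding of in/out booleans."""
        from itertools import groupby

        inside_xy, outside_xy = (100.0, 75.0), (10.0, 10.0)
        rng = np.random.default_rng(2)
        for _ in range(1000):
            k = int(rng.integers(1, 15))
            flags = rng.random(k) < 0.5
            xy = [inside_xy if f else outside_xy for f in flags]
            rec = gs.aoi_metrics(make_fixseq("a", xy), square_aoi)
            expected = sum(1 for val, _ in groupby(flags) if val)
            assert rec.n_visits == expected

    def test_metrics_table_shape(self, square_aoi):
        seqs = [make_fixseq(i, [(100, 75), (10, 10)]) for i in range(3)]
        tri = gs.AOI("tri", [(0, 0), (30, 0), (15, 30)])
        df = gs.aoi_metrics_table(seqs, [square_aoi, tri])
        assert len(df) == 6
        assert set(df.columns) >= {"participant", "aoi", *gs.AOI_METRICS}


@pytest.fixture(scope="module")
def population():
    rng = np.random.default_rng(3)
    seqs = []
    for i in range(60):
        k = int(rng.integers(3, 10))
        xy = np.column_stack([rng.uniform(0, 200, k), rng.uniform(0, 150, k)])
        seqs.append(make_fixseq(f"p{i:03d}", xy))
    return seqs


class TestVarianceCurve:
    def test_full_sample_has_zero_range(self, population, square_aoi):
        c = gs.variance_curve(population, square_aoi, "n_visits", [10, 60], n_bootstrap=50, seed=1)
        assert c.range95_at(60) == 0.0
        assert c.range95_at(10) > 0.0

    def test_mean_stable_across_sample_sizes(self, population, square_aoi):
        c = gs.variance_curve(
            population, square_aoi, "n_visits", [5, 15, 60], n_bootstrap=300, seed=2
        )
        full_mean = c.mean[-1]
        for j in range(len(c.sample_sizes)):
            assert c.lo_2_5[j] - 1e-9 <= full_mean <= c.hi_97_5[j] + 1e-9

    def test_missing_values_excluded_pairwise(self, square_aoi):
        inside, outside = (100.0, 75.0), (10.0, 10.0)
        seqs = [make_fixseq("hit", [inside]), make_fixseq("miss", [outside])]
        c = gs.variance_curve(seqs, square_aoi, "ttff_s", [2], n_bootstrap=5, seed=0)
        assert c.n_missing == 1
        assert c.mean[0] == pytest.approx(0.0)  # only the hit contributes

    def test_exchangeability(self, population, square_aoi):
        kw = dict(metric="total_dwell_s", n_grid=[5, 20], n_bootstrap=40, seed=9)
        a = gs.variance_curve(population, square_aoi, **kw)
        b = gs.variance_curve(list(reversed(population)), square_aoi, **kw)
        np.testing.assert_array_equal(a.range95, b.range95)

    def test_oversized_grid_rejected(self, population, square_aoi):
        with pytest.raises(ValueError):
            gs.variance_curve(population, square_aoi, "n_visits", [100], n_bootstrap=2)


def analytic_curve(ns, c=2.0):
    ns = np.asarray(ns)
    r = c / np.sqrt(ns)
    return gs.VarianceCurve(
        aoi_name="analytic", metric="n_visits", sample_sizes=ns,
        mean=np.ones_like(r), range95=r, lo_2_5=-r / 2, hi_97_5=r / 2, n_bootstrap=1,
    )


class TestVarianceTables:
    def test_reduction_table_matches_closed_form_on_sqrt_curve(self):
        """On range95 = c / sqrt(n), each row needs n' >= n / 0.75^2."""
        ns = np.arange(1, 200)
        t = gs.variance_reduction_table(analytic_curve(ns), rel_decrease=0.25)
        body = t[t["n"].apply(lambda v: isinstance(v, int))]
        # exact integer arithmetic: need n >= prev / 0.75^2 = 16 prev / 9
        expected = [1]
        while True:
            nxt = max(-(-16 * expected[-1] // 9), expected[-1] + 1)
            if nxt > ns[-1]:
                break
            expected.append(int(nxt))
        assert body["n"].tolist() == expected

    def test_flat_curve_single_row(self):
        ns = np.array([1, 5, 10])
        c = gs.VarianceCurve("a", "n_visits", ns, np.ones(3), np.full(3, 0.4),
                             np.zeros(3), np.full(3, 0.4), 1)
        t = gs.variance_reduction_table(c)
        ints = [v for v in t["n"] if isinstance(v, int)]
        assert ints == [1]
        assert t["n"].iloc[-1] == "> 10"

    def test_monotone_curve_strictly_increasing_rows(self):
        t = gs.variance_reduction_table(analytic_curve(np.arange(1, 100)))
        ints = [v for v in t["n"] if isinstance(v, int)]
        assert ints == sorted(set(ints))

    def test_cross_reference_identities(self):
        c = analytic_curve([10, 40])
        xr = gs.variance_cross_reference(c, [10, 40], [10, 40])
        assert xr.loc[10, 10] == 0.0
        assert xr.loc[10, 40] == pytest.approx(-50.0)


class TestModelResults:
    def test_fit_and_outputs(self, square_aoi, tmp_path):
        rng = np.random.default_rng(4)
        seqs = [
            make_fixseq(
                f"p{i:02d}",
                np.column_stack([rng.uniform(0, 200, 6), rng.uniform(0, 150, 6)]),
            )
            for i in range(20)
        ]
        model = gs.AOIVarianceAnalysis(
            seqs, [square_aoi], metrics=("n_visits", "total_dwell_s"),
            n_grid=[2, 5, 10], n_bootstrap=30,
        )
        res = model.fit(seed=5)
        assert set(res.curves) == {("box", "n_visits"), ("box", "total_dwell_s")}
        assert "box" in res.summary()
        res.to_csv(tmp_path)
        for name in ("aoi_metrics.csv", "aoi_variance_curve.csv", "aoi_tables.csv"):
            assert (tmp_path / name).exists()
        df = pd.read_csv(tmp_path / "aoi_variance_curve.csv")
        assert set(df["metric"]) == {"n_visits", "total_dwell_s"}

    def test_refit_same_seed_reproduces(self, square_aoi):
        rng = np.random.default_rng(6)
        seqs = [
            make_fixseq(
                f"p{i:02d}",
                np.column_stack([rng.uniform(0, 200, 5), rng.uniform(0, 150, 5)]),
            )
            for i in range(12)
        ]
        model = gs.AOIVarianceAnalysis(seqs, [square_aoi], metrics=("n_visits",),
                                       n_grid=[2, 6], n_bootstrap=25)
        a = model.fit(seed=8)
        b = model.fit(seed=8)
        np.testing.assert_array_equal(
            a.curve("box", "n_visits").range95, b.curve("box", "n_visits").range95
        )
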