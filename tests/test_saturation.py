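"""Leave-n-out bootstrap engine, curves and guideline-table arithmetic."""

import numpy as np
import pandas as pd
import pytest

import gazesat as gs
from gazesat.exceptions import LeaveNOutError, MissingSampleSizeError, UndefinedChangeError


def toy_curve(metric, ns, means, n_boot=100):
    ns = np.asarray(ns)
    means = np.asarray(means, float)
    return gs.SaturationCurve(
        metric=metric,
        sample_sizes=ns,
        mean=means,
        lo_2_5=means - 0.01,
        hi_97_5=means + 0.01,
        n_bootstrap=n_boot,
    )


class TestBootstrapEngine:
    def test_single_iteration_reduces_to_direct_metric_call(self, small_geometry):
        """With B=1 and n=1 on 3 participants the engine value must equal a
        plain nss()/auc() evaluation of one of the 3 possible splits."""
        rng = np.random.default_rng(0)
        point_sets = {
            f"p{i}": np.column_stack(
                [rng.uniform(0, 200, 30), rng.uniform(0, 150, 30)]
            )
            for i in range(3)
        }
        for metric, func in [("NSS", gs.nss), ("AUC", gs.auc)]:
            curve = gs.bootstrap_curve(
                point_sets, metric=metric, n_grid=[1], n_bootstrap=1,
                seed=5, geometry=small_geometry, downscale=5,
            )
            candidates = []
            for held in point_sets:
                comp = gs.accumulate(point_sets[held], small_geometry, downscale=5)
                others = np.vstack([point_sets[k] for k in point_sets if k != held])
                bench = gs.accumulate(others, small_geometry, downscale=5)
                candidates.append(func(comp, bench).value)
            assert any(abs(curve.mean[0] - c) < 1e-9 for c in candidates)
            assert curve.lo_2_5[0] == curve.hi_97_5[0] == curve.mean[0]

    def test_exchangeability_under_participant_permutation(self, small_geometry):
        rng = np.random.default_rng(1)
        point_sets = {
            f"p{i}": np.column_stack([rng.uniform(0, 200, 20), rng.uniform(0, 150, 20)])
            for i in range(8)
        }
        shuffled = {k: point_sets[k] for k in reversed(list(point_sets))}
        kw = dict(metric="AUC", n_grid=[1, 2, 4], n_bootstrap=20, seed=3,
                  geometry=small_geometry, downscale=5)
        a = gs.bootstrap_curve(point_sets, **kw)
        b = gs.bootstrap_curve(shuffled, **kw)
        np.testing.assert_array_equal(a.mean, b.mean)
        np.testing.assert_array_equal(a.lo_2_5, b.lo_2_5)

    def test_oversized_sample_rejected(self, small_geometry):
        point_sets = {f"p{i}": [(10.0, 10.0)] for i in range(6)}
        with pytest.raises(LeaveNOutError, match="floor"):
            gs.bootstrap_curve(point_sets, n_grid=[4], geometry=small_geometry)

    def test_percentile_bounds_contain_mean(self, medium_auc_result):
        c = medium_auc_result.curve("AUC")
        assert np.all(c.lo_2_5 <= c.mean + 1e-12)
        assert np.all(c.mean <= c.hi_97_5 + 1e-12)

    def test_mean_auc_saturates_with_sample_size(self, medium_auc_result):
        """Information gain concentrates at small n and flattens out."""
        c = medium_auc_result.curve("AUC")
        assert np.all(np.diff(c.mean) >= 0)
        increments = np.diff(c.mean)
        assert increments[0] == max(increments)

    def test_95_range_shrinks_and_roughly_halves_per_4x(self, medium_auc_result):
        c = medium_auc_result.curve("AUC")
        rng95 = c.hi_97_5 - c.lo_2_5
        assert np.all(np.diff(rng95) < 0)
        sizes = list(c.sample_sizes)
        # CLT-dominated regime: quadrupling n halves the 95% range
        for a, b in [(1, 4), (2, 8), (4, 16), (8, 32)]:
            ratio = rng95[sizes.index(b)] / rng95[sizes.index(a)]
            assert 0.35 <= ratio <= 0.65


@pytest.fixture(scope="module")
def image_points():
    rng = np.random.default_rng(2)

    def one_image():
        return {
            f"p{i}": np.column_stack([rng.uniform(0, 200, 15), rng.uniform(0, 150, 15)])
            for i in range(10)
        }

    return {"imgA": one_image(), "imgB": one_image(), "imgC": one_image()}


class TestMultiImage:
    def test_identical_images_match_single_image_curve(self, small_geometry, image_points):
        one = image_points["imgA"]
        kw = dict(metric="AUC", n_grid=[1, 2, 4], n_bootstrap=10, seed=4, downscale=5)
        single = gs.bootstrap_curve(one, geometry=small_geometry, **kw)
        double = gs.multi_image_curve(
            {"x": one, "y": one}, geometry=small_geometry, **kw
        )
        np.testing.assert_allclose(double.mean, single.mean, atol=1e-12)

    def test_averaging_images_reduces_dispersion(self, small_geometry, image_points):
        kw = dict(metric="AUC", n_grid=[1, 2, 4], n_bootstrap=60, seed=6, downscale=5)
        single = gs.bootstrap_curve(image_points["imgA"], geometry=small_geometry, **kw)
        multi = gs.multi_image_curve(image_points, geometry=small_geometry, **kw)
        assert np.mean(multi.hi_97_5 - multi.lo_2_5) < np.mean(single.hi_97_5 - single.lo_2_5)

    def test_stratum_filter_restricts_image_set(self, small_geometry, image_points):
        cats = {"imgA": "urban", "imgB": "urban", "imgC": "natural"}
        kw = dict(metric="AUC", n_grid=[1, 2], n_bootstrap=5, seed=7, downscale=5)
        urban = gs.multi_image_curve(
            image_points, geometry=small_geometry, categories=cats, stratum="urban", **kw
        )
        assert urban.stratum == "urban"
        with pytest.raises(ValueError, match="at least 2"):
            gs.multi_image_curve(
                image_points, geometry=small_geometry, categories=cats, stratum="natural", **kw
            )

    def test_undersized_image_rejected(self, small_geometry, image_points):
        small = {k: v for k, v in list(image_points["imgA"].items())[:4]}
        with pytest.raises(LeaveNOutError, match="image"):
            gs.multi_image_curve(
                {"big": image_points["imgB"], "small": small},
                metric="AUC", n_grid=[1, 2, 4], n_bootstrap=2,
                geometry=small_geometry, downscale=5,
            )


class TestPctChange:
    def test_flat_curve_zero_everywhere(self):
        c = toy_curve("NSS", [1, 2, 3], [0.8, 0.8, 0.8])
        assert (gs.pct_change(c)["pct_change"] == 0).all()

    def test_five_percent_step(self):
        c = toy_curve("NSS", [1, 2], [1.0, 1.05])
        assert gs.pct_change(c)["pct_change"].iloc[0] == pytest.approx(5.0)

    def test_monotone_curve_nonnegative_changes(self):
        c = toy_curve("AUC", [1, 2, 3, 4], [0.6, 0.65, 0.7, 0.7])
        assert (gs.pct_change(c)["pct_change"] >= 0).all()

    def test_nonconsecutive_sizes_skipped(self):
        c = toy_curve("AUC", [1, 2, 10], [0.6, 0.65, 0.8])
        assert gs.pct_change(c)["n"].tolist() == [2]

    def test_zero_baseline_rejected(self):
        c = toy_curve("NSS", [1, 2], [0.0, 0.5])
        with pytest.raises(UndefinedChangeError):
            gs.pct_change(c)


class TestThresholdTable:
    def test_geometric_curve_selects_every_step(self):
        ns = np.arange(1, 8)
        c = toy_curve("NSS", ns, np.cumprod(np.full(7, 1.05)))
        t = gs.threshold_table(c, rel_increase=0.05)
        assert [n for n, _ in t.rows] == list(ns)
        assert t.to_frame()["n"].iloc[-1] == "> 7"

    def test_flat_curve_single_row_then_exhausted(self):
        c = toy_curve("AUC", [1, 2, 4, 8], [0.7, 0.7, 0.7, 0.7])
        t = gs.threshold_table(c)
        assert t.rows == [(1, 0.7)]
        assert t.exhausted
        frame = t.to_frame()
        assert frame["n"].iloc[-1] == "> 8"

    def test_rows_respect_relative_increase_invariant(self):
        rng_means = 0.5 * 1.03 ** np.arange(20)
        c = toy_curve("NSS", np.arange(1, 21), rng_means)
        t = gs.threshold_table(c, rel_increase=0.05)
        vals = [v for _, v in t.rows]
        assert all(b >= 1.05 * a for a, b in zip(vals, vals[1:]))


class TestCrossReference:
    def test_diagonal_is_zero(self):
        c = toy_curve("NSS", [5, 10, 15], [0.9, 1.0, 1.068])
        xr = gs.cross_reference(c, [10], [10])
        assert xr.loc[10, 10] == 0.0

    def test_arithmetic_example(self):
        c = toy_curve("NSS", [10, 15], [1.0, 1.068])
        assert gs.cross_reference(c, [10], [15]).loc[10, 15] == pytest.approx(6.8)

    def test_antisymmetry_identity(self):
        c = toy_curve("NSS", [10, 15], [1.0, 1.068])
        fwd = gs.cross_reference(c, [10], [15]).loc[10, 15]
        back = gs.cross_reference(c, [15], [10]).loc[15, 10]
        assert back == pytest.approx(-fwd / 1.068)

    def test_missing_sample_size_rejected(self):
        c = toy_curve("NSS", [10, 15], [1.0, 1.068])
        with pytest.raises(MissingSampleSizeError):
            gs.cross_reference(c, [10], [20])


class TestModelResults:
    def test_fit_computes_both_metrics_on_shared_draws(self, small_geometry):
        rng = np.random.default_rng(11)
        point_sets = {
            f"p{i}": np.column_stack([rng.uniform(0, 200, 25), rng.uniform(0, 150, 25)])
            for i in range(10)
        }
        model = gs.SaturationAnalysis(
            point_sets, geometry=small_geometry, n_grid=[1, 2, 4],
            n_bootstrap=15, downscale=5,
        )
        res = model.fit(seed=2)
        assert set(res.curves) == {"NSS", "AUC"}
        frame = res.curve_frame()
        assert set(frame["metric"]) == {"NSS", "AUC"}
        assert len(frame) == 6

    def test_summary_and_plot_smoke(self, medium_auc_result):
        text = medium_auc_result.summary()
        assert "AUC" in text and "bootstrap" in text
        fig = medium_auc_result.plot()
        assert fig is not None

    def test_default_grid_caps_at_half(self):
        grid = gs.default_sample_grid(1248)
        assert grid[0] == 1
        assert grid[-1] == 624
        assert all(b > a for a, b in zip(grid, grid[1:]))
        assert 13 in grid and 100 in grid

    def test_curve_frame_round_trip(self, medium_auc_result):
        frame = medium_auc_result.curve("AUC").to_frame()
        back = gs.SaturationCurve.from_frame(frame)
        np.testing.assert_allclose(back.mean, medium_auc_result.curve("AUC").mean)
        assert back.metric == "AUC"
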