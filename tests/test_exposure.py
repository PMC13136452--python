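"""Exposure aggregation: weights, daily values, annual means, screening."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

import holcair as h
from holcair.exposure import WeightVector, annual_average


def _cells(*specs):
    return pd.DataFrame([{"cell_id": cid, "geometry": geom}
                         for cid, geom in specs])


class TestAreaWeights:
    def test_congruent_cell(self):
        cells = _cells(("c0", box(0, 0, 1000, 1000)))
        wv = h.compute_area_weights(box(0, 0, 1000, 1000), cells)
        assert wv.weights == pytest.approx({"c0": 1.0})
        assert wv.coverage == pytest.approx(1.0)

    def test_30_70_split(self):
        cells = _cells(("left", box(0, 0, 300, 1000)),
                       ("right", box(300, 0, 1000, 1000)))
        wv = h.compute_area_weights(box(0, 0, 1000, 1000), cells)
        assert wv.weights == pytest.approx({"left": 0.3, "right": 0.7})

    def test_partial_grid_coverage(self):
        # grid covers only 90% of the tract
        cells = _cells(("c0", box(0, 0, 900, 1000)))
        wv = h.compute_area_weights(box(0, 0, 1000, 1000), cells)
        assert wv.coverage == pytest.approx(0.9)

    def test_zero_area_tract_rejected(self):
        from shapely.geometry import Polygon
        with pytest.raises(ValueError):
            h.compute_area_weights(Polygon(), _cells(("c0", box(0, 0, 1, 1))))


class TestTractDailyValue:
    def test_uniform_field_is_exact(self):
        wv = WeightVector("t", {"a": 0.4, "b": 0.6}, 1.0)
        assert h.tract_daily_value(wv, {"a": 7.3, "b": 7.3}) == pytest.approx(7.3)

    def test_dot_product(self):
        wv = WeightVector("t", {"a": 0.25, "b": 0.75}, 1.0)
        assert h.tract_daily_value(wv, {"a": 8.0, "b": 12.0}) == pytest.approx(11.0)

    def test_missing_cell_renormalizes(self):
        wv = WeightVector("t", {"a": 0.5, "b": 0.5}, 1.0)
        # only one of two cells reports; its value carries the day
        got = h.tract_daily_value(wv, {"a": 9.0}, min_coverage=0.4)
        assert got == pytest.approx(9.0)

    def test_below_coverage_threshold_missing(self):
        wv = WeightVector("t", {"a": 0.5, "b": 0.5}, 1.0)
        assert np.isnan(h.tract_daily_value(wv, {"a": 9.0}, min_coverage=0.8))

    def test_convexity(self):
        wv = WeightVector("t", {"a": 0.2, "b": 0.3, "c": 0.5}, 1.0)
        vals = {"a": 3.0, "b": 9.0, "c": 5.5}
        got = h.tract_daily_value(wv, vals)
        assert min(vals.values()) <= got <= max(vals.values())


class TestAnnualAverage:
    def test_constant_year(self):
        idx = pd.date_range("2001-01-01", "2001-12-31")
        ae = annual_average(pd.Series(10.0, index=idx), 2001)
        assert ae.mean == 10.0 and ae.n_days == 365

    def test_linear_ramp_mean(self):
        idx = pd.date_range("2001-01-01", "2001-12-31")
        ae = annual_average(pd.Series(np.arange(365.0), index=idx), 2001)
        assert ae.mean == pytest.approx(182.0)

    def test_insufficient_days_missing(self):
        idx = pd.date_range("2001-01-01", periods=100)
        ae = annual_average(pd.Series(5.0, index=idx), 2001, min_day_frac=0.75)
        assert np.isnan(ae.mean) and ae.n_days == 100

    def test_constant_survives_any_coverage_above_threshold(self):
        idx = pd.date_range("2004-01-01", "2004-12-31")  # leap year
        s = pd.Series(4.2, index=idx)
        s.iloc[:60] = np.nan
        ae = annual_average(s, 2004, min_day_frac=0.75)
        assert ae.mean == pytest.approx(4.2) and ae.n_days == 306


class TestScreening:
    def test_clean_grid_no_removals(self, small_grid):
        _, _, grid = small_grid
        _, report = h.screen_aberrant(grid, threshold=4.0, min_run_days=14)
        assert report.n_removed.sum() == 0

    def test_injection_recovery(self, truth):
        tracts = h.generate_tracts(5, 5, 1000.0, seed=11)
        graded = h.generate_holc_map(tracts, truth.grade_layout, seed=11)
        scores = h.score_city(tracts, graded)
        grid = h.generate_pollution_grid(tracts, scores, (2000, 2016), truth,
                                         seed=11)
        inj = h.inject_aberrant_values(grid, ("2002-01-01", "2003-12-31"),
                                       delta=-15.0, frac_cells=0.5, seed=12)
        cleaned, report = h.screen_aberrant(inj, threshold=5.0, min_run_days=14)
        removed = cleaned.values.attrs["removed_mask"]
        sens = (removed & inj.injected_mask).sum() / inj.injected_mask.sum()
        fp = (removed & ~inj.injected_mask).sum() / (~inj.injected_mask).sum()
        assert sens >= 0.90
        assert fp < 0.01
        assert set(report.loc[report.n_removed > 0, "year"]) <= {2001, 2002, 2003, 2004}

    def test_manual_list_removes_exact_window(self, small_grid):
        _, _, grid = small_grid
        inj = h.inject_aberrant_values(grid, ("2001-01-01", "2001-06-30"),
                                       delta=-9.0, frac_cells=1.0, seed=0)
        manual = [{"cells": "all", "start": "2001-01-01", "end": "2001-06-30"}]
        cleaned, report = h.screen_aberrant(inj, method="manual_list",
                                            manual_list=manual)
        removed = cleaned.values.attrs["removed_mask"]
        assert np.array_equal(removed, inj.injected_mask)

    def test_screening_clean_data_idempotent(self, small_grid):
        _, _, grid = small_grid
        once, r1 = h.screen_aberrant(grid, threshold=5.0, min_run_days=14)
        twice, r2 = h.screen_aberrant(once, threshold=5.0, min_run_days=14)
        assert r1.n_removed.sum() == 0 and r2.n_removed.sum() == 0

    def test_unknown_method_rejected(self, small_grid):
        _, _, grid = small_grid
        with pytest.raises(ValueError):
            h.screen_aberrant(grid, method="zscore")


class TestAggregateCity:
    def test_noise_free_identity(self):
        from holcair.synthetic_city import SyntheticTruth
        truth = SyntheticTruth(
            category_intercepts={c: 35.0 for c in ("A", "B", "C", "D", "ungraded")},
            category_slopes={c: -0.84 for c in ("A", "B", "C", "D", "ungraded")},
            seasonal_amplitude=0.0, noise_sd=0.0, tract_re_sd=0.0)
        tracts = h.generate_tracts(3, 3, 1000.0, 0)
        graded = h.generate_holc_map(tracts, {"D": 1.0}, seed=0)
        scores = h.score_city(tracts, graded)
        grid = h.generate_pollution_grid(tracts, scores, (2000, 2002), truth)
        panel = h.aggregate_city(tracts, grid)
        expected = 35.0 - 0.84 * (panel.year - 2000)
        assert np.allclose(panel["mean"], expected)
        assert len(panel) == 9 * 3  # tracts x years, nothing missing

    def test_linearity(self, small_grid):
        tracts, _, grid = small_grid
        panel = h.aggregate_city(tracts, grid)
        scaled = h.PollutionGrid(grid.pollutant, grid.cells,
                                 grid.values.assign(value=2 * grid.values.value + 1))
        panel2 = h.aggregate_city(tracts, scaled)
        assert np.allclose(panel2["mean"], 2 * panel["mean"] + 1)

    def test_offset_grid_monte_carlo_oracle(self, truth):
        """Area weights vs uniform point sampling on a misaligned grid."""
        tracts = h.generate_tracts(4, 4, 1000.0, seed=7)
        graded = h.generate_holc_map(tracts, truth.grade_layout, seed=7)
        scores = h.score_city(tracts, graded)
        grid = h.generate_pollution_grid(tracts, scores, (2000, 2000), truth,
                                         cell_m=1000.0, origin=(-500.0, -500.0),
                                         seed=7)
        panel = h.aggregate_city(tracts, grid)
        vals = grid.values.copy()
        vals["year"] = pd.to_datetime(vals.date).dt.year
        cell_means = vals.groupby("cell_id").value.mean()
        cell_lookup = {cid: geom for cid, geom in
                       zip(grid.cells.cell_id, grid.cells.geometry)}
        rng = np.random.default_rng(0)
        npts = 20000
        for t in tracts.sample(4, random_state=1).itertuples(index=False):
            x0, y0, x1, y1 = t.geometry.bounds
            px = rng.uniform(x0, x1, npts)
            py = rng.uniform(y0, y1, npts)
            ix = np.floor((px + 500) / 1000).astype(int)
            iy = np.floor((py + 500) / 1000).astype(int)
            ids = [f"g{a:03d}{b:03d}" for a, b in zip(ix, iy)]
            pts = cell_means.reindex(ids).to_numpy()
            mc_mean, mc_se = pts.mean(), pts.std(ddof=1) / np.sqrt(npts)
            got = panel.loc[panel.tract_id == t.tract_id, "mean"].iloc[0]
            assert abs(got - mc_mean) <= max(3 * mc_se, 1e-9)

    def test_low_coverage_tract_missing(self, truth):
        tracts = h.generate_tracts(2, 1, 1000.0, 0)
        graded = h.generate_holc_map(tracts, {"D": 1.0}, seed=0)
        scores = h.score_city(tracts, graded)
        # grid covers only the left tract
        grid = h.generate_pollution_grid(tracts, scores, (2000, 2000), truth,
                                         extent=(0, 0, 1000, 1000), seed=0)
        panel = h.aggregate_city(tracts, grid)
        left = panel[panel.tract_id == "T000000"]["mean"].iloc[0]
        right = panel[panel.tract_id == "T001000"]["mean"].iloc[0]
        assert np.isfinite(left) and np.isnan(right)
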