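"""Mixed-model trend estimation: recovery, oracles, tests, contrasts."""

import numpy as np
import pandas as pd
import pytest

import holcair as h
from holcair.synthetic_city import SyntheticTruth
from holcair.trends import FitError

CATS = ("A", "B", "C", "D", "ungraded")


@pytest.fixture(scope="module")
def noise_free():
    truth = SyntheticTruth()
    panel, scores = h.generate_annual_panel(truth, 5, (2000, 2016), seed=0,
                                            resid_sd=0.0, re_sd=0.0)
    return truth, panel, scores


@pytest.fixture(scope="module")
def noisy_fit():
    truth = SyntheticTruth()
    panel, scores = h.generate_annual_panel(truth, 30, (2000, 2016), seed=1,
                                            resid_sd=0.3, re_sd=0.5)
    return truth, h.fit_trend(panel, scores)


class TestFitTrend:
    def test_noise_free_recovery(self, noise_free):
        truth, panel, scores = noise_free
        fit = h.fit_trend(panel, scores)
        for c in CATS:
            lvl, _ = h.predicted_level(fit, c, 2000)
            slp, _ = h.category_slope(fit, c)
            assert lvl == pytest.approx(truth.category_intercepts[c], abs=1e-6)
            assert slp == pytest.approx(truth.category_slopes[c], abs=1e-6)
        assert fit.sigma2_u == 0.0 and fit.sigma2_e == 0.0

    def test_balanced_design_equals_ols(self):
        """On a balanced panel the GLS fixed effects collapse to OLS."""
        truth = SyntheticTruth()
        panel, scores = h.generate_annual_panel(truth, 10, (2000, 2016), seed=2,
                                                resid_sd=0.4, re_sd=0.6)
        fit = h.fit_trend(panel, scores)
        df = panel.merge(scores, on="tract_id")
        df["yr"] = df.year - 2000
        X = np.column_stack(
            [np.ones(len(df))]
            + [(df.category == c).to_numpy(float) for c in fit.categories]
            + [df.yr.to_numpy(float)]
            + [((df.category == c) * df.yr).to_numpy(float) for c in fit.categories])
        beta_ols = np.linalg.lstsq(X, df["mean"].to_numpy(), rcond=None)[0]
        assert np.allclose(fit.params.to_numpy(), beta_ols, atol=1e-6)
        # with sigma2_u > 0, level-term SEs exceed the naive OLS SEs (slope
        # terms are within-tract contrasts and get *more* precise)
        resid = df["mean"].to_numpy() - X @ beta_ols
        s2 = resid @ resid / (len(df) - X.shape[1])
        se_ols = np.sqrt(np.diag(s2 * np.linalg.inv(X.T @ X)))
        se_fit = np.sqrt(np.diag(fit.cov.to_numpy()))
        n_level = 1 + len(fit.categories)
        assert (se_fit[:n_level] >= se_ols[:n_level] - 1e-8).all()
        assert (se_fit[n_level:] <= se_ols[n_level:] + 1e-8).all()

    def test_zero_random_effect_variance_detected(self):
        truth = SyntheticTruth()
        panel, scores = h.generate_annual_panel(truth, 30, (2000, 2016), seed=3,
                                                resid_sd=0.5, re_sd=0.0)
        fit = h.fit_trend(panel, scores)
        assert fit.sigma2_u <= 1e-4 * fit.sigma2_e

    def test_reparameterization_invariance(self, noisy_fit):
        truth, fit = noisy_fit
        panel, scores = h.generate_annual_panel(truth, 30, (2000, 2016), seed=1,
                                                resid_sd=0.3, re_sd=0.5)
        fit2 = h.fit_trend(panel, scores, year_origin=2008)
        for c in CATS:
            for y in (2000, 2008, 2016):
                a, _ = h.predicted_level(fit, c, y)
                b, _ = h.predicted_level(fit2, c, y)
                assert a == pytest.approx(b, abs=1e-8)
            assert h.category_slope(fit, c)[0] == pytest.approx(
                h.category_slope(fit2, c)[0], abs=1e-8)

    def test_missing_category_and_degenerate_inputs(self, noise_free):
        _, panel, scores = noise_free
        with pytest.raises(ValueError):
            h.fit_trend(panel, scores, reference="Z")
        one_year = panel[panel.year == 2000]
        with pytest.raises(ValueError):
            h.fit_trend(one_year, scores)
        with pytest.raises(ValueError):
            h.fit_trend(panel.assign(tract_id="X" + panel.tract_id), scores)


class TestPredictions:
    def test_reference_at_origin_is_intercept(self, noisy_fit):
        _, fit = noisy_fit
        est, se = h.predicted_level(fit, "A", fit.year_origin)
        assert est == pytest.approx(fit.params["Intercept"])
        assert se == pytest.approx(np.sqrt(fit.cov.loc["Intercept", "Intercept"]))

    def test_arithmetic_identity(self, noisy_fit):
        _, fit = noisy_fit
        p = fit.params
        got, _ = h.predicted_level(fit, "D", fit.year_origin + 16)
        want = (p["Intercept"] + p["level[D]"]
                + (p["year"] + p["slope[D]"]) * 16)
        assert got == pytest.approx(want)

    def test_slope_is_level_difference(self, noisy_fit):
        _, fit = noisy_fit
        for c in CATS:
            d = (h.predicted_level(fit, c, fit.year_origin + 1)[0]
                 - h.predicted_level(fit, c, fit.year_origin)[0])
            assert h.category_slope(fit, c)[0] == pytest.approx(d, abs=1e-10)

    def test_unknown_category_rejected(self, noisy_fit):
        _, fit = noisy_fit
        with pytest.raises(ValueError):
            h.predicted_level(fit, "E", 2000)
        with pytest.raises(ValueError):
            h.category_slope(fit, "E")


class TestOverallTests:
    def test_separated_categories_reject_hard(self, noisy_fit):
        _, fit = noisy_fit
        assert h.overall_level_test(fit, 2000) < 1e-6
        assert h.overall_slope_test(fit) < 1e-6

    def test_level_test_at_origin_uses_level_offsets_only(self):
        """At the origin year the slope offsets multiply zero: a panel with
        equal intercepts but different slopes must not reject at t0."""
        truth = SyntheticTruth(
            category_intercepts={c: 30.0 for c in CATS},
            category_slopes={"A": -1.0, "B": -0.9, "C": -0.8, "D": -0.7,
                             "ungraded": -0.6})
        panel, scores = h.generate_annual_panel(truth, 30, (2000, 2016), seed=5,
                                                resid_sd=0.3, re_sd=0.5)
        fit = h.fit_trend(panel, scores)
        assert h.overall_level_test(fit, 2000) > 1e-4
        assert h.overall_slope_test(fit) < 1e-10


class TestPairwiseContrasts:
    def test_bonferroni_divisor_matches_categories_present(self):
        truth = SyntheticTruth()
        # Nashville-like: A-D only -> m=3; with ungraded -> m=4
        for cats, m in ((("A", "B", "C", "D"), 3), (CATS, 4)):
            panel, scores = h.generate_annual_panel(truth, 10, (2000, 2016),
                                                    seed=6, categories=cats,
                                                    resid_sd=0.3, re_sd=0.5)
            fit = h.fit_trend(panel, scores)
            contrasts = h.pairwise_contrasts(fit, "slope")
            assert len(contrasts) == m
            assert len(fit.categories) == m

    def test_gating_blocks_contrasts_under_null(self):
        truth = SyntheticTruth(
            category_intercepts={c: 30.0 for c in CATS},
            category_slopes={c: -1.0 for c in CATS})
        panel, scores = h.generate_annual_panel(truth, 10, (2000, 2016), seed=77,
                                                resid_sd=0.3, re_sd=0.5)
        fit = h.fit_trend(panel, scores)
        if h.overall_slope_test(fit) >= 0.05:  # typical draw under the null
            contrasts = h.pairwise_contrasts(fit, "slope", gate=True)
            assert all(not c.evaluated and not c.significant for c in contrasts)
        ungated = h.pairwise_contrasts(fit, "slope", gate=False)
        assert all(c.evaluated for c in ungated)

    def test_contrast_estimates_match_level_differences(self, noisy_fit):
        _, fit = noisy_fit
        contrasts = h.pairwise_contrasts(fit, "level", year=2008, gate=False)
        for c in contrasts:
            cat = c.label.split(" vs ")[0]
            want = (h.predicted_level(fit, cat, 2008)[0]
                    - h.predicted_level(fit, "A", 2008)[0])
            assert c.estimate == pytest.approx(want)


class TestTrendTable:
    def test_internal_consistency_and_order(self, noise_free):
        truth, panel, scores = noise_free
        result = h.build_trend_table(panel, scores, [2000, 2008, 2016])
        table = result["table"]
        assert list(table.category) == ["D", "C", "B", "ungraded", "A (ref)"]
        fit = result["fit"]
        for row in table.itertuples(index=False):
            cat = row.category.replace(" (ref)", "")
            for y in (2000, 2008, 2016):
                direct = h.predicted_level(fit, cat, y)[0]
                assert getattr(row, f"level_{y}") == pytest.approx(direct)
                want = (truth.category_intercepts[cat]
                        + truth.category_slopes[cat] * (y - 2000))
                assert getattr(row, f"level_{y}") == pytest.approx(want, abs=1e-6)
            assert row.slope == pytest.approx(truth.category_slopes[cat], abs=1e-6)
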