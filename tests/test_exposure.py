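"""Prediction surfaces, EA overlay, WHO-threshold exposure shares, and
SES-inequality statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from shapely.geometry import box

import lurmap.exposure as xp
import lurmap.features as ft
import lurmap.synthetic_city as sc
from lurmap.geo import Grid
from lurmap.lur import FittedLUR


def _make_fit(terms, params, standardization=None, response="log_pm25"):
    names = ["intercept"] + terms
    s = pd.Series([params.get(n, 0.0) for n in names], index=names)
    zero = pd.Series(0.0, index=names)
    return FittedLUR(
        response=response, season=None, term_names=terms, params=s,
        bse=zero, pvalues=zero, conf_int=pd.DataFrame({"lo": s, "hi": s}),
        cov_params=pd.DataFrame(0.0, index=names, columns=names),
        sigma2_site=0.0, sigma2_week=0.0, sigma2_eps=0.0,
        n_obs=10, n_sites=5, n_weeks=2, converged=True, reml_criterion=0.0,
        standardization=standardization or {},
    )


@pytest.fixture(scope="module")
def met52():
    return sc.generate_meteorology(seed=3)


class TestPredictSurface:
    def test_intercept_only_gives_exp_alpha(self, met52):
        fit = _make_fit([], {"intercept": 3.0})
        template = xp.grid_template((0, 0, 1000, 1000), 100.0)
        cells = xp.grid_cell_table(template)
        surf = xp.predict_surface(fit, template, cells, met52,
                                  ft.default_registry(), weeks=[1, 2])
        assert np.allclose(surf.weekly, math.exp(3.0))

    def test_temporal_only_model_is_spatially_constant(self, met52):
        std = {"relative_humidity": (70.0, 10.0), "temperature": (28.0, 1.5)}
        fit = _make_fit(["relative_humidity", "temperature", "month_1"],
                        {"intercept": 3.9, "relative_humidity": -0.49,
                         "temperature": 0.18, "month_1": 0.56}, std)
        template = xp.grid_template((0, 0, 2000, 2000), 100.0)
        cells = xp.grid_cell_table(template)
        surf = xp.predict_surface(fit, template, cells, met52,
                                  ft.default_registry(), weeks=[1, 2, 3])
        for w in range(3):
            assert np.ptp(surf.weekly[w]) == 0.0  # one value city-wide

    def test_cell_prediction_matches_manual_dot_product(self, met52):
        std = {"ndvi_100": (0.3, 0.1)}
        fit = _make_fit(["ndvi_100"], {"intercept": 3.0, "ndvi_100": -0.12}, std)
        template = xp.grid_template((0, 0, 300, 300), 100.0)
        cells = xp.grid_cell_table(template)
        cells["ndvi_100"] = np.linspace(0.1, 0.6, len(cells))
        surf = xp.predict_surface(fit, template, cells, met52,
                                  ft.default_registry(), weeks=[1])
        i = 4
        manual = math.exp(3.0 - 0.12 * (cells.ndvi_100.iloc[i] - 0.3) / 0.1)
        assert surf.weekly[0].ravel()[i] == pytest.approx(manual, rel=1e-12)

    def test_missing_standardization_raises(self, met52):
        fit = _make_fit(["ndvi_100"], {"intercept": 3.0, "ndvi_100": -0.12}, {})
        template = xp.grid_template((0, 0, 300, 300), 100.0)
        cells = xp.grid_cell_table(template)
        cells["ndvi_100"] = 0.5
        with pytest.raises(xp.ContractError):
            xp.predict_surface(fit, template, cells, met52,
                               ft.default_registry(), weeks=[1])


class TestSeasonalAnnual:
    def _surface(self, values_by_season):
        template = xp.grid_template((0, 0, 200, 200), 100.0)
        weeks = list(range(1, 53))
        cal = sc.DEFAULT_CALENDAR
        weekly = np.stack([
            np.full((template.ny, template.nx),
                    values_by_season[cal.season_of_week(w)])
            for w in weeks
        ])
        return xp.ExposureSurface(template=template, weeks=weeks, weekly=weekly)

    def test_week_count_weighted_annual(self):
        # 35 non-harmattan weeks at 15 and 17 harmattan weeks at 79
        surf = self._surface({"non_harmattan": 15.0, "harmattan": 79.0})
        surf = xp.seasonal_annual_means(surf)
        expect = (35 * 15.0 + 17 * 79.0) / 52
        assert np.allclose(surf.annual, expect)
        assert expect == pytest.approx(35.92, abs=0.01)

    def test_constant_field(self):
        surf = xp.seasonal_annual_means(self._surface(
            {"non_harmattan": 9.0, "harmattan": 9.0}))
        assert np.allclose(surf.seasonal["harmattan"], 9.0)
        assert np.allclose(surf.annual, 9.0)

    def test_annual_between_seasonal_means(self):
        surf = xp.seasonal_annual_means(self._surface(
            {"non_harmattan": 10.0, "harmattan": 50.0}))
        assert (surf.annual >= surf.seasonal["non_harmattan"]).all()
        assert (surf.annual <= surf.seasonal["harmattan"]).all()


class TestEAMean:
    def test_mean_over_covered_cells(self):
        grid = Grid(np.array([[1.0, 2.0], [3.0, 4.0]]), 0.0, 0.0, 100.0)
        eas = pd.DataFrame({"ea_id": ["e1"], "geometry": [box(0, 0, 200, 200)]})
        out = xp.ea_mean(grid, eas)
        assert out.mean_value.iloc[0] == pytest.approx(2.5)

    def test_single_cell_fallback(self):
        grid = Grid(np.array([[7.0, 1.0], [1.0, 1.0]]), 0.0, 0.0, 100.0)
        tiny = box(10, 110, 40, 140)  # inside the top-left cell, no centre
        eas = pd.DataFrame({"ea_id": ["e1"], "geometry": [tiny]})
        out = xp.ea_mean(grid, eas)
        assert out.mean_value.iloc[0] == pytest.approx(7.0)

    def test_cell_center_close_to_area_weighted_on_large_eas(self):
        rng = np.random.default_rng(0)
        smooth = rng.normal(0, 1, (30, 30)).cumsum(axis=0).cumsum(axis=1)
        smooth = 20 + 5 * (smooth - smooth.mean()) / smooth.std()
        grid = Grid(smooth, 0.0, 0.0, 100.0)
        eas = pd.DataFrame({
            "ea_id": ["a", "b"],
            "geometry": [box(130, 170, 1480, 1520), box(800, 900, 2500, 2300)],
        })
        cc = xp.ea_mean(grid, eas, method="cell_center")
        aw = xp.ea_mean(grid, eas, method="area_weighted")
        assert np.allclose(cc.mean_value, aw.mean_value, rtol=0.05)

    def test_ea_outside_extent_flagged(self):
        grid = Grid(np.ones((2, 2)), 0.0, 0.0, 100.0)
        eas = pd.DataFrame({"ea_id": ["far"], "geometry": [box(5000, 5000, 5100, 5100)]})
        assert np.isnan(xp.ea_mean(grid, eas).mean_value.iloc[0])


class TestExposureCDF:
    def _eas(self):
        return pd.DataFrame({"ea_id": ["a", "b", "c"],
                             "population": [100.0, 300.0, 600.0],
                             "mean_value": [12.0, 18.0, 30.0]})

    def test_brute_force_shares(self):
        out = xp.population_exposure_cdf(self._eas())
        assert out["shares"]["it3"] == pytest.approx(0.90)
        assert out["shares"]["it2"] == pytest.approx(0.60)
        assert out["shares"]["guideline"] == pytest.approx(1.0)
        assert out["shares"]["it1"] == pytest.approx(0.0)

    def test_monotone_curve_and_limits(self):
        out = xp.population_exposure_cdf(self._eas())
        shares = out["curve"].share_above.to_numpy()
        assert (np.diff(shares) <= 1e-12).all()
        assert shares[0] == pytest.approx(1.0)
        assert shares[-1] == pytest.approx(0.0)

    def test_zero_population_raises(self):
        eas = self._eas().assign(population=0.0)
        with pytest.raises(ValueError):
            xp.population_exposure_cdf(eas)

    def test_thresholds_must_increase(self):
        with pytest.raises(ValueError):
            xp.ExposureThresholds(guideline=5, it3=4, it2=25, it1=35)


class TestSESQuintiles:
    def test_equal_groups_of_two(self):
        eas = pd.DataFrame({"ea_id": [f"e{i}" for i in range(10)],
                            "ses": np.arange(10.0)})
        q = xp.ses_quintiles(eas)
        assert np.bincount(q, minlength=6)[1:].tolist() == [2] * 5

    def test_monotone_in_ses_and_matches_sort_slice(self):
        rng = np.random.default_rng(1)
        eas = pd.DataFrame({"ea_id": [f"e{i}" for i in range(23)],
                            "ses": rng.normal(size=23)})
        q = xp.ses_quintiles(eas)
        ordered = eas.sort_values(["ses", "ea_id"], kind="mergesort")
        expected = np.concatenate([
            np.full(len(chunk), i + 1)
            for i, chunk in enumerate(np.array_split(ordered.index.to_numpy(), 5))
        ])
        assert (q.loc[ordered.index].to_numpy() == expected).all()
        assert (q.loc[ordered.index].diff().dropna() >= 0).all()

    def test_too_few_eas_raises(self):
        eas = pd.DataFrame({"ea_id": ["a"], "ses": [1.0]})
        with pytest.raises(ValueError):
            xp.ses_quintiles(eas)


class TestInequalityStats:
    def test_textbook_anova_matches_hand_computation(self):
        groups = {1: [6.0, 8.0, 4.0, 5.0, 3.0],
                  2: [8.0, 12.0, 9.0, 11.0, 6.0],
                  3: [13.0, 9.0, 11.0, 8.0, 7.0]}
        eas = pd.DataFrame([
            {"ea_id": f"e{g}{i}", "quintile": g, "mean_value": v}
            for g, vals in groups.items() for i, v in enumerate(vals)
        ])
        out = xp.inequality_tests(eas)
        allv = np.concatenate(list(groups.values()))
        grand = allv.mean()
        ssb = sum(len(v) * (np.mean(v) - grand) ** 2 for v in groups.values())
        ssw = sum(((np.array(v) - np.mean(v)) ** 2).sum() for v in groups.values())
        f_hand = (ssb / 2) / (ssw / 12)
        assert out["anova_f"] == pytest.approx(f_hand, rel=1e-10)
        assert len(out["tukey"]) == 3

    def test_identical_group_means_give_zero_f(self):
        eas = pd.DataFrame({
            "ea_id": list("abcdef"), "quintile": [1, 1, 1, 2, 2, 2],
            "mean_value": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]})
        out = xp.inequality_tests(eas)
        assert out["anova_f"] == pytest.approx(0.0, abs=1e-12)

    def test_null_groups_rarely_reject(self):
        rng = np.random.default_rng(0)
        eas = pd.DataFrame({
            "ea_id": [f"e{i}" for i in range(100)],
            "quintile": np.repeat([1, 2, 3, 4, 5], 20),
            "mean_value": rng.normal(20, 3, 100)})
        out = xp.inequality_tests(eas)
        assert out["anova_p"] > 0.05

    def test_degenerate_variance_raises(self):
        eas = pd.DataFrame({"ea_id": list("abcd"), "quintile": [1, 1, 2, 2],
                            "mean_value": [3.0, 3.0, 3.0, 3.0]})
        with pytest.raises(ValueError):
            xp.inequality_tests(eas)


class TestEducationBivariate:
    def test_perfect_negative_relation(self):
        eas = pd.DataFrame({"post_secondary_share": np.linspace(0, 1, 20),
                            "mean_value": np.linspace(30, 10, 20)})
        out = xp.education_bivariate(eas)
        assert out["r"] == pytest.approx(-1.0)

    def test_slope_equals_cov_over_var(self):
        rng = np.random.default_rng(2)
        edu = rng.uniform(0, 1, 50)
        conc = 25 - 8 * edu + rng.normal(0, 1, 50)
        eas = pd.DataFrame({"post_secondary_share": edu, "mean_value": conc})
        out = xp.education_bivariate(eas)
        expect = np.cov(edu, conc, ddof=1)[0, 1] / np.var(edu, ddof=1)
        assert out["slope"] == pytest.approx(expect)

    def test_shuffled_pairs_uncorrelated(self):
        rng = np.random.default_rng(5)
        edu = np.linspace(0, 1, 400)
        conc = 25 - 8 * rng.permutation(edu) + rng.normal(0, 0.5, 400)
        eas = pd.DataFrame({"post_secondary_share": edu, "mean_value": conc})
        assert abs(xp.education_bivariate(eas)["r"]) < 0.12

    def test_zero_variance_raises(self):
        eas = pd.DataFrame({"post_secondary_share": np.ones(10),
                            "mean_value": np.arange(10.0)})
        with pytest.raises(ValueError):
            xp.education_bivariate(eas)


class TestBCConversionOrdering:
    def test_monotone_transform_preserves_surface_ordering(self):
        from lurmap.measurements import absorbance_to_ec
        vals = np.array([[1.0, 4.0], [2.5, 0.5]])
        ec = absorbance_to_ec(vals)
        assert np.array_equal(np.argsort(vals.ravel()), np.argsort(ec.ravel()))
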