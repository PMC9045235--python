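"""Hierarchical prevalence model: fitting, prediction, lagged windows."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import attribwork as aw
from attribwork.exposure import ExposureSurface, expit, windowed_prevalence


def _constant_surveys(p=0.5, countries=("AAA", "BBB", "CCC", "DDD"), years=range(2000, 2011)):
    rows = [
        {"iso3": c, "year": y, "prevalence": p, "sample_size": 1000}
        for c in countries
        for y in years
    ]
    return pd.DataFrame(rows)


HIER = {"AAA": "EUR", "BBB": "EUR", "CCC": "AFR", "DDD": "AFR"}


class TestFit:
    def test_constant_observations_give_flat_surface(self):
        fit = aw.fit_prevalence_model(_constant_surveys(0.5), HIER)
        surface = aw.predict_prevalence(fit)
        assert np.all(np.abs(surface.data["prevalence"] - 0.5) < 1e-6)

    def test_noise_free_hierarchical_data_is_recovered_exactly(self):
        # Surveys at every country-year carrying the exact model prevalence:
        # the fit must interpolate the truth to numerical tolerance.
        effects = {"AAA": 0.4, "BBB": -0.2, "CCC": 0.1, "DDD": -0.5}
        rows = []
        for c, u in effects.items():
            for y in range(2000, 2021):
                rows.append(
                    {
                        "iso3": c,
                        "year": y,
                        "prevalence": float(expit(-2.0 + u + 0.02 * (y - 2010))),
                        "sample_size": 5000,
                    }
                )
        fit = aw.fit_prevalence_model(pd.DataFrame(rows), HIER)
        surface = aw.predict_prevalence(fit)
        truth = pd.DataFrame(rows)
        merged = surface.data.merge(truth, on=["iso3", "year"], suffixes=("_hat", ""))
        assert np.max(np.abs(merged["prevalence_hat"] - merged["prevalence"])) < 1e-6

    def test_recovers_true_surface_within_tolerance(self, recovery_scenario, recovery_fit):
        _, _, truth = recovery_scenario
        _, surface = recovery_fit
        tru = truth.surface.data[["iso3", "year", "prevalence"]].rename(columns={"prevalence": "p_true"})
        merged = surface.data.merge(tru, on=["iso3", "year"])
        mae = np.abs(merged["prevalence"] - merged["p_true"]).mean()
        assert mae < 0.02

    def test_prediction_intervals_cover_truth(self, recovery_scenario, recovery_fit):
        _, _, truth = recovery_scenario
        _, surface = recovery_fit
        tru = truth.surface.data[["iso3", "year", "prevalence"]].rename(columns={"prevalence": "p_true"})
        m = surface.data.merge(tru, on=["iso3", "year"])
        z = (np.log(m.prevalence / (1 - m.prevalence)) - np.log(m.p_true / (1 - m.p_true))) / m.se_logit
        coverage = (z.abs() <= 1.959964).mean()
        assert 0.90 <= coverage <= 0.99

    def test_single_country_degrades_to_trend_fit(self):
        df = _constant_surveys(countries=("AAA",))
        df.loc[:, "prevalence"] = np.linspace(0.1, 0.2, len(df))
        fit = aw.fit_prevalence_model(df, {"AAA": "EUR"})
        assert fit.lmm.tau2_region == 0.0
        assert fit.lmm.tau2_country == 0.0
        assert fit.trend > 0

    def test_empty_observations_error(self):
        with pytest.raises(ValueError, match="no survey observations"):
            aw.fit_prevalence_model(pd.DataFrame(columns=["iso3", "year", "prevalence", "sample_size"]), HIER)

    def test_unknown_country_error_names_the_code(self):
        df = _constant_surveys(countries=("AAA", "ZZZ"))
        with pytest.raises(KeyError, match="ZZZ"):
            aw.fit_prevalence_model(df, HIER)

    def test_weighting_favours_large_surveys(self):
        # Same country-year measured twice: huge survey at 0.10, tiny at 0.40.
        rows = []
        for c in ("AAA", "BBB", "CCC", "DDD"):
            for y in range(2000, 2006):
                rows.append({"iso3": c, "year": y, "prevalence": 0.10, "sample_size": 100000})
                rows.append({"iso3": c, "year": y, "prevalence": 0.40, "sample_size": 100})
        fit = aw.fit_prevalence_model(pd.DataFrame(rows), HIER)
        surface = aw.predict_prevalence(fit)
        assert (surface.data["prevalence"] < 0.15).all()

    def test_matches_statsmodels_mixedlm(self):
        # Independent route: same logit-linear random-intercept model fitted
        # with statsmodels must give nearly identical cell predictions.
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(3)
        rows = []
        for c, u in zip("ABCDEFGH", rng.normal(0, 0.4, 8)):
            iso = c * 3
            for y in range(2000, 2016):
                p = float(expit(-2.0 + u + 0.015 * (y - 2008) + rng.normal(0, 0.08)))
                rows.append({"iso3": iso, "year": y, "prevalence": p, "sample_size": 2000})
        df = pd.DataFrame(rows)
        hier = {c * 3: "R1" for c in "ABCDEFGH"}  # single region: country level only
        fit = aw.fit_prevalence_model(df, hier)
        surface = aw.predict_prevalence(fit)

        df["y"] = np.log(df.prevalence / (1 - df.prevalence))
        df["t"] = df.year - fit.ref_year
        sm_fit = smf.mixedlm("y ~ t", df, groups=df["iso3"]).fit(reml=True)
        re = sm_fit.random_effects
        df["pred_sm"] = [
            float(expit(sm_fit.params["Intercept"] + sm_fit.params["t"] * t + re[c]["Group"]))
            for c, t in zip(df.iso3, df.t)
        ]
        merged = df.merge(surface.data, on=["iso3", "year"])
        assert np.max(np.abs(merged["pred_sm"] - merged["prevalence_y"])) < 1e-3


class TestPredict:
    def test_in_sample_prediction_is_model_fitted_value(self):
        fit = aw.fit_prevalence_model(_constant_surveys(0.3), HIER)
        mu, se = fit.cell_logit("AAA", 2005)
        surface = aw.predict_prevalence(fit, countries=["AAA"], years=[2005])
        assert surface.data["prevalence"].iloc[0] == pytest.approx(float(expit(mu)))
        assert se >= 0

    def test_monotone_trend_gives_monotone_surface(self):
        rows = []
        for c in ("AAA", "BBB", "CCC", "DDD"):
            for y in range(2000, 2011):
                rows.append(
                    {"iso3": c, "year": y, "prevalence": float(expit(-2 + 0.05 * (y - 2005))), "sample_size": 1000}
                )
        fit = aw.fit_prevalence_model(pd.DataFrame(rows), HIER)
        surface = aw.predict_prevalence(fit, years=range(1995, 2016))
        for _, sub in surface.data.groupby("iso3"):
            assert sub.sort_values("year")["prevalence"].is_monotonic_increasing

    def test_extrapolated_years_are_flagged(self):
        fit = aw.fit_prevalence_model(_constant_surveys(), HIER)
        surface = aw.predict_prevalence(fit, years=range(1995, 2016))
        flags = surface.data.set_index("year")["extrapolated"]
        assert flags.loc[1999].all() and flags.loc[2011].all()
        assert not flags.loc[2005].any()

    def test_unseen_country_out_of_hierarchy_errors(self):
        fit = aw.fit_prevalence_model(_constant_surveys(), HIER)
        with pytest.raises(KeyError, match="QQQ"):
            aw.predict_prevalence(fit, countries=["QQQ"], years=[2005])

    def test_unseen_country_in_hierarchy_gets_region_prediction(self):
        fit = aw.fit_prevalence_model(_constant_surveys(0.3), HIER)
        fit.hierarchy["EEE"] = "EUR"
        surface = aw.predict_prevalence(fit, countries=["EEE"], years=[2005])
        assert surface.data["prevalence"].iloc[0] == pytest.approx(0.3, abs=1e-6)


class TestWindow:
    def test_published_window_convention(self):
        w = aw.window_years(2016, aw.LagWindow(lag=10, width=10))
        assert (w[0], w[-1]) == (2001, 2010)

    def test_no_lag_single_year(self):
        w = aw.window_years(2016, aw.LagWindow(lag=0, width=1))
        assert list(w) == [2016]

    def test_shifted_window(self):
        w = aw.window_years(2000, aw.LagWindow(lag=10, width=10))
        assert (w[0], w[-1]) == (1985, 1994)

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            aw.LagWindow(lag=10, width=0)
        with pytest.raises(ValueError):
            aw.LagWindow(lag=-1, width=10)

    def test_constant_surface_windowed_mean(self):
        data = pd.DataFrame(
            [{"iso3": "AAA", "year": y, "prevalence": 0.2, "se_logit": 0.0} for y in range(1990, 2011)]
        )
        wp = windowed_prevalence(ExposureSurface(data), 2016, aw.LagWindow(10, 10))
        assert wp["prevalence"].iloc[0] == pytest.approx(0.2)

    def test_windowed_mean_by_hand(self):
        vals = np.arange(0.10, 0.29, 0.02)  # 0.10, 0.12, ..., 0.28 over 2001-2010
        data = pd.DataFrame(
            [{"iso3": "AAA", "year": 2001 + i, "prevalence": v, "se_logit": 0.0} for i, v in enumerate(vals)]
        )
        wp = windowed_prevalence(ExposureSurface(data), 2016, aw.LagWindow(10, 10))
        assert wp["prevalence"].iloc[0] == pytest.approx(0.19)

    def test_width_one_is_the_lagged_year(self):
        data = pd.DataFrame(
            [{"iso3": "AAA", "year": y, "prevalence": 0.1 + 0.01 * (y - 2000), "se_logit": 0.0}
             for y in range(2000, 2011)]
        )
        wp = windowed_prevalence(ExposureSurface(data), 2016, aw.LagWindow(10, 1))
        assert wp["prevalence"].iloc[0] == pytest.approx(0.16)  # year 2006

    def test_empty_overlap_errors(self):
        data = pd.DataFrame([{"iso3": "AAA", "year": 2015, "prevalence": 0.2, "se_logit": 0.0}])
        with pytest.raises(ValueError, match="no overlap"):
            windowed_prevalence(ExposureSurface(data), 2016, aw.LagWindow(10, 10))

    @given(
        st.lists(st.floats(min_value=0.01, max_value=0.99), min_size=10, max_size=10),
        st.integers(min_value=0, max_value=15),
        st.integers(min_value=1, max_value=10),
    )
    def test_windowed_prevalence_bounded_by_annual_extremes(self, vals, lag, width):
        data = pd.DataFrame(
            [{"iso3": "AAA", "year": 2001 + i, "prevalence": v, "se_logit": 0.0} for i, v in enumerate(vals)]
        )
        surface = ExposureSurface(data)
        years = aw.window_years(2020, aw.LagWindow(lag, width))
        overlap = [y for y in years if 2001 <= y <= 2010]
        if not overlap:
            return
        wp = windowed_prevalence(surface, 2020, aw.LagWindow(lag, width))
        sub = [vals[y - 2001] for y in overlap]
        assert min(sub) - 1e-12 <= wp["prevalence"].iloc[0] <= max(sub) + 1e-12

    def test_window_choice_does_not_alter_the_surface(self):
        fit = aw.fit_prevalence_model(_constant_surveys(0.3), HIER)
        surface = aw.predict_prevalence(fit)
        before = surface.data.copy()
        windowed_prevalence(surface, 2016, aw.LagWindow(10, 10))
        windowed_prevalence(surface, 2016, aw.LagWindow(5, 3))
        pd.testing.assert_frame_equal(surface.data, before)
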