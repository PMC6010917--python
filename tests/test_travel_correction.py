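"""Daily travel distance, diel profile, and correction-factor fitting."""

import numpy as np
import pandas as pd
import pytest

from grazetrack.geo import utm13n_inverse
from grazetrack.travel_correction import (CorrectionModel, coverage_filter,
                                          daily_distance, fit_correction,
                                          hourly_profile, percent_of_constant,
                                          validate_correction)


def _fixes_from_utm(easting, northing, times):
    lat, lon = utm13n_inverse(np.asarray(easting, float),
                              np.asarray(northing, float))
    return pd.DataFrame({
        "time_local": pd.to_datetime(times),
        "lat_dd": np.atleast_1d(lat),
        "lon_dd": np.atleast_1d(lon),
    })


class TestDailyDistance:
    def test_single_fix_day_reports_zero_flagged(self):
        fx = _fixes_from_utm([500_000], [5_100_000], ["2017-07-07 10:00"])
        dd = daily_distance(fx)
        assert dd["distance_m"].iloc[0] == 0.0
        assert dd["few_fixes"].iloc[0]

    def test_square_loop_400m(self):
        e = 500_000 + np.array([0.0, 100.0, 100.0, 0.0, 0.0])
        n = 5_100_000 + np.array([0.0, 0.0, 100.0, 100.0, 0.0])
        t = pd.date_range("2017-07-07 10:00", periods=5, freq="1min")
        dd = daily_distance(_fixes_from_utm(e, n, t))
        assert dd["distance_m"].iloc[0] == pytest.approx(400.0, rel=1e-3)

    def test_corner_cutting_under_subsampling(self):
        e = 500_000 + np.array([0.0, 100.0, 100.0])
        n = 5_100_000 + np.array([0.0, 0.0, 100.0])
        t = pd.date_range("2017-07-07 10:00", periods=3, freq="1min")
        full = daily_distance(_fixes_from_utm(e, n, t))
        cut = daily_distance(_fixes_from_utm(e[[0, 2]], n[[0, 2]], t[[0, 2]]))
        assert full["distance_m"].iloc[0] == pytest.approx(200.0, rel=1e-3)
        assert cut["distance_m"].iloc[0] == pytest.approx(141.42, rel=1e-3)

    def test_overnight_segment_excluded(self):
        e = 500_000 + np.array([0.0, 100.0, 5000.0, 5100.0])
        n = np.full(4, 5_100_000.0)
        t = ["2017-07-07 21:00", "2017-07-07 21:30",
             "2017-07-08 05:00", "2017-07-08 05:30"]
        dd = daily_distance(_fixes_from_utm(e, n, t))
        assert len(dd) == 2
        assert dd["distance_m"].sum() == pytest.approx(200.0, rel=1e-3)


class TestPercentOfConstant:
    def _daily(self, vals, dates=None):
        dates = dates or pd.date_range("2017-07-01", periods=len(vals))
        return pd.DataFrame({"date": dates, "distance_m": vals})

    def test_equal_gives_100(self):
        d = self._daily([1000.0, 2000.0])
        out = percent_of_constant(d, d)
        assert np.allclose(out["pct_of_constant"], 100.0)

    def test_half_gives_50(self):
        c = self._daily([1000.0])
        s = self._daily([500.0])
        assert percent_of_constant(s, c)["pct_of_constant"].iloc[0] == 50.0

    def test_zero_constant_days_excluded(self):
        c = self._daily([0.0, 1000.0])
        s = self._daily([0.0, 800.0])
        out = percent_of_constant(s, c)
        assert len(out) == 1

    def test_disjoint_days_raise(self):
        c = self._daily([1000.0], dates=[pd.Timestamp("2017-07-01")])
        s = self._daily([800.0], dates=[pd.Timestamp("2017-08-01")])
        with pytest.raises(ValueError):
            percent_of_constant(s, c)


class TestHourlyProfile:
    def test_stationary_animal_flat_zero(self):
        e = np.full(100, 500_000.0)
        t = pd.date_range("2017-07-07 08:00", periods=100, freq="20s")
        prof = hourly_profile(_fixes_from_utm(e, np.full(100, 5_100_000.0), t))
        assert (prof == 0).all()

    def test_simulator_night_hours_are_minima(self):
        from grazetrack.synthetic_herd import HerdSimConfig
        from grazetrack.workflows import simulate_deployment

        cfg = HerdSimConfig(n_animals=1, duration_days=2, fine_step_s=5,
                            gps_sd_m=0.0, fix_failure_prob=0.0,
                            outlier_prob=0.0, seed=13)
        fixes = simulate_deployment(cfg, daytime=False)["A01"]
        prof = hourly_profile(fixes)
        night = prof.loc[[22, 23, 0, 1, 2, 3]].mean()
        peaks = prof.loc[[5, 6, 7, 8, 16, 17, 18, 19]].mean()
        mid = prof.loc[[10, 11, 12, 13, 14]].mean()
        assert night < mid < peaks


class TestFitCorrection:
    def test_exact_proportional_data(self):
        x = np.array([1000.0, 2000.0, 3000.0, 4000.0])
        model = fit_correction(x, 2.0 * x)
        assert model.beta == pytest.approx(2.0, rel=1e-12)
        assert model.sigma == pytest.approx(0.0, abs=1e-9)

    def test_identity_data(self):
        x = np.array([1000.0, 2500.0, 4000.0])
        assert fit_correction(x, x).beta == pytest.approx(1.0, rel=1e-12)

    def test_matches_statsmodels_ols_through_origin(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(17)
        x = rng.uniform(1000, 6000, 40)
        y = 1.6 * x + rng.normal(0, 150, 40)
        model = fit_correction(x, y)
        sm_fit = sm.OLS(y, x).fit()
        assert model.beta == pytest.approx(sm_fit.params[0], rel=1e-10)
        # MLE sigma uses 1/n; statsmodels uses 1/(n-1) -> rescale the SE
        se_mle = sm_fit.bse[0] * np.sqrt((len(x) - 1) / len(x))
        wald_half = (model.beta_ci95[1] - model.beta_ci95[0]) / 2
        assert wald_half == pytest.approx(1.959964 * se_mle, rel=1e-6)

    def test_parameter_recovery_with_noise(self):
        """true beta = 1.6, 5% noise, 60 days: the 95% CI covers the
        truth in >= 90% of replicates."""
        rng = np.random.default_rng(23)
        hits = 0
        n_rep = 50
        for _ in range(n_rep):
            x = rng.uniform(1000, 6000, 60)
            y = 1.6 * x + rng.normal(0, 0.05 * x.mean(), 60)
            lo, hi = fit_correction(x, y).beta_ci95
            hits += lo <= 1.6 <= hi
        assert hits / n_rep >= 0.90

    def test_intercept_option(self):
        x = np.array([1000.0, 2000.0, 3000.0, 4000.0])
        y = 500.0 + 1.5 * x
        model = fit_correction(x, y, intercept=True)
        assert model.beta == pytest.approx(1.5, rel=1e-10)
        assert model.intercept == pytest.approx(500.0, rel=1e-8)

    def test_profile_ci_close_to_wald_for_clean_data(self):
        rng = np.random.default_rng(29)
        x = rng.uniform(1000, 6000, 80)
        y = 1.4 * x + rng.normal(0, 100, 80)
        wald = fit_correction(x, y, ci_method="wald").beta_ci95
        prof = fit_correction(x, y, ci_method="profile").beta_ci95
        assert prof[0] == pytest.approx(wald[0], abs=5e-3)
        assert prof[1] == pytest.approx(wald[1], abs=5e-3)

    @pytest.mark.parametrize("x,y", [
        (np.zeros(5), np.ones(5)),           # degenerate
        (np.ones(2), np.ones(2)),            # too few pairs
    ])
    def test_rejects_bad_training_sets(self, x, y):
        with pytest.raises(ValueError):
            fit_correction(x, y)


class TestValidateCorrection:
    def test_identity_model_on_identical_pairs(self):
        x = np.array([1000.0, 2000.0, 3000.0])
        model = CorrectionModel("regular_5", 1.0, (0.9, 1.1), 0.0, 3)
        res = validate_correction(model, x, x)
        assert res.slope == pytest.approx(1.0)
        assert res.contains_one

    def test_holdout_from_same_law(self):
        rng = np.random.default_rng(31)
        x_tr = rng.uniform(1000, 6000, 60)
        y_tr = 1.7 * x_tr + rng.normal(0, 150, 60)
        model = fit_correction(x_tr, y_tr)
        x_ho = rng.uniform(1000, 6000, 30)
        y_ho = 1.7 * x_ho + rng.normal(0, 150, 30)
        assert validate_correction(model, x_ho, y_ho).contains_one

    def test_wrong_beta_detected(self):
        rng = np.random.default_rng(37)
        x = rng.uniform(1000, 6000, 40)
        y = x + rng.normal(0, 100, 40)
        model = CorrectionModel("burst_5", 3.0, (2.8, 3.2), 100.0, 40)
        assert not validate_correction(model, x, y).contains_one

    def test_empty_holdout_raises(self):
        model = CorrectionModel("burst_5", 1.5, (1.4, 1.6), 10.0, 5)
        with pytest.raises(ValueError):
            validate_correction(model, np.empty(0), np.empty(0))


def test_coverage_filter_drops_ragged_days():
    t_full = pd.date_range("2017-07-07 04:00", "2017-07-07 21:59",
                           freq="20min")
    t_part = pd.date_range("2017-07-08 04:00", "2017-07-08 08:59",
                           freq="20min")
    fx = pd.DataFrame({"time_local": t_full.append(t_part)})
    out = coverage_filter(fx, min_hours=12)
    days = pd.to_datetime(out["time_local"]).dt.normalize().unique()
    assert list(days) == [pd.Timestamp("2017-07-07")]
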