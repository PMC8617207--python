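"""Event-date extraction: logistic snow timing, crossings, spline timings."""

import numpy as np
import pandas as pd
import pytest

import phenoflux as pf
from phenoflux.timings import (
    TimingResult, gsi_timings, half_max_productivity, logistic_crossing,
    nee_to_nep_gc, source_sink_transition, snowmelt_timing, snowpack_timing,
    timing_agreement,
)
from phenoflux.synthetic import inject_gap

from conftest import make_year_frame


def logistic_snow_year(mid=140.0, scale=3.0, c=0.0, d=1.0, noise=0.0,
                       seed=0, year=2005):
    dates = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)
    frac = c + (d - c) / (1.0 + np.exp((doy - mid) / scale))
    if noise:
        rng = np.random.default_rng(seed)
        frac = np.clip(frac + rng.normal(0, noise, len(frac)), 0, 1)
    return pd.DataFrame({"date": dates, "snow_frac": frac,
                         "quality": "good"})


class TestSnowTimings:
    def test_noiseless_recovery_within_half_day(self):
        snow = logistic_snow_year(mid=140.0, scale=3.0)
        expected = logistic_crossing(0.0, 1.0, 140.0, 3.0)
        res = snowmelt_timing(snow, 2005)
        assert res and abs(res.doy - expected) < 0.5

    def test_no_snow_season(self):
        snow = make_year_frame(snow_frac=0.0, quality=lambda d: 0 * d)
        snow["quality"] = "good"
        res = snowmelt_timing(snow, 2005)
        assert res.doy is None and not res.rejected
        assert "no snow" in res.reason

    def test_gap_rule_rejects(self):
        snow = logistic_snow_year(mid=140.0, scale=3.0)
        gappy = inject_gap(snow, start_doy=135, length=20, year=2005)
        res = snowmelt_timing(gappy, 2005)
        assert res.rejected and "gap" in res.reason

    def test_gap_far_from_crossing_is_tolerated(self):
        snow = logistic_snow_year(mid=140.0, scale=3.0)
        gappy = inject_gap(snow, start_doy=20, length=20, year=2005)
        res = snowmelt_timing(gappy, 2005)
        assert res and abs(res.doy - logistic_crossing(0, 1, 140, 3.0)) < 0.5

    def test_snowpack_increasing_logistic(self):
        dates = pd.date_range("2005-01-01", "2005-12-31", freq="D")
        doy = dates.dayofyear.to_numpy(float)
        frac = 1.0 / (1.0 + np.exp(-(doy - 280.0) / 4.0))
        snow = pd.DataFrame({"date": dates, "snow_frac": frac,
                             "quality": "good"})
        expected = logistic_crossing(0.0, 1.0, 280.0, -4.0)
        res = snowpack_timing(snow, 2005)
        assert res and abs(res.doy - expected) < 0.5

    def test_snow_free_autumn(self):
        snow = make_year_frame(snow_frac=0.0)
        snow["quality"] = "good"
        res = snowpack_timing(snow, 2005)
        assert res.doy is None and "no snowpack" in res.reason

    def test_translation_equivariance(self):
        a = snowmelt_timing(logistic_snow_year(mid=135.0), 2005)
        b = snowmelt_timing(logistic_snow_year(mid=145.0), 2005)
        assert b.doy - a.doy == pytest.approx(10.0, abs=0.1)

    def test_noisy_recovery_rate(self):
        """sigma = 0.05 cover noise: crossing within 2 d in >= 95% of seeds."""
        expected = logistic_crossing(0.0, 1.0, 140.0, 3.0)
        hits = 0
        n = 200
        for seed in range(n):
            snow = logistic_snow_year(noise=0.05, seed=seed)
            res = snowmelt_timing(snow, 2005)
            if res and abs(res.doy - expected) <= 2.0:
                hits += 1
        assert hits / n >= 0.95


class TestGSITimings:
    def test_linear_ramp_interpolation(self):
        # ramp 0 -> 1 over DOY 100..200: 0.1 at 110, 0.5 at 150
        def ramp(d):
            return np.clip((d - 100.0) / 100.0, 0.0, 1.0)
        g = make_year_frame(gsi=ramp)
        t01, t50 = gsi_timings(g, 2005)
        assert t01 == pytest.approx(110.0, abs=0.01)
        assert t50 == pytest.approx(150.0, abs=0.01)

    def test_no_crossing(self):
        g = make_year_frame(gsi=0.05)
        t01, t50 = gsi_timings(g, 2005)
        assert np.isnan(t01) and np.isnan(t50)

    def test_order_invariant(self, index):
        for year in (2003, 2010):
            t01, t50 = gsi_timings(index, year)
            if np.isfinite(t01) and np.isfinite(t50):
                assert t01 <= t50


class TestFluxTimings:
    def test_sine_zero_crossing_oracle(self):
        def nep(d):
            return 2.0 * np.sin((d - 155.0) / 40.0) * ((d > 100) & (d < 300)) \
                - 0.3 * ((d <= 100) | (d >= 300))
        df = make_year_frame(nep=nep)
        res = source_sink_transition(df, 2005)
        assert res and abs(res.doy - 155.0) < 1.0

    def test_permanent_source(self):
        df = make_year_frame(nep=-0.5)
        res = source_sink_transition(df, 2005)
        assert res.doy is None and "never a sink" in res.reason

    def test_noisy_zero_crossing_rate(self):
        """sigma = 0.3 g C m-2 d-1 noise: within 4 d in >= 90% of seeds."""
        def nep(d):
            return 2.0 * np.sin((d - 155.0) / 40.0) * ((d > 100) & (d < 300)) \
                - 0.3 * ((d <= 100) | (d >= 300))
        hits, n = 0, 200
        base = make_year_frame(nep=nep)
        for seed in range(n):
            rng = np.random.default_rng(seed)
            noisy = base.copy()
            noisy["nep"] = noisy["nep"] + rng.normal(0, 0.3, len(noisy))
            res = source_sink_transition(noisy, 2005)
            if res and abs(res.doy - 155.0) <= 4.0:
                hits += 1
        assert hits / n >= 0.90

    def test_triangular_half_max(self):
        def gpp(d):
            up = np.clip((d - 120.0) / 80.0, 0, 1)
            down = np.clip((280.0 - d) / 80.0, 0, 1)
            return 6.0 * np.minimum(up, down)
        df = make_year_frame(gpp=gpp)
        res = half_max_productivity(df, 2005)
        assert res and abs(res.doy - 160.0) < 1.5

    def test_gaussian_half_max_oracle(self):
        def gpp(d):
            return 5.0 * np.exp(-0.5 * ((d - 200.0) / 40.0) ** 2)
        expected = 200.0 - 40.0 * np.sqrt(2.0 * np.log(2.0))
        res = half_max_productivity(make_year_frame(gpp=gpp), 2005)
        assert res and abs(res.doy - expected) < 1.0

    def test_flat_zero_gpp_absent(self):
        res = half_max_productivity(make_year_frame(gpp=0.0), 2005)
        assert res.doy is None


class TestAgreement:
    def test_identical_vectors(self):
        t = pd.DataFrame({
            "year": range(2001, 2008),
            "t_gsi_01": np.linspace(130, 150, 7),
            "t_source_sink": np.linspace(130, 150, 7),
            "t_gsi_halfmax": np.linspace(140, 160, 7),
            "t_gpp_halfmax": np.linspace(140, 160, 7),
        })
        out = timing_agreement(t)
        assert np.allclose(out["r"], 1.0)
        assert np.allclose(out["rmse"], 0.0)

    def test_delayed_years_reduce_agreement(self):
        rng = np.random.default_rng(4)
        met_t = np.linspace(130, 150, 8) + rng.normal(0, 0.5, 8)
        flux_t = met_t + rng.normal(0, 0.5, 8)
        flux_t[[6, 7]] += 10.0  # delayed snowmelt shifts flux onset only
        t = pd.DataFrame({
            "year": range(2001, 2009), "t_gsi_01": met_t,
            "t_source_sink": flux_t,
            "t_gsi_halfmax": met_t + 8, "t_gpp_halfmax": flux_t + 8,
        })
        out = timing_agreement(t, delayed_years=[2007, 2008])
        sub = out[out["met_timing"] == "t_gsi_01"].set_index("subset")
        assert sub.loc["excl_delayed", "r"] > sub.loc["all", "r"]

    def test_zero_variance_reports_absent(self):
        t = pd.DataFrame({
            "year": range(2001, 2007),
            "t_gsi_01": 140.0,
            "t_source_sink": np.linspace(135, 150, 6),
            "t_gsi_halfmax": 150.0,
            "t_gpp_halfmax": np.linspace(145, 160, 6),
        })
        out = timing_agreement(t)
        assert out["r"].isna().all()

    def test_too_few_pairs(self):
        t = pd.DataFrame({
            "year": [2001, 2002, 2003],
            "t_gsi_01": [1.0, 2, 3], "t_source_sink": [1.0, 2, 3],
            "t_gsi_halfmax": [1.0, 2, 3], "t_gpp_halfmax": [1.0, 2, 3],
        })
        with pytest.raises(ValueError):
            timing_agreement(t)


def test_nee_unit_conversion():
    # 1 umol CO2 m-2 s-1 over a day = 1.037... g C m-2, sign flipped
    assert nee_to_nep_gc(-1.0) == pytest.approx(12.011e-6 * 86400.0)
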