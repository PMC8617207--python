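"""Deviation regressions, similarity screening, seasonal aggregation."""

import numpy as np
import pandas as pd
import pytest

import phenoflux as pf
from phenoflux.effects import DeviationRegression, weekly_mean_gsi

from conftest import make_year_frame


def multi_year_frame(years, fn):
    frames = []
    for y in years:
        f = make_year_frame(year=y, val=fn(y))
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


class TestSeasonalValues:
    def test_constant_total(self):
        df = make_year_frame(nep=1.0)
        out = pf.seasonal_values(df, pf.EARLY_GS, "nep", "total")
        assert out.loc[2005] == pytest.approx(61.0)  # May + Jun days

    def test_constant_mean(self):
        df = make_year_frame(nep=2.5)
        out = pf.seasonal_values(df, pf.PEAK_GS, "nep", "mean")
        assert out.loc[2005] == pytest.approx(2.5)

    def test_aggregation_oracle(self, index):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"date": index["date"],
                           "x": rng.normal(size=len(index))})
        out = pf.seasonal_values(df, pf.GS, "x", "total")
        d = pd.DatetimeIndex(df["date"])
        sel = d.month.isin([5, 6, 7, 8, 9, 10])
        expected = df.loc[sel].groupby(d[sel].year)["x"].sum()
        pd.testing.assert_series_equal(out, expected, check_names=False)

    def test_missing_month_raises(self):
        df = make_year_frame(nep=1.0)
        d = pd.DatetimeIndex(df["date"])
        with pytest.raises(ValueError, match="missing"):
            pf.seasonal_values(df[d.month != 6], pf.EARLY_GS, "nep", "total")


class TestSimilarMetYears:
    def test_identical_years_all_similar(self):
        df = multi_year_frame(range(2001, 2009),
                              lambda y: lambda d: np.sin(d / 60.0) ** 2)
        df = df.rename(columns={"val": "gsi"})
        out = pf.similar_met_years(df)
        assert out["met_similar"].all()

    def test_heatwave_year_excluded(self):
        def fn(y):
            def f(d):
                base = np.clip((d - 120.0) / 60.0, 0, 1) * np.clip((280.0 - d) / 60.0, 0, 1)
                if y == 2005:  # one anomalous mid-summer spike
                    base = base + 3.0 * ((d > 180) & (d < 195))
                return np.clip(base + 0.01 * ((y % 3) - 1), 0, 4)
            return f
        df = multi_year_frame(range(2001, 2010), fn).rename(columns={"val": "gsi"})
        out = pf.similar_met_years(df)
        flagged = out.set_index("year")["met_similar"]
        assert not flagged.loc[2005]

    def test_needs_five_years(self):
        df = multi_year_frame(range(2001, 2004), lambda y: 0.5)
        df = df.rename(columns={"val": "gsi"})
        with pytest.raises(ValueError):
            pf.similar_met_years(df)

    def test_weekly_blocks_are_jan1_anchored(self):
        df = make_year_frame(gsi=lambda d: d)
        wk = weekly_mean_gsi(df)
        # week 0 = DOY 1..7 -> mean 4
        assert wk.loc[2005, 0] == pytest.approx(4.0)

    def test_monte_carlo_pass_rate(self):
        """iid weekly noise: fraction of met-similar years matches a
        direct simulation of the same +-1 SD all-weeks rule."""
        rng = np.random.default_rng(1)
        n_years, n_weeks = 18, 26
        def run_rule(vals):
            mean = vals.mean(axis=0)
            sd = vals.std(axis=0, ddof=1)
            return (np.abs(vals - mean) <= sd).all(axis=1).mean()
        # oracle: direct Monte Carlo of the rule on weekly matrices
        oracle = np.mean([
            run_rule(rng.normal(size=(n_years, n_weeks))) for _ in range(300)
        ])
        # implementation route: build daily series with iid weekly values
        rates = []
        for rep in range(40):
            frames = []
            for i, y in enumerate(range(2001, 2001 + n_years)):
                weekly = rng.normal(0.5, 0.1, 53)
                f = make_year_frame(year=y, gsi=lambda d, w=weekly:
                                    w[((d - 1) // 7).astype(int)])
                frames.append(f)
            df = pd.concat(frames, ignore_index=True)
            out = pf.similar_met_years(df)
            rates.append(out["met_similar"].mean())
        assert abs(np.mean(rates) - oracle) < 0.1


class TestGreenupExclusion:
    def test_all_equal_pass(self):
        t = pd.DataFrame({"year": range(2001, 2008), "greenup_doy": 140.0})
        out = pf.greenup_exclusion(t)
        assert out["greenup_ok"].all()

    def test_outlier_excluded_arithmetic_oracle(self):
        vals = [140.0, 141.0, 142.0, 160.0, 141.0]
        t = pd.DataFrame({"year": range(2001, 2006), "greenup_doy": vals})
        out = pf.greenup_exclusion(t).set_index("year")
        mean, sd = np.mean(vals), np.std(vals, ddof=1)
        for y, v in zip(range(2001, 2006), vals):
            assert out.loc[y, "greenup_ok"] == (abs(v - mean) <= sd)
        assert not out.loc[2004, "greenup_ok"]

    def test_exactly_one_sd_retained(self):
        # construct so one year sits exactly at 1 SD
        vals = np.array([139.0, 141.0, 139.0, 141.0, 140.0])
        t = pd.DataFrame({"year": range(2001, 2006), "greenup_doy": vals})
        out = pf.greenup_exclusion(t)
        sd = np.std(vals, ddof=1)
        assert (np.abs(vals - vals.mean()) <= sd + 1e-12).all()
        assert out["greenup_ok"].all()


class TestDeviationRegression:
    def test_exact_linear_relation(self):
        dev = np.array([-5.0, -2, 0, 3, 4])
        est = DeviationRegression(dev, 2.0 * dev).fit()
        assert est.slope == pytest.approx(2.0)
        assert est.pearson_r == pytest.approx(1.0)
        assert est.per10day == pytest.approx(20.0)

    def test_null_noise_p_uniform(self):
        rng = np.random.default_rng(2)
        ps = []
        for _ in range(300):
            x = rng.normal(0, 3, 12)
            y = rng.normal(0, 1, 12)
            ps.append(DeviationRegression(x - x.mean(), y - y.mean()).fit().p)
        # p-values approximately uniform: mean near 0.5, ~5% below 0.05
        assert abs(np.mean(ps) - 0.5) < 0.06
        assert abs(np.mean(np.array(ps) < 0.05) - 0.05) < 0.04

    def test_deviations_sum_to_zero(self, index):
        g = pf.seasonal_values(
            pd.DataFrame({"date": index["date"], "x": index["gsi"]}),
            pf.GS, "x", "mean")
        dev = g - g.mean()
        assert abs(dev.sum()) < 1e-9

    def test_insufficient_years(self):
        with pytest.raises(ValueError):
            DeviationRegression([1.0, 2.0], [1.0, 2.0])


class TestTimingRegressions:
    def make_inputs(self, slope=2.0, seed=3, n=12):
        rng = np.random.default_rng(seed)
        years = np.arange(2001, 2001 + n)
        melt = 145.0 + rng.normal(0, 5, n)
        nep = 30.0 + slope * (melt - melt.mean()) + rng.normal(0, 0.5, n)
        snow = pd.DataFrame({"year": years, "snowmelt_doy": melt})
        values = pd.Series(nep, index=pd.Index(years, name="year"))
        return snow, values

    def test_recovery_within_2se(self):
        snow, values = self.make_inputs(slope=2.0)
        est = pf.snowmelt_deviation_regression(snow, values)
        assert abs(est.slope - 2.0) < 2 * est.se

    def test_masks_remove_years(self):
        snow, values = self.make_inputs()
        masks = pd.DataFrame({"year": snow["year"],
                              "met_similar": True, "greenup_ok": True})
        masks.loc[masks.index[:4], "met_similar"] = False
        est = pf.snowmelt_deviation_regression(snow, values, masks)
        assert est.n_years == len(snow) - 4

    def test_all_similar_equals_unmasked(self):
        snow, values = self.make_inputs()
        masks = pd.DataFrame({"year": snow["year"],
                              "met_similar": True, "greenup_ok": True})
        a = pf.snowmelt_deviation_regression(snow, values, masks)
        b = pf.snowmelt_deviation_regression(snow, values, None)
        assert a.slope == pytest.approx(b.slope)

    def test_greenup_sign_bookkeeping(self):
        # earlier greenup (negative deviation) with higher NEP -> negative
        # slope; "NEP gain per 10 early days" is then -per10day > 0
        rng = np.random.default_rng(4)
        years = np.arange(2001, 2013)
        greenup = 140.0 + rng.normal(0, 4, 12)
        nep = 50.0 - 4.0 * (greenup - greenup.mean()) + rng.normal(0, 0.1, 12)
        t = pd.DataFrame({"year": years, "greenup_doy": greenup})
        est = pf.greenup_deviation_regression(
            t, pd.Series(nep, index=pd.Index(years, name="year")))
        assert est.slope < 0
        assert -est.per10day == pytest.approx(40.0, rel=0.05)


class TestDifferenceRegression:
    def test_identical_runs_empty(self):
        tbl = pd.DataFrame({"delayed_days": [0.0] * 6, "d_nep": [0.0] * 6})
        assert pf.gsi_sgsi_difference(tbl) is None

    def test_constructed_linear_truth(self):
        days = np.arange(1.0, 13.0)
        tbl = pd.DataFrame({"delayed_days": days, "d_nep": -2.0 * days})
        est = pf.gsi_sgsi_difference(tbl)
        assert est.slope == pytest.approx(-2.0)


class TestEffectReport:
    def test_single_site_class_no_sd(self):
        df = pd.DataFrame({
            "site": ["a", "b", "c"],
            "limit_class": ["SCL", "SCL", "WWL"],
            "season": "early", "variable": "NEP", "control": "greenup",
            "per10day": [10.0, 20.0, 30.0],
        })
        out = pf.effect_report(df).set_index("limit_class")
        assert out.loc["SCL", "per10day_mean"] == pytest.approx(15.0)
        assert np.isnan(out.loc["WWL", "per10day_sd"])

    def test_arithmetic_oracle(self):
        df = pd.DataFrame({
            "site": list("abc"), "limit_class": "MCL", "season": "GS",
            "variable": "NEP", "control": "snowmelt",
            "per10day": [10.0, 20.0, 30.0],
        })
        out = pf.effect_report(df)
        assert out["per10day_mean"].iloc[0] == pytest.approx(20.0)
        assert out["per10day_sd"].iloc[0] == pytest.approx(10.0)

    def test_unknown_class_rejected(self):
        df = pd.DataFrame({
            "site": ["a"], "limit_class": ["XXX"], "season": "GS",
            "variable": "NEP", "control": "greenup", "per10day": [1.0],
        })
        with pytest.raises(ValueError):
            pf.effect_report(df)
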