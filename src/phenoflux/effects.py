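"""Net and lagged effects of snowmelt and greenup timing on seasonal
ecosystem variables.

The design isolates timing effects from interannual weather by a
constrained deviation regression: years are first screened for
meteorological similarity (weekly mean GSI within one standard deviation
of the across-year weekly mean) and for unexceptional greenup (within
one standard deviation of the mean greenup date); over the retained
years, the seasonal deviation of each variable (value minus across-year
mean) is regressed on the timing deviation (date minus mean date).
Slopes are reported per day of timing deviation and, following the
field's convention, multiplied by 10 as a "per 10 days" effect.

The gated/ungated (SGSI vs GSI) run differencing isolates the pure
snow-gate effect: for years in which unmelted snow delayed greenup, the
difference of each seasonal variable between the two schemes is
regressed on the number of delayed days.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .seasons import SeasonWindow, GS


@dataclass(frozen=True)
class EffectEstimate:
    """Sensitivity of one seasonal variable to one timing control.

    ``slope`` is in the variable's units per day of timing deviation;
    ``per10day`` is ``slope * 10``.
    """

    season: str
    variable: str
    control: str
    slope: float
    pearson_r: float
    p: float
    n_years: int
    se: float = np.nan

    @property
    def per10day(self) -> float:
        return self.slope * 10.0

    @property
    def significant(self) -> bool:
        return bool(self.p < 0.05)

    def summary(self) -> pd.Series:
        return pd.Series(
            {
                "season": self.season,
                "variable": self.variable,
                "control": self.control,
                "slope": self.slope,
                "se": self.se,
                "r": self.pearson_r,
                "p": self.p,
                "n": self.n_years,
                "per10day": self.per10day,
            }
        )


def seasonal_values(
    state: pd.DataFrame,
    window: SeasonWindow,
    column: str,
    mode: str = "mean",
) -> pd.Series:
    """Per-year seasonal mean or total of one daily column.

    ``mode="total"`` sums over the window days (fluxes, g C m-2 per
    season); ``mode="mean"`` averages (state variables).  Every window
    month must be present in every year.
    """
    dates = pd.DatetimeIndex(state["date"])
    sel = np.isin(dates.month, list(window.months))
    sub = state.loc[sel, column]
    years = dates[sel].year
    months = dates[sel].month
    present = pd.DataFrame({"y": years, "m": months}).groupby("y")["m"].nunique()
    for y, k in present.items():
        if k < len(window.months):
            raise ValueError(
                f"year {y} is missing months of season {window.name!r}"
            )
    g = sub.groupby(years)
    if mode == "total":
        out = g.sum()
    elif mode == "mean":
        out = g.mean()
    else:
        raise ValueError("mode must be 'mean' or 'total'")
    out.index.name = "year"
    return out


def weekly_mean_gsi(gsi: pd.DataFrame, col: str = "gsi") -> pd.DataFrame:
    """Weekly mean index per year; weeks are Jan-1-anchored 7-day blocks.

    Returns a (year x week) table; week numbers start at 0.
    """
    dates = pd.DatetimeIndex(gsi["date"])
    week = (dates.dayofyear - 1) // 7
    df = pd.DataFrame({"year": dates.year, "week": week,
                       "val": gsi[col].to_numpy()})
    return df.groupby(["year", "week"])["val"].mean().unstack("week")


def similar_met_years(
    gsi: pd.DataFrame,
    col: str = "gsi",
    gs_weeks_only: bool = True,
    required_fraction: float = 1.0,
) -> pd.DataFrame:
    """Flag years whose weekly GSI stays within +-1 SD of the weekly norm.

    For each Jan-1-anchored week the across-year mean and standard
    deviation of the weekly mean index are computed; a year passes a
    week when its value lies within one SD (weeks with zero across-year
    SD auto-pass).  A year is met-similar when it passes at least
    ``required_fraction`` of the assessed weeks (all of them by
    default).  With ``gs_weeks_only`` the assessment is restricted to
    weeks overlapping May-Oct.
    """
    wk = weekly_mean_gsi(gsi, col)
    if len(wk) < 5:
        raise ValueError("need >= 5 years to assess meteorological similarity")
    if gs_weeks_only:
        # weeks whose block midpoint falls in May-Oct (DOY 121-304)
        mid_doy = wk.columns.to_numpy() * 7 + 4
        wk = wk.loc[:, (mid_doy >= 121) & (mid_doy <= 304)]
    mean = wk.mean(axis=0)
    sd = wk.std(axis=0, ddof=1)
    within = (wk.sub(mean, axis=1).abs() <= sd) | (sd == 0)
    frac = within.mean(axis=1)
    ok = frac >= required_fraction
    return pd.DataFrame(
        {
            "year": wk.index.astype(int),
            "met_similar": ok.to_numpy(),
            "fraction_weeks_within": frac.to_numpy(),
        }
    ).reset_index(drop=True)


def greenup_exclusion(greenup: pd.DataFrame, column: str = "greenup_doy") -> pd.DataFrame:
    """Flag years whose greenup deviates more than one SD from the mean.

    A year passes when |greenup - mean| <= SD (strictly greater than one
    SD excludes; exactly one SD is retained).  All years pass when the
    SD is zero.
    """
    sub = greenup.dropna(subset=[column])
    if len(sub) < 5:
        raise ValueError("need >= 5 years of greenup timings")
    vals = sub[column].to_numpy(dtype=float)
    mean, sd = vals.mean(), vals.std(ddof=1)
    ok = np.abs(vals - mean) <= sd if sd > 0 else np.ones(len(vals), bool)
    return pd.DataFrame(
        {
            "year": sub["year"].astype(int).to_numpy(),
            "greenup_ok": ok,
            "greenup_deviation": vals - mean,
        }
    )


class DeviationRegression:
    """Least-squares regression of seasonal deviations on timing deviations.

    Both sides are centred on their across-year means over the retained
    years, so the fitted line passes near the origin by construction and
    the slope reads directly as "variable units per day of timing
    change".
    """

    def __init__(self, timing_dev, value_dev, season="GS", variable="NEP",
                 control="snowmelt"):
        x = np.asarray(timing_dev, dtype=float)
        y = np.asarray(value_dev, dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        self.x, self.y = x[ok], y[ok]
        if len(self.x) < 3:
            raise ValueError("need >= 3 years for a deviation regression")
        self.season, self.variable, self.control = season, variable, control

    def fit(self) -> EffectEstimate:
        res = stats.linregress(self.x, self.y)
        return EffectEstimate(
            season=self.season,
            variable=self.variable,
            control=self.control,
            slope=float(res.slope),
            pearson_r=float(res.rvalue),
            p=float(res.pvalue),
            n_years=len(self.x),
            se=float(res.stderr),
        )


def _masked_years(masks: pd.DataFrame | None, years) -> np.ndarray:
    years = np.asarray(years, dtype=int)
    if masks is None:
        return np.ones(len(years), bool)
    m = masks.set_index("year")
    keep = np.ones(len(years), bool)
    for i, y in enumerate(years):
        if y in m.index:
            row = m.loc[y]
            if "met_similar" in m.columns and not bool(row["met_similar"]):
                keep[i] = False
            if "greenup_ok" in m.columns and not bool(row["greenup_ok"]):
                keep[i] = False
        else:
            keep[i] = False
    return keep


def snowmelt_deviation_regression(
    snowmelt: pd.DataFrame,
    values: pd.Series,
    masks: pd.DataFrame | None = None,
    season: str = "GS",
    variable: str = "NEP",
    timing_col: str = "snowmelt_doy",
) -> EffectEstimate:
    """Regress a seasonal variable's deviation on snowmelt-date deviation.

    ``snowmelt`` holds per-year timings; ``values`` is a year-indexed
    seasonal series (from :func:`seasonal_values`); ``masks`` carries
    ``met_similar`` / ``greenup_ok`` flags — a year enters only when
    both are true.  Deviations are computed over the retained years;
    negative timing deviations mean early snowmelt.
    """
    merged = snowmelt.merge(
        values.rename("value"), left_on="year", right_index=True
    ).dropna(subset=[timing_col, "value"])
    keep = _masked_years(masks, merged["year"])
    sub = merged.loc[keep]
    if len(sub) < 3:
        raise ValueError(
            f"only {len(sub)} masked-in years; need >= 3"
        )
    t_dev = sub[timing_col] - sub[timing_col].mean()
    v_dev = sub["value"] - sub["value"].mean()
    return DeviationRegression(
        t_dev, v_dev, season=season, variable=variable, control="snowmelt"
    ).fit()


def greenup_deviation_regression(
    greenup: pd.DataFrame,
    values: pd.Series,
    masks: pd.DataFrame | None = None,
    season: str = "GS",
    variable: str = "NEP",
    timing_col: str = "greenup_doy",
) -> EffectEstimate:
    """As :func:`snowmelt_deviation_regression` with greenup date as the
    predictor (the greenup-exclusion mask is not applied to the
    predictor itself)."""
    if masks is not None and "greenup_ok" in masks.columns:
        masks = masks.drop(columns=["greenup_ok"])
    est = snowmelt_deviation_regression(
        greenup, values, masks, season=season, variable=variable,
        timing_col=timing_col,
    )
    return EffectEstimate(
        season=est.season, variable=est.variable, control="greenup",
        slope=est.slope, pearson_r=est.pearson_r, p=est.p,
        n_years=est.n_years, se=est.se,
    )


def gsi_sgsi_difference(
    diff_table: pd.DataFrame,
    value_col: str = "d_nep",
    season: str = "early",
    variable: str = "NEP",
) -> EffectEstimate | None:
    """Regress gated-minus-ungated differences on delayed-greenup days.

    ``diff_table`` has one row per year (or per imposed delay) with
    ``delayed_days`` and the per-variable difference columns, as
    produced by :func:`phenoflux.emulator.snowmelt_delay_experiment`.
    Only rows with ``delayed_days > 0`` enter (plus the zero-delay rows
    needed to anchor the regression are unnecessary: deviations are of
    differences).  Returns None when no year was delayed.
    """
    sub = diff_table.dropna(subset=["delayed_days", value_col])
    delayed = sub[sub["delayed_days"] > 0]
    if len(delayed) == 0:
        return None
    if len(delayed) < 3:
        raise ValueError("need >= 3 delayed rows for the difference regression")
    return DeviationRegression(
        delayed["delayed_days"], delayed[value_col],
        season=season, variable=variable, control="delayed_snowmelt",
    ).fit()


def effect_report(estimates: pd.DataFrame) -> pd.DataFrame:
    """Cross-site summary by climatic-limit class.

    ``estimates`` is tidy with columns ``site, limit_class, season,
    variable, control, per10day``; classes are ``SCL`` (strongly
    colimited), ``MCL`` (moderately colimited) and ``WWL`` (weakly
    water-limited).  Returns mean and SD of ``per10day`` per class x
    season x control; SD is NaN for single-site classes.
    """
    known = {"SCL", "MCL", "WWL"}
    bad = set(estimates["limit_class"]) - known
    if bad:
        raise ValueError(f"unknown climatic-limit class(es): {sorted(bad)}")
    g = estimates.groupby(["limit_class", "season", "variable", "control"])
    out = g["per10day"].agg(["mean", "std", "count"]).reset_index()
    return out.rename(columns={"mean": "per10day_mean", "std": "per10day_sd",
                               "count": "n_sites"})
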