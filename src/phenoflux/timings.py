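"""Per-year event-date extraction from snow, index and flux series.

Four families of timings:

* snowmelt / snowpack onset — a four-parameter logistic is fitted by
  least squares to the good-quality snow-cover fraction over the melt
  (Jan-Jul, decreasing) or accumulation (Aug-Dec, increasing) limb, and
  the fractional day-of-year where the fitted curve crosses 0.1 is
  returned.  A year is rejected when the good-data record has a gap
  longer than 14 days within +-14 days of the crossing.
* GSI timings — first upward crossings of 0.1 and of 0.5 (the half-max
  of a [0, 1] index) by linear interpolation.
* source-sink transition — first spring upward zero-crossing of a
  smoothing spline through daily NEP (NEP = -NEE; positive NEP = sink)
  that is followed by at least 7 consecutive positive spline days.
* half-max productivity — first upward crossing of half the spline
  maximum of daily GPP.

All fits are deterministic for identical input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from scipy.optimize import brentq, curve_fit
from scipy.stats import pearsonr

GAP_LIMIT_DAYS = 14
SNOW_THRESHOLD = 0.1

# umol CO2 m-2 s-1 (daily mean) -> g C m-2 d-1
UMOL_CO2_TO_GC_PER_DAY = 12.011e-6 * 86400.0


@dataclass(frozen=True)
class TimingResult:
    """Outcome of one timing extraction: a fractional DOY or a reason."""

    doy: float | None
    rejected: bool = False
    reason: str = ""

    def __bool__(self):
        return self.doy is not None and not self.rejected


def _logistic(t, c, d, m, s):
    """Decreasing (s > 0) or increasing (s < 0) logistic in t."""
    z = np.clip((t - m) / s, -500.0, 500.0)
    return c + (d - c) / (1.0 + np.exp(z))


def logistic_crossing(c, d, m, s, level=SNOW_THRESHOLD):
    """Closed-form t where the logistic equals ``level`` (NaN if never)."""
    lo, hi = (min(c, d), max(c, d))
    if not (lo < level < hi):
        return np.nan
    return m + s * np.log((d - c) / (level - c) - 1.0)


def _fit_logistic(doy, frac, decreasing=True):
    mid0 = float(doy[np.argmin(np.abs(frac - 0.5 * (frac.max() + frac.min())))])
    s0 = 5.0 if decreasing else -5.0
    p0 = (max(frac.min(), 0.0), min(frac.max(), 1.0), mid0, s0)
    # scale bounded away from 0 (its sign fixes the limb direction)
    s_lo, s_hi = (0.1, 60.0) if decreasing else (-60.0, -0.1)
    bounds = ([0.0, 0.0, doy.min() - 30, s_lo],
              [1.0, 1.0, doy.max() + 30, s_hi])
    popt, _ = curve_fit(_logistic, doy, frac, p0=p0, bounds=bounds,
                        maxfev=20000)
    return popt


def _gap_rejection(good_doy: np.ndarray, crossing: float) -> str:
    """Return a reason string when a good-data gap longer than the limit
    falls within +-14 d of the crossing, else ''."""
    window = (crossing - GAP_LIMIT_DAYS, crossing + GAP_LIMIT_DAYS)
    edges = np.concatenate([good_doy, [np.inf]])
    prev = -np.inf
    for x in edges:
        gap = (prev, x)
        if gap[1] - gap[0] - 1 > GAP_LIMIT_DAYS:  # days missing strictly inside
            if gap[0] < window[1] and gap[1] > window[0]:
                return (f"good-data gap of {gap[1] - gap[0] - 1:.0f} d "
                        f"near the crossing")
        prev = x
    return ""


def _snow_limb(snow: pd.DataFrame, year: int, limb: str):
    dates = pd.DatetimeIndex(snow["date"])
    if limb == "melt":
        sel = (dates.year == year) & (dates.month <= 7)
    else:
        sel = (dates.year == year) & (dates.month >= 8)
    sub = snow.loc[sel]
    doy = dates[sel].dayofyear.to_numpy(dtype=float)
    good = sub["quality"].to_numpy() == "good" if "quality" in sub else \
        np.ones(len(sub), bool)
    return doy, sub["snow_frac"].to_numpy(dtype=float), good


def snowmelt_timing(snow: pd.DataFrame, year: int) -> TimingResult:
    """Fractional DOY when fitted spring snow cover falls past 0.1.

    Fits the decreasing logistic to good-quality days of Jan-Jul and
    returns the closed-form 0.1 down-crossing of the fit.  Rejection
    reasons: no snow season, fit failure, or a >14-day good-data gap
    within two weeks of the crossing.
    """
    doy, frac, good = _snow_limb(snow, year, "melt")
    if len(doy) == 0:
        return TimingResult(None, True, "no data")
    if np.all(frac[good] <= SNOW_THRESHOLD):
        return TimingResult(None, False, "no snow season")
    if np.all(frac[good] > SNOW_THRESHOLD):
        return TimingResult(None, True, "snow never cleared by Jul 31")
    try:
        c, d, m, s = _fit_logistic(doy[good], frac[good], decreasing=True)
    except RuntimeError:
        return TimingResult(None, True, "logistic fit did not converge")
    t = logistic_crossing(c, d, m, s)
    if np.isnan(t):
        return TimingResult(None, True, "fitted curve never crosses 0.1")
    reason = _gap_rejection(doy[good], t)
    if reason:
        return TimingResult(None, True, reason)
    return TimingResult(float(t))


def snowpack_timing(snow: pd.DataFrame, year: int) -> TimingResult:
    """Mirror of :func:`snowmelt_timing`: fall 0.1 up-crossing of an
    increasing logistic over Aug-Dec."""
    doy, frac, good = _snow_limb(snow, year, "pack")
    if len(doy) == 0:
        return TimingResult(None, True, "no data")
    if np.all(frac[good] <= SNOW_THRESHOLD):
        return TimingResult(None, False, "no snowpack onset")
    try:
        c, d, m, s = _fit_logistic(doy[good], frac[good], decreasing=False)
    except RuntimeError:
        return TimingResult(None, True, "logistic fit did not converge")
    t = logistic_crossing(c, d, m, s)
    if np.isnan(t):
        return TimingResult(None, True, "fitted curve never crosses 0.1")
    reason = _gap_rejection(doy[good], t)
    if reason:
        return TimingResult(None, True, reason)
    return TimingResult(float(t))


def _interp_crossing(doy: np.ndarray, y: np.ndarray, level: float):
    """First upward crossing of ``level``, linearly interpolated."""
    above = y > level
    if above[0]:
        return float(doy[0])
    idx = np.flatnonzero(~above[:-1] & above[1:])
    if idx.size == 0:
        return np.nan
    i = idx[0]
    f = (level - y[i]) / (y[i + 1] - y[i])
    return float(doy[i] + f * (doy[i + 1] - doy[i]))


def gsi_timings(gsi: pd.DataFrame, year: int, col: str = "gsi"):
    """(0.1-GSI timing, half-max GSI timing) for one year.

    First upward crossings of 0.1 and 0.5 of the daily index, linearly
    interpolated to fractional DOY; NaN where never crossed.
    """
    dates = pd.DatetimeIndex(gsi["date"])
    sel = (dates.year == year) & (dates.month <= 7)
    doy = dates[sel].dayofyear.to_numpy(dtype=float)
    y = gsi.loc[sel, col].to_numpy(dtype=float)
    if len(doy) == 0:
        return np.nan, np.nan
    return _interp_crossing(doy, y, 0.1), _interp_crossing(doy, y, 0.5)


def _spline_fit(doy, y, lam=None):
    return make_smoothing_spline(doy, y, lam=lam)


def source_sink_transition(
    nep: pd.DataFrame, year: int, col: str = "nep",
    lam: float | None = None, sustained_days: int = 7,
) -> TimingResult:
    """Spring day the smoothed daily NEP first turns (and stays) positive.

    A smoothing spline (generalized cross-validated smoothing by
    default) is fitted to the year's daily NEP; the first upward zero
    crossing followed by ``sustained_days`` consecutive positive spline
    days is located by bisection on the spline.
    """
    dates = pd.DatetimeIndex(nep["date"])
    sel = dates.year == year
    doy = dates[sel].dayofyear.to_numpy(dtype=float)
    y = nep.loc[sel, col].to_numpy(dtype=float)
    ok = np.isfinite(y)
    doy, y = doy[ok], y[ok]
    if len(doy) < 10:
        return TimingResult(None, True, "too few NEP days")
    spl = _spline_fit(doy, y, lam)
    grid = np.arange(doy.min(), doy.max() + 1.0)
    v = spl(grid)
    pos = v > 0
    if not pos.any():
        return TimingResult(None, False, "never a sink")
    for i in np.flatnonzero(~pos[:-1] & pos[1:]):
        run = pos[i + 1: i + 1 + sustained_days]
        if len(run) >= sustained_days and run.all():
            t = brentq(spl, grid[i], grid[i + 1])
            return TimingResult(float(t))
    if pos[0]:
        return TimingResult(float(grid[0]))
    return TimingResult(None, True, "no sustained positive period")


def half_max_productivity(
    gpp: pd.DataFrame, year: int, col: str = "gpp", lam: float | None = None
) -> TimingResult:
    """Day the smoothed daily GPP first exceeds half its annual maximum."""
    dates = pd.DatetimeIndex(gpp["date"])
    sel = dates.year == year
    doy = dates[sel].dayofyear.to_numpy(dtype=float)
    y = gpp.loc[sel, col].to_numpy(dtype=float)
    ok = np.isfinite(y)
    doy, y = doy[ok], y[ok]
    if len(doy) < 10 or np.all(y <= 0):
        return TimingResult(None, False, "no productivity")
    spl = _spline_fit(doy, y, lam)
    grid = np.arange(doy.min(), doy.max() + 1.0)
    v = spl(grid)
    half = 0.5 * v.max()
    if half <= 0:
        return TimingResult(None, False, "no productivity")
    above = v > half
    if above[0]:
        return TimingResult(float(grid[0]))
    idx = np.flatnonzero(~above[:-1] & above[1:])
    if idx.size == 0:
        return TimingResult(None, True, "never exceeds half-max")
    i = idx[0]
    t = brentq(lambda x: spl(x) - half, grid[i], grid[i + 1])
    return TimingResult(float(t))


def extract_timings(
    snow: pd.DataFrame | None = None,
    gsi: pd.DataFrame | None = None,
    flux: pd.DataFrame | None = None,
    years=None,
) -> pd.DataFrame:
    """One row per year with every available timing and rejection flag."""
    if years is None:
        for df in (snow, gsi, flux):
            if df is not None:
                years = np.unique(pd.DatetimeIndex(df["date"]).year)
                break
        else:
            raise ValueError("no input series given")
    rows = []
    for year in years:
        row: dict = {"year": int(year)}
        if snow is not None:
            melt = snowmelt_timing(snow, int(year))
            pack = snowpack_timing(snow, int(year))
            row.update(
                snowmelt_doy=melt.doy, snowmelt_rejected=melt.rejected,
                snowmelt_reason=melt.reason,
                snowpack_doy=pack.doy, snowpack_rejected=pack.rejected,
                snowpack_reason=pack.reason,
            )
        if gsi is not None:
            t01, t50 = gsi_timings(gsi, int(year))
            row.update(t_gsi_01=t01, t_gsi_halfmax=t50)
            if "sgsi" in gsi:
                s01, s50 = gsi_timings(gsi, int(year), col="sgsi")
                row.update(t_sgsi_01=s01, t_sgsi_halfmax=s50)
        if flux is not None:
            ss = source_sink_transition(flux, int(year))
            hm = half_max_productivity(flux, int(year))
            row.update(
                t_source_sink=ss.doy, source_sink_reason=ss.reason,
                t_gpp_halfmax=hm.doy, gpp_halfmax_reason=hm.reason,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def timing_agreement(
    timings: pd.DataFrame,
    delayed_years=(),
    pairs=(("t_gsi_01", "t_source_sink"), ("t_gsi_halfmax", "t_gpp_halfmax")),
) -> pd.DataFrame:
    """Pearson r and RMSE between meteorological and flux timings.

    Computed with and without the years flagged as delayed snowmelt.
    Requires at least 4 complete pairs; r is reported absent (NaN) when
    either timing has zero variance.
    """
    rows = []
    delayed = set(int(y) for y in delayed_years)
    for met_col, flux_col in pairs:
        sub = timings[["year", met_col, flux_col]].dropna()
        for label, data in (
            ("all", sub),
            ("excl_delayed", sub[~sub["year"].isin(delayed)]),
        ):
            x = data[met_col].to_numpy(dtype=float)
            y = data[flux_col].to_numpy(dtype=float)
            if len(x) < 4:
                raise ValueError(
                    f"need >= 4 paired years for {met_col} vs {flux_col} "
                    f"({label}); got {len(x)}"
                )
            if np.std(x) == 0 or np.std(y) == 0:
                r = np.nan
            else:
                r = pearsonr(x, y).statistic
            rows.append(
                {
                    "met_timing": met_col,
                    "flux_timing": flux_col,
                    "subset": label,
                    "r": r,
                    "rmse": float(np.sqrt(np.mean((x - y) ** 2))),
                    "n": len(x),
                }
            )
    return pd.DataFrame(rows)


def nee_to_nep_gc(nee_umol) -> np.ndarray:
    """Convert daily-mean NEE (umol CO2 m-2 s-1) to NEP (g C m-2 d-1).

    NEP = -NEE; one umol CO2 m-2 s-1 sustained for a day carries
    12.011e-6 * 86400 g C m-2.
    """
    return -np.asarray(nee_umol, dtype=float) * UMOL_CO2_TO_GC_PER_DAY
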