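"""Growing-season index (GSI) and its snowmelt-gated variant (SGSI).

The GSI is the daily product of three [0, 1] ramp scalars applied to
daylength, vapour pressure deficit and a growing-degree-day sum; it
measures whether meteorology alone is ready for leaf growth.  The SGSI
multiplies the GSI by a binary snow gate that is 0 while snow-cover
fraction exceeds 0.1, so that greenup cannot begin before snowmelt even
when meteorology is favourable.

Spring indices run Jan 1 - Jul 31 with a degree-day sum above -5 degC
accumulated from Jan 1; fall indices run Aug 1 - Dec 31 with a chilling
sum below 20 degC accumulated from Aug 1.  Ramp thresholds are
calibrated from observed phenology dates: the minimum over years of each
variable's value on the greenup day (spring x_min) and on the maturity
day (spring x_max); dormancy and senescence play those roles in fall.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SNOW_GATE_THRESHOLD = 0.1
GDD_BASE_SPRING = -5.0
GDD_BASE_FALL = 20.0


class ThresholdError(ValueError):
    """Raised when ramp thresholds are degenerate (x_min >= x_max)."""


class AlignmentError(ValueError):
    """Raised when two daily series do not share the same dates."""


@dataclass(frozen=True)
class Ramp:
    """One piecewise-linear index ramp.

    ``increasing``: 0 at or below x_min, 1 at or above x_max.
    ``decreasing``: the mirror image (1 at or below x_min).
    """

    x_min: float
    x_max: float
    direction: str = "increasing"

    def __post_init__(self):
        if not np.isfinite(self.x_min) or not np.isfinite(self.x_max):
            raise ThresholdError("ramp thresholds must be finite")
        if self.x_min >= self.x_max:
            raise ThresholdError(
                f"x_min ({self.x_min}) must be < x_max ({self.x_max})"
            )
        if self.direction not in ("increasing", "decreasing"):
            raise ValueError("direction must be 'increasing' or 'decreasing'")

    def __call__(self, x):
        return index_scalar(x, self.x_min, self.x_max, self.direction)


@dataclass(frozen=True)
class GSIThresholds:
    """Calibrated ramps for one season (daylength, vpd, gdd)."""

    season: str
    daylength: Ramp
    vpd: Ramp
    gdd: Ramp

    def __post_init__(self):
        if self.season not in ("spring", "fall"):
            raise ValueError("season must be 'spring' or 'fall'")


def index_scalar(x, x_min: float, x_max: float, direction: str = "increasing"):
    """Piecewise-linear [0, 1] ramp of a meteorological variable.

    Increasing: 0 for x <= x_min, 1 for x >= x_max, linear between.
    Decreasing mirrors it (high values limiting, e.g. VPD).
    """
    if x_min >= x_max:
        raise ThresholdError(f"x_min ({x_min}) must be < x_max ({x_max})")
    x = np.asarray(x, dtype=float)
    up = np.clip((x - x_min) / (x_max - x_min), 0.0, 1.0)
    if direction == "increasing":
        out = up
    elif direction == "decreasing":
        out = 1.0 - up
    else:
        raise ValueError("direction must be 'increasing' or 'decreasing'")
    return out if out.ndim else float(out)


def _require_window_start(dates: pd.DatetimeIndex, month: int, what: str) -> None:
    first = dates[0]
    if (first.month, first.day) != (month, 1):
        raise AlignmentError(f"{what} series must start on {month:02d}-01")


def gdd_spring(tair, dates=None) -> np.ndarray:
    """Cumulative growing-degree-day sum above -5 degC from Jan 1.

    Exceedance convention: each day contributes max(0, T - (-5)) degC d.
    If ``dates`` is given the series must start on Jan 1.
    """
    if dates is not None:
        _require_window_start(pd.DatetimeIndex(dates), 1, "spring GDD")
    t = np.asarray(tair, dtype=float)
    return np.cumsum(np.maximum(0.0, t - GDD_BASE_SPRING))


def gdd_fall(tair, dates=None) -> np.ndarray:
    """Cumulative chilling sum below 20 degC from Aug 1.

    Each day contributes max(0, 20 - T) degC d; non-decreasing.
    """
    if dates is not None:
        _require_window_start(pd.DatetimeIndex(dates), 8, "fall GDD")
    t = np.asarray(tair, dtype=float)
    return np.cumsum(np.maximum(0.0, GDD_BASE_FALL - t))


def snow_index(snow_frac):
    """Binary snow gate: 0 where cover fraction is strictly above 0.1."""
    f = np.asarray(snow_frac, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("snow_frac must lie in [0, 1]")
    out = np.where(f > SNOW_GATE_THRESHOLD, 0.0, 1.0)
    return out if out.ndim else float(out)


def _season_slice(dates: pd.DatetimeIndex, season: str) -> np.ndarray:
    if season == "spring":
        return dates.month <= 7
    if season == "fall":
        return dates.month >= 8
    raise ValueError("season must be 'spring' or 'fall'")


def _check_contiguous(dates: pd.DatetimeIndex) -> None:
    gaps = np.diff(dates.to_numpy()) != np.timedelta64(1, "D")
    if gaps.any():
        missing = dates[:-1][gaps]
        raise AlignmentError(
            f"met series has gaps after: {list(missing.strftime('%Y-%m-%d')[:5])}"
        )


def compute_gsi(
    met: pd.DataFrame,
    thresholds: GSIThresholds,
    season: str = "spring",
    smooth_days: int | None = None,
) -> pd.DataFrame:
    """Daily GSI for every year of a met record, one season at a time.

    The three component ramps are applied to daylength (h), VPD (hPa)
    and the seasonal GDD accumulator (degC d, restarted every year).
    ``smooth_days`` optionally applies a centred running mean (off by
    default; the index is a daily product).

    Returns a DataFrame ``date, ix_daylength, ix_vpd, ix_gdd, gsi``
    restricted to the season window (spring: Jan 1 - Jul 31; fall:
    Aug 1 - Dec 31).
    """
    if thresholds.season != season:
        raise ValueError(
            f"thresholds calibrated for {thresholds.season!r}, not {season!r}"
        )
    dates = pd.DatetimeIndex(met["date"])
    _check_contiguous(dates)
    sel = _season_slice(dates, season)
    d = dates[sel]
    sub = met.loc[sel].reset_index(drop=True)

    gdd_fun = gdd_spring if season == "spring" else gdd_fall
    gdd = np.concatenate(
        [
            gdd_fun(sub["tair"].to_numpy()[idx.to_numpy()])
            for _, idx in pd.Series(np.arange(len(sub))).groupby(d.year)
        ]
    )

    ix_dl = thresholds.daylength(sub["daylength"].to_numpy())
    ix_vpd = thresholds.vpd(sub["vpd"].to_numpy())
    ix_gdd = thresholds.gdd(gdd)
    gsi = ix_dl * ix_vpd * ix_gdd
    out = pd.DataFrame(
        {
            "date": d.to_numpy(),
            "ix_daylength": ix_dl,
            "ix_vpd": ix_vpd,
            "ix_gdd": ix_gdd,
            "gdd": gdd,
            "gsi": gsi,
        }
    )
    if smooth_days:
        out["gsi"] = (
            out["gsi"].rolling(smooth_days, center=True, min_periods=1).mean()
        )
    return out


def compute_sgsi(gsi: pd.DataFrame, snow: pd.DataFrame) -> pd.DataFrame:
    """Gate a GSI series by snow cover: ``sgsi = gsi * i_s``.

    The two series are matched on date; the snow series must cover every
    GSI day.
    """
    snow_by_date = snow.set_index(pd.DatetimeIndex(snow["date"]))["snow_frac"]
    dates = pd.DatetimeIndex(gsi["date"])
    try:
        frac = snow_by_date.loc[dates].to_numpy()
    except KeyError as exc:
        raise AlignmentError(f"snow series missing GSI dates: {exc}") from None
    out = gsi.copy()
    out["i_s"] = snow_index(frac)
    out["sgsi"] = out["gsi"].to_numpy() * out["i_s"].to_numpy()
    return out


def annual_index(
    met: pd.DataFrame,
    spring: GSIThresholds,
    fall: GSIThresholds | None = None,
    snow: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Full-year daily index: spring GSI through Jul 31, fall GSI after.

    If ``fall`` is None the fall index is the spring index's seasonal
    decay mirrored from the fall ramps being absent — instead a simple
    symmetric closure is used: the fall half is computed with the spring
    daylength/VPD ramps and a decreasing chilling ramp is required, so a
    calibrated fall threshold set is strongly recommended.  If ``snow``
    is given the gated column ``sgsi`` is included.
    """
    parts = [compute_gsi(met, spring, "spring")]
    if fall is not None:
        parts.append(compute_gsi(met, fall, "fall"))
    idx = pd.concat(parts, ignore_index=True).sort_values("date").reset_index(drop=True)
    if snow is not None:
        idx = compute_sgsi(idx, snow)
    return idx


def calibrate_thresholds(
    met: pd.DataFrame,
    timings: pd.DataFrame,
    season: str = "spring",
    vpd_direction: str = "increasing",
) -> GSIThresholds:
    """Calibrate ramp thresholds from yearly phenology dates.

    Spring: for each variable, x_min is the minimum over years of its
    value on the greenup day and x_max the minimum of its value on the
    maturity day.  Fall uses dormancy (x_min role) and senescence
    (x_max role).  For variables whose ramp is decreasing (VPD by
    default; fall daylength/chilling are oriented so the index falls
    toward dormancy) the two calibrated values swap roles so that the
    index is ~0 at onset and ~1 at full leaf-out (spring) or the
    reverse in fall.

    Raises
    ------
    ThresholdError
        If any variable's calibrated x_min >= x_max (named in the
        message; never silently fixed).
    """
    if season == "spring":
        onset_col, full_col = "greenup_doy", "maturity_doy"
    elif season == "fall":
        onset_col, full_col = "dormancy_doy", "senescence_doy"
    else:
        raise ValueError("season must be 'spring' or 'fall'")

    dates = pd.DatetimeIndex(met["date"])
    sel = _season_slice(dates, season)
    d = dates[sel]
    sub = met.loc[sel].reset_index(drop=True)
    gdd_fun = gdd_spring if season == "spring" else gdd_fall
    year_of = d.year

    values = {"daylength": [], "vpd": [], "gdd": []}

    def sample(year: int, doy: float) -> dict | None:
        mask = year_of == year
        yd = d[mask].dayofyear.to_numpy()
        pos = np.flatnonzero(yd == int(round(doy)))
        if pos.size == 0:
            return None
        i = pos[0]
        t = sub.loc[mask.nonzero()[0], "tair"].to_numpy()
        gdd = gdd_fun(t)
        row = sub.loc[mask.nonzero()[0]].reset_index(drop=True)
        return {
            "daylength": float(row.loc[i, "daylength"]),
            "vpd": float(row.loc[i, "vpd"]),
            "gdd": float(gdd[i]),
        }

    onset_vals = {k: [] for k in values}
    full_vals = {k: [] for k in values}
    n_used = 0
    for _, row in timings.iterrows():
        if np.isnan(row.get(onset_col, np.nan)) or np.isnan(row.get(full_col, np.nan)):
            continue
        a = sample(int(row["year"]), row[onset_col])
        b = sample(int(row["year"]), row[full_col])
        if a is None or b is None:
            continue
        for k in values:
            onset_vals[k].append(a[k])
            full_vals[k].append(b[k])
        n_used += 1
    if n_used == 0:
        raise ValueError(
            f"no year with valid {onset_col} and {full_col} to calibrate from"
        )

    # Daylength favours growth when long in either season (increasing
    # ramp); the fall chilling sum is limiting when large (decreasing).
    # The VPD ramp defaults to increasing: the calibration anchors the
    # index at ~0 on the onset day and ~1 on the full-canopy day, and in
    # climates where VPD rises from greenup to maturity only an
    # increasing ramp is consistent with those anchors.  A decreasing
    # ramp (high VPD limiting, the classic index convention) remains
    # available via ``vpd_direction``.
    directions = {
        "daylength": "increasing",
        "vpd": vpd_direction,
        "gdd": "increasing" if season == "spring" else "decreasing",
    }
    # Orientation: x_min is the smaller and x_max the larger of the two
    # calibrated values; the configured direction carries the semantics
    # (which end of the ramp maps to 1).  Degenerate pairs are an error.
    ramps = {}
    for k in values:
        v_onset = min(onset_vals[k])
        v_full = min(full_vals[k])
        lo, hi = min(v_onset, v_full), max(v_onset, v_full)
        if lo >= hi:
            raise ThresholdError(
                f"calibrated x_min >= x_max for index {k!r} "
                f"({lo:.3g} >= {hi:.3g})"
            )
        ramps[k] = Ramp(lo, hi, directions[k])

    return GSIThresholds(season=season, daylength=ramps["daylength"],
                         vpd=ramps["vpd"], gdd=ramps["gdd"])
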