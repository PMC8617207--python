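"""Climatic limits on vegetation growing days.

Monthly limit scalars express the percentage reduction of vegetation
growing days attributable to each of three constraints:

* temperature — monthly mean T linearly scaled from 100% (no growth)
  at -5 degC to 0% at +5 degC;
* water — the monthly ratio of precipitation to Priestley-Taylor
  potential evapotranspiration, scaled from 100% at 0 to 0% at 0.75;
* radiation — 0.5% of growing days lost per 1% of monthly cloudiness
  above a 10% threshold, cloudiness inverted from
  ``R = R0 * (1 - 0.75 * n**3.4)``.

All ramps are continuous, piecewise linear and clamped to [0, 100].
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .seasons import SeasonWindow, GS

# Priestley-Taylor constants: alpha, latent heat (MJ kg-1),
# psychrometric constant (kPa K-1), shortwave albedo
PT_ALPHA = 1.26
LAMBDA_MJ = 2.45
GAMMA_KPA = 0.066
ALBEDO = 0.2


def _scalar_or_array(x, out):
    return out if np.ndim(x) else float(out)


def temperature_limit(monthly_mean_t):
    """Percent growing-day reduction from monthly mean temperature.

    100% at T <= -5 degC, 0% at T >= 5 degC, linear between.
    """
    t = np.asarray(monthly_mean_t, dtype=float)
    if np.any(np.isnan(t)):
        raise ValueError("temperature contains missing values")
    out = np.clip((5.0 - t) / 10.0 * 100.0, 0.0, 100.0)
    return _scalar_or_array(monthly_mean_t, out)


def priestley_taylor_pet(monthly_mean_t, net_radiation, days_in_month=30):
    """Monthly Priestley-Taylor potential evapotranspiration, mm.

    PET = alpha * Delta/(Delta+gamma) * (Rn - G) / lambda, with the
    slope of the saturation curve Delta from the Magnus relation, ground
    heat flux G = 0 and ``net_radiation`` as a daily-mean W m-2 energy
    proxy.  Floored at zero (freezing months would otherwise go
    negative through Rn).
    """
    t = np.asarray(monthly_mean_t, dtype=float)
    rn = np.asarray(net_radiation, dtype=float)
    if np.any(np.isnan(t)) or np.any(np.isnan(rn)):
        raise ValueError("PET inputs contain missing values")
    es = 0.6108 * np.exp(17.27 * t / (t + 237.3))  # kPa
    delta = 4098.0 * es / (t + 237.3) ** 2
    rn_mj = rn * 86400.0 * 1e-6 * days_in_month  # MJ m-2 month-1
    pet = PT_ALPHA * delta / (delta + GAMMA_KPA) * rn_mj / LAMBDA_MJ
    out = np.maximum(pet, 0.0)
    return _scalar_or_array(monthly_mean_t, out)


def water_limit(monthly_precip, monthly_pet):
    """Percent growing-day reduction from the P/PET ratio.

    100% at P/PET = 0, 0% at P/PET >= 0.75, linear between.  When
    PET = 0 the ratio is undefined; the documented convention is 0%
    reduction when any precipitation fell and 100% when none did.
    """
    p = np.asarray(monthly_precip, dtype=float)
    pet = np.asarray(monthly_pet, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(pet > 0, p / np.where(pet > 0, pet, 1.0), np.nan)
    out = np.clip((0.75 - ratio) / 0.75 * 100.0, 0.0, 100.0)
    out = np.where(pet > 0, out, np.where(p > 0, 0.0, 100.0))
    return _scalar_or_array(monthly_precip, out)


def cloudiness_from_radiation(r, r0):
    """Invert monthly cloudiness n from R = R0 * (1 - 0.75 * n**3.4).

    Clipped to [0, 1]; R > R0 clips to clear sky with a warning.
    """
    r = np.asarray(r, dtype=float)
    r0_arr = np.asarray(r0, dtype=float)
    if np.any(r0_arr <= 0):
        raise ValueError("clear-sky radiation R0 must be positive")
    if np.any(r > r0_arr):
        warnings.warn("R exceeds clear-sky R0; cloudiness clipped to 0",
                      stacklevel=2)
    frac = np.clip((1.0 - r / r0_arr) / 0.75, 0.0, 1.0)
    out = frac ** (1.0 / 3.4)
    return _scalar_or_array(r, out)


def radiation_limit(cloudiness):
    """Percent growing-day reduction from cloudiness.

    0.5% per 1% of cloudiness above the 10% threshold:
    max(0, (100 n - 10) * 0.5).
    """
    n = np.asarray(cloudiness, dtype=float)
    if np.any((n < 0) | (n > 1)):
        raise ValueError("cloudiness must lie in [0, 1]")
    out = np.maximum(0.0, (100.0 * n - 10.0) * 0.5)
    return _scalar_or_array(cloudiness, out)


def monthly_limits(met: pd.DataFrame) -> pd.DataFrame:
    """Per calendar month limit scalars from a daily met record.

    Aggregates daily means (T, radiation) and sums (precipitation) to
    calendar months, then applies the three limit ramps.  Returns one
    row per (year, month) with ``t_limit, w_limit, r_limit, pet,
    cloudiness``.
    """
    dates = pd.DatetimeIndex(met["date"])
    df = met.copy()
    df["year"] = dates.year
    df["month"] = dates.month
    g = df.groupby(["year", "month"])
    agg = g.agg(
        tair=("tair", "mean"),
        precip=("precip", "sum"),
        sw_down=("sw_down", "mean"),
        sw_clear=("sw_clear", "mean"),
        ndays=("tair", "size"),
    ).reset_index()
    rn = (1.0 - ALBEDO) * agg["sw_down"].to_numpy()
    pet = priestley_taylor_pet(agg["tair"].to_numpy(), rn,
                               agg["ndays"].to_numpy())
    # polar night: no radiation -> cloudiness undefined, treat as clear
    r0 = agg["sw_clear"].to_numpy()
    ok = r0 > 0
    n = np.zeros(len(agg))
    n[ok] = cloudiness_from_radiation(
        np.minimum(agg["sw_down"].to_numpy()[ok], r0[ok]), r0[ok]
    )
    return pd.DataFrame(
        {
            "year": agg["year"],
            "month": agg["month"],
            "t_limit": temperature_limit(agg["tair"].to_numpy()),
            "w_limit": water_limit(agg["precip"].to_numpy(), pet),
            "r_limit": radiation_limit(n),
            "pet": pet,
            "cloudiness": n,
        }
    )


def seasonal_limit_summary(
    met: pd.DataFrame,
    window: SeasonWindow = GS,
    averaging: str = "year-then-month",
) -> pd.Series:
    """Season-scale limit percentages for one site.

    Monthly scalars are computed from monthly aggregates of the daily
    record, averaged over the window months within each year and then
    across years (``year-then-month``, default) or pooled over all
    window months at once (``pooled``).
    """
    if not window.months <= GS.months:
        raise ValueError("window must lie within the growing season (May-Oct)")
    monthly = monthly_limits(met)
    sel = monthly["month"].isin(window.months)
    if not sel.any():
        raise ValueError(f"no data in season window {window.name!r}")
    cols = ["t_limit", "w_limit", "r_limit", "pet", "cloudiness"]
    sub = monthly.loc[sel]
    if averaging == "year-then-month":
        out = sub.groupby("year")[cols].mean().mean()
    elif averaging == "pooled":
        out = sub[cols].mean()
    else:
        raise ValueError("averaging must be 'year-then-month' or 'pooled'")
    out["season"] = window.name
    return out


def classify_site(t_limit: float, w_limit: float) -> str:
    """Assign the climatic-limit class used for cross-site reporting.

    ``SCL`` (strongly temperature-and-water colimited) when both limits
    exceed 35%; ``MCL`` (moderately colimited) when both exceed 15%;
    ``WWL`` (weakly water-limited) otherwise.
    """
    if t_limit >= 35.0 and w_limit >= 35.0:
        return "SCL"
    if t_limit >= 15.0 and w_limit >= 15.0:
        return "MCL"
    return "WWL"
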