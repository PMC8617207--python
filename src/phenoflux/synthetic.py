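"""Synthetic Arctic site generator: meteorology, snowpack and phenology timings.

This module emulates the data streams a site-level tundra carbon study
needs — daily meteorological forcing, a daily snow-cover record with
quality flags, and yearly land-surface phenology dates — with known,
configurable behaviour.  It is a declared stand-in for reanalysis
forcing, satellite snow/phenology products and eddy-covariance towers:
simple enough to reason about, rich enough that snowmelt timing responds
to winter precipitation and spring temperature, and greenup timing to
spring thermal sums.

All randomness flows from a single integer seed; identical configuration
gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

# Solar constant for daily extraterrestrial radiation, MJ m-2 min-1
_GSC = 0.0820
# Clear-sky transmissivity applied to top-of-atmosphere radiation
_CLEAR_SKY_TAU = 0.75
# Day of year of the climatological temperature maximum (mid July)
PEAK_DOY = 197


@dataclass(frozen=True)
class SiteConfig:
    """Configuration of one synthetic site.

    Parameters
    ----------
    site_id : str
        Label carried through all generated tables.
    latitude : float
        Site latitude in decimal degrees (drives daylength and clear-sky
        radiation).
    mean_annual_T : float
        Annual mean air temperature, degC.
    annual_T_amplitude : float
        Half peak-to-trough amplitude of the seasonal temperature cycle,
        degC; the seasonal maximum is ``mean_annual_T + annual_T_amplitude``.
    annual_precip : float
        Expected annual total precipitation, mm.
    winter_precip_fraction : float
        Fraction of annual precipitation expected during November-April.
    met_noise_sd : float
        Standard deviation of the AR(1) day-to-day temperature noise,
        degC; also scales the cloudiness noise.  Zero gives a noiseless
        sinusoidal climate (precipitation event timing stays stochastic).
    years : int
        Number of simulated calendar years.
    start_year : int
        First calendar year.
    seed : int
        Seed for the site's random number generator.
    """

    site_id: str = "SYN-1"
    latitude: float = 68.0
    mean_annual_T: float = -6.0
    annual_T_amplitude: float = 18.0
    annual_precip: float = 300.0
    winter_precip_fraction: float = 0.45
    met_noise_sd: float = 2.0
    years: int = 18
    start_year: int = 2001
    seed: int = 0
    ar1_rho: float = 0.7
    mean_cloudiness: float = 0.45

    def __post_init__(self):
        if self.years < 1:
            raise ValueError("years must be >= 1")
        if self.annual_T_amplitude <= 0:
            raise ValueError("annual_T_amplitude must be > 0")
        if self.annual_precip < 0:
            raise ValueError("annual_precip must be >= 0")
        if not 0.0 <= self.winter_precip_fraction <= 1.0:
            raise ValueError("winter_precip_fraction must be in [0, 1]")

    def replace(self, **kw) -> "SiteConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class SnowParams:
    """Degree-day snowpack parameters.

    ``melt_factor`` is the melt rate per positive degree day
    (mm degC-1 d-1); ``swe_full_cover`` the snow water equivalent at
    which cover fraction saturates at 1 (mm); ``missing_prob`` the
    per-day probability of a degraded (missing) quality flag.
    """

    melt_factor: float = 2.5
    swe_full_cover: float = 20.0
    missing_prob: float = 0.0

    def __post_init__(self):
        if self.melt_factor < 0:
            raise ValueError("melt factor must be non-negative")
        if self.swe_full_cover <= 0:
            raise ValueError("swe_full_cover must be > 0")
        if not 0 <= self.missing_prob < 1:
            raise ValueError("missing_prob must be in [0, 1)")


@dataclass(frozen=True)
class PhenologyRules:
    """Thermal-sum rules mapping meteorology to yearly phenology dates.

    Greenup / maturity fire when the spring growing-degree-day sum
    (base -5 degC from Jan 1) first exceeds the respective threshold;
    senescence / dormancy when the fall chilling sum (below 20 degC from
    Aug 1) does.  Units degC d.
    """

    greenup_gdd: float = 120.0
    maturity_gdd: float = 300.0
    senescence_gdd: float = 350.0
    dormancy_gdd: float = 900.0


def solar_declination(doy: np.ndarray) -> np.ndarray:
    """Solar declination (radians) for day-of-year."""
    return 0.409 * np.sin(2.0 * np.pi * doy / 365.0 - 1.39)


def daylength_hours(latitude: float, doy: np.ndarray) -> np.ndarray:
    """Astronomical daylength in hours from the sunset hour angle.

    Handles polar day/night by clipping the hour-angle cosine.
    """
    phi = np.deg2rad(latitude)
    delta = solar_declination(np.asarray(doy, dtype=float))
    cos_ws = np.clip(-np.tan(phi) * np.tan(delta), -1.0, 1.0)
    ws = np.arccos(cos_ws)
    return 24.0 / np.pi * ws


def clear_sky_radiation(latitude: float, doy: np.ndarray) -> np.ndarray:
    """Daily-mean clear-sky shortwave radiation, W m-2.

    Extraterrestrial radiation from standard solar geometry scaled by a
    fixed clear-sky transmissivity.
    """
    phi = np.deg2rad(latitude)
    doy = np.asarray(doy, dtype=float)
    delta = solar_declination(doy)
    dr = 1.0 + 0.033 * np.cos(2.0 * np.pi * doy / 365.0)
    cos_ws = np.clip(-np.tan(phi) * np.tan(delta), -1.0, 1.0)
    ws = np.arccos(cos_ws)
    ra = (
        24.0 * 60.0 / np.pi
        * _GSC
        * dr
        * (ws * np.sin(phi) * np.sin(delta) + np.cos(phi) * np.cos(delta) * np.sin(ws))
    )  # MJ m-2 d-1
    ra = np.maximum(ra, 0.0)
    return _CLEAR_SKY_TAU * ra * 1e6 / 86400.0


def saturation_vapor_pressure(tair: np.ndarray) -> np.ndarray:
    """Saturation vapour pressure over water, hPa (Magnus form)."""
    t = np.asarray(tair, dtype=float)
    return 6.112 * np.exp(17.67 * t / (t + 243.5))


def _ar1(rng: np.random.Generator, n: int, rho: float, sd: float) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation ``sd``."""
    if sd == 0.0:
        return np.zeros(n)
    eps = rng.normal(0.0, sd * np.sqrt(1.0 - rho**2), n)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + eps[i]
    return x


def generate_met(config: SiteConfig) -> pd.DataFrame:
    """Generate a multi-year daily meteorological record.

    The air temperature is a sinusoid peaking mid July plus AR(1) noise;
    precipitation falls as Bernoulli-gamma events with a winter/summer
    intensity split; shortwave radiation is clear-sky solar geometry
    attenuated by an autocorrelated cloudiness series through
    ``sw = sw_clear * (1 - 0.75 n**3.4)``; VPD follows the saturation
    deficit at the generated temperature under a seasonal relative
    humidity climatology.

    Returns
    -------
    pandas.DataFrame
        Columns ``date, tair, precip, sw_down, sw_clear, vpd, par,
        daylength, cloudiness``; one row per calendar day.
    """
    rng = np.random.default_rng(config.seed)
    dates = pd.date_range(
        f"{config.start_year}-01-01",
        f"{config.start_year + config.years - 1}-12-31",
        freq="D",
    )
    n = len(dates)
    doy = dates.dayofyear.to_numpy()

    tair = (
        config.mean_annual_T
        + config.annual_T_amplitude * np.cos(2.0 * np.pi * (doy - PEAK_DOY) / 365.25)
        + _ar1(rng, n, config.ar1_rho, config.met_noise_sd)
    )

    # Precipitation: wet days ~ Bernoulli(0.35); gamma amounts with a
    # seasonal mean so winter (Nov-Apr) receives winter_precip_fraction
    # of the annual total in expectation.
    month = dates.month.to_numpy()
    winter = np.isin(month, (11, 12, 1, 2, 3, 4))
    n_w = max(int(winter[: min(n, 366)].sum()), 1)
    days_per_year = 365.25
    winter_days = 181.0
    summer_days = days_per_year - winter_days
    mean_daily = np.where(
        winter,
        config.annual_precip * config.winter_precip_fraction / winter_days,
        config.annual_precip * (1.0 - config.winter_precip_fraction) / summer_days,
    )
    p_wet = 0.35
    shape = 0.7
    wet = rng.random(n) < p_wet
    amounts = rng.gamma(shape, 1.0, n) * (mean_daily / (p_wet * shape))
    precip = np.where(wet, amounts, 0.0)

    # Cloudiness: mean-reverting AR(1), clipped to [0, 1]
    cloud_sd = 0.15 * (config.met_noise_sd / 2.0 if config.met_noise_sd > 0 else 0.0)
    cloud = np.clip(
        config.mean_cloudiness + _ar1(rng, n, 0.6, cloud_sd), 0.0, 1.0
    )

    sw_clear = clear_sky_radiation(config.latitude, doy)
    sw_down = sw_clear * (1.0 - 0.75 * cloud**3.4)

    # Relative humidity climatology: moist winters, drier mid-summer
    rh = 0.85 - 0.10 * np.cos(2.0 * np.pi * (doy - PEAK_DOY) / 365.25)
    vpd = np.maximum(saturation_vapor_pressure(tair) * (1.0 - rh), 0.0)

    # Photosynthetic photon flux density, ~2.1 umol J-1 of shortwave
    par = 2.1 * sw_down

    return pd.DataFrame(
        {
            "date": dates,
            "tair": tair,
            "precip": precip,
            "sw_down": sw_down,
            "sw_clear": sw_clear,
            "vpd": vpd,
            "par": par,
            "daylength": daylength_hours(config.latitude, doy),
            "cloudiness": cloud,
        }
    )


def generate_snow(
    met: pd.DataFrame,
    params: SnowParams = SnowParams(),
    seed: int | None = None,
) -> pd.DataFrame:
    """Run a single-layer degree-day snowpack over a met record.

    Snow water equivalent accumulates from precipitation on days with
    ``tair < 0`` degC and melts at ``melt_factor * tair`` on days above
    freezing.  Cover fraction is a capped linear ramp
    ``min(1, swe / swe_full_cover)``.  Quality flags are ``good`` unless
    degraded at random (``missing_prob``) to emulate observation gaps.

    Returns
    -------
    pandas.DataFrame
        Columns ``date, snow_frac, swe, melt, quality``; ``melt`` is the
        liquid water released that day (mm).
    """
    if params.melt_factor < 0:
        raise ValueError("melt factor must be non-negative")
    tair = met["tair"].to_numpy()
    precip = met["precip"].to_numpy()
    n = len(met)
    swe = np.zeros(n)
    melt = np.zeros(n)
    s = 0.0
    for i in range(n):
        if tair[i] < 0.0:
            s += precip[i]
        else:
            m = min(s, params.melt_factor * tair[i])
            s -= m
            melt[i] = m
        swe[i] = s
    snow_frac = np.minimum(1.0, swe / params.swe_full_cover)

    quality = np.full(n, "good", dtype=object)
    if params.missing_prob > 0:
        rng = np.random.default_rng(seed)
        quality[rng.random(n) < params.missing_prob] = "missing"

    return pd.DataFrame(
        {
            "date": met["date"].to_numpy(),
            "snow_frac": snow_frac,
            "swe": swe,
            "melt": melt,
            "quality": quality,
        }
    )


def delay_snow(snow: pd.DataFrame, days: int) -> pd.DataFrame:
    """Hold snow on the ground ``days`` extra days.

    Implemented as a trailing rolling maximum of cover and SWE, which
    postpones every clearance date by exactly ``days`` while leaving
    accumulation onset unchanged.
    """
    if days < 0:
        raise ValueError("delay must be non-negative")
    out = snow.copy()
    if days == 0:
        return out
    for col in ("snow_frac", "swe"):
        x = snow[col].to_numpy()
        out[col] = (
            pd.Series(x).rolling(days + 1, min_periods=1).max().to_numpy()
        )
    # melt water is released later; recompute as SWE decrease
    swe = out["swe"].to_numpy()
    out["melt"] = np.maximum(0.0, -np.diff(swe, prepend=swe[0]))
    return out


def inject_gap(snow: pd.DataFrame, start_doy: int, length: int, year: int) -> pd.DataFrame:
    """Flag ``length`` consecutive days starting at ``start_doy`` of
    ``year`` as missing (for gap-rejection testing)."""
    out = snow.copy()
    dates = pd.DatetimeIndex(out["date"])
    mask = (dates.year == year) & (dates.dayofyear >= start_doy) & (
        dates.dayofyear < start_doy + length
    )
    out.loc[mask, "quality"] = "missing"
    return out


def derive_phenology(
    met: pd.DataFrame, rules: PhenologyRules = PhenologyRules()
) -> pd.DataFrame:
    """Derive yearly phenology dates from thermal sums.

    Greenup and maturity are the first days the spring degree-day sum
    (base -5 degC, accumulated from Jan 1) exceeds the configured
    thresholds; senescence and dormancy come from the fall chilling sum
    (degrees below 20 degC from Aug 1).  This mimics a satellite
    phenology product in which greenup responds to spring warmth.

    Returns a DataFrame with one row per year and columns
    ``year, greenup_doy, maturity_doy, senescence_doy, dormancy_doy``
    (NaN where a threshold is never reached).
    """
    dates = pd.DatetimeIndex(met["date"])
    tair = met["tair"].to_numpy()
    rows = []
    for year, idx in pd.Series(np.arange(len(met))).groupby(dates.year):
        i = idx.to_numpy()
        d = dates[i]
        t = tair[i]
        doy = d.dayofyear.to_numpy()
        spring = d.month <= 7
        gdd_s = np.cumsum(np.where(spring, np.maximum(0.0, t - (-5.0)), 0.0))
        fall = d.month >= 8
        chill = np.where(fall, np.maximum(0.0, 20.0 - t), 0.0)
        gdd_f = np.cumsum(chill)

        def first_doy(series, thr, valid):
            hit = np.flatnonzero((series >= thr) & valid)
            return float(doy[hit[0]]) if hit.size else np.nan

        rows.append(
            {
                "year": int(year),
                "greenup_doy": first_doy(gdd_s, rules.greenup_gdd, spring),
                "maturity_doy": first_doy(gdd_s, rules.maturity_gdd, spring),
                "senescence_doy": first_doy(gdd_f, rules.senescence_gdd, fall),
                "dormancy_doy": first_doy(gdd_f, rules.dormancy_gdd, fall),
            }
        )
    return pd.DataFrame(rows)


# --- delimited-text I/O -------------------------------------------------

_MET_HEADERS = {
    "tair": "TA",
    "precip": "P",
    "sw_down": "SW_IN",
    "sw_clear": "SW_IN_POT",
    "vpd": "VPD",
    "par": "PPFD_IN",
    "daylength": "DAY_LENGTH",
    "cloudiness": "CLOUD_FRAC",
}


def write_met(met: pd.DataFrame, path) -> None:
    """Write a met table with flux-network style column headers."""
    out = met.rename(columns=_MET_HEADERS).copy()
    out["date"] = pd.DatetimeIndex(out["date"]).strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_met(path) -> pd.DataFrame:
    """Read a met table written by :func:`write_met`."""
    df = pd.read_csv(path, parse_dates=["date"])
    inv = {v: k for k, v in _MET_HEADERS.items()}
    return df.rename(columns=inv)


def write_snow(snow: pd.DataFrame, path) -> None:
    out = snow.copy()
    out["date"] = pd.DatetimeIndex(out["date"]).strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_snow(path) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=["date"])
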