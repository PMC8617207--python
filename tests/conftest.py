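import numpy as np
import pandas as pd
import pytest

import phenoflux as pf


@pytest.fixture(scope="session")
def site_config():
    return pf.SiteConfig(years=18, seed=42)


@pytest.fixture(scope="session")
def met(site_config):
    return pf.generate_met(site_config)


@pytest.fixture(scope="session")
def snow(met):
    return pf.generate_snow(met)


@pytest.fixture(scope="session")
def phenology(met):
    return pf.derive_phenology(met)


@pytest.fixture(scope="session")
def thresholds(met, phenology):
    spring = pf.calibrate_thresholds(met, phenology, "spring")
    fall = pf.calibrate_thresholds(met, phenology, "fall")
    return spring, fall


@pytest.fixture(scope="session")
def index(met, snow, thresholds):
    spring, fall = thresholds
    return pf.annual_index(met, spring, fall, snow=snow)


@pytest.fixture(scope="session")
def quiet_site():
    """Noise-free six-year site used for paired-run experiments."""
    cfg = pf.SiteConfig(years=6, seed=42, met_noise_sd=0.0)
    met = pf.generate_met(cfg)
    snow = pf.generate_snow(met)
    phen = pf.derive_phenology(met)
    spring = pf.calibrate_thresholds(met, phen, "spring")
    fall = pf.calibrate_thresholds(met, phen, "fall")
    index = pf.annual_index(met, spring, fall, snow=snow)
    return {"met": met, "snow": snow, "phenology": phen,
            "spring": spring, "fall": fall, "index": index}


def make_year_frame(year=2005, **columns):
    """One calendar year of daily data as a DataFrame."""
    dates = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)
    out = {"date": dates}
    for name, fn in columns.items():
        out[name] = fn(doy) if callable(fn) else np.full(len(doy), fn, float)
    return pd.DataFrame(out)
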