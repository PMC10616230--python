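import numpy as np
import pandas as pd
import pytest

from vpdgrowth.rings import RingSeries
from vpdgrowth.synthgen import (
    SimulationConfig,
    SiteClimateParams,
    simulate_daily_weather,
    simulate_site_dataset,
    simulate_summer_vpd,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_weather():
    """Three years of daily weather for a cool mid-latitude site."""
    sp = SiteClimateParams(mat=2.0, map_mm=600.0, seasonal_amplitude=15.0)
    return simulate_daily_weather(sp, range(2000, 2003), seed=3)


@pytest.fixture(scope="session")
def site_dataset():
    """One simulated site ready for model fitting, with ground truth."""
    cfg = SimulationConfig(n_sites=1, trees_per_site=5, year_start=1960,
                           year_end=2014, alpha=0.3, beta1=-0.4, beta2=-1.0,
                           sigma_tree=0.3, phi=0.5, sigma_eps=0.25, seed=42)
    df, truth = simulate_site_dataset(cfg, seed=42)
    return df, truth, cfg


@pytest.fixture
def simple_series():
    return RingSeries(tree_id="T1", widths=np.array([10.0, 10.0, 5.0]),
                      first_year=1990, site_id="S1", species="PIMA")


@pytest.fixture(scope="session")
def summer_vpd():
    return simulate_summer_vpd(range(1900, 2020), seed=9, mean=0.8, sd=0.15)
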