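"""Coupled synthetic daily weather and tree-ring generation with known
ground truth.

The growth generator is the log-linear recursion

    log BAI(t) = alpha * log BA(t-1) + g(age) + beta1 * VPD(t)
               + beta2 * VPD(t-1) + b_tree + e(t)

with ``b_tree ~ N(0, sigma_tree^2)`` and ``e`` a stationary AR1 process
with coefficient ``phi`` and innovation SD ``sigma_eps``.  Basal area
accumulates as ``BA(t) = BA(t-1) + BAI(t)`` and is inverted to ring
widths through the radius, so downstream width-to-BAI conversion
recovers the simulated increments exactly.

``g(age)`` is a two-parameter log-normal-shaped ontogeny curve (rise to
a peak, slow decline) standing in for a fitted age smooth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .rings import RingSeries, write_rwl

__all__ = [
    "AgeCurve",
    "SiteClimateParams",
    "SimulationConfig",
    "SimulationError",
    "age_curve_value",
    "simulate_daily_weather",
    "simulate_summer_vpd",
    "simulate_ring_series",
    "simulate_site_dataset",
    "write_fixture_bundle",
]


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class AgeCurve:
    """log-normal-shaped log-BAI age effect: baseline + amplitude *
    exp(-(ln(age/peak_age))^2 / (2 width^2))."""

    baseline: float = 0.0
    amplitude: float = 1.0
    peak_age: float = 30.0
    width: float = 0.9


def age_curve_value(age, curve: AgeCurve):
    a = np.asarray(age, dtype=float)
    if np.any(a <= 0):
        raise SimulationError("age must be positive")
    z = np.log(a / curve.peak_age) / curve.width
    out = curve.baseline + curve.amplitude * np.exp(-0.5 * z * z)
    return float(out) if np.isscalar(age) else out


@dataclass(frozen=True)
class SiteClimateParams:
    """Per-site weather regime."""

    mat: float = 0.5                 # degC, mean annual temperature
    map_mm: float = 700.0            # mm, mean annual precipitation
    seasonal_amplitude: float = 16.0  # degC, half peak-to-trough of the annual cycle
    diurnal_range: float = 8.0       # degC, tmax - tmin
    temp_noise_sd: float = 3.0
    rh_mean: float = 70.0            # %
    rh_sd: float = 8.0
    rh_trend_per_year: float = 0.0   # % per year (negative -> rising VPD)
    wet_prob: float = 0.35
    wet_persistence: float = 0.6     # P(wet | wet)
    gamma_shape: float = 0.8
    lat: float = 52.0
    lon: float = -95.0
    elev: float = 350.0

    def __post_init__(self):
        if self.seasonal_amplitude < 0:
            raise ValueError("seasonal amplitude must be >= 0")
        if not (0 < self.rh_mean <= 100):
            raise ValueError("rh_mean must lie in (0, 100]")


@dataclass
class SimulationConfig:
    """Full ground-truth parameterization of the synthetic study."""

    n_sites: int = 5
    trees_per_site: int = 5
    year_start: int = 1955
    year_end: int = 2014
    species_labels: tuple[str, ...] = ("PIMA", "PIGL")
    alpha: float = 0.3
    beta1: float = -0.4
    beta2: float = -1.0
    age_curve: AgeCurve = field(default_factory=AgeCurve)
    sigma_tree: float = 0.3
    phi: float = 0.5
    sigma_eps: float = 0.25
    climate_params: SiteClimateParams | list[SiteClimateParams] = field(
        default_factory=SiteClimateParams)
    min_age_offset: int = 12
    max_age_offset: int = 30
    initial_radius_mean_cm: float = 0.5
    initial_radius_sd_log: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if not -1.0 < self.phi < 1.0:
            raise ValueError("phi must lie in (-1, 1)")
        if self.sigma_tree < 0 or self.sigma_eps < 0:
            raise ValueError("sigma_tree and sigma_eps must be >= 0")
        if self.trees_per_site < 1:
            raise ValueError("trees_per_site must be >= 1")
        if self.year_end - self.year_start + 1 < 25:
            raise ValueError("simulated span must cover >= 25 years for model fitting")
        if self.min_age_offset < 1:
            raise ValueError("min_age_offset must be >= 1")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)

    def site_params(self, i: int) -> SiteClimateParams:
        if isinstance(self.climate_params, SiteClimateParams):
            return self.climate_params
        return self.climate_params[i % len(self.climate_params)]


# ---------------------------------------------------------------------------
# Weather


def simulate_daily_weather(site_params: SiteClimateParams, years, seed) -> pd.DataFrame:
    """Daily tmin/tmax/prcp/rh over calendar ``years`` (deterministic in seed).

    Temperature: seasonal cosine around MAT plus iid noise; fixed diurnal
    range.  Precipitation: two-state wet/dry occurrence chain with gamma
    amounts scaled to the configured MAP.  RH: noisy mean with an optional
    linear trend (the mechanism for injecting a VPD trend)."""
    years = np.asarray(sorted(years))
    if years.size == 0:
        raise ValueError("years must be non-empty")
    rng = np.random.default_rng(seed)
    sp = site_params
    dates = pd.date_range(f"{years[0]}-01-01", f"{years[-1]}-12-31", freq="D")
    doy = dates.dayofyear.to_numpy()
    yr = dates.year.to_numpy()
    n = len(dates)

    tmean = sp.mat - sp.seasonal_amplitude * np.cos(2 * np.pi * (doy - 15) / 365.25)
    if sp.temp_noise_sd > 0:
        tmean = tmean + rng.normal(0.0, sp.temp_noise_sd, n)
    tmin = tmean - sp.diurnal_range / 2.0
    tmax = tmean + sp.diurnal_range / 2.0

    # two-state occurrence chain with stationary wet probability wet_prob
    p11 = sp.wet_persistence
    pw = sp.wet_prob
    p01 = np.clip(pw * (1 - p11) / max(1 - pw, 1e-9), 0.0, 1.0)
    wet = np.zeros(n, dtype=bool)
    u = rng.random(n)
    wet[0] = u[0] < pw
    for i in range(1, n):
        wet[i] = u[i] < (p11 if wet[i - 1] else p01)
    mean_wet_amount = sp.map_mm / (365.25 * pw) if pw > 0 else 0.0
    amounts = rng.gamma(sp.gamma_shape, mean_wet_amount / sp.gamma_shape, n) if mean_wet_amount > 0 else np.zeros(n)
    prcp = np.where(wet, amounts, 0.0)

    rh = sp.rh_mean + sp.rh_trend_per_year * (yr - years[0])
    if sp.rh_sd > 0:
        rh = rh + rng.normal(0.0, sp.rh_sd, n)
    rh = np.clip(rh, 1.0, 100.0)

    return pd.DataFrame({
        "date": dates, "tmin": tmin, "tmax": tmax, "prcp": prcp, "rh": rh,
    })


def simulate_summer_vpd(years, seed, mean=0.8, sd=0.15, trend_per_year=0.0,
                        ar1=0.0) -> pd.DataFrame:
    """Fast site-climate stand-in: summer VPD series (kPa), clipped > 0.

    Anomalies are stationary AR1 with coefficient ``ar1`` (0 = iid) and
    marginal SD ``sd`` — real summer VPD is persistent, and that
    persistence is what makes naive (autocorrelation-blind) inference
    anti-conservative.  Convenient when only the growth model is under
    test; the full daily weather path goes through
    :mod:`vpdgrowth.climate`."""
    years = np.asarray(sorted(years))
    rng = np.random.default_rng(seed)
    if ar1 != 0.0:
        innov_sd = sd * np.sqrt(1.0 - ar1**2)
        anom = _ar1_path_given(years.size, ar1, innov_sd, rng)
    else:
        anom = rng.normal(0.0, sd, years.size)
    vpd = mean + trend_per_year * (years - years[0]) + anom
    return pd.DataFrame({"year": years, "vpd_summer": np.maximum(vpd, 0.01)})


def _ar1_path_given(n, phi, innov_sd, rng):
    e = np.empty(n)
    e[0] = rng.normal(0.0, innov_sd / np.sqrt(1.0 - phi**2))
    w = rng.normal(0.0, innov_sd, n - 1)
    for t in range(1, n):
        e[t] = phi * e[t - 1] + w[t - 1]
    return e


# ---------------------------------------------------------------------------
# Ring growth


def _ar1_path(n: int, phi: float, sigma_eps: float, rng) -> np.ndarray:
    if sigma_eps == 0.0:
        return np.zeros(n)
    e = np.empty(n)
    marg = sigma_eps / np.sqrt(1.0 - phi**2) if abs(phi) < 1 else sigma_eps
    e[0] = rng.normal(0.0, marg)
    innov = rng.normal(0.0, sigma_eps, n - 1) if n > 1 else np.empty(0)
    for t in range(1, n):
        e[t] = phi * e[t - 1] + innov[t - 1]
    return e


def simulate_ring_series(config: SimulationConfig, site_climate: dict[str, pd.DataFrame],
                         seed=None) -> tuple[list[RingSeries], dict]:
    """Simulate ring-width series for all sites and trees.

    ``site_climate`` maps site_id -> table with ``year`` and
    ``vpd_summer`` covering every simulated year *and* the year before
    the oldest tree's first ring.  Returns the series plus a ground-truth
    record holding every drawn parameter."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    series: list[RingSeries] = []
    truth_trees = []
    for s in range(config.n_sites):
        site_id = f"S{s:03d}"
        species = config.species_labels[s % len(config.species_labels)]
        clim = site_climate[site_id]
        vpd_by_year = dict(zip(clim["year"].astype(int), clim["vpd_summer"].astype(float)))
        for t in range(config.trees_per_site):
            tree_id = f"{site_id}T{t:02d}"
            offset = int(rng.integers(config.min_age_offset, config.max_age_offset + 1))
            birth_year = config.year_start - offset
            n_years = config.year_end - birth_year + 1
            intercept = rng.normal(0.0, config.sigma_tree) if config.sigma_tree > 0 else 0.0
            r0 = config.initial_radius_mean_cm * np.exp(
                rng.normal(0.0, config.initial_radius_sd_log)
            ) if config.initial_radius_sd_log > 0 else config.initial_radius_mean_cm
            e = _ar1_path(n_years, config.phi, config.sigma_eps, rng)
            ba = np.pi * r0**2
            bai = np.empty(n_years)
            for k in range(n_years):
                year = birth_year + k
                age = k + 1
                try:
                    v_t = vpd_by_year[year]
                    v_t1 = vpd_by_year[year - 1]
                except KeyError as exc:
                    raise SimulationError(
                        f"site climate for {site_id} missing year {exc.args[0]}"
                    ) from None
                log_bai = (
                    config.alpha * np.log(ba)
                    + age_curve_value(age, config.age_curve)
                    + config.beta1 * v_t
                    + config.beta2 * v_t1
                    + intercept
                    + e[k]
                )
                if not np.isfinite(log_bai) or log_bai > 50:
                    raise SimulationError(
                        f"degenerate growth for tree {tree_id} year {year}: "
                        f"log BAI = {log_bai}"
                    )
                bai[k] = np.exp(log_bai)
                ba += bai[k]
            radii = np.sqrt((np.pi * r0**2 + np.cumsum(bai)) / np.pi)
            widths_mm = 10.0 * np.diff(np.concatenate([[r0], radii]))
            series.append(RingSeries(
                tree_id=tree_id, widths=widths_mm, first_year=birth_year,
                site_id=site_id, species=species, pith_offset_mm=10.0 * r0,
            ))
            truth_trees.append({
                "tree_id": tree_id, "site_id": site_id, "species": species,
                "birth_year": birth_year, "age_offset": offset,
                "intercept": float(intercept), "initial_radius_cm": float(r0),
            })
    truth = {
        "config": _config_dict(config),
        "trees": truth_trees,
    }
    return series, truth


def _config_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    if isinstance(d.get("climate_params"), list):
        d["climate_params"] = [dict(c) for c in d["climate_params"]]
    return d


def simulate_site_dataset(config: SimulationConfig, site_index: int = 0,
                          site_climate: pd.DataFrame | None = None,
                          seed=None, vpd_kwargs: dict | None = None
                          ) -> tuple[pd.DataFrame, dict]:
    """One site's ready-to-fit model frame with ground truth.

    Returns a table with columns ``tree_id, year, log_bai, log_ba_prev,
    age, vpd_t, vpd_t1`` restricted to the analysis window (so every tree
    is already past its juvenile phase by construction), derived exactly
    from the simulated recursion."""
    rng_seed = (config.seed if seed is None else seed)
    site_id = f"S{site_index:03d}"
    if site_climate is None:
        site_climate = simulate_summer_vpd(
            np.arange(config.year_start - config.max_age_offset - 1, config.year_end + 1),
            seed=np.random.default_rng(rng_seed).integers(2**31),
            **(vpd_kwargs or {}),
        )
    one = SimulationConfig(**{**_config_dict(config), "n_sites": 1,
                              "climate_params": config.site_params(site_index),
                              "age_curve": config.age_curve})
    series, truth = simulate_ring_series(one, {"S000": site_climate}, seed=rng_seed)
    vpd_by_year = dict(zip(site_climate["year"].astype(int),
                           site_climate["vpd_summer"].astype(float)))
    rows = []
    from .rings import widths_to_bai  # local import to avoid cycle at module load
    for rs in series:
        bs = widths_to_bai(rs)
        mask = bs.years >= config.year_start
        for yr, bai, ba_prev, age in zip(bs.years[mask], bs.bai[mask],
                                         bs.ba_prev[mask], bs.age[mask]):
            rows.append({
                "tree_id": rs.tree_id, "site_id": site_id, "species": rs.species,
                "year": int(yr), "log_bai": np.log(bai), "log_ba_prev": np.log(ba_prev),
                "age": int(age), "vpd_t": vpd_by_year[yr], "vpd_t1": vpd_by_year[yr - 1],
            })
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# Fixture bundles


def write_fixture_bundle(ring_series: list[RingSeries], weather: dict[str, pd.DataFrame],
                         ground_truth: dict, out_dir) -> dict:
    """Persist a complete text-only fixture: rwl, weather CSV, site
    metadata CSV and ground-truth JSON.  Round-trips through the rings
    readers at 0.001 mm precision."""
    if not ring_series:
        raise ValueError("refusing to write an empty fixture bundle")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rwl_path = out / "rings.rwl"
    write_rwl(ring_series, rwl_path, precision=0.001)
    frames = []
    for site_id, wdf in weather.items():
        w = wdf.copy()
        w.insert(0, "site_id", site_id)
        frames.append(w)
    weather_path = out / "weather.csv"
    pd.concat(frames, ignore_index=True).to_csv(weather_path, index=False)
    meta_rows = {}
    cfg = ground_truth.get("config", {})
    for tr in ground_truth.get("trees", []):
        meta_rows.setdefault(tr["site_id"], {
            "site_id": tr["site_id"], "species": tr["species"],
        })
    cp = cfg.get("climate_params", {})
    if isinstance(cp, dict):
        for m in meta_rows.values():
            m.update(lat=cp.get("lat"), lon=cp.get("lon"), elev=cp.get("elev"))
    meta_path = out / "sites.csv"
    pd.DataFrame(list(meta_rows.values())).to_csv(meta_path, index=False)
    truth_path = out / "ground_truth.json"
    with open(truth_path, "w") as fh:
        json.dump(ground_truth, fh, indent=1, default=_json_default)
    return {"rwl": rwl_path, "weather": weather_path, "sites": meta_path,
            "ground_truth": truth_path}


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
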