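"""Daily vapour pressure deficit, potential evapotranspiration and soil
moisture accounting, with summer (JJA) aggregation to site-year covariates.

Conventions
-----------
* Saturation vapour pressure follows the FAO-56 Tetens-type exponential
  (coefficients 0.6108, 17.27, 237.3); daily saturation pressure is the
  mean of ``es(tmax)`` and ``es(tmin)``.
* Actual vapour pressure comes from measured relative humidity when
  available (``ea = es(tmean) * rh / 100``), otherwise from a
  Kimball-style dewpoint regression driven by an annual aridity ratio.
* The soil moisture index uses a quadratic-plus-linear evapotranspiration
  restriction: below the critical storage (default 300 mm) the actual/
  potential ratio ramps quadratically, above it evapotranspiration is
  unrestricted; storage is capped at 400 mm and reported as percent of
  that capacity.
* Potential evapotranspiration is a simplified Penman-Monteith reference
  formulation with configurable albedo/wind/radiation defaults; solar
  input is estimated from extraterrestrial radiation and the diurnal
  temperature range.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SoilMoistureState",
    "PETParams",
    "ClimateParams",
    "saturation_vapour_pressure",
    "estimate_dewpoint",
    "actual_vapour_pressure",
    "daily_vpd",
    "step_soil_moisture",
    "soil_moisture_fixed_point",
    "potential_evapotranspiration",
    "extraterrestrial_radiation",
    "assign_grid_node",
    "haversine_km",
    "derive_daily_climate",
    "summarize_site_climate",
]

# Tetens-type coefficients (kPa, degC)
_SVP_A = 0.6108
_SVP_B = 17.27
_SVP_C = 237.3

_EARTH_RADIUS_KM = 6371.0


class ClimateConfigError(ValueError):
    """Invalid climate configuration or forcing."""


@dataclass(frozen=True)
class SoilMoistureState:
    """Soil water store in mm, with critical and maximum capacities."""

    water_content: float
    capacity_critical: float = 300.0
    capacity_max: float = 400.0

    def __post_init__(self):
        if not self.capacity_critical < self.capacity_max:
            raise ClimateConfigError(
                f"capacity_critical ({self.capacity_critical}) must be < "
                f"capacity_max ({self.capacity_max})"
            )
        if not 0.0 <= self.water_content <= self.capacity_max:
            raise ClimateConfigError(
                f"water_content {self.water_content} outside [0, {self.capacity_max}]"
            )

    @property
    def smi(self) -> float:
        """Soil moisture index: percent of maximum water-holding capacity."""
        return 100.0 * self.water_content / self.capacity_max


@dataclass(frozen=True)
class PETParams:
    """Defaults for the simplified Penman-Monteith reference surface."""

    albedo: float = 0.23
    wind_2m: float = 2.0          # m/s
    pressure_kpa: float = 101.3
    krs: float = 0.16             # Hargreaves radiation coefficient
    psychrometric: float = 0.0665  # kPa/degC at default pressure


@dataclass(frozen=True)
class ClimateParams:
    """Bundle of module-level parameters, all overridable via config."""

    smi_critical_mm: float = 300.0
    smi_capacity_mm: float = 400.0
    summer_months: tuple[int, ...] = (6, 7, 8)
    spinup_years: int = 1
    pet: PETParams = field(default_factory=PETParams)


def saturation_vapour_pressure(temp_c):
    """Saturation vapour pressure (kPa) at air temperature ``temp_c`` (degC).

    ``es(T) = 0.6108 * exp(17.27 T / (T + 237.3))``; strictly increasing.
    """
    t = np.asarray(temp_c, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ClimateConfigError("non-finite temperature passed to saturation_vapour_pressure")
    if np.any(t <= -100.0):
        raise ClimateConfigError("temperature below -100 degC is not supported")
    out = _SVP_A * np.exp(_SVP_B * t / (t + _SVP_C))
    return float(out) if np.isscalar(temp_c) else out


def estimate_dewpoint(tmin_c, annual_prcp_mm, pet_proxy_mm, tmax_c=None):
    """Daily dewpoint (degC) from a Kimball-style regression.

    The regression scales minimum temperature (in Kelvin) by a polynomial
    in the aridity ratio ``EF = pet_proxy / annual_prcp`` plus a small
    diurnal-range term.  In humid regimes (EF -> 0) dewpoint approaches
    Tmin; increasing aridity lowers it.  Output is capped at concurrent
    Tmax when supplied.
    """
    tmin = np.asarray(tmin_c, dtype=float)
    if np.any(~np.isfinite(tmin)):
        gaps = np.flatnonzero(~np.isfinite(tmin))
        raise ClimateConfigError(f"missing Tmin at day indices {gaps[:10].tolist()}")
    if annual_prcp_mm <= 0:
        raise ClimateConfigError("annual precipitation must be positive")
    ef = np.clip(np.asarray(pet_proxy_mm, dtype=float) / annual_prcp_mm, 0.0, 0.09)
    dtr = 0.0
    if tmax_c is not None:
        dtr = np.asarray(tmax_c, dtype=float) - tmin
    tmin_k = tmin + 273.15
    factor = (
        -0.127
        + 1.121 * (1.003 - 1.444 * ef + 12.312 * ef**2 - 32.766 * ef**3)
        + 0.0006 * dtr
    )
    td = tmin_k * factor - 273.15
    td = np.minimum(td, tmin)  # dewpoint cannot exceed the daily minimum here
    if tmax_c is not None:
        td = np.minimum(td, np.asarray(tmax_c, dtype=float))
    return float(td) if np.isscalar(tmin_c) else td


def actual_vapour_pressure(tmean_c=None, rh=None, dewpoint_c=None):
    """Actual vapour pressure (kPa) from RH (preferred) or dewpoint."""
    if rh is not None:
        rh_arr = np.asarray(rh, dtype=float)
        if np.any((rh_arr <= 0) | (rh_arr > 100)):
            raise ClimateConfigError("relative humidity must lie in (0, 100]")
        if tmean_c is None:
            raise ClimateConfigError("tmean_c required with rh")
        return saturation_vapour_pressure(tmean_c) * rh_arr / 100.0
    if dewpoint_c is None:
        raise ClimateConfigError("provide rh or dewpoint_c")
    return saturation_vapour_pressure(dewpoint_c)


def daily_vpd(tmax_c, tmin_c, ea_kpa):
    """Daily vapour pressure deficit (kPa), floored at zero.

    ``VPD = (es(tmax) + es(tmin)) / 2 - ea``.
    """
    tmax = np.asarray(tmax_c, dtype=float)
    tmin = np.asarray(tmin_c, dtype=float)
    ea = np.asarray(ea_kpa, dtype=float)
    if np.any(tmax < tmin):
        raise ClimateConfigError("tmax < tmin in daily_vpd input")
    if np.any(ea < 0):
        raise ClimateConfigError("actual vapour pressure must be >= 0")
    es_mean = 0.5 * (saturation_vapour_pressure(tmax) + saturation_vapour_pressure(tmin))
    vpd = es_mean - ea
    if np.any(vpd < 0):
        warnings.warn("supersaturated input: VPD floored at 0", stacklevel=2)
    vpd = np.maximum(vpd, 0.0)
    return float(vpd) if np.isscalar(tmax_c) else vpd


def _ql_ratio(water: float, critical: float) -> float:
    """Actual/potential evapotranspiration ratio: quadratic ramp below the
    critical storage, unity above it."""
    if water >= critical:
        return 1.0
    u = water / critical
    return u * (2.0 - u)


def step_soil_moisture(state: SoilMoistureState, prcp_mm: float, pet_mm: float) -> SoilMoistureState:
    """Advance the soil water balance by one day.

    AET = PET * g(W); W' = clamp(W + prcp - AET, 0, capacity_max).
    Excess above capacity is runoff.
    """
    if prcp_mm < 0 or pet_mm < 0:
        raise ClimateConfigError("precipitation and PET forcing must be non-negative")
    aet = pet_mm * _ql_ratio(state.water_content, state.capacity_critical)
    w_new = state.water_content + prcp_mm - aet
    w_new = min(max(w_new, 0.0), state.capacity_max)
    return replace(state, water_content=w_new)


def soil_moisture_fixed_point(prcp_mm: float, pet_mm: float,
                              critical: float = 300.0, capacity: float = 400.0) -> float:
    """Analytic equilibrium storage under constant forcing.

    For prcp < pet the balance settles where ``prcp = pet * g(W)`` with g
    the quadratic ramp, i.e. ``W* = critical * (1 - sqrt(1 - prcp/pet))``;
    for prcp >= pet storage fills to capacity.
    """
    if pet_mm <= 0 or prcp_mm >= pet_mm:
        return capacity
    return critical * (1.0 - math.sqrt(1.0 - prcp_mm / pet_mm))


def extraterrestrial_radiation(latitude_deg: float, doy) -> np.ndarray:
    """Daily extraterrestrial radiation Ra (MJ m-2 d-1), FAO-56 closed form."""
    if not -90.0 <= latitude_deg <= 90.0:
        raise ClimateConfigError(f"latitude {latitude_deg} outside [-90, 90]")
    j = np.asarray(doy, dtype=float)
    phi = math.radians(latitude_deg)
    dr = 1.0 + 0.033 * np.cos(2 * np.pi * j / 365.0)
    delta = 0.409 * np.sin(2 * np.pi * j / 365.0 - 1.39)
    x = -np.tan(phi) * np.tan(delta)
    ws = np.arccos(np.clip(x, -1.0, 1.0))  # clipped for polar day/night
    ra = (24 * 60 / np.pi) * 0.0820 * dr * (
        ws * np.sin(phi) * np.sin(delta) + np.cos(phi) * np.cos(delta) * np.sin(ws)
    )
    return np.maximum(ra, 0.0)


def potential_evapotranspiration(tmax_c, tmin_c, ea_kpa, latitude_deg, doy,
                                 params: PETParams | None = None):
    """Simplified Penman-Monteith reference PET (mm/day), floored at zero.

    Solar radiation is estimated from extraterrestrial radiation and the
    diurnal temperature range (Hargreaves coefficient ``krs``); net
    longwave follows the FAO-56 form; wind and albedo are fixed defaults
    from ``params``.
    """
    p = params or PETParams()
    tmax = np.asarray(tmax_c, dtype=float)
    tmin = np.asarray(tmin_c, dtype=float)
    ea = np.asarray(ea_kpa, dtype=float)
    if np.any(tmax < tmin):
        raise ClimateConfigError("tmax < tmin in PET input")
    tmean = 0.5 * (tmax + tmin)
    ra = extraterrestrial_radiation(latitude_deg, doy)
    rs = p.krs * np.sqrt(np.maximum(tmax - tmin, 0.0)) * ra
    rso = 0.75 * ra
    rns = (1.0 - p.albedo) * rs
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(rso > 0, np.clip(rs / np.maximum(rso, 1e-9), 0.3, 1.0), 0.3)
    sigma = 4.903e-9
    rnl = (
        sigma * 0.5 * ((tmax + 273.16) ** 4 + (tmin + 273.16) ** 4)
        * (0.34 - 0.14 * np.sqrt(np.maximum(ea, 0.0)))
        * (1.35 * rel - 0.35)
    )
    rn = rns - rnl
    es_mean = 0.5 * (saturation_vapour_pressure(tmax) + saturation_vapour_pressure(tmin))
    delta = 4098.0 * saturation_vapour_pressure(tmean) / (tmean + _SVP_C) ** 2
    gamma = p.psychrometric * p.pressure_kpa / 101.3
    num = 0.408 * delta * np.maximum(rn, 0.0) + gamma * (900.0 / (tmean + 273.0)) * p.wind_2m * np.maximum(es_mean - ea, 0.0)
    den = delta + gamma * (1.0 + 0.34 * p.wind_2m)
    pet = np.maximum(num / den, 0.0)
    return float(pet) if np.isscalar(tmax_c) else pet


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance in km."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlmb = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlmb / 2) ** 2
    return 2 * _EARTH_RADIUS_KM * math.asin(math.sqrt(a))


def assign_grid_node(lat: float, lon: float) -> tuple[int, int]:
    """Nearest integer-degree grid node by great-circle distance.

    Ties broken toward the equator, then westward, for determinism.
    """
    cands = [
        (la, lo)
        for la in (math.floor(lat), math.ceil(lat))
        for lo in (math.floor(lon), math.ceil(lon))
    ]
    # sort key: distance, then |lat| (equatorward), then lon (westward)
    best = min(cands, key=lambda c: (round(haversine_km(lat, lon, c[0], c[1]), 9), abs(c[0]), c[1]))
    return int(best[0]), int(best[1])


def derive_daily_climate(weather: pd.DataFrame, latitude: float,
                         params: ClimateParams | None = None) -> pd.DataFrame:
    """Compute daily VPD, PET and SMI from a site's daily weather table.

    ``weather`` needs columns date, tmin, tmax, prcp and optionally rh.
    The soil store starts full and runs through a spin-up period whose
    SMI values are still reported (callers discard spin-up years when
    summarizing).
    """
    p = params or ClimateParams()
    df = weather.sort_values("date").reset_index(drop=True).copy()
    df["date"] = pd.to_datetime(df["date"])
    if (df["tmax"] < df["tmin"]).any():
        raise ClimateConfigError("tmax < tmin in weather input")
    if (df["prcp"] < 0).any():
        raise ClimateConfigError("negative precipitation in weather input")
    doy = df["date"].dt.dayofyear.to_numpy()
    tmean = 0.5 * (df["tmax"] + df["tmin"]).to_numpy()
    if "rh" in df.columns and df["rh"].notna().all():
        ea = actual_vapour_pressure(tmean_c=tmean, rh=df["rh"].to_numpy())
    else:
        years = df["date"].dt.year
        annual_prcp = max(float(df.groupby(years)["prcp"].sum().mean()), 1.0)
        # first pass PET proxy (without ea) via Hargreaves-like scaling
        ra = extraterrestrial_radiation(latitude, doy)
        pet_proxy = 0.0023 * ra / 2.45 * np.sqrt(np.maximum(df["tmax"] - df["tmin"], 0.0)) * np.maximum(tmean + 17.8, 0.0)
        td = estimate_dewpoint(df["tmin"].to_numpy(), annual_prcp, pet_proxy, df["tmax"].to_numpy())
        ea = actual_vapour_pressure(dewpoint_c=td)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vpd = daily_vpd(df["tmax"].to_numpy(), df["tmin"].to_numpy(), ea)
    pet = potential_evapotranspiration(
        df["tmax"].to_numpy(), df["tmin"].to_numpy(), ea, latitude, doy, p.pet
    )
    state = SoilMoistureState(p.smi_capacity_mm, p.smi_critical_mm, p.smi_capacity_mm)
    smi = np.empty(len(df))
    prcp = df["prcp"].to_numpy()
    for i in range(len(df)):
        state = step_soil_moisture(state, float(prcp[i]), float(pet[i]))
        smi[i] = state.smi
    out = df[["date", "tmin", "tmax", "prcp"]].copy()
    out["vpd"] = vpd
    out["pet"] = pet
    out["smi"] = smi
    return out


def summarize_site_climate(daily: pd.DataFrame, site_id: str, latitude: float,
                           longitude: float, years=None,
                           params: ClimateParams | None = None,
                           climatology_years=None) -> pd.DataFrame:
    """Summer (JJA) mean VPD and SMI per year, plus long-term climatologies.

    Returns one row per reported year with columns ``site_id, year,
    vpd_summer, smi_summer, mat, map, mean_summer_smi, grid_lat,
    grid_lon``.  A year missing more than 10% of its JJA days is dropped
    with a warning rather than imputed.  ``daily`` is the output of
    :func:`derive_daily_climate`; the first ``spinup_years`` of record are
    excluded from SMI summaries.
    """
    p = params or ClimateParams()
    df = daily.copy()
    df["date"] = pd.to_datetime(df["date"])
    df["year"] = df["date"].dt.year
    df["month"] = df["date"].dt.month
    first_year = int(df["year"].min())
    usable = df[df["year"] >= first_year + p.spinup_years]
    summer = usable[usable["month"].isin(p.summer_months)]
    if years is None:
        years = sorted(summer["year"].unique())
    node = assign_grid_node(latitude, longitude)

    rows = []
    for y in years:
        sub = summer[summer["year"] == y]
        # JJA always spans 92 calendar days regardless of leap years
        if len(sub) < 0.9 * 92:
            warnings.warn(f"site {site_id}: year {y} missing >10% of JJA days; flagged missing",
                          stacklevel=2)
            continue
        rows.append({
            "site_id": site_id,
            "year": int(y),
            "vpd_summer": float(sub["vpd"].mean()),
            "smi_summer": float(sub["smi"].mean()),
        })
    out = pd.DataFrame(rows)
    clim = usable
    if climatology_years is not None:
        clim = usable[usable["year"].isin(climatology_years)]
    tmean = 0.5 * (clim["tmax"] + clim["tmin"])
    mat = float(tmean.mean())
    map_mm = float(clim.groupby("year")["prcp"].sum().mean())
    clim_summer = clim[clim["month"].isin(p.summer_months)]
    mean_summer_smi = float(clim_summer["smi"].mean())
    if out.empty:
        out = pd.DataFrame(columns=["site_id", "year", "vpd_summer", "smi_summer"])
    out["mat"] = mat
    out["map"] = map_mm
    out["mean_summer_smi"] = mean_summer_smi
    out["grid_lat"] = node[0]
    out["grid_lon"] = node[1]
    return out
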