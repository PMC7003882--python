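"""Synthetic microclimate, gas-exchange and leaf-trait generators.

Emulates the data a field/lab campaign on an understory *Daphne* shrub would
produce, so the whole pipeline runs and is testable without field downloads:

* a 2-min understory microclimate series (PAR, air temperature) beneath a
  deciduous canopy at ~35°N — deep shade in summer (canopy openness ~8%),
  open canopy in winter (~30%), air temperature from ~3 °C in January to
  ~25 °C in August;
* a laboratory light × temperature factorial of net-photosynthesis
  measurements (six chamber temperatures × ten PAR levels) around a known
  "true" response surface;
* species trait tables of dark respiration against A_max scattered about
  known generating regression lines.

Understory PAR is modelled as clear-sky above-canopy PAR (solar-geometry
model for the configured latitude, peak ≈ 2000 µmol m⁻² s⁻¹) times a
piecewise-linear seasonal canopy-openness schedule, with optional rare
sunfleck events and Gaussian daytime noise.  Air temperature is the sum of
an annual and a diurnal sinusoid plus noise.  All generators are
deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .surfaces import (HybridResponseSurface, LorentzianParams,
                       ParaboloidParams)

STEP_SECONDS = 120
#: chamber temperatures (°C) of the laboratory factorial design
DEFAULT_TEMPS = (5.0, 10.0, 15.0, 20.0, 25.0, 30.0)
#: PAR levels (µmol m⁻² s⁻¹) of the laboratory factorial design
DEFAULT_PARS = (0.0, 10.0, 30.0, 50.0, 100.0, 300.0, 500.0, 700.0, 900.0, 1100.0)
#: day-of-year of the warmest day of the annual temperature sinusoid
WARM_PEAK_DOY = 220.0


@dataclass
class ClimateConfig:
    """Configuration of the understory microclimate generator.

    Openness fractions act as canopy transmittance for PAR; the schedule is
    open before ``leafout_doy``, closes linearly over ``transition_days``,
    stays closed until ``leaffall_doy`` and reopens linearly.  The span is
    ``year_start``..``year_end`` (full calendar years) unless explicit
    ``start_date``/``end_date`` ISO dates are given (both inclusive).
    """

    latitude_deg: float = 35.4
    year_start: int = 2006
    year_end: int = 2006
    start_date: str | None = None
    end_date: str | None = None
    openness_closed: float = 0.08
    openness_open: float = 0.30
    leafout_doy: int = 110
    leaffall_doy: int = 310
    transition_days: int = 20
    temp_mean_jan: float = 3.0
    temp_mean_aug: float = 25.0
    diurnal_temp_range: float = 8.0
    peak_par: float = 2000.0
    sunfleck_prob: float = 0.001
    sunfleck_gain: float = 8.0
    noise_sd_par: float = 5.0
    noise_sd_temp: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if abs(self.latitude_deg) > 90:
            raise ValueError("latitude_deg must lie in [-90, 90]")
        if not (0 < self.openness_closed < self.openness_open <= 1):
            raise ValueError("require 0 < openness_closed < openness_open <= 1")
        if not self.leafout_doy < self.leaffall_doy:
            raise ValueError("leafout_doy must precede leaffall_doy")
        for name in ("noise_sd_par", "noise_sd_temp", "sunfleck_prob"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def span(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        if self.start_date is not None or self.end_date is not None:
            if self.start_date is None or self.end_date is None:
                raise ValueError("start_date and end_date must be given together")
            start = pd.Timestamp(self.start_date)
            end = pd.Timestamp(self.end_date)
        else:
            start = pd.Timestamp(year=self.year_start, month=1, day=1)
            end = pd.Timestamp(year=self.year_end, month=12, day=31)
        if end < start:
            raise ValueError("empty time span: end precedes start")
        return start, end


def solar_elevation_sine(doy, hour, latitude_deg: float):
    """Sine of solar elevation from day-of-year and local solar hour.

    Uses the standard declination approximation
    δ = 23.44°·sin(2π(284 + doy)/365.25) and hour angle 15°·(hour − 12).
    """
    doy = np.asarray(doy, dtype=float)
    hour = np.asarray(hour, dtype=float)
    lat = np.radians(latitude_deg)
    decl = np.radians(23.44) * np.sin(2 * np.pi * (284.0 + doy) / 365.25)
    hour_angle = np.radians(15.0 * (hour - 12.0))
    return (np.sin(lat) * np.sin(decl)
            + np.cos(lat) * np.cos(decl) * np.cos(hour_angle))


def canopy_openness(doy, config: ClimateConfig):
    """Piecewise-linear seasonal canopy openness (= PAR transmittance)."""
    doy = np.asarray(doy, dtype=float)
    xp = [1.0, float(config.leafout_doy),
          float(config.leafout_doy + config.transition_days),
          float(config.leaffall_doy),
          float(config.leaffall_doy + config.transition_days), 367.0]
    fp = [config.openness_open, config.openness_open, config.openness_closed,
          config.openness_closed, config.openness_open, config.openness_open]
    return np.interp(doy, xp, fp)


def _annual_temperature_coefficients(config: ClimateConfig) -> tuple[float, float]:
    # solve mean + amp*cos(...) so the January and August monthly means hit
    # the configured targets given the fixed warm-peak day
    doy_jan = np.arange(1, 32)
    doy_aug = np.arange(213, 244)
    c_jan = np.cos(2 * np.pi * (doy_jan - WARM_PEAK_DOY) / 365.25).mean()
    c_aug = np.cos(2 * np.pi * (doy_aug - WARM_PEAK_DOY) / 365.25).mean()
    amp = (config.temp_mean_aug - config.temp_mean_jan) / (c_aug - c_jan)
    mean = config.temp_mean_jan - amp * c_jan
    return mean, amp


def generate_climate(config: ClimateConfig) -> pd.DataFrame:
    """Generate a 2-min understory climate series.

    Returns a DataFrame with columns ``timestamp`` (datetime64), ``par``
    (µmol m⁻² s⁻¹, ≥ 0, exactly 0 at night) and ``temp_air`` (°C).
    """
    start, end = config.span()
    idx = pd.date_range(start, end + pd.Timedelta(days=1),
                        freq=f"{STEP_SECONDS}s", inclusive="left")
    doy = idx.dayofyear.to_numpy(dtype=float)
    hour = (idx.hour + idx.minute / 60.0 + idx.second / 3600.0).to_numpy()
    rng = np.random.default_rng(config.seed)

    sin_elev = solar_elevation_sine(doy, hour, config.latitude_deg)
    par_above = config.peak_par * np.clip(sin_elev, 0.0, None)
    day = sin_elev > 0
    par = par_above * canopy_openness(doy, config)
    if config.sunfleck_prob > 0:
        flecks = day & (rng.random(par.size) < config.sunfleck_prob)
        par[flecks] = np.minimum(par[flecks] * config.sunfleck_gain,
                                 par_above[flecks])
    if config.noise_sd_par > 0:
        par[day] = par[day] + rng.normal(0.0, config.noise_sd_par, day.sum())
    par = np.clip(par, 0.0, None)

    mean, amp = _annual_temperature_coefficients(config)
    temp = (mean + amp * np.cos(2 * np.pi * (doy - WARM_PEAK_DOY) / 365.25)
            + 0.5 * config.diurnal_temp_range
            * np.cos(2 * np.pi * (hour - 14.0) / 24.0))
    if config.noise_sd_temp > 0:
        temp = temp + rng.normal(0.0, config.noise_sd_temp, temp.size)

    return pd.DataFrame({"timestamp": idx, "par": par, "temp_air": temp})


def leaf_temperature_model(julian_day, extrapolate: bool = False):
    """Seasonal leaf-temperature regression (°C) on day-of-year.

    Leaf temperature = −12.05 + 0.346·JD − 0.0008·JD², the quadratic fitted
    to field leaf-temperature readings across the season.  Days outside
    [1, 366] require ``extrapolate=True``.
    """
    jd = np.asarray(julian_day, dtype=float)
    if not extrapolate and (np.any(jd < 1) or np.any(jd > 366)):
        raise ValueError("julian_day outside [1, 366]; pass extrapolate=True to allow")
    out = -12.05 + 0.346 * jd - 0.0008 * jd**2
    return float(out) if np.isscalar(julian_day) else out


# ---------------------------------------------------------------------------
# reference response surface and laboratory measurements

#: Low-light paraboloid of the reference shrub: dark respiration rises
#: steeply with temperature (Rd ≈ 0.3 − 0.01·T + 0.0025·T², i.e. ≈ 1.6 µmol
#: m⁻² s⁻¹ at 25 °C), apparent quantum yield ≈ 0.05.
REFERENCE_LOW = ParaboloidParams(k=-0.3, a=-0.01, b=0.05, c=-0.0025, d=1e-4)
#: High-light Lorentzian of the reference shrub: peak rate 7.5 µmol m⁻² s⁻¹
#: at a cool 13 °C optimum with a narrow temperature width — a high-light,
#: cool-season leaf that performs poorly in summer heat.
REFERENCE_HIGH = LorentzianParams(a=7.5, k=13.0, b=8.0, l=900.0, c=800.0)


def reference_surface() -> HybridResponseSurface:
    """The package's reference light × temperature response surface.

    A high-light-adapted, cool-optimum wintergreen leaf: substantial A_max,
    strongly temperature-dependent dark respiration, photosynthetic optimum
    around 16 °C.  Used as the generating truth for laboratory-measurement
    simulation and as the default plant in the demo pipeline.
    """
    return HybridResponseSurface(low=REFERENCE_LOW, high=REFERENCE_HIGH)


def make_plant_surfaces(n_plants: int, seed: int = 0,
                        cv: float = 0.06) -> dict[str, HybridResponseSurface]:
    """Reference surface with modest lognormal plant-to-plant variation.

    Peak rate, quantum yield and the respiration scale vary with coefficient
    of variation ``cv``; optima shift by a degree or two.
    """
    rng = np.random.default_rng(seed)
    plants = {}
    for i in range(n_plants):
        g = rng.lognormal(0.0, cv, size=3)
        low = ParaboloidParams(k=REFERENCE_LOW.k * g[0], a=REFERENCE_LOW.a * g[0],
                               b=REFERENCE_LOW.b * g[1], c=REFERENCE_LOW.c * g[0],
                               d=REFERENCE_LOW.d)
        high = LorentzianParams(a=REFERENCE_HIGH.a * g[2],
                                k=REFERENCE_HIGH.k + rng.normal(0.0, 1.0),
                                b=REFERENCE_HIGH.b, l=REFERENCE_HIGH.l,
                                c=REFERENCE_HIGH.c)
        plants[f"plant{i + 1:02d}"] = HybridResponseSurface(low=low, high=high)
    return plants


def generate_response_measurements(true_surface: HybridResponseSurface,
                                   temps: Sequence[float] = DEFAULT_TEMPS,
                                   pars: Sequence[float] = DEFAULT_PARS,
                                   noise_sd: float = 0.4,
                                   seed: int = 0,
                                   plant_id: str = "plant01") -> pd.DataFrame:
    """Simulate a full-factorial chamber gas-exchange campaign.

    One record per (temperature, PAR) cell: the true surface prediction plus
    Gaussian noise.  Defaults reproduce the six-temperature × ten-PAR
    laboratory design (60 records).
    """
    temps = np.asarray(list(temps), dtype=float)
    pars = np.asarray(list(pars), dtype=float)
    if temps.size == 0 or pars.size == 0:
        raise ValueError("temps and pars must be non-empty")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    tt, pp = np.meshgrid(temps, pars, indexing="ij")
    tt, pp = tt.ravel(), pp.ravel()
    pn = true_surface.predict(tt, pp)
    if noise_sd > 0:
        pn = pn + np.random.default_rng(seed).normal(0.0, noise_sd, pn.size)
    return pd.DataFrame({"temp": tt, "par": pp, "pn": pn,
                         "plant_id": plant_id})


# ---------------------------------------------------------------------------
# trait tables


@dataclass
class TraitSimConfig:
    """Generator for two-species (A_max, Rd) trait tables.

    Rd is drawn from the group's generating line Rd = intercept + slope·A_max
    plus Gaussian noise; A_max is uniform on ``amax_range``.  Defaults are
    the field-calibrated regression lines of the wintergreen shrub (group 0,
    "Dpm") and its summergreen congener (group 1, "koreana").
    """

    n_per_group: int = 50
    amax_range: tuple[float, float] = (3.0, 13.0)
    intercept_g0: float = 0.2201
    slope_g0: float = 0.0503
    intercept_g1: float = 0.4048
    slope_g1: float = 0.0504
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 3:
            raise ValueError("n_per_group must be >= 3")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.amax_range[0] < self.amax_range[1]:
            raise ValueError("amax_range must be increasing")


def generate_trait_table(config: TraitSimConfig) -> pd.DataFrame:
    """Draw 2·n_per_group rows of (group, species, site, amax, rd)."""
    rng = np.random.default_rng(config.seed)
    rows = []
    lines = [(0, "Dpm", config.intercept_g0, config.slope_g0),
             (1, "koreana", config.intercept_g1, config.slope_g1)]
    for group, species, intercept, slope in lines:
        amax = rng.uniform(*config.amax_range, size=config.n_per_group)
        rd = intercept + slope * amax
        if config.noise_sd > 0:
            rd = rd + rng.normal(0.0, config.noise_sd, config.n_per_group)
        rows.append(pd.DataFrame({"group": group, "species": species,
                                  "site": "synthetic", "amax": amax, "rd": rd}))
    return pd.concat(rows, ignore_index=True)
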