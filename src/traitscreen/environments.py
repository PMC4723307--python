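"""Synthetic target population of environments (TPE).

Four Australian wheatbelt site archetypes — Emerald (central Queensland,
summer-dominant rainfall on a deep black vertosol), Narrabri (northern NSW,
summer-dominant, high PAWC grey vertosol), Yanco (southern NSW, evenly
distributed rainfall) and Merredin (WA, winter-dominant, shallow loamy
duplex) — are emulated by a stochastic weather generator plus fixed soil and
management fixtures.  The generator targets the sites' first-order climate
statistics: long-run annual and May-November rainfall means, the declared
rainfall seasonality class, and mean temperature and radiation.  Interannual
structure (ENSO, autocorrelation) is deliberately not modelled.

Rainfall uses a Bernoulli wet-day occurrence chain with a seasonal harmonic
and gamma-distributed wet-day amounts whose seasonal mean compensates the
occurrence probability, so the expected daily depth follows the harmonic
exactly.  Temperature and radiation are seasonal sinusoids (southern
hemisphere phase: maxima in January) plus Gaussian noise.  Years are
synthetic 365-day years with an annual reset of soil water and nitrogen at
sowing.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulator import ManagementPlan, NApplication, SoilProfile, Weather

__all__ = [
    "SiteArchetype",
    "SITES",
    "daylength",
    "generate_weather",
    "management_plan",
    "build_environment_grid",
    "EnvironmentSpec",
    "write_met",
    "read_met",
    "SOWING_DOYS",
]

DAYS_PER_YEAR = 365
SEASON_START, SEASON_END = 121, 304  # 1 May .. 31 Oct (May-Nov window)
SOWING_DOYS = {"early": 111, "tpe": 135, "late": 158}  # 21/04, 15/05, 07/06
CO2_LEVELS = (380.0, 555.0)


def daylength(latitude: float, day_of_year: int) -> float:
    """Astronomical daylength (h) from solar declination and hour angle."""
    if abs(latitude) >= 66.5:
        raise ValueError("polar latitudes are out of range")
    phi = math.radians(latitude)
    # solar declination, Spencer-style harmonic in fractional year
    gamma = 2.0 * math.pi * (day_of_year - 1) / 365.0
    decl = (0.006918 - 0.399912 * math.cos(gamma) + 0.070257 * math.sin(gamma)
            - 0.006758 * math.cos(2 * gamma) + 0.000907 * math.sin(2 * gamma)
            - 0.002697 * math.cos(3 * gamma) + 0.00148 * math.sin(3 * gamma))
    cos_h = -math.tan(phi) * math.tan(decl)
    cos_h = min(1.0, max(-1.0, cos_h))
    return 24.0 / math.pi * math.acos(cos_h)


@dataclass(frozen=True)
class SiteArchetype:
    """Long-run climate, soil and local management for one TPE location."""

    name: str
    latitude: float
    annual_rain: float  # mm, long-run mean
    seasonal_rain: float  # mm May-Nov
    pattern: str  # summer-dominant | evenly-distributed | winter-dominant
    tmean: float  # degC daily mean
    radn_mean: float  # MJ/m2 daily mean
    pawc: float  # mm
    sowing_paw: float  # mm plant-available water at sowing
    initial_n: float  # kg/ha
    n_doses: tuple[float, float, float]  # kg/ha at sowing / tillering / stem elongation
    tillering_condition: tuple[str, float] | None = None
    elongation_condition: tuple[str, float] | None = None

    def __post_init__(self) -> None:
        if self.annual_rain <= 0 or self.seasonal_rain <= 0:
            raise ValueError("rainfall means must be positive")
        if self.latitude >= 0:
            raise ValueError("packaged archetypes are southern-hemisphere sites")

    def soil(self) -> SoilProfile:
        return make_soil(self.pawc, self.sowing_paw, self.initial_n)


def make_soil(pawc: float, sowing_paw: float, initial_n: float) -> SoilProfile:
    """Four-layer profile hitting a target PAWC, extraction fading with depth."""
    thickness = (300.0, 300.0, 450.0, 450.0)
    shares = (0.30, 0.30, 0.25, 0.15)
    ll = (0.16, 0.17, 0.18, 0.19)
    dul = tuple(l + s * pawc / t for l, s, t in zip(ll, shares, thickness))
    return SoilProfile(
        thickness=thickness, ll=ll, dul=dul, kl=(0.07, 0.05, 0.035, 0.02),
        initial_water=min(sowing_paw, pawc), initial_no3=initial_n,
    )


# Packaged archetypes: climate and management descriptors for the four sites.
SITES: dict[str, SiteArchetype] = {
    s.name: s
    for s in [
        SiteArchetype("Emerald", -23.53, 635.0, 170.0, "summer-dominant",
                      18.4, 18.3, 133.5, 132.0, 30.0, (50.0, 0.0, 0.0)),
        SiteArchetype("Narrabri", -30.32, 650.0, 249.0, "summer-dominant",
                      13.9, 15.7, 217.5, 175.0, 30.0, (130.0, 0.0, 0.0)),
        SiteArchetype("Yanco", -34.61, 425.0, 228.0, "evenly-distributed",
                      11.9, 13.3, 190.8, 99.0, 50.0, (40.0, 40.0, 40.0),
                      tillering_condition=("rain_gt", 100.0),
                      elongation_condition=("paw_frac_gt", 0.6)),
        SiteArchetype("Merredin", -31.5, 303.0, 209.0, "winter-dominant",
                      13.1, 14.5, 101.1, 39.0, 30.0, (20.0, 20.0, 30.0),
                      elongation_condition=("paw_gt", 60.0)),
    ]
}


def _rain_harmonic(site: SiteArchetype) -> tuple[float, int]:
    """Amplitude and peak day of the seasonal harmonic in expected daily rain.

    The amplitude is solved so the May-Nov share of the annual mean matches
    the site's seasonal rainfall; the peak sits in January for
    summer-dominant sites and July otherwise.
    """
    peak = 15 if site.pattern == "summer-dominant" else 196
    doys = np.arange(1, DAYS_PER_YEAR + 1)
    cos_term = np.cos(2.0 * math.pi * (doys - peak) / DAYS_PER_YEAR)
    in_season = (doys >= SEASON_START) & (doys <= SEASON_END)
    f = in_season.sum() / DAYS_PER_YEAR
    g = cos_term[in_season].sum() / DAYS_PER_YEAR
    target = site.seasonal_rain / site.annual_rain
    a = (target - f) / g
    return float(np.clip(a, -0.95, 0.95)), peak


def generate_weather(
    site: SiteArchetype, year_count: int, seed: int | None = None,
    co2: float = 380.0,
) -> Weather:
    """Synthetic daily weather for ``year_count`` 365-day years.

    Reproducible for a fixed seed; the long-run annual rainfall mean matches
    the archetype in expectation and its seasonality class is reproduced by
    construction of the harmonic.
    """
    if year_count < 1:
        raise ValueError("year_count must be >= 1")
    rng = np.random.default_rng(seed)
    n = year_count * DAYS_PER_YEAR
    doy = np.tile(np.arange(1, DAYS_PER_YEAR + 1), year_count)
    year = np.repeat(np.arange(1, year_count + 1), DAYS_PER_YEAR)

    a, peak = _rain_harmonic(site)
    cos_term = np.cos(2.0 * math.pi * (doy - peak) / DAYS_PER_YEAR)
    mean_daily = site.annual_rain / DAYS_PER_YEAR * (1.0 + a * cos_term)
    p_wet = np.clip(0.30 * (1.0 + a * cos_term), 0.02, 0.95)
    wet = rng.random(n) < p_wet
    shape = 0.75
    amounts = rng.gamma(shape, (mean_daily / p_wet) / shape)
    rain = np.where(wet, amounts, 0.0)

    summer = np.cos(2.0 * math.pi * (doy - 15) / DAYS_PER_YEAR)
    tmean = site.tmean + 6.5 * summer + rng.normal(0.0, 2.0, n)
    half_range = np.maximum(0.5, 6.0 + rng.normal(0.0, 1.0, n))
    maxt = tmean + half_range
    mint = tmean - half_range
    radn = np.maximum(0.5, site.radn_mean * (1.0 + 0.38 * summer)
                      + rng.normal(0.0, 1.5, n))
    dl = np.array([daylength(site.latitude, int(d)) for d in
                   np.arange(1, DAYS_PER_YEAR + 1)])
    return Weather(year=year, doy=doy, radn=radn, maxt=maxt, mint=mint,
                   rain=rain, daylength=np.tile(dl, year_count), co2=co2)


def management_plan(
    site: SiteArchetype, sowing_tag: str = "tpe", n_tag: str = "tpe",
    co2: float = 380.0,
) -> ManagementPlan:
    """Site management: sowing date, split N doses with decision rules, CO2.

    N levels: ``low`` halves every scheduled dose, ``tpe`` applies the site
    schedule, ``high`` adds 50 kg/ha on top at sowing.  The tillering and
    stem-elongation doses carry the site's runtime conditions (cumulative
    rainfall / plant-available water triggers) and are evaluated in-season
    by the simulator.
    """
    if sowing_tag not in SOWING_DOYS:
        raise ValueError(f"unknown sowing tag {sowing_tag!r}")
    if n_tag not in ("low", "tpe", "high"):
        raise ValueError(f"unknown N tag {n_tag!r}")
    if co2 not in CO2_LEVELS:
        raise ValueError(f"CO2 must be one of {CO2_LEVELS}")
    a, b, c = site.n_doses
    if n_tag == "low":
        a, b, c = 0.5 * a, 0.5 * b, 0.5 * c
    elif n_tag == "high":
        a = a + 50.0
    apps = []
    if a > 0:
        apps.append(NApplication(a, "sowing"))
    if b > 0:
        apps.append(NApplication(b, "end_of_tillering", site.tillering_condition))
    if c > 0:
        apps.append(NApplication(c, "mid_stem_elongation", site.elongation_condition))
    return ManagementPlan(sowing_doy=SOWING_DOYS[sowing_tag],
                          applications=tuple(apps), co2=co2,
                          n_tag=n_tag, sowing_tag=sowing_tag)


@dataclass(frozen=True)
class EnvironmentSpec:
    """One cell of the environment grid: site x year x sowing x N x CO2."""

    env_id: str
    site: str
    year: int
    sowing_tag: str
    n_tag: str
    co2: float


def build_environment_grid(
    sites: list[str],
    years: list[int],
    sowings: list[str] = ("tpe",),
    n_levels: list[str] = ("tpe",),
    co2_levels: list[float] = (380.0,),
) -> list[EnvironmentSpec]:
    """Cartesian product of the grid dimensions with unique environment ids."""
    if not (sites and years and sowings and n_levels and co2_levels):
        raise ValueError("all grid dimensions must be non-empty")
    grid = []
    for s, y, sow, ntag, co2 in itertools.product(sites, years, sowings,
                                                  n_levels, co2_levels):
        grid.append(EnvironmentSpec(
            env_id=f"{s}_y{y}_{sow}_{ntag}_{int(co2)}",
            site=s, year=y, sowing_tag=sow, n_tag=ntag, co2=float(co2)))
    return grid


def write_met(weather: Weather, path) -> None:
    """Plain tabular met layout: year day radn maxt mint rain (+ daylength)."""
    with open(path, "w") as fh:
        fh.write("! synthetic daily weather, traitscreen generator\n")
        fh.write("year day radn maxt mint rain daylength\n")
        for i in range(len(weather)):
            fh.write(f"{int(weather.year[i])} {int(weather.doy[i])} "
                     f"{weather.radn[i]:.2f} {weather.maxt[i]:.2f} "
                     f"{weather.mint[i]:.2f} {weather.rain[i]:.2f} "
                     f"{weather.daylength[i]:.3f}\n")


def read_met(path, co2: float = 380.0) -> Weather:
    """Read the tabular met layout; lines starting with '!' are comments."""
    df = pd.read_csv(path, sep=r"\s+", comment="!")
    if "daylength" not in df.columns:
        raise ValueError("met file lacks a daylength column")
    return Weather(year=df["year"].to_numpy(), doy=df["day"].to_numpy(),
                   radn=df["radn"].to_numpy(float), maxt=df["maxt"].to_numpy(float),
                   mint=df["mint"].to_numpy(float), rain=df["rain"].to_numpy(float),
                   daylength=df["daylength"].to_numpy(float), co2=co2)
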