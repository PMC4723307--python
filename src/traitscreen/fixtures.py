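"""Packaged extreme-environment fixtures for simulator audits.

Two synthetic single-season environments bracketing the water-stress axis:
a benign season (full deep profile, regular rain, generous nitrogen) where
water never limits growth, and a terminal-drought season (profile at the
crop lower limit, zero rain) where the crop cannot transpire at all.  Both
are generated, not measured: they exist to pin the stress-index scale and
the model's degenerate behavior, not to represent any real site.
"""

from __future__ import annotations

import numpy as np

from .environments import SITES, generate_weather, management_plan
from .simulator import ManagementPlan, NApplication, SoilProfile, Weather

__all__ = ["no_stress_environment", "terminal_drought_environment"]


def no_stress_environment(seed: int = 0) -> tuple[Weather, SoilProfile, ManagementPlan]:
    """Benign season: deep full profile, rain every fourth day, ample N."""
    base = generate_weather(SITES["Narrabri"], 2, seed=seed)
    rain = np.where(np.arange(len(base)) % 4 == 0, 12.0, 0.0)
    weather = Weather(year=base.year, doy=base.doy, radn=base.radn,
                      maxt=base.maxt, mint=base.mint, rain=rain,
                      daylength=base.daylength)
    soil = SoilProfile(thickness=(300.0, 300.0, 450.0, 450.0),
                       ll=(0.16, 0.17, 0.18, 0.19),
                       dul=(0.38, 0.39, 0.38, 0.35),
                       kl=(0.09, 0.07, 0.05, 0.04),
                       initial_water=280.0, initial_no3=250.0)
    man = ManagementPlan(sowing_doy=135,
                         applications=(NApplication(150.0, "sowing"),
                                       NApplication(100.0, "end_of_tillering")))
    return weather, soil, man


def terminal_drought_environment(seed: int = 0) -> tuple[Weather, SoilProfile, ManagementPlan]:
    """Season-long drought: soil at the crop lower limit, no rain at all."""
    base = generate_weather(SITES["Merredin"], 2, seed=seed)
    weather = Weather(year=base.year, doy=base.doy, radn=base.radn,
                      maxt=base.maxt, mint=base.mint,
                      rain=np.zeros(len(base)), daylength=base.daylength)
    soil = SoilProfile(thickness=(300.0, 300.0, 450.0, 450.0),
                       ll=(0.16, 0.17, 0.18, 0.19),
                       dul=(0.26, 0.27, 0.27, 0.26),
                       kl=(0.07, 0.05, 0.035, 0.02),
                       initial_water=0.0, initial_no3=60.0)
    man = ManagementPlan(sowing_doy=135,
                         applications=(NApplication(50.0, "sowing"),))
    return weather, soil, man
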