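"""Surrogate daily wheat crop model.

A deliberately simplified process-based model in the APSIM lineage, built so
that the screened trait parameters keep their causal roles: phenology driven
by thermal time modulated by photoperiod and vernalization; light
interception by Beer's law; daily biomass as the minimum of radiation-limited
(RUE) and transpiration-limited (TE / VPD) growth; a layered bucket soil
water balance with supply = sum of kl-weighted extractable water and demand
derived from potential growth; a single mineral-N pool feeding a crop N
status factor; grain set proportional to stem mass at flowering and grain
fill limited by potential rate, assimilate plus stem reserve, and the
max-grain-size cap.  It is a screening surrogate, not a calibrated wheat
model: magnitudes are plausible, not field-accurate.

All state is advanced with plain Python floats in a tight daily loop so a
full screen (tens of thousands of season runs) stays cheap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .parameters import Curve, VirtualGenotype

__all__ = [
    "Weather",
    "SoilProfile",
    "ManagementPlan",
    "NApplication",
    "CropParameters",
    "CropOutputs",
    "thermal_time",
    "run_crop",
]

# development temperature response (degC -> degCd/day): trapezoid over the
# cardinal temperatures 0 / 26 / 34 degC, species-level and not screened
DEV_TEMP_X = (0.0, 26.0, 34.0)
DEV_TEMP_Y = (0.0, 26.0, 0.0)

KG_HA_TO_G_M2 = 0.1
GRAIN_N_CONC = 0.023  # g N per g grain at unconstrained N fill
N_TO_PROTEIN = 5.7


def _interp(x: float, xs, ys) -> float:
    """Piecewise-linear interpolation with flat extrapolation (pure python)."""
    if x <= xs[0]:
        return ys[0]
    for i in range(1, len(xs)):
        if x <= xs[i]:
            w = (x - xs[i - 1]) / (xs[i] - xs[i - 1])
            return ys[i - 1] + w * (ys[i] - ys[i - 1])
    return ys[-1]


def thermal_time(tmin: float, tmax: float,
                 response_x=DEV_TEMP_X, response_y=DEV_TEMP_Y) -> float:
    """Daily thermal time (degCd) from a cardinal-temperature trapezoid.

    Zero at or below the base temperature, maximal at the optimum, back to
    zero at the maximum cardinal temperature; evaluated at the daily mean.
    """
    if tmin > tmax:
        raise ValueError("tmin exceeds tmax")
    return max(0.0, _interp(0.5 * (tmin + tmax), response_x, response_y))


def _svp(t: float) -> float:
    """Saturation vapour pressure (kPa), Tetens form."""
    return 0.6108 * math.exp(17.27 * t / (t + 237.3))


def vpd(tmin: float, tmax: float) -> float:
    """Daytime vapour pressure deficit: fixed 0.75 fraction of svp(tmax)-svp(tmin)."""
    return max(0.1, 0.75 * (_svp(tmax) - _svp(tmin)))


@dataclass
class Weather:
    """One or more years of daily weather as parallel numpy arrays."""

    year: np.ndarray
    doy: np.ndarray
    radn: np.ndarray  # MJ/m2
    maxt: np.ndarray  # degC
    mint: np.ndarray  # degC
    rain: np.ndarray  # mm
    daylength: np.ndarray  # h
    co2: float = 380.0  # ppm, constant per run

    def __post_init__(self) -> None:
        n = len(self.year)
        for name in ("doy", "radn", "maxt", "mint", "rain", "daylength"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"weather column {name} has wrong length")
        if np.any(self.mint > self.maxt):
            raise ValueError("mint exceeds maxt")
        if np.any(self.radn < 0) or np.any(self.rain < 0):
            raise ValueError("negative radiation or rainfall")

    def __len__(self) -> int:
        return len(self.year)

    def index_of(self, year: int, doy: int) -> int:
        hit = np.flatnonzero((self.year == year) & (self.doy == doy))
        if hit.size == 0:
            raise ValueError(f"date year={year} doy={doy} not in weather record")
        return int(hit[0])


@dataclass
class SoilProfile:
    """Layered bucket soil; water held between crop lower limit and drained upper limit."""

    thickness: tuple[float, ...]  # mm
    ll: tuple[float, ...]  # mm/mm volumetric lower limit
    dul: tuple[float, ...]  # mm/mm drained upper limit
    kl: tuple[float, ...]  # /day extraction coefficient
    initial_water: float = 0.0  # mm plant-available at sowing
    initial_no3: float = 30.0  # kg/ha

    def __post_init__(self) -> None:
        n = len(self.thickness)
        if not (len(self.ll) == len(self.dul) == len(self.kl) == n):
            raise ValueError("soil layer vectors must have equal length")
        for l, d in zip(self.ll, self.dul):
            if l >= d:
                raise ValueError("layer LL must be below DUL")
        if self.initial_water > self.pawc + 1e-9:
            raise ValueError("initial water exceeds PAWC")

    @property
    def pawc(self) -> float:
        """Plant available water capacity (mm): sum of (DUL-LL)*thickness."""
        return sum((d - l) * t for l, d, t in zip(self.ll, self.dul, self.thickness))

    @property
    def depth(self) -> float:
        return sum(self.thickness)

    def initial_layer_water(self) -> list[float]:
        """Per-layer water (mm), filling plant-available space top-down."""
        left = self.initial_water
        sw = []
        for l, d, t in zip(self.ll, self.dul, self.thickness):
            cap = (d - l) * t
            add = min(cap, max(0.0, left))
            sw.append(l * t + add)
            left -= add
        return sw


@dataclass(frozen=True)
class NApplication:
    """One scheduled fertilizer dose with an optional runtime condition.

    ``stage``: sowing | end_of_tillering | mid_stem_elongation.
    ``condition``: None (always applied) or one of
    ("rain_gt", mm) cumulative rain since sowing, ("paw_frac_gt", fraction)
    plant-available water over PAWC, ("paw_gt", mm) absolute PAW.
    """

    amount: float  # kg/ha
    stage: str
    condition: tuple[str, float] | None = None


@dataclass(frozen=True)
class ManagementPlan:
    sowing_doy: int
    applications: tuple[NApplication, ...]
    co2: float = 380.0
    n_tag: str = "tpe"
    sowing_tag: str = "tpe"


@dataclass
class CropParameters:
    """Concrete trait values consumed by the surrogate model (Hartog defaults)."""

    tt_emergence: float = 150.0  # degCd sowing -> emergence
    tt_end_of_juvenile: float = 555.0  # degCd emergence -> floral initiation
    tt_floral_initiation: float = 400.0  # degCd floral initiation -> flowering
    tt_start_grain_fill: float = 120.0  # degCd flowering -> grain fill
    tt_grain_fill: float = 545.0  # degCd grain-fill duration
    photop_sens: float = 3.0
    vern_sens: float = 1.5
    rue: float = 1.24  # g/MJ
    extinct_coef: float = 0.42
    sla: float = 0.0235  # m2 leaf per g leaf
    transp_eff_cf: float = 0.006  # kPa (TE = cf/VPD g biomass per g water)
    ll_modifier: float = 1.0  # >1 deepens root water extraction below LL
    grains_per_gram_stem: float = 25.0
    potential_grain_filling_rate: float = 7.0e-5  # g/grain/degCd
    max_grain_size: float = 0.041  # g
    frac_pod: float = 0.30
    co2_rue_modifier: float = 0.25  # fractional RUE response per unit rel. CO2
    senescence_rate: float = 0.0025  # /day baseline green-area decay
    sw_demand_threshold: float = 1.1  # supply/demand ratio below which expansion slows
    temp_grain_fill: Curve = field(
        default_factory=lambda: Curve((0.0, 10.0, 15.0, 25.0, 35.0),
                                      (0.0, 0.5, 1.0, 1.0, 0.0)))
    temp_grain_n_fill: Curve = field(
        default_factory=lambda: Curve((0.0, 10.0, 15.0, 25.0, 40.0),
                                      (0.0, 0.6, 1.0, 1.0, 0.0)))
    co2_te_curve: Curve = field(
        default_factory=lambda: Curve((350.0, 700.0), (1.0, 1.37)))

    @classmethod
    def from_genotype(cls, genotype: VirtualGenotype) -> "CropParameters":
        """Map materialized registry values onto the simulator's traits.

        Registry parameters absent from the genotype keep their Hartog
        defaults; inert registry entries are simply never read here, which
        is what makes them true null controls in the screen.
        """
        v = genotype.values
        p = cls()

        def scalar(name: str, attr: str) -> None:
            if name in v:
                setattr(p, attr, float(v[name]))  # type: ignore[arg-type]

        scalar("tt_end_of_juvenile", "tt_end_of_juvenile")
        scalar("tt_floral_initiation", "tt_floral_initiation")
        scalar("tt_start_grain_fill", "tt_start_grain_fill")
        scalar("photop_sens", "photop_sens")
        scalar("vern_sens", "vern_sens")
        scalar("transp_eff_cf", "transp_eff_cf")
        scalar("ll_modifier", "ll_modifier")
        scalar("grains_per_gram_stem", "grains_per_gram_stem")
        scalar("potential_grain_filling_rate", "potential_grain_filling_rate")
        scalar("max_grain_size", "max_grain_size")
        scalar("co2_rue_modifier", "co2_rue_modifier")
        scalar("senescence_rate", "senescence_rate")
        if "y_rue" in v:
            p.rue = float(v["y_rue"].y[0])  # type: ignore[union-attr]
        if "y_extinct_coef" in v:
            p.extinct_coef = float(v["y_extinct_coef"].y[0])  # type: ignore[union-attr]
        if "y_sla" in v:
            c: Curve = v["y_sla"]  # type: ignore[assignment]
            p.sla = float(sum(c.y) / len(c.y))
        if "y_frac_pod" in v:
            p.frac_pod = float(v["y_frac_pod"].y[0])  # type: ignore[union-attr]
        if "x_temp_grain_fill" in v:
            p.temp_grain_fill = v["x_temp_grain_fill"]  # type: ignore[assignment]
        if "x_temp_grain_n_filling" in v:
            p.temp_grain_n_fill = v["x_temp_grain_n_filling"]  # type: ignore[assignment]
        if "y_co2_te_modifier" in v:
            p.co2_te_curve = v["y_co2_te_modifier"]  # type: ignore[assignment]
        if "x_sw_demand_ratio" in v:
            p.sw_demand_threshold = float(v["x_sw_demand_ratio"].x[1])  # type: ignore[union-attr]
        return p


@dataclass
class CropOutputs:
    """The eight integrated outputs plus seasonal stress indices for one run."""

    flowering_das: int
    maturity_das: int
    lai_flowering: float
    biomass: float  # t/ha at maturity
    grain_number: float  # grains/m2
    grain_size: float  # g/grain
    grain_protein: float  # %
    yield_t_ha: float
    water_stress_index: float  # 0 (none) .. 1 (extreme)
    n_stress_index: float
    failed: bool = False
    # audit and analysis extras (not part of the 8 screened outputs)
    veg_stress: float = 0.0  # mean water deficit (1 - supply/demand), emergence->flowering
    grainfill_stress: float = 0.0  # same, flowering->maturity
    carbon_gain: float = 0.0  # g/m2 cumulative growth, for the carbon audit
    water_balance_error: float = 0.0  # mm, season closure residual
    stress_trajectory: np.ndarray | None = None
    flowering_index: int | None = None

    OUTPUT_NAMES = ("flowering_das", "maturity_das", "lai_flowering", "biomass",
                    "grain_number", "grain_size", "grain_protein", "yield_t_ha")

    def as_dict(self) -> dict[str, float]:
        d = {k: getattr(self, k) for k in self.OUTPUT_NAMES}
        d["water_stress_index"] = self.water_stress_index
        d["n_stress_index"] = self.n_stress_index
        d["failed"] = float(self.failed)
        return d


# phase codes
_PRE_EMERG, _JUVENILE, _SPIKE, _LAG, _GRAINFILL, _MATURE = range(6)

# shoot partitioning fractions to leaf by phase (rest to stem, pod share
# taken out during head growth)
_LEAF_FRAC = {_JUVENILE: 0.40, _SPIKE: 0.20, _LAG: 0.0, _GRAINFILL: 0.0}


def run_crop(
    params: CropParameters,
    weather: Weather,
    soil: SoilProfile,
    management: ManagementPlan,
    start_year: int | None = None,
    keep_trajectory: bool = False,
) -> CropOutputs:
    """Run one sowing-to-maturity season and integrate the screened outputs.

    The daily loop advances development, the soil water balance, growth,
    nitrogen and grain state; the seasonal stress indices are the complements
    of the mean daily water supply/demand ratio and of the mean daily N
    photosynthesis factor over emergence to maturity.  A crop that fails to
    mature within the weather record is returned with ``failed=True`` and
    zero yield.
    """
    p = params
    year = int(start_year if start_year is not None else weather.year[0])
    d0 = weather.index_of(year, management.sowing_doy)
    ndays = len(weather)

    # soil state (per-layer mm); effective lower limit shifted by ll_modifier
    sw = soil.initial_layer_water()
    nlay = len(sw)
    ll_mm = [l * t for l, t in zip(soil.ll, soil.thickness)]
    dul_mm = [d * t for d, t in zip(soil.dul, soil.thickness)]
    ll_eff = [lm - (p.ll_modifier - 1.0) * 0.5 * (dm - lm)
              for lm, dm in zip(ll_mm, dul_mm)]
    depth_cum = np.cumsum(soil.thickness)

    soil_n = soil.initial_no3 * KG_HA_TO_G_M2  # g/m2 mineral N
    crop_n = 0.0

    phase = _PRE_EMERG
    cum_tt = 0.0
    cum_vd = 0.0
    root_depth = 50.0
    lai = 0.0
    biomass = 0.0
    leaf_bio = stem_bio = pod_bio = 0.0
    grain_mass = grain_no = grain_n = 0.0
    reserve = 0.0
    carbon_gain = 0.0
    flowering_das = maturity_das = -1
    flowering_idx = -1
    lai_flowering = 0.0

    sum_ratio = 0.0
    sum_fn = 0.0
    n_stress_days = 0
    veg_sum = veg_n = gf_sum = gf_n = 0
    traj: list[float] = []

    cum_rain = 0.0
    sum_transp = sum_evap = sum_drain = sum_rain = 0.0
    sw0_total = sum(sw)

    pending = list(management.applications)
    applied_stages: set[str] = set()
    f_co2_rue = 1.0 + p.co2_rue_modifier * (management.co2 - 350.0) / 350.0
    f_co2_te = p.co2_te_curve(management.co2)

    targets = {
        _PRE_EMERG: p.tt_emergence,
        _JUVENILE: p.tt_end_of_juvenile,
        _SPIKE: p.tt_floral_initiation,
        _LAG: p.tt_start_grain_fill,
        _GRAINFILL: p.tt_grain_fill,
    }

    def paw() -> float:
        return sum(max(0.0, w - lm) for w, lm in zip(sw, ll_mm))

    def trigger(stage: str) -> None:
        nonlocal soil_n
        for app in [a for a in pending if a.stage == stage]:
            ok = True
            if app.condition is not None:
                kind, thresh = app.condition
                if kind == "rain_gt":
                    ok = cum_rain > thresh
                elif kind == "paw_frac_gt":
                    ok = paw() > thresh * soil.pawc
                elif kind == "paw_gt":
                    ok = paw() > thresh
                else:
                    raise ValueError(f"unknown N condition {kind!r}")
            if ok:
                soil_n += app.amount * KG_HA_TO_G_M2
            pending.remove(app)
        applied_stages.add(stage)

    trigger("sowing")

    for d in range(d0, ndays):
        das = d - d0
        tmin = float(weather.mint[d])
        tmax = float(weather.maxt[d])
        radn = float(weather.radn[d])
        rain = float(weather.rain[d])
        dl = float(weather.daylength[d])
        tmean = 0.5 * (tmin + tmax)

        # --- development -------------------------------------------------
        tt = max(0.0, _interp(tmean, DEV_TEMP_X, DEV_TEMP_Y))
        if phase in (_JUVENILE, _SPIKE):
            fp = 1.0 - 0.002 * p.photop_sens * (20.0 - dl) ** 2
            fp = min(1.0, max(0.0, fp))
            if cum_vd < 50.0 and -5.0 < tmean < 15.0:
                cum_vd = min(50.0, cum_vd + max(0.0, min(1.0, (15.0 - tmean) / 12.5)))
            fv = 1.0 - (0.0054545 * p.vern_sens + 0.0003) * (50.0 - cum_vd)
            fv = min(1.0, max(0.0, fv))
            dtt = tt * fp * (fv if phase == _JUVENILE else 1.0)
        else:
            dtt = tt
        cum_tt += dtt

        # --- water in: infiltration, drainage, soil evaporation ----------
        cum_rain += rain
        sum_rain += rain
        inflow = rain
        for i in range(nlay):
            sw[i] += inflow
            inflow = max(0.0, sw[i] - dul_mm[i])
            sw[i] = min(sw[i], dul_mm[i])
        sum_drain += inflow

        cover = 1.0 - math.exp(-p.extinct_coef * lai) if lai > 0 else 0.0
        air_dry = 0.5 * ll_mm[0]
        es = min(max(0.0, sw[0] - air_dry), 1.5 * (1.0 - cover))
        sw[0] -= es
        sum_evap += es

        if phase == _PRE_EMERG:
            if cum_tt >= targets[_PRE_EMERG]:
                phase = _JUVENILE
                cum_tt = 0.0
                lai = 0.05
                biomass = leaf_bio = 2.0  # seed reserve as initial gain
                carbon_gain += 2.0
                crop_n = 0.08
            continue
        if phase == _MATURE:
            break

        # --- crop N status ------------------------------------------------
        ncrit = {_JUVENILE: 0.025, _SPIKE: 0.022, _LAG: 0.018, _GRAINFILL: 0.014}[phase]
        nmin = 0.5 * ncrit
        nconc = crop_n / biomass if biomass > 0 else ncrit
        f_n = min(1.0, max(0.0, (nconc - nmin) / (ncrit - nmin)))

        # --- potential growth and water demand ---------------------------
        day_vpd = vpd(tmin, tmax)
        db_pot = p.rue * radn * cover * f_n * f_co2_rue
        te_mm = 1000.0 * p.transp_eff_cf * f_co2_te / day_vpd  # g/m2 per mm
        demand = db_pot / te_mm if te_mm > 0 else 0.0

        # --- supply and transpiration ------------------------------------
        supply = 0.0
        avail = [0.0] * nlay
        for i in range(nlay):
            if depth_cum[i] - soil.thickness[i] < root_depth:
                frac = min(1.0, (root_depth - (depth_cum[i] - soil.thickness[i]))
                           / soil.thickness[i])
                avail[i] = max(0.0, sw[i] - ll_eff[i]) * frac
                supply += soil.kl[i] * avail[i]
        if demand > 1e-12:
            transp = min(supply, demand)
            ratio = min(1.0, supply / demand)
        else:
            transp = 0.0
            ratio = 1.0
        if transp > 0 and supply > 0:
            for i in range(nlay):
                sw[i] -= transp * (soil.kl[i] * avail[i]) / supply
        sum_transp += transp

        sum_ratio += ratio
        sum_fn += f_n
        n_stress_days += 1
        if keep_trajectory:
            traj.append(1.0 - ratio)
        if phase in (_JUVENILE, _SPIKE):
            veg_sum += 1.0 - ratio
            veg_n += 1
        else:
            gf_sum += 1.0 - ratio
            gf_n += 1

        # --- actual growth and partitioning ------------------------------
        db = db_pot * ratio  # = min(RUE-limited, TE-limited supply*te)
        biomass += db
        carbon_gain += db
        if phase in (_JUVENILE, _SPIKE):
            leaf_frac = _LEAF_FRAC[phase]
            pod_frac = p.frac_pod if phase == _SPIKE else 0.0
            d_leaf = db * leaf_frac
            leaf_bio += d_leaf
            pod_bio += db * pod_frac
            stem_bio += db * (1.0 - leaf_frac - pod_frac)
            f_exp = _interp(ratio, (0.1, p.sw_demand_threshold), (0.0, 1.0))
            lai += d_leaf * p.sla * f_exp
        elif phase == _LAG:
            pod_bio += db * p.frac_pod
            stem_bio += db * (1.0 - p.frac_pod)

        # --- nitrogen uptake ----------------------------------------------
        soil_n += 0.003  # background mineralization, g/m2/day
        n_demand = max(0.0, ncrit * biomass - crop_n)
        uptake = min(n_demand, 0.15 * soil_n, 0.25 * ratio + 0.02)
        soil_n -= uptake
        crop_n += uptake

        # --- grain filling -------------------------------------------------
        if phase == _GRAINFILL and grain_no > 0:
            f_tgf = p.temp_grain_fill(tmean)
            pot_fill = p.potential_grain_filling_rate * grain_no * tt * f_tgf
            pot_fill = min(pot_fill, grain_no * p.max_grain_size - grain_mass)
            draw = min(reserve, max(0.0, pot_fill - db))
            fill = min(pot_fill, db + draw)
            from_reserve = max(0.0, fill - db)
            reserve -= from_reserve
            stem_bio -= from_reserve
            stem_bio += max(0.0, db - fill)  # surplus assimilate back to stem
            grain_mass += fill
            f_tn = p.temp_grain_n_fill(tmean)
            n_demand_grain = fill * GRAIN_N_CONC * f_tn
            n_avail = 0.05 * crop_n
            dn = min(n_demand_grain, n_avail)
            grain_n += dn
            crop_n -= dn

        # --- senescence (green area only; dead matter stays in biomass) ---
        if phase in (_LAG, _GRAINFILL):
            age = 2.0 if phase == _GRAINFILL else 1.0
            lai = max(0.0, lai - lai * p.senescence_rate * age
                      * (1.0 + 3.0 * (1.0 - ratio)))

        # --- root growth and phase transitions ----------------------------
        if phase in (_JUVENILE, _SPIKE):
            root_depth = min(soil.depth, root_depth + 1.5 * tt)

        if cum_tt >= targets[phase]:
            cum_tt = 0.0
            if phase == _JUVENILE:
                phase = _SPIKE
                trigger("end_of_tillering")
            elif phase == _SPIKE:
                phase = _LAG
                flowering_das = das
                flowering_idx = len(traj)
                lai_flowering = lai
                grain_no = p.grains_per_gram_stem * stem_bio
                reserve = 0.25 * stem_bio
                trigger("mid_stem_elongation")
            elif phase == _LAG:
                phase = _GRAINFILL
            elif phase == _GRAINFILL:
                phase = _MATURE
                maturity_das = das
                break

    failed = phase != _MATURE or flowering_das < 0
    if failed:
        grain_mass = 0.0
        maturity_das = max(flowering_das + 1, ndays - d0 - 1)

    days = max(1, n_stress_days)
    water_idx = min(1.0, max(0.0, 1.0 - sum_ratio / days))
    n_idx = min(1.0, max(0.0, 1.0 - sum_fn / days))
    grain_size = grain_mass / grain_no if grain_no > 0 else 0.0
    protein = 100.0 * N_TO_PROTEIN * grain_n / grain_mass if grain_mass > 0 else 0.0

    balance = (sw0_total + sum_rain) - (sum(sw) + sum_transp + sum_evap + sum_drain)

    return CropOutputs(
        flowering_das=flowering_das,
        maturity_das=maturity_das,
        lai_flowering=lai_flowering,
        biomass=biomass / 100.0,
        grain_number=grain_no,
        grain_size=grain_size,
        grain_protein=protein,
        yield_t_ha=grain_mass / 100.0,
        water_stress_index=water_idx,
        n_stress_index=n_idx,
        failed=failed,
        veg_stress=veg_sum / veg_n if veg_n else 0.0,
        grainfill_stress=gf_sum / gf_n if gf_n else 0.0,
        carbon_gain=carbon_gain,
        water_balance_error=balance,
        stress_trajectory=np.array(traj) if keep_trajectory else None,
        flowering_index=flowering_idx if keep_trajectory else None,
    )
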