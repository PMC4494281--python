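"""Reduced-order daily pasture growth, quality, soil water and nitrogen model.

A single-bucket soil and a two-pool (green/dead) sward stand in for a full
biophysical pasture engine.  The structure keeps the limiting-factor view of
pasture growth — temperature, water and nitrogen can each cap daily growth —
with C3 (phalaris/subclover) and C4 (kikuyu/subclover) parameterisations.
Nitrogen enters through legume fixation, excreta and litter; it leaves by
leaching, ammonia volatilisation from urine, denitrification, animal
retention and herbage removal.

Units: biomass t DM/ha (fluxes kg DM/ha/d), water mm, nitrogen kg N/ha.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .climate import DailyWeather, saturation_vapour_pressure

KG_PER_T = 1000.0


@dataclass
class SpeciesParams:
    """Pasture sward parameters (sward = grass + legume companion).

    ``rue`` is an effective radiation-use efficiency on total incident solar
    radiation (g DM/MJ) at full cover; light interception follows a Beer-law
    saturation on green biomass.
    """

    pathway: str  # "C3" | "C4"
    rue: float  # g DM/MJ total solar at full cover
    t_base: float
    t_opt: float
    t_max: float
    max_growth: float  # kg DM/ha/d ceiling
    senescence_rate: float  # fraction of green /d
    digestibility_new: float  # % of DM for fresh growth
    digestibility_floor: float  # % of DM, aged green asymptote
    quality_decay: float  # % digestibility /d of standing green
    legume_fraction: float  # fraction of growth that is legume
    fixation_coeff: float  # kg N fixed per kg legume DM grown
    n_new: float = 3.0  # % N of new growth DM
    dead_digestibility: float = 45.0
    dead_decay: float = 0.012  # fraction of dead to litter /d
    cover_scale: float = 0.9  # t DM/ha for ~63% light interception
    me_slope: float = 1.0 / 6.0  # MJ ME per kg DM per % digestibility
    me_intercept: float = -0.3
    water_stress_frac: float = 0.45  # soil fill fraction below which growth declines
    n_half_sat: float = 8.0  # kg N/ha mineral-N half saturation

    def __post_init__(self) -> None:
        if not (self.t_base < self.t_opt < self.t_max):
            raise ValueError("cardinal temperatures must satisfy t_base < t_opt < t_max")
        if not (self.digestibility_floor < self.digestibility_new <= 85.0):
            raise ValueError("digestibility_floor < digestibility_new <= 85 required")
        for frac in (self.senescence_rate, self.legume_fraction, self.dead_decay):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")


@dataclass
class SoilParams:
    capacity: float  # mm plant-available water
    k_mineralisation: float = 3.0e-4  # /d organic -> mineral
    k_denit: float = 0.010  # /d of mineral N at full wfps/temp factors
    wfps_anaerobic: float = 0.6  # wfps threshold for denitrification
    wfps_at_capacity: float = 0.9  # wfps when the bucket is full
    leach_eff: float = 0.5  # efficiency of mineral-N export with drainage
    urine_volat_frac: float = 0.10  # fraction of urine N volatilised
    et_fill_frac: float = 0.5  # soil fill fraction below which ET declines


@dataclass
class SoilState:
    water: float  # mm
    mineral_n: float  # kg N/ha
    organic_n: float  # kg N/ha

    def __post_init__(self) -> None:
        if self.water < 0 or self.mineral_n < 0 or self.organic_n < 0:
            raise ValueError("soil pools must be non-negative")


@dataclass
class SwardState:
    """Paddock herbage: green and dead pools with quality and N content."""

    green: float  # t DM/ha
    dead: float  # t DM/ha
    green_digestibility: float  # % of DM
    green_n: float  # kg N/ha in green herbage
    dead_n: float  # kg N/ha in dead herbage

    @property
    def biomass(self) -> float:
        return self.green + self.dead


@dataclass(frozen=True)
class WaterFluxes:
    rain: float
    et: float
    drainage: float


@dataclass(frozen=True)
class NFluxes:
    fixation: float
    mineralisation: float
    leach_n: float
    volat_n: float
    denit_n: float
    litter_n: float


def wfps(soil: SoilState, sp: SoilParams) -> float:
    """Water-filled pore space proxy: bucket fill scaled by drainage class."""
    if sp.capacity <= 0:
        return 0.0
    return min(1.0, soil.water / sp.capacity) * sp.wfps_at_capacity


def potential_et(w: DailyWeather) -> float:
    """Radiation-temperature (Makkink-type) potential evapotranspiration, mm/d."""
    t = w.tmean
    delta = 4098.0 * saturation_vapour_pressure(t) / (t + 237.3) ** 2
    gamma = 0.066
    return max(0.0, 0.65 * delta / (delta + gamma) * w.radiation / 2.45)


def update_soil_water(soil: SoilState, w: DailyWeather, sp: SoilParams
                      ) -> tuple[SoilState, WaterFluxes]:
    """Daily bucket water balance: water' = clamp(water + rain - et - drainage).

    ET is potential ET scaled down once the bucket falls below
    ``et_fill_frac`` of capacity; drainage is the overflow above capacity.
    The returned fluxes close the balance exactly.
    """
    pet = potential_et(w)
    stress = min(1.0, soil.water / max(1e-9, sp.et_fill_frac * sp.capacity))
    et = min(pet * stress, soil.water + w.rain)
    water = soil.water + w.rain - et
    drainage = max(0.0, water - sp.capacity)
    water -= drainage
    return replace(soil, water=water), WaterFluxes(w.rain, et, drainage)


def temperature_factor(tmean: float, sp: SpeciesParams) -> float:
    """Piecewise hat on the cardinal temperatures, in [0, 1]."""
    if tmean <= sp.t_base or tmean >= sp.t_max:
        return 0.0
    if tmean <= sp.t_opt:
        return (tmean - sp.t_base) / (sp.t_opt - sp.t_base)
    return (sp.t_max - tmean) / (sp.t_max - sp.t_opt)


def water_factor(soil: SoilState, soil_p: SoilParams, sp: SpeciesParams) -> float:
    return min(1.0, soil.water / max(1e-9, sp.water_stress_frac * soil_p.capacity))


def nitrogen_factor(soil: SoilState, sp: SpeciesParams) -> float:
    return soil.mineral_n / (soil.mineral_n + sp.n_half_sat)


def daily_growth(sward: SwardState, soil: SoilState, w: DailyWeather,
                 sp: SpeciesParams, soil_p: SoilParams) -> float:
    """Daily herbage growth, kg DM/ha/d.

    growth = RUE x radiation x light interception x min(f_temp, f_water, f_N),
    bounded by [0, max_growth].
    """
    f_t = temperature_factor(w.tmean, sp)
    f_w = water_factor(soil, soil_p, sp)
    f_n = nitrogen_factor(soil, sp)
    cover = 1.0 - math.exp(-max(0.0, sward.green) / sp.cover_scale)
    growth = sp.rue * w.radiation * 10.0 * cover * min(f_t, f_w, f_n)
    return min(max(0.0, growth), sp.max_growth)


def me_from_digestibility(d: float, sp: SpeciesParams) -> float:
    """Affine digestibility (% DM) -> ME (MJ/kg DM) map."""
    return sp.me_slope * d + sp.me_intercept


def age_and_senesce(sward: SwardState, growth: float, sp: SpeciesParams,
                    growth_n: float | None = None
                    ) -> tuple[SwardState, float, float]:
    """Apply quality decay, add new growth, transfer senesced green to dead.

    Standing green digestibility decays linearly by ``quality_decay`` %/d
    toward ``digestibility_floor``; new growth enters at
    ``digestibility_new``.  ``growth_n`` is the N actually acquired with
    today's growth (fixation + soil uptake, kg N/ha); when omitted the
    nominal tissue N content is assumed.  Returns the updated sward, the
    litter DM flux (kg DM/ha/d) lost from the dead pool and the litter N
    flux (kg N/ha/d) that accompanies it (destined for the soil organic
    pool).
    """
    g_t = growth / KG_PER_T
    aged_d = max(sp.digestibility_floor, sward.green_digestibility - sp.quality_decay)
    green_total = sward.green + g_t
    if green_total > 1e-12:
        digest = (aged_d * sward.green + sp.digestibility_new * g_t) / green_total
    else:
        digest = sp.digestibility_new
    if growth_n is None:
        growth_n = growth * sp.n_new / 100.0  # nominal kg N/ha in today's growth
    green_n = sward.green_n + growth_n

    senesced = sp.senescence_rate * green_total
    sen_n = sp.senescence_rate * green_n
    green = green_total - senesced
    green_n -= sen_n

    litter = sp.dead_decay * sward.dead  # t DM/ha
    litter_n = sp.dead_decay * sward.dead_n
    dead = sward.dead - litter + senesced
    dead_n = sward.dead_n - litter_n + sen_n
    out = SwardState(green=green, dead=dead, green_digestibility=digest,
                     green_n=green_n, dead_n=dead_n)
    return out, litter * KG_PER_T, litter_n


def denit_temperature_factor(tmean: float) -> float:
    return min(1.0, max(0.0, (tmean - 2.0) / 23.0))


def nitrogen_cycle(soil: SoilState, growth: float, fluxes: WaterFluxes,
                   w: DailyWeather, sp: SpeciesParams, soil_p: SoilParams,
                   urine_n: float = 0.0, dung_n: float = 0.0,
                   litter_n: float = 0.0) -> tuple[SoilState, NFluxes]:
    """Daily soil-N update.  All arguments in kg N/ha/d.

    Fixation (legume share of growth x fixation coefficient) is credited to
    the sward by the caller; here it is reported as the system N input.
    Plant uptake is handled by the caller (it depends on how much of the
    growth N demand fixation meets).  Urine N volatilises partially at
    deposition, the remainder joins the mineral pool; dung and litter N join
    the organic pool.  Losses: leaching (with drainage), denitrification
    (above an anaerobic wfps threshold, temperature-scaled).
    """
    legume_growth = sp.legume_fraction * growth
    fixation = legume_growth * sp.fixation_coeff

    volat = soil_p.urine_volat_frac * urine_n
    mineral = soil.mineral_n + urine_n - volat
    organic = soil.organic_n + dung_n + litter_n

    mineralised = soil_p.k_mineralisation * organic
    organic -= mineralised
    mineral += mineralised

    leach = 0.0
    if fluxes.drainage > 0.0 and soil_p.capacity > 0.0:
        leach = mineral * min(1.0, soil_p.leach_eff * fluxes.drainage / soil_p.capacity)
    mineral -= leach

    f_w = wfps(soil, soil_p)
    if f_w > soil_p.wfps_anaerobic:
        f_wfps = (f_w - soil_p.wfps_anaerobic) / (1.0 - soil_p.wfps_anaerobic)
    else:
        f_wfps = 0.0
    denit = soil_p.k_denit * mineral * f_wfps * denit_temperature_factor(w.tmean)
    mineral -= denit

    out = SoilState(water=soil.water, mineral_n=max(0.0, mineral),
                    organic_n=max(0.0, organic))
    return out, NFluxes(fixation, mineralised, leach, volat, denit, litter_n)


def plant_uptake(soil: SoilState, growth: float, fixation: float,
                 sp: SpeciesParams) -> tuple[SoilState, float]:
    """Withdraw the soil share of growth-N demand from the mineral pool.

    Demand = growth x n_new minus what fixation supplies; bounded by the
    mineral pool.  Returns the updated soil and the soil-N actually taken up.
    """
    demand = max(0.0, growth * sp.n_new / 100.0 - fixation)
    uptake = min(demand, soil.mineral_n)
    return replace(soil, mineral_n=soil.mineral_n - uptake), uptake
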