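"""Grazing management: rotation, surplus cutting, silage pool, supplementation
and carrying-capacity estimation.

The herd rotates around four paddocks so standing biomass stays between the
species residual (0.5 t DM/ha phalaris, 1.0 t DM/ha kikuyu) and 2.5 t DM/ha.
In supplemented runs, paddocks reaching 2.5 t DM/ha are flagged for cutting,
executed at 3.5 t DM/ha with 10% wastage; the conserved grass enters a silage
pool with a 12-month shelf life and is fed back (oldest lot first), topped up
with bought-in grain, whenever pasture leaves an ME deficit or the cow drops
below its 450 kg floor.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

from .herd import EnergyParams

SILAGE_SHELF_DAYS = 365


@dataclass
class ManagementRules:
    residual: float  # t DM/ha not grazed below
    upper_bound: float = 2.5  # grazing band ceiling, t DM/ha
    cut_assign: float = 2.5  # flag paddock for cutting, t DM/ha
    cut_execute: float = 3.5  # cut when flagged paddock reaches this
    post_cut: float = 2.0  # biomass left after a cut, t DM/ha
    cut_wastage: float = 0.10
    cow_lw_floor: float = 450.0  # kg
    silage_shelf_months: int = 12
    supplement_me: float = 10.5  # MJ/kg DM (10.0 for the kikuyu site)
    supplement_n: float = 2.5  # % of DM (2.0 for the kikuyu site)
    n_paddocks: int = 4
    cutting_enabled: bool = True

    def __post_init__(self) -> None:
        if not (self.residual < self.upper_bound <= self.cut_execute):
            raise ValueError("require residual < upper_bound <= cut_execute")
        if not 0.0 <= self.cut_wastage < 1.0:
            raise ValueError("cut_wastage must lie in [0, 1)")


@dataclass
class SilageLot:
    harvest_date: dt.date
    mass: float  # t DM
    me: float  # MJ/kg DM
    n: float  # % of DM


@dataclass
class SilagePool:
    lots: list[SilageLot] = field(default_factory=list)
    harvested: float = 0.0  # t DM, cumulative (post-wastage)
    fed: float = 0.0
    expired: float = 0.0

    @property
    def mass(self) -> float:
        return sum(lot.mass for lot in self.lots)


@dataclass
class CapacityConfig:
    steer_lw: float = 500.0
    steer_requirement: float = 67.5  # MJ/d incl. activity
    conversion: float = 1.5  # cow+calf units per steer-equivalent
    run_years: int = 20
    discard_years: int = 5
    rounding: float = 0.1  # cows/ha

    def __post_init__(self) -> None:
        if min(self.steer_lw, self.steer_requirement, self.conversion,
               self.run_years, self.rounding) <= 0:
            raise ValueError("capacity parameters must be positive")
        if self.discard_years >= self.run_years:
            raise ValueError("discard_years must be < run_years")


def rotate(biomasses: list[float], current: int | None, rules: ManagementRules
           ) -> int | None:
    """Pick today's grazed paddock.

    The herd stays on its paddock until it is eaten down to the residual,
    then moves to the paddock with the most biomass above the residual.
    Returns None (no grazable pasture) when every paddock is at or below the
    residual.
    """
    eps = 1e-9
    if current is not None and biomasses[current] > rules.residual + eps:
        return current
    best = max(range(len(biomasses)), key=lambda i: biomasses[i])
    if biomasses[best] > rules.residual + eps:
        return best
    return None


@dataclass
class CutResult:
    lot: SilageLot
    cut_dm: float  # t DM/ha removed from the paddock (pre-wastage)


def cut_surplus(biomass: float, flagged: bool, rules: ManagementRules,
                date: dt.date, area_ha: float = 1.0
                ) -> tuple[CutResult | None, bool]:
    """Surplus-cutting state machine for one paddock.

    A paddock is flagged once biomass reaches ``cut_assign``; when a flagged
    paddock reaches ``cut_execute`` it is cut back to ``post_cut`` and the
    harvested mass (less wastage) becomes a silage lot.  Returns the cut (or
    None) and the updated flag.
    """
    if not rules.cutting_enabled:
        return None, False
    if biomass >= rules.cut_assign:
        flagged = True
    if flagged and biomass >= rules.cut_execute:
        cut_dm = biomass - rules.post_cut
        lot = SilageLot(harvest_date=date, mass=cut_dm * (1.0 - rules.cut_wastage) * area_ha,
                        me=rules.supplement_me, n=rules.supplement_n)
        return CutResult(lot=lot, cut_dm=cut_dm), False
    return None, flagged


@dataclass(frozen=True)
class SupplementDraw:
    silage_dm: float  # kg DM for the herd today
    grain_dm: float
    me: float  # MJ supplied
    n_kg: float  # kg N fed


def supplement(deficit_mj: float, dmi_headroom_kg: float, pool: SilagePool,
               rules: ManagementRules, cow_below_floor: bool) -> SupplementDraw:
    """Fill an ME deficit from silage (oldest lot first) then bought-in grain.

    Feeding happens when there is a deficit or the cow is below its LW floor;
    total DM stays within the intake headroom left by pasture.  Pool lots are
    mutated in place; grain is unlimited at the configured fixed quality.
    """
    if deficit_mj <= 0.0 and not cow_below_floor:
        return SupplementDraw(0.0, 0.0, 0.0, 0.0)
    need = max(0.0, deficit_mj)
    headroom = max(0.0, dmi_headroom_kg)
    silage_kg = 0.0
    me = 0.0
    n_kg = 0.0
    for lot in sorted(pool.lots, key=lambda l: l.harvest_date):
        if need <= 1e-9 or headroom <= 1e-9:
            break
        want_kg = min(need / lot.me, headroom, lot.mass * 1000.0)
        if want_kg <= 0.0:
            continue
        lot.mass -= want_kg / 1000.0
        pool.fed += want_kg / 1000.0
        silage_kg += want_kg
        me += want_kg * lot.me
        n_kg += want_kg * lot.n / 100.0
        need -= want_kg * lot.me
        headroom -= want_kg
    pool.lots = [l for l in pool.lots if l.mass > 1e-9]
    grain_kg = 0.0
    if need > 1e-9 and headroom > 1e-9:
        grain_kg = min(need / rules.supplement_me, headroom)
        me += grain_kg * rules.supplement_me
        n_kg += grain_kg * rules.supplement_n / 100.0
    return SupplementDraw(silage_kg, grain_kg, me, n_kg)


def expire_silage(pool: SilagePool, date: dt.date) -> list[SilageLot]:
    """Remove lots harvested more than twelve months ago; returns removals."""
    cutoff = SILAGE_SHELF_DAYS
    removed = [l for l in pool.lots if (date - l.harvest_date).days > cutoff]
    pool.lots = [l for l in pool.lots if (date - l.harvest_date).days <= cutoff]
    pool.expired += sum(l.mass for l in removed)
    return removed


def estimate_carrying_capacity(site, met, cc: CapacityConfig,
                               p: EnergyParams | None = None) -> float:
    """Long-term carrying capacity, cows/ha (one calf at foot each).

    Steers at constant reference live weight graze a one-hectare paddock;
    each day the (continuous-valued) steer number is set so that their
    summed intake consumes the biomass above the species residual.  The
    run-average steers/ha, divided by the cow+calf conversion, is rounded to
    the configured step.  Implemented by the simulation driver; this wrapper
    keeps the management-facing signature.
    """
    from .simulate import run_capacity  # local import: avoids module cycle

    if len(met) == 0:
        raise ValueError("empty met series")
    mean_steers = run_capacity(site, met, cc, p)
    cows = mean_steers / cc.conversion
    return round(round(cows / cc.rounding) * cc.rounding, 10)
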