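"""Animal energy requirements, intake and live-weight dynamics.

The grazing unit is a beef cow with (seasonally) a single suckling calf,
treated as one metabolizable-energy pool: the cow's maintenance is funded
first, then pregnancy, then the calf's keep (lactation plus calf
maintenance), then calf gain, then cow live-weight recovery toward its
target.  A steer at constant reference live weight is used for carrying
capacity estimation; the cow+calf unit is calibrated so its annualised
unrestricted requirement equals 1.5x the steer reference.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

CALVING_MONTH, CALVING_DAY = 7, 1  # July 1


@dataclass
class EnergyParams:
    maint_coeff: float = 0.58  # MJ/kg^0.75/d
    maint_exponent: float = 0.75
    activity_fraction: float = 0.10
    cow_calf_ratio: float = 1.5  # x steer requirement (annualised)
    max_dmi: float = 16.9  # kg DM/d for the unit
    steer_ref_lw: float = 500.0
    kg_gain_me: float = 40.0  # MJ ME per kg cow LW gain
    kg_loss_me: float = 28.0  # MJ ME released per kg cow LW mobilised
    cow_target_lw: float = 500.0
    recovery_max_gain: float = 0.5  # kg/d regain toward target
    lact_peak: float = 74.0  # MJ/d lactation cost at full milk
    lact_ramp_days: float = 15.0
    preg_peak: float = 30.0  # MJ/d at term
    preg_ramp_days: float = 90.0
    calf_gain_me: float = 15.0  # MJ ME per kg calf gain

    def __post_init__(self) -> None:
        if not 0.0 <= self.activity_fraction <= 0.5:
            raise ValueError("activity_fraction must lie in [0, 0.5]")
        for name in ("maint_coeff", "cow_calf_ratio", "max_dmi", "steer_ref_lw",
                     "kg_gain_me", "kg_loss_me"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class CalfParams:
    birth_lw: float = 28.0  # kg; 28 + 0.6*120 reaches the 100 kg target exactly
    max_gain: float = 0.6  # kg/d
    weaning_age: int = 120  # d
    target_weaning_lw: float = 100.0
    calving_month_day: tuple[int, int] = (CALVING_MONTH, CALVING_DAY)
    calving_rate: float = 1.0
    mortality: float = 0.0

    def __post_init__(self) -> None:
        if self.birth_lw + self.max_gain * self.weaning_age < self.target_weaning_lw:
            raise ValueError("weaning target unreachable at max_gain")


@dataclass
class CowCalfUnit:
    cow_lw: float
    calf_lw: float | None = None
    calf_age: int | None = None
    pregnant: bool = False
    lactating: bool = False

    def __post_init__(self) -> None:
        if self.cow_lw <= 0:
            raise ValueError("cow_lw must be positive")
        if self.calf_age is not None and not 0 <= self.calf_age <= 120:
            raise ValueError("calf_age must lie in [0, 120]")


@dataclass
class EnergyBudget:
    """MJ ME/d demand components. ``lw_change`` is the planned recovery
    demand when positive; realised mobilisation is reported by the
    allocation step, not here."""

    maintenance: float = 0.0
    activity: float = 0.0
    pregnancy: float = 0.0
    lactation: float = 0.0
    calf_growth: float = 0.0
    lw_change: float = 0.0

    @property
    def total_requirement(self) -> float:
        return (self.maintenance + self.activity + self.pregnancy +
                self.lactation + self.calf_growth + max(0.0, self.lw_change))


@dataclass
class Ration:
    pasture_dm: float = 0.0  # kg DM/d
    silage_dm: float = 0.0
    grain_dm: float = 0.0
    me_content: float = 0.0  # MJ/kg DM intake-weighted
    digestibility: float = 0.0  # % intake-weighted
    n_content: float = 0.0  # % of DM intake-weighted
    me_intake: float = 0.0  # MJ/d

    @property
    def total_dm(self) -> float:
        return self.pasture_dm + self.silage_dm + self.grain_dm


class StarvationError(RuntimeError):
    """Cow live weight driven to zero — simulation failure."""


def maintenance_energy(lw: float, p: EnergyParams, with_activity: bool = True) -> float:
    """Maintenance ME requirement: maint_coeff x LW^maint_exponent, +10% activity."""
    if lw < 0:
        raise ValueError("live weight must be non-negative")
    m = p.maint_coeff * lw ** p.maint_exponent
    return m * (1.0 + p.activity_fraction) if with_activity else m


def _days_to_calving(date: dt.date, cp: CalfParams) -> int:
    month, day = cp.calving_month_day
    calving = dt.date(date.year, month, day)
    if calving < date:
        calving = dt.date(date.year + 1, month, day)
    return (calving - date).days


def pregnancy_energy(date: dt.date, p: EnergyParams, cp: CalfParams) -> float:
    """Linear ramp from 0 to preg_peak over the last preg_ramp_days of gestation."""
    d = _days_to_calving(date, cp)
    if d > p.preg_ramp_days:
        return 0.0
    return p.preg_peak * (1.0 - d / p.preg_ramp_days)


def lactation_energy(calf_age: int, p: EnergyParams, cp: CalfParams) -> float:
    if calf_age is None or calf_age > cp.weaning_age:
        return 0.0
    shape = min(1.0, calf_age / p.lact_ramp_days) if p.lact_ramp_days > 0 else 1.0
    return p.lact_peak * shape


def cow_calf_requirement(unit: CowCalfUnit, p: EnergyParams, cp: CalfParams,
                         date: dt.date, with_activity: bool = True) -> EnergyBudget:
    """Daily ME demand budget for the cow(+calf) unit.

    Lactation and calf components are present only while a calf under
    weaning age is at foot; pregnancy ramps toward the July 1 calving.
    A live-weight recovery demand is added while the cow is below target.
    """
    maint = maintenance_energy(unit.cow_lw, p, with_activity=False)
    activity = maint * p.activity_fraction if with_activity else 0.0
    preg = pregnancy_energy(date, p, cp) if unit.pregnant else 0.0
    lact = calf = 0.0
    if unit.calf_lw is not None and unit.calf_age is not None and unit.calf_age <= cp.weaning_age:
        lact = lactation_energy(unit.calf_age, p, cp)
        calf = (maintenance_energy(unit.calf_lw, p, with_activity=False)
                + cp.max_gain * p.calf_gain_me)
    recovery = 0.0
    if unit.cow_lw < p.cow_target_lw:
        regain = min(p.recovery_max_gain, p.cow_target_lw - unit.cow_lw)
        recovery = regain * p.kg_gain_me
    return EnergyBudget(maintenance=maint, activity=activity, pregnancy=preg,
                        lactation=lact, calf_growth=calf, lw_change=recovery)


def compute_intake(requirement: float, available_dm_per_head: float,
                   me_content: float, p: EnergyParams) -> float:
    """Pasture DM intake per head, kg DM/d.

    min(requirement/ME, max DMI, herbage available above the paddock
    residual); the residual exclusion is applied by the caller through
    ``available_dm_per_head``.
    """
    if requirement < 0:
        raise ValueError("requirement must be non-negative")
    if available_dm_per_head <= 0.0 or me_content <= 0.0:
        return 0.0
    return min(requirement / me_content, p.max_dmi, available_dm_per_head)


def plan_intake(requirement: float, available_dm_per_head: float,
                me_pasture: float, me_supplement: float, p: EnergyParams
                ) -> tuple[float, float]:
    """Pasture intake when supplement can substitute within the DMI cap.

    Pasture is eaten first, but when the requirement cannot be met inside
    ``max_dmi`` on pasture alone and the supplement is more energy-dense,
    pasture intake is scaled back just far enough that supplement fed into
    the remaining gut fill can close the gap.  Returns (pasture kg DM/d,
    remaining ME deficit to be supplemented).
    """
    p0 = compute_intake(requirement, available_dm_per_head, me_pasture, p)
    if me_supplement > me_pasture > 0.0:
        bound = (p.max_dmi * me_supplement - requirement) / (me_supplement - me_pasture)
        p0 = min(p0, max(0.0, bound))
    return p0, max(0.0, requirement - p0 * me_pasture)


@dataclass(frozen=True)
class Allocation:
    """Realised daily energy allocation (MJ), for conservation bookkeeping."""

    maintenance: float
    pregnancy: float
    keep: float  # lactation + calf maintenance
    gain: float  # calf gain energy funded
    recovery: float  # cow regain energy funded
    cow_lw_delta: float  # kg (negative = mobilisation)
    calf_gain: float  # kg

    @property
    def lw_energy(self) -> float:
        """Energy stored (+) or released (-) by cow LW change, MJ."""
        return self.recovery if self.cow_lw_delta >= 0 else 0.0


def allocate_energy(unit: CowCalfUnit, budget: EnergyBudget, me_intake: float,
                    p: EnergyParams, cp: CalfParams) -> Allocation:
    """Partition today's ME intake across the demand hierarchy.

    Order: cow maintenance+activity, pregnancy, calf keep, calf gain, cow
    recovery.  A shortfall below maintenance is met by mobilising cow live
    weight (kg_loss_me MJ/kg); unfunded lactation dries off rather than
    drawing on body reserves (the calf simply does not gain).
    """
    e = me_intake
    m = budget.maintenance + budget.activity
    if e < m:
        deficit = m - e
        return Allocation(maintenance=m, pregnancy=0.0, keep=0.0, gain=0.0,
                          recovery=0.0, cow_lw_delta=-deficit / p.kg_loss_me,
                          calf_gain=0.0)
    e -= m
    preg = min(e, budget.pregnancy)
    e -= preg
    has_calf = budget.calf_growth > 0.0 or budget.lactation > 0.0
    calf_maint = 0.0
    gain_demand = 0.0
    if has_calf:
        gain_demand = cp.max_gain * p.calf_gain_me
        calf_maint = budget.calf_growth - gain_demand
    keep_demand = budget.lactation + calf_maint
    keep = min(e, keep_demand)
    e -= keep
    gain_e = min(e, gain_demand) if keep >= keep_demand - 1e-9 else 0.0
    e -= gain_e
    calf_gain = cp.max_gain * (gain_e / gain_demand) if gain_demand > 0 else 0.0
    recovery = min(e, max(0.0, budget.lw_change))
    # intake never exceeds the requirement by construction; any residual from
    # supplement granularity also goes to cow LW at gain efficiency
    recovery += max(0.0, e - recovery)
    return Allocation(maintenance=m, pregnancy=preg, keep=keep, gain=gain_e,
                      recovery=recovery, cow_lw_delta=recovery / p.kg_gain_me,
                      calf_gain=calf_gain)


def update_liveweights(unit: CowCalfUnit, alloc: Allocation, cp: CalfParams
                       ) -> tuple[CowCalfUnit, float | None]:
    """Apply an allocation; age the calf; wean at ``weaning_age``.

    Returns the updated unit and the weaning live weight when today is
    weaning day (else None).  Raises :class:`StarvationError` when cow live
    weight is exhausted.
    """
    cow_lw = unit.cow_lw + alloc.cow_lw_delta
    if cow_lw <= 0:
        raise StarvationError("cow live weight exhausted")
    weaned = None
    calf_lw, calf_age, lactating = unit.calf_lw, unit.calf_age, unit.lactating
    if calf_lw is not None and calf_age is not None:
        calf_lw = calf_lw + alloc.calf_gain
        calf_age = calf_age + 1
        if calf_age >= cp.weaning_age:
            weaned = calf_lw
            calf_lw, calf_age, lactating = None, None, False
    return (CowCalfUnit(cow_lw=cow_lw, calf_lw=calf_lw, calf_age=calf_age,
                        pregnant=unit.pregnant, lactating=lactating), weaned)
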