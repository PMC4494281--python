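"""Cow+calf energetics: requirements, intake, allocation, live weights."""

import datetime as dt

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cowcalf.herd import (
    Allocation,
    CalfParams,
    CowCalfUnit,
    EnergyParams,
    StarvationError,
    allocate_energy,
    compute_intake,
    cow_calf_requirement,
    maintenance_energy,
    plan_intake,
    update_liveweights,
)

EP = EnergyParams()
CP = CalfParams()


class TestMaintenance:
    def test_reference_steer_requirement(self):
        assert maintenance_energy(500.0, EP, with_activity=True) == pytest.approx(67.5, abs=0.1)

    def test_zero_liveweight_zero_requirement(self):
        assert maintenance_energy(0.0, EP) == 0.0

    def test_450kg_with_activity(self):
        # 0.58 x 450^0.75 x 1.10
        assert maintenance_energy(450.0, EP, True) == pytest.approx(62.3, abs=0.1)

    def test_negative_liveweight_rejected(self):
        with pytest.raises(ValueError):
            maintenance_energy(-1.0, EP)

    @settings(max_examples=50, deadline=None)
    @given(lw=st.floats(1.0, 900.0), step=st.floats(1.0, 100.0))
    def test_monotone_increasing_and_concave(self, lw, step):
        f = lambda x: maintenance_energy(x, EP)
        assert f(lw + step) > f(lw)
        # concavity: increments shrink
        assert f(lw + step) - f(lw) > f(lw + 2 * step) - f(lw + step)


class TestRequirement:
    def test_dry_open_cow_maintenance_only(self):
        unit = CowCalfUnit(cow_lw=500.0, pregnant=False)
        ep = EnergyParams(cow_target_lw=500.0)
        budget = cow_calf_requirement(unit, ep, CP, dt.date(2000, 2, 1),
                                      with_activity=False)
        assert budget.total_requirement == pytest.approx(61.3, abs=0.1)
        assert budget.pregnancy == budget.lactation == budget.calf_growth == 0.0

    def test_annualised_reference_unit_is_1point5x_steer(self):
        """Unrestricted cow+calf demand averages ~1.5x the 67.5 MJ/d steer."""
        unit = CowCalfUnit(cow_lw=500.0, pregnant=True)
        total = 0.0
        date = dt.date(1999, 7, 1)
        calf_age = None
        for _ in range(365):
            if (date.month, date.day) == CP.calving_month_day:
                calf_age = 0
            if calf_age is not None and calf_age >= CP.weaning_age:
                calf_age = None
            calf_lw = CP.birth_lw + CP.max_gain * calf_age if calf_age is not None else None
            u = CowCalfUnit(cow_lw=500.0, calf_lw=calf_lw, calf_age=calf_age,
                            pregnant=True)
            total += cow_calf_requirement(u, EP, CP, date).total_requirement
            if calf_age is not None:
                calf_age += 1
            date += dt.timedelta(days=1)
        annual_mean = total / 365.0
        target = EP.cow_calf_ratio * 67.5
        assert annual_mean == pytest.approx(target, rel=0.05)

    def test_lactation_only_while_calf_at_foot(self):
        with_calf = CowCalfUnit(cow_lw=500.0, calf_lw=60.0, calf_age=60, pregnant=False)
        no_calf = CowCalfUnit(cow_lw=500.0, pregnant=False)
        date = dt.date(2000, 9, 1)
        assert cow_calf_requirement(with_calf, EP, CP, date).lactation > 0.0
        assert cow_calf_requirement(no_calf, EP, CP, date).lactation == 0.0

    def test_pregnancy_ramps_toward_july_calving(self):
        unit = CowCalfUnit(cow_lw=500.0, pregnant=True)
        early = cow_calf_requirement(unit, EP, CP, dt.date(2000, 1, 15)).pregnancy
        late = cow_calf_requirement(unit, EP, CP, dt.date(2000, 6, 25)).pregnancy
        assert early == 0.0
        assert late > 20.0


class TestIntake:
    def test_requirement_over_me_content(self):
        assert compute_intake(86.0, 100.0, 10.2, EP) == pytest.approx(86.0 / 10.2)

    def test_dmi_cap_binds_on_poor_feed(self):
        assert compute_intake(10_000.0, 1e6, 5.0, EP) == 16.9

    def test_nothing_above_residual_means_no_intake(self):
        assert compute_intake(86.0, 0.0, 10.2, EP) == 0.0

    def test_substitution_reserves_gut_fill_for_supplement(self):
        # poor pasture cannot meet a lactation-peak demand inside the DMI cap
        req, me_p, me_s = 165.0, 9.3, 10.0
        p_dm, deficit = plan_intake(req, 1e6, me_p, me_s, EP)
        assert p_dm + deficit / me_s <= EP.max_dmi + 1e-9
        assert p_dm * me_p + deficit == pytest.approx(req)


class TestLiveweights:
    def _unit(self):
        return CowCalfUnit(cow_lw=500.0, calf_lw=60.0, calf_age=53,
                           pregnant=True, lactating=True)

    def test_full_requirement_grows_calf_and_holds_cow(self):
        unit = self._unit()
        budget = cow_calf_requirement(unit, EP, CP, dt.date(2000, 8, 23))
        alloc = allocate_energy(unit, budget, budget.total_requirement, EP, CP)
        assert alloc.calf_gain == pytest.approx(CP.max_gain)
        assert alloc.cow_lw_delta == pytest.approx(0.0, abs=1e-9)

    def test_maintenance_only_intake_freezes_calf_and_cow(self):
        unit = self._unit()
        budget = cow_calf_requirement(unit, EP, CP, dt.date(2000, 8, 23))
        alloc = allocate_energy(unit, budget,
                                budget.maintenance + budget.activity, EP, CP)
        assert alloc.calf_gain == 0.0
        assert alloc.cow_lw_delta == 0.0

    def test_unrestricted_feeding_weans_at_target(self):
        unit = CowCalfUnit(cow_lw=500.0, calf_lw=CP.birth_lw, calf_age=0,
                           pregnant=True, lactating=True)
        date = dt.date(2000, 7, 1)
        weaned = None
        while weaned is None:
            budget = cow_calf_requirement(unit, EP, CP, date)
            alloc = allocate_energy(unit, budget, budget.total_requirement, EP, CP)
            unit, weaned = update_liveweights(unit, alloc, CP)
            date += dt.timedelta(days=1)
        assert weaned == pytest.approx(CP.birth_lw + CP.max_gain * CP.weaning_age)
        assert weaned == pytest.approx(100.0)

    def test_starvation_collapse_is_signalled(self):
        unit = CowCalfUnit(cow_lw=2.0)
        alloc = Allocation(maintenance=10.0, pregnancy=0.0, keep=0.0, gain=0.0,
                           recovery=0.0, cow_lw_delta=-3.0, calf_gain=0.0)
        with pytest.raises(StarvationError):
            update_liveweights(unit, alloc, CP)

    @settings(max_examples=80, deadline=None)
    @given(intake=st.floats(0.0, 220.0), cow_lw=st.floats(300.0, 600.0),
           calf_age=st.integers(0, 119))
    def test_daily_energy_conservation(self, intake, cow_lw, calf_age):
        """Intake equals allocated demand plus stored minus mobilised energy."""
        unit = CowCalfUnit(cow_lw=cow_lw, calf_lw=CP.birth_lw + 0.5 * calf_age,
                           calf_age=calf_age, pregnant=True, lactating=True)
        budget = cow_calf_requirement(unit, EP, CP, dt.date(2000, 8, 1))
        alloc = allocate_energy(unit, budget, min(intake, budget.total_requirement),
                                EP, CP)
        used = alloc.maintenance + alloc.pregnancy + alloc.keep + alloc.gain
        stored = alloc.recovery
        mobilised = -alloc.cow_lw_delta * EP.kg_loss_me if alloc.cow_lw_delta < 0 else 0.0
        assert min(intake, budget.total_requirement) - used - stored + mobilised == \
            pytest.approx(0.0, abs=1e-9)

    def test_weaning_weight_never_exceeds_growth_potential(self, system_runs):
        cap = CP.birth_lw + CP.max_gain * CP.weaning_age
        for (_, _), (summaries, _) in system_runs.items():
            for s in summaries:
                assert s.calf_weaning_lw <= cap + 0.5
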