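"""Worked examples and edge cases of the hourly capacity computation.

The randomized property suites (monotonicity, substitution dominance,
homogeneity, the feasibility oracle) live in test_acceptance.py; here each
operation is pinned to hand-computed values.
"""

from dataclasses import replace

import pytest

from wardcap import (
    DemandProfile,
    NoDemandError,
    PatientAcuityCount,
    SkillType,
    StaffingStatus,
    SupplyProfile,
    acuity_weight,
    adt_minutes,
    baseline_demand,
    binding_tier,
    capacity_difference,
    dynamic_bed_count,
    equivalent_capacity,
    equivalent_census,
    pn_capacity,
    staffing_status,
)

RN, LPN, NA = SkillType.RN, SkillType.LPN_LVN, SkillType.NA


class TestBaselineDemand:
    def test_six_nhppd_even_mix_gives_15_minutes_per_patient_hour(self, unit_policy):
        d = baseline_demand(unit_policy, 10)
        assert d.total == pytest.approx(15.0)
        assert d.per_skill[RN] == pytest.approx(10.5)
        assert d.per_skill[LPN] == pytest.approx(3.0)
        assert d.per_skill[NA] == pytest.approx(1.5)

    def test_zero_nhppd_gives_zero_demand(self, unit_policy):
        policy = replace(
            unit_policy, nhppd_policy=replace(unit_policy.nhppd_policy, nhppd=0.0)
        )
        assert baseline_demand(policy, 10).total == 0.0

    def test_zero_shift_share_gives_zero_demand_in_that_shift(self, unit_policy):
        policy = replace(
            unit_policy,
            nhppd_policy=replace(
                unit_policy.nhppd_policy,
                shift_mix={"night": 0.0, "day": 0.5, "evening": 0.5},
            ),
        )
        assert baseline_demand(policy, 2).total == 0.0  # 02:00 is night
        assert baseline_demand(policy, 10).total == pytest.approx(6.0 * 0.5 / 8 * 60)


class TestAcuityScaling:
    @pytest.mark.parametrize(
        "ratio, baseline, expected", [(4, 4, 1.0), (1, 4, 4.0), (2, 4, 2.0), (5, 5, 1.0)]
    )
    def test_weight_is_baseline_over_ratio(self, ratio, baseline, expected):
        assert acuity_weight(ratio, baseline) == pytest.approx(expected)

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError):
            acuity_weight(0, 4)

    def test_equivalent_census_worked_example(self):
        counts = (
            PatientAcuityCount(1, 2),
            PatientAcuityCount(2, 4),
            PatientAcuityCount(4, 14),
        )
        assert equivalent_census(counts, 4) == pytest.approx(30.0)

    def test_all_baseline_equals_census(self):
        assert equivalent_census((PatientAcuityCount(4, 17),), 4) == pytest.approx(17.0)

    def test_empty_census_is_zero(self):
        assert equivalent_census((), 4) == 0.0


class TestAdtMinutes:
    def test_one_admission_one_discharge(self, unit_policy):
        out = adt_minutes(1, 1, unit_policy)
        assert out == {RN: 90.0, LPN: 0.0, NA: 0.0}

    def test_no_turnover_means_no_load(self, unit_policy):
        assert sum(adt_minutes(0, 0, unit_policy).values()) == 0.0

    def test_charged_skill_is_configurable(self, unit_policy):
        policy = replace(unit_policy, adt_skill=LPN)
        assert adt_minutes(2, 0, policy)[LPN] == pytest.approx(120.0)
        assert adt_minutes(2, 0, policy)[RN] == 0.0


class TestEquivalentCapacity:
    DEMAND = DemandProfile({RN: 10.5, LPN: 3.0, NA: 1.5})

    def test_tiered_minimum_worked_example(self):
        supply = SupplyProfile({RN: 240.0, LPN: 60.0, NA: 60.0})
        # min(240/10.5, 300/13.5, 360/15.0) — the middle tier binds
        assert equivalent_capacity(supply, self.DEMAND) == pytest.approx(300.0 / 13.5)
        assert binding_tier(supply, self.DEMAND) == LPN

    def test_single_tier_division(self):
        supply = SupplyProfile({RN: 240.0, LPN: 0.0, NA: 0.0})
        demand = DemandProfile({RN: 15.0, LPN: 0.0, NA: 0.0})
        assert equivalent_capacity(supply, demand) == pytest.approx(16.0)

    def test_no_staff_means_no_capacity(self):
        supply = SupplyProfile({RN: 0.0, LPN: 0.0, NA: 0.0})
        assert equivalent_capacity(supply, self.DEMAND) == 0.0

    def test_zero_demand_is_an_error_not_infinity(self):
        supply = SupplyProfile({RN: 240.0, LPN: 0.0, NA: 0.0})
        with pytest.raises(NoDemandError, match="no demand profile"):
            equivalent_capacity(supply, DemandProfile({RN: 0.0, LPN: 0.0, NA: 0.0}))

    def test_adt_minutes_reduce_supply_on_charged_skill(self):
        supply = SupplyProfile({RN: 240.0, LPN: 60.0, NA: 60.0})
        with_adt = equivalent_capacity(supply, self.DEMAND, {RN: 90.0})
        assert with_adt == pytest.approx(min(150.0 / 10.5, 210.0 / 13.5, 270.0 / 15.0))

    def test_adt_exceeding_supply_clamps_at_zero(self):
        supply = SupplyProfile({RN: 60.0, LPN: 0.0, NA: 0.0})
        assert equivalent_capacity(supply, self.DEMAND, {RN: 120.0}) == 0.0


class TestDynamicBedCount:
    def test_worked_example_14_8(self, unit_policy, make_snapshot):
        # C = 300/13.5 = 22.22, E = 30 over census 20 so the mean acuity
        # weight is 1.5; DBC = 22.22/1.5 = 14.8
        res = dynamic_bed_count(make_snapshot(), unit_policy)
        assert res.equivalent_capacity == pytest.approx(300.0 / 13.5)
        assert res.mean_acuity_weight == pytest.approx(1.5)
        assert res.dbc == 14.8
        assert res.status is StaffingStatus.UNDERSTAFFED

    def test_empty_unit_uses_unit_acuity_weight(self, unit_policy, make_snapshot):
        snap = make_snapshot(census=0, acuity=(0, 0, 0, 0, 0), rn=4, lpn=0, na=0)
        res = dynamic_bed_count(snap, unit_policy)
        assert res.mean_acuity_weight == 1.0
        # C = min(240/10.5, 240/13.5, 240/15) = 16.0
        assert res.dbc == 16.0

    def test_capped_at_authorized_capacity(self, unit_policy, make_snapshot):
        policy = replace(unit_policy, authorized_capacity=12)
        snap = make_snapshot(
            census=12, acuity=(0, 0, 0, 12, 0), rn=8, lpn=2, na=2,
            rn_ratios=(4,) * 8,
        )
        res = dynamic_bed_count(snap, policy)
        assert res.dbc == 12.0

    def test_dbc_not_clamped_to_census(self, unit_policy, make_snapshot):
        # more capacity than patients: census 5 but staffing supports ~22
        snap = make_snapshot(census=5, acuity=(0, 0, 0, 5, 0), rn=4, lpn=1, na=1)
        res = dynamic_bed_count(snap, unit_policy)
        assert res.dbc > 5


class TestPnCapacity:
    def test_uniform_ratios(self, make_snapshot):
        snap = make_snapshot(rn=6, rn_ratios=(5,) * 6)
        assert pn_capacity(snap) == 30.0

    def test_mixed_ratios_sum(self, make_snapshot):
        snap = make_snapshot(rn=5, rn_ratios=(5, 5, 5, 5, 4))
        assert pn_capacity(snap) == 24.0

    def test_no_rns_means_zero(self, make_snapshot):
        assert pn_capacity(make_snapshot(rn=0, rn_ratios=())) == 0.0

    def test_cap_applies_when_given(self, make_snapshot):
        snap = make_snapshot(rn=8, rn_ratios=(5,) * 8)
        assert pn_capacity(snap, authorized_capacity=34) == 34.0


class TestReporting:
    def test_difference_identity_is_zero(self):
        assert capacity_difference(21.4, 21.4) == 0.0

    @pytest.mark.parametrize(
        "dbc, census, expected",
        [
            (18.7, 21, StaffingStatus.UNDERSTAFFED),
            (20.0, 20, StaffingStatus.ADEQUATE),
            (29.3, 20, StaffingStatus.OVERSTAFFED),
            (20.4, 20, StaffingStatus.ADEQUATE),
        ],
    )
    def test_status_thresholds(self, dbc, census, expected):
        assert staffing_status(dbc, census, 0.5) is expected
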