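from datetime import datetime

import pytest

from wardcap import (
    DEFAULT_SHIFTS,
    HourlySnapshot,
    NhppdPolicy,
    PatientAcuityCount,
    SkillType,
    UnitPolicy,
    validate_policy,
)

THIRD = 1.0 / 3.0


@pytest.fixture
def unit_policy() -> UnitPolicy:
    """A 34-bed acute unit: NHPPD 6 h split evenly over three 8-h shifts,
    skill mix RN 70 / LPN 20 / NA 10, baseline acuity ratio 4:1."""
    return validate_policy(
        UnitPolicy(
            unit_id="3C",
            authorized_capacity=34,
            baseline_ratio=4,
            nhppd_policy=NhppdPolicy(
                nhppd=6.0,
                shift_mix={"night": THIRD, "day": THIRD, "evening": THIRD},
                skill_mix={
                    SkillType.RN: 0.7,
                    SkillType.LPN_LVN: 0.2,
                    SkillType.NA: 0.1,
                },
            ),
            shifts=DEFAULT_SHIFTS,
            adm_minutes=60.0,
            dis_minutes=30.0,
            status_tolerance=0.5,
        )
    )


@pytest.fixture
def make_snapshot():
    """Factory for well-formed snapshots with overridable fields."""

    def _make(
        census=20,
        acuity=(2, 4, 0, 14, 0),
        rn=4,
        lpn=1,
        na=1,
        rn_ratios=None,
        admissions=0,
        discharges=0,
        unit_id="3C",
        timestamp=datetime(2023, 1, 1, 10),
    ) -> HourlySnapshot:
        if rn_ratios is None:
            rn_ratios = (4,) * rn
        return HourlySnapshot(
            unit_id=unit_id,
            timestamp=timestamp,
            census=census,
            acuity_counts=tuple(
                PatientAcuityCount(r, c) for r, c in zip((1, 2, 3, 4, 5), acuity)
            ),
            direct_staff={SkillType.RN: rn, SkillType.LPN_LVN: lpn, SkillType.NA: na},
            rn_assigned_ratios=tuple(rn_ratios),
            admissions=admissions,
            discharges=discharges,
        )

    return _make
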