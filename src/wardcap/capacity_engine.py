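"""The dynamic bed count: hourly, acuity- and skill-mix-aware capacity.

The calculation compares two quantities every hour:

* **target staffing** — the minutes of care the unit's patients require in
  the hour, derived from the unit's NHPPD policy (daily hours per patient,
  split by shift mix and skill mix) and scaled by patient acuity;
* **current staffing** — the minutes the on-duty *direct-care* staff supply,
  by skill, net of the minutes consumed by admissions and discharges.

Their ratio, taken tier by tier down the skill order (an RN may absorb
LPN/LVN- or NA-level work, never the reverse), is the *equivalent capacity*
``C``: how many average-acuity patients current staffing can support.
Dividing by the census-mean acuity weight converts ``C`` into patients at
the unit's current case mix — the dynamic bed count (DBC).  The legacy
patient-to-nurse capacity is simply the sum of the supervisor-assigned P/N
ratios over direct-care RNs.

Every modelling commitment (demand per hour, the 1/ratio acuity curve,
strict downward substitution, ADT minutes subtracted from supply on the
charged skill) is isolated behind one function here, so an alternative
formulation is a local change.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .core_model import (
    SKILL_ORDER,
    CapacityResult,
    HourlySnapshot,
    PatientAcuityCount,
    SkillType,
    StaffingStatus,
    UnitPolicy,
    shift_of_hour,
)

__all__ = [
    "DemandProfile",
    "SupplyProfile",
    "NoDemandError",
    "baseline_demand",
    "acuity_weight",
    "equivalent_census",
    "adt_minutes",
    "equivalent_capacity",
    "binding_tier",
    "dynamic_bed_count",
    "pn_capacity",
    "capacity_difference",
    "staffing_status",
]


class NoDemandError(ValueError):
    """Zero total demand with nonzero supply: capacity is undefined."""


@dataclass(frozen=True)
class DemandProfile:
    """Baseline care demand, minutes per average patient per hour, by skill."""

    per_skill: Mapping[SkillType, float]

    def __post_init__(self) -> None:
        for s, d in self.per_skill.items():
            if d < 0:
                raise ValueError(f"negative demand for {SkillType(s).label}")

    @property
    def total(self) -> float:
        return sum(self.per_skill.values())


@dataclass(frozen=True)
class SupplyProfile:
    """Supplied direct-care minutes in the hour, by skill (60 per head)."""

    minutes: Mapping[SkillType, float]

    @classmethod
    def from_counts(cls, direct_staff: Mapping[SkillType, int]) -> "SupplyProfile":
        return cls({s: 60.0 * direct_staff.get(s, 0) for s in SKILL_ORDER})

    def __post_init__(self) -> None:
        for s, m in self.minutes.items():
            if m < 0:
                raise ValueError(f"negative supply for {SkillType(s).label}")


def baseline_demand(policy: UnitPolicy, hour: int) -> DemandProfile:
    """Per-patient demand minutes for the hour, from the NHPPD policy.

    With shift *t* covering the hour, the per-patient-per-hour total is
    ``d = NHPPD * shift_mix[t] / length[t] * 60`` minutes, split across
    skills by the skill mix.  Shift mix fractions are per-shift totals of
    the daily NHPPD, spread evenly over the shift's hours.
    """
    shift = shift_of_hour(policy, hour)
    np_ = policy.nhppd_policy
    sigma = float(np_.shift_mix.get(shift.name, 0.0))
    d_total = np_.nhppd * sigma / shift.length_hours * 60.0
    return DemandProfile(
        {s: d_total * float(np_.skill_mix.get(s, 0.0)) for s in SKILL_ORDER}
    )


def acuity_weight(ratio: int, baseline_ratio: int) -> float:
    """Care-demand multiplier of one patient at acuity ``ratio``.

    Linear in 1/ratio: a 1:1 patient consumes ``baseline_ratio`` times the
    average patient's minutes; a patient at the baseline ratio weighs 1.
    """
    if ratio <= 0:
        raise ValueError(f"acuity ratio must be positive, got {ratio}")
    if baseline_ratio < 1:
        raise ValueError(f"baseline ratio must be >= 1, got {baseline_ratio}")
    return baseline_ratio / ratio


def equivalent_census(
    acuity_counts: Sequence[PatientAcuityCount], baseline_ratio: int
) -> float:
    """Census in average-patient units: sum of count x acuity weight."""
    return float(
        sum(a.count * acuity_weight(a.ratio, baseline_ratio) for a in acuity_counts)
    )


def adt_minutes(
    admissions: int, discharges: int, policy: UnitPolicy
) -> dict[SkillType, float]:
    """Care minutes consumed by the hour's admissions and discharges.

    Charged entirely to ``policy.adt_skill`` (RN by default: admission
    assessment and discharge education are RN scope-of-practice tasks).
    """
    if admissions < 0 or discharges < 0:
        raise ValueError("admissions and discharges must be nonnegative")
    load = admissions * policy.adm_minutes + discharges * policy.dis_minutes
    return {s: (load if s == policy.adt_skill else 0.0) for s in SKILL_ORDER}


def _tier_ratios(
    supply: SupplyProfile,
    demand: DemandProfile,
    adt: Optional[Mapping[SkillType, float]],
) -> list[tuple[SkillType, float]]:
    adt = adt or {}
    out: list[tuple[SkillType, float]] = []
    s_cum = d_cum = a_cum = 0.0
    for skill in SKILL_ORDER:
        s_cum += float(supply.minutes.get(skill, 0.0))
        d_cum += float(demand.per_skill.get(skill, 0.0))
        a_cum += float(adt.get(skill, 0.0))
        net = s_cum - a_cum
        if d_cum <= 0.0:
            # no baseline demand reachable by this prefix: no ratio bound —
            # but ADT work beyond the prefix's supply is unstaffable (only
            # this prefix may serve it), which clamps capacity to zero
            if net < 0.0:
                out.append((skill, 0.0))
            continue
        out.append((skill, max(0.0, net / d_cum)))
    return out


def equivalent_capacity(
    supply: SupplyProfile,
    demand: DemandProfile,
    adt: Optional[Mapping[SkillType, float]] = None,
) -> float:
    """Average-acuity patients supportable by the hour's direct-care supply.

    Skills are ordered RN > LPN/LVN > NA; demand for a skill may be served
    by that skill or any higher one, never a lower one.  Hence for every
    prefix of the order the prefix's net supply must cover the prefix's
    demand, and capacity is the minimum over prefixes of
    ``(supply - ADT minutes) / demand``, clamped below at zero.  Prefixes
    with zero demand impose no bound and are skipped.
    """
    if demand.total <= 0.0:
        raise NoDemandError(
            "no demand profile: zero total demand minutes; capacity undefined"
        )
    ratios = _tier_ratios(supply, demand, adt)
    return min(r for _, r in ratios)


def binding_tier(
    supply: SupplyProfile,
    demand: DemandProfile,
    adt: Optional[Mapping[SkillType, float]] = None,
) -> SkillType:
    """Skill prefix that bounds :func:`equivalent_capacity` (ties: highest).

    Exposed for logging: an RN-bound hour and a cumulative (NA)-bound hour
    call for different staffing moves.
    """
    if demand.total <= 0.0:
        raise NoDemandError("no demand profile")
    ratios = _tier_ratios(supply, demand, adt)
    best = min(r for _, r in ratios)
    for skill, r in ratios:
        if r == best:
            return skill
    raise AssertionError("unreachable")


def pn_capacity(
    snapshot: HourlySnapshot, authorized_capacity: Optional[int] = None
) -> float:
    """Legacy patient-to-nurse capacity: sum of assigned ratios over RNs.

    Capped at the unit's authorized capacity when given.  Assigned ratios
    are carried per direct-care RN, so the total need not be a multiple of
    any single ratio.
    """
    total = float(sum(snapshot.rn_assigned_ratios))
    if authorized_capacity is not None:
        total = min(total, float(authorized_capacity))
    return total


def capacity_difference(dbc: float, pn: float) -> float:
    """Signed capacity gap ``dbc - pn`` at 1-decimal reporting precision.

    Negative: the unit should hold fewer patients than the P/N method
    allows; positive: it could take on more.
    """
    return round(dbc - pn, 1)


def staffing_status(dbc: float, census: int, tolerance: float) -> StaffingStatus:
    """Classify the hour by comparing census with the dynamic bed count."""
    if tolerance < 0:
        raise ValueError("tolerance must be nonnegative")
    if census - dbc > tolerance:
        return StaffingStatus.UNDERSTAFFED
    if dbc - census > tolerance:
        return StaffingStatus.OVERSTAFFED
    return StaffingStatus.ADEQUATE


def dynamic_bed_count(snapshot: HourlySnapshot, policy: UnitPolicy) -> CapacityResult:
    """Full per-hour capacity computation for one snapshot.

    Pipeline: baseline demand for the hour -> supply from direct staff ->
    ADT minutes -> tiered equivalent capacity ``C`` -> census-mean acuity
    weight ``a = E/n`` (1 for an empty unit) -> ``DBC = C / a``, capped at
    the authorized capacity and reported to 1 decimal (round-half-even).
    DBC is *not* clamped to the census: hours where the unit holds more
    patients than staffing supports are exactly what the status flag and
    difference column are meant to expose.
    """
    demand = baseline_demand(policy, snapshot.hour)
    supply = SupplyProfile.from_counts(snapshot.direct_staff)
    adt = adt_minutes(snapshot.admissions, snapshot.discharges, policy)
    c = equivalent_capacity(supply, demand, adt)

    e = equivalent_census(snapshot.acuity_counts, policy.baseline_ratio)
    a_bar = e / snapshot.census if snapshot.census > 0 else 1.0

    dbc = min(c / a_bar, float(policy.authorized_capacity))
    dbc = round(dbc, 1)
    pn = pn_capacity(snapshot, policy.authorized_capacity)
    return CapacityResult(
        dbc=dbc,
        pn_capacity=pn,
        difference=capacity_difference(dbc, pn),
        status=staffing_status(dbc, snapshot.census, policy.status_tolerance),
        equivalent_capacity=c,
        mean_acuity_weight=a_bar,
    )
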