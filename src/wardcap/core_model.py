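"""Domain types for hourly ward-capacity accounting.

The data model mirrors how an acute-care unit is described operationally:

* a static :class:`UnitPolicy` — authorized bed capacity, the unit's NHPPD
  (nursing hours per patient day) target with its shift and skill mixes,
  admission/discharge care-minute costs, and the baseline patient-to-nurse
  ratio that defines "average" acuity;
* an :class:`HourlySnapshot` — one observed unit-hour: census broken down by
  acuity class, direct-care staff by skill, supervisor-assigned P/N ratios,
  and the hour's admissions and discharges;
* a :class:`CapacityResult` — the computed capacities for that hour;
* a :class:`WardTrace` — an ordered sequence of snapshots (and, once
  computed, results) for one unit over an assessment period.

Timestamps denote the left-closed hour interval ``[h, h+1)``: events with
times inside the interval belong to that hour.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Iterator, Mapping, Optional, Sequence

__all__ = [
    "SkillType",
    "SKILL_ORDER",
    "StaffingStatus",
    "ShiftDefinition",
    "NhppdPolicy",
    "UnitPolicy",
    "PatientAcuityCount",
    "HourlySnapshot",
    "CapacityResult",
    "WardTrace",
    "PolicyError",
    "SnapshotError",
    "validate_policy",
    "shift_of_hour",
    "policy_to_dict",
    "policy_from_dict",
]

ACUITY_RATIOS = (1, 2, 3, 4, 5)

_MIX_TOL = 1e-9


class PolicyError(ValueError):
    """A unit policy violates one of its structural invariants."""


class SnapshotError(ValueError):
    """An hourly snapshot violates one of its structural invariants."""


class SkillType(enum.IntEnum):
    """Direct-care staff skill, totally ordered RN > LPN/LVN > NA.

    A higher skill is qualified to absorb work targeted at any lower skill;
    the reverse never holds.  The integer values encode only the order.
    """

    RN = 3
    LPN_LVN = 2
    NA = 1

    @property
    def label(self) -> str:
        return {SkillType.RN: "RN", SkillType.LPN_LVN: "LPN/LVN", SkillType.NA: "NA"}[self]


#: Skills from most to least qualified — the substitution order used by the
#: tiered capacity calculation.
SKILL_ORDER: tuple[SkillType, ...] = (SkillType.RN, SkillType.LPN_LVN, SkillType.NA)


class StaffingStatus(str, enum.Enum):
    UNDERSTAFFED = "understaffed"
    ADEQUATE = "adequate"
    OVERSTAFFED = "overstaffed"


@dataclass(frozen=True)
class ShiftDefinition:
    """One named shift occupying ``[start_hour, start_hour+length_hours)`` mod 24."""

    name: str
    start_hour: int
    length_hours: int

    def contains(self, hour: int) -> bool:
        return (hour - self.start_hour) % 24 < self.length_hours


@dataclass(frozen=True)
class NhppdPolicy:
    """NHPPD target with its fractional split across shifts and skills.

    ``nhppd`` is hours of care each patient must receive per 24 h;
    ``shift_mix`` maps shift name -> fraction of those hours delivered in
    that shift; ``skill_mix`` maps skill -> fraction delivered by that skill.
    Both mixes sum to 1.
    """

    nhppd: float
    shift_mix: Mapping[str, float]
    skill_mix: Mapping[SkillType, float]


@dataclass(frozen=True)
class UnitPolicy:
    """Static parameters of one unit."""

    unit_id: str
    authorized_capacity: int
    baseline_ratio: int
    nhppd_policy: NhppdPolicy
    shifts: tuple[ShiftDefinition, ...]
    adm_minutes: float = 60.0
    dis_minutes: float = 30.0
    adt_skill: SkillType = SkillType.RN
    status_tolerance: float = 0.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "shifts", tuple(self.shifts))


@dataclass(frozen=True)
class PatientAcuityCount:
    """Number of patients at one acuity class (its P/N ratio, 1:1 … 5:1)."""

    ratio: int
    count: int

    def __post_init__(self) -> None:
        if self.ratio not in ACUITY_RATIOS:
            raise SnapshotError(f"acuity ratio must be one of {ACUITY_RATIOS}, got {self.ratio}")
        if self.count < 0:
            raise SnapshotError(f"acuity count must be nonnegative, got {self.count}")


@dataclass(frozen=True)
class HourlySnapshot:
    """One observed unit-hour.

    ``rn_assigned_ratios`` carries the supervisor-assigned P/N ratio of every
    direct-care RN individually (not one unit-wide ratio), so the legacy
    capacity can be a non-multiple such as 26 or 29.
    """

    unit_id: str
    timestamp: datetime
    census: int
    acuity_counts: tuple[PatientAcuityCount, ...]
    direct_staff: Mapping[SkillType, int]
    rn_assigned_ratios: tuple[int, ...]
    admissions: int
    discharges: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "acuity_counts", tuple(self.acuity_counts))
        object.__setattr__(self, "rn_assigned_ratios", tuple(int(r) for r in self.rn_assigned_ratios))
        if self.census < 0 or self.admissions < 0 or self.discharges < 0:
            raise SnapshotError("census, admissions and discharges must be nonnegative")
        total = sum(a.count for a in self.acuity_counts)
        if total != self.census:
            raise SnapshotError(
                f"acuity counts sum to {total} but census is {self.census}"
            )
        for skill, n in self.direct_staff.items():
            if n < 0:
                raise SnapshotError(f"direct staff count for {SkillType(skill).label} is negative")
        n_rn = int(self.direct_staff.get(SkillType.RN, 0))
        if len(self.rn_assigned_ratios) != n_rn:
            raise SnapshotError(
                f"{len(self.rn_assigned_ratios)} assigned ratios for {n_rn} direct RNs"
            )

    @property
    def hour(self) -> int:
        return self.timestamp.hour

    def acuity_census(self) -> dict[int, int]:
        """Census per acuity ratio, aggregating duplicate classes."""
        out = {r: 0 for r in ACUITY_RATIOS}
        for a in self.acuity_counts:
            out[a.ratio] += a.count
        return out


@dataclass(frozen=True)
class CapacityResult:
    """Computed capacities for one unit-hour.

    ``dbc`` is the dynamic bed count (1-decimal reporting precision),
    ``pn_capacity`` the legacy sum of assigned P/N ratios, ``difference``
    their signed gap (negative: the unit should hold fewer patients than the
    P/N method allows), ``equivalent_capacity`` the acuity-unweighted staffed
    capacity C, and ``mean_acuity_weight`` the census-average acuity weight
    used to convert C into patients.
    """

    dbc: float
    pn_capacity: float
    difference: float
    status: StaffingStatus
    equivalent_capacity: float
    mean_acuity_weight: float

    def __post_init__(self) -> None:
        if self.dbc < 0 or self.pn_capacity < 0:
            raise ValueError("capacities must be nonnegative")
        if abs(self.difference - (self.dbc - self.pn_capacity)) > 0.05 + 1e-9:
            raise ValueError(
                "difference inconsistent with dbc - pn_capacity beyond rounding slack"
            )


@dataclass
class WardTrace:
    """Ordered unit-hours for one unit; ``results`` is filled by the engine."""

    unit_id: str
    authorized_capacity: int
    snapshots: list[HourlySnapshot]
    results: Optional[list[CapacityResult]] = None

    def __post_init__(self) -> None:
        prev: Optional[datetime] = None
        for s in self.snapshots:
            if s.unit_id != self.unit_id:
                raise SnapshotError(f"snapshot unit {s.unit_id!r} in trace for {self.unit_id!r}")
            if prev is not None:
                gap = (s.timestamp - prev) / timedelta(hours=1)
                if gap <= 0:
                    raise SnapshotError("trace timestamps must be strictly increasing")
                if abs(gap - round(gap)) > 1e-9:
                    raise SnapshotError("trace timestamps must be whole hours apart")
            prev = s.timestamp
        if self.results is not None and len(self.results) != len(self.snapshots):
            raise ValueError("results length does not match snapshots length")

    def __len__(self) -> int:
        return len(self.snapshots)

    def rows(self) -> Iterator[tuple[HourlySnapshot, CapacityResult]]:
        if self.results is None:
            raise ValueError("trace has no computed results")
        return iter(zip(self.snapshots, self.results))


# ---------------------------------------------------------------------------
# Policy validation


def _check_mix(name: str, mix: Mapping, keys: Sequence) -> None:
    total = 0.0
    for k in keys:
        f = float(mix.get(k, 0.0))
        if not 0.0 <= f <= 1.0:
            raise PolicyError(f"{name} fraction for {k} is {f}, outside [0, 1]")
        total += f
    if abs(total - 1.0) > _MIX_TOL:
        raise PolicyError(f"{name} sums to {total:.10g}, must sum to 1")


def validate_policy(policy: UnitPolicy) -> UnitPolicy:
    """Check every structural invariant of a unit policy.

    Returns the policy unchanged if valid; raises :class:`PolicyError` naming
    the first violated invariant otherwise.
    """
    if policy.authorized_capacity < 1:
        raise PolicyError(f"authorized capacity must be >= 1, got {policy.authorized_capacity}")
    if not 1 <= policy.baseline_ratio <= 10:
        raise PolicyError(f"baseline P/N ratio must be in 1..10, got {policy.baseline_ratio}")
    if policy.adm_minutes < 0 or policy.dis_minutes < 0:
        raise PolicyError("admission/discharge minutes must be nonnegative")
    if policy.status_tolerance < 0:
        raise PolicyError("status tolerance must be nonnegative")
    if policy.adt_skill not in SkillType.__members__.values():
        raise PolicyError(f"unknown ADT skill {policy.adt_skill!r}")

    np_ = policy.nhppd_policy
    if np_.nhppd < 0:
        raise PolicyError(f"NHPPD must be nonnegative, got {np_.nhppd}")

    if not policy.shifts:
        raise PolicyError("policy defines no shifts")
    names = [s.name for s in policy.shifts]
    if len(set(names)) != len(names):
        raise PolicyError("duplicate shift names")
    total_len = sum(s.length_hours for s in policy.shifts)
    if total_len != 24:
        raise PolicyError(f"shifts do not tile 24 hours (total {total_len})")
    covered = [0] * 24
    for s in policy.shifts:
        if not 0 <= s.start_hour <= 23:
            raise PolicyError(f"shift {s.name!r} start hour {s.start_hour} outside 0..23")
        if s.length_hours < 1:
            raise PolicyError(f"shift {s.name!r} has nonpositive length")
        for k in range(s.length_hours):
            covered[(s.start_hour + k) % 24] += 1
    if any(c != 1 for c in covered):
        raise PolicyError("shifts overlap or leave hours uncovered")

    _check_mix("shift mix", np_.shift_mix, names)
    extra = set(np_.shift_mix) - set(names)
    if extra:
        raise PolicyError(f"shift mix names unknown shifts: {sorted(extra)}")
    _check_mix("skill mix", np_.skill_mix, list(SKILL_ORDER))
    return policy


def shift_of_hour(policy: UnitPolicy, hour: int) -> ShiftDefinition:
    """The unique shift whose interval (mod 24, left-closed) contains ``hour``."""
    if not 0 <= hour <= 23:
        raise ValueError(f"hour must be in 0..23, got {hour}")
    for s in policy.shifts:
        if s.contains(hour):
            return s
    raise PolicyError(f"no shift covers hour {hour}")  # unreachable for a valid policy


# ---------------------------------------------------------------------------
# Config serialization (plain dicts; YAML/JSON file IO lives in io_cli)

_SKILL_KEYS = {SkillType.RN: "RN", SkillType.LPN_LVN: "LPN_LVN", SkillType.NA: "NA"}
_SKILL_FROM_KEY = {v: k for k, v in _SKILL_KEYS.items()}


def policy_to_dict(policy: UnitPolicy) -> dict:
    np_ = policy.nhppd_policy
    return {
        "unit_id": policy.unit_id,
        "authorized_capacity": int(policy.authorized_capacity),
        "baseline_ratio": int(policy.baseline_ratio),
        "nhppd": float(np_.nhppd),
        "shift_mix": {k: float(v) for k, v in np_.shift_mix.items()},
        "skill_mix": {_SKILL_KEYS[k]: float(v) for k, v in np_.skill_mix.items()},
        "shifts": [
            {"name": s.name, "start_hour": int(s.start_hour), "length_hours": int(s.length_hours)}
            for s in policy.shifts
        ],
        "adm_minutes": float(policy.adm_minutes),
        "dis_minutes": float(policy.dis_minutes),
        "adt_skill": _SKILL_KEYS[policy.adt_skill],
        "status_tolerance": float(policy.status_tolerance),
    }


def policy_from_dict(data: Mapping) -> UnitPolicy:
    try:
        skill_mix = {_SKILL_FROM_KEY[k]: float(v) for k, v in data["skill_mix"].items()}
    except KeyError as exc:
        raise PolicyError(f"unknown skill key in skill_mix: {exc}") from exc
    policy = UnitPolicy(
        unit_id=str(data["unit_id"]),
        authorized_capacity=int(data["authorized_capacity"]),
        baseline_ratio=int(data["baseline_ratio"]),
        nhppd_policy=NhppdPolicy(
            nhppd=float(data["nhppd"]),
            shift_mix={str(k): float(v) for k, v in data["shift_mix"].items()},
            skill_mix=skill_mix,
        ),
        shifts=tuple(
            ShiftDefinition(str(s["name"]), int(s["start_hour"]), int(s["length_hours"]))
            for s in data["shifts"]
        ),
        adm_minutes=float(data.get("adm_minutes", 60.0)),
        dis_minutes=float(data.get("dis_minutes", 30.0)),
        adt_skill=_SKILL_FROM_KEY[str(data.get("adt_skill", "RN"))],
        status_tolerance=float(data.get("status_tolerance", 0.5)),
    )
    return validate_policy(policy)


#: Default shift clock (overridable in config): night 23–07, day 07–15,
#: evening 15–23 — three 8-hour shifts.
DEFAULT_SHIFTS: tuple[ShiftDefinition, ...] = (
    ShiftDefinition("night", 23, 8),
    ShiftDefinition("day", 7, 8),
    ShiftDefinition("evening", 15, 8),
)
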