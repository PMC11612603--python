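"""Synthetic acute-care ward generator.

Emulates the statistical structure of an hourly unit trace so the capacity
engine and analytics can be exercised without protected hospital data:
Poisson admissions (optionally shift-dependent), a length-of-stay draw at
admission (exponential or lognormal), per-hour Markov evolution of patient
acuity over the five P/N classes, shift-based rosters thinned by absences
and by hourly direct/indirect reassignment, and a heuristic supervisor
assignment of per-RN P/N ratios.

What it does *not* emulate: clinical detail (diagnoses, orders), transfer
traffic between units, queued admissions (arrivals beyond authorized
capacity are diverted and logged), and sub-hourly event timing.

Determinism is a hard contract: identical ``(params, policy)`` with the
same seed produce an identical trace, snapshot for snapshot.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Mapping, Optional, Union

import numpy as np

from .capacity_engine import dynamic_bed_count
from .core_model import (
    ACUITY_RATIOS,
    DEFAULT_SHIFTS,
    HourlySnapshot,
    NhppdPolicy,
    PatientAcuityCount,
    SkillType,
    UnitPolicy,
    WardTrace,
    shift_of_hour,
    validate_policy,
)

__all__ = ["SimulationParams", "validate_params", "simulate_ward", "scenario_fixtures"]

logger = logging.getLogger("wardcap.simulator")

_LOS_DISTRIBUTIONS = ("exponential", "lognormal")


@dataclass(frozen=True)
class SimulationParams:
    """Generator settings for one synthetic ward trace.

    ``admission_rate`` is the expected admissions per hour (lambda), either a
    single rate or a per-shift-name map.  ``los_mean`` is mean length of stay
    in hours; for the lognormal option ``los_sigma`` is the shape (sigma of
    the underlying normal) and the scale is chosen so the mean equals
    ``los_mean``.  ``acuity_init`` is the admission acuity distribution over
    ratios 1..5; ``acuity_transition`` the per-hour Markov matrix over the
    same classes.  ``roster_by_shift`` maps shift name to scheduled staff per
    skill; each scheduled member is absent for the whole shift with
    ``absence_prob`` and each present member is reassigned to indirect care,
    hour by hour, with ``indirect_prob``.
    """

    admission_rate: Union[float, Mapping[str, float]]
    los_mean: float
    los_distribution: str
    acuity_init: tuple[float, ...]
    acuity_transition: tuple[tuple[float, ...], ...]
    roster_by_shift: Mapping[str, Mapping[SkillType, int]]
    absence_prob: float = 0.0
    indirect_prob: float = 0.0
    horizon_hours: int = 24
    seed: int = 0
    los_sigma: float = 0.5
    start: datetime = datetime(2023, 1, 1, 0)


def validate_params(params: SimulationParams, policy: UnitPolicy) -> SimulationParams:
    if params.los_distribution not in _LOS_DISTRIBUTIONS:
        raise ValueError(
            f"unknown LOS distribution {params.los_distribution!r}; "
            f"choose one of {_LOS_DISTRIBUTIONS}"
        )
    if params.los_mean <= 0:
        raise ValueError("mean length of stay must be positive")
    if params.horizon_hours < 1:
        raise ValueError("horizon must be at least one hour")
    rates = (
        params.admission_rate.values()
        if isinstance(params.admission_rate, Mapping)
        else [params.admission_rate]
    )
    if any(r < 0 for r in rates):
        raise ValueError("admission rate must be nonnegative")
    for p in (params.absence_prob, params.indirect_prob):
        if not 0.0 <= p <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
    init = np.asarray(params.acuity_init, dtype=float)
    if init.shape != (5,) or (init < 0).any() or abs(init.sum() - 1.0) > 1e-9:
        raise ValueError("acuity_init must be 5 nonnegative probabilities summing to 1")
    trans = np.asarray(params.acuity_transition, dtype=float)
    if trans.shape != (5, 5) or (trans < 0).any():
        raise ValueError("acuity_transition must be a nonnegative 5x5 matrix")
    if not np.allclose(trans.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("acuity_transition rows must each sum to 1 (stochastic matrix)")
    shift_names = {s.name for s in policy.shifts}
    if isinstance(params.admission_rate, Mapping):
        missing = shift_names - set(params.admission_rate)
        if missing:
            raise ValueError(f"admission_rate missing shifts: {sorted(missing)}")
    missing = shift_names - set(params.roster_by_shift)
    if missing:
        raise ValueError(f"roster_by_shift missing shifts: {sorted(missing)}")
    return params


def _hour_rate(params: SimulationParams, shift_name: str) -> float:
    if isinstance(params.admission_rate, Mapping):
        return float(params.admission_rate[shift_name])
    return float(params.admission_rate)


def _draw_los(params: SimulationParams, rng: np.random.Generator) -> float:
    if params.los_distribution == "exponential":
        return float(rng.exponential(params.los_mean))
    # lognormal parametrised by mean: mu = ln(mean) - sigma^2 / 2
    mu = math.log(params.los_mean) - params.los_sigma**2 / 2.0
    return float(rng.lognormal(mu, params.los_sigma))


def _assign_rn_ratios(
    n_rn: int, acuity_census: Mapping[int, int], baseline: int
) -> tuple[int, ...]:
    """Heuristic supervisor assignment of per-RN P/N ratios.

    RNs covering 1:1 patients get ratio 1 (one each), RNs covering 2:1
    patients get ratio 2 (two each), and the remainder get the unit
    baseline.  This stands in for a judgement call the real supervisors
    make; the true assignment distribution is unobserved.
    """
    ratios: list[int] = []
    remaining = n_rn
    take_ones = min(acuity_census.get(1, 0), remaining)
    ratios += [1] * take_ones
    remaining -= take_ones
    take_twos = min(math.ceil(acuity_census.get(2, 0) / 2), remaining)
    ratios += [2] * take_twos
    remaining -= take_twos
    ratios += [baseline] * remaining
    return tuple(ratios)


def simulate_ward(params: SimulationParams, policy: UnitPolicy) -> WardTrace:
    """Generate one synthetic ward trace and compute its capacity results.

    Per hour: patients present evolve their acuity by one Markov step;
    patients whose stay has elapsed are discharged (at the first hour
    boundary at or past admission + LOS); Poisson admissions arrive, each
    with an initial acuity and a stay drawn at admission — arrivals beyond
    the authorized capacity are diverted and logged; the shift roster is
    realized (absences fixed per shift, indirect reassignment redrawn per
    hour); per-RN ratios are assigned heuristically; and the snapshot plus
    its :class:`~wardcap.core_model.CapacityResult` are emitted.
    """
    validate_policy(policy)
    validate_params(params, policy)
    rng = np.random.default_rng(params.seed)
    init_cum = np.cumsum(np.asarray(params.acuity_init, dtype=float))
    trans_cum = np.cumsum(np.asarray(params.acuity_transition, dtype=float), axis=1)

    # patient state: parallel lists of acuity ratio and due hour index
    acuities: list[int] = []
    due: list[int] = []

    snapshots: list[HourlySnapshot] = []
    current_shift: Optional[str] = None
    present: dict[SkillType, int] = {}
    diverted_total = 0

    for h in range(params.horizon_hours):
        ts = params.start + timedelta(hours=h)
        shift = shift_of_hour(policy, ts.hour)

        # acuity evolution (one Markov step for everyone already in the unit,
        # inverse-CDF sampled against the cumulative transition rows)
        if acuities:
            arr = np.asarray(acuities, dtype=int) - 1
            u = rng.random(arr.size)
            acuities = ((trans_cum[arr] < u[:, None]).sum(axis=1) + 1).tolist()

        # discharges due this hour
        keep = [i for i in range(len(acuities)) if due[i] > h]
        n_dis = len(acuities) - len(keep)
        acuities = [acuities[i] for i in keep]
        due = [due[i] for i in keep]

        # admissions, diverted beyond authorized capacity
        arrivals = int(rng.poisson(_hour_rate(params, shift.name)))
        space = policy.authorized_capacity - len(acuities)
        admitted = min(arrivals, space)
        if arrivals > admitted:
            diverted_total += arrivals - admitted
            logger.info(
                "event=diversion unit=%s hour=%d arrivals=%d admitted=%d",
                policy.unit_id, h, arrivals, admitted,
            )
        for _ in range(admitted):
            acuities.append(int((init_cum < rng.random()).sum()) + 1)
            los = _draw_los(params, rng)
            due.append(h + max(1, math.ceil(los)))

        # roster: absences frozen at shift change, indirect flips every hour
        if shift.name != current_shift:
            current_shift = shift.name
            sched = params.roster_by_shift[shift.name]
            present = {
                s: int(rng.binomial(int(sched.get(s, 0)), 1.0 - params.absence_prob))
                for s in SkillType
            }
        direct = {
            s: int(rng.binomial(present.get(s, 0), 1.0 - params.indirect_prob))
            for s in SkillType
        }

        acuity_census = {r: 0 for r in ACUITY_RATIOS}
        for a in acuities:
            acuity_census[a] += 1
        snapshots.append(
            HourlySnapshot(
                unit_id=policy.unit_id,
                timestamp=ts,
                census=len(acuities),
                acuity_counts=tuple(
                    PatientAcuityCount(r, acuity_census[r]) for r in ACUITY_RATIOS
                ),
                direct_staff=direct,
                rn_assigned_ratios=_assign_rn_ratios(
                    direct[SkillType.RN], acuity_census, policy.baseline_ratio
                ),
                admissions=admitted,
                discharges=n_dis,
            )
        )

    if diverted_total:
        logger.info(
            "event=diversion_summary unit=%s diverted=%d", policy.unit_id, diverted_total
        )
    results = [dynamic_bed_count(s, policy) for s in snapshots]
    return WardTrace(
        unit_id=policy.unit_id,
        authorized_capacity=policy.authorized_capacity,
        snapshots=snapshots,
        results=results,
    )


# ---------------------------------------------------------------------------
# Scenario presets

# Hour-to-hour acuity chain, recovery-biased: stay 0.90, deteriorate one
# class (toward 1:1) 0.03, recover one class (toward 5:1) 0.07, reflected at
# the ends.  The bias keeps the stationary mix low-acuity-heavy (roughly
# 2/5/11/25/58% over ratios 1..5), as on a real acute unit, instead of
# drifting long-stay patients toward a uniform acuity spread.
_P_WORSEN, _P_RECOVER = 0.03, 0.07


def _transition_row(r: int) -> tuple[float, ...]:
    row = [0.0] * 5
    if r > 1:
        row[r - 2] = _P_WORSEN
    if r < 5:
        row[r] = _P_RECOVER
    row[r - 1] = 1.0 - sum(row)
    return tuple(row)


_DEFAULT_TRANSITION: tuple[tuple[float, ...], ...] = tuple(
    _transition_row(r) for r in ACUITY_RATIOS
)


def _acute_policy(unit_id: str, capacity: int) -> UnitPolicy:
    """Med-surg-style policy: NHPPD 6 h, RN-heavy skill mix, 1:5 baseline."""
    return UnitPolicy(
        unit_id=unit_id,
        authorized_capacity=capacity,
        baseline_ratio=5,
        nhppd_policy=NhppdPolicy(
            nhppd=6.0,
            shift_mix={"day": 0.40, "evening": 0.35, "night": 0.25},
            skill_mix={SkillType.RN: 0.70, SkillType.LPN_LVN: 0.10, SkillType.NA: 0.20},
        ),
        shifts=DEFAULT_SHIFTS,
    )


def scenario_fixtures() -> dict[str, tuple[SimulationParams, UnitPolicy]]:
    """Named (params, policy) presets spanning the unit profiles of interest.

    ``acute-large``: a 34-bed medical-surgical unit running near 23 patients;
    ``acute-small``: an 18-bed unit of the same type near 14 patients;
    ``icu-like``: a 15-bed critical-care unit near 9 patients with acuity
    mass on the 1:1/2:1 classes, NHPPD 16 h and a 1:2 baseline ratio.
    Admission rates and mean stays were chosen so the offered load
    (rate x mean stay) sits at those censuses.
    """
    presets: dict[str, tuple[SimulationParams, UnitPolicy]] = {}

    large = _acute_policy("acute-large", 34)
    presets["acute-large"] = (
        SimulationParams(
            admission_rate={"day": 0.42, "evening": 0.36, "night": 0.20},
            los_mean=72.0,
            los_distribution="lognormal",
            los_sigma=0.7,
            acuity_init=(0.05, 0.10, 0.15, 0.40, 0.30),
            acuity_transition=_DEFAULT_TRANSITION,
            roster_by_shift={
                "day": {SkillType.RN: 6, SkillType.LPN_LVN: 1, SkillType.NA: 3},
                "evening": {SkillType.RN: 6, SkillType.LPN_LVN: 1, SkillType.NA: 2},
                "night": {SkillType.RN: 5, SkillType.LPN_LVN: 1, SkillType.NA: 2},
            },
            absence_prob=0.05,
            indirect_prob=0.08,
        ),
        large,
    )

    small = _acute_policy("acute-small", 18)
    presets["acute-small"] = (
        SimulationParams(
            admission_rate={"day": 0.26, "evening": 0.22, "night": 0.12},
            los_mean=72.0,
            los_distribution="lognormal",
            los_sigma=0.7,
            acuity_init=(0.05, 0.10, 0.15, 0.40, 0.30),
            acuity_transition=_DEFAULT_TRANSITION,
            roster_by_shift={
                "day": {SkillType.RN: 4, SkillType.LPN_LVN: 1, SkillType.NA: 2},
                "evening": {SkillType.RN: 4, SkillType.LPN_LVN: 0, SkillType.NA: 2},
                "night": {SkillType.RN: 3, SkillType.LPN_LVN: 0, SkillType.NA: 1},
            },
            absence_prob=0.05,
            indirect_prob=0.08,
        ),
        small,
    )

    icu = UnitPolicy(
        unit_id="icu-like",
        authorized_capacity=15,
        baseline_ratio=2,
        nhppd_policy=NhppdPolicy(
            nhppd=16.0,
            shift_mix={"day": 0.38, "evening": 0.34, "night": 0.28},
            skill_mix={SkillType.RN: 0.85, SkillType.LPN_LVN: 0.05, SkillType.NA: 0.10},
        ),
        shifts=DEFAULT_SHIFTS,
    )
    presets["icu-like"] = (
        SimulationParams(
            admission_rate={"day": 0.14, "evening": 0.12, "night": 0.08},
            los_mean=84.0,
            los_distribution="lognormal",
            los_sigma=0.8,
            acuity_init=(0.35, 0.40, 0.15, 0.07, 0.03),
            acuity_transition=_DEFAULT_TRANSITION,
            roster_by_shift={
                "day": {SkillType.RN: 6, SkillType.LPN_LVN: 0, SkillType.NA: 1},
                "evening": {SkillType.RN: 6, SkillType.LPN_LVN: 0, SkillType.NA: 1},
                "night": {SkillType.RN: 5, SkillType.LPN_LVN: 0, SkillType.NA: 1},
            },
            absence_prob=0.04,
            indirect_prob=0.06,
        ),
        icu,
    )

    for name, (p, pol) in presets.items():
        validate_params(p, validate_policy(pol))
    return presets
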