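# wardcap

Hourly nursing-capacity calculation for hospital units: the **dynamic bed
count** — an acuity- and skill-mix-aware measure of how many patients a
unit's *current* direct-care staffing can optimally support — computed side
by side with the legacy **patient-to-nurse (P/N) capacity**, plus a
synthetic ward simulator and the comparison analytics (per-unit summaries,
paired *t* tests, delta series, seeded random sampling of hours).

It is written for nursing informatics and health-care operations analysts
who want to evaluate staffing calculations on hourly unit data — real
(as CSV snapshots) or simulated.

## The calculation

For one unit-hour, with a unit policy giving NHPPD *N* (nursing hours per
patient per day), shift mix σ_t, skill mix φ_s over skills ordered
RN > LPN/LVN > NA, baseline P/N ratio *r*₀ and authorized capacity *K*:

- **Baseline demand.** In the hour covered by shift *t* of length *L_t*,
  an average patient needs `d = N·σ_t/L_t·60` minutes of care, split by
  skill: `d_s = d·φ_s`.
- **Supply.** Each on-duty *direct-care* staff member contributes 60
  minutes on their own skill; admission/discharge (ADT) work consumes
  `A·m_adm + D·m_dis` minutes from the charged skill (RN by default).
- **Tiered capacity.** Care targeted at a skill may be delivered by that
  skill or any higher one, never a lower one, so every prefix *P_j* of the
  skill order constrains capacity:
  `C = min_j (Σ_{s∈P_j} S_s − adt_s) / (Σ_{s∈P_j} d_s)`, clamped at 0.
- **Acuity.** A patient at P/N class *r* ∈ {1..5} weighs `a = r₀/r`
  (a 1:1 patient needs *r*₀ times the average patient's minutes). With
  equivalent census `E = Σ count_r · r₀/r` and mean weight `ā = E/n`, the
  dynamic bed count is `DBC = min(C/ā, K)`, reported to one decimal.
- **Comparison.** The legacy capacity is `PN = Σ assigned ratios` over
  direct-care RNs (capped at *K*); the reported difference `DBC − PN` is
  negative when the unit should hold fewer patients than the P/N method
  allows, and each hour is flagged understaffed / adequate / overstaffed
  by comparing census with DBC.

## Worked example

A 34-bed unit, NHPPD 6 h split evenly across three 8-h shifts, skill mix
RN/LPN/NA = 0.7/0.2/0.1, baseline ratio 4:1. At 10:00 the unit holds 20
patients (2 at 1:1, 4 at 2:1, 14 at 4:1) with 4 RNs, 1 LPN and 1 NA on
direct care:

```python
from datetime import datetime
from wardcap import *

policy = validate_policy(UnitPolicy(
    unit_id="3C", authorized_capacity=34, baseline_ratio=4,
    nhppd_policy=NhppdPolicy(
        nhppd=6.0,
        shift_mix={"night": 1/3, "day": 1/3, "evening": 1/3},
        skill_mix={SkillType.RN: 0.7, SkillType.LPN_LVN: 0.2, SkillType.NA: 0.1},
    ),
    shifts=DEFAULT_SHIFTS,
))
snap = HourlySnapshot(
    unit_id="3C", timestamp=datetime(2023, 1, 1, 10), census=20,
    acuity_counts=(PatientAcuityCount(1, 2), PatientAcuityCount(2, 4),
                   PatientAcuityCount(4, 14)),
    direct_staff={SkillType.RN: 4, SkillType.LPN_LVN: 1, SkillType.NA: 1},
    rn_assigned_ratios=(5, 5, 5, 5), admissions=0, discharges=0,
)
res = dynamic_bed_count(snap, policy)
print(res.dbc, res.pn_capacity, res.difference, res.status.value)
```

prints

```
14.8 20.0 -5.2 understaffed
```

Reading: demand is 15 min/patient/h (10.5 RN + 3.0 LPN + 1.5 NA); supply
is 240/60/60 min, so the tiered capacity is min(240/10.5, 300/13.5,
360/15) = 22.2 average patients. The case mix weighs ā = 30/20 = 1.5
average patients each, so staffing optimally supports 14.8 of *these*
patients — while the assigned P/N ratios would admit 20. The unit holds 20:
understaffed by the dynamic count, 5.2 beds over what the P/N ratio
suggests.

## Command line

```
wardcap simulate --preset acute-large --seed 42 --hours 3480 --out snaps.csv
wardcap compute  --policy policy.yaml --snapshots snaps.csv --out results.csv
wardcap compare  --results results.csv --out summary.csv
wardcap sample   --results results.csv -k 10 --seed 7 --out table2.csv
wardcap run      --preset acute-large --seed 42 --hours 3480 --outdir out/
```

`run` chains the four stages and writes a JSON manifest with input/output
digests. Presets `acute-large` (34 beds), `acute-small` (18) and
`icu-like` (15, high acuity) are built in; `--policy`/`--params` YAML
files override them. Every command that draws random numbers requires
`--seed`, and identical seeds reproduce byte-identical outputs.

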