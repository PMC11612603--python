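# Methods

## The capacity model

`wardcap` quantifies, hour by hour, how many patients a unit's current
direct-care staffing can optimally support. Two quantities are computed per
unit-hour and compared:

**Dynamic bed count (DBC).** Target care is anchored in the unit's NHPPD
policy: each patient must receive *N* hours of nursing care per 24 h,
delivered in fractions σ_t per shift (night/day/evening) and φ_s per skill
(RN, LPN/LVN, NA). We interpret σ_t as the *per-shift total* share of daily
care, spread evenly over the shift's hours, giving a baseline demand of
`d = N·σ_t/L_t·60` minutes per average patient per hour, split as
`d_s = d·φ_s`. Supply is 60 minutes per on-duty direct-care staff member on
their own skill; minutes for admissions (`m_adm`, default 60) and
discharges (`m_dis`, default 30) are subtracted from the supply of the
charged skill (RN by default — admission assessment and discharge education
are RN scope-of-practice work). Skills substitute strictly downward: an RN
can absorb LPN/LVN- or NA-level work, never the reverse. Feasibility of
staffing *m* average patients therefore reduces to prefix constraints along
the skill order, and the equivalent capacity is the tier minimum

    C = min over prefixes P_j of  (Σ_{s∈P_j} S_s − adt_s) / (Σ_{s∈P_j} d_s),

clamped below at zero. A prefix with zero baseline demand imposes no ratio
bound, but ADT minutes charged into such a prefix beyond its supply are
unstaffable and clamp capacity to zero (only that prefix may serve them).
Patient acuity is expressed as the P/N ratio class r ∈ {1..5} appropriate
for the patient, and its demand multiplier is linear in 1/r:
`a = r_base/r`, so a 1:1 patient consumes `r_base` average patients' worth
of minutes and a patient at the unit's baseline ratio weighs exactly 1.
With equivalent census `E = Σ_r count_r · a_r` and mean weight `ā = E/n`
(ā = 1 for an empty unit, keeping DBC defined), the dynamic bed count is
`DBC = min(C/ā, K)` where *K* is the authorized (physical) bed capacity.
DBC is deliberately *not* clamped to the census: hours where the unit holds
more patients than staffing supports are the finding, not an error.

**P/N capacity.** The legacy figure is the sum of supervisor-assigned P/N
ratios over direct-care RNs, capped at *K*. Ratios are carried per RN, not
as one unit-wide ratio, so totals like 26 or 29 are representable. LPN/LVN
and NA staff do not enter this figure — that asymmetry versus the DBC is
the point of the comparison.

**Reporting.** DBC, P/N capacity and their difference are reported to one
decimal (round-half-even; internal computation is full precision). The
staffing status flag compares census against DBC with a tolerance
(default 0.5 patients): understaffed if `census − DBC > tol`, overstaffed
if `DBC − census > tol`, adequate otherwise.

### Parameters that matter

| parameter | units | default | why |
|---|---|---|---|
| `nhppd` | h/patient/day | 6 (acute), 16 (ICU preset) | typical med-surg vs critical-care care targets |
| `shift_mix` | fractions | day-weighted (0.40/0.35/0.25) | daytime care concentration |
| `skill_mix` | fractions | RN-heavy (0.70/0.10/0.20) | med-surg staffing composition |
| `baseline_ratio` | patients/nurse | 5 (acute), 2 (ICU) | med-surg and ICU ratio rules |
| `m_adm`, `m_dis` | min/event | 60, 30 | admission workup is roughly an hour; discharge education about half |
| `status_tolerance` | patients | 0.5 | half a bed: below reporting resolution |
| shift clock | — | night 23–07, day 07–15, evening 15–23 | conventional 8/8/8 pattern; overridable in config |

Timestamps denote the left-closed hour `[h, h+1)`; ADT events inside the
interval belong to that hour. Hours are assigned to shifts by the same
left-closed convention, wrapping midnight.

## Synthetic ward generator

The simulator produces hourly snapshot streams with the statistical
structure the engine consumes: Poisson admissions (optionally per shift),
length of stay drawn at admission (exponential, or lognormal parametrised
by its mean), acuity evolving on the hour grid by a stationary Markov chain
over the five ratio classes, shift rosters thinned by whole-shift absences
and by hourly direct/indirect reassignment, and a heuristic supervisor
assignment of per-RN ratios (RNs covering 1:1 patients take ratio 1, pairs
of 2:1 patients pin ratio 2, the remainder take the unit baseline).
Admissions beyond authorized capacity are diverted (dropped and logged),
not queued; discharge occurs at the first hour boundary at or past
admission + LOS. One `numpy` generator seeded per trace makes byte-level
reproducibility a hard contract.

The default acuity chain is recovery-biased (stay 0.90, worsen 0.03,
recover 0.07 per hour, reflected at the ends), whose stationary mix
(≈2/5/11/25/58% over ratios 1..5) stays low-acuity-heavy like a real acute
unit; a symmetric walk would drift long-stay patients toward a uniform
acuity spread. Preset admission rates and mean stays put the offered load
(rate × mean stay) near the intended censuses: `acute-large` ≈ 23 patients
in 34 beds, `acute-small` ≈ 14 in 18, `icu-like` ≈ 9 in 15 with acuity
mass on 1:1/2:1.

What the generator does **not** emulate: clinical content, inter-unit
transfers, admission queues, sub-hourly timing, day-of-week or seasonal
census cycles, and any empirical distribution of supervisor-assigned
ratios (the heuristic is a documented stand-in). Passing tests therefore
demonstrate correctness of the calculations and pipeline on structurally
realistic data, not calibration to any particular hospital's records.

## Statistical layer

Summaries report arithmetic means and sample SDs (n−1) of census,
authorized capacity, DBC and P/N capacity per unit, with a pooled
"All units" row that concatenates unit-hours rather than averaging unit
means — consequently its authorized-capacity SD is nonzero whenever units
have different bed counts. The paired two-tailed Student *t* test runs on
aligned hourly series (`t = mean(d)/(sd(d)/√n)`, df = n−1, p from the *t*
distribution at every n, no normal approximation). Zero-variance
differences are reported as degenerate rather than silently producing a
statistic: identical series mean "no difference" (summaries record p = 1),
a constant nonzero offset means "p → 0" (recorded as p = 0). Random
sampling of hours is uniform without replacement via the standard-library
`random` generator, seeded explicitly, output chronological.

## Numerical and design choices

- Tie-break in the tier minimum: the highest (most-RN-ward) binding prefix
  is logged as the bottleneck; prefixes with zero demand are skipped.
- Zero total demand with nonzero supply raises an error ("no demand
  profile") instead of returning infinite capacity.
- Mix fractions must sum to 1 within 1e-9; shifts must tile the 24-h day
  exactly, left-closed.
- The SD tie in most-variable-unit selection breaks lexicographically and
  is logged.
- CSV outputs format reported quantities at one decimal and carry full
  precision for the diagnostic columns (equivalent capacity, mean acuity
  weight) in shortest round-trip form; every output is re-readable by the
  package's own readers.
- The run manifest records a wall-clock timestamp, so determinism is
  defined over the four data files, not the manifest.

Problem sizes used by the test suite and the acceptance script — 3,480
simulated hours for the pipeline (a ~145-day assessment window), 10 seeds ×
4,000 h for the offered-load check, 1,000 random instances for the
capacity-vs-oracle comparison, 10,000 replicates for the type-I-error
check — were chosen so each check's sampling error is far below the
tolerance it asserts.

## Known limitations

- The acuity-to-minutes curve is linear in 1/ratio; if real units follow a
  different multiplier curve, `acuity_weight` is the single place to change.
- Whether ADT minutes are subtracted from supply (as here) or added to
  demand is equivalent in aggregate but shifts per-skill bottlenecks; the
  subtraction convention is a committed choice.
- Indirect-care overhead (charge-nurse duties, float coordination) is
  modeled only as the binary direct/indirect flag.
- The P/N capacity counts RNs only; jurisdictions that count LPN/LVNs
  toward ratios would need a policy switch that does not yet exist.
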