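# Methods

This note documents the algorithms, the constants they depend on, the
synthetic-data model used to exercise them, and the design decisions made
where the underlying definitions were genuinely open.

## Castration ascertainment

**Medical castration** requires at least 90 covered days of GnRH supply
inside some 183-day window ("3 months within 6 months", with months
expressed as 90/183 integer days). Coverage is the union of
`[fill date, fill date + days supplied)` periods — overlapping fills
count once. The castration date is the day the criterion is first
fulfilled: the 90th covered day of the earliest qualifying window, not
the first fill date. The implementation is a vectorised rolling-window
count over a boolean day array and is property-tested against a
day-by-day brute force.

**Surgical castration** starts at the hospital admission date and never
ends. Antiandrogen monotherapy never establishes castration; such men
are outside the cohort by design.

A medical castration interval closes when the coverage gap exceeds
`grace_days` (default **90 days**). The gap rule is deliberately
configurable: refill adherence in practice is high but not perfect, and
the threshold that should terminate an episode is a judgement call. PSA
values up to `grace_days` after coverage ends still count as "whilst
castrated" unless `strict_castration` is set (the sensitivity analysis
that ignores PSA after long GnRH gaps).

## CRPC detection

The running nadir is the prefix minimum of PSA from castration start;
ties keep the earliest date. Pre-castration PSA never contributes. A
CRPC event is the **first** measurement, eligible as above, with

* value ≥ 2·nadir **and** value > 2 ng/ml (*doubling* clause), or
* value − nadir ≥ 5 ng/ml (*absolute* clause),

recording which clause(s) fired. Both comparisons are inclusive (≥): the
doubling clause reads "doubling of the nadir" as attaining twice its
value, and the absolute clause as "5 ng/ml or more". Whether the
original definitions were inclusive is not documentable from the printed
rule; the inclusive reading is used consistently and the detector is
verified exactly (event presence, date and rule) against an exhaustive
re-scan oracle on 10,000 random series.

## PSA kinetics

PSA-DT is ln 2 divided by the OLS slope of ln PSA on time (days) over
**[nadir date, CRPC date] inclusive** — the regrowth phase that defines
the event. A non-positive slope yields +∞ (flat or falling PSA). A
two-point estimator (nadir and triggering measurements only) is provided
as `dt_method="two_point"` for sensitivity analysis; OLS is the default
because it uses all regrowth measurements and is exact on noise-free
exponentials. Halving time applies the same machinery to
[castration start, nadir]; it is *not applicable* when PSA never fell
below its starting value or the fitted slope is non-negative.

Categorical bins follow the baseline-table conventions of the field,
with months = 30.44 days. Printed doubling-time categories ("1–2
months", "3–4 months", …) are rounded labels with a gap between 2 and 3;
they are implemented as a contiguous partition with internal edges at
the midpoints — 1, 2.5, 4.5, 6.5 and 12 months — left-open,
right-closed, so every value maps to exactly one bin (property-tested by
grid scan).

## Risk score

```
score = ln(PSA at CRPC) − 1.40 · ln(PSA-DT)
cutoffs: −6.09, −4.73, −3.34, −1.58   (boundary → lower group)
```

The published constants do not state the log base or the DT unit. Only
**natural logarithms with DT in days** are consistent with the
qualitative description of group 1 — reachable at PSA near 200 ng/ml
only with a multi-year doubling time (1.40·ln DT ≥ ln 200 + 6.09 needs
DT ≈ 3,400 days ≈ 9 years; impossible in months/years units or base-10
logs), and reachable at a ~4-month doubling time only just above the
2 ng/ml floor. Both choices are fields of `RiskModel`, so alternates are
a one-line change. An infinite doubling time maps to score −∞, hence
group 1, with a warning: no PSA growth is the lowest-risk limit.

The coefficient and cutoffs are treated as **inputs**, not re-derived:
the spline/GAM interaction fit that produced them requires the original
registry data.

## Survival stage

* Time zero is the CRPC date (GnRH start selectable for sensitivity).
* KM median OS with 95% CI from the log(−log) (exponential Greenwood)
  transform, via lifelines.
* Cox models are **cause-specific** (other-cause death censored for
  PC-specific mortality) with Efron tie handling — registry deaths are
  recorded to the day, so ties are common. Covariate levels without any
  event are merged into the reference with a warning rather than left to
  separate. Reference levels follow the forest-plot conventions (PSA-DT
  "1+ years", PSA at CRPC "≤3 ng/ml", age "≤65", M0, …).
* Harrell's C uses event-anchored comparable pairs; marker ties count
  0.5; pairs censored before the earlier event are not comparable. It is
  verified against O(n²) enumeration and, on tie-free times, against
  lifelines.
* The Aalen–Johansen estimator is computed directly from the event
  table: at each event time *s*, cause *k* gains S(s⁻)·d_k(s)/n(s) with
  S the all-cause KM survivor function. This makes
  cif_pc + cif_other + surv = 1 hold to machine precision at every step
  and keeps integer-day ties exact (library AJ implementations jitter
  tied times). It is cross-checked against lifelines on tie-free data
  and against the constant-hazard closed form
  (λ_pc/λ)(1 − e^(−λt)).

## Synthetic registry model

The generator produces the registry the analysis assumes, with full
ground truth. Per patient (all draws from a stream seeded with
`(seed, patient index)`, so cohorts extend without reshuffling):

| quantity | default | rationale |
|---|---|---|
| PSA at ADT start | log-normal, median 40 ng/ml, σ=1.4 | broad registry distribution from ≤10 to 500+ |
| nadir fraction | log-normal, median 0.05, σ=1.6, capped at 1 | deep but variable response; the ≥1 tail (~5%) never declines, yielding "halving time not applicable" patients |
| time to nadir | log-normal, median 180 d, σ=0.5 | months-scale decline |
| true doubling time | log-normal, median 140 d, σ=0.7 | centred between 3 and 6 months |
| measurement noise | multiplicative log-normal, CV 0.15 | PSA assays have roughly constant CV |
| sampling interval | mean 75 d, uniform ±50% jitter | quarterly-ish surveillance testing |
| refills | 90-day GnRH supply, adherence 0.95 | high long-term adherence |
| surgical fraction | 0.10 of primary-ADT men | registry share of orchiectomy |
| composition | 13% curative, 24% deferred, 63% primary ADT; M1 27%; neoadjuvant 3% | baseline-table structure |

The noise-free trajectory is bi-exponential with a single nadir —
exponential decay from ADT start to the nadir, then
value(t) = nadir · 2^((t − t_nadir)/DT). The **true CRPC date** is the
first time this curve satisfies the detection rule with the running
nadir tracked from castration start (if eligibility begins after the
curve minimum, the reference nadir is the curve value at eligibility
start, exactly as the detector would see it). For medical castration the
truth assumes the 3-months-in-6 criterion completes 89 days after the
first fill; with adherence below 1 the detected castration date can
shift slightly, which is part of what the noisy-path tests tolerate.

Event times are competing exponentials: per-day PC-death hazard
`exp(−5.49 + 0.41·score)` from the true CRPC date, other-cause hazard
`exp(−14.39 + 0.08·age)` from ADT start, migration censoring at
0.01/year, administrative censoring at the region's follow-up end
(2014-12-31 or 2016-12-31). The two hazard calibrations are solved once
from the cohort-level survival structure the pipeline is meant to
reproduce qualitatively — group-level median OS of roughly 3.7 y (group
1) down to 0.6 y (group 5) with PC-death shares rising from ~57% to
~89% — assuming an other-cause hazard of ~9%/year at age 76. Constant
(piecewise-trivial) hazards keep the Aalen–Johansen stage checkable in
closed form.

**What the generator does not emulate:** assay drift and
lab-changeovers, treatment switching (chemotherapy, novel
antiandrogens), bone-scan/metastasis dynamics, hazard non-proportionality
over calendar time, and correlation between PSA kinetics and comorbidity.
Passing tests therefore demonstrate the *algorithmic* correctness of the
pipeline and its behaviour under the stated statistical structure, not
the clinical validity of the score on any real cohort.

## Problem sizes and tolerances in the test suite

Detection-oracle equivalence runs on 10,000 random series (exact
agreement required); Harrell's C on fixtures up to n = 200 (exact);
Aalen–Johansen closed form at n = 5,000 within 0.02 sup-norm; parameter
recovery at n = 2,000 over 50 seeded replicates (orderings in ≥ 95%,
known-HR coverage in ≥ 90%); and the mortality-gradient check on the
default simulation at n = 4,098, the size of the cohort the generator
emulates. Noise-free doubling-time recovery is required to 1e-9 relative
error; partition-of-unity identities to 1e-12.

## Known limitations

* The detection rule sees only measured PSA: the detected CRPC date lags
  the true crossing by up to one sampling interval, and measurement
  noise can fire the rule slightly early or late near the threshold.
* With `grace_days` large, a PSA taken long after effective castration
  ended can still trigger; the strict mode errs the other way. Neither
  matches an unobservable testosterone-based definition.
* The score's constants are fixed inputs; no uncertainty in them is
  propagated.
* Cause-specific hazard ratios do not estimate subdistribution
  (Fine–Gray) effects; the cumulative-incidence stage is the correct
  absolute-risk summary under competing risks.
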