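# Methods

## Model structure

The disease process is a three-state discrete-time Markov chain — UNHEALED
(active venous leg ulcer), HEALED (post-ulcer), DEAD (absorbing) — with a
monthly cycle and a 36-month base-case horizon. The whole cohort enters
unhealed at cycle 0; transitions and payoffs accrue for cycles 1..horizon.
Cycle `t` represents month `t`, and segment boundaries use half-open
intervals `[start, end)`: a "month 1 to <6" segment covers cycles 1–5 and
month 6 belongs to the next segment. Open-ended final segments (`end: null`)
make the schedule cover any horizon; when a closed last segment is exceeded
(only relevant if a user writes one), the engine reuses its value.

Competing risks within a cycle are composed multiplicatively with death
first: `P(U→H) = (1−m)h(t)`, `P(H→U) = (1−m)r(t)`, `P(alive→DEAD) = m`.
This keeps every matrix row exactly stochastic without renormalization. The
ordering is a modelling convention; at the probability magnitudes involved
(h ≤ 0.133, m = 0.001) the alternative orderings differ in the fifth
decimal of an occupancy.

No half-cycle correction is applied by default; a `half_cycle_correction`
settings flag replaces end-of-cycle occupancy with the mean of the adjacent
cycle boundaries in payoff weighting (event-timed payments — ablation, the
initial visit — are not corrected). At a monthly cycle length the
correction moves totals by well under 1%.

## Transition inputs

Per-arm monthly probabilities are piecewise constant (early arm healing
0.133 / 0.090 / 0.045 over months [1,6), [6,12), [12,∞); deferred 0.119 /
0.065 / 0.032; recurrence 0.011 / 0.004 / 0.007 and 0.016 / 0.005 / 0.007
over [1,12), [12,24), [24,∞); mortality 0.001 everywhere). These printed
monthly values are the authoritative inputs. A constant-hazard
(declining-exponential) conversion utility,
`deale_monthly_probability(CI, window) = 1 − exp(ln(1−CI)/window)`, is
provided for deriving monthly probabilities from interval cumulative
incidences — the microsimulation tests exercise it against an exponential
event-time oracle — but the shipped schedule is not regenerated from
cumulative rates: the printed monthly values and the published interval
rates they were derived from are not mutually consistent under the standard
conversion, so the monthly values are taken as-is.

## Cost assembly (2021 USD, Medicare payments)

Unhealed state, per patient-month:

* **Outpatient visits** — 1/week → 52/12 ≈ 4.333 visits/month
  (configurable). Each visit bills either debridement (physician 97597 $36 +
  facility 97597 $114) with per-visit probability 12.5% during the first 3
  months only, or compression (99212 $36 + facility 29581 $83) otherwise —
  the two are mutually exclusive because compression cannot be billed on a
  debridement visit.
* **Home health** — 25% of patients; the $2 808 60-day episode is prorated
  to $1 404/month. Proration by episode (rather than by visit count) was
  chosen because only the episode payment is defined.
* **Hospitalization expectation** — monthly probabilities 0.83% (ulcer with
  complications), 0.08% (cellulitis, major complications), 0.33%
  (cellulitis, no major). The pooled 0.83% covers two DRGs (571 $10 832 and
  593 $8 882); it is split 50/50 by default via `ulcer_drg_weights`
  (configurable) since no finer breakdown is defined.
* **Pain medication** — 40% amitriptyline $43, 10% gabapentin $124, 50%
  hydrocodone $22 → $40.60/month.

Healed state: compression stockings, $72 per 6-month pair → $12/month. Dead
state accrues nothing.

One-time payments:

* **Initial visit** (99203 $85 + 11042 $63 physician; 99213 $86 + 11042
  $220 facility) charged once to the entering cohort at cycle 1, on by
  default and toggleable (`include_initial_visit`); since both arms pay it
  identically at the same cycle it cancels from every incremental result.
* **Ablation procedure** — expected cost from a 40/40/20
  mechanochemical/radiofrequency/laser mix ($1 448/$1 323/$1 215) plus a 10%
  multi-vein add-on share ($296/$314/$138): $1 378.56. The early arm pays it
  at cycle 1. The deferred arm pays at the *first* healing during months
  1–6, or at month 6 if still unhealed — implemented with a never-healed
  survivor recursion rather than unhealed-state occupancy, because occupancy
  re-admits recurred patients and would double-charge them; with zero
  mortality exactly 100% of the cohort is charged once. Recurrence never
  triggers a second ablation: each arm delivers a single intervention.

Antibiotic costs are excluded (negligible). All ±20% sensitivity ranges are
generated programmatically as (0.8×base, 1.2×base) rather than read from
rounded printed ranges.

## Utilities and discounting

State utilities: unhealed 0.69, healed 0.75, dead 0. Both alive-state
utilities are multiplied by a single aging-adjustment factor representing
the preference decrement of a 65+ cohort relative to the younger
populations the raw scores describe. The published aging-disutility values
behind that adjustment are not available, so the factor was calibrated once
— `scripts/calibrate_age_adjustment.py` solves (by a single division; QALYs
are linear in the factor) for the value making the deferred-arm 3-year
discounted QALY total equal 1.985 — and frozen at 0.970706 in
`basecase.yaml`. The calibration is disclosed rather than hidden; it pins
one QALY level and leaves every incremental quantity untouched (the factor
multiplies both arms).

QALYs accrue at utility/12 per monthly cycle. Costs and QALYs are both
discounted at 3%/year compounded monthly, `d(t) = 1.03^(−t/12)`.

## Sensitivity analyses

A parameter registry enumerates every independently variable scalar: 13
transition probabilities (12 segment values + mortality), 23 unit costs,
the 3 hospitalization probabilities, multi-vein / debridement / home-health
fractions, visits per month, and the 2 state utilities (45 in all).
Sum-to-one mixes (procedure, pain medication, DRG split) and the calibrated
aging factor are held fixed.

**Tornado.** Each parameter is set to 0.8× and 1.2× base (others fixed) and
the deterministic model rerun; entries are sorted by the spread of the
resulting INMB interval. Perturbations violating a hard constraint are
clipped with a warning: probabilities at 1, and the alive-state utilities
at their ordering (varying unhealed up to 0.828 clips at healed 0.75).

**PSA.** Every registered probability, cost and utility (not visits/month,
a rate rather than a measured quantity) is drawn independently, by default
from Uniform(0.8×base, 1.2×base) — the only uncertainty statement the
inputs carry is the ±20% range. A `beta-gamma` family (beta for
probabilities/utilities, gamma for costs, mean = base and sd = 0.2·base/1.96
so ±20% ≈ a 95% interval) is available. Out-of-range probability draws and
utility pairs violating unhealed ≤ healed are rejection-resampled; note the
ordering constraint truncates the joint utility distribution toward larger
healed−unhealed gaps, which is why the mean PSA INMB sits above the
deterministic base-case INMB (~$5.5k vs ~$4.1k at default settings). All
randomness flows from one `numpy` Generator seed; a fixed seed makes the
draw matrix bit-reproducible. The default iteration count is 10 000
(configurable).

CEAC and EVPI are computed from the stored (ΔC, ΔQ) matrix with no
resampling, so mean INMB, CEAC and EVPI are mutually consistent:
`CEAC(λ) = P(λΔQ − ΔC > 0)` and, with deferred ablation as the zero-NMB
reference, `EVPI = E[max(INMB,0)] − max(E[INMB],0) ≥ 0`, zero whenever one
strategy wins in every draw.

A structural note on magnitudes: with a $100 000/QALY threshold, a 0.06
utility gap and a 36-month horizon, moving a single monthly transition
probability by ±20% can shift INMB by at most a few thousand dollars (the
QALY term is bounded by gap × occupancy-months moved / 12 × λ, and the cost
term by the unhealed monthly cost times the same occupancy shift). Under
independent ±20% draws the INMB distribution therefore concentrates well
above zero: the acceptability curve is near 1 at every threshold and the
EVPI is near zero — parameter uncertainty at this scale does not threaten
the adoption decision.

## Budget impact

Per-patient cost differences (deferred minus early = saving) are taken from
the discounted arm totals at the matching horizon and scaled to a
hypothetical plan (1 million members, 1000 cases):
`total = cases × saving`, `PMPM = total / (members × 12 × years)`, reported
at 1, 3 and 5 years. Discounted differences are the default for consistency
with the cost-effectiveness results; an undiscounted flag covers
budget-impact guidance that prefers nominal dollars. The 5-year run extends
the horizon to 60 cycles, reusing each schedule's final open-ended segment
beyond month 36.

## Synthetic data / microsimulation

`simulate_patients` draws individual monthly paths under exactly the
process the cohort engine assumes — death first, then healing or recurrence
among survivors, per-segment probabilities, censoring only at the horizon —
so the cohort trace is the exact expectation of the empirical occupancy,
and agreement is tested within binomial Monte Carlo error rather than
asymptotically. `estimate_monthly_probabilities` inverts the generator:
per-segment events divided by patient-months at risk, with binomial
standard errors, flagging segments with nobody at risk.

What the generator does *not* emulate: covariates and patient
heterogeneity, site effects, administrative censoring patterns of a real
trial, and patient-level cost variation (costs stay cohort-level
expectations). Passing the round-trip and oracle tests therefore
demonstrates internal consistency of the engine and estimator, not fidelity
to any real patient population.

## Numerical choices and test scale

Trace rows are checked to sum to 1 within 1e−10 over all cycles; matrix
rows within 1e−12; the cost-component decomposition must match the direct
total within $1e−6. Oracle-agreement tests run 200 000 simulated patients
(3 binomial SEs at months 6/12/36), parameter recovery 100 000, and the
PSA-based checks 10 000 iterations — sizes at which the whole suite runs in
well under a minute on one CPU.

## Known limitations

* Single all-cause mortality: no arm-, state- or age-dependence over the
  horizon, and no excess ulcer mortality.
* No tunnel states: a recurred ulcer behaves exactly like an incident one
  (same healing schedule, no second ablation).
* Independent PSA draws: no correlation between parameters, and mixture
  fractions are not varied (a Dirichlet draw would be the natural
  extension).
* The utility-ordering rejection step biases the mean drawn utility gap
  upward (quantified above).
* The 5-year budget projection rests on extrapolated transition
  probabilities (final-segment carry-forward) and has no external anchor.
* One configuration convention — the 50/50 DRG split of the pooled
  hospitalization probability, episode-based home-health proration, and the
  once-charged initial visit — is defensible but not uniquely determined by
  the available inputs; all three are configurable.
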