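# vlucea

Cost-effectiveness modelling of compression therapy with **early versus
deferred endovenous ablation** for venous leg ulcers (VLU), from the US
Medicare perspective.

Venous leg ulcers are slow-healing, frequently recurring lower-extremity
wounds. Standard care is compression therapy; ablating the refluxing
superficial vein early (within ~2 weeks) rather than after the ulcer heals
(or at 6 months if it has not) speeds healing. This package asks the payer's
question: does early ablation's up-front procedure cost pay for itself by
shortening the expensive unhealed phase, and by how much? It is written for
health-economics analysts: a fully importable API, a small CLI, and
YAML-configurable inputs.

## Model

A 3-state Markov cohort model with monthly cycles:

```
UNHEALED  --h(t)-->  HEALED  --r(t)-->  UNHEALED
    \                   |
     m                  m
      \                 v
       +------------> DEAD (absorbing)
```

* `h(t)`, `r(t)` — piecewise-constant monthly healing / recurrence
  probabilities per arm (segments: months [1,6), [6,12), [12,∞) for healing;
  [1,12), [12,24), [24,∞) for recurrence), from trial-derived inputs.
* `m` — all-cause monthly mortality (65+), identical across arms and alive
  states. Within a cycle death is applied first, then events among
  survivors, so `P(U→H) = (1−m)·h(t)`.
* The cohort enters unhealed; occupancy evolves as `x_t = x_{t-1} M(t)`.

Per-cycle payoffs (costs in 2021 USD from Medicare CPT/DRG payments,
utilities 0.69 unhealed / 0.75 healed with a calibrated aging factor) are
discounted at 3%/year, `d(t) = 1.03^(−t/12)`, and folded into per-arm totals.
Decision metrics follow the standard calculus: ICER = ΔC/ΔE with dominance
flagging, and the incremental net monetary benefit
`INMB = λ·ΔE − ΔC` at λ = $100 000/QALY (early minus deferred; positive
favors early). On top of the deterministic model sit a tornado analysis
(±20% one-way), a probabilistic sensitivity analysis with
cost-effectiveness acceptability curve `CEAC(λ) = P(INMB > 0)` and
per-person expected value of perfect information
`EVPI = E[max(INMB, 0)] − max(E[INMB], 0)`, a plan-level budget-impact
analysis (totals and per-member-per-month), and a patient-level
microsimulation used to validate the cohort engine and re-estimate the
transition probabilities from simulated records.

## Worked example

```python
from vlucea import load_config, run_base_case

bundle = load_config()                      # shipped base case
res = run_base_case(bundle, horizon_months=36)
print(round(res.early.total_cost), round(res.deferred.total_cost))
print(round(res.early.total_qalys, 3), round(res.deferred.total_qalys, 3))
print(res.incremental.icer_flag, round(res.incremental.inmb))
```

prints

```
12920 15661
1.998 1.985
dominant 4074
```

Over 3 years the early-ablation arm costs $12 920 and yields 1.998
discounted QALYs per patient, versus $15 661 and 1.985 QALYs for deferred
ablation: early ablation *dominates* (cheaper and
more effective), with an incremental net monetary benefit of about $4 074
per patient at $100 000/QALY. `examples/` contains runnable scripts for each
capability (base case, tornado, PSA/CEAC/EVPI, budget impact,
microsimulation validation), and the same analyses are available from the
shell:

```bash
vlucea basecase --outdir out/
vlucea sensitivity --mode psa --iterations 10000 --seed 1 --outdir out/
vlucea budget --outdir out/
```

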