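"""Cost and QALY accumulation over cohort traces, and incremental results.

Costs are assembled bottom-up from Medicare unit payments and utilization
assumptions:

* one-time ablation procedure (procedure mix + multi-vein add-on), timed per
  arm (at entry for early ablation; at healing or month 6 for deferred);
* an initial outpatient visit charged once to the entering cohort;
* weekly outpatient visits while unhealed, with per-visit debridement during
  the first 3 months only (compression billing is disallowed on a
  debridement visit, so the two visit types are mutually exclusive);
* home health for a fraction of unhealed patients, episode cost prorated
  monthly;
* expected hospitalization (ulcer complications and cellulitis) while
  unhealed;
* pain medication while unhealed;
* compression stockings while healed.

QALYs accrue at utility/12 per monthly cycle, with a multiplicative aging
adjustment on both alive states. Everything is discounted at the annual rate
compounded in months: d(t) = (1 + rate)^(-t/12).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .markov import CohortTrace, HealthState, run_cohort
from .params import (
    AnalysisSettings,
    CostParameters,
    ParameterBundle,
    TransitionSchedule,
    UtilityParameters,
)

__all__ = [
    "ArmResult",
    "IncrementalResult",
    "BaseCaseResult",
    "discount_factor",
    "ablation_cost",
    "initial_visit_cost",
    "unhealed_monthly_cost",
    "healed_monthly_cost",
    "ablation_timing_costs",
    "accumulate",
    "incremental",
    "evaluate_deltas",
    "run_base_case",
]

COST_COMPONENTS = (
    "ablation",
    "initial_visit",
    "outpatient",
    "home_health",
    "hospitalization",
    "pain_meds",
    "stockings",
)


def discount_factor(cycle: int | np.ndarray, annual_rate: float):
    """Present-value factor (1 + rate)^(-cycle/12) for a monthly cycle index."""
    return (1.0 + annual_rate) ** (-np.asarray(cycle, dtype=float) / 12.0)


def ablation_cost(costs: CostParameters) -> float:
    """Expected one-time cost of the endovenous ablation procedure.

    Mixes mechanochemical, radiofrequency and laser ablation payments, plus
    the multi-vein add-on payment for the fraction with more than one vein
    treated.
    """
    mix = costs.ablation_mix
    primary = (
        mix["mechanochemical"] * costs.cost("ablation_mechanochemical")
        + mix["radiofrequency"] * costs.cost("ablation_radiofrequency")
        + mix["laser"] * costs.cost("ablation_laser")
    )
    addon = (
        mix["mechanochemical"] * costs.cost("ablation_mechanochemical_addon")
        + mix["radiofrequency"] * costs.cost("ablation_radiofrequency_addon")
        + mix["laser"] * costs.cost("ablation_laser_addon")
    )
    return primary + costs.multi_vein_fraction * addon


def initial_visit_cost(costs: CostParameters) -> float:
    """One-time cost of the initial evaluation + debridement visit
    (physician and facility components); zero when disabled."""
    if not costs.include_initial_visit:
        return 0.0
    return (
        costs.cost("initial_eval_physician")
        + costs.cost("initial_debridement_physician")
        + costs.cost("initial_visit_facility")
        + costs.cost("initial_debridement_facility")
    )


def _visit_cost(costs: CostParameters, cycle: int) -> float:
    p_d = costs.debride_prob_per_visit if cycle <= costs.debride_window_months else 0.0
    debride = costs.cost("visit_debridement_physician") + costs.cost("visit_debridement_facility")
    compression = costs.cost("visit_compression_physician") + costs.cost("visit_compression_facility")
    return costs.visits_per_month * (p_d * debride + (1.0 - p_d) * compression)


def _home_health_cost(costs: CostParameters) -> float:
    return costs.home_health_fraction * (
        costs.cost("home_health_episode") / costs.home_health_episode_months
    )


def _pain_med_cost(costs: CostParameters) -> float:
    return (
        costs.pain_med_mix["amitriptyline"] * costs.cost("pain_amitriptyline")
        + costs.pain_med_mix["gabapentin"] * costs.cost("pain_gabapentin")
        + costs.pain_med_mix["hydrocodone"] * costs.cost("pain_hydrocodone")
    )


def _hospitalization_cost(costs: CostParameters) -> float:
    ulcer_drg = sum(
        w * costs.cost(key) for key, w in costs.ulcer_drg_weights.items()
    )
    return (
        costs.hosp_monthly_probs["ulcer"] * ulcer_drg
        + costs.hosp_monthly_probs["cellulitis_major"] * costs.cost("hosp_cellulitis_major")
        + costs.hosp_monthly_probs["cellulitis_no_major"] * costs.cost("hosp_cellulitis_no_major")
    )


def unhealed_monthly_cost(costs: CostParameters, cycle: int) -> float:
    """Expected monthly cost of one patient-month in the unhealed state."""
    if cycle < 1:
        raise ValueError("cycle must be >= 1")
    return (
        _visit_cost(costs, cycle)
        + _home_health_cost(costs)
        + _pain_med_cost(costs)
        + _hospitalization_cost(costs)
    )


def healed_monthly_cost(costs: CostParameters) -> float:
    """Monthly cost in the healed state: compression stockings prorated from
    the 6-month supply price."""
    return costs.cost("stockings_6mo") / 6.0


def ablation_timing_costs(
    trace: CohortTrace, schedule: TransitionSchedule, costs: CostParameters
) -> np.ndarray:
    """Per-cycle expected ablation spend (undiscounted), length horizon + 1.

    Early arm: the full expected procedure cost is charged to the entering
    cohort at cycle 1. Deferred arm: the cost is charged to the fraction
    newly healed at each cycle up to month 6, plus the fraction alive and
    still unhealed at month 6 (ablation proceeds then regardless of healing);
    every patient alive at their ablation point incurs exactly one procedure.
    """
    horizon = trace.horizon
    stream = np.zeros(horizon + 1)
    unit = ablation_cost(costs)
    if trace.arm == "early":
        stream[1] = unit
        return stream
    # ablation attaches to the FIRST healing, so track the never-healed
    # survivors rather than unhealed occupancy (which re-admits recurrences)
    m = schedule.mortality
    never_healed = 1.0
    for t in range(1, min(6, horizon) + 1):
        first_heal_flow = never_healed * (1 - m) * schedule.heal(t, extend=True)
        stream[t] = first_heal_flow * unit
        never_healed *= (1 - m) * (1 - schedule.heal(t, extend=True))
    if horizon >= 6:
        stream[6] += never_healed * unit
    return stream


@dataclass(frozen=True)
class ArmResult:
    """Discounted totals for one arm with a per-cycle component breakdown.

    ``breakdown`` rows are cycles 1..horizon; columns are the discounted
    cost components plus ``total_cost`` and ``qalys``.
    """

    arm: str
    total_cost: float
    total_qalys: float
    breakdown: pd.DataFrame

    @property
    def component_totals(self) -> pd.Series:
        return self.breakdown[list(COST_COMPONENTS)].sum()


def accumulate(
    trace: CohortTrace,
    schedule: TransitionSchedule,
    costs: CostParameters,
    utilities: UtilityParameters,
    settings: AnalysisSettings,
) -> ArmResult:
    """Fold a cohort trace into discounted cost and QALY totals.

    With half-cycle correction enabled, state payoffs are weighted by the
    mean of start- and end-of-cycle occupancy; event-timed ablation and the
    initial visit are unaffected.
    """
    horizon = trace.horizon
    cycles = np.arange(1, horizon + 1)
    d = discount_factor(cycles, settings.annual_discount_rate)

    occ = trace.occupancy
    if settings.half_cycle_correction:
        occ_eff = 0.5 * (occ[:-1] + occ[1:])
    else:
        occ_eff = occ[1:]
    occ_u = occ_eff[:, int(HealthState.UNHEALED)]
    occ_h = occ_eff[:, int(HealthState.HEALED)]

    unhealed_c = np.array([unhealed_monthly_cost(costs, int(t)) for t in cycles])
    healed_c = healed_monthly_cost(costs)
    abl = ablation_timing_costs(trace, schedule, costs)[1:]
    init = np.zeros(horizon)
    init[0] = initial_visit_cost(costs)

    visit_c = np.array([_visit_cost(costs, int(t)) for t in cycles])
    comp = pd.DataFrame(
        {
            "cycle": cycles,
            "ablation": d * abl,
            "initial_visit": d * init,
            "outpatient": d * occ_u * visit_c,
            "home_health": d * occ_u * _home_health_cost(costs),
            "hospitalization": d * occ_u * _hospitalization_cost(costs),
            "pain_meds": d * occ_u * _pain_med_cost(costs),
            "stockings": d * occ_h * healed_c,
        }
    )
    comp["total_cost"] = comp[list(COST_COMPONENTS)].sum(axis=1)
    comp["qalys"] = (
        d
        * (settings.cycle_length_months / 12.0)
        * (occ_u * utilities.adjusted_unhealed + occ_h * utilities.adjusted_healed)
    )
    # consistency of the decomposition with the direct total
    direct = float(np.sum(d * (occ_u * unhealed_c + occ_h * healed_c + abl + init)))
    total = float(comp["total_cost"].sum())
    assert math.isclose(total, direct, rel_tol=0, abs_tol=1e-6)
    return ArmResult(
        arm=trace.arm,
        total_cost=total,
        total_qalys=float(comp["qalys"].sum()),
        breakdown=comp,
    )


@dataclass(frozen=True)
class IncrementalResult:
    """Early-minus-deferred incremental results at a given willingness to
    pay; a positive INMB favors early ablation."""

    delta_cost: float
    delta_qalys: float
    wtp: float
    icer: float | None
    icer_flag: Literal["dominant", "dominated", "undefined", "icer"]
    inmb: float

    def summary(self) -> dict:
        return {
            "delta_cost": self.delta_cost,
            "delta_qalys": self.delta_qalys,
            "wtp": self.wtp,
            "icer": self.icer,
            "icer_flag": self.icer_flag,
            "inmb": self.inmb,
        }


def incremental(early: ArmResult, deferred: ArmResult, wtp: float) -> IncrementalResult:
    """Incremental cost-effectiveness of early vs deferred ablation.

    ICER is flagged "dominant" when early is cheaper and more effective,
    "dominated" in the reverse case, and "undefined" when the QALY difference
    is zero with a nonzero cost difference.
    """
    dc = early.total_cost - deferred.total_cost
    dq = early.total_qalys - deferred.total_qalys
    inmb = wtp * dq - dc
    if dq == 0.0:
        flag = "undefined" if dc != 0.0 else "icer"
        icer = None if dc != 0.0 else 0.0
    elif dc < 0.0 and dq > 0.0:
        flag, icer = "dominant", None
    elif dc > 0.0 and dq < 0.0:
        flag, icer = "dominated", None
    else:
        flag, icer = "icer", dc / dq
    return IncrementalResult(
        delta_cost=dc, delta_qalys=dq, wtp=wtp, icer=icer, icer_flag=flag, inmb=inmb
    )


@dataclass(frozen=True)
class BaseCaseResult:
    early: ArmResult
    deferred: ArmResult
    incremental: IncrementalResult

    def to_frame(self) -> pd.DataFrame:
        """One row per arm, Table-style: cost, QALYs, and incremental
        columns on the early-ablation row."""
        inc = self.incremental
        return pd.DataFrame(
            [
                {
                    "arm": "deferred",
                    "cost": self.deferred.total_cost,
                    "qalys": self.deferred.total_qalys,
                    "cost_difference": None,
                    "incremental_qalys": None,
                    "icer": None,
                    "inmb": None,
                },
                {
                    "arm": "early",
                    "cost": self.early.total_cost,
                    "qalys": self.early.total_qalys,
                    "cost_difference": inc.delta_cost,
                    "incremental_qalys": inc.delta_qalys,
                    "icer": "early ablation dominates" if inc.icer_flag == "dominant" else inc.icer,
                    "inmb": inc.inmb,
                },
            ]
        )


def evaluate_deltas(bundle: ParameterBundle, horizon_months: int | None = None) -> tuple[float, float]:
    """(delta_cost, delta_qalys), early minus deferred, without building the
    per-cycle breakdown tables; the workhorse of the sensitivity loops.

    Agrees with :func:`run_base_case` exactly (asserted in the test suite).
    """
    settings = bundle.settings
    if horizon_months is not None:
        settings = replace(settings, horizon_months=horizon_months)
    horizon = settings.horizon_months
    cycles = np.arange(1, horizon + 1)
    d = discount_factor(cycles, settings.annual_discount_rate)

    totals = {}
    for arm in ("early", "deferred"):
        schedule = bundle.schedule(arm)
        trace = run_cohort(schedule, settings)
        occ = trace.occupancy
        occ_eff = 0.5 * (occ[:-1] + occ[1:]) if settings.half_cycle_correction else occ[1:]
        occ_u = occ_eff[:, int(HealthState.UNHEALED)]
        occ_h = occ_eff[:, int(HealthState.HEALED)]
        unhealed_c = np.array([unhealed_monthly_cost(bundle.costs, int(t)) for t in cycles])
        abl = ablation_timing_costs(trace, schedule, bundle.costs)[1:]
        cost = float(
            np.sum(d * (occ_u * unhealed_c + occ_h * healed_monthly_cost(bundle.costs) + abl))
        ) + initial_visit_cost(bundle.costs) * d[0]
        qalys = float(
            np.sum(
                d
                * (settings.cycle_length_months / 12.0)
                * (
                    occ_u * bundle.utilities.adjusted_unhealed
                    + occ_h * bundle.utilities.adjusted_healed
                )
            )
        )
        totals[arm] = (cost, qalys)
    return (
        totals["early"][0] - totals["deferred"][0],
        totals["early"][1] - totals["deferred"][1],
    )


def run_base_case(bundle: ParameterBundle, horizon_months: int | None = None) -> BaseCaseResult:
    """Run both arms deterministically and return arm and incremental
    results; ``horizon_months`` overrides the configured horizon."""
    settings = bundle.settings
    if horizon_months is not None:
        settings = replace(settings, horizon_months=horizon_months)
    arms = {}
    for arm in ("early", "deferred"):
        schedule = bundle.schedule(arm)
        trace = run_cohort(schedule, settings)
        arms[arm] = accumulate(trace, schedule, bundle.costs, bundle.utilities, settings)
    return BaseCaseResult(
        early=arms["early"],
        deferred=arms["deferred"],
        incremental=incremental(arms["early"], arms["deferred"], settings.wtp),
    )
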