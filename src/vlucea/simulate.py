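"""Patient-level microsimulation of the three-state ulcer process.

Serves two purposes: an independent oracle for the deterministic cohort
engine (simulated occupancy must converge to the cohort trace), and a
generator of synthetic trial datasets from which the per-segment monthly
transition probabilities can be re-estimated (parameter recovery).

The generative model is exactly the per-cycle Bernoulli process the cohort
model assumes: each month an alive patient first faces death with the
all-cause monthly probability, then a surviving unhealed patient heals with
the healing probability of the segment containing that month, and a
surviving healed patient recurs with the corresponding recurrence
probability. Censoring occurs only at the horizon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markov import HealthState
from .params import Segment, TransitionSchedule

__all__ = [
    "PatientCohort",
    "SegmentEstimate",
    "ScheduleEstimate",
    "simulate_patients",
    "estimate_monthly_probabilities",
]


@dataclass(frozen=True)
class PatientCohort:
    """Simulated patient-level state paths for one arm.

    ``states`` has one row per patient and one column per cycle 0..horizon,
    holding :class:`HealthState` integer codes; column 0 is all UNHEALED.
    """

    arm: str
    states: np.ndarray  # (n, horizon + 1), int8
    seed: int

    @property
    def n(self) -> int:
        return self.states.shape[0]

    @property
    def horizon(self) -> int:
        return self.states.shape[1] - 1

    def occupancy(self) -> np.ndarray:
        """Fraction of patients in each state per cycle, shape
        (horizon + 1, 3); the empirical analogue of a cohort trace."""
        out = np.empty((self.horizon + 1, 3))
        for s in HealthState:
            out[:, int(s)] = (self.states == int(s)).mean(axis=0)
        return out

    def first_healing_month(self) -> np.ndarray:
        """First cycle at which each patient is healed; -1 if never."""
        healed = self.states == int(HealthState.HEALED)
        any_heal = healed.any(axis=1)
        first = healed.argmax(axis=1)
        return np.where(any_heal, first, -1)

    def to_frame(self) -> pd.DataFrame:
        """Long format (patient, month, state) for export."""
        n, width = self.states.shape
        return pd.DataFrame(
            {
                "patient": np.repeat(np.arange(n), width),
                "month": np.tile(np.arange(width), n),
                "state": pd.Categorical.from_codes(
                    self.states.ravel(), categories=[s.name for s in HealthState]
                ),
            }
        )


def simulate_patients(
    schedule: TransitionSchedule, n: int, horizon: int, seed: int
) -> PatientCohort:
    """Simulate ``n`` patients month by month under a transition schedule.

    Vectorized over patients; event ordering inside a month (death first,
    then healing/recurrence among survivors) mirrors the cohort engine so
    that the two agree exactly in expectation, not just asymptotically.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    states = np.empty((n, horizon + 1), dtype=np.int8)
    states[:, 0] = int(HealthState.UNHEALED)
    current = states[:, 0].copy()
    for t in range(1, horizon + 1):
        h = schedule.heal(t, extend=True)
        r = schedule.recur(t, extend=True)
        m = schedule.mortality
        alive = current != int(HealthState.DEAD)
        dies = alive & (rng.random(n) < m)
        u = rng.random(n)
        heals = (current == int(HealthState.UNHEALED)) & ~dies & (u < h)
        recurs = (current == int(HealthState.HEALED)) & ~dies & (u < r)
        current = current.copy()
        current[dies] = int(HealthState.DEAD)
        current[heals] = int(HealthState.HEALED)
        current[recurs] = int(HealthState.UNHEALED)
        states[:, t] = current
    return PatientCohort(arm=schedule.arm, states=states, seed=seed)


@dataclass(frozen=True)
class SegmentEstimate:
    """Per-segment event probability estimated from simulated patient-months
    at risk, with its binomial standard error; ``p`` is None when no
    patient-months were at risk."""

    start: int
    end: int | None
    events: int
    at_risk: int
    p: float | None
    se: float | None


@dataclass(frozen=True)
class ScheduleEstimate:
    arm: str
    heal: tuple[SegmentEstimate, ...]
    recur: tuple[SegmentEstimate, ...]
    mortality: SegmentEstimate


def _estimate(events: np.ndarray, at_risk: np.ndarray, segs, horizon: int):
    out = []
    for seg in segs:
        end = horizon + 1 if seg.end is None else min(seg.end, horizon + 1)
        ev = int(events[seg.start:end].sum())
        ar = int(at_risk[seg.start:end].sum())
        if ar == 0:
            out.append(SegmentEstimate(seg.start, seg.end, ev, ar, None, None))
        else:
            p = ev / ar
            out.append(
                SegmentEstimate(
                    seg.start, seg.end, ev, ar, p, float(np.sqrt(p * (1 - p) / ar))
                )
            )
    return tuple(out)


def estimate_monthly_probabilities(
    cohort: PatientCohort, schedule: TransitionSchedule
) -> ScheduleEstimate:
    """Recover per-segment monthly probabilities from simulated paths.

    For each segment, the healing estimate is healing events divided by
    unhealed patient-months at risk (survivors of that month's mortality),
    and analogously for recurrence; mortality is pooled over all alive
    patient-months. Segment boundaries are taken from ``schedule``; its
    probability values are not consulted.
    """
    if cohort.n == 0:
        raise ValueError("empty cohort")
    horizon = cohort.horizon
    prev = cohort.states[:, :-1]
    curr = cohort.states[:, 1:]
    per_cycle = np.zeros((horizon + 1, 6), dtype=np.int64)  # heal ev/ar, recur ev/ar, death ev/ar
    for t in range(1, horizon + 1):
        p, c = prev[:, t - 1], curr[:, t - 1]
        alive_now = c != int(HealthState.DEAD)
        was_u = p == int(HealthState.UNHEALED)
        was_h = p == int(HealthState.HEALED)
        was_alive = p != int(HealthState.DEAD)
        per_cycle[t, 0] = int((was_u & (c == int(HealthState.HEALED))).sum())
        per_cycle[t, 1] = int((was_u & alive_now).sum())
        per_cycle[t, 2] = int((was_h & (c == int(HealthState.UNHEALED))).sum())
        per_cycle[t, 3] = int((was_h & alive_now).sum())
        per_cycle[t, 4] = int((was_alive & ~alive_now).sum())
        per_cycle[t, 5] = int(was_alive.sum())
    heal = _estimate(per_cycle[:, 0], per_cycle[:, 1], schedule.heal_segments, horizon)
    recur = _estimate(per_cycle[:, 2], per_cycle[:, 3], schedule.recur_segments, horizon)
    mortality = _estimate(
        per_cycle[:, 4], per_cycle[:, 5], [Segment(1, None, schedule.mortality)], horizon
    )[0]
    return ScheduleEstimate(arm=cohort.arm, heal=heal, recur=recur, mortality=mortality)
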