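"""Deterministic 3-state Markov cohort engine.

States are UNHEALED (active venous leg ulcer), HEALED (post-ulcer) and DEAD
(absorbing). The cohort enters entirely unhealed at cycle 0 and is propagated
through per-cycle transition matrices; transitions and payoffs accrue for
cycles 1..horizon.

Within a cycle, death is applied first and healing/recurrence only among
survivors, so each row of the transition matrix is stochastic by
construction without renormalization.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .params import AnalysisSettings, TransitionSchedule

__all__ = ["HealthState", "CohortTrace", "build_matrix", "run_cohort"]


class HealthState(enum.IntEnum):
    UNHEALED = 0
    HEALED = 1
    DEAD = 2


@dataclass(frozen=True)
class CohortTrace:
    """State-occupancy fractions per cycle for one arm.

    ``occupancy`` has one row per cycle 0..horizon and one column per
    :class:`HealthState`; row 0 is (1, 0, 0).
    """

    arm: str
    occupancy: np.ndarray  # (horizon + 1, 3)

    @property
    def horizon(self) -> int:
        return self.occupancy.shape[0] - 1

    def state(self, state: HealthState) -> np.ndarray:
        """Occupancy of one state over cycles 0..horizon."""
        return self.occupancy[:, int(state)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": np.arange(self.occupancy.shape[0]),
                "unhealed": self.occupancy[:, 0],
                "healed": self.occupancy[:, 1],
                "dead": self.occupancy[:, 2],
                "arm": self.arm,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_matrix(schedule: TransitionSchedule, cycle: int, *, extend: bool = False) -> np.ndarray:
    """Transition matrix for one cycle (row = from-state, column = to-state).

    With monthly mortality m, healing probability h and recurrence
    probability r for the segments containing ``cycle``:

    * UNHEALED row: ((1-m)(1-h), (1-m)h, m)
    * HEALED row:   ((1-m)r, (1-m)(1-r), m)
    * DEAD row:     (0, 0, 1)
    """
    m = schedule.mortality
    h = schedule.heal(cycle, extend=extend)
    r = schedule.recur(cycle, extend=extend)
    M = np.array(
        [
            [(1 - m) * (1 - h), (1 - m) * h, m],
            [(1 - m) * r, (1 - m) * (1 - r), m],
            [0.0, 0.0, 1.0],
        ]
    )
    if (M < -1e-15).any() or (M > 1 + 1e-15).any():
        raise ValueError(f"transition matrix entries outside [0, 1] at cycle {cycle}")
    return M


def run_cohort(schedule: TransitionSchedule, settings: AnalysisSettings) -> CohortTrace:
    """Propagate the cohort: occupancy[t] = occupancy[t-1] @ M(t).

    Cycles beyond the schedule's last closed segment reuse the final
    segment's probabilities, which only matters for horizons longer than the
    schedule's stated coverage.
    """
    horizon = settings.horizon_months
    occ = np.zeros((horizon + 1, 3))
    occ[0, int(HealthState.UNHEALED)] = 1.0
    for t in range(1, horizon + 1):
        occ[t] = occ[t - 1] @ build_matrix(schedule, t, extend=True)
    return CohortTrace(arm=schedule.arm, occupancy=occ)
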