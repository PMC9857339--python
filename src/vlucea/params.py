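"""Model parameters: transition schedules, costs, utilities and run settings.

All monetary values are 2021 US dollars (Medicare national average
reimbursement rates, keyed by CPT/DRG code where one exists; codes are
treated as opaque labels). Probabilities are per monthly cycle.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterator, Literal, Sequence

import yaml

__all__ = [
    "ConfigError",
    "bundle_from_dict",
    "bundle_to_dict",
    "Segment",
    "TransitionSchedule",
    "UnitCost",
    "CostParameters",
    "UtilityParameters",
    "AnalysisSettings",
    "ParameterBundle",
    "load_config",
    "default_config_path",
    "segment_probability",
    "deale_monthly_probability",
]

Arm = Literal["early", "deferred"]
Event = Literal["heal", "recur"]


class ConfigError(ValueError):
    """Raised when a configuration file is missing a field or violates a
    range/shape constraint; the message names the offending field."""


@dataclass(frozen=True)
class Segment:
    """Half-open month interval [start, end) with a constant monthly
    probability; ``end=None`` means the segment is open-ended."""

    start: int
    end: int | None
    p: float

    def contains(self, cycle: int) -> bool:
        return cycle >= self.start and (self.end is None or cycle < self.end)


@dataclass(frozen=True)
class TransitionSchedule:
    """Per-arm, piecewise-constant monthly transition probabilities.

    Cycle ``t`` represents month ``t``; a segment labelled "month 1 to <6"
    covers cycles 1..5. Mortality is a single all-cause monthly probability
    applied to every alive state (it carries no arm or state dependence).
    """

    arm: str
    heal_segments: tuple[Segment, ...]
    recur_segments: tuple[Segment, ...]
    mortality: float

    def __post_init__(self) -> None:
        for name, segs in (("heal", self.heal_segments), ("recur", self.recur_segments)):
            _validate_segments(f"{self.arm}.{name}", segs)
            for s in segs:
                if not 0.0 <= s.p <= 1.0:
                    raise ConfigError(
                        f"{self.arm}.{name} segment [{s.start},{s.end}): "
                        f"probability {s.p} outside [0, 1]"
                    )
        if not 0.0 <= self.mortality <= 1.0:
            raise ConfigError(f"{self.arm}.mortality {self.mortality} outside [0, 1]")
        for s in self.heal_segments:
            if self.mortality + s.p > 1.0:
                raise ConfigError(
                    f"{self.arm}.heal segment [{s.start},{s.end}): "
                    f"mortality + healing probability exceeds 1"
                )

    def heal(self, cycle: int, *, extend: bool = False) -> float:
        return segment_probability(self, "heal", cycle, extend=extend)

    def recur(self, cycle: int, *, extend: bool = False) -> float:
        return segment_probability(self, "recur", cycle, extend=extend)


def _validate_segments(name: str, segs: Sequence[Segment]) -> None:
    if not segs:
        raise ConfigError(f"{name}: at least one segment required")
    if segs[0].start != 1:
        raise ConfigError(f"{name}: first segment must start at month 1")
    for a, b in zip(segs, segs[1:]):
        if a.end is None:
            raise ConfigError(f"{name}: open-ended segment must be last")
        if b.start != a.end:
            raise ConfigError(
                f"{name}: segments [{a.start},{a.end}) and [{b.start},{b.end}) "
                f"are not contiguous"
            )


def segment_probability(
    schedule: TransitionSchedule, event: Event, cycle: int, *, extend: bool = False
) -> float:
    """Monthly probability for ``event`` in the segment containing ``cycle``.

    Segments are half-open, so month 6 belongs to a "month 6 to <12" segment.
    With ``extend=True`` a cycle beyond the last closed segment reuses the
    final segment's value (used when running horizons longer than the
    schedule's stated coverage, e.g. 5-year budget projections).
    """
    segs = schedule.heal_segments if event == "heal" else schedule.recur_segments
    if cycle < 1:
        raise ValueError(f"cycle must be >= 1, got {cycle}")
    for s in segs:
        if s.contains(cycle):
            return s.p
    if extend:
        return segs[-1].p
    raise ValueError(f"cycle {cycle} outside the {schedule.arm} {event} segments")


def deale_monthly_probability(cumulative_incidence: float, window_months: float) -> float:
    """Constant-hazard (DEALE) conversion of a cumulative incidence over a
    window into a per-month probability.

    Solves 1 - (1 - p)**window = cumulative_incidence for p, i.e.
    ``p = 1 - exp(ln(1 - CI) / window)``. Provided as a documented utility
    for deriving cycle probabilities from interval rates; the shipped
    base-case schedule uses directly specified monthly values.
    """
    if not 0.0 <= cumulative_incidence < 1.0:
        raise ValueError("cumulative_incidence must lie in [0, 1)")
    if window_months <= 0:
        raise ValueError("window_months must be positive")
    return 1.0 - math.exp(math.log1p(-cumulative_incidence) / window_months)


@dataclass(frozen=True)
class UnitCost:
    """One Medicare payment rate (2021 USD) with its billing code label."""

    code: str | None
    base: float

    def __post_init__(self) -> None:
        if self.base < 0:
            raise ConfigError(f"unit cost {self.code}: negative value {self.base}")


# unit-cost keys the cost model requires
REQUIRED_UNIT_COSTS = (
    "ablation_mechanochemical",
    "ablation_mechanochemical_addon",
    "ablation_radiofrequency",
    "ablation_radiofrequency_addon",
    "ablation_laser",
    "ablation_laser_addon",
    "initial_eval_physician",
    "initial_debridement_physician",
    "initial_visit_facility",
    "initial_debridement_facility",
    "visit_debridement_physician",
    "visit_debridement_facility",
    "visit_compression_physician",
    "visit_compression_facility",
    "home_health_episode",
    "stockings_6mo",
    "hosp_debridement_complication",
    "hosp_ulcer_complication",
    "hosp_cellulitis_major",
    "hosp_cellulitis_no_major",
    "pain_amitriptyline",
    "pain_gabapentin",
    "pain_hydrocodone",
)


@dataclass(frozen=True)
class CostParameters:
    """Unit costs plus the utilization assumptions that turn them into
    per-cycle state costs.

    ``hosp_monthly_probs`` holds the monthly probabilities of hospitalization
    for (ulcer with complications, cellulitis with major complications,
    cellulitis without major complications); the single pooled ulcer
    probability is split across DRG 571/593 by ``ulcer_drg_weights``.
    """

    unit_costs: dict[str, UnitCost]
    ablation_mix: dict[str, float]  # mechanochemical / radiofrequency / laser
    multi_vein_fraction: float
    visits_per_month: float  # weekly visits prorated, 52/12 by default
    debride_prob_per_visit: float
    debride_window_months: int
    home_health_fraction: float
    home_health_episode_months: float  # 60-day episode = 2 months
    hosp_monthly_probs: dict[str, float]
    ulcer_drg_weights: dict[str, float]
    pain_med_mix: dict[str, float]
    include_initial_visit: bool = True

    def __post_init__(self) -> None:
        missing = [k for k in REQUIRED_UNIT_COSTS if k not in self.unit_costs]
        if missing:
            raise ConfigError(f"unit_costs: missing keys {missing}")
        for name, mix in (
            ("ablation_mix", self.ablation_mix),
            ("ulcer_drg_weights", self.ulcer_drg_weights),
            ("pain_med_mix", self.pain_med_mix),
        ):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ConfigError(f"{name}: fractions sum to {sum(mix.values())}, not 1")
        for name, p in (
            ("multi_vein_fraction", self.multi_vein_fraction),
            ("debride_prob_per_visit", self.debride_prob_per_visit),
            ("home_health_fraction", self.home_health_fraction),
            *((f"hosp_monthly_probs.{k}", v) for k, v in self.hosp_monthly_probs.items()),
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name}: {p} outside [0, 1]")
        if self.visits_per_month < 0:
            raise ConfigError("visits_per_month must be non-negative")
        if self.home_health_episode_months <= 0:
            raise ConfigError("home_health_episode_months must be positive")

    def cost(self, key: str) -> float:
        return self.unit_costs[key].base


@dataclass(frozen=True)
class UtilityParameters:
    """State utilities on the 0 (dead) to 1 (perfect health) scale.

    ``age_adjustment`` is a single multiplicative factor applied to both
    alive-state utilities to represent the preference decrement of a cohort
    aged 65+ relative to the populations the raw scores came from. The
    shipped default was calibrated once (scripts/calibrate_age_adjustment.py)
    and then frozen in the configuration.
    """

    unhealed: float
    healed: float
    dead: float = 0.0
    age_adjustment: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dead <= self.unhealed <= self.healed <= 1.0:
            raise ConfigError(
                f"utilities must satisfy 0 <= dead <= unhealed <= healed <= 1, "
                f"got ({self.dead}, {self.unhealed}, {self.healed})"
            )
        if not 0.0 < self.age_adjustment <= 1.0:
            raise ConfigError(f"age_adjustment {self.age_adjustment} outside (0, 1]")

    @property
    def adjusted_unhealed(self) -> float:
        return self.unhealed * self.age_adjustment

    @property
    def adjusted_healed(self) -> float:
        return self.healed * self.age_adjustment


@dataclass(frozen=True)
class AnalysisSettings:
    horizon_months: int = 36
    cycle_length_months: int = 1
    annual_discount_rate: float = 0.03
    wtp: float = 100_000.0
    psa_iterations: int = 10_000
    seed: int = 0
    range_fraction: float = 0.20
    half_cycle_correction: bool = False

    def __post_init__(self) -> None:
        if self.horizon_months < 1:
            raise ConfigError("horizon_months must be >= 1")
        if self.annual_discount_rate < 0:
            raise ConfigError("annual_discount_rate must be >= 0")
        if self.wtp <= 0:
            raise ConfigError("wtp must be > 0")
        if self.psa_iterations < 1:
            raise ConfigError("psa_iterations must be >= 1")
        if not 0.0 <= self.range_fraction:
            raise ConfigError("range_fraction must be >= 0")


@dataclass(frozen=True)
class ParameterBundle:
    """Everything a model run needs: both arms' schedules, costs, utilities
    and analysis settings."""

    early: TransitionSchedule
    deferred: TransitionSchedule
    costs: CostParameters
    utilities: UtilityParameters
    settings: AnalysisSettings

    def schedule(self, arm: Arm) -> TransitionSchedule:
        if arm == "early":
            return self.early
        if arm == "deferred":
            return self.deferred
        raise ValueError(f"unknown arm {arm!r}")

    def copy(self) -> "ParameterBundle":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# configuration loading


def default_config_path() -> Path:
    """Path of the shipped base-case configuration."""
    return Path(str(resources.files("vlucea").joinpath("data/basecase.yaml")))


def load_config(path: str | Path | None = None) -> ParameterBundle:
    """Load and validate a YAML configuration; ``None`` loads the shipped
    base case.

    Raises :class:`ConfigError` naming the offending field on any missing
    key, out-of-range value or non-contiguous segment list.
    """
    if path is None:
        path = default_config_path()
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return bundle_from_dict(raw)


def _require(section: dict, key: str, where: str):
    if key not in section:
        raise ConfigError(f"missing required field {where}.{key}")
    return section[key]


def _segments(raw: list, where: str) -> tuple[Segment, ...]:
    if not isinstance(raw, list) or not raw:
        raise ConfigError(f"{where}: must be a non-empty list of segments")
    out = []
    for i, item in enumerate(raw):
        try:
            out.append(Segment(int(item["start"]),
                               None if item.get("end") is None else int(item["end"]),
                               float(item["p"])))
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"{where}[{i}]: malformed segment ({exc})") from exc
    return tuple(out)


def bundle_from_dict(raw: dict) -> ParameterBundle:
    """Build a validated :class:`ParameterBundle` from a parsed mapping."""
    trans = _require(raw, "transitions", "<config>")
    mortality = float(_require(trans, "mortality", "transitions"))
    schedules = {}
    for arm in ("early", "deferred"):
        arm_raw = _require(trans, arm, "transitions")
        schedules[arm] = TransitionSchedule(
            arm=arm,
            heal_segments=_segments(
                _require(arm_raw, "healing", f"transitions.{arm}"),
                f"transitions.{arm}.healing"),
            recur_segments=_segments(
                _require(arm_raw, "recurrence", f"transitions.{arm}"),
                f"transitions.{arm}.recurrence"),
            mortality=mortality,
        )

    craw = _require(raw, "costs", "<config>")
    unit_raw = _require(craw, "unit_costs", "costs")
    unit_costs = {}
    for key, item in unit_raw.items():
        if isinstance(item, dict):
            unit_costs[key] = UnitCost(item.get("code"), float(_require(item, "base", f"costs.unit_costs.{key}")))
        else:
            unit_costs[key] = UnitCost(None, float(item))
    costs = CostParameters(
        unit_costs=unit_costs,
        ablation_mix={k: float(v) for k, v in _require(craw, "ablation_mix", "costs").items()},
        multi_vein_fraction=float(_require(craw, "multi_vein_fraction", "costs")),
        visits_per_month=float(_require(craw, "visits_per_month", "costs")),
        debride_prob_per_visit=float(_require(craw, "debride_prob_per_visit", "costs")),
        debride_window_months=int(_require(craw, "debride_window_months", "costs")),
        home_health_fraction=float(_require(craw, "home_health_fraction", "costs")),
        home_health_episode_months=float(craw.get("home_health_episode_months", 2.0)),
        hosp_monthly_probs={k: float(v) for k, v in _require(craw, "hosp_monthly_probs", "costs").items()},
        ulcer_drg_weights={k: float(v) for k, v in _require(craw, "ulcer_drg_weights", "costs").items()},
        pain_med_mix={k: float(v) for k, v in _require(craw, "pain_med_mix", "costs").items()},
        include_initial_visit=bool(craw.get("include_initial_visit", True)),
    )

    uraw = _require(raw, "utilities", "<config>")
    utilities = UtilityParameters(
        unhealed=float(_require(uraw, "unhealed", "utilities")),
        healed=float(_require(uraw, "healed", "utilities")),
        dead=float(uraw.get("dead", 0.0)),
        age_adjustment=float(uraw.get("age_adjustment", 1.0)),
    )

    sraw = raw.get("settings", {})
    settings = AnalysisSettings(
        horizon_months=int(sraw.get("horizon_months", 36)),
        cycle_length_months=int(sraw.get("cycle_length_months", 1)),
        annual_discount_rate=float(sraw.get("annual_discount_rate", 0.03)),
        wtp=float(sraw.get("wtp", 100_000.0)),
        psa_iterations=int(sraw.get("psa_iterations", 10_000)),
        seed=int(sraw.get("seed", 0)),
        range_fraction=float(sraw.get("range_fraction", 0.20)),
        half_cycle_correction=bool(sraw.get("half_cycle_correction", False)),
    )

    return ParameterBundle(
        early=schedules["early"],
        deferred=schedules["deferred"],
        costs=costs,
        utilities=utilities,
        settings=settings,
    )


def bundle_to_dict(bundle: ParameterBundle) -> dict:
    """Serialize a bundle back to the configuration mapping shape; the
    inverse of :func:`bundle_from_dict` (used by the sensitivity machinery
    to perturb single parameters and rebuild a validated bundle)."""

    def segs(segments: tuple[Segment, ...]) -> list[dict]:
        return [{"start": s.start, "end": s.end, "p": s.p} for s in segments]

    c = bundle.costs
    s = bundle.settings
    u = bundle.utilities
    return {
        "transitions": {
            "mortality": bundle.early.mortality,
            "early": {
                "healing": segs(bundle.early.heal_segments),
                "recurrence": segs(bundle.early.recur_segments),
            },
            "deferred": {
                "healing": segs(bundle.deferred.heal_segments),
                "recurrence": segs(bundle.deferred.recur_segments),
            },
        },
        "costs": {
            "unit_costs": {
                k: {"code": v.code, "base": v.base} for k, v in c.unit_costs.items()
            },
            "ablation_mix": dict(c.ablation_mix),
            "multi_vein_fraction": c.multi_vein_fraction,
            "visits_per_month": c.visits_per_month,
            "debride_prob_per_visit": c.debride_prob_per_visit,
            "debride_window_months": c.debride_window_months,
            "home_health_fraction": c.home_health_fraction,
            "home_health_episode_months": c.home_health_episode_months,
            "hosp_monthly_probs": dict(c.hosp_monthly_probs),
            "ulcer_drg_weights": dict(c.ulcer_drg_weights),
            "pain_med_mix": dict(c.pain_med_mix),
            "include_initial_visit": c.include_initial_visit,
        },
        "utilities": {
            "unhealed": u.unhealed,
            "healed": u.healed,
            "dead": u.dead,
            "age_adjustment": u.age_adjustment,
        },
        "settings": {
            "horizon_months": s.horizon_months,
            "cycle_length_months": s.cycle_length_months,
            "annual_discount_rate": s.annual_discount_rate,
            "wtp": s.wtp,
            "psa_iterations": s.psa_iterations,
            "seed": s.seed,
            "range_fraction": s.range_fraction,
            "half_cycle_correction": s.half_cycle_correction,
        },
    }
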