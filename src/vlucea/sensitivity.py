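"""One-way (tornado) and probabilistic sensitivity analyses, CEAC and EVPI.

Every scalar model input — transition probabilities, unit costs, utilization
probabilities and state utilities — is registered with a name and a kind.
The tornado varies each one to (1 - f) and (1 + f) times its base value
(f = the configured range fraction, 0.20 by default) and reruns the full
deterministic model; the PSA draws all of them jointly and independently,
by default from Uniform((1-f)·base, (1+f)·base), matching the published
±20% ranges. Beta (probabilities, utilities) and gamma (costs)
distributions with the same mean and an approximate 95% interval at ±f are
available as an alternative family.

Mixture fractions that must sum to one (procedure mix, pain-medication mix,
DRG split) and the calibrated aging adjustment are held fixed.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd

from .economics import evaluate_deltas
from .params import ParameterBundle, bundle_from_dict, bundle_to_dict

__all__ = [
    "ParameterRef",
    "parameter_registry",
    "TornadoEntry",
    "tornado",
    "PsaDraws",
    "draw_parameters",
    "run_psa",
    "CeacCurve",
    "ceac",
    "evpi",
    "mean_inmb",
]

Kind = Literal["probability", "cost", "utility", "utilization"]


@dataclass(frozen=True)
class ParameterRef:
    """A scalar model input addressed by its path in the configuration
    mapping."""

    name: str
    path: tuple
    kind: Kind

    def get(self, raw: dict) -> float:
        node = raw
        for key in self.path:
            node = node[key]
        return float(node)

    def set(self, raw: dict, value: float) -> None:
        node = raw
        for key in self.path[:-1]:
            node = node[key]
        node[self.path[-1]] = float(value)


def parameter_registry(bundle: ParameterBundle) -> list[ParameterRef]:
    """All independently varied scalar inputs of a bundle."""
    refs: list[ParameterRef] = [
        ParameterRef("transitions.mortality", ("transitions", "mortality"), "probability")
    ]
    for arm in ("early", "deferred"):
        schedule = bundle.schedule(arm)
        for event, key, segs in (
            ("healing", "healing", schedule.heal_segments),
            ("recurrence", "recurrence", schedule.recur_segments),
        ):
            for i, seg in enumerate(segs):
                end = "inf" if seg.end is None else seg.end
                refs.append(
                    ParameterRef(
                        f"transitions.{arm}.{event}[{seg.start},{end})",
                        ("transitions", arm, key, i, "p"),
                        "probability",
                    )
                )
    for cost_key in bundle.costs.unit_costs:
        refs.append(
            ParameterRef(
                f"costs.unit_costs.{cost_key}",
                ("costs", "unit_costs", cost_key, "base"),
                "cost",
            )
        )
    for key in ("multi_vein_fraction", "debride_prob_per_visit", "home_health_fraction"):
        refs.append(ParameterRef(f"costs.{key}", ("costs", key), "probability"))
    for key in bundle.costs.hosp_monthly_probs:
        refs.append(
            ParameterRef(
                f"costs.hosp_monthly_probs.{key}",
                ("costs", "hosp_monthly_probs", key),
                "probability",
            )
        )
    refs.append(ParameterRef("costs.visits_per_month", ("costs", "visits_per_month"), "utilization"))
    refs.append(ParameterRef("utilities.unhealed", ("utilities", "unhealed"), "utility"))
    refs.append(ParameterRef("utilities.healed", ("utilities", "healed"), "utility"))
    return refs


def _rebuild(raw: dict) -> ParameterBundle:
    return bundle_from_dict(raw)


def _clip_for_kind(ref: ParameterRef, value: float, raw: dict) -> float:
    """Keep a perturbed value inside its admissible range, warning when a
    clip occurs."""
    if ref.kind in ("probability", "utility") and value > 1.0:
        warnings.warn(f"{ref.name}: perturbed value {value:.4g} clipped to 1")
        value = 1.0
    if ref.kind == "utility":
        # keep the alive-state utilities ordered when one is varied alone
        if ref.name.endswith("unhealed") and value > raw["utilities"]["healed"]:
            warnings.warn(
                f"{ref.name}: perturbed value {value:.4g} clipped to healed utility"
            )
            value = raw["utilities"]["healed"]
        elif ref.name.endswith(".healed") and value < raw["utilities"]["unhealed"]:
            warnings.warn(
                f"{ref.name}: perturbed value {value:.4g} clipped to unhealed utility"
            )
            value = raw["utilities"]["unhealed"]
    return max(value, 0.0)


# ---------------------------------------------------------------------------
# tornado


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low_value: float
    high_value: float
    inmb_low: float
    inmb_high: float

    @property
    def spread(self) -> float:
        return abs(self.inmb_high - self.inmb_low)


def tornado(
    bundle: ParameterBundle,
    horizon_months: int | None = None,
    wtp: float | None = None,
) -> list[TornadoEntry]:
    """One-way sensitivity of INMB to every registered parameter, sorted by
    spread (widest first).

    Each entry reruns the full deterministic model twice, at
    (1 - range_fraction) and (1 + range_fraction) times the base value with
    everything else fixed.
    """
    wtp = bundle.settings.wtp if wtp is None else wtp
    f = bundle.settings.range_fraction
    base_raw = bundle_to_dict(bundle)
    entries = []
    for ref in parameter_registry(bundle):
        base = ref.get(base_raw)
        inmbs = []
        bounds = []
        for factor in (1.0 - f, 1.0 + f):
            raw = copy.deepcopy(base_raw)
            value = _clip_for_kind(ref, base * factor, raw)
            ref.set(raw, value)
            bounds.append(value)
            dc, dq = evaluate_deltas(_rebuild(raw), horizon_months)
            inmbs.append(wtp * dq - dc)
        entries.append(
            TornadoEntry(
                parameter=ref.name,
                low_value=bounds[0],
                high_value=bounds[1],
                inmb_low=inmbs[0],
                inmb_high=inmbs[1],
            )
        )
    entries.sort(key=lambda e: e.spread, reverse=True)
    return entries


def tornado_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": [e.parameter for e in entries],
            "low_value": [e.low_value for e in entries],
            "high_value": [e.high_value for e in entries],
            "inmb_low": [e.inmb_low for e in entries],
            "inmb_high": [e.inmb_high for e in entries],
            "spread": [e.spread for e in entries],
        }
    )


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis

Distribution = Literal["uniform", "beta-gamma"]

# ±f interpreted as an approximate 95% interval when using beta/gamma:
# sd = f * base / 1.96
_Z95 = 1.959963984540054


def draw_parameters(
    bundle: ParameterBundle,
    rng: np.random.Generator,
    distribution: Distribution = "uniform",
    max_redraws: int = 100,
) -> ParameterBundle:
    """Draw every registered parameter independently around its base value.

    Uniform draws span (1-f, 1+f) times the base. Probability and utility
    draws landing outside [0, 1], and unhealed-utility draws exceeding the
    healed draw, are redrawn (truncation by rejection); a zero range
    fraction returns the base bundle exactly.
    """
    f = bundle.settings.range_fraction
    raw = copy.deepcopy(bundle_to_dict(bundle))
    drawn: dict[str, float] = {}

    def one_draw(ref: ParameterRef, base: float) -> float:
        if f == 0.0 or base == 0.0:
            return base
        if distribution == "uniform":
            return rng.uniform((1.0 - f) * base, (1.0 + f) * base)
        sd = f * base / _Z95
        if ref.kind == "cost":
            shape = (base / sd) ** 2
            return rng.gamma(shape, base / shape)
        # probabilities and utilities: beta with matched mean and sd
        var = sd**2
        nu = base * (1.0 - base) / var - 1.0
        if nu <= 0:  # variance too large for a beta; fall back to uniform
            return rng.uniform((1.0 - f) * base, (1.0 + f) * base)
        return rng.beta(base * nu, (1.0 - base) * nu)

    refs = [r for r in parameter_registry(bundle) if r.kind in ("probability", "cost", "utility")]
    for ref in refs:
        base = ref.get(raw)
        value = one_draw(ref, base)
        tries = 0
        while ref.kind in ("probability", "utility") and not 0.0 <= value <= 1.0:
            tries += 1
            if tries > max_redraws:
                raise RuntimeError(f"{ref.name}: could not draw a value in [0, 1]")
            value = one_draw(ref, base)
        drawn[ref.name] = value

    # the alive-state utilities must stay ordered; redraw the pair if not
    tries = 0
    while drawn["utilities.unhealed"] > drawn["utilities.healed"]:
        tries += 1
        if tries > max_redraws:
            raise RuntimeError("could not draw ordered state utilities")
        for name in ("utilities.unhealed", "utilities.healed"):
            ref = next(r for r in refs if r.name == name)
            drawn[name] = one_draw(ref, ref.get(bundle_to_dict(bundle)))

    for ref in refs:
        ref.set(raw, drawn[ref.name])
    return _rebuild(raw)


@dataclass(frozen=True)
class PsaDraws:
    """Paired incremental outcomes from the PSA: one (ΔCost, ΔQALY) row per
    Monte Carlo iteration, early minus deferred."""

    delta_cost: np.ndarray
    delta_qalys: np.ndarray
    seed: int | None

    def __post_init__(self) -> None:
        if self.delta_cost.shape != self.delta_qalys.shape:
            raise ValueError("delta_cost and delta_qalys must have equal length")
        if not (np.isfinite(self.delta_cost).all() and np.isfinite(self.delta_qalys).all()):
            raise ValueError("PSA draws contain non-finite values")

    @property
    def iterations(self) -> int:
        return self.delta_cost.shape[0]

    def inmb(self, wtp: float) -> np.ndarray:
        return wtp * self.delta_qalys - self.delta_cost

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": np.arange(self.iterations),
                "delta_cost": self.delta_cost,
                "delta_qalys": self.delta_qalys,
            }
        )


def run_psa(
    bundle: ParameterBundle,
    iterations: int | None = None,
    seed: int | None = None,
    distribution: Distribution = "uniform",
    horizon_months: int | None = None,
) -> PsaDraws:
    """Monte Carlo propagation of parameter uncertainty.

    Each iteration draws a full parameter bundle, runs both arms
    deterministically and stores the incremental cost and QALYs. Fixing the
    seed makes the draw matrix bit-reproducible.
    """
    iterations = bundle.settings.psa_iterations if iterations is None else iterations
    seed = bundle.settings.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    dc = np.empty(iterations)
    dq = np.empty(iterations)
    for i in range(iterations):
        drawn = draw_parameters(bundle, rng, distribution)
        dc[i], dq[i] = evaluate_deltas(drawn, horizon_months)
    return PsaDraws(delta_cost=dc, delta_qalys=dq, seed=seed)


# ---------------------------------------------------------------------------
# decision-uncertainty summaries


@dataclass(frozen=True)
class CeacCurve:
    """Cost-effectiveness acceptability curve: P(early ablation is
    cost-effective) across willingness-to-pay thresholds."""

    thresholds: np.ndarray
    probabilities: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "probability": self.probabilities}
        )

    def at(self, wtp: float) -> float:
        idx = np.nonzero(np.isclose(self.thresholds, wtp))[0]
        if idx.size == 0:
            raise KeyError(f"threshold {wtp} not on the curve")
        return float(self.probabilities[idx[0]])


def ceac(draws: PsaDraws, thresholds: Sequence[float]) -> CeacCurve:
    """Fraction of PSA draws with positive INMB at each threshold."""
    thresholds = np.asarray(list(thresholds), dtype=float)
    if thresholds.size == 0:
        raise ValueError("at least one threshold required")
    if draws.iterations == 0:
        raise ValueError("no PSA draws")
    probs = np.array(
        [float(np.mean(draws.inmb(t) > 0.0)) for t in thresholds]
    )
    return CeacCurve(thresholds=thresholds, probabilities=probs)


def evpi(draws: PsaDraws, wtp: float) -> float:
    """Per-person expected value of perfect information.

    With deferred ablation as the reference (NMB 0) and the early arm's NMB
    equal to the INMB, EVPI = E[max(INMB, 0)] - max(E[INMB], 0): the
    expected gain of choosing per-draw with perfect knowledge over choosing
    once on expectations.
    """
    if draws.iterations == 0:
        raise ValueError("no PSA draws")
    inmb = draws.inmb(wtp)
    return float(np.mean(np.maximum(inmb, 0.0)) - max(float(np.mean(inmb)), 0.0))


def mean_inmb(draws: PsaDraws, wtp: float) -> float:
    """Average INMB over the PSA draws."""
    return float(np.mean(draws.inmb(wtp)))
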