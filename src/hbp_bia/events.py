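"""Expected annual cardiovascular events per scenario-year.

Treated patients face the annual event probabilities of their blood
pressure control regime (standard, SBP < 140, or intensive, SBP < 120 —
the two arms of the SPRINT trial); untreated patients face separately
calibrated, higher probabilities. Events are expected (real-valued)
counts: the cohort model is deterministic given its parameters, and
per-outcome probabilities are applied independently (no competing risks),
so one patient may contribute expectation to several outcomes in a year.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from .cohort import CohortYearState

__all__ = [
    "OUTCOMES",
    "OutcomeProbs",
    "EventProbabilities",
    "EventCounts",
    "expected_events",
    "hazard_ratio",
    "annualize_probability",
]

OUTCOMES: tuple[str, ...] = ("ami", "stroke", "hf", "cvdeath")


@dataclass(frozen=True)
class OutcomeProbs:
    """Annual event probabilities for one treatment regime."""

    ami: float
    stroke: float
    hf: float
    cvdeath: float | None = None  # absent for the untreated calibration

    def __post_init__(self) -> None:
        for name in OUTCOMES:
            p = getattr(self, name)
            if p is not None and not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {name} out of [0, 1]: {p}")


@dataclass(frozen=True)
class EventProbabilities:
    """Per-regime annual outcome probabilities.

    ``untreated_cvdeath_fallback`` decides what cardiovascular-death
    probability applies to untreated patients when the untreated set has
    none: ``"standard"`` borrows the standard-control value (deaths drive
    survivor carry-over, so some value is required), ``"zero"`` uses 0.
    """

    standard: OutcomeProbs
    intensive: OutcomeProbs
    untreated: OutcomeProbs
    untreated_cvdeath_fallback: str = "standard"

    @classmethod
    def from_values(
        cls, values: Mapping[str, float], untreated_cvdeath_fallback: str = "standard"
    ) -> "EventProbabilities":
        """Build from a flat parameter-value mapping (canonical names)."""
        regime = lambda r: OutcomeProbs(
            ami=values[f"ami_{r}"],
            stroke=values[f"stroke_{r}"],
            hf=values[f"hf_{r}"],
            cvdeath=values.get(f"cvdeath_{r}"),
        )
        return cls(
            standard=regime("standard"),
            intensive=regime("intensive"),
            untreated=regime("untreated"),
            untreated_cvdeath_fallback=untreated_cvdeath_fallback,
        )

    def untreated_cvdeath(self) -> float:
        if self.untreated.cvdeath is not None:
            return self.untreated.cvdeath
        if self.untreated_cvdeath_fallback == "standard":
            return self.standard.cvdeath or 0.0
        if self.untreated_cvdeath_fallback == "zero":
            return 0.0
        raise ValueError(f"bad fallback {self.untreated_cvdeath_fallback!r}")


@dataclass(frozen=True)
class EventCounts:
    """Expected event counts for one scenario-year."""

    year: int
    scenario: str
    ami: float
    stroke: float
    hf: float
    cvdeath: float

    def __post_init__(self) -> None:
        for name in OUTCOMES:
            if getattr(self, name) < 0:
                raise ValueError(f"negative expected count for {name}")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in OUTCOMES}


def expected_events(
    state: CohortYearState,
    probs: EventProbabilities,
    treated_regime: str,
) -> EventCounts:
    """Expected events: treated at their regime's probabilities, untreated
    at the untreated calibration (cardiovascular death falls back per the
    configured rule)."""
    if treated_regime not in ("standard", "intensive"):
        raise ValueError(f"treated_regime must be standard|intensive, got {treated_regime!r}")
    tp: OutcomeProbs = getattr(probs, treated_regime)
    up = probs.untreated

    def outcome(name: str) -> float:
        p_t = getattr(tp, name) or 0.0
        p_u = probs.untreated_cvdeath() if name == "cvdeath" else getattr(up, name)
        return state.n_treated * p_t + state.n_untreated * p_u

    return EventCounts(
        year=state.year,
        scenario="",
        ami=outcome("ami"),
        stroke=outcome("stroke"),
        hf=outcome("hf"),
        cvdeath=outcome("cvdeath"),
    )


def hazard_ratio(
    events_a: EventCounts,
    exposure_a: int,
    events_b: EventCounts,
    exposure_b: int,
) -> dict[str, float | None]:
    """Per-outcome hazard ratio of arm *a* versus arm *b*.

    Annual cumulative incidences are converted to hazards via
    ``-ln(1 - incidence)``; the ratio is ``ln(1 - r_a) / ln(1 - r_b)``.
    Outcomes with zero events in the denominator arm are undefined and
    reported as ``None``.
    """
    if exposure_a <= 0 or exposure_b <= 0:
        raise ValueError("exposures must be positive")
    out: dict[str, float | None] = {}
    for name in OUTCOMES:
        ra = getattr(events_a, name) / exposure_a
        rb = getattr(events_b, name) / exposure_b
        if not (0.0 <= ra < 1.0 and 0.0 <= rb < 1.0):
            raise ValueError(f"{name}: incidences must lie in [0, 1)")
        if rb == 0.0:
            out[name] = None
        elif ra == 0.0:
            out[name] = 0.0
        else:
            out[name] = math.log1p(-ra) / math.log1p(-rb)
    return out


def annualize_probability(events: float, n: float, followup_years: float) -> float:
    """Annual probability implied by ``events`` out of ``n`` over a follow-up.

    Under a constant hazard, ``p_annual = 1 - (1 - events/n)**(1/T)``. This
    is how trial event counts over a multi-year follow-up relate to the
    annual probabilities used by the cohort model.
    """
    if followup_years <= 0:
        raise ValueError("followup_years must be positive")
    if not 0 <= events <= n:
        raise ValueError("need 0 <= events <= n")
    return 1.0 - (1.0 - events / n) ** (1.0 / followup_years)
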