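"""Per-year care-cascade compartments of the hypertensive cohort.

Each scenario-year the prevalent hypertensive population is split into a
treated compartment (prescribed by a guideline-adherent physician AND
adherent to the prescription) and an untreated remainder (never
prescribed, or prescribed but non-adherent — pooled, since both face the
untreated event probabilities). Under the lower diagnostic cut-off the
newly classified stratum (BP 130-139/80-89) enters the same cascade with
its own, lower adherence. Treated patients who survive the year are
carried into the next year's prevalent pool.

Counts are integers (people); products are rounded half-to-even at
compartment boundaries and the rounding residual is assigned to the
untreated compartment so that treated + untreated = hypertensive exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

from .synthetic import PopulationProjection, PrevalenceTable

logger = logging.getLogger(__name__)

__all__ = [
    "FixedRate",
    "AgeWeighted",
    "CountOverride",
    "PrevalenceRule",
    "ScenarioSpec",
    "CohortYearState",
    "estimate_prevalent_population",
    "partition_treatment",
    "advance_year",
    "treated_survivors",
]


def _round_half_even(x: float) -> int:
    """Banker's rounding to an integer (ties to even)."""
    import math

    floor = math.floor(x)
    frac = x - floor
    if frac > 0.5:
        return floor + 1
    if frac < 0.5:
        return floor
    return floor if floor % 2 == 0 else floor + 1


# --------------------------------------------------------------------------
# prevalence rules


@dataclass(frozen=True)
class FixedRate:
    """Prevalents = overall rate x total adults over 20."""

    rate: float


@dataclass(frozen=True)
class AgeWeighted:
    """Prevalents = sum over age bands of band count x band proportion."""

    table: PrevalenceTable


@dataclass(frozen=True)
class CountOverride:
    """Absolute prevalent counts per year.

    Years not listed are extrapolated from the nearest listed year by the
    population projection's total over-20 growth (the override anchors the
    level; the projection supplies the trend).
    """

    counts: Mapping[int, int]


PrevalenceRule = FixedRate | AgeWeighted | CountOverride


@dataclass(frozen=True)
class ScenarioSpec:
    """A guideline scenario: cut-off, cascade probabilities, treatment goal.

    Cascade probabilities and tablets/day are referenced by parameter name
    (resolved against a value mapping at run time) so that one scenario
    definition serves both the deterministic run and every PSA draw.
    ``established_prevalence_rule`` is set only for the lowered-cut-off
    scenario: it sizes the stratum that would be hypertensive under the old
    cut-off; the excess over it is the newly classified stratum, which gets
    ``adherence_new_param`` instead of ``adherence_established_param``.
    """

    name: str
    diagnostic_cutoff: str  # "140/90" | "130/80"
    treatment_goal: str  # "SBP<140" | "SBP<120"
    prevalence_rule: PrevalenceRule
    event_probability_set: str  # "standard" | "intensive"
    established_prevalence_rule: PrevalenceRule | None = None
    physician_param: str = "physician_prescription"
    adherence_established_param: str = "adherence_standard"
    adherence_new_param: str = "adherence_new_stratum"
    tablets_param: str = "tablets_per_day_standard"

    def __post_init__(self) -> None:
        if self.event_probability_set not in ("standard", "intensive"):
            raise ValueError(f"bad event probability set {self.event_probability_set!r}")


@dataclass(frozen=True)
class CohortYearState:
    """Compartment counts for one scenario-year."""

    year: int
    n_hypertensive: int
    n_prescribed: int
    n_treated: int  # prescribed AND adherent
    n_untreated: int  # pooled: unprescribed + prescribed-non-adherent
    n_new_stratum: int = 0  # patients added by the 130-139/80-89 cut-off

    def __post_init__(self) -> None:
        if self.n_treated + self.n_untreated != self.n_hypertensive:
            raise ValueError("treated + untreated must equal hypertensive")
        if not self.n_treated <= self.n_prescribed <= self.n_hypertensive:
            raise ValueError("need treated <= prescribed <= hypertensive")


def estimate_prevalent_population(
    projection: PopulationProjection,
    scenario: ScenarioSpec,
    year: int,
    rule: PrevalenceRule | None = None,
) -> int:
    """Prevalent hypertensives in ``year`` under the scenario's rule.

    ``rule`` overrides the scenario's own rule (used internally to size the
    established stratum of the lowered-cut-off scenario).
    """
    rule = scenario.prevalence_rule if rule is None else rule
    if isinstance(rule, FixedRate):
        return _round_half_even(projection.total(year) * rule.rate)
    if isinstance(rule, AgeWeighted):
        counts = projection.counts(year)
        props = rule.table.proportions()
        missing = set(counts.index) - set(props.index)
        if missing:
            raise KeyError(f"prevalence table lacks age groups {sorted(missing)}")
        return _round_half_even(float((counts * props.reindex(counts.index)).sum()))
    if isinstance(rule, CountOverride):
        if year in rule.counts:
            return int(rule.counts[year])
        anchor = min(rule.counts, key=lambda y: abs(y - year))
        scale = projection.total(year) / projection.total(anchor)
        return _round_half_even(rule.counts[anchor] * scale)
    raise TypeError(f"unknown prevalence rule {rule!r}")


def partition_treatment(
    n_hypertensive: int,
    n_new_stratum: int,
    physician_p: float,
    adherence_established: float,
    adherence_new: float,
    year: int = 0,
) -> CohortYearState:
    """Split the prevalent pool into treated / untreated compartments.

    Established-stratum treated = (N - N_new) * physician_p * adherence_established;
    new-stratum treated = N_new * physician_p * adherence_new. Both products
    are rounded half-to-even; the residual goes to the untreated compartment,
    which therefore conserves the total exactly.
    """
    if not 0 <= n_new_stratum <= n_hypertensive:
        raise ValueError("need 0 <= n_new_stratum <= n_hypertensive")
    for pname, p in (
        ("physician_p", physician_p),
        ("adherence_established", adherence_established),
        ("adherence_new", adherence_new),
    ):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{pname} must be in [0, 1], got {p}")

    n_established = n_hypertensive - n_new_stratum
    prescribed_est = _round_half_even(n_established * physician_p)
    prescribed_new = _round_half_even(n_new_stratum * physician_p)
    treated_est = min(prescribed_est, _round_half_even(n_established * physician_p * adherence_established))
    treated_new = min(prescribed_new, _round_half_even(n_new_stratum * physician_p * adherence_new))
    n_treated = treated_est + treated_new
    return CohortYearState(
        year=year,
        n_hypertensive=n_hypertensive,
        n_prescribed=prescribed_est + prescribed_new,
        n_treated=n_treated,
        n_untreated=n_hypertensive - n_treated,
        n_new_stratum=n_new_stratum,
    )


def treated_survivors(state: CohortYearState, deaths: float) -> int:
    """Treated patients surviving the year.

    Deaths are attributed to compartments proportionally to their size; the
    treated share is subtracted from the treated compartment.
    """
    if deaths < 0 or deaths > state.n_hypertensive:
        raise ValueError("need 0 <= deaths <= n_hypertensive")
    if state.n_hypertensive == 0:
        return 0
    treated_deaths = deaths * state.n_treated / state.n_hypertensive
    return max(0, _round_half_even(state.n_treated - treated_deaths))


def advance_year(
    state: CohortYearState,
    deaths: float,
    next_year_prevalent: int,
    *,
    physician_p: float,
    adherence_established: float,
    adherence_new: float = 0.0,
    n_new_stratum: int = 0,
) -> CohortYearState:
    """Roll the cohort into the next calendar year.

    Next year's prevalent pool is the projected/override prevalence plus the
    treated survivors of this year (early treatment improves survival, so
    survivors re-enter the prevalent pool and the whole cascade is
    re-partitioned). A negative pool is clamped to zero with a warning.
    """
    carry = treated_survivors(state, deaths)
    n_hyp = next_year_prevalent + carry
    if n_hyp < 0:
        logger.warning("negative prevalent pool in %d clamped to 0", state.year + 1)
        n_hyp = 0
    return partition_treatment(
        n_hyp,
        min(n_new_stratum, n_hyp),
        physician_p,
        adherence_established,
        adherence_new,
        year=state.year + 1,
    )
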