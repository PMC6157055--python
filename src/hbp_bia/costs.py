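"""Costing of each scenario-year, in USD.

Three components: antihypertensive medication for treated patients
(tablets/day x unit cost x 365), the diagnostic-aid panel for every
diagnosed prevalent hypertensive (annual prescription frequency x panel
cost), and complication management (per-episode acute costs for AMI and
stroke; heart failure incurs decompensation episodes plus one year of
chronic outpatient management). AMI episode costs are year-specific as
published; deaths carry no direct cost. Nominal yearly amounts can be
expressed in constant base-year terms by CPI deflation when aggregating.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .events import EventCounts

__all__ = [
    "CostBreakdown",
    "medication_cost",
    "diagnostics_cost",
    "complication_cost",
    "deflate",
    "year_costs",
]


@dataclass(frozen=True)
class CostBreakdown:
    """Per-component USD costs for one scenario-year; total is exact sum."""

    year: int
    scenario: str
    medication_usd: float
    diagnostics_usd: float
    ami_usd: float
    stroke_usd: float
    hf_usd: float

    def __post_init__(self) -> None:
        for f in ("medication_usd", "diagnostics_usd", "ami_usd", "stroke_usd", "hf_usd"):
            if getattr(self, f) < 0:
                raise ValueError(f"negative cost component {f}")

    @property
    def total_usd(self) -> float:
        return (
            self.medication_usd
            + self.diagnostics_usd
            + self.ami_usd
            + self.stroke_usd
            + self.hf_usd
        )

    @property
    def complications_usd(self) -> float:
        return self.ami_usd + self.stroke_usd + self.hf_usd

    def as_dict(self) -> dict[str, float]:
        return {
            "medication_usd": self.medication_usd,
            "diagnostics_usd": self.diagnostics_usd,
            "ami_usd": self.ami_usd,
            "stroke_usd": self.stroke_usd,
            "hf_usd": self.hf_usd,
            "total_usd": self.total_usd,
        }


def medication_cost(n_treated: float, tablets_per_day: float, daily_cost_per_tablet: float) -> float:
    """Annual medication cost: people x tablets/day x USD/tablet-day x 365."""
    if min(n_treated, tablets_per_day, daily_cost_per_tablet) < 0:
        raise ValueError("medication cost inputs must be non-negative")
    return n_treated * tablets_per_day * daily_cost_per_tablet * 365.0


def diagnostics_cost(n_diagnosed: float, annual_frequency: float, unit_cost: float) -> float:
    """Annual diagnostic-aid cost over the diagnosed prevalent pool."""
    if min(n_diagnosed, annual_frequency, unit_cost) < 0:
        raise ValueError("diagnostics cost inputs must be non-negative")
    return n_diagnosed * annual_frequency * unit_cost


def complication_cost(
    events: EventCounts, values: Mapping[str, float], year: int
) -> tuple[float, float, float]:
    """(AMI, stroke, HF) USD costs of one year's expected events.

    AMI uses the published year-specific episode cost; stroke a constant
    per-episode cost; each heart-failure case incurs the mean number of
    decompensation episodes plus one year of chronic management.
    """
    key = f"ami_episode_cost_{year}"
    if key not in values:
        raise KeyError(f"no AMI episode cost for year {year}")
    ami_usd = events.ami * values[key]
    stroke_usd = events.stroke * values["stroke_episode_cost"]
    hf_per_case = (
        values["hf_decompensation_episodes"] * values["hf_decompensation_cost"]
        + values["hf_chronic_cost"]
    )
    hf_usd = events.hf * hf_per_case
    return ami_usd, stroke_usd, hf_usd


def deflate(
    amount: float,
    year: int,
    cpi_by_year: Mapping[int, float],
    base_year: int | None = None,
) -> float:
    """Express a nominal ``year`` amount in constant ``base_year`` terms.

    Divides by the compound CPI factor over every year after the base up to
    and including ``year`` (CPI given in percent); base-year amounts are
    unchanged. Missing CPI for an intervening year is an error.
    """
    base = min(cpi_by_year) if base_year is None else base_year
    if year < base:
        raise ValueError(f"year {year} precedes base year {base}")
    factor = 1.0
    for y in range(base + 1, year + 1):
        if y not in cpi_by_year:
            raise KeyError(f"no CPI for year {y}")
        factor *= 1.0 + cpi_by_year[y] / 100.0
    return amount / factor


def year_costs(
    scenario_name: str,
    year: int,
    n_treated: float,
    n_diagnosed: float,
    tablets_per_day: float,
    events: EventCounts,
    values: Mapping[str, float],
) -> CostBreakdown:
    """Assemble the full nominal cost breakdown for one scenario-year."""
    ami_usd, stroke_usd, hf_usd = complication_cost(events, values, year)
    return CostBreakdown(
        year=year,
        scenario=scenario_name,
        medication_usd=medication_cost(
            n_treated, tablets_per_day, values["medication_cost_per_tablet_day"]
        ),
        diagnostics_usd=diagnostics_cost(
            n_diagnosed, values["diagnostic_aid_frequency"], values["diagnostic_aids_cost"]
        ),
        ami_usd=ami_usd,
        stroke_usd=stroke_usd,
        hf_usd=hf_usd,
    )
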