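"""Synthetic stand-ins for the three external data sources.

The real model consumes (a) national population projections of adults over
20 (DANE), (b) age-specific hypertension prevalence under the diagnostic
cut-offs, and (c) annual administrative event counts per ICD-10 code
(SISPRO claims). None of these are redistributable, so this module
generates structurally faithful substitutes: a smoothly growing adult
population apportioned into decadal age bands, age-increasing prevalence
fractions whose population-weighted means hit requested overall rates, and
noisy trending annual event series.

All generators are pure functions of their arguments, including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AGE_GROUPS",
    "DEFAULT_AGE_STRUCTURE",
    "PopulationProjection",
    "PrevalenceTable",
    "EventHistory",
    "generate_population",
    "generate_prevalence_table",
    "generate_event_history",
]

#: Decadal age bands for adults over 20.
AGE_GROUPS: tuple[str, ...] = ("20-29", "30-39", "40-49", "50-59", "60-69", "70-79", "80+")

#: Adult (20+) age composition of a demographically young middle-income
#: country, late 2010s.
DEFAULT_AGE_STRUCTURE: tuple[float, ...] = (0.26, 0.21, 0.17, 0.15, 0.11, 0.07, 0.03)


@dataclass(frozen=True)
class PopulationProjection:
    """Adults over 20 per calendar year and age band."""

    table: pd.DataFrame  # columns: year, age_group, count

    def total(self, year: int) -> int:
        sub = self.table[self.table["year"] == year]
        if sub.empty:
            raise KeyError(f"year {year} not in projection")
        return int(sub["count"].sum())

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(sorted(self.table["year"].unique()))

    def counts(self, year: int) -> pd.Series:
        sub = self.table[self.table["year"] == year]
        if sub.empty:
            raise KeyError(f"year {year} not in projection")
        return sub.set_index("age_group")["count"]

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PopulationProjection":
        df = pd.read_csv(path)
        return cls(df[["year", "age_group", "count"]])


@dataclass(frozen=True)
class PrevalenceTable:
    """Proportion hypertensive per age band under one diagnostic cut-off."""

    table: pd.DataFrame  # columns: age_group, proportion_hypertensive

    def proportions(self) -> pd.Series:
        return self.table.set_index("age_group")["proportion_hypertensive"]

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PrevalenceTable":
        df = pd.read_csv(path)
        return cls(df[["age_group", "proportion_hypertensive"]])


@dataclass(frozen=True)
class EventHistory:
    """Annual administrative event counts for one ICD-10 code."""

    icd10_code: str  # I219 (AMI), I509 (heart failure), I64 (stroke)
    table: pd.DataFrame  # columns: year, count

    def counts(self) -> np.ndarray:
        return self.table["count"].to_numpy()

    def to_csv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.insert(0, "icd10_code", self.icd10_code)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "EventHistory":
        df = pd.read_csv(path)
        code = str(df["icd10_code"].iloc[0])
        return cls(code, df[["year", "count"]].reset_index(drop=True))


def _largest_remainder(total: int, shares: np.ndarray) -> np.ndarray:
    """Apportion ``total`` into integer parts proportional to ``shares``.

    Largest-remainder (Hamilton) rounding: the integer parts always sum to
    ``total`` exactly.
    """
    quotas = shares / shares.sum() * total
    floors = np.floor(quotas).astype(np.int64)
    short = int(total - floors.sum())
    order = np.argsort(-(quotas - floors), kind="stable")
    floors[order[:short]] += 1
    return floors


def generate_population(
    base_total: int = 34_000_000,
    annual_growth: float = 0.012,
    years: Sequence[int] = (2018, 2019, 2020),
    age_structure: Sequence[float] = DEFAULT_AGE_STRUCTURE,
    seed: int = 0,
) -> PopulationProjection:
    """Compound-growth population projection apportioned into age bands.

    Year ``t`` total is ``round(base_total * (1 + annual_growth) ** (t - t0))``;
    age-band counts are the largest-remainder apportionment of that total, so
    bands sum to the year total exactly. ``seed`` perturbs the age structure
    slightly (a few per-mille, fixed across years) so distinct seeds give
    distinct but equally plausible pyramids.
    """
    shares = np.asarray(age_structure, dtype=float)
    if abs(shares.sum() - 1.0) > 1e-6:
        raise ValueError(f"age_structure must sum to 1, got {shares.sum():.8f}")
    if annual_growth <= -1:
        raise ValueError("annual_growth must be > -1")
    if len(shares) != len(AGE_GROUPS):
        raise ValueError(f"expected {len(AGE_GROUPS)} age-structure proportions")
    rng = np.random.default_rng(seed)
    jitter = 1.0 + 0.005 * rng.standard_normal(len(shares))
    shares = shares * jitter
    shares /= shares.sum()

    t0 = min(years)
    rows = []
    for year in years:
        total = int(round(base_total * (1.0 + annual_growth) ** (year - t0)))
        counts = _largest_remainder(total, shares)
        rows.extend(
            {"year": int(year), "age_group": g, "count": int(c)}
            for g, c in zip(AGE_GROUPS, counts)
        )
    return PopulationProjection(pd.DataFrame(rows))


def generate_prevalence_table(
    old_overall: float = 0.072,
    new_overall: float = 0.1102,
    age_groups: Sequence[str] = AGE_GROUPS,
    seed: int = 0,
    age_weights: Sequence[float] = DEFAULT_AGE_STRUCTURE,
) -> tuple[PrevalenceTable, PrevalenceTable]:
    """Age-increasing prevalence tables for the old and new cut-offs.

    Both tables share an increasing base shape (hypertension risk rises with
    age); each is scaled so its ``age_weights``-weighted overall prevalence
    equals the requested target to within 1e-6. Because the new table is a
    uniform up-scaling of the old one, its proportion dominates the old one
    in every age band.
    """
    if not 0.0 < old_overall < new_overall < 1.0:
        raise ValueError("need 0 < old_overall < new_overall < 1")
    w = np.asarray(age_weights, dtype=float)
    w = w / w.sum()
    rng = np.random.default_rng(seed)
    # Increasing base shape: roughly doubling odds per decade, mild jitter
    # that preserves monotonicity.
    base = np.array([1.0, 2.0, 3.8, 7.0, 12.0, 18.0, 24.0])[: len(age_groups)]
    base = base * (1.0 + 0.02 * rng.random(len(base)))
    base = np.maximum.accumulate(base)

    def scaled(target: float) -> np.ndarray:
        props = base * (target / float(w @ base))
        if props.max() >= 1.0:
            raise ValueError(f"target {target} infeasible with this age shape")
        return props

    old_p, new_p = scaled(old_overall), scaled(new_overall)
    mk = lambda p: PrevalenceTable(
        pd.DataFrame({"age_group": list(age_groups), "proportion_hypertensive": p})
    )
    return mk(old_p), mk(new_p)


def generate_event_history(
    code: str,
    base_count: float,
    trend_per_year: float = 0.0,
    noise_sd: float = 0.0,
    n_years: int = 8,
    seed: int = 0,
    start_year: int = 2010,
) -> EventHistory:
    """Noisy linear annual event-count series for one ICD-10 code.

    ``count_k = round(base + trend * k + eps_k)`` with Gaussian
    ``eps_k ~ N(0, noise_sd)``, clipped at zero; reproducible per seed.
    """
    if n_years < 3:
        raise ValueError("need at least 3 years of history")
    rng = np.random.default_rng(seed)
    k = np.arange(n_years)
    noise = rng.normal(0.0, noise_sd, size=n_years) if noise_sd > 0 else np.zeros(n_years)
    counts = np.maximum(np.round(base_count + trend_per_year * k + noise), 0).astype(np.int64)
    return EventHistory(
        icd10_code=code,
        table=pd.DataFrame({"year": start_year + k, "count": counts}),
    )
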