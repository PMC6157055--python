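"""Model parameters: representation, file I/O, sampling and reconciliation.

The budget-impact model is driven by a flat table of named parameters
(event probabilities, care-cascade probabilities, resource-use means and
unit costs), each carrying a deterministic point estimate and, where the
uncertainty is modelled, a probabilistic-sensitivity-analysis (PSA)
distribution:

* **beta(a, b)** for probabilities — ``a`` patients with the event of
  interest, ``b`` without;
* **poisson(lam)** for resource quantities — ``lam`` is the mean count;
* **gamma(a, b)** for costs — shape ``a`` and scale ``b``, parameterised
  on the Colombian-peso (COP) scale and converted to USD after sampling;
* **fixed(value)** for quantities with no uncertainty model.

Several shipped rows have a point estimate that disagrees with the
analytic mean of their distribution; :func:`reconcile` resolves this
under an explicit policy rather than silently preferring one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import yaml

__all__ = [
    "Distribution",
    "Parameter",
    "ParameterSet",
    "ParameterFileError",
    "ParameterValidationError",
    "MANDATORY_PARAMETERS",
    "load_parameters",
    "save_parameters",
    "default_parameters",
    "mean_of",
    "sample",
    "reconcile",
]

DistKind = Literal["beta", "poisson", "gamma", "fixed"]
ReconcilePolicy = Literal["point_estimate", "distribution_mean", "rescaled_distribution"]


class ParameterFileError(ValueError):
    """Raised when a parameter file cannot be parsed or has a bad schema."""


class ParameterValidationError(ValueError):
    """Raised when parameter values violate their domain constraints."""


@dataclass(frozen=True)
class Distribution:
    """A PSA prior with an analytic mean.

    Exactly the fields required by ``kind`` are set: ``a``/``b`` for beta
    and gamma (shape/scale), ``lam`` for poisson, ``value`` for fixed.
    """

    kind: DistKind
    a: float | None = None
    b: float | None = None
    lam: float | None = None
    value: float | None = None

    def __post_init__(self) -> None:
        required = {
            "beta": ("a", "b"),
            "gamma": ("a", "b"),
            "poisson": ("lam",),
            "fixed": ("value",),
        }
        if self.kind not in required:
            raise ParameterValidationError(f"unknown distribution kind {self.kind!r}")
        for name in ("a", "b", "lam", "value"):
            val = getattr(self, name)
            if name in required[self.kind]:
                if val is None:
                    raise ParameterValidationError(
                        f"{self.kind} distribution requires field {name!r}"
                    )
                if name != "value" and val <= 0:
                    raise ParameterValidationError(
                        f"{self.kind} field {name!r} must be > 0, got {val}"
                    )
            elif val is not None:
                raise ParameterValidationError(
                    f"{self.kind} distribution must not set field {name!r}"
                )

    @property
    def mean(self) -> float:
        if self.kind == "beta":
            return self.a / (self.a + self.b)
        if self.kind == "poisson":
            return float(self.lam)
        if self.kind == "gamma":
            return self.a * self.b
        return float(self.value)

    def sample(self, rng: np.random.Generator) -> float:
        """One draw from the distribution.

        Poisson draws are integer-valued (they model counts that are then
        used as population means); fixed returns ``value`` exactly.
        """
        if self.kind == "beta":
            return float(rng.beta(self.a, self.b))
        if self.kind == "poisson":
            return float(rng.poisson(self.lam))
        if self.kind == "gamma":
            return float(rng.gamma(self.a, self.b))
        return float(self.value)


@dataclass(frozen=True)
class Parameter:
    """One named model input.

    ``dist_scale`` records the scale the distribution is parameterised on:
    ``"natural"`` (same units as the point estimate) or ``"cop"`` (Colombian
    pesos, converted to USD at the configured exchange rate after sampling).
    """

    name: str
    point_estimate: float
    units: str
    distribution: Distribution | None = None
    dist_scale: Literal["natural", "cop"] = "natural"
    source_note: str = ""

    def __post_init__(self) -> None:
        if self.units.startswith("probability"):
            if not 0.0 <= self.point_estimate <= 1.0:
                raise ParameterValidationError(
                    f"probability parameter {self.name!r} out of [0, 1]: "
                    f"{self.point_estimate}"
                )
        elif self.point_estimate < 0:
            raise ParameterValidationError(
                f"parameter {self.name!r} must be non-negative: {self.point_estimate}"
            )

    def sample(self, rng: np.random.Generator, fx_cop_per_usd: float | None = None) -> float:
        """Draw one value on the point-estimate scale (USD for cost rows)."""
        if self.distribution is None:
            return self.point_estimate
        draw = self.distribution.sample(rng)
        if self.dist_scale == "cop":
            if fx_cop_per_usd is None:
                raise ValueError(f"{self.name}: COP-scale draw needs an exchange rate")
            draw /= fx_cop_per_usd
        return draw


#: Every Table-1-derived row the model requires, by canonical name.
MANDATORY_PARAMETERS: tuple[str, ...] = (
    "physician_prescription",
    "adherence_standard",
    "adherence_new_stratum",
    "ami_standard",
    "stroke_standard",
    "hf_standard",
    "cvdeath_standard",
    "ami_intensive",
    "stroke_intensive",
    "hf_intensive",
    "cvdeath_intensive",
    "ami_untreated",
    "stroke_untreated",
    "hf_untreated",
    "tablets_per_day_intensive",
    "tablets_per_day_standard",
    "diagnostic_aid_frequency",
    "hf_decompensation_episodes",
    "medication_cost_per_tablet_day",
    "diagnostic_aids_cost",
    "ami_episode_cost_2018",
    "ami_episode_cost_2019",
    "ami_episode_cost_2020",
    "stroke_episode_cost",
    "hf_decompensation_cost",
    "hf_chronic_cost",
)


@dataclass(frozen=True)
class ParameterSet:
    """All model parameters plus global settings for one analysis."""

    parameters: Mapping[str, Parameter]
    baseline_prevalence: float = 0.072
    horizon_years: tuple[int, ...] = (2018, 2019, 2020)
    cpi_by_year: Mapping[int, float] = field(
        default_factory=lambda: {2018: 3.95, 2019: 4.35, 2020: 3.95}
    )
    fx_cop_per_usd: float = 2877.0
    psa_iterations: int = 5000
    #: scenario label -> {year: prevalent hypertensive count}; absolute-count
    #: overrides used when national projections cannot reproduce the inputs.
    prevalent_count_overrides: Mapping[str, Mapping[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [n for n in MANDATORY_PARAMETERS if n not in self.parameters]
        if missing:
            raise ParameterValidationError(
                "missing mandatory parameters: " + ", ".join(missing)
            )

    def __getitem__(self, name: str) -> Parameter:
        return self.parameters[name]

    def value(self, name: str) -> float:
        """Point estimate of a parameter."""
        return self.parameters[name].point_estimate

    def point_values(self) -> dict[str, float]:
        """All point estimates as a flat name -> value mapping."""
        return {n: p.point_estimate for n, p in self.parameters.items()}

    def sample_values(
        self,
        rng: np.random.Generator,
        policy: ReconcilePolicy = "rescaled_distribution",
    ) -> dict[str, float]:
        """One PSA draw of every parameter (fixed rows keep their estimate).

        Distributions are first reconciled against the point estimate under
        ``policy``; parameters without a distribution are left at their
        point estimate. Draws are made in the deterministic iteration order
        of the mapping, so a seeded generator reproduces the stream.
        """
        out: dict[str, float] = {}
        for name, p in self.parameters.items():
            p2 = reconcile(p, policy, fx_cop_per_usd=self.fx_cop_per_usd)
            out[name] = p2.sample(rng, fx_cop_per_usd=self.fx_cop_per_usd)
        return out

    def to_dict(self) -> dict:
        """Plain-data form (the on-disk schema)."""
        params = {}
        for name, p in self.parameters.items():
            row: dict = {"estimate": p.point_estimate, "units": p.units}
            d = p.distribution
            if d is not None:
                row["dist"] = d.kind
                row["params"] = {
                    k: getattr(d, k)
                    for k in ("a", "b", "lam", "value")
                    if getattr(d, k) is not None
                }
                if p.dist_scale != "natural":
                    row["dist_scale"] = p.dist_scale
            if p.source_note:
                row["note"] = p.source_note
            params[name] = row
        return {
            "schema_version": 1,
            "globals": {
                "baseline_prevalence": self.baseline_prevalence,
                "horizon_years": list(self.horizon_years),
                "cpi_by_year": {int(k): v for k, v in self.cpi_by_year.items()},
                "fx_cop_per_usd": self.fx_cop_per_usd,
                "psa_iterations": self.psa_iterations,
                "prevalent_count_overrides": {
                    s: {int(y): int(c) for y, c in byyear.items()}
                    for s, byyear in self.prevalent_count_overrides.items()
                },
            },
            "parameters": params,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def mean_of(d: Distribution) -> float:
    """Analytic expectation of a PSA distribution."""
    return d.mean


def sample(d: Distribution, rng: np.random.Generator) -> float:
    """One draw from ``d`` using a seeded generator."""
    return d.sample(rng)


def reconcile(
    p: Parameter,
    policy: ReconcilePolicy,
    fx_cop_per_usd: float | None = None,
) -> Parameter:
    """Resolve a point-estimate / distribution-mean disagreement.

    ``point_estimate`` keeps the row verbatim; ``distribution_mean`` replaces
    the point estimate by the distribution's analytic mean (COP-scale means
    are converted to USD); ``rescaled_distribution`` adjusts the distribution
    so its mean equals the point estimate — beta keeps a+b fixed and moves a,
    poisson sets lam, gamma keeps the shape and moves the scale.
    """
    if policy == "point_estimate" or p.distribution is None:
        return p
    d = p.distribution
    fx = fx_cop_per_usd
    if p.dist_scale == "cop" and fx is None:
        raise ValueError(f"{p.name}: COP-scale reconcile needs an exchange rate")

    if policy == "distribution_mean":
        mean = d.mean / fx if p.dist_scale == "cop" else d.mean
        return replace(p, point_estimate=mean)

    if policy == "rescaled_distribution":
        target = p.point_estimate * fx if p.dist_scale == "cop" else p.point_estimate
        if d.kind == "beta":
            n = d.a + d.b
            if not 0.0 < target < 1.0:
                raise ParameterValidationError(
                    f"{p.name}: cannot rescale beta to mean {target}"
                )
            new = Distribution("beta", a=target * n, b=(1.0 - target) * n)
        elif d.kind == "poisson":
            new = Distribution("poisson", lam=target)
        elif d.kind == "gamma":
            new = Distribution("gamma", a=d.a, b=target / d.a)
        else:  # fixed; target is on the distribution's own scale
            new = Distribution("fixed", value=target)
        return replace(p, distribution=new)

    raise ValueError(f"unknown reconcile policy {policy!r}")


# ---------------------------------------------------------------------------
# file I/O


def _parameter_from_row(name: str, row: Mapping) -> Parameter:
    try:
        estimate = float(row["estimate"])
        units = str(row.get("units", ""))
    except (KeyError, TypeError, ValueError) as exc:
        raise ParameterFileError(f"parameter {name!r}: bad row: {exc}") from exc
    dist = None
    if "dist" in row:
        kind = row["dist"]
        dp = dict(row.get("params", {}))
        dist = Distribution(kind, **{k: float(v) for k, v in dp.items()})
    return Parameter(
        name=name,
        point_estimate=estimate,
        units=units,
        distribution=dist,
        dist_scale=row.get("dist_scale", "natural"),
        source_note=str(row.get("note", "")),
    )


def parameter_set_from_dict(doc: Mapping) -> ParameterSet:
    """Build a :class:`ParameterSet` from the plain-data schema."""
    if not isinstance(doc, Mapping) or "parameters" not in doc:
        raise ParameterFileError("document must be a mapping with a 'parameters' key")
    rows = doc["parameters"]
    missing = [n for n in MANDATORY_PARAMETERS if n not in rows]
    if missing:
        raise ParameterValidationError(
            "missing mandatory parameters: " + ", ".join(sorted(missing))
        )
    parameters = {name: _parameter_from_row(name, row) for name, row in rows.items()}
    g = doc.get("globals", {})
    return ParameterSet(
        parameters=parameters,
        baseline_prevalence=float(g.get("baseline_prevalence", 0.072)),
        horizon_years=tuple(int(y) for y in g.get("horizon_years", (2018, 2019, 2020))),
        cpi_by_year={int(k): float(v) for k, v in g.get("cpi_by_year", {}).items()}
        or {2018: 3.95, 2019: 4.35, 2020: 3.95},
        fx_cop_per_usd=float(g.get("fx_cop_per_usd", 2877.0)),
        psa_iterations=int(g.get("psa_iterations", 5000)),
        prevalent_count_overrides={
            s: {int(y): int(c) for y, c in byyear.items()}
            for s, byyear in g.get("prevalent_count_overrides", {}).items()
        },
    )


def load_parameters(path: str | Path) -> ParameterSet:
    """Load a parameter file (YAML mapping, schema documented in the README)."""
    path = Path(path)
    try:
        with path.open("r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f" at line {mark.line + 1}" if mark is not None else ""
        raise ParameterFileError(f"cannot parse {path}{where}: {exc}") from exc
    return parameter_set_from_dict(doc)


def save_parameters(ps: ParameterSet, path: str | Path) -> None:
    """Write a ParameterSet back to the on-disk YAML schema (lossless)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        yaml.safe_dump(ps.to_dict(), fh, sort_keys=True)


def default_parameters() -> ParameterSet:
    """The packaged parameter fixture (the model's published input table)."""
    from importlib.resources import files

    with (files("hbp_bia") / "data" / "table1_params.yaml").open("r", encoding="utf-8") as fh:
        return parameter_set_from_dict(yaml.safe_load(fh))
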