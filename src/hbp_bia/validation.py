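"""External-validation machinery.

The model's expected event counts are checked against administrative
claims series: each ICD-10 series is projected forward with simple
exponential smoothing (SES, level-only recursion ``S_t = a*y_t +
(1-a)*S_{t-1}``, a = 0.1 by default) and a 95% prediction interval, and
the model's count is declared adequately predicted if it falls inside
the interval. Effect sizes are additionally checked by computing
per-outcome hazard ratios between scenarios and testing them against
externally supplied trial confidence intervals.

The prediction interval used here is the standard Gaussian interval from
the standard deviation of the one-step-ahead residuals, held flat over
the forecast horizon; it is isolated in :func:`ses_forecast` so an
alternative construction can be swapped in.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .synthetic import EventHistory

__all__ = [
    "ICD10_TO_OUTCOME",
    "SESForecast",
    "ses_forecast",
    "check_event_containment",
    "check_hazard_ratios",
    "validation_report",
]

#: Outcome mapping of the administrative codes the model is validated on.
ICD10_TO_OUTCOME: dict[str, str] = {"I219": "ami", "I509": "hf", "I64": "stroke"}


@dataclass(frozen=True)
class SESForecast:
    """A flat SES forecast with a 95% prediction interval."""

    alpha: float
    smoothed: np.ndarray  # level after each observation
    horizon_years: tuple[int, ...]
    forecast: float  # flat point forecast for every horizon year
    sigma: float  # one-step-ahead residual SD
    ci_low: float
    ci_high: float

    def contains(self, value: float) -> bool:
        """Closed-interval containment check."""
        return self.ci_low <= value <= self.ci_high


def ses_forecast(history: EventHistory, alpha: float = 0.1, horizon: int = 3) -> SESForecast:
    """Simple exponential smoothing forecast of an annual event series.

    Level recursion initialised at the first observation: ``S_1 = y_1``,
    ``S_t = alpha*y_t + (1-alpha)*S_{t-1}``; the point forecast is ``S_n``
    for every horizon year. The 95% interval is ``forecast +/- 1.96*sigma``
    with ``sigma`` the standard deviation (ddof=1) of the one-step-ahead
    errors ``y_t - S_{t-1}``.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    y = np.asarray(history.counts(), dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 observations to forecast")
    level = np.empty_like(y)
    level[0] = y[0]
    for t in range(1, y.size):
        level[t] = alpha * y[t] + (1.0 - alpha) * level[t - 1]
    residuals = y[1:] - level[:-1]
    sigma = float(np.std(residuals, ddof=1)) if residuals.size > 1 else 0.0
    forecast = float(level[-1])
    last_year = int(history.table["year"].iloc[-1])
    return SESForecast(
        alpha=alpha,
        smoothed=level,
        horizon_years=tuple(last_year + k for k in range(1, horizon + 1)),
        forecast=forecast,
        sigma=sigma,
        ci_low=forecast - 1.96 * sigma,
        ci_high=forecast + 1.96 * sigma,
    )


def check_event_containment(
    predicted: Mapping[int, float] | Sequence[float] | float,
    forecast: SESForecast,
) -> dict[int, bool]:
    """Is each predicted annual count inside the forecast's 95% interval?

    ``predicted`` may be a single count (applied to every horizon year), a
    sequence aligned with the horizon, or a year -> count mapping. The
    interval is closed: a count equal to a bound is contained.
    """
    if isinstance(predicted, Mapping):
        items = {int(y): float(v) for y, v in predicted.items()}
    elif isinstance(predicted, (int, float)):
        items = {y: float(predicted) for y in forecast.horizon_years}
    else:
        if len(predicted) != len(forecast.horizon_years):
            raise ValueError("predicted sequence does not match the forecast horizon")
        items = dict(zip(forecast.horizon_years, map(float, predicted)))
    unknown = set(items) - set(forecast.horizon_years)
    if unknown:
        raise KeyError(f"years {sorted(unknown)} not in forecast horizon")
    return {y: forecast.contains(v) for y, v in items.items()}


def check_hazard_ratios(
    model_hrs: Mapping[str, float | None],
    reference_cis: Mapping[str, tuple[float, float]],
) -> dict[str, bool | None]:
    """Check per-outcome hazard ratios against external trial intervals.

    Returns True/False for checked outcomes; ``None`` (unchecked) when the
    model HR is undefined or no reference interval was supplied. Reference
    intervals come from configuration — they belong to an external trial
    publication and are never hard-coded.
    """
    out: dict[str, bool | None] = {}
    for outcome, hr in model_hrs.items():
        ref = reference_cis.get(outcome)
        if hr is None or ref is None:
            out[outcome] = None
            continue
        low, high = ref
        if low > high:
            raise ValueError(f"{outcome}: malformed reference interval {ref}")
        out[outcome] = low <= hr <= high
    return out


def validation_report(
    histories: Sequence[EventHistory],
    model_events_by_year: Mapping[str, Mapping[int, float]],
    model_hrs: Mapping[str, float | None] | None = None,
    reference_cis: Mapping[str, tuple[float, float]] | None = None,
    alpha: float = 0.1,
    horizon: int = 3,
) -> dict:
    """Full validation report (JSON-serialisable).

    ``model_events_by_year`` maps outcome name (ami/stroke/hf) to the
    model's expected annual counts per calendar year.
    """
    outcomes = {}
    all_contained = True
    for hist in histories:
        outcome = ICD10_TO_OUTCOME.get(hist.icd10_code)
        if outcome is None:
            raise KeyError(f"unknown ICD-10 code {hist.icd10_code!r}")
        fc = ses_forecast(hist, alpha=alpha, horizon=horizon)
        predicted = {
            y: v
            for y, v in model_events_by_year.get(outcome, {}).items()
            if y in fc.horizon_years
        }
        contained = check_event_containment(predicted, fc) if predicted else {}
        all_contained &= all(contained.values()) if contained else True
        outcomes[outcome] = {
            "icd10_code": hist.icd10_code,
            "alpha": alpha,
            "forecast": fc.forecast,
            "ci_low": fc.ci_low,
            "ci_high": fc.ci_high,
            "horizon_years": list(fc.horizon_years),
            "model_events": {int(y): float(v) for y, v in predicted.items()},
            "contained": {int(y): bool(c) for y, c in contained.items()},
        }
    report: dict = {"outcomes": outcomes, "all_contained": bool(all_contained)}
    if model_hrs is not None:
        checks = check_hazard_ratios(model_hrs, reference_cis or {})
        report["hazard_ratios"] = {
            k: {"model": model_hrs[k], "within_reference": checks[k]} for k in model_hrs
        }
    return report


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True), encoding="utf-8")
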