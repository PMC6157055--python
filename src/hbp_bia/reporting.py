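"""Tabular report views over deterministic and PSA results.

Reports are pure views: every number is read from an upstream result
object, so regenerating a report from the same artifacts is
bit-identical. Output currency is USD throughout; COP intermediates
exist only inside the PSA's cost sampling.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .engine import BudgetImpactResult, PSAResult, ScenarioRun

__all__ = [
    "fig2_table",
    "fig4_table",
    "fig3_histogram_data",
    "run_report",
    "write_run_report",
]

SCHEMA_VERSION = 1


def fig2_table(run: ScenarioRun) -> pd.DataFrame:
    """Per-year cost components for one scenario (the cost-structure view).

    One row per horizon year: medication, diagnostic aids, complication
    management and their exact total, in USD.
    """
    rows = []
    for r in run.years:
        c = r.costs
        rows.append(
            {
                "year": r.state.year,
                "scenario": run.scenario.name,
                "medication_usd": c.medication_usd,
                "diagnostics_usd": c.diagnostics_usd,
                "complications_usd": c.complications_usd,
                "total_usd": c.total_usd,
            }
        )
    return pd.DataFrame(rows)


def fig4_table(baseline: ScenarioRun, new: ScenarioRun) -> pd.DataFrame:
    """Expected cardiovascular events per outcome, scenario and year."""
    rows = []
    for run in (baseline, new):
        for r in run.years:
            for outcome, count in r.events.as_dict().items():
                rows.append(
                    {
                        "year": r.state.year,
                        "scenario": run.scenario.name,
                        "outcome": outcome,
                        "expected_events": count,
                    }
                )
    return pd.DataFrame(rows)


def fig3_histogram_data(psa: PSAResult, bins: int = 40) -> dict[int, dict[str, list[float]]]:
    """Binned per-year iteration cost differences (the PSA histogram view).

    Returns, per year, ``bin_edges`` (length bins+1) and integer ``counts``
    (length bins) that sum to the iteration count.
    """
    out: dict[int, dict[str, list[float]]] = {}
    for j, year in enumerate(psa.years):
        diffs = psa.diffs_by_year[:, j]
        counts, edges = np.histogram(diffs, bins=bins)
        out[int(year)] = {
            "bin_edges": [float(e) for e in edges],
            "counts": [int(c) for c in counts],
        }
    return out


def run_report(
    impact: BudgetImpactResult,
    psa: PSAResult | None = None,
    provenance: Mapping[str, object] | None = None,
) -> dict:
    """Human-readable JSON run summary tying every output table together."""
    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "provenance": dict(provenance or {}),
        "budget_impact": impact.summary(),
        "costs": {
            run.scenario.name: fig2_table(run).to_dict(orient="records")
            for run in (impact.baseline, impact.new)
        },
        "events": fig4_table(impact.baseline, impact.new).to_dict(orient="records"),
        "cohort": {
            run.scenario.name: run.states_frame().to_dict(orient="records")
            for run in (impact.baseline, impact.new)
        },
    }
    if psa is not None:
        report["psa"] = psa.summary()
        report["psa_histograms"] = fig3_histogram_data(psa)
    return report


def write_run_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True), encoding="utf-8")
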