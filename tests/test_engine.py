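"""Scenario orchestration: deterministic chain, budget impact, PSA."""

import dataclasses

import numpy as np
import pytest

from hbp_bia import engine
from hbp_bia.cohort import FixedRate, ScenarioSpec
from hbp_bia.synthetic import generate_population


def _zero_prevalence_spec():
    return ScenarioSpec(
        name="empty",
        diagnostic_cutoff="140/90",
        treatment_goal="SBP<140",
        prevalence_rule=FixedRate(0.0),
        event_probability_set="standard",
    )


class TestRunScenario:
    def test_zero_prevalence_all_zero(self, params, projection):
        run = engine.run_scenario(_zero_prevalence_spec(), params, projection)
        for r in run.years:
            assert r.state.n_hypertensive == 0
            assert all(v == 0 for v in r.events.as_dict().values())
            assert r.costs.total_usd == 0.0

    def test_deterministic_repeatability(self, params, projection, scenarios):
        a = engine.run_scenario(scenarios[0], params, projection)
        b = engine.run_scenario(scenarios[0], params, projection)
        assert a.costs_frame().equals(b.costs_frame())
        assert a.events_frame().equals(b.events_frame())

    def test_first_year_matches_hand_chained_recomputation(self, params, baseline_run, new_run):
        """Every 2018 intermediate equals an independent spreadsheet-style
        recomputation from the published inputs."""
        v = params.point_values()

        # baseline cascade
        n_b = 8_675_154
        treated_b = round(n_b * 0.52 * 0.45)
        untreated_b = n_b - treated_b
        st_b = baseline_run.year(2018).state
        assert (st_b.n_hypertensive, st_b.n_treated, st_b.n_untreated) == (
            n_b, treated_b, untreated_b,
        )

        # lowered-cut-off cascade: excess over the established stratum gets
        # the newly-classified adherence
        n_n = 13_271_577
        new_stratum = n_n - n_b
        treated_n = round(n_b * 0.52 * 0.45) + round(new_stratum * 0.52 * 0.2)
        st_n = new_run.year(2018).state
        assert st_n.n_new_stratum == new_stratum
        assert st_n.n_treated == treated_n

        # baseline events and costs
        ev = baseline_run.year(2018).events
        assert ev.ami == pytest.approx(treated_b * 0.0078 + untreated_b * 0.047)
        assert ev.stroke == pytest.approx(treated_b * 0.0047 + untreated_b * 0.1040)
        assert ev.hf == pytest.approx(treated_b * 0.0067 + untreated_b * 0.0396)
        assert ev.cvdeath == pytest.approx(treated_b * 0.0043 + untreated_b * 0.0043)

        c = baseline_run.year(2018).costs
        assert c.medication_usd == pytest.approx(treated_b * 1.8 * 0.00556 * 365)
        assert c.diagnostics_usd == pytest.approx(n_b * 0.61 * 57.91)
        assert c.ami_usd == pytest.approx(ev.ami * 2938)
        assert c.stroke_usd == pytest.approx(ev.stroke * 3430)
        assert c.hf_usd == pytest.approx(ev.hf * (2.2 * 1990 + 1131))

    def test_three_year_chain_matches_hand_recomputation(self, params, projection, baseline_run):
        """Survivor carry-over: year t+1 prevalents equal the growth-scaled
        override plus treated survivors of year t, recomputed independently."""
        n = 8_675_154
        state_n = n
        for year in params.horizon_years:
            got = baseline_run.year(year).state
            assert got.n_hypertensive == state_n
            treated = round(state_n * 0.52 * 0.45)
            untreated = state_n - treated
            deaths = treated * 0.0043 + untreated * 0.0043
            survivors = round(treated - deaths * treated / state_n)
            if year < params.horizon_years[-1]:
                scaled = round(n * projection.total(year + 1) / projection.total(2018))
                state_n = scaled + survivors

    def test_compartment_conservation_every_scenario_year(self, baseline_run, new_run):
        for run in (baseline_run, new_run):
            for r in run.years:
                assert r.state.n_treated + r.state.n_untreated == r.state.n_hypertensive

    def test_treated_monotone_in_adherence(self, params, projection, scenarios):
        lo = dict(params.point_values(), adherence_standard=0.30)
        hi = dict(params.point_values(), adherence_standard=0.60)
        run_lo = engine.run_scenario(scenarios[0], params, projection, lo)
        run_hi = engine.run_scenario(scenarios[0], params, projection, hi)
        for a, b in zip(run_lo.years, run_hi.years):
            assert b.state.n_treated >= a.state.n_treated


class TestBudgetImpact:
    def test_identical_scenarios_zero_difference(self, params, projection, scenarios):
        base_spec = scenarios[0]
        clone = dataclasses.replace(base_spec, name="clone")
        a = engine.run_scenario(base_spec, params, projection)
        b = engine.run_scenario(clone, params, projection)
        impact = engine.budget_impact(a, b, params.cpi_by_year)
        assert all(d == 0.0 for d in impact.difference_by_year.values())
        assert impact.total_difference_usd == 0.0

    def test_difference_equals_total_gap_exactly(self, impact):
        for y in impact.years:
            assert impact.difference(y) == (
                impact.new.year(y).costs.total_usd - impact.baseline.year(y).costs.total_usd
            )

    def test_real_terms_total_deflated(self, params, impact):
        nominal = impact.total_difference_usd
        real = impact.total_difference_real_usd
        # deflation shrinks later-year magnitudes toward the 2018 level
        expected = sum(
            impact.difference(y) / np.prod([1 + params.cpi_by_year[z] / 100 for z in range(2019, y + 1)])
            for y in impact.years
        )
        assert real == pytest.approx(expected)
        assert real != nominal

    def test_mismatched_years_rejected(self, params, projection, scenarios, baseline_run):
        short = dataclasses.replace(params, horizon_years=(2018, 2019))
        b = engine.run_scenario(scenarios[1], short, projection)
        with pytest.raises(ValueError, match="mismatched"):
            engine.budget_impact(baseline_run, b, params.cpi_by_year)

    def test_med_and_diagnostics_rise_under_new_scenario(self, impact):
        """More diagnosed and treated patients cost more in medication and
        diagnostic aids — the direction the published analysis reports."""
        for y in impact.years:
            b, n = impact.baseline.year(y).costs, impact.new.year(y).costs
            assert n.medication_usd + n.diagnostics_usd > b.medication_usd + b.diagnostics_usd


class TestPSA:
    def test_same_seed_identical(self, params):
        a = engine.run_psa(params, n_iter=50, seed=3)
        b = engine.run_psa(params, n_iter=50, seed=3)
        assert np.array_equal(a.diffs_by_year, b.diffs_by_year)

    def test_degenerate_psa_equals_deterministic(self, params, projection, scenarios, impact):
        """With every distribution stripped, each iteration reproduces the
        deterministic run exactly and the saving fraction is 0 or 1."""
        from dataclasses import replace

        fixed = {
            name: replace(p, distribution=None)
            for name, p in params.parameters.items()
        }
        degenerate = replace(params, parameters=fixed)
        psa = engine.run_psa(degenerate, scenarios, projection, n_iter=5, seed=0)
        det = np.array([impact.difference(y) for y in impact.years])
        assert np.allclose(psa.diffs_by_year, det[None, :], rtol=0, atol=0)
        assert psa.fraction_saving in (0.0, 1.0)

    def test_disjoint_seed_streams_agree(self, params, small_psa):
        other = engine.run_psa(params, n_iter=300, seed=8)
        n = 300
        pooled = (small_psa.fraction_saving + other.fraction_saving) / 2
        sigma = np.sqrt(max(pooled * (1 - pooled), 1e-6) / n)
        assert abs(small_psa.fraction_saving - other.fraction_saving) <= max(3 * sigma * np.sqrt(2), 0.02)

    def test_fraction_bounds_and_quantiles_monotone(self, small_psa):
        assert 0.0 <= small_psa.fraction_saving <= 1.0
        qs = list(small_psa.quantiles().values())
        assert qs == sorted(qs)

    def test_iterations_frame_shape(self, small_psa):
        df = small_psa.iterations_frame()
        assert len(df) == 300
        assert set(df.columns) == {"iteration", "2018", "2019", "2020", "horizon_total"}
        assert np.allclose(df[["2018", "2019", "2020"]].sum(axis=1), df["horizon_total"])

    def test_n_iter_validated(self, params):
        with pytest.raises(ValueError):
            engine.run_psa(params, n_iter=0, seed=1)
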