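"""Parameter table: loading, distributions, sampling, reconciliation."""

import math

import numpy as np
import pytest
import yaml
from hypothesis import given
from hypothesis import strategies as st

from hbp_bia.params import (
    MANDATORY_PARAMETERS,
    Distribution,
    Parameter,
    ParameterFileError,
    ParameterValidationError,
    default_parameters,
    load_parameters,
    mean_of,
    parameter_set_from_dict,
    reconcile,
    sample,
    save_parameters,
)


class TestDistribution:
    @pytest.mark.parametrize(
        "dist, expected",
        [
            (Distribution("beta", a=45, b=55), 0.45),
            (Distribution("poisson", lam=2.8), 2.8),
            (Distribution("gamma", a=0.44604, b=19360084), 0.44604 * 19360084),
            (Distribution("fixed", value=0.52), 0.52),
        ],
    )
    def test_analytic_mean(self, dist, expected):
        assert mean_of(dist) == pytest.approx(expected, rel=1e-12)

    def test_fields_must_match_kind(self):
        with pytest.raises(ParameterValidationError):
            Distribution("beta", a=2.0)  # missing b
        with pytest.raises(ParameterValidationError):
            Distribution("poisson", lam=1.0, a=2.0)  # extraneous field
        with pytest.raises(ParameterValidationError):
            Distribution("gamma", a=-1.0, b=2.0)  # non-positive shape

    def test_fixed_draws_value_exactly(self):
        d = Distribution("fixed", value=0.52)
        rng = np.random.default_rng(0)
        assert all(sample(d, rng) == 0.52 for _ in range(10))

    def test_gamma_draws_positive(self):
        d = Distribution("gamma", a=0.44604, b=19360084)
        rng = np.random.default_rng(0)
        assert all(sample(d, rng) > 0 for _ in range(1000))

    def test_seeded_stream_reproducible(self):
        d = Distribution("beta", a=45, b=55)
        a = [sample(d, np.random.default_rng(42)) for _ in range(1)]
        b = [sample(d, np.random.default_rng(42)) for _ in range(1)]
        assert a == b

    @pytest.mark.parametrize(
        "dist",
        [
            Distribution("beta", a=45, b=55),
            Distribution("poisson", lam=1.5),
            Distribution("gamma", a=0.44248, b=14526853),
        ],
    )
    def test_sample_mean_converges_to_analytic(self, dist):
        """Empirical mean of 1e5 seeded draws is within 3 SE of the mean."""
        rng = np.random.default_rng(123)
        n = 100_000
        draws = np.array([dist.sample(rng) for _ in range(n)])
        se = draws.std(ddof=1) / math.sqrt(n)
        assert abs(draws.mean() - mean_of(dist)) < 3 * se


class TestReconcile:
    def test_rescaled_beta_hits_point_estimate(self):
        p = Parameter("physician_prescription", 0.52, "probability",
                      Distribution("beta", a=29, b=31))
        r = reconcile(p, "rescaled_distribution")
        assert r.distribution.a == pytest.approx(31.2)
        assert r.distribution.b == pytest.approx(28.8)
        assert mean_of(r.distribution) == pytest.approx(0.52, rel=1e-12)

    def test_consistent_row_unchanged_in_mean(self):
        p = Parameter("adherence_standard", 0.45, "probability",
                      Distribution("beta", a=45, b=55))
        for policy in ("point_estimate", "distribution_mean", "rescaled_distribution"):
            r = reconcile(p, policy)
            assert r.point_estimate == pytest.approx(0.45)
            assert mean_of(r.distribution) == pytest.approx(0.45)

    def test_rescaled_gamma_cop_scale(self):
        p = Parameter("hf_chronic_cost", 1131, "usd_per_year",
                      Distribution("gamma", a=0.1599, b=1902392), dist_scale="cop")
        r = reconcile(p, "rescaled_distribution", fx_cop_per_usd=2877)
        # distribution mean must equal the point estimate on the COP scale
        assert mean_of(r.distribution) == pytest.approx(1131 * 2877, rel=1e-12)
        # shape preserved, only the scale moves
        assert r.distribution.a == pytest.approx(0.1599)

    def test_distribution_mean_policy_replaces_estimate(self):
        p = Parameter("stroke_episode_cost", 3430, "usd",
                      Distribution("gamma", a=0.44604, b=19360084), dist_scale="cop")
        r = reconcile(p, "distribution_mean", fx_cop_per_usd=2877)
        assert r.point_estimate == pytest.approx(0.44604 * 19360084 / 2877, rel=1e-12)

    def test_beta_rescale_out_of_range_errors(self):
        p = Parameter("x", 1.5, "count", Distribution("beta", a=2, b=2))
        with pytest.raises(ParameterValidationError):
            reconcile(p, "rescaled_distribution")

    @given(
        target=st.floats(0.01, 0.99),
        a=st.floats(1, 500),
        b=st.floats(1, 500),
    )
    def test_rescaled_beta_mean_matches_target(self, target, a, b):
        p = Parameter("p", target, "probability", Distribution("beta", a=a, b=b))
        r = reconcile(p, "rescaled_distribution")
        assert abs(mean_of(r.distribution) - target) < 1e-9 * max(target, 1.0)
        assert r.distribution.a + r.distribution.b == pytest.approx(a + b)


class TestParameterSet:
    def test_fixture_has_all_table_rows(self, params):
        assert set(MANDATORY_PARAMETERS) <= set(params.parameters)
        assert len(params.parameters) == 26

    def test_fixture_key_values(self, params):
        adher = params["adherence_standard"]
        assert adher.point_estimate == 0.45
        assert adher.distribution == Distribution("beta", a=45, b=55)
        assert params.value("stroke_untreated") == 0.1040
        assert params.value("ami_episode_cost_2019") == 3235
        assert params.fx_cop_per_usd == 2877
        assert params.psa_iterations == 5000
        assert params.cpi_by_year == {2018: 3.95, 2019: 4.35, 2020: 3.95}
        assert params.prevalent_count_overrides["baseline"][2018] == 8_675_154
        assert params.prevalent_count_overrides["new"][2018] == 13_271_577

    def test_probability_rows_in_unit_interval(self, params):
        for name, p in params.parameters.items():
            if p.units.startswith("probability"):
                assert 0.0 <= p.point_estimate <= 1.0, name
            else:
                assert p.point_estimate >= 0, name

    def test_round_trip_lossless(self, params, tmp_path):
        path = tmp_path / "params.yaml"
        save_parameters(params, path)
        assert load_parameters(path) == params

    def test_json_export_parses(self, params):
        import json

        doc = json.loads(params.to_json())
        assert doc["parameters"]["adherence_standard"]["estimate"] == 0.45

    def test_missing_mandatory_key_named(self, params, tmp_path):
        doc = params.to_dict()
        del doc["parameters"]["stroke_episode_cost"]
        path = tmp_path / "broken.yaml"
        path.write_text(yaml.safe_dump(doc), encoding="utf-8")
        with pytest.raises(ParameterValidationError, match="stroke_episode_cost"):
            load_parameters(path)

    def test_malformed_yaml_names_line(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("parameters:\n  x: {estimate: [unclosed\n", encoding="utf-8")
        with pytest.raises(ParameterFileError, match="line"):
            load_parameters(path)

    def test_out_of_range_probability_rejected(self, params):
        doc = params.to_dict()
        doc["parameters"]["adherence_standard"]["estimate"] = 1.3
        with pytest.raises(ParameterValidationError, match="adherence_standard"):
            parameter_set_from_dict(doc)

    def test_sample_values_deterministic_given_seed(self, params):
        a = params.sample_values(np.random.default_rng(5))
        b = params.sample_values(np.random.default_rng(5))
        assert a == b
        # fixed rows keep their point estimates
        assert a["medication_cost_per_tablet_day"] == 0.00556
        assert a["ami_episode_cost_2019"] == 3235

    def test_cop_gamma_samples_converted_to_usd(self, params):
        """COP-scale cost draws land on a USD-magnitude scale."""
        rng = np.random.default_rng(11)
        draws = [params.sample_values(rng)["stroke_episode_cost"] for _ in range(200)]
        mean = float(np.mean(draws))
        # rescaled policy: distribution mean equals the printed USD estimate
        assert 1000 < mean < 10000
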