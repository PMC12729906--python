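"""Triangular sampling, Monte Carlo propagation and tornado ranking."""

import numpy as np
import pytest

from stewardcost import (
    UncertainInput,
    default_uncertain_inputs,
    multivariate,
    net_reduction_model,
    one_way,
    sample_triangular,
    tornado,
)


class TestTriangularSampler:
    def test_zero_width_is_the_constant_base(self):
        draws = sample_triangular(100.0, 0.0, 50, seed=1)
        assert np.all(draws == 100.0)

    def test_support_and_mean(self):
        draws = sample_triangular(100.0, 0.1, 20_000, seed=2)
        assert draws.min() >= 90.0 and draws.max() <= 110.0
        # symmetric triangular: mean = mode = 100, sd = 100*0.1/sqrt(6)
        se = 100 * 0.1 / np.sqrt(6) / np.sqrt(20_000)
        assert abs(draws.mean() - 100.0) < 3 * se

    def test_median_at_the_mode(self):
        draws = sample_triangular(100.0, 0.2, 40_000, seed=3)
        cdf_at_base = np.mean(draws <= 100.0)
        assert cdf_at_base == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(40_000))

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            sample_triangular(1.0, 0.1, -1)

    def test_seed_reproducibility(self):
        a = sample_triangular(5.0, 0.3, 100, seed=9)
        b = sample_triangular(5.0, 0.3, 100, seed=9)
        assert np.array_equal(a, b)


def linear_model(coefs):
    return lambda assignment: sum(c * assignment[n] for n, c in coefs.items())


class TestOneWay:
    inputs = [
        UncertainInput(name="x", base_value=10.0, pct_range=0.2),
        UncertainInput(name="y", base_value=5.0, pct_range=0.2),
    ]

    def test_zero_uncertainty_recovers_base_case(self):
        inputs = [UncertainInput(name="x", base_value=10.0, pct_range=0.0)]
        res = one_way(linear_model({"x": 3.0}), inputs, "x", n_iterations=100, seed=0)
        assert np.all(res.outcomes == 30.0)
        assert res.conclusion_stable

    def test_linear_model_outcome_range(self):
        """y = c*x under a +/-20% triangular input spans c*base*[0.8, 1.2]."""
        res = one_way(linear_model({"x": 3.0, "y": 0.0}), self.inputs, "x",
                      n_iterations=5_000, seed=4)
        assert res.outcomes.min() >= 3.0 * 10.0 * 0.8 - 1e-9
        assert res.outcomes.max() <= 3.0 * 10.0 * 1.2 + 1e-9
        assert res.base_outcome == pytest.approx(30.0)

    def test_other_inputs_stay_pinned(self):
        res = one_way(linear_model({"x": 1.0, "y": 2.0}), self.inputs, "y",
                      n_iterations=50, seed=5)
        # outcome = 10 + 2*y ; only y moves
        assert np.allclose(res.outcomes, 10.0 + 2.0 * res.draws[:, 0])

    def test_endpoint_mode_is_deterministic(self):
        res = one_way(linear_model({"x": 2.0, "y": 0.0}), self.inputs, "x",
                      mode="endpoints")
        assert sorted(res.outcomes) == [pytest.approx(16.0), pytest.approx(24.0)]

    def test_unknown_input_name(self):
        with pytest.raises(LookupError, match="bogus"):
            one_way(linear_model({"x": 1.0}), self.inputs, "bogus")


class TestMultivariate:
    def test_all_point_masses_recover_base_case_exactly(self):
        inputs = [
            UncertainInput(name="x", base_value=10.0, pct_range=0.0),
            UncertainInput(name="y", base_value=-5.0, pct_range=0.0),
        ]
        res = multivariate(linear_model({"x": 2.0, "y": 1.0}), inputs, 200, seed=6)
        assert np.all(res.outcomes == res.base_outcome)
        assert res.probability_in_favor == 1.0  # base case 15 > 0

    def test_inputs_sampled_independently(self):
        inputs = [UncertainInput(name=n, base_value=1.0, pct_range=0.1)
                  for n in ("a", "b", "c")]
        res = multivariate(linear_model({"a": 1, "b": 1, "c": 1}), inputs,
                           5_000, seed=7)
        corr = np.corrcoef(res.draws, rowvar=False)
        off_diag = corr[~np.eye(3, dtype=bool)]
        assert np.all(np.abs(off_diag) < 3 / np.sqrt(5_000))

    def test_seed_determinism_end_to_end(self):
        inputs = default_uncertain_inputs(0.1)
        model = linear_model({n.name: 1.0 for n in inputs})
        a = multivariate(model, inputs, 300, seed=11)
        b = multivariate(model, inputs, 300, seed=11)
        assert np.array_equal(a.draws, b.draws)
        assert np.array_equal(a.outcomes, b.outcomes)
        assert a.probability_in_favor == b.probability_in_favor
        assert a.tornado == b.tornado

    def test_monte_carlo_mean_matches_closed_form(self):
        """Linear model: E[outcome] = sum(c_i * base_i) within 3 SEs at n=10,000."""
        inputs = [
            UncertainInput(name="x", base_value=10.0, pct_range=0.2),
            UncertainInput(name="y", base_value=20.0, pct_range=0.1),
        ]
        model = linear_model({"x": 3.0, "y": -1.0})
        res = multivariate(model, inputs, 10_000, seed=8)
        closed_form = 3.0 * 10.0 - 1.0 * 20.0
        var = (3.0 * 10.0 * 0.2) ** 2 / 6 + (1.0 * 20.0 * 0.1) ** 2 / 6
        assert abs(res.outcome_mean - closed_form) < 3 * np.sqrt(var / 10_000)

    def test_empty_input_list_rejected(self):
        with pytest.raises(ValueError):
            multivariate(linear_model({}), [], 10)


class TestTornado:
    def test_three_to_one_coefficient_ratio(self):
        """y = 3a + b with equal bases and relative ranges ranks a first, 3:1."""
        inputs = [UncertainInput(name=n, base_value=10.0, pct_range=0.1)
                  for n in ("a", "b")]
        res = multivariate(linear_model({"a": 3.0, "b": 1.0}), inputs, 4_000, seed=9)
        (first, c1), (second, c2) = res.tornado
        assert first == "a" and second == "b"
        assert c1 / c2 == pytest.approx(3.0, rel=0.1)

    def test_single_input_coefficient_is_unity(self):
        inputs = [UncertainInput(name="a", base_value=10.0, pct_range=0.1)]
        res = multivariate(linear_model({"a": 2.0}), inputs, 500, seed=10)
        assert res.tornado[0][0] == "a"
        assert abs(res.tornado[0][1]) == pytest.approx(1.0, abs=1e-9)

    def test_zero_variance_input_warns_and_scores_zero(self):
        inputs = [
            UncertainInput(name="a", base_value=10.0, pct_range=0.1),
            UncertainInput(name="frozen", base_value=5.0, pct_range=0.0),
        ]
        model = linear_model({"a": 1.0, "frozen": 1.0})
        with pytest.warns(UserWarning, match="frozen"):
            res = multivariate(model, inputs, 200, seed=12)
        assert dict(res.tornado)["frozen"] == 0.0

    def test_matches_independent_ols(self):
        """Standardized coefficients agree with a statsmodels fit."""
        sm = pytest.importorskip("statsmodels.api")
        inputs = [UncertainInput(name=n, base_value=10.0, pct_range=0.15)
                  for n in ("a", "b", "c")]
        model = linear_model({"a": 2.0, "b": -1.0, "c": 0.5})
        res = multivariate(model, inputs, 2_000, seed=13)
        X = (res.draws - res.draws.mean(0)) / res.draws.std(0)
        y = (res.outcomes - res.outcomes.mean()) / res.outcomes.std()
        fit = sm.OLS(y, X).fit()
        expected = dict(zip(("a", "b", "c"), fit.params))
        for name, coef in res.tornado:
            assert coef == pytest.approx(expected[name], abs=1e-8)


class TestNetReductionModel:
    def test_base_assignment_recovers_compare_periods(self, printed_summaries):
        from stewardcost import compare_periods

        pre, dev = printed_summaries
        model = net_reduction_model(pre, dev)
        base = model({n.name: 1.0 for n in default_uncertain_inputs()})
        assert base == pytest.approx(compare_periods(pre, dev).net_reduction)

    def test_bed_day_factor_scales_all_bed_day_terms(self, printed_summaries):
        pre, dev = printed_summaries
        model = net_reduction_model(pre, dev)
        lo = model({"hospitalization_cost": 0.9})
        hi = model({"hospitalization_cost": 1.1})
        bed_linked = (
            pre.ledger.avoidance.hospitalization - dev.ledger.avoidance.hospitalization
            + pre.ledger.avoidance.ade - dev.ledger.avoidance.ade
        )
        assert hi - lo == pytest.approx(0.2 * bed_linked)

    def test_per_patient_outcome(self, printed_summaries):
        from stewardcost import compare_periods

        pre, dev = printed_summaries
        model = net_reduction_model(pre, dev, per_patient=True)
        assert model({}) == pytest.approx(
            compare_periods(pre, dev).net_reduction_per_patient
        )

    def test_degenerate_pipeline_recovers_base_bit_for_bit(self, printed_summaries):
        pre, dev = printed_summaries
        model = net_reduction_model(pre, dev)
        res = multivariate(model, default_uncertain_inputs(0.0), 100, seed=14)
        assert np.all(res.outcomes == res.base_outcome)
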