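"""Backward selection, the printed-equation linear score, and
population-scaled incidence."""

import numpy as np
import pandas as pd
import pytest

from snakerisk.incidence import (
    backward_select,
    compare_scenarios,
    incidence_map,
    linear_score,
    load_coefficients,
    significance_stars,
    total_incidence,
)
from conftest import make_grid, make_stack

EQ1_TERMS = {
    "annual_mean_temperature": 13.299,
    "mean_diurnal_range": 5.196,
    "isothermality": -5.075,
    "mean_temperature_of_wettest_quarter": -5.338,
    "annual_precipitation": -3.61,
    "precipitation_of_driest_month": 0.275,
    "precipitation_seasonality": 5.068,
    "precipitation_of_warmest_quarter": 0.309,
    "elevation": 0.601,
    "human_population": 1.573,
}


class TestLinearScore:
    def test_printed_equation_at_zero_vector(self):
        fit = {"intercept": -0.778, "terms": EQ1_TERMS}
        assert linear_score(fit, {t: 0.0 for t in EQ1_TERMS}) == pytest.approx(-0.778)

    def test_printed_equation_at_ones_vector(self):
        fit = {"intercept": -0.778, "terms": EQ1_TERMS}
        # manual summation of the ten printed coefficients minus 0.778
        assert linear_score(fit, {t: 1.0 for t in EQ1_TERMS}) == pytest.approx(11.520)

    def test_zero_coefficients_return_intercept(self):
        fit = {"intercept": 2.5, "terms": {}}
        assert linear_score(fit, {}) == 2.5

    def test_missing_term_raises_by_name(self):
        fit = {"intercept": 0.0, "terms": {"elevation": 1.0}}
        with pytest.raises(KeyError, match="elevation"):
            linear_score(fit, {})

    def test_exact_linearity(self, rng):
        fit = {"intercept": 1.0, "terms": {"a": 2.0, "b": -3.0}}
        xa, xb = rng.normal(size=2)
        s1 = linear_score(fit, {"a": xa, "b": xb})
        s2 = linear_score(fit, {"a": 2 * xa, "b": 2 * xb})
        assert s2 - 1.0 == pytest.approx(2 * (s1 - 1.0))

    def test_config_block_loader(self, tmp_path):
        p = tmp_path / "eq.yaml"
        p.write_text("intercept: -0.778\nterms:\n  elevation: 0.601\n")
        block = load_coefficients(p)
        assert linear_score(block, {"elevation": 0.0}) == pytest.approx(-0.778)


class TestBackwardSelect:
    def test_planted_noise_predictor_removed(self, rng):
        n = 200
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)  # pure noise
        y = 3.0 * x1 + rng.normal(0, 0.1, n)
        fit = backward_select(pd.DataFrame({"x1": x1, "x2": x2}), y)
        assert fit.terms == ["x1"]
        assert [t for t, _ in fit.trace] == ["x2"]
        se = 0.1 / np.sqrt(n)  # rough; 3 SE band is generous at sigma = 0.1
        assert abs(fit.coef["x1"] - 3.0) < 3 * max(se, 0.01)
        assert fit.stars["x1"] == "***" and fit.r2_adjusted > 0.99

    def test_all_significant_is_noop(self, rng):
        n = 300
        X = pd.DataFrame(rng.normal(size=(n, 2)), columns=["a", "b"])
        y = 2.0 * X["a"] - 1.5 * X["b"] + rng.normal(0, 0.2, n)
        fit = backward_select(X, y)
        assert fit.terms == ["a", "b"] and fit.trace == []

    def test_constant_response_intercept_only(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 2)), columns=["a", "b"])
        fit = backward_select(X, np.full(50, 7.0))
        assert fit.terms == [] and fit.intercept == 7.0 and fit.r2_adjusted == 0.0

    def test_pure_noise_warns_and_returns_intercept_only(self, rng):
        X = pd.DataFrame(rng.normal(size=(100, 2)), columns=["a", "b"])
        y = rng.normal(size=100)
        with pytest.warns(UserWarning, match="intercept-only"):
            fit = backward_select(X, y)
        assert fit.terms == []

    def test_binomial_family_recovers_signal(self, rng):
        from scipy.special import expit

        n = 1500
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=["s", "t", "noise"])
        y = (rng.random(n) < expit(1.2 * X["s"] - 1.0 * X["t"])).astype(float)
        fit = backward_select(X, y, family="binomial_logit")
        assert set(fit.terms) == {"s", "t"}
        assert 0 < fit.r2_adjusted < 1  # McFadden pseudo-R2

    def test_trace_strictly_decreasing_and_max_p(self, rng):
        n = 120
        X = pd.DataFrame(rng.normal(size=(n, 5)), columns=list("abcde"))
        y = 2.0 * X["a"] + rng.normal(0, 1.0, n)
        fit = backward_select(X, y)
        # each removal shrinks the term set by one; removed p-values exceeded alpha
        assert len(fit.trace) == 5 - len(fit.terms)
        assert all(p > fit.alpha for _, p in fit.trace)

    def test_stars_mapping(self):
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.009) == "**"
        assert significance_stars(0.0009) == "***"
        assert significance_stars(0.2) == ""


class TestIncidenceMap:
    def test_risk_one_scales_population(self):
        stack = make_stack({"a": np.zeros((2, 5))})
        pop = make_grid(np.full((2, 5), 100.0))
        fit = {"intercept": 1.0, "terms": {"a": 0.0}, "family": "gaussian_identity"}
        _, inc = incidence_map(fit, stack, pop)
        np.testing.assert_allclose(inc.values, 100.0)
        assert total_incidence(inc) == pytest.approx(1000.0)

    def test_risk_times_population_arithmetic(self):
        stack = make_stack({"a": [[0.2, 0.4]]})
        pop = make_grid([[10.0, 20.0]])
        fit = {"intercept": 0.0, "terms": {"a": 1.0}}
        _, inc = incidence_map(fit, stack, pop)
        np.testing.assert_allclose(inc.values, [[2.0, 8.0]])

    def test_identity_risk_clamped_to_unit_interval(self):
        stack = make_stack({"a": [[-5.0, 5.0]]})
        fit = {"intercept": 0.0, "terms": {"a": 1.0}}
        risk, _ = incidence_map(fit, stack, make_grid([[1.0, 1.0]]))
        np.testing.assert_allclose(risk.values, [[0.0, 1.0]])

    def test_population_nodata_propagates(self):
        stack = make_stack({"a": [[0.5, 0.5]]})
        mask = np.array([[True, False]])
        pop = make_grid(np.where(mask, np.nan, [[50.0, 50.0]]), mask=mask)
        fit = {"intercept": 0.0, "terms": {"a": 1.0}}
        _, inc = incidence_map(fit, stack, pop)
        assert bool(inc.mask[0, 0]) and total_incidence(inc) == pytest.approx(25.0)

    def test_georeference_mismatch_rejected(self):
        stack = make_stack({"a": [[0.5]]})
        with pytest.raises(ValueError):
            incidence_map({"intercept": 0, "terms": {"a": 1.0}}, stack,
                          make_grid([[1.0]], origin_x=10.0))


def test_population_at_risk_counts_cells_meeting_cutoff():
    from snakerisk.incidence import population_at_risk

    risk = make_grid([[0.2, 0.5, 0.9]])
    pop = make_grid([[100.0, 10.0, 1.0]])
    assert population_at_risk(risk, pop, cutoff=0.5) == pytest.approx(11.0)
    assert population_at_risk(risk, pop, cutoff=0.0) == pytest.approx(111.0)


class TestScenarios:
    FIT = {"intercept": 0.0, "terms": {"a": 1.0}, "family": "gaussian_identity"}

    def test_identical_scenarios_identical_totals(self, rng):
        stack = make_stack({"a": rng.random((4, 4))})
        pop = make_grid(rng.uniform(10, 100, (4, 4)))
        out = compare_scenarios(self.FIT, {"now": (stack, pop), "later": (stack, pop)})
        assert out["totals"]["now"] == pytest.approx(out["totals"]["later"])
        assert np.allclose(out["risk_change"]["later"].values, 0.0)

    def test_population_doubling_doubles_total(self, rng):
        stack = make_stack({"a": rng.random((4, 4))})
        pop = make_grid(rng.uniform(10, 100, (4, 4)))
        pop2 = make_grid(pop.values * 2)
        out = compare_scenarios(self.FIT, {"now": (stack, pop), "later": (stack, pop2)})
        assert out["totals"]["later"] == pytest.approx(2 * out["totals"]["now"])

    def test_warming_shifts_risk_uphill(self, rng):
        # constructed truth: risk rises with temperature, and the scenario
        # warms high-elevation cells -> positive risk change exactly there
        elev = np.tile(np.linspace(0, 1, 10), (10, 1))
        temp_now = 0.3 + 0.2 * rng.random((10, 10))
        temp_future = temp_now + 0.3 * (elev > 0.5)
        fit = {"intercept": 0.0, "terms": {"temp": 1.0}, "family": "gaussian_identity"}
        pop = make_grid(np.full((10, 10), 10.0))
        out = compare_scenarios(fit, {
            "now": (make_stack({"temp": temp_now}), pop),
            "warm": (make_stack({"temp": temp_future}), pop),
        })
        delta = out["risk_change"]["warm"].values
        assert np.all(delta[:, elev[0] > 0.5] > 0)
        assert np.allclose(delta[:, elev[0] <= 0.5], 0.0)

    def test_total_additive_over_disjoint_regions(self, rng):
        vals = rng.random((6, 6))
        pop = rng.uniform(1, 10, (6, 6))
        stack = make_stack({"a": vals})
        _, inc = incidence_map(self.FIT, stack, make_grid(pop))
        west_mask = np.zeros((6, 6), bool)
        west_mask[:, 3:] = True
        east_mask = ~west_mask
        west = inc.with_values(np.where(west_mask, np.nan, inc.values), mask=west_mask)
        east = inc.with_values(np.where(east_mask, np.nan, inc.values), mask=east_mask)
        assert total_incidence(west) + total_incidence(east) == pytest.approx(
            total_incidence(inc)
        )
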