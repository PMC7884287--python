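import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tobaccopolicy as tp
from tobaccopolicy.counterfactual import (
    COVAR_KEYS,
    Scenario,
    ScenarioProjector,
    aggregate_global,
    apply_scenario,
    compute_price_floor,
    default_scenarios,
    draw_coefficients,
    identity_scenario,
    predict_counterfactual_prevalence,
    redistribute_age_counts,
    restrict_balanced_countries,
    summarize_ui,
)
from tobaccopolicy.exceptions import (
    AlignmentError,
    ConfigurationError,
    DomainError,
    EmptyInputError,
)
from tobaccopolicy.panel import expit


from conftest import make_results as _results_from


class TestScenarios:
    def test_empty_rule_set_rejected(self):
        with pytest.raises(ConfigurationError):
            Scenario(name="nothing")

    def test_invalid_override_rejected(self):
        with pytest.raises(ConfigurationError):
            Scenario(name="bad", score_override={"p": 7})
        with pytest.raises(ConfigurationError):
            Scenario(name="bad", score_override={"x": 5})

    def test_default_scenarios_reporting_order(self):
        names = [s.name for s in default_scenarios()]
        assert names == ["1_status_quo_2008", "2_price_floor",
                         "3_max_policy", "4_combined"]

    def test_max_policy_sets_scores_to_five(self):
        obs16 = {"p": 3, "w": 2, "e": 4, "price": 4.0, "gdp_pc": 10000.0}
        out = apply_scenario(obs16, None, Scenario(name="m", score_override={"p": 5, "w": 5, "e": 5}))
        assert (out["p"], out["w"], out["e"]) == (5.0, 5.0, 5.0)
        assert out["rip"] == pytest.approx(tp.compute_rip(4.0, 10000.0))

    @pytest.mark.parametrize("price, expected", [(5.00, 7.73), (9.00, 9.00)])
    def test_price_floor_only_raises(self, price, expected):
        obs16 = {"p": 3, "w": 3, "e": 3, "price": price, "gdp_pc": 10000.0}
        out = apply_scenario(obs16, None, Scenario(name="f", price_floor=7.73))
        assert out["rip"] == pytest.approx(tp.compute_rip(expected, 10000.0))

    def test_identity_scenario_keeps_covariates(self):
        obs16 = {"p": 3, "w": 2, "e": 4, "price": 4.0, "gdp_pc": 10000.0}
        out = apply_scenario(obs16, None, identity_scenario())
        assert (out["p"], out["w"], out["e"]) == (3.0, 2.0, 4.0)
        assert out["rip"] == tp.compute_rip(4.0, 10000.0)

    def test_reference_year_returns_2008_verbatim(self):
        obs16 = {"p": 5, "w": 5, "e": 5, "price": 9.0, "gdp_pc": 20000.0}
        obs08 = {"p": 2, "w": 3, "e": 2, "price": 2.0, "gdp_pc": 15000.0}
        out = apply_scenario(obs16, obs08, Scenario(name="r", use_reference_year=True))
        assert (out["p"], out["w"], out["e"]) == (2.0, 3.0, 2.0)
        assert out["rip"] == pytest.approx(tp.compute_rip(2.0, 15000.0))

    def test_reference_year_without_2008_data_errors(self):
        obs16 = {"p": 5, "w": 5, "e": 5, "price": 9.0, "gdp_pc": 20000.0}
        with pytest.raises(EmptyInputError):
            apply_scenario(obs16, None, Scenario(name="r", use_reference_year=True))


def test_price_floor_percentile():
    df = pd.DataFrame({"price": np.arange(1.0, 101.0)})
    # 90th percentile of 1..100 with linear interpolation
    assert compute_price_floor(df) == pytest.approx(np.percentile(np.arange(1.0, 101.0), 90))


class TestBalancedCountries:
    def test_no_missingness_keeps_everyone(self):
        cfg = tp.GeneratorConfig(n_countries=15, missing_rate=0.0, seed=8,
                                 strata=[("both", "15plus")])
        pol = tp.generate_policy_trajectories(cfg)
        assert len(restrict_balanced_countries(pol)) == 15

    def test_missing_2008_price_excludes_country(self):
        cfg = tp.GeneratorConfig(n_countries=6, missing_rate=0.0, seed=8,
                                 strata=[("both", "15plus")])
        pol = tp.generate_policy_trajectories(cfg)
        pol.loc[(pol["country"] == "C0") & (pol["year"] == 2008), "price"] = np.nan
        kept = restrict_balanced_countries(pol)
        assert "C0" not in kept and len(kept) == 5

    def test_score_one_in_2016_excludes_country(self):
        cfg = tp.GeneratorConfig(n_countries=6, missing_rate=0.0, seed=8,
                                 strata=[("both", "15plus")])
        pol = tp.generate_policy_trajectories(cfg)
        pol.loc[(pol["country"] == "C1") & (pol["year"] == 2016), "w_score"] = 1
        assert "C1" not in restrict_balanced_countries(pol)


class TestPrediction:
    def test_zero_delta_returns_observed(self):
        assert predict_counterfactual_prevalence(
            [-0.01, -0.02, -0.02, -0.009], 0.37, [0, 0, 0, 0]
        ) == pytest.approx(0.37, abs=1e-12)

    def test_closed_form_shift(self):
        out = predict_counterfactual_prevalence([0.0, -0.1, 0.0, 0.0], 0.5, [0, 2, 0, 0])
        assert out == pytest.approx(expit(-0.2))
        # closed form: 1 / (1 + e^0.2) = 0.4501660...
        assert out == pytest.approx(0.4501660027, abs=1e-9)

    def test_logit_scale_invertibility(self):
        beta = np.array([-0.01, -0.02, -0.015, -0.009])
        delta = np.array([2.0, 1.0, 3.0, 12.0])
        forward = predict_counterfactual_prevalence(beta, 0.27, delta)
        back = predict_counterfactual_prevalence(beta, forward, -delta)
        assert back == pytest.approx(0.27, abs=1e-12)

    def test_nonfinite_delta_rejected(self):
        with pytest.raises(DomainError):
            predict_counterfactual_prevalence([0.1] * 4, 0.3, [np.nan, 0, 0, 0])


class TestAggregation:
    def test_singleton(self):
        assert aggregate_global(pd.Series({"A": 0.25}), pd.Series({"A": 1000.0})) \
            == (0.25, 250.0)

    def test_hand_arithmetic(self):
        wprev, smokers = aggregate_global(
            pd.Series({"A": 0.2, "B": 0.4}), pd.Series({"A": 100.0, "B": 300.0})
        )
        assert wprev == pytest.approx(0.35)
        assert smokers == pytest.approx(140.0)

    def test_constant_prevalence_any_weights(self):
        p = pd.Series({"A": 0.3, "B": 0.3, "C": 0.3})
        w = pd.Series({"A": 1.0, "B": 50.0, "C": 7.0})
        assert aggregate_global(p, w)[0] == pytest.approx(0.3)

    def test_mismatched_keys_error(self):
        with pytest.raises(AlignmentError):
            aggregate_global(pd.Series({"A": 0.3}), pd.Series({"B": 100.0}))

    @given(
        st.lists(
            st.tuples(st.floats(0.001, 0.999), st.floats(1.0, 1e7)),
            min_size=1, max_size=20,
        )
    )
    @settings(max_examples=1000, derandomize=True, deadline=None)
    def test_matches_bruteforce_summation(self, pairs):
        """Weighted mean and smoker totals equal naive Python loops."""
        p = pd.Series({f"C{i}": a for i, (a, _) in enumerate(pairs)})
        w = pd.Series({f"C{i}": b for i, (_, b) in enumerate(pairs)})
        wprev, smokers = aggregate_global(p, w)
        brute_smokers = sum(a * b for a, b in pairs)
        brute_wprev = brute_smokers / sum(b for _, b in pairs)
        assert smokers == pytest.approx(brute_smokers, rel=1e-9)
        assert wprev == pytest.approx(brute_wprev, rel=1e-9)


class TestRedistribution:
    def test_hand_arithmetic(self):
        out = redistribute_age_counts({"a": 30.0, "b": 40.0, "c": 50.0}, 90.0)
        assert out == pytest.approx({"a": 22.5, "b": 30.0, "c": 37.5})

    def test_noop_when_already_consistent(self):
        counts = {"a": 10.0, "b": 20.0}
        assert redistribute_age_counts(counts, 30.0) == pytest.approx(counts)

    def test_zeros_preserved(self):
        out = redistribute_age_counts({"a": 0.0, "b": 0.0, "c": 100.0}, 80.0)
        assert out == pytest.approx({"a": 0.0, "b": 0.0, "c": 80.0})

    def test_all_zero_counts_rejected(self):
        with pytest.raises(DomainError):
            redistribute_age_counts({"a": 0.0}, 10.0)

    @given(
        st.lists(st.floats(0.01, 1e6), min_size=1, max_size=6),
        st.floats(0.1, 1e6),
    )
    @settings(max_examples=300, derandomize=True)
    def test_conservation(self, counts, envelope):
        mapping = {str(i): c for i, c in enumerate(counts)}
        out = redistribute_age_counts(mapping, envelope)
        assert sum(out.values()) == pytest.approx(envelope, rel=1e-9)


class TestDraws:
    def test_degenerate_covariance_returns_point_estimate(self):
        res = _results_from([-0.3, -0.01, -0.02, -0.02, -0.009])
        ds = draw_coefficients(res, 50, seed=4)
        assert np.allclose(ds.values, res.params.to_numpy())

    def test_seed_reproducibility(self, small_fit):
        a = draw_coefficients(small_fit, 100, seed=11)
        b = draw_coefficients(small_fit, 100, seed=11)
        assert np.array_equal(a.values, b.values)
        c = draw_coefficients(small_fit, 100, seed=12)
        assert not np.array_equal(a.values, c.values)

    def test_large_sample_mean_near_point_estimate(self, small_fit):
        ds = draw_coefficients(small_fit, 100_000, seed=2)
        se_of_mean = small_fit.bse.to_numpy() / np.sqrt(ds.n_draws)
        gap = np.abs(ds.values.mean(axis=0) - small_fit.params.to_numpy())
        assert (gap <= 3 * se_of_mean + 1e-12).all()


class TestUI:
    def test_degenerate_draws(self):
        assert summarize_ui([4.2] * 10) == (4.2, 4.2)

    def test_percentile_formula_on_1_to_1000(self):
        lo, hi = summarize_ui(np.arange(1, 1001))
        assert lo == pytest.approx(25.975)
        assert hi == pytest.approx(975.025)

    def test_median_within_interval(self):
        rng = np.random.default_rng(3)
        draws = rng.normal(size=500)
        lo, hi = summarize_ui(draws)
        assert lo <= np.median(draws) <= hi

    def test_too_few_draws(self):
        with pytest.raises(EmptyInputError):
            summarize_ui([1.0])


class TestProjector:
    def test_identity_scenario_changes_nothing(self, multi_stratum_run):
        policies, prevalence, _, results = multi_stratum_run
        proj = ScenarioProjector(results, policies, prevalence)
        table = proj.run([identity_scenario()], n_draws=50, seed=5)
        assert (table["rel_change_pct"] == 0).all()
        assert (table["change_smokers_m"] == 0).all()
        assert (table["cf_prev_pct"] == table["observed_prev_pct"]).all()

    def test_monotone_under_strengthening_with_negative_coefficients(self, multi_stratum_run):
        policies, prevalence, truth, _ = multi_stratum_run
        results = {
            s: _results_from(truth.betas(s)) for s in
            [("male", a) for a in ("15-29", "30-49", "50plus", "15plus")]
        }
        proj = ScenarioProjector(results, policies, prevalence)
        sc = Scenario(name="3_max_policy", score_override={"p": 5, "w": 5, "e": 5})
        table = proj.run([sc], n_draws=10, seed=5)
        assert (table["cf_prev_pct"] <= table["observed_prev_pct"] + 1e-12).all()
        # per-country check through the prediction primitive
        _, prev_s, pop, obs16, obs08 = proj._stratum_inputs("male", "15plus")
        beta = results[("male", "15plus")].slope_params()
        for c in prev_s.index:
            cov = apply_scenario(obs16.loc[c], obs08.loc[c], sc)
            delta = [cov[k] - obs16.loc[c, k] for k in COVAR_KEYS]
            assert predict_counterfactual_prevalence(beta, prev_s[c], delta) \
                <= prev_s[c] + 1e-12

    def test_combined_at_least_as_strong_as_components(self, multi_stratum_run):
        policies, prevalence, truth, _ = multi_stratum_run
        strata = [("male", a) for a in ("15-29", "30-49", "50plus", "15plus")]
        results = {s: _results_from(truth.betas(s)) for s in strata}
        proj = ScenarioProjector(results, policies, prevalence)
        table = proj.run(default_scenarios(), n_draws=10, seed=5)
        for (sex, age), grp in table.groupby(["sex", "age_group"]):
            g = grp.set_index("scenario")
            combined = g.loc["4_combined", "change_smokers_m"]
            assert combined <= g.loc["2_price_floor", "change_smokers_m"] + 1e-9
            assert combined <= g.loc["3_max_policy", "change_smokers_m"] + 1e-9

    def test_age_changes_sum_to_envelope_change(self, multi_stratum_run):
        policies, prevalence, _, results = multi_stratum_run
        proj = ScenarioProjector(results, policies, prevalence)
        table = proj.run(default_scenarios(), n_draws=20, seed=9)
        for (sex, sc), grp in table.groupby(["sex", "scenario"]):
            env = grp[grp["age_group"] == "15plus"]["change_smokers_m"].iloc[0]
            ages = grp[grp["age_group"] != "15plus"]["change_smokers_m"].sum()
            assert ages == pytest.approx(env, rel=1e-9, abs=1e-12)
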