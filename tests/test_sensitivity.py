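"""Tornado, threshold search, scenarios, PSA and acceptability curves."""

import math

import numpy as np
import pandas as pd
import pytest

from artcea.pipeline import (
    INTERVENTION,
    ORIGINAL,
    apply_parameter,
    base_parameter_values,
    run_pair,
)
from artcea.sensitivity import (
    ParamDistribution,
    ParamRange,
    PSADistributionSet,
    ceac,
    ceac_indifference_point,
    default_psa_distributions,
    one_way_sensitivity,
    run_psa,
    scenario_retention,
    threshold_search,
)


class TestApplyParameter:
    def test_unknown_parameter_rejected(self, pair):
        with pytest.raises(KeyError):
            apply_parameter(pair, "adherence", 0.5)

    def test_shared_parameters_hit_both_arms(self, pair):
        new = apply_parameter(pair, "utility_retained", 0.7)
        assert new.original.arm.utility_retained == 0.7
        assert new.intervention.arm.utility_retained == 0.7

    def test_costs_hit_one_arm_only(self, pair):
        new = apply_parameter(pair, "cost_intervention", 500.0)
        assert new.intervention.arm.annual_cost_retained == 500.0
        assert new.original.arm.annual_cost_retained == pytest.approx(
            pair.original.arm.annual_cost_retained
        )

    def test_start_age_shifts_horizon(self, pair):
        younger = apply_parameter(pair, "start_age", 20)
        older = apply_parameter(pair, "start_age", 50)
        assert younger.original.horizon == pair.original.horizon + 10
        assert older.original.horizon == pair.original.horizon - 20
        # extended curve holds the terminal retention flat
        assert younger.original.arm.retention.retention_at(50) == pytest.approx(
            pair.original.arm.retention.retention_at(40)
        )


class TestTornado:
    def test_degenerate_range_has_zero_swing(self, pair):
        base = base_parameter_values(pair)
        entry = one_way_sensitivity(
            pair,
            [ParamRange("utility_retained", base["utility_retained"],
                        base["utility_retained"], base["utility_retained"])],
        )[0]
        assert entry.swing == pytest.approx(0.0, abs=1e-9)

    def test_sorted_by_swing_descending(self, pair, config):
        base = base_parameter_values(pair)
        ranges = [
            ParamRange(n, base[n], r.low, r.high)
            for n, r in config.sensitivity.ranges.items()
        ]
        entries = one_way_sensitivity(pair, ranges)
        swings = [e.swing for e in entries if not math.isnan(e.swing)]
        assert swings == sorted(swings, reverse=True)

    def test_entries_match_independent_rerun(self, pair):
        """No caching: an entry equals a from-scratch pipeline re-run."""
        entry = one_way_sensitivity(
            pair, [ParamRange("mortality_retained", 0.094, 0.04, 0.17)]
        )[0]
        lo = run_pair(apply_parameter(pair, "mortality_retained", 0.04)).icer
        hi = run_pair(apply_parameter(pair, "mortality_retained", 0.17)).icer
        assert entry.icer_low == lo and entry.icer_high == hi


class TestThresholdSearch:
    def test_flat_response_returns_none(self, pair):
        # utility of the not-retained state barely moves the ICER and
        # never crosses an absurdly high WTP
        found = threshold_search(
            pair, "utility_not_retained", 0.4, 0.6,
            criterion="icer_crosses_wtp", wtp=1e9,
        )
        assert found is None

    def test_found_threshold_sits_on_the_wtp(self, pair):
        """Plugging the root back in gives |ICER - WTP| < 1 USD/QALY."""
        wtp = pair.wtp.value
        root = threshold_search(
            pair, "cost_intervention", 125.10, 500.26,
            criterion="icer_crosses_wtp", wtp=wtp, tol=1e-6,
        )
        assert root is not None
        check = run_pair(apply_parameter(pair, "cost_intervention", root)).icer
        assert abs(check - wtp) < 1.0

    def test_decision_flip_margin_vanishes_at_root(self, pair):
        wtp = pair.wtp.value
        root = threshold_search(
            pair, "cost_intervention", 125.10, 500.26,
            criterion="decision_flip_at_wtp", wtp=wtp, tol=1e-6,
        )
        assert root is not None
        from artcea.cea import net_monetary_benefit

        res = run_pair(apply_parameter(pair, "cost_intervention", root))
        diff = net_monetary_benefit(
            res.strategies[INTERVENTION], wtp
        ) - net_monetary_benefit(res.strategies[ORIGINAL], wtp)
        assert abs(diff) < 1.0


class TestScenarios:
    def test_identical_reductions_make_arms_equal(self, pair):
        res = scenario_retention(pair, 0.05, 0.05)
        assert res.incremental_effectiveness == pytest.approx(0.0, abs=1e-12)
        assert res.icer is None

    def test_best_beats_worst(self, pair):
        best = scenario_retention(pair, 0.10, 0.03)
        worst = scenario_retention(pair, 0.03, 0.10)
        assert best.incremental_effectiveness > 0
        assert worst.incremental_effectiveness < 0
        assert (
            best.incremental_effectiveness == pytest.approx(
                -worst.incremental_effectiveness, rel=1e-9
            )
        )  # symmetric swap of the same two curves


class TestPSA:
    def test_degenerate_distributions_reproduce_base_case(self, pair):
        base = base_parameter_values(pair)
        dists = PSADistributionSet(
            {
                "utility_retained": ParamDistribution(
                    "fixed", base["utility_retained"]
                )
            },
            n_iterations=5,
            seed=1,
        )
        samples = run_psa(pair, dists)
        expected = run_pair(pair)
        assert np.allclose(
            samples["cost_original"], expected.strategies[ORIGINAL].cost
        )
        assert samples["cost_intervention"].nunique() == 1

    def test_same_seed_reproduces_table(self, pair, config):
        ranges = {k: (r.low, r.high) for k, r in config.sensitivity.ranges.items()}
        dists = default_psa_distributions(pair, ranges, n_iterations=50, seed=9)
        a = run_psa(pair, dists)
        b = run_psa(pair, dists)
        pd.testing.assert_frame_equal(a, b)

    def test_sample_means_match_distribution_means(self, pair, config):
        """Law-of-large-numbers check against the generator itself."""
        ranges = {k: (r.low, r.high) for k, r in config.sensitivity.ranges.items()}
        dists = default_psa_distributions(pair, ranges, n_iterations=4000, seed=3)
        samples = run_psa(pair, dists)
        for name, dist in dists.distributions.items():
            se = dist.sd / np.sqrt(len(samples))
            assert abs(samples[name].mean() - dist.mean) <= 3 * se


class TestCEAC:
    @staticmethod
    def _samples_from(pair, n=200, seed=4):
        dists = PSADistributionSet(
            {
                "cost_intervention": ParamDistribution(
                    "gamma",
                    pair.intervention.arm.annual_cost_retained,
                    60.0,
                )
            },
            n_iterations=n,
            seed=seed,
        )
        return run_psa(pair, dists)

    def test_probabilities_sum_to_one(self, pair):
        samples = self._samples_from(pair)
        curve = ceac(samples, np.arange(0, 4001, 250.0))
        total = curve["prob_original_optimal"] + curve["prob_intervention_optimal"]
        np.testing.assert_allclose(total, 1.0, atol=1e-9)

    def test_degenerate_psa_gives_step_at_the_icer(self, pair):
        dists = PSADistributionSet(
            {"utility_retained": ParamDistribution("fixed", 0.82)},
            n_iterations=3,
            seed=1,
        )
        samples = run_psa(pair, dists)
        base_icer = run_pair(pair).icer
        grid = np.array([base_icer - 50, base_icer + 50])
        curve = ceac(samples, grid)
        assert curve["prob_intervention_optimal"].tolist() == [0.0, 1.0]

    def test_zero_wtp_prefers_cheaper_arm(self, pair):
        samples = self._samples_from(pair)
        curve = ceac(samples, np.array([0.0]))
        cheaper_int = (
            samples["cost_intervention"] < samples["cost_original"]
        ).mean()
        assert curve["prob_intervention_optimal"][0] == pytest.approx(cheaper_int)

    def test_monte_carlo_stability_small_vs_large(self, pair, config):
        """CEAC from 10^3 vs 10^4 iterations differs by < 0.05 everywhere."""
        ranges = {k: (r.low, r.high) for k, r in config.sensitivity.ranges.items()}
        grid = np.arange(0, 6001, 500.0)
        curves = []
        for n, seed in ((1_000, 11), (10_000, 12)):
            dists = default_psa_distributions(pair, ranges, n_iterations=n, seed=seed)
            curves.append(ceac(run_psa(pair, dists), grid))
        gap = np.abs(
            curves[0]["prob_intervention_optimal"]
            - curves[1]["prob_intervention_optimal"]
        )
        assert gap.max() < 0.05

    def test_indifference_point_interpolates(self):
        table = pd.DataFrame(
            {
                "wtp": [0.0, 100.0, 200.0],
                "prob_original_optimal": [1.0, 0.6, 0.2],
                "prob_intervention_optimal": [0.0, 0.4, 0.8],
            }
        )
        assert ceac_indifference_point(table) == pytest.approx(125.0)
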