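"""Policy families, frequency reporting, national policy and population scaling."""

import numpy as np
import pandas as pd
import pytest

from ckdscreen import (
    AgeBinnedFrequencyPolicy,
    FixedIntervalPolicy,
    NeverScreenPolicy,
    approximate_national_policy,
    evaluate_policy_pair,
    population_scale,
    screening_threshold_ages,
    simulate_cohort,
    status_quo_policy,
)
from ckdscreen.policy_eval import NationalPolicy, averted_cases, deltas_from_report

from conftest import immortal_params


class TestPolicyFamilies:
    def test_status_quo_is_every_fourth_epoch(self):
        policy = status_quo_policy()
        assert policy.interval == 4
        eligible = np.ones(3, dtype=bool)
        screened = [t for t in range(1, 13)
                    if policy.screen_mask(t, None, None, eligible).any()]
        assert screened == [1, 5, 9]

    def test_interval_below_one_rejected(self):
        with pytest.raises(ValueError):
            FixedIntervalPolicy(interval=0)

    def test_frequency_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            AgeBinnedFrequencyPolicy(frequencies={"30-40": 5.0})

    def test_binned_frequency_policy_attains_target_frequencies(self):
        """With no exits, the realized frequency equals the configured target."""
        p = immortal_params()
        target = {"30-40": 1.0, "41-50": 2.0, "51-60": 4.0, "61-70": 2.0,
                  "71-80": 1.0}
        policy = AgeBinnedFrequencyPolicy(frequencies=target)
        out = simulate_cohort(p, policy, 10, 1)
        for label, f in target.items():
            assert out.mean_screens_per_year_by_agebin[label] == pytest.approx(f)


class TestScreeningFrequency:
    def test_annual_policy_frequency_exactly_one(self, wm_params):
        out = simulate_cohort(wm_params, status_quo_policy(), 400, 2)
        assert out.mean_screens_per_year == 1.0

    def test_every_epoch_policy_frequency_exactly_four(self):
        p = immortal_params()
        out = simulate_cohort(p, FixedIntervalPolicy(1), 20, 1)
        for v in out.mean_screens_per_year_by_agebin.values():
            assert v == 4.0

    def test_never_screen_frequency_zero(self, wm_params):
        out = simulate_cohort(wm_params, NeverScreenPolicy(), 100, 1)
        assert out.mean_screens_per_year == 0.0


class TestComparison:
    def test_policy_compared_to_itself_has_zero_deltas(self, wm_params):
        report = evaluate_policy_pair(wm_params, status_quo_policy(), 200, 4)
        assert report.delta_nmb == 0.0
        assert report.delta_qalys == 0.0
        assert report.averted_stage4 == 0.0

    def test_averted_cases_formula(self):
        assert averted_cases(1200, 800) == 400

    def test_zero_benefit_treatment_makes_screening_dominated(self, wm_params):
        """No treatment effect + positive screening cost: NMB decreases with
        screening frequency, and QALYs are bit-identical under common seeds."""
        p = wm_params.copy()
        p.treatment_egfr_reduction = 0.0
        p.treatment_proteinuria_reduction = 0.0
        p.treatment_mortality_reduction = 0.0
        n, seed = 1500, 8
        outs = [simulate_cohort(p, policy, n, seed) for policy in
                (NeverScreenPolicy(), status_quo_policy(), FixedIntervalPolicy(1))]
        assert outs[0].mean_qalys == outs[1].mean_qalys == outs[2].mean_qalys
        assert outs[0].mean_nmb > outs[1].mean_nmb > outs[2].mean_nmb

    def test_common_random_numbers_reduce_delta_variance(self, wm_params):
        n = 400
        annual = simulate_cohort(wm_params, status_quo_policy(), n, 1)
        never_same = simulate_cohort(wm_params, NeverScreenPolicy(), n, 1)
        never_other = simulate_cohort(wm_params, NeverScreenPolicy(), n, 2)
        var_crn = np.var(annual.per_agent_nmb - never_same.per_agent_nmb)
        var_ind = np.var(annual.per_agent_nmb - never_other.per_agent_nmb)
        assert var_crn < var_ind


class TestNationalPolicy:
    @staticmethod
    def _traj(agent, n_epochs, screen_epochs, in_process_until):
        rows = []
        for t in range(1, n_epochs + 1):
            rows.append({
                "agent": agent, "epoch": t, "age": 30 + 0.25 * (t - 1),
                "in_process": t <= in_process_until,
                "action": "screen" if (t in screen_epochs
                                       and t <= in_process_until) else "wait",
            })
        return rows

    def test_three_agent_counting_oracle(self):
        """Hand-built fixture: frequencies verified by direct counting."""
        rows = (self._traj("a", 12, {1, 3}, 8)        # 2 years at risk, 2 screens
                + self._traj("b", 12, set(), 4)       # 1 year at risk, 0 screens
                + self._traj("c", 12, {5, 9}, 12))    # 3 years at risk, 2 screens
        nat = approximate_national_policy(pd.DataFrame(rows))
        assert nat.mean_annual_frequency["30-40"] == pytest.approx(4 / 6)
        assert nat.first_screen_age == 30.0
        assert nat.last_screen_age == 32.0

    def test_never_screened_cohort_reports_absent_ages(self, wm_params):
        out = simulate_cohort(wm_params, NeverScreenPolicy(), 50, 3,
                              record_trajectories=True)
        nat = approximate_national_policy(out.trajectories)
        assert nat.first_screen_age is None and nat.last_screen_age is None
        assert all(v == 0.0 for v in nat.mean_annual_frequency.values())

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            approximate_national_policy(pd.DataFrame())

    def test_round_trip_through_binned_policy(self):
        """Frequencies observed from a binned policy reproduce its targets."""
        p = immortal_params()
        target = {"30-40": 1.0, "41-50": 2.0, "51-60": 1.0, "61-70": 4.0,
                  "71-80": 2.0}
        out = simulate_cohort(p, AgeBinnedFrequencyPolicy(frequencies=target),
                              5, 1, record_trajectories=True)
        nat = approximate_national_policy(out.trajectories)
        for label, f in target.items():
            assert nat.mean_annual_frequency[label] == pytest.approx(f)

    def test_invalid_age_ordering_rejected(self):
        with pytest.raises(ValueError):
            NationalPolicy(first_screen_age=50, last_screen_age=40,
                           mean_annual_frequency={})


PRINTED_SHARES = {"White Male": 0.2365, "Black Male": 0.2217,
                  "White Female": 0.3054, "Black Female": 0.2217}


class TestPopulationScale:
    def test_zero_deltas_give_zero_totals(self):
        deltas = {k: {"qalys": 0.0, "costs": 0.0, "nmb": 0.0} for k in PRINTED_SHARES}
        totals = population_scale(deltas, 43e6, 0.03, PRINTED_SHARES)
        assert totals == {"qalys": 0.0, "costs": 0.0, "nmb": 0.0}

    def test_published_cost_delta_scaling(self):
        """Printed per-person cost deltas x printed population constants
        reproduce the published $576 million to the nearest million."""
        deltas = {
            "White Male": {"qalys": 0.05, "costs": 386.0, "nmb": 7842.0},
            "Black Male": {"qalys": 0.01, "costs": -411.0, "nmb": 1709.0},
            "White Female": {"qalys": 0.02, "costs": 1059.0, "nmb": 2320.0},
            "Black Female": {"qalys": 0.02, "costs": 556.0, "nmb": 2035.0},
        }
        totals = population_scale(deltas, 43_000_000, 0.03, PRINTED_SHARES)
        assert round(totals["costs"] / 1e6) == 576

    def test_linearity_in_population(self):
        deltas = {"White Male": {"qalys": 1.0, "costs": 2.0, "nmb": 3.0}}
        shares = {"White Male": 1.0}
        single = population_scale(deltas, 1e6, 0.03, shares)
        double = population_scale(deltas, 2e6, 0.03, shares)
        for q in single:
            assert double[q] == 2 * single[q]

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            population_scale({}, -1, 0.03, {})


class TestThresholdAges:
    def test_fixture_gap_schedule(self):
        """Screens at 40,42,44,45,46,46.5,46.75: threshold ages by direct scan."""
        ages = [40, 42, 44, 45, 46, 46.5, 46.75]
        out = screening_threshold_ages(ages, [2, 1.5, 1, 0.5, 0.25])
        assert out == {2: 40, 1.5: 44, 1: 44, 0.5: 46, 0.25: 46.5}

    def test_always_screening_reaches_all_thresholds_at_first_age(self):
        ages = [30 + 0.25 * k for k in range(20)]
        out = screening_threshold_ages(ages, [2, 1, 0.25])
        assert all(v == 30 for v in out.values())

    def test_never_screening_reports_absent(self):
        out = screening_threshold_ages([], [2, 1])
        assert out == {2: None, 1: None}

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            screening_threshold_ages([40], [0])


class TestDeltasHelper:
    def test_deltas_match_report_fields(self, wm_params):
        report = evaluate_policy_pair(wm_params, NeverScreenPolicy(), 100, 6)
        d = deltas_from_report(report)
        assert d["nmb"] == report.delta_nmb
        assert d["costs"] == report.delta_costs
        assert d["qalys"] == report.delta_qalys
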