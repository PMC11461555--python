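"""Natural-history stepping, screening, cohort simulation and estimators."""

import numpy as np
import pytest

from ckdscreen import (
    Agent,
    FixedIntervalPolicy,
    NeverScreenPolicy,
    estimate_terminal_rewards,
    estimate_transition_tensor,
    fill_unobserved_rows,
    natural_history_step,
    screen_agent,
    simulate_cohort,
    status_quo_policy,
)
from ckdscreen.microsim import DRAWS_PER_QUARTER, INIT_DRAWS, TransitionTensor
from ckdscreen.synthetic_params import annual_to_quarterly

from conftest import immortal_params


def make_agent(egfr=95.0, prot=False, age=30.0, **kw):
    return Agent(age=age, egfr=egfr, proteinuria=prot, **kw)


class TestNaturalHistoryStep:
    def test_degenerate_parameters_only_age_advances(self, wm_params):
        p = immortal_params()
        p.state_costs = np.zeros(10)
        p.qaly_weights = np.zeros(10)
        a = make_agent()
        natural_history_step(a, p, np.random.default_rng(0))
        assert a.age == 30.25
        assert (a.egfr, a.proteinuria, a.alive) == (95.0, False, True)
        assert a.accrued_qalys == 0.0 and a.accrued_costs == 0.0

    def test_certain_mortality_kills_without_accrual(self, wm_params):
        p = immortal_params()
        p.mortality_hazard = np.ones_like(p.mortality_hazard)
        a = make_agent()
        natural_history_step(a, p, np.random.default_rng(0))
        assert not a.alive
        assert a.accrued_qalys == 0.0 and a.accrued_costs == 0.0

    def test_treated_decline_uses_printed_multiplier(self, wm_params):
        """4.0 mL/min/yr on treatment with 32.7% reduction: 0.673 per quarter."""
        p = immortal_params()
        p.egfr_decrement_schedule = np.full((2, 5), 4.0)
        a = make_agent(on_treatment=True)
        natural_history_step(a, p, np.random.default_rng(0))
        assert a.egfr == pytest.approx(95.0 - 4.0 * 0.25 * 0.673, abs=1e-12)

    def test_dead_agent_rejected(self, wm_params):
        a = make_agent(alive=False)
        with pytest.raises(ValueError):
            natural_history_step(a, wm_params, np.random.default_rng(0))


class TestScreenAgent:
    @pytest.mark.parametrize("egfr,prot", [(95, False), (95, True), (45, False),
                                           (45, True), (20, True), (10, False)])
    def test_perfect_test_reveals_true_state(self, wm_params, egfr, prot):
        a = make_agent(egfr=egfr, prot=prot)
        assert screen_agent(a, wm_params, np.random.default_rng(0)) == a.state
        assert a.screens_taken == 1
        assert a.accrued_costs == pytest.approx(wm_params.screening_cost)

    def test_two_test_miss_probability(self, wm_params):
        """Proteinuric patient, sensitivity 0.76: both tests negative w.p. 0.24^2."""
        p, n = 0.0576, 30_000
        wm_params.test_sensitivity = 0.76
        rng = np.random.default_rng(5)
        misses = 0
        for _ in range(n):
            a = make_agent(egfr=95, prot=True)
            misses += screen_agent(a, wm_params, rng) == 1
        se = np.sqrt(p * (1 - p) / n)
        assert misses / n == pytest.approx(p, abs=3 * se)

    def test_two_test_false_positive_probability(self, wm_params):
        """Non-proteinuric patient, specificity 0.96: >=1 false positive w.p. 1-0.96^2."""
        p, n = 0.0784, 30_000
        wm_params.test_specificity = 0.96
        rng = np.random.default_rng(6)
        fps = 0
        for _ in range(n):
            a = make_agent(egfr=95, prot=False)
            fps += screen_agent(a, wm_params, rng) != 1
        se = np.sqrt(p * (1 - p) / n)
        assert fps / n == pytest.approx(p, abs=3 * se)

    def test_dead_agent_rejected(self, wm_params):
        with pytest.raises(ValueError):
            screen_agent(make_agent(alive=False), wm_params, np.random.default_rng(0))


class _FixedDraws:
    """rng facade replaying a pre-drawn uniform array (for engine parity)."""

    def __init__(self, values):
        self.values, self.i = values, 0

    def random(self, k):
        out = self.values[self.i:self.i + k]
        self.i += k
        return out

    def skip(self, k):
        self.i += k


class TestEngineParity:
    def test_scalar_steps_reproduce_vectorized_cohort(self, wm_params):
        """Agent-by-agent scalar stepping matches the vectorized engine exactly."""
        from ckdscreen.synthetic_params import EGFR_BANDS, PROTEINURIA_STATES
        n, seed = 40, 13
        out = simulate_cohort(wm_params, NeverScreenPolicy(), n, seed)
        T = wm_params.n_epochs
        cum = np.cumsum(wm_params.initial_prevalence)
        for i in range(n):
            u = np.random.default_rng((seed, i)).random(
                INIT_DRAWS + DRAWS_PER_QUARTER * (T - 1))
            draws = _FixedDraws(u)
            u0, u1 = draws.random(2)
            s0 = int(np.searchsorted(cum, u0 * cum[-1], side="right")) + 1
            lo, hi = EGFR_BANDS[s0]
            a = make_agent(egfr=lo + u1 * (hi - lo), prot=s0 in PROTEINURIA_STATES)
            for _ in range(T - 1):
                if not a.alive:
                    break
                natural_history_step(a, wm_params, draws)
                draws.skip(2)   # unused screening-test slots
            assert a.accrued_qalys == pytest.approx(out.per_agent_qalys[i], abs=1e-9)
            assert a.accrued_costs == pytest.approx(out.per_agent_costs[i], abs=1e-6)


class TestSimulateCohort:
    def test_deterministic_and_block_invariant(self, wm_params):
        a = simulate_cohort(wm_params, status_quo_policy(), 300, 7)
        b = simulate_cohort(wm_params, status_quo_policy(), 300, 7, block_size=77)
        assert a.mean_qalys == b.mean_qalys
        assert np.array_equal(a.per_agent_costs, b.per_agent_costs)

    def test_never_screen_takes_no_screens(self, wm_params):
        out = simulate_cohort(wm_params, NeverScreenPolicy(), 200, 3)
        assert out.per_agent_screens.sum() == 0
        assert all(v == 0 for v in out.mean_screens_per_year_by_agebin.values())

    def test_annual_policy_frequency_is_exactly_one(self, wm_params):
        out = simulate_cohort(wm_params, status_quo_policy(), 500, 9)
        assert out.mean_screens_per_year == 1.0
        for label, v in out.mean_screens_per_year_by_agebin.items():
            if out.person_years_by_agebin[label] > 0:
                assert v == 1.0

    def test_nmb_identity(self, wm_params):
        out = simulate_cohort(wm_params, status_quo_policy(), 200, 5)
        assert out.mean_nmb == pytest.approx(
            wm_params.wtp * out.mean_qalys - out.mean_costs, rel=1e-12)

    def test_invalid_n(self, wm_params):
        with pytest.raises(ValueError):
            simulate_cohort(wm_params, NeverScreenPolicy(), 0, 1)

    def test_trajectory_monotonicity_invariants(self, wm_params):
        out = simulate_cohort(wm_params, status_quo_policy(), 100, 21,
                              record_trajectories=True)
        for _, traj in out.trajectories.groupby("agent"):
            traj = traj.sort_values("epoch")
            alive = traj.alive.to_numpy()
            live = traj[traj.alive]
            assert np.all(np.diff(live.egfr.to_numpy()) <= 1e-12)
            assert np.all(np.diff(live.proteinuria.astype(int)) >= 0)
            assert np.all(np.diff(live.on_treatment.astype(int)) >= 0)
            assert np.all(np.diff(alive.astype(int)) <= 0)   # death absorbing


class TestTreatmentEffectDominance:
    def test_higher_effectiveness_never_lowers_qalys(self, wm_params):
        """32.7% -> 40% eGFR-decline reduction cannot reduce QALYs (paired seeds)."""
        n = 3000
        low = wm_params.copy()
        low.treatment_egfr_reduction = 0.20
        high = wm_params.copy()
        high.treatment_egfr_reduction = 0.40
        out_low = simulate_cohort(low, status_quo_policy(), n, 17)
        out_high = simulate_cohort(high, status_quo_policy(), n, 17)
        diff = out_high.per_agent_qalys - out_low.per_agent_qalys
        se = diff.std(ddof=1) / np.sqrt(n)
        assert diff.mean() >= -3 * se


class TestTransitionTensor:
    def test_degenerate_parameters_give_identity(self):
        p = immortal_params()
        p.end_age = 35.0
        tensor = estimate_transition_tensor(p, 200, 3)
        assert np.allclose(tensor.untreated(), np.eye(10))

    def test_structural_properties(self, short_params):
        tensor = estimate_transition_tensor(short_params, 2000, 5)
        tensor.validate()   # row-stochastic, absorbing death, no reversal
        assert np.allclose(tensor.matrices.sum(axis=-1), 1.0, atol=1e-12)
        dead_row = tensor.matrices[:, :, 9, :]
        assert np.all(dead_row[:, :, 9] == 1.0)
        assert np.all(dead_row[:, :, :9] == 0.0)

    def test_empirical_onset_matches_closed_form_hazard(self):
        """Constant-hazard toy: p(1 -> proteinuric) converges to the quarterly rate."""
        p = immortal_params()
        p.end_age = 32.0
        p.proteinuria_onset_hazard = np.full(5, 0.08)
        n = 100_000
        tensor = estimate_transition_tensor(p, n, 29)
        q = annual_to_quarterly(0.08)
        for treat, scale in ((0, 1.0), (1, 1.0 - p.treatment_proteinuria_reduction)):
            expected = q * scale
            got = tensor.matrices[treat, 0, 0, 1] + tensor.matrices[treat, 0, 0, 2]
            se = np.sqrt(expected * (1 - expected) / n)
            assert got == pytest.approx(expected, abs=3 * se)

    def test_invalid_n(self, short_params):
        with pytest.raises(ValueError):
            estimate_transition_tensor(short_params, 0, 1)

    def test_fill_unobserved_rows_borrows_nearest_epoch(self):
        matrices = np.tile(np.eye(10), (2, 4, 1, 1))
        observed = np.ones((2, 4, 10), dtype=bool)
        row = np.zeros(10)
        row[0], row[3] = 0.6, 0.4
        matrices[0, 1, 0] = row
        observed[0, [0, 2, 3], 0] = False
        tensor = TransitionTensor(matrices=matrices, observed=observed)
        filled = fill_unobserved_rows(tensor)
        for t in range(4):
            assert np.allclose(filled.matrices[0, t, 0], row)
        assert np.allclose(tensor.matrices[0, 0, 0], np.eye(10)[0])  # input untouched


class TestTerminalRewards:
    def test_dead_and_horizon_rows_are_zero(self, short_params):
        R = estimate_terminal_rewards(short_params, 100, 3, epoch_stride=20)
        assert np.all(R[:, 9] == 0.0)
        assert np.all(R[-1] == 0.0)

    def test_zero_wtp_gives_nonpositive_rewards(self, short_params):
        p = short_params.copy()
        p.wtp = 0.0
        R = estimate_terminal_rewards(p, 200, 3, epoch_stride=20)
        assert np.all(R <= 0.0)

    def test_rewards_decrease_with_severity(self, short_params):
        R = estimate_terminal_rewards(short_params, 2000, 11, epoch_stride=20)
        assert R[0, 3] >= R[0, 5] >= R[0, 7]
        assert R[0, 3] > 0
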