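"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from ckdscreen import DemographicProfile, default_parameters
from ckdscreen.pomdp_build import (
    SCREEN,
    WAIT,
    ObservationModel,
    POMDPSpec,
    RewardSpec,
)

WM = DemographicProfile("White", "Male")


@pytest.fixture
def wm_params():
    return default_parameters(WM)


@pytest.fixture
def short_params():
    """Default parameters on a ten-year horizon (T=41) for fast pipeline tests."""
    p = default_parameters(WM)
    p.end_age = 40.0
    return p


def immortal_params():
    """No mortality, no progression, no proteinuria: agents stay healthy."""
    p = default_parameters(WM)
    p.mortality_hazard = np.zeros_like(p.mortality_hazard)
    p.egfr_decrement_schedule = np.zeros_like(p.egfr_decrement_schedule)
    p.proteinuria_onset_hazard = np.zeros_like(p.proteinuria_onset_hazard)
    p.initial_prevalence = np.zeros(10)
    p.initial_prevalence[0] = 1.0
    return p


# --------------------------------------------------------------------------
# Random toy POMDP specs and independent solution oracles
# --------------------------------------------------------------------------

def random_toy_spec(rng: np.random.Generator, *, max_states: int = 4,
                    max_epochs: int = 4, identity_obs: bool | None = None) -> POMDPSpec:
    """Small random POMDP with an absorbing dead state (the last state)."""
    m = int(rng.integers(3, max_states + 1))
    T = int(rng.integers(2, max_epochs + 1))
    dead = m
    trans = rng.random((T - 1, m, m)) + 0.05
    trans[:, dead - 1, :] = 0.0
    trans[:, dead - 1, dead - 1] = 1.0
    trans /= trans.sum(axis=-1, keepdims=True)

    if identity_obs is None:
        identity_obs = bool(rng.integers(0, 2))
    if identity_obs:
        screen = np.eye(m)
    else:
        screen = rng.random((m, m)) + 0.1
        screen[dead - 1, :] = 0.0
        screen[dead - 1, dead - 1] = 1.0
        screen /= screen.sum(axis=-1, keepdims=True)
    wait = np.zeros((m, 2))
    wait[: dead - 1, 0] = 1.0
    wait[dead - 1, 1] = 1.0

    stage = rng.uniform(-5, 10, size=(m, 2))
    cost = float(rng.uniform(0.1, 3.0))
    stage[:, SCREEN] = stage[:, WAIT] - cost
    stage[dead - 1, :] = 0.0
    terminal = rng.uniform(-5, 20, size=(T, m))
    terminal[:, dead - 1] = 0.0

    n_treat = int(rng.integers(0, m - 1))
    treat = tuple(sorted(rng.choice(np.arange(1, m), size=n_treat,
                                    replace=False).tolist())) if n_treat else ()
    belief = rng.random(m) + 0.01
    belief[dead - 1] = 0.0
    belief /= belief.sum()
    spec = POMDPSpec(
        n_states=m, horizon=T, start_age=30.0, transitions=trans,
        observations=ObservationModel(screen, wait),
        rewards=RewardSpec(stage, terminal, wtp=1.0,
                           gamma=float(rng.uniform(0.9, 0.999)),
                           screening_cost=cost),
        initial_belief=belief, treat_states=treat, dead_state=dead,
    )
    spec.validate()
    return spec


def _branches(spec: POMDPSpec, t: int, belief: np.ndarray, action: str):
    """(prob, is_terminal, value_or_posterior) per positive-probability observation."""
    P = spec.transitions[t - 1]
    pred = belief @ P
    R = spec.rewards.terminal_rewards
    out = []
    if action == "wait":
        cols = [(spec.observations.wait_matrix[:, 0], False),
                (spec.observations.wait_matrix[:, 1], True)]
        for col, is_dead in cols:
            p = float(pred @ col)
            if p <= 1e-15:
                continue
            post = pred * col / p
            terminal = is_dead or t + 1 == spec.horizon
            out.append((p, terminal, float(post @ R[t]) if terminal else post))
    else:
        for k in range(1, spec.n_states + 1):
            col = spec.observations.screen_matrix[:, k - 1]
            p = float(pred @ col)
            if p <= 1e-15:
                continue
            post = pred * col / p
            terminal = (k == spec.dead_state or k in spec.treat_states
                        or t + 1 == spec.horizon)
            out.append((p, terminal, float(post @ R[t]) if terminal else post))
    return out


def oracle_value(spec: POMDPSpec) -> float:
    """Optimal value by direct, cache-free recursion on the Bellman equations.

    Independent of the solver's graph enumeration and dedup machinery; the
    maximum over history-dependent policies distributes over independent
    observation subtrees, so this evaluates the exhaustive policy search
    exactly.
    """
    stage, gamma = spec.rewards.stage_rewards, spec.rewards.gamma

    def rec(t, belief):
        if t == spec.horizon:
            return float(belief @ spec.rewards.terminal_rewards[t - 1])
        best = -np.inf
        for aname, acol in (("wait", WAIT), ("screen", SCREEN)):
            v = float(belief @ stage[:, acol])
            for p, terminal, child in _branches(spec, t, belief, aname):
                v += spec.rewards.gamma * p * (child if terminal else rec(t + 1, child))
            best = max(best, v)
        return best

    return rec(1, np.asarray(spec.initial_belief, dtype=float))


def enumerate_policy_values(spec: POMDPSpec) -> list:
    """Values of every deterministic history-dependent policy (tiny specs only)."""
    stage = spec.rewards.stage_rewards

    def rec(t, belief):
        if t == spec.horizon:
            return [float(belief @ spec.rewards.terminal_rewards[t - 1])]
        values = []
        for aname, acol in (("wait", WAIT), ("screen", SCREEN)):
            r = float(belief @ stage[:, acol])
            child_lists = []
            for p, terminal, child in _branches(spec, t, belief, aname):
                opts = [child] if terminal else rec(t + 1, child)
                child_lists.append([(p, v) for v in opts])
            combos = [r]
            for opts in child_lists:
                combos = [c + spec.rewards.gamma * p * v
                          for c in combos for (p, v) in opts]
            values.extend(combos)
        return values

    return rec(1, np.asarray(spec.initial_belief, dtype=float))
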