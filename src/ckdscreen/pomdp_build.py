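"""Assembly of the screening POMDP tuple (S, A, P, O, R).

The decision problem: every quarter from age 30 to a final decision at age
84.75 (epochs t = 1..T-1, horizon T = 221 at age 85), a physician holding a
belief over the ten health states chooses Screen or Wait for an untreated
diabetic patient.  Screening yields an observation of the patient's state at
the next visit; waiting only reveals survival.  A screen revealing CKD stage
3+ starts treatment, ends the process, and pays the terminal reward R^t(s);
at the horizon every state pays R^T(s).  Stage and terminal rewards are net
monetary benefit (NMB = wtp x QALYs - costs) in USD, discounted per quarter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .microsim import TransitionTensor
from .synthetic_params import (
    DEAD,
    N_STATES,
    PROTEINURIA_STATES,
    TREATMENT_STATES,
    ParameterSet,
)

WAIT, SCREEN = 0, 1
ACTION_NAMES = ("wait", "screen")
OBS_ALIVE, OBS_DEAD = 0, 1


def quarterly_discount(annual_rate: float) -> float:
    """Per-quarter discount factor gamma with gamma^4 = 1/(1 + annual_rate)."""
    if not 0.0 <= annual_rate < 1.0:
        raise ValueError(f"annual rate must be in [0, 1), got {annual_rate}")
    return (1.0 + annual_rate) ** -0.25


def nmb(qalys: float, costs: float, wtp: float) -> float:
    """Net monetary benefit: wtp x QALYs - costs (USD)."""
    if wtp < 0:
        raise ValueError("wtp must be non-negative")
    return wtp * qalys - costs


def epoch_to_age(t: int, start_age: float = 30.0, horizon: int = 221) -> float:
    """Age at decision epoch t: start_age + 0.25 (t - 1); t = 1..T."""
    if not 1 <= t <= horizon:
        raise ValueError(f"epoch {t} outside 1..{horizon}")
    return start_age + 0.25 * (t - 1)


def validate_belief(belief: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    b = np.asarray(belief, dtype=float)
    if np.any(b < -tol) or abs(b.sum() - 1.0) > 1e-9:
        raise ValueError("belief must be a probability vector")
    return b


@dataclass
class ObservationModel:
    """Observation distributions for both actions.

    ``screen_matrix[j, k]`` is the probability of reporting state ``k+1`` when
    the true state is ``j+1``; under perfect testing it is the identity.
    ``wait_matrix[j, :]`` is the (alive, dead) observation distribution.
    """

    screen_matrix: np.ndarray   # (m, m)
    wait_matrix: np.ndarray     # (m, 2)

    def validate(self) -> None:
        for mat in (self.screen_matrix, self.wait_matrix):
            if np.any(mat < 0) or np.any(np.abs(mat.sum(axis=1) - 1.0) > 1e-9):
                raise ValueError("observation rows must be distributions")


def _reported_state(state: int, observed_prot: bool) -> list[tuple[int, float]]:
    """Reported state(s) given a true state and the proteinuria test outcome.

    eGFR is measured exactly, so the report stays within the true state's eGFR
    band.  For state 1 (eGFR >= 60 without proteinuria) a false-positive
    proteinuria result is split equally between CKD1 and CKD2 reports, since
    the 90 threshold falls midway through the healthy band.
    """
    if state == 1:
        return [(2, 0.5), (3, 0.5)] if observed_prot else [(1, 1.0)]
    if state == 2:
        return [(2, 1.0)] if observed_prot else [(1, 1.0)]
    if state == 3:
        return [(3, 1.0)] if observed_prot else [(1, 1.0)]
    base = {4: 4, 5: 4, 6: 6, 7: 6, 8: 8, 9: 8}[state]
    return [(base + 1, 1.0)] if observed_prot else [(base, 1.0)]


def build_observation_models(sensitivity: float, specificity: float) -> ObservationModel:
    """Observation model for the two-proteinuria-test screening procedure.

    Perfect characteristics yield the identity screen matrix.  Otherwise each
    proteinuria test is positive with probability ``sensitivity`` (truly
    proteinuric) or ``1 - specificity`` (not), the composite result is
    positive if at least one of the two tests is, and eGFR is measured
    exactly.
    """
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    m = N_STATES
    screen = np.zeros((m, m))
    for s in range(1, m):
        truly_prot = s in PROTEINURIA_STATES
        p_pos = (1.0 - (1.0 - sensitivity) ** 2 if truly_prot
                 else 1.0 - specificity ** 2)
        for obs_prot, p in ((True, p_pos), (False, 1.0 - p_pos)):
            if p == 0.0:
                continue
            for rep, w in _reported_state(s, obs_prot):
                screen[s - 1, rep - 1] += p * w
    screen[DEAD - 1, DEAD - 1] = 1.0
    wait = np.zeros((m, 2))
    wait[: DEAD - 1, OBS_ALIVE] = 1.0
    wait[DEAD - 1, OBS_DEAD] = 1.0
    model = ObservationModel(screen_matrix=screen, wait_matrix=wait)
    model.validate()
    return model


@dataclass
class RewardSpec:
    """Stage and terminal rewards in USD.

    ``stage_rewards[i, a]`` is the quarterly NMB accrued in state ``i+1``
    under action ``a`` (WAIT=0, SCREEN=1): quarterly QALY x wtp minus the
    quarterly state cost, minus the screening cost when screening.  Screening
    cost is the only difference between the two actions.  ``terminal_rewards``
    has shape (T, m): row t-1 is R^t; the Dead column is zero.
    """

    stage_rewards: np.ndarray     # (m, 2)
    terminal_rewards: np.ndarray  # (T, m)
    wtp: float
    gamma: float
    screening_cost: float

    def validate(self, dead_state: int | None = None) -> None:
        """``dead_state`` is the 1-based absorbing state (default: the last)."""
        dead = dead_state if dead_state is not None else self.stage_rewards.shape[0]
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError("gamma must be in (0, 1]")
        alive = [i for i in range(self.stage_rewards.shape[0]) if i != dead - 1]
        diff = self.stage_rewards[alive, SCREEN] - self.stage_rewards[alive, WAIT]
        if np.any(np.abs(diff + self.screening_cost) > 1e-9):
            raise ValueError("screening cost must be the only stage-reward difference")
        if np.any(self.stage_rewards[dead - 1] != 0):
            raise ValueError("dead stage rewards must be zero")
        if np.any(self.terminal_rewards[:, dead - 1] != 0):
            raise ValueError("dead terminal rewards must be zero")


@dataclass
class POMDPSpec:
    """Complete finite-horizon POMDP: states, horizon, dynamics, observations, rewards."""

    n_states: int
    horizon: int                       # T
    start_age: float
    transitions: np.ndarray            # (T-1, m, m), untreated quarterly dynamics
    observations: ObservationModel
    rewards: RewardSpec
    initial_belief: np.ndarray         # (m,)
    treat_states: tuple = tuple(sorted(TREATMENT_STATES))   # 1-based
    dead_state: int = DEAD             # 1-based
    schema_version: int = 1
    meta: dict = field(default_factory=dict)

    def epoch_to_age(self, t: int) -> float:
        return epoch_to_age(t, self.start_age, self.horizon)

    def validate(self) -> None:
        m, T = self.n_states, self.horizon
        if self.transitions.shape != (T - 1, m, m):
            raise ValueError(f"transitions must be ({T - 1}, {m}, {m}), "
                             f"got {self.transitions.shape}")
        if np.any(np.abs(self.transitions.sum(axis=-1) - 1.0) > 1e-9):
            raise ValueError("non-stochastic transition row")
        if np.any(self.transitions < -1e-15):
            raise ValueError("negative transition probability")
        if self.rewards.terminal_rewards.shape != (T, m):
            raise ValueError("terminal rewards must be (T, m)")
        if self.observations.screen_matrix.shape != (m, m):
            raise ValueError("screen observation matrix must be (m, m)")
        validate_belief(self.initial_belief)
        self.observations.validate()
        self.rewards.validate(self.dead_state)

    # ------------------------------------------------------------- serialization
    def to_json(self, path=None) -> str:
        d = {
            "schema_version": self.schema_version,
            "n_states": self.n_states,
            "horizon": self.horizon,
            "start_age": self.start_age,
            "transitions": self.transitions.tolist(),
            "screen_matrix": self.observations.screen_matrix.tolist(),
            "wait_matrix": self.observations.wait_matrix.tolist(),
            "stage_rewards": self.rewards.stage_rewards.tolist(),
            "terminal_rewards": self.rewards.terminal_rewards.tolist(),
            "wtp": self.rewards.wtp,
            "gamma": self.rewards.gamma,
            "screening_cost": self.rewards.screening_cost,
            "initial_belief": self.initial_belief.tolist(),
            "treat_states": list(self.treat_states),
            "dead_state": self.dead_state,
            "meta": self.meta,
        }
        text = json.dumps(d)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "POMDPSpec":
        if hasattr(source, "read"):
            d = json.load(source)
        elif isinstance(source, str) and source.lstrip().startswith("{"):
            d = json.loads(source)
        else:
            with open(source) as fh:
                d = json.load(fh)
        spec = cls(
            n_states=d["n_states"], horizon=d["horizon"], start_age=d["start_age"],
            transitions=np.array(d["transitions"]),
            observations=ObservationModel(np.array(d["screen_matrix"]),
                                          np.array(d["wait_matrix"])),
            rewards=RewardSpec(np.array(d["stage_rewards"]),
                               np.array(d["terminal_rewards"]),
                               d["wtp"], d["gamma"], d["screening_cost"]),
            initial_belief=np.array(d["initial_belief"]),
            treat_states=tuple(d["treat_states"]),
            dead_state=d["dead_state"],
            schema_version=d["schema_version"],
            meta=d.get("meta", {}),
        )
        spec.validate()
        return spec


def reroot(spec: POMDPSpec, epoch: int, belief: np.ndarray) -> POMDPSpec:
    """New POMDP starting at ``epoch`` with the given initial belief.

    Slices transitions and terminal rewards to the remaining horizon, so a
    policy can be solved for a patient first seen at an arbitrary age (e.g.
    entering care at 50) rather than only from the model's start age.
    """
    if not 1 <= epoch < spec.horizon:
        raise ValueError(f"epoch {epoch} outside 1..{spec.horizon - 1}")
    belief = validate_belief(belief)
    rewards = RewardSpec(
        stage_rewards=spec.rewards.stage_rewards.copy(),
        terminal_rewards=spec.rewards.terminal_rewards[epoch - 1:].copy(),
        wtp=spec.rewards.wtp, gamma=spec.rewards.gamma,
        screening_cost=spec.rewards.screening_cost)
    out = POMDPSpec(
        n_states=spec.n_states,
        horizon=spec.horizon - epoch + 1,
        start_age=spec.epoch_to_age(epoch),
        transitions=spec.transitions[epoch - 1:].copy(),
        observations=spec.observations,
        rewards=rewards,
        initial_belief=np.asarray(belief, dtype=float),
        treat_states=spec.treat_states,
        dead_state=spec.dead_state,
        meta={**spec.meta, "rerooted_from_epoch": epoch},
    )
    out.validate()
    return out


def assemble_pomdp(params: ParameterSet, tensor: TransitionTensor,
                   terminal: np.ndarray) -> POMDPSpec:
    """Build a validated :class:`POMDPSpec` from microsimulation outputs.

    Uses the untreated transition matrices (patients in the decision process
    are untreated; treatment enters only through the terminal rewards), the
    observation model implied by the parameter set's test characteristics,
    and stage rewards composed from quarterly QALY x wtp minus quarterly state
    cost, with the screening cost as the only Screen/Wait difference.
    """
    T = params.n_epochs
    if tensor.n_epochs != T:
        raise ValueError(f"tensor covers {tensor.n_epochs - 1} decision epochs, "
                         f"parameter set requires {T - 1}")
    terminal = np.asarray(terminal, dtype=float)
    if terminal.shape != (T, N_STATES):
        raise ValueError(f"terminal rewards must be ({T}, {N_STATES})")

    stage = np.zeros((N_STATES, 2))
    alive = slice(0, DEAD - 1)
    health = params.wtp * np.asarray(params.qaly_weights) - np.asarray(params.state_costs)
    stage[alive, WAIT] = health[alive]
    stage[alive, SCREEN] = health[alive] - params.screening_cost
    rewards = RewardSpec(
        stage_rewards=stage,
        terminal_rewards=terminal,
        wtp=params.wtp,
        gamma=quarterly_discount(params.annual_discount),
        screening_cost=params.screening_cost,
    )
    spec = POMDPSpec(
        n_states=N_STATES,
        horizon=T,
        start_age=params.start_age,
        transitions=np.array(tensor.untreated(), dtype=float),
        observations=build_observation_models(params.test_sensitivity,
                                              params.test_specificity),
        rewards=rewards,
        initial_belief=np.array(params.initial_prevalence, dtype=float),
        meta={"profile": params.profile.key},
    )
    spec.validate()
    return spec
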