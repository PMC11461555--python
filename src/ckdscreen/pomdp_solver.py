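"""Exact finite-horizon POMDP solution over the reachable belief set.

Because the process starts from a single initial belief and the action and
observation sets are finite, the beliefs reachable at each epoch form a finite
set.  The solver enumerates that set breadth-first (merging beliefs that
coincide within a tolerance), then applies backward induction: the value of a
belief at the horizon is its expected terminal reward, and earlier values are

    v*(t, pi) = max_a [ r(t, pi, a) + gamma * sum_k Pr(k | pi, a) v*(t+1, pi') ]

where pi' is the Bayes posterior after action a and observation k.  A screen
whose observation is a treatment state or death terminates the process, as
does the horizon.  Under perfect observation every post-screen belief is a
unit vector, so each reachable belief is characterized by (last observed
state, epochs since last screen) — the sufficient statistic used to export
the policy as a clinical lookup table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .pomdp_build import (
    OBS_ALIVE,
    OBS_DEAD,
    SCREEN,
    WAIT,
    ObservationModel,
    POMDPSpec,
    validate_belief,
)

_EPS = 1e-15
TIE_TOL = 1e-9


def belief_update(belief: np.ndarray, action: str, observation,
                  P: np.ndarray, obs_model: ObservationModel) -> np.ndarray:
    """Bayes posterior over next-epoch states given an action and observation.

    ``action`` is ``"screen"`` or ``"wait"``.  For a screen the observation is
    a 1-based reported state index; for a wait it is ``OBS_ALIVE`` (0) or
    ``OBS_DEAD`` (1).  Raises ``ValueError`` when the observation has zero
    predicted probability (the posterior is undefined; a zero vector is never
    silently renormalized).
    """
    b = validate_belief(belief)
    pred = b @ P
    if action == "screen":
        k = int(observation)
        if not 1 <= k <= len(b):
            raise ValueError(f"invalid screen observation {observation}")
        num = pred * obs_model.screen_matrix[:, k - 1]
    elif action == "wait":
        if observation not in (OBS_ALIVE, OBS_DEAD):
            raise ValueError(f"invalid wait observation {observation}")
        num = pred * obs_model.wait_matrix[:, observation]
    else:
        raise ValueError(f"unknown action {action!r}")
    denom = num.sum()
    if denom <= _EPS:
        raise ValueError(
            f"observation {observation!r} has zero probability under "
            f"action {action!r}; posterior undefined")
    return num / denom


@dataclass
class BeliefNode:
    """One reachable belief at one epoch.

    ``terminal_kind`` is ``None`` for decision nodes, else ``"treatment"``
    (screen revealed a treatment state), ``"dead"`` or ``"horizon"``.
    ``children[action]`` lists ``(observation, probability, child_key)``;
    branch probabilities for one action sum to 1 (terminal children carry the
    termination mass).
    """

    t: int
    belief: np.ndarray
    key: tuple
    terminal_kind: Optional[str] = None
    terminal_value: Optional[float] = None
    children: dict = field(default_factory=dict)
    histories: set = field(default_factory=set)
    provenance: Optional[tuple] = None
    reach_prob: float = 0.0

    @property
    def terminal(self) -> bool:
        return self.terminal_kind is not None


@dataclass
class BeliefGraph:
    """Reachable-belief graph: nodes per epoch, rooted at the initial belief."""

    spec: POMDPSpec
    levels: dict            # t -> {key: BeliefNode}
    root_key: tuple
    dedup_tol: float

    @property
    def nodes(self):
        for level in self.levels.values():
            yield from level.values()

    @property
    def n_nodes(self) -> int:
        return sum(len(v) for v in self.levels.values())

    @property
    def root(self) -> BeliefNode:
        return self.levels[1][self.root_key]


def _quantize(belief: np.ndarray, tol: float) -> tuple:
    return tuple(np.round(belief / tol).astype(np.int64).tolist())


def enumerate_reachable_beliefs(spec: POMDPSpec,
                                dedup_tol: float = 1e-9) -> BeliefGraph:
    """Breadth-first expansion of all positive-probability beliefs.

    From every decision node both actions are expanded over every
    positive-probability observation.  Same-epoch beliefs equal within
    ``dedup_tol`` (max-norm, via quantization) are merged.  Screens observing
    a treatment state terminate (treatment initiation), as do death
    observations and the horizon.  Terminal values are the belief-weighted
    terminal rewards of the node's epoch.
    """
    spec.validate()
    m, T = spec.n_states, spec.horizon
    R = spec.rewards.terminal_rewards
    screen_mat = spec.observations.screen_matrix
    wait_mat = spec.observations.wait_matrix
    identity_obs = np.allclose(screen_mat, np.eye(m))
    treat = set(spec.treat_states)
    levels: dict[int, dict] = {t: {} for t in range(1, T + 1)}

    def get_node(t, belief, kind, provenance):
        key = (t, kind, _quantize(belief, dedup_tol))
        node = levels[t].get(key)
        if node is None:
            value = float(belief @ R[t - 1]) if kind is not None else None
            node = BeliefNode(t=t, belief=belief, key=key, terminal_kind=kind,
                              terminal_value=value, provenance=provenance)
            levels[t][key] = node
        return node

    root_belief = np.asarray(spec.initial_belief, dtype=float)
    root_kind = "horizon" if T == 1 else None
    root = get_node(1, root_belief, root_kind, None)
    root.histories.add((0, 0))
    root.reach_prob = 1.0

    for t in range(1, T):
        P = spec.transitions[t - 1]
        for node in list(levels[t].values()):
            if node.terminal:
                continue
            pred = node.belief @ P
            child_kind_at = "horizon" if t + 1 == T else None

            # ---- wait
            entries = []
            for obs, col in ((OBS_ALIVE, wait_mat[:, 0]), (OBS_DEAD, wait_mat[:, 1])):
                p = float(pred @ col)
                if p <= _EPS:
                    continue
                posterior = pred * col / p
                kind = "dead" if obs == OBS_DEAD else child_kind_at
                child = get_node(t + 1, posterior, kind, (node.key, "wait", obs))
                if kind is None:
                    for (s0, ksince) in node.histories:
                        child.histories.add((s0, ksince + 1))
                entries.append((obs, p, child.key))
            node.children["wait"] = entries

            # ---- screen
            entries = []
            for k in range(1, m + 1):
                col = screen_mat[:, k - 1]
                p = float(pred @ col)
                if p <= _EPS:
                    continue
                posterior = pred * col / p
                if k == spec.dead_state:
                    kind = "dead"
                elif k in treat:
                    kind = "treatment"
                else:
                    kind = child_kind_at
                child = get_node(t + 1, posterior, kind, (node.key, "screen", k))
                if kind is None and identity_obs:
                    child.histories.add((k, 0))
                entries.append((k, p, child.key))
            node.children["screen"] = entries

    return BeliefGraph(spec=spec, levels=levels, root_key=root.key,
                       dedup_tol=dedup_tol)


@dataclass
class PolicyTree:
    """Solved policy: optimal action and value for every reachable belief."""

    graph: BeliefGraph
    values: dict            # key -> float
    actions: dict           # key -> "screen" | "wait" | "stop"
    history_index: dict     # (t, last observed state (0 = none), epochs since) -> key

    @property
    def spec(self) -> POMDPSpec:
        return self.graph.spec

    @property
    def root_value(self) -> float:
        return self.values[self.graph.root_key]

    def node_for_history(self, t: int, history: tuple) -> BeliefNode:
        key = self.history_index.get((t, history[0], history[1]))
        if key is None:
            raise KeyError(f"history {history} unreachable at epoch {t}")
        return self.graph.levels[t][key]

    def to_frame(self) -> pd.DataFrame:
        """Clinical lookup table keyed by (epoch, last observed state, epochs since screen)."""
        rows = []
        for (t, s0, k), key in sorted(self.history_index.items()):
            node = self.graph.levels[t][key]
            rows.append({
                "epoch": t, "age": self.spec.epoch_to_age(t),
                "last_observed_state": s0, "epochs_since_screen": k,
                "action": self.actions[key], "value": self.values[key],
                "reach_probability": node.reach_prob,
            })
        return pd.DataFrame(rows)


def backward_induction(spec: POMDPSpec, graph: BeliefGraph,
                       tie_tol: float = TIE_TOL) -> PolicyTree:
    """Solve the enumerated graph exactly by backward induction.

    Ties within ``tie_tol`` break toward Wait (minimal intervention at equal
    value).  After solving, reach probabilities are propagated forward along
    the optimal actions.
    """
    m, T = spec.n_states, spec.horizon
    stage = spec.rewards.stage_rewards
    gamma = spec.rewards.gamma
    values: dict = {}
    actions: dict = {}

    for t in range(T, 0, -1):
        for key, node in graph.levels[t].items():
            if node.terminal:
                values[key] = node.terminal_value
                actions[key] = "stop"
                continue
            if not node.children:
                raise ValueError(f"decision node at epoch {t} has no children")
            v_by_action = {}
            for aname, acol in (("wait", WAIT), ("screen", SCREEN)):
                entries = node.children.get(aname, [])
                r = float(node.belief @ stage[:, acol])
                cont = 0.0
                for _obs, p, child_key in entries:
                    if child_key not in values:
                        raise ValueError("missing child value; graph incomplete")
                    cont += p * values[child_key]
                v_by_action[aname] = r + gamma * cont
            if v_by_action["screen"] > v_by_action["wait"] + tie_tol:
                best = "screen"
            else:
                best = "wait"
            actions[key] = best
            values[key] = v_by_action[best]

    # forward reach probabilities under the chosen actions
    for node in graph.nodes:
        node.reach_prob = 0.0
    graph.root.reach_prob = 1.0
    for t in range(1, T):
        for key, node in graph.levels[t].items():
            if node.terminal or node.reach_prob == 0.0:
                continue
            for _obs, p, child_key in node.children.get(actions[key], []):
                graph.levels[t + 1][child_key].reach_prob += node.reach_prob * p

    history_index = {}
    for t, level in graph.levels.items():
        for key, node in level.items():
            for hist in node.histories:
                history_index[(t, hist[0], hist[1])] = key
    return PolicyTree(graph=graph, values=values, actions=actions,
                      history_index=history_index)


def solve(spec: POMDPSpec, dedup_tol: float = 1e-9,
          tie_tol: float = TIE_TOL) -> PolicyTree:
    """Enumerate reachable beliefs and solve by backward induction."""
    return backward_induction(spec, enumerate_reachable_beliefs(spec, dedup_tol),
                              tie_tol)


def optimal_action(policy: PolicyTree, t: int, history: tuple) -> str:
    """Action for a patient history (last observed state, epochs since screen).

    Returns ``"screen"``, ``"wait"``, or ``"stop"`` at terminal nodes and the
    horizon.  Raises ``KeyError`` for histories outside the reachable graph.
    """
    if t == policy.spec.horizon:
        return "stop"
    s0 = history[0]
    if s0 in policy.spec.treat_states or s0 == policy.spec.dead_state:
        return "stop"   # treatment initiated or patient dead: process over
    node = policy.node_for_history(t, history)
    return policy.actions[node.key]
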