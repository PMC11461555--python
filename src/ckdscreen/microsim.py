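"""Agent-level CKD natural-history engine.

Simulates quarterly lifetime trajectories of diabetic adults from age 30 to
death or age 85 under any screening policy, and from those trajectories
estimates (a) the quarterly state-transition tensor and (b) the terminal
rewards (discounted remaining net monetary benefit once treatment starts) that
parameterize the screening POMDP.

Within each quarter the event order is fixed: mortality draw, eGFR decline,
proteinuria onset, ESRD entry, then cost/QALY accrual for the quarter
(discounted at the quarter's epoch).  Proteinuria and treatment are
irreversible, eGFR never increases, and death is absorbing.

Randomness contract: every agent consumes an independent, counter-derived
random stream keyed by (cohort seed, agent id), with a fixed number of draws
per quarter.  Cohort results are therefore independent of iteration order and
block size, and two policies evaluated under the same seed share agent
trajectories until their screening decisions diverge (common random numbers).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .synthetic_params import (
    DEAD,
    EGFR_BANDS,
    N_BANDS,
    N_STATES,
    PROTEINURIA_STATES,
    TREATMENT_STATES,
    ParameterSet,
    age_band_index,
    annual_to_quarterly,
    state_from_measurements,
    states_from_arrays,
)

#: uniforms consumed per agent-quarter: mortality, proteinuria, ESRD, two
#: proteinuria screening tests (slots drawn whether used or not, so
#: trajectories are invariant to the screening policy until diagnosis).
DRAWS_PER_QUARTER = 5
#: leading draws per agent: initial state, initial eGFR position in band.
INIT_DRAWS = 2

#: age-bin edges for screening-frequency reporting (year-start ages).
FREQ_BIN_LABELS = ("30-40", "41-50", "51-60", "61-70", "71-80")


def _freq_bin(age: float) -> int:
    """Bin index for a process-year starting at integer ``age``; -1 if unbinned."""
    if 30 <= age <= 40:
        return 0
    if age <= 50:
        return 1
    if age <= 60:
        return 2
    if age <= 70:
        return 3
    if age <= 80:
        return 4
    return -1


# --------------------------------------------------------------------------
# Scalar agent API (reference semantics; the vectorized engine below is the
# workhorse and follows the same event order and draw layout).
# --------------------------------------------------------------------------

@dataclass
class Agent:
    """One simulated diabetic adult."""

    age: float
    egfr: float
    proteinuria: bool
    on_treatment: bool = False
    esrd: bool = False
    alive: bool = True
    accrued_qalys: float = 0.0
    accrued_costs: float = 0.0
    screens_taken: int = 0
    last_observed_state: Optional[int] = None

    @property
    def state(self) -> int:
        return state_from_measurements(self.egfr, self.proteinuria, self.alive)

    def epoch(self, params: ParameterSet) -> int:
        return int(round((self.age - params.start_age) * 4)) + 1


def natural_history_step(agent: Agent, params: ParameterSet, rng) -> Agent:
    """Advance one quarter of natural history (in place; returns the agent).

    Consumes exactly three uniforms (mortality, proteinuria, ESRD) in fixed
    order regardless of which events are possible, mirroring the vectorized
    engine's draw layout.
    """
    if not agent.alive:
        raise ValueError("cannot step a dead agent")
    u_mort, u_prot, u_esrd = rng.random(3)
    t = agent.epoch(params)
    gamma = (1.0 + params.annual_discount) ** -0.25
    band = int(age_band_index(agent.age))
    state = agent.state

    q_mort = annual_to_quarterly(params.mortality_hazard[band, state - 1])
    if agent.on_treatment:
        q_mort *= 1.0 - params.treatment_mortality_reduction
    if u_mort < q_mort:
        agent.alive = False
        agent.age += 0.25
        return agent

    dec = params.egfr_decrement_schedule[int(agent.proteinuria), band] / 4.0
    if agent.on_treatment:
        dec *= 1.0 - params.treatment_egfr_reduction
    agent.egfr = max(agent.egfr - dec, 0.0)

    if not agent.proteinuria:
        q_on = annual_to_quarterly(params.proteinuria_onset_hazard[band])
        if agent.on_treatment:
            q_on *= 1.0 - params.treatment_proteinuria_reduction
        if u_prot < q_on:
            agent.proteinuria = True

    if agent.egfr < 15 and not agent.esrd and u_esrd < params.esrd_entry_hazard:
        agent.esrd = True

    agent.age += 0.25
    disc = gamma ** (t - 1)
    s_new = agent.state
    agent.accrued_qalys += disc * params.qaly_weights[s_new - 1]
    agent.accrued_costs += disc * params.state_costs[s_new - 1]
    return agent


def screen_agent(agent: Agent, params: ParameterSet, rng) -> int:
    """Screen a living agent and return the diagnosed state.

    Two proteinuria tests are run (each with the configured sensitivity and
    specificity); eGFR is measured exactly and concurrently, so the diagnosed
    state is ``state_from_measurements(egfr, observed proteinuria)``.  With
    perfect test characteristics this always equals the agent's true state.
    Increments ``screens_taken`` and charges the screening cost at the agent's
    current epoch discount.
    """
    if not agent.alive:
        raise ValueError("cannot screen a dead agent")
    u1, u2 = rng.random(2)
    p_pos = params.test_sensitivity if agent.proteinuria else 1.0 - params.test_specificity
    observed_prot = (u1 < p_pos) or (u2 < p_pos)
    state = state_from_measurements(agent.egfr, observed_prot, True)
    gamma = (1.0 + params.annual_discount) ** -0.25
    agent.screens_taken += 1
    agent.accrued_costs += params.screening_cost * gamma ** (agent.epoch(params) - 1)
    agent.last_observed_state = state
    return state


# --------------------------------------------------------------------------
# Vectorized cohort engine
# --------------------------------------------------------------------------

def _uniforms(seed_key: tuple, agent_ids: np.ndarray, n_draws: int) -> np.ndarray:
    """Per-agent uniform draws from counter-derived independent streams."""
    out = np.empty((len(agent_ids), n_draws))
    for i, aid in enumerate(agent_ids):
        out[i] = np.random.default_rng((*seed_key, int(aid))).random(n_draws)
    return out


_BAND_LO = np.array([EGFR_BANDS.get(s, (0.0, 0.0))[0] for s in range(1, N_STATES + 1)])
_BAND_HI = np.array([EGFR_BANDS.get(s, (0.0, 0.0))[1] for s in range(1, N_STATES + 1)])
_PROT_MASK = np.array([s in PROTEINURIA_STATES for s in range(1, N_STATES + 1)])


def _simulate_block(params: ParameterSet, agent_ids: np.ndarray, seed_key: tuple,
                    *, policy=None, start_epoch: int = 1, init_state: int | None = None,
                    treated_init: bool = False, discount_to_start: bool = False,
                    entrant_egfr: bool = False, record_states: bool = False,
                    record_rows: bool = False) -> dict:
    """Simulate one block of agents; see :func:`simulate_cohort` for semantics."""
    T = params.n_epochs
    n_quarters = T - start_epoch
    m = len(agent_ids)
    u = _uniforms(seed_key, agent_ids, INIT_DRAWS + DRAWS_PER_QUARTER * n_quarters)

    gamma = (1.0 + params.annual_discount) ** -0.25
    t_ref = start_epoch if discount_to_start else 1
    q_mort = annual_to_quarterly(params.mortality_hazard)     # (bands, 10)
    q_onset = annual_to_quarterly(params.proteinuria_onset_hazard)
    dec_q = np.asarray(params.egfr_decrement_schedule) / 4.0   # (2, bands)
    qw = np.asarray(params.qaly_weights)
    cost = np.asarray(params.state_costs)
    tmr = params.treatment_mortality_reduction
    ter = params.treatment_egfr_reduction
    tpr = params.treatment_proteinuria_reduction
    sens, spec = params.test_sensitivity, params.test_specificity

    # ---- initial conditions
    if init_state is None:
        cum = np.cumsum(params.initial_prevalence)
        s0 = np.searchsorted(cum, u[:, 0] * cum[-1], side="right") + 1
        s0 = np.clip(s0, 1, N_STATES - 1)
    else:
        if not 1 <= init_state <= N_STATES - 1:
            raise ValueError(f"invalid initial state {init_state}")
        s0 = np.full(m, init_state, dtype=np.int64)
    lo, hi = _BAND_LO[s0 - 1], _BAND_HI[s0 - 1]
    if entrant_egfr:
        # newly detected patients: eGFR just below the stage threshold
        # (within one year's decline of entering the band)
        band0 = int(age_band_index(params.start_age + 0.25 * (start_epoch - 1)))
        dec_year = params.egfr_decrement_schedule[
            _PROT_MASK[s0 - 1].astype(int), band0]
        width = np.minimum(dec_year, hi - lo)
        egfr = hi - width * (0.001 + 0.999 * u[:, 1])
    else:
        egfr = lo + u[:, 1] * (hi - lo)
    prot = _PROT_MASK[s0 - 1].copy()
    alive = np.ones(m, dtype=bool)
    treated = np.full(m, treated_init)
    esrd = np.zeros(m, dtype=bool)
    in_process = ~treated.copy()
    last_obs = np.zeros(m, dtype=np.int16)
    last_result_epoch = np.full(m, start_epoch, dtype=np.int32)
    screens = np.zeros(m, dtype=np.int64)
    qalys = np.zeros(m)
    costs = np.zeros(m)
    ever4 = egfr < 30
    ever5 = egfr < 15

    n_bins = len(FREQ_BIN_LABELS)
    years_by_bin = np.zeros(n_bins)
    screens_by_bin = np.zeros(n_bins)
    years_total = 0.0
    screens_total = 0.0

    states_path = None
    if record_states:
        states_path = np.empty((m, n_quarters + 1), dtype=np.int8)
        states_path[:, 0] = s0
    rows = [] if record_rows else None

    for t in range(start_epoch, T):
        k = t - start_epoch
        col = INIT_DRAWS + DRAWS_PER_QUARTER * k
        u_m, u_p, u_e = u[:, col], u[:, col + 1], u[:, col + 2]
        u_t1, u_t2 = u[:, col + 3], u[:, col + 4]
        age_t = params.start_age + 0.25 * (t - 1)
        band = int(age_band_index(age_t))
        state_now = states_from_arrays(egfr, prot)
        eligible = alive & in_process

        # ---- screening decision (cost charged immediately, result observed
        # at the end of the quarter, reflecting within-quarter progression)
        screened = np.zeros(m, dtype=bool)
        if policy is not None:
            screened = policy.screen_mask(t, last_obs, t - last_result_epoch, eligible)
            screened &= eligible
            screens += screened
            costs += screened * params.screening_cost * gamma ** (t - 1)
            is_year_start = (t - 1) % 4 == 0
            if is_year_start:
                n_active = float(eligible.sum())
                years_total += n_active
                b = _freq_bin(age_t)
                if b >= 0:
                    years_by_bin[b] += n_active
            n_scr = float(screened.sum())
            screens_total += n_scr
            year_start_age = params.start_age + 0.25 * ((t - 1) - (t - 1) % 4)
            b = _freq_bin(year_start_age)
            if b >= 0:
                screens_by_bin[b] += n_scr

        # ---- mortality
        qm = q_mort[band, state_now - 1] * np.where(treated, 1.0 - tmr, 1.0)
        died = alive & (u_m < qm)
        alive &= ~died

        # ---- eGFR decline
        dq = np.where(prot, dec_q[1, band], dec_q[0, band])
        dq = dq * np.where(treated, 1.0 - ter, 1.0)
        egfr = np.where(alive, np.maximum(egfr - dq, 0.0), egfr)

        # ---- proteinuria onset (irreversible)
        q_on = q_onset[band] * np.where(treated, 1.0 - tpr, 1.0)
        prot |= alive & ~prot & (u_p < q_on)

        # ---- ESRD entry from CKD stage 5
        esrd |= alive & ~esrd & (egfr < 15) & (u_e < params.esrd_entry_hazard)

        # ---- accrual for the quarter (post-progression state)
        s_new = states_from_arrays(egfr, prot)
        disc = gamma ** (t - t_ref)
        qalys += np.where(alive, qw[s_new - 1], 0.0) * disc
        costs += np.where(alive, cost[s_new - 1], 0.0) * disc
        ever4 |= alive & (egfr < 30)
        ever5 |= alive & (egfr < 15)

        # ---- screening observation (state at end of quarter)
        obs_state = np.zeros(m, dtype=np.int16)
        if policy is not None and screened.any():
            observed = screened & alive
            p_pos = np.where(prot, sens, 1.0 - spec)
            obs_prot = observed & ((u_t1 < p_pos) | (u_t2 < p_pos))
            obs = states_from_arrays(egfr, obs_prot)
            obs_state[observed] = obs[observed]
            last_obs[observed] = obs[observed]
            last_result_epoch[observed] = t + 1
            diagnosed = observed & (obs >= 4)
            treated |= diagnosed
            in_process &= ~diagnosed
        in_process &= alive

        if record_states:
            states_path[:, k + 1] = np.where(alive, s_new, DEAD)
        if record_rows:
            rows.append(pd.DataFrame({
                "agent": agent_ids, "epoch": t, "age": age_t,
                "state": state_now, "egfr": egfr, "proteinuria": prot,
                "on_treatment": treated, "esrd": esrd, "alive": alive,
                "in_process": eligible,  # at decision time
                "action": np.where(screened, "screen", "wait"),
                "observation": obs_state,
                "d_qalys": np.where(alive, qw[s_new - 1], 0.0) * disc,
                "d_costs": (np.where(alive, cost[s_new - 1], 0.0) * disc
                            + screened * params.screening_cost * gamma ** (t - 1)),
            }))

    result = {
        "qalys": qalys, "costs": costs, "screens": screens,
        "ever_stage4": ever4, "ever_stage5": ever5, "esrd": esrd,
        "alive": alive, "egfr": egfr,
        "years_by_bin": years_by_bin, "screens_by_bin": screens_by_bin,
        "years_total": years_total, "screens_total": screens_total,
    }
    if record_states:
        result["states"] = states_path
    if record_rows:
        result["trajectories"] = pd.concat(rows, ignore_index=True)
    return result


@dataclass
class CohortOutcome:
    """Per-person discounted outcomes of simulating one screening policy."""

    n_agents: int
    wtp: float
    mean_qalys: float
    mean_costs: float
    cases_stage4: float   # per 100,000 population
    cases_stage5: float
    cases_esrd: float
    mean_screens_per_year_by_agebin: dict
    person_years_by_agebin: dict
    mean_screens_per_year: float
    per_agent_qalys: np.ndarray = field(repr=False, default=None)
    per_agent_costs: np.ndarray = field(repr=False, default=None)
    per_agent_screens: np.ndarray = field(repr=False, default=None)
    trajectories: Optional[pd.DataFrame] = field(repr=False, default=None)

    @property
    def mean_nmb(self) -> float:
        return self.wtp * self.mean_qalys - self.mean_costs

    @property
    def per_agent_nmb(self) -> np.ndarray:
        return self.wtp * self.per_agent_qalys - self.per_agent_costs


class _NoScreenPolicy:
    """Internal: never screen (used for natural-history-only runs)."""

    def screen_mask(self, t, last_obs, since_screen, eligible):
        return np.zeros_like(eligible, dtype=bool)


def simulate_cohort(params: ParameterSet, policy, n: int, seed: int,
                    *, block_size: int = 20_000,
                    record_trajectories: bool = False) -> CohortOutcome:
    """Simulate ``n`` agents from age 30 under ``policy`` (common-random-number safe).

    Agents start from ``initial_prevalence`` with eGFR uniform within the
    state's band.  Each quarter the policy decides whether to screen; a screen
    whose result reveals CKD stage 3+ (states 4-9) starts treatment and ends
    the screening process, while health simulation continues to death or the
    horizon.  Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if policy is None:
        policy = _NoScreenPolicy()
    agg = None
    traj = []
    for lo in range(0, n, block_size):
        ids = np.arange(lo, min(lo + block_size, n))
        res = _simulate_block(params, ids, (seed,), policy=policy,
                              record_rows=record_trajectories)
        if record_trajectories:
            traj.append(res.pop("trajectories"))
        if agg is None:
            agg = res
        else:
            for key in ("qalys", "costs", "screens", "ever_stage4",
                        "ever_stage5", "esrd", "alive", "egfr"):
                agg[key] = np.concatenate([agg[key], res[key]])
            for key in ("years_by_bin", "screens_by_bin", "years_total",
                        "screens_total"):
                agg[key] = agg[key] + res[key]

    with np.errstate(invalid="ignore", divide="ignore"):
        by_bin = np.where(agg["years_by_bin"] > 0,
                          agg["screens_by_bin"] / np.maximum(agg["years_by_bin"], 1e-300),
                          0.0)
    overall = (agg["screens_total"] / agg["years_total"]
               if agg["years_total"] > 0 else 0.0)
    out = CohortOutcome(
        n_agents=n,
        wtp=params.wtp,
        mean_qalys=float(agg["qalys"].mean()),
        mean_costs=float(agg["costs"].mean()),
        cases_stage4=float(agg["ever_stage4"].sum()) / n * 100_000,
        cases_stage5=float(agg["ever_stage5"].sum()) / n * 100_000,
        cases_esrd=float(agg["esrd"].sum()) / n * 100_000,
        mean_screens_per_year_by_agebin=dict(zip(FREQ_BIN_LABELS, by_bin)),
        person_years_by_agebin=dict(zip(FREQ_BIN_LABELS, agg["years_by_bin"])),
        mean_screens_per_year=float(overall),
        per_agent_qalys=agg["qalys"],
        per_agent_costs=agg["costs"],
        per_agent_screens=agg["screens"],
        trajectories=pd.concat(traj, ignore_index=True) if traj else None,
    )
    return out


# --------------------------------------------------------------------------
# Transition tensor
# --------------------------------------------------------------------------

#: (from, to) pairs forbidden structurally: proteinuria never reverts.
_REVERSAL = np.zeros((N_STATES, N_STATES), dtype=bool)
for _i in PROTEINURIA_STATES:
    for _j in range(1, N_STATES):
        if _j not in PROTEINURIA_STATES and _j != DEAD:
            _REVERSAL[_i - 1, _j - 1] = True


@dataclass
class TransitionTensor:
    """Quarterly transition matrices p_ij^t by epoch and treatment status.

    ``matrices[treatment, t-1]`` is the 10x10 row-stochastic matrix for the
    quarter starting at epoch ``t`` (t = 1..T-1).  ``observed`` flags rows
    estimated from at least ``min_visits`` agent-quarters; unobserved rows are
    identity (state persists).
    """

    matrices: np.ndarray          # (2, T-1, 10, 10)
    observed: np.ndarray          # (2, T-1, 10)
    min_visits: int = 1

    @property
    def n_epochs(self) -> int:
        return self.matrices.shape[1] + 1

    def untreated(self) -> np.ndarray:
        return self.matrices[0]

    def treated(self) -> np.ndarray:
        return self.matrices[1]

    def validate(self) -> None:
        if np.any(np.abs(self.matrices.sum(axis=-1) - 1.0) > 1e-9):
            raise ValueError("transition rows must sum to 1")
        if np.any(self.matrices < -1e-15):
            raise ValueError("negative transition probability")
        dead_rows = self.matrices[:, :, DEAD - 1, :]
        expect = np.zeros(N_STATES)
        expect[DEAD - 1] = 1.0
        if np.any(np.abs(dead_rows - expect) > 1e-12):
            raise ValueError("death must be absorbing")
        if np.any(self.matrices[:, :, _REVERSAL] > 0):
            raise ValueError("proteinuria reversal must have zero probability")

    def to_frame(self) -> pd.DataFrame:
        t_idx, i_idx, j_idx = np.meshgrid(
            np.arange(1, self.n_epochs), np.arange(1, N_STATES + 1),
            np.arange(1, N_STATES + 1), indexing="ij")
        frames = []
        for treat in (0, 1):
            frames.append(pd.DataFrame({
                "epoch": t_idx.ravel(), "from_state": i_idx.ravel(),
                "to_state": j_idx.ravel(), "treatment": treat,
                "probability": self.matrices[treat].ravel(),
            }))
        return pd.concat(frames, ignore_index=True)


def estimate_transition_tensor(params: ParameterSet, n: int, seed: int,
                               *, min_visits: int = 1,
                               block_size: int = 20_000) -> TransitionTensor:
    """Empirical quarterly transition frequencies from simulated trajectories.

    One untreated and one treated-from-entry cohort of ``n`` agents are run
    without screening; transitions are counted per epoch and row-normalized.
    Death is forced absorbing and proteinuria-reverting entries are structural
    zeros.  Rows with fewer than ``min_visits`` visits are identity and
    flagged unobserved.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    T = params.n_epochs
    counts = np.zeros((2, T - 1, N_STATES * N_STATES))
    for treat in (0, 1):
        for lo in range(0, n, block_size):
            ids = np.arange(lo, min(lo + block_size, n))
            res = _simulate_block(params, ids, (seed, treat),
                                  treated_init=bool(treat), record_states=True)
            s = res["states"].astype(np.int64)
            pair = (s[:, :-1] - 1) * N_STATES + (s[:, 1:] - 1)
            for t in range(T - 1):
                counts[treat, t] += np.bincount(pair[:, t],
                                                minlength=N_STATES * N_STATES)
    counts = counts.reshape(2, T - 1, N_STATES, N_STATES)
    counts[:, :, _REVERSAL] = 0.0
    row_tot = counts.sum(axis=-1)
    observed = row_tot >= min_visits
    matrices = np.where(observed[..., None], counts / np.maximum(row_tot[..., None], 1),
                        np.eye(N_STATES)[None, None])
    matrices[:, :, DEAD - 1, :] = 0.0
    matrices[:, :, DEAD - 1, DEAD - 1] = 1.0
    observed[:, :, DEAD - 1] = True
    tensor = TransitionTensor(matrices=matrices, observed=observed,
                              min_visits=min_visits)
    tensor.validate()
    return tensor


# --------------------------------------------------------------------------
# Terminal rewards
# --------------------------------------------------------------------------

def estimate_terminal_rewards(params: ParameterSet, n: int, seed: int,
                              *, epoch_stride: int = 4) -> np.ndarray:
    """Terminal-reward table R[t-1, s-1]: discounted remaining NMB at treatment start.

    For each state s in 4..9 and a grid of start epochs (every
    ``epoch_stride`` quarters, plus the final decision epoch), ``n`` agents
    are initialized in state s on treatment at that epoch and simulated to
    death or the horizon; the mean NMB (wtp x QALYs - costs), discounted back
    to the start epoch, is linearly interpolated over intermediate epochs.
    Because treatment follows a positive screen, entrants represent newly
    detected patients: their eGFR is drawn from just below the stage
    threshold (within one year's decline of entering the band) rather than
    uniformly across it.  The horizon row R[T-1, :] and the Dead column are
    zero, as are states 1-3 (treatment is never initiated there).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    T = params.n_epochs
    grid = sorted(set(range(1, T, epoch_stride)) | {T - 1})
    R = np.zeros((T, N_STATES))
    ids = np.arange(n)
    for s in sorted(TREATMENT_STATES):
        vals = []
        for t0 in grid:
            res = _simulate_block(params, ids, (seed, t0, s), start_epoch=t0,
                                  init_state=s, treated_init=True,
                                  discount_to_start=True, entrant_egfr=True)
            vals.append(params.wtp * res["qalys"].mean() - res["costs"].mean())
        R[: T - 1, s - 1] = np.interp(np.arange(1, T), grid, vals)
    return R


def fill_unobserved_rows(tensor: TransitionTensor) -> TransitionTensor:
    """Replace identity fallback rows with the nearest observed epoch's row.

    Some states are structurally vacated at some ages (e.g. CKD1 requires
    eGFR >= 90, which no agent retains late in life), so their rows cannot be
    estimated there and default to identity.  Identity rows freeze belief
    mass, which misleads the solver; for solving, each unobserved
    (state, epoch) row is borrowed from the nearest epoch at which the same
    state and treatment status was observed.  Rows observed nowhere stay
    identity.  Returns a new tensor; the input is unchanged.
    """
    matrices = tensor.matrices.copy()
    observed = tensor.observed.copy()
    n_ep = matrices.shape[1]
    epochs = np.arange(n_ep)
    for treat in (0, 1):
        for s in range(N_STATES):
            obs = tensor.observed[treat, :, s]
            if obs.all() or not obs.any():
                continue
            src = epochs[obs][np.abs(epochs[obs][None, :]
                                     - epochs[~obs][:, None]).argmin(axis=1)]
            matrices[treat, ~obs, s, :] = tensor.matrices[treat, src, s, :]
    filled = TransitionTensor(matrices=matrices, observed=observed,
                              min_visits=tensor.min_visits)
    filled.validate()
    return filled


def terminal_rewards_frame(R: np.ndarray) -> pd.DataFrame:
    """Tabular export of a terminal-reward table keyed by (epoch, state)."""
    T, m = R.shape
    t_idx, s_idx = np.meshgrid(np.arange(1, T + 1), np.arange(1, m + 1),
                               indexing="ij")
    return pd.DataFrame({"epoch": t_idx.ravel(), "state": s_idx.ravel(),
                         "terminal_reward": R.ravel()})
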