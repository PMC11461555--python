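"""Screening-policy evaluation, reporting and national-policy approximation.

Policies are pure functions of the observable history (epoch, last observed
state, epochs since the last screen).  This module provides the concrete
policy families (fixed interval, solved policy tree, age-binned frequency),
head-to-head evaluation of a candidate against the annual status quo under
common random numbers, translation of policy-tree output into age-binned
national screening frequencies and threshold ages, and scaling of per-person
deltas to population totals.

Screening frequency is reported per process-year: model years start at
integer ages, a year enters the denominator when the agent is alive,
undiagnosed and still in the screening process at the year's first decision
epoch, and screens taken within counted years form the numerator.  Under this
convention the annual status-quo policy has frequency exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .microsim import FREQ_BIN_LABELS, CohortOutcome, simulate_cohort, _freq_bin
from .pomdp_solver import PolicyTree, optimal_action
from .synthetic_params import ParameterSet


# --------------------------------------------------------------------------
# Policy families
# --------------------------------------------------------------------------

class ScreeningPolicy:
    """Base class; subclasses implement ``screen_mask`` (vectorized over agents)."""

    kind: str = "abstract"

    def screen_mask(self, t: int, last_obs: np.ndarray, since_screen: np.ndarray,
                    eligible: np.ndarray) -> np.ndarray:
        raise NotImplementedError


@dataclass
class FixedIntervalPolicy(ScreeningPolicy):
    """Screen every ``interval`` epochs, starting at the first epoch."""

    interval: int
    kind: str = "fixed-interval"

    def __post_init__(self):
        if self.interval < 1:
            raise ValueError("interval must be >= 1 epoch")

    def screen_mask(self, t, last_obs, since_screen, eligible):
        if (t - 1) % self.interval == 0:
            return eligible.copy()
        return np.zeros_like(eligible)


class NeverScreenPolicy(ScreeningPolicy):
    kind = "never"

    def screen_mask(self, t, last_obs, since_screen, eligible):
        return np.zeros_like(eligible)


def status_quo_policy() -> FixedIntervalPolicy:
    """Annual screening (every 4th epoch), the guideline comparator."""
    return FixedIntervalPolicy(interval=4)


@dataclass
class PolicyTreePolicy(ScreeningPolicy):
    """Executes a solved :class:`~ckdscreen.pomdp_solver.PolicyTree`.

    The tree's history index is compiled into a dense lookup table over
    (epoch, last observed state in {none, 1, 2, 3}, epochs since screen).
    Histories outside the reachable graph default to Wait.
    """

    tree: PolicyTree
    kind: str = "pomdp-tree"
    _table: np.ndarray = field(init=False, repr=False, default=None)

    def __post_init__(self):
        T = self.tree.spec.horizon
        table = np.zeros((T + 1, 4, T + 1), dtype=bool)
        for (t, s0, k), key in self.tree.history_index.items():
            if s0 <= 3 and self.tree.actions.get(key) == "screen":
                table[t, s0, k] = True
        self._table = table

    def screen_mask(self, t, last_obs, since_screen, eligible):
        if t >= self._table.shape[0]:
            return np.zeros_like(eligible)
        s0 = np.clip(last_obs, 0, 3).astype(np.int64)
        k = np.clip(since_screen, 0, self._table.shape[2] - 1).astype(np.int64)
        return eligible & self._table[t, s0, k]


@dataclass
class AgeBinnedFrequencyPolicy(ScreeningPolicy):
    """Deterministic screening at a target annual frequency per 10-year age bin.

    Within each model year the target frequency (screens/year, 0..4)
    accumulates quarterly; a screen fires whenever the accumulator reaches 1.
    History-independent, so the schedule is precomputed once.
    """

    frequencies: dict                      # bin label -> screens/year
    start_age: float = 30.0
    horizon: int = 221
    first_screen_age: Optional[float] = None
    last_screen_age: Optional[float] = None
    kind: str = "age-binned-frequency"
    _epochs: set = field(init=False, repr=False, default=None)

    def __post_init__(self):
        for label, f in self.frequencies.items():
            if not 0.0 <= f <= 4.0:
                raise ValueError(f"frequency for {label} must be in [0, 4]")
        acc, epochs = 0.0, set()
        for t in range(1, self.horizon):
            age = self.start_age + 0.25 * (t - 1)
            year_age = self.start_age + 0.25 * ((t - 1) - (t - 1) % 4)
            b = _freq_bin(year_age)
            f = self.frequencies.get(FREQ_BIN_LABELS[b], 0.0) if b >= 0 else 0.0
            acc += f / 4.0
            if acc >= 1.0 - 1e-12:
                if ((self.first_screen_age is None or age >= self.first_screen_age)
                        and (self.last_screen_age is None or age <= self.last_screen_age)):
                    epochs.add(t)
                acc -= 1.0
        self._epochs = epochs

    def screen_mask(self, t, last_obs, since_screen, eligible):
        if t in self._epochs:
            return eligible.copy()
        return np.zeros_like(eligible)


# --------------------------------------------------------------------------
# Head-to-head evaluation
# --------------------------------------------------------------------------

def averted_cases(cases_without: float, cases_with: float) -> float:
    """Averted cases per 100,000: cases without minus cases with the intervention."""
    return cases_without - cases_with


@dataclass
class ComparisonReport:
    """Status-quo vs. candidate-policy outcomes with exact pairwise deltas."""

    outcome_status_quo: CohortOutcome
    outcome_pomdp: CohortOutcome
    profile: str = ""

    @property
    def delta_nmb(self) -> float:
        return self.outcome_pomdp.mean_nmb - self.outcome_status_quo.mean_nmb

    @property
    def delta_costs(self) -> float:
        return self.outcome_pomdp.mean_costs - self.outcome_status_quo.mean_costs

    @property
    def delta_qalys(self) -> float:
        return self.outcome_pomdp.mean_qalys - self.outcome_status_quo.mean_qalys

    @property
    def averted_stage4(self) -> float:
        return averted_cases(self.outcome_status_quo.cases_stage4,
                             self.outcome_pomdp.cases_stage4)

    @property
    def averted_stage5(self) -> float:
        return averted_cases(self.outcome_status_quo.cases_stage5,
                             self.outcome_pomdp.cases_stage5)

    @property
    def averted_esrd(self) -> float:
        return averted_cases(self.outcome_status_quo.cases_esrd,
                             self.outcome_pomdp.cases_esrd)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, o in (("status_quo", self.outcome_status_quo),
                        ("pomdp", self.outcome_pomdp)):
            rows.append({"profile": self.profile, "policy": name,
                         "nmb": o.mean_nmb, "costs": o.mean_costs,
                         "qalys": o.mean_qalys,
                         "cases_stage4": o.cases_stage4,
                         "cases_stage5": o.cases_stage5,
                         "cases_esrd": o.cases_esrd})
        return pd.DataFrame(rows)


def evaluate_policy_pair(params: ParameterSet, pomdp_policy: ScreeningPolicy,
                         n: int, seed: int, *,
                         baseline: Optional[ScreeningPolicy] = None,
                         record_trajectories: bool = False) -> ComparisonReport:
    """Evaluate a candidate policy against the status quo on common random numbers.

    Both cohorts share agent seeds, so trajectories coincide until screening
    decisions diverge and outcome deltas are paired.
    """
    if baseline is None:
        baseline = status_quo_policy()
    sq = simulate_cohort(params, baseline, n, seed,
                         record_trajectories=record_trajectories)
    po = simulate_cohort(params, pomdp_policy, n, seed,
                         record_trajectories=record_trajectories)
    return ComparisonReport(outcome_status_quo=sq, outcome_pomdp=po,
                            profile=params.profile.key)


# --------------------------------------------------------------------------
# National policy approximation
# --------------------------------------------------------------------------

@dataclass
class NationalPolicy:
    """Non-belief screening guideline: age-binned annual frequencies."""

    first_screen_age: Optional[float]
    last_screen_age: Optional[float]
    mean_annual_frequency: dict      # bin label -> screens per person-year

    def __post_init__(self):
        if (self.first_screen_age is not None and self.last_screen_age is not None
                and self.first_screen_age > self.last_screen_age):
            raise ValueError("first screen age must be <= last screen age")
        for label, f in self.mean_annual_frequency.items():
            if not 0.0 <= f <= 4.0:
                raise ValueError(f"frequency for {label} outside [0, 4]")

    def to_policy(self, start_age: float = 30.0,
                  horizon: int = 221) -> AgeBinnedFrequencyPolicy:
        return AgeBinnedFrequencyPolicy(
            frequencies=dict(self.mean_annual_frequency),
            start_age=start_age, horizon=horizon,
            first_screen_age=self.first_screen_age,
            last_screen_age=self.last_screen_age)


def approximate_national_policy(trajectories: pd.DataFrame) -> NationalPolicy:
    """Age-binned mean screening frequency observed in simulated trajectories.

    The denominator is in-process person-time at process-year granularity
    (see module docstring); the numerator counts screens within counted
    years.  Also reports the earliest and latest ages at which any screen
    occurred (absent when no screens were taken).
    """
    if trajectories is None or len(trajectories) == 0:
        raise ValueError("empty trajectory table")
    df = trajectories
    year_start = ((df["epoch"] - 1) % 4) == 0
    bins = df["age"].where(year_start, df["age"] - 0.25 * ((df["epoch"] - 1) % 4))
    bin_idx = bins.map(_freq_bin)
    years = np.zeros(len(FREQ_BIN_LABELS))
    screens = np.zeros(len(FREQ_BIN_LABELS))
    active = df["in_process"] & year_start
    for b, cnt in bin_idx[active].value_counts().items():
        if b >= 0:
            years[int(b)] += cnt
    screened = df["action"] == "screen"
    for b, cnt in bin_idx[screened].value_counts().items():
        if b >= 0:
            screens[int(b)] += cnt
    with np.errstate(invalid="ignore"):
        freq = np.where(years > 0, screens / np.maximum(years, 1), 0.0)
    if screened.any():
        first = float(df.loc[screened, "age"].min())
        last = float(df.loc[screened, "age"].max())
    else:
        first = last = None
    return NationalPolicy(first_screen_age=first, last_screen_age=last,
                          mean_annual_frequency=dict(zip(FREQ_BIN_LABELS, freq)))


# --------------------------------------------------------------------------
# Population scaling and threshold ages
# --------------------------------------------------------------------------

def population_scale(deltas_by_profile: dict, population: float,
                     diabetic_fraction: float, shares: dict) -> dict:
    """Scale per-person deltas to population totals.

    ``deltas_by_profile`` maps profile keys to dicts with per-person
    ``qalys``, ``costs`` and ``nmb`` deltas (e.g. from
    :class:`ComparisonReport`); ``shares`` maps the same keys to demographic
    fractions.  Totals are population x diabetic_fraction x share-weighted
    per-person delta.
    """
    if population < 0 or diabetic_fraction < 0:
        raise ValueError("population and diabetic fraction must be non-negative")
    if any(s < 0 for s in shares.values()):
        raise ValueError("shares must be non-negative")
    n_diabetic = population * diabetic_fraction
    totals = {"qalys": 0.0, "costs": 0.0, "nmb": 0.0}
    for key, share in shares.items():
        d = deltas_by_profile[key]
        for q in totals:
            totals[q] += n_diabetic * share * d[q]
    return totals


def deltas_from_report(report: ComparisonReport) -> dict:
    return {"qalys": report.delta_qalys, "costs": report.delta_costs,
            "nmb": report.delta_nmb}


def example_screening_ages(tree: PolicyTree, observed_state: int = 1) -> list:
    """Screen ages for an example individual whose screens all report ``observed_state``.

    Follows the solved policy from the root, assuming every screen result is
    the given non-terminal state (default: Normal).  Mirrors the published
    per-patient policy summaries.
    """
    if observed_state not in (1, 2, 3):
        raise ValueError("observed state must be 1, 2 or 3 (process continues)")
    T = tree.spec.horizon
    t, hist = 1, (0, 0)
    ages = []
    while t < T:
        try:
            action = optimal_action(tree, t, hist)
        except KeyError:
            break
        if action == "stop":
            break
        if action == "screen":
            ages.append(tree.spec.epoch_to_age(t))
            hist = (observed_state, 0)
        else:
            hist = (hist[0], hist[1] + 1)
        t += 1
    return ages


def screening_threshold_ages(screen_ages, thresholds_years) -> dict:
    """Earliest age from which inter-screen gaps stay at or below each threshold.

    ``screen_ages`` is the ordered list of ages at which a policy screens an
    example individual.  For each threshold (years) the result is the age of
    the earliest screen such that every subsequent inter-screen gap is <= the
    threshold (the final screen has no following gap and is vacuously
    sustained); ``None`` when never attained.
    """
    ages = sorted(screen_ages)
    out = {}
    gaps = [b - a for a, b in zip(ages, ages[1:])]
    for thr in thresholds_years:
        if thr <= 0:
            raise ValueError("thresholds must be positive")
        attained = None
        for i in range(len(ages)):
            if all(g <= thr + 1e-12 for g in gaps[i:]):
                attained = ages[i]
                break
        out[thr] = attained
    return out
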