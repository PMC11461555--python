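"""Health-state vocabulary and synthetic natural-history / economic parameter sets.

The model tracks a diagnosed diabetic adult through ten health states defined by
estimated glomerular filtration rate (eGFR, mL/min/1.73m^2) and persistent
proteinuria:

====== ============================ ===========
state  stage                        proteinuria
====== ============================ ===========
1      Normal (eGFR >= 60)          no
2      CKD 1  (eGFR >= 90)          yes
3      CKD 2  (60 <= eGFR < 90)     yes
4, 5   CKD 3  (30 <= eGFR < 60)     no / yes
6, 7   CKD 4  (15 <= eGFR < 30)     no / yes
8, 9   CKD 5  (eGFR < 15)           no / yes
10     Dead
====== ============================ ===========

Stage thresholds follow the KDIGO convention with half-open intervals, so the
(eGFR, proteinuria) -> state mapping is a partition.

Population inputs (eGFR decrement schedules, proteinuria onset hazards,
mortality, per-state costs and utilities) are packaged as :class:`ParameterSet`
values per race/gender group.  Quantities that national survey and registry
data would normally supply are synthetic defaults chosen to be
clinically plausible; values printed in the source literature (willingness to
pay, discount rate, treatment-effect multipliers, the published CKD cost set)
are used directly.  See ``docs/methods.md`` for the provenance of every
default.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

N_STATES = 10
DEAD = 10
#: 1-based indices of proteinuria-positive states.
PROTEINURIA_STATES = frozenset({2, 3, 5, 7, 9})
#: States whose observation triggers treatment and ends the screening process.
TREATMENT_STATES = frozenset({4, 5, 6, 7, 8, 9})

STAGE_NAMES = {
    1: "Normal", 2: "CKD1", 3: "CKD2", 4: "CKD3", 5: "CKD3",
    6: "CKD4", 7: "CKD4", 8: "CKD5", 9: "CKD5", 10: "Dead",
}

#: eGFR band (lo, hi) used when sampling an initial eGFR uniformly within a
#: state.  State 1 and 2 need a finite upper bound; 120 is a generous healthy
#: ceiling.
EGFR_BANDS = {
    1: (60.0, 120.0), 2: (90.0, 120.0), 3: (60.0, 90.0),
    4: (30.0, 60.0), 5: (30.0, 60.0), 6: (15.0, 30.0), 7: (15.0, 30.0),
    8: (0.0, 15.0), 9: (0.0, 15.0),
}

RACES = ("White", "Black")
GENDERS = ("Male", "Female")

AGE_BAND_EDGES = np.array([30.0, 40.0, 50.0, 60.0, 70.0, 85.0])
N_BANDS = len(AGE_BAND_EDGES) - 1


@dataclass(frozen=True)
class DemographicProfile:
    """Race/gender group; the four combinations define the modelled cohorts."""

    race: str
    gender: str

    def __post_init__(self) -> None:
        if self.race not in RACES:
            raise ValueError(f"race must be one of {RACES}, got {self.race!r}")
        if self.gender not in GENDERS:
            raise ValueError(f"gender must be one of {GENDERS}, got {self.gender!r}")

    @property
    def key(self) -> str:
        return f"{self.race} {self.gender}"


ALL_PROFILES = tuple(DemographicProfile(r, g) for r in RACES for g in GENDERS)


def state_from_measurements(egfr: float, proteinuria: bool, alive: bool = True) -> int:
    """Map (eGFR, proteinuria, vital status) to the 1..10 state index.

    Half-open eGFR intervals: CKD5 [0,15), CKD4 [15,30), CKD3 [30,60),
    CKD2 [60,90), CKD1 [90,inf).  Dead dominates everything.
    """
    if not alive:
        return DEAD
    if egfr < 0:
        raise ValueError(f"eGFR must be non-negative, got {egfr}")
    if proteinuria:
        if egfr >= 90:
            return 2
        if egfr >= 60:
            return 3
        if egfr >= 30:
            return 5
        if egfr >= 15:
            return 7
        return 9
    if egfr >= 60:
        return 1
    if egfr >= 30:
        return 4
    if egfr >= 15:
        return 6
    return 8


def states_from_arrays(egfr: np.ndarray, proteinuria: np.ndarray) -> np.ndarray:
    """Vectorized ``state_from_measurements`` for living agents."""
    base = np.where(egfr >= 60, 1, np.where(egfr >= 30, 4, np.where(egfr >= 15, 6, 8)))
    with_prot = np.where(egfr >= 90, 2, np.where(egfr >= 60, 3, base + 1))
    return np.where(proteinuria, with_prot, base).astype(np.int8)


def age_band_index(age) -> np.ndarray | int:
    """Index into the decade age bands (30-40, 40-50, 50-60, 60-70, 70-85)."""
    idx = np.searchsorted(AGE_BAND_EDGES[1:-1], age, side="right")
    return np.clip(idx, 0, N_BANDS - 1)


def annual_to_quarterly(p: np.ndarray | float) -> np.ndarray | float:
    """Convert an annual event probability to quarterly assuming a constant hazard."""
    return 1.0 - (1.0 - np.asarray(p, dtype=float)) ** 0.25


@dataclass
class ParameterSet:
    """All natural-history, economic and test-characteristic inputs for one group.

    Schedules are indexed by the decade age bands in :data:`AGE_BAND_EDGES`.
    Costs and QALY weights are stored per quarter (a quarter is the decision
    cycle); hazards are stored as annual probabilities and converted with
    :func:`annual_to_quarterly` where the simulator consumes them.
    """

    profile: DemographicProfile
    start_age: float = 30.0
    end_age: float = 85.0
    #: annual eGFR decline, shape (2, bands): row 0 without, row 1 with proteinuria
    egfr_decrement_schedule: np.ndarray = field(default=None)
    #: annual probability of acquiring proteinuria, shape (bands,)
    proteinuria_onset_hazard: np.ndarray = field(default=None)
    #: annual death probability, shape (bands, 10); dead column is zero
    mortality_hazard: np.ndarray = field(default=None)
    #: quarterly probability of ESRD onset while in CKD stage 5
    esrd_entry_hazard: float = 0.05
    #: per-quarter cost (USD) by state, shape (10,)
    state_costs: np.ndarray = field(default=None)
    screening_cost: float = 75.0
    #: per-quarter utility by state (annual utility / 4), shape (10,)
    qaly_weights: np.ndarray = field(default=None)
    treatment_egfr_reduction: float = 0.327
    treatment_proteinuria_reduction: float = 0.55
    treatment_mortality_reduction: float = 0.23
    test_sensitivity: float = 1.0
    test_specificity: float = 1.0
    wtp: float = 150_000.0
    annual_discount: float = 0.03
    #: probability of each state at start_age, shape (10,), zero mass on Dead
    initial_prevalence: np.ndarray = field(default=None)
    #: hook for factors (comorbidities, adherence, ...) not modelled explicitly
    extras: dict = field(default_factory=dict)

    # ------------------------------------------------------------------ basics
    @property
    def n_epochs(self) -> int:
        """Horizon T: quarterly epochs from start_age through end_age inclusive."""
        return int(round((self.end_age - self.start_age) * 4)) + 1

    def copy(self) -> "ParameterSet":
        new = dataclasses.replace(self)
        for name in ("egfr_decrement_schedule", "proteinuria_onset_hazard",
                     "mortality_hazard", "state_costs", "qaly_weights",
                     "initial_prevalence"):
            setattr(new, name, np.array(getattr(self, name), dtype=float))
        new.extras = dict(self.extras)
        return new

    def validate(self) -> None:
        dec = np.asarray(self.egfr_decrement_schedule, dtype=float)
        if dec.shape != (2, N_BANDS):
            raise ValueError(f"decrement schedule must be (2, {N_BANDS})")
        if np.any(dec < 0):
            raise ValueError("eGFR decrements must be non-negative")
        if np.any(np.diff(dec, axis=1) < -1e-12):
            raise ValueError("eGFR decrements must be non-decreasing in age")
        if np.any(dec[1] < dec[0] - 1e-12):
            raise ValueError("proteinuria-positive decrement must be >= negative")
        for name, arr, lo, hi in (
            ("proteinuria_onset_hazard", self.proteinuria_onset_hazard, 0, 1),
            ("mortality_hazard", self.mortality_hazard, 0, 1),
            ("qaly_weights", self.qaly_weights, 0, 0.25),
        ):
            a = np.asarray(arr, dtype=float)
            if np.any(a < lo) or np.any(a > hi):
                raise ValueError(f"{name} out of [{lo}, {hi}]")
        for name, val in (("esrd_entry_hazard", self.esrd_entry_hazard),
                          ("treatment_egfr_reduction", self.treatment_egfr_reduction),
                          ("treatment_proteinuria_reduction", self.treatment_proteinuria_reduction),
                          ("treatment_mortality_reduction", self.treatment_mortality_reduction),
                          ("test_sensitivity", self.test_sensitivity),
                          ("test_specificity", self.test_specificity)):
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if np.any(np.asarray(self.state_costs) < 0) or self.screening_cost < 0:
            raise ValueError("costs must be non-negative")
        prev = np.asarray(self.initial_prevalence, dtype=float)
        if prev.shape != (N_STATES,):
            raise ValueError("initial_prevalence must have length 10")
        if abs(prev.sum() - 1.0) > 1e-9 or np.any(prev < 0):
            raise ValueError("initial_prevalence must be a probability vector")
        if prev[DEAD - 1] != 0:
            raise ValueError("initial_prevalence must put zero mass on Dead")
        if not 0.0 <= self.annual_discount < 1.0:
            raise ValueError("annual_discount must be in [0, 1)")
        if self.wtp < 0:
            raise ValueError("wtp must be non-negative")
        if self.end_age <= self.start_age:
            raise ValueError("end_age must exceed start_age")

    # -------------------------------------------------------------- derived
    def quarterly_mortality(self) -> np.ndarray:
        return annual_to_quarterly(self.mortality_hazard)

    def quarterly_proteinuria_onset(self) -> np.ndarray:
        return annual_to_quarterly(self.proteinuria_onset_hazard)

    # --------------------------------------------------------- serialization
    _ARRAY_FIELDS = ("egfr_decrement_schedule", "proteinuria_onset_hazard",
                     "mortality_hazard", "state_costs", "qaly_weights",
                     "initial_prevalence")
    _SCALAR_FIELDS = ("start_age", "end_age", "esrd_entry_hazard", "screening_cost",
                      "treatment_egfr_reduction", "treatment_proteinuria_reduction",
                      "treatment_mortality_reduction", "test_sensitivity",
                      "test_specificity", "wtp", "annual_discount")

    def to_dict(self) -> dict:
        d = {"race": self.profile.race, "gender": self.profile.gender}
        for name in self._SCALAR_FIELDS:
            d[name] = float(getattr(self, name))
        for name in self._ARRAY_FIELDS:
            d[name] = np.asarray(getattr(self, name), dtype=float).tolist()
        d["extras"] = dict(self.extras)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        kwargs = {"profile": DemographicProfile(d["race"], d["gender"])}
        for name in cls._SCALAR_FIELDS:
            kwargs[name] = float(d[name])
        for name in cls._ARRAY_FIELDS:
            kwargs[name] = np.array(d[name], dtype=float)
        kwargs["extras"] = dict(d.get("extras", {}))
        return cls(**kwargs)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "ParameterSet":
        if hasattr(source, "read"):
            d = yaml.safe_load(source)
        else:
            try:
                with open(source) as fh:
                    d = yaml.safe_load(fh)
            except (OSError, ValueError):
                d = yaml.safe_load(io.StringIO(source))
        return cls.from_dict(d)

    def to_frame(self) -> pd.DataFrame:
        """Flat tabular form: one row per parameter x age-band x state cell."""
        rows = []
        d = self.to_dict()
        for name in ("race", "gender"):
            rows.append((name, -1, -1, d[name]))
        for name in self._SCALAR_FIELDS:
            rows.append((name, -1, -1, d[name]))
        dec = np.asarray(self.egfr_decrement_schedule)
        for p in (0, 1):
            for b in range(N_BANDS):
                rows.append(("egfr_decrement_schedule", b, p, dec[p, b]))
        for b in range(N_BANDS):
            rows.append(("proteinuria_onset_hazard", b, -1,
                         float(self.proteinuria_onset_hazard[b])))
            for s in range(N_STATES):
                rows.append(("mortality_hazard", b, s + 1,
                             float(self.mortality_hazard[b, s])))
        for s in range(N_STATES):
            rows.append(("state_costs", -1, s + 1, float(self.state_costs[s])))
            rows.append(("qaly_weights", -1, s + 1, float(self.qaly_weights[s])))
            rows.append(("initial_prevalence", -1, s + 1,
                         float(self.initial_prevalence[s])))
        return pd.DataFrame(rows, columns=["parameter", "age_band", "state", "value"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ParameterSet":
        get = lambda name: frame.loc[frame.parameter == name]
        d = {}
        d["race"] = get("race")["value"].iloc[0]
        d["gender"] = get("gender")["value"].iloc[0]
        for name in cls._SCALAR_FIELDS:
            d[name] = float(get(name)["value"].iloc[0])
        dec = np.zeros((2, N_BANDS))
        sub = get("egfr_decrement_schedule")
        for _, r in sub.iterrows():
            dec[int(r.state), int(r.age_band)] = float(r.value)
        d["egfr_decrement_schedule"] = dec.tolist()
        onset = np.zeros(N_BANDS)
        for _, r in get("proteinuria_onset_hazard").iterrows():
            onset[int(r.age_band)] = float(r.value)
        d["proteinuria_onset_hazard"] = onset.tolist()
        mort = np.zeros((N_BANDS, N_STATES))
        for _, r in get("mortality_hazard").iterrows():
            mort[int(r.age_band), int(r.state) - 1] = float(r.value)
        d["mortality_hazard"] = mort.tolist()
        for name in ("state_costs", "qaly_weights", "initial_prevalence"):
            vec = np.zeros(N_STATES)
            for _, r in get(name).iterrows():
                vec[int(r.state) - 1] = float(r.value)
            d[name] = vec.tolist()
        return cls.from_dict(d)


# --------------------------------------------------------------------------
# Synthetic defaults.  Magnitudes chosen to be clinically plausible for a
# diabetic cohort: decrements ~1-4 mL/min/yr rising with age, proteinuria
# onset 1-5 %/yr, per-state annual costs from the published CKD cost set with
# CKD5/ESRD at the registry-scale value.  These are NOT survey-derived.
# --------------------------------------------------------------------------

_BASE_DECREMENT_NOPROT = np.array([1.0, 1.3, 1.6, 2.0, 2.4])
_BASE_DECREMENT_PROT = np.array([1.8, 2.2, 2.7, 3.2, 3.8])
_BASE_ONSET = np.array([0.012, 0.016, 0.022, 0.030, 0.040])
_BASE_MORT_NORMAL = np.array([0.003, 0.006, 0.012, 0.028, 0.075])
#: mortality multiplier by state 1..9 (dead handled structurally)
_MORT_STATE_FACTOR = np.array([1.0, 1.05, 1.15, 1.4, 1.5, 2.2, 2.4, 4.5, 5.0])

#: annual per-state cost, USD.  States 2..9 follow the published per-stage
#: values ($12,505 / $17,049 / $18,263 / $25,048 for CKD 1-4 and $76,153 for
#: CKD 5 with ESRD); Normal carries a background diabetes-care cost.
_BASE_COSTS_ANNUAL = np.array(
    [4_000.0, 12_505.0, 17_049.0, 18_263.0, 18_263.0,
     25_048.0, 25_048.0, 76_153.0, 76_153.0, 0.0])

#: annual utility weight by state (diabetic baseline 0.90, declining by stage,
#: small proteinuria penalty).
_BASE_QALY_ANNUAL = np.array(
    [0.90, 0.88, 0.86, 0.81, 0.79, 0.73, 0.71, 0.62, 0.60, 0.0])

_INITIAL_PREVALENCE = {
    "White": np.array([0.920, 0.026, 0.026, 0.012, 0.008, 0.004, 0.003,
                       0.0006, 0.0004, 0.0]),
    "Black": np.array([0.895, 0.034, 0.034, 0.015, 0.010, 0.005, 0.004,
                       0.0018, 0.0012, 0.0]),
}

#: Black cohorts progress strictly faster than White at every age band.
_RACE_PROGRESSION_FACTOR = {"White": 1.0, "Black": 1.25}
_RACE_MORTALITY_FACTOR = {"White": 1.0, "Black": 1.12}
#: male mortality exceeds female mortality.
_GENDER_MORTALITY_FACTOR = {"Male": 1.0, "Female": 0.82}


def default_parameters(profile: DemographicProfile) -> ParameterSet:
    """Fully populated parameter set for one race/gender group.

    Uses every literature-printed value (WTP $150,000/QALY, 3% annual discount,
    treatment multipliers 0.327/0.55/0.23, perfect test characteristics, ages
    30-85, the published CKD stage cost set) and documented synthetic defaults
    elsewhere.
    """
    rp = _RACE_PROGRESSION_FACTOR[profile.race]
    rm = _RACE_MORTALITY_FACTOR[profile.race]
    gm = _GENDER_MORTALITY_FACTOR[profile.gender]
    dec = np.vstack([_BASE_DECREMENT_NOPROT, _BASE_DECREMENT_PROT]) * rp
    onset = np.clip(_BASE_ONSET * rp, 0.0, 1.0)
    mort = np.clip(np.outer(_BASE_MORT_NORMAL, _MORT_STATE_FACTOR) * rm * gm, 0.0, 0.95)
    mort = np.concatenate([mort, np.zeros((N_BANDS, 1))], axis=1)
    ps = ParameterSet(
        profile=profile,
        egfr_decrement_schedule=dec,
        proteinuria_onset_hazard=onset,
        mortality_hazard=mort,
        state_costs=_BASE_COSTS_ANNUAL / 4.0,
        qaly_weights=_BASE_QALY_ANNUAL / 4.0,
        initial_prevalence=_INITIAL_PREVALENCE[profile.race].copy(),
    )
    ps.validate()
    return ps


def sample_parameters(profile: DemographicProfile, seed: int,
                      jitter: float) -> ParameterSet:
    """Default set with each value perturbed multiplicatively by up to +-jitter.

    All :class:`ParameterSet` invariants are restored after perturbation
    (schedules re-monotonized, probabilities clipped, prevalence renormalized).
    Deterministic given ``seed``; ``jitter=0`` reproduces the defaults exactly.
    """
    if not 0.0 <= jitter <= 0.5:
        raise ValueError(f"jitter must be in [0, 0.5], got {jitter}")
    ps = default_parameters(profile)
    if jitter == 0.0:
        return ps
    rng = np.random.default_rng(seed)
    bump = lambda x: np.asarray(x, dtype=float) * (
        1.0 + rng.uniform(-jitter, jitter, size=np.shape(x)))

    dec = bump(ps.egfr_decrement_schedule)
    dec = np.maximum.accumulate(np.clip(dec, 0.0, None), axis=1)
    dec[1] = np.maximum(dec[1], dec[0])
    ps.egfr_decrement_schedule = dec
    ps.proteinuria_onset_hazard = np.clip(bump(ps.proteinuria_onset_hazard), 0.0, 1.0)
    ps.mortality_hazard = np.clip(bump(ps.mortality_hazard), 0.0, 1.0)
    ps.esrd_entry_hazard = float(np.clip(bump(ps.esrd_entry_hazard), 0.0, 1.0))
    ps.state_costs = np.clip(bump(ps.state_costs), 0.0, None)
    ps.screening_cost = float(np.clip(bump(ps.screening_cost), 0.0, None))
    ps.qaly_weights = np.clip(bump(ps.qaly_weights), 0.0, 0.25)
    for name in ("treatment_egfr_reduction", "treatment_proteinuria_reduction",
                 "treatment_mortality_reduction", "test_sensitivity",
                 "test_specificity"):
        setattr(ps, name, float(np.clip(bump(getattr(ps, name)), 0.0, 1.0)))
    ps.wtp = float(np.clip(bump(ps.wtp), 0.0, None))
    ps.annual_discount = float(np.clip(bump(ps.annual_discount), 0.0, 0.5))
    prev = np.clip(bump(ps.initial_prevalence), 0.0, None)
    prev[DEAD - 1] = 0.0
    ps.initial_prevalence = prev / prev.sum()
    ps.validate()
    return ps
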