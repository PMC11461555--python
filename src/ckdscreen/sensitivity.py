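"""Scenario engine: one-way and simultaneous sensitivity analyses.

The screening policy is solved once under base-case inputs and then
stress-tested: each scenario re-evaluates the *fixed* policy (and the annual
status quo) in a microsimulated world whose inputs are perturbed — treatment
effectiveness (20%/40% eGFR-decrement reduction instead of 32.7%), alternative
CKD cost sets (USRDS: $28,913 CKD 1-2, $30,780 CKD 3, $41,976 stages 4-5;
Honeycutt: $1,600/$1,700/$3,500/$12,700 for CKD 1-4 with base-case stage-5
costs), +10% eGFR decrements, willingness-to-pay of $50k or $100k per QALY,
an alternative QALY weight set, and an imperfect proteinuria test
(sensitivity 0.76, specificity 0.96) under the two-test algorithm.  The
simultaneous analysis draws all levers (except WTP, fixed at $150k) uniformly
and independently per replicate, 72 replicates by default, and reports
replicate-based 95% confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import scipy.stats

from .policy_eval import ComparisonReport, ScreeningPolicy, evaluate_policy_pair
from .synthetic_params import ParameterSet

TREATMENT_LEVELS = (0.20, 0.327, 0.40)
COST_SETS = ("base", "usrds", "honeycutt")
DECREMENT_LEVELS = (1.0, 1.1)
WTP_LEVELS = (50_000.0, 100_000.0, 150_000.0)
QALY_SETS = ("base", "alternative")
TEST_LEVELS = ("perfect", "imperfect")
IMPERFECT_TEST = (0.76, 0.96)

#: annual per-state costs (indexed by state 1..9) for the alternative sets;
#: ``None`` keeps the base-case value for that state.
_USRDS_ANNUAL = {2: 28_913.0, 3: 28_913.0, 4: 30_780.0, 5: 30_780.0,
                 6: 41_976.0, 7: 41_976.0, 8: 41_976.0, 9: 41_976.0}
_HONEYCUTT_ANNUAL = {2: 1_600.0, 3: 1_700.0, 4: 3_500.0, 5: 3_500.0,
                     6: 12_700.0, 7: 12_700.0}   # stage 5/ESRD stay at base

#: alternative annual QALY weights: smaller stage-to-stage decrements.
_ALT_QALY_ANNUAL = np.array(
    [0.92, 0.91, 0.90, 0.87, 0.86, 0.82, 0.81, 0.73, 0.72, 0.0])


@dataclass
class ScenarioConfig:
    """One sensitivity scenario: a level for every varied input."""

    treatment_egfr_reduction: float = 0.327
    cost_set: str = "base"
    egfr_decrement_multiplier: float = 1.0
    wtp: float = 150_000.0
    qaly_weight_set: str = "base"
    test_characteristics: str = "perfect"
    n_reps: int = 1
    seed: int = 0

    def __post_init__(self):
        checks = (
            ("treatment_egfr_reduction", self.treatment_egfr_reduction, TREATMENT_LEVELS),
            ("cost_set", self.cost_set, COST_SETS),
            ("egfr_decrement_multiplier", self.egfr_decrement_multiplier, DECREMENT_LEVELS),
            ("wtp", self.wtp, WTP_LEVELS),
            ("qaly_weight_set", self.qaly_weight_set, QALY_SETS),
            ("test_characteristics", self.test_characteristics, TEST_LEVELS),
        )
        for name, value, levels in checks:
            if value not in levels:
                raise ValueError(f"{name}={value!r} not in allowed levels {levels}")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")

    @property
    def is_base(self) -> bool:
        return (self.treatment_egfr_reduction == 0.327 and self.cost_set == "base"
                and self.egfr_decrement_multiplier == 1.0 and self.wtp == 150_000.0
                and self.qaly_weight_set == "base"
                and self.test_characteristics == "perfect")


def apply_scenario(base: ParameterSet, scenario: ScenarioConfig) -> ParameterSet:
    """Copy of the base parameter set with the scenario levels substituted.

    Side-effect free on the base set and idempotent (levels replace, never
    compound).
    """
    ps = base.copy()
    ps.treatment_egfr_reduction = scenario.treatment_egfr_reduction
    if scenario.cost_set != "base":
        table = _USRDS_ANNUAL if scenario.cost_set == "usrds" else _HONEYCUTT_ANNUAL
        costs = np.array(ps.state_costs, dtype=float)
        for state, annual in table.items():
            costs[state - 1] = annual / 4.0
        ps.state_costs = costs
    ps.egfr_decrement_schedule = (np.array(base.egfr_decrement_schedule)
                                  * scenario.egfr_decrement_multiplier)
    ps.wtp = scenario.wtp
    if scenario.qaly_weight_set == "alternative":
        ps.qaly_weights = _ALT_QALY_ANNUAL / 4.0
    if scenario.test_characteristics == "imperfect":
        ps.test_sensitivity, ps.test_specificity = IMPERFECT_TEST
    else:
        ps.test_sensitivity = ps.test_specificity = 1.0
    ps.validate()
    return ps


@dataclass
class ScenarioResult:
    """Outcomes of one scenario for both policies, with Monte-Carlo CIs."""

    name: str
    scenario: ScenarioConfig
    profile: str
    means: dict                 # policy -> {"nmb", "costs", "qalys"}
    ci_halfwidths: dict         # policy -> {"nmb", "costs", "qalys"}
    replicates: Optional[pd.DataFrame] = field(default=None, repr=False)

    @property
    def incremental_nmb(self) -> float:
        return self.means["pomdp"]["nmb"] - self.means["status_quo"]["nmb"]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for policy in ("status_quo", "pomdp"):
            row = {"scenario": self.name, "profile": self.profile, "policy": policy}
            for q in ("nmb", "costs", "qalys"):
                row[q] = self.means[policy][q]
                row[f"{q}_ci"] = self.ci_halfwidths[policy][q]
            rows.append(row)
        return pd.DataFrame(rows)


def _result_from_report(name: str, scenario: ScenarioConfig,
                        report: ComparisonReport) -> ScenarioResult:
    means, cis = {}, {}
    for policy, out in (("status_quo", report.outcome_status_quo),
                        ("pomdp", report.outcome_pomdp)):
        nmb = out.per_agent_nmb
        means[policy] = {"nmb": out.mean_nmb, "costs": out.mean_costs,
                        "qalys": out.mean_qalys}
        half = lambda x: float(1.96 * np.std(x, ddof=1) / np.sqrt(len(x)))
        cis[policy] = {"nmb": half(nmb), "costs": half(out.per_agent_costs),
                       "qalys": half(out.per_agent_qalys)}
    return ScenarioResult(name=name, scenario=scenario, profile=report.profile,
                          means=means, ci_halfwidths=cis)


def scenarios_from_yaml(source) -> dict:
    """Load named scenarios from a YAML document: {name: {lever: level, ...}}."""
    import yaml
    if hasattr(source, "read"):
        raw = yaml.safe_load(source)
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    return {name: ScenarioConfig(**(levels or {})) for name, levels in raw.items()}


ONE_WAY_SCENARIOS = {
    "treatment_20": {"treatment_egfr_reduction": 0.20},
    "treatment_40": {"treatment_egfr_reduction": 0.40},
    "cost_usrds": {"cost_set": "usrds"},
    "cost_honeycutt": {"cost_set": "honeycutt"},
    "decrement_plus10": {"egfr_decrement_multiplier": 1.1},
    "wtp_50k": {"wtp": 50_000.0},
    "wtp_100k": {"wtp": 100_000.0},
    "qaly_alternative": {"qaly_weight_set": "alternative"},
    "test_imperfect": {"test_characteristics": "imperfect"},
}


def run_one_way_suite(base: ParameterSet, policy: ScreeningPolicy, n: int,
                      seed: int, *, include_base: bool = True) -> dict:
    """Evaluate the fixed policy and the status quo under each one-way scenario.

    The policy is never re-solved; every scenario reuses the same cohort seed,
    so scenario contrasts share random numbers with the base case.
    """
    names = (["base"] if include_base else []) + list(ONE_WAY_SCENARIOS)
    results = {}
    for name in names:
        scenario = ScenarioConfig(**ONE_WAY_SCENARIOS.get(name, {}), seed=seed)
        params = apply_scenario(base, scenario)
        report = evaluate_policy_pair(params, policy, n, seed)
        results[name] = _result_from_report(name, scenario, report)
    return results


def run_simultaneous(base: ParameterSet, policy: ScreeningPolicy,
                     n_reps: int = 72, seed: int = 0, *,
                     n_per_rep: int = 1_000) -> ScenarioResult:
    """Simultaneous uncertainty analysis over all levers except WTP.

    Each replicate draws every lever uniformly and independently from its
    level set (WTP fixed at $150,000/QALY), simulates both policies with a
    replicate-specific cohort seed, and the result aggregates replicate means
    with 95% t-based confidence intervals.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2 for confidence intervals")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_reps):
        scenario = ScenarioConfig(
            treatment_egfr_reduction=float(rng.choice(TREATMENT_LEVELS)),
            cost_set=str(rng.choice(COST_SETS)),
            egfr_decrement_multiplier=float(rng.choice(DECREMENT_LEVELS)),
            wtp=150_000.0,
            qaly_weight_set=str(rng.choice(QALY_SETS)),
            test_characteristics=str(rng.choice(TEST_LEVELS)),
            seed=seed,
        )
        params = apply_scenario(base, scenario)
        rep_seed = int(rng.integers(0, 2**31 - 1))
        report = evaluate_policy_pair(params, policy, n_per_rep, rep_seed)
        row = {"replicate": rep,
               "treatment_egfr_reduction": scenario.treatment_egfr_reduction,
               "cost_set": scenario.cost_set,
               "egfr_decrement_multiplier": scenario.egfr_decrement_multiplier,
               "qaly_weight_set": scenario.qaly_weight_set,
               "test_characteristics": scenario.test_characteristics,
               "cohort_seed": rep_seed}
        for policy_name, out in (("status_quo", report.outcome_status_quo),
                                 ("pomdp", report.outcome_pomdp)):
            row[f"{policy_name}_nmb"] = out.mean_nmb
            row[f"{policy_name}_costs"] = out.mean_costs
            row[f"{policy_name}_qalys"] = out.mean_qalys
        rows.append(row)
    reps = pd.DataFrame(rows)

    tcrit = scipy.stats.t.ppf(0.975, df=n_reps - 1)
    means, cis = {}, {}
    for policy_name in ("status_quo", "pomdp"):
        means[policy_name], cis[policy_name] = {}, {}
        for q in ("nmb", "costs", "qalys"):
            x = reps[f"{policy_name}_{q}"].to_numpy()
            means[policy_name][q] = float(x.mean())
            cis[policy_name][q] = float(tcrit * x.std(ddof=1) / np.sqrt(n_reps))
    scenario = ScenarioConfig(n_reps=n_reps, seed=seed)
    return ScenarioResult(name="simultaneous", scenario=scenario,
                          profile=base.profile.key, means=means,
                          ci_halfwidths=cis, replicates=reps)
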