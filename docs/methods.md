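# Methods

## Overview

`ckdscreen` asks how often a diagnosed diabetic adult should be screened for
chronic kidney disease (CKD) between ages 30 and 85, by race and gender.  It
couples two models:

1. a **quarterly natural-history microsimulation** of eGFR decline,
   proteinuria onset, ESRD entry and death, which simulates lifetime
   trajectories under any screening policy and supplies the decision model's
   inputs; and
2. a **finite-horizon POMDP** over ten health states (Normal, CKD 1-5 split
   by proteinuria, Dead) with actions Screen/Wait every quarter
   (t = 1..T, T = 221; the final decision is at age 84.75), solved exactly by
   backward induction over the finite set of beliefs reachable from a single
   initial belief.

The objective is expected discounted net monetary benefit,
NMB = lambda x QALYs - costs, with willingness-to-pay
lambda = $150,000/QALY and a 3% annual discount applied as a per-quarter
factor gamma = (1.03)^(-1/4).

## Health states and staging

States follow KDIGO staging by eGFR with half-open intervals —
CKD5 [0,15), CKD4 [15,30), CKD3 [30,60), CKD2 [60,90), CKD1 [90,inf) — in
combination with persistent proteinuria.  eGFR >= 60 without proteinuria is
Normal (no latent CKD2 state; some clinical definitions differ, but the
staging table used here treats kidney damage as required below the 60
threshold).  The mapping (eGFR, proteinuria) -> state is therefore a
partition, tested at every boundary.

## Microsimulation

Each agent carries continuous eGFR, proteinuria / treatment / ESRD flags and
discounted accruals.  Within a quarter, events occur in a fixed order
(required for reproducibility; the underlying biology does not order them):
mortality draw, eGFR decline, proteinuria onset, ESRD entry from CKD5, then
cost and QALY accrual for the quarter at discount gamma^(t-1), using the
post-progression state.  Annual hazards convert to quarterly ones as
q = 1 - (1-p)^(1/4) (constant hazard within the year); quarterly QALY weight
is the annual utility / 4 with no half-cycle correction.  Proteinuria and
treatment never revert, eGFR never rises, death is absorbing; these are
asserted as trajectory invariants in the tests.

Treatment (started when a screen reveals CKD stage 3+, i.e. measured
eGFR < 60) multiplies the eGFR decrement by 1 - 0.327, quarterly proteinuria
onset by 1 - 0.55, and quarterly mortality by 1 - 0.23.

A screen measures eGFR exactly and runs **two proteinuria tests**, positive
if at least one is positive; the diagnosed state combines the exact eGFR with
the composite proteinuria result.  With the base-case perfect test this
reproduces the true state (the POMDP's identity observation matrix).  With
imperfect characteristics (sensitivity 0.76, specificity 0.96 per test) a
truly proteinuric patient is mis-reported with probability (1-0.76)^2 =
0.0576 and a healthy one receives a false-positive proteinuria label with
probability 1 - 0.96^2 = 0.0784.  eGFR is measured concurrently with the
proteinuria tests, as in routine practice where both are part of one
screening panel; consequently CKD stage 3+ without proteinuria is still
detectable and the perfect-test screen is exactly the identity observation.

**Randomness.**  Every agent consumes an independent random stream keyed by
(cohort seed, agent id) with a fixed draw layout (five uniforms per quarter,
drawn whether used or not).  Results are independent of iteration order and
block size, and two policies share trajectories until their decisions
diverge, giving common-random-number pairing for free.  A test verifies that
scalar agent-by-agent stepping reproduces the vectorized engine exactly.

## POMDP construction

- **Transitions** p^t_ij are empirical quarterly frequencies from a
  no-screening cohort (untreated, and treated-from-entry for the treated
  matrices), row-normalized per epoch, with death forced absorbing and
  proteinuria-reversal entries structural zeros.  Unvisited rows default to
  identity and are flagged unobserved; for solving, each such row is borrowed
  from the nearest epoch at which that state was observed
  (`fill_unobserved_rows`), because some states are structurally vacated at
  some ages (no one retains eGFR >= 90 late in life) and frozen identity
  rows would mislead the belief dynamics.  Because disease is monotone
  (states are never re-entered from below), the state-and-epoch-conditional
  transition rates are policy-invariant, so matrices estimated without
  screening apply unchanged under any screening policy.
- **Observations**: identity screen matrix in the base case; Alive/Dead for
  waiting.  The imperfect-test composite observation model exists for
  evaluation and exploratory solving but the base-case policy is solved
  under perfect observation and stress-tested with imperfect tests in the
  microsimulation, mirroring how the sensitivity analysis is designed.
- **Stage rewards** r^t(i,a): quarterly QALY x lambda minus quarterly state
  cost for both actions, minus the screening cost (the only Screen/Wait
  difference — an invariant the assembler validates).  Waiting must carry
  the health accrual: a reward of zero for waiting would make survival
  worthless.  No testing disutility is applied.
- **Terminal rewards** R^t(s), s in 4..9: mean discounted NMB of agents
  starting treatment in state s at epoch t, simulated to death or age 85,
  estimated on an annual grid of start epochs and linearly interpolated.
  Entrant eGFR is drawn from just below the stage threshold (within one
  year's decline of the band edge): treatment follows a positive screen, and
  under screening at roughly guideline frequency a newly detected patient
  has recently crossed the threshold.  Everything terminates at age 85, so
  the horizon table R^T(s) is identically zero and the model optimizes NMB
  accrued over ages 30-85; this keeps the decision model and its
  microsimulation evaluation on exactly the same accounting.

One deliberate approximation: the solver's stage reward uses the epoch-t
state while the microsimulation accrues the post-progression state within
each quarter — a one-quarter staging offset that is policy-independent to
first order.

## Solution method

From the single initial belief (the group's state prevalence at age 30),
breadth-first expansion over both actions and all positive-probability
observations produces the reachable belief set per epoch; beliefs equal
within 1e-9 (max-norm, by quantization) merge.  Screens observing states 4-9
terminate with the terminal reward (treatment initiation), death observations
terminate with zero, and the horizon pays the belief-weighted R^T.  Backward
induction then computes exact values; ties within 1e-9 break toward Wait
(minimal intervention at equal value).  Under perfect observation each
reachable belief is characterized by (last observed state, epochs since last
screen), which is the key of the exported policy lookup table and the
sufficient statistic used when simulating the policy.

Values are kept in USD without scaling (magnitudes ~1e6 are comfortably
inside double precision).  The solver is validated against two independent
oracles on random small instances: a literal enumeration of every
history-dependent policy (T <= 3) and a cache-free recursion on the Bellman
equations (100 instances, <= 4 states, <= 4 epochs, agreement to 1e-9).
Off-graph beliefs (e.g. a patient first seen at age 50) are outside the
solved policy; the spec can be re-rooted at any epoch/belief and re-solved,
but no default is assigned.

## Policy evaluation and reporting

The annual status-quo comparator screens every 4th epoch from the first.
Screening frequency is reported per **process-year**: model years start at
integer ages; a year enters the denominator when the agent is alive,
undiagnosed and in-process at the year's first decision epoch, and screens
within counted years form the numerator.  This makes the annual policy's
frequency exactly 1 (and every-epoch screening exactly 4 absent mid-year
exit), so the metric is anchored to the guideline it compares against.
Averted cases are (cases without - cases with the intervention) per 100,000.
Threshold-age summaries ("starts screening at least every X years") use
sustained attainment: the earliest screen from which every later inter-screen
gap stays at or below the threshold.  Population totals multiply per-person
deltas by 43 million adults aged 30-39, 3% diabetic, with group shares
23.65 / 22.17 / 30.54 / 22.17%.

## Synthetic parameter sets

The natural-history and economic inputs that national survey and registry
data would normally supply are synthetic defaults, chosen once to be
clinically plausible and clearly separated from literature-printed values
(WTP, discount, treatment multipliers, test characteristics, the published
per-stage cost sets):

- eGFR decrements rise from 1.0 to 2.4 mL/min/1.73m^2/yr across decade bands
  (1.8-3.8 with proteinuria); Black cohorts are 25% faster at every band.
- proteinuria onset rises from 1.2%/yr to 4%/yr with age.
- all-cause mortality rises from 0.3%/yr to 7.5%/yr in the Normal state with
  stage multipliers up to 5x for CKD5; male mortality exceeds female
  (x 1/0.82) and Black exceeds White (x 1.12).
- annual state costs use the published per-stage set ($12,505 / $17,049 /
  $18,263 / $25,048 for CKD 1-4 and $76,153 for CKD 5 with ESRD) plus a
  $4,000 background diabetes-care cost for the Normal state; screening costs
  $75.
- annual utilities decline from 0.90 (diabetic, no CKD) to 0.60 (CKD5 with
  proteinuria); the alternative sensitivity set uses smaller stage
  decrements (0.92 down to 0.72).
- initial state prevalence at age 30 is ~92% Normal for White and ~89.5% for
  Black cohorts with the remainder spread over CKD 1-5.

`sample_parameters` perturbs every default multiplicatively (up to +-50%)
while restoring all invariants, for property testing.

What the generator does **not** emulate: calibration to registry or survey
targets, explicit comorbidity attributes (hypertension, smoking,
cardiovascular disease enter only implicitly through the hazard and cost
schedules, with an `extras` extension hook), kidney transplantation or
dialysis modality, background (non-screening) diagnosis of symptomatic
late-stage disease, and diabetes onset (all agents are diagnosed diabetics
throughout).  Passing tests therefore demonstrate correctness of the
machinery and the model's internal logic, not agreement with US
epidemiology: absolute NMB/QALY levels and case counts in `results/` are
properties of this synthetic world.

## Sensitivity engine

Scenarios substitute levels into a copy of the base parameter set: treatment
effectiveness {20%, 32.7%, 40%}; cost sets {base, USRDS, Honeycutt} (USRDS:
$28,913 CKD 1-2, $30,780 CKD 3, $41,976 for stages 4-5 applied to states
6-9 since the source aggregates stages 4, 5 and ESRD; Honeycutt: $1,600 /
$1,700 / $3,500 / $12,700 for CKD 1-4 with base-case stage-5 costs); eGFR
decrements x1.1; WTP {$50k, $100k, $150k}; QALY sets {base, alternative};
test characteristics {perfect, (0.76, 0.96)}.  The solved policy is **not**
re-solved per scenario — the design question is robustness of the fixed
policy.  The simultaneous analysis draws all levers except WTP uniformly and
independently (72 replicates by default, configurable; per-replicate cohort
size is configuration with no canonical value) and reports t-based 95%
confidence intervals over replicates.

## Numerical choices and problem sizes

- dedup tolerance 1e-9 (beliefs are exactly reproducible under perfect
  observation; the tolerance only absorbs float noise); tie tolerance 1e-9.
- zero-probability observations raise rather than renormalize a zero vector.
- transition estimation uses 20,000 agents per treatment arm and terminal
  rewards 1,000 agents per (state, annual-grid epoch) cell in the analysis
  scripts; tests use smaller cohorts with Monte-Carlo error bounds (3
  standard errors) where sampling noise enters.
- the full 221-epoch solve enumerates ~63,000 belief nodes and takes a few
  seconds; cohort simulation is vectorized over agents in blocks of 20,000.

## Known limitations

- The ten-state abstraction discards within-band eGFR position.  The
  transition tensor is exact for the undiagnosed process (monotone disease
  makes state-and-epoch-conditional rates policy-invariant), so the
  approximation is concentrated in the terminal rewards: R^t(s) assumes
  newly detected patients sit within one year's decline of the stage
  threshold, which matches roughly-annual screening but understates the
  severity of patients detected after long gaps and overstates it under
  very frequent screening.  More fundamentally, delaying a diagnosis
  degrades the patient *within* a band (eGFR 45 -> 40 is still CKD3 but a
  markedly worse treated prognosis), a cost no state-only terminal reward
  can represent.  In this synthetic world that within-band delay cost
  dominates: the solved policy — which screens sparsely before age 50 —
  evaluates a few thousand dollars per person *below* annual screening in
  the microsimulation even though it is optimal inside its own model, and
  the loss traces to agents whose diagnosis it delays by two or more years
  at young ages.  The analysis scripts report both the model value and the
  microsimulated value so this gap is visible.  A self-consistent fixed
  point — re-estimating terminal rewards from the detection distribution the
  solved policy induces, then re-solving — or a finer eGFR discretization
  are natural extensions not pursued here.
- Terminal rewards for states 1-3 are undefined (treatment never starts
  there) and stored as zero.
- The approximate national policy is a deterministic frequency schedule; it
  discards the history dependence that gives the belief-based policy its
  edge.
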