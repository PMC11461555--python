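"""Stress-test the fixed solved policy under perturbed model inputs.

One-way scenarios (treatment effectiveness 20/40%, USRDS and Honeycutt cost
sets, +10% eGFR decrements, WTP $50k/$100k, alternative QALY weights,
imperfect proteinuria testing) and the simultaneous 72-replicate uniform
variation, for each demographic group.  The policy is never re-solved: the
question is whether the base-case policy remains preferable when the world
differs from the model that produced it.  Cohorts of 4,000 per scenario and
1,000 per simultaneous replicate.
"""

from pathlib import Path

import pandas as pd

from ckdscreen import (
    ALL_PROFILES,
    POMDPSpec,
    PolicyTreePolicy,
    default_parameters,
    run_one_way_suite,
    run_simultaneous,
    solve,
)

ROOT = Path(__file__).resolve().parent.parent / "results"
N_ONE_WAY, N_PER_REP, N_REPS, SEED = 4_000, 1_000, 72, 515


def main() -> None:
    out = ROOT / "sensitivity"
    out.mkdir(parents=True, exist_ok=True)
    frames, sim_frames = [], []
    for profile in ALL_PROFILES:
        params = default_parameters(profile)
        slug = profile.key.lower().replace(" ", "_")
        policy = PolicyTreePolicy(
            solve(POMDPSpec.from_json(ROOT / "pomdp" / f"{slug}.json")))

        suite = run_one_way_suite(params, policy, N_ONE_WAY, SEED)
        frames.extend(r.to_frame() for r in suite.values())
        worst = min(suite.values(), key=lambda r: r.incremental_nmb)
        print(f"{profile.key}: incremental NMB ranges "
              f"${worst.incremental_nmb:,.0f} ({worst.name}) to "
              f"${max(r.incremental_nmb for r in suite.values()):,.0f}")

        sim = run_simultaneous(params, policy, n_reps=N_REPS, seed=SEED,
                               n_per_rep=N_PER_REP)
        sim.replicates.to_csv(out / f"{slug}_simultaneous_replicates.csv",
                              index=False)
        sim_frames.append(sim.to_frame())
        ci = sim.ci_halfwidths
        print(f"  simultaneous ({N_REPS} reps): incremental NMB "
              f"${sim.incremental_nmb:,.0f}; QALY CIs +-"
              f"{ci['pomdp']['qalys']:.3f} (POMDP) / "
              f"+-{ci['status_quo']['qalys']:.3f} (SQ)")

    pd.concat(frames, ignore_index=True).to_csv(out / "one_way_suite.csv",
                                                index=False)
    pd.concat(sim_frames, ignore_index=True).to_csv(
        out / "simultaneous_summary.csv", index=False)
    print(f"\nwrote scenario tables to {out}")


if __name__ == "__main__":
    main()
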