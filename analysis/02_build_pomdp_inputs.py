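"""Microsimulate CKD natural history and estimate the POMDP inputs.

For each demographic group, estimates the quarterly transition tensor from a
no-screening cohort (untreated and treated-from-entry), fills structurally
unobservable rows from the nearest observed epoch, estimates terminal rewards
(discounted remaining NMB at treatment start, by epoch and state), and stores
the assembled POMDP. Problem sizes: 20,000 agents for transitions, 1,000 per
terminal-reward cell on an annual epoch grid.
"""

from pathlib import Path

from ckdscreen import (
    ALL_PROFILES,
    assemble_pomdp,
    default_parameters,
    estimate_terminal_rewards,
    estimate_transition_tensor,
    fill_unobserved_rows,
)
from ckdscreen.microsim import terminal_rewards_frame

ROOT = Path(__file__).resolve().parent.parent / "results"
N_TENSOR, N_TERMINAL, SEED = 20_000, 1_000, 20260923


def main() -> None:
    out = ROOT / "pomdp"
    out.mkdir(parents=True, exist_ok=True)
    for profile in ALL_PROFILES:
        params = default_parameters(profile)
        slug = profile.key.lower().replace(" ", "_")
        tensor = fill_unobserved_rows(
            estimate_transition_tensor(params, N_TENSOR, SEED))
        terminal = estimate_terminal_rewards(params, N_TERMINAL, SEED + 1)
        spec = assemble_pomdp(params, tensor, terminal)
        spec.to_json(out / f"{slug}.json")
        terminal_rewards_frame(terminal).to_csv(
            out / f"{slug}_terminal_rewards.csv", index=False)
        print(f"{profile.key}: POMDP with T={spec.horizon} stored; "
              f"terminal reward at entry, CKD3 w/o proteinuria: "
              f"${terminal[0, 3]:,.0f}")
    print(f"\nwrote POMDP inputs to {out}")


if __name__ == "__main__":
    main()
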