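"""Baseline behaviour of the MITF-PIAS3-STAT3 model.

Computes the resting steady state at baseline kinase inputs, checks the
closed-form RSK1 phosphorylation fraction, and simulates the canonical
activation transients (stepping phospho-ERK and phospho-JAK from 10 to
1000 au).  Writes tidy CSVs under results/.

Findings (printed on run): at rest the three proteins sit at comparable
total levels (hundreds of au), about 9.1% of RSK1 is phosphorylated
(= 0.004/0.044 exactly), and strong MAPK+JAK activation drives MITF into
its phosphorylated forms within ~30 minutes while phospho-STAT3 rises
roughly tenfold.
"""

from pathlib import Path

import numpy as np

from pias3net import (
    InputSchedule,
    STATE_NAMES,
    find_steady_state,
    make_default_parameters,
    simulate,
)
from pias3net.model import phospho_mitf, total_mitf, total_pias3, total_stat3

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    params = make_default_parameters("methods")
    rest = find_steady_state(params)

    print("== resting steady state (ERKp = JAKp = 10 au) ==")
    for name, value in zip(STATE_NAMES, rest):
        print(f"  {name:16s} {value:10.4g}")
    totals = {"MITF": total_mitf(rest), "PIAS3": total_pias3(rest),
              "STAT3": total_stat3(rest)}
    print("  totals:", {k: round(v, 1) for k, v in totals.items()})
    print(f"  RSK1p fraction: {rest[10] / params.RSK1_total:.5f} "
          f"(closed form {0.004 / 0.044:.5f})")

    import pandas as pd

    pd.DataFrame({"state": STATE_NAMES, "amount": rest}).to_csv(
        OUT / "baseline_steady_state.csv", index=False)

    traj = simulate(params, InputSchedule.constant(1000, 1000), rest, 120.0)
    frame = traj.to_frame()
    frame.to_csv(OUT / "activation_trajectory.csv", index=False)
    frac30 = phospho_mitf(traj.state_at(30.0)) / total_mitf(traj.state_at(30.0))
    print("\n== activation: ERKp, JAKp 10 -> 1000 ==")
    print(f"  phosphorylated MITF fraction at 30 min: {frac30:.3f}")
    print(f"  phospho-STAT3: {rest[12]:.2f} -> {traj.final_state[12]:.2f} au "
          f"at 120 min")
    print(f"\nwrote {OUT / 'baseline_steady_state.csv'} and "
          f"{OUT / 'activation_trajectory.csv'}")


if __name__ == "__main__":
    main()
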