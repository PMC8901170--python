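#!/usr/bin/env python
"""Generate the synthetic session library used by the downstream analyses.

Builds one control-like population (mostly opponent neurons: positive
running drive, balanced negative flow drive, mismatch impulses) and one
knockout-like population (mostly additively coupled neurons), records
each under closed-loop-with-mismatches, open-loop, dark, and grating
conditions, and writes the sessions as HDF5 plus a session inventory
CSV under results/sessions/.
"""

import argparse
from pathlib import Path

import pandas as pd

from visuomotor import (
    generate_behavior,
    generate_grating_session,
    generate_population,
    insert_mismatches,
    render_calcium,
    session_io,
)

MIXES = {
    "control": {"opponent": 0.6, "visual": 0.3, "coupled": 0.1},
    "knockout": {"opponent": 0.1, "visual": 0.3, "coupled": 0.6},
}
DURATION_S = 600.0
DT = 0.1
N_NEURONS = 100


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", type=Path, default=Path("results/sessions"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    inventory = []
    for g, (group, mix) in enumerate(MIXES.items()):
        models = generate_population(N_NEURONS, mix, seed=args.seed + g)
        for c, condition in enumerate(("closed_loop", "open_loop", "dark", "grating")):
            seed = args.seed + 10 * g + 100 * c
            if condition == "grating":
                behavior, events = generate_grating_session(DURATION_S, DT, seed=seed)
            else:
                behavior = generate_behavior(DURATION_S, DT, condition, seed=seed)
                events = None
                if condition == "closed_loop":
                    behavior, events = insert_mismatches(behavior, 2.0, seed=seed + 1)
            session = render_calcium(models, behavior, events, seed=seed + 2)
            path = args.outdir / f"{group}_{condition}.h5"
            session_io.write_session(path, session)
            inventory.append(
                {
                    "group": group,
                    "condition": condition,
                    "file": path.name,
                    "n_neurons": session.n_neurons,
                    "n_events": len(session.events),
                    "duration_s": behavior.duration_s,
                }
            )
            print(f"wrote {path} ({len(session.events)} events)")
    frame = pd.DataFrame(inventory)
    frame.to_csv(args.outdir / "inventory.csv", index=False)
    print(f"\n{len(frame)} sessions; inventory at {args.outdir / 'inventory.csv'}")


if __name__ == "__main__":
    main()
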