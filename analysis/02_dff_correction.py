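#!/usr/bin/env python
"""Demonstrate ΔF/F drift correction on synthetic raw fluorescence.

Takes noiseless ground-truth ΔF/F activity from the generator, embeds
it in raw fluorescence with slow multiplicative drift (bleaching-like)
and shot-like noise, runs the 8th-percentile / 100 s rolling-baseline
correction, and reports how well the known activity is recovered.
Writes per-neuron recovery statistics to results/dff_recovery.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from visuomotor import (
    compute_dff,
    generate_behavior,
    generate_population,
    insert_mismatches,
    render_calcium,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    behavior = generate_behavior(600.0, 0.1, "closed_loop", seed=args.seed)
    behavior, events = insert_mismatches(behavior, 2.0, seed=args.seed + 1)
    models = generate_population(
        20, {"opponent": 0.6, "visual": 0.3, "coupled": 0.1},
        seed=args.seed + 2, noise_sd=0.0,
    )
    truth = render_calcium(models, behavior, events).traces

    rng = np.random.default_rng(args.seed + 3)
    n = truth.shape[1]
    t = np.arange(n) * 0.1
    rows = []
    raw_all = np.empty_like(truth)
    for i, dff in enumerate(truth):
        f0 = rng.uniform(80.0, 150.0)
        drift = 1.0 - 0.2 * t / t[-1] + 0.05 * np.sin(2 * np.pi * t / 300.0)
        raw_all[i] = f0 * drift * (1.0 + dff) + rng.normal(0.0, 0.02 * f0, n)
    recovered = compute_dff(raw_all, dt=0.1)
    for i in range(truth.shape[0]):
        r = np.corrcoef(recovered[i], truth[i])[0, 1]
        rows.append({"neuron": i, "pearson_r_truth": r,
                     "rms_error": float(np.sqrt(np.mean((recovered[i] - truth[i]) ** 2)))})
    frame = pd.DataFrame(rows)
    frame.to_csv(args.outdir / "dff_recovery.csv", index=False)
    print(f"median correlation with ground-truth activity: {frame['pearson_r_truth'].median():.3f}")
    print(f"median RMS error (ΔF/F): {frame['rms_error'].median():.4f}")
    print(f"wrote {args.outdir / 'dff_recovery.csv'}")


if __name__ == "__main__":
    main()
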