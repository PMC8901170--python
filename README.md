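# visuomotor

Analyses for studying **visuomotor integration in mouse primary visual
cortex (V1)** with two-photon calcium imaging and virtual-reality
behavior, together with a synthetic-data generator that reproduces the
statistical structure those analyses assume.

In a closed-loop virtual environment, locomotion drives backward visual
flow. L2/3 neurons in V1 integrate the two streams: many carry opposing
motor-related excitation and visually driven inhibition, respond to
brief halts of visual flow during running (*visuomotor mismatch*, a
negative prediction-error signal), and show suppression of
running-onset activity when visual feedback is present. This package
implements the quantities used to characterize that circuit, and a
simulator of the adaptive virtual-corridor navigation task used to
probe visuomotor skill:

- **ΔF/F processing** — slow-drift correction with an 8th-percentile
  rolling filter (100 s window) and normalization by the trace median:
  `dff = (F − P8(F)) / median(F)`.
- **Event-triggered responses** — averages around mismatch, grating,
  and running onsets (baseline −0.3–0 s, response +0.1–1.5 s); session
  exclusion when a session has fewer than three running or mismatch
  onsets; the **suppression index**, the dark-minus-closed-loop
  running-onset response in the 2.5–3.5 s window.
- **Correlation geometry** — per-neuron Pearson correlations of
  activity with visual flow and with running speed in the open-loop
  (playback) condition; mean pairwise correlation between neurons; the
  **PC angle**, the signed angle between the first principal component
  of the (r_flow, r_run) scatter and the running-correlation axis.
  Opponent (subtractive) populations sit near −45°, additively coupled
  populations near +45°.
- **Navigation task** — an elongating virtual corridor whose length is
  multiplied every four trials by clamp(20 s / mean duration, 1, 1.5),
  capped at 400% of the day-1 length; random ±30° heading-offset
  perturbations at 20–80% of the corridor; the **performance index**

  PI = (∫cos θ(t) · v(t) dt / ∫v(t) dt) × (time running / total time),

  with θ the angle between the running direction and the direction to
  the target; and the perturbation-learning metric (left-minus-right
  turning response in the +1–3 s window, late minus early in training).
- **Optogenetic protocol arithmetic** — pulse schedule (1 s on / 4 s
  off → 0.2 Hz, 20% duty), time-averaged power density of a 3 mm-FWHM
  disk beam shared across hemispheres, exponential depth attenuation,
  and the >2-puncta positivity rule for in situ hybridization counts.
- **Synthetic sessions** — spontaneous running bouts, closed-loop /
  open-loop / dark / grating conditions, 1 s flow halts, and neurons
  whose ΔF/F is a calcium-kernel-filtered linear mixture of running
  drive, flow drive, and event impulses, with stored ground truth for
  recovery tests.

## Worked example

```python
import numpy as np
from visuomotor import *
from visuomotor.synthetic import BehaviorTraces

# a 10-minute closed-loop session with 1 s mismatches, and its dark twin
beh = generate_behavior(600, dt=0.1, condition="closed_loop", seed=41)
dark = BehaviorTraces(beh.t, beh.running_speed, np.zeros(len(beh)), "dark", beh.dt)
beh, events = insert_mismatches(beh, rate_per_min=2.0, seed=42)

# 50 opponent neurons: positive running drive, balanced flow inhibition
models = generate_population(50, {"opponent": 1.0}, seed=42, noise_sd=0.05)
closed = render_calcium(models, beh, events, seed=43)

onsets = detect_running_onsets(beh.running_speed, beh.dt)
eta_cl = baseline_subtract(event_triggered_average(closed, onsets))
eta_dk = baseline_subtract(event_triggered_average(render_calcium(models, dark, seed=44), onsets))
sup = suppression_index(eta_dk, eta_cl)
print(f"{onsets.size} running onsets, mean suppression {sup.mean():+.3f} ΔF/F")
```

prints

```
12 running onsets, mean suppression +0.292 ΔF/F
```

a positive suppression index: in the closed-loop condition the visual
flow coupled to running suppresses the sustained motor-related
response that persists in darkness.

The numbered scripts under `analysis/` run the full narrative —
session generation, ΔF/F recovery, group response comparisons,
correlation geometry, navigation learning, and protocol arithmetic —
writing tables to `results/`:

```bash
python analysis/01_simulate_sessions.py --seed 1
python analysis/03_event_responses.py --seed 1
...
```

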