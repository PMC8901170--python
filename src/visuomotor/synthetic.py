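"""Synthetic virtual-reality sessions with known ground truth.

Generates the kind of data the downstream analyses assume: a head-fixed
animal running spontaneously on a treadmill while a virtual corridor
provides visual flow that is either coupled to locomotion (closed loop),
replayed from an earlier closed-loop episode (open loop), absent (dark),
or replaced by drifting-grating stimuli. Neuronal calcium traces are a
noisy, kernel-filtered linear mixture of running drive, visual-flow drive,
and impulse responses at mismatch and grating onsets, so every statistic
the analysis modules estimate has a generative counterpart that recovery
tests can check against.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

CONDITIONS = ("closed_loop", "open_loop", "dark", "grating")

ARCHETYPES = ("opponent", "visual", "coupled")

#: Default calcium indicator decay (s), GCaMP6f-like.
DEFAULT_TAU_CA = 0.6

#: Default frame interval (s); 10 Hz effective frame rate.
DEFAULT_DT = 0.1


@dataclass(frozen=True)
class BoutParams:
    """Parameters of the alternating rest/run bout process.

    ``rate_per_min`` is the rate at which running bouts are initiated
    while the animal is at rest (so mean rest duration is 60/rate
    seconds); ``mean_bout_s`` is the mean running-bout duration; the
    speed profile within a bout is a Gaussian bump peaking at
    ``speed_scale`` cm/s.
    """

    rate_per_min: float = 3.0
    mean_bout_s: float = 10.0
    speed_scale: float = 15.0

    def __post_init__(self) -> None:
        if self.rate_per_min < 0:
            raise ValueError("bout rate must be non-negative")
        if self.mean_bout_s <= 0 or self.speed_scale < 0:
            raise ValueError("mean bout duration must be positive and speed non-negative")

    @property
    def run_occupancy(self) -> float:
        """Stationary fraction of time in the running state."""
        if self.rate_per_min == 0:
            return 0.0
        mean_rest = 60.0 / self.rate_per_min
        return self.mean_bout_s / (self.mean_bout_s + mean_rest)


@dataclass
class BehaviorTraces:
    """Time base, running speed, and visual flow for one session."""

    t: np.ndarray
    running_speed: np.ndarray
    visual_flow: np.ndarray
    condition: str
    dt: float
    gain: float = 1.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.running_speed = np.asarray(self.running_speed, dtype=float)
        self.visual_flow = np.asarray(self.visual_flow, dtype=float)
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        n = len(self.t)
        if len(self.running_speed) != n or len(self.visual_flow) != n:
            raise ValueError("behavior arrays must have equal length")
        for name in ("t", "running_speed", "visual_flow"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite values in {name}")
        if np.any(self.running_speed < 0) or np.any(self.visual_flow < 0):
            raise ValueError("speed and flow must be non-negative")
        if self.condition == "dark" and np.any(self.visual_flow != 0):
            raise ValueError("dark condition must have zero visual flow")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration_s(self) -> float:
        return len(self.t) * self.dt

    def copy(self) -> "BehaviorTraces":
        return replace(
            self,
            t=self.t.copy(),
            running_speed=self.running_speed.copy(),
            visual_flow=self.visual_flow.copy(),
        )


EVENT_KINDS = ("mismatch", "grating_onset", "grating_offset", "running_onset", "perturbation")


@dataclass
class EventTable:
    """Flat table of timestamped session events with per-event attributes."""

    kind: list[str] = field(default_factory=list)
    time: np.ndarray = field(default_factory=lambda: np.empty(0))
    attrs: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if not (len(self.kind) == len(self.time) == len(self.attrs)):
            raise ValueError("kind, time and attrs must have equal length")
        for k in self.kind:
            if k not in EVENT_KINDS:
                raise ValueError(f"unknown event kind {k!r}")

    def __len__(self) -> int:
        return len(self.time)

    def times_of(self, kind: str) -> np.ndarray:
        """Sorted onset times of all events of the given kind."""
        sel = np.array([k == kind for k in self.kind], dtype=bool)
        if not sel.any():
            return np.empty(0)
        return np.sort(self.time[sel])

    def count(self, kind: str) -> int:
        return sum(k == kind for k in self.kind)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "kind": self.kind,
                "time": self.time,
                "attrs": [json.dumps(a) for a in self.attrs],
            }
        )

    @staticmethod
    def concat(tables: Sequence["EventTable"]) -> "EventTable":
        kind: list[str] = []
        attrs: list[dict] = []
        times: list[np.ndarray] = []
        for tab in tables:
            kind.extend(tab.kind)
            attrs.extend(tab.attrs)
            times.append(tab.time)
        return EventTable(kind, np.concatenate(times) if times else np.empty(0), attrs)


@dataclass(frozen=True)
class NeuronModel:
    """Generative weights of one simulated neuron.

    ``w_run``/``w_flow`` are linear gains (ΔF/F per cm/s) on running
    speed and visual flow; ``m_amp``/``v_amp`` are impulse amplitudes
    (ΔF/F) applied at mismatch and grating onsets; the drive is filtered
    with an exp(−t/``tau_ca``) calcium kernel and white noise of SD
    ``noise_sd`` is added.
    """

    w_run: float
    w_flow: float
    m_amp: float = 0.0
    v_amp: float = 0.0
    tau_ca: float = DEFAULT_TAU_CA
    noise_sd: float = 0.05
    archetype: str = ""

    def __post_init__(self) -> None:
        if self.tau_ca <= 0:
            raise ValueError("tau_ca must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class SessionData:
    """One simulated or recorded session: behavior, events, traces."""

    behavior: BehaviorTraces
    events: EventTable
    traces: np.ndarray  # neurons x time
    dt: float
    is_dff: bool = True
    ground_truth: list[NeuronModel] | None = None

    def __post_init__(self) -> None:
        self.traces = np.atleast_2d(np.asarray(self.traces, dtype=float))
        if self.traces.shape[1] != len(self.behavior):
            raise ValueError("trace time dimension must match behavior length")
        if not np.all(np.isfinite(self.traces)):
            raise ValueError("non-finite values in traces")
        if abs(self.dt - self.behavior.dt) > 1e-12:
            raise ValueError("dt mismatch between traces and behavior")

    @property
    def n_neurons(self) -> int:
        return self.traces.shape[0]


def _bout_speed(n: int, dt: float, params: BoutParams, rng: np.random.Generator) -> np.ndarray:
    """Alternating exponential rest/run bouts with Gaussian speed bumps."""
    speed = np.zeros(n)
    if params.rate_per_min == 0 or params.speed_scale == 0:
        return speed
    mean_rest = 60.0 / params.rate_per_min
    t = 0.0
    duration = n * dt
    while t < duration:
        t += rng.exponential(mean_rest)
        bout = rng.exponential(params.mean_bout_s)
        i0 = int(np.ceil(t / dt))
        i1 = min(int(np.floor((t + bout) / dt)), n - 1)
        if i1 >= i0 and i0 < n:
            idx = np.arange(i0, i1 + 1)
            centre = (t + bout / 2.0) / dt
            sigma = max(bout / 4.0, dt) / dt
            speed[idx] = params.speed_scale * np.exp(-0.5 * ((idx - centre) / sigma) ** 2)
        t += bout
    return speed


def generate_behavior(
    duration_s: float,
    dt: float = DEFAULT_DT,
    condition: str = "closed_loop",
    bout_params: BoutParams | None = None,
    gain: float = 1.0,
    seed: int | None = None,
) -> BehaviorTraces:
    """Generate running speed and visual flow for one session.

    Running is an alternating rest/run bout process (spontaneous running
    on the treadmill). Visual flow depends on the condition: coupled to
    speed by ``gain`` in closed loop, an independently drawn bout trace
    in open loop (standing in for replayed self-generated flow), and
    identically zero in darkness and during grating blocks (gratings are
    events, not flow).
    """
    if duration_s <= 0 or dt <= 0:
        raise ValueError("duration_s and dt must be positive")
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    params = bout_params if bout_params is not None else BoutParams()
    rng = np.random.default_rng(seed)
    n = int(round(duration_s / dt))
    t = np.arange(n) * dt
    speed = _bout_speed(n, dt, params, rng)
    if condition == "closed_loop":
        flow = gain * speed
    elif condition == "open_loop":
        flow = gain * _bout_speed(n, dt, params, rng)
    else:
        flow = np.zeros(n)
    return BehaviorTraces(t, speed, flow, condition, dt, gain)


def insert_mismatches(
    behavior: BehaviorTraces,
    rate_per_min: float,
    duration_s: float = 1.0,
    seed: int | None = None,
    edge_guard_s: float = 2.0,
) -> tuple[BehaviorTraces, EventTable]:
    """Halt visual flow for ``duration_s`` at Poisson-random times.

    Only defined for closed-loop sessions: a mismatch is a transient
    breach of the locomotion/flow coupling. The number of mismatches is
    Poisson with mean ``rate_per_min x session minutes``; onsets are
    placed uniformly away from session edges and never overlap.
    """
    if behavior.condition != "closed_loop":
        raise ValueError("mismatches are only defined for closed-loop sessions")
    if rate_per_min < 0:
        raise ValueError("rate must be non-negative")
    rng = np.random.default_rng(seed)
    out = behavior.copy()
    total = behavior.duration_s
    n_target = rng.poisson(rate_per_min * total / 60.0)
    lo = edge_guard_s
    hi = total - edge_guard_s - duration_s
    onsets: list[float] = []
    if n_target > 0 and hi > lo:
        tries = 0
        while len(onsets) < n_target and tries < 1000 * n_target:
            cand = rng.uniform(lo, hi)
            if all(abs(cand - o) >= duration_s for o in onsets):
                onsets.append(cand)
            tries += 1
    onsets.sort()
    for onset in onsets:
        i0 = int(np.ceil(onset / behavior.dt - 1e-9))
        i1 = int(np.ceil((onset + duration_s) / behavior.dt - 1e-9))
        out.visual_flow[i0:i1] = 0.0
    events = EventTable(
        ["mismatch"] * len(onsets),
        np.asarray(onsets),
        [{"duration_s": duration_s} for _ in onsets],
    )
    return out, events


def generate_grating_session(
    duration_s: float,
    dt: float = DEFAULT_DT,
    directions: Sequence[float] = (0.0, 45.0, 90.0, 270.0),
    seed: int | None = None,
    bout_params: BoutParams | None = None,
    on_range_s: tuple[float, float] = (3.0, 8.0),
    gap_range_s: tuple[float, float] = (2.0, 6.0),
) -> tuple[BehaviorTraces, EventTable]:
    """Grating block: random-direction drifting gratings with gray gaps.

    Stimulus durations are uniform on ``on_range_s`` and inter-trial
    gray gaps uniform on ``gap_range_s``; directions are sampled
    uniformly from ``directions`` per presentation. The animal keeps
    running spontaneously; no visual flow is associated with gratings.
    """
    if len(directions) == 0:
        raise ValueError("direction list must be non-empty")
    if duration_s < on_range_s[0]:
        raise ValueError("duration too short for a single stimulus epoch")
    rng = np.random.default_rng(seed)
    behavior = generate_behavior(
        duration_s, dt, "grating", bout_params,
        seed=rng.integers(0, 2**31 - 1),
    )
    kind: list[str] = []
    times: list[float] = []
    attrs: list[dict] = []
    t = 0.0
    first = True
    while True:
        hi = min(on_range_s[1], duration_s - t) if first else on_range_s[1]
        if hi < on_range_s[0]:
            break
        on = rng.uniform(on_range_s[0], hi)
        if t + on > duration_s:
            break
        direction = float(rng.choice(np.asarray(directions, dtype=float)))
        kind += ["grating_onset", "grating_offset"]
        times += [t, t + on]
        attrs += [{"direction": direction}, {"direction": direction}]
        t += on + rng.uniform(*gap_range_s)
        first = False
    if not kind:
        raise ValueError("duration too short for a single stimulus epoch")
    return behavior, EventTable(kind, np.asarray(times), attrs)


def _largest_remainder_counts(n: int, fractions: Sequence[float]) -> list[int]:
    raw = [n * f for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    remainder = n - sum(counts)
    order = np.argsort([-(r - np.floor(r)) for r in raw], kind="stable")
    for j in range(remainder):
        counts[order[j]] += 1
    return counts


def generate_population(
    n: int,
    archetype_mix: Mapping[str, float],
    seed: int | None = None,
    noise_sd: float = 0.05,
    tau_ca: float = DEFAULT_TAU_CA,
) -> list[NeuronModel]:
    """Draw neuron models from a mixture of response archetypes.

    ``opponent`` neurons have positive running drive, balanced negative
    flow drive of matched magnitude, and a mismatch impulse (the
    configuration associated with negative prediction errors);
    ``visual`` neurons are flow/grating driven; ``coupled`` neurons
    carry same-sign running and flow drive of matched magnitude
    (additive integration, as after development without visuomotor
    coupling). Matching the run/flow magnitudes per neuron — strong
    neurons are strong in both channels — is what stretches the
    correlation scatter along the negative (opponent) or positive
    (coupled) diagonal. Counts follow the requested fractions exactly
    up to largest-remainder rounding.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    keys = list(archetype_mix)
    for key in keys:
        if key not in ARCHETYPES:
            raise ValueError(f"unknown archetype {key!r}")
        if not 0.0 <= archetype_mix[key] <= 1.0:
            raise ValueError("archetype fractions must be within [0, 1]")
    if abs(sum(archetype_mix.values()) - 1.0) > 1e-9:
        raise ValueError("archetype fractions must sum to 1")
    rng = np.random.default_rng(seed)
    counts = _largest_remainder_counts(n, [archetype_mix[k] for k in keys])
    models: list[NeuronModel] = []
    for key, count in zip(keys, counts):
        for _ in range(count):
            # per-neuron drive magnitude, shared by both channels; the
            # spread against the noise floor keeps correlations off the
            # unit circle, as in real data
            amp = rng.uniform(0.0005, 0.012)
            if key == "opponent":
                model = NeuronModel(
                    w_run=amp * rng.uniform(0.9, 1.1),
                    w_flow=-amp * rng.uniform(0.9, 1.1),
                    m_amp=rng.uniform(0.2, 0.6),
                    v_amp=rng.uniform(0.0, 0.1),
                    tau_ca=tau_ca,
                    noise_sd=noise_sd,
                    archetype=key,
                )
            elif key == "visual":
                model = NeuronModel(
                    w_run=rng.normal(0.0, 0.002),
                    w_flow=amp * rng.uniform(0.9, 1.1),
                    m_amp=0.0,
                    v_amp=rng.uniform(0.2, 0.6),
                    tau_ca=tau_ca,
                    noise_sd=noise_sd,
                    archetype=key,
                )
            else:  # coupled
                model = NeuronModel(
                    w_run=amp * rng.uniform(0.9, 1.1),
                    w_flow=amp * rng.uniform(0.9, 1.1),
                    m_amp=rng.uniform(0.0, 0.1),
                    v_amp=rng.uniform(0.0, 0.1),
                    tau_ca=tau_ca,
                    noise_sd=noise_sd,
                    archetype=key,
                )
            models.append(model)
    return models


def calcium_kernel(tau_ca: float, dt: float, n_tau: float = 10.0) -> np.ndarray:
    """Discrete single-exponential calcium kernel, k[i] = exp(-i dt / tau)."""
    if tau_ca <= 0 or dt <= 0:
        raise ValueError("tau_ca and dt must be positive")
    m = max(int(np.ceil(n_tau * tau_ca / dt)), 1)
    return np.exp(-np.arange(m) * dt / tau_ca)


def kernel_gain(tau_ca: float, dt: float) -> float:
    """Steady-state trace value produced by a unit constant drive."""
    return float(calcium_kernel(tau_ca, dt).sum())


def render_calcium(
    models: Sequence[NeuronModel],
    behavior: BehaviorTraces,
    events: EventTable | None = None,
    seed: int | None = None,
) -> SessionData:
    """Render ΔF/F traces for a population given behavior and events.

    Per neuron the instantaneous drive is ``w_run * speed + w_flow *
    flow`` plus an impulse of ``m_amp`` at each mismatch onset and
    ``v_amp`` at each grating onset; the drive is convolved with the
    neuron's exponential calcium kernel (so an impulse of amplitude a
    peaks at a) and white Gaussian noise is added.
    """
    if len(models) == 0:
        raise ValueError("models must be non-empty")
    events = events if events is not None else EventTable()
    rng = np.random.default_rng(seed)
    n_t = len(behavior)
    dt = behavior.dt
    # first frame at or after the event time, matching the flow-halt convention
    mm_idx = np.ceil(events.times_of("mismatch") / dt - 1e-9).astype(int)
    gr_idx = np.ceil(events.times_of("grating_onset") / dt - 1e-9).astype(int)
    mm_idx = mm_idx[(mm_idx >= 0) & (mm_idx < n_t)]
    gr_idx = gr_idx[(gr_idx >= 0) & (gr_idx < n_t)]
    traces = np.empty((len(models), n_t))
    for i, m in enumerate(models):
        drive = m.w_run * behavior.running_speed + m.w_flow * behavior.visual_flow
        if mm_idx.size:
            drive[mm_idx] += m.m_amp
        if gr_idx.size:
            drive[gr_idx] += m.v_amp
        kernel = calcium_kernel(m.tau_ca, dt)
        trace = np.convolve(drive, kernel)[:n_t]
        if m.noise_sd > 0:
            trace = trace + rng.normal(0.0, m.noise_sd, n_t)
        traces[i] = trace
    return SessionData(behavior, events, traces, dt, is_dff=True, ground_truth=list(models))
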