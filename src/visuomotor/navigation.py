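"""Adaptive virtual-corridor navigation task and its performance metrics.

A simulated agent (standing in for a head-fixed mouse on a spherical
treadmill) steers through an elongating virtual corridor toward a water
reward at the far end. Task difficulty adapts: every four trials the
corridor length is multiplied by clamp(target_time / mean trial
duration, 1, 1.5), capped at 400% of the first-day length, so reward
rate stays roughly constant as the agent improves. Once per trial the
virtual heading is instantaneously offset by +-30 deg at a random
position in the middle of the corridor, probing corrective steering.

Performance is summarised by the performance index

    PI = (sum_i cos(theta_i) v_i dt / sum_i v_i dt) * (time running / total time)

where theta is the angle between the instantaneous movement direction
and the direction to the target and v the running speed: the fraction
of distance travelled toward the target, discounted when the agent
rarely runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Speed threshold (units/s) below which the agent counts as stationary;
#: the same threshold used for running-onset detection on the treadmill.
RUNNING_THRESHOLD = 1e-2


@dataclass(frozen=True)
class TaskConfig:
    """Virtual-corridor task parameters.

    Distances are in arbitrary corridor units; the corridor width is
    fixed at ``initial_length / length_to_width_ratio`` while the
    length elongates with performance.
    """

    initial_length: float = 60.0
    length_to_width_ratio: float = 5.0
    target_time_s: float = 20.0
    update_every_n_trials: int = 4
    factor_bounds: tuple[float, float] = (1.0, 1.5)
    max_length_factor: float = 4.0
    perturb_angle_deg: float = 30.0
    perturb_position_range: tuple[float, float] = (0.2, 0.8)
    reward_iti_s: float = 5.0
    trial_timeout_s: float = 120.0
    dt: float = 0.05
    running_threshold: float = RUNNING_THRESHOLD

    def __post_init__(self) -> None:
        if self.initial_length <= 0 or self.length_to_width_ratio <= 0:
            raise ValueError("corridor dimensions must be positive")
        if not self.factor_bounds[0] <= self.factor_bounds[1]:
            raise ValueError("factor bounds must be ordered")
        lo, hi = self.perturb_position_range
        if not 0.0 < lo < hi < 1.0:
            raise ValueError("perturbation position range must lie within (0, 1)")
        if self.perturb_angle_deg <= 0:
            raise ValueError("perturbation angle must be positive")
        if self.dt <= 0 or self.trial_timeout_s <= 0:
            raise ValueError("dt and timeout must be positive")

    @property
    def width(self) -> float:
        return self.initial_length / self.length_to_width_ratio


@dataclass(frozen=True)
class AgentParams:
    """Steering agent standing in for the mouse.

    The agent runs in alternating bouts (mean run bout
    ``mean_run_bout_s``; rest bouts scaled so the long-run running
    fraction is ``run_fraction``), steers its intended heading toward
    the target at rate ``corrective_gain`` with white rotational noise
    of SD ``heading_noise_sd`` (deg per sqrt-second), and corrects
    perturbation-induced heading offsets at the separate rate
    ``perturb_corrective_gain`` — the quantity that improves as animals
    learn the task.
    """

    speed: float = 15.0
    run_fraction: float = 0.8
    heading_noise_sd: float = 30.0
    corrective_gain: float = 1.0
    perturb_corrective_gain: float = 1.0
    mean_run_bout_s: float = 8.0

    def __post_init__(self) -> None:
        if self.speed < 0:
            raise ValueError("speed must be non-negative")
        if not 0.0 <= self.run_fraction <= 1.0:
            raise ValueError("run_fraction must be in [0, 1]")
        if self.corrective_gain < 0 or self.perturb_corrective_gain < 0:
            raise ValueError("gains must be non-negative")


@dataclass
class TrialRecord:
    """One navigation trial: trajectory, headings, and metadata."""

    positions: np.ndarray          # (n, 2) x/y in corridor units
    headings: np.ndarray           # deg, 0 = toward corridor end, + = rightward
    speeds: np.ndarray             # units/s
    duration_s: float
    corridor_length: float
    dt: float
    perturbation: dict | None = None   # {"time": s, "sign": +-1, "position_frac": f}
    outcome: str = "reward"            # "reward" | "timeout"


@dataclass(frozen=True)
class PerfResult:
    """Performance index with an all-stationary flag."""

    pi: float
    stationary: bool = False


def length_update_factor(
    last_n_durations: np.ndarray,
    config: TaskConfig | None = None,
) -> float:
    """Clamped corridor elongation factor from the last block of trials.

    factor = clamp(target_time / mean(durations), factor_bounds): a
    block finished at the target pace leaves the corridor unchanged; a
    block twice as fast as target saturates at a 50% elongation.
    """
    config = config if config is not None else TaskConfig()
    durations = np.asarray(last_n_durations, dtype=float)
    if durations.size != config.update_every_n_trials:
        raise ValueError(
            f"expected {config.update_every_n_trials} durations, got {durations.size}"
        )
    if np.any(durations <= 0):
        raise ValueError("trial durations must be positive")
    factor = config.target_time_s / float(durations.mean())
    lo, hi = config.factor_bounds
    return float(min(max(factor, lo), hi))


def update_corridor_length(
    last_n_durations: np.ndarray,
    current_length: float,
    initial_length: float,
    config: TaskConfig | None = None,
) -> float:
    """Apply the adaptive-difficulty rule, capped at 400% of day-1 length."""
    config = config if config is not None else TaskConfig()
    factor = length_update_factor(last_n_durations, config)
    return float(min(current_length * factor, config.max_length_factor * initial_length))


def _wrap_deg(a: float) -> float:
    return (a + 180.0) % 360.0 - 180.0


def simulate_trial(
    agent: AgentParams,
    corridor_length: float,
    config: TaskConfig,
    rng: np.random.Generator,
    perturb_position_frac: float | None = None,
    perturb_sign: int | None = None,
) -> TrialRecord:
    """Simulate one trial; perturbation parameters default to random.

    Heading dynamics per step: the intended heading (displayed heading
    minus any uncorrected perturbation offset) drifts toward the
    direction of the corridor-end target at ``corrective_gain`` with
    additive rotational noise; a perturbation instantaneously adds
    ``+-perturb_angle_deg`` to the displayed heading, and that offset
    decays at ``perturb_corrective_gain``. Walls clamp the lateral
    position; the trial ends at the corridor end (reward) or at the
    timeout.
    """
    dt = config.dt
    width = config.width
    max_steps = int(round(config.trial_timeout_s / dt))
    if perturb_position_frac is None:
        perturb_position_frac = rng.uniform(*config.perturb_position_range)
    if perturb_sign is None:
        perturb_sign = int(rng.choice((-1, 1)))
    noise = rng.standard_normal(max_steps) * agent.heading_noise_sd * math.sqrt(dt)

    # running bout state machine
    running = rng.random() < agent.run_fraction
    if agent.run_fraction <= 0.0:
        mean_rest = math.inf
        running = False
    elif agent.run_fraction >= 1.0:
        mean_rest = 0.0
        running = True
    else:
        mean_rest = agent.mean_run_bout_s * (1.0 - agent.run_fraction) / agent.run_fraction
    switch_at = rng.exponential(agent.mean_run_bout_s if running else mean_rest) if math.isfinite(mean_rest) else math.inf

    x, y = 0.0, 0.0
    heading = 0.0
    offset = 0.0
    perturbation: dict | None = None
    xs = [x]
    ys = [y]
    hs = [heading]
    vs = [agent.speed if running else 0.0]
    outcome = "timeout"
    perturb_y = perturb_position_frac * corridor_length
    t = 0.0
    for step in range(max_steps):
        # perturbation triggers once, on reaching the drawn corridor position
        if perturbation is None and y >= perturb_y:
            heading += perturb_sign * config.perturb_angle_deg
            offset += perturb_sign * config.perturb_angle_deg
            perturbation = {
                "time": t,
                "sign": perturb_sign,
                "position_frac": perturb_position_frac,
            }
        target_dir = math.degrees(math.atan2(-x, corridor_length - y))
        intended = heading - offset
        steer = -agent.corrective_gain * _wrap_deg(intended - target_dir)
        correction = -agent.perturb_corrective_gain * offset
        heading += (steer + correction) * dt + noise[step]
        offset += -agent.perturb_corrective_gain * offset * dt
        v = agent.speed if running else 0.0
        x += v * math.sin(math.radians(heading)) * dt
        y += v * math.cos(math.radians(heading)) * dt
        x = min(max(x, -width / 2.0), width / 2.0)
        y = max(y, 0.0)
        t += dt
        xs.append(x)
        ys.append(y)
        hs.append(heading)
        vs.append(v)
        if math.isfinite(switch_at) and t >= switch_at:
            running = not running
            mean = agent.mean_run_bout_s if running else mean_rest
            switch_at = t + rng.exponential(mean)
        if y >= corridor_length:
            outcome = "reward"
            break
    return TrialRecord(
        positions=np.column_stack([xs, ys]),
        headings=np.asarray(hs),
        speeds=np.asarray(vs),
        duration_s=t,
        corridor_length=corridor_length,
        dt=dt,
        perturbation=perturbation,
        outcome=outcome,
    )


def simulate_session(
    agent: AgentParams,
    config: TaskConfig | None = None,
    n_trials: int = 100,
    seed: int | None = None,
) -> list[TrialRecord]:
    """Run a session of trials under the adaptive-difficulty controller.

    The corridor starts at ``initial_length`` and is updated every
    ``update_every_n_trials`` trials from that block's durations
    (timeout trials contribute the timeout duration, so the controller
    sees slow performance). Exactly one heading perturbation occurs per
    trial at a uniform position within the configured range, with
    equiprobable sign.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be positive")
    config = config if config is not None else TaskConfig()
    rng = np.random.default_rng(seed)
    length = config.initial_length
    trials: list[TrialRecord] = []
    block: list[float] = []
    for _ in range(n_trials):
        trial = simulate_trial(agent, length, config, rng)
        trials.append(trial)
        block.append(trial.duration_s if trial.outcome == "reward" else config.trial_timeout_s)
        if len(block) == config.update_every_n_trials:
            length = update_corridor_length(block, length, config.initial_length, config)
            block = []
    return trials


def performance_index(
    positions: np.ndarray,
    dt: float,
    target: tuple[float, float],
    config: TaskConfig | None = None,
) -> PerfResult:
    """Performance index of one trajectory.

    Velocities come from finite differences of the positions; theta_i is
    the angle between the step velocity and the vector from the current
    position to ``target``. A trajectory that never moves gets PI = 0
    with the ``stationary`` flag set rather than an error.
    """
    config = config if config is not None else TaskConfig()
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 2 or positions.shape[1] != 2 or positions.shape[0] < 2:
        raise ValueError("positions must be (n, 2) with n >= 2")
    if dt <= 0:
        raise ValueError("dt must be positive")
    num, den, run_time = _pi_terms(positions, dt, target, config.running_threshold)
    total_time = (positions.shape[0] - 1) * dt
    if den == 0.0:
        return PerfResult(0.0, stationary=True)
    return PerfResult((num / den) * (run_time / total_time))


def _pi_terms(
    positions: np.ndarray,
    dt: float,
    target: tuple[float, float],
    threshold: float,
) -> tuple[float, float, float]:
    """Accumulators for the PI: weighted cosine, total path, running time."""
    vel = np.diff(positions, axis=0) / dt
    speed = np.hypot(vel[:, 0], vel[:, 1])
    to_target = np.asarray(target, dtype=float) - positions[:-1]
    dist = np.hypot(to_target[:, 0], to_target[:, 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_theta = (vel * to_target).sum(axis=1) / (speed * dist)
    cos_theta = np.where(speed * dist > 0, cos_theta, np.where(speed > 0, 1.0, 0.0))
    num = float((cos_theta * speed).sum() * dt)
    den = float(speed.sum() * dt)
    run_time = float((speed > threshold).sum() * dt)
    return num, den, run_time


def _trial_pi_terms(trial: TrialRecord, threshold: float) -> tuple[float, float, float]:
    """PI accumulators from ball motion (heading and treadmill speed).

    The running direction is the virtual heading and v the treadmill
    speed, so steering error counts even while a corridor wall clamps
    the virtual lateral position.
    """
    pos = trial.positions[:-1]
    to_target = np.array([0.0, trial.corridor_length]) - pos
    target_dir = np.degrees(np.arctan2(to_target[:, 0], to_target[:, 1]))
    cos_theta = np.cos(np.radians(trial.headings[1:] - target_dir))
    v = trial.speeds[1:]
    num = float((cos_theta * v).sum() * trial.dt)
    den = float(v.sum() * trial.dt)
    run_time = float((v > threshold).sum() * trial.dt)
    return num, den, run_time


def session_performance(
    trials: list[TrialRecord],
    config: TaskConfig | None = None,
) -> PerfResult:
    """Session-level PI accumulated over all trials' samples.

    Uses ball motion (heading direction, treadmill speed) as the
    running direction and speed entering the index.
    """
    config = config if config is not None else TaskConfig()
    if not trials:
        raise ValueError("no trials")
    num = den = run_time = total = 0.0
    for trial in trials:
        n, d, r = _trial_pi_terms(trial, config.running_threshold)
        num += n
        den += d
        run_time += r
        total += (trial.positions.shape[0] - 1) * trial.dt
    if den == 0.0:
        return PerfResult(0.0, stationary=True)
    return PerfResult((num / den) * (run_time / total))


def turning_response(
    trial: TrialRecord,
    window: tuple[float, float] = (1.0, 3.0),
) -> float | None:
    """Cumulative heading change after the perturbation, averaged over a window.

    Heading change is measured relative to the last pre-perturbation
    sample, so the instantaneous offset itself is part of the response;
    returns None when the trial has no perturbation or ended before the
    window completed.
    """
    if trial.perturbation is None:
        return None
    onset_idx = int(round(trial.perturbation["time"] / trial.dt))
    lo = onset_idx + int(round(window[0] / trial.dt))
    hi = onset_idx + int(round(window[1] / trial.dt))
    if hi >= trial.headings.size or onset_idx < 1:
        return None
    ref = trial.headings[onset_idx]  # sample recorded before the offset applied
    return float(np.mean(trial.headings[lo : hi + 1]) - ref)


def _epoch_metric(trials: list[TrialRecord], window: tuple[float, float]) -> float:
    left = []
    right = []
    for trial in trials:
        resp = turning_response(trial, window)
        if resp is None:
            continue
        (left if trial.perturbation["sign"] < 0 else right).append(resp)
    if not left or not right:
        raise ValueError("epoch lacks left or right perturbation trials")
    return float(np.mean(left) - np.mean(right))


def perturbation_response(
    trials: list[TrialRecord],
    window: tuple[float, float] = (1.0, 3.0),
    split: tuple[slice, slice] | None = None,
) -> dict:
    """Perturbation-learning metric: late minus early corrective turning.

    Per epoch the metric is mean(left-perturbation turning response)
    minus mean(right-perturbation response); an agent that corrects the
    offsets pulls this difference toward zero from its uncorrected value
    of about -2x the offset angle, so late-minus-early is positive when
    corrective steering improves over the session. By default early/late
    are the first and last quarters of trials.
    """
    if split is None:
        q = max(len(trials) // 4, 1)
        split = (slice(0, q), slice(len(trials) - q, len(trials)))
    early = _epoch_metric(trials[split[0]], window)
    late = _epoch_metric(trials[split[1]], window)
    return {"early": early, "late": late, "learning": late - early}
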