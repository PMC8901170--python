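"""Event-triggered responses, onset scalars, QC, and the suppression index.

The central object is the event-triggered average (``Eta``): ΔF/F
snippets around event onsets are averaged over events for each neuron,
and population summaries then average over neurons. Scalar onset
responses subtract a short pre-onset baseline window from a response
window; the suppression index compares running-onset responses between
darkness and the closed-loop condition in a late window, where coupled
visual flow suppresses sustained motor-related activity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import SessionData

Window = tuple[float, float]


@dataclass(frozen=True)
class ResponseWindows:
    """Analysis windows in seconds relative to event onset.

    Windows are half-open, [start, end): the baseline window ending at
    0 therefore excludes the onset sample itself.
    """

    baseline: Window = (-0.3, 0.0)
    response: Window = (0.1, 1.5)
    suppression: Window = (2.5, 3.5)
    perturbation: Window = (1.0, 3.0)

    def __post_init__(self) -> None:
        for name in ("baseline", "response", "suppression", "perturbation"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} window must have start < end")
        if self.baseline[1] > self.response[0]:
            raise ValueError("baseline window must precede response window")


@dataclass(frozen=True)
class OnsetCriteria:
    """Running-onset detection: threshold plus persistence requirements.

    An onset is an upward crossing of ``speed_threshold`` preceded by at
    least ``min_quiescence_s`` below threshold and followed by at least
    ``min_running_s`` above it. The persistence requirements guard
    against jitter around the (very low) threshold.
    """

    speed_threshold: float = 1e-2
    min_quiescence_s: float = 1.0
    min_running_s: float = 1.0

    def __post_init__(self) -> None:
        if self.speed_threshold <= 0:
            raise ValueError("speed threshold must be positive")
        if self.min_quiescence_s < 0 or self.min_running_s < 0:
            raise ValueError("durations must be non-negative")


@dataclass
class Eta:
    """Event-triggered average: one mean snippet per neuron."""

    time: np.ndarray          # s relative to onset
    mean: np.ndarray          # neurons x time
    n_events: int
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.mean = np.atleast_2d(np.asarray(self.mean, dtype=float))
        if self.mean.shape[1] != self.time.size:
            raise ValueError("mean and time axis length mismatch")
        if self.n_events < 1:
            raise ValueError("Eta requires at least one retained event")

    def window_mask(self, window: Window) -> np.ndarray:
        """Boolean mask of samples in the half-open window [lo, hi)."""
        lo, hi = window
        eps = 1e-9
        mask = (self.time >= lo - eps) & (self.time < hi - eps)
        if not mask.any():
            raise ValueError(f"window {window} outside Eta time span")
        return mask

    def window_mean(self, window: Window) -> np.ndarray:
        """Per-neuron mean over a time window."""
        return self.mean[:, self.window_mask(window)].mean(axis=1)


def detect_running_onsets(
    speed: np.ndarray,
    dt: float,
    criteria: OnsetCriteria | None = None,
) -> np.ndarray:
    """Return times (s) of running onsets satisfying the criteria."""
    criteria = criteria if criteria is not None else OnsetCriteria()
    speed = np.asarray(speed, dtype=float)
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not np.all(np.isfinite(speed)):
        raise ValueError("non-finite speed values")
    above = speed > criteria.speed_threshold
    q = int(round(criteria.min_quiescence_s / dt))
    r = int(round(criteria.min_running_s / dt))
    onsets = []
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    n = speed.size
    for i in crossings:
        if i - q < 0 or i + r > n:
            continue
        if q > 0 and above[i - q : i].any():
            continue
        if r > 0 and not above[i : i + r].all():
            continue
        onsets.append(i * dt)
    return np.asarray(onsets)


def event_triggered_average(
    session: SessionData,
    event_times: np.ndarray,
    pre_s: float = 1.0,
    post_s: float = 4.0,
) -> Eta:
    """Average ΔF/F snippets over events, per neuron.

    Events whose full [-pre_s, +post_s] window does not fit inside the
    recording are dropped (and counted in ``n_dropped``), never padded.
    """
    event_times = np.asarray(event_times, dtype=float)
    if event_times.size == 0:
        raise ValueError("no events given")
    dt = session.dt
    pre_n = int(round(pre_s / dt))
    post_n = int(round(post_s / dt))
    n_t = session.traces.shape[1]
    snippets = []
    dropped = 0
    for t0 in event_times:
        idx = int(round(t0 / dt))
        if idx - pre_n < 0 or idx + post_n + 1 > n_t:
            dropped += 1
            continue
        snippets.append(session.traces[:, idx - pre_n : idx + post_n + 1])
    if not snippets:
        raise RuntimeError("all events fell outside the recording bounds")
    time = np.arange(-pre_n, post_n + 1) * dt
    mean = np.mean(snippets, axis=0)
    return Eta(time, mean, n_events=len(snippets), n_dropped=dropped)


def baseline_subtract(eta: Eta, window: Window = (-0.3, 0.0)) -> Eta:
    """Subtract each neuron's mean over the baseline window."""
    base = eta.window_mean(window)
    return Eta(eta.time.copy(), eta.mean - base[:, None], eta.n_events, eta.n_dropped)


def onset_response(eta: Eta, windows: ResponseWindows | None = None) -> np.ndarray:
    """Per-neuron onset response: response-window mean minus baseline mean."""
    windows = windows if windows is not None else ResponseWindows()
    return eta.window_mean(windows.response) - eta.window_mean(windows.baseline)


def population_response(per_neuron: np.ndarray) -> tuple[float, float]:
    """Population summary: mean over neurons and SEM across neurons."""
    per_neuron = np.asarray(per_neuron, dtype=float)
    n = per_neuron.size
    sem = float(per_neuron.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
    return float(per_neuron.mean()), sem


@dataclass(frozen=True)
class QCResult:
    include: bool
    reason: str = ""


def session_qc(event_counts: dict[str, int], min_events: int = 3) -> QCResult:
    """Include/exclude a session based on event counts.

    A session is excluded when it has fewer than ``min_events`` running
    or mismatch onsets (only for the event kinds present in
    ``event_counts``: a dark session carries no mismatch count).
    """
    for kind in ("running_onset", "mismatch"):
        if kind in event_counts:
            count = event_counts[kind]
            if count < 0:
                raise ValueError("event counts must be non-negative")
            if count < min_events:
                return QCResult(
                    False, f"only {count} {kind} events (< {min_events} required)"
                )
    return QCResult(True)


def suppression_index(
    eta_dark: Eta,
    eta_closed_loop: Eta,
    windows: ResponseWindows | None = None,
) -> np.ndarray:
    """Per-neuron visual-flow suppression of running-onset activity.

    Difference between the running-onset response in darkness and in
    the closed-loop condition over the late (default 2.5-3.5 s) window.
    Both inputs must share a time axis and be baseline-subtracted with
    the same baseline window; positive values mean closed-loop visual
    flow suppressed the sustained motor-related response.
    """
    windows = windows if windows is not None else ResponseWindows()
    if eta_dark.time.size != eta_closed_loop.time.size or not np.allclose(
        eta_dark.time, eta_closed_loop.time
    ):
        raise ValueError("mismatched time axes between dark and closed-loop Etas")
    return eta_dark.window_mean(windows.suppression) - eta_closed_loop.window_mean(
        windows.suppression
    )
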