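"""Raw fluorescence to drift-corrected ΔF/F.

Slow drift in the raw fluorescence (bleaching, z-drift) is estimated
with a low-percentile rolling filter — by default the 8th percentile in
a 100 s window — subtracted, and the result normalised by the median of
the raw trace:

    dff = (F - P8_window(F)) / median(F)

The low percentile tracks the activity-free baseline rather than the
transients riding on it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class DffParams:
    """Parameters of the ΔF/F pipeline.

    percentile
        Order statistic tracked by the rolling baseline, in (0, 100).
    window_s
        Length of the rolling window in seconds.
    window_alignment
        ``"centered"`` (window straddles the sample; no phase lag in the
        drift estimate) or ``"trailing"`` (causal window ending at the
        sample).
    percent
        If true, report ΔF/F in percent rather than as a fraction.
    """

    percentile: float = 8.0
    window_s: float = 100.0
    window_alignment: str = "centered"
    percent: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.percentile < 100.0:
            raise ValueError("percentile must be in (0, 100)")
        if self.window_s <= 0:
            raise ValueError("window_s must be positive")
        if self.window_alignment not in ("centered", "trailing"):
            raise ValueError("window_alignment must be 'centered' or 'trailing'")


def rolling_percentile(
    values: np.ndarray,
    window_samples: int,
    percentile: float,
    alignment: str = "centered",
) -> np.ndarray:
    """Rolling percentile with truncated (not padded) edge windows.

    At interior points the output equals the linear-interpolation
    percentile of the ``window_samples`` samples around (centered) or up
    to (trailing) each index; near the edges the window shrinks to the
    available samples, so no data are invented. A centered window is
    forced to an odd sample count (rounded up) so it is symmetric
    around the sample.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if values.size == 0:
        raise ValueError("empty trace")
    if window_samples < 1:
        raise ValueError("window must span at least one sample")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite values in trace")
    window = min(window_samples, values.size)
    if alignment == "centered" and window % 2 == 0:
        window += 1
    series = pd.Series(values)
    roll = series.rolling(window, center=(alignment == "centered"), min_periods=1)
    return roll.quantile(percentile / 100.0, interpolation="linear").to_numpy()


def compute_dff(
    raw: np.ndarray,
    dt: float,
    params: DffParams | None = None,
) -> np.ndarray:
    """Convert raw fluorescence (neurons x time or 1-D) to ΔF/F.

    The rolling-percentile baseline is subtracted from each trace and
    the difference is divided by the median of that trace's raw values.
    The result is invariant to rescaling the raw trace by any positive
    constant.
    """
    params = params if params is not None else DffParams()
    if dt <= 0:
        raise ValueError("dt must be positive")
    arr = np.asarray(raw, dtype=float)
    squeeze = arr.ndim == 1
    arr = np.atleast_2d(arr)
    window_samples = max(int(round(params.window_s / dt)), 1)
    out = np.empty_like(arr)
    for i, trace in enumerate(arr):
        med = float(np.median(trace))
        if med <= 0:
            raise ValueError(f"non-positive median fluorescence for neuron {i}")
        baseline = rolling_percentile(
            trace, window_samples, params.percentile, params.window_alignment
        )
        out[i] = (trace - baseline) / med
    if params.percent:
        out = out * 100.0
    return out[0] if squeeze else out
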