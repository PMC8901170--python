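"""Activity-behavior correlation geometry of a population.

Each neuron is summarised by two Pearson correlations computed in the
open-loop condition — activity vs. visual flow and activity vs. running
speed. The shape of this two-dimensional scatter distinguishes
subtractive visuomotor integration (opponent signs, first principal
axis near the negative diagonal) from additive integration (same signs,
axis rotated toward the positive diagonal). The scatter's orientation
is quantified as the signed angle between the leading principal
component and the running-correlation (y) axis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic import SessionData


class DegenerateGeometryError(ValueError):
    """Raised when the correlation scatter has no well-defined long axis."""


def _pearson_rows(traces: np.ndarray, regressor: np.ndarray) -> np.ndarray:
    """Pearson r of each trace row against one regressor; NaN if undefined."""
    x = regressor - regressor.mean()
    sx = np.sqrt((x**2).sum())
    rows = traces - traces.mean(axis=1, keepdims=True)
    sr = np.sqrt((rows**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = rows @ x / (sr * sx)
    if sx == 0:
        r = np.full(traces.shape[0], np.nan)
    return r


def activity_behavior_correlations(
    session: SessionData,
    mismatch_response: np.ndarray | None = None,
    require_open_loop: bool = True,
) -> pd.DataFrame:
    """Per-neuron correlations with visual flow and running speed.

    Computed sample-for-sample on the imaging frame grid over the whole
    session, with no smoothing or lag. Pairs involving a zero-variance
    trace or regressor get ``r = NaN`` and ``valid = False`` rather
    than being dropped. ``mismatch_response`` (one scalar per neuron,
    e.g. from a closed-loop session) is attached as a column when given.
    """
    if require_open_loop and session.behavior.condition != "open_loop":
        raise ValueError(
            "correlations are defined on the open-loop condition "
            "(pass require_open_loop=False to override)"
        )
    r_flow = _pearson_rows(session.traces, session.behavior.visual_flow)
    r_run = _pearson_rows(session.traces, session.behavior.running_speed)
    frame = pd.DataFrame(
        {
            "r_flow": r_flow,
            "r_run": r_run,
            "valid": np.isfinite(r_flow) & np.isfinite(r_run),
        }
    )
    if mismatch_response is not None:
        frame["mismatch_response"] = np.asarray(mismatch_response, dtype=float)
    return frame


def mean_pairwise_correlation(traces: np.ndarray) -> tuple[np.ndarray, float]:
    """Mean correlation of each neuron with all other neurons.

    Returns the per-neuron means (self-correlation excluded) and their
    population mean.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    n = traces.shape[0]
    if n < 2:
        raise ValueError("pairwise correlation requires at least two neurons")
    corr = np.corrcoef(traces)
    np.fill_diagonal(corr, np.nan)
    per_neuron = np.nanmean(corr, axis=1)
    return per_neuron, float(np.nanmean(per_neuron))


def pc_angle(
    r_flow: np.ndarray,
    r_run: np.ndarray,
    gap_tol: float = 1e-6,
) -> float:
    """Signed angle (deg) between the leading principal axis and the y axis.

    The covariance of the mean-subtracted (r_flow, r_run) points is
    eigendecomposed; the leading eigenvector's sign is fixed by
    requiring a non-negative y component (non-negative x on ties), and
    the angle from the running-correlation axis is reported in
    (-90, +90], positive toward positive r_flow. Opponent populations
    sit near -45 deg, additively coupled ones near +45 deg.
    """
    x = np.asarray(r_flow, dtype=float)
    y = np.asarray(r_run, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("r_flow and r_run must be equal-length 1-D arrays")
    if x.size < 3:
        raise ValueError("pc_angle requires at least three points")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite correlation values")
    pts = np.column_stack([x, y])
    cov = np.cov(pts, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    if (evals[1] - evals[0]) <= gap_tol * np.trace(cov):
        raise DegenerateGeometryError(
            "isotropic correlation scatter: leading axis undefined"
        )
    v = evecs[:, 1]
    if v[1] < 0 or (v[1] == 0 and v[0] < 0):
        v = -v
    return float(np.degrees(np.arctan2(v[0], v[1])))


def geometry_summary(
    points: pd.DataFrame,
    traces: np.ndarray | None = None,
    gap_tol: float = 1e-6,
) -> dict:
    """Population summary: PC angle, mean correlations, mean pairwise r."""
    valid = points["valid"] if "valid" in points else np.ones(len(points), bool)
    sub = points[np.asarray(valid, bool)]
    out = {
        "pc_angle_deg": pc_angle(
            sub["r_flow"].to_numpy(), sub["r_run"].to_numpy(), gap_tol
        ),
        "mean_r_flow": float(sub["r_flow"].mean()),
        "mean_r_run": float(sub["r_run"].mean()),
        "n_neurons": int(len(sub)),
    }
    if traces is not None:
        out["mean_pairwise_r"] = mean_pairwise_correlation(traces)[1]
    return out
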