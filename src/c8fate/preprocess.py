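"""Trajectory preprocessing: control subtraction, smoothing, derivative, tau.

The processing order is fixed: subtract the mean untreated-control trajectory,
smooth with a zero-phase filter, shift so the minimum is zero, then take the
finite-difference derivative (itself smoothed the same way).  The time of the
derivative maximum, tau, marks the end of the C8 activation phase and is the
endpoint for the quadratic model fit; secondary local maxima are kept as
fallback fit endpoints.

The smoother is an 11-frame (55 min) Savitzky-Golay filter of polynomial
order 2.  Its symmetric kernel is zero-phase, and — because the signal model
is locally quadratic — it reproduces quadratic segments exactly (including at
the series edges, where a polynomial fit replaces the kernel), so smoothing
never biases the curvature that the model fit estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .datatypes import FATE_DIED, Trajectory

#: Smoothing window, frames (55 min at 5-min sampling).
SMOOTH_WINDOW = 11
#: Analysis window (min): activation and death events are scored in the first 10 h.
ANALYSIS_WINDOW = 600.0


@dataclass
class DerivedTrajectory:
    """A preprocessed trajectory with derivative features.

    ``fr_smooth`` is the control-subtracted, smoothed, baseline-shifted series
    used for the derivative; ``fr_fit`` is the control-subtracted,
    baseline-shifted but unsmoothed series the quadratic model is fit to
    (smoothing a one-sided quadratic distorts it around the onset kink, which
    would bias the fit).  ``tau_primary`` is the time of the global derivative
    maximum inside the analysis window; ``secondary_maxima`` lists other local
    maxima, best first.
    """

    traj: Trajectory
    fr_smooth: np.ndarray
    fr_fit: np.ndarray
    dfr: np.ndarray
    tau_primary: float
    secondary_maxima: list[float] = field(default_factory=list)
    short_series: bool = False

    @property
    def times(self) -> np.ndarray:
        return self.traj.times


def subtract_control(
    traj: Trajectory,
    control_times: np.ndarray | None = None,
    control_fr: np.ndarray | None = None,
) -> Trajectory:
    """Subtract the average untreated-cell trajectory pointwise.

    The control may be sampled on a different (overlapping) grid; it is then
    linearly interpolated onto the trajectory's grid.  With no control given
    the trajectory is returned unchanged.
    """
    if control_fr is None:
        return traj
    control_fr = np.asarray(control_fr, dtype=float)
    if control_times is None:
        if len(control_fr) != len(traj.times):
            raise ValueError("control series length mismatch and no control grid given")
        corrected = traj.fr - control_fr
    else:
        control_times = np.asarray(control_times, dtype=float)
        if traj.times[0] < control_times[0] - 1e-9 or traj.times[-1] > control_times[-1] + 1e-9:
            raise ValueError("control grid does not span the trajectory grid")
        corrected = traj.fr - np.interp(traj.times, control_times, control_fr)
    return Trajectory(traj.cell_id, traj.times, corrected, traj.fate, traj.death_time)


def smooth_zero_phase(series: np.ndarray, window_frames: int = SMOOTH_WINDOW) -> np.ndarray:
    """Zero-phase smoothing (order-2 Savitzky-Golay, symmetric kernel).

    Series shorter than the window are returned unsmoothed with a warning.
    """
    x = np.asarray(series, dtype=float)
    if window_frames % 2 == 0:
        raise ValueError("window_frames must be odd")
    if len(x) < window_frames:
        warnings.warn(
            f"series length {len(x)} < window {window_frames}; returned unsmoothed",
            stacklevel=2,
        )
        return x.copy()
    return savgol_filter(x, window_frames, polyorder=2, mode="interp")


def baseline_shift(series: np.ndarray) -> np.ndarray:
    """Shift so the minimum is zero."""
    x = np.asarray(series, dtype=float)
    if len(x) == 0:
        raise ValueError("empty series")
    return x - x.min()


def compute_derivative(
    series: np.ndarray, dt: float = 5.0, window_frames: int = SMOOTH_WINDOW
) -> np.ndarray:
    """Finite-difference derivative (central interior, one-sided ends), smoothed.

    Central differences are exact for quadratics, so on noise-free model input
    the derivative is ``2 k (t - t0)`` to rounding error; the smoother
    preserves that linear profile exactly.
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points for a derivative")
    d = np.gradient(x, dt, edge_order=2)  # 2nd order: exact for quadratics at edges too
    return smooth_zero_phase(d, window_frames)


def locate_tau(
    times: np.ndarray,
    dfr: np.ndarray,
    window_end: float = ANALYSIS_WINDOW,
    death_time: float | None = None,
) -> tuple[float, list[float]]:
    """Find the primary derivative maximum and ranked secondary local maxima.

    The search window is [0, window_end], clipped at the death time for dying
    cells (for which the global maximum typically sits on the truncation
    boundary).  Secondary maxima are strict local maxima of the smoothed
    derivative, ordered by decreasing derivative value.
    """
    end = window_end if death_time is None else min(window_end, death_time)
    mask = times <= end + 1e-9
    if not np.any(mask):
        raise ValueError("empty analysis window")
    t_w, d_w = times[mask], dfr[mask]
    i_max = int(np.argmax(d_w))
    tau_primary = float(t_w[i_max])

    interior = np.zeros(len(d_w), dtype=bool)
    if len(d_w) >= 3:
        interior[1:-1] = (d_w[1:-1] > d_w[:-2]) & (d_w[1:-1] > d_w[2:])
    idx = [i for i in np.flatnonzero(interior) if i != i_max]
    idx.sort(key=lambda i: -d_w[i])
    return tau_primary, [float(t_w[i]) for i in idx]


def preprocess_trajectory(
    traj: Trajectory,
    control_times: np.ndarray | None = None,
    control_fr: np.ndarray | None = None,
    window_frames: int = SMOOTH_WINDOW,
    analysis_window: float = ANALYSIS_WINDOW,
) -> DerivedTrajectory:
    """Full preprocessing pipeline for one trajectory.

    Order is fixed: control subtraction -> smoothing -> baseline shift ->
    derivative -> tau location.  The fit series skips the smoothing step but
    shares the control subtraction and its own baseline shift.
    """
    corrected = subtract_control(traj, control_times, control_fr)
    short = len(corrected.fr) < window_frames
    smooth = smooth_zero_phase(corrected.fr, window_frames) if not short else corrected.fr.copy()
    smooth = baseline_shift(smooth)
    fr_fit = baseline_shift(corrected.fr)
    dfr = compute_derivative(smooth, corrected.dt, window_frames) if len(smooth) >= 3 else np.zeros_like(smooth)
    tau_primary, secondary = locate_tau(
        corrected.times, dfr, analysis_window, corrected.death_time
    )
    return DerivedTrajectory(
        traj=corrected,
        fr_smooth=smooth,
        fr_fit=fr_fit,
        dfr=dfr,
        tau_primary=tau_primary,
        secondary_maxima=secondary,
        short_series=short,
    )
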