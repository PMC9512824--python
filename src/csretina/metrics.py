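"""Response-shape and enhancement metrics.

These are applied identically to simulated traces and imaging ROIs: the
transiency index, static-edge and emerging-object enhancement ratios, the
direction-selectivity index (DSI), receptive-field position from opposed
motion trials, edge/full-field location classification, and sigmoid-rise /
exponential-decay kinetics fits.

All ratio metrics are invariant to positive rescaling of the traces.  Peak
means the maximum of the (polarity-corrected) trace within the stimulus
window; OFF traces are negated before metrics are taken.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .traces import ResponseTrace

__all__ = [
    "KineticsFit",
    "transiency_index",
    "edge_enhancement",
    "emerging_enhancement",
    "dsi",
    "rf_position",
    "classify_location",
    "rise_t50",
    "fit_kinetics",
]


def _windowed(trace: ResponseTrace | np.ndarray, window=None) -> np.ndarray:
    if isinstance(trace, ResponseTrace):
        return trace.windowed(window)
    return np.asarray(trace, dtype=float)


def transiency_index(
    trace: ResponseTrace | np.ndarray,
    window: tuple[float, float] | None = None,
    literal: bool = False,
) -> float:
    """Transiency index of the response within the stimulation window.

    The default form ``TI = 1 - mean/peak`` maps a sustained plateau to 0 and
    an ever-sharper transient toward 1.  ``literal=True`` returns the raw
    peak/mean ratio instead (>= 1 for non-negative traces).  A non-positive
    peak makes the index undefined (NaN).
    """
    v = _windowed(trace, window)
    peak = v.max()
    if peak <= 0:
        return float("nan")
    ratio = peak / v.mean()
    return float(ratio) if literal else float(1.0 - 1.0 / ratio)


def edge_enhancement(r_edge: float, r_ff: float) -> float:
    """Static edge enhancement: ``R_edge / R_full_field - 1``."""
    if r_ff <= 0:
        raise ValueError("full-field peak must be positive")
    return r_edge / r_ff - 1.0


def emerging_enhancement(r_from_edge: float, r_to_edge: float) -> float:
    """Emerging-object enhancement: ``R_from_edge / R_to_edge - 1``.

    Positive values mean motion emerging from behind the occluder evokes a
    larger peak than the same motion toward the occluder.
    """
    if r_to_edge <= 0:
        raise ValueError("to-edge peak must be positive")
    return r_from_edge / r_to_edge - 1.0


def dsi(peaks, directions_deg) -> float:
    """Direction-selectivity index: |vector sum| / scalar sum of peaks.

    Each response peak R_i contributes a vector of length R_i pointing in its
    stimulus direction; DSI = 0 for direction-balanced responses, 1 when only
    one direction evokes a response.  All-zero peaks are undefined (NaN).
    """
    peaks = np.asarray(peaks, dtype=float)
    ang = np.deg2rad(np.asarray(directions_deg, dtype=float))
    if peaks.shape != ang.shape or peaks.size < 2:
        raise ValueError("need >= 2 matched peaks and directions")
    if np.any(peaks < 0):
        raise ValueError("peaks must be >= 0")
    total = peaks.sum()
    if total == 0:
        return float("nan")
    vx = np.sum(peaks * np.cos(ang))
    vy = np.sum(peaks * np.sin(ang))
    return float(np.hypot(vx, vy) / total)


def rf_position(
    t50_left: float, t50_right: float, speed: float = 0.5, display_center: float = 0.0
) -> float:
    """Horizontal RF-center offset from opposed motion trials.

    A unit left of the display center responds earlier to a rightward bar
    than to a leftward one; the offset is half the 50%-rise-time difference
    multiplied by the stimulus speed (mm/s == µm/ms).  Positive offsets point
    toward the side the rightward bar reaches later.
    """
    if not (np.isfinite(t50_left) and np.isfinite(t50_right)):
        return float("nan")
    return display_center + 0.5 * (t50_right - t50_left) * speed


def classify_location(rf_pos: float, edges) -> str:
    """Full-field / near-edge / intermediate classification of an RF position.

    ``full_field`` requires the nearest visual edge (mask boundary or display
    border) at least 100 µm away; ``near_edge`` requires one closer than
    50 µm; anything between is ``intermediate`` (excluded from both
    analyses).
    """
    edges = np.asarray(edges, dtype=float)
    if edges.size == 0:
        raise ValueError("need at least one edge position")
    d = np.min(np.abs(edges - rf_pos))
    if d >= 100.0:
        return "full_field"
    if d < 50.0:
        return "near_edge"
    return "intermediate"


def rise_t50(
    trace: ResponseTrace | np.ndarray,
    window: tuple[float, float] | None = None,
    dt: float | None = None,
) -> float:
    """Model-free 50%-of-peak rise time (ms from window start), interpolated."""
    v = _windowed(trace, window)
    if isinstance(trace, ResponseTrace):
        dt = trace.dt
        t_off = trace.window_slice(window).start * trace.dt
    else:
        dt = dt or 1.0
        t_off = 0.0
    peak_idx = int(np.argmax(v))
    peak = v[peak_idx]
    if peak <= 0:
        return float("nan")
    half = peak / 2.0
    above = np.flatnonzero(v[: peak_idx + 1] >= half)
    if above.size == 0:
        return float("nan")
    k = above[0]
    if k == 0:
        return float(t_off)
    # linear interpolation between the straddling samples
    frac = (half - v[k - 1]) / (v[k] - v[k - 1])
    return float(t_off + (k - 1 + frac) * dt)


@dataclass
class KineticsFit:
    """Sigmoid-rise / exponential-decay description of a response waveform."""

    rise_t50: float = float("nan")
    sigmoid_midpoint: float = float("nan")
    sigmoid_slope: float = float("nan")
    sigmoid_amplitude: float = float("nan")
    sigmoid_baseline: float = float("nan")
    decay_tau: float = float("nan")
    time_to_peak: float = float("nan")
    fit_ok: bool = False


def _logistic(t, base, amp, mid, slope):
    return base + amp / (1.0 + np.exp(-(t - mid) / slope))


def fit_kinetics(
    trace: ResponseTrace | np.ndarray,
    window: tuple[float, float] | None = None,
    dt: float | None = None,
) -> KineticsFit:
    """Least-squares kinetics fit of one response.

    Fits a 4-parameter logistic to the rising phase (window start to peak)
    and a single exponential to the decay phase (peak to window end); also
    reports the model-free interpolated 50% rise time and time-to-peak.
    Degenerate traces (flat, or peak pinned to a window edge) return
    ``fit_ok = False``.
    """
    v = _windowed(trace, window)
    dt = trace.dt if isinstance(trace, ResponseTrace) else (dt or 1.0)
    out = KineticsFit()
    if v.size < 5 or np.ptp(v) < 1e-12:
        return out
    peak_idx = int(np.argmax(v))
    out.time_to_peak = peak_idx * dt
    out.rise_t50 = rise_t50(v, dt=dt)
    if peak_idx < 2 or peak_idx > v.size - 3:
        return out
    t_rise = np.arange(peak_idx + 1) * dt
    y_rise = v[: peak_idx + 1]
    amp0 = y_rise[-1] - y_rise[0]
    try:
        p_rise, _ = curve_fit(
            _logistic,
            t_rise,
            y_rise,
            p0=[y_rise[0], amp0, t_rise[-1] / 2, max(dt, t_rise[-1] / 10)],
            maxfev=5000,
        )
    except (RuntimeError, ValueError):
        return out
    t_dec = np.arange(v.size - peak_idx) * dt
    y_dec = v[peak_idx:]
    floor0 = min(y_dec.min(), 0.0)

    def _expdec(t, amp, tau, floor):
        return floor + amp * np.exp(-t / tau)

    try:
        p_dec, _ = curve_fit(
            _expdec,
            t_dec,
            y_dec,
            p0=[y_dec[0] - floor0, max(t_dec[-1] / 3, dt), floor0],
            bounds=([0, dt / 10, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=5000,
        )
    except (RuntimeError, ValueError):
        return out
    out.sigmoid_baseline, out.sigmoid_amplitude = p_rise[0], p_rise[1]
    out.sigmoid_midpoint, out.sigmoid_slope = p_rise[2], p_rise[3]
    out.decay_tau = float(p_dec[1])
    out.fit_ok = True
    return out
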