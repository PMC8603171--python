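"""Simplified pulse-to-heart-rate extraction on a 1-Hz output grid.

This is a transparent stand-in matching the *interface* of the wrist
device's embedded algorithm (5-second sliding window, one output per
second, quality index 0-4), not its internals, which are proprietary.
The quality-index surrogate here is a documented step function of the
motion fraction per window — it is NOT a reimplementation of the
device's confidence estimator.
"""

from __future__ import annotations

import numpy as np

from .streams import HRStream, PulseEventSeries

#: motion-fraction breakpoints for QI 4, 3, 2, 1 (else 0); monotone by design
DEFAULT_QI_THRESHOLDS: tuple[float, float, float, float] = (0.1, 0.25, 0.5, 0.75)


def extract_hr(
    pulses: PulseEventSeries,
    window_s: int = 5,
    step_s: int = 1,
    phase: str = "surgery",
) -> HRStream:
    """Heart rate from pulse events: trailing window, one output per step.

    For each output time t (integers from 0 to the last pulse), HR is
    60 / mean(interpulse intervals fully inside the half-open trailing
    window (t - window_s, t]).  Windows holding fewer than two pulses
    yield a missing sample with QI 0; covered samples get QI 4 (later
    refined by :func:`assign_qi`).
    """
    if window_s < 1:
        raise ValueError("window_s must be >= 1 second")
    if step_s < 1:
        raise ValueError("step_s must be >= 1 second")
    times = np.asarray(pulses.times, dtype=float)
    if times.size and np.any(np.diff(times) <= 0):
        raise ValueError("pulse times must be sorted ascending")

    if times.size == 0:
        return HRStream(t=np.array([], dtype=np.int64), hr=np.array([]),
                        qi=np.array([], dtype=np.int64), source="PPG", phase=phase)

    t_out = np.arange(0, int(np.floor(times[-1])) + 1, step_s, dtype=np.int64)
    hr = np.full(t_out.size, np.nan)
    qi = np.zeros(t_out.size, dtype=np.int64)
    # pulses strictly inside (t - window, t]
    lo = np.searchsorted(times, t_out - window_s, side="right")
    hi = np.searchsorted(times, t_out, side="right")
    for k, (i, j) in enumerate(zip(lo, hi)):
        if j - i >= 2:
            ipis = np.diff(times[i:j])
            hr[k] = 60.0 / float(np.mean(ipis))
            qi[k] = 4
    return HRStream(t=t_out, hr=hr, qi=qi, source="PPG", phase=phase)


def assign_qi(
    stream: HRStream,
    motion_fraction: np.ndarray,
    thresholds: tuple[float, float, float, float] = DEFAULT_QI_THRESHOLDS,
) -> HRStream:
    """Map per-window motion fraction to a 0-4 quality index.

    The mapping is a non-increasing step function: QI=4 only when the
    motion fraction is at or below the first (good) threshold, default
    0.1; samples whose HR is missing keep QI 0 regardless.
    """
    motion_fraction = np.asarray(motion_fraction, dtype=float)
    if motion_fraction.size != len(stream):
        raise ValueError("motion_fraction must align with the stream (same length)")
    if np.any((motion_fraction < 0) | (motion_fraction > 1)):
        raise ValueError("motion fractions must lie in [0, 1]")
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be non-decreasing")

    out = stream.copy()
    qi = np.zeros(len(stream), dtype=np.int64)
    for level, thr in zip((4, 3, 2, 1), thresholds):
        qi = np.where((qi == 0) & (motion_fraction <= thr), level, qi)
    qi[np.isnan(out.hr)] = 0
    out.qi = qi
    return out


def motion_fraction_per_window(
    pulses: PulseEventSeries, stream: HRStream, window_s: int = 5
) -> np.ndarray:
    """Fraction of pulses in each sample's trailing window that carry a
    motion flag (0 where the window holds no pulses)."""
    times = pulses.times
    flagged = pulses.motion.astype(float)
    cum = np.concatenate([[0.0], np.cumsum(flagged)])
    lo = np.searchsorted(times, stream.t - window_s, side="right")
    hi = np.searchsorted(times, stream.t, side="right")
    n = (hi - lo).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n > 0, (cum[hi] - cum[lo]) / np.maximum(n, 1.0), 0.0)
    return frac
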