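"""Interpulse-interval arrhythmia masking over 30-second windows.

Pipeline: tile the pulse series into consecutive 30-s windows of
interpulse intervals (IPIs); reject IPIs contaminated by motion; score the
retained IPI sequence with a small Markov model that contrasts atrial
fibrillation (AF, irregular) against normal sinus rhythm (NSR, regular);
label a window *arrhythmia* when more than half its detected IPIs were
rejected or the AF score crosses a threshold; finally force the quality
index of every heart-rate sample inside an arrhythmia window to 0 so those
samples never enter the agreement analysis.

The Markov model is a transparent surrogate for the proprietary detector
the device uses: successive IPI changes are quantized into three states
(shorter / similar / longer, +-50 ms by default) and the window's score is
the logistic of the mean log-likelihood ratio of the observed state
transitions under an AF transition table (near-uniform) versus an NSR
table (strongly diagonal).  It is configurable and makes no clinical
claim.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .streams import HRStream, PulseEventSeries

WINDOW_LEN_S = 30.0
STATES = ("shorter", "similar", "longer")


def _uniform_table() -> np.ndarray:
    return np.full((3, 3), 1.0 / 3.0)


def _diagonal_table(stay: float = 0.9) -> np.ndarray:
    off = (1.0 - stay) / 2.0
    return np.full((3, 3), off) + np.eye(3) * (stay - off)


@dataclass
class MarkovTables:
    """Transition-probability tables for the AF-vs-NSR likelihood ratio."""

    af: np.ndarray = field(default_factory=_uniform_table)
    nsr: np.ndarray = field(default_factory=_diagonal_table)
    delta_tol_s: float = 0.05  # |delta IPI| below this counts as "similar"

    def __post_init__(self) -> None:
        for name in ("af", "nsr"):
            tab = np.asarray(getattr(self, name), dtype=float)
            if tab.shape != (3, 3) or np.any(tab <= 0):
                raise ValueError(f"{name} table must be 3x3 with positive entries")
            if not np.allclose(tab.sum(axis=1), 1.0):
                raise ValueError(f"{name} table rows must sum to 1")
            setattr(self, name, tab)
        if self.delta_tol_s <= 0:
            raise ValueError("delta_tol_s must be positive")


@dataclass
class IPIWindow:
    """IPIs of one consecutive 30-s interval with its arrhythmia verdict."""

    start: float
    length: float
    ipis: np.ndarray            # durations, seconds
    motion: np.ndarray          # True where a bounding pulse carried a flag
    rejected: np.ndarray | None = None  # set by reject_motion
    rejected_fraction: float = 0.0
    af_probability: float | None = None
    label: str = "good"

    def __post_init__(self) -> None:
        self.ipis = np.asarray(self.ipis, dtype=float)
        self.motion = np.asarray(self.motion, dtype=bool)
        if self.ipis.size != self.motion.size:
            raise ValueError("ipis and motion flags must have equal length")

    @property
    def n_detected(self) -> int:
        return self.ipis.size

    def retained_ipis(self) -> np.ndarray:
        if self.rejected is None:
            return self.ipis
        return self.ipis[~self.rejected]


def window_ipis(
    pulses: PulseEventSeries,
    window_len_s: float = WINDOW_LEN_S,
    start_at: float = 0.0,
) -> list[IPIWindow]:
    """Tile pulses into consecutive, non-overlapping IPI windows.

    Each IPI is assigned to the window containing its *end* pulse, with the
    right edge inclusive: an IPI ending exactly at a window boundary stays
    in that window, while an IPI spanning a boundary (ending after it)
    falls in the later window.  Every IPI appears in exactly one window.
    """
    if len(pulses) < 2:
        return []
    ends = pulses.times[1:]
    ipis = np.diff(pulses.times)
    motion = pulses.motion[1:] | pulses.motion[:-1]  # either bounding pulse
    # window index: end in (start + k*L, start + (k+1)*L]
    idx = np.ceil((ends - start_at) / window_len_s).astype(int) - 1
    idx = np.maximum(idx, 0)
    n_win = int(idx.max()) + 1
    out = []
    for k in range(n_win):
        sel = idx == k
        out.append(IPIWindow(
            start=start_at + k * window_len_s,
            length=window_len_s,
            ipis=ipis[sel],
            motion=motion[sel],
        ))
    return out


def reject_motion(window: IPIWindow) -> IPIWindow:
    """Reject every IPI with a motion-flagged bounding pulse.

    ``rejected_fraction`` is rejected / detected (0 when nothing was
    detected); a fraction strictly above 0.5 labels the window arrhythmia.
    """
    rejected = window.motion.copy()
    n = window.n_detected
    frac = float(rejected.sum()) / n if n else 0.0
    label = "arrhythmia" if frac > 0.5 else window.label
    return replace(window, rejected=rejected, rejected_fraction=frac, label=label)


def _quantize(ipis: np.ndarray, tol: float) -> np.ndarray:
    """Successive IPI changes -> state indices 0=shorter, 1=similar, 2=longer."""
    delta = np.diff(ipis)
    states = np.ones(delta.size, dtype=np.int64)
    states[delta < -tol] = 0
    states[delta > tol] = 2
    return states


def af_score(window: IPIWindow, model: MarkovTables | None = None) -> float | None:
    """Probability-like AF score in [0, 1] from the retained IPIs.

    The retained IPI sequence is quantized into shorter/similar/longer
    states; the score is logistic(mean log P_AF / P_NSR) over the observed
    state transitions.  Returns None when fewer than three IPIs remain
    (the window then falls back to the motion-rejection rule alone).
    """
    model = model or MarkovTables()
    ipis = window.retained_ipis()
    if ipis.size < 3:
        return None
    states = _quantize(ipis, model.delta_tol_s)
    llr = np.log(model.af[states[:-1], states[1:]]) - \
        np.log(model.nsr[states[:-1], states[1:]])
    return 1.0 / (1.0 + math.exp(-float(np.mean(llr))))


def label_windows(
    windows: list[IPIWindow],
    model: MarkovTables | None = None,
    af_threshold: float = 0.5,
    empty_label: str = "arrhythmia",
) -> list[IPIWindow]:
    """Full window verdict: motion rejection, AF scoring, labeling.

    A window is *arrhythmia* when >50% of detected IPIs were rejected or
    the AF score reaches ``af_threshold``.  Windows with no detected IPIs
    carry no evidence of sinus rhythm and default to ``empty_label``
    (conservative; configurable).
    """
    model = model or MarkovTables()
    out = []
    for w in windows:
        w = reject_motion(w)
        score = af_score(w, model)
        label = w.label
        if w.n_detected == 0:
            label = empty_label
        elif score is not None and score >= af_threshold:
            label = "arrhythmia"
        out.append(replace(w, af_probability=score, label=label))
    return out


def apply_arrhythmia_mask(
    stream: HRStream,
    windows: list[IPIWindow],
    af_threshold: float = 0.5,
) -> HRStream:
    """Force QI to 0 for samples inside arrhythmia-labeled windows.

    Sample membership uses the half-open interval [start, start + length);
    masking never raises a QI and leaves other samples untouched.  Windows
    must not overlap.
    """
    if windows:
        order = sorted(windows, key=lambda w: w.start)
        for a, b in zip(order[:-1], order[1:]):
            if b.start < a.start + a.length - 1e-9:
                raise ValueError("windows must not overlap")
    out = stream.copy()
    for w in windows:
        bad = w.label == "arrhythmia" or (
            w.af_probability is not None and w.af_probability >= af_threshold)
        if not bad:
            continue
        sel = (out.t >= w.start) & (out.t < w.start + w.length)
        out.qi[sel] = 0
        out.arrhythmia[sel] = True
    return out


def windows_to_frame(windows: list[IPIWindow]):
    """Window labels as a BED-like interval table."""
    import pandas as pd

    return pd.DataFrame({
        "start_s": [w.start for w in windows],
        "end_s": [w.start + w.length for w in windows],
        "label": [w.label for w in windows],
        "rejected_fraction": [w.rejected_fraction for w in windows],
        "af_probability": [w.af_probability for w in windows],
    })
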