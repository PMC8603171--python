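"""Core time-series containers shared by every stage of the pipeline.

Heart-rate streams live on a 1-Hz integer time grid; pulse events are
irregular float timestamps with a per-pulse motion flag.  Both round-trip
through a small CSV dialect (plain text, one file per patient/source).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

SOURCES = ("ECG", "PPG")
PHASES = ("surgery", "recovery")
QI_MIN, QI_MAX = 0, 4


@dataclass
class HRStream:
    """One source's heart-rate samples on a 1-Hz grid.

    Parameters
    ----------
    t : int array, strictly increasing, unit spacing within a phase.
    hr : float array, beats per minute; NaN marks a missing sample.
    qi : int array, 0-4 quality index.  For ECG (the reference) the index
        is carried but ignored downstream.  The convention ``hr missing
        <=> qi == 0`` holds at extraction time; arrhythmia masking later
        forces qi to 0 without blanking hr (those samples are tracked via
        ``arrhythmia`` and never enter the agreement analysis).
    arrhythmia : bool array, True where an arrhythmia window covered the
        sample (set by :func:`hragree.arrhythmia.apply_arrhythmia_mask`).
    """

    t: np.ndarray
    hr: np.ndarray
    qi: np.ndarray
    source: str = "PPG"
    phase: str = "surgery"
    arrhythmia: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.int64)
        self.hr = np.asarray(self.hr, dtype=float)
        self.qi = np.asarray(self.qi, dtype=np.int64)
        if self.arrhythmia is None:
            self.arrhythmia = np.zeros(self.t.size, dtype=bool)
        self.arrhythmia = np.asarray(self.arrhythmia, dtype=bool)
        if not (self.t.size == self.hr.size == self.qi.size == self.arrhythmia.size):
            raise ValueError("t, hr, qi and arrhythmia must have equal length")
        if self.t.size and np.any(np.diff(self.t) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if self.qi.size and (self.qi.min() < QI_MIN or self.qi.max() > QI_MAX):
            raise ValueError(f"quality index must lie in [{QI_MIN}, {QI_MAX}]")
        if self.source not in SOURCES:
            raise ValueError(f"source must be one of {SOURCES}")
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}")

    def __len__(self) -> int:
        return self.t.size

    def copy(self) -> "HRStream":
        return replace(
            self,
            t=self.t.copy(),
            hr=self.hr.copy(),
            qi=self.qi.copy(),
            arrhythmia=self.arrhythmia.copy(),
        )

    def shift(self, seconds: int) -> "HRStream":
        """Return a copy with all sample times shifted by ``seconds``."""
        out = self.copy()
        out.t = out.t + int(seconds)
        return out

    def to_frame(self) -> pd.DataFrame:
        qi = self.qi.astype(object)
        if self.source == "ECG":
            qi = np.full(self.t.size, "", dtype=object)  # QI not defined for ECG
        return pd.DataFrame(
            {"time_s": self.t, "hr_bpm": self.hr, "qi": qi, "phase": self.phase}
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path, source: str) -> "HRStream":
        df = pd.read_csv(path)
        qi = df["qi"]
        if source == "ECG":
            qi = np.full(len(df), QI_MAX, dtype=np.int64)
        else:
            qi = qi.fillna(0).astype(np.int64).to_numpy()
        phase = str(df["phase"].iloc[0]) if len(df) else "surgery"
        return cls(
            t=df["time_s"].to_numpy(),
            hr=df["hr_bpm"].to_numpy(dtype=float),
            qi=qi,
            source=source,
            phase=phase,
        )


@dataclass
class PulseEventSeries:
    """Detected pulse occurrence times (s) with per-pulse motion flags."""

    times: np.ndarray
    motion: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.motion = np.asarray(self.motion, dtype=bool)
        if self.times.size != self.motion.size:
            raise ValueError("times and motion flags must have equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("pulse times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    def shift(self, seconds: float) -> "PulseEventSeries":
        return PulseEventSeries(self.times + seconds, self.motion.copy())

    def write_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"pulse_time_s": self.times, "motion": self.motion.astype(int)}
        ).to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "PulseEventSeries":
        df = pd.read_csv(path)
        return cls(
            times=df["pulse_time_s"].to_numpy(dtype=float),
            motion=df["motion"].to_numpy().astype(bool),
        )
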