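"""Seeded synthetic perioperative cohorts of paired ECG/PPG heart-rate data.

The generator emulates the statistical structure the downstream agreement
analysis assumes: each patient carries a shared true heart-rate trajectory
through a surgery and a recovery phase; the wrist-optical (PPG) stream
equals the reference (ECG) stream plus a fixed device bias, a patient-level
random offset a_i ~ N(0, sigma_b2) and per-second noise e_ij ~ N(0,
sigma_w2); quality-index dropout follows a two-state persistence chain;
motion bursts and occasional atrial-fibrillation episodes perturb the
pulse-event series; and an integer clock offset misaligns the PPG stream so
that synchronization has an exact expected answer.

Everything is reproducible: one global seed fans out to independent
per-patient substreams, so the same config always yields a bit-identical
cohort.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .streams import HRStream, PulseEventSeries
from .preprocess import PatientSession

HR_LO, HR_HI = 30.0, 180.0  # physiological band enforced by reflection


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Durations are lognormal around the configured medians (87 min surgery,
    58 min recovery); ``duration_log_sd`` is the lognormal sigma and may be
    set to 0 for fixed-length sessions.  ``true_bias`` is the device-level
    PPG-minus-ECG offset d, ``sigma_b2``/``sigma_w2`` the between- and
    within-patient variances of the paired differences (bpm^2).
    """

    n_patients: int = 99
    surgery_minutes: float = 87.0
    recovery_minutes: float = 58.0
    duration_log_sd: float = 0.5
    true_bias: float = -0.15
    sigma_b2: float = 0.20
    sigma_w2: float = 2.04
    hr_baseline_range: tuple[float, float] = (50.0, 90.0)
    hr_walk_sd: float = 0.3
    af_prevalence: float = 8.0 / 99.0
    motion_burst_rate: float = 2.0  # bursts per hour
    motion_burst_mean_s: float = 20.0
    qi_good_prob: float = 0.765
    qi_dwell_s: float = 60.0
    clock_offset_range: tuple[int, int] = (-30, 30)
    nsr_jitter_cv: float = 0.02
    af_ipi_cv: float = 0.25
    phases: tuple[str, ...] = ("surgery", "recovery")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in ("surgery_minutes", "recovery_minutes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("sigma_b2", "sigma_w2", "duration_log_sd", "hr_walk_sd",
                     "motion_burst_rate", "motion_burst_mean_s", "qi_dwell_s",
                     "nsr_jitter_cv", "af_ipi_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("af_prevalence", "qi_good_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        lo, hi = self.hr_baseline_range
        if not (HR_LO <= lo <= hi <= HR_HI):
            raise ValueError(f"hr_baseline_range must lie inside [{HR_LO}, {HR_HI}]")
        olo, ohi = self.clock_offset_range
        if olo > ohi:
            raise ValueError("clock_offset_range must be (low, high) with low <= high")
        self.clock_offset_range = (int(olo), int(ohi))
        self.phases = tuple(self.phases)
        for p in self.phases:
            if p not in ("surgery", "recovery"):
                raise ValueError(f"unknown phase {p!r}")

    def phase_minutes(self, phase: str) -> float:
        return self.surgery_minutes if phase == "surgery" else self.recovery_minutes

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})

    def to_file(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d = {k: list(v) if isinstance(v, tuple) else v for k, v in d.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclass
class GroundTruth:
    """Latent quantities of a simulated cohort, for parameter-recovery tests."""

    a_i: dict[str, float] = field(default_factory=dict)
    af_episodes: dict[str, list[tuple[float, float]]] = field(default_factory=dict)
    clock_offset: dict[str, int] = field(default_factory=dict)
    true_hr: dict[str, np.ndarray] = field(default_factory=dict)  # key "pid/phase"

    def to_json(self, path: str | Path) -> None:
        payload = {
            "a_i": self.a_i,
            "af_episodes": {k: [list(iv) for iv in v] for k, v in self.af_episodes.items()},
            "clock_offset": self.clock_offset,
            "true_hr": {k: np.asarray(v).tolist() for k, v in self.true_hr.items()},
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        raw = json.loads(Path(path).read_text())
        return cls(
            a_i=raw["a_i"],
            af_episodes={k: [tuple(iv) for iv in v] for k, v in raw["af_episodes"].items()},
            clock_offset={k: int(v) for k, v in raw["clock_offset"].items()},
            true_hr={k: np.asarray(v, dtype=float) for k, v in raw["true_hr"].items()},
        )


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold values back into [lo, hi] (reflecting boundaries)."""
    span = hi - lo
    y = np.mod(x - lo, 2.0 * span)
    return lo + np.minimum(y, 2.0 * span - y)


def simulate_true_hr(
    duration_s: int,
    config: SimulationConfig,
    phase: str = "surgery",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Shared true heart-rate trajectory at 1 Hz.

    A bounded Gaussian random walk, reflected at the physiological band
    [30, 180] bpm, starting from a baseline drawn uniformly from
    ``hr_baseline_range``.  ``hr_walk_sd = 0`` yields a constant series.
    """
    duration_s = int(duration_s)
    if duration_s <= 0:
        raise ValueError("duration must be a positive number of seconds")
    if phase not in ("surgery", "recovery"):
        raise ValueError(f"unknown phase {phase!r}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    baseline = rng.uniform(*config.hr_baseline_range)
    steps = rng.normal(0.0, config.hr_walk_sd, size=duration_s)
    steps[0] = 0.0
    return _reflect(baseline + np.cumsum(steps), HR_LO, HR_HI)


def simulate_pulse_events(
    true_hr: np.ndarray,
    rhythm: str = "NSR",
    motion_schedule: list[tuple[float, float]] | None = None,
    rng: np.random.Generator | int | None = None,
    jitter_cv: float | None = None,
    af_cv: float | None = None,
    af_intervals: list[tuple[float, float]] | None = None,
    config: SimulationConfig | None = None,
) -> PulseEventSeries:
    """Pulse occurrence times consistent with a true HR trajectory.

    Normal sinus rhythm (NSR) draws each interpulse interval as
    60/HR * (1 + jitter_cv * z); atrial fibrillation (AF) uses a high
    coefficient of variation (default 0.25) so successive intervals are
    irregular.  ``af_intervals`` optionally switches NSR segments to AF
    rhythm inside the given [start, end) windows.  Pulses falling inside
    any ``motion_schedule`` interval are flagged.
    """
    true_hr = np.asarray(true_hr, dtype=float)
    if true_hr.size == 0:
        raise ValueError("true_hr must be a non-empty series")
    if np.any(~np.isfinite(true_hr)) or np.any(true_hr <= 0):
        raise ValueError("true_hr must be finite and positive")
    if rhythm not in ("NSR", "AF"):
        raise ValueError("rhythm must be 'NSR' or 'AF'")
    cfg = config or SimulationConfig()
    jcv = cfg.nsr_jitter_cv if jitter_cv is None else jitter_cv
    acv = cfg.af_ipi_cv if af_cv is None else af_cv
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    af_intervals = af_intervals or []
    motion_schedule = motion_schedule or []

    duration = float(true_hr.size)
    times: list[float] = []
    t = 0.0
    while t < duration:
        hr = true_hr[min(int(t), true_hr.size - 1)]
        base = 60.0 / hr
        in_af = rhythm == "AF" or any(a <= t < b for a, b in af_intervals)
        cv = acv if in_af else jcv
        factor = max(0.2, 1.0 + cv * rng.standard_normal()) if cv > 0 else 1.0
        times.append(t)
        t += base * factor
    times_arr = np.asarray(times, dtype=float)
    motion = np.zeros(times_arr.size, dtype=bool)
    for a, b in motion_schedule:
        motion |= (times_arr >= a) & (times_arr < b)
    return PulseEventSeries(times_arr, motion)


def _qi_labels(n: int, config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Two-state persistence chain: QI=4 (good) vs. QI in {0..3} (degraded).

    Transition probabilities are chosen so the stationary probability of
    the good state equals qi_good_prob with mean dwell on the order of
    qi_dwell_s seconds.
    """
    p = config.qi_good_prob
    if p >= 1.0:
        return np.full(n, 4, dtype=np.int64)
    if p <= 0.0:
        return rng.integers(0, 4, size=n)
    dwell = max(config.qi_dwell_s, 1.0)
    leave_good = min(1.0, (1.0 - p) / dwell)
    leave_bad = min(1.0, p / dwell)
    good = np.empty(n, dtype=bool)
    good[0] = rng.random() < p
    u = rng.random(n)
    for i in range(1, n):
        good[i] = (u[i] >= leave_good) if good[i - 1] else (u[i] < leave_bad)
    qi = np.where(good, 4, 0).astype(np.int64)
    bad = ~good
    qi[bad] = rng.integers(0, 4, size=int(bad.sum()))
    return qi


def _draw_intervals(duration: float, n: int, lo: float, hi: float,
                    rng: np.random.Generator) -> list[tuple[float, float]]:
    out = []
    for _ in range(n):
        length = rng.uniform(lo, min(hi, duration))
        start = rng.uniform(0.0, max(duration - length, 0.0))
        out.append((float(start), float(start + length)))
    return sorted(out)


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[PatientSession], GroundTruth]:
    """Generate a full cohort: one :class:`PatientSession` per patient-phase.

    The ECG stream is the reference (true HR); the PPG stream carries the
    injected difference structure true_bias + a_i + e_ij, quality-index
    dropout, an integer clock offset on its time axis, and a pulse-event
    series (same clock) with motion flags and AF-episode irregularity.
    """
    gt = GroundTruth()
    sessions: list[PatientSession] = []
    children = np.random.SeedSequence(config.seed).spawn(config.n_patients)
    sd_b = float(np.sqrt(config.sigma_b2))
    sd_w = float(np.sqrt(config.sigma_w2))
    olo, ohi = config.clock_offset_range

    for idx, child in enumerate(children):
        rng = np.random.default_rng(child)
        pid = f"P{idx + 1:03d}"
        a_i = rng.normal(0.0, sd_b) if sd_b > 0 else 0.0
        offset = int(rng.integers(olo, ohi + 1))
        has_af = rng.random() < config.af_prevalence
        gt.a_i[pid] = float(a_i)
        gt.clock_offset[pid] = offset

        for phase in config.phases:
            median_s = 60.0 * config.phase_minutes(phase)
            if config.duration_log_sd > 0:
                duration = int(round(median_s * np.exp(
                    rng.normal(0.0, config.duration_log_sd))))
            else:
                duration = int(round(median_s))
            duration = max(duration, 60)

            true_hr = simulate_true_hr(duration, config, phase, rng)
            gt.true_hr[f"{pid}/{phase}"] = true_hr

            af_eps: list[tuple[float, float]] = []
            if has_af:
                n_ep = 1 + int(rng.poisson(0.5))
                af_eps = _draw_intervals(duration, n_ep, 60.0, 300.0, rng)
            gt.af_episodes.setdefault(pid, []).extend(af_eps)

            n_bursts = int(rng.poisson(config.motion_burst_rate * duration / 3600.0))
            bursts = []
            if n_bursts and config.motion_burst_mean_s > 0:
                lengths = rng.exponential(config.motion_burst_mean_s, size=n_bursts)
                starts = rng.uniform(0.0, duration, size=n_bursts)
                bursts = sorted(
                    (float(s), float(min(s + L, duration)))
                    for s, L in zip(starts, lengths)
                )

            t = np.arange(duration, dtype=np.int64)
            ecg = HRStream(t=t, hr=true_hr.copy(),
                           qi=np.full(duration, 4, dtype=np.int64),
                           source="ECG", phase=phase)

            e_ij = rng.normal(0.0, sd_w, size=duration) if sd_w > 0 else 0.0
            ppg_hr = true_hr + config.true_bias + a_i + e_ij
            qi = _qi_labels(duration, config, rng)
            ppg_hr = np.where(qi == 0, np.nan, ppg_hr)  # QI=0: output unavailable
            ppg = HRStream(t=t + offset, hr=ppg_hr, qi=qi, source="PPG", phase=phase)

            pulses = simulate_pulse_events(
                true_hr, rhythm="NSR", motion_schedule=bursts, rng=rng,
                af_intervals=af_eps, config=config,
            ).shift(offset)

            sessions.append(PatientSession(
                patient_id=pid, phase=phase, ecg=ecg, ppg=ppg,
                lag_applied=None, pulses=pulses,
            ))
    return sessions, gt


# ---------------------------------------------------------------------------
# Cohort serialization (plain-text CSV dialect + JSON ground-truth sidecar)
# ---------------------------------------------------------------------------

def write_cohort(sessions: list[PatientSession], gt: GroundTruth,
                 outdir: str | Path) -> Path:
    """Write one CSV per patient-phase-source, pulse CSVs, ground truth and
    a manifest; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in sessions:
        stem = f"{s.patient_id}_{s.phase}"
        ecg_path = outdir / f"{stem}_ecg.csv"
        ppg_path = outdir / f"{stem}_ppg.csv"
        s.ecg.write_csv(ecg_path)
        s.ppg.write_csv(ppg_path)
        pulse_path = ""
        if s.pulses is not None:
            pulse_path = str(outdir / f"{stem}_pulses.csv")
            s.pulses.write_csv(pulse_path)
        rows.append({
            "patient_id": s.patient_id, "phase": s.phase,
            "ecg_path": str(ecg_path), "ppg_path": str(ppg_path),
            "pulse_path": pulse_path,
        })
    gt.to_json(outdir / "ground_truth.json")
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_cohort(manifest: str | Path) -> list[PatientSession]:
    df = pd.read_csv(manifest, keep_default_na=False)
    sessions = []
    for _, row in df.iterrows():
        pulses = None
        if row.get("pulse_path", ""):
            pulses = PulseEventSeries.read_csv(row["pulse_path"])
        sessions.append(PatientSession(
            patient_id=str(row["patient_id"]), phase=str(row["phase"]),
            ecg=HRStream.read_csv(row["ecg_path"], source="ECG"),
            ppg=HRStream.read_csv(row["ppg_path"], source="PPG"),
            lag_applied=None, pulses=pulses,
        ))
    return sessions
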