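"""Stream synchronization, quality categorization, coverage and exclusion.

The two heart-rate streams of a session are aligned by maximizing the
Pearson correlation over integer lags (the recording clocks may differ by
tens of seconds); each 1-Hz sample is then put into one of three quality
categories — good (QI=4), low (QI<=3) or arrhythmia (masked) — from which
coverage statistics and the 5-minute session-exclusion rule follow.  Only
good-category samples enter the downstream agreement analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .streams import HRStream, PulseEventSeries

CATEGORIES = ("good", "low", "arrhythmia")
MIN_OVERLAP_S = 60


@dataclass
class PatientSession:
    """One patient-phase pair of ECG/PPG streams (plus optional pulses)."""

    patient_id: str
    phase: str
    ecg: HRStream
    ppg: HRStream
    lag_applied: int | None = None
    pulses: PulseEventSeries | None = None
    categories: np.ndarray | None = None  # set by categorize()

    @property
    def aligned(self) -> bool:
        return (self.lag_applied is not None
                and len(self.ecg) == len(self.ppg)
                and bool(np.array_equal(self.ecg.t, self.ppg.t)))


@dataclass
class CoverageSummary:
    """Category durations in hours and the good-quality fraction."""

    good_hours: float
    low_hours: float
    arrhythmia_hours: float
    total_hours: float
    good_fraction: float
    per_patient: dict[str, float] = field(default_factory=dict)

    @property
    def good_percent(self) -> float:
        return 100.0 * self.good_fraction

    def per_patient_median_iqr(self) -> tuple[float, float, float]:
        vals = np.asarray(list(self.per_patient.values()), dtype=float)
        if vals.size == 0:
            return (float("nan"),) * 3
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        return float(med), float(q1), float(q3)


def _lag_order(max_lag: int) -> list[int]:
    """Candidate lags ordered for tie-breaking: |lag| ascending, negative first."""
    return sorted(range(-max_lag, max_lag + 1), key=lambda L: (abs(L), L))


def synchronize(
    ecg: HRStream,
    ppg: HRStream,
    max_lag_s: int = 120,
    patient_id: str = "",
) -> tuple[int, PatientSession]:
    """Cross-correlation alignment of the PPG stream onto the ECG clock.

    The lag is the integer shift in [-max_lag, +max_lag] maximizing the
    Pearson correlation of overlapping, mean-centered, pairwise-complete
    samples; ties break toward the smallest absolute lag, then toward the
    negative one.  The returned session holds both streams restricted to
    their common grid, the PPG times shifted by -lag.
    """
    if ecg.phase != ppg.phase:
        raise ValueError("streams must belong to the same phase")
    best_lag: int | None = None
    best_r = -np.inf
    any_overlap = False
    for lag in _lag_order(int(max_lag_s)):
        # pair ecg[t] with ppg[t + lag]
        t0 = max(ecg.t.min(), ppg.t.min() - lag)
        t1 = min(ecg.t.max(), ppg.t.max() - lag)
        if t1 - t0 + 1 < MIN_OVERLAP_S:
            continue
        ei = np.searchsorted(ecg.t, t0)
        pi = np.searchsorted(ppg.t, t0 + lag)
        n = int(t1 - t0 + 1)
        x = ecg.hr[ei:ei + n]
        y = ppg.hr[pi:pi + n]
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < MIN_OVERLAP_S:
            continue
        any_overlap = True
        xs, ys = x[ok] - x[ok].mean(), y[ok] - y[ok].mean()
        denom = np.sqrt((xs ** 2).sum() * (ys ** 2).sum())
        if denom == 0:
            continue  # constant stream: correlation undefined at this lag
        r = float((xs * ys).sum() / denom)
        if r > best_r:
            best_r, best_lag = r, lag
    if not any_overlap:
        raise ValueError(
            f"insufficient overlap (<{MIN_OVERLAP_S} complete pairs) at every "
            f"lag in [-{max_lag_s}, {max_lag_s}]")
    if best_lag is None:
        warnings.warn("correlation undefined (constant stream); using lag 0")
        best_lag = 0

    shifted = ppg.shift(-best_lag)
    t0 = max(ecg.t.min(), shifted.t.min())
    t1 = min(ecg.t.max(), shifted.t.max())
    ei = np.searchsorted(ecg.t, t0)
    pi = np.searchsorted(shifted.t, t0)
    n = int(t1 - t0 + 1)
    ecg_cut = HRStream(t=ecg.t[ei:ei + n], hr=ecg.hr[ei:ei + n],
                       qi=ecg.qi[ei:ei + n], source="ECG", phase=ecg.phase,
                       arrhythmia=ecg.arrhythmia[ei:ei + n])
    ppg_cut = HRStream(t=shifted.t[pi:pi + n], hr=shifted.hr[pi:pi + n],
                       qi=shifted.qi[pi:pi + n], source="PPG", phase=ppg.phase,
                       arrhythmia=shifted.arrhythmia[pi:pi + n])
    session = PatientSession(patient_id=patient_id, phase=ecg.phase,
                             ecg=ecg_cut, ppg=ppg_cut, lag_applied=best_lag)
    return best_lag, session


def categorize(session: PatientSession) -> np.ndarray:
    """Per-sample category with precedence arrhythmia > good (QI=4) > low."""
    ppg = session.ppg
    cats = np.where(ppg.arrhythmia, "arrhythmia",
                    np.where(ppg.qi == 4, "good", "low"))
    session.categories = cats
    return cats


def _session_categories(session: PatientSession) -> np.ndarray:
    if session.categories is None:
        return categorize(session)
    return session.categories


def coverage(
    sessions: list[PatientSession],
    group_by: str = "overall",
) -> CoverageSummary | dict[str, CoverageSummary]:
    """Category durations and good-quality fraction, at 1 sample = 1 second.

    ``group_by`` is "overall" (one summary, with per-patient fractions
    attached), "phase" or "patient" (dict of summaries).  The denominator
    is the entire recorded duration, good + low + arrhythmia == total
    exactly in sample counts.
    """
    if not sessions:
        raise ValueError("coverage requires at least one session")
    if group_by == "overall":
        return _summary(sessions)
    if group_by == "phase":
        keys = sorted({s.phase for s in sessions})
        return {k: _summary([s for s in sessions if s.phase == k]) for k in keys}
    if group_by == "patient":
        keys = sorted({s.patient_id for s in sessions})
        return {k: _summary([s for s in sessions if s.patient_id == k]) for k in keys}
    raise ValueError("group_by must be 'overall', 'phase' or 'patient'")


def _summary(sessions: list[PatientSession]) -> CoverageSummary:
    counts = {c: 0 for c in CATEGORIES}
    per_patient_good: dict[str, int] = {}
    per_patient_total: dict[str, int] = {}
    for s in sessions:
        cats = _session_categories(s)
        for c in CATEGORIES:
            counts[c] += int((cats == c).sum())
        per_patient_good[s.patient_id] = (
            per_patient_good.get(s.patient_id, 0) + int((cats == "good").sum()))
        per_patient_total[s.patient_id] = (
            per_patient_total.get(s.patient_id, 0) + cats.size)
    total = sum(counts.values())
    frac = counts["good"] / total if total else float("nan")
    return CoverageSummary(
        good_hours=counts["good"] / 3600.0,
        low_hours=counts["low"] / 3600.0,
        arrhythmia_hours=counts["arrhythmia"] / 3600.0,
        total_hours=total / 3600.0,
        good_fraction=frac,
        per_patient={
            pid: per_patient_good[pid] / per_patient_total[pid]
            for pid in per_patient_total if per_patient_total[pid]
        },
    )


def exclude_short(
    sessions: list[PatientSession],
    min_good_minutes: float = 5.0,
) -> tuple[list[PatientSession], list[tuple[PatientSession, str]]]:
    """Drop phase-sessions with less than 5 minutes of good-quality data.

    The comparison is strict (< excludes, exactly 5 minutes is kept) and
    applies per phase: a patient losing one phase keeps the other.
    Idempotent by construction.
    """
    kept: list[PatientSession] = []
    excluded: list[tuple[PatientSession, str]] = []
    thr = min_good_minutes * 60.0
    for s in sessions:
        good_s = float((_session_categories(s) == "good").sum())
        if good_s < thr:
            excluded.append((s, f"{good_s / 60.0:.2f} min good quality "
                                f"< {min_good_minutes:g} min ({s.phase})"))
        else:
            kept.append(s)
    return kept, excluded


def paired_coverage_test(
    surgery_fractions: np.ndarray,
    recovery_fractions: np.ndarray,
) -> float:
    """Two-sided Wilcoxon signed-rank p-value on paired coverage fractions.

    All-zero difference vectors return p = 1 by convention (no evidence of
    any shift); fewer than 6 complete pairs are rejected.
    """
    x = np.asarray(surgery_fractions, dtype=float)
    y = np.asarray(recovery_fractions, dtype=float)
    if x.size != y.size:
        raise ValueError("paired vectors must have equal length")
    if x.size < 6:
        raise ValueError("need at least 6 complete pairs")
    if np.allclose(x, y):
        return 1.0
    return float(stats.wilcoxon(x, y, alternative="two-sided").pvalue)


def session_manifest(sessions: list[PatientSession],
                     excluded: list[tuple[PatientSession, str]]) -> pd.DataFrame:
    rows = []
    for s, reason in [(s, "") for s in sessions] + excluded:
        good_min = float((_session_categories(s) == "good").sum()) / 60.0
        rows.append({
            "patient_id": s.patient_id, "phase": s.phase,
            "lag_applied": s.lag_applied, "good_minutes": good_min,
            "excluded": bool(reason), "reason": reason,
        })
    return pd.DataFrame(rows)
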