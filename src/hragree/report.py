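"""End-to-end pipeline (sync -> mask -> categorize -> exclude -> agreement)
and the study's three figures: a per-patient session overlay, Bland-Altman
plots with bias/LoA lines, and the coverage-fraction histogram."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import arrhythmia as arr
from . import preprocess as pre
from .agreement import (AgreementResult, analyze_differences,
                        check_reference_standard, compute_differences,
                        results_table)
from .preprocess import PatientSession

QI_COLORS = {0: "#d62728", 1: "#ff7f0e", 2: "#bcbd22", 3: "#17becf", 4: "#2ca02c"}


@dataclass
class RunConfig:
    """Serializable analysis settings; a run is reproducible from these."""

    scales: tuple[str, ...] = ("absolute", "percent")
    min_good_minutes: float = 5.0
    af_threshold: float = 0.5
    max_lag_s: int = 120
    per_phase: bool = True
    alpha: float = 0.05
    z: float = 1.96
    seed: int = 0

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["scales"] = list(self.scales)
        return d


@dataclass
class PhaseResults:
    phase: str
    results: dict[str, AgreementResult]
    coverage: pre.CoverageSummary
    n_sessions: int
    n_excluded: int
    reference_standard: object = None
    exclusions: list[str] = field(default_factory=list)


def prepare_sessions(
    sessions: list[PatientSession], config: RunConfig | None = None
) -> list[PatientSession]:
    """Synchronize each raw session and apply the arrhythmia mask.

    Pulse events (recorded on the PPG clock) are shifted onto the aligned
    grid before windowing so mask intervals line up with sample times.
    """
    config = config or RunConfig()
    out = []
    for s in sessions:
        lag, aligned = pre.synchronize(s.ecg, s.ppg, max_lag_s=config.max_lag_s,
                                       patient_id=s.patient_id)
        if s.pulses is not None and len(s.pulses) >= 2:
            pulses = s.pulses.shift(-lag)
            windows = arr.window_ipis(pulses, start_at=float(aligned.ppg.t[0]))
            windows = arr.label_windows(windows, af_threshold=config.af_threshold)
            aligned.ppg = arr.apply_arrhythmia_mask(
                aligned.ppg, windows, af_threshold=config.af_threshold)
            aligned.pulses = pulses
        pre.categorize(aligned)
        out.append(aligned)
    return out


def analyze_phase(
    sessions: list[PatientSession], phase: str, config: RunConfig
) -> PhaseResults | None:
    """Coverage, exclusion and both-scale agreement for one phase."""
    phase_sessions = [s for s in sessions if s.phase == phase]
    if not phase_sessions:
        return None
    cov = pre.coverage(phase_sessions)
    kept, excluded = pre.exclude_short(phase_sessions, config.min_good_minutes)
    if len(kept) < 2:
        return PhaseResults(phase=phase, results={}, coverage=cov,
                            n_sessions=len(phase_sessions), n_excluded=len(excluded),
                            exclusions=[r for _, r in excluded])
    results = {}
    for scale in config.scales:
        ds = compute_differences(kept, scale=scale)
        results[scale] = analyze_differences(ds, alpha=config.alpha, z=config.z)
    ref = None
    if "absolute" in results and "percent" in results:
        ref = check_reference_standard(results["absolute"], results["percent"])
    return PhaseResults(phase=phase, results=results, coverage=cov,
                        n_sessions=len(phase_sessions), n_excluded=len(excluded),
                        reference_standard=ref,
                        exclusions=[f"{s.patient_id}: {r}" for s, r in excluded])


def run_analysis(
    sessions: list[PatientSession],
    config: RunConfig | None = None,
    outdir: str | Path | None = None,
) -> dict[str, PhaseResults]:
    """Full chain per phase (and pooled); optionally write tables to disk."""
    config = config or RunConfig()
    prepared = prepare_sessions(sessions, config)
    phases = sorted({s.phase for s in prepared}) if config.per_phase else []
    out: dict[str, PhaseResults] = {}
    for phase in phases:
        res = analyze_phase(prepared, phase, config)
        if res is not None:
            out[phase] = res
    pooled = analyze_phase(prepared, phase="__all__", config=config) \
        if not config.per_phase else None
    if pooled is not None:
        out["overall"] = pooled
    if outdir is not None:
        write_results(out, prepared, config, Path(outdir))
    out["_sessions"] = prepared  # type: ignore[assignment]
    return out


def analyze_phase_pooled(sessions, config):  # pragma: no cover - thin alias
    return analyze_phase(sessions, "__all__", config)


def write_results(results: dict[str, PhaseResults],
                  sessions: list[PatientSession],
                  config: RunConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    payload: dict = {"config": config.to_dict(), "phases": {}}
    for phase, res in results.items():
        if not isinstance(res, PhaseResults):
            continue
        if res.results:
            results_table(res.results).to_csv(outdir / f"agreement_{phase}.csv")
        cov = res.coverage
        payload["phases"][phase] = {
            "coverage": {
                "good_hours": cov.good_hours, "low_hours": cov.low_hours,
                "arrhythmia_hours": cov.arrhythmia_hours,
                "total_hours": cov.total_hours,
                "good_percent": cov.good_percent,
            },
            "n_sessions": res.n_sessions,
            "n_excluded": res.n_excluded,
            "exclusions": res.exclusions,
            "reference_standard": (
                None if res.reference_standard is None else {
                    "passed": res.reference_standard.passed,
                    "detail": res.reference_standard.detail,
                }),
            "agreement": {
                scale: {
                    "bias": r.bias, "se_bias": r.se_bias, "sd_diff": r.sd_diff,
                    "loa_lower": r.loa_lower, "loa_upper": r.loa_upper,
                    "ci_loa_lower": list(r.ci_loa_lower),
                    "ci_loa_upper": list(r.ci_loa_upper),
                    "icc": r.icc,
                    "sigma_w2": r.vc.sigma_w2, "sigma_b2": r.vc.sigma_b2,
                } for scale, r in res.results.items()
            },
        }
    (outdir / "results.json").write_text(json.dumps(payload, indent=2))
    pre.session_manifest(sessions, []).to_csv(outdir / "sessions.csv", index=False)


# ---------------------------------------------------------------------------
# Figures
# ---------------------------------------------------------------------------

def plot_session(session: PatientSession, path: str | Path) -> Path:
    """ECG line with QI-colored PPG points for one session."""
    fig, ax = plt.subplots(figsize=(10, 4))
    ax.plot(session.ecg.t / 60.0, session.ecg.hr, color="0.5", lw=1,
            label="ECG HR", zorder=1)
    for level, color in QI_COLORS.items():
        sel = session.ppg.qi == level
        if sel.any():
            ax.scatter(session.ppg.t[sel] / 60.0, session.ppg.hr[sel], s=4,
                       color=color, label=f"PPG QI={level}", zorder=2)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("heart rate (bpm)")
    ax.set_title(f"{session.patient_id} / {session.phase}")
    ax.legend(fontsize=7, ncol=3)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_bland_altman(sessions: list[PatientSession], result: AgreementResult,
                      path: str | Path, max_points: int = 20000,
                      seed: int = 0) -> Path:
    """Differences vs. means with bias and LoA lines."""
    means, diffs = [], []
    for s in sessions:
        cats = s.categories if s.categories is not None else pre.categorize(s)
        ok = (cats == "good") & np.isfinite(s.ecg.hr) & np.isfinite(s.ppg.hr)
        ppg, ecg = s.ppg.hr[ok], s.ecg.hr[ok]
        if result.scale == "percent":
            nz = ecg != 0
            ppg, ecg = ppg[nz], ecg[nz]
            diffs.append(100.0 * (ppg - ecg) / ecg)
        else:
            diffs.append(ppg - ecg)
        means.append((ppg + ecg) / 2.0)
    x = np.concatenate(means) if means else np.array([])
    y = np.concatenate(diffs) if diffs else np.array([])
    if x.size > max_points:
        keep = np.random.default_rng(seed).choice(x.size, max_points, replace=False)
        x, y = x[keep], y[keep]
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(x, y, s=3, alpha=0.3, color="#1f77b4")
    unit = "%" if result.scale == "percent" else "bpm"
    for val, style, lbl in ((result.bias, "-", "bias"),
                            (result.loa_lower, "--", "LoA"),
                            (result.loa_upper, "--", None)):
        ax.axhline(val, color="k", ls=style, lw=1,
                   label=lbl if lbl else None)
    ax.set_xlabel("mean of PPG and ECG HR (bpm)")
    ax.set_ylabel(f"PPG - ECG difference ({unit})")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_coverage_hist(cov: pre.CoverageSummary, path: str | Path,
                       bins: int = 20) -> Path:
    """Histogram of per-patient good-quality coverage fractions."""
    vals = np.asarray(list(cov.per_patient.values()), dtype=float)
    fig, ax = plt.subplots(figsize=(6, 4))
    counts, _, _ = ax.hist(vals, bins=bins, range=(0.0, 1.0), color="#1f77b4",
                           edgecolor="white")
    ax.set_xlabel("coverage fraction (good-quality share of recording)")
    ax.set_ylabel("patients")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    assert int(counts.sum()) == vals.size
    return Path(path)
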