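"""Repeated-measures Bland-Altman agreement with MOVER confidence intervals.

The paired per-second difference d_ij = HR_PPG - HR_ECG (or its percentage
analogue) of measurement j on patient i is modeled with a one-way
random-effects structure

    d_ij = d + a_i + e_ij,   a_i ~ N(0, sigma_b^2),  e_ij ~ N(0, sigma_w^2),

so the SD of a single difference is sqrt(sigma_b^2 + sigma_w^2) and the 95%
limits of agreement are d +- 1.96 * sqrt(sigma_b^2 + sigma_w^2).  Because
patients contribute unequal numbers of seconds, the bias is the
observation-weighted grand mean and the variance components come from the
unbalanced one-way ANOVA method of moments:

    MSW = sum_ij (d_ij - dbar_i)^2 / (N - n)           -> sigma_w^2
    MSB = sum_i m_i (dbar_i - dbar)^2 / (n - 1)
    m0  = (N - sum_i m_i^2 / N) / (n - 1)
    sigma_b^2 = max(0, (MSB - MSW) / m0)

Confidence intervals for the limits use the MOVER (method of variance
estimates recovery): a modified-large-sample chi-square interval for the
total variance sigma^2 = MSB/m0 + (1 - 1/m0) MSW from its two mean squares,
merged with the normal interval for the bias by the square-and-add rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .preprocess import PatientSession, categorize

Z95 = 1.96  # the conventional 95% LoA multiplier; configurable via z=


@dataclass
class DifferenceSet:
    """Good-quality paired differences grouped by patient."""

    groups: list[np.ndarray]
    patient_ids: list[str]
    scale: str  # "absolute" | "percent"
    n_excluded_zero_ecg: int = 0

    def __post_init__(self) -> None:
        if self.scale not in ("absolute", "percent"):
            raise ValueError("scale must be 'absolute' or 'percent'")
        self.groups = [np.asarray(g, dtype=float) for g in self.groups]
        if any(g.size < 1 for g in self.groups):
            raise ValueError("every patient group must hold at least one difference")

    @property
    def n(self) -> int:
        return len(self.groups)

    @property
    def m_i(self) -> np.ndarray:
        return np.array([g.size for g in self.groups], dtype=np.int64)

    @property
    def N(self) -> int:
        return int(self.m_i.sum())


@dataclass
class VarianceComponents:
    """Between/within-patient variance estimates with their mean squares."""

    sigma_b2: float
    sigma_w2: float
    msb: float
    msw: float
    m0: float
    df_between: int
    df_within: int

    @property
    def total(self) -> float:
        return self.sigma_b2 + self.sigma_w2


@dataclass
class AgreementResult:
    bias: float
    se_bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    ci_loa_lower: tuple[float, float]
    ci_loa_upper: tuple[float, float]
    icc: float
    vc: VarianceComponents = field(repr=False, default=None)  # type: ignore
    z: float = Z95
    scale: str = "absolute"


def compute_differences(
    sessions: PatientSession | list[PatientSession],
    scale: str = "absolute",
) -> DifferenceSet:
    """PPG-minus-ECG differences per good-quality paired second.

    Only samples categorized *good* (QI=4, unmasked) with both HRs present
    enter; on the percent scale d% = 100 (PPG - ECG) / ECG and pairs with
    ECG HR = 0 are excluded (their count is reported).  Patients with no
    good pairs are dropped.
    """
    if isinstance(sessions, PatientSession):
        sessions = [sessions]
    per_patient: dict[str, list[np.ndarray]] = {}
    n_zero = 0
    for s in sessions:
        if not s.aligned:
            raise ValueError(
                f"session {s.patient_id}/{s.phase} is not synchronized")
        cats = s.categories if s.categories is not None else categorize(s)
        ok = (cats == "good") & np.isfinite(s.ecg.hr) & np.isfinite(s.ppg.hr)
        ppg, ecg = s.ppg.hr[ok], s.ecg.hr[ok]
        if scale == "percent":
            nz = ecg != 0
            n_zero += int((~nz).sum())
            d = 100.0 * (ppg[nz] - ecg[nz]) / ecg[nz]
        elif scale == "absolute":
            d = ppg - ecg
        else:
            raise ValueError("scale must be 'absolute' or 'percent'")
        if d.size:
            per_patient.setdefault(s.patient_id, []).append(d)
    ids = sorted(per_patient)
    return DifferenceSet(
        groups=[np.concatenate(per_patient[i]) for i in ids],
        patient_ids=ids, scale=scale, n_excluded_zero_ecg=n_zero,
    )


def fit_components(ds: DifferenceSet) -> tuple[float, float, VarianceComponents]:
    """Observation-weighted bias and method-of-moments variance components.

    Returns (bias, se_bias, components).  Requires >= 2 patients and at
    least one patient with repeated observations; a negative raw
    between-patient estimate is truncated to zero.  The bias SE uses the
    random-effects variance of the weighted mean,
    sqrt(sum_i w_i^2 (sigma_b^2 + sigma_w^2 / m_i)) with w_i = m_i / N.
    """
    n = ds.n
    m = ds.m_i.astype(float)
    N = float(ds.N)
    if n < 2:
        raise ValueError("variance components need at least 2 patients")
    if N - n <= 0:
        raise ValueError("variance components need repeated observations "
                         "(all patients have a single pair)")
    means = np.array([g.mean() for g in ds.groups])
    bias = float(sum(g.sum() for g in ds.groups) / N)
    ssw = float(sum(((g - mu) ** 2).sum() for g, mu in zip(ds.groups, means)))
    msw = ssw / (N - n)
    msb = float((m * (means - bias) ** 2).sum() / (n - 1))
    m0 = (N - float((m ** 2).sum()) / N) / (n - 1)
    sigma_b2 = max(0.0, (msb - msw) / m0)
    vc = VarianceComponents(
        sigma_b2=sigma_b2, sigma_w2=msw, msb=msb, msw=msw, m0=m0,
        df_between=n - 1, df_within=int(N - n),
    )
    w = m / N
    se_bias = float(np.sqrt((w ** 2 * (sigma_b2 + msw / m)).sum()))
    return bias, se_bias, vc


def limits_of_agreement(
    bias: float, vc: VarianceComponents, z: float = Z95
) -> tuple[float, float, float]:
    """95% limits of agreement: (lower, upper, sd_diff) = bias -+ z*sd."""
    total = vc.total
    assert total >= 0.0, "total variance cannot be negative after truncation"
    sd = float(np.sqrt(total))
    return bias - z * sd, bias + z * sd, sd


def _total_variance_ci(vc: VarianceComponents, alpha: float) -> tuple[float, float]:
    """Modified-large-sample CI for sigma_b^2 + sigma_w^2 = c1*MSB + c2*MSW."""
    if vc.df_between <= 0 or vc.df_within <= 0:
        raise ValueError("both variance-component dfs must be positive")
    c1, c2 = 1.0 / vc.m0, 1.0 - 1.0 / vc.m0
    point = c1 * vc.msb + c2 * vc.msw  # untruncated total
    terms = []
    for c, ms, df in ((c1, vc.msb, vc.df_between), (c2, vc.msw, vc.df_within)):
        hi_q = stats.chi2.ppf(1.0 - alpha / 2.0, df)
        lo_q = stats.chi2.ppf(alpha / 2.0, df)
        terms.append((c * ms * (1.0 - df / hi_q), c * ms * (df / lo_q - 1.0)))
    lo = point - float(np.sqrt(sum(t[0] ** 2 for t in terms)))
    hi = point + float(np.sqrt(sum(t[1] ** 2 for t in terms)))
    return max(lo, 0.0), hi


def mover_ci(
    bias: float,
    se_bias: float,
    vc: VarianceComponents,
    alpha: float = 0.05,
    z: float = Z95,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """MOVER confidence intervals for the lower and upper LoA.

    The chi-square interval (l_s2, u_s2) for the total variance and the
    normal interval for the bias are combined by the square-and-add rule;
    by construction each LoA lies inside its own interval, the lower LoA's
    interval extending below it and the upper LoA's above it.
    """
    zq = stats.norm.ppf(1.0 - alpha / 2.0)
    lo_s2, hi_s2 = _total_variance_ci(vc, alpha)
    sd = float(np.sqrt(vc.total))
    l_sd, u_sd = float(np.sqrt(lo_s2)), float(np.sqrt(hi_s2))
    half_bias = zq * se_bias

    lower = bias - z * sd
    upper = bias + z * sd
    # upper LoA = bias + z*sd: down-error from bias low & sd low, up-error opposite
    up_lo = upper - np.sqrt(half_bias ** 2 + (z * (sd - l_sd)) ** 2)
    up_hi = upper + np.sqrt(half_bias ** 2 + (z * (u_sd - sd)) ** 2)
    # lower LoA = bias - z*sd: down-error from bias low & sd high
    lo_lo = lower - np.sqrt(half_bias ** 2 + (z * (u_sd - sd)) ** 2)
    lo_hi = lower + np.sqrt(half_bias ** 2 + (z * (sd - l_sd)) ** 2)
    return (float(lo_lo), float(lo_hi)), (float(up_lo), float(up_hi))


def icc(vc: VarianceComponents) -> float:
    """Intraclass correlation: between-patient share of the total variance."""
    if vc.total <= 0:
        return float("nan")
    return vc.sigma_b2 / vc.total


def analyze_differences(
    ds: DifferenceSet, alpha: float = 0.05, z: float = Z95
) -> AgreementResult:
    """Full agreement analysis of one difference set."""
    bias, se_bias, vc = fit_components(ds)
    lo, hi, sd = limits_of_agreement(bias, vc, z)
    ci_lo, ci_hi = mover_ci(bias, se_bias, vc, alpha=alpha, z=z)
    return AgreementResult(
        bias=bias, se_bias=se_bias, sd_diff=sd, loa_lower=lo, loa_upper=hi,
        ci_loa_lower=ci_lo, ci_loa_upper=ci_hi, icc=icc(vc), vc=vc, z=z,
        scale=ds.scale,
    )


@dataclass
class ReferenceStandardCheck:
    passed: bool
    bpm_ok: bool
    pct_ok: bool
    detail: str


def check_reference_standard(
    result_bpm: AgreementResult,
    result_pct: AgreementResult,
    bpm_limit: float = 5.0,
    pct_limit: float = 10.0,
    include_se: bool = False,
) -> ReferenceStandardCheck:
    """Accuracy band of -5..5 bpm or -10..10% — whichever is largest.

    The check passes when the limits of agreement fall inside the bpm band
    OR inside the percent band (logical OR implements "whichever is
    largest").  With ``include_se`` the limits are widened by one SE (the
    half-width of their MOVER interval divided by z) before comparison.
    """
    def band_ok(res: AgreementResult, limit: float) -> bool:
        lo, hi = res.loa_lower, res.loa_upper
        if include_se:
            zq = stats.norm.ppf(0.975)
            lo -= (lo - res.ci_loa_lower[0]) / zq
            hi += (res.ci_loa_upper[1] - hi) / zq
        return -limit <= lo and hi <= limit

    bpm_ok = band_ok(result_bpm, bpm_limit)
    pct_ok = band_ok(result_pct, pct_limit)
    passed = bpm_ok or pct_ok
    detail = (f"bpm LoA ({result_bpm.loa_lower:.2f}, {result_bpm.loa_upper:.2f}) "
              f"vs +-{bpm_limit:g} bpm: {'ok' if bpm_ok else 'violated'}; "
              f"percent LoA ({result_pct.loa_lower:.2f}, {result_pct.loa_upper:.2f}) "
              f"vs +-{pct_limit:g}%: {'ok' if pct_ok else 'violated'}")
    return ReferenceStandardCheck(passed=passed, bpm_ok=bpm_ok, pct_ok=pct_ok,
                                  detail=detail)


def results_table(results: dict[str, AgreementResult]):
    """Bland-Altman summary table, one column per scale, rounded to 2 dp."""
    import pandas as pd

    rows = ["Bias, mean (SE)", "SD of differences", "Lower LoA (95% CI)",
            "Upper LoA (95% CI)", "Within-patient variance",
            "Between-patient variance", "Intraclass correlation coefficient"]
    cols = {}
    for name, r in results.items():
        cols[name] = [
            f"{r.bias:.2f} ({r.se_bias:.2f})",
            f"{r.sd_diff:.2f}",
            f"{r.loa_lower:.2f} ({r.ci_loa_lower[0]:.2f} to {r.ci_loa_lower[1]:.2f})",
            f"{r.loa_upper:.2f} ({r.ci_loa_upper[0]:.2f} to {r.ci_loa_upper[1]:.2f})",
            f"{r.vc.sigma_w2:.2f}",
            f"{r.vc.sigma_b2:.2f}",
            f"{r.icc:.2f}",
        ]
    return pd.DataFrame(cols, index=rows)
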