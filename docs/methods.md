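# Methods

## Scope and data model

The package analyzes paired heart-rate (HR) streams from two sources on a
shared 1-Hz grid: a reference ECG-derived stream and a wrist-optical
(PPG-derived) stream carrying a 0–4 quality index (QI), optionally
accompanied by a pulse-event series (pulse times + motion flags). Sessions
are phase-labeled (surgery, recovery) and analyzed per phase. All
containers round-trip through plain CSV (`time_s`, `hr_bpm`, `qi`, `phase`;
pulse files with `pulse_time_s`, `motion`), with a JSON ground-truth
sidecar for simulated cohorts.

## HR extraction and the QI surrogate

`extract_hr` converts pulse events to HR with a **trailing, half-open 5-s
window (t−5, t]**, one output per second: HR = 60 / mean(IPIs fully inside
the window); fewer than two pulses in a window yields a missing sample with
QI 0. Window alignment (trailing vs. centered) is a convention, not a
claim — the upstream device documentation does not state it. HR from the
mean IPI (rather than a pulse count) makes the estimate exact on regular
pulse trains, which the tests exploit.

The real device computes its QI by proprietary methods. `assign_qi` is a
**transparent surrogate**: a non-increasing step function of the motion
fraction per window (defaults: QI 4 at ≤0.10, then 3/2/1 at 0.25/0.50/0.75,
else 0). It preserves the only property the pipeline relies on —
monotonicity: more motion never raises the QI — and is not a
reimplementation of the device's confidence estimator.

## Arrhythmia masking

Pulses are tiled into consecutive, non-overlapping 30-s windows. An IPI
belongs to the window containing its **end pulse**, right edge inclusive:
an IPI ending exactly on a boundary stays in that window, an IPI spanning a
boundary falls in the later one, and every IPI appears exactly once. For
*sample* masking the window interval is half-open [start, start+30), so a
1-Hz sample at exactly t = start+30 belongs to the next window. (The two
conventions disagree only on events exactly at a boundary; both are fixed
here and tested.)

Within a window, an IPI is rejected iff either bounding pulse carries a
motion flag; the rejected fraction uses all *detected* IPIs as denominator
(0 if none detected). A window is labeled **arrhythmia** when the rejected
fraction exceeds 0.5 — strictly, so exactly half is kept — or when the AF
score reaches the threshold (default 0.5). Windows with zero detected IPIs
default to arrhythmia (no evidence of sinus rhythm; configurable).

The AF score is a **surrogate Markov model**, since the original detector
is proprietary: successive IPI changes are quantized into three states
(shorter / similar / longer, tolerance ±50 ms), and the score is
logistic(mean log-likelihood ratio) of the observed state transitions under
an AF transition table (uniform, 1/3 everywhere) versus a normal-sinus
table (strongly diagonal, 0.9 stay probability). At least three retained
IPIs are required; otherwise the score is undefined and the window falls
back to the rejection rule alone. The defaults give regular trains scores
below 0.5 and alternating short/long trains scores near 1; a seeded power
test (200 windows per class, AF IPI CV 0.25 vs. NSR jitter CV 0.02) checks
that AF windows score above NSR windows on average and at the 0.5
threshold. No clinical AF-diagnosis claim is made. Whether score-positive
windows (beyond rejection-rule windows) masked QI in the original study is
ambiguous; here both paths mask, and the threshold is configurable.

Masking forces QI to 0 inside arrhythmia windows and never raises a QI.

## Synchronization, categories, coverage, exclusion

`synchronize` maximizes the Pearson correlation of overlapping,
mean-centered, pairwise-complete samples over integer lags in ±120 s
(configurable); ties break toward the smallest |lag|, then toward the
negative lag — a deterministic stand-in for the original visual
inspection. At least 60 complete overlapping pairs are required; an
all-constant stream makes the correlation undefined and returns lag 0 with
a warning. Alignment is per phase. Seeded tests confirm exact recovery of
injected integer lags with within-patient noise up to σw² = 4 and ≥1800
samples; at 600 samples occasional ±1-s flips are expected statistically
and observed.

Each aligned sample is categorized with precedence **arrhythmia > good
(QI=4) > low (QI≤3)**. Coverage sums category durations (1 sample = 1 s);
the denominator is the **entire recorded duration**, not the post-masking
duration, so good + low + arrhythmia = total exactly. A phase-session is
excluded when its good-quality duration is **strictly below 5 minutes**
(exactly 5.0 min is kept); exclusion is per phase, so a patient losing one
phase keeps the other. The paired coverage comparison between phases is a
two-sided Wilcoxon signed-rank test (≥6 complete pairs; an all-zero
difference vector returns p = 1 by convention).

## Agreement estimators

Differences d_ij = HR_PPG − HR_ECG enter only for samples categorized
*good*; the percentage scale uses d% = 100·(PPG − ECG)/ECG with the **ECG
(reference) HR as denominator**, because the accuracy band is stated
relative to the true HR (pairs with ECG = 0 are excluded and counted; the
classic mean-of-both denominator was considered and not used). On a
constant reference HR h, every percent difference equals (100/h)× the
absolute difference exactly, which is property-tested.

The one-way random-effects fit is the **unbalanced ANOVA method of
moments**, chosen over likelihood methods because the published procedure
specifies observation-weighted bias and between-variance and the method of
moments reproduces it in closed form (REML from statsmodels serves as an
independent cross-check on balanced data in the tests, where the two
coincide):

- bias = Σ d_ij / N (observation-weighted grand mean), N = Σ m_i;
- σ̂w² = MSW = Σ (d_ij − d̄_i)² / (N − n);
- MSB = Σ m_i (d̄_i − bias)² / (n − 1), m₀ = (N − Σ m_i²/N)/(n − 1);
- σ̂b² = max(0, (MSB − MSW)/m₀) — negative estimates truncated to 0, which
  propagates to the ICC and the LoA;
- SE(bias) = √(Σ w_i² (σ̂b² + σ̂w²/m_i)), w_i = m_i/N (random-effects
  variance of the weighted mean);
- LoA = bias ± z·√(σ̂b² + σ̂w²) with z = 1.96 (the conventional 95%
  multiplier; configurable);
- ICC = σ̂b²/(σ̂b² + σ̂w²).

**MOVER confidence intervals.** The total variance is the linear
combination σ̂² = MSB/m₀ + (1 − 1/m₀)·MSW of two independent mean squares
with dfs (n−1, N−n); its 95% interval is the modified-large-sample
(Graybill–Wang) construction, and the LoA intervals merge it with the
normal interval for the bias by the MOVER square-and-add rule. The exact
df recipe of the original reference is not reproduced in the source text;
this construction satisfies the method's defining contract, verified by
simulation: each true LoA is covered by its 95% interval in 95% ± 4% of
200 seeded replicates (n = 30 patients, m = 50 pairs), intervals always
contain their point LoA, and widths shrink monotonically in n.

The accuracy-band check passes when the LoA fit inside −5..5 bpm **or**
−10..10% ("whichever is largest" = logical OR of the two scale checks);
optionally the limits are widened by one SE first.

Rounding in report tables is 2 decimals; all internal computation is full
precision.

## Synthetic cohorts

The generator states a world and stays there; its defaults are the study's
published operating point where one exists:

| parameter | default | origin |
|---|---|---|
| n_patients | 99 | analyzed cohort size |
| surgery / recovery median duration | 87 / 58 min | published medians |
| duration_log_sd | 0.5 | lognormal dispersion ≈ published IQRs |
| true_bias | −0.15 bpm | surgery-phase bias |
| sigma_b2 / sigma_w2 | 0.20 / 2.04 bpm² | surgery-phase components |
| qi_good_prob | 0.765 | overall good-quality coverage |
| af_prevalence | 8/99 | AF history count in the cohort table |
| clock offset | ±30 s integer | so synchronization has an exact answer |
| hr_baseline_range | 50–90 bpm | plausible perioperative resting range |
| hr_walk_sd | 0.3 bpm/s | smooth trajectories, chosen once |
| motion bursts | 2/h, mean 20 s | patients mostly immobilized |
| NSR jitter CV / AF IPI CV | 0.02 / 0.25 | separates the rhythm classes |

True HR is a bounded Gaussian random walk reflected at [30, 180] bpm — the
source only requires that HR varies smoothly over a session, so any bounded
smooth process suffices and the parameters are exposed. Differences are
injected additively onto the reference stream (d_ij is defined as PPG −
ECG). QI is generated as a label process (two-state persistence chain,
dwell ≈ 60 s) rather than computed from a waveform, since the real QI is
proprietary and the pipeline consumes labels either way; QI=0 samples have
their HR blanked (output unavailable). One global seed fans out through
`numpy.random.SeedSequence.spawn` to per-patient substreams, so cohorts are
bit-identical given config + seed and patients are independently
reproducible. Per-patient durations are lognormal around the phase medians
because the observation-time distribution was reported only as non-normal;
the dispersion is a parameter, not a claim.

**What a green test does not establish:** the simulator emulates HR samples
and pulse events, not optical waveforms; no drug/pharmacology effects, no
heteroscedasticity (variance growing with HR), and no autocorrelation of
within-patient differences. The last is the analysis model's own stated
assumption — repeated differences on a patient are treated as independent —
and real perioperative data likely violate it; the simulator can be
extended to inject AR(1) differences to *measure* the resulting CI
undercoverage, but no correction is applied. Cohort-level results of the
original study (its coverage medians, its biases, its Wilcoxon p-value)
are data-dependent and not reproducible without the raw recordings; tests
pin the arithmetic the published summary tables make self-consistent plus
the estimator and simulation properties above.

## Numerical and degenerate-input choices

- Two printed cells in the published per-phase tables are inconsistent with
  their own inputs at full precision (surgery upper LoA prints 2.79 where
  bias −0.15 gives 2.78; recovery lower LoA prints −2.80 and SD 1.38 where
  the components give −2.79 and 1.37) — consistent with a printed bias
  rounded from a slightly smaller magnitude. The implementation reports
  full-precision values; tests pin the arithmetically consistent cells.
- Variance components are inestimable with fewer than 2 patients or with no
  patient contributing repeated observations; these raise clear errors.
- ICC with zero total variance is reported as missing (NaN).
- Zero-variance inputs collapse both LoA onto the bias.
- `exclude_short` is idempotent; categories conserve total duration exactly
  in sample counts.
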