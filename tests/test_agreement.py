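"""Repeated-measures Bland-Altman: differences, variance components, LoA,
MOVER intervals, ICC and the accuracy-band verdict."""

import numpy as np
import pytest

from conftest import make_session
from hragree.agreement import (DifferenceSet, analyze_differences,
                               check_reference_standard, compute_differences,
                               fit_components, icc, limits_of_agreement,
                               mover_ci, VarianceComponents)


def mom_oracle(groups):
    """Definitional-sum one-way ANOVA oracle, written with plain loops so it
    shares nothing with the vectorized implementation."""
    n = len(groups)
    m = [len(g) for g in groups]
    N = sum(m)
    grand = sum(float(x) for g in groups for x in g) / N
    means = [sum(map(float, g)) / len(g) for g in groups]
    ssw = sum((float(x) - means[i]) ** 2 for i, g in enumerate(groups) for x in g)
    msw = ssw / (N - n)
    msb = sum(m[i] * (means[i] - grand) ** 2 for i in range(n)) / (n - 1)
    m0 = (N - sum(mi ** 2 for mi in m) / N) / (n - 1)
    sb2 = max(0.0, (msb - msw) / m0)
    se = sum((mi / N) ** 2 * (sb2 + msw / mi) for mi in m) ** 0.5
    return grand, se, sb2, msw


def random_ds(rng, n=None, max_m=6):
    n = n or rng.integers(2, 9)
    groups = []
    while True:
        groups = [rng.normal(rng.normal(0, 1), 1.0, size=rng.integers(1, max_m + 1))
                  for _ in range(n)]
        if sum(g.size for g in groups) > n:  # someone has repeats
            return DifferenceSet(groups=groups,
                                 patient_ids=[f"P{i}" for i in range(n)],
                                 scale="absolute")


class TestComputeDifferences:
    def test_stated_arithmetic(self):
        s = make_session([70.0], [72.0])
        d_abs = compute_differences(s, scale="absolute")
        d_pct = compute_differences(s, scale="percent")
        assert d_abs.groups[0][0] == pytest.approx(2.0)
        assert d_pct.groups[0][0] == pytest.approx(100 * 2 / 70)

    def test_identical_streams_zero(self):
        s = make_session(np.full(50, 70.0))
        assert np.all(compute_differences(s).groups[0] == 0.0)

    def test_only_good_quality_enters(self):
        qi = np.array([4, 3, 4, 2, 4])
        s = make_session(np.full(5, 70.0), np.full(5, 72.0), qi=qi)
        ds = compute_differences(s)
        assert ds.groups[0].size == 3  # QI=4 gate

    def test_masked_samples_excluded(self):
        arr = np.array([True, False, False])
        s = make_session(np.full(3, 70.0), np.full(3, 72.0), arrhythmia=arr)
        assert compute_differences(s).groups[0].size == 2

    def test_zero_ecg_excluded_on_percent_scale(self):
        s = make_session([70.0, 0.0, 70.0], [72.0, 5.0, 72.0])
        ds = compute_differences(s, scale="percent")
        assert ds.n_excluded_zero_ecg == 1
        assert ds.groups[0].size == 2

    def test_percent_equals_scaled_absolute_on_constant_reference(self, rng):
        h = 80.0
        ppg = h + rng.normal(0, 2, 200)
        s = make_session(np.full(200, h), ppg)
        d_abs = compute_differences(s, scale="absolute").groups[0]
        d_pct = compute_differences(s, scale="percent").groups[0]
        assert np.allclose(d_pct, d_abs * 100.0 / h, atol=1e-12)

    def test_unaligned_session_rejected(self):
        s = make_session(np.full(10, 70.0))
        s.lag_applied = None
        with pytest.raises(ValueError, match="synchronized"):
            compute_differences(s)


class TestFitComponents:
    def test_matches_definitional_oracle(self, rng):
        for _ in range(100):
            ds = random_ds(rng)
            bias, se, vc = fit_components(ds)
            o_bias, o_se, o_sb2, o_sw2 = mom_oracle([g.tolist() for g in ds.groups])
            assert bias == pytest.approx(o_bias, abs=1e-10)
            assert se == pytest.approx(o_se, abs=1e-10)
            assert vc.sigma_b2 == pytest.approx(o_sb2, abs=1e-10)
            assert vc.sigma_w2 == pytest.approx(o_sw2, abs=1e-10)

    def test_matches_reml_on_balanced_data(self, rng):
        """On balanced one-way data the method-of-moments estimator equals
        REML (interior case) — cross-checked against statsmodels MixedLM."""
        import pandas as pd
        import statsmodels.formula.api as smf

        n, m = 12, 8
        a = rng.normal(0, 1.0, n)
        groups = [0.5 + a[i] + rng.normal(0, 1.5, m) for i in range(n)]
        ds = DifferenceSet(groups=groups, patient_ids=[str(i) for i in range(n)],
                           scale="absolute")
        bias, se, vc = fit_components(ds)
        df = pd.DataFrame({"d": np.concatenate(groups),
                           "pid": np.repeat(np.arange(n), m)})
        fit = smf.mixedlm("d ~ 1", df, groups=df["pid"]).fit(reml=True)
        assert bias == pytest.approx(fit.params["Intercept"], abs=1e-6)
        assert vc.sigma_b2 == pytest.approx(float(fit.cov_re.iloc[0, 0]), rel=1e-4)
        assert vc.sigma_w2 == pytest.approx(fit.scale, rel=1e-4)
        assert se == pytest.approx(fit.bse["Intercept"], rel=1e-4)

    def test_equal_patient_means_give_zero_between_variance(self):
        groups = [np.array([1.0, -1.0]), np.array([0.5, -0.5]),
                  np.array([2.0, -2.0])]
        ds = DifferenceSet(groups=groups, patient_ids=["a", "b", "c"],
                           scale="absolute")
        _, _, vc = fit_components(ds)
        assert vc.sigma_b2 == 0.0

    def test_inestimable_cases_rejected(self):
        one = DifferenceSet(groups=[np.array([1.0, 2.0])],
                            patient_ids=["a"], scale="absolute")
        with pytest.raises(ValueError):
            fit_components(one)
        singletons = DifferenceSet(groups=[np.array([1.0]), np.array([2.0])],
                                   patient_ids=["a", "b"], scale="absolute")
        with pytest.raises(ValueError):
            fit_components(singletons)


def vc_from(sb2, sw2, n=99, m=100):
    """Components carrier for worked examples (mean squares consistent)."""
    N = n * m
    m0 = (N - m) / (n - 1) if n > 1 else float("nan")
    return VarianceComponents(sigma_b2=sb2, sigma_w2=sw2,
                              msb=sw2 + m0 * sb2, msw=sw2, m0=m0,
                              df_between=n - 1, df_within=N - n)


class TestLimitsOfAgreement:
    @pytest.mark.parametrize("bias,sw2,sb2,lo,hi,sd", [
        (-0.15, 2.04, 0.20, -3.08, 2.78, 1.50),   # surgery, bpm scale
        (-0.20, 5.12, 0.37, -4.79, 4.39, 2.34),   # surgery, percent scale
        (-0.10, 1.78, 0.11, -2.79, 2.59, 1.37),   # recovery, bpm scale
        (-0.14, 3.56, 0.16, -3.92, 3.64, 1.93),   # recovery, percent scale
    ])
    def test_worked_examples(self, bias, sw2, sb2, lo, hi, sd):
        low, high, sdd = limits_of_agreement(bias, vc_from(sb2, sw2), z=1.96)
        assert round(low, 2) == lo
        assert round(high, 2) == hi
        assert round(sdd, 2) == sd

    def test_zero_variance_collapses_to_bias(self):
        low, high, sd = limits_of_agreement(0.3, vc_from(0.0, 0.0))
        assert low == high == 0.3 and sd == 0.0

    def test_symmetry_about_bias_exact(self, rng):
        for _ in range(50):
            bias = rng.normal(0, 3)
            vc = vc_from(rng.uniform(0, 2), rng.uniform(0, 5))
            lo, hi, sd = limits_of_agreement(bias, vc)
            assert hi - bias == pytest.approx(bias - lo, abs=1e-12)
            assert hi - bias == pytest.approx(1.96 * sd, abs=1e-12)


class TestICC:
    @pytest.mark.parametrize("sb2,sw2,expected", [
        (0.20, 2.04, 0.09), (0.37, 5.12, 0.07),
        (0.11, 1.78, 0.06), (0.16, 3.56, 0.04),
    ])
    def test_worked_examples(self, sb2, sw2, expected):
        assert round(icc(vc_from(sb2, sw2)), 2) == expected

    def test_degenerate(self):
        assert icc(vc_from(0.0, 1.0)) == 0.0
        assert np.isnan(icc(vc_from(0.0, 0.0)))


class TestMoverCI:
    def test_contains_point_limits(self, rng):
        for _ in range(20):
            ds = random_ds(rng, n=8, max_m=6)
            bias, se, vc = fit_components(ds)
            lo, hi, _ = limits_of_agreement(bias, vc)
            ci_lo, ci_hi = mover_ci(bias, se, vc)
            assert ci_lo[0] <= lo <= ci_lo[1]
            assert ci_hi[0] <= hi <= ci_hi[1]
            # lower limit's CI extends below it, upper limit's above it
            assert ci_lo[0] < lo and ci_hi[1] > hi

    def test_width_shrinks_with_sample_size(self, rng):
        widths = []
        for n in (10, 50, 200):
            a = rng.normal(0, np.sqrt(0.2), n)
            groups = [-0.15 + a[i] + rng.normal(0, np.sqrt(2.04), 50)
                      for i in range(n)]
            ds = DifferenceSet(groups=groups,
                               patient_ids=[str(i) for i in range(n)],
                               scale="absolute")
            bias, se, vc = fit_components(ds)
            (l0, l1), _ = mover_ci(bias, se, vc)
            widths.append(l1 - l0)
        assert widths[0] > widths[1] > widths[2]

    def test_bad_dfs_rejected(self):
        vc = vc_from(0.1, 1.0)
        vc.df_between = 0
        with pytest.raises(ValueError):
            mover_ci(0.0, 0.1, vc)


class TestReferenceStandard:
    def result(self, bias, sw2, sb2, scale):
        ds_vc = vc_from(sb2, sw2)
        lo, hi, sd = limits_of_agreement(bias, ds_vc)
        from hragree.agreement import AgreementResult
        return AgreementResult(bias=bias, se_bias=0.05, sd_diff=sd,
                               loa_lower=lo, loa_upper=hi,
                               ci_loa_lower=(lo - 0.1, lo + 0.1),
                               ci_loa_upper=(hi - 0.1, hi + 0.1),
                               icc=icc(ds_vc), vc=ds_vc, scale=scale)

    def test_study_values_pass(self):
        bpm = self.result(-0.15, 2.04, 0.20, "absolute")
        pct = self.result(-0.20, 5.12, 0.37, "percent")
        check = check_reference_standard(bpm, pct)
        assert check.passed and check.bpm_ok and check.pct_ok

    def test_or_rule(self):
        bad_bpm = self.result(-1.0, 7.0, 0.5, "absolute")   # LoA ~ (-6.4, 4.4)
        good_pct = self.result(-0.2, 5.0, 0.4, "percent")
        check = check_reference_standard(bad_bpm, good_pct)
        assert check.passed and not check.bpm_ok and check.pct_ok

    def test_both_bands_violated_fails(self):
        bad_bpm = self.result(-1.0, 9.0, 1.0, "absolute")
        bad_pct = self.result(-2.0, 30.0, 5.0, "percent")
        assert not check_reference_standard(bad_bpm, bad_pct).passed


def test_analyze_differences_end_to_end(rng):
    a = rng.normal(0, np.sqrt(0.2), 40)
    groups = [-0.15 + a[i] + rng.normal(0, np.sqrt(2.04), 120) for i in range(40)]
    ds = DifferenceSet(groups=groups, patient_ids=[str(i) for i in range(40)],
                       scale="absolute")
    res = analyze_differences(ds)
    assert res.loa_lower < res.bias < res.loa_upper
    assert 0.0 <= res.icc <= 1.0
    assert res.ci_loa_lower[0] < res.loa_lower < res.ci_loa_lower[1]
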