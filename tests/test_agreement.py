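import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cocompare.agreement import (
    bland_altman,
    combine_repeatability,
    combined_repeatability,
    interchangeability,
    loa_confidence_intervals,
    mpe,
    mpe_confidence_interval,
    nonparametric_loa,
    normality_check,
    proportional_bias,
    repeatability_percent,
    repeatability_supports_interchangeability,
    repeated_measures_loa,
)
from cocompare.datamodel import PairedObservation
from cocompare.errors import DomainError, InsufficientDataError

from conftest import build_pairs


class TestBlandAltman:
    def test_degenerate_agreement(self):
        pairs = build_pairs([("P1", 1, 2.5, 2.5), ("P2", 1, 2.5, 2.5), ("P3", 1, 2.5, 2.5)])
        res = bland_altman(pairs)
        assert res.bias == 0
        assert res.precision == 0
        assert (res.loa_lower, res.loa_upper) == (0, 0)
        assert res.mpe == 0

    def test_three_point_closed_form(self):
        pairs = build_pairs([("A", 1, 4.0, 5.0), ("B", 1, 5.0, 5.0), ("C", 1, 6.0, 5.0)])
        res = bland_altman(pairs)
        assert res.bias == pytest.approx(0)
        assert res.precision == pytest.approx(1.0)
        assert res.loa_lower == pytest.approx(-1.96)
        assert res.loa_upper == pytest.approx(1.96)
        assert res.grand_mean == pytest.approx(5.0)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            bland_altman(build_pairs([("A", 1, 2.5, 2.4)]))

    def test_loa_symmetric_about_bias(self, rng):
        pairs = build_pairs(
            [(f"P{i}", 1, float(rng.uniform(2, 4)), float(rng.uniform(2, 4))) for i in range(30)]
        )
        res = bland_altman(pairs)
        assert res.loa_upper - res.bias == pytest.approx(res.bias - res.loa_lower, abs=1e-12)

    def test_permutation_invariance(self, rng):
        recs = [(f"P{i}", 1, float(rng.uniform(2, 4)), float(rng.uniform(2, 4))) for i in range(20)]
        a = bland_altman(build_pairs(recs))
        order = rng.permutation(len(recs))
        b = bland_altman(build_pairs([recs[i] for i in order]))
        assert a.bias == pytest.approx(b.bias)
        assert a.precision == pytest.approx(b.precision)

    @given(k=st.floats(min_value=0.1, max_value=10))
    @settings(max_examples=25)
    def test_scaling_property(self, k):
        rng = np.random.default_rng(7)
        recs = [(f"P{i}", 1, float(rng.uniform(2, 4)), float(rng.uniform(2, 4))) for i in range(20)]
        base = bland_altman(build_pairs(recs))
        scaled = bland_altman(build_pairs([(p, t, k * a, k * b) for p, t, a, b in recs]))
        assert scaled.bias == pytest.approx(k * base.bias, rel=1e-9)
        assert scaled.precision == pytest.approx(k * base.precision, rel=1e-9)
        assert scaled.loa_upper == pytest.approx(k * base.loa_upper, rel=1e-9)
        assert scaled.mpe == pytest.approx(base.mpe, rel=1e-9)


class TestMpe:
    def test_perfect_precision(self):
        assert mpe(0, 3.1) == 0

    def test_direct_formula(self):
        assert mpe(1.0, 10.0) == pytest.approx(19.6)

    def test_printed_inputs(self):
        assert mpe(0.20, 2.65) == pytest.approx(14.79, abs=0.005)

    def test_domain(self):
        with pytest.raises(DomainError):
            mpe(0.2, 0)

    def test_interchangeability(self):
        assert interchangeability(14.7)
        assert not interchangeability(30.0)
        assert not interchangeability(45.2)


class TestLoaConfidenceIntervals:
    def test_reproduces_study_bias_ci(self):
        ci_bias, _, _ = loa_confidence_intervals(0.0241, 0.20, 273)
        assert round(ci_bias[0], 2) == 0.00
        assert round(ci_bias[1], 2) == 0.05

    def test_zero_precision_collapses(self):
        ci_bias, ci_lo, ci_hi = loa_confidence_intervals(0.5, 0.0, 50)
        assert ci_bias == (0.5, 0.5)
        assert ci_lo == (0.5, 0.5)
        assert ci_hi == (0.5, 0.5)

    def test_asymptotic_width(self):
        n = 10000
        ci_bias, _, _ = loa_confidence_intervals(0.0, 1.0, n)
        assert ci_bias[1] == pytest.approx(1.96 / math.sqrt(n), rel=0.005)

    def test_insufficient(self):
        with pytest.raises(InsufficientDataError):
            loa_confidence_intervals(0, 1, 1)

    def test_mpe_ci_brackets_point(self):
        lo, hi = mpe_confidence_interval(0.20, 2.65, 273)
        point = mpe(0.20, 2.65)
        assert lo < point < hi


class TestNormalityCheck:
    def test_heavy_tailed_rejected(self):
        rng = np.random.default_rng(42)
        x = rng.standard_t(df=2, size=500) * 0.2
        _, p = normality_check(x)
        assert p < 0.05

    def test_normal_majority_pass(self):
        passed = 0
        for seed in range(20):
            x = np.random.default_rng(seed).normal(size=500)
            _, p = normality_check(x)
            passed += p > 0.05
        assert passed >= 15

    def test_constant_sample(self):
        assert normality_check([0.1] * 10) == (1.0, 1.0)

    def test_domain(self):
        with pytest.raises(DomainError):
            normality_check([1.0, 2.0])


def _brute_force_quantile(xs, p):
    """Linear interpolation between order statistics at 1 + (n-1)p."""
    xs = sorted(xs)
    h = 1 + (len(xs) - 1) * p
    lo = math.floor(h)
    frac = h - lo
    if lo >= len(xs):
        return xs[-1]
    return xs[lo - 1] + frac * (xs[lo] - xs[lo - 1])


class TestNonparametricLoa:
    def test_constant(self):
        assert nonparametric_loa([0.3] * 10) == (0.3, 0.3)

    def test_one_to_twenty(self):
        lo, hi = nonparametric_loa(list(range(1, 21)))
        assert lo == pytest.approx(1.95)
        assert hi == pytest.approx(19.05)

    def test_outlier_robustness(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 0.2, size=200)
        x_out = np.append(x, 50.0)
        par_width = 2 * 1.96 * x.std(ddof=1)
        par_width_out = 2 * 1.96 * x_out.std(ddof=1)
        np_lo, np_hi = nonparametric_loa(x)
        np_lo2, np_hi2 = nonparametric_loa(x_out)
        assert (par_width_out - par_width) > ((np_hi2 - np_lo2) - (np_hi - np_lo))

    @given(
        xs=st.lists(
            st.floats(min_value=-100, max_value=100, allow_nan=False),
            min_size=2,
            max_size=50,
        )
    )
    @settings(max_examples=200)
    def test_matches_brute_force_oracle(self, xs):
        lo, hi = nonparametric_loa(xs)
        assert lo == pytest.approx(_brute_force_quantile(xs, 0.05), abs=1e-9)
        assert hi == pytest.approx(_brute_force_quantile(xs, 0.95), abs=1e-9)

    def test_insufficient(self):
        with pytest.raises(InsufficientDataError):
            nonparametric_loa([1.0])


class TestRepeatedMeasuresLoa:
    def test_reduces_to_naive_with_single_pairs(self, rng):
        diffs = {f"P{i}": [float(rng.normal(0.1, 0.2))] for i in range(25)}
        lo, hi, sd_total = repeated_measures_loa(diffs)
        flat = np.array([v[0] for v in diffs.values()])
        naive_sd = flat.std(ddof=1)
        assert sd_total == pytest.approx(naive_sd, rel=1e-12)
        assert lo == pytest.approx(flat.mean() - 1.96 * naive_sd, rel=1e-9)
        assert hi == pytest.approx(flat.mean() + 1.96 * naive_sd, rel=1e-9)

    def test_two_patient_worked_example(self):
        lo, hi, sd_total = repeated_measures_loa({"P1": [0.0, 0.0], "P2": [2.0, 2.0]})
        assert sd_total == pytest.approx(math.sqrt(2), abs=1e-6)
        naive = np.array([0, 0, 2, 2.0]).std(ddof=1)
        assert naive == pytest.approx(1.1547, abs=1e-4)
        assert sd_total > naive
        assert lo == pytest.approx(1 - 1.96 * math.sqrt(2))
        assert hi == pytest.approx(1 + 1.96 * math.sqrt(2))

    def test_wider_than_naive_with_between_patient_variance(self):
        rng = np.random.default_rng(11)
        diffs = {}
        for i in range(40):
            b = rng.normal(0, 0.3)
            diffs[f"P{i}"] = list(b + rng.normal(0, 0.1, size=5))
        _, _, sd_total = repeated_measures_loa(diffs)
        flat = np.concatenate(list(diffs.values()))
        assert sd_total > flat.std(ddof=1)

    def test_single_patient_error(self):
        with pytest.raises(InsufficientDataError):
            repeated_measures_loa({"P1": [0.1, 0.2]})


class TestRepeatability:
    def test_combine_pythagoras(self):
        assert combine_repeatability(10, 10) == pytest.approx(math.sqrt(200))

    def test_zero_variance_degeneracy(self):
        flat = [[5.0, 5.0], [5.0, 5.0], [5.0, 5.0]]
        noisy = [[9.0, 11.0], [10.0, 10.0], [8.0, 12.0]]
        combined = combined_repeatability(flat, noisy)
        assert combined == pytest.approx(repeatability_percent(noisy))

    def test_anova_within_sd(self):
        # each group mean 10 with replicates +/-1: pooled within sd = sqrt(2)
        groups = [[9.0, 11.0]] * 6
        rep = repeatability_percent(groups)
        assert rep == pytest.approx(1.96 * math.sqrt(2) / 10 * 100)

    def test_interchangeability_rule(self):
        assert repeatability_supports_interchangeability(14.7, 40.6)
        assert not repeatability_supports_interchangeability(41.0, 40.6)

    def test_no_replicates_error(self):
        with pytest.raises(InsufficientDataError):
            repeatability_percent([[1.0], [2.0]])


class TestProportionalBias:
    def test_recovers_planted_slope(self):
        rng = np.random.default_rng(21)
        pairs = []
        for i in range(50):
            b = rng.normal(0, 0.05)
            for tp in range(1, 6):
                ref = float(rng.uniform(2.0, 3.5))
                diff = 0.1 * ref + b + rng.normal(0, 0.05)
                pairs.append(PairedObservation(f"P{i}", tp, ref + diff, ref))
        slope, se, p = proportional_bias(pairs)
        assert slope == pytest.approx(0.1, abs=0.02)
        assert p < 0.05

    def test_null_simulation(self):
        non_significant = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            pairs = []
            for i in range(50):
                b = rng.normal(0, 0.1)
                for tp in range(1, 6):
                    ref = float(rng.uniform(2.0, 3.5))
                    diff = b + rng.normal(0, 0.2)
                    pairs.append(PairedObservation(f"P{i}", tp, max(0.1, ref + diff), ref))
            slope, _, p = proportional_bias(pairs)
            non_significant += p > 0.05
        assert non_significant >= 15

    def test_uniform_bias_verdict_logic(self):
        # p >= 0.05 means no proportional bias detected
        assert not (0.785 < 0.05)

    def test_constant_reference_error(self):
        pairs = build_pairs([(f"P{i}", 1, 2.6, 2.5) for i in range(5)])
        with pytest.raises(DomainError):
            proportional_bias(pairs)

    def test_too_few_patients(self):
        pairs = build_pairs([("A", 1, 2.6, 2.5), ("B", 1, 2.7, 2.9)])
        with pytest.raises(InsufficientDataError):
            proportional_bias(pairs)
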