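"""Bland-Altman agreement analysis with confidence intervals and the four
robustness checks (normality/non-parametric limits, repeated-measures
correction, combined repeatability, proportional bias).

Conventions
-----------
* Differences are test minus reference; the bias is their mean, the
  precision their sample standard deviation (n-1 denominator).
* Limits of agreement (LoA) are bias +/- z * sd with z = 1.96 by default.
* The mean percentage error (MPE) is z * sd / grand mean * 100; values below
  30% are conventionally taken as clinically acceptable interchangeability.
* Non-normality of the differences does not switch the parametric analysis
  off: parametric and percentile LoA are always reported side by side.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .datamodel import PairedObservation
from .errors import DomainError, InsufficientDataError

Z_DEFAULT = 1.96
MPE_THRESHOLD_DEFAULT = 30.0


@dataclass(frozen=True)
class AgreementResult:
    """Bland-Altman summary for one set of paired observations."""

    n: int
    bias: float
    precision: float
    loa_lower: float
    loa_upper: float
    ci_bias: tuple[float, float]
    ci_loa_lower: tuple[float, float]
    ci_loa_upper: tuple[float, float]
    grand_mean: float
    mpe: float
    ci_mpe: tuple[float, float]


@dataclass(frozen=True)
class RobustnessChecks:
    """Outputs of the four Bland-Altman robustness checks."""

    shapiro_w: float
    shapiro_p: float
    np_loa_lower: float
    np_loa_upper: float
    corrected_loa_lower: float
    corrected_loa_upper: float
    corrected_sd_total: float
    combined_repeatability: float | None
    prop_slope: float
    prop_slope_se: float
    prop_slope_p: float


def mpe(precision: float, grand_mean: float, z: float = Z_DEFAULT) -> float:
    """Mean percentage error: z * sd of differences / grand mean * 100."""
    if grand_mean <= 0:
        raise DomainError(f"grand_mean must be > 0, got {grand_mean}")
    if precision < 0:
        raise DomainError(f"precision must be >= 0, got {precision}")
    return z * precision / grand_mean * 100.0


def interchangeability(mpe_value: float, threshold: float = MPE_THRESHOLD_DEFAULT) -> bool:
    """Clinical acceptability verdict: strictly below the MPE threshold."""
    if mpe_value < 0 or threshold < 0:
        raise DomainError("mpe_value and threshold must be >= 0")
    return mpe_value < threshold


def loa_confidence_intervals(
    bias: float, precision: float, n: int, z: float = Z_DEFAULT
) -> tuple[tuple[float, float], tuple[float, float], tuple[float, float]]:
    """95% confidence intervals for the bias and each limit of agreement.

    Bias CI uses the exact t interval sd/sqrt(n). Each LoA CI uses the
    standard-error form sd * sqrt(1/n + z^2 / (2(n-1))) with a t(n-1)
    multiplier.
    """
    if n < 2:
        raise InsufficientDataError(f"need n >= 2 for confidence intervals, got {n}")
    if precision < 0:
        raise DomainError("precision must be >= 0")
    t = stats.t.ppf(0.975, n - 1)
    se_bias = precision / math.sqrt(n)
    se_loa = precision * math.sqrt(1.0 / n + z**2 / (2.0 * (n - 1)))
    lower, upper = bias - z * precision, bias + z * precision
    return (
        (bias - t * se_bias, bias + t * se_bias),
        (lower - t * se_loa, lower + t * se_loa),
        (upper - t * se_loa, upper + t * se_loa),
    )


def mpe_confidence_interval(
    precision: float, grand_mean: float, n: int, z: float = Z_DEFAULT
) -> tuple[float, float]:
    """Approximate 95% CI for the MPE.

    Propagates the chi-square sampling distribution of the sd (df = n-1)
    through the MPE formula, holding the grand mean fixed. This is an
    approximation; it ignores uncertainty in the denominator.
    """
    if n < 2:
        raise InsufficientDataError(f"need n >= 2, got {n}")
    df = n - 1
    sd_lo = precision * math.sqrt(df / stats.chi2.ppf(0.975, df))
    sd_hi = precision * math.sqrt(df / stats.chi2.ppf(0.025, df))
    return (mpe(sd_lo, grand_mean, z), mpe(sd_hi, grand_mean, z))


def _differences(pairs: Sequence[PairedObservation]) -> np.ndarray:
    return np.asarray([p.difference for p in pairs], dtype=float)


def bland_altman(
    pairs: Sequence[PairedObservation], z: float = Z_DEFAULT
) -> AgreementResult:
    """Full Bland-Altman analysis of a collection of paired observations."""
    n = len(pairs)
    if n < 2:
        raise InsufficientDataError(f"need at least 2 pairs, got {n}")
    diffs = _differences(pairs)
    means = np.asarray([p.mean_pair for p in pairs], dtype=float)
    bias = float(diffs.mean())
    precision = float(diffs.std(ddof=1))
    grand_mean = float(means.mean())
    ci_bias, ci_lo, ci_hi = loa_confidence_intervals(bias, precision, n, z)
    return AgreementResult(
        n=n,
        bias=bias,
        precision=precision,
        loa_lower=bias - z * precision,
        loa_upper=bias + z * precision,
        ci_bias=ci_bias,
        ci_loa_lower=ci_lo,
        ci_loa_upper=ci_hi,
        grand_mean=grand_mean,
        mpe=mpe(precision, grand_mean, z),
        ci_mpe=mpe_confidence_interval(precision, grand_mean, n, z),
    )


def normality_check(differences: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk test of the differences; returns (W, p).

    The caller decides the parametric vs non-parametric path (conventionally
    at p < 0.05). A constant sample is reported as (1.0, 1.0): there is no
    evidence against normality in a degenerate sample.
    """
    x = np.asarray(list(differences), dtype=float)
    if not 3 <= x.size <= 5000:
        raise DomainError(f"Shapiro-Wilk supported for 3 <= n <= 5000, got {x.size}")
    if np.ptp(x) == 0:
        return (1.0, 1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.shapiro(x)
    return (float(res.statistic), float(res.pvalue))


def nonparametric_loa(
    differences: Sequence[float],
    tail_proportion: float = 0.05,
    method: str = "linear",
) -> tuple[float, float]:
    """Percentile limits of agreement (default 5th and 95th percentiles).

    The default quantile definition interpolates linearly between order
    statistics at position 1 + (n-1)p; alternatives accepted by
    ``numpy.quantile`` may be passed via ``method``.
    """
    x = np.asarray(list(differences), dtype=float)
    if x.size < 2:
        raise InsufficientDataError(f"need n >= 2, got {x.size}")
    if not 0 < tail_proportion < 0.5:
        raise DomainError("tail_proportion must be in (0, 0.5)")
    lo, hi = np.quantile(x, [tail_proportion, 1 - tail_proportion], method=method)
    return (float(lo), float(hi))


def repeated_measures_loa(
    diffs_by_patient: Mapping[str, Sequence[float]], z: float = Z_DEFAULT
) -> tuple[float, float, float]:
    """Limits of agreement corrected for repeated measures per patient.

    Uses the method-of-moments one-way ANOVA decomposition for multiple
    observations per subject when the true value varies between occasions:
    sd_total = sqrt(sigma2_between + sigma2_within), with the between
    component recovered from the between-subject mean square via the
    unbalanced-design coefficient n0. With one observation per subject this
    reduces exactly to the ordinary sample sd.
    """
    groups = [np.asarray(list(v), dtype=float) for v in diffs_by_patient.values()]
    k = len(groups)
    if k < 2:
        raise InsufficientDataError("need >= 2 patients to separate variance components")
    if any(g.size == 0 for g in groups):
        raise DomainError("every patient must contribute at least one difference")
    sizes = np.array([g.size for g in groups], dtype=float)
    n_total = float(sizes.sum())
    grand = float(np.concatenate(groups).mean())
    group_means = np.array([g.mean() for g in groups])

    ss_between = float(np.sum(sizes * (group_means - grand) ** 2))
    ms_between = ss_between / (k - 1)
    df_within = n_total - k
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    ms_within = ss_within / df_within if df_within > 0 else 0.0

    n0 = (n_total - float(np.sum(sizes**2)) / n_total) / (k - 1)
    var_between = max(0.0, (ms_between - ms_within) / n0)
    sd_total = math.sqrt(var_between + ms_within)
    return (grand - z * sd_total, grand + z * sd_total, sd_total)


def repeatability_percent(
    replicate_groups: Sequence[Sequence[float]], z: float = Z_DEFAULT
) -> float:
    """One method's repeatability as a percentage of its grand mean.

    ``replicate_groups`` holds the replicate readings for each
    subject-condition. The within-group sd comes from the pooled one-way
    ANOVA mean square; repeatability = z * within-sd / grand mean * 100.
    """
    groups = [np.asarray(list(g), dtype=float) for g in replicate_groups]
    usable = [g for g in groups if g.size >= 2]
    if len(usable) < 2:
        raise InsufficientDataError(
            "need >= 2 subjects with >= 2 replicates to estimate repeatability"
        )
    df = sum(g.size - 1 for g in usable)
    ssw = sum(float(((g - g.mean()) ** 2).sum()) for g in usable)
    within_sd = math.sqrt(ssw / df)
    grand = float(np.concatenate(groups).mean())
    if grand <= 0:
        raise DomainError("grand mean of replicates must be > 0")
    return z * within_sd / grand * 100.0


def combine_repeatability(rep_ref: float, rep_test: float) -> float:
    """Root-sum-of-squares combination of two methods' repeatability (%)."""
    if rep_ref < 0 or rep_test < 0:
        raise DomainError("repeatability values must be >= 0")
    return math.hypot(rep_ref, rep_test)


def combined_repeatability(
    replicate_sets_ref: Sequence[Sequence[float]],
    replicate_sets_test: Sequence[Sequence[float]],
    z: float = Z_DEFAULT,
) -> float:
    """Combined repeatability (%) of reference and test replicate readings.

    Interchangeability is supported when the MPE does not exceed this value
    (see :func:`repeatability_supports_interchangeability`).
    """
    return combine_repeatability(
        repeatability_percent(replicate_sets_ref, z),
        repeatability_percent(replicate_sets_test, z),
    )


def repeatability_supports_interchangeability(mpe_value: float, combined: float) -> bool:
    """True when the MPE does not exceed the combined repeatability."""
    return mpe_value <= combined


def proportional_bias(
    pairs: Sequence[PairedObservation],
) -> tuple[float, float, float]:
    """Proportional-bias slope from a random-intercept mixed model.

    Fits difference ~ intercept + slope * ci_ref with a per-patient random
    intercept (REML); returns (slope, se, two-sided p) with the p-value from
    a normal approximation on slope/se. A p >= 0.05 supports a uniform bias
    over the measurement range.
    """
    patients = sorted({p.patient_id for p in pairs})
    if len(patients) < 3:
        raise InsufficientDataError(f"need >= 3 patients, got {len(patients)}")
    ref = np.asarray([p.ci_ref for p in pairs], dtype=float)
    if np.ptp(ref) == 0:
        raise DomainError("reference values are constant; slope is unidentifiable")
    diff = _differences(pairs)
    if np.ptp(diff) == 0:
        # perfectly constant differences: flat regression line by definition
        return (0.0, 0.0, 1.0)
    groups = np.asarray([p.patient_id for p in pairs])
    exog = np.column_stack([np.ones_like(ref), ref])

    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(diff, exog, groups=groups)
        fit = model.fit(reml=True)
    slope = float(fit.params[1])
    se = float(fit.bse[1])
    p = float(2 * stats.norm.sf(abs(slope) / se)) if se > 0 else 0.0
    return (slope, se, p)


def robustness_checks(
    pairs: Sequence[PairedObservation],
    replicate_sets_ref: Sequence[Sequence[float]] | None = None,
    replicate_sets_test: Sequence[Sequence[float]] | None = None,
    z: float = Z_DEFAULT,
) -> RobustnessChecks:
    """Run all four robustness checks on a paired dataset.

    Combined repeatability needs trace-level replicate data and is reported
    as None when that is not supplied.
    """
    diffs = _differences(pairs)
    w, p = normality_check(diffs)
    np_lo, np_hi = nonparametric_loa(diffs)
    by_patient: dict[str, list[float]] = {}
    for obs in pairs:
        by_patient.setdefault(obs.patient_id, []).append(obs.difference)
    corr_lo, corr_hi, sd_total = repeated_measures_loa(by_patient, z)
    combined = None
    if replicate_sets_ref is not None and replicate_sets_test is not None:
        combined = combined_repeatability(replicate_sets_ref, replicate_sets_test, z)
    slope, se, slope_p = proportional_bias(pairs)
    return RobustnessChecks(
        shapiro_w=w,
        shapiro_p=p,
        np_loa_lower=np_lo,
        np_loa_upper=np_hi,
        corrected_loa_lower=corr_lo,
        corrected_loa_upper=corr_hi,
        corrected_sd_total=sd_total,
        combined_repeatability=combined,
        prop_slope=slope,
        prop_slope_se=se,
        prop_slope_p=slope_p,
    )
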