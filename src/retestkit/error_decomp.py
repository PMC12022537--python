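"""Systematic-bias testing, random-error magnitude and Bland-Altman
agreement quantities.

Systematic error (learning effect) is the mean paired difference
bias = mean(x - y), with x the chronologically earlier measurement, tested
by a two-sided paired t-test; with this sign convention a test scored in
time units shows positive bias under learning (times shrink) and a
count-scored test shows negative bias (counts grow).  Family-wise type-I
control across the many comparisons of one report uses Holm's step-down
(default) or plain Bonferroni.

Random error is summarized on the score scale by the mean absolute error
MAE = mean |x_i - y_i| and on the percent scale by the mean absolute
percentage error MAPE = mean |(x_i - y_i)/x_i| * 100, always with the
earlier measurement as reference; and distributionally by the Bland-Altman
limits of agreement bias +/- 1.96 * SD(diff), the interval expected to
contain ~95% of test-retest differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import (
    DegenerateDataError,
    InsufficientDataError,
    UndefinedReferenceError,
)
from .study_data import PairedComparison


@dataclass
class AnalysisConfig:
    """Family-wise error policy for a report.

    ``family_size`` is only needed when thresholding externally; the
    adjustment functions infer the family from the p-value vector given.
    """

    alpha: float = 0.05
    multiplicity: str = "holm"  # holm | bonferroni | none
    family_size: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha {self.alpha} outside (0, 1)")
        if self.multiplicity not in {"holm", "bonferroni", "none"}:
            raise ValueError(f"unknown multiplicity {self.multiplicity!r}")
        if self.family_size is not None and self.family_size < 1:
            raise ValueError("family_size must be >= 1")


@dataclass
class BiasTest:
    bias: float
    t_stat: float
    df: int
    p_raw: float
    p_adjusted: float | None = None
    significant: bool | None = None
    degenerate: bool = False  # sd(diff) == 0 with zero bias; p = 1 by convention


@dataclass(frozen=True)
class RandomError:
    mae: float
    mape: float  # percent


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    ci_bias: tuple[float, float] | None
    ci_loa_low: tuple[float, float] | None
    ci_loa_high: tuple[float, float] | None
    n: int


def paired_bias_test(pair: PairedComparison) -> BiasTest:
    """Two-sided paired t-test on d_i = x_i - y_i.

    A zero-variance difference vector with zero bias yields p = 1 by
    convention (flagged ``degenerate``); zero variance with nonzero bias is
    a :class:`DegenerateDataError`.
    """
    d = pair.x - pair.y
    bias = float(d.mean())
    df = pair.n - 1
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        if bias == 0.0:
            return BiasTest(bias=0.0, t_stat=0.0, df=df, p_raw=1.0, degenerate=True)
        raise DegenerateDataError(
            f"{pair.label}: identical nonzero differences; t-test undefined"
        )
    res = stats.ttest_rel(pair.x, pair.y)
    return BiasTest(
        bias=bias, t_stat=float(res.statistic), df=df, p_raw=float(res.pvalue)
    )


def adjust_pvalues(p_list, method: str = "holm") -> np.ndarray:
    """Family-wise adjusted p-values (Holm step-down or Bonferroni).

    ``method='none'`` returns the input unchanged; an empty family returns
    an empty array.
    """
    p = np.asarray(list(p_list), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "none":
        return p.copy()
    if method not in {"holm", "bonferroni"}:
        raise ValueError(f"unknown adjustment method {method!r}")
    _, p_adj, _, _ = multipletests(p, method=method)
    return p_adj


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance threshold alpha / m for a family of m tests."""
    if m < 1:
        raise ValueError("family size must be >= 1")
    return alpha / m


def mae(pair: PairedComparison) -> float:
    """Mean absolute error (1/n) sum |x_i - y_i|, in score units."""
    return float(np.mean(np.abs(pair.x - pair.y)))


def mape(pair: PairedComparison) -> float:
    """Mean absolute percentage error with the earlier measurement (x) as
    reference, in percent."""
    zeros = np.flatnonzero(pair.x == 0.0)
    if zeros.size:
        who = pair.subjects[zeros[0]] if pair.subjects else f"index {zeros[0]}"
        raise UndefinedReferenceError(
            f"{pair.label}: reference value is zero for subject {who}"
        )
    return float(np.mean(np.abs((pair.x - pair.y) / pair.x)) * 100.0)


def random_error(pair: PairedComparison) -> RandomError:
    return RandomError(mae=mae(pair), mape=mape(pair))


def bland_altman(pair: PairedComparison, loa_factor: float = 1.96) -> BlandAltmanResult:
    """Bland-Altman bias, limits of agreement, and their 95% CIs.

    The bias CI is the exact t-interval; each LoA CI uses the standard
    large-sample approximation with variance
    sd^2 (1/n + loa_factor^2 / (2 (n - 1))).  CIs require n >= 3.
    """
    if pair.n < 2:
        raise InsufficientDataError(f"{pair.label}: need n >= 2")
    d = pair.x - pair.y
    n = pair.n
    bias = float(d.mean())
    sd = float(np.std(d, ddof=1))
    loa_low = bias - loa_factor * sd
    loa_high = bias + loa_factor * sd
    ci_bias = ci_lo = ci_hi = None
    if n >= 3:
        tcrit = stats.t.ppf(0.975, n - 1)
        half_bias = tcrit * sd / math.sqrt(n)
        ci_bias = (bias - half_bias, bias + half_bias)
        se_loa = math.sqrt(sd * sd * (1.0 / n + loa_factor**2 / (2.0 * (n - 1))))
        half_loa = tcrit * se_loa
        ci_lo = (loa_low - half_loa, loa_low + half_loa)
        ci_hi = (loa_high - half_loa, loa_high + half_loa)
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        loa_low=loa_low,
        loa_high=loa_high,
        ci_bias=ci_bias,
        ci_loa_low=ci_lo,
        ci_loa_high=ci_hi,
        n=n,
    )


def bland_altman_export(pair: PairedComparison) -> pd.DataFrame:
    """Plot-ready per-subject (mean, difference) table with the constant
    bias/LoA/CI columns repeated, for external Bland-Altman plotting."""
    res = bland_altman(pair)
    df = pd.DataFrame(
        {
            "subject": pair.subjects or range(pair.n),
            "mean": (pair.x + pair.y) / 2.0,
            "difference": pair.x - pair.y,
        }
    )
    df["bias"] = res.bias
    df["loa_low"] = res.loa_low
    df["loa_high"] = res.loa_high
    if res.ci_bias is not None:
        df["ci_bias_low"], df["ci_bias_high"] = res.ci_bias
        df["ci_loa_low_lower"], df["ci_loa_low_upper"] = res.ci_loa_low
        df["ci_loa_high_lower"], df["ci_loa_high_upper"] = res.ci_loa_high
    return df


def normality_check(values) -> tuple[float, float]:
    """Shapiro-Wilk W statistic and p-value for a sample of 3..5000 values.

    Applied to paired differences ahead of bias tests and to raw scores for
    descriptive reporting.  Constant input is degenerate.
    """
    v = np.asarray(values, dtype=float)
    if not 3 <= v.size <= 5000:
        raise InsufficientDataError(
            f"Shapiro-Wilk supports 3 <= n <= 5000; got n={v.size}"
        )
    if np.ptp(v) == 0.0:
        raise DegenerateDataError("constant vector: normality test undefined")
    res = stats.shapiro(v)
    return float(res.statistic), float(res.pvalue)
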