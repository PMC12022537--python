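"""Relative-reliability metrics for paired test-retest data.

The central quantity is the two-way absolute-agreement single-measure
intraclass correlation: subjects are rows, the two testing occasions are
columns of an n x 2 matrix, and a two-way ANOVA decomposes the total sum of
squares into row (subject), column (occasion) and residual parts.  The
agreement ICC,

    ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)),

penalizes systematic shifts between occasions through the MSC term, which
is what makes it the right coefficient when learning effects are on trial.
A second variant, ``paper_formula``, evaluates the same mean squares as
(MSR - MSE) / (MSR + (MSC - MSE)/n) — a form that circulates in the applied
reliability literature without the (k-1) MSE term — so both conventions can
be reported side by side.

95% confidence intervals for ICC(A,1) use the F-based McGraw & Wong
construction (their case for two-way random effects, absolute agreement,
single measures).

From the ICC follow the absolute-error indices

    SEM = SD * sqrt(1 - ICC),      MDC = SEM * 1.96 * sqrt(2),

where the SD basis is, by default, the standard deviation of the paired
differences (a pooled-scores basis is available).  MDC is the smallest
change exceeding measurement error with 95% confidence.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import DomainError, InsufficientDataError, UndefinedIccError
from .study_data import PairedComparison

#: MDC/SEM ratio, 1.96 * sqrt(2)
MDC_FACTOR = 1.96 * math.sqrt(2.0)


@dataclass(frozen=True)
class AnovaDecomposition:
    """Mean squares of the two-way (subjects x occasions) ANOVA."""

    MSR: float
    MSC: float
    MSE: float
    n: int
    k: int

    @property
    def df_rows(self) -> int:
        return self.n - 1

    @property
    def df_cols(self) -> int:
        return self.k - 1

    @property
    def df_error(self) -> int:
        return (self.n - 1) * (self.k - 1)


@dataclass(frozen=True)
class ICCResult:
    estimate: float
    ci_low: float | None
    ci_high: float | None
    variant: str  # standard_A1 | paper_formula
    band: str     # poor | moderate | good | excellent


@dataclass(frozen=True)
class SemMdc:
    sd_basis: float
    sem: float
    mdc: float


def ms_decomposition(pair: PairedComparison) -> AnovaDecomposition:
    """Two-way mean-square decomposition of the n x 2 paired matrix.

    SS_total = SS_rows + SS_cols + SS_error holds exactly (up to floating
    error); the residual SS is clamped at zero against tiny negative
    round-off.
    """
    if pair.n < 2:
        raise InsufficientDataError(f"{pair.label}: need n >= 2")
    m = np.column_stack([pair.x, pair.y])
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * float(np.sum((row_means - grand) ** 2))
    ss_cols = n * float(np.sum((col_means - grand) ** 2))
    ss_total = float(np.sum((m - grand) ** 2))
    ss_error = max(ss_total - ss_rows - ss_cols, 0.0)
    return AnovaDecomposition(
        MSR=ss_rows / (n - 1),
        MSC=ss_cols / (k - 1),
        MSE=ss_error / ((n - 1) * (k - 1)),
        n=n,
        k=k,
    )


def icc_band(estimate: float) -> str:
    """Qualitative reliability band for an ICC point estimate.

    Thresholds: < 0.50 poor, [0.50, 0.75) moderate, [0.75, 0.90) good,
    >= 0.90 excellent.
    """
    if not -1.0 <= estimate <= 1.0:
        raise DomainError(f"ICC estimate {estimate} outside [-1, 1]")
    if estimate < 0.50:
        return "poor"
    if estimate < 0.75:
        return "moderate"
    if estimate < 0.90:
        return "good"
    return "excellent"


def _a1_confidence_interval(
    decomp: AnovaDecomposition, est: float, alpha: float
) -> tuple[float, float]:
    """McGraw-Wong F-based CI for the absolute-agreement single-measure ICC."""
    msr, msc, mse = decomp.MSR, decomp.MSC, decomp.MSE
    n, k = decomp.n, decomp.k
    if mse == 0.0 and msc == 0.0:
        return (1.0, 1.0)
    if est >= 1.0:
        return (1.0, 1.0)
    a = (k * est) / (n * (1.0 - est))
    b = 1.0 + (k * est * (n - 1)) / (n * (1.0 - est))
    num = (a * msc + b * mse) ** 2
    den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = num / den if den > 0 else float(decomp.df_error)
    f_l = stats.f.ppf(1.0 - alpha / 2.0, n - 1, v)
    f_u = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1)
    lower = (n * (msr - f_l * mse)) / (
        f_l * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = (n * (f_u * msr - mse)) / (
        k * msc + (k * n - k - n) * mse + n * f_u * msr
    )
    lower = float(np.clip(lower, -1.0, 1.0))
    upper = float(np.clip(upper, -1.0, 1.0))
    return min(lower, est), max(upper, est)


def icc_agreement(
    decomp: AnovaDecomposition,
    variant: str = "standard_A1",
    alpha: float = 0.05,
) -> ICCResult:
    """Agreement ICC from a mean-square decomposition.

    ``standard_A1`` is the two-way absolute-agreement single-measure ICC
    with an F-based 95% CI; ``paper_formula`` evaluates
    (MSR - MSE) / (MSR + (MSC - MSE)/n) and carries no CI.

    Raises :class:`UndefinedIccError` on a zero denominator and warns on a
    negative estimate (for which the SEM is undefined unless the caller
    clamps to zero).
    """
    msr, msc, mse = decomp.MSR, decomp.MSC, decomp.MSE
    n, k = decomp.n, decomp.k
    if variant == "paper_formula":
        denom = msr + (msc - mse) / n
        ci: tuple[float | None, float | None] = (None, None)
    elif variant == "standard_A1":
        denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    else:
        raise ValueError(f"unknown ICC variant {variant!r}")
    if denom == 0.0:
        raise UndefinedIccError(
            f"ICC denominator is zero (MSR={msr}, MSC={msc}, MSE={mse})"
        )
    est = float((msr - mse) / denom)
    est = float(np.clip(est, -1.0, 1.0))
    if est < 0:
        warnings.warn(
            f"negative ICC estimate {est:.3f}; SEM is undefined unless "
            "clamped to zero",
            stacklevel=2,
        )
    if variant == "standard_A1":
        ci = _a1_confidence_interval(decomp, est, alpha)
    band = icc_band(est)
    return ICCResult(
        estimate=est, ci_low=ci[0], ci_high=ci[1], variant=variant, band=band
    )


def difference_sd(pair: PairedComparison) -> float:
    """Sample SD (ddof=1) of the paired differences x - y; the default SD
    basis of the SEM."""
    return float(np.std(pair.x - pair.y, ddof=1))


def pooled_sd(pair: PairedComparison) -> float:
    """Pooled sample SD of the two score vectors (alternative SEM basis)."""
    vx = np.var(pair.x, ddof=1)
    vy = np.var(pair.y, ddof=1)
    return float(math.sqrt((vx + vy) / 2.0))


def sem_from(sd_basis: float, icc: float) -> float:
    """Standard error of measurement: SD * sqrt(1 - ICC)."""
    if not 0.0 <= icc <= 1.0:
        raise DomainError(f"ICC {icc} outside [0, 1]; clamp or reject first")
    if sd_basis < 0:
        raise DomainError(f"negative SD basis {sd_basis}")
    return sd_basis * math.sqrt(1.0 - icc)


def mdc_from(sem: float) -> float:
    """Minimal detectable change: SEM * 1.96 * sqrt(2)."""
    if sem < 0:
        raise DomainError(f"negative SEM {sem}")
    return sem * MDC_FACTOR


def sem_mdc(pair: PairedComparison, icc: float, basis: str = "diff") -> SemMdc:
    """SEM and MDC for one comparison, with the configured SD basis."""
    if basis == "diff":
        sd = difference_sd(pair)
    elif basis == "pooled":
        sd = pooled_sd(pair)
    else:
        raise ValueError(f"unknown SD basis {basis!r}")
    sem = sem_from(sd, icc)
    return SemMdc(sd_basis=sd, sem=sem, mdc=mdc_from(sem))
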