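"""Reliability and method-agreement statistics.

Single-measures intraclass correlation coefficients from a two-way ANOVA
decomposition (absolute-agreement and consistency forms, with F-based 95%
confidence intervals), Bland-Altman limits of agreement, paired t
comparisons, reconstruction of limits of agreement from published summary
statistics, and the Walter-Eliasziw-Donner sample-size formula for planning
reliability studies.

Notation: a ratings matrix has ``n`` targets (subjects) in rows and ``k``
measurements (sessions, observers or systems) in columns. The two-way model
is ``x_ij = mu + r_i + c_j + e_ij`` with subjects random; the
absolute-agreement single-measures ICC charges systematic column offsets to
the error term, the consistency form does not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "RatingsMatrix",
    "AnovaComponents",
    "ICCResult",
    "BlandAltmanResult",
    "PairedTResult",
    "SampleSizeSpec",
    "two_way_anova",
    "icc_single",
    "interpret_icc",
    "bland_altman",
    "loa_from_summary",
    "paired_t",
    "walter_sample_size",
]

LOA_MULTIPLIER = 1.96  # conventional 95% limits-of-agreement multiplier


class AgreementError(ValueError):
    """Raised for invalid inputs to the agreement statistics."""


@dataclass(frozen=True)
class RatingsMatrix:
    """``n`` targets x ``k`` measurements, complete (no missing cells)."""

    values: np.ndarray
    row_labels: tuple = ()
    col_labels: tuple = ()

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2:
            raise AgreementError("ratings must be a 2D matrix")
        n, k = arr.shape
        if n < 2 or k < 2:
            raise AgreementError("need at least 2 targets and 2 measurements")
        if not np.all(np.isfinite(arr)):
            raise AgreementError("ratings matrix has missing or non-finite cells")
        object.__setattr__(self, "values", arr)
        if self.row_labels and len(self.row_labels) != n:
            raise AgreementError("row_labels length mismatch")
        if self.col_labels and len(self.col_labels) != k:
            raise AgreementError("col_labels length mismatch")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class AnovaComponents:
    """Mean squares of the two-way (subjects x measurements) decomposition."""

    ms_rows: float
    ms_cols: float
    ms_error: float
    ss_rows: float
    ss_cols: float
    ss_error: float
    ss_total: float
    n: int
    k: int


@dataclass(frozen=True)
class ICCResult:
    """Single-measures ICC point estimate with a 95% confidence interval."""

    estimate: float
    ci_low: float
    ci_high: float
    model: str  # 'absolute_agreement_single' | 'consistency_single'
    band: str = ""
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate and not (self.ci_low <= self.estimate <= self.ci_high):
            raise AgreementError("confidence interval must contain the estimate")


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bias and 95% limits of agreement of paired differences (x - y)."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int
    means: np.ndarray = field(default_factory=lambda: np.empty(0))
    differences: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def width(self) -> float:
        return self.loa_high - self.loa_low


@dataclass(frozen=True)
class PairedTResult:
    """Dependent-samples t comparison of two measurement columns."""

    md: float
    ci_low: float
    ci_high: float
    t_stat: float
    df: int
    p: float
    zero_variance: bool = False


@dataclass(frozen=True)
class SampleSizeSpec:
    """Inputs of the ICC sample-size calculation.

    ``rho0`` is the minimally acceptable ICC under the null, ``rho1`` the
    expected ICC, ``k`` the measurements per subject; ``alpha`` is one-sided.
    """

    rho0: float = 0.6
    rho1: float = 0.8
    k: int = 2
    alpha: float = 0.05
    power: float = 0.8
    attrition: float = 0.10

    def __post_init__(self) -> None:
        if not 0 <= self.rho0 < 1 or not 0 < self.rho1 < 1:
            raise AgreementError("rho0 and rho1 must lie in [0, 1)")
        if self.rho0 >= self.rho1:
            raise AgreementError("rho1 must exceed rho0")
        if self.k < 2:
            raise AgreementError("k must be >= 2")
        if not 0 < self.alpha < 0.5:
            raise AgreementError("alpha must be in (0, 0.5)")
        if not 0 < self.power < 1:
            raise AgreementError("power must be in (0, 1)")
        if not 0 <= self.attrition < 1:
            raise AgreementError("attrition must be in [0, 1)")


# --------------------------------------------------------------------------
# ANOVA and ICC
# --------------------------------------------------------------------------

def two_way_anova(m: RatingsMatrix) -> AnovaComponents:
    """Two-way decomposition: rows (subjects), columns (measurements), residual.

    ``MSR = k * sum_i (rowmean_i - grand)^2 / (n-1)``, analogously for
    columns; the residual sum of squares is the remainder of the total and
    carries ``(n-1)(k-1)`` degrees of freedom. The partition
    ``SST = SSR + SSC + SSE`` holds to numerical precision.
    """
    x = m.values
    n, k = m.n, m.k
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * float(np.sum((row_means - grand) ** 2))
    ss_cols = n * float(np.sum((col_means - grand) ** 2))
    ss_total = float(np.sum((x - grand) ** 2))
    resid = x - row_means[:, None] - col_means[None, :] + grand
    ss_error = float(np.sum(resid**2))
    return AnovaComponents(
        ms_rows=ss_rows / (n - 1),
        ms_cols=ss_cols / (k - 1),
        ms_error=ss_error / ((n - 1) * (k - 1)),
        ss_rows=ss_rows,
        ss_cols=ss_cols,
        ss_error=ss_error,
        ss_total=ss_total,
        n=n,
        k=k,
    )


def _icc_absolute_ci(icc: float, an: AnovaComponents, alpha: float) -> tuple[float, float]:
    """Satterthwaite F interval for the absolute-agreement single-measures ICC."""
    n, k = an.n, an.k
    msr, msc, mse = an.ms_rows, an.ms_cols, an.ms_error
    fj = msc / mse
    vn = (k - 1) * (n - 1) * (k * icc * fj + n * (1 + (k - 1) * icc) - k * icc) ** 2
    vd = (n - 1) * k**2 * icc**2 * fj**2 + (n * (1 + (k - 1) * icc) - k * icc) ** 2
    v = vn / vd
    f_u = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_l = stats.f.ppf(1 - alpha / 2, v, n - 1)
    low = n * (msr - f_u * mse) / (f_u * (k * msc + (k * n - k - n) * mse) + n * msr)
    high = n * (f_l * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_l * msr)
    return float(low), float(high)


def _icc_consistency_ci(an: AnovaComponents, alpha: float) -> tuple[float, float]:
    n, k = an.n, an.k
    fstat = an.ms_rows / an.ms_error
    df1, df2 = n - 1, (n - 1) * (k - 1)
    f_u = stats.f.ppf(1 - alpha / 2, df1, df2)
    f_l = stats.f.ppf(1 - alpha / 2, df2, df1)
    low = (fstat / f_u - 1) / (fstat / f_u + k - 1)
    high = (fstat * f_l - 1) / (fstat * f_l + k - 1)
    return float(low), float(high)


def icc_single(m: RatingsMatrix, model: str = "absolute_agreement_single",
               alpha: float = 0.05) -> ICCResult:
    """Single-measures ICC with a 95% confidence interval.

    ``absolute_agreement_single`` is the two-way random/mixed absolute-
    agreement form ``(MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))``;
    ``consistency_single`` is ``(MSR - MSE) / (MSR + (k-1) MSE)``, which
    ignores systematic column offsets. Confidence limits use the standard
    F-based formulas for each form.

    A matrix with no variance at all (all cells equal) has an undefined ICC
    and is returned flagged ``degenerate`` with NaN estimate. A matrix with
    zero residual variance but real subject variance returns its exact point
    estimate with a collapsed confidence interval.
    """
    an = two_way_anova(m)
    n, k = an.n, an.k
    msr, msc, mse = an.ms_rows, an.ms_cols, an.ms_error
    if model == "absolute_agreement_single":
        denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    elif model == "consistency_single":
        denom = msr + (k - 1) * mse
    else:
        raise AgreementError(f"unknown ICC model {model!r}")
    if denom <= 0:
        return ICCResult(estimate=float("nan"), ci_low=float("nan"), ci_high=float("nan"),
                         model=model, band="undefined", degenerate=True)
    est = (msr - mse) / denom
    if mse <= 1e-12 * max(msr, msc):
        # residual variance zero (to rounding) relative to the signal: the
        # F-based interval degenerates to the point estimate
        return ICCResult(estimate=float(est), ci_low=float(est), ci_high=float(est),
                         model=model, band=interpret_icc(est))
    if model == "absolute_agreement_single":
        low, high = _icc_absolute_ci(est, an, alpha)
    else:
        low, high = _icc_consistency_ci(an, alpha)
    low = min(low, est)
    high = max(high, est)
    return ICCResult(estimate=float(est), ci_low=low, ci_high=high, model=model,
                     band=interpret_icc(est))


def interpret_icc(r: float) -> str:
    """Conventional qualitative band for an ICC point estimate.

    ``poor`` below 0.5, ``moderate`` for 0.5-0.75, ``good`` for values above
    0.75 up to and including 0.9, ``excellent`` above 0.9. The mapping is a
    total, order-preserving step function.
    """
    if not math.isfinite(r):
        raise AgreementError("ICC must be finite to interpret")
    if r < 0.5:
        return "poor"
    if r <= 0.75:
        return "moderate"
    if r <= 0.9:
        return "good"
    return "excellent"


# --------------------------------------------------------------------------
# Bland-Altman and paired comparisons
# --------------------------------------------------------------------------

def bland_altman(x: Sequence[float], y: Sequence[float]) -> BlandAltmanResult:
    """Bias and 95% limits of agreement of the differences ``x - y``.

    The order of the arguments fixes the sign of the bias and must be
    documented per contrast (e.g. session1 - session2, observer1 - observer2,
    video - reference). The limits are ``bias +/- 1.96 * SD`` of the
    differences (sample SD); the per-pair means and differences are retained
    for plotting.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise AgreementError("x and y must have equal length")
    if x.size < 2:
        raise AgreementError("need at least 2 pairs")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - LOA_MULTIPLIER * sd,
        loa_high=bias + LOA_MULTIPLIER * sd,
        n=int(x.size),
        means=(x + y) / 2.0,
        differences=d,
    )


def loa_from_summary(md: float, ci_low: float, ci_high: float, n: int) -> BlandAltmanResult:
    """Reconstruct limits of agreement from a published mean difference and CI.

    Assumes the reported 95% CI of the mean difference is t-based with
    ``n - 1`` degrees of freedom, so
    ``sd_diff = (half CI width) / t_{0.975, n-1} * sqrt(n)`` and the limits
    are ``md +/- 1.96 * sd_diff``. Useful for checking the internal
    consistency of published agreement tables.
    """
    if n < 2:
        raise AgreementError("n must be >= 2")
    if not ci_low < ci_high:
        raise AgreementError("invalid confidence interval: ci_low must be < ci_high")
    tcrit = stats.t.ppf(0.975, n - 1)
    sd = (ci_high - ci_low) / 2.0 / tcrit * math.sqrt(n)
    return BlandAltmanResult(
        bias=float(md),
        sd_diff=float(sd),
        loa_low=float(md - LOA_MULTIPLIER * sd),
        loa_high=float(md + LOA_MULTIPLIER * sd),
        n=int(n),
    )


def paired_t(x: Sequence[float], y: Sequence[float], alpha: float = 0.05) -> PairedTResult:
    """Dependent-samples t test of the mean difference ``mean(x - y)``.

    Returns the mean difference with its t-based CI and the two-sided p
    value. Zero-variance differences are flagged: with a nonzero mean
    difference the p value is reported as 0 (below machine precision); with
    zero mean difference ``t = 0`` and ``p = 1``.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise AgreementError("x and y must have equal length")
    if x.size < 2:
        raise AgreementError("need at least 2 pairs")
    d = x - y
    n = d.size
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        if md == 0.0:
            return PairedTResult(md=0.0, ci_low=0.0, ci_high=0.0, t_stat=0.0, df=df,
                                 p=1.0, zero_variance=True)
        return PairedTResult(md=md, ci_low=md, ci_high=md,
                             t_stat=math.copysign(math.inf, md), df=df, p=0.0,
                             zero_variance=True)
    se = sd / math.sqrt(n)
    t_stat = md / se
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    p = 2.0 * float(stats.t.sf(abs(t_stat), df))
    return PairedTResult(md=md, ci_low=md - tcrit * se, ci_high=md + tcrit * se,
                         t_stat=float(t_stat), df=df, p=min(p, 1.0))


# --------------------------------------------------------------------------
# sample size
# --------------------------------------------------------------------------

def walter_sample_size(spec: SampleSizeSpec) -> tuple[int, int]:
    """Subjects needed to show an ICC exceeds ``rho0`` when it is ``rho1``.

    Closed form based on a Fisher-type transformation of the ICC: with
    ``theta = rho / (1 - rho)`` and ``C0 = (1 + k*theta0) / (1 + k*theta1)``,

        ``n0 = ceil(1 + 2k (z_{1-alpha} + z_{1-beta})^2 / ((k-1) ln(C0)^2))``

    with one-sided ``alpha``. Returns ``(n0, n_inflated)`` where the second
    value multiplies by ``1 + attrition`` and rounds up again.
    """
    theta0 = spec.rho0 / (1 - spec.rho0)
    theta1 = spec.rho1 / (1 - spec.rho1)
    c0 = (1 + spec.k * theta0) / (1 + spec.k * theta1)
    ln_c0 = math.log(c0)
    if ln_c0 == 0.0:
        raise AgreementError("rho0 and rho1 must differ")
    z_a = stats.norm.ppf(1 - spec.alpha)
    z_b = stats.norm.ppf(spec.power)
    n0 = math.ceil(1 + 2 * spec.k * (z_a + z_b) ** 2 / ((spec.k - 1) * ln_c0**2))
    n_inflated = math.ceil(n0 * (1 + spec.attrition))
    return int(n0), int(n_inflated)
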