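"""Single-measurement intraclass correlation coefficients with F-based CIs.

Two forms are provided, both from the two-way random-effects layout without
replication (subjects x raters, raters being runs or scanners):

* ICC(A,1) -- absolute agreement: systematic offsets between raters count as
  disagreement.  Used for within-scanner scan-rescan repeatability.
* ICC(C,1) -- consistency: rater offsets are ignored; only the ordering and
  spacing of subjects matters.  Used for between-scanner reproducibility,
  where fixed scanner biases are assessed separately.

Point estimates and 95% confidence intervals follow the classical
mean-squares formulation (exact F interval for consistency, Satterthwaite-
approximated F interval for absolute agreement).  Values are classified as
poor (< 0.5), moderate (0.5-0.75), good (0.75-0.9) or excellent (>= 0.9);
boundaries are lower-inclusive and 0.9 counts as excellent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, UndefinedICCError
from .cohort import RatingsMatrix

CLASS_LABELS = ("poor", "moderate", "good", "excellent")


@dataclass(frozen=True)
class ICCEstimate:
    """One ICC with its confidence interval and reliability class."""

    model: str  # "absolute_agreement" | "consistency"
    value: float
    ci_low: float
    ci_high: float
    alpha: float
    n: int
    k: int
    classification: str
    dropped_subjects: int = 0


def two_way_mean_squares(m: RatingsMatrix | np.ndarray) -> tuple[float, float, float]:
    """Row (subject), column (rater) and residual mean squares.

    Standard two-way ANOVA decomposition without replication; the three sums
    of squares partition the total sum of squares exactly:
    (n-1)*MSR + (k-1)*MSC + (n-1)(k-1)*MSE = sum((x - grand mean)^2).
    """
    x = m.values if isinstance(m, RatingsMatrix) else np.asarray(m, dtype=float)
    if x.ndim != 2:
        raise InsufficientDataError("expected a 2-D subjects x raters matrix")
    n, k = x.shape
    if n < 3 or k < 2:
        raise InsufficientDataError(f"degenerate matrix {n}x{k}: need n>=3, k>=2")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def icc_consistency(m: RatingsMatrix, alpha: float = 0.05) -> ICCEstimate:
    """Single-rater consistency ICC(C,1) with an exact F confidence interval.

    value = (MSR - MSE) / (MSR + (k-1) MSE); the CI transforms the central F
    interval for MSR/MSE with (n-1, (n-1)(k-1)) degrees of freedom.
    """
    msr, _, mse = two_way_mean_squares(m)
    n, k = m.n, m.k
    denom = msr + (k - 1) * mse
    if denom == 0:
        raise UndefinedICCError("zero total variance; consistency ICC undefined")
    value = (msr - mse) / denom

    df1, df2 = n - 1, (n - 1) * (k - 1)
    if mse == 0:
        lo = hi = 1.0
    else:
        fobs = msr / mse
        fl = fobs / stats.f.ppf(1 - alpha / 2, df1, df2)
        fu = fobs * stats.f.ppf(1 - alpha / 2, df2, df1)
        lo = (fl - 1) / (fl + k - 1)
        hi = (fu - 1) / (fu + k - 1)
    return ICCEstimate(
        model="consistency",
        value=float(value),
        ci_low=float(lo),
        ci_high=float(hi),
        alpha=alpha,
        n=n,
        k=k,
        classification=classify_icc(value),
        dropped_subjects=m.dropped_subjects,
    )


def icc_absolute(m: RatingsMatrix, alpha: float = 0.05) -> ICCEstimate:
    """Single-rater absolute-agreement ICC(A,1), Satterthwaite F interval.

    value = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)).  The CI uses
    the approximate F procedure with Satterthwaite degrees of freedom for the
    denominator mean-square combination.
    """
    msr, msc, mse = two_way_mean_squares(m)
    n, k = m.n, m.k
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        raise UndefinedICCError("zero denominator; absolute-agreement ICC undefined")
    value = (msr - mse) / denom

    if msc == 0 and mse == 0:
        lo = hi = 1.0
    else:
        a = k * value / (n * (1 - value)) if value != 1 else np.inf
        b = 1 + k * value * (n - 1) / (n * (1 - value)) if value != 1 else np.inf
        if np.isinf(a) or np.isinf(b):
            lo = hi = 1.0
        else:
            num = (a * msc + b * mse) ** 2
            den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            v = num / den if den > 0 else 1.0
            f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
            f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
            lo = (
                n * (msr - f1 * mse)
                / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
            )
            hi = (
                n * (f2 * msr - mse)
                / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
            )
    return ICCEstimate(
        model="absolute_agreement",
        value=float(value),
        ci_low=float(lo),
        ci_high=float(hi),
        alpha=alpha,
        n=n,
        k=k,
        classification=classify_icc(value),
        dropped_subjects=m.dropped_subjects,
    )


def classify_icc(value: float) -> str:
    """Reliability class of an ICC value.

    Lower-inclusive boundaries: < 0.5 poor, [0.5, 0.75) moderate,
    [0.75, 0.9) good, >= 0.9 excellent.  Negative estimates (reported as
    computed, never floored) classify as poor.
    """
    if value > 1:
        raise ValueError(f"ICC cannot exceed 1, got {value}")
    if value < 0.5:
        return "poor"
    if value < 0.75:
        return "moderate"
    if value < 0.9:
        return "good"
    return "excellent"
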