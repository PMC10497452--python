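"""Systematic between-scanner differences: omnibus tests, post-hocs, Bland-Altman.

High agreement (ICC) does not rule out systematic offsets between scanners,
so each (software, structure) cell is additionally tested for a scanner main
effect on raw volumes: a one-within-factor repeated-measures ANOVA when the
within-subject residuals look normal (Shapiro-Wilk), otherwise a Friedman
test, with matched pairwise post-hocs (paired t / Wilcoxon signed-rank)
Bonferroni-corrected over the scanner pairs.  Pairwise fixed and proportional
bias is quantified with Bland-Altman statistics.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort import CohortTable, pivot_ratings
from .errors import InsufficientDataError

#: Limits-of-agreement multiplier (95% of differences under normality).
LOA_Z = 1.96


@dataclass(frozen=True)
class PosthocResult:
    scanner_pair: tuple[str, str]
    test: str  # "paired_t" | "wilcoxon"
    raw_p: float
    bonferroni_p: float
    mean_difference: float  # mean(first - second), signed


@dataclass(frozen=True)
class BiasTestResult:
    software: str
    structure: str
    omnibus_test: str  # "rm_anova" | "friedman"
    statistic: float
    p_value: float
    posthoc: tuple[PosthocResult, ...] = ()
    n_subjects: int = 0
    # metadata recording the decisions taken for this cell
    residuals_normal: bool = True
    sphericity_correction: str = "greenhouse-geisser"
    posthoc_gate: float | None = 0.05


@dataclass(frozen=True)
class BlandAltmanResult:
    scanner_pair: tuple[str, str]
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    ci_bias: tuple[float, float]
    ci_loa_low: tuple[float, float]
    ci_loa_high: tuple[float, float]
    proportional_slope: float
    proportional_p: float
    n: int
    degenerate: bool = False  # zero-variance differences: slope undefined, set to 0


def check_normality(values: np.ndarray, alpha: float = 0.05) -> bool:
    """Shapiro-Wilk normality screen; True when normality is not rejected.

    A constant vector is treated as normal (with a warning) so that degenerate
    cells fall through to the parametric branch rather than erroring.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise InsufficientDataError("need at least 3 values for a normality check")
    if np.ptp(values) == 0.0:
        warnings.warn("constant vector: normality check is vacuous", stacklevel=2)
        return True
    _, p = stats.shapiro(values)
    return bool(p >= alpha)


def _gg_epsilon(x: np.ndarray) -> float:
    """Greenhouse-Geisser sphericity epsilon for an n x k within-subject matrix."""
    k = x.shape[1]
    S = np.cov(x, rowvar=False)
    C = np.eye(k) - 1.0 / k
    Sc = C @ S @ C
    num = np.trace(Sc) ** 2
    den = (k - 1) * np.sum(Sc * Sc)
    if den == 0:
        return 1.0
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0))


def rm_anova(x: np.ndarray, correction: str = "greenhouse-geisser") -> tuple[float, float]:
    """One-within-factor repeated-measures ANOVA on an n x k matrix.

    Returns (F, p); p uses Greenhouse-Geisser corrected degrees of freedom
    unless ``correction="none"``.
    """
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    grand = x.mean()
    col_means = x.mean(axis=0)
    row_means = x.mean(axis=1)
    ss_c = n * np.sum((col_means - grand) ** 2)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    ss_e = np.sum(resid**2)
    df1, df2 = k - 1, (n - 1) * (k - 1)
    if ss_e == 0.0:
        if ss_c == 0.0:
            return 0.0, 1.0
        return float("inf"), 0.0
    F = (ss_c / df1) / (ss_e / df2)
    if correction == "greenhouse-geisser":
        eps = _gg_epsilon(x)
        p = stats.f.sf(F, eps * df1, eps * df2)
    else:
        p = stats.f.sf(F, df1, df2)
    return float(F), float(p)


def omnibus_scanner_test(
    table: CohortTable,
    software: str,
    structure: str,
    *,
    alpha: float = 0.05,
    run_policy: str = "first",
    posthoc_gate: float | None = 0.05,
    sphericity_correction: bool = True,
    lesion_filled: bool | None = None,
) -> BiasTestResult:
    """Omnibus test for a scanner effect in one (software, structure) cell.

    Complete-case subjects (a value on every scanner, first run by default,
    raw volumes).  RM-ANOVA with Greenhouse-Geisser correction when the
    double-centered residuals pass Shapiro-Wilk at ``alpha``, Friedman
    otherwise.  Post-hoc pairwise tests (matched to the omnibus family) are
    run when the omnibus p falls below ``posthoc_gate`` (``None`` = always),
    Bonferroni-corrected over the scanner pairs.
    """
    m = pivot_ratings(
        table, software, structure,
        between_scanners=table.design.scanners,
        run_policy=run_policy,
        lesion_filled=lesion_filled,
    )
    x = m.values
    n, k = x.shape
    scanners = m.raters

    if np.ptp(x) == 0.0:
        # identical values everywhere: no scanner effect, nothing to test
        return BiasTestResult(
            software=software, structure=structure, omnibus_test="friedman",
            statistic=0.0, p_value=1.0, posthoc=(), n_subjects=n,
            residuals_normal=True,
            sphericity_correction="greenhouse-geisser" if sphericity_correction else "none",
            posthoc_gate=posthoc_gate,
        )

    resid = x - x.mean(axis=1, keepdims=True) - x.mean(axis=0) + x.mean()
    normal = check_normality(resid.ravel(), alpha=alpha)

    if normal:
        corr = "greenhouse-geisser" if sphericity_correction else "none"
        statistic, p = rm_anova(x, correction=corr)
        omnibus, pair_test = "rm_anova", "paired_t"
    else:
        corr = "none"
        statistic, p = stats.friedmanchisquare(*(x[:, j] for j in range(k)))
        statistic, p = float(statistic), float(p)
        omnibus, pair_test = "friedman", "wilcoxon"

    posthoc: list[PosthocResult] = []
    if posthoc_gate is None or p < posthoc_gate:
        pairs = list(itertools.combinations(range(k), 2))
        for i, j in pairs:
            d = x[:, i] - x[:, j]
            if pair_test == "paired_t":
                _, raw = stats.ttest_rel(x[:, i], x[:, j])
            else:
                if np.ptp(d) == 0.0 and np.all(d == 0):
                    raw = 1.0
                else:
                    _, raw = stats.wilcoxon(x[:, i], x[:, j])
            raw = float(raw)
            posthoc.append(
                PosthocResult(
                    scanner_pair=(scanners[i], scanners[j]),
                    test=pair_test,
                    raw_p=raw,
                    bonferroni_p=min(1.0, raw * len(pairs)),
                    mean_difference=float(d.mean()),
                )
            )

    return BiasTestResult(
        software=software, structure=structure, omnibus_test=omnibus,
        statistic=statistic, p_value=p, posthoc=tuple(posthoc), n_subjects=n,
        residuals_normal=normal, sphericity_correction=corr,
        posthoc_gate=posthoc_gate,
    )


def bland_altman(
    pairs: np.ndarray,
    alpha: float = 0.05,
    scanner_pair: tuple[str, str] = ("A", "B"),
) -> BlandAltmanResult:
    """Bland-Altman statistics for an n x 2 matrix of paired measurements.

    bias = mean(A - B); limits of agreement = bias +/- 1.96 * sd(A - B) with
    t-based confidence intervals (SE of a limit: sd * sqrt(1/n + z^2/(2(n-1)))).
    Proportional bias is the slope of (A - B) regressed on (A + B)/2.
    Zero-variance differences leave the slope undefined; it is reported as 0
    with the ``degenerate`` flag set.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise InsufficientDataError("expected an n x 2 matrix of paired values")
    n = pairs.shape[0]
    if n < 3:
        raise InsufficientDataError("need at least 3 pairs for Bland-Altman analysis")
    a, b = pairs[:, 0], pairs[:, 1]
    d = a - b
    mean_ab = (a + b) / 2.0
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa_low, loa_high = bias - LOA_Z * sd, bias + LOA_Z * sd
    tq = stats.t.ppf(1 - alpha / 2, n - 1)
    se_bias = sd / np.sqrt(n)
    se_loa = sd * np.sqrt(1.0 / n + LOA_Z**2 / (2 * (n - 1)))
    ci_bias = (bias - tq * se_bias, bias + tq * se_bias)
    ci_lo = (loa_low - tq * se_loa, loa_low + tq * se_loa)
    ci_hi = (loa_high - tq * se_loa, loa_high + tq * se_loa)

    degenerate = sd == 0.0 or np.ptp(mean_ab) == 0.0
    if degenerate:
        slope, slope_p = 0.0, 1.0
    else:
        res = stats.linregress(mean_ab, d)
        slope, slope_p = float(res.slope), float(res.pvalue)

    return BlandAltmanResult(
        scanner_pair=scanner_pair,
        bias=bias,
        sd_diff=sd,
        loa_low=float(loa_low),
        loa_high=float(loa_high),
        ci_bias=(float(ci_bias[0]), float(ci_bias[1])),
        ci_loa_low=(float(ci_lo[0]), float(ci_lo[1])),
        ci_loa_high=(float(ci_hi[0]), float(ci_hi[1])),
        proportional_slope=slope,
        proportional_p=slope_p,
        n=n,
        degenerate=degenerate,
    )


def bland_altman_pairs(
    table: CohortTable,
    software: str,
    structure: str,
    *,
    alpha: float = 0.05,
    run_policy: str = "first",
    lesion_filled: bool | None = None,
) -> list[BlandAltmanResult]:
    """Bland-Altman results for every scanner pair of one cell."""
    out = []
    for sa, sb in itertools.combinations(table.design.scanners, 2):
        m = pivot_ratings(
            table, software, structure,
            between_scanners=(sa, sb),
            run_policy=run_policy,
            lesion_filled=lesion_filled,
        )
        out.append(bland_altman(m.values, alpha=alpha, scanner_pair=(sa, sb)))
    return out
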