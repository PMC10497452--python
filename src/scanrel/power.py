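"""Two-sample power planning under within- vs between-scanner error.

Measurement error inflates the SD seen by a cross-sectional group comparison:
a study run on one scanner carries sigma2_subject + sigma2_eps, while a
multi-scanner study carries sigma2_subject + sigma2_scanner + sigma2_eps.
This module sizes a two-sided, equal-variance two-sample t-test to detect a
stated percent volume difference (default 1%, alpha 0.05, power 0.80) under
each error regime and reports the participant ratio between/within -- the
price, in sample size, of pooling scanners.

Sample sizes come from an exact search over the noncentral-t power function;
the classical z-approximation is available for reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, ValidationError
from .variance import VarianceComponents


@dataclass(frozen=True)
class PowerSpec:
    """Detection target: percent group difference, alpha, power.

    ``subject_sd_pct`` optionally overrides the between-subject SD (percent
    of mean) otherwise taken from the variance components' subject term.
    """

    delta_pct: float = 1.0
    alpha: float = 0.05
    power: float = 0.80
    subject_sd_pct: float | None = None

    def __post_init__(self) -> None:
        if self.delta_pct <= 0:
            raise ValidationError("delta_pct must be positive")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise ValidationError("power must be in (0, 1)")


@dataclass(frozen=True)
class PowerResult:
    """Per-group sample sizes and their between/within ratio."""

    n_within: int
    n_between: int
    ratio: float  # n_between / n_within (integer sample sizes, as reported)
    variance_ratio: float  # continuous (s2_s + s2_r + s2_e) / (s2_s + s2_e)
    sd_within_pct: float
    sd_between_pct: float


def power_two_sample_t(n: int, delta: float, sd: float, alpha: float = 0.05) -> float:
    """Power of a two-sided, equal-variance two-sample t-test, n per group."""
    if n < 2:
        return 0.0
    df = 2 * (n - 1)
    nc = delta / (sd * np.sqrt(2.0 / n))
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    return float(stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))


def sample_size_two_group(total_sd_pct: float, spec: PowerSpec) -> int:
    """Smallest per-group n reaching the specified power.

    Exact noncentral-t iteration: exponential bracketing followed by
    bisection on the (monotone in n) power function.  The search floor is
    n = 2, the smallest group allowing a variance estimate.
    """
    if total_sd_pct <= 0:
        raise ValidationError("total SD must be positive")

    def achieved(n: int) -> float:
        return power_two_sample_t(n, spec.delta_pct, total_sd_pct, spec.alpha)

    lo, hi = 2, 2
    while achieved(hi) < spec.power:
        lo, hi = hi, hi * 2
        if hi > 10**8:
            raise ValidationError("required sample size exceeds 1e8; check inputs")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if achieved(mid) >= spec.power:
            hi = mid
        else:
            lo = mid
    return hi if achieved(lo) < spec.power else lo


def sample_size_z_approx(total_sd_pct: float, spec: PowerSpec) -> float:
    """Classical normal-approximation n = 2 (z_a + z_b)^2 sd^2 / delta^2."""
    if total_sd_pct <= 0:
        raise ValidationError("total SD must be positive")
    za = stats.norm.ppf(1 - spec.alpha / 2)
    zb = stats.norm.ppf(spec.power)
    return float(2 * (za + zb) ** 2 * (total_sd_pct / spec.delta_pct) ** 2)


def power_pair(vc: VarianceComponents, spec: PowerSpec = PowerSpec()) -> PowerResult:
    """Within- vs between-scanner sample sizes from fitted variance components.

    The between-subject variance comes from the VCA subject term of the same
    cell unless ``spec.subject_sd_pct`` overrides it.  SDs are expressed as
    percent of the cell's mean volume, matching ``spec.delta_pct``.
    """
    if vc.mean_volume <= 0:
        raise ValidationError("mean volume must be positive")
    if spec.subject_sd_pct is not None:
        s2_subj_pct = spec.subject_sd_pct**2
    else:
        s2_subj_pct = 1e4 * vc.sigma2_subject / vc.mean_volume**2
    s2_eps_pct = 1e4 * vc.sigma2_residual / vc.mean_volume**2
    s2_scan_pct = 1e4 * vc.sigma2_scanner / vc.mean_volume**2

    var_within = s2_subj_pct + s2_eps_pct
    var_between = s2_subj_pct + s2_scan_pct + s2_eps_pct
    if var_within <= 0:
        raise InsufficientDataError("zero total variance; power analysis undefined")

    sd_w, sd_b = float(np.sqrt(var_within)), float(np.sqrt(var_between))
    n_w = sample_size_two_group(sd_w, spec)
    n_b = sample_size_two_group(sd_b, spec)
    return PowerResult(
        n_within=n_w,
        n_between=n_b,
        ratio=n_b / n_w,
        variance_ratio=var_between / var_within,
        sd_within_pct=sd_w,
        sd_between_pct=sd_b,
    )
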