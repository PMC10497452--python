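"""Crossed variance components and SEM / SDC reliability summaries.

Per (software, structure) cell the observed (TIV-normalized) volumes are
decomposed under the crossed random-effects model

    value_ijk = mu + subject_i + scanner_j + (subject x scanner)_ij + eps_ijk

For balanced data the components come from the classical expected-mean-squares
method of moments; unbalanced data (a missing run) are fitted by REML via
Fisher scoring on the variance parameters.  Negative estimates are truncated
at zero and flagged.

From the fitted components the two measurement-error summaries are derived,
both as percentages of the grand mean volume V:

    SEM_within  = 100 * sqrt(sigma2_eps) / V
    SEM_between = 100 * sqrt(sigma2_r + sigma2_eps) / V
    SDC         = 1.96 * sqrt(2) * SEM

SEM_within is the scan-rescan noise floor on a single scanner; SEM_between
additionally carries the scanner-associated variance sigma2_r, which by
default folds the subject-by-scanner interaction into the scanner term (the
interaction perturbs between-scanner but not within-scanner comparisons).
The SDC is the smallest change in one subject distinguishable from
measurement error with 95% confidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .cohort import CohortTable
from .errors import InsufficientDataError, StateError, ValidationError

#: SDC / SEM conversion constant, 1.96 * sqrt(2).
SDC_FACTOR: float = 1.96 * float(np.sqrt(2.0))

INTERACTION_POLICIES = ("fold_into_scanner", "pool_into_residual", "drop")


@dataclass(frozen=True)
class VarianceComponents:
    """Fitted components for one (software, structure) cell.

    ``sigma2_scanner`` is the scanner-associated variance as reported under
    the chosen interaction policy (default: scanner main effect plus
    subject-by-scanner interaction).  The raw pieces are kept in
    ``sigma2_scanner_main`` and ``sigma2_interaction`` for transparency.
    """

    sigma2_subject: float
    sigma2_scanner: float
    sigma2_residual: float
    mean_volume: float
    n_observations: int
    method: str  # "moments" | "reml"
    sigma2_scanner_main: float = 0.0
    sigma2_interaction: float = 0.0
    interaction_policy: str = "fold_into_scanner"
    truncated: bool = False
    converged: bool = True


def _crossed_mean_squares(arr: np.ndarray) -> tuple[float, float, float, float]:
    """Mean squares of a balanced subjects x scanners x runs array."""
    a, b, r = arr.shape
    grand = arr.mean()
    mi = arr.mean(axis=(1, 2))
    mj = arr.mean(axis=(0, 2))
    mij = arr.mean(axis=2)
    ms_a = b * r * np.sum((mi - grand) ** 2) / (a - 1)
    ms_b = a * r * np.sum((mj - grand) ** 2) / (b - 1)
    inter = mij - mi[:, None] - mj[None, :] + grand
    ms_ab = r * np.sum(inter**2) / ((a - 1) * (b - 1))
    if r > 1:
        ms_e = np.sum((arr - mij[:, :, None]) ** 2) / (a * b * (r - 1))
    else:
        ms_e = np.nan
    return float(ms_a), float(ms_b), float(ms_ab), float(ms_e)


def _moments_balanced(arr: np.ndarray) -> dict[str, float]:
    """Untruncated expected-mean-squares estimators on balanced data."""
    a, b, r = arr.shape
    ms_a, ms_b, ms_ab, ms_e = _crossed_mean_squares(arr)
    s2_e = ms_e
    s2_ab = (ms_ab - ms_e) / r
    s2_b = (ms_b - ms_ab) / (a * r)
    s2_a = (ms_a - ms_ab) / (b * r)
    return {
        "sigma2_subject": s2_a,
        "sigma2_scanner": s2_b,
        "sigma2_interaction": s2_ab,
        "sigma2_residual": s2_e,
    }


def _reml_crossed(
    y: np.ndarray,
    subj: np.ndarray,
    scan: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> tuple[dict[str, float], bool, int]:
    """REML fit of the crossed model by Fisher scoring.

    ``subj`` and ``scan`` are integer level codes.  Works for unbalanced
    layouts (missing runs).  Variance parameters are constrained to be
    non-negative via an active-set rule: a component driven to the boundary
    with a negative score is pinned at zero.
    """
    n = len(y)
    scale = float(np.std(y))
    if scale == 0.0:
        zero = {k: 0.0 for k in (
            "sigma2_subject", "sigma2_scanner", "sigma2_interaction", "sigma2_residual"
        )}
        return zero, True, 0
    z = (y - y.mean()) / scale

    def onehot(codes: np.ndarray) -> np.ndarray:
        m = np.zeros((n, codes.max() + 1))
        m[np.arange(n), codes] = 1.0
        return m

    cell = subj * (scan.max() + 1) + scan
    _, cell = np.unique(cell, return_inverse=True)
    Zs = [onehot(subj), onehot(scan), onehot(cell)]
    G = [Z @ Z.T for Z in Zs] + [np.eye(n)]
    m = len(G)

    v0 = float(np.var(z, ddof=1))
    theta = np.array([v0 / 4] * 3 + [v0 / 2])
    pinned = np.zeros(m, dtype=bool)
    floor = 1e-12

    def neg2_loglik_and_P(th):
        V = sum(t * Gc for t, Gc in zip(th, G))
        cf = cho_factor(V, lower=True)
        logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        Vi = cho_solve(cf, np.eye(n))
        vix = Vi.sum(axis=1)  # V^-1 X for X = 1
        xtvix = float(vix.sum())
        P = Vi - np.outer(vix, vix) / xtvix
        Py = P @ z
        n2l = logdet + np.log(xtvix) + float(z @ Py)
        return n2l, P, Py

    n2l, P, Py = neg2_loglik_and_P(theta)
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        score = np.empty(m)
        A = [P @ Gc for Gc in G]
        for c in range(m):
            score[c] = -0.5 * (np.trace(A[c]) - float(Py @ G[c] @ Py))
        info = np.empty((m, m))
        for c in range(m):
            for d in range(c, m):
                info[c, d] = info[d, c] = 0.5 * float(np.sum(A[c] * A[d].T))

        # release pinned components whose score turned positive
        pinned &= ~(pinned & (score > 0))
        free = ~pinned
        if not free.any():
            converged = True
            break
        delta = np.zeros(m)
        try:
            delta[free] = np.linalg.solve(info[np.ix_(free, free)], score[free])
        except np.linalg.LinAlgError:
            delta[free] = score[free] / np.maximum(np.diag(info)[free], 1e-10)

        step = 1.0
        for _ in range(30):
            cand = theta + step * delta
            hit = cand < floor
            cand = np.maximum(cand, floor)
            # residual variance must stay strictly positive
            cand[-1] = max(cand[-1], floor)
            try:
                n2l_new, P_new, Py_new = neg2_loglik_and_P(cand)
            except np.linalg.LinAlgError:
                step /= 2
                continue
            if n2l_new <= n2l + 1e-12:
                break
            step /= 2
        else:
            converged = True  # cannot improve further
            break

        change = np.max(np.abs(cand - theta) / (np.abs(theta) + v0 * 1e-3))
        theta, n2l, P, Py = cand, n2l_new, P_new, Py_new
        # pin components that landed on the floor with a negative score
        pinned |= hit & (score <= 0)
        theta[pinned & (np.arange(m) < m - 1)] = floor
        if change < tol:
            converged = True
            break

    theta = theta * scale**2
    theta[theta <= 10 * floor * scale**2] = 0.0  # boundary estimates -> exact zero
    out = {
        "sigma2_subject": float(theta[0]),
        "sigma2_scanner": float(theta[1]),
        "sigma2_interaction": float(theta[2]),
        "sigma2_residual": float(theta[3]),
    }
    return out, converged, it


def fit_crossed(
    data: pd.DataFrame,
    method: str = "auto",
    interaction: str = "fold_into_scanner",
    tol: float = 1e-8,
    max_iter: int = 500,
) -> VarianceComponents:
    """Fit the crossed model to a long DataFrame (subject, scanner, run, value).

    ``method`` is ``"moments"`` (balanced data only), ``"reml"``, or
    ``"auto"`` (moments when balanced, REML otherwise).
    """
    if interaction not in INTERACTION_POLICIES:
        raise ValidationError(
            f"interaction policy must be one of {INTERACTION_POLICIES}"
        )
    df = data[["subject", "scanner", "run", "value"]].copy()
    subjects = sorted(df["subject"].unique())
    scanners = sorted(df["scanner"].unique())
    runs = sorted(df["run"].unique())
    if len(subjects) < 3 or len(scanners) < 2 or len(runs) < 2:
        raise InsufficientDataError(
            "need >=3 subjects, >=2 scanners and >=2 runs to decompose variance"
        )

    counts = df.groupby(["subject", "scanner"])["value"].count()
    balanced = (
        len(counts) == len(subjects) * len(scanners)
        and counts.nunique() == 1
        and counts.iloc[0] == len(runs)
    )
    if method == "auto":
        method = "moments" if balanced else "reml"
    if method == "moments" and not balanced:
        raise InsufficientDataError("moments estimator requires balanced data; use reml")

    y = df["value"].to_numpy(dtype=float)
    mean_volume = float(y.mean())
    if np.ptp(y) == 0.0:
        raw = {k: 0.0 for k in (
            "sigma2_subject", "sigma2_scanner", "sigma2_interaction", "sigma2_residual"
        )}
        converged = True
    elif method == "moments":
        arr = (
            df.set_index(["subject", "scanner", "run"])["value"]
            .unstack(["scanner", "run"])
            .loc[subjects]
            .to_numpy()
            .reshape(len(subjects), len(scanners), len(runs))
        )
        raw = _moments_balanced(arr)
        converged = True
    else:
        subj_codes = pd.Categorical(df["subject"], categories=subjects).codes
        scan_codes = pd.Categorical(df["scanner"], categories=scanners).codes
        raw, converged, _ = _reml_crossed(
            y, subj_codes.astype(int), scan_codes.astype(int),
            tol=tol, max_iter=max_iter,
        )

    truncated = any(v < 0 for v in raw.values())
    s2_subj = max(raw["sigma2_subject"], 0.0)
    s2_scan = max(raw["sigma2_scanner"], 0.0)
    s2_int = max(raw["sigma2_interaction"], 0.0)
    s2_eps = max(raw["sigma2_residual"], 0.0)

    if interaction == "fold_into_scanner":
        reported_scanner, reported_resid = s2_scan + s2_int, s2_eps
    elif interaction == "pool_into_residual":
        reported_scanner, reported_resid = s2_scan, s2_eps + s2_int
    else:  # drop
        reported_scanner, reported_resid = s2_scan, s2_eps

    return VarianceComponents(
        sigma2_subject=s2_subj,
        sigma2_scanner=reported_scanner,
        sigma2_residual=reported_resid,
        mean_volume=mean_volume,
        n_observations=len(y),
        method=method,
        sigma2_scanner_main=s2_scan,
        sigma2_interaction=s2_int,
        interaction_policy=interaction,
        truncated=truncated,
        converged=converged,
    )


def fit_variance_components(
    table: CohortTable,
    software: str,
    structure: str,
    *,
    method: str = "auto",
    interaction: str = "fold_into_scanner",
    lesion_filled: bool | None = None,
    allow_unnormalized: bool = False,
) -> VarianceComponents:
    """Variance components of one (software, structure) cell of a cohort.

    The default policy expects a TIV-normalized table (head-size differences
    otherwise inflate the subject component); pass ``allow_unnormalized=True``
    to override deliberately.
    """
    if not table.normalized and not allow_unnormalized:
        raise StateError(
            "variance components are fitted on TIV-normalized volumes by default; "
            "call normalize_by_tiv first or pass allow_unnormalized=True"
        )
    df = table.subset(software=software, structure=structure)
    if lesion_filled is not None:
        df = df[df["lesion_filled"] == lesion_filled]
    if df.empty:
        raise InsufficientDataError(
            f"no records for software={software!r}, structure={structure!r}"
        )
    data = df.rename(
        columns={"subject_id": "subject", "scanner_id": "scanner", "volume_mm3": "value"}
    )[["subject", "scanner", "run", "value"]]
    return fit_crossed(data, method=method, interaction=interaction)


def sem_within(vc: VarianceComponents) -> float:
    """Within-scanner SEM: 100 * sqrt(sigma2_eps) / mean, in percent."""
    if vc.mean_volume <= 0:
        raise ValidationError("mean volume must be positive")
    return 100.0 * float(np.sqrt(vc.sigma2_residual)) / vc.mean_volume


def sem_between(vc: VarianceComponents) -> float:
    """Between-scanner SEM: 100 * sqrt(sigma2_r + sigma2_eps) / mean, percent."""
    if vc.mean_volume <= 0:
        raise ValidationError("mean volume must be positive")
    return (
        100.0 * float(np.sqrt(vc.sigma2_scanner + vc.sigma2_residual)) / vc.mean_volume
    )


def sdc_from_sem(sem_pct: float) -> float:
    """Smallest detectable change, 1.96 * sqrt(2) * SEM (same units as SEM)."""
    if sem_pct < 0:
        raise ValidationError("SEM must be non-negative")
    return SDC_FACTOR * sem_pct


def summarize_reliability(
    table: CohortTable,
    *,
    method: str = "auto",
    interaction: str = "fold_into_scanner",
) -> pd.DataFrame:
    """SEM / SDC summary per (software, structure, lesion-filled) cell.

    Returns a tidy DataFrame with within/between SEM and SDC as percent of
    the mean, one row per cell; lesion-filled and non-filled tables are
    analyzed separately.
    """
    rows = []
    df = table.records
    for (software, structure, filled), _ in df.groupby(
        ["software", "structure", "lesion_filled"], sort=False
    ):
        vc = fit_variance_components(
            table, software, structure,
            method=method, interaction=interaction, lesion_filled=filled,
        )
        sw = sem_within(vc)
        sb = sem_between(vc)
        rows.append(
            {
                "software": software,
                "structure": structure,
                "lesion_filled": filled,
                "mean_volume": vc.mean_volume,
                "sigma2_subject": vc.sigma2_subject,
                "sigma2_scanner": vc.sigma2_scanner,
                "sigma2_residual": vc.sigma2_residual,
                "method": vc.method,
                "sem_within_pct": sw,
                "sem_between_pct": sb,
                "sdc_within_pct": sdc_from_sem(sw),
                "sdc_between_pct": sdc_from_sem(sb),
            }
        )
    return pd.DataFrame(rows)


def reliability_extremes(summary: pd.DataFrame) -> dict[str, dict]:
    """Min/max cells of each SEM / SDC column, with their labels."""
    out: dict[str, dict] = {}
    for col in ("sem_within_pct", "sem_between_pct", "sdc_within_pct", "sdc_between_pct"):
        lo = summary.loc[summary[col].idxmin()]
        hi = summary.loc[summary[col].idxmax()]
        out[col] = {
            "min": {"software": lo["software"], "structure": lo["structure"],
                    "value": float(lo[col])},
            "max": {"software": hi["software"], "structure": hi["structure"],
                    "value": float(hi[col])},
        }
    return out
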