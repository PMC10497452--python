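"""Synthetic scan-rescan cohorts with planted reliability structure.

The generator emulates the statistical anatomy that the reliability pipeline
assumes in real multi-scanner volumetry: stable between-subject anatomical
variation, fixed multiplicative per-scanner segmentation biases, a
subject-by-scanner interaction, and scan-rescan replicate noise.  All effects
are multiplicative (mean-one lognormal factors), which matches the pipeline's
percent-of-mean error metrics and guarantees positive volumes; on the log
scale the model is exactly the additive crossed random-effects layout the
variance-component stage fits.

volume(i, j, r, s) = mean_s * head_i * subj_is * bias_js * inter_ijs * noise_ijrs

where head_i = TIV_i / mean(TIV) is the subject's head-size factor, shared by
every structure and by the TIV itself.  Dividing by TIV therefore removes
head-size variance -- as normalization does in real cohorts -- and
``subject_cv`` is the anatomical between-subject CV that remains after
normalization (head-size coupling can be disabled per config).  A fixed seed
makes the output bit-identical between runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import CohortTable, DesignSpec
from .errors import ConfigurationError

#: Default scanner labels of the three-vendor preset design.
PRESET_SCANNERS = ("GE", "Philips", "Toshiba")


@dataclass(frozen=True)
class StructureSim:
    """One simulated structure: label, population mean volume and between-subject CV."""

    name: str
    mean_mm3: float
    subject_cv: float


@dataclass(frozen=True)
class SyntheticConfig:
    """Full parameterization of a synthetic cohort.

    CVs are coefficients of variation (SD as a fraction of the mean) of the
    corresponding mean-one lognormal factor.  ``scanner_bias`` maps
    (scanner, structure) to a multiplicative bias, e.g. 0.97 = 3% low;
    unspecified pairs default to 1.0.  ``missing`` lists
    (subject index, scanner, run) records to omit, emulating QC exclusions.
    """

    n_subjects: int
    scanners: tuple[str, ...]
    n_runs: int
    structures: tuple[StructureSim, ...]
    scanner_bias: Mapping[tuple[str, str], float] = field(default_factory=dict)
    residual_cv: Mapping[str, float] = field(default_factory=dict)
    interaction_cv: float = 0.0
    tiv_mean_mm3: float = 1.55e6
    tiv_cv: float = 0.04
    missing: tuple[tuple[int, str, int], ...] = ()
    head_size_coupling: bool = True
    software: str = "simseg"
    lesion_filled: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ConfigurationError("n_subjects must be at least 3")
        if self.n_runs < 1:
            raise ConfigurationError("n_runs must be at least 1")
        cvs = [self.interaction_cv, self.tiv_cv]
        cvs += [s.subject_cv for s in self.structures]
        cvs += list(self.residual_cv.values())
        if any(c < 0 for c in cvs):
            raise ConfigurationError("coefficients of variation must be >= 0")
        if any(s.mean_mm3 <= 0 for s in self.structures) or self.tiv_mean_mm3 <= 0:
            raise ConfigurationError("mean volumes must be positive")
        if any(b <= 0 for b in self.scanner_bias.values()):
            raise ConfigurationError("scanner biases must be positive factors")

    def bias(self, scanner: str, structure: str) -> float:
        return float(self.scanner_bias.get((scanner, structure), 1.0))


def _lognormal_sigma(cv: float) -> float:
    """Log-scale SD of a lognormal with the given coefficient of variation."""
    return float(np.sqrt(np.log1p(cv * cv)))


def _mean_one_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Draw mean-one lognormal factors with coefficient of variation ``cv``."""
    if cv == 0.0:
        return np.ones(size)
    s = _lognormal_sigma(cv)
    return np.exp(rng.normal(loc=-0.5 * s * s, scale=s, size=size))


def generate_cohort(config: SyntheticConfig) -> CohortTable:
    """Generate a :class:`~scanrel.cohort.CohortTable` from a config.

    Draw order is fixed (TIV, then per structure: subject factors,
    interactions, noise) and independent of the missing-record list, so
    editing ``missing`` removes rows without perturbing the remaining values.
    """
    rng = np.random.default_rng(config.seed)
    n, scanners, runs = config.n_subjects, config.scanners, range(1, config.n_runs + 1)
    subjects = tuple(f"s{i + 1:02d}" for i in range(n))
    J, R = len(scanners), config.n_runs

    head = _mean_one_factor(rng, config.tiv_cv, n)
    tiv = config.tiv_mean_mm3 * head

    frames = []
    for spec in config.structures:
        subj = _mean_one_factor(rng, spec.subject_cv, n)
        if config.head_size_coupling:
            subj = subj * head
        inter = _mean_one_factor(rng, config.interaction_cv, (n, J))
        noise = _mean_one_factor(rng, config.residual_cv.get(spec.name, 0.0), (n, J, R))
        bias = np.array([config.bias(sc, spec.name) for sc in scanners])
        vol = spec.mean_mm3 * subj[:, None, None] * bias[None, :, None]
        vol = vol * inter[:, :, None] * noise
        idx = pd.MultiIndex.from_product(
            [subjects, scanners, list(runs)], names=["subject_id", "scanner_id", "run"]
        )
        df = pd.DataFrame({"volume_mm3": vol.reshape(-1)}, index=idx).reset_index()
        df["structure"] = spec.name
        frames.append(df)

    out = pd.concat(frames, ignore_index=True)
    out["software"] = config.software
    out["lesion_filled"] = config.lesion_filled
    out["tiv_mm3"] = out["subject_id"].map(dict(zip(subjects, tiv)))

    if config.missing:
        drop = set()
        for i, scanner, run in config.missing:
            if not 0 <= i < n:
                raise ConfigurationError(f"missing-record subject index {i} out of range")
            drop.add((subjects[i], scanner, int(run)))
        mask = ~out.apply(
            lambda r: (r["subject_id"], r["scanner_id"], r["run"]) in drop, axis=1
        )
        out = out[mask].reset_index(drop=True)

    design = DesignSpec(
        subjects=subjects,
        scanners=scanners,
        software=(config.software,),
        structures=tuple(s.name for s in config.structures),
        runs=tuple(runs),
    )
    return CohortTable(records=out, design=design)


# Default structure means (mm^3) and between-subject CVs for the preset
# three-scanner design.  These are plausible adult bilateral volumes and
# dispersions -- free parameters of the simulator, not estimates from any
# particular cohort.  The brain subject CV of 4.6% is consistent with
# two-sample power calculations that require ~640 participants per group to
# detect a 1% volume difference under a between-scanner SEM of ~4.4%.
PRESET_STRUCTURES: tuple[StructureSim, ...] = (
    StructureSim("brain", 1.05e6, 0.046),
    StructureSim("gm", 6.0e5, 0.055),
    StructureSim("wm", 4.5e5, 0.060),
    StructureSim("csf", 3.3e5, 0.120),
    StructureSim("amygdala", 3.1e3, 0.080),
    StructureSim("accumbens", 9.5e2, 0.100),
    StructureSim("caudate", 6.8e3, 0.080),
    StructureSim("hippocampus", 7.8e3, 0.080),
    StructureSim("pallidum", 3.2e3, 0.080),
    StructureSim("putamen", 9.6e3, 0.080),
    StructureSim("thalamus", 1.5e4, 0.070),
)

#: Scan-rescan replicate noise CVs per structure: small for large aggregates,
#: larger for CSF and small deep-gray structures that are harder to segment.
PRESET_RESIDUAL_CV: Mapping[str, float] = {
    "brain": 0.004,
    "gm": 0.006,
    "wm": 0.007,
    "csf": 0.030,
    "amygdala": 0.020,
    "accumbens": 0.030,
    "caudate": 0.012,
    "hippocampus": 0.012,
    "pallidum": 0.015,
    "putamen": 0.010,
    "thalamus": 0.008,
}

#: Planted systematic biases: GE segments gray matter high and white matter
#: low relative to the other two vendors.  Directions follow the systematic
#: differences the pipeline is designed to detect; magnitudes are free
#: parameters.
PRESET_SCANNER_BIAS: Mapping[tuple[str, str], float] = {
    ("GE", "gm"): 1.02,
    ("GE", "wm"): 0.97,
}


def preset_study_design(seed: int = 0, **overrides) -> SyntheticConfig:
    """The default study design: 21 subjects x 3 scanners x 2 runs.

    Eleven structures, one missing record (the first subject's rescan on GE,
    emulating a motion-artifact QC exclusion), and GM-high / WM-low biases on
    the GE scanner.  Keyword overrides replace any config field.
    """
    cfg = SyntheticConfig(
        n_subjects=21,
        scanners=PRESET_SCANNERS,
        n_runs=2,
        structures=PRESET_STRUCTURES,
        scanner_bias=dict(PRESET_SCANNER_BIAS),
        residual_cv=dict(PRESET_RESIDUAL_CV),
        interaction_cv=0.01,
        tiv_mean_mm3=1.55e6,
        tiv_cv=0.04,
        missing=((0, "GE", 2),),
        software="simseg",
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


def log_scale_truth(config: SyntheticConfig, structure: str) -> dict[str, float]:
    """Exact log-scale variance components implied by a config.

    Because every factor is lognormal, log-volumes follow the additive crossed
    model with subject variance log(1+cv_s^2) (plus log(1+cv_tiv^2) when
    head-size coupling is on), interaction variance
    log(1+cv_i^2) and residual variance log(1+cv_e^2); the fixed scanner
    log-biases contribute their (J-1)-denominator variance to the expected
    scanner component of a random-effects fit.  Used by parameter-recovery
    tests as the closed-form truth.
    """
    spec = {s.name: s for s in config.structures}[structure]
    lam = np.log([config.bias(sc, structure) for sc in config.scanners])
    s2_subj = _lognormal_sigma(spec.subject_cv) ** 2
    if config.head_size_coupling:
        s2_subj += _lognormal_sigma(config.tiv_cv) ** 2
    return {
        "sigma2_subject": s2_subj,
        "sigma2_scanner": float(np.var(lam, ddof=1)),
        "sigma2_interaction": _lognormal_sigma(config.interaction_cv) ** 2,
        "sigma2_residual": _lognormal_sigma(config.residual_cv.get(structure, 0.0)) ** 2,
    }
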