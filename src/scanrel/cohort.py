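"""Long-format cohort tables of scan-rescan brain volumes.

The atomic input of the pipeline is one measured volume per
(subject, scanner, run, segmentation software, structure, lesion-filled flag),
together with the intracranial-volume (TIV) estimate that the same software
emitted for head-size normalization.  This module provides the validated
in-memory container (:class:`CohortTable`, a thin wrapper around a pandas
DataFrame), CSV/TSV readers and writers, TIV normalization, QC exclusion of
individual runs, and the extraction of subjects x raters ratings matrices
that every downstream agreement statistic consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    InsufficientDataError,
    StateError,
    ValidationError,
)

#: Controlled vocabulary of structures the pipeline understands.  The seven
#: bilateral deep-gray-matter structures are reported as single (left+right)
#: volumes.
STRUCTURES: tuple[str, ...] = (
    "brain",
    "gm",
    "wm",
    "csf",
    "amygdala",
    "accumbens",
    "caudate",
    "hippocampus",
    "pallidum",
    "putamen",
    "thalamus",
)

#: Logical column names of the long-format schema.
COLUMNS: tuple[str, ...] = (
    "subject_id",
    "scanner_id",
    "run",
    "software",
    "structure",
    "lesion_filled",
    "volume_mm3",
    "tiv_mm3",
)

#: Columns that jointly key one record.
KEY_COLUMNS: tuple[str, ...] = (
    "subject_id",
    "scanner_id",
    "run",
    "software",
    "structure",
    "lesion_filled",
)

VALID_RUNS = (1, 2)


@dataclass(frozen=True)
class DesignSpec:
    """Declared factor levels of a scan-rescan study design."""

    subjects: tuple[str, ...]
    scanners: tuple[str, ...]
    software: tuple[str, ...]
    structures: tuple[str, ...]
    runs: tuple[int, ...] = VALID_RUNS

    def __post_init__(self) -> None:
        for s in self.structures:
            if s not in STRUCTURES:
                raise ValidationError(
                    f"unknown structure {s!r}; allowed: {', '.join(STRUCTURES)}"
                )
        if any(r not in VALID_RUNS for r in self.runs):
            raise ValidationError(f"runs must be a subset of {VALID_RUNS}")


@dataclass
class CohortTable:
    """Validated long-format table of volume records.

    Parameters
    ----------
    records
        DataFrame with the columns of :data:`COLUMNS`.  ``volume_mm3`` holds
        raw volumes in mm^3, or dimensionless fractions once
        :func:`normalize_by_tiv` has been applied.
    design
        Declared factor levels; every record must reference declared levels.
    normalized
        Provenance flag: True once volumes have been divided by TIV.
    exclusions
        Log of (subject_id, scanner_id, run) keys removed by
        :func:`exclude_records`.
    """

    records: pd.DataFrame
    design: DesignSpec
    normalized: bool = False
    exclusions: list[tuple[str, str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.records = _coerce_and_validate(self.records, self.design, self.normalized)

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, **levels) -> pd.DataFrame:
        """Return the records matching the given column=value filters."""
        df = self.records
        for col, val in levels.items():
            if col not in COLUMNS:
                raise ConfigurationError(f"unknown column {col!r}")
            df = df[df[col] == val]
        return df

    def lesion_flags(self) -> tuple[bool, ...]:
        return tuple(sorted(self.records["lesion_filled"].unique()))


def _coerce_and_validate(
    df: pd.DataFrame, design: DesignSpec, normalized: bool
) -> pd.DataFrame:
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"missing required columns: {missing}")
    df = df.loc[:, list(COLUMNS)].copy()
    df["run"] = df["run"].astype(int)
    df["lesion_filled"] = df["lesion_filled"].map(_parse_bool)
    df["volume_mm3"] = df["volume_mm3"].astype(float)
    df["tiv_mm3"] = df["tiv_mm3"].astype(float)
    for col in ("subject_id", "scanner_id", "software", "structure"):
        df[col] = df[col].astype(str)

    bad = df.index[df["volume_mm3"] <= 0]
    if len(bad):
        raise ValidationError(f"non-positive volume at row(s) {list(bad[:5])}")
    bad = df.index[df["tiv_mm3"] <= 0]
    if len(bad):
        raise ValidationError(f"non-positive TIV at row(s) {list(bad[:5])}")
    unknown = sorted(set(df["structure"]) - set(STRUCTURES))
    if unknown:
        raise ValidationError(
            f"unknown structure label(s) {unknown}; allowed vocabulary: "
            f"{', '.join(STRUCTURES)}"
        )
    bad = df.index[~df["run"].isin(VALID_RUNS)]
    if len(bad):
        raise ValidationError(f"run outside {VALID_RUNS} at row(s) {list(bad[:5])}")
    if not normalized:
        # Each record is a single structure, so its volume cannot exceed the
        # same software's intracranial volume.  No cross-record sum constraint.
        bad = df.index[df["volume_mm3"] > df["tiv_mm3"]]
        if len(bad):
            raise ValidationError(f"volume exceeds TIV at row(s) {list(bad[:5])}")

    for col, allowed in (
        ("subject_id", design.subjects),
        ("scanner_id", design.scanners),
        ("software", design.software),
        ("structure", design.structures),
    ):
        extra = sorted(set(df[col]) - set(allowed))
        if extra:
            raise ValidationError(f"{col} value(s) {extra} not in declared design")

    dup = df.duplicated(subset=list(KEY_COLUMNS), keep=False)
    if dup.any():
        first = df.loc[dup, list(KEY_COLUMNS)].iloc[0].to_dict()
        raise ValidationError(f"duplicate record key: {first}")
    return df.reset_index(drop=True)


def _parse_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    s = str(x).strip().lower()
    if s in ("true", "1", "t", "yes"):
        return True
    if s in ("false", "0", "f", "no"):
        return False
    raise ValidationError(f"cannot parse boolean lesion_filled value {x!r}")


def design_from_records(df: pd.DataFrame) -> DesignSpec:
    """Infer a :class:`DesignSpec` from the distinct levels present in a table."""
    return DesignSpec(
        subjects=tuple(sorted(df["subject_id"].astype(str).unique())),
        scanners=tuple(sorted(df["scanner_id"].astype(str).unique())),
        software=tuple(sorted(df["software"].astype(str).unique())),
        structures=tuple(s for s in STRUCTURES if s in set(df["structure"])),
        runs=tuple(sorted(int(r) for r in df["run"].unique())),
    )


def read_volume_table(
    path: str | Path,
    *,
    delimiter: str = ",",
    column_map: Mapping[str, str] | None = None,
    design: DesignSpec | None = None,
    normalized: bool = False,
) -> CohortTable:
    """Read a long-format volume table from delimited text.

    Parameters
    ----------
    path
        CSV/TSV file with one header row.
    delimiter
        Field delimiter, ``","`` by default.
    column_map
        Optional map from the logical column names of :data:`COLUMNS` to the
        names actually used in the file.
    design
        Declared design; inferred from the file when omitted.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"input file not found: {path}")
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    if column_map:
        rename = {v: k for k, v in column_map.items()}
        df = df.rename(columns=rename)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"file {path} lacks required column(s) {missing}; "
            "supply a column_map if the header uses different names"
        )
    if design is None:
        # validate structures before inferring, so unknown labels raise the
        # vocabulary error rather than a design-membership error
        unknown = sorted(set(df["structure"].astype(str)) - set(STRUCTURES))
        if unknown:
            raise ValidationError(
                f"unknown structure label(s) {unknown}; allowed vocabulary: "
                f"{', '.join(STRUCTURES)}"
            )
        design = design_from_records(df)
    return CohortTable(records=df, design=design, normalized=normalized)


def write_volume_table(
    table: CohortTable, path: str | Path, *, delimiter: str = ","
) -> Path:
    """Write a table in the standard schema.

    String and integer fields are emitted verbatim; real-valued fields with
    six significant digits, which round-trips through :func:`read_volume_table`
    to identical logical content.
    """
    path = Path(path)
    df = table.records.copy()
    df["volume_mm3"] = df["volume_mm3"].map(lambda v: f"{v:.6g}")
    df["tiv_mm3"] = df["tiv_mm3"].map(lambda v: f"{v:.6g}")
    df.to_csv(path, sep=delimiter, index=False)
    return path


def normalize_by_tiv(table: CohortTable) -> CohortTable:
    """Divide every volume by its record's TIV, yielding dimensionless fractions.

    Head-size normalization is standard practice for cross-sectional volume
    comparisons; the variance-component / SEM / SDC stages consume normalized
    tables while agreement (ICC) and bias tests run on raw volumes.
    Normalizing twice is a state error.
    """
    if table.normalized:
        raise StateError("table is already TIV-normalized")
    df = table.records.copy()
    df["volume_mm3"] = df["volume_mm3"] / df["tiv_mm3"]
    return CohortTable(
        records=df,
        design=table.design,
        normalized=True,
        exclusions=list(table.exclusions),
    )


def exclude_records(
    table: CohortTable, exclusions: Iterable[tuple[str, str, int]]
) -> CohortTable:
    """Drop whole runs flagged at QC (e.g. motion artifacts).

    Each exclusion key is a (subject_id, scanner_id, run) triple; all software
    and structure records of that run are removed.  Keys matching nothing
    produce a warning, not an error.  The applied exclusions are logged on the
    returned table.
    """
    df = table.records
    keep = pd.Series(True, index=df.index)
    applied: list[tuple[str, str, int]] = []
    for subj, scanner, run in exclusions:
        hit = (
            (df["subject_id"] == str(subj))
            & (df["scanner_id"] == str(scanner))
            & (df["run"] == int(run))
        )
        if not hit.any():
            warnings.warn(
                f"exclusion key ({subj}, {scanner}, {run}) matched no records",
                stacklevel=2,
            )
            continue
        keep &= ~hit
        applied.append((str(subj), str(scanner), int(run)))
    return CohortTable(
        records=df[keep].reset_index(drop=True),
        design=table.design,
        normalized=table.normalized,
        exclusions=list(table.exclusions) + applied,
    )


@dataclass(frozen=True)
class RatingsMatrix:
    """An n-subjects x k-raters complete matrix for agreement statistics.

    ``raters`` are either the two runs of one scanner (repeatability) or the
    first-run values on each of several scanners (reproducibility).  Subjects
    with any missing cell are dropped listwise before construction and counted
    in ``dropped_subjects``.
    """

    values: np.ndarray
    subjects: tuple[str, ...]
    raters: tuple[str, ...]
    rater_kind: str  # "runs_within_scanner" | "scanners_first_run"
    dropped_subjects: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2:
            raise ValidationError("ratings matrix must be two-dimensional")
        if not np.isfinite(v).all():
            raise ValidationError("ratings matrix contains missing cells")
        if self.k < 2:
            raise InsufficientDataError("ratings matrix needs at least 2 raters")
        if self.n < 3:
            raise InsufficientDataError(
                f"only {self.n} complete subjects; at least 3 required"
            )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


def pivot_ratings(
    table: CohortTable,
    software: str,
    structure: str,
    *,
    within_scanner: str | None = None,
    between_scanners: Sequence[str] | None = None,
    run_policy: str = "first",
    lesion_filled: bool | None = None,
    warn_if_normalized: bool = True,
) -> RatingsMatrix:
    """Extract the ratings matrix for one (software, structure) cell.

    Exactly one of ``within_scanner`` (columns = runs 1 and 2 of that scanner)
    or ``between_scanners`` (columns = the listed scanners) must be given.
    Between-scanner columns use the first run by default (``run_policy
    "first"``); ``"mean"`` averages the available runs of each scanner as a
    sensitivity variant.  Agreement statistics are computed on raw volumes by
    default, so a warning is issued when the table has been TIV-normalized.
    """
    if (within_scanner is None) == (between_scanners is None):
        raise ConfigurationError(
            "specify exactly one of within_scanner or between_scanners"
        )
    if run_policy not in ("first", "mean"):
        raise ConfigurationError(f"unknown run_policy {run_policy!r}")
    if table.normalized and warn_if_normalized:
        warnings.warn(
            "ratings matrices are built from raw volumes by default; "
            "this table is TIV-normalized",
            stacklevel=2,
        )

    df = table.subset(software=software, structure=structure)
    if lesion_filled is None:
        flags = df["lesion_filled"].unique()
        if len(flags) > 1:
            raise ConfigurationError(
                "table holds both lesion-filled and non-filled records; "
                "pass lesion_filled explicitly"
            )
    else:
        df = df[df["lesion_filled"] == lesion_filled]
    if df.empty:
        raise InsufficientDataError(
            f"no records for software={software!r}, structure={structure!r}"
        )

    if within_scanner is not None:
        if within_scanner not in table.design.scanners:
            raise ConfigurationError(f"scanner {within_scanner!r} not in design")
        sub = df[df["scanner_id"] == within_scanner]
        wide = sub.pivot(index="subject_id", columns="run", values="volume_mm3")
        wide = wide.reindex(columns=list(table.design.runs))
        raters = tuple(f"run{r}" for r in table.design.runs)
        kind = "runs_within_scanner"
    else:
        scanners = tuple(between_scanners)
        bad = [s for s in scanners if s not in table.design.scanners]
        if bad:
            raise ConfigurationError(f"scanner(s) {bad} not in design")
        if len(scanners) < 2:
            raise ConfigurationError("between_scanners needs at least two scanners")
        sub = df[df["scanner_id"].isin(scanners)]
        if run_policy == "first":
            sub = sub[sub["run"] == 1]
            wide = sub.pivot(index="subject_id", columns="scanner_id", values="volume_mm3")
        else:
            wide = sub.pivot_table(
                index="subject_id", columns="scanner_id", values="volume_mm3",
                aggfunc="mean",
            )
        wide = wide.reindex(columns=list(scanners))
        raters = scanners
        kind = "scanners_first_run"

    wide = wide.reindex(index=list(table.design.subjects))
    complete = wide.dropna()
    dropped = len(table.design.subjects) - len(complete)
    if len(complete) < 3:
        raise InsufficientDataError(
            f"only {len(complete)} complete subjects for software={software!r}, "
            f"structure={structure!r}"
        )
    return RatingsMatrix(
        values=complete.to_numpy(dtype=float),
        subjects=tuple(complete.index),
        raters=raters,
        rater_kind=kind,
        dropped_subjects=dropped,
    )
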