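"""End-to-end orchestration: cohort -> ICC -> bias tests -> VCA -> power.

`run_pipeline` drives the whole analysis from a single config (YAML/JSON or
an in-memory :class:`PipelineConfig`) and writes tidy CSV tables plus
heatmap-ready wide matrices, with a JSON manifest recording the seed,
policies, per-stage log and a content hash of every emitted file.  Rerunning
with the same config and seed reproduces all numeric outputs byte-for-byte.

Default policies follow the analysis design: agreement (ICC) and bias tests
run on raw volumes; variance components, SEM/SDC and power planning run on
TIV-normalized volumes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohort import (
    CohortTable,
    exclude_records,
    normalize_by_tiv,
    pivot_ratings,
    read_volume_table,
    write_volume_table,
)
from .bias import bland_altman_pairs, omnibus_scanner_test
from .errors import ConfigurationError
from .icc import icc_absolute, icc_consistency
from .power import PowerSpec, power_pair
from .simulate import SyntheticConfig, generate_cohort, preset_study_design
from .variance import fit_variance_components, sdc_from_sem, sem_between, sem_within

log = logging.getLogger("scanrel")

ALL_STAGES = ("icc", "bias", "vca", "power")
FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Everything `run_pipeline` needs.

    Either ``input_path`` (a long-format volume CSV) or ``synthetic`` (a
    :class:`~scanrel.simulate.SyntheticConfig`; default the preset design)
    must be provided.  ``icc_on_normalized=True`` forces the agreement stage
    onto normalized volumes -- allowed, but logged as a deviation from the
    default raw-volume policy.
    """

    input_path: str | None = None
    synthetic: SyntheticConfig | None = None
    delimiter: str = ","
    column_map: dict | None = None
    exclusions: list = field(default_factory=list)
    alpha: float = 0.05
    run_policy: str = "first"
    interaction: str = "fold_into_scanner"
    icc_on_normalized: bool = False
    posthoc_gate: float | None = 0.05
    power: PowerSpec = field(default_factory=PowerSpec)
    out_dir: str = "scanrel_out"
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a config from YAML or JSON."""
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigurationError(f"config file {path} must hold a mapping")
        kwargs: dict = {}
        simple = (
            "input_path", "delimiter", "column_map", "exclusions", "alpha",
            "run_policy", "interaction", "icc_on_normalized", "posthoc_gate",
            "out_dir", "seed",
        )
        for key in simple:
            if key in raw:
                kwargs[key] = raw[key]
        if "power" in raw:
            kwargs["power"] = PowerSpec(**raw["power"])
        if "synthetic" in raw:
            syn = dict(raw["synthetic"])
            if syn.pop("preset", True):
                kwargs["synthetic"] = preset_study_design(**syn)
            else:
                raise ConfigurationError(
                    "non-preset synthetic configs must be built in Python"
                )
        kwargs.update(overrides)
        return cls(**kwargs)


def _load_cohort(config: PipelineConfig) -> CohortTable:
    if (config.input_path is None) == (config.synthetic is None):
        raise ConfigurationError("provide exactly one of input_path or synthetic")
    if config.input_path is not None:
        table = read_volume_table(
            config.input_path,
            delimiter=config.delimiter,
            column_map=config.column_map,
        )
    else:
        syn = dataclasses.replace(config.synthetic, seed=config.seed)
        table = generate_cohort(syn)
    if config.exclusions:
        table = exclude_records(
            table, [(s, sc, int(r)) for s, sc, r in config.exclusions]
        )
    return table


def _cells(table: CohortTable):
    df = table.records
    return sorted(
        df.groupby(["software", "structure", "lesion_filled"]).groups.keys()
    )


def _icc_stage(table: CohortTable, config: PipelineConfig) -> dict[str, pd.DataFrame]:
    if config.icc_on_normalized:
        if not table.normalized:
            table = normalize_by_tiv(table)
        warnings.warn(
            "ICC stage forced onto TIV-normalized volumes; the default policy "
            "computes agreement on raw volumes",
            stacklevel=2,
        )
        log.warning("icc stage running on normalized volumes (non-default policy)")
    rows_w, rows_b = [], []
    for software, structure, filled in _cells(table):
        for scanner in table.design.scanners:
            m = pivot_ratings(
                table, software, structure,
                within_scanner=scanner, lesion_filled=filled,
                warn_if_normalized=False,
            )
            est = icc_absolute(m, alpha=config.alpha)
            rows_w.append(
                dict(software=software, structure=structure, lesion_filled=filled,
                     scanner=scanner, model=est.model, icc=est.value,
                     ci_low=est.ci_low, ci_high=est.ci_high,
                     classification=est.classification, n=est.n,
                     dropped_subjects=est.dropped_subjects)
            )
        combos = list(itertools.combinations(table.design.scanners, 2))
        if len(table.design.scanners) > 2:
            combos.append(tuple(table.design.scanners))
        for combo in combos:
            m = pivot_ratings(
                table, software, structure,
                between_scanners=combo, run_policy=config.run_policy,
                lesion_filled=filled, warn_if_normalized=False,
            )
            est = icc_consistency(m, alpha=config.alpha)
            rows_b.append(
                dict(software=software, structure=structure, lesion_filled=filled,
                     scanners="-".join(combo), model=est.model, icc=est.value,
                     ci_low=est.ci_low, ci_high=est.ci_high,
                     classification=est.classification, n=est.n,
                     dropped_subjects=est.dropped_subjects)
            )
    within = pd.DataFrame(rows_w)
    between = pd.DataFrame(rows_b)
    wide_w = within.pivot_table(
        index=["software", "structure", "lesion_filled"], columns="scanner",
        values="icc",
    ).reset_index()
    wide_b = between.pivot_table(
        index=["software", "structure", "lesion_filled"], columns="scanners",
        values="icc",
    ).reset_index()
    return {
        "icc_within.csv": within,
        "icc_between.csv": between,
        "icc_within_wide.csv": wide_w,
        "icc_between_wide.csv": wide_b,
    }


def _bias_stage(table: CohortTable, config: PipelineConfig) -> dict[str, pd.DataFrame]:
    rows, ba_rows = [], []
    for software, structure, filled in _cells(table):
        res = omnibus_scanner_test(
            table, software, structure,
            alpha=config.alpha, run_policy=config.run_policy,
            posthoc_gate=config.posthoc_gate, lesion_filled=filled,
        )
        if res.posthoc:
            for ph in res.posthoc:
                rows.append(
                    dict(software=software, structure=structure,
                         lesion_filled=filled, omnibus=res.omnibus_test,
                         omnibus_statistic=res.statistic, omnibus_p=res.p_value,
                         pair="-".join(ph.scanner_pair), pair_test=ph.test,
                         raw_p=ph.raw_p, bonferroni_p=ph.bonferroni_p,
                         mean_difference=ph.mean_difference,
                         n=res.n_subjects)
                )
        else:
            rows.append(
                dict(software=software, structure=structure, lesion_filled=filled,
                     omnibus=res.omnibus_test, omnibus_statistic=res.statistic,
                     omnibus_p=res.p_value, pair="", pair_test="", raw_p="",
                     bonferroni_p="", mean_difference="", n=res.n_subjects)
            )
        for ba in bland_altman_pairs(
            table, software, structure,
            alpha=config.alpha, run_policy=config.run_policy, lesion_filled=filled,
        ):
            ba_rows.append(
                dict(software=software, structure=structure, lesion_filled=filled,
                     pair="-".join(ba.scanner_pair), bias=ba.bias,
                     sd_diff=ba.sd_diff, loa_low=ba.loa_low, loa_high=ba.loa_high,
                     ci_bias_low=ba.ci_bias[0], ci_bias_high=ba.ci_bias[1],
                     proportional_slope=ba.proportional_slope,
                     proportional_p=ba.proportional_p, n=ba.n)
            )
    return {
        "bias_tests.csv": pd.DataFrame(rows),
        "bland_altman.csv": pd.DataFrame(ba_rows),
    }


def _vca_stage(table: CohortTable, config: PipelineConfig) -> dict[str, pd.DataFrame]:
    norm = table if table.normalized else normalize_by_tiv(table)
    rows = []
    for software, structure, filled in _cells(norm):
        vc = fit_variance_components(
            norm, software, structure,
            interaction=config.interaction, lesion_filled=filled,
        )
        sw, sb = sem_within(vc), sem_between(vc)
        rows.append(
            dict(software=software, structure=structure, lesion_filled=filled,
                 mean_volume=vc.mean_volume, method=vc.method,
                 sigma2_subject=vc.sigma2_subject, sigma2_scanner=vc.sigma2_scanner,
                 sigma2_residual=vc.sigma2_residual,
                 sem_within_pct=sw, sem_between_pct=sb,
                 sdc_within_pct=sdc_from_sem(sw), sdc_between_pct=sdc_from_sem(sb),
                 n=vc.n_observations)
        )
    tidy = pd.DataFrame(rows)
    sem_wide = tidy.pivot_table(
        index=["structure", "lesion_filled"], columns="software",
        values=["sem_within_pct", "sem_between_pct"],
    ).reset_index()
    sem_wide.columns = ["_".join(str(c) for c in col if c) for col in sem_wide.columns]
    sdc_wide = tidy.pivot_table(
        index=["structure", "lesion_filled"], columns="software",
        values=["sdc_within_pct", "sdc_between_pct"],
    ).reset_index()
    sdc_wide.columns = ["_".join(str(c) for c in col if c) for col in sdc_wide.columns]
    return {
        "reliability.csv": tidy,
        "sem_matrix.csv": sem_wide,
        "sdc_matrix.csv": sdc_wide,
    }


def _power_stage(table: CohortTable, config: PipelineConfig) -> dict[str, pd.DataFrame]:
    norm = table if table.normalized else normalize_by_tiv(table)
    rows = []
    for software, structure, filled in _cells(norm):
        vc = fit_variance_components(
            norm, software, structure,
            interaction=config.interaction, lesion_filled=filled,
        )
        res = power_pair(vc, config.power)
        rows.append(
            dict(software=software, structure=structure, lesion_filled=filled,
                 n_within=res.n_within, n_between=res.n_between, ratio=res.ratio,
                 variance_ratio=res.variance_ratio,
                 sd_within_pct=res.sd_within_pct, sd_between_pct=res.sd_between_pct)
        )
    return {"power.csv": pd.DataFrame(rows)}


_STAGE_FUNCS = {
    "icc": _icc_stage,
    "bias": _bias_stage,
    "vca": _vca_stage,
    "power": _power_stage,
}


def run_pipeline(
    config: PipelineConfig, stages: tuple[str, ...] = ALL_STAGES
) -> dict:
    """Run the requested stages and write outputs + manifest to ``out_dir``.

    Returns the manifest dict.  A stage failure is recorded in the manifest
    (with partial outputs retained) and re-raised.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "scanrel_version": __version__,
        "seed": config.seed,
        "policies": {
            "run_policy": config.run_policy,
            "interaction": config.interaction,
            "icc_on_normalized": config.icc_on_normalized,
            "alpha": config.alpha,
            "posthoc_gate": config.posthoc_gate,
        },
        "stages": {},
        "files": {},
        "failed_stage": None,
    }

    table = _load_cohort(config)
    if config.synthetic is not None:
        write_volume_table(table, out / "cohort.csv")
        manifest["files"]["cohort.csv"] = _sha256(out / "cohort.csv")

    try:
        for stage in stages:
            if stage not in _STAGE_FUNCS:
                raise ConfigurationError(f"unknown stage {stage!r}")
            t0 = time.perf_counter()
            outputs = _STAGE_FUNCS[stage](table, config)
            for name, df in outputs.items():
                path = out / name
                df.to_csv(path, index=False, float_format=FLOAT_FMT)
                manifest["files"][name] = _sha256(path)
            manifest["stages"][stage] = {
                "seconds": round(time.perf_counter() - t0, 3),
                "outputs": sorted(outputs),
            }
            log.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)
    except Exception as exc:
        manifest["failed_stage"] = {"stage": stage, "error": str(exc)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()
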