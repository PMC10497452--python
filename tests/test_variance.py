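"""Variance components, SEM/SDC derivation and reliability summaries."""

import numpy as np
import pandas as pd
import pytest

import scanrel as sr
from scanrel.errors import InsufficientDataError, StateError, ValidationError
from scanrel.simulate import StructureSim
from scanrel.variance import SDC_FACTOR, fit_crossed


def crossed_df(table, structure, log=False):
    df = table.subset(structure=structure).rename(
        columns={"subject_id": "subject", "scanner_id": "scanner",
                 "volume_mm3": "value"}
    )[["subject", "scanner", "run", "value"]].copy()
    if log:
        df["value"] = np.log(df["value"])
    return df


def vc_of(**kw):
    base = dict(sigma2_subject=1.0, sigma2_scanner=0.0, sigma2_residual=1.0,
                mean_volume=100.0, n_observations=10, method="moments")
    base.update(kw)
    return sr.VarianceComponents(**base)


class TestFitCrossed:
    def test_constant_data_yields_zero_components(self):
        cfg = sr.preset_study_design(
            seed=0, missing=(), tiv_cv=0.0, interaction_cv=0.0,
            structures=(StructureSim("brain", 1.0e6, 0.0),),
            residual_cv={}, scanner_bias={},
        )
        table = sr.generate_cohort(cfg)
        vc = sr.fit_variance_components(table, "simseg", "brain",
                                        allow_unnormalized=True)
        assert vc.sigma2_subject == vc.sigma2_scanner == vc.sigma2_residual == 0.0
        assert vc.mean_volume == pytest.approx(1.0e6)

    def test_moments_equal_reml_on_balanced_data(self):
        for seed in (3, 11):
            table = sr.generate_cohort(sr.preset_study_design(seed=seed, missing=()))
            df = crossed_df(table, "wm", log=True)
            mom = fit_crossed(df, method="moments")
            reml = fit_crossed(df, method="reml")
            for f in ("sigma2_subject", "sigma2_scanner_main",
                      "sigma2_interaction", "sigma2_residual"):
                assert getattr(mom, f) == pytest.approx(getattr(reml, f), abs=1e-8)

    def test_reml_robust_to_one_deleted_run(self):
        """Dropping a single run barely moves the REML estimates."""
        balanced = sr.generate_cohort(sr.preset_study_design(seed=21, missing=()))
        holed = sr.exclude_records(balanced, [("s01", "GE", 2)])
        full = fit_crossed(crossed_df(balanced, "gm", log=True), method="reml")
        part = fit_crossed(crossed_df(holed, "gm", log=True), method="reml")
        assert part.sigma2_subject == pytest.approx(full.sigma2_subject, rel=0.1)
        assert part.sigma2_residual == pytest.approx(full.sigma2_residual, rel=0.35)

    def test_reml_matches_mixed_model_reference(self):
        """Unbalanced fit agrees with statsmodels MixedLM variance components."""
        smf = pytest.importorskip("statsmodels.formula.api")
        table = sr.generate_cohort(sr.preset_study_design(seed=5))
        df = crossed_df(table, "gm", log=True)
        mine = fit_crossed(df, method="reml")
        df = df.copy()
        df["g"] = 1
        df["cell"] = df["subject"] + ":" + df["scanner"]
        md = smf.mixedlm(
            "value ~ 1", df, groups="g",
            vc_formula={"subject": "0 + C(subject)",
                        "scanner": "0 + C(scanner)",
                        "cell": "0 + C(cell)"},
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = md.fit(reml=True, method="lbfgs", maxiter=2000)
        ref = dict(zip(fit.model.exog_vc.names, fit.vcomp))
        assert mine.sigma2_subject == pytest.approx(ref["subject"], abs=1e-4)
        assert mine.sigma2_scanner_main == pytest.approx(ref["scanner"], abs=1e-4)
        assert mine.sigma2_interaction == pytest.approx(ref["cell"], abs=1e-4)
        assert mine.sigma2_residual == pytest.approx(fit.scale, abs=1e-4)

    def test_moments_requires_balance(self, preset_cohort):
        with pytest.raises(InsufficientDataError):
            fit_crossed(crossed_df(preset_cohort, "brain"), method="moments")

    def test_requires_normalized_table_by_default(self, preset_cohort):
        with pytest.raises(StateError):
            sr.fit_variance_components(preset_cohort, "simseg", "brain")

    def test_insufficient_levels(self):
        df = pd.DataFrame({
            "subject": ["a", "b", "c"] * 2,
            "scanner": ["X"] * 6,
            "run": [1, 1, 1, 2, 2, 2],
            "value": np.arange(6.0),
        })
        with pytest.raises(InsufficientDataError):
            fit_crossed(df)

    def test_interaction_policies(self, normalized_preset):
        fold = sr.fit_variance_components(normalized_preset, "simseg", "wm",
                                          interaction="fold_into_scanner")
        pool = sr.fit_variance_components(normalized_preset, "simseg", "wm",
                                          interaction="pool_into_residual")
        drop = sr.fit_variance_components(normalized_preset, "simseg", "wm",
                                          interaction="drop")
        assert fold.sigma2_scanner == pytest.approx(
            drop.sigma2_scanner + fold.sigma2_interaction)
        assert pool.sigma2_residual == pytest.approx(
            drop.sigma2_residual + pool.sigma2_interaction)


class TestSemSdc:
    def test_sem_within_arithmetic(self):
        assert sr.sem_within(vc_of(sigma2_residual=4.0, mean_volume=200.0)) == 1.0
        assert sr.sem_within(vc_of(sigma2_residual=0.0)) == 0.0

    def test_sem_between_arithmetic(self):
        vc = vc_of(sigma2_scanner=3.0, sigma2_residual=1.0, mean_volume=100.0)
        assert sr.sem_between(vc) == pytest.approx(2.0)
        vc0 = vc_of(sigma2_scanner=0.0, sigma2_residual=2.5)
        assert sr.sem_between(vc0) == sr.sem_within(vc0)

    def test_sdc_constant(self):
        assert SDC_FACTOR == pytest.approx(2.771859, abs=1e-6)
        assert sr.sdc_from_sem(0.0) == 0.0
        # reported two-decimal pairs from published SEM/SDC tables
        assert round(sr.sdc_from_sem(5.25), 2) == 14.55
        assert round(sr.sdc_from_sem(1.63), 2) == 4.52
        with pytest.raises(ValidationError):
            sr.sdc_from_sem(-1.0)

    def test_planted_residual_cv_sets_sem_within(self):
        """residual_cv of 0.5% shows up as SEM_within near 0.5%."""
        vals = []
        for s in range(60):
            cfg = sr.preset_study_design(
                seed=5000 + s, missing=(),
                structures=(StructureSim("brain", 1.05e6, 0.046),),
                residual_cv={"brain": 0.005}, scanner_bias={},
            )
            norm = sr.normalize_by_tiv(sr.generate_cohort(cfg))
            vals.append(sr.sem_within(
                sr.fit_variance_components(norm, "simseg", "brain")))
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - 0.5) < max(3 * se, 0.01)

    def test_planted_bias_moves_only_between_scanner_sem(self):
        sem_w, sem_b = [], []
        for b in (1.0, 0.98, 0.95):
            cfg = sr.preset_study_design(
                seed=11, missing=(),
                structures=(StructureSim("wm", 4.5e5, 0.06),),
                scanner_bias={("GE", "wm"): b},
            )
            norm = sr.normalize_by_tiv(sr.generate_cohort(cfg))
            vc = sr.fit_variance_components(norm, "simseg", "wm")
            sem_w.append(sr.sem_within(vc))
            sem_b.append(sr.sem_between(vc))
        assert sem_b[0] < sem_b[1] < sem_b[2]
        assert max(sem_w) - min(sem_w) < 0.01  # within-scanner SEM untouched


class TestSummary:
    def test_summary_invariants(self, normalized_preset):
        summary = sr.summarize_reliability(normalized_preset)
        assert len(summary) == 11
        ratio_w = summary["sdc_within_pct"] / summary["sem_within_pct"]
        ratio_b = summary["sdc_between_pct"] / summary["sem_between_pct"]
        assert np.allclose(ratio_w, SDC_FACTOR, atol=1e-9)
        assert np.allclose(ratio_b, SDC_FACTOR, atol=1e-9)
        assert (summary["sem_between_pct"] >= summary["sem_within_pct"]).all()

    def test_percent_outputs_invariant_to_global_rescaling(self):
        table = sr.generate_cohort(sr.preset_study_design(
            seed=3, structures=(StructureSim("thalamus", 1.5e4, 0.07),)))
        scaled_records = table.records.copy()
        scaled_records[["volume_mm3", "tiv_mm3"]] *= 3.7
        scaled = sr.CohortTable(records=scaled_records, design=table.design)
        a = sr.summarize_reliability(sr.normalize_by_tiv(table))
        b = sr.summarize_reliability(sr.normalize_by_tiv(scaled))
        for col in ("sem_within_pct", "sem_between_pct",
                    "sdc_within_pct", "sdc_between_pct"):
            assert np.allclose(a[col], b[col], rtol=1e-9)

    def test_extremes_extraction_on_hand_built_summary(self):
        summary = pd.DataFrame({
            "software": ["a", "a", "b"],
            "structure": ["brain", "csf", "brain"],
            "sem_within_pct": [0.4, 2.0, 0.6],
            "sem_between_pct": [1.0, 5.0, 0.9],
            "sdc_within_pct": [1.1, 5.5, 1.7],
            "sdc_between_pct": [2.8, 13.9, 2.5],
        })
        ext = sr.reliability_extremes(summary)
        assert ext["sem_within_pct"]["min"]["software"] == "a"
        assert ext["sem_within_pct"]["min"]["structure"] == "brain"
        assert ext["sem_between_pct"]["max"]["structure"] == "csf"
        assert ext["sdc_between_pct"]["min"]["software"] == "b"

    def test_zero_bias_cohort_has_similar_within_between(self):
        """With no scanner bias and no interaction, the two SEM columns agree
        up to Monte-Carlo error."""
        cfg = sr.preset_study_design(
            seed=8, missing=(), interaction_cv=0.0, scanner_bias={},
            structures=(StructureSim("brain", 1.05e6, 0.046),),
            residual_cv={"brain": 0.005},
        )
        norm = sr.normalize_by_tiv(sr.generate_cohort(cfg))
        row = sr.summarize_reliability(norm).iloc[0]
        assert row["sem_between_pct"] <= 2.0 * row["sem_within_pct"]
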