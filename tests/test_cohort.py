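"""Cohort I/O, validation, normalization, exclusion and ratings extraction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import scanrel as sr
from scanrel.errors import (
    ConfigurationError,
    InsufficientDataError,
    StateError,
    ValidationError,
)
from scanrel.simulate import StructureSim


def small_cohort(seed=0, n=4) -> sr.CohortTable:
    cfg = sr.preset_study_design(
        seed=seed,
        n_subjects=n,
        structures=(
            StructureSim("brain", 1.05e6, 0.046),
            StructureSim("thalamus", 1.5e4, 0.07),
        ),
        missing=(),
    )
    return sr.generate_cohort(cfg)


def records_df(**overrides) -> pd.DataFrame:
    base = dict(
        subject_id=["s01", "s01"],
        scanner_id=["GE", "GE"],
        run=[1, 2],
        software=["simseg", "simseg"],
        structure=["brain", "brain"],
        lesion_filled=[False, False],
        volume_mm3=[1.1e6, 1.09e6],
        tiv_mm3=[1.5e6, 1.5e6],
    )
    base.update(overrides)
    return pd.DataFrame(base)


class TestReadWrite:
    def test_round_trip_is_exact(self, tmp_path):
        """Writer output re-reads and re-writes to byte-identical content."""
        table = small_cohort()
        p1 = tmp_path / "a.csv"
        p2 = tmp_path / "b.csv"
        sr.write_volume_table(table, p1)
        again = sr.read_volume_table(p1)
        sr.write_volume_table(again, p2)
        assert p1.read_text() == p2.read_text()
        pd.testing.assert_frame_equal(
            again.records[["subject_id", "scanner_id", "run", "software",
                           "structure", "lesion_filled"]],
            table.records[["subject_id", "scanner_id", "run", "software",
                           "structure", "lesion_filled"]],
        )

    def test_tsv_dialect_and_column_map(self, tmp_path):
        table = small_cohort()
        path = tmp_path / "c.tsv"
        sr.write_volume_table(table, path, delimiter="\t")
        renamed = path.read_text().replace("volume_mm3", "vol")
        path.write_text(renamed)
        got = sr.read_volume_table(
            path, delimiter="\t", column_map={"volume_mm3": "vol"}
        )
        assert len(got) == len(table)

    def test_missing_column_is_configuration_error(self, tmp_path):
        df = records_df().drop(columns=["tiv_mm3"])
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ConfigurationError, match="tiv_mm3"):
            sr.read_volume_table(path)

    def test_nonexistent_file(self, tmp_path):
        with pytest.raises(ConfigurationError, match="not found"):
            sr.read_volume_table(tmp_path / "nope.csv")

    def test_duplicate_key_names_the_key(self, tmp_path):
        df = records_df(run=[1, 1])
        path = tmp_path / "dup.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValidationError, match="duplicate record key.*s01"):
            sr.read_volume_table(path)

    def test_negative_volume_flags_row(self, tmp_path):
        df = records_df(volume_mm3=[1.1e6, -5.0])
        path = tmp_path / "neg.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValidationError, match="non-positive volume.*1"):
            sr.read_volume_table(path)

    def test_unknown_structure_lists_vocabulary(self, tmp_path):
        df = records_df(structure=["brain", "cerebellum"])
        path = tmp_path / "voc.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValidationError, match="thalamus"):
            sr.read_volume_table(path)

    def test_volume_exceeding_tiv_rejected(self):
        df = records_df(volume_mm3=[1.6e6, 1.1e6])
        with pytest.raises(ValidationError, match="exceeds TIV"):
            sr.CohortTable(records=df, design=sr.design_from_records(df))


class TestNormalize:
    def test_fraction_arithmetic(self):
        df = records_df(volume_mm3=[1.2e6, 1.2e6], tiv_mm3=[1.5e6, 1.5e6])
        table = sr.CohortTable(records=df, design=sr.design_from_records(df))
        norm = sr.normalize_by_tiv(table)
        assert norm.normalized
        assert np.allclose(norm.records["volume_mm3"], 0.8)

    def test_double_normalization_is_state_error(self):
        norm = sr.normalize_by_tiv(small_cohort())
        with pytest.raises(StateError):
            sr.normalize_by_tiv(norm)

    def test_software_specific_tiv_definitions(self):
        """Same subject, two software with different TIVs: hand-computed ratios."""
        df = pd.DataFrame(
            dict(
                subject_id=["s01"] * 4,
                scanner_id=["GE"] * 4,
                run=[1, 1, 1, 1],
                software=["alpha", "alpha", "beta", "beta"],
                structure=["gm", "wm", "gm", "wm"],
                lesion_filled=[False] * 4,
                volume_mm3=[600000.0, 450000.0, 615000.0, 440000.0],
                tiv_mm3=[1500000.0, 1500000.0, 1480000.0, 1480000.0],
            )
        )
        table = sr.CohortTable(records=df, design=sr.design_from_records(df))
        norm = sr.normalize_by_tiv(table).records
        expected = {
            ("alpha", "gm"): 0.4,
            ("alpha", "wm"): 0.3,
            ("beta", "gm"): 615000.0 / 1480000.0,
            ("beta", "wm"): 440000.0 / 1480000.0,
        }
        for (software, structure), frac in expected.items():
            got = norm[(norm.software == software) & (norm.structure == structure)]
            assert got["volume_mm3"].iloc[0] == pytest.approx(frac, rel=1e-12)


class TestExclusions:
    def test_excluded_run_removed_across_structures(self):
        table = small_cohort()
        out = sr.exclude_records(table, [("s01", "GE", 2)])
        gone = out.subset(subject_id="s01", scanner_id="GE")
        assert set(gone["run"]) == {1}
        # both structures lost that run
        assert len(table) - len(out) == 2
        assert out.exclusions == [("s01", "GE", 2)]

    def test_empty_exclusion_list_is_identity(self):
        table = small_cohort()
        out = sr.exclude_records(table, [])
        pd.testing.assert_frame_equal(out.records, table.records)

    def test_unmatched_key_warns_not_fatal(self):
        table = small_cohort()
        with pytest.warns(UserWarning, match="matched no records"):
            out = sr.exclude_records(table, [("s99", "GE", 1)])
        assert len(out) == len(table)

    def test_excluding_whole_scanner_shrinks_between_matrices(self):
        table = small_cohort(n=6)
        keys = [(s, "Toshiba", r) for s in ("s01",) for r in (1, 2)]
        out = sr.exclude_records(table, keys)
        m = sr.pivot_ratings(out, "simseg", "brain",
                             between_scanners=("GE", "Toshiba"))
        assert m.n == 5 and m.dropped_subjects == 1


class TestPivotRatings:
    def test_within_scanner_excluded_rescan(self, preset_cohort):
        m = sr.pivot_ratings(preset_cohort, "simseg", "brain", within_scanner="GE")
        assert (m.n, m.k) == (20, 2)
        assert m.dropped_subjects == 1
        assert m.rater_kind == "runs_within_scanner"

    def test_between_pair_and_all(self, preset_cohort):
        pair = sr.pivot_ratings(preset_cohort, "simseg", "brain",
                                between_scanners=("GE", "Philips"))
        assert (pair.n, pair.k) == (21, 2)
        trio = sr.pivot_ratings(preset_cohort, "simseg", "brain",
                                between_scanners=preset_cohort.design.scanners)
        assert (trio.n, trio.k) == (21, 3)
        assert trio.rater_kind == "scanners_first_run"

    def test_row_count_plus_dropped_is_design_size(self, preset_cohort):
        for scanner in preset_cohort.design.scanners:
            m = sr.pivot_ratings(preset_cohort, "simseg", "thalamus",
                                 within_scanner=scanner)
            assert m.n + m.dropped_subjects == len(preset_cohort.design.subjects)

    def test_run_mean_policy_changes_values(self, preset_cohort):
        first = sr.pivot_ratings(preset_cohort, "simseg", "brain",
                                 between_scanners=("Philips", "Toshiba"))
        mean = sr.pivot_ratings(preset_cohort, "simseg", "brain",
                                between_scanners=("Philips", "Toshiba"),
                                run_policy="mean")
        assert not np.allclose(first.values, mean.values)

    def test_too_few_complete_subjects(self):
        table = small_cohort(n=3)
        out = sr.exclude_records(table, [("s01", "GE", 2)])
        with pytest.raises(InsufficientDataError):
            sr.pivot_ratings(out, "simseg", "brain", within_scanner="GE")

    def test_normalized_table_warns(self, normalized_preset):
        with pytest.warns(UserWarning, match="raw volumes"):
            sr.pivot_ratings(normalized_preset, "simseg", "brain",
                             within_scanner="GE")

    @given(st.sets(st.integers(min_value=0, max_value=7), max_size=4))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_dropped_plus_rows_invariant_under_exclusions(self, idxs):
        """Listwise deletion always accounts for every design subject."""
        table = small_cohort(n=8)
        keys = [(f"s{i + 1:02d}", "GE", 2) for i in idxs]
        out = sr.exclude_records(table, keys)
        try:
            m = sr.pivot_ratings(out, "simseg", "brain", within_scanner="GE")
        except InsufficientDataError:
            assert len(idxs) > 5
            return
        assert m.n + m.dropped_subjects == 8
        assert m.dropped_subjects == len(idxs)
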