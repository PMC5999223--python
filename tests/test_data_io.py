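"""Slide/clinical table reading, validation diagnostics and per-case summaries."""

import io
import textwrap

import numpy as np
import pandas as pd
import pytest

from thymentropy import (
    CohortConfig,
    SchemaError,
    read_clinical_table,
    read_slide_table,
    simulate_cohort,
    summarize_per_case,
)

SLIDE_HEADER = "case_id,region,slide_id,staining,grading_atrophy,n_follicle,intrathymic_fat"


def _slide_csv(rows: list[str]) -> io.StringIO:
    return io.StringIO("\n".join([SLIDE_HEADER, *rows]) + "\n")


class TestReadSlideTable:
    def test_three_row_fixture_loads_one_case(self):
        table = read_slide_table(
            _slide_csv(
                [
                    "37T004,A,S1,HE,2,1,40",
                    "37T004,RU,S2,HE,3,0,55",
                    "37T004,LL,S3,CD23,,8,",
                ]
            )
        )
        assert table.n_cases == 1
        assert table.case_ids == ["37T004"]
        assert table.n_slides("37T004") == 3
        assert not table.row_errors

    def test_out_of_range_grade_rejects_row_with_diagnostics(self):
        table = read_slide_table(
            _slide_csv(["C1,A,S1,HE,7,1,40", "C1,A,S2,HE,2,1,40"])
        )
        assert table.n_slides("C1") == 1
        (err,) = table.row_errors
        assert err.column == "grading_atrophy"
        assert err.row == 0
        assert "7" in err.message

    def test_unparseable_numeric_is_row_error(self):
        table = read_slide_table(_slide_csv(["C1,A,S1,HE,two,1,40", "C1,A,S2,HE,2,1,40"]))
        assert table.n_slides("C1") == 1
        assert table.row_errors[0].column == "grading_atrophy"

    def test_missing_cells_preserved_as_missing(self):
        table = read_slide_table(_slide_csv(["C1,A,S1,HE,2,,40"]))
        assert table.m_points("C1", "n_follicle") == 0
        assert table.m_points("C1", "grading_atrophy") == 1

    def test_missing_required_column_is_fatal(self):
        csv = io.StringIO("case_id,region,staining\nC1,A,HE\n")
        with pytest.raises(SchemaError, match="slide_id"):
            read_slide_table(csv)

    def test_unknown_staining_and_region_reject_rows(self):
        table = read_slide_table(
            _slide_csv(["C1,A,S1,PAS,2,1,40", "C1,Q,S2,HE,2,1,40", "C1,A,S3,HE,2,1,40"])
        )
        assert table.n_slides("C1") == 1
        assert {e.column for e in table.row_errors} == {"staining", "region"}

    def test_duplicate_slide_id_rejected(self):
        table = read_slide_table(_slide_csv(["C1,A,S1,HE,2,1,40", "C1,A,S1,HE,3,1,40"]))
        assert table.n_slides("C1") == 1
        assert table.row_errors[0].column == "slide_id"

    def test_synthetic_cohort_roundtrip_matches_manifest(self, tmp_path):
        cohort = simulate_cohort(CohortConfig(seed=3, n_cases=55))
        path = tmp_path / "slides.csv"
        cohort.slides.to_csv(path, index=False)
        table = read_slide_table(path)
        assert table.n_cases == 55
        assert not table.row_errors
        for truth in cohort.manifest.cases[:5]:
            assert table.m_points(truth.case_id, "n_follicle", "CD23") == truth.n_blocks


class TestRoundTrip:
    def test_write_read_is_value_identical(self, fixture_table, tmp_path):
        path = tmp_path / "slides.csv"
        fixture_table.write_csv(path)
        again = read_slide_table(path)
        pd.testing.assert_frame_equal(fixture_table.frame, again.frame)

    def test_m_points_mask_locality(self, fixture_table):
        frame = fixture_table.frame
        m_before = fixture_table.m_points("FIX001", "n_follicle", "CD23")
        mask_row = frame[
            (frame["case_id"] == "FIX001") & (frame["staining"] == "CD23")
        ].index[0]
        frame.loc[mask_row, "n_follicle"] = np.nan
        from thymentropy import CaseTable

        masked = CaseTable(frame)
        assert masked.m_points("FIX001", "n_follicle", "CD23") == m_before - 1
        assert m_before <= 6


CLIN_HEADER = (
    "case_id,age,sex,bmi,qmg_baseline,qmg_drop_m12_36,mms_m12_36,"
    "mg_duration_months,prednisone_pre_g,prednisone_post_g"
)


class TestReadClinicalTable:
    def test_two_cases_two_records(self):
        csv = io.StringIO(
            f"{CLIN_HEADER}\nC1,40,female,25,12,1,0,10,20,60\nC2,55,male,30,8,0,1,24,15,45\n"
        )
        records = read_clinical_table(csv)
        assert len(records) == 2
        assert records[0].sex == "female"
        assert records[1].mms_m12_36 == 1

    def test_duplicate_case_id_is_error(self):
        csv = io.StringIO(
            f"{CLIN_HEADER}\nC1,40,female,25,12,1,0,10,20,60\nC1,41,male,26,9,0,0,12,10,50\n"
        )
        with pytest.raises(SchemaError, match="duplicate"):
            read_clinical_table(csv)

    def test_non_binary_endpoint_is_error(self):
        csv = io.StringIO(f"{CLIN_HEADER}\nC1,40,female,25,12,2,0,10,20,60\n")
        with pytest.raises(ValueError, match="qmg_drop"):
            read_clinical_table(csv)

    def test_synthetic_clinical_roundtrip(self, small_cohort, tmp_path):
        path = tmp_path / "clinical.csv"
        small_cohort.clinical.to_csv(path, index=False)
        records = read_clinical_table(path)
        assert len(records) == small_cohort.manifest.n_cases
        assert [r.case_id for r in records] == list(small_cohort.clinical["case_id"])


class TestSummarizePerCase:
    def test_median_and_range(self):
        table = read_slide_table(
            _slide_csv(["C1,A,S1,CD23,,2,", "C1,A,S2,CD23,,2,", "C1,A,S3,CD23,,8,"])
        )
        s = summarize_per_case(table, "n_follicle").loc["C1"]
        assert s["median"] == 2 and (s["min"], s["max"]) == (2, 8)
        assert s["mode"] == 2

    def test_all_missing_case_retained_with_nan(self):
        table = read_slide_table(_slide_csv(["C1,A,S1,HE,2,,40", "C2,A,S2,CD23,,5,"]))
        out = summarize_per_case(table, "n_follicle")
        assert set(out.index) == {"C1", "C2"}
        assert np.isnan(out.loc["C1", "mean"]) and out.loc["C1", "n"] == 0

    def test_nominal_variable_unsupported(self, fixture_table):
        with pytest.raises(ValueError, match="nominal"):
            summarize_per_case(fixture_table, "follicle_morphology")

    def test_mean_matches_independent_recomputation(self, small_cohort, tmp_path):
        path = tmp_path / "slides.csv"
        small_cohort.slides.to_csv(path, index=False)
        table = read_slide_table(path)
        out = summarize_per_case(table, "intrathymic_fat", staining="HE")
        df = small_cohort.slides
        for cid in table.case_ids:
            vals = df[(df.case_id == cid) & (df.staining == "HE")]["intrathymic_fat"].dropna()
            assert out.loc[cid, "mean"] == pytest.approx(sum(vals) / len(vals))
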