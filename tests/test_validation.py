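"""Count reconciliation, record-wise equivalence and statistic comparison."""

import pytest

from claims_omop import SourceGenConfig, generate_source, generate_study, run_pipeline
from claims_omop.etl import EtlConfig
from claims_omop.validation import (
    ValidationReport,
    check_equivalence,
    compare_stats,
    corruption_suite,
    descriptive_stats,
    descriptive_stats_cdm,
    descriptive_stats_source,
    lower_median,
    reconcile_counts,
    validate,
)

from .oracles import oracle_stats


# ---------------------------------------------------------------------------
# medians & stats arithmetic
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "values,expected",
    [
        ([3, 5, 7], 5),
        ([1, 2, 3, 4], 2),  # lower median for even counts
        ([9], 9),
        ([], None),
    ],
)
def test_lower_median_convention(values, expected):
    assert lower_median(values) == expected


def test_percent_female_simple_arithmetic():
    source, _ = generate_source(SourceGenConfig(seed=1, n_patients=0))
    source.patient = source.patient.iloc[0:0]
    import pandas as pd

    source.patient = pd.DataFrame(
        {
            "patient_key": ["P1", "P2", "P3", "P4"],
            "birth_year": [1930, 1935, 1936, 1925],
            "sex_code": ["F", "F", "M", "M"],
            "sei": pd.array([1, 2, 3, 4], dtype="Int64"),
        }
    )
    stats = descriptive_stats_source(source)
    assert stats["percent_female"] == 50.0


def test_length_of_stay_median_from_known_lengths():
    import pandas as pd

    source, _ = generate_source(SourceGenConfig(seed=1, n_patients=0))
    source.patient = pd.DataFrame(
        {"patient_key": ["P1"], "birth_year": [1930], "sex_code": ["F"],
         "sei": pd.array([1], dtype="Int64")}
    )
    source.hospital_stay = pd.DataFrame(
        {
            "stay_key": ["S1", "S2", "S3"],
            "patient_key": ["P1", "P1", "P1"],
            "admission_date": ["2009-01-01", "2009-02-01", "2009-03-01"],
            "discharge_date": ["2009-01-04", "2009-02-06", "2009-03-08"],
        }
    )
    stats = descriptive_stats_source(source)
    assert stats["median_length_of_stay_days"] == 5  # lengths {3, 5, 7}


def test_empty_person_table_gives_undefined_indicators():
    source, _ = generate_source(SourceGenConfig(seed=1, n_patients=0))
    stats = descriptive_stats_source(source)
    assert all(v is None for v in stats.values())


def test_stats_match_straight_line_oracle(study):
    stats = descriptive_stats_source(study["source"])
    oracle = oracle_stats(study["source"])
    for key, expected in oracle.items():
        assert stats[key] == expected, key


def test_source_and_cdm_stats_dispatch_agree(study):
    src_stats = descriptive_stats(study["source"])
    cdm_stats = descriptive_stats(study["result"].cdm)
    comparison = compare_stats(src_stats, cdm_stats)
    assert comparison.passed
    assert src_stats == cdm_stats


# ---------------------------------------------------------------------------
# count reconciliation
# ---------------------------------------------------------------------------

def test_clean_run_reconciles_with_dedup_allowance(study):
    rec = reconcile_counts(study["source"], study["result"].cdm, study["result"].etl_report)
    assert rec.passed
    by_pair = {e.pair: e for e in rec.entries}
    assert by_pair["person<-patient"].duplicates_removed == 0
    visits = by_pair["visit_occurrence<-hospital_stay"]
    assert visits.expected_cdm_count == visits.source_count - visits.duplicates_removed


def test_hand_deleted_visit_row_fails_with_delta_one(study):
    cdm = study["result"].cdm.copy()
    cdm.tables["visit_occurrence"] = cdm["visit_occurrence"].iloc[:-1]
    rec = reconcile_counts(study["source"], cdm, study["result"].etl_report)
    assert not rec.passed
    entry = next(e for e in rec.entries if e.pair == "visit_occurrence<-hospital_stay")
    assert entry.expected_cdm_count - entry.cdm_count == 1


# ---------------------------------------------------------------------------
# record-wise equivalence
# ---------------------------------------------------------------------------

def test_untouched_pipeline_output_has_zero_diffs(study):
    assert check_equivalence(study["source"], study["result"].cdm) == []


def test_flipped_gender_yields_exactly_one_diff_naming_the_field(study):
    cdm = study["result"].cdm.copy()
    person = cdm["person"].copy()
    original = person.loc[0, "gender_source_value"]
    person.loc[0, "gender_source_value"] = "M" if original == "F" else "F"
    cdm.tables["person"] = person
    diffs = check_equivalence(study["source"], cdm)
    assert len(diffs) == 1
    assert diffs[0].fld == "sex_code"
    assert diffs[0].source_row_id == person.loc[0, "person_source_value"]


def test_equivalence_holds_across_seeds():
    for seed in range(3):
        config = SourceGenConfig(seed=seed, n_patients=60,
                                 mean_prescriptions_per_person=6.0)
        source, store, truth = generate_study(seed, source_config=config)
        result = run_pipeline(source, store, hints=truth.hints)
        assert check_equivalence(source, result.cdm) == []


# ---------------------------------------------------------------------------
# aggregation, serialization, sensitivity
# ---------------------------------------------------------------------------

def test_clean_run_passes_overall(study):
    report = validate(study["source"], study["result"].cdm, study["result"].etl_report)
    assert report.passed
    assert report.failed_components == []


def test_report_json_round_trip(tmp_path, study):
    report = validate(study["source"], study["result"].cdm, study["result"].etl_report)
    path = tmp_path / "validation.json"
    report.to_json(path)
    back = ValidationReport.from_json(path)
    assert back.to_dict() == report.to_dict()
    assert back.passed == report.passed


def test_every_scripted_corruption_fails_and_names_a_component(study):
    source, result = study["source"], study["result"]
    for label, corrupted in corruption_suite(result.cdm):
        report = validate(source, corrupted, result.etl_report)
        assert not report.passed, label
        assert report.failed_components, label


def test_source_value_corruptions_flip_exactly_the_equivalence_check(study):
    """Corruptions confined to source-value fields leave counts and
    statistics untouched and trip only record equivalence."""
    source, result = study["source"], study["result"]
    only_equivalence = {
        "flip_person_gender_source",
        "alter_drug_source_value",
        "alter_condition_source_value",
    }
    for label, corrupted in corruption_suite(result.cdm):
        if label not in only_equivalence:
            continue
        report = validate(source, corrupted, result.etl_report)
        assert report.failed_components == ["record_equivalence"], label


def test_stats_equal_on_both_sides_for_clean_run(study):
    report = validate(study["source"], study["result"].cdm, study["result"].etl_report)
    assert report.stats.passed
    assert report.stats.source["percent_female"] == report.stats.cdm["percent_female"]
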