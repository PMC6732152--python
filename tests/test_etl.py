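"""ETL builders, deduplication and orchestration."""

import pandas as pd
import pandas.testing as pdt
import pytest
from hypothesis import given, settings, strategies as st

from claims_omop import EtlConfig, EtlError, SourceGenConfig, generate_study, run_pipeline
from claims_omop.etl import (
    build_drug_exposures,
    build_observation_periods,
    build_person,
    build_providers,
    build_sei_observations,
    build_visits,
    deduplicate,
    run_etl,
)
from claims_omop.source_model import SOURCE_TABLES
from claims_omop.synthetic_data import generate_source
from claims_omop.vocabulary import MappingAssessment

from .oracles import oracle_duplicates

CFG = EtlConfig()


def _patients(rows):
    return pd.DataFrame(rows, columns=SOURCE_TABLES["patient"]).astype(
        {"birth_year": "int64", "sei": "Int64"}
    )


# ---------------------------------------------------------------------------
# person / observation period
# ---------------------------------------------------------------------------

def test_person_without_death_row_has_no_death_datetime():
    patients = _patients([("P1", 1936, "F", 3)])
    deaths = pd.DataFrame(columns=SOURCE_TABLES["death"])
    person = build_person(patients, deaths, CFG)
    assert person.loc[0, "death_datetime"] == ""


def test_person_with_death_row_carries_the_date():
    patients = _patients([("P1", 1936, "F", 3)])
    deaths = pd.DataFrame([("P1", "2010-06-01")], columns=SOURCE_TABLES["death"])
    person = build_person(patients, deaths, CFG)
    assert person.loc[0, "death_datetime"] == "2010-06-01 00:00:00"


def test_sex_outside_map_gets_gender_concept_zero_and_keeps_source():
    patients = _patients([("P1", 1936, "X", None)])
    person = build_person(patients, pd.DataFrame(columns=SOURCE_TABLES["death"]), CFG)
    assert int(person.loc[0, "gender_concept_id"]) == 0
    assert person.loc[0, "gender_source_value"] == "X"
    assert int(person.loc[0, "race_concept_id"]) == 0
    assert int(person.loc[0, "ethnicity_concept_id"]) == 0


def test_duplicate_patient_key_is_fatal():
    patients = _patients([("P1", 1936, "F", 3), ("P1", 1930, "M", 1)])
    with pytest.raises(EtlError, match="duplicate"):
        build_person(patients, pd.DataFrame(columns=SOURCE_TABLES["death"]), CFG)


def test_observation_period_spans_study_period_for_every_person():
    patients = _patients([("P1", 1936, "F", 3), ("P2", 1930, "M", 1)])
    person = build_person(patients, pd.DataFrame(columns=SOURCE_TABLES["death"]), CFG)
    periods = build_observation_periods(person, CFG)
    assert len(periods) == len(person)
    assert set(periods["observation_period_start_date"]) == {"2008-01-01"}
    assert set(periods["observation_period_end_date"]) == {"2011-12-31"}


# ---------------------------------------------------------------------------
# providers
# ---------------------------------------------------------------------------

def _rx(rows):
    return pd.DataFrame(rows, columns=SOURCE_TABLES["prescription"])


def test_one_provider_per_distinct_specialty():
    rx = _rx([
        ("P1", "2009-01-01", "100", "A01AA01", "cardiology"),
        ("P1", "2009-01-02", "101", "A01AA01", "neurology"),
        ("P2", "2009-01-03", "100", "A01AA01", "cardiology"),
    ])
    providers, provider_map = build_providers(rx, {}, CFG)
    assert len(providers) == 2
    assert sorted(provider_map) == ["cardiology", "neurology"]


def test_unmatched_group_gets_concept_zero():
    rx = _rx([("P1", "2009-01-01", "100", "A01AA01", "other facility")])
    assessments = {("PROF-GROUP", "other facility"): MappingAssessment(
        "other facility", "PROF-GROUP", "S3")}
    providers, _ = build_providers(rx, assessments, CFG)
    assert int(providers.loc[0, "specialty_concept_id"]) == 0
    assert providers.loc[0, "specialty_source_value"] == "other facility"


def test_no_prescriptions_no_providers():
    providers, provider_map = build_providers(_rx([]), {}, CFG)
    assert len(providers) == 0 and provider_map == {}


# ---------------------------------------------------------------------------
# deduplicate
# ---------------------------------------------------------------------------

def _stays(rows):
    return pd.DataFrame(rows, columns=SOURCE_TABLES["hospital_stay"])


def test_byte_identical_rows_deduplicate_to_one():
    df = _stays([("S1", "P1", "2009-01-01", "2009-01-06")] * 2)
    kept, removed, log = deduplicate(df, row_key="stay_key")
    assert (len(kept), removed, len(log)) == (1, 1, 1)


def test_all_distinct_input_removes_nothing():
    df = _stays([
        ("S1", "P1", "2009-01-01", "2009-01-06"),
        ("S2", "P1", "2009-02-01", "2009-02-06"),
    ])
    kept, removed, _ = deduplicate(df, row_key="stay_key")
    assert removed == 0
    pdt.assert_frame_equal(kept, df)


def test_dedup_is_idempotent_and_matches_grouping_oracle():
    for seed in range(5):
        config = SourceGenConfig(seed=seed, n_patients=60, stay_duplicate_rate=0.15,
                                 mean_prescriptions_per_person=2.0)
        ds, truth = generate_source(config)
        stays = ds.hospital_stay
        kept, removed, _ = deduplicate(stays, row_key="stay_key")
        tuples = [tuple(r) for r in stays.drop(columns="stay_key").itertuples(index=False)]
        assert removed == oracle_duplicates(tuples) == len(truth.duplicate_stay_keys)
        again, removed2, _ = deduplicate(kept, row_key="stay_key")
        assert removed2 == 0
        pdt.assert_frame_equal(again, kept)
        # kept + removed partitions the input
        assert len(kept) + removed == len(stays)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(st.sampled_from("AB"), st.integers(0, 3), st.integers(0, 1)),
        max_size=30,
    )
)
def test_dedup_matches_counter_oracle_on_arbitrary_frames(rows):
    df = pd.DataFrame(rows, columns=["a", "b", "c"])
    kept, removed, log = deduplicate(df)
    assert removed == oracle_duplicates(rows)
    assert len(kept) + len(log) == len(df)
    assert not kept.duplicated().any()


# ---------------------------------------------------------------------------
# visits / drugs / events / SEI
# ---------------------------------------------------------------------------

def test_visit_dates_equal_source_dates():
    stays = _stays([("S1", "P1", "2008-01-01", "2008-01-06")])
    visits = build_visits(stays, {"P1": 1}, CFG)
    assert visits.loc[0, "visit_start_date"] == "2008-01-01"
    assert visits.loc[0, "visit_end_date"] == "2008-01-06"
    assert visits.loc[0, "visit_source_value"] == "S1"
    assert int(visits.loc[0, "visit_concept_id"]) == CFG.inpatient_visit_concept_id


def test_visit_for_unknown_person_is_fatal():
    stays = _stays([("S1", "P9", "2008-01-01", "2008-01-06")])
    with pytest.raises(EtlError, match="P9"):
        build_visits(stays, {"P1": 1}, CFG)


def test_drug_exposure_end_date_equals_start_and_prn_kept():
    rx = _rx([("P1", "2009-03-04", "1234567", "A01AA01", "cardiology")])
    assessments = {("ATC-LOCAL", "A01AA01"): MappingAssessment(
        "A01AA01", "ATC-LOCAL", "S1", standard_concept_id=10, evidence="verbatim")}
    drugs = build_drug_exposures(rx, assessments, {"cardiology": 1}, CFG,
                                 person_map={"P1": 1})
    row = drugs.iloc[0]
    assert row["drug_exposure_end_date"] == row["drug_exposure_start_date"] == "2009-03-04"
    assert row["drug_source_value"] == "1234567"
    assert int(row["drug_concept_id"]) == 10
    assert int(row["provider_id"]) == 1


def test_unmapped_atc_gets_drug_concept_zero():
    rx = _rx([("P1", "2009-03-04", "1234567", "Z99ZZ99", "cardiology")])
    drugs = build_drug_exposures(rx, {}, {"cardiology": 1}, CFG, person_map={"P1": 1})
    assert int(drugs.loc[0, "drug_concept_id"]) == 0


def test_sei_observation_rows_only_for_patients_with_sei():
    patients = _patients([("P1", 1936, "F", 4), ("P2", 1930, "M", None)])
    obs = build_sei_observations(patients, {"P1": 1, "P2": 2}, CFG)
    assert len(obs) == 1
    assert int(obs.loc[0, "observation_concept_id"]) == 0
    assert float(obs.loc[0, "value_as_number"]) == 4.0
    assert obs.loc[0, "observation_source_value"] == "SEI"


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def test_empty_source_gives_empty_cdm_and_zero_counts(study):
    config = SourceGenConfig(seed=0, n_patients=0)
    source, _ = generate_source(config)
    cdm, report = run_etl(source, study["store"], {}, CFG)
    for name, n in report.output_rows.items():
        assert n == 0, name
    assert report.stay_duplicates_removed == 0
    assert report.diagnosis_duplicates_removed == 0


def test_no_duplicate_fixture_preserves_every_count():
    config = SourceGenConfig(seed=11, n_patients=50, stay_duplicate_rate=0.0,
                             diagnosis_duplicate_rate=0.0,
                             mean_prescriptions_per_person=4.0)
    source, store, truth = generate_study(11, source_config=config)
    result = run_pipeline(source, store, hints=truth.hints)
    rpt = result.etl_report
    assert rpt.stay_duplicates_removed == 0
    assert rpt.output_rows["person"] == len(source.patient)
    assert rpt.output_rows["drug_exposure"] == len(source.prescription)
    assert rpt.output_rows["visit_occurrence"] == len(source.hospital_stay)


def test_conservation_and_routing_partition(study):
    """persons = distinct patients; drugs = prescriptions; visits + removed
    = stays; events + removed = diagnoses; event tables partition the kept
    diagnoses."""
    source, result = study["source"], study["result"]
    rpt, cdm = result.etl_report, result.cdm
    assert rpt.output_rows["person"] == source.patient["patient_key"].nunique()
    assert rpt.output_rows["drug_exposure"] == len(source.prescription)
    assert rpt.output_rows["visit_occurrence"] + rpt.stay_duplicates_removed == len(
        source.hospital_stay
    )
    n_sei = int((cdm["observation"]["observation_source_value"] == "SEI").sum())
    n_events = (
        len(cdm["condition_occurrence"]) + len(cdm["procedure_occurrence"])
        + len(cdm["measurement"]) + (len(cdm["observation"]) - n_sei)
    )
    assert n_events + rpt.diagnosis_duplicates_removed == len(source.diagnosis)


def test_event_date_prefers_diag_date_then_admission(study):
    """Dated diagnoses keep their date; undated stay-linked diagnoses
    inherit the stay's admission date; routing and linkage are preserved."""
    from claims_omop.etl import build_clinical_events

    store = study["result"].store
    assessments = study["result"].summary.assessments
    icd = next(
        code for (vocab, code), a in assessments.items()
        if vocab == "ICD10-BMSG" and a.state == "S1"
        and store.get(a.standard_concept_id).domain_id == "Condition"
    )
    diags = pd.DataFrame(
        [
            ("D1", "P1", icd, "S1", ""),             # undated, stay-linked
            ("D2", "P1", icd, "", "2009-07-07"),     # dated, ambulatory
        ],
        columns=SOURCE_TABLES["diagnosis"],
    )
    events = build_clinical_events(
        diags, assessments, store, visit_map={"S1": 4},
        admission_map={"S1": "2009-02-02"}, person_map={"P1": 1}, config=CFG,
    )
    cond = events["condition_occurrence"]
    assert cond["condition_start_date"].tolist() == ["2009-02-02", "2009-07-07"]
    assert cond["visit_occurrence_id"].tolist()[0] == 4
    assert pd.isna(cond["visit_occurrence_id"].tolist()[1])
    # the generator exercises the fallback in realistic data too
    src = study["source"].diagnosis
    assert ((src["diag_date"] == "") & (src["stay_ref"] != "")).any()


def test_run_etl_is_deterministic(study):
    source, store, truth = study["source"], study["store"], study["truth"]
    r1 = run_pipeline(source, store, hints=truth.hints)
    r2 = run_pipeline(source, store, hints=truth.hints)
    for name in r1.cdm.tables:
        pdt.assert_frame_equal(r1.cdm[name], r2.cdm[name])
    assert r1.etl_report.to_dict() == r2.etl_report.to_dict()
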