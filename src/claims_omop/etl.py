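"""Extract-Transform-Load: claims source tables -> OMOP CDM v6.0 tables.

The transform mirrors how a claims extract with patient/death/prescription/
hospital-stay/diagnosis tables maps onto the CDM:

* patients and death dates are combined into ``person`` (v6.0 carries the
  death on the person row);
* every person gets exactly one ``observation_period`` spanning the study
  period, because claims extracts carry no per-person enrolment window;
* prescriber specialties become *virtual providers* (one provider per
  distinct professional group — the CDM allows one specialty per provider
  and the source identifies prescribers only by specialty);
* hospital stays become inpatient ``visit_occurrence`` rows after exact-
  duplicate removal;
* prescriptions become ``drug_exposure`` rows one-for-one (the product
  PRN is kept as the source value, the ATC ingredient mapping supplies the
  drug concept, and the unavailable end date is filled with the start
  date);
* diagnoses, after duplicate removal, are routed by the domain of their
  mapped standard concept across ``condition_occurrence`` /
  ``procedure_occurrence`` / ``measurement`` / ``observation``;
* the socio-economic index, having no standard concept, lands in
  ``observation`` with concept id 0 and its numeric value preserved.

Mandatory fields with no source counterpart (race, ethnicity, provider
gender, type concepts) are filled with concept id 0.  All source rows are
staged before transformation, every output row keeps its source identity
in a ``*_source_value`` field, and the whole run is deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import date
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd
import yaml

from .cdm_model import CDM_TABLES, EVENT_TABLES, CdmDataset, column_dtype, route_domain
from .source_model import SourceDataset
from .vocabulary import ConceptStore, MappingAssessment

__all__ = [
    "EtlConfig",
    "EtlError",
    "EtlReport",
    "StagingArea",
    "deduplicate",
    "build_person",
    "build_observation_periods",
    "build_providers",
    "build_visits",
    "build_drug_exposures",
    "build_clinical_events",
    "build_sei_observations",
    "run_etl",
    "SEI_SOURCE_VALUE",
]

#: observation rows carrying the socio-economic index are tagged with this
#: source value so they are distinguishable from diagnosis-derived rows.
SEI_SOURCE_VALUE = "SEI"


class EtlError(RuntimeError):
    """Unrecoverable ETL failure (invalid inputs or broken linkage)."""


@dataclass
class EtlConfig:
    """Deterministic ETL parameters.

    ``study_period`` bounds every observation period; the sex-code map
    translates source sex codes to OMOP gender concepts (anything outside
    the map becomes concept 0 with the source value kept).
    """

    study_start: str = "2008-01-01"
    study_end: str = "2011-12-31"
    default_event_table: str = "condition_occurrence"
    inpatient_visit_concept_id: int = 9201
    gender_map: dict[str, int] = field(default_factory=lambda: {"F": 8532, "M": 8507})
    female_codes: tuple[str, ...] = ("F",)
    dedup_policy: str = "full_row"  # or "business_key"
    event_vocabulary_id: str = "ICD10-BMSG"
    drug_vocabulary_id: str = "ATC-LOCAL"
    provider_vocabulary_id: str = "PROF-GROUP"
    sei_observation_date: Optional[str] = None  # defaults to study_start

    def __post_init__(self):
        date.fromisoformat(self.study_start)
        date.fromisoformat(self.study_end)
        if self.study_start > self.study_end:
            raise EtlError("study_start must not be after study_end")
        if self.default_event_table not in EVENT_TABLES:
            raise EtlError(f"default_event_table {self.default_event_table!r} invalid")
        if self.dedup_policy not in ("full_row", "business_key"):
            raise EtlError(f"unknown dedup_policy {self.dedup_policy!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["female_codes"] = list(self.female_codes)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "EtlConfig":
        d = dict(d)
        if "female_codes" in d:
            d["female_codes"] = tuple(d["female_codes"])
        if "gender_map" in d:
            d["gender_map"] = {k: int(v) for k, v in d["gender_map"].items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EtlConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


@dataclass
class EtlReport:
    """Machine-readable account of one ETL run: every source row is either
    kept (counted in an output table) or removed as a duplicate."""

    input_rows: dict[str, int] = field(default_factory=dict)
    output_rows: dict[str, int] = field(default_factory=dict)
    stay_duplicates_removed: int = 0
    diagnosis_duplicates_removed: int = 0
    removed_stay_keys: list[str] = field(default_factory=list)
    removed_diag_keys: list[str] = field(default_factory=list)
    unmapped: dict[str, int] = field(default_factory=dict)
    defaulted: dict[str, int] = field(default_factory=dict)
    dedup_policy: str = "full_row"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "EtlReport":
        return cls(**dict(d))

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "EtlReport":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class StagingArea:
    """Source rows gathered for transformation, pre- and post-dedup."""

    patients: pd.DataFrame
    deaths: pd.DataFrame
    prescriptions: pd.DataFrame
    stays_raw: pd.DataFrame
    diagnoses_raw: pd.DataFrame
    stays: pd.DataFrame = None  # deduplicated
    diagnoses: pd.DataFrame = None


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _frame(table: str, data: dict[str, list]) -> pd.DataFrame:
    """Build a CDM-typed frame with the table's exact column order."""
    cols = CDM_TABLES[table]
    n = len(next(iter(data.values()))) if data else 0
    out = {}
    for c in cols:
        values = data.get(c, [None] * n)
        dtype = column_dtype(c)
        if dtype in ("Int64", "Float64"):
            out[c] = pd.array(values, dtype=dtype)
        else:
            out[c] = pd.array(["" if v is None else v for v in values], dtype=object)
    return pd.DataFrame(out, columns=cols)


def _dedup_key_columns(df: pd.DataFrame, row_key: str, policy: str) -> list[str]:
    cols = [c for c in df.columns if c != row_key]
    if policy == "business_key":
        # drop free-floating date granularity: stays keep their dates (they ARE
        # the business key); diagnoses drop diag_date
        if "diag_date" in cols:
            cols = [c for c in cols if c != "diag_date"]
    return cols


def deduplicate(
    records: pd.DataFrame,
    key: Optional[list[str]] = None,
    row_key: str = "",
    policy: str = "full_row",
) -> tuple[pd.DataFrame, int, pd.DataFrame]:
    """Remove duplicate staged records, keeping the first occurrence.

    ``key`` is the field tuple defining equality; by default all columns
    except ``row_key`` (exact-duplicate semantics).  Returns the kept rows
    (original order), the removed count and the removal log.  Idempotent.
    """
    if key is None:
        key = _dedup_key_columns(records, row_key, policy)
    dup_mask = records.duplicated(subset=key, keep="first")
    kept = records.loc[~dup_mask].reset_index(drop=True)
    removed = records.loc[dup_mask].reset_index(drop=True)
    return kept, int(dup_mask.sum()), removed


# ---------------------------------------------------------------------------
# table builders
# ---------------------------------------------------------------------------

def build_person(
    patients: pd.DataFrame, deaths: pd.DataFrame, config: EtlConfig
) -> pd.DataFrame:
    """One person per source patient, death date merged on, ids sequential
    in source row order."""
    if patients["patient_key"].duplicated().any():
        raise EtlError("duplicate patient_key in source patient table")
    death_map = dict(zip(deaths["patient_key"], deaths["death_date"]))
    n = len(patients)
    sex = patients["sex_code"].tolist()
    return _frame(
        "person",
        {
            "person_id": list(range(1, n + 1)),
            "gender_concept_id": [config.gender_map.get(s, 0) for s in sex],
            "year_of_birth": patients["birth_year"].tolist(),
            "birth_datetime": [None] * n,
            "death_datetime": [
                f"{death_map[k]} 00:00:00" if k in death_map else None
                for k in patients["patient_key"]
            ],
            "race_concept_id": [0] * n,
            "ethnicity_concept_id": [0] * n,
            "person_source_value": patients["patient_key"].tolist(),
            "gender_source_value": sex,
            "gender_source_concept_id": [0] * n,
        },
    )


def build_observation_periods(person: pd.DataFrame, config: EtlConfig) -> pd.DataFrame:
    """Exactly one period per person, spanning the configured study period
    regardless of the person's event dates (no enrolment data exists)."""
    n = len(person)
    return _frame(
        "observation_period",
        {
            "observation_period_id": list(range(1, n + 1)),
            "person_id": person["person_id"].tolist(),
            "observation_period_start_date": [config.study_start] * n,
            "observation_period_end_date": [config.study_end] * n,
            "period_type_concept_id": [0] * n,
        },
    )


def build_providers(
    prescriptions: pd.DataFrame,
    assessments: Mapping[tuple[str, str], MappingAssessment],
    config: EtlConfig = EtlConfig(),
    store: Optional[ConceptStore] = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """One virtual provider per distinct professional group, ids in sorted
    specialty order.  Unmatched (S3) groups get specialty concept 0."""
    groups = sorted(set(prescriptions["professional_group"]) - {""})
    rows: dict[str, list] = {c: [] for c in ("provider_id", "specialty_concept_id",
                                             "gender_concept_id", "provider_source_value",
                                             "specialty_source_value",
                                             "specialty_source_concept_id")}
    provider_map: dict[str, int] = {}
    for i, group in enumerate(groups, start=1):
        a = assessments.get((config.provider_vocabulary_id, group))
        concept = a.standard_concept_id if a is not None and a.state != "S3" else 0
        src_cid = 0
        if store is not None:
            local = store.lookup(config.provider_vocabulary_id, group)
            if local is not None:
                src_cid = local.concept_id
        rows["provider_id"].append(i)
        rows["specialty_concept_id"].append(concept)
        rows["gender_concept_id"].append(0)  # provider gender not in source
        rows["provider_source_value"].append(group)
        rows["specialty_source_value"].append(group)
        rows["specialty_source_concept_id"].append(src_cid)
        provider_map[group] = i
    return _frame("provider", rows), provider_map


def build_visits(
    stays: pd.DataFrame, person_map: Mapping[str, int], config: EtlConfig
) -> pd.DataFrame:
    """One inpatient visit per deduplicated stay; stay_key preserved in
    visit_source_value."""
    unknown = sorted(set(stays["patient_key"]) - set(person_map))
    if unknown:
        raise EtlError(f"hospital stay for unknown patient(s): {unknown[:10]}")
    n = len(stays)
    return _frame(
        "visit_occurrence",
        {
            "visit_occurrence_id": list(range(1, n + 1)),
            "person_id": [person_map[k] for k in stays["patient_key"]],
            "visit_concept_id": [config.inpatient_visit_concept_id] * n,
            "visit_start_date": stays["admission_date"].tolist(),
            "visit_end_date": stays["discharge_date"].tolist(),
            "visit_type_concept_id": [0] * n,
            "visit_source_value": stays["stay_key"].tolist(),
            "visit_source_concept_id": [0] * n,
        },
    )


def build_drug_exposures(
    prescriptions: pd.DataFrame,
    assessments: Mapping[tuple[str, str], MappingAssessment],
    provider_map: Mapping[str, int],
    config: EtlConfig = EtlConfig(),
    person_map: Optional[Mapping[str, int]] = None,
    store: Optional[ConceptStore] = None,
) -> pd.DataFrame:
    """One drug exposure per prescription (no dedup applies to drugs).

    drug_concept_id comes from the ATC ingredient's standard concept (0 when
    unmapped); the end date, absent in claims, is set to the start date;
    drug_source_value carries the product PRN and drug_source_concept_id the
    imported local ATC concept, so the ATC code stays recoverable.
    """
    person_map = person_map or {}
    unknown = sorted(set(prescriptions["patient_key"]) - set(person_map))
    if unknown:
        raise EtlError(f"prescription for unknown patient(s): {unknown[:10]}")

    atc_codes = prescriptions["atc_code"]
    std_map: dict[str, int] = {}
    src_map: dict[str, int] = {}
    for code in sorted(set(atc_codes)):
        a = assessments.get((config.drug_vocabulary_id, code))
        std_map[code] = (
            a.standard_concept_id if a is not None and a.state != "S3" else 0
        )
        src_map[code] = 0
        if store is not None:
            local = store.lookup(config.drug_vocabulary_id, code)
            if local is not None:
                src_map[code] = local.concept_id

    n = len(prescriptions)
    return _frame(
        "drug_exposure",
        {
            "drug_exposure_id": list(range(1, n + 1)),
            "person_id": [person_map[k] for k in prescriptions["patient_key"]],
            "drug_concept_id": [std_map[c] for c in atc_codes],
            "drug_exposure_start_date": prescriptions["prescription_date"].tolist(),
            "drug_exposure_end_date": prescriptions["prescription_date"].tolist(),
            "drug_type_concept_id": [0] * n,
            "provider_id": [provider_map.get(g) for g in prescriptions["professional_group"]],
            "drug_source_value": prescriptions["prn"].tolist(),
            "drug_source_concept_id": [src_map[c] for c in atc_codes],
        },
    )


def build_clinical_events(
    diagnoses: pd.DataFrame,
    assessments: Mapping[tuple[str, str], MappingAssessment],
    store: ConceptStore,
    visit_map: Mapping[str, int],
    admission_map: Mapping[str, str],
    person_map: Mapping[str, int],
    config: EtlConfig = EtlConfig(),
) -> dict[str, pd.DataFrame]:
    """Route deduplicated diagnoses across the four clinical-event tables.

    The event date is the diagnosis's own date when present, else the
    linked stay's admission date.  The ICD code is kept in the table's
    source-value field; the source-concept field points at the imported
    local concept when one exists.
    """
    unknown = sorted(set(diagnoses["patient_key"]) - set(person_map))
    if unknown:
        raise EtlError(f"diagnosis for unknown patient(s): {unknown[:10]}")

    table_map: dict[str, str] = {}
    std_map: dict[str, int] = {}
    src_map: dict[str, int] = {}
    for code in sorted(set(diagnoses["icd10_code"])):
        a = assessments.get((config.event_vocabulary_id, code))
        std = a.standard_concept_id if a is not None and a.state != "S3" else 0
        std_map[code] = std
        concept = store.get(std) if std else None
        table_map[code] = route_domain(concept, config.default_event_table)
        local = store.lookup(config.event_vocabulary_id, code)
        src_map[code] = local.concept_id if local is not None else 0

    buckets: dict[str, dict[str, list]] = {t: {k: [] for k in ("person_id", "concept_id",
                                                               "event_date", "visit_id",
                                                               "source_value", "source_cid")}
                                           for t in EVENT_TABLES}
    for row in diagnoses.itertuples(index=False):
        if row.diag_date != "":
            event_date = row.diag_date
        elif row.stay_ref != "":
            try:
                event_date = admission_map[row.stay_ref]
            except KeyError:
                raise EtlError(f"diagnosis {row.diag_key}: dangling stay_ref {row.stay_ref!r}") from None
        else:
            raise EtlError(f"diagnosis {row.diag_key}: no diagnosis date and no stay")
        if row.stay_ref != "" and row.stay_ref not in visit_map:
            raise EtlError(f"diagnosis {row.diag_key}: dangling stay_ref {row.stay_ref!r}")
        b = buckets[table_map[row.icd10_code]]
        b["person_id"].append(person_map[row.patient_key])
        b["concept_id"].append(std_map[row.icd10_code])
        b["event_date"].append(event_date)
        b["visit_id"].append(visit_map.get(row.stay_ref) if row.stay_ref != "" else None)
        b["source_value"].append(row.icd10_code)
        b["source_cid"].append(src_map[row.icd10_code])

    out: dict[str, pd.DataFrame] = {}
    spec = {
        "condition_occurrence": ("condition_occurrence_id", "condition_concept_id",
                                 "condition_start_date", "condition_source_value",
                                 "condition_source_concept_id", "condition_type_concept_id"),
        "procedure_occurrence": ("procedure_occurrence_id", "procedure_concept_id",
                                 "procedure_date", "procedure_source_value",
                                 "procedure_source_concept_id", "procedure_type_concept_id"),
        "measurement": ("measurement_id", "measurement_concept_id", "measurement_date",
                        "measurement_source_value", "measurement_source_concept_id",
                        "measurement_type_concept_id"),
        "observation": ("observation_id", "observation_concept_id", "observation_date",
                        "observation_source_value", "observation_source_concept_id",
                        "observation_type_concept_id"),
    }
    for table, b in buckets.items():
        id_col, concept_col, date_col, sv_col, scid_col, type_col = spec[table]
        n = len(b["person_id"])
        out[table] = _frame(
            table,
            {
                id_col: list(range(1, n + 1)),
                "person_id": b["person_id"],
                concept_col: b["concept_id"],
                date_col: b["event_date"],
                type_col: [0] * n,
                "visit_occurrence_id": b["visit_id"],
                sv_col: b["source_value"],
                scid_col: b["source_cid"],
            },
        )
    return out


def build_sei_observations(
    patients: pd.DataFrame,
    person_map: Mapping[str, int],
    config: EtlConfig = EtlConfig(),
    id_start: int = 1,
) -> pd.DataFrame:
    """One observation per patient with a socio-economic index.

    The SEI has no standard concept (state S3), so the concept id is 0 and
    the numeric value is preserved; rows are tagged with source value
    ``"SEI"``.  The observation date defaults to the study start (the index
    is a per-person attribute without a date in the source).
    """
    with_sei = patients.loc[patients["sei"].notna()]
    n = len(with_sei)
    obs_date = config.sei_observation_date or config.study_start
    return _frame(
        "observation",
        {
            "observation_id": list(range(id_start, id_start + n)),
            "person_id": [person_map[k] for k in with_sei["patient_key"]],
            "observation_concept_id": [0] * n,
            "observation_date": [obs_date] * n,
            "observation_type_concept_id": [0] * n,
            "value_as_number": [float(v) for v in with_sei["sei"]],
            "observation_source_value": [SEI_SOURCE_VALUE] * n,
            "observation_source_concept_id": [0] * n,
        },
    )


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def stage(source: SourceDataset) -> StagingArea:
    """Gather every source row into the temporary staging structure."""
    return StagingArea(
        patients=source.patient.copy(),
        deaths=source.death.copy(),
        prescriptions=source.prescription.copy(),
        stays_raw=source.hospital_stay.copy(),
        diagnoses_raw=source.diagnosis.copy(),
    )


def run_etl(
    source: SourceDataset,
    store: ConceptStore,
    assessments: Mapping[tuple[str, str], MappingAssessment],
    config: EtlConfig = EtlConfig(),
) -> tuple[CdmDataset, EtlReport]:
    """Full deterministic transform: stage, dedup, build every CDM table.

    ``store`` must already contain the imported local concepts (see
    :func:`claims_omop.vocabulary.import_local_vocabulary`); ``assessments``
    maps (local_vocabulary_id, code) to its classification.  Returns the
    populated dataset and a report accounting for every source row.
    """
    source.validate()
    staging = stage(source)

    staging.stays, n_stay_dup, stay_log = deduplicate(
        staging.stays_raw, row_key="stay_key", policy=config.dedup_policy
    )
    staging.diagnoses, n_diag_dup, diag_log = deduplicate(
        staging.diagnoses_raw, row_key="diag_key", policy=config.dedup_policy
    )

    person = build_person(staging.patients, staging.deaths, config)
    person_map = dict(zip(person["person_source_value"], person["person_id"].astype(int)))
    periods = build_observation_periods(person, config)
    providers, provider_map = build_providers(
        staging.prescriptions, assessments, config, store=store
    )
    visits = build_visits(staging.stays, person_map, config)
    visit_map = dict(
        zip(visits["visit_source_value"], visits["visit_occurrence_id"].astype(int))
    )
    admission_map = dict(
        zip(staging.stays["stay_key"], staging.stays["admission_date"])
    )
    drugs = build_drug_exposures(
        staging.prescriptions, assessments, provider_map, config,
        person_map=person_map, store=store,
    )
    events = build_clinical_events(
        staging.diagnoses, assessments, store, visit_map, admission_map,
        person_map, config,
    )
    sei = build_sei_observations(
        staging.patients, person_map, config,
        id_start=len(events["observation"]) + 1,
    )
    observation = pd.concat([events["observation"], sei], ignore_index=True)

    cdm = CdmDataset.empty()
    cdm["person"] = person
    cdm["observation_period"] = periods
    cdm["provider"] = providers
    cdm["visit_occurrence"] = visits
    cdm["drug_exposure"] = drugs
    cdm["condition_occurrence"] = events["condition_occurrence"]
    cdm["procedure_occurrence"] = events["procedure_occurrence"]
    cdm["measurement"] = events["measurement"]
    cdm["observation"] = observation

    # vocabulary tables travel with the data (local imports included)
    concept = store.concepts.copy()
    concept["concept_id"] = concept["concept_id"].astype("Int64")
    rel = store.relationships.copy()
    rel["concept_id_1"] = rel["concept_id_1"].astype("Int64")
    rel["concept_id_2"] = rel["concept_id_2"].astype("Int64")
    vocab = store.vocabularies.copy()
    vocab["vocabulary_concept_id"] = (
        pd.to_numeric(vocab["vocabulary_concept_id"]).astype("Int64")
    )
    cdm["concept"] = concept[CDM_TABLES["concept"]]
    cdm["concept_relationship"] = rel[CDM_TABLES["concept_relationship"]]
    cdm["vocabulary"] = vocab[CDM_TABLES["vocabulary"]]

    cdm.validate()

    report = EtlReport(
        input_rows={name: len(df) for name, df in source.tables.items()},
        output_rows={
            name: len(cdm[name])
            for name in ("person", "observation_period", "provider",
                         "visit_occurrence", "drug_exposure", "condition_occurrence",
                         "procedure_occurrence", "measurement", "observation")
        },
        stay_duplicates_removed=n_stay_dup,
        diagnosis_duplicates_removed=n_diag_dup,
        removed_stay_keys=stay_log["stay_key"].tolist(),
        removed_diag_keys=diag_log["diag_key"].tolist(),
        unmapped={
            "drug_exposures_concept_0": int((drugs["drug_concept_id"] == 0).sum()),
            "events_concept_0": sum(
                int((events[t][c] == 0).sum())
                for t, c in (
                    ("condition_occurrence", "condition_concept_id"),
                    ("procedure_occurrence", "procedure_concept_id"),
                    ("measurement", "measurement_concept_id"),
                    ("observation", "observation_concept_id"),
                )
            ),
            "providers_concept_0": int((providers["specialty_concept_id"] == 0).sum()),
            "persons_gender_0": int((person["gender_concept_id"] == 0).sum()),
        },
        defaulted={
            "race_concept_0": len(person),
            "ethnicity_concept_0": len(person),
            "drug_end_date_filled": len(drugs),
            "sei_observations": len(sei),
        },
        dedup_policy=config.dedup_policy,
    )
    return cdm, report
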