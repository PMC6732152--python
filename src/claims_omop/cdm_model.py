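"""OMOP CDM v6.0 target model: schema, domain routing, persistence.

Only the subset of CDM tables a claims extract populates is filled
(person, observation_period, provider, visit_occurrence, drug_exposure,
the four clinical-event tables and the three vocabulary tables); the
remaining data tables of the model are still emitted, empty, so the sink
is a structurally complete CDM instance.  CDM v6.0 semantics apply: death
is carried on ``person.death_datetime``, there is no separate death table.

Persistence is one CSV per table with OMOP's exact lower-case column
names; an equivalent SQLite sink and a DDL rendering are provided for
reference.
"""

from __future__ import annotations

import shutil
import sqlite3
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "CdmDataset",
    "CdmIntegrityError",
    "CDM_TABLES",
    "DOMAIN_TABLE",
    "EVENT_TABLES",
    "route_domain",
    "write_cdm",
    "read_cdm",
]


class CdmIntegrityError(ValueError):
    """A CDM dataset violates schema or referential integrity."""


#: table -> ordered column list (CDM v6.0 subset relevant to claims data)
CDM_TABLES: dict[str, list[str]] = {
    "person": [
        "person_id", "gender_concept_id", "year_of_birth", "month_of_birth",
        "day_of_birth", "birth_datetime", "death_datetime", "race_concept_id",
        "ethnicity_concept_id", "person_source_value", "gender_source_value",
        "gender_source_concept_id",
    ],
    "observation_period": [
        "observation_period_id", "person_id", "observation_period_start_date",
        "observation_period_end_date", "period_type_concept_id",
    ],
    "provider": [
        "provider_id", "provider_name", "specialty_concept_id", "year_of_birth",
        "gender_concept_id", "provider_source_value", "specialty_source_value",
        "specialty_source_concept_id", "gender_source_value",
    ],
    "visit_occurrence": [
        "visit_occurrence_id", "person_id", "visit_concept_id", "visit_start_date",
        "visit_end_date", "visit_type_concept_id", "provider_id",
        "visit_source_value", "visit_source_concept_id",
    ],
    "drug_exposure": [
        "drug_exposure_id", "person_id", "drug_concept_id",
        "drug_exposure_start_date", "drug_exposure_end_date",
        "drug_type_concept_id", "quantity", "provider_id", "visit_occurrence_id",
        "drug_source_value", "drug_source_concept_id",
    ],
    "condition_occurrence": [
        "condition_occurrence_id", "person_id", "condition_concept_id",
        "condition_start_date", "condition_type_concept_id",
        "visit_occurrence_id", "provider_id", "condition_source_value",
        "condition_source_concept_id",
    ],
    "procedure_occurrence": [
        "procedure_occurrence_id", "person_id", "procedure_concept_id",
        "procedure_date", "procedure_type_concept_id", "visit_occurrence_id",
        "provider_id", "procedure_source_value", "procedure_source_concept_id",
    ],
    "measurement": [
        "measurement_id", "person_id", "measurement_concept_id",
        "measurement_date", "measurement_type_concept_id", "value_as_number",
        "visit_occurrence_id", "provider_id", "measurement_source_value",
        "measurement_source_concept_id",
    ],
    "observation": [
        "observation_id", "person_id", "observation_concept_id",
        "observation_date", "observation_type_concept_id", "value_as_number",
        "value_as_string", "visit_occurrence_id", "provider_id",
        "observation_source_value", "observation_source_concept_id",
    ],
    # vocabulary tables (populated from the concept store incl. local imports)
    "concept": [
        "concept_id", "concept_name", "domain_id", "vocabulary_id",
        "concept_class_id", "standard_concept", "concept_code",
        "valid_start_date", "valid_end_date", "invalid_reason",
    ],
    "concept_relationship": [
        "concept_id_1", "concept_id_2", "relationship_id", "valid_start_date",
        "valid_end_date", "invalid_reason",
    ],
    "vocabulary": [
        "vocabulary_id", "vocabulary_name", "vocabulary_reference",
        "vocabulary_version", "vocabulary_concept_id",
    ],
    # structurally present but unpopulated for a claims source of this shape
    "location": ["location_id", "address_1", "city", "zip", "location_source_value"],
    "care_site": ["care_site_id", "care_site_name", "place_of_service_concept_id",
                  "location_id", "care_site_source_value"],
    "visit_detail": ["visit_detail_id", "person_id", "visit_detail_concept_id",
                     "visit_detail_start_date", "visit_detail_end_date",
                     "visit_occurrence_id"],
    "device_exposure": ["device_exposure_id", "person_id", "device_concept_id",
                        "device_exposure_start_date", "device_type_concept_id",
                        "device_source_value"],
    "specimen": ["specimen_id", "person_id", "specimen_concept_id",
                 "specimen_type_concept_id", "specimen_date", "specimen_source_value"],
    "note": ["note_id", "person_id", "note_date", "note_type_concept_id",
             "note_class_concept_id", "note_text"],
    "note_nlp": ["note_nlp_id", "note_id", "lexical_variant",
                 "note_nlp_concept_id", "nlp_date"],
    "survey_conduct": ["survey_conduct_id", "person_id", "survey_concept_id",
                       "survey_start_date", "survey_end_date"],
    "fact_relationship": ["domain_concept_id_1", "fact_id_1", "domain_concept_id_2",
                          "fact_id_2", "relationship_concept_id"],
    "payer_plan_period": ["payer_plan_period_id", "person_id",
                          "payer_plan_period_start_date",
                          "payer_plan_period_end_date", "payer_concept_id"],
    "cost": ["cost_id", "person_id", "cost_event_id", "cost_concept_id",
             "currency_concept_id", "total_charge"],
    "drug_era": ["drug_era_id", "person_id", "drug_concept_id",
                 "drug_era_start_date", "drug_era_end_date", "drug_exposure_count"],
    "dose_era": ["dose_era_id", "person_id", "drug_concept_id", "unit_concept_id",
                 "dose_value", "dose_era_start_date", "dose_era_end_date"],
    "condition_era": ["condition_era_id", "person_id", "condition_concept_id",
                      "condition_era_start_date", "condition_era_end_date",
                      "condition_occurrence_count"],
}

#: clinical-event tables a routed diagnosis may land in
EVENT_TABLES = ("condition_occurrence", "procedure_occurrence", "measurement", "observation")

DOMAIN_TABLE: dict[str, str] = {
    "Condition": "condition_occurrence",
    "Procedure": "procedure_occurrence",
    "Measurement": "measurement",
    "Observation": "observation",
}

#: *_id columns that are nevertheless strings in OMOP
_STRING_ID_COLUMNS = {"vocabulary_id", "domain_id", "concept_class_id", "relationship_id"}
_FLOAT_COLUMNS = {"value_as_number", "quantity", "total_charge", "dose_value"}
_INT_ALSO = {"year_of_birth", "month_of_birth", "day_of_birth", "fact_id_1", "fact_id_2",
             "concept_id_1", "concept_id_2", "domain_concept_id_1", "domain_concept_id_2",
             "drug_exposure_count", "condition_occurrence_count"}


def column_dtype(column: str) -> str:
    """Logical dtype of a CDM column: 'Int64', 'Float64' or 'string'."""
    if column in _STRING_ID_COLUMNS:
        return "string"
    if column in _FLOAT_COLUMNS:
        return "Float64"
    if column.endswith("_id") or column in _INT_ALSO:
        return "Int64"
    return "string"


def _empty_frame(table: str) -> pd.DataFrame:
    data = {c: pd.Series(dtype=column_dtype(c).lower() if column_dtype(c) == "string"
                         else column_dtype(c))
            for c in CDM_TABLES[table]}
    df = pd.DataFrame(data)
    # plain object strings behave better with "" missing markers
    for c in CDM_TABLES[table]:
        if column_dtype(c) == "string":
            df[c] = df[c].astype(object)
    return df


@dataclass
class CdmDataset:
    """A populated OMOP CDM v6.0 subset held as one DataFrame per table."""

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)

    @classmethod
    def empty(cls) -> "CdmDataset":
        return cls(tables={name: _empty_frame(name) for name in CDM_TABLES})

    def __getitem__(self, table: str) -> pd.DataFrame:
        return self.tables[table]

    def __setitem__(self, table: str, df: pd.DataFrame) -> None:
        if table not in CDM_TABLES:
            raise CdmIntegrityError(f"unknown CDM table {table!r}")
        if list(df.columns) != CDM_TABLES[table]:
            raise CdmIntegrityError(
                f"{table}: columns {list(df.columns)} != {CDM_TABLES[table]}"
            )
        self.tables[table] = df.reset_index(drop=True)

    def copy(self) -> "CdmDataset":
        return CdmDataset(tables={k: v.copy() for k, v in self.tables.items()})

    # -- integrity -----------------------------------------------------------

    def validate(self) -> None:
        """Check schema, primary keys, foreign keys, and that every
        concept-id-valued field is 0 or resolves in the concept table."""
        for name in CDM_TABLES:
            if name not in self.tables:
                raise CdmIntegrityError(f"missing CDM table {name!r}")
            if list(self.tables[name].columns) != CDM_TABLES[name]:
                raise CdmIntegrityError(f"{name}: column mismatch")
        persons = set(self["person"]["person_id"].dropna().astype(int))
        visits = set(self["visit_occurrence"]["visit_occurrence_id"].dropna().astype(int))
        providers = set(self["provider"]["provider_id"].dropna().astype(int))
        concepts = set(self["concept"]["concept_id"].dropna().astype(int)) | {0}

        pk = {"person": "person_id", "observation_period": "observation_period_id",
              "provider": "provider_id", "visit_occurrence": "visit_occurrence_id",
              "drug_exposure": "drug_exposure_id",
              "condition_occurrence": "condition_occurrence_id",
              "procedure_occurrence": "procedure_occurrence_id",
              "measurement": "measurement_id", "observation": "observation_id"}
        for table, col in pk.items():
            s = self[table][col]
            if s.isna().any() or s.duplicated().any():
                raise CdmIntegrityError(f"{table}.{col}: null or duplicate primary key")

        def check_fk(table: str, col: str, valid: set[int]) -> None:
            if col not in self[table].columns:
                return
            vals = self[table][col].dropna().astype(int)
            dangling = sorted(set(vals) - valid)
            if dangling:
                raise CdmIntegrityError(
                    f"{table}.{col}: dangling foreign key(s) {dangling[:10]}"
                )

        for table in ("observation_period", "visit_occurrence", "drug_exposure",
                      *EVENT_TABLES):
            check_fk(table, "person_id", persons)
        for table in ("drug_exposure", *EVENT_TABLES):
            check_fk(table, "visit_occurrence_id", visits)
            check_fk(table, "provider_id", providers)
        check_fk("visit_occurrence", "provider_id", providers)
        for table, cols in CDM_TABLES.items():
            for col in cols:
                if col.endswith("concept_id") and col not in _STRING_ID_COLUMNS:
                    check_fk(table, col, concepts)

    # -- persistence ---------------------------------------------------------

    def write(self, directory: str | Path) -> None:
        """Write one CSV per table.  The write is all-or-nothing: tables are
        staged in a temporary directory and moved into place on success."""
        self.validate()
        directory = Path(directory)
        directory.parent.mkdir(parents=True, exist_ok=True)
        staging = Path(tempfile.mkdtemp(prefix=".cdm-staging-", dir=directory.parent))
        try:
            for name in CDM_TABLES:
                self[name].to_csv(staging / f"{name}.csv", index=False)
            if directory.exists():
                shutil.rmtree(directory)
            staging.rename(directory)
        except Exception:
            shutil.rmtree(staging, ignore_errors=True)
            raise

    @classmethod
    def read(cls, directory: str | Path) -> "CdmDataset":
        directory = Path(directory)
        tables = {}
        for name, cols in CDM_TABLES.items():
            path = directory / f"{name}.csv"
            if not path.exists():
                raise CdmIntegrityError(f"missing CDM table file {path}")
            df = pd.read_csv(path, dtype=str, keep_default_na=False)
            if list(df.columns) != cols:
                raise CdmIntegrityError(f"{path}: column mismatch")
            for c in cols:
                dtype = column_dtype(c)
                if dtype in ("Int64", "Float64"):
                    df[c] = pd.to_numeric(df[c].replace("", None)).astype(dtype)
            tables[name] = df
        return cls(tables=tables)

    def ddl(self, dialect: str = "generic") -> str:
        """SQL DDL text for the emitted schema (reference only)."""
        type_map = {"Int64": "BIGINT", "Float64": "DOUBLE PRECISION", "string": "TEXT"}
        stmts = []
        for name, cols in CDM_TABLES.items():
            body = ",\n".join(
                f"    {c} {type_map[column_dtype(c)]}" for c in cols
            )
            stmts.append(f"CREATE TABLE {name} (\n{body}\n);")
        return "\n\n".join(stmts) + "\n"

    def to_sqlite(self, path: str | Path) -> None:
        """Materialise the dataset into an embedded SQLite database."""
        self.validate()
        path = Path(path)
        if path.exists():
            path.unlink()
        with sqlite3.connect(path) as conn:
            for name in CDM_TABLES:
                self[name].to_sql(name, conn, index=False)


def route_domain(concept, default_table: str = "condition_occurrence") -> str:
    """Route a standard concept to its clinical-event table by domain.

    ``concept`` is a :class:`~claims_omop.vocabulary.Concept` or ``None``
    (the zero concept), which lands in the configured default table.
    Non-event domains (e.g. Drug) are a routing error.
    """
    if default_table not in EVENT_TABLES:
        raise CdmIntegrityError(f"default table {default_table!r} is not an event table")
    if concept is None or concept.concept_id == 0:
        return default_table
    try:
        return DOMAIN_TABLE[concept.domain_id]
    except KeyError:
        raise CdmIntegrityError(
            f"concept {concept.concept_id} has unroutable domain {concept.domain_id!r}"
        ) from None


def write_cdm(ds: CdmDataset, directory: str | Path) -> None:
    """Module-level alias of :meth:`CdmDataset.write`."""
    ds.write(directory)


def read_cdm(directory: str | Path) -> CdmDataset:
    """Module-level alias of :meth:`CdmDataset.read`."""
    return CdmDataset.read(directory)
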