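"""Post-ETL validation: integrity and equivalence to the claims source.

Three independent checks, mirroring how a claims-to-CDM transform is
audited in practice:

1. **Count reconciliation** — for each source/CDM table pair the CDM row
   count must equal the source count minus the duplicates the ETL reports
   having removed ("no records were lost").
2. **Record-wise equivalence** — a source-shaped view is reconstructed
   from the CDM rows alone (through ``*_source_value`` fields, the imported
   local concepts and the virtual-provider table) and compared field by
   field against the deduplicated source.
3. **Descriptive statistics** — percent female, median age at study start,
   median hospitalizations and prescriptions per person (among persons
   having at least one), and median length of stay, computed on both sides
   with the same conventions, must be exactly equal.

Medians use the lower-median convention (for even n the lower of the two
middle values), so every indicator on integer inputs is an integer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .cdm_model import CdmDataset, EVENT_TABLES
from .etl import EtlConfig, EtlReport, SEI_SOURCE_VALUE, deduplicate
from .source_model import SourceDataset

__all__ = [
    "CountEntry",
    "CountReconciliation",
    "RecordDiff",
    "StatsComparison",
    "ValidationReport",
    "reconcile_counts",
    "check_equivalence",
    "descriptive_stats",
    "descriptive_stats_source",
    "descriptive_stats_cdm",
    "compare_stats",
    "validate",
    "lower_median",
    "corruption_suite",
    "STAT_KEYS",
]

STAT_KEYS = (
    "percent_female",
    "median_age",
    "median_hospitalizations_per_person",
    "median_prescriptions_per_person",
    "median_length_of_stay_days",
    # both denominators for the per-person medians are reported
    "median_hospitalizations_including_zero",
    "median_prescriptions_including_zero",
)


def lower_median(values: Sequence) -> Optional[float]:
    """Lower median: element at index (n-1)//2 of the sorted values."""
    vals = sorted(values)
    if not vals:
        return None
    return vals[(len(vals) - 1) // 2]


# ---------------------------------------------------------------------------
# report dataclasses
# ---------------------------------------------------------------------------

@dataclass
class CountEntry:
    pair: str  # e.g. "person<-patient"
    source_count: int
    cdm_count: int
    duplicates_removed: int
    expected_cdm_count: int
    passed: bool


@dataclass
class CountReconciliation:
    entries: list[CountEntry] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(e.passed for e in self.entries)


@dataclass
class RecordDiff:
    pair: str
    source_row_id: str
    fld: str  # field name, or "*row*" for a missing/extra record
    source_value: str
    cdm_value: str


@dataclass
class StatsComparison:
    source: dict[str, Optional[float]] = field(default_factory=dict)
    cdm: dict[str, Optional[float]] = field(default_factory=dict)
    equal: dict[str, bool] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return all(self.equal.values()) if self.equal else False


@dataclass
class ValidationReport:
    counts: CountReconciliation
    diffs: list[RecordDiff]
    stats: StatsComparison

    @property
    def equivalence_passed(self) -> bool:
        return len(self.diffs) == 0

    @property
    def passed(self) -> bool:
        return self.counts.passed and self.equivalence_passed and self.stats.passed

    @property
    def failed_components(self) -> list[str]:
        out = []
        if not self.counts.passed:
            out.append("count_reconciliation")
        if not self.equivalence_passed:
            out.append("record_equivalence")
        if not self.stats.passed:
            out.append("descriptive_statistics")
        return out

    def to_dict(self) -> dict:
        return {
            "counts": asdict(self.counts),
            "diffs": [asdict(d) for d in self.diffs],
            "stats": asdict(self.stats),
            "passed": self.passed,
            "failed_components": self.failed_components,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ValidationReport":
        return cls(
            counts=CountReconciliation(
                entries=[CountEntry(**e) for e in d["counts"]["entries"]]
            ),
            diffs=[RecordDiff(**r) for r in d["diffs"]],
            stats=StatsComparison(**d["stats"]),
        )

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "ValidationReport":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# check 1: count reconciliation
# ---------------------------------------------------------------------------

def _cdm_event_count(cdm: CdmDataset) -> int:
    n = 0
    for table in EVENT_TABLES:
        df = cdm[table]
        if table == "observation":
            n += int((df["observation_source_value"] != SEI_SOURCE_VALUE).sum())
        else:
            n += len(df)
    return n


def reconcile_counts(
    source: SourceDataset, cdm: CdmDataset, etl_report: EtlReport
) -> CountReconciliation:
    """Compare row counts of corresponding table pairs, allowing the dedup
    difference only where the ETL report claims removals."""
    for required in ("person", "drug_exposure", "visit_occurrence", *EVENT_TABLES):
        if required not in cdm.tables:
            raise KeyError(f"CDM table {required!r} missing; cannot reconcile")
    pairs = [
        ("person<-patient", len(source.patient), len(cdm["person"]), 0),
        (
            "drug_exposure<-prescription",
            len(source.prescription),
            len(cdm["drug_exposure"]),
            0,
        ),
        (
            "visit_occurrence<-hospital_stay",
            len(source.hospital_stay),
            len(cdm["visit_occurrence"]),
            etl_report.stay_duplicates_removed,
        ),
        (
            "clinical_events<-diagnosis",
            len(source.diagnosis),
            _cdm_event_count(cdm),
            etl_report.diagnosis_duplicates_removed,
        ),
    ]
    entries = []
    for pair, n_src, n_cdm, removed in pairs:
        expected = n_src - removed
        entries.append(
            CountEntry(
                pair=pair,
                source_count=n_src,
                cdm_count=n_cdm,
                duplicates_removed=removed,
                expected_cdm_count=expected,
                passed=n_cdm == expected,
            )
        )
    return CountReconciliation(entries=entries)


# ---------------------------------------------------------------------------
# check 2: record-wise equivalence
# ---------------------------------------------------------------------------

def _person_key_map(cdm: CdmDataset) -> dict[int, str]:
    p = cdm["person"]
    return dict(zip(p["person_id"].astype(int), p["person_source_value"]))


def _multiset_diffs(
    pair: str,
    src: pd.DataFrame,
    rec: pd.DataFrame,
    cols: list[str],
    id_lookup: Optional[dict[tuple, str]] = None,
) -> list[RecordDiff]:
    """Diff two row multisets on ``cols``; unmatched rows on either side
    become RecordDiff entries."""
    a = src[cols].astype(str).groupby(cols, dropna=False).size().rename("n_src")
    b = rec[cols].astype(str).groupby(cols, dropna=False).size().rename("n_cdm")
    merged = pd.concat([a, b], axis=1).fillna(0).astype(int)
    out: list[RecordDiff] = []
    for key, row in merged[merged["n_src"] != merged["n_cdm"]].iterrows():
        key = key if isinstance(key, tuple) else (key,)
        rid = id_lookup.get(key, "") if id_lookup else ""
        out.append(
            RecordDiff(
                pair=pair,
                source_row_id=rid,
                fld="*row*",
                source_value=f"x{row['n_src']}: " + "|".join(key),
                cdm_value=f"x{row['n_cdm']}: " + "|".join(key),
            )
        )
    return out


def _keyed_diffs(
    pair: str,
    src: pd.DataFrame,
    rec: pd.DataFrame,
    key: str,
    fields: list[str],
) -> list[RecordDiff]:
    """Diff two keyed tables field by field.

    A key duplicated on either side is itself a diff (the key columns are
    unique in a well-formed view) and is excluded from field comparison.
    """
    out: list[RecordDiff] = []
    for df, side in ((src, "source"), (rec, "cdm")):
        for k in df.loc[df[key].duplicated(), key].unique():
            out.append(RecordDiff(pair, str(k), "*row*",
                                  "duplicated key" if side == "source" else "unique key",
                                  "duplicated key" if side == "cdm" else "unique key"))
    src = src.drop_duplicates(subset=key, keep=False)
    rec = rec.drop_duplicates(subset=key, keep=False)
    s = src.set_index(key)
    r = rec.set_index(key)
    for k in s.index.difference(r.index):
        out.append(RecordDiff(pair, str(k), "*row*", "present", "absent"))
    for k in r.index.difference(s.index):
        out.append(RecordDiff(pair, str(k), "*row*", "absent", "present"))
    common = s.index.intersection(r.index)
    sv = s.loc[common, fields].astype(str)
    rv = r.loc[common, fields].astype(str)
    neq = sv != rv
    for k in common[neq.any(axis=1)]:
        for f in fields:
            if sv.at[k, f] != rv.at[k, f]:
                out.append(RecordDiff(pair, str(k), f, sv.at[k, f], rv.at[k, f]))
    return out


def check_equivalence(
    source: SourceDataset, cdm: CdmDataset, config: EtlConfig = EtlConfig()
) -> list[RecordDiff]:
    """Reconstruct a source-shaped view from the CDM and diff it against
    the deduplicated source.  An empty list means full equivalence."""
    diffs: list[RecordDiff] = []
    pkey = _person_key_map(cdm)
    concept_code = dict(
        zip(cdm["concept"]["concept_id"].astype(int), cdm["concept"]["concept_code"])
    )
    prov = cdm["provider"]
    provider_specialty = dict(
        zip(prov["provider_id"].astype(int), prov["specialty_source_value"])
    )
    visits = cdm["visit_occurrence"]
    visit_stay = dict(
        zip(visits["visit_occurrence_id"].astype(int), visits["visit_source_value"])
    )

    # patients -----------------------------------------------------------
    p = cdm["person"]
    sei_rows = cdm["observation"]
    sei_rows = sei_rows.loc[sei_rows["observation_source_value"] == SEI_SOURCE_VALUE]
    sei_by_person = {
        int(r.person_id): "" if pd.isna(r.value_as_number) else str(int(r.value_as_number))
        for r in sei_rows.itertuples(index=False)
    }
    rec_pat = pd.DataFrame(
        {
            "patient_key": p["person_source_value"],
            "birth_year": p["year_of_birth"].astype(int).astype(str),
            "sex_code": p["gender_source_value"],
            "sei": [sei_by_person.get(int(i), "") for i in p["person_id"]],
        }
    )
    src_pat = source.patient.copy()
    src_pat["birth_year"] = src_pat["birth_year"].astype(str)
    src_pat["sei"] = src_pat["sei"].map(lambda v: "" if pd.isna(v) else str(int(v)))
    diffs += _keyed_diffs(
        "person<-patient", src_pat, rec_pat, "patient_key",
        ["birth_year", "sex_code", "sei"],
    )

    # deaths -------------------------------------------------------------
    dd = p.loc[p["death_datetime"] != "", ["person_source_value", "death_datetime"]]
    rec_death = pd.DataFrame(
        {
            "patient_key": dd["person_source_value"],
            "death_date": dd["death_datetime"].str.slice(0, 10),
        }
    )
    diffs += _keyed_diffs(
        "person<-death", source.death, rec_death, "patient_key", ["death_date"]
    )

    # prescriptions ------------------------------------------------------
    dx = cdm["drug_exposure"]
    rec_rx = pd.DataFrame(
        {
            "patient_key": [pkey.get(int(i), "") for i in dx["person_id"]],
            "prescription_date": dx["drug_exposure_start_date"],
            "prn": dx["drug_source_value"],
            "atc_code": [
                concept_code.get(int(c), "") if c != 0 else ""
                for c in dx["drug_source_concept_id"].fillna(0)
            ],
            "professional_group": [
                provider_specialty.get(int(i)) if pd.notna(i) else ""
                for i in dx["provider_id"]
            ],
        }
    )
    rx_cols = ["patient_key", "prescription_date", "prn", "atc_code", "professional_group"]
    diffs += _multiset_diffs(
        "drug_exposure<-prescription", source.prescription, rec_rx, rx_cols
    )

    # hospital stays -----------------------------------------------------
    stays_dedup, _, _ = deduplicate(
        source.hospital_stay, row_key="stay_key", policy=config.dedup_policy
    )
    rec_stay = pd.DataFrame(
        {
            "stay_key": visits["visit_source_value"],
            "patient_key": [pkey.get(int(i), "") for i in visits["person_id"]],
            "admission_date": visits["visit_start_date"],
            "discharge_date": visits["visit_end_date"],
        }
    )
    diffs += _keyed_diffs(
        "visit_occurrence<-hospital_stay", stays_dedup, rec_stay, "stay_key",
        ["patient_key", "admission_date", "discharge_date"],
    )

    # diagnoses ----------------------------------------------------------
    diag_dedup, _, _ = deduplicate(
        source.diagnosis, row_key="diag_key", policy=config.dedup_policy
    )
    admission = dict(
        zip(source.hospital_stay["stay_key"], source.hospital_stay["admission_date"])
    )
    src_dg = diag_dedup.copy()
    src_dg["event_date"] = [
        d if d != "" else admission.get(s, "")
        for d, s in zip(src_dg["diag_date"], src_dg["stay_ref"])
    ]
    dg_cols = ["patient_key", "icd10_code", "stay_ref", "event_date"]
    id_lookup = {
        (r.patient_key, r.icd10_code, r.stay_ref, r.event_date): r.diag_key
        for r in src_dg.itertuples(index=False)
    }

    rec_rows = []
    spec = {
        "condition_occurrence": ("condition_source_value", "condition_start_date"),
        "procedure_occurrence": ("procedure_source_value", "procedure_date"),
        "measurement": ("measurement_source_value", "measurement_date"),
        "observation": ("observation_source_value", "observation_date"),
    }
    for table, (sv_col, date_col) in spec.items():
        df = cdm[table]
        if table == "observation":
            df = df.loc[df["observation_source_value"] != SEI_SOURCE_VALUE]
        for r in df.itertuples(index=False):
            visit_id = getattr(r, "visit_occurrence_id")
            rec_rows.append(
                {
                    "patient_key": pkey.get(int(r.person_id), ""),
                    "icd10_code": getattr(r, sv_col),
                    "stay_ref": visit_stay.get(int(visit_id), "") if pd.notna(visit_id) else "",
                    "event_date": getattr(r, date_col),
                }
            )
    rec_dg = pd.DataFrame(rec_rows, columns=dg_cols)
    diffs += _multiset_diffs(
        "clinical_events<-diagnosis", src_dg, rec_dg, dg_cols, id_lookup=id_lookup
    )
    return diffs


# ---------------------------------------------------------------------------
# check 3: descriptive statistics
# ---------------------------------------------------------------------------

def _stats_from_parts(
    n_persons: int,
    n_female: int,
    ages: list[int],
    stays_per_person: list[int],
    rx_per_person: list[int],
    lengths_of_stay: list[int],
) -> dict[str, Optional[float]]:
    if n_persons == 0:
        return {k: None for k in STAT_KEYS}
    return {
        "percent_female": 100.0 * n_female / n_persons,
        "median_age": lower_median(ages),
        "median_hospitalizations_per_person": lower_median(
            [c for c in stays_per_person if c > 0]
        ),
        "median_prescriptions_per_person": lower_median(
            [c for c in rx_per_person if c > 0]
        ),
        "median_length_of_stay_days": lower_median(lengths_of_stay),
        "median_hospitalizations_including_zero": lower_median(stays_per_person),
        "median_prescriptions_including_zero": lower_median(rx_per_person),
    }


def _days(d1: str, d0: str) -> int:
    return (date.fromisoformat(d1) - date.fromisoformat(d0)).days


def descriptive_stats_source(
    source: SourceDataset, config: EtlConfig = EtlConfig()
) -> dict[str, Optional[float]]:
    """Indicators on the (deduplicated) source view.

    Age is taken at the study-period start; length of stay is
    discharge − admission in calendar days (same-day = 0); the per-person
    medians count persons with at least one stay/prescription, with the
    all-person variants reported alongside.
    """
    pat = source.patient
    n = len(pat)
    study_year = date.fromisoformat(config.study_start).year
    stays, _, _ = deduplicate(
        source.hospital_stay, row_key="stay_key", policy=config.dedup_policy
    )
    stay_counts = stays.groupby("patient_key").size()
    rx_counts = source.prescription.groupby("patient_key").size()
    return _stats_from_parts(
        n_persons=n,
        n_female=int(pat["sex_code"].isin(config.female_codes).sum()),
        ages=[study_year - y for y in pat["birth_year"]],
        stays_per_person=[int(stay_counts.get(k, 0)) for k in pat["patient_key"]],
        rx_per_person=[int(rx_counts.get(k, 0)) for k in pat["patient_key"]],
        lengths_of_stay=[
            _days(d, a) for a, d in zip(stays["admission_date"], stays["discharge_date"])
        ],
    )


def descriptive_stats_cdm(
    cdm: CdmDataset, config: EtlConfig = EtlConfig()
) -> dict[str, Optional[float]]:
    """The same indicators computed purely from the CDM tables."""
    p = cdm["person"]
    n = len(p)
    study_year = date.fromisoformat(config.study_start).year
    female_ids = {config.gender_map[c] for c in config.female_codes if c in config.gender_map}
    visits = cdm["visit_occurrence"]
    stay_counts = visits.groupby("person_id").size()
    rx_counts = cdm["drug_exposure"].groupby("person_id").size()
    return _stats_from_parts(
        n_persons=n,
        n_female=int(p["gender_concept_id"].astype(int).isin(female_ids).sum()),
        ages=[study_year - int(y) for y in p["year_of_birth"]],
        stays_per_person=[int(stay_counts.get(i, 0)) for i in p["person_id"].astype(int)],
        rx_per_person=[int(rx_counts.get(i, 0)) for i in p["person_id"].astype(int)],
        lengths_of_stay=[
            _days(d, a)
            for a, d in zip(visits["visit_start_date"], visits["visit_end_date"])
        ],
    )


def descriptive_stats(
    dataset: SourceDataset | CdmDataset, config: EtlConfig = EtlConfig()
) -> dict[str, Optional[float]]:
    """Dispatch on the dataset kind (source extract or CDM instance)."""
    if isinstance(dataset, SourceDataset):
        return descriptive_stats_source(dataset, config)
    return descriptive_stats_cdm(dataset, config)


def compare_stats(
    src_stats: dict[str, Optional[float]], cdm_stats: dict[str, Optional[float]]
) -> StatsComparison:
    equal = {k: src_stats.get(k) == cdm_stats.get(k) for k in STAT_KEYS}
    return StatsComparison(source=dict(src_stats), cdm=dict(cdm_stats), equal=equal)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def validate(
    source: SourceDataset,
    cdm: CdmDataset,
    etl_report: EtlReport,
    config: EtlConfig = EtlConfig(),
) -> ValidationReport:
    """Run all three checks; overall pass iff every component passes."""
    counts = reconcile_counts(source, cdm, etl_report)
    diffs = check_equivalence(source, cdm, config)
    stats = compare_stats(
        descriptive_stats_source(source, config), descriptive_stats_cdm(cdm, config)
    )
    return ValidationReport(counts=counts, diffs=diffs, stats=stats)


# ---------------------------------------------------------------------------
# corruption harness (sensitivity self-check)
# ---------------------------------------------------------------------------

def corruption_suite(cdm: CdmDataset) -> list[tuple[str, CdmDataset]]:
    """Ten scripted single-field/row corruptions of a CDM dataset.

    Each returned dataset differs from the input in exactly one place; a
    sound validation run must fail on every one of them and name a failing
    component.
    """
    out: list[tuple[str, CdmDataset]] = []

    def corrupted(label, fn):
        c = cdm.copy()
        fn(c)
        out.append((label, c))

    corrupted("drop_visit_row", lambda c: c.tables.__setitem__(
        "visit_occurrence", c["visit_occurrence"].iloc[:-1].reset_index(drop=True)))
    corrupted("drop_drug_exposure_row", lambda c: c.tables.__setitem__(
        "drug_exposure", c["drug_exposure"].iloc[:-1].reset_index(drop=True)))
    corrupted("drop_condition_row", lambda c: c.tables.__setitem__(
        "condition_occurrence", c["condition_occurrence"].iloc[:-1].reset_index(drop=True)))
    corrupted("drop_person_row", lambda c: c.tables.__setitem__(
        "person", c["person"].iloc[:-1].reset_index(drop=True)))

    def flip_gender(c):
        v = c["person"].at[0, "gender_source_value"]
        c["person"].at[0, "gender_source_value"] = "M" if v == "F" else "F"

    corrupted("flip_person_gender_source", flip_gender)

    def shift_visit_start(c):
        d = date.fromisoformat(c["visit_occurrence"].at[0, "visit_start_date"])
        c["visit_occurrence"].at[0, "visit_start_date"] = (
            d - timedelta(days=1)
        ).isoformat()

    corrupted("shift_visit_start_date", shift_visit_start)

    def alter_drug_source(c):
        df = c["drug_exposure"]
        df.loc[0, "drug_source_value"] = "__CORRUPT__"

    corrupted("alter_drug_source_value", alter_drug_source)

    def shift_birth_year(c):
        df = c["person"]
        df.loc[0, "year_of_birth"] = int(df.loc[0, "year_of_birth"]) - 40

    corrupted("shift_person_birth_year", shift_birth_year)

    def alter_condition_source(c):
        df = c["condition_occurrence"]
        df.loc[0, "condition_source_value"] = "__CORRUPT__"

    corrupted("alter_condition_source_value", alter_condition_source)

    def duplicate_visit(c):
        first = c["visit_occurrence"].iloc[[0]].copy()
        first["visit_occurrence_id"] = int(c["visit_occurrence"]["visit_occurrence_id"].max()) + 1
        c.tables["visit_occurrence"] = pd.concat(
            [c["visit_occurrence"], first], ignore_index=True
        )

    corrupted("duplicate_visit_row", duplicate_visit)
    return out
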