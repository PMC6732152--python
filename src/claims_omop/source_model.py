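"""Source-side data model for Austrian-style claims extracts.

The source shape mirrors the GAP-DRG research database: five flat tables
(patients, deaths, prescriptions, hospital stays, stay-linked or ambulatory
diagnoses) keyed by an opaque patient pseudonym.  This module owns the
schema, CSV round-trip I/O with referential-integrity checking, and a
WhiteRabbit-style scan report (per-table row counts, per-column inferred
types, missing fractions and top-k value frequencies) that downstream
table-mapping decisions are based on.

Conventions
-----------
* Dates are canonicalised to ISO-8601 (``YYYY-MM-DD``) strings; an input
  dialect may declare a different parse format.
* Missing values are empty strings in date/text columns and pandas ``NA``
  in nullable integer columns (``sei``).
* Row keys (``stay_key``, ``diag_key``) are assigned sequentially in file
  order when the source files leave them blank, so that deduplication and
  record-wise validation have stable identities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import datetime
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "CsvDialect",
    "SourceDataset",
    "ScanReport",
    "SourceIntegrityError",
    "SOURCE_TABLES",
    "read_source",
    "write_source",
    "profile_source",
]

#: canonical table -> ordered column list
SOURCE_TABLES: dict[str, list[str]] = {
    "patient": ["patient_key", "birth_year", "sex_code", "sei"],
    "death": ["patient_key", "death_date"],
    "prescription": [
        "patient_key",
        "prescription_date",
        "prn",
        "atc_code",
        "professional_group",
    ],
    "hospital_stay": ["stay_key", "patient_key", "admission_date", "discharge_date"],
    "diagnosis": ["diag_key", "patient_key", "icd10_code", "stay_ref", "diag_date"],
}

_DATE_COLUMNS: dict[str, list[str]] = {
    "death": ["death_date"],
    "prescription": ["prescription_date"],
    "hospital_stay": ["admission_date", "discharge_date"],
    "diagnosis": ["diag_date"],
}

#: columns that may be blank in a valid dataset
_OPTIONAL_COLUMNS = {("patient", "sei"), ("patient", "sex_code"),
                     ("diagnosis", "stay_ref"), ("diagnosis", "diag_date")}

_ROW_KEY_PREFIX = {"hospital_stay": ("stay_key", "HS"), "diagnosis": ("diag_key", "DG")}


class SourceIntegrityError(ValueError):
    """A source dataset violates its schema or referential integrity."""


@dataclass(frozen=True)
class CsvDialect:
    """File dialect of a claims extract.

    ``date_format`` applies to *input* parsing; canonical in-memory and
    written dates are always ISO-8601.
    """

    delimiter: str = ","
    encoding: str = "utf-8"
    date_format: str = "%Y-%m-%d"


@dataclass
class SourceDataset:
    """The five claims source tables plus their file dialect."""

    patient: pd.DataFrame
    death: pd.DataFrame
    prescription: pd.DataFrame
    hospital_stay: pd.DataFrame
    diagnosis: pd.DataFrame
    dialect: CsvDialect = field(default_factory=CsvDialect)

    @property
    def tables(self) -> dict[str, pd.DataFrame]:
        return {name: getattr(self, name) for name in SOURCE_TABLES}

    def validate(self, birth_year_range: tuple[int, int] = (1850, 2100)) -> None:
        """Raise :class:`SourceIntegrityError` on any invariant violation."""
        for name, cols in SOURCE_TABLES.items():
            df = self.tables[name]
            if list(df.columns) != cols:
                raise SourceIntegrityError(
                    f"table '{name}' has columns {list(df.columns)}, expected {cols}"
                )
        pat = self.patient
        dup = pat["patient_key"][pat["patient_key"].duplicated()]
        if len(dup):
            raise SourceIntegrityError(
                f"duplicate patient_key in patient table: {sorted(set(dup))[:10]}"
            )
        lo, hi = birth_year_range
        bad_year = pat.loc[(pat["birth_year"] < lo) | (pat["birth_year"] > hi)]
        if len(bad_year):
            raise SourceIntegrityError(
                f"birth_year outside plausible range {birth_year_range}: "
                f"{bad_year['patient_key'].tolist()[:10]}"
            )
        known = set(pat["patient_key"])
        for name in ("death", "prescription", "hospital_stay", "diagnosis"):
            df = self.tables[name]
            unknown = sorted(set(df["patient_key"]) - known)
            if unknown:
                raise SourceIntegrityError(
                    f"table '{name}' references unknown patient_key(s): {unknown[:10]}"
                )
        dup_death = self.death["patient_key"][self.death["patient_key"].duplicated()]
        if len(dup_death):
            raise SourceIntegrityError(
                f"more than one death row for patient_key(s): {sorted(set(dup_death))[:10]}"
            )
        if (self.prescription["atc_code"] == "").any():
            rows = self.prescription.index[self.prescription["atc_code"] == ""].tolist()
            raise SourceIntegrityError(f"empty atc_code in prescription rows {rows[:10]}")
        hs = self.hospital_stay
        bad = hs.loc[(hs["admission_date"] > hs["discharge_date"])]
        if len(bad):
            raise SourceIntegrityError(
                f"admission after discharge for stay_key(s): {bad['stay_key'].tolist()[:10]}"
            )
        dg = self.diagnosis
        if (dg["icd10_code"] == "").any():
            rows = dg.index[dg["icd10_code"] == ""].tolist()
            raise SourceIntegrityError(f"empty icd10_code in diagnosis rows {rows[:10]}")
        stays = set(hs["stay_key"])
        refs = dg.loc[dg["stay_ref"] != "", "stay_ref"]
        dangling = sorted(set(refs) - stays)
        if dangling:
            raise SourceIntegrityError(
                f"diagnosis stay_ref(s) without hospital stay: {dangling[:10]}"
            )


def _parse_dates(df: pd.DataFrame, table: str, cols: list[str], fmt: str) -> None:
    for col in cols:
        out = []
        for i, raw in enumerate(df[col]):
            if raw == "":
                if (table, col) not in _OPTIONAL_COLUMNS:
                    raise SourceIntegrityError(
                        f"{table}.{col}: missing date in data row {i + 1}"
                    )
                out.append("")
                continue
            try:
                out.append(datetime.strptime(raw, fmt).date().isoformat())
            except ValueError as exc:
                raise SourceIntegrityError(
                    f"{table}.{col}: unparseable date {raw!r} in data row {i + 1}"
                ) from exc
        df[col] = out


def read_source(
    source: str | Path | Mapping[str, str | Path],
    dialect: CsvDialect | None = None,
) -> SourceDataset:
    """Read the five claims tables from CSV and verify all invariants.

    ``source`` is a directory containing ``patient.csv`` ... ``diagnosis.csv``
    or a mapping of table name to file path.  Missing stay/diagnosis row keys
    are assigned sequentially in file order and are stable across re-reads.
    """
    dialect = dialect or CsvDialect()
    if isinstance(source, (str, Path)):
        paths = {name: Path(source) / f"{name}.csv" for name in SOURCE_TABLES}
    else:
        paths = {name: Path(p) for name, p in source.items()}
    frames: dict[str, pd.DataFrame] = {}
    for name, cols in SOURCE_TABLES.items():
        path = paths.get(name)
        if path is None or not path.exists():
            raise FileNotFoundError(f"source table '{name}' not found at {path}")
        df = pd.read_csv(
            path,
            sep=dialect.delimiter,
            encoding=dialect.encoding,
            dtype=str,
            keep_default_na=False,
        )
        if list(df.columns) != cols:
            raise SourceIntegrityError(
                f"{path}: header {list(df.columns)} does not match schema {cols}"
            )
        _parse_dates(df, name, _DATE_COLUMNS.get(name, []), dialect.date_format)
        frames[name] = df

    pat = frames["patient"]
    try:
        pat["birth_year"] = pat["birth_year"].astype("int64")
    except ValueError as exc:
        raise SourceIntegrityError(f"patient.birth_year not integer: {exc}") from exc
    pat["sei"] = pd.to_numeric(pat["sei"].replace("", None), errors="raise").astype("Int64")

    for name, (key_col, prefix) in _ROW_KEY_PREFIX.items():
        df = frames[name]
        if len(df) and (df[key_col] == "").all():
            df[key_col] = [f"{prefix}{i + 1:06d}" for i in range(len(df))]
        elif (df[key_col] == "").any():
            raise SourceIntegrityError(
                f"table '{name}': {key_col} must be all present or all blank"
            )

    ds = SourceDataset(dialect=dialect, **frames)
    ds.validate()
    return ds


def write_source(ds: SourceDataset, directory: str | Path) -> None:
    """Write the five tables as CSV; ``read_source`` of the result is identity."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in SOURCE_TABLES:
        ds.tables[name].to_csv(
            directory / f"{name}.csv",
            index=False,
            sep=ds.dialect.delimiter,
            encoding=ds.dialect.encoding,
        )


# ---------------------------------------------------------------------------
# scan report
# ---------------------------------------------------------------------------

@dataclass
class ColumnProfile:
    name: str
    inferred_type: str
    n_missing: int
    fraction_missing: float
    top_values: list[dict]  # [{"value": str, "count": int}], count desc, value asc


@dataclass
class TableProfile:
    name: str
    row_count: int
    columns: list[ColumnProfile]


@dataclass
class ScanReport:
    """WhiteRabbit-style profile of a claims extract."""

    tables: list[TableProfile]

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _infer_type(values: pd.Series) -> str:
    if len(values) == 0:
        return "empty"
    as_str = values.astype(str)
    if (as_str.str.fullmatch(r"-?\d+")).all():
        return "integer"
    num = pd.to_numeric(as_str, errors="coerce")
    if num.notna().all():
        return "float"
    if as_str.str.fullmatch(r"\d{4}-\d{2}-\d{2}").all():
        return "date"
    return "string"


def profile_source(ds: SourceDataset, top_k: int = 20) -> ScanReport:
    """Profile every table and column of a validated dataset.

    Missing means empty string or NA.  Top-k frequencies are ordered by
    count descending then value ascending (deterministic).
    """
    tables = []
    for name, df in ds.tables.items():
        cols = []
        for col in df.columns:
            series = df[col]
            missing_mask = series.isna() | (series.astype(str) == "")
            present = series[~missing_mask]
            counts = present.astype(str).value_counts()
            freq = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top_k]
            cols.append(
                ColumnProfile(
                    name=col,
                    inferred_type=_infer_type(present),
                    n_missing=int(missing_mask.sum()),
                    fraction_missing=float(missing_mask.mean()) if len(df) else 0.0,
                    top_values=[{"value": v, "count": int(c)} for v, c in freq],
                )
            )
        tables.append(TableProfile(name=name, row_count=len(df), columns=cols))
    return ScanReport(tables=tables)
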