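"""Registry data model and delimited-text I/O.

The analysis consumes three linked tables mirroring a national prescription
registry extract: *prescriptions* (one row per dispensed fill, with its ATC
code and optional reimbursement ICD-10 code), *persons* (demographics,
emigration, and death at month resolution), and *diagnoses* (specialist-care
ICD-10 visits, used only to validate the prescription-based case
classification).  A :class:`RegistrySnapshot` bundles them with a drug
catalogue and the coverage window whose end date is the administrative
censoring date.

All tables travel as UTF-8, comma-delimited CSV with a header row; column
names can be remapped through a YAML schema config.  Dates are ISO-8601.
Death is recorded as (year, month) only; where a calendar day is needed the
day is imputed (default: the 15th).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .atc import parse_atc_levels

__all__ = [
    "RegistryError",
    "RegistrySnapshot",
    "read_registry",
    "write_registry",
    "death_dates",
]

PRESCRIPTION_COLUMNS = ["person_id", "atc_code", "dispense_date", "reimbursement_icd"]
PERSON_COLUMNS = [
    "person_id",
    "sex",
    "birth_year",
    "education_level",
    "emigration_date",
    "death_year",
    "death_month",
]
DIAGNOSIS_COLUMNS = ["person_id", "icd10_code", "visit_date"]
CATALOGUE_COLUMNS = ["atc_code", "drug_name"]

_TABLE_FILES = {
    "persons": "persons.csv",
    "prescriptions": "prescriptions.csv",
    "diagnoses": "diagnoses.csv",
    "catalogue": "catalogue.csv",
    "coverage": "coverage.csv",
}


class RegistryError(ValueError):
    """Raised for schema violations, orphan ids, or unparseable fields."""


@dataclasses.dataclass
class RegistrySnapshot:
    """The three linked registry tables plus catalogue and coverage window.

    Attributes
    ----------
    prescriptions, persons, diagnoses : pandas.DataFrame
        Canonical-column tables (see module constants).
    catalogue : pandas.DataFrame
        Drug catalogue with columns ``atc_code`` and ``drug_name``.
    coverage : tuple of pandas.Timestamp
        ``(start, end)``; ``end`` is the administrative censoring date.
    death_day : int
        Day of month imputed for deaths recorded at month granularity.
    """

    prescriptions: pd.DataFrame
    persons: pd.DataFrame
    diagnoses: pd.DataFrame
    catalogue: pd.DataFrame
    coverage: tuple[pd.Timestamp, pd.Timestamp]
    death_day: int = 15

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name, df, cols in (
            ("prescriptions", self.prescriptions, PRESCRIPTION_COLUMNS),
            ("persons", self.persons, PERSON_COLUMNS),
            ("diagnoses", self.diagnoses, DIAGNOSIS_COLUMNS),
            ("catalogue", self.catalogue, CATALOGUE_COLUMNS),
        ):
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise RegistryError(f"table {name!r} lacks required columns {missing}")
        if self.persons["person_id"].duplicated().any():
            dup = self.persons.loc[self.persons["person_id"].duplicated(), "person_id"]
            raise RegistryError(f"duplicate person_id in persons table: {dup.iloc[0]!r}")
        known = set(self.persons["person_id"])
        for name, df in (("prescriptions", self.prescriptions), ("diagnoses", self.diagnoses)):
            orphan = ~df["person_id"].isin(known)
            if orphan.any():
                row = df.index[orphan][0]
                raise RegistryError(
                    f"orphan person_id {df.loc[row, 'person_id']!r} in {name} row {row}"
                )
        start, end = self.coverage
        if not start < end:
            raise RegistryError("coverage start must precede coverage end")
        if len(self.prescriptions):
            d = self.prescriptions["dispense_date"]
            bad = (d < start) | (d > end)
            if bad.any():
                row = self.prescriptions.index[bad][0]
                raise RegistryError(
                    f"dispense_date outside coverage window at prescriptions row {row}"
                )
        for code in self.catalogue["atc_code"]:
            parse_atc_levels(code)

    def death_dates(self) -> pd.Series:
        """Imputed death dates (NaT when alive), indexed by person_id."""
        return death_dates(self.persons, day=self.death_day)

    def end_of_followup(self) -> pd.Series:
        """Per-person end of observability: min(death, emigration, admin end)."""
        end = pd.Series(self.coverage[1], index=self.persons["person_id"].to_numpy())
        emig = pd.Series(
            self.persons["emigration_date"].to_numpy(),
            index=self.persons["person_id"].to_numpy(),
        )
        dd = self.death_dates()
        out = pd.concat([end, emig, dd], axis=1).min(axis=1)
        out.name = "end_of_followup"
        return out


def death_dates(persons: pd.DataFrame, day: int = 15) -> pd.Series:
    """Impute month-resolution deaths to a calendar day (default the 15th)."""
    has = persons["death_year"].notna() & persons["death_month"].notna()
    out = pd.Series(pd.NaT, index=persons["person_id"].to_numpy(), dtype="datetime64[ns]")
    if has.any():
        sub = persons.loc[has]
        dates = pd.to_datetime(
            {
                "year": sub["death_year"].astype(int),
                "month": sub["death_month"].astype(int),
                "day": day,
            }
        )
        out.loc[sub["person_id"].to_numpy()] = dates.to_numpy()
    out.name = "death_date"
    return out


def _load_schema(schema_config) -> dict:
    """Schema config: mapping table -> {canonical column -> file column}."""
    if schema_config is None:
        return {}
    if isinstance(schema_config, (str, Path)):
        with open(schema_config) as fh:
            return yaml.safe_load(fh) or {}
    return dict(schema_config)


def _parse_dates(df: pd.DataFrame, cols: list[str], table: str) -> None:
    for col in cols:
        try:
            df[col] = pd.to_datetime(df[col], format="ISO8601")
        except (ValueError, TypeError) as exc:
            raise RegistryError(f"unparseable date in {table}.{col}: {exc}") from exc


def read_registry(path, schema_config=None, death_day: int = 15) -> RegistrySnapshot:
    """Read a registry directory (or explicit file mapping) into a snapshot.

    ``path`` is a directory holding ``persons.csv``, ``prescriptions.csv``,
    ``diagnoses.csv``, ``catalogue.csv`` and ``coverage.csv``, or a mapping
    of those table names to file paths.  ``schema_config`` optionally remaps
    column names (YAML file path or nested dict, canonical -> actual).
    """
    if isinstance(path, (str, Path)):
        base = Path(path)
        files = {k: base / v for k, v in _TABLE_FILES.items()}
    else:
        files = {k: Path(v) for k, v in path.items()}
    schema = _load_schema(schema_config)

    def _read(table: str, cols: list[str]) -> pd.DataFrame:
        df = pd.read_csv(files[table], dtype=str, keep_default_na=False)
        rename = {v: k for k, v in schema.get(table, {}).items()}
        df = df.rename(columns=rename)
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise RegistryError(f"file {files[table]} lacks required columns {missing}")
        df = df[cols].replace({"": None})
        return df

    persons = _read("persons", PERSON_COLUMNS)
    persons["birth_year"] = persons["birth_year"].astype(int)
    for col in ("death_year", "death_month"):
        persons[col] = persons[col].astype("Int64")
    persons["education_level"] = persons["education_level"].fillna("missing")
    _parse_dates(persons, ["emigration_date"], "persons")

    prescriptions = _read("prescriptions", PRESCRIPTION_COLUMNS)
    _parse_dates(prescriptions, ["dispense_date"], "prescriptions")

    diagnoses = _read("diagnoses", DIAGNOSIS_COLUMNS)
    _parse_dates(diagnoses, ["visit_date"], "diagnoses")

    catalogue = _read("catalogue", CATALOGUE_COLUMNS)

    cov = pd.read_csv(files["coverage"])
    if not {"start", "end"} <= set(cov.columns) or len(cov) != 1:
        raise RegistryError("coverage.csv must have one row with columns start,end")
    coverage = (pd.Timestamp(cov["start"].iloc[0]), pd.Timestamp(cov["end"].iloc[0]))

    return RegistrySnapshot(
        prescriptions=prescriptions,
        persons=persons,
        diagnoses=diagnoses,
        catalogue=catalogue,
        coverage=coverage,
        death_day=death_day,
    )


def write_registry(snapshot: RegistrySnapshot, path) -> None:
    """Write a snapshot to a directory of CSVs; inverse of :func:`read_registry`."""
    base = Path(path)
    base.mkdir(parents=True, exist_ok=True)

    persons = snapshot.persons.copy()
    persons["emigration_date"] = persons["emigration_date"].dt.strftime("%Y-%m-%d")
    persons.to_csv(base / _TABLE_FILES["persons"], index=False)

    rx = snapshot.prescriptions.copy()
    rx["dispense_date"] = rx["dispense_date"].dt.strftime("%Y-%m-%d")
    rx.to_csv(base / _TABLE_FILES["prescriptions"], index=False)

    dx = snapshot.diagnoses.copy()
    dx["visit_date"] = dx["visit_date"].dt.strftime("%Y-%m-%d")
    dx.to_csv(base / _TABLE_FILES["diagnoses"], index=False)

    snapshot.catalogue.to_csv(base / _TABLE_FILES["catalogue"], index=False)
    pd.DataFrame(
        {
            "start": [snapshot.coverage[0].strftime("%Y-%m-%d")],
            "end": [snapshot.coverage[1].strftime("%Y-%m-%d")],
        }
    ).to_csv(base / _TABLE_FILES["coverage"], index=False)
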