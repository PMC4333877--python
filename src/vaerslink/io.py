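"""Read, write, validate, and join VAERS-style three-table CSV data.

A spontaneous-report dataset is split across three comma-separated tables
keyed by report ID: a Data table (demographics, received date, outcome
flags), a Vaccine table (one row per administered vaccine), and a Symptom
table (up to five MedDRA terms per row, several rows per report allowed).
This module parses those tables and joins them into a
:class:`ReportCollection`, the normalized container the rest of the
pipeline consumes.
"""

from __future__ import annotations

import dataclasses
import enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

DATA_COLUMNS = [
    "VAERS_ID", "RECVDATE", "STATE", "AGE_YRS", "SEX",
    "DIED", "L_THREAT", "ER_VISIT", "HOSPDAYS",
]
VAX_COLUMNS = [
    "VAERS_ID", "VAX_TYPE", "VAX_MANU", "VAX_DOSE",
    "VAX_ROUTE", "VAX_SITE", "VAX_NAME",
]
SYMPTOM_COLUMNS = ["VAERS_ID", "SYMPTOM1", "SYMPTOM2", "SYMPTOM3", "SYMPTOM4", "SYMPTOM5"]

#: wide Symptom-table rows carry at most this many terms; longer reports spill
#: onto additional rows for the same report ID
MAX_SYMPTOMS_PER_ROW = 5

_FILE_SUFFIXES = {"data": "DATA.csv", "vaccine": "VAX.csv", "symptom": "SYMPTOMS.csv"}


class FormatError(ValueError):
    """Raised when a raw table file is missing or its header is wrong."""


class Sex(str, enum.Enum):
    MALE = "MALE"
    FEMALE = "FEMALE"
    UNKNOWN = "UNKNOWN"


_SEX_CODES = {"M": Sex.MALE, "F": Sex.FEMALE}


@dataclasses.dataclass
class RawTables:
    """The three tables as string-typed DataFrames (missing values are '')."""

    data: pd.DataFrame
    vaccine: pd.DataFrame
    symptom: pd.DataFrame

    def equals(self, other: "RawTables") -> bool:
        return (
            self.data.reset_index(drop=True).equals(other.data.reset_index(drop=True))
            and self.vaccine.reset_index(drop=True).equals(other.vaccine.reset_index(drop=True))
            and self.symptom.reset_index(drop=True).equals(other.symptom.reset_index(drop=True))
        )


@dataclasses.dataclass(frozen=True)
class Report:
    """One spontaneous report's demographic and outcome fields."""

    report_id: str
    year: int
    state: str | None = None
    age_years: float | None = None
    sex: Sex = Sex.UNKNOWN
    died: bool = False
    life_threatening: bool = False
    er_visit: bool = False

    def __post_init__(self) -> None:
        if self.age_years is not None and self.age_years < 0:
            raise ValueError(f"report {self.report_id}: negative age {self.age_years}")


@dataclasses.dataclass(frozen=True)
class ReportEntry:
    """A report joined with its de-duplicated vaccine and symptom sets."""

    report: Report
    vaccines: frozenset[str]
    symptoms: frozenset[str]


@dataclasses.dataclass
class ReportCollection:
    """Joined reports keyed by report ID, plus orphan-row tallies.

    Vaccine or Symptom rows whose report ID has no Data-table entry are
    dropped during the join and counted here as orphans (a data-quality
    warning, not an error).
    """

    entries: dict[str, ReportEntry]
    orphan_vaccine_rows: int = 0
    orphan_symptom_rows: int = 0

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[ReportEntry]:
        return iter(self.entries.values())

    def __getitem__(self, report_id: str) -> ReportEntry:
        return self.entries[report_id]

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple],
    ) -> "ReportCollection":
        """Build a collection directly from in-memory records.

        Each record is ``(report_id, year, sex, age_years, vaccines,
        symptoms)`` with ``vaccines`` and ``symptoms`` iterables of strings.
        Intended for tests and small hand-built fixtures.
        """
        entries: dict[str, ReportEntry] = {}
        for report_id, year, sex, age, vaccines, symptoms in records:
            report = Report(
                report_id=str(report_id),
                year=int(year),
                age_years=age,
                sex=sex if isinstance(sex, Sex) else _SEX_CODES.get(str(sex), Sex.UNKNOWN),
            )
            entries[report.report_id] = ReportEntry(
                report=report,
                vaccines=frozenset(vaccines),
                symptoms=frozenset(symptoms),
            )
        return cls(entries=entries)


def _read_csv(path: Path) -> pd.DataFrame:
    # real VAERS exports are Latin-1; ours are UTF-8 -- accept both
    try:
        return pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    except UnicodeDecodeError:
        return pd.read_csv(path, dtype=str, keep_default_na=False, encoding="latin-1")


def _check_columns(frame: pd.DataFrame, expected: Sequence[str], path: Path) -> pd.DataFrame:
    for col in expected:
        if col not in frame.columns:
            raise FormatError(f"{path.name}: missing required column {col!r}")
    return frame.loc[:, list(expected)]


def _detect_prefix(directory: Path) -> str:
    candidates = sorted(directory.glob("*DATA.csv"))
    if not candidates:
        raise FormatError(f"no *DATA.csv file found in {directory}")
    return candidates[0].name[: -len("DATA.csv")]


def read_raw_tables(directory: str | Path, prefix: str | None = None) -> RawTables:
    """Parse the three CSV files under ``directory`` into :class:`RawTables`.

    ``prefix`` is the shared filename prefix (``<prefix>DATA.csv`` etc.,
    e.g. ``"2009VAERS"``); when *None* it is auto-detected from the
    ``*DATA.csv`` file present. Raises :class:`FormatError` when a file or
    a required column is missing.
    """
    directory = Path(directory)
    if prefix is None:
        prefix = _detect_prefix(directory)
    frames = {}
    for key, suffix in _FILE_SUFFIXES.items():
        path = directory / f"{prefix}{suffix}"
        if not path.exists():
            raise FormatError(f"missing table file {path.name} in {directory}")
        frames[key] = _read_csv(path)
    return RawTables(
        data=_check_columns(frames["data"], DATA_COLUMNS, directory / f"{prefix}{_FILE_SUFFIXES['data']}"),
        vaccine=_check_columns(frames["vaccine"], VAX_COLUMNS, directory / f"{prefix}{_FILE_SUFFIXES['vaccine']}"),
        symptom=_check_columns(frames["symptom"], SYMPTOM_COLUMNS, directory / f"{prefix}{_FILE_SUFFIXES['symptom']}"),
    )


def write_raw_tables(tables: RawTables, directory: str | Path, prefix: str = "") -> dict[str, Path]:
    """Write the three tables as CSV under ``directory``; returns the paths.

    Emits the VAERS dialect: comma-separated, double-quote quoting where
    needed, header row, LF line endings, empty string for missing values.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for key, frame in (("data", tables.data), ("vaccine", tables.vaccine), ("symptom", tables.symptom)):
        path = directory / f"{prefix}{_FILE_SUFFIXES[key]}"
        frame.to_csv(path, index=False, lineterminator="\n")
        paths[key] = path
    return paths


def _parse_year(recvdate: str, report_id: str) -> int:
    # dates are MM/DD/YYYY; only the year is used downstream
    parts = recvdate.split("/")
    if len(parts) != 3 or not parts[2].strip().isdigit():
        raise FormatError(f"report {report_id}: cannot parse RECVDATE {recvdate!r}")
    return int(parts[2])


def _parse_report(row: Mapping[str, str]) -> Report:
    age_raw = row["AGE_YRS"].strip()
    return Report(
        report_id=row["VAERS_ID"],
        year=_parse_year(row["RECVDATE"], row["VAERS_ID"]),
        state=row["STATE"].strip() or None,
        age_years=float(age_raw) if age_raw else None,
        sex=_SEX_CODES.get(row["SEX"].strip().upper(), Sex.UNKNOWN),
        died=row["DIED"].strip().upper() == "Y",
        life_threatening=row["L_THREAT"].strip().upper() == "Y",
        er_visit=row["ER_VISIT"].strip().upper() == "Y",
    )


def join_reports(tables: RawTables) -> ReportCollection:
    """Join the three tables by report ID into a :class:`ReportCollection`.

    One entry per Data-table row; duplicate vaccine codes or symptom terms
    within a report collapse to a single set element, so each
    vaccine-symptom pair is counted at most once per report downstream.
    Vaccine/Symptom rows with an unknown report ID are dropped and tallied
    as orphans.
    """
    reports = {row["VAERS_ID"]: _parse_report(row) for row in tables.data.to_dict("records")}
    vaccines: dict[str, set[str]] = {rid: set() for rid in reports}
    symptoms: dict[str, set[str]] = {rid: set() for rid in reports}

    orphan_vax = 0
    for row in tables.vaccine.to_dict("records"):
        rid, vax = row["VAERS_ID"], row["VAX_TYPE"].strip()
        if rid not in reports:
            orphan_vax += 1
            continue
        if vax:
            vaccines[rid].add(vax)

    orphan_sym = 0
    symptom_cols = [c for c in SYMPTOM_COLUMNS if c != "VAERS_ID"]
    for row in tables.symptom.to_dict("records"):
        rid = row["VAERS_ID"]
        if rid not in reports:
            orphan_sym += 1
            continue
        for col in symptom_cols:
            term = row[col].strip()
            if term:
                symptoms[rid].add(term)

    entries = {
        rid: ReportEntry(
            report=rep,
            vaccines=frozenset(vaccines[rid]),
            symptoms=frozenset(symptoms[rid]),
        )
        for rid, rep in reports.items()
    }
    return ReportCollection(
        entries=entries,
        orphan_vaccine_rows=orphan_vax,
        orphan_symptom_rows=orphan_sym,
    )
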