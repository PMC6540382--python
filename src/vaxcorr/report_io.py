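"""Reading and writing spontaneous-report tables and their side files.

Spontaneous post-vaccination reports arrive as delimited text, one record per
report, with multi-valued vaccine and symptom fields.  This module parses them
into :class:`RawReport` objects, reads the vaccine metadata table (code ->
class/attenuation) and the non-adverse-term exclusion list, and round-trips
processed long-format ``(year, vaccine, symptom, count)`` records.

Two input layouts are supported:

``canonical``
    One row per report with columns ``report_id``, ``year``, ``vaccines``,
    ``symptoms``; the multi-valued fields are ``;``-separated.  Rows sharing a
    report identifier are merged (their vaccine and symptom lists are
    concatenated in row order).

``vaers-triplet``
    An adapter for the yearly three-file layout used by the public U.S.
    surveillance extracts (a DATA file with one row per report and a receipt
    date, a VAX file with one row per administered vaccine, and a SYMPTOMS
    file with up to five symptom columns per row), joined on the report
    identifier.  The adapter maps that column layout only; it has not been
    exercised against live downloads.

Malformed rows (unparseable year, no vaccine, or no symptom) are skipped, not
fatal, and tallied in a :class:`ReadSummary` — spontaneous-report data sets
are known to contain erroneous and incomplete records.
"""

from __future__ import annotations

import glob
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import pandas as pd

__all__ = [
    "RawReport",
    "VaccineMeta",
    "ExclusionList",
    "ReadSummary",
    "VACCINE_CLASSES",
    "ATTENUATIONS",
    "LONG_COLUMNS",
    "normalize_term",
    "read_reports",
    "write_reports",
    "read_vaccine_meta",
    "write_vaccine_meta",
    "read_exclusions",
    "write_exclusions",
    "read_long_records",
    "write_long_records",
]

#: Allowed vaccine taxonomy labels.
VACCINE_CLASSES = frozenset({"bacteria", "virus", "combined", "unknown"})
#: Allowed attenuation labels (live attenuated vs killed/inactivated).
ATTENUATIONS = frozenset({"live", "inactivated", "unknown"})

#: Column order of the processed long-record table.
LONG_COLUMNS = ["year", "vaccine", "symptom", "count"]

_MULTI_SEP = ";"


def normalize_term(term: str) -> str:
    """Normalize a symptom term for matching: trim and case-fold.

    Terms are treated as given nominal categories; there is no spelling
    correction or ontology mapping.
    """
    return term.strip().casefold()


@dataclass(frozen=True)
class RawReport:
    """One spontaneous report as filed.

    A single report frequently lists several vaccines administered together
    and several observed symptoms; both collections keep filing order and may
    contain duplicates as filed.
    """

    report_id: str
    year: int
    vaccines: tuple[str, ...]
    symptoms: tuple[str, ...]

    def __post_init__(self) -> None:
        if int(self.year) <= 0:
            raise ValueError(f"report {self.report_id!r}: year must be positive")
        if not self.vaccines:
            raise ValueError(f"report {self.report_id!r}: no vaccines listed")
        if not self.symptoms:
            raise ValueError(f"report {self.report_id!r}: no symptoms listed")


@dataclass(frozen=True)
class VaccineMeta:
    """Vaccine code with taxonomy labels driving ordering and sub-matrix selection."""

    code: str
    vaccine_class: str
    attenuation: str

    def __post_init__(self) -> None:
        if self.vaccine_class not in VACCINE_CLASSES:
            raise ValueError(
                f"vaccine {self.code!r}: unknown class {self.vaccine_class!r} "
                f"(expected one of {sorted(VACCINE_CLASSES)})"
            )
        if self.attenuation not in ATTENUATIONS:
            raise ValueError(
                f"vaccine {self.code!r}: unknown attenuation {self.attenuation!r} "
                f"(expected one of {sorted(ATTENUATIONS)})"
            )


class ExclusionList:
    """Set of symptom terms flagged non-adverse.

    Membership is invariant to letter case and surrounding whitespace, e.g.
    a list containing ``drug ineffective`` matches ``Drug ineffective``.
    """

    def __init__(self, terms: Iterable[str] = ()) -> None:
        self._terms = frozenset(normalize_term(t) for t in terms if t.strip())

    def __contains__(self, term: str) -> bool:
        return normalize_term(term) in self._terms

    def __len__(self) -> int:
        return len(self._terms)

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self._terms))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"ExclusionList({len(self)} terms)"

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "ExclusionList":
        terms = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if line:
                    terms.append(line)
        return cls(terms)


@dataclass
class ReadSummary:
    """Tally of what a report read saw, kept for audit rather than raised."""

    rows_read: int = 0
    reports: int = 0
    bad_year_rows: int = 0
    dropped_no_vaccine: int = 0
    dropped_no_symptom: int = 0
    notes: list[str] = field(default_factory=list)

    @property
    def dropped(self) -> int:
        return self.bad_year_rows + self.dropped_no_vaccine + self.dropped_no_symptom


def _split_multi(value: object) -> list[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return []
    parts = [p.strip() for p in str(value).split(_MULTI_SEP)]
    return [p for p in parts if p]


def _read_table(path: str | os.PathLike) -> pd.DataFrame:
    # sep=None lets the python engine sniff TSV vs CSV.
    return pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)


def read_reports(
    path: str | os.PathLike, dialect: str = "canonical"
) -> tuple[list[RawReport], ReadSummary]:
    """Read spontaneous reports from ``path``.

    Parameters
    ----------
    path
        Canonical layout: a single delimited file.  ``vaers-triplet`` layout:
        a directory containing one ``*DATA*.csv``, one ``*VAX*.csv`` and one
        ``*SYMPTOMS*.csv`` file.
    dialect
        ``"canonical"`` or ``"vaers-triplet"``.

    Returns
    -------
    (reports, summary)
        Validated reports (rows sharing an identifier merged) and a
        :class:`ReadSummary` of skipped rows.
    """
    if dialect == "canonical":
        return _read_canonical(path)
    if dialect == "vaers-triplet":
        return _read_vaers_triplet(path)
    raise ValueError(f"unknown dialect {dialect!r} (expected 'canonical' or 'vaers-triplet')")


def _assemble(
    rows: Iterable[tuple[str, object, list[str], list[str]]], summary: ReadSummary
) -> tuple[list[RawReport], ReadSummary]:
    """Merge rows by report id (concatenating lists) and validate."""
    merged: dict[str, dict] = {}
    order: list[str] = []
    for rid, year_raw, vaccines, symptoms in rows:
        summary.rows_read += 1
        if rid not in merged:
            merged[rid] = {"year": None, "vaccines": [], "symptoms": [], "bad_year": False}
            order.append(rid)
        entry = merged[rid]
        if entry["year"] is None:
            try:
                year = int(str(year_raw).strip())
                if year <= 0:
                    raise ValueError
                entry["year"] = year
            except (TypeError, ValueError):
                entry["bad_year"] = True
        entry["vaccines"].extend(vaccines)
        entry["symptoms"].extend(symptoms)

    reports: list[RawReport] = []
    for rid in order:
        entry = merged[rid]
        if entry["year"] is None:
            summary.bad_year_rows += 1
            continue
        if not entry["vaccines"]:
            summary.dropped_no_vaccine += 1
            continue
        if not entry["symptoms"]:
            summary.dropped_no_symptom += 1
            continue
        reports.append(
            RawReport(
                report_id=rid,
                year=entry["year"],
                vaccines=tuple(entry["vaccines"]),
                symptoms=tuple(entry["symptoms"]),
            )
        )
    summary.reports = len(reports)
    return reports, summary


def _read_canonical(path: str | os.PathLike) -> tuple[list[RawReport], ReadSummary]:
    frame = _read_table(path)
    required = {"report_id", "year", "vaccines", "symptoms"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    summary = ReadSummary()
    rows = (
        (
            str(rec.report_id),
            rec.year,
            _split_multi(rec.vaccines),
            _split_multi(rec.symptoms),
        )
        for rec in frame.itertuples(index=False)
    )
    return _assemble(rows, summary)


def _find_one(directory: str | os.PathLike, pattern: str) -> str:
    hits = sorted(glob.glob(os.path.join(str(directory), pattern)))
    if len(hits) != 1:
        raise FileNotFoundError(
            f"expected exactly one {pattern} file in {directory}, found {len(hits)}"
        )
    return hits[0]


def _read_vaers_triplet(
    directory: str | os.PathLike, date_field: str = "RECVDATE"
) -> tuple[list[RawReport], ReadSummary]:
    """Adapter for the yearly DATA/VAX/SYMPTOMS file trio.

    The year is taken from ``date_field`` (default the receipt date, matching
    the convention of counting reports by filing year; pass ``VAX_DATE`` to
    use the vaccination date instead).
    """
    data = pd.read_csv(_find_one(directory, "*DATA*.csv"), dtype=str, keep_default_na=False)
    vax = pd.read_csv(_find_one(directory, "*VAX*.csv"), dtype=str, keep_default_na=False)
    symp = pd.read_csv(_find_one(directory, "*SYMPTOMS*.csv"), dtype=str, keep_default_na=False)

    vaccines_by_id: dict[str, list[str]] = {}
    for rec in vax.itertuples(index=False):
        code = str(getattr(rec, "VAX_TYPE", "")).strip()
        if code:
            vaccines_by_id.setdefault(str(rec.VAERS_ID), []).append(code)

    symptom_cols = [c for c in symp.columns if c.upper().startswith("SYMPTOM")]
    symptoms_by_id: dict[str, list[str]] = {}
    for _, row in symp.iterrows():
        rid = str(row["VAERS_ID"])
        for col in symptom_cols:
            term = str(row[col]).strip()
            if term:
                symptoms_by_id.setdefault(rid, []).append(term)

    summary = ReadSummary()

    def year_of(value: str) -> object:
        value = value.strip()
        if not value:
            return ""
        # MM/DD/YYYY or YYYY-MM-DD
        for sep, idx in (("/", -1), ("-", 0)):
            if sep in value:
                return value.split(sep)[idx]
        return value

    rows = (
        (
            str(row["VAERS_ID"]),
            year_of(str(row.get(date_field, ""))),
            vaccines_by_id.get(str(row["VAERS_ID"]), []),
            symptoms_by_id.get(str(row["VAERS_ID"]), []),
        )
        for _, row in data.iterrows()
    )
    return _assemble(rows, summary)


def write_reports(reports: Sequence[RawReport], path: str | os.PathLike) -> int:
    """Write reports in the canonical one-row-per-report layout; returns row count."""
    frame = pd.DataFrame(
        {
            "report_id": [r.report_id for r in reports],
            "year": [r.year for r in reports],
            "vaccines": [_MULTI_SEP.join(r.vaccines) for r in reports],
            "symptoms": [_MULTI_SEP.join(r.symptoms) for r in reports],
        }
    )
    frame.to_csv(path, sep="\t", index=False)
    return len(frame)


def read_vaccine_meta(path: str | os.PathLike) -> list[VaccineMeta]:
    """Read the vaccine metadata table (columns ``code``, ``class``, ``attenuation``)."""
    frame = _read_table(path)
    required = {"code", "class", "attenuation"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    codes = frame["code"].str.strip()
    dupes = codes[codes.duplicated()].tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate vaccine codes {sorted(set(dupes))}")
    frame = frame.rename(columns={"class": "vaccine_class"})
    return [
        VaccineMeta(
            code=str(rec.code).strip(),
            vaccine_class=str(rec.vaccine_class).strip(),
            attenuation=str(rec.attenuation).strip(),
        )
        for rec in frame.itertuples(index=False)
    ]


def write_vaccine_meta(meta: Sequence[VaccineMeta], path: str | os.PathLike) -> int:
    frame = pd.DataFrame(
        {
            "code": [m.code for m in meta],
            "class": [m.vaccine_class for m in meta],
            "attenuation": [m.attenuation for m in meta],
        }
    )
    frame.to_csv(path, index=False)
    return len(frame)


def read_exclusions(path: str | os.PathLike) -> ExclusionList:
    """Read a plain-text exclusion list (one term per line, ``#`` comments)."""
    return ExclusionList.from_file(path)


def write_exclusions(exclusions: ExclusionList, path: str | os.PathLike) -> int:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# non-adverse symptom terms, one per line\n")
        for term in exclusions:
            fh.write(term + "\n")
    return len(exclusions)


def write_long_records(records: pd.DataFrame, path: str | os.PathLike) -> int:
    """Write aggregated long records as TSV, sorted by (year, vaccine, symptom).

    Round-trips losslessly through :func:`read_long_records`.
    """
    frame = records.loc[:, LONG_COLUMNS].copy()
    if len(frame) and (frame["count"] < 1).any():
        raise ValueError("long records must have count >= 1")
    if frame.duplicated(subset=["year", "vaccine", "symptom"]).any():
        raise ValueError("(year, vaccine, symptom) triples must be unique")
    frame = frame.sort_values(["year", "vaccine", "symptom"], kind="mergesort")
    frame.to_csv(path, sep="\t", index=False)
    return len(frame)


def read_long_records(path: str | os.PathLike) -> pd.DataFrame:
    """Read a long-record TSV back into the standard four-column frame."""
    frame = pd.read_csv(
        path,
        sep="\t",
        dtype={"year": "int64", "vaccine": str, "symptom": str, "count": "int64"},
        keep_default_na=False,
    )
    missing = set(LONG_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return frame.loc[:, LONG_COLUMNS]
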