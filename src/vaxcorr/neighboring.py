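"""The neighboring method: expanding multi-listed reports into pair counts.

A spontaneous report that lists vaccines A and B together with symptoms C, D
and E does not say which vaccine triggered which symptom.  The neighboring
method resolves this by counting every listed symptom once under every listed
vaccine: the report above contributes one occurrence to each of the six
(vaccine, symptom) pairs.  Aggregating these unit increments over all reports
in a year yields long records ``(year, vaccine, symptom, count)`` where
``count`` is the number of reports filed that year listing that pair.  Taken
together across many reports, this "neighboring information" lets pair-level
patterns emerge even though no single report attributes a symptom to a
vaccine.

Counting rules:

* vaccines and symptoms are de-duplicated *within* a report before expansion
  (a term filed twice in one report counts once; set ``dedupe=False`` to
  count repeats);
* symptom terms are normalized (trimmed, case-folded) before counting;
* there is no per-report weight normalization — a 2-vaccine x 3-symptom
  report contributes total mass 6, not 1, which is exactly the counting rule
  the method defines;
* only pairs that actually occur are kept (every count is >= 1).
"""

from __future__ import annotations

from typing import Iterable, NamedTuple, Sequence

import pandas as pd

from .report_io import LONG_COLUMNS, ExclusionList, RawReport, VaccineMeta, normalize_term

__all__ = [
    "LongRecord",
    "expand_report",
    "aggregate",
    "filter_unknown_vaccine",
    "filter_nonadverse",
    "records_frame",
]


class LongRecord(NamedTuple):
    """One processed record: reports in ``year`` listing ``vaccine`` with ``symptom``."""

    year: int
    vaccine: str
    symptom: str
    count: int


def _unique_in_order(items: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    for item in items:
        if item not in seen:
            seen.add(item)
            out.append(item)
    return out


def expand_report(report: RawReport, dedupe: bool = True) -> list[tuple[int, str, str]]:
    """Expand one report into its unit (year, vaccine, symptom) increments.

    Returns the Cartesian product of the report's distinct vaccines and
    distinct symptoms (terms normalized), each at the report's year and with
    implicit weight 1.
    """
    vaccines = [v.strip() for v in report.vaccines]
    symptoms = [normalize_term(s) for s in report.symptoms]
    if dedupe:
        vaccines = _unique_in_order(vaccines)
        symptoms = _unique_in_order(symptoms)
    return [(report.year, v, s) for v in vaccines for s in symptoms]


def records_frame(records: Iterable[LongRecord | tuple]) -> pd.DataFrame:
    """Build the standard long-record frame from an iterable of 4-tuples."""
    frame = pd.DataFrame(list(records), columns=LONG_COLUMNS)
    frame["year"] = frame["year"].astype("int64")
    frame["count"] = frame["count"].astype("int64")
    return frame


def aggregate(reports: Sequence[RawReport], dedupe: bool = True) -> pd.DataFrame:
    """Aggregate reports into long records via the neighboring expansion.

    For every (year, vaccine, symptom) triple, ``count`` is the number of
    reports whose expansion contains that triple; triples never observed are
    absent (not zero rows).  Total count mass equals
    ``sum over reports of |distinct vaccines| * |distinct symptoms|``.
    """
    triples: list[tuple[int, str, str]] = []
    for report in reports:
        triples.extend(expand_report(report, dedupe=dedupe))
    if not triples:
        return records_frame([])
    frame = pd.DataFrame(triples, columns=["year", "vaccine", "symptom"])
    out = (
        frame.groupby(["year", "vaccine", "symptom"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    out["year"] = out["year"].astype("int64")
    out["count"] = out["count"].astype("int64")
    return out.loc[:, LONG_COLUMNS]


def filter_unknown_vaccine(
    records: pd.DataFrame, meta: Sequence[VaccineMeta]
) -> pd.DataFrame:
    """Drop records whose vaccine is of class ``unknown``.

    Reports filed against an unidentified vaccine carry no pair information,
    so the adverse-only analyses exclude them.  Every vaccine appearing in
    ``records`` must be present in ``meta``.
    """
    class_of = {m.code: m.vaccine_class for m in meta}
    present = set(records["vaccine"].unique())
    missing = present - set(class_of)
    if missing:
        raise ValueError(f"vaccines absent from metadata: {sorted(missing)}")
    keep = records["vaccine"].map(class_of) != "unknown"
    return records.loc[keep].reset_index(drop=True)


def filter_nonadverse(records: pd.DataFrame, exclusions: ExclusionList) -> pd.DataFrame:
    """Drop records whose (normalized) symptom is on the non-adverse list."""
    if len(exclusions) == 0 or records.empty:
        return records.copy()
    keep = [symptom not in exclusions for symptom in records["symptom"]]
    return records.loc[keep].reset_index(drop=True)
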