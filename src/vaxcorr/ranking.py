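"""Ranking symptoms by overall occurrence frequency.

The overall frequency of a symptom is the sum of its long-record counts over
all years and vaccines.  The top-K *adverse* symptoms are the first K entries
of that ranking after removing terms on the non-adverse exclusion list; the
selection also reports how deep into the unfiltered ranking it had to reach
(with 7 non-adverse terms interleaved above the cut, selecting 100 adverse
terms consumes a head of 107).
"""

from __future__ import annotations

from typing import NamedTuple

import pandas as pd

from .report_io import ExclusionList

__all__ = ["SymptomRank", "TopKResult", "rank_symptoms", "top_k_adverse"]


class SymptomRank(NamedTuple):
    rank: int
    symptom: str
    frequency: int


class TopKResult(NamedTuple):
    """Top-K adverse selection plus the unfiltered head size it consumed."""

    table: pd.DataFrame
    head_consumed: int


def rank_symptoms(records: pd.DataFrame) -> pd.DataFrame:
    """Rank all distinct symptoms by total frequency, descending.

    Ties are broken alphabetically for determinism.  Returns a frame with
    columns ``rank`` (1-based, consecutive), ``symptom``, ``frequency``.
    """
    if records.empty:
        return pd.DataFrame({"rank": pd.Series(dtype="int64"),
                             "symptom": pd.Series(dtype=object),
                             "frequency": pd.Series(dtype="int64")})
    totals = records.groupby("symptom", sort=True)["count"].sum().reset_index()
    totals = totals.rename(columns={"count": "frequency"})
    totals = totals.sort_values(
        ["frequency", "symptom"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    totals.insert(0, "rank", totals.index + 1)
    return totals


def top_k_adverse(ranked: pd.DataFrame, k: int, exclusions: ExclusionList) -> TopKResult:
    """Select the first ``k`` non-excluded entries of a ranking.

    Ranks are re-numbered 1..k.  ``head_consumed`` is the size of the
    unfiltered head spanned by the selection, i.e. ``k`` plus the number of
    excluded terms interleaved above the cut.
    """
    if k < 1:
        raise ValueError("k must be a positive integer")
    adverse_mask = [symptom not in exclusions for symptom in ranked["symptom"]]
    n_adverse = sum(adverse_mask)
    if k > n_adverse:
        raise ValueError(f"k={k} exceeds the {n_adverse} non-excluded symptoms available")
    selected = ranked.loc[adverse_mask].head(k)
    head_consumed = int(selected.iloc[-1]["rank"]) if k else 0
    table = selected.reset_index(drop=True).copy()
    table["rank"] = table.index + 1
    return TopKResult(table=table, head_consumed=head_consumed)
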