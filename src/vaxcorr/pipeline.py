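"""End-to-end convenience driver: reports -> long records -> ranking ->
year-stratified block correlation matrix -> block-pattern summary.

This wires the individual modules together in the order the cross-board
analysis uses them; every step is available separately for custom runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from . import corrmat, neighboring, patterns, ranking
from .corrmat import CorrelationMatrix
from .report_io import ExclusionList, RawReport, VaccineMeta

__all__ = ["CrossBoardResult", "run_cross_board"]


@dataclass
class CrossBoardResult:
    """Artifacts of one cross-board run."""

    records_all: pd.DataFrame      # aggregated long records, nothing filtered
    records: pd.DataFrame          # unknown-vaccine-excluded records
    ranking: pd.DataFrame          # full adverse-frequency ranking
    top: pd.DataFrame              # the top-K adverse symptoms
    head_consumed: int             # unfiltered head size the selection spanned
    corr: CorrelationMatrix        # year-stratified pair correlation matrix
    profiles: pd.DataFrame         # one BlockProfile row per off-diagonal pair
    aggregates: pd.DataFrame       # class-pair aggregates
    outliers: pd.DataFrame         # blocks disagreeing with their class-pair majority


def run_cross_board(
    reports: Sequence[RawReport],
    meta: Sequence[VaccineMeta],
    exclusions: ExclusionList,
    *,
    top_k: int = 100,
    years: Sequence[int] | None = None,
    t: float | None = None,
    tau: float = 0.5,
) -> CrossBoardResult:
    """Run the full adverse-only, year-stratified analysis.

    Parameters
    ----------
    top_k
        Number of top adverse symptoms to analyse (the reference geometry
        uses 100).
    years
        Year rows of the frequency matrix; defaults to all years present.
    t
        Entry-classification threshold for block profiling.  Defaults to the
        significance-based threshold for the number of year rows (see
        :func:`vaxcorr.patterns.significance_threshold`); pass 0.01 to
        reproduce the display-map convention instead.
    tau
        Dominance fraction for block labels.
    """
    records_all = neighboring.aggregate(reports)
    records = neighboring.filter_unknown_vaccine(records_all, meta)
    adverse = neighboring.filter_nonadverse(records, exclusions)

    ranked = ranking.rank_symptoms(records)
    top, head_consumed = ranking.top_k_adverse(ranked, top_k, exclusions)

    if years is None:
        years = sorted(records["year"].unique())
    vaccine_order = corrmat.order_vaccines(meta, include_unknown=False)
    freq = corrmat.build_year_by_pair(
        adverse, vaccine_order, list(top["symptom"]), list(years)
    )
    corr = corrmat.pearson_matrix(freq)

    if t is None:
        t = patterns.significance_threshold(len(years))
    profiles, aggregates = patterns.class_pair_summary(corr, meta, t=t, tau=tau)
    outliers = patterns.outlier_blocks(profiles)

    return CrossBoardResult(
        records_all=records_all,
        records=records,
        ranking=ranked,
        top=top,
        head_consumed=head_consumed,
        corr=corr,
        profiles=profiles,
        aggregates=aggregates,
        outliers=outliers,
    )
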