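"""Shared fixtures: small hand-built datasets and seeded synthetic runs."""

from __future__ import annotations

import pandas as pd
import pytest

from vaxcorr import synthetic_data
from vaxcorr.neighboring import records_frame
from vaxcorr.report_io import ExclusionList, RawReport, VaccineMeta


@pytest.fixture
def toy_reports() -> list[RawReport]:
    """Two reports sharing a vaccine and a symptom (worked expansion example)."""
    return [
        RawReport("r1", 1991, ("DTP",), ("Pyrexia", "Rash")),
        RawReport("r2", 1991, ("DTP", "MMR"), ("Pyrexia",)),
    ]


@pytest.fixture
def toy_records() -> pd.DataFrame:
    """Aggregation of ``toy_reports`` (derived by hand)."""
    return records_frame(
        [
            (1991, "DTP", "pyrexia", 2),
            (1991, "DTP", "rash", 1),
            (1991, "MMR", "pyrexia", 1),
        ]
    )


@pytest.fixture
def tiny_meta() -> list[VaccineMeta]:
    return [
        VaccineMeta("DTP", "bacteria", "inactivated"),
        VaccineMeta("MMR", "virus", "live"),
        VaccineMeta("UNK", "unknown", "unknown"),
    ]


@pytest.fixture
def nonadverse() -> ExclusionList:
    return ExclusionList(["drug ineffective", "No adverse event"])


@pytest.fixture(scope="session")
def small_synthetic():
    """A reduced seeded report stream used by several conservation tests."""
    config = synthetic_data.SyntheticConfig(
        n_years=4, reports_per_year=250, n_symptoms=60, cluster_size=30,
        nonadverse_head_ranks=(3, 8, 14), seed=99,
    )
    reports = synthetic_data.generate_reports(config)
    return config, reports
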