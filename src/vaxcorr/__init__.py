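"""vaxcorr: cross-board correlation analysis of spontaneous vaccine
adverse-event reports.

The package processes multi-listed spontaneous reports with the neighboring
method (every listed symptom counted once under every listed vaccine), ranks
symptoms by overall frequency, builds block-structured Pearson correlation
matrices over vaccines or years, classifies block-level patterns by vaccine
class and attenuation, and renders the matrices as threshold / binned pixel
maps.  A seeded synthetic-report generator with planted year-level factors
supplies data with known structure for validation.
"""

from . import corrmat, neighboring, patterns, pipeline, ranking, report_io, synthetic_data, viz
from .corrmat import CorrelationMatrix, FrequencyMatrix, order_vaccines, pearson_matrix
from .neighboring import aggregate, expand_report
from .pipeline import run_cross_board
from .ranking import rank_symptoms, top_k_adverse
from .report_io import ExclusionList, RawReport, VaccineMeta
from .synthetic_data import SyntheticConfig, expected_structure, generate_reports, make_dataset

__version__ = "0.1.0"

__all__ = [
    "corrmat",
    "neighboring",
    "patterns",
    "pipeline",
    "ranking",
    "report_io",
    "synthetic_data",
    "viz",
    "CorrelationMatrix",
    "FrequencyMatrix",
    "order_vaccines",
    "pearson_matrix",
    "aggregate",
    "expand_report",
    "run_cross_board",
    "rank_symptoms",
    "top_k_adverse",
    "ExclusionList",
    "RawReport",
    "VaccineMeta",
    "SyntheticConfig",
    "expected_structure",
    "generate_reports",
    "make_dataset",
    "__version__",
]
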