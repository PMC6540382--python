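"""Frequency matrices and block-structured sample correlation matrices.

Three constructions are used to study cross-board patterns:

* **vaccine x symptom** — one row per vaccine, one column per symptom term;
  entry = total reports (over all years) listing that pair.  Columns may be
  ordered alphabetically or by descending overall frequency.  Correlating the
  columns over the vaccine rows asks: do two symptoms rise and fall together
  across vaccines?

* **year x (vaccine, symptom) pair** — one row per calendar year, one column
  per (vaccine, symptom) pair, vaccine-major then symptom-rank-minor; entry =
  reports that year listing the pair.  Correlating the columns over the year
  rows asks: do symptom j under vaccine i and symptom q under vaccine l rise
  and fall together across years?  With V vaccines and S top symptoms the
  resulting VS x VS correlation matrix decomposes into V^2 blocks M_ij of
  dimension S x S, where M_ij holds the correlations between the top symptoms
  under vaccine i and under vaccine j, and M_ij^T = M_ji.

Correlations are ordinary sample (Pearson) correlation coefficients computed
across the observation rows.  A column whose counts never vary has an
undefined correlation (zero denominator); such entries are stored as 0 and
flagged in ``defined_mask`` so downstream classification and rendering can
treat them as "no information" rather than "uncorrelated".

Missing (year, vaccine, symptom) cells are true zeros — an absent pair means
zero occurrences, not missing data.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Hashable, Sequence

import numpy as np
import pandas as pd

from .report_io import VaccineMeta

logger = logging.getLogger(__name__)

__all__ = [
    "FrequencyMatrix",
    "BlockIndex",
    "CorrelationMatrix",
    "order_vaccines",
    "build_vaccine_by_symptom",
    "build_year_by_pair",
    "pearson_matrix",
    "get_block",
    "get_block_mask",
    "subset_by_class",
    "save_frequency_mtx",
    "load_frequency_mtx",
    "save_correlation_tsv",
    "load_correlation_tsv",
]


def order_vaccines(meta: Sequence[VaccineMeta], include_unknown: bool = True) -> list[str]:
    """Canonical vaccine ordering: bacteria, virus, combined — each
    alphabetical — with the unknown sentinel last (or dropped)."""
    by_class = {"bacteria": [], "virus": [], "combined": [], "unknown": []}
    for m in meta:
        by_class[m.vaccine_class].append(m.code)
    ordered = (
        sorted(by_class["bacteria"])
        + sorted(by_class["virus"])
        + sorted(by_class["combined"])
    )
    if include_unknown:
        ordered += sorted(by_class["unknown"])
    return ordered


@dataclass
class FrequencyMatrix:
    """Dense observation-units x variables count matrix with labels."""

    row_labels: list
    col_labels: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError(
                f"values shape {self.values.shape} does not match labels "
                f"({len(self.row_labels)}, {len(self.col_labels)})"
            )
        if len(self.col_labels) != len(set(self.col_labels)):
            raise ValueError("column labels must be unique")
        if self.values.size and self.values.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class BlockIndex:
    """Maps (vaccine, symptom) pairs to column positions of a pair matrix.

    Columns are vaccine-major: vaccine i occupies the contiguous slice
    ``[i*S, (i+1)*S)`` where S is the number of symptoms per vaccine.
    """

    vaccine_order: tuple[str, ...]
    symptom_order: tuple[str, ...]

    @property
    def block_size(self) -> int:
        return len(self.symptom_order)

    @property
    def n_vaccines(self) -> int:
        return len(self.vaccine_order)

    def vaccine_position(self, vaccine: int | str) -> int:
        if isinstance(vaccine, str):
            try:
                return self.vaccine_order.index(vaccine)
            except ValueError:
                raise KeyError(f"vaccine {vaccine!r} not in block index") from None
        if not 0 <= vaccine < self.n_vaccines:
            raise IndexError(f"vaccine index {vaccine} out of range [0, {self.n_vaccines})")
        return int(vaccine)

    def vaccine_slice(self, vaccine: int | str) -> slice:
        i = self.vaccine_position(vaccine)
        s = self.block_size
        return slice(i * s, (i + 1) * s)

    def position(self, vaccine: str, symptom: str) -> int:
        i = self.vaccine_position(vaccine)
        try:
            j = self.symptom_order.index(symptom)
        except ValueError:
            raise KeyError(f"symptom {symptom!r} not in block index") from None
        return i * self.block_size + j


@dataclass
class CorrelationMatrix:
    """Square symmetric sample-correlation matrix with label and mask metadata."""

    labels: list
    values: np.ndarray
    defined_mask: np.ndarray
    block_index: BlockIndex | None = None

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.values.shape != (n, n) or self.defined_mask.shape != (n, n):
            raise ValueError("values and defined_mask must be square and match labels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n(self) -> int:
        return self.values.shape[0]


def build_vaccine_by_symptom(
    records: pd.DataFrame,
    symptom_order: Sequence[str],
    vaccine_order: Sequence[str],
) -> FrequencyMatrix:
    """Total (over years) counts, one row per vaccine, one column per symptom.

    Every vaccine and symptom present in ``records`` must appear in the given
    orders; labels in the orders that never occur yield all-zero rows/columns.
    """
    v_index = {v: i for i, v in enumerate(vaccine_order)}
    s_index = {s: j for j, s in enumerate(symptom_order)}
    oov_v = set(records["vaccine"].unique()) - set(v_index)
    oov_s = set(records["symptom"].unique()) - set(s_index)
    if oov_v or oov_s:
        raise ValueError(
            f"records contain labels outside the given orders: "
            f"vaccines {sorted(oov_v)[:5]}, symptoms {sorted(oov_s)[:5]}"
        )
    values = np.zeros((len(vaccine_order), len(symptom_order)), dtype=np.int64)
    rows = records["vaccine"].map(v_index).to_numpy()
    cols = records["symptom"].map(s_index).to_numpy()
    np.add.at(values, (rows, cols), records["count"].to_numpy())
    return FrequencyMatrix(list(vaccine_order), list(symptom_order), values)


def build_year_by_pair(
    records: pd.DataFrame,
    vaccine_order: Sequence[str],
    top_symptoms: Sequence[str],
    years: Sequence[int],
) -> FrequencyMatrix:
    """Yearly counts, one row per year, one column per (vaccine, symptom) pair.

    Columns run vaccine-major then symptom-minor in the given orders (with V
    vaccines and S symptoms the column count is V*S; the reference geometry
    of 71 vaccines x 100 top symptoms gives 7100 columns over 24 year rows).
    Records outside the given vaccines/symptoms/years are dropped with a
    logged count — this is how the analysis restricts itself to the top
    adverse symptoms.
    """
    if not len(years):
        raise ValueError("years must be non-empty")
    v_index = {v: i for i, v in enumerate(vaccine_order)}
    s_index = {s: j for j, s in enumerate(top_symptoms)}
    y_index = {int(y): k for k, y in enumerate(years)}
    S = len(top_symptoms)

    mask = (
        records["vaccine"].isin(v_index)
        & records["symptom"].isin(s_index)
        & records["year"].isin(y_index)
    )
    dropped = int((~mask).sum())
    if dropped:
        logger.info("build_year_by_pair: dropped %d records outside the given scope", dropped)
    kept = records.loc[mask]

    values = np.zeros((len(years), len(vaccine_order) * S), dtype=np.int64)
    rows = kept["year"].map(y_index).to_numpy()
    cols = kept["vaccine"].map(v_index).to_numpy() * S + kept["symptom"].map(s_index).to_numpy()
    np.add.at(values, (rows, cols), kept["count"].to_numpy())

    col_labels = [(v, s) for v in vaccine_order for s in top_symptoms]
    return FrequencyMatrix(list(int(y) for y in years), col_labels, values)


def pearson_matrix(freq: FrequencyMatrix) -> CorrelationMatrix:
    """Sample correlation coefficients between all column pairs of ``freq``.

    The coefficient for columns i and j is the standard two-pass formula

        rho_ij = sum_k (X_ki - mean_i)(X_kj - mean_j)
                 / sqrt(sum_k (X_ki - mean_i)^2) / sqrt(sum_k (X_kj - mean_j)^2)

    over the observation rows k.  Columns with zero variance have every entry
    (including the diagonal) stored as 0 and marked undefined.  The result is
    exactly symmetric, clipped to [-1, 1], with unit diagonal on defined
    columns.  If the column labels are (vaccine, symptom) pairs laid out
    vaccine-major, a :class:`BlockIndex` is attached for block access.
    """
    X = freq.values.astype(np.float64)
    n_obs = X.shape[0]
    if n_obs < 2:
        raise ValueError("need at least 2 observation rows to correlate")
    centered = X - X.mean(axis=0, keepdims=True)
    ss = np.sqrt(np.einsum("ki,ki->i", centered, centered))
    defined = ss > 0.0
    denom = np.where(defined, ss, 1.0)
    Z = centered / denom
    corr = Z.T @ Z
    corr = (corr + corr.T) / 2.0  # exact symmetry despite BLAS rounding
    np.clip(corr, -1.0, 1.0, out=corr)
    np.fill_diagonal(corr, 1.0)
    corr[~defined, :] = 0.0
    corr[:, ~defined] = 0.0
    mask = np.logical_and.outer(defined, defined)

    block_index = _infer_block_index(freq.col_labels)
    return CorrelationMatrix(
        labels=list(freq.col_labels), values=corr, defined_mask=mask, block_index=block_index
    )


def _infer_block_index(col_labels: Sequence[Hashable]) -> BlockIndex | None:
    """Detect a vaccine-major (vaccine, symptom) pair layout in column labels."""
    if not col_labels or not all(isinstance(c, tuple) and len(c) == 2 for c in col_labels):
        return None
    vaccines: list[str] = []
    for v, _ in col_labels:
        if not vaccines or vaccines[-1] != v:
            vaccines.append(v)
    if len(set(vaccines)) != len(vaccines):
        return None  # vaccines not contiguous
    S, rem = divmod(len(col_labels), len(vaccines))
    if rem:
        return None
    symptoms = [s for _, s in col_labels[:S]]
    expected = [(v, s) for v in vaccines for s in symptoms]
    if list(col_labels) != expected:
        return None
    return BlockIndex(tuple(vaccines), tuple(symptoms))


def _require_blocks(corr: CorrelationMatrix) -> BlockIndex:
    if corr.block_index is None:
        raise ValueError("correlation matrix has no block index (not a pair matrix)")
    return corr.block_index


def get_block(corr: CorrelationMatrix, i: int | str, j: int | str) -> np.ndarray:
    """The S x S block M_ij of correlations between top symptoms under vaccine
    i and under vaccine j.  Accepts 0-based positions or vaccine codes.
    Satisfies ``get_block(c, i, j).T == get_block(c, j, i)`` entry-wise."""
    bx = _require_blocks(corr)
    return corr.values[bx.vaccine_slice(i), bx.vaccine_slice(j)]


def get_block_mask(corr: CorrelationMatrix, i: int | str, j: int | str) -> np.ndarray:
    """Defined-entry mask aligned with :func:`get_block`."""
    bx = _require_blocks(corr)
    return corr.defined_mask[bx.vaccine_slice(i), bx.vaccine_slice(j)]


def subset_by_class(
    corr: CorrelationMatrix,
    meta: Sequence[VaccineMeta],
    selector: str | Sequence[str],
) -> CorrelationMatrix:
    """Restrict a pair correlation matrix to vaccines matching ``selector``.

    ``selector`` may be a vaccine class (``bacteria``/``virus``/``combined``),
    an attenuation value (``live``/``inactivated``), or an explicit sequence
    of vaccine codes (e.g. a named flu subset).  Vaccine order is preserved.
    """
    bx = _require_blocks(corr)
    if isinstance(selector, str):
        by_code = {m.code: m for m in meta}
        missing = [v for v in bx.vaccine_order if v not in by_code]
        if missing:
            raise ValueError(f"vaccines absent from metadata: {missing[:5]}")
        if selector in {"bacteria", "virus", "combined", "unknown"}:
            wanted = [v for v in bx.vaccine_order if by_code[v].vaccine_class == selector]
        elif selector in {"live", "inactivated"}:
            wanted = [v for v in bx.vaccine_order if by_code[v].attenuation == selector]
        else:
            raise ValueError(f"unknown selector {selector!r}")
    else:
        unknown = set(selector) - set(bx.vaccine_order)
        if unknown:
            raise ValueError(f"selector codes not in matrix: {sorted(unknown)}")
        wanted = [v for v in bx.vaccine_order if v in set(selector)]
    if not wanted:
        raise ValueError(f"selector {selector!r} matches no vaccine in the matrix")

    idx = np.concatenate([np.arange(*bx.vaccine_slice(v).indices(corr.n)[:2]) for v in wanted])
    new_bx = BlockIndex(tuple(wanted), bx.symptom_order)
    return CorrelationMatrix(
        labels=[corr.labels[i] for i in idx],
        values=corr.values[np.ix_(idx, idx)],
        defined_mask=corr.defined_mask[np.ix_(idx, idx)],
        block_index=new_bx,
    )


# ---------------------------------------------------------------------------
# persistence


def save_frequency_mtx(freq: FrequencyMatrix, path: str | os.PathLike) -> None:
    """Write counts as Matrix Market plus ``.rows``/``.cols`` label sidecars."""
    from scipy.io import mmwrite
    from scipy.sparse import coo_matrix

    path = str(path)
    mmwrite(path, coo_matrix(freq.values))
    base = path[:-4] if path.endswith(".mtx") else path
    with open(base + ".rows", "w", encoding="utf-8") as fh:
        fh.writelines(_label_line(lbl) for lbl in freq.row_labels)
    with open(base + ".cols", "w", encoding="utf-8") as fh:
        fh.writelines(_label_line(lbl) for lbl in freq.col_labels)


def load_frequency_mtx(path: str | os.PathLike) -> FrequencyMatrix:
    from scipy.io import mmread

    path = str(path)
    values = np.asarray(mmread(path).todense()).astype(np.int64)
    base = path[:-4] if path.endswith(".mtx") else path
    row_labels = _read_labels(base + ".rows")
    col_labels = _read_labels(base + ".cols")
    return FrequencyMatrix(row_labels, col_labels, values)


def _label_line(label) -> str:
    if isinstance(label, tuple):
        return "\t".join(str(p) for p in label) + "\n"
    return f"{label}\n"


def _read_labels(path: str) -> list:
    labels: list = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) == 1:
                part = parts[0]
                labels.append(int(part) if part.lstrip("-").isdigit() else part)
            else:
                labels.append(tuple(parts))
    return labels


def save_correlation_tsv(corr: CorrelationMatrix, path: str | os.PathLike) -> None:
    """Write a correlation matrix as TSV with header labels; undefined entries
    are written empty so the mask round-trips."""
    header = [_format_label(lbl) for lbl in corr.labels]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join([""] + header) + "\n")
        for i, lbl in enumerate(header):
            cells = [
                format(corr.values[i, j], ".10g") if corr.defined_mask[i, j] else ""
                for j in range(corr.n)
            ]
            fh.write("\t".join([lbl] + cells) + "\n")


def load_correlation_tsv(path: str | os.PathLike) -> CorrelationMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False)
    labels = [_parse_label(c) for c in frame.columns]
    raw = frame.to_numpy()
    mask = raw != ""
    values = np.zeros(raw.shape, dtype=np.float64)
    values[mask] = [float(v) for v in raw[mask]]
    return CorrelationMatrix(
        labels=labels,
        values=values,
        defined_mask=mask,
        block_index=_infer_block_index(labels),
    )


def _format_label(label) -> str:
    return "|".join(str(p) for p in label) if isinstance(label, tuple) else str(label)


def _parse_label(text: str):
    return tuple(text.split("|")) if "|" in text else text
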