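"""Quantitative block-level pattern statistics for correlation matrices.

The cross-board claims of interest are statements about whole blocks of a
pair correlation matrix — "the top adverse symptoms are mostly uncorrelated
or negatively correlated under different bacteria vaccines, but in many cases
positively correlated under different virus vaccines".  This module makes
such statements testable:

* each entry is classified positive / negligible / negative against a
  threshold ``t`` (the display convention uses ``t = 0.01``: red above,
  white within, blue below);
* each off-diagonal vaccine block M_ij gets a :class:`BlockProfile` with the
  fraction of defined entries in each category and a dominance label
  (``mostly_positive`` etc. once a fraction reaches ``tau``, default a
  simple majority);
* profiles aggregate by vaccine-class pair (or attenuation, or a named
  subset), and :func:`outlier_blocks` surfaces blocks that disagree with
  their class-pair majority — the mechanism that flags an anomalous
  bacteria-vaccine pair behaving like the virus class.

A caution on thresholds: with ``n`` observation rows the sample correlation
of two truly independent columns has standard deviation ~ 1/sqrt(n-1), so a
display threshold like 0.01 cannot separate "truly uncorrelated" from noise
when ``n`` is a couple dozen years.  :func:`significance_threshold` returns
the two-sided critical value for testing zero correlation, which is the
appropriate ``t`` when block labels are meant as inferences rather than as
pixel colors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .corrmat import CorrelationMatrix, get_block, get_block_mask
from .report_io import VaccineMeta

__all__ = [
    "POSITIVE",
    "NEGATIVE",
    "NEGLIGIBLE",
    "BlockProfile",
    "classify_entry",
    "classify_matrix",
    "significance_threshold",
    "block_profile",
    "class_pair_summary",
    "outlier_blocks",
]

POSITIVE = "positive"
NEGATIVE = "negative"
NEGLIGIBLE = "negligible"


def classify_entry(rho: float, t: float = 0.01, defined: bool = True) -> str:
    """Tricolor classification of one correlation value.

    Positive if ``rho > t``, negative if ``rho < -t``, negligible otherwise;
    the boundary ``|rho| = t`` is negligible.  Undefined entries are
    negligible by convention (the caller already knows they are undefined).
    """
    if t <= 0:
        raise ValueError("threshold t must be positive")
    if not -1.0 <= rho <= 1.0:
        raise ValueError(f"correlation {rho} outside [-1, 1]")
    if not defined:
        return NEGLIGIBLE
    if rho > t:
        return POSITIVE
    if rho < -t:
        return NEGATIVE
    return NEGLIGIBLE


def classify_matrix(
    values: np.ndarray, mask: np.ndarray | None = None, t: float = 0.01
) -> np.ndarray:
    """Vectorized tricolor classification: +1 / 0 / -1 per entry (0 where undefined)."""
    if t <= 0:
        raise ValueError("threshold t must be positive")
    out = np.zeros(values.shape, dtype=np.int8)
    out[values > t] = 1
    out[values < -t] = -1
    if mask is not None:
        out[~mask] = 0
    return out


def significance_threshold(n_obs: int, alpha: float = 0.05) -> float:
    """Two-sided critical |r| for testing zero correlation with ``n_obs`` rows.

    Derived from the exact t-test of a Pearson coefficient:
    ``r_crit = t_crit / sqrt(df + t_crit^2)`` with ``df = n_obs - 2``.
    """
    if n_obs < 3:
        raise ValueError("need at least 3 observations")
    df = n_obs - 2
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(t_crit / np.sqrt(df + t_crit**2))


@dataclass(frozen=True)
class BlockProfile:
    """Category fractions and dominance label for one vaccine-pair block."""

    vaccine_i: str
    vaccine_j: str
    f_pos: float
    f_neg: float
    f_zero: float
    label: str
    t: float
    n_defined: int
    mean_rho: float

    @property
    def f_zero_or_neg(self) -> float:
        """The compound "uncorrelated or negatively correlated" share."""
        return self.f_zero + self.f_neg


def block_profile(
    M: np.ndarray,
    mask: np.ndarray | None = None,
    *,
    t: float = 0.01,
    tau: float = 0.5,
    exclude_diagonal: bool = False,
    vaccine_i: str = "",
    vaccine_j: str = "",
) -> BlockProfile:
    """Profile one block: fractions of defined entries per tricolor category.

    ``exclude_diagonal`` should be set for diagonal blocks M_ii, whose unit
    self-correlations carry no information.  The label is ``mostly_positive``
    if ``f_pos >= tau`` (similarly negative / uncorrelated), else ``mixed``;
    an all-undefined block is labelled ``mixed`` with a warning.
    """
    M = np.asarray(M, dtype=np.float64)
    use = np.ones(M.shape, dtype=bool) if mask is None else mask.copy()
    if exclude_diagonal:
        np.fill_diagonal(use, False)
    n_defined = int(use.sum())
    if n_defined == 0:
        warnings.warn(
            f"block ({vaccine_i!r}, {vaccine_j!r}): all entries undefined", stacklevel=2
        )
        return BlockProfile(vaccine_i, vaccine_j, 0.0, 0.0, 0.0, "mixed", t, 0, float("nan"))
    vals = M[use]
    f_pos = float((vals > t).sum()) / n_defined
    f_neg = float((vals < -t).sum()) / n_defined
    f_zero = 1.0 - f_pos - f_neg
    if f_pos >= tau:
        label = "mostly_positive"
    elif f_neg >= tau:
        label = "mostly_negative"
    elif f_zero >= tau:
        label = "mostly_uncorrelated"
    else:
        label = "mixed"
    return BlockProfile(
        vaccine_i, vaccine_j, f_pos, f_neg, f_zero, label, t, n_defined, float(vals.mean())
    )


def _group_value(meta_by_code: dict[str, VaccineMeta], code: str, group_by: str) -> str:
    m = meta_by_code[code]
    return m.vaccine_class if group_by == "class" else m.attenuation


def class_pair_summary(
    corr: CorrelationMatrix,
    meta: Sequence[VaccineMeta],
    *,
    t: float = 0.01,
    tau: float = 0.5,
    group_by: str = "class",
    subset: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Profile every off-diagonal vaccine-pair block and aggregate by group.

    Parameters
    ----------
    group_by
        ``"class"`` (bacteria/virus/combined) or ``"attenuation"``
        (live/inactivated).
    subset
        Optional explicit vaccine codes (e.g. the flu vaccines) restricting
        the profiled pairs.

    Returns
    -------
    (profiles, aggregates)
        ``profiles`` has one row per unordered off-diagonal pair i < j (block
        profiles are transpose-invariant, so M_ij and M_ji are the same row).
        ``aggregates`` has one row per group pair with mean fractions, the
        compound uncorrelated-or-negative share, label shares and the modal
        label.
    """
    if group_by not in {"class", "attenuation"}:
        raise ValueError("group_by must be 'class' or 'attenuation'")
    bx = corr.block_index
    if bx is None:
        raise ValueError("correlation matrix has no block index")
    meta_by_code = {m.code: m for m in meta}
    vaccines = list(bx.vaccine_order)
    if subset is not None:
        chosen = set(subset)
        vaccines = [v for v in vaccines if v in chosen]
    missing = [v for v in vaccines if v not in meta_by_code]
    if missing:
        raise ValueError(f"vaccines absent from metadata: {missing[:5]}")

    rows = []
    for a in range(len(vaccines)):
        for b in range(a + 1, len(vaccines)):
            vi, vj = vaccines[a], vaccines[b]
            prof = block_profile(
                get_block(corr, vi, vj),
                get_block_mask(corr, vi, vj),
                t=t,
                tau=tau,
                vaccine_i=vi,
                vaccine_j=vj,
            )
            gi = _group_value(meta_by_code, vi, group_by)
            gj = _group_value(meta_by_code, vj, group_by)
            group_pair = tuple(sorted((gi, gj)))
            rows.append(
                {
                    "vaccine_i": vi,
                    "vaccine_j": vj,
                    "group_i": group_pair[0],
                    "group_j": group_pair[1],
                    "f_pos": prof.f_pos,
                    "f_neg": prof.f_neg,
                    "f_zero": prof.f_zero,
                    "f_zero_or_neg": prof.f_zero_or_neg,
                    "mean_rho": prof.mean_rho,
                    "n_defined": prof.n_defined,
                    "label": prof.label,
                }
            )
    profiles = pd.DataFrame(
        rows,
        columns=[
            "vaccine_i", "vaccine_j", "group_i", "group_j",
            "f_pos", "f_neg", "f_zero", "f_zero_or_neg",
            "mean_rho", "n_defined", "label",
        ],
    )
    if profiles.empty:
        return profiles, profiles.copy()

    def _agg(sub: pd.DataFrame) -> pd.Series:
        label_shares = sub["label"].value_counts(normalize=True)
        return pd.Series(
            {
                "n_blocks": len(sub),
                "mean_f_pos": sub["f_pos"].mean(),
                "mean_f_neg": sub["f_neg"].mean(),
                "mean_f_zero": sub["f_zero"].mean(),
                "mean_f_zero_or_neg": sub["f_zero_or_neg"].mean(),
                "mean_rho": sub["mean_rho"].mean(),
                "modal_label": label_shares.idxmax(),
                "share_mostly_positive": label_shares.get("mostly_positive", 0.0),
                "share_mostly_negative": label_shares.get("mostly_negative", 0.0),
                "share_mostly_uncorrelated": label_shares.get("mostly_uncorrelated", 0.0),
                "share_mixed": label_shares.get("mixed", 0.0),
            }
        )
    aggregates = (
        profiles.groupby(["group_i", "group_j"]).apply(_agg, include_groups=False).reset_index()
    )
    return profiles, aggregates


def outlier_blocks(profiles: pd.DataFrame, within_label: str | None = None) -> pd.DataFrame:
    """Blocks whose label disagrees with the modal label of their group pair.

    Returned sorted by ``|f_pos - group mean f_pos|`` descending, so a single
    strongly positive block inside a mostly-uncorrelated class pair comes
    first.  ``within_label`` optionally restricts to outliers carrying that
    label (e.g. ``mostly_positive``).
    """
    if profiles.empty:
        return profiles.copy()
    grouped = profiles.groupby(["group_i", "group_j"])
    modal = grouped["label"].transform(lambda s: s.value_counts().idxmax())
    mean_fpos = grouped["f_pos"].transform("mean")
    out = profiles.loc[profiles["label"] != modal].copy()
    out["group_modal_label"] = modal[out.index]
    out["deviation"] = (profiles["f_pos"] - mean_fpos).abs()[out.index]
    if within_label is not None:
        out = out.loc[out["label"] == within_label]
    return out.sort_values("deviation", ascending=False, kind="mergesort").reset_index(drop=True)
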