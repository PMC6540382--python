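"""Frequency matrices, the Pearson correlation core, and block access."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as npst

from vaxcorr import corrmat, synthetic_data
from vaxcorr.corrmat import (
    BlockIndex,
    FrequencyMatrix,
    build_vaccine_by_symptom,
    build_year_by_pair,
    get_block,
    get_block_mask,
    order_vaccines,
    pearson_matrix,
    subset_by_class,
)
from vaxcorr.neighboring import records_frame


def naive_pearson(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Independent two-pass oracle: explicit loops over the textbook formula."""
    n_obs, n_var = X.shape
    means = [sum(X[k, i] for k in range(n_obs)) / n_obs for i in range(n_var)]
    ss = [
        math.sqrt(sum((X[k, i] - means[i]) ** 2 for k in range(n_obs)))
        for i in range(n_var)
    ]
    corr = np.zeros((n_var, n_var))
    mask = np.zeros((n_var, n_var), dtype=bool)
    for i in range(n_var):
        for j in range(n_var):
            if ss[i] > 0 and ss[j] > 0:
                num = sum(
                    (X[k, i] - means[i]) * (X[k, j] - means[j]) for k in range(n_obs)
                )
                corr[i, j] = num / (ss[i] * ss[j])
                mask[i, j] = True
    return corr, mask


def freq_of(values, rows=None, cols=None) -> FrequencyMatrix:
    values = np.asarray(values)
    rows = rows or [f"r{i}" for i in range(values.shape[0])]
    cols = cols or [f"c{j}" for j in range(values.shape[1])]
    return FrequencyMatrix(rows, cols, values)


class TestOrderVaccines:
    def test_default_taxonomy_order(self):
        meta = synthetic_data.default_vaccine_metadata()
        order = order_vaccines(meta)
        assert len(order) == 72
        assert order[-1] == "UNK"
        assert order[:24] == sorted(order[:24])          # bacteria, alphabetical
        assert order[24:62] == sorted(order[24:62])      # virus, alphabetical
        assert order[62:71] == sorted(order[62:71])      # combined, alphabetical
        # reference geometry: MNQ is the 16th and PPV the 21st bacteria vaccine
        assert order[15] == "MNQ" and order[20] == "PPV"
        assert order[26] == "FLU" and order[29] == "FLUN(H1N1)"
        assert len(order_vaccines(meta, include_unknown=False)) == 71


class TestFrequencyBuilders:
    def test_vaccine_by_symptom_sums_over_years(self):
        records = records_frame(
            [(1991, "DTP", "pyrexia", 2), (1992, "DTP", "pyrexia", 3)]
        )
        freq = build_vaccine_by_symptom(records, ["pyrexia", "rash"], ["DTP", "MMR"])
        assert freq.values[0, 0] == 5
        assert freq.values[0, 1] == 0 and freq.values[1, 0] == 0

    def test_out_of_vocabulary_label_rejected(self):
        records = records_frame([(1991, "DTP", "pyrexia", 2)])
        with pytest.raises(ValueError, match="outside"):
            build_vaccine_by_symptom(records, ["rash"], ["DTP"])

    def test_year_by_pair_single_placement(self):
        records = records_frame([(1991, "v2", "s1", 4)])
        freq = build_year_by_pair(
            records, ["v1", "v2"], ["s1", "s2", "s3"], [1990, 1991]
        )
        assert freq.shape == (2, 6)
        assert freq.col_labels[3] == ("v2", "s1")
        expected = np.zeros((2, 6), dtype=int)
        expected[1, 3] = 4
        np.testing.assert_array_equal(freq.values, expected)

    def test_year_by_pair_empty_records_keep_shape(self):
        freq = build_year_by_pair(records_frame([]), ["v1"], ["s1", "s2"], [1990, 1991])
        assert freq.shape == (2, 2)
        assert not freq.values.any()

    def test_year_by_pair_requires_years(self):
        with pytest.raises(ValueError, match="years"):
            build_year_by_pair(records_frame([]), ["v1"], ["s1"], [])

    def test_out_of_scope_records_are_dropped(self):
        records = records_frame(
            [(1991, "v1", "s1", 2), (1991, "v9", "s1", 5), (1989, "v1", "s1", 7)]
        )
        freq = build_year_by_pair(records, ["v1"], ["s1"], [1990, 1991])
        assert freq.values.sum() == 2


class TestPearsonMatrix:
    def test_known_small_example(self):
        # columns (1,2,3,4) and (1,3,2,4): covariance sum 4, sum-of-squares 5
        freq = freq_of(np.array([[1, 1], [2, 3], [3, 2], [4, 4]]))
        corr = pearson_matrix(freq)
        assert corr.values[0, 1] == pytest.approx(0.8, abs=1e-15)
        np.testing.assert_array_equal(np.diag(corr.values), [1.0, 1.0])

    def test_perfect_anticorrelation(self):
        corr = pearson_matrix(freq_of(np.array([[1, 3], [2, 2], [3, 1]])))
        assert corr.values[0, 1] == pytest.approx(-1.0, abs=1e-15)

    def test_constant_column_masked_undefined(self):
        corr = pearson_matrix(freq_of(np.array([[2, 1], [2, 5], [2, 9]])))
        assert not corr.defined_mask[0].any() and not corr.defined_mask[:, 0].any()
        assert (corr.values[0] == 0).all()
        assert corr.values[0, 0] == 0.0  # diagonal of an undefined column
        assert corr.defined_mask[1, 1] and corr.values[1, 1] == 1.0

    def test_requires_two_rows(self):
        with pytest.raises(ValueError, match="2 observation rows"):
            pearson_matrix(freq_of(np.array([[1, 2]])))

    @settings(max_examples=40, deadline=None)
    @given(
        X=npst.arrays(
            dtype=np.int64,
            shape=st.tuples(st.integers(2, 8), st.integers(1, 10)),
            elements=st.integers(0, 50),
        )
    )
    def test_matches_naive_two_pass_oracle(self, X):
        corr = pearson_matrix(freq_of(X))
        expected, mask = naive_pearson(X)
        np.testing.assert_array_equal(corr.defined_mask, mask)
        np.testing.assert_allclose(
            corr.values[mask], expected[mask], rtol=0, atol=1e-12
        )

    @settings(max_examples=30, deadline=None)
    @given(
        X=npst.arrays(
            dtype=np.int64,
            shape=st.tuples(st.integers(2, 6), st.integers(2, 6)),
            elements=st.integers(0, 20),
        ),
        col=st.integers(0, 5),
        factor=st.integers(2, 9),
        shift=st.integers(1, 50),
    )
    def test_symmetry_and_scale_shift_invariance(self, X, col, factor, shift):
        corr = pearson_matrix(freq_of(X))
        assert (corr.values == corr.values.T).all()
        assert (np.abs(corr.values) <= 1).all()
        assert (corr.values[np.diag_indices_from(corr.values)][
            corr.defined_mask.diagonal()] == 1).all()
        col = col % X.shape[1]
        scaled = X.copy()
        scaled[:, col] = scaled[:, col] * factor + shift
        corr2 = pearson_matrix(freq_of(scaled))
        both = corr.defined_mask & corr2.defined_mask
        np.testing.assert_allclose(
            corr2.values[both], corr.values[both], rtol=0, atol=1e-12
        )


class TestBlocks:
    @pytest.fixture
    def pair_corr(self):
        rng = np.random.default_rng(5)
        vaccines, symptoms, years = ["v1", "v2", "v3"], ["s1", "s2"], [2000, 2001, 2002, 2003]
        rows = [
            (y, v, s, int(c))
            for y in years
            for v in vaccines
            for s in symptoms
            if (c := rng.integers(0, 9)) > 0
        ]
        freq = build_year_by_pair(records_frame(rows), vaccines, symptoms, years)
        return pearson_matrix(freq)

    def test_block_index_inferred_from_pair_labels(self, pair_corr):
        bx = pair_corr.block_index
        assert isinstance(bx, BlockIndex)
        assert bx.vaccine_order == ("v1", "v2", "v3") and bx.block_size == 2

    def test_transpose_identity_between_mirror_blocks(self, pair_corr):
        M12 = get_block(pair_corr, "v1", "v2")
        M21 = get_block(pair_corr, "v2", "v1")
        np.testing.assert_array_equal(M12.T, M21)

    def test_diagonal_block_has_unit_diagonal_on_defined(self, pair_corr):
        M = get_block(pair_corr, 0, 0)
        mask = get_block_mask(pair_corr, 0, 0)
        assert (np.diag(M)[np.diag(mask)] == 1).all()

    def test_reassembled_blocks_reproduce_full_matrix(self, pair_corr):
        bx = pair_corr.block_index
        n = bx.n_vaccines
        rebuilt = np.block(
            [[get_block(pair_corr, i, j) for j in range(n)] for i in range(n)]
        )
        np.testing.assert_array_equal(rebuilt, pair_corr.values)

    def test_index_out_of_range(self, pair_corr):
        with pytest.raises(IndexError):
            get_block(pair_corr, 0, 5)
        with pytest.raises(KeyError):
            get_block(pair_corr, "v1", "nope")


class TestSubsetByClass:
    @pytest.fixture
    def paper_geometry_corr(self):
        """Pair matrix over the full 71-vaccine taxonomy with 3 symptoms."""
        meta = synthetic_data.default_vaccine_metadata()
        vaccines = order_vaccines(meta, include_unknown=False)
        symptoms = ["s1", "s2", "s3"]
        rng = np.random.default_rng(11)
        rows = [
            (y, v, s, int(rng.integers(1, 9)))
            for y in (2000, 2001, 2002, 2003)
            for v in vaccines
            for s in symptoms
        ]
        freq = build_year_by_pair(records_frame(rows), vaccines, symptoms,
                                  [2000, 2001, 2002, 2003])
        return meta, pearson_matrix(freq)

    def test_class_and_attenuation_dimensions(self, paper_geometry_corr):
        meta, corr = paper_geometry_corr
        assert subset_by_class(corr, meta, "bacteria").n == 24 * 3
        assert subset_by_class(corr, meta, "virus").n == 38 * 3
        assert subset_by_class(corr, meta, "live").n == 23 * 3
        assert subset_by_class(corr, meta, "inactivated").n == 47 * 3

    def test_explicit_code_subset_preserves_order(self, paper_geometry_corr):
        meta, corr = paper_geometry_corr
        sub = subset_by_class(corr, meta, synthetic_data.FLU_CODES)
        assert sub.block_index.vaccine_order == ("FLU", "FLU(H1N1)", "FLUN", "FLUN(H1N1)")
        assert sub.n == 4 * 3
        # sub-matrix values equal the corresponding slice of the original
        i = corr.block_index.vaccine_slice("FLU")
        np.testing.assert_array_equal(
            sub.values[:3, :3], corr.values[i, i]
        )

    def test_selector_matching_all_is_identity_subset(self, pair_corr=None):
        meta = [
            synthetic_data.VaccineMeta("v1", "virus", "live"),
            synthetic_data.VaccineMeta("v2", "virus", "live"),
        ]
        rows = [(2000, "v1", "s", 1), (2000, "v2", "s", 4),
                (2001, "v1", "s", 2), (2001, "v2", "s", 3)]
        freq = build_year_by_pair(records_frame(rows), ["v1", "v2"], ["s"], [2000, 2001])
        corr = pearson_matrix(freq)
        sub = subset_by_class(corr, meta, "virus")
        np.testing.assert_array_equal(sub.values, corr.values)

    def test_empty_selector_is_an_error(self, paper_geometry_corr):
        meta, corr = paper_geometry_corr
        with pytest.raises(ValueError, match="matches no vaccine"):
            subset_by_class(corr, meta, "unknown")


class TestPersistence:
    def test_frequency_mtx_roundtrip(self, tmp_path):
        freq = freq_of(np.array([[0, 2], [3, 0]]), rows=[1990, 1991], cols=["a", "b"])
        path = tmp_path / "freq.mtx"
        corrmat.save_frequency_mtx(freq, path)
        back = corrmat.load_frequency_mtx(path)
        np.testing.assert_array_equal(back.values, freq.values)
        assert back.row_labels == freq.row_labels
        assert back.col_labels == freq.col_labels

    def test_correlation_tsv_roundtrip_preserves_mask_and_blocks(self, tmp_path):
        rows = [(2000, "v1", "s1", 1), (2000, "v2", "s2", 4),
                (2001, "v1", "s1", 3), (2001, "v2", "s1", 2)]
        freq = build_year_by_pair(records_frame(rows), ["v1", "v2"], ["s1", "s2"],
                                  [2000, 2001])
        corr = pearson_matrix(freq)
        path = tmp_path / "corr.tsv"
        corrmat.save_correlation_tsv(corr, path)
        back = corrmat.load_correlation_tsv(path)
        np.testing.assert_array_equal(back.defined_mask, corr.defined_mask)
        np.testing.assert_allclose(back.values, corr.values, atol=1e-9)
        assert back.block_index.vaccine_order == ("v1", "v2")
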