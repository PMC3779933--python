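"""Fragmentation, TNF vectors, ESOM training, U-matrix, bin extraction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fosmidscreen import binning as tb
from fosmidscreen.errors import DataError, InsufficientDataError, InvalidParameterError

dna = st.text(alphabet="ACGT", min_size=50, max_size=300)


def naive_tnf(seq: str, strand_symmetric: bool = True) -> np.ndarray:
    """Independent oracle: per-window dictionary counting."""
    comp = str.maketrans("ACGT", "TGCA")
    counts: dict[str, int] = {}
    strands = [seq]
    if strand_symmetric:
        strands.append(seq.translate(comp)[::-1])
    for s in strands:
        for i in range(len(s) - 3):
            w = s[i : i + 4]
            if "N" not in w:
                counts[w] = counts.get(w, 0) + 1
    vec = np.array([counts.get(k, 0) for k in tb.KMERS], dtype=float)
    total = vec.sum()
    return vec / total if total else vec


class TestFragmentSequence:
    def test_remainder_dropped(self):
        frags = tb.fragment_sequence("A" * 35_000)
        assert len(frags) == 17
        assert all(len(s) == 2000 for _, s in frags)
        assert [off for off, _ in frags] == list(range(0, 34_000, 2000))

    def test_below_minimum_length_excluded(self):
        assert tb.fragment_sequence("A" * 1999) == []

    def test_exact_minimum_gives_one_fragment(self):
        frags = tb.fragment_sequence("A" * 2000)
        assert len(frags) == 1 and frags[0][0] == 0

    def test_bad_characters_rejected(self):
        with pytest.raises(DataError):
            tb.fragment_sequence("ACGT" * 600 + "X")

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(2000, 60_000))
    def test_fragment_count_is_floor_of_length(self, length):
        assert len(tb.fragment_sequence("A" * length)) == length // 2000


class TestTnfVector:
    def test_polyA_strand_symmetric_counts(self):
        vec = tb.tnf_vector("A" * 2000)
        assert vec[tb.KMERS.index("AAAA")] == pytest.approx(0.5)
        assert vec[tb.KMERS.index("TTTT")] == pytest.approx(0.5)
        assert vec.sum() == pytest.approx(1.0)

    def test_forward_window_count(self):
        # L - k + 1 forward windows on an N-free fragment
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), 2000))
        codes = tb._encode(seq)
        c0, c1, c2, c3 = codes[:-3], codes[1:-2], codes[2:-1], codes[3:]
        assert ((c0 >= 0) & (c1 >= 0) & (c2 >= 0) & (c3 >= 0)).sum() == 1997

    def test_n_windows_skipped(self):
        vec = tb.tnf_vector("AAAANAAAA", strand_symmetric=False)
        # windows overlapping the N are dropped: 2 x AAAA survive of 6
        assert vec[tb.KMERS.index("AAAA")] == pytest.approx(1.0)

    def test_all_n_fragment_yields_zero_vector(self):
        assert tb.tnf_vector("N" * 100).sum() == 0.0

    def test_too_short_rejected(self):
        with pytest.raises(InvalidParameterError):
            tb.tnf_vector("ACG")

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(dna)
    def test_matches_naive_recount(self, seq):
        np.testing.assert_allclose(tb.tnf_vector(seq), naive_tnf(seq), atol=1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(dna)
    def test_strand_invariance(self, seq):
        comp = str.maketrans("ACGT", "TGCA")
        rc = seq.translate(comp)[::-1]
        np.testing.assert_allclose(tb.tnf_vector(seq), tb.tnf_vector(rc), atol=1e-12)


class TestNormalizeFeatures:
    def test_constant_column_maps_to_zero(self):
        m = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [0.0, 1.0, 2.0]})
        out = tb.normalize_features(m)
        assert (out["a"] == 0.0).all()
        assert out["b"].mean() == pytest.approx(0.0, abs=1e-12)

    def test_none_is_identity(self):
        m = pd.DataFrame({"a": [1.0, 2.0]})
        assert tb.normalize_features(m, "none") is m

    def test_single_row_zscore_rejected(self):
        with pytest.raises(InsufficientDataError):
            tb.normalize_features(pd.DataFrame({"a": [1.0]}))


class TestTrainEsom:
    def test_grid_satisfies_neuron_ratio(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.normal(size=(100, 8)))
        som = tb.train_esom(m, tb.EsomParams(seed=3, epochs=2))
        assert som.n_neurons >= int(np.ceil(5.5 * 100)) >= 550

    def test_training_log_starts_at_radius_24(self):
        rng = np.random.default_rng(4)
        m = pd.DataFrame(rng.normal(size=(20, 4)))
        som = tb.train_esom(m, tb.EsomParams(seed=5, epochs=3))
        epoch0, radius0, _lr0 = som.training_log[0]
        assert epoch0 == 0 and radius0 == 24.0
        assert som.training_log[-1][1] == pytest.approx(1.0)

    def test_identical_inputs_converge_to_input(self):
        v = np.linspace(0, 1, 6)
        m = pd.DataFrame(np.tile(v, (30, 1)))
        som = tb.train_esom(m, tb.EsomParams(seed=6, epochs=5))
        bmu_r, bmu_c = tb.best_matching_unit(som, v)
        cb = som.codebook_grid()[bmu_r, bmu_c]
        np.testing.assert_allclose(cb, v, atol=1e-6)

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(7)
        m = pd.DataFrame(rng.normal(size=(30, 6)))
        a = tb.train_esom(m, tb.EsomParams(seed=8, epochs=2))
        b = tb.train_esom(m, tb.EsomParams(seed=8, epochs=2))
        np.testing.assert_array_equal(a.codebook, b.codebook)

    def test_undersized_grid_rejected(self):
        rng = np.random.default_rng(9)
        m = pd.DataFrame(rng.normal(size=(100, 4)))
        with pytest.raises(InvalidParameterError):
            tb.train_esom(m, tb.EsomParams(seed=1, grid_rows=5, grid_cols=5))


class TestBestMatchingUnit:
    def test_exact_match_neuron(self):
        codebook = np.eye(4)
        som = tb.SOMap(2, 2, codebook, feature_names=list("abcd"))
        assert tb.best_matching_unit(som, codebook[3]) == (1, 1)

    def test_tie_breaks_to_lowest_row_major_index(self):
        codebook = np.zeros((6, 3))
        som = tb.SOMap(2, 3, codebook, feature_names=list("abc"))
        assert tb.best_matching_unit(som, np.ones(3)) == (0, 0)

    def test_dimension_mismatch_rejected(self):
        som = tb.SOMap(2, 2, np.zeros((4, 3)), feature_names=list("abc"))
        with pytest.raises(InvalidParameterError):
            tb.best_matching_unit(som, np.zeros(5))

    def test_matches_bruteforce_argmin(self):
        rng = np.random.default_rng(10)
        for _ in range(200):
            codebook = rng.normal(size=(50, 8))
            som = tb.SOMap(5, 10, codebook, feature_names=[str(i) for i in range(8)])
            v = rng.normal(size=8)
            best, best_d = None, np.inf
            for idx in range(50):
                d = float(np.sqrt(((codebook[idx] - v) ** 2).sum()))
                if d < best_d:
                    best, best_d = idx, d
            assert tb.best_matching_unit(som, v) == divmod(best, 10)


class TestUmatrix:
    def test_uniform_codebook_is_flat(self):
        som = tb.SOMap(4, 5, np.ones((20, 3)), feature_names=list("abc"))
        np.testing.assert_array_equal(tb.compute_umatrix(som), np.zeros((4, 5)))

    def test_block_boundary_has_higher_ridge(self):
        grid = np.zeros((8, 8, 2))
        grid[:, 4:, :] = 5.0  # two homogeneous blocks
        som = tb.SOMap(8, 8, grid.reshape(64, 2), feature_names=["a", "b"])
        u = tb.compute_umatrix(som)
        interior = u[:, 2]
        boundary = u[:, 4]
        assert (boundary > interior).all()
        assert (u >= 0).all()


class TestExtractBins:
    def _flat_som(self, rows, cols, d=2):
        return tb.SOMap(rows, cols, np.zeros((rows * cols, d)), feature_names=["a", "b"])

    def test_q_100_spans_whole_map(self):
        som = self._flat_som(6, 6)
        u = np.random.default_rng(11).random((6, 6))
        part = tb.extract_bins(som, u, q=100, min_neurons=1)
        assert part.bin_ids == [1]
        assert (part.labels == 1).all()

    def test_identical_data_single_bin(self):
        som = self._flat_som(6, 6)
        part = tb.extract_bins(som, np.zeros((6, 6)))
        assert part.bin_ids == [1]

    def test_two_low_regions_split_by_ridge(self):
        u = np.ones((10, 10))
        u[1:4, 1:4] = 0.0
        u[6:9, 6:9] = 0.0
        som = self._flat_som(10, 10)
        part = tb.extract_bins(som, u, q=15, min_neurons=2, merge_q=None)
        assert len(part.bin_ids) == 2

    def test_shallow_ridge_components_merge_at_relaxed_threshold(self):
        # two low basins separated by a shallow ridge (0.5) inside a high
        # plateau (1.0): strict components are distinct, but they reconnect
        # below the relaxed threshold and merge into one bin
        u = np.ones((10, 10))
        u[1:4, 1:4] = 0.0
        u[6:9, 1:4] = 0.0
        u[4:6, 1:4] = 0.5
        som = self._flat_som(10, 10)
        assert len(tb.extract_bins(som, u, q=15, min_neurons=2,
                                   merge_q=None).bin_ids) == 2
        part = tb.extract_bins(som, u, q=15, min_neurons=2, merge_q=20)
        assert len(part.bin_ids) == 1

    def test_toroidal_wraparound_merges_components(self):
        u = np.ones((8, 8))
        u[0, :] = 0.0
        u[7, :] = 0.0  # one band across the top/bottom seam
        som = self._flat_som(8, 8)
        part = tb.extract_bins(som, u, q=25, min_neurons=2)
        assert len(part.bin_ids) == 1

    def test_invalid_percentile_rejected(self):
        som = self._flat_som(4, 4)
        with pytest.raises(InvalidParameterError):
            tb.extract_bins(som, np.zeros((4, 4)), q=0)

    def test_kmedoids_partitions_codebook(self):
        rng = np.random.default_rng(12)
        cb = np.vstack([rng.normal(0, 0.1, (8, 2)), rng.normal(5, 0.1, (8, 2))])
        som = tb.SOMap(4, 4, cb, feature_names=["a", "b"])
        part = tb.extract_bins(som, np.zeros((4, 4)), method="kmedoids", k=2, seed=13)
        labels = part.labels.ravel()
        assert len(set(labels[:8])) == 1 and len(set(labels[8:])) == 1
        assert labels[0] != labels[8]


class TestAssignClones:
    def _partition(self):
        labels = np.zeros((2, 4), dtype=int)
        labels[0, :2] = 1  # bin A at (0,0),(0,1)
        labels[1, :2] = 2  # bin B at (1,0),(1,1)
        return tb.BinPartition(labels=labels, method="manual")

    def _bmus(self, rows, cols, dists, clone="c1"):
        idx = [f"{clone}:{i * 2000}" for i in range(len(rows))]
        bmus = pd.DataFrame({"row": rows, "col": cols, "distance": dists}, index=idx)
        frag_index = pd.DataFrame(
            {"fragment_id": idx, "clone_id": clone, "offset": [i * 2000 for i in range(len(rows))]}
        )
        return bmus, frag_index

    def test_plurality_assignment(self):
        bmus, fi = self._bmus([0, 0, 0, 1, 1], [0, 1, 0, 0, 1], [0.1] * 5)
        out = tb.assign_clones(self._partition(), bmus, fi)
        row = out.iloc[0]
        assert row["bin"] == 1
        assert row["majority_fraction"] == pytest.approx(0.6)
        assert not row["tie_flag"]

    def test_single_fragment_clone(self):
        bmus, fi = self._bmus([1], [0], [0.5])
        out = tb.assign_clones(self._partition(), bmus, fi)
        assert out.iloc[0]["bin"] == 2
        assert out.iloc[0]["majority_fraction"] == 1.0

    def test_tie_resolved_by_codebook_distance(self):
        bmus, fi = self._bmus([0, 0, 1, 1], [0, 1, 0, 1], [0.9, 0.9, 0.1, 0.1])
        out = tb.assign_clones(self._partition(), bmus, fi)
        assert out.iloc[0]["bin"] == 2  # closer on average
        assert bool(out.iloc[0]["tie_flag"])

    def test_unassigned_neurons_ignored_unless_only_option(self):
        bmus, fi = self._bmus([0, 0, 1], [3, 3, 0], [0.1, 0.1, 0.2])
        out = tb.assign_clones(self._partition(), bmus, fi)
        assert out.iloc[0]["bin"] == 2  # the single labelled fragment wins
        bmus0, fi0 = self._bmus([0, 0], [3, 3], [0.1, 0.1], clone="c2")
        out0 = tb.assign_clones(self._partition(), bmus0, fi0)
        assert out0.iloc[0]["bin"] == 0


def test_fragment_conservation_over_library():
    rng = np.random.default_rng(14)
    seqs = {}
    for i in range(12):
        L = int(rng.integers(1500, 12_000))
        seqs[f"c{i}"] = "".join(rng.choice(list("ACGT"), L))
    matrix, index, excluded = tb.tnf_matrix(seqs)
    expected = sum(len(s) // 2000 for s in seqs.values() if len(s) >= 2000)
    assert len(matrix) == expected
    assert set(excluded) == {c for c, s in seqs.items() if len(s) < 2000}
    per_clone = index.groupby("clone_id").size()
    for c, n in per_clone.items():
        assert n == len(seqs[c]) // 2000
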