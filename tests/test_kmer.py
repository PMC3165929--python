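"""Canonical l-mer counting and feature-matrix construction."""

from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lmerbin as lb
from lmerbin.errors import DegenerateFragmentError, InputError, ParameterError
from lmerbin.kmer import corrupted_window_count

from conftest import random_dna


def brute_force_classes(l: int) -> set[frozenset]:
    """Independent enumeration of reverse-complement equivalence classes."""
    mers = ["".join(p) for p in product("ACGT", repeat=l)]
    return {frozenset({m, lb.reverse_complement(m)}) for m in mers}


class TestCanonicalIndex:
    @pytest.mark.parametrize("l", range(1, 7))
    def test_class_count_matches_brute_force(self, l):
        idx = lb.build_canonical_index(l)
        assert idx.n_classes == len(brute_force_classes(l))

    @pytest.mark.parametrize("l,expected", [(1, 2), (3, 32), (4, 136)])
    def test_known_class_counts(self, l, expected):
        assert lb.build_canonical_index(l).n_classes == expected

    @pytest.mark.parametrize("l", range(1, 7))
    def test_class_count_formula(self, l):
        expected = 4**l // 2 if l % 2 else (4**l + 4**(l // 2)) // 2
        assert lb.build_canonical_index(l).n_classes == expected

    def test_lookup_collapses_reverse_complements(self):
        idx = lb.build_canonical_index(4)
        for mer in idx.lookup:
            assert idx.lookup[mer] == idx.lookup[lb.reverse_complement(mer)]

    def test_canonical_representative_is_lexicographic_min(self):
        idx = lb.build_canonical_index(3)
        for mer, col in idx.lookup.items():
            assert idx.classes[col] == min(mer, lb.reverse_complement(mer))

    def test_class_order_is_sorted(self):
        idx = lb.build_canonical_index(4)
        assert list(idx.classes) == sorted(idx.classes)

    @pytest.mark.parametrize("l", [0, 9, -1, 2.5])
    def test_l_out_of_range(self, l):
        with pytest.raises(ParameterError):
            lb.build_canonical_index(l)


class TestCountLmers:
    @pytest.mark.parametrize("length,expected", [(500, 497), (2000, 1997)])
    def test_window_totals_for_clean_fragments(self, length, expected):
        rng = np.random.default_rng(42)
        frag = lb.Fragment("f", random_dna(rng, length))
        idx = lb.build_canonical_index(4)
        assert lb.count_lmers(frag, idx).total == expected

    def test_reverse_complement_collapse_example(self):
        # windows AACG, ACGT, CGTT; rc(AACG)=CGTT, ACGT is palindromic
        idx = lb.build_canonical_index(4)
        cv = lb.count_lmers(lb.Fragment("f", "AACGTT"), idx)
        assert cv.total == 3
        assert cv.counts[idx.lookup["AACG"]] == 2
        assert cv.counts[idx.lookup["ACGT"]] == 1
        assert cv.counts.sum() == 3

    def test_ambiguous_windows_skipped(self):
        idx = lb.build_canonical_index(4)
        assert lb.count_lmers(lb.Fragment("f", "ACGNACG"), idx).total == 0

    def test_lowercase_is_counted(self):
        idx = lb.build_canonical_index(4)
        upper = lb.count_lmers(lb.Fragment("f", "AACGTT"), idx)
        lower = lb.count_lmers(lb.Fragment("f", "aacgtt"), idx)
        np.testing.assert_array_equal(upper.counts, lower.counts)

    @pytest.mark.parametrize("seq", ["", "ACG"])
    def test_short_or_empty_sequence_rejected(self, seq):
        idx = lb.build_canonical_index(4)
        with pytest.raises(InputError):
            lb.count_lmers(lb.Fragment("f", seq), idx)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGTN", min_size=4, max_size=120))
    def test_window_conservation(self, seq):
        """Counted + skipped windows partition all length-4 windows."""
        idx = lb.build_canonical_index(4)
        cv = lb.count_lmers(lb.Fragment("f", seq), idx)
        skipped = sum(1 for i in range(len(seq) - 3) if "N" in seq[i:i + 4])
        assert cv.total + skipped == len(seq) - 3


class TestNormalize:
    def test_direct_division(self):
        counts = np.zeros(136, dtype=np.int64)
        counts[0], counts[1] = 2, 1
        values = lb.normalize_counts(lb.CountVector(counts, 3))
        assert values[0] == pytest.approx(2 / 3)
        assert values[1] == pytest.approx(1 / 3)
        assert values.sum() == pytest.approx(1.0)

    def test_uniform_counts(self):
        counts = np.full(32, 5, dtype=np.int64)
        values = lb.normalize_counts(lb.CountVector(counts, 160))
        np.testing.assert_allclose(values, 1 / 32)

    def test_zero_total_rejected(self):
        with pytest.raises(DegenerateFragmentError):
            lb.normalize_counts(lb.CountVector(np.zeros(136, dtype=int), 0))


class TestFeatureMatrix:
    def test_shape_and_row_normalization(self):
        rng = np.random.default_rng(0)
        frags = [lb.Fragment(f"f{i}", random_dna(rng, 300)) for i in range(10)]
        fm = lb.build_feature_matrix(frags, l=4)
        assert fm.values.shape == (10, 136)
        np.testing.assert_allclose(fm.values.sum(axis=1), 1.0, atol=1e-9)
        assert (fm.values >= 0).all() and (fm.values <= 1).all()

    def test_identical_sequences_identical_rows(self):
        rng = np.random.default_rng(1)
        seq = random_dna(rng, 200)
        fm = lb.build_feature_matrix(
            [lb.Fragment("a", seq), lb.Fragment("b", seq)])
        np.testing.assert_array_equal(fm.values[0], fm.values[1])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=10, max_size=200))
    def test_strand_invariance(self, seq):
        """A fragment and its reverse complement get identical features."""
        fm = lb.build_feature_matrix(
            [lb.Fragment("fwd", seq),
             lb.Fragment("rev", lb.reverse_complement(seq))])
        assert np.max(np.abs(fm.values[0] - fm.values[1])) == 0.0

    def test_zero_window_fragment_dropped_and_reported(self):
        rng = np.random.default_rng(2)
        frags = [lb.Fragment("ok", random_dna(rng, 100)),
                 lb.Fragment("bad", "NNNNNNNN")]
        fm = lb.build_feature_matrix(frags)
        assert fm.fragment_ids == ("ok",)
        assert fm.dropped_ids == ("bad",)

    def test_empty_list_rejected(self):
        with pytest.raises(InputError):
            lb.build_feature_matrix([])

    def test_duplicate_ids_rejected(self):
        with pytest.raises(InputError):
            lb.build_feature_matrix(
                [lb.Fragment("x", "ACGTACGT"), lb.Fragment("x", "TTTTAAAA")])

    def test_tsv_roundtrip(self, tmp_path):
        rng = np.random.default_rng(3)
        frags = [lb.Fragment(f"f{i}", random_dna(rng, 150)) for i in range(4)]
        fm = lb.build_feature_matrix(frags)
        path = tmp_path / "features.tsv"
        fm.to_tsv(path)
        import pandas as pd
        df = pd.read_csv(path, sep="\t", index_col=0)
        assert list(df.columns) == list(fm.index.classes)
        np.testing.assert_allclose(df.values, fm.values, atol=1e-9)


class TestCorruptedWindows:
    def test_single_interior_substitution_corrupts_l_windows(self):
        rng = np.random.default_rng(4)
        seq = random_dna(rng, 100)
        pos = 50
        alt = "A" if seq[pos] != "A" else "C"
        mutated = seq[:pos] + alt + seq[pos + 1:]
        assert corrupted_window_count(seq, mutated, l=4) == 4

    def test_identical_sequences_corrupt_nothing(self):
        assert corrupted_window_count("ACGTACGT", "ACGTACGT", l=4) == 0
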