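"""Shift-compare passes, compensation, and the indicator matrix."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helios import (
    DNA,
    PROTEIN,
    CodingParams,
    align_row,
    compare_entry,
    compensate,
    encode_sequence,
    helios_align,
    random_sequence,
)
from helpers import oracle_indicator

dna_seq = st.text(alphabet="ATGC", min_size=6, max_size=30)


class TestCompareEntry:
    def test_identical(self):
        assert compare_entry((450.0, 9.0), (450.0, 9.0)) == 1

    def test_same_self_different_nearby(self):
        # e.g. two 'S' residues whose lookback characters differ
        assert compare_entry((450.0, 9.0), (450.0, 18.0)) == 0

    def test_different_self_same_nearby(self):
        assert compare_entry((450.0, 9.0), (460.0, 9.0)) == 0


class TestAlignRow:
    def test_self_comparison_is_all_ones(self, rng):
        seq = random_sequence(DNA, 25, rng=rng)
        for big_r in (1, 2, 3):
            params = CodingParams(R=big_r)
            coded = encode_sequence(seq, params, DNA)
            assert align_row(coded, coded, big_r).values.tolist() == [1] * 25

    def test_single_substitution_k2_r1_pattern(self):
        # one substitution at position 3 zeroes position 3 (self-label
        # differs) and position 5 (its nearby-label looks back k=2 to
        # the mutated character); compensation via position 7 recovers
        # position 5 but leaves the genuine mutation at 3 untouched
        params = CodingParams(R=1, k=2)
        c1 = encode_sequence("TRAVSQLW", params, PROTEIN)
        c2 = encode_sequence("TREVSQLW", params, PROTEIN)
        raw = align_row(c1, c2, 1)
        assert raw.values.tolist() == [1, 1, 0, 1, 0, 1, 1, 1]
        assert compensate(raw, 2).tolist() == [1, 1, 0, 1, 1, 1, 1, 1]

    def test_matches_nested_loop_evaluation(self, rng):
        # random length-30 coded pairs against a brute-force (j, x) loop
        for big_r in (1, 2, 3):
            params = CodingParams(R=big_r)
            s1 = random_sequence(DNA, 30, rng=rng)
            s2 = random_sequence(DNA, 30, rng=rng)
            c1 = encode_sequence(s1, params, DNA)
            c2 = encode_sequence(s2, params, DNA)
            got = align_row(c1, c2, big_r).values.tolist()
            want = []
            for j in range(30):
                hit = 0
                for x in range(j - big_r, j + big_r + 1):
                    if 0 <= x < 30 and c1.entries[j] == c2.entries[x]:
                        hit = 1
                want.append(hit)
            assert got == want

    def test_invalid_r_rejected(self):
        params = CodingParams(R=1, k=2)
        coded = encode_sequence("ACGT", params, DNA)
        with pytest.raises(ValueError, match="R"):
            align_row(coded, coded, 0)


class TestCompensate:
    def test_all_ones_is_fixed_point(self):
        ones = np.ones(10, dtype=np.uint8)
        assert compensate(ones, 3).tolist() == [1] * 10

    def test_random_vectors_against_direct_or(self, rng):
        for _ in range(25):
            vec = rng.integers(0, 2, size=20).astype(np.uint8)
            k = int(rng.integers(1, 20))
            got = compensate(vec, k).tolist()
            want = [
                int(vec[i] or (vec[i + k] if i + k < 20 else 0))
                for i in range(20)
            ]
            assert got == want

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            compensate(np.ones(5, dtype=np.uint8), 6)


class TestHeliosAlign:
    def test_identical_sequences_all_ones(self, default_params, rng):
        seq = random_sequence(PROTEIN, 40, rng=rng)
        ind = helios_align(seq, seq, default_params, PROTEIN)
        assert ind.rows.min() == 1

    def test_single_substitution_zero_in_both_rows(self):
        params = CodingParams(R=1, k=2)
        ind = helios_align("TRAVSQLW", "TREVSQLW", params, PROTEIN)
        assert ind.rows[0].tolist() == [1, 1, 0, 1, 1, 1, 1, 1]
        assert ind.rows[1].tolist() == [1, 1, 0, 1, 1, 1, 1, 1]

    def test_symmetry_of_the_two_passes(self, default_params, rng):
        for _ in range(10):
            s1 = random_sequence(DNA, 30, rng=rng)
            s2 = random_sequence(DNA, 30, rng=rng)
            fwd = helios_align(s1, s2, default_params, DNA)
            rev = helios_align(s2, s1, default_params, DNA)
            assert np.array_equal(fwd.rows[0], rev.rows[1])
            assert np.array_equal(fwd.rows[1], rev.rows[0])

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(s1=dna_seq, s2=dna_seq)
    def test_monotone_in_r(self, s1, s2):
        # a wider shift window ORs over a superset: 1s never become 0s
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            small = helios_align(s1, s2, CodingParams(R=1, k=3), DNA)
            large = helios_align(s1, s2, CodingParams(R=2, k=3), DNA)
        assert np.all(large.rows >= small.rows)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(s1=dna_seq, s2=dna_seq)
    def test_equals_literal_loop_transcription(self, s1, s2):
        params = CodingParams(R=2, k=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ind = helios_align(s1, s2, params, DNA)
        row1, row2 = oracle_indicator(s1, s2, params, DNA)
        assert ind.rows[0].tolist() == row1
        assert ind.rows[1].tolist() == row2

    def test_spaced_substitutions_zero_exactly_at_sites(self, rng):
        # substitutions mutually separated by more than k leave zeros
        # exactly at the substituted positions in both rows
        params = CodingParams(R=1, k=2)
        s1 = "ARNDCQEGHILKMFPSTWYV" * 2
        s2 = list(s1)
        sites = [5, 15, 25, 35]  # 1-based, spacing 10 > k
        for p in sites:
            s2[p - 1] = "W" if s1[p - 1] != "W" else "Y"
        ind = helios_align(s1, "".join(s2), params, PROTEIN)
        for row in ind.rows:
            assert [i + 1 for i, b in enumerate(row) if not b] == sites

    def test_length_difference_beyond_r_warns(self, default_params):
        with pytest.warns(UserWarning, match="length difference"):
            helios_align("ACGTACGTACGTACGT", "ACGTA", default_params, DNA)

    def test_empty_sequence_rejected(self, default_params):
        with pytest.raises(ValueError):
            helios_align("", "ACGT", default_params, DNA)
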