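"""Homology metrics and classification metrics."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helios import (
    ConfusionCounts,
    ScoringScheme,
    alignment_score,
    classification_metrics,
    confusion,
    identity,
    similarity,
)
from helpers import ga

SCHEME = ScoringScheme()


class TestIdentity:
    def test_identical_sequences_are_100(self):
        assert identity(ga("MKTAYI", "MKTAYI")) == 100.0

    def test_nine_of_ten_columns(self):
        aln = ga("AAAAAAAAAA", "AAAAAAAAAC")
        assert identity(aln) == 90.0

    def test_all_mutation_is_zero(self):
        assert identity(ga("AAAA", "CCCC")) == 0.0

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            identity(ga("", ""))

    def test_shorter_sequence_denominator_switch(self):
        aln = ga("ACGT--", "ACGTAC")
        assert identity(aln) == pytest.approx(100 * 4 / 6)
        assert identity(aln, denominator="shorter") == 100.0


class TestSimilarity:
    def test_within_group_column_counts(self):
        # L and I share the aliphatic group GAVLI
        assert similarity(ga("L", "I"), SCHEME) == 100.0

    def test_three_identical_one_group_two_cross(self):
        # A=A, C=C, W=W identical; F~Y within FYW; L/K and D/P cross-group
        aln = ga("ACWFLD", "ACWYKP")
        assert similarity(aln, SCHEME) == pytest.approx(66.67, abs=0.01)
        assert identity(aln) == 50.0

    def test_nucleotide_kind_equals_identity(self):
        aln = ga("ACGT", "ACGA")
        assert similarity(aln, kind="dna") == identity(aln) == 75.0

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError, match="'B'"):
            similarity(ga("B", "A"), SCHEME)

    def test_groups_partition_the_twenty_residues(self):
        residues = "".join(SCHEME.similarity_groups)
        assert sorted(residues) == sorted("ACDEFGHIKLMNPQRSTVWY")


class TestAlignmentScore:
    def test_self_alignment_is_diagonal_sum(self):
        seq = "MKTAYIAKQR"
        expected = sum(SCHEME.score(c, c) for c in seq)
        assert alignment_score(ga(seq, seq), SCHEME) == expected

    def test_gap_run_of_three_costs_eleven(self):
        base = ga("MKTAYI", "MKTAYI")
        gapped = ga("MKTAYIQQQ", "MKTAYI---")
        assert alignment_score(gapped, SCHEME) == alignment_score(base, SCHEME) - 11.0

    def test_two_separate_runs_each_pay_opening(self):
        aln = ga("MK-TA-YI", "MKQTAQYI")
        no_gaps = sum(SCHEME.score(c, c) for c in "MKTAYI")
        assert alignment_score(aln, SCHEME) == no_gaps - 20.0

    def test_empty_alignment_scores_zero(self):
        assert alignment_score(ga("", ""), SCHEME) == 0.0

    def test_zero_gap_penalties_reduce_to_substitution_sum(self):
        scheme = ScoringScheme(gap_open=0.0, gap_extend=0.0)
        aln = ga("MK-TA", "MKQTA")
        assert alignment_score(aln, scheme) == sum(
            SCHEME.score(a, b)
            for a, b in zip(aln.aligned_s1, aln.aligned_s2)
            if "-" not in (a, b)
        )


class TestConfusion:
    def test_perfect_agreement(self):
        aln = ga("MKTA", "MKTA")
        c = confusion(aln, aln)
        assert (c.TP, c.FP, c.FN) == (4, 0, 0)
        assert c.total == 16
        assert all(v == 1.0 for v in classification_metrics(c).values())

    def test_shifted_alignment_counts_by_grid_enumeration(self):
        # reference pairs the diagonal; the test alignment slips a gap:
        # test pairs {(1,1), (3,2), (4,3)} on the 4x4 grid
        reference = ga("MKTA", "MKTA")
        test = ga("MKTA-", "M-KTA")
        c = confusion(test, reference)
        assert (c.TP, c.FP, c.FN, c.TN) == (1, 2, 3, 10)

    def test_different_sequences_rejected(self):
        with pytest.raises(ValueError, match="same sequences"):
            confusion(ga("MKTA", "MKTA"), ga("MKTC", "MKTC"))

    def test_empty_test_alignment_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            confusion(ga("", ""), ga("", ""))


class TestClassificationMetrics:
    def test_worked_counts(self):
        m = classification_metrics(ConfusionCounts(TP=3, TN=11, FP=1, FN=1))
        assert m["F_score"] == pytest.approx(0.75)
        assert m["ACC"] == pytest.approx(0.875)
        assert m["SEN"] == pytest.approx(0.75)
        assert m["PPV"] == pytest.approx(0.75)

    def test_balanced_counts_give_zero_mcc(self):
        m = classification_metrics(ConfusionCounts(TP=5, TN=5, FP=5, FN=5))
        assert m["MCC"] == 0.0

    def test_zero_denominators_are_undefined_not_zero(self):
        m = classification_metrics(ConfusionCounts(TP=0, TN=4, FP=0, FN=0))
        assert math.isnan(m["SEN"]) and math.isnan(m["PPV"])
        assert m["Spec"] == 1.0

    @settings(max_examples=100, derandomize=True)
    @given(st.tuples(*[st.integers(0, 50)] * 4))
    def test_bounds(self, counts):
        tp, tn, fp, fn = counts
        m = classification_metrics(ConfusionCounts(tp, tn, fp, fn))
        for key in ("SEN", "Spec", "ACC", "PPV", "NPV", "F_score"):
            assert math.isnan(m[key]) or 0.0 <= m[key] <= 1.0
        assert math.isnan(m["MCC"]) or -1.0 <= m["MCC"] <= 1.0


@settings(max_examples=60, derandomize=True)
@given(st.lists(st.sampled_from("ACDEFGHIKLMNPQRSTVWY"), min_size=1, max_size=25),
       st.lists(st.sampled_from("ACDEFGHIKLMNPQRSTVWY"), min_size=1, max_size=25))
def test_similarity_never_below_identity(res1, res2):
    n = min(len(res1), len(res2))
    aln = ga("".join(res1[:n]), "".join(res2[:n]))
    assert similarity(aln, SCHEME) >= identity(aln)
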