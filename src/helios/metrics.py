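"""Homology metrics on gapped alignments and classification metrics
between a test alignment and a reference alignment.

Homology side: Identity is the percentage of alignment columns whose
two residues are identical; Similarity additionally credits columns
whose residues fall in the same physicochemical group (GAVLI, FYW,
STCM, KRH, DENQ, P); the Alignment Score sums BLOSUM62 substitution
scores over residue columns plus affine gap penalties (open -10,
extend -0.5; the first character of a gap run is charged the opening
penalty and each further character the extension penalty).

Classification side: a test alignment is compared with a reference
alignment over the full N x M residue-pairing grid of the two ungapped
sequences.  "Positive" means residue i of S1 is paired with residue j
of S2; TP/FP/FN/TN count grid cells by agreement, and the usual
sensitivity/specificity/accuracy/PPV/NPV/MCC/F-score formulas follow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from Bio.Align import substitution_matrices

from .interpret import GAP, GappedAlignment

__all__ = [
    "SIMILARITY_GROUPS",
    "ScoringScheme",
    "ConfusionCounts",
    "HomologyReport",
    "identity",
    "similarity",
    "alignment_score",
    "homology_report",
    "confusion",
    "classification_metrics",
]

#: Physicochemical amino-acid groups used by the Similarity metric.
SIMILARITY_GROUPS: tuple[str, ...] = ("GAVLI", "FYW", "STCM", "KRH", "DENQ", "P")


def _load_blosum62():
    return substitution_matrices.load("BLOSUM62")


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix + affine gap penalties + similarity groups.

    Defaults: BLOSUM62, gap open -10, gap extend -0.5 (stored as the
    signed penalty added to the score), and the six standard groups.
    """

    substitution_matrix: object = field(default_factory=_load_blosum62)
    gap_open: float = -10.0
    gap_extend: float = -0.5
    similarity_groups: tuple[str, ...] = SIMILARITY_GROUPS

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for group in self.similarity_groups:
            if seen & set(group):
                raise ValueError("similarity groups must be disjoint")
            seen |= set(group)

    def score(self, a: str, b: str) -> float:
        return float(self.substitution_matrix[a, b])

    def group_of(self, residue: str) -> str | None:
        for group in self.similarity_groups:
            if residue in group:
                return group
        return None


def _check_nonempty(aln: GappedAlignment) -> None:
    if len(aln) == 0:
        raise ValueError("metrics are undefined on a zero-length alignment")


def identity(aln: GappedAlignment, *, denominator: str = "columns") -> float:
    """Percentage of columns with identical (non-gap) residues.

    ``denominator`` is "columns" (alignment length, the default) or
    "shorter" (length of the shorter ungapped sequence).
    """
    _check_nonempty(aln)
    matched = sum(
        1
        for a, b in zip(aln.aligned_s1, aln.aligned_s2)
        if a == b and a != GAP
    )
    if denominator == "columns":
        denom = len(aln)
    elif denominator == "shorter":
        denom = min(len(aln.ungapped_s1), len(aln.ungapped_s2))
    else:
        raise ValueError("denominator must be 'columns' or 'shorter'")
    return 100.0 * matched / denom


def similarity(
    aln: GappedAlignment,
    scheme: ScoringScheme | None = None,
    *,
    kind: str = "protein",
    denominator: str = "columns",
) -> float:
    """Percentage of columns identical or within one similarity group.

    Only meaningful for protein alignments; for nucleotide alignments
    (``kind`` "dna"/"rna") there are no groups and similarity equals
    identity.  Protein residues outside the 20-letter set are rejected.
    """
    _check_nonempty(aln)
    if kind.lower() in ("dna", "rna"):
        return identity(aln, denominator=denominator)
    if scheme is None:
        scheme = ScoringScheme()
    valid = set("".join(scheme.similarity_groups))
    similar = 0
    for a, b in zip(aln.aligned_s1, aln.aligned_s2):
        if a == GAP or b == GAP:
            continue
        if a not in valid or b not in valid:
            bad = a if a not in valid else b
            raise ValueError(f"residue {bad!r} is outside the 20-symbol amino set")
        if a == b or scheme.group_of(a) == scheme.group_of(b):
            similar += 1
    if denominator == "columns":
        denom = len(aln)
    elif denominator == "shorter":
        denom = min(len(aln.ungapped_s1), len(aln.ungapped_s2))
    else:
        raise ValueError("denominator must be 'columns' or 'shorter'")
    return 100.0 * similar / denom


def alignment_score(aln: GappedAlignment, scheme: ScoringScheme | None = None) -> float:
    """Substitution-sum plus affine gap penalties over a gapped alignment.

    Each maximal run of gap characters in either row contributes
    ``gap_open + gap_extend * (run_length - 1)`` (both negative).
    An empty alignment scores 0.
    """
    if scheme is None:
        scheme = ScoringScheme()
    score = 0.0
    for a, b in zip(aln.aligned_s1, aln.aligned_s2):
        if a != GAP and b != GAP:
            score += scheme.score(a, b)
    for row in (aln.aligned_s1, aln.aligned_s2):
        run = 0
        for ch in row + "x":  # sentinel flushes a trailing run
            if ch == GAP:
                run += 1
            elif run:
                score += scheme.gap_open + scheme.gap_extend * (run - 1)
                run = 0
    return score


@dataclass(frozen=True)
class HomologyReport:
    identity_pct: float
    similarity_pct: float
    alignment_score: float


def homology_report(
    aln: GappedAlignment,
    scheme: ScoringScheme | None = None,
    *,
    kind: str = "protein",
) -> HomologyReport:
    if scheme is None:
        scheme = ScoringScheme()
    return HomologyReport(
        identity_pct=identity(aln),
        similarity_pct=similarity(aln, scheme, kind=kind),
        alignment_score=alignment_score(aln, scheme),
    )


@dataclass(frozen=True)
class ConfusionCounts:
    """Residue-pairing confusion counts over the N x M grid."""

    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def _aligned_pairs(aln: GappedAlignment) -> set[tuple[int, int]]:
    pairs = set()
    i = j = 0
    for a, b in zip(aln.aligned_s1, aln.aligned_s2):
        if a != GAP and b != GAP:
            i += 1
            j += 1
            pairs.add((i, j))
        elif b == GAP:
            i += 1
        else:
            j += 1
    return pairs


def confusion(test: GappedAlignment, reference: GappedAlignment) -> ConfusionCounts:
    """Compare which residue pairs two alignments declare aligned.

    Both alignments must be over the same pair of ungapped sequences.
    """
    if len(test) == 0:
        raise ValueError("empty test alignment")
    if (test.ungapped_s1, test.ungapped_s2) != (
        reference.ungapped_s1,
        reference.ungapped_s2,
    ):
        raise ValueError(
            "test and reference alignments are not over the same sequences"
        )
    n = len(test.ungapped_s1)
    m = len(test.ungapped_s2)
    t = _aligned_pairs(test)
    r = _aligned_pairs(reference)
    tp = len(t & r)
    fp = len(t - r)
    fn = len(r - t)
    tn = n * m - tp - fp - fn
    return ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def classification_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Sensitivity, specificity, accuracy, PPV, NPV, MCC and F-score.

    Metrics with a zero denominator are reported as NaN (undefined),
    never as 0.
    """
    tp, tn, fp, fn = c.TP, c.TN, c.FP, c.FN
    mcc_den = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    return {
        "SEN": _ratio(tp, tp + fn),
        "Spec": _ratio(tn, tn + fp),
        "ACC": _ratio(tp + tn, c.total),
        "PPV": _ratio(tp, tp + fp),
        "NPV": _ratio(tn, tn + fn),
        "MCC": (tp * tn - fp * fn) / mcc_den if mcc_den > 0 else math.nan,
        "F_score": _ratio(2 * tp, 2 * tp + fp + fn),
    }
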