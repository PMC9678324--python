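"""Turning the 2xN indicator matrix into calls and a gapped alignment.

Row 1 of the indicator matrix states, for each character of S1, whether
it has a counterpart in S2; row 2 does the same for S2.  Reading the
bit pair at a position: (1,1) match, (0,0) mutation, and a mixed pair
an indel -- the sequence whose row shows 0 carries an unmatched extra
character.

``decode_gapped`` realises those per-character states as a concrete
gapped pairwise alignment with a left-to-right two-pointer sweep, each
pointer consulting its own row.  A mixed state consumes one character
from the zero-row sequence against a gap in the other; by default the
gap is therefore placed in the sequence whose row entry is nonzero,
which is the only reading under which stripping the gaps restores the
original inputs (the placement is flippable for completeness).  The
decode reflects the indicator's calls verbatim -- it makes no attempt
to optimise a score.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .align import IndicatorMatrix

__all__ = [
    "State",
    "StateCall",
    "GappedAlignment",
    "VariantEvent",
    "call_states",
    "decode_gapped",
    "called_variants",
]

GAP = "-"


class State(str, Enum):
    MATCH = "match"
    MUTATION = "mutation"
    INDEL_S1 = "indel_in_s1"  # extra character in S1, gap in S2
    INDEL_S2 = "indel_in_s2"  # extra character in S2, gap in S1


@dataclass(frozen=True)
class StateCall:
    position: int  # 1-based
    state: State


def call_states(indicator: IndicatorMatrix) -> list[StateCall]:
    """Classify every position of the indicator matrix by its bit pair."""
    calls = []
    for i, (b1, b2) in enumerate(zip(indicator.rows[0], indicator.rows[1]), start=1):
        if b1 and b2:
            state = State.MATCH
        elif not b1 and not b2:
            state = State.MUTATION
        elif b2:  # row 1 zero: S1 carries the unmatched character
            state = State.INDEL_S1
        else:
            state = State.INDEL_S2
        calls.append(StateCall(i, state))
    return calls


@dataclass(frozen=True)
class GappedAlignment:
    """Two equal-length gapped sequences plus per-column state labels."""

    aligned_s1: str
    aligned_s2: str
    column_states: tuple[State, ...]

    def __post_init__(self) -> None:
        if len(self.aligned_s1) != len(self.aligned_s2):
            raise ValueError("gapped rows must have equal length")
        if len(self.column_states) != len(self.aligned_s1):
            raise ValueError("one state label per column required")
        for i, (a, b) in enumerate(zip(self.aligned_s1, self.aligned_s2)):
            if a == GAP and b == GAP:
                raise ValueError(f"column {i + 1} is a gap in both rows")

    def __len__(self) -> int:
        return len(self.aligned_s1)

    @property
    def ungapped_s1(self) -> str:
        return self.aligned_s1.replace(GAP, "")

    @property
    def ungapped_s2(self) -> str:
        return self.aligned_s2.replace(GAP, "")


def _column_state(a: str, b: str) -> State:
    if a == GAP:
        return State.INDEL_S2
    if b == GAP:
        return State.INDEL_S1
    return State.MATCH if a == b else State.MUTATION


def decode_gapped(
    s1: str,
    s2: str,
    indicator: IndicatorMatrix,
    *,
    gap_in_nonzero_row: bool = True,
) -> GappedAlignment:
    """Realise the indicator matrix as a gapped alignment of s1 and s2.

    Two pointers sweep the sequences left to right; at each step the bit
    of row 1 at the s1 pointer and the bit of row 2 at the s2 pointer
    decide the column: both set or both clear consumes one character
    from each sequence (match / mutation), a mixed pair consumes only
    the zero-row character against a gap.  Any unconsumed tail (e.g.
    from a length difference larger than the shift window) is emitted
    as terminal gap columns so the round-trip invariant always holds.

    Indel runs are emitted left-aligned in the order encountered.
    Column states are labelled from the realised characters, so a
    position whose bits were corrupted by a neighbouring event still
    gets the scientifically right label when the pairing is unaffected.
    """
    s1, s2 = s1.upper(), s2.upper()
    n1, n2 = len(s1), len(s2)
    if indicator.lengths != (n1, n2):
        raise ValueError(
            f"indicator was produced for lengths {indicator.lengths}, "
            f"got sequences of lengths {(n1, n2)}"
        )
    if indicator.n < max(n1, n2):
        raise ValueError(
            f"indicator has {indicator.n} columns but the longer input "
            f"has {max(n1, n2)} characters (first inconsistent column "
            f"{indicator.n + 1})"
        )
    row1, row2 = indicator.rows
    a1, a2 = [], []
    p1 = p2 = 0
    while p1 < n1 and p2 < n2:
        b1, b2 = bool(row1[p1]), bool(row2[p2])
        if b1 == b2:  # match or mutation: consume one character of each
            a1.append(s1[p1])
            a2.append(s2[p2])
            p1 += 1
            p2 += 1
        elif (not b1) == gap_in_nonzero_row:
            a1.append(s1[p1])  # extra character in s1, gap opposite
            a2.append(GAP)
            p1 += 1
        else:
            a1.append(GAP)
            a2.append(s2[p2])
            p2 += 1
    # terminal gap columns for whichever tail remains
    a1.extend(s1[p1:])
    a2.extend(GAP * (n1 - p1))
    a1.extend(GAP * (n2 - p2))
    a2.extend(s2[p2:])
    aligned_s1, aligned_s2 = "".join(a1), "".join(a2)
    states = tuple(_column_state(a, b) for a, b in zip(aligned_s1, aligned_s2))
    return GappedAlignment(aligned_s1, aligned_s2, states)


@dataclass(frozen=True)
class VariantEvent:
    """One substitution/insertion/deletion, in s1 (original) coordinates.

    ``position`` is 1-based on the ungapped s1: the substituted or first
    deleted character for substitutions/deletions, and for insertions
    the s1 character *after which* the payload is inserted (0 = before
    the first character).  ``payload`` holds the new, inserted, or
    deleted characters respectively.
    """

    kind: str  # "substitution" | "insertion" | "deletion"
    position: int
    payload: str


def called_variants(aln: GappedAlignment) -> tuple[VariantEvent, ...]:
    """Extract the variant events implied by a gapped alignment.

    Treats s1 as the original and s2 as the derived sequence; adjacent
    same-kind columns merge into single run events (left-aligned).
    """
    events: list[VariantEvent] = []
    origin = 0  # s1 characters consumed
    run_kind: str | None = None
    run_pos = 0
    run_payload: list[str] = []

    def flush() -> None:
        nonlocal run_kind, run_payload
        if run_kind is not None:
            events.append(VariantEvent(run_kind, run_pos, "".join(run_payload)))
            run_kind, run_payload = None, []

    for a, b in zip(aln.aligned_s1, aln.aligned_s2):
        if a != GAP and b != GAP:
            flush()
            origin += 1
            if a != b:
                events.append(VariantEvent("substitution", origin, b))
        elif b == GAP:  # s1 character absent from s2
            if run_kind != "deletion":
                flush()
                run_kind, run_pos = "deletion", origin + 1
            run_payload.append(a)
            origin += 1
        else:  # a == GAP: character inserted into s2
            if run_kind != "insertion":
                flush()
                run_kind, run_pos = "insertion", origin
            run_payload.append(b)
    flush()
    return tuple(events)
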