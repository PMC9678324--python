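"""Shared test utilities: tiny constructors and independent oracles.

The oracles here are deliberate re-derivations from first principles
(literal loops, exhaustive enumeration) so they stay independent of the
library code paths they are used to check.
"""

from __future__ import annotations

import math

from helios import GappedAlignment
from helios.interpret import GAP, State


def ga(a1: str, a2: str) -> GappedAlignment:
    """Build a GappedAlignment from two gapped strings."""
    states = []
    for a, b in zip(a1, a2):
        if a == GAP:
            states.append(State.INDEL_S2)
        elif b == GAP:
            states.append(State.INDEL_S1)
        else:
            states.append(State.MATCH if a == b else State.MUTATION)
    return GappedAlignment(a1, a2, tuple(states))


# ---------------------------------------------------------------------------
# Literal-loop oracle for the shift-compare indicator matrix
# ---------------------------------------------------------------------------


def oracle_indicator(s1: str, s2: str, params, alphabet):
    """Direct nested-loop transcription of the coding + two-pass method.

    Codes each sequence with a circular lookback over its own length,
    compares entry j of the fixed sequence with entries [j-R, j+R] of
    the sliding one (no wrap of the window), aggregates with OR, and
    compensates entry i with entry i+k (no wrap).  Positions past a
    sequence's own length never match anything.
    """
    k, big_r = params.k, params.R

    def codes(seq):
        seq = seq.upper()
        n = len(seq)
        out = []
        for i in range(n):
            v_self = alphabet.value_map[seq[i]]
            v_near = alphabet.value_map[seq[(i - k) % n]]
            out.append(
                (
                    params.offset_self + params.step_self * v_self,
                    params.offset_nearby + params.step_nearby * v_near,
                )
            )
        return out

    c1, c2 = codes(s1), codes(s2)
    n = max(len(c1), len(c2))

    def one_pass(fixed, sliding):
        raw = [0] * n
        for j in range(n):
            if j >= len(fixed):
                continue
            for x in range(j - big_r, j + big_r + 1):
                if 0 <= x < len(sliding) and fixed[j] == sliding[x]:
                    raw[j] = 1
        return [raw[i] | (raw[i + k] if i + k < n else 0) for i in range(n)]

    return one_pass(c1, c2), one_pass(c2, c1)


# ---------------------------------------------------------------------------
# Exhaustive-enumeration oracle for affine-gap alignment scores
# ---------------------------------------------------------------------------


def _score_columns(cols, scheme) -> float:
    total = 0.0
    for a, b in cols:
        if a != GAP and b != GAP:
            total += scheme.score(a, b)
    for row in (0, 1):
        run = 0
        for col in cols + [("x", "x")]:
            if col[row] == GAP:
                run += 1
            elif run:
                total += scheme.gap_open + scheme.gap_extend * (run - 1)
                run = 0
    return total


def enumerate_global_score(s1: str, s2: str, scheme) -> float:
    """Best global affine-gap score by enumerating every alignment."""
    best = -math.inf

    def rec(i, j, cols):
        nonlocal best
        if i == len(s1) and j == len(s2):
            best = max(best, _score_columns(cols, scheme))
            return
        if i < len(s1) and j < len(s2):
            rec(i + 1, j + 1, cols + [(s1[i], s2[j])])
        if i < len(s1):
            rec(i + 1, j, cols + [(s1[i], GAP)])
        if j < len(s2):
            rec(i, j + 1, cols + [(GAP, s2[j])])

    rec(0, 0, [])
    return best


def enumerate_local_score(s1: str, s2: str, scheme) -> float:
    """Best local score: every substring pair, globally enumerated."""
    best = 0.0
    for i1 in range(len(s1)):
        for i2 in range(i1 + 1, len(s1) + 1):
            for j1 in range(len(s2)):
                for j2 in range(j1 + 1, len(s2) + 1):
                    best = max(
                        best,
                        enumerate_global_score(s1[i1:i2], s2[j1:j2], scheme),
                    )
    return best
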