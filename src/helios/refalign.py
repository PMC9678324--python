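"""Affine-gap dynamic-programming aligners used as comparison oracles.

Gotoh three-state recurrences (match state plus one insertion state per
sequence) with the same gap convention as the metrics module: the first
character of a gap run is charged the opening penalty and each further
character the extension penalty, so scores are directly comparable with
``metrics.alignment_score``.  Traceback ties break deterministically in
the order diagonal > up > left.  Clarity over speed: plain-Python
matrices, no banding or SIMD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .interpret import GAP, GappedAlignment, _column_state
from .metrics import ScoringScheme

__all__ = ["DPResult", "needleman_wunsch", "smith_waterman"]

NEG = -math.inf
_M, _IX, _IY, _START = 0, 1, 2, 3  # Ix: gap in s2 ("up"); Iy: gap in s1 ("left")


@dataclass(frozen=True)
class DPResult:
    alignment: GappedAlignment
    score: float
    mode: str  # "global" | "local"


def _argmax3(m: float, ix: float, iy: float) -> tuple[float, int]:
    # preference order on ties: diagonal/match > up > left
    if m >= ix and m >= iy:
        return m, _M
    if ix >= iy:
        return ix, _IX
    return iy, _IY


def _build(cols: list[tuple[str, str]]) -> GappedAlignment:
    a1 = "".join(c[0] for c in cols)
    a2 = "".join(c[1] for c in cols)
    states = tuple(_column_state(a, b) for a, b in cols)
    return GappedAlignment(a1, a2, states)


def needleman_wunsch(
    s1: str, s2: str, scheme: ScoringScheme | None = None
) -> DPResult:
    """Optimal global alignment with affine gaps; end gaps penalised."""
    if scheme is None:
        scheme = ScoringScheme()
    s1, s2 = s1.upper(), s2.upper()
    if not s1 or not s2:
        raise ValueError("sequences must be non-empty")
    n, m = len(s1), len(s2)
    go, ge = scheme.gap_open, scheme.gap_extend

    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]
    pM = [[_START] * (m + 1) for _ in range(n + 1)]
    pIx = [[_START] * (m + 1) for _ in range(n + 1)]
    pIy = [[_START] * (m + 1) for _ in range(n + 1)]

    M[0][0] = 0.0
    for i in range(1, n + 1):
        Ix[i][0] = go + ge * (i - 1)
        pIx[i][0] = _M if i == 1 else _IX
    for j in range(1, m + 1):
        Iy[0][j] = go + ge * (j - 1)
        pIy[0][j] = _M if j == 1 else _IY

    for i in range(1, n + 1):
        a = s1[i - 1]
        for j in range(1, m + 1):
            sub = scheme.score(a, s2[j - 1])
            prev, state = _argmax3(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
            M[i][j] = sub + prev
            pM[i][j] = state
            Ix[i][j], pIx[i][j] = _argmax3(
                M[i - 1][j] + go, Ix[i - 1][j] + ge, Iy[i - 1][j] + go
            )
            Iy[i][j], pIy[i][j] = _argmax3(
                M[i][j - 1] + go, Ix[i][j - 1] + go, Iy[i][j - 1] + ge
            )

    score, state = _argmax3(M[n][m], Ix[n][m], Iy[n][m])
    cols: list[tuple[str, str]] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == _M:
            cols.append((s1[i - 1], s2[j - 1]))
            state = pM[i][j]
            i, j = i - 1, j - 1
        elif state == _IX:
            cols.append((s1[i - 1], GAP))
            state = pIx[i][j]
            i -= 1
        else:
            cols.append((GAP, s2[j - 1]))
            state = pIy[i][j]
            j -= 1
    cols.reverse()
    return DPResult(_build(cols), score, "global")


def smith_waterman(
    s1: str, s2: str, scheme: ScoringScheme | None = None
) -> DPResult:
    """Optimal local alignment with affine gaps (score floor 0).

    Under all-negative substitution scores the optimum is the empty
    alignment with score 0.
    """
    if scheme is None:
        scheme = ScoringScheme()
    s1, s2 = s1.upper(), s2.upper()
    if not s1 or not s2:
        raise ValueError("sequences must be non-empty")
    n, m = len(s1), len(s2)
    go, ge = scheme.gap_open, scheme.gap_extend

    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]
    pM = [[_START] * (m + 1) for _ in range(n + 1)]
    pIx = [[_START] * (m + 1) for _ in range(n + 1)]
    pIy = [[_START] * (m + 1) for _ in range(n + 1)]

    best, bi, bj = 0.0, 0, 0
    for i in range(1, n + 1):
        a = s1[i - 1]
        for j in range(1, m + 1):
            sub = scheme.score(a, s2[j - 1])
            prev, state = _argmax3(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
            if prev <= 0.0:  # restart a fresh local alignment here
                prev, state = 0.0, _START
            M[i][j] = sub + prev
            pM[i][j] = state
            Ix[i][j], pIx[i][j] = _argmax3(
                M[i - 1][j] + go, Ix[i - 1][j] + ge, Iy[i - 1][j] + go
            )
            Iy[i][j], pIy[i][j] = _argmax3(
                M[i][j - 1] + go, Ix[i][j - 1] + go, Iy[i][j - 1] + ge
            )
            if M[i][j] > best:
                best, bi, bj = M[i][j], i, j

    if best <= 0.0:
        return DPResult(GappedAlignment("", "", ()), 0.0, "local")

    cols: list[tuple[str, str]] = []
    i, j, state = bi, bj, _M
    while True:
        if state == _M:
            cols.append((s1[i - 1], s2[j - 1]))
            state = pM[i][j]
            i, j = i - 1, j - 1
            if state == _START:
                break
        elif state == _IX:
            cols.append((s1[i - 1], GAP))
            state = pIx[i][j]
            i -= 1
        else:
            cols.append((GAP, s2[j - 1]))
            state = pIy[i][j]
            j -= 1
    cols.reverse()
    return DPResult(_build(cols), best, "local")
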