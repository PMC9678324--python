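"""Shift-compare-aggregate alignment core.

The method runs two symmetric passes.  The S1-pass holds the coded S1
vector fixed and compares it against the coded S2 vector at every
horizontal shift in [-R, +R]; entry j of the pass outcome is 1 iff some
shifted position x in [j-R, j+R] carries an identical (self-label,
nearby-label) code pair.  The S2-pass swaps the roles.  A mutation at
position i also corrupts the nearby-label of position i+k, so each raw
outcome is *compensated* by OR-ing entry i with entry i+k before the
two rows are assembled into the 2xN indicator matrix:

    row 1, entry i = 1  <=>  character i of S1 has a counterpart in S2
    row 2, entry i = 1  <=>  character i of S2 has a counterpart in S1

(1,1) marks a match, (0,0) a substitution, and a mixed pair an indel.

Boundary policy: shift positions outside [1, N] contribute nothing (the
comparison window is not circular -- only the coding lookback wraps),
and compensation falls back to the raw entry when i+k runs off the end.
Unequal-length inputs are right-padded with never-matching sentinel
entries to the longer length.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .coding import Alphabet, CodedSequence, CodingParams, DNA, encode_sequence

__all__ = [
    "ComparisonOutcome",
    "IndicatorMatrix",
    "compare_entry",
    "align_row",
    "compensate",
    "helios_align",
]


@dataclass(frozen=True)
class ComparisonOutcome:
    """Aggregated (pre-compensation) outcome of one shift-compare pass."""

    row: int | None
    values: np.ndarray  # length-N uint8 vector of {0,1}


@dataclass(frozen=True)
class IndicatorMatrix:
    """The 2xN binary output of the two compensated passes.

    ``rows[0]`` indexes the characters of S1 and ``rows[1]`` those of
    S2; positions past a sequence's own length (padding of the shorter
    input) carry no information for that row.
    """

    rows: np.ndarray  # shape (2, N), uint8
    params_used: CodingParams
    lengths: tuple[int, int]

    @property
    def n(self) -> int:
        return self.rows.shape[1]


def compare_entry(a: tuple[float, float], b: tuple[float, float]) -> int:
    """1 iff both the self-label and nearby-label codes are identical."""
    return int(a[0] == b[0] and a[1] == b[1])


def _code_arrays(seq) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(seq, CodedSequence):
        return seq.self_codes, seq.nearby_codes
    s, nb = seq
    return np.asarray(s, dtype=float), np.asarray(nb, dtype=float)


def align_row(fixed, sliding, R: int | None = None) -> ComparisonOutcome:
    """One shift-compare-aggregate pass with ``fixed`` held in place.

    ``Out_j = OR over x in [j-R, j+R] (within bounds) of
    [codes of fixed[j] == codes of sliding[x]]``.  The OR saturates, so
    the result does not depend on the order shifts are visited, and a
    larger R can only turn zeros into ones.

    Both inputs must be coded with identical parameters and already be
    of equal length (pad beforehand; NaN codes never match anything).
    """
    fs, fn = _code_arrays(fixed)
    ss, sn = _code_arrays(sliding)
    if R is None:
        if not isinstance(fixed, CodedSequence):
            raise ValueError("R must be given when passing raw code arrays")
        R = fixed.params.R
    if R < 1:
        raise ValueError(f"R must be >= 1, got {R}")
    n = len(fs)
    if len(ss) != n:
        raise ValueError(
            f"coded vectors must have equal length ({n} != {len(ss)}); "
            "pad the shorter input first"
        )
    out = np.zeros(n, dtype=bool)
    for shift in range(-R, R + 1):
        # fixed[j] vs sliding[j + shift] on the overlapping region.
        if shift >= 0:
            if shift >= n:
                continue
            hit = (fs[: n - shift] == ss[shift:]) & (fn[: n - shift] == sn[shift:])
            out[: n - shift] |= hit
        else:
            if -shift >= n:
                continue
            hit = (fs[-shift:] == ss[: n + shift]) & (fn[-shift:] == sn[: n + shift])
            out[-shift:] |= hit
    return ComparisonOutcome(row=None, values=out.astype(np.uint8))


def compensate(outcome, k: int) -> np.ndarray:
    """Recover false mismatches: entry i becomes ``Out_i OR Out_{i+k}``.

    A substitution at i corrupts the nearby-label of i+k, zeroing that
    entry too; the character at i+k still has its true counterpart at
    i+k, detected through the entry at i+2k in turn, so OR-ing i with
    i+k restores it.  A genuine mutation at i stays 0 because both its
    own entry and the entry at i+k are 0.  Where i+k exceeds N the
    entry falls back to Out_i alone (the window is not circular).
    """
    values = outcome.values if isinstance(outcome, ComparisonOutcome) else outcome
    values = np.asarray(values)
    n = len(values)
    if not 1 <= k <= n:
        raise ValueError(f"k must satisfy 1 <= k <= N={n}, got {k}")
    result = values.astype(bool).copy()
    if k < n:
        result[: n - k] |= values[k:].astype(bool)
    return result.astype(np.uint8)


_PAD_A = (math.inf, math.inf)   # sentinels compare unequal to all real codes
_PAD_B = (-math.inf, -math.inf)  # and to each other


def _padded(coded: CodedSequence, n: int, pad: tuple[float, float]):
    s = np.full(n, pad[0], dtype=float)
    nb = np.full(n, pad[1], dtype=float)
    s[: len(coded)] = coded.self_codes
    nb[: len(coded)] = coded.nearby_codes
    return s, nb


def helios_align(
    s1: str,
    s2: str,
    params: CodingParams | None = None,
    alphabet: Alphabet = DNA,
) -> IndicatorMatrix:
    """Code both sequences and run the two compensated passes.

    Returns the 2xN indicator matrix (N = longer input length).  The
    number of consecutive indels between the inputs is assumed not to
    exceed R; in particular a warning is emitted when R is smaller than
    the length difference, which no shift window can bridge.
    """
    if params is None:
        params = CodingParams()
    c1 = encode_sequence(s1, params, alphabet)
    c2 = encode_sequence(s2, params, alphabet)
    n = max(len(c1), len(c2))
    diff = abs(len(c1) - len(c2))
    if params.R < diff:
        warnings.warn(
            f"R={params.R} is smaller than the length difference {diff}; "
            "trailing characters of the longer sequence cannot be matched",
            stacklevel=2,
        )
    a1 = _padded(c1, n, _PAD_A)
    a2 = _padded(c2, n, _PAD_B)
    row1 = compensate(align_row(a1, a2, params.R), params.k)
    row2 = compensate(align_row(a2, a1, params.R), params.k)
    return IndicatorMatrix(
        rows=np.stack([row1, row2]),
        params_used=params,
        lengths=(len(c1), len(c2)),
    )
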