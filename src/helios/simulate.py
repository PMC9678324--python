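"""Ground-truthed synthetic inputs: random sequences and variant imposition.

``impose_variants`` plants a requested number of substitutions,
insertions and deletions into a sequence and returns the mutant plus a
machine-readable truth log, emulating a validation protocol in which
variants are imposed by hand and the aligner's calls are checked
against them.

The generator imposes only *cleanly detectable* variants.  The dual
(self-label, nearby-label) code of a character collides with another
position's code whenever both the character and its k-th predecessor
agree, and when such a collision falls inside the +/-R shift window of
an imposed variant, no shift-and-compare scheme can recover the truth
-- the outcome is ambiguous by construction, not by implementation.
For 4-letter alphabets such collisions are common in random sequence
(per-position collision odds 1/16 inside an 2R+1 window), so candidate
event sets are rejection-sampled against an independent literal-loop
evaluation of the coded comparison until the compensated rows equal
the truth pattern exactly.  Events are also kept away from the
sequence ends (outside the circular-lookback wrap region) and mutually
separated, by default by k+1, so the compensation mechanism is
exercised without compound interference.

Randomness comes from ``numpy.random.default_rng`` seeded explicitly;
identical inputs and seed reproduce the identical mutant and log.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .coding import Alphabet, CodingParams, DNA
from .interpret import VariantEvent

__all__ = ["random_sequence", "impose_variants", "replay", "VariantEvent"]


def random_sequence(
    alphabet: Alphabet,
    length: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> str:
    """Uniform i.i.d. sequence of ``length`` characters over ``alphabet``."""
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    if rng is None:
        rng = np.random.default_rng(seed)
    idx = rng.integers(0, alphabet.size, size=length)
    return "".join(alphabet.symbols[i] for i in idx)


def replay(seq: str, events: Iterable[VariantEvent]) -> str:
    """Apply a variant log to ``seq``, reproducing the mutant exactly."""
    s = list(seq.upper())
    for ev in sorted(events, key=lambda e: e.position, reverse=True):
        p = ev.position
        if ev.kind == "substitution":
            if len(ev.payload) != 1:
                raise ValueError("substitution payload must be one character")
            s[p - 1] = ev.payload
        elif ev.kind == "deletion":
            removed = "".join(s[p - 1 : p - 1 + len(ev.payload)])
            if removed != ev.payload:
                raise ValueError(
                    f"deletion payload {ev.payload!r} does not match "
                    f"sequence content {removed!r} at position {p}"
                )
            del s[p - 1 : p - 1 + len(ev.payload)]
        elif ev.kind == "insertion":
            s[p:p] = list(ev.payload)
        else:
            raise ValueError(f"unknown event kind {ev.kind!r}")
    return "".join(s)


# ---------------------------------------------------------------------------
# Literal-loop evaluation of the coded comparison, kept deliberately
# independent of the align module so the generator's detectability guard
# does not share code with the pipeline it helps to test.
# ---------------------------------------------------------------------------


def _literal_codes(seq: str, alphabet: Alphabet, params: CodingParams):
    n = len(seq)
    vs = [alphabet.value_map[c] for c in seq]
    return [
        (
            params.offset_self + params.step_self * vs[i],
            params.offset_nearby + params.step_nearby * vs[(i - params.k) % n],
        )
        for i in range(n)
    ]


def _literal_row(fixed, sliding, params: CodingParams) -> list[int]:
    n = max(len(fixed), len(sliding))
    out = [0] * n
    for j in range(min(n, len(fixed))):
        for x in range(j - params.R, j + params.R + 1):
            if 0 <= x < len(sliding) and fixed[j] == sliding[x]:
                out[j] = 1
                break
    k = params.k
    return [out[i] | (out[i + k] if i + k < n else 0) for i in range(n)]


def _literal_rows(s1: str, s2: str, alphabet: Alphabet, params: CodingParams):
    c1 = _literal_codes(s1, alphabet, params)
    c2 = _literal_codes(s2, alphabet, params)
    return _literal_row(c1, c2, params), _literal_row(c2, c1, params)


def _truth_zero_sets(events: Sequence[VariantEvent]):
    """0-based positions that must read 0 in row 1 (s1) and row 2 (s2)."""
    z1: set[int] = set()
    z2: set[int] = set()
    offset = 0  # s2 coordinate minus s1 coordinate, left of the cursor
    for ev in sorted(events, key=lambda e: e.position):
        p = ev.position
        if ev.kind == "substitution":
            z1.add(p - 1)
            z2.add(p - 1 + offset)
        elif ev.kind == "deletion":
            r = len(ev.payload)
            z1.update(range(p - 1, p - 1 + r))
            offset -= r
        else:  # insertion after s1 position p
            r = len(ev.payload)
            z2.update(range(p + offset, p + offset + r))
            offset += r
    return z1, z2


def _detectable(
    s1: str,
    s2: str,
    events: Sequence[VariantEvent],
    alphabet: Alphabet,
    params: CodingParams,
) -> bool:
    row1, row2 = _literal_rows(s1, s2, alphabet, params)
    z1, z2 = _truth_zero_sets(events)
    got1 = {i for i in range(len(s1)) if not row1[i]}
    got2 = {i for i in range(len(s2)) if not row2[i]}
    return got1 == z1 and got2 == z2


def impose_variants(
    seq: str,
    n_sub: int = 0,
    n_ins: int = 0,
    n_del: int = 0,
    *,
    alphabet: Alphabet = DNA,
    params: CodingParams | None = None,
    max_run: int | None = None,
    min_spacing: int | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    max_attempts: int = 1000,
) -> tuple[str, tuple[VariantEvent, ...]]:
    """Impose variants on ``seq`` and return (mutant, truth log).

    Exactly ``n_sub`` substitutions (the new character always differs
    from the original), ``n_ins`` insertions and ``n_del`` deletions,
    with indel run lengths uniform in [1, max_run] (max_run <= R so a
    single shift window can bridge every run) and events mutually
    separated by at least ``min_spacing`` (default k+1).  The log
    replays to the mutant exactly.  Raises when the requested events
    cannot be placed, reporting the counts.
    """
    if params is None:
        params = CodingParams()
    if max_run is None:
        max_run = min(3, params.R)
    if not 1 <= max_run <= params.R:
        raise ValueError(f"max_run must be in [1, R={params.R}], got {max_run}")
    if min_spacing is None:
        min_spacing = params.k + 1
    if rng is None:
        rng = np.random.default_rng(seed)

    seq = seq.upper()
    n = len(seq)
    total = n_sub + n_ins + n_del
    if total == 0:
        return seq, ()

    k, big_r = params.k, params.R
    # keep events clear of the circular-lookback wrap at the head and of
    # the un-compensatable region at the tail
    lo = 2 * k + big_r + 1
    hi = n - (2 * k + big_r + max_run)
    stride = min_spacing + max_run
    capacity = 0 if hi < lo else (hi - lo) // stride + 1
    if total > capacity:
        raise ValueError(
            f"cannot place {total} events (={n_sub} sub + {n_ins} ins + "
            f"{n_del} del) in a length-{n} sequence with spacing "
            f">= {min_spacing} and runs <= {max_run}; capacity is {capacity}"
        )

    kinds = ["substitution"] * n_sub + ["insertion"] * n_ins + ["deletion"] * n_del

    def draw_event(kind: str, p: int) -> VariantEvent:
        if kind == "substitution":
            old = seq[p - 1]
            choices = [c for c in alphabet.symbols if c != old]
            return VariantEvent(kind, p, choices[rng.integers(0, len(choices))])
        run = int(rng.integers(1, max_run + 1))
        if kind == "insertion":
            payload = "".join(
                alphabet.symbols[i]
                for i in rng.integers(0, alphabet.size, size=run)
            )
        else:
            payload = seq[p - 1 : p - 1 + run]
        return VariantEvent(kind, p, payload)

    def span(ev: VariantEvent) -> tuple[int, int]:
        if ev.kind == "deletion":
            return ev.position, ev.position + len(ev.payload) - 1
        return ev.position, ev.position + (ev.kind == "insertion")

    # Events are placed one at a time; each candidate addition must keep
    # the full event set cleanly detectable (checked against the literal
    # rows), so event-event interactions are rejected and resampled too.
    inner_attempts = max(50, max_attempts // max(1, total))
    for _ in range(10):
        order = [kinds[i] for i in rng.permutation(total)]
        events: list[VariantEvent] = []
        for kind in order:
            for _ in range(inner_attempts):
                p = int(rng.integers(lo, hi + 1))
                cand = draw_event(kind, p)
                lo_c, hi_c = span(cand)
                if any(
                    max(lo_c - e_hi, e_lo - hi_c) < min_spacing
                    for e_lo, e_hi in map(span, events)
                ):
                    continue
                trial = events + [cand]
                if _detectable(seq, replay(seq, trial), trial, alphabet, params):
                    events = trial
                    break
            else:
                break  # this event could not be placed; restart from scratch
        if len(events) == total:
            mutant = replay(seq, events)
            return mutant, tuple(sorted(events, key=lambda e: e.position))
    raise ValueError(
        f"no cleanly detectable placement of {total} events (={n_sub} sub + "
        f"{n_ins} ins + {n_del} del) found; try a longer sequence or fewer events"
    )
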