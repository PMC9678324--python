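"""Dual-channel (self-label / nearby-label) sequence coding.

Every character of a DNA, RNA or protein sequence is mapped to an entry
with two numeric codes:

* the *self-label* code depends only on the character itself::

      c_self(i) = offset_self + step_self * V(ch_i)

* the *nearby-label* code depends on the k-th previous character, with
  the sequence treated as circular so the lookback can wrap around::

      c_nearby(i) = offset_nearby + step_nearby * V(ch_{(i-k) mod N})

``V`` is a fixed per-character integer in ``[0, B-1]`` where ``B`` is 4
for nucleotides and 20 for amino acids.  Two coded entries are equal iff
both the character and its k-th predecessor agree, which is what keeps
shift-and-compare alignment from producing false matches inside repeats
such as ``AAAAAA`` or ``ACACAC``.

The default numeric scales mirror the optical realisation of the codes:
self-label codes are modulation wavelengths (450, 460, ... nm at 10 nm
spacing) and nearby-label codes are linear polarisation angles (0, 9,
... degrees), so the worked examples reproduce bit-exactly even though
only code *equality* matters to the alignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Alphabet",
    "CodingParams",
    "CodedSequence",
    "OpticalCodeMap",
    "DNA",
    "RNA",
    "PROTEIN",
    "get_alphabet",
    "char_value",
    "encode_sequence",
    "optical_codes",
]


@dataclass(frozen=True)
class Alphabet:
    """An ordered residue alphabet with its character-value assignment.

    ``value_map`` is a bijection from the upper-case one-letter symbols
    onto ``{0 .. B-1}``.  The nucleotide orders are fixed (A,T,G,C for
    DNA and A,U,G,C for RNA); amino acids use alphabetical one-letter
    order by default, which is arbitrary but deterministic -- only code
    equality ever matters downstream.
    """

    kind: str
    symbols: tuple[str, ...]
    value_map: Mapping[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        vm = {ch: v for v, ch in enumerate(self.symbols)}
        if len(vm) != len(self.symbols):
            raise ValueError("alphabet symbols must be unique")
        object.__setattr__(self, "value_map", vm)

    @property
    def size(self) -> int:
        return len(self.symbols)


DNA = Alphabet("DNA", tuple("ATGC"))
RNA = Alphabet("RNA", tuple("AUGC"))
PROTEIN = Alphabet("protein", tuple("ACDEFGHIKLMNPQRSTVWY"))

_ALPHABETS = {"dna": DNA, "rna": RNA, "protein": PROTEIN}


def get_alphabet(name: str) -> Alphabet:
    """Look up a built-in alphabet by name (case-insensitive)."""
    try:
        return _ALPHABETS[name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown alphabet {name!r}; choose from {sorted(_ALPHABETS)}"
        ) from None


def char_value(alphabet: Alphabet, ch: str, position: int | None = None) -> int:
    """Return the preset integer value V of ``ch`` under ``alphabet``.

    Input is case-insensitive.  Unknown characters (including ambiguity
    codes such as N or X) are rejected with a message naming the
    character and, when known, its 1-based position -- never silently
    skipped.
    """
    try:
        return alphabet.value_map[ch.upper()]
    except KeyError:
        where = "" if position is None else f" at position {position}"
        raise ValueError(
            f"character {ch!r}{where} is not in the {alphabet.kind} alphabet "
            f"({''.join(alphabet.symbols)})"
        ) from None


@dataclass(frozen=True)
class CodingParams:
    """Offsets/steps of the two coding channels plus the k and R knobs.

    Parameters
    ----------
    offset_self, step_self :
        Affine map of the self-label channel.  Defaults (450, 10) put
        self-label codes on the optical wavelength scale in nanometres.
    offset_nearby, step_nearby :
        Affine map of the nearby-label channel.  Defaults (0, 9) put
        nearby-label codes on the polarisation-angle scale in degrees.
    R :
        Maximum number of horizontal shifts in the compare step; also
        the upper bound on the length of a detectable consecutive indel
        run.  Default 4, the functional-validation setting.
    k :
        Lookback distance of the nearby-label code.  Defaults to R + 1.
    """

    offset_self: float = 450.0
    step_self: float = 10.0
    offset_nearby: float = 0.0
    step_nearby: float = 9.0
    R: int = 4
    k: int | None = None

    def __post_init__(self) -> None:
        if self.step_self == 0 or self.step_nearby == 0:
            raise ValueError("coding steps must be nonzero so codes stay distinct")
        if self.R < 1:
            raise ValueError(f"R must be a positive integer, got {self.R}")
        if self.k is None:
            object.__setattr__(self, "k", self.R + 1)
        if self.k < 1:
            raise ValueError(f"k must be a positive integer, got {self.k}")


@dataclass(frozen=True)
class CodedSequence:
    """A sequence together with its per-character dual-code vectors."""

    source: str
    alphabet: Alphabet
    params: CodingParams
    self_codes: np.ndarray
    nearby_codes: np.ndarray

    def __len__(self) -> int:
        return len(self.source)

    @property
    def entries(self) -> list[tuple[float, float]]:
        """The (c_self, c_nearby) pair for every position, in order."""
        return list(zip(self.self_codes.tolist(), self.nearby_codes.tolist()))


def encode_sequence(
    seq: str,
    params: CodingParams | None = None,
    alphabet: Alphabet = DNA,
    *,
    ambiguous: str = "reject",
) -> CodedSequence:
    """Encode ``seq`` into its dual (self-label, nearby-label) vectors.

    The nearby-label of position i (1-based) is taken from position
    i - k with circular wrap, i.e. index arithmetic modulo N, so the
    first k characters borrow their context from the sequence tail.

    ``ambiguous`` controls what happens to characters outside the
    alphabet: ``"reject"`` (default) raises; ``"mask"`` assigns NaN
    codes, which compare unequal to everything -- a never-matches
    entry.  No silent conversion (e.g. U <-> T) is ever performed.
    """
    if params is None:
        params = CodingParams()
    n = len(seq)
    if n == 0:
        raise ValueError("cannot encode an empty sequence")
    if params.k > n:
        raise ValueError(
            f"lookback k={params.k} exceeds the sequence length {n}"
        )
    if ambiguous not in ("reject", "mask"):
        raise ValueError("ambiguous must be 'reject' or 'mask'")

    src = seq.upper()
    values = np.empty(n, dtype=float)
    for i, ch in enumerate(src):
        try:
            values[i] = alphabet.value_map[ch]
        except KeyError:
            if ambiguous == "mask":
                values[i] = math.nan
            else:
                char_value(alphabet, ch, position=i + 1)  # raises

    self_codes = params.offset_self + params.step_self * values
    lookback = np.roll(values, params.k)  # values[(i - k) mod n]
    nearby_codes = params.offset_nearby + params.step_nearby * lookback
    return CodedSequence(src, alphabet, params, self_codes, nearby_codes)


@dataclass(frozen=True)
class OpticalCodeMap:
    """Numeric wavelength/polarisation code tables, one entry per V.

    A pure lookup table: wavelength(V) = 450 + 10 V nanometres within
    [450, 650], polarisation(V) = 9 V degrees within [0, 180].  All
    twenty code pairs exist; nucleotide alphabets use only the first
    four.  No filter physics (bandwidth, cross-talk) is modelled.
    """

    wavelengths: Mapping[int, float]
    polarizations: Mapping[int, float]


def optical_codes(alphabet: Alphabet) -> OpticalCodeMap:
    """Return the wavelength/polarisation code map for ``alphabet``."""
    vs: Sequence[int] = range(alphabet.size)
    return OpticalCodeMap(
        wavelengths={v: 450.0 + 10.0 * v for v in vs},
        polarizations={v: 9.0 * v for v in vs},
    )
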