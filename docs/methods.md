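# Methods notes

## Model and assumptions

The aligner detects variation between two sequences by code equality under
bounded horizontal shifts, not by optimising an objective.  Its guarantees
are therefore *conditional*:

- A substitution is located exactly when the dual code of the affected
  position does not collide with any coded entry of the partner inside the
  ±R shift window.  Two positions collide exactly when both the character
  and its k-th predecessor agree; for a B-letter alphabet and random
  sequence the per-window collision odds are roughly `1 − (1 − 1/B²)^(2R)`
  — negligible for proteins (B = 20) but of order 40 % for DNA/RNA (B = 4)
  at the default R = 4.  Where a collision falls inside the window, the
  shifted copy is indistinguishable from a true counterpart and *no*
  shift-compare scheme can call the site correctly.
- An indel run is recovered when its length is at most R and the
  surrounding k-neighbourhood is collision-free in the same sense.
- The compensation step (`Output_i = Out_i OR Out_{i+k}`) relies on the
  position i+k of a genuinely substituted site being a *false* mismatch;
  events closer than about 2k can therefore interact.

The decode of the indicator matrix into a gapped alignment is a two-pointer
sweep in which each pointer consults its own row.  It makes no attempt at
score-optimal gap placement; it realises the indicator's calls and is exact
only under the conditions above.

## Synthetic data: what the generator emulates

`simulate.impose_variants` emulates a validation protocol in which variants
are imposed *by hand* and then recovered: it plants the requested numbers of
substitutions, insertions and deletions and returns a machine-readable truth
log.  Because hand-imposed validation variants are implicitly chosen to be
recoverable, the generator guarantees the same property explicitly: a
candidate event set is accepted only if an independent literal-loop
evaluation of the coded comparison yields compensated rows whose zeros equal
the truth pattern exactly.  Candidates are placed one at a time with
rejection sampling, kept

- within `[2k+R+1, N−(2k+R+max_run)]`, outside the circular-lookback wrap
  region at the head and the un-compensatable tail,
- mutually separated by at least `min_spacing` (default k+1), so the
  compensation mechanism is exercised without compound interference,
- with substituted characters always different from the original, and indel
  runs of at most `max_run ≤ R` characters.

A green end-to-end test therefore establishes that the *pipeline* (coding,
shifting, compensation, decode, variant extraction) is implemented
correctly on inputs the method can in principle resolve.  It does **not**
establish that arbitrary variants in arbitrary sequence context are called
correctly — for 4-letter alphabets a large fraction of random substitution
sites is unresolvable by construction (see above).  The generator also does
not model realistic evolution: no transition/transversion bias, no
empirical indel length distribution, uniform base composition.

Randomness is `numpy.random.default_rng` (PCG64) seeded explicitly; a
(sequence, parameters, seed) triple reproduces the mutant and log bit for
bit.

## Parameters

| Parameter | Default | Meaning |
| --- | --- | --- |
| `R` | 4 | max shift count; bounds detectable indel run length |
| `k` | R+1 = 5 | nearby-label lookback distance (circular) |
| `offset_self`, `step_self` | 450, 10 | self-label scale (wavelength nm) |
| `offset_nearby`, `step_nearby` | 0, 9 | nearby-label scale (polarisation °) |
| `gap_open`, `gap_extend` | −10, −0.5 | affine penalties, EMBOSS-style |
| aperture `L×W`, switching time `T` | 1024×1024 px, 1e-8 s | performance model |

Only code *equality* matters to the alignment, so the offsets/steps affect
nothing but the printed tables; they default to the optical scales so worked
examples reproduce exactly.  The amino-acid value assignment `V` uses
alphabetical one-letter order (A→0 … Y→19); it is configurable and
irrelevant to correctness for the same reason.

## Numerical and design choices

- **Shift/compensation boundaries.** Only the coding lookback wraps
  circularly.  The comparison window contributes nothing outside `[1, N]`,
  and compensation falls back to `Out_i` when `i+k > N` — wrapping either
  would couple unrelated sequence ends.
- **Unequal lengths.** The shorter coded vector is right-padded with
  sentinel entries (±∞ pairs, distinct per side) that match nothing; a
  warning is emitted when R is smaller than the length difference.
- **Gap placement in the decode.** A mixed bit pair places the gap opposite
  the unmatched extra character, i.e. in the sequence whose row entry is
  nonzero.  This is the only reading under which stripping gaps restores
  the inputs; the inverse reading is available behind a flag.  Indel runs
  are emitted left-aligned; an unconsumed tail becomes terminal gap
  columns so the round trip always holds.
- **Column labels vs bit labels.** `call_states` classifies positions
  strictly by bit pair; the decode labels realised columns by their
  characters, which keeps labels right when a neighbouring event corrupts
  bits without affecting the pairing.
- **Metric denominators.** Identity/Similarity divide by the alignment
  column count by default (switchable to shorter-sequence length): the
  choice is not standardised and is stated rather than guessed.
- **Gap penalty convention.** The first gap character of a run is charged
  the opening penalty, each further character the extension penalty
  (`open + extend·(len−1)`); half-integer scores in benchmark tables
  require the −0.5 to apply per extension character.  The DP aligners use
  the identical convention so scores are directly comparable.
- **Sensitivity formula.** The conventional `SEN = TP/(TP+FN)` is
  implemented.  Metrics with zero denominators are reported as NaN
  ("undefined"), never coerced to 0.
- **Confusion counts** are computed over the full N×M residue-pairing
  grid (a pairing of residue i with residue j is "positive"), which is
  what makes specificity values on ~600-residue proteins come out near
  0.9999 — a column-based definition would not.
- **DP tie-breaks.** Traceback prefers diagonal > up > left; local
  alignments restart whenever the best predecessor is ≤ 0, trimming
  zero-score prefixes.  BLOSUM62 comes from Biopython's bundled copy
  (no network access).
- **Performance model.** The published closed form omits the switching
  time T, yet every published numeric estimate equals `(2NM/(L²W))·T`;
  the T factor is adopted as the contract (erratum note).  Memory is
  reported in pixels (exact) and in MB at 1 byte/pixel.

## Known limitations

- No calling of duplications, inversions or translocations; no multiple
  sequence alignment.
- Indel runs longer than R, variants in collision-prone context, and
  events closer than the compensation reach are outside the method's
  guarantee; the decode still produces *an* alignment (round-trip safe)
  but its calls may be shifted.
- The optical hardware itself (filters, lenses, chiral medium, noise,
  cross-talk) is not simulated; the optical code map is a pure numeric
  table and the performance model is closed-form arithmetic.
- Ambiguity codes (N, X, …) have no defined semantics; they are rejected,
  or optionally masked to never-matching entries.
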