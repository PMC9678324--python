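"""FASTA and alignment I/O. UTF-8, LF line endings, '-' gap character,
1-based coordinates in every user-facing table."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

from Bio.SeqIO.FastaIO import SimpleFastaParser

from .interpret import GAP, GappedAlignment, StateCall, _column_state

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_gapped_fasta",
    "write_alignment",
    "state_calls_tsv",
]

_WIDTH = 60


def read_fasta(path) -> list[tuple[str, str]]:
    """Parse a multi-record FASTA file into (header, sequence) pairs.

    Headers are preserved verbatim (without '>'), wrapped lines joined.
    Files with no records or with empty records are rejected.
    """
    path = Path(path)
    with path.open() as fh:
        records = [(title, seq.replace(" ", "")) for title, seq in SimpleFastaParser(fh)]
    if not records:
        raise ValueError(f"{path}: no FASTA records found (missing '>' header?)")
    for idx, (title, seq) in enumerate(records, 1):
        if not seq:
            raise ValueError(f"{path}: record {idx} ({title!r}) has an empty sequence")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    lines = []
    for title, seq in records:
        lines.append(f">{title}")
        lines.extend(seq[i : i + _WIDTH] for i in range(0, len(seq), _WIDTH))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gapped_fasta(path) -> GappedAlignment:
    """Read a 2-record gapped FASTA as a pairwise alignment."""
    records = read_fasta(path)
    if len(records) != 2:
        raise ValueError(f"{path}: expected exactly 2 records, found {len(records)}")
    a1, a2 = records[0][1].upper(), records[1][1].upper()
    states = tuple(_column_state(a, b) for a, b in zip(a1, a2))
    return GappedAlignment(a1, a2, states)


def _pairwise_text(aln: GappedAlignment, names: Sequence[str]) -> str:
    """Plain text with a midline: '|' match, space otherwise."""
    mid = "".join(
        "|" if a == b and a != GAP else " "
        for a, b in zip(aln.aligned_s1, aln.aligned_s2)
    )
    w = max(len(n) for n in names) if names else 0
    blocks = []
    for i in range(0, len(aln), _WIDTH):
        blocks.append(
            "\n".join(
                [
                    f"{names[0]:<{w}} {aln.aligned_s1[i : i + _WIDTH]}",
                    f"{'':<{w}} {mid[i : i + _WIDTH]}",
                    f"{names[1]:<{w}} {aln.aligned_s2[i : i + _WIDTH]}",
                ]
            )
        )
    return "\n\n".join(blocks) + "\n"


def write_alignment(
    aln: GappedAlignment,
    format: str,
    path,
    names: Sequence[str] = ("seq1", "seq2"),
) -> None:
    """Write a gapped alignment as 'fasta', 'pairwise' or 'json'."""
    path = Path(path)
    if format == "fasta":
        write_fasta(
            [(names[0], aln.aligned_s1), (names[1], aln.aligned_s2)], path
        )
    elif format == "pairwise":
        path.write_text(_pairwise_text(aln, names))
    elif format == "json":
        path.write_text(
            json.dumps(
                {
                    "aligned_s1": aln.aligned_s1,
                    "aligned_s2": aln.aligned_s2,
                    "column_states": [s.value for s in aln.column_states],
                },
                indent=2,
            )
            + "\n"
        )
    else:
        raise ValueError(f"unknown alignment format {format!r}")


def state_calls_tsv(calls: Iterable[StateCall]) -> str:
    lines = ["position\tstate"]
    lines.extend(f"{c.position}\t{c.state.value}" for c in calls)
    return "\n".join(lines) + "\n"
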