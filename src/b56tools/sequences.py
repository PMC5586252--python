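"""Protein records, phospho-mark parsing and FASTA I/O.

Peptides from display experiments and synthetic phospho-peptides may carry
phosphorylation marks written as ``pS``/``pT`` (lower-case ``p`` immediately
before the modified residue).  Internally every sequence is represented as a
plain upper-case residue string plus a set of 1-based phosphorylated
positions; the mark grammar is strict and any other use of ``p`` is a
format error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
STANDARD_AA_SET = frozenset(STANDARD_AA)
#: Ambiguity/nonstandard codes that invalidate a candidate window but not a protein.
NONSTANDARD_AA = frozenset("BJOUXZ")


@dataclass
class ProteinRecord:
    """A named amino-acid sequence with optional per-residue annotations.

    ``disorder`` is a per-residue score list (same length as the sequence),
    ``phosphosites`` a set of 1-based known phospho positions, ``locations``
    a set of organelle/super-complex labels.
    """

    id: str
    sequence: str
    disorder: list[float] | None = None
    phosphosites: set[int] = field(default_factory=set)
    locations: set[str] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.sequence)


def parse_phospho(sequence: str) -> tuple[str, frozenset[int]]:
    """Split a marked sequence into plain residues and phospho positions.

    Returns ``(residues, positions)`` where ``positions`` are 1-based indices
    into ``residues``.  ``"LEPVRpSEE"`` -> ``("LEPVRSEE", {6})``.
    """
    residues: list[str] = []
    phospho: set[int] = set()
    i = 0
    while i < len(sequence):
        ch = sequence[i]
        if ch == "p":
            if i + 1 >= len(sequence) or sequence[i + 1] not in "ST":
                raise FormatError(
                    f"'p' must be immediately followed by S or T in {sequence!r}"
                )
            residues.append(sequence[i + 1])
            phospho.add(len(residues))
            i += 2
        elif ch.isalpha() and ch.isupper():
            residues.append(ch)
            i += 1
        else:
            raise FormatError(f"unexpected character {ch!r} in {sequence!r}")
    if not residues:
        raise FormatError("empty sequence after phospho-mark parsing")
    return "".join(residues), frozenset(phospho)


def strip_phospho(sequence: str) -> str:
    """Plain residue string with phospho marks removed."""
    return parse_phospho(sequence)[0]


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    return [
        ProteinRecord(id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records),
        str(path),
        "fasta",
    )
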