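"""File-format front door: FASTA, aligned FASTA, Newick and TSV tables.

Every other module consumes and produces the types defined in
:mod:`domaindrift.records` and :mod:`domaindrift.tree`; this module is the
only place that touches files. FASTA parsing is delegated to Biopython;
validation (duplicate ids, illegal characters with positions) is layered on
top so error messages carry the information callers need.
"""

from __future__ import annotations

import os
from typing import Iterable

from Bio import SeqIO

from .errors import DuplicateIdError, ParseError
from .records import GAP, Msa, SeqRecord
from .tree import PhyloTree, format_newick
from .tree import read_newick as _read_newick_text

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_alignment",
    "write_alignment",
    "read_newick",
    "read_newick_file",
    "write_newick",
    "write_newick_file",
    "Msa",
    "SeqRecord",
    "PhyloTree",
]


def read_fasta(path: str | os.PathLike, allow_gaps: bool = False) -> list[SeqRecord]:
    """Read a FASTA file into SeqRecords (residues uppercased, order kept).

    Raises ParseError on an empty file, DuplicateIdError naming a repeated
    id, and AlphabetError with the position of an illegal character.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for bio_rec in SeqIO.parse(os.fspath(path), "fasta"):
        rec = SeqRecord(
            id=bio_rec.id,
            residues=str(bio_rec.seq).upper(),
            description=bio_rec.description,
        )
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
        rec.validate_alphabet(allow_gaps=allow_gaps)
        records.append(rec)
    if not records:
        raise ParseError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id
            if rec.description and rec.description != rec.id:
                header = rec.description if rec.description.startswith(rec.id) else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def read_alignment(path: str | os.PathLike) -> Msa:
    """Read an aligned FASTA file. '-' is the only accepted gap character;
    '.' is rejected. Unequal lengths raise AlignmentError listing offenders."""
    records = read_fasta(path, allow_gaps=True)
    return Msa(records)


def write_alignment(msa: Msa, path: str | os.PathLike, width: int = 70) -> None:
    write_fasta(msa.records, path, width=width)


def read_newick(text: str) -> PhyloTree:
    return _read_newick_text(text)


def write_newick(tree: PhyloTree) -> str:
    return format_newick(tree)


def read_newick_file(path: str | os.PathLike) -> PhyloTree:
    with open(path) as fh:
        return _read_newick_text(fh.read())


def write_newick_file(tree: PhyloTree, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(format_newick(tree) + "\n")


# gap character re-exported for convenience
GAP_CHAR = GAP
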