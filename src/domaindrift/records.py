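"""Sequence containers: records, alignments and half-open regions.

Coordinates are 0-based half-open everywhere inside the package; 1-based
closed coordinates appear only in human-readable report output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import AlignmentError, AlphabetError, DuplicateIdError

DNA_ALPHABET = frozenset("ACGT")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY*")
GAP = "-"

# coordinate spaces for Region
SEQUENCE = "sequence"
ALIGNMENT_COLUMN = "alignment_column"
CODON = "codon"


@dataclass(frozen=True)
class Region:
    """Half-open interval [start, end) in one of three coordinate spaces:
    residue positions of a single ungapped sequence (``sequence``), columns
    of an alignment (``alignment_column``), or codon indices of a CDS
    (``codon``)."""

    start: int
    end: int
    space: str = SEQUENCE

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid region [{self.start}, {self.end})")
        if self.space not in (SEQUENCE, ALIGNMENT_COLUMN, CODON):
            raise ValueError(f"unknown coordinate space {self.space!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class SeqRecord:
    """A named sequence. ``residues`` is uppercase; '-' is permitted only when
    the record is part of an alignment."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise ValueError("record id must be non-empty")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")

    def validate_alphabet(self, allow_gaps: bool = False) -> str:
        """Check residues against the DNA then protein alphabet.

        Returns "dna" or "protein". Raises AlphabetError naming the first
        offending character and its 0-based position.
        """
        seen = set(self.residues) - ({GAP} if allow_gaps else set())
        if seen <= DNA_ALPHABET:
            return "dna"
        if seen <= PROTEIN_ALPHABET:
            return "protein"
        bad = seen - PROTEIN_ALPHABET - ({GAP} if allow_gaps else set())
        for pos, ch in enumerate(self.residues):
            if ch in bad:
                raise AlphabetError(
                    f"illegal character {ch!r} in record {self.id!r}", position=pos
                )
        raise AlphabetError(f"gap character in ungapped record {self.id!r}")


@dataclass
class Msa:
    """An aligned, equal-length set of gapped sequences (>= 2, unique ids)."""

    records: list[SeqRecord] = field(default_factory=list)

    def __post_init__(self):
        if len(self.records) < 2:
            raise AlignmentError("an alignment needs at least 2 records")
        lengths = {len(r) for r in self.records}
        if len(lengths) > 1:
            offenders = ", ".join(
                f"{r.id}({len(r)})" for r in self.records
            )
            raise AlignmentError(f"records of unequal length: {offenders}")
        ids = [r.id for r in self.records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise DuplicateIdError(f"duplicate id(s): {sorted(dupes)}")
        self._index = {r.id: r for r in self.records}

    @property
    def n_cols(self) -> int:
        return len(self.records[0])

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def __getitem__(self, rec_id: str) -> SeqRecord:
        return self._index[rec_id]

    def __contains__(self, rec_id: str) -> bool:
        return rec_id in self._index

    def __len__(self) -> int:
        return len(self.records)

    def column(self, j: int) -> str:
        return "".join(r.residues[j] for r in self.records)
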