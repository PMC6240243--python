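"""Multiple alignments, codon alignments and reference-coordinate maps.

FASTA reading/writing goes through Biopython; the in-memory container is a
plain (n_sequences, n_columns) array of single characters, which is what the
rate and likelihood machinery consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AlignmentError",
    "Alignment",
    "CodonAlignment",
    "ReferenceCoordinateMap",
    "map_to_reference",
    "AMINO_ACIDS",
    "GAP",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
_AA_ALPHABET = set(AMINO_ACIDS + GAP + "X")
_NT_ALPHABET = set("ACGT" + GAP + "N")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class AlignmentError(ValueError):
    """Invalid alignment (ragged rows, bad alphabet, stop codons, ...)."""


class Alignment:
    """Protein multiple alignment with equal-length rows.

    Parameters
    ----------
    ids : sequence identifiers, unique.
    rows : iterable of equal-length strings over the amino-acid alphabet
        plus gap (``-``) and ambiguity (``X``).
    """

    alphabet = _AA_ALPHABET
    kind = "protein"

    def __init__(self, ids: Sequence[str], rows: Sequence[str]):
        ids = list(ids)
        rows = [str(r).upper() for r in rows]
        if len(ids) != len(rows):
            raise AlignmentError("ids and rows differ in length")
        if len(set(ids)) != len(ids):
            raise AlignmentError("duplicate sequence ids")
        if rows:
            L = len(rows[0])
            for i, r in enumerate(rows):
                if len(r) != L:
                    raise AlignmentError(
                        f"row {ids[i]!r} has length {len(r)}, expected {L}"
                    )
                bad = set(r) - self.alphabet
                if bad:
                    raise AlignmentError(
                        f"row {ids[i]!r} contains invalid characters {sorted(bad)}"
                    )
        self.ids = ids
        self.matrix = (
            np.array([list(r) for r in rows], dtype="U1")
            if rows
            else np.empty((0, 0), dtype="U1")
        )

    # -- basic protocol ----------------------------------------------
    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1] if self.matrix.size else (
            self.matrix.shape[1] if self.matrix.ndim == 2 else 0
        )

    def row(self, seq_id: str) -> str:
        try:
            i = self.ids.index(seq_id)
        except ValueError:
            raise AlignmentError(f"sequence id {seq_id!r} not in alignment") from None
        return "".join(self.matrix[i])

    def __len__(self) -> int:
        return self.n_sequences

    # -- gaps ---------------------------------------------------------
    def gap_fraction(self) -> np.ndarray:
        """Per-column fraction of rows that are gaps."""
        if self.n_sequences == 0:
            return np.zeros(0)
        return (self.matrix == GAP).mean(axis=0)

    # -- I/O ----------------------------------------------------------
    @classmethod
    def read_fasta(cls, path) -> "Alignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        return cls([r.id for r in records], [str(r.seq) for r in records])

    def write_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq("".join(row)), id=sid, description="")
            for sid, row in zip(self.ids, self.matrix)
        ]
        SeqIO.write(records, str(path), "fasta")


class CodonAlignment(Alignment):
    """In-frame nucleotide alignment: length divisible by 3, no internal stops.

    Codons fully made of gaps are treated as missing data downstream;
    codons mixing gap and nucleotide characters are treated as ambiguous
    (also missing).  A gap-free stop codon anywhere before the final codon
    of a row is rejected.
    """

    alphabet = _NT_ALPHABET
    kind = "codon"

    def __init__(self, ids: Sequence[str], rows: Sequence[str]):
        super().__init__(ids, rows)
        L = self.n_columns
        if L % 3 != 0:
            raise AlignmentError(f"codon alignment length {L} not divisible by 3")
        for sid, row in zip(self.ids, ["".join(r) for r in self.matrix]):
            codons = [row[i : i + 3] for i in range(0, L, 3)]
            # index of the last codon containing any nucleotide
            last = max(
                (k for k, c in enumerate(codons) if set(c) - {GAP}), default=-1
            )
            for k, codon in enumerate(codons):
                if codon in STOP_CODONS and k < last:
                    raise AlignmentError(
                        f"internal stop codon {codon} at codon position {k + 1} "
                        f"in sequence {sid!r}"
                    )

    @property
    def n_codons(self) -> int:
        return self.n_columns // 3

    def codon(self, row_index: int, site: int) -> str:
        """The three-character codon of a row at 0-based codon site."""
        return "".join(self.matrix[row_index, 3 * site : 3 * site + 3])


@dataclass(frozen=True)
class ReferenceCoordinateMap:
    """Alignment column <-> residue position in a named reference sequence.

    Both coordinate systems are 1-based inclusive.  Columns where the
    reference carries a gap are unmapped (0 in ``col_to_residue``).
    """

    reference_id: str
    col_to_residue: tuple[int, ...]  # 0 where unmapped; len == n_columns

    @property
    def n_columns(self) -> int:
        return len(self.col_to_residue)

    @property
    def n_residues(self) -> int:
        return max(self.col_to_residue, default=0)

    def residue_of(self, column: int) -> int | None:
        """Residue position for a 1-based column, or None if unmapped."""
        r = self.col_to_residue[column - 1]
        return r if r else None

    def column_of(self, residue: int) -> int:
        """1-based alignment column of a 1-based reference residue."""
        try:
            return self.col_to_residue.index(residue) + 1
        except ValueError:
            raise AlignmentError(
                f"residue {residue} outside reference {self.reference_id!r}"
            ) from None

    def mapped_columns(self) -> list[int]:
        return [c + 1 for c, r in enumerate(self.col_to_residue) if r]


def map_to_reference(alignment: Alignment, reference_id: str) -> ReferenceCoordinateMap:
    """Build the column <-> residue map for one reference row.

    Every non-gap character of the reference row receives consecutive
    residue numbers 1, 2, ...; gap columns are flagged unmapped.
    """
    row = alignment.row(reference_id)
    out = []
    pos = 0
    for ch in row:
        if ch == GAP:
            out.append(0)
        else:
            pos += 1
            out.append(pos)
    return ReferenceCoordinateMap(reference_id, tuple(out))
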