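"""Sequencing read container and FASTQ I/O.

Reads are either full-length nanopore reads (concatemers of ligated amplicon
monomers) or monomer segments produced by deconcatenation.  Qualities are
plain phred scores (phred+33 on disk).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Byte-level base encoding used by the simulator and aligner hot paths.
BASE_CODES = {"A": 0, "C": 1, "G": 2, "T": 3}
CODE_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(sequence: str) -> str:
    """Reverse complement of a DNA string (IUPAC N preserved)."""
    return sequence.translate(_COMPLEMENT)[::-1]


def seq_to_codes(sequence: str) -> np.ndarray:
    """Encode A/C/G/T as uint8 codes 0-3; other characters map to 4."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    codes = np.full(raw.shape, 4, dtype=np.uint8)
    for base, code in BASE_CODES.items():
        codes[raw == ord(base)] = code
    return codes


def codes_to_seq(codes: np.ndarray) -> str:
    return CODE_BASES[codes].tobytes().decode("ascii")


@dataclass
class Read:
    """One sequencing read or monomer segment.

    ``source_role`` distinguishes raw concatemer reads from monomer segments
    cut out of them; segments keep a ``parent_read`` link and the slice
    coordinates on the parent.
    """

    id: str
    sequence: str
    qualities: np.ndarray
    source_role: str = "concatemer"  # "concatemer" | "monomer-segment"
    parent_read: str | None = None
    strand: str = "+"
    parent_span: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.qualities = np.asarray(self.qualities, dtype=np.int16)
        if len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.id!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )
        if len(self.qualities) and self.qualities.min() < 0:
            raise ValueError(f"read {self.id!r}: negative phred score")

    def __len__(self) -> int:
        return len(self.sequence)


class ReadSet:
    """An ordered collection of :class:`Read` objects."""

    def __init__(self, reads: Iterable[Read] = ()) -> None:
        self.reads: list[Read] = list(reads)

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self) -> Iterator[Read]:
        return iter(self.reads)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return ReadSet(self.reads[i])
        return self.reads[i]

    def append(self, read: Read) -> None:
        self.reads.append(read)

    def extend(self, reads: Iterable[Read]) -> None:
        self.reads.extend(reads)

    @property
    def total_bases(self) -> int:
        return sum(len(r) for r in self.reads)

    def __repr__(self) -> str:
        return f"ReadSet(n={len(self.reads)}, bases={self.total_bases})"


def read_fastq(path: str | Path, source_role: str = "concatemer") -> ReadSet:
    """Load a phred+33 FASTQ file.

    Raises a record-level :class:`ValueError` naming the read when a record
    is malformed (Biopython already rejects sequence/quality length
    mismatches and truncated records; the error is re-raised with context).
    """
    reads = ReadSet()
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            reads.append(
                Read(
                    id=rec.id,
                    sequence=str(rec.seq).upper(),
                    qualities=np.array(
                        rec.letter_annotations["phred_quality"], dtype=np.int16
                    ),
                    source_role=source_role,
                )
            )
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ record in {path}: {exc}") from exc
    return reads


def write_fastq(reads: ReadSet | Sequence[Read], path: str | Path) -> None:
    """Write reads as phred+33 FASTQ."""
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = [int(q) for q in r.qualities]
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")
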