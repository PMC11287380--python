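"""Sequence input/output and elementary sequence operations.

This module handles FASTA/FASTQ parsing (transparently gzipped), genetic-code
translation, reverse complementation with full IUPAC ambiguity support, and
sliding-window fragmentation of long sequences.  All downstream stages of the
pipeline consume the :class:`SeqRecord` container defined here.

Intervals are 0-based half-open throughout the package; user-facing reports
use 1-based inclusive coordinates.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable


class ParseError(ValueError):
    """Raised when an input file violates its declared format."""


GAP = "-"

#: Full IUPAC nucleotide complement table (upper case; lower case handled by
#: upcasing on entry).
_COMPLEMENT = {
    "A": "T", "T": "A", "G": "C", "C": "G", "U": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N", GAP: GAP,
}

_UNAMBIGUOUS = set("ACGTU")


@dataclass(frozen=True)
class SeqRecord:
    """One input sequence or read.

    Attributes
    ----------
    id:
        Record identifier, non-empty.
    source:
        Label of the source (sample/species) the record belongs to.
    residues:
        Residue string (nucleotide or amino acid, may contain IUPAC
        ambiguity codes and ``-`` gaps).
    qualities:
        Optional per-residue Phred scores.  Parsed for completeness but not
        used by the pipeline (no quality filtering is applied).
    offset:
        Start offset of this record within its parent sequence when it is a
        fragment; 0 for intact records.
    parent_id:
        Identifier of the unfragmented parent sequence, if any.  Fragments
        of one parent are counted once in read tallies.
    """

    id: str
    source: str
    residues: str
    qualities: Optional[tuple] = None
    offset: int = 0
    parent_id: Optional[str] = None

    def __post_init__(self):
        if not self.id:
            raise ValueError("SeqRecord id must be non-empty")
        if self.qualities is not None and len(self.qualities) != len(self.residues):
            raise ValueError(
                f"record {self.id!r}: {len(self.qualities)} qualities for "
                f"{len(self.residues)} residues"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GeneticCode:
    """An NCBI translation table as a total map over the 64 codons."""

    table_id: int
    codon_to_aa: dict

    @classmethod
    def from_ncbi(cls, table_id: int = 1) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[table_id]
        mapping = dict(table.forward_table)
        for stop in table.stop_codons:
            mapping[stop] = "*"
        if len(mapping) != 64:  # pragma: no cover - NCBI tables are total
            raise ValueError(f"translation table {table_id} is not total")
        return cls(table_id=table_id, codon_to_aa=mapping)


def _open_text(path) -> Iterator:
    """Open a possibly gzip-compressed text file for reading."""
    path = Path(path)
    handle = open(path, "rb")
    magic = handle.read(2)
    handle.seek(0)
    if magic == b"\x1f\x8b":
        return gzip.open(handle, "rt")
    import io

    return io.TextIOWrapper(handle)


def read_sequences(path, format: str, source_label: str = "") -> Iterator[SeqRecord]:
    """Stream records from a FASTA or FASTQ file (gzip transparent).

    Yields records lazily in file order, so arbitrarily large files can be
    consumed without holding all records in memory.  An empty file yields
    nothing.  Malformed records raise :class:`ParseError`.
    """
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    handle = _open_text(path)
    try:
        for rec in SeqIO.parse(handle, format):
            quals = rec.letter_annotations.get("phred_quality")
            yield SeqRecord(
                id=rec.id,
                source=source_label,
                residues=str(rec.seq).upper(),
                qualities=tuple(quals) if quals is not None else None,
            )
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    finally:
        handle.close()


def write_fasta(records: Iterable, path, width: int = 60) -> None:
    """Write (id, residues) pairs or SeqRecords as line-wrapped FASTA."""
    with open(path, "w") as out:
        for rec in records:
            if isinstance(rec, SeqRecord):
                name, seq = rec.id, rec.residues
            else:
                name, seq = rec
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


def write_fastq(records: Iterable[SeqRecord], path) -> None:
    with open(path, "w") as out:
        for rec in records:
            quals = rec.qualities or (40,) * len(rec.residues)
            qstr = "".join(chr(q + 33) for q in quals)
            out.write(f"@{rec.id}\n{rec.residues}\n+\n{qstr}\n")


def reverse_complement(residues: str) -> str:
    """Reverse complement over the full IUPAC nucleotide alphabet."""
    try:
        return "".join(_COMPLEMENT[c] for c in reversed(residues.upper()))
    except KeyError as exc:
        raise ValueError(f"non-nucleotide character {exc.args[0]!r}") from None


def translate(residues: str, code: GeneticCode, frame: int = 0) -> str:
    """Translate one reading frame; ambiguous codons become ``X``.

    Output length is ``(len(residues) - frame) // 3``.  Stop codons are
    rendered ``*``.  Codons containing gaps or ambiguity codes translate to
    ``X``, except the fully gapped codon ``---`` which becomes ``-``.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    seq = residues.upper().replace("U", "T")
    aas = []
    for i in range(frame, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if codon == "---":
            aas.append(GAP)
        elif set(codon) <= set("ACGT"):
            aas.append(code.codon_to_aa[codon])
        else:
            aas.append("X")
    return "".join(aas)


#: (strand, phase) labels for the six translation frames.
SIX_FRAMES = tuple(("+", p) for p in range(3)) + tuple(("-", p) for p in range(3))


def six_frame_translations(record: SeqRecord, code: GeneticCode):
    """All six translation frames of a nucleotide record.

    Returns a list of ``((strand, phase), aa_string)`` pairs in the fixed
    order +0, +1, +2, -0, -1, -2.  Phases are offsets into the forward
    (``+``) or reverse-complemented (``-``) sequence, which is the
    information codon back-mapping needs.
    """
    fwd = record.residues
    rev = reverse_complement(fwd)
    out = []
    for strand, phase in SIX_FRAMES:
        seq = fwd if strand == "+" else rev
        out.append(((strand, phase), translate(seq, code, phase)))
    return out


def fragment_sequence(record: SeqRecord, window: int, step: int) -> list:
    """Cut a record into overlapping fragments covering every position.

    Fragments start at 0, step, 2*step, ...; the final fragment always ends
    at the sequence end, so the union of fragment intervals is the whole
    sequence.  Requires ``window >= step >= 1`` (otherwise positions between
    consecutive windows would be uncovered).
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    if window < step:
        raise ValueError("window must be >= step (otherwise bases are uncovered)")
    n = len(record.residues)
    if n <= window:
        return [replace(record, offset=record.offset, parent_id=record.parent_id or record.id)]
    starts = list(range(0, n - window + 1, step))
    if starts[-1] + window < n:
        starts.append(n - window)
    frags = []
    for s in starts:
        frags.append(
            SeqRecord(
                id=f"{record.id}|frag{s}",
                source=record.source,
                residues=record.residues[s : s + window],
                offset=record.offset + s,
                parent_id=record.parent_id or record.id,
            )
        )
    return frags
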