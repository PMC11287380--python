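"""Laying search hits onto reference columns and assembling contigs.

Reference coordinates are fixed: query residues aligned to match states are
placed at the corresponding columns, deletions appear as ``-`` inside the
covered interval, and insertions relative to the reference are discarded
(tallied for diagnostics) because the output MSA can never grow new columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

from .profile_search import SearchHit
from .seq_io import GAP, reverse_complement


@dataclass
class MappedSegment:
    """Residues of one query laid onto a run of reference columns.

    ``residues[k]`` is the symbol at column ``start + k`` (a residue or
    ``-`` for a deletion); ``query_indices[k]`` is the index of that residue
    in the searched query string (``None`` at deletions), which codon
    back-mapping needs.  ``read_ids`` identifies the underlying reads:
    fragments of one parent sequence share a read id and therefore count
    once.
    """

    source: str
    query_id: str
    locus_id: str
    start: int
    residues: str
    query_indices: Tuple[Optional[int], ...]
    read_ids: FrozenSet[str]
    frame: Optional[Tuple[str, int]] = None
    n_insertions: int = 0

    def __post_init__(self):
        if len(self.residues) != len(self.query_indices):
            raise ValueError("residues and query_indices length mismatch")

    @property
    def end(self) -> int:
        return self.start + len(self.residues)

    @property
    def read_count(self) -> int:
        return len(self.read_ids)

    def symbol_at(self, column: int) -> Optional[str]:
        if self.start <= column < self.end:
            return self.residues[column - self.start]
        return None


@dataclass
class Contig:
    """An assembled run of overlapping segments in reference coordinates."""

    source: str
    locus_id: str
    start: int
    residues: str
    read_ids: FrozenSet[str]
    member_ids: Tuple[str, ...]

    @property
    def end(self) -> int:
        return self.start + len(self.residues)

    @property
    def read_count(self) -> int:
        return len(self.read_ids)

    def symbol_at(self, column: int) -> Optional[str]:
        if self.start <= column < self.end:
            return self.residues[column - self.start]
        return None


def map_hit_to_columns(hit: SearchHit, n_match_states: Optional[int] = None) -> MappedSegment:
    """Convert a search hit into a residue-per-column segment.

    Match pairs place the query residue at its column; deletion pairs place
    ``-``; insertion pairs are dropped and counted in ``n_insertions``.
    """
    states = [sj for _, sj in hit.aligned_pairs if sj is not None]
    if not states:
        raise ValueError(f"hit {hit.query_id!r} has no match/delete pairs")
    if n_match_states is not None and states[-1] >= n_match_states:
        raise ValueError(
            f"hit {hit.query_id!r}: state {states[-1]} out of profile bounds")
    start, end = states[0], states[-1] + 1
    residues = [GAP] * (end - start)
    qidx: List[Optional[int]] = [None] * (end - start)
    n_ins = 0
    for qi, sj in hit.aligned_pairs:
        if sj is None:
            n_ins += 1
            continue
        if qi is not None:
            residues[sj - start] = hit.residues[qi].upper()
            qidx[sj - start] = qi
    read_id = hit.parent_id or hit.query_id
    return MappedSegment(
        source=hit.source, query_id=hit.query_id, locus_id=hit.locus_id,
        start=start, residues="".join(residues), query_indices=tuple(qidx),
        read_ids=frozenset([read_id]), frame=hit.frame, n_insertions=n_ins,
    )


def backmap_codons(protein_segment: MappedSegment, nucleotide_residues: str,
                   frame: Tuple[str, int]) -> MappedSegment:
    """Back-map an amino-acid segment to its codons in nucleotide columns.

    Amino-acid column ``c`` maps to nucleotide columns ``[3c, 3c+3)``; the
    codon residues come from the original nucleotide sequence (reverse
    complemented first for minus-strand frames); a ``-`` amino acid becomes
    ``---``.
    """
    strand, phase = frame
    nuc = nucleotide_residues.upper()
    if strand == "-":
        nuc = reverse_complement(nuc)
    residues: List[str] = []
    qidx: List[Optional[int]] = []
    for k, (aa, qi) in enumerate(zip(protein_segment.residues,
                                     protein_segment.query_indices)):
        if qi is None:
            residues.append(GAP * 3)
            qidx.extend([None, None, None])
        else:
            off = phase + 3 * qi
            if off + 3 > len(nuc):
                raise ValueError(
                    f"{protein_segment.query_id!r}: codon for aa index {qi} "
                    f"(frame {strand}{phase}) exceeds nucleotide length {len(nuc)}")
            residues.append(nuc[off : off + 3])
            qidx.extend([off, off + 1, off + 2])
    return MappedSegment(
        source=protein_segment.source,
        query_id=protein_segment.query_id,
        locus_id=protein_segment.locus_id,
        start=3 * protein_segment.start,
        residues="".join(residues),
        query_indices=tuple(qidx),
        read_ids=protein_segment.read_ids,
        frame=frame,
        n_insertions=protein_segment.n_insertions,
    )


def overlap_identity(a, b) -> Tuple[int, float]:
    """Shared non-gap columns of two items and identity over them.

    Columns where either side holds a gap are not shared; an overlap that is
    entirely gapped therefore has 0 shared columns.
    """
    lo = max(a.start, b.start)
    hi = min(a.end, b.end)
    shared = 0
    match = 0
    for c in range(lo, hi):
        ra = a.symbol_at(c)
        rb = b.symbol_at(c)
        if ra is None or rb is None or ra == GAP or rb == GAP:
            continue
        shared += 1
        if ra == rb:
            match += 1
    return shared, (match / shared if shared else 0.0)


class _ContigBuilder:
    """Accumulates weighted per-column residue votes for one contig."""

    def __init__(self, seg: MappedSegment):
        self.source = seg.source
        self.locus_id = seg.locus_id
        self.start = seg.start
        self.end = seg.end
        self.votes: Dict[int, Dict[str, int]] = {}
        self.read_ids: set = set()
        self.member_ids: List[str] = []
        self._cache: Optional[str] = None
        self.add(seg)

    def add(self, seg: MappedSegment) -> None:
        w = seg.read_count
        for k, r in enumerate(seg.residues):
            col = seg.start + k
            self.votes.setdefault(col, {})[r] = self.votes.get(col, {}).get(r, 0) + w
        self.start = min(self.start, seg.start)
        self.end = max(self.end, seg.end)
        self.read_ids |= seg.read_ids
        self.member_ids.append(seg.query_id)
        self._cache = None

    @property
    def residues(self) -> str:
        if self._cache is None:
            out = []
            for c in range(self.start, self.end):
                votes = self.votes.get(c)
                if not votes:
                    out.append(GAP)
                    continue
                # read-count-weighted plurality, alphabetic tie-break;
                # gap symbol competes like a residue within the contig
                out.append(max(sorted(votes), key=lambda r: votes[r]))
            self._cache = "".join(out)
        return self._cache

    def symbol_at(self, column: int) -> Optional[str]:
        if self.start <= column < self.end:
            return self.residues[column - self.start]
        return None

    def finalize(self) -> Contig:
        return Contig(
            source=self.source, locus_id=self.locus_id, start=self.start,
            residues=self.residues, read_ids=frozenset(self.read_ids),
            member_ids=tuple(self.member_ids),
        )


def assemble_segments(segments: Sequence[MappedSegment], min_overlap: float = 30,
                      min_identity: float = 0.98) -> List[Contig]:
    """Greedy coordinate-based assembly of segments into contigs.

    Segments are processed in (start, end, query_id) order; a segment merges
    into the first contig with which it shares at least ``min_overlap``
    non-gap columns at identity >= ``min_identity``, otherwise it seeds a
    new contig.  Residue conflicts are resolved per column by
    read-count-weighted plurality with an alphabetic tie-break; read counts
    accumulate (fragments of one parent read count once).  The result is
    independent of input order.  ``min_overlap=math.inf`` disables merging.
    """
    if not segments:
        return []
    loci = {s.locus_id for s in segments}
    sources = {s.source for s in segments}
    if len(loci) > 1 or len(sources) > 1:
        raise ValueError("assemble_segments requires a single locus and source")
    ordered = sorted(segments, key=lambda s: (s.start, s.end, s.query_id))
    builders: List[_ContigBuilder] = []
    for seg in ordered:
        merged = False
        if min_overlap != math.inf:
            for b in builders:
                if b.end <= seg.start or seg.end <= b.start:
                    continue
                shared, ident = overlap_identity(b, seg)
                if shared >= min_overlap and ident >= min_identity:
                    b.add(seg)
                    merged = True
                    break
        if not merged:
            builders.append(_ContigBuilder(seg))
    builders.sort(key=lambda b: (b.start, b.end, b.member_ids[0]))
    return [b.finalize() for b in builders]
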