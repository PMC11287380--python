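"""Reference MSA loading, conservation profiles, splitting and concatenation.

A reference MSA fixes the column coordinate system every downstream result
lives in.  The per-column ingroup residue frequencies computed here (the
"conservation profile") later drive foreign-contamination scoring: a mapped
sequence is scored by summing, over its covered columns, the ingroup
frequency of the residue it carries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio import SeqIO

from .seq_io import GAP, GeneticCode, translate, write_fasta

ALPHABETS = ("dna", "protein", "codon")

#: Characters that carry no frequency mass in profiles (gaps + unknowns).
_NO_MASS_DNA = set("-NRYSWKMBVDH.?*")
_NO_MASS_PROT = set("-X.?*BJZ")


@dataclass
class ReferenceAlignment:
    """A validated reference MSA with fixed column coordinates."""

    locus_id: str
    rows: Dict[str, str]  # taxon id -> aligned residues, insertion order kept
    n_columns: int
    alphabet: str  # dna | protein | codon
    outgroup_id: Optional[str] = None
    col_offset: int = 0  # original-column offset when this is a split window
    parent_locus: Optional[str] = None

    def __post_init__(self):
        if self.alphabet not in ALPHABETS:
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        for taxon, row in self.rows.items():
            if len(row) != self.n_columns:
                raise ValueError(
                    f"{self.locus_id}: row {taxon!r} has length {len(row)}, "
                    f"expected {self.n_columns}"
                )
        if self.alphabet == "codon" and self.n_columns % 3:
            raise ValueError(
                f"{self.locus_id}: codon alignment length {self.n_columns} "
                "is not divisible by 3"
            )
        if self.outgroup_id is not None and self.outgroup_id not in self.rows:
            raise ValueError(
                f"{self.locus_id}: outgroup {self.outgroup_id!r} is not a row"
            )

    @property
    def taxa(self) -> List[str]:
        return list(self.rows)

    @property
    def ingroup_ids(self) -> List[str]:
        return [t for t in self.rows if t != self.outgroup_id]

    def translated(self, code: GeneticCode) -> "ReferenceAlignment":
        """Amino-acid view of a codon alignment (columns /3)."""
        if self.alphabet != "codon":
            raise ValueError("translated() requires a codon alignment")
        rows = {t: translate(r, code, 0) for t, r in self.rows.items()}
        return ReferenceAlignment(
            locus_id=self.locus_id,
            rows=rows,
            n_columns=self.n_columns // 3,
            alphabet="protein",
            outgroup_id=self.outgroup_id,
            col_offset=self.col_offset,
            parent_locus=self.parent_locus,
        )


@dataclass
class ConservationProfile:
    """Per-column ingroup residue frequencies.

    ``columns[c]`` maps residue -> frequency in [0, 1].  The denominator is
    the total ingroup row count, so rows gapped at a column shrink the
    residue mass there; ambiguity codes contribute no mass.  For codon
    references the profile lives on the translated amino-acid columns.
    """

    locus_id: str
    columns: List[Dict[str, float]]

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    def freq(self, column: int, residue: str) -> float:
        return self.columns[column].get(residue.upper(), 0.0)

    def modal_residue(self, column: int) -> Optional[str]:
        col = self.columns[column]
        if not col:
            return None
        return max(sorted(col), key=lambda r: col[r])


def load_reference_msa(path, alphabet: str, outgroup_id: Optional[str] = None,
                       locus_id: Optional[str] = None) -> ReferenceAlignment:
    """Load and validate an aligned FASTA reference MSA."""
    path = Path(path)
    rows: Dict[str, str] = {}
    n_columns = None
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in rows:
            raise ValueError(f"{path}: duplicate taxon id {rec.id!r}")
        row = str(rec.seq).upper()
        if n_columns is None:
            n_columns = len(row)
        elif len(row) != n_columns:
            raise ValueError(
                f"{path}: row {rec.id!r} has length {len(row)}, expected {n_columns}"
            )
        rows[rec.id] = row
    if len(rows) < 2:
        raise ValueError(f"{path}: reference MSA needs >= 2 rows")
    return ReferenceAlignment(
        locus_id=locus_id or path.name.split(".")[0],
        rows=rows,
        n_columns=n_columns,
        alphabet=alphabet,
        outgroup_id=outgroup_id,
    )


def compute_ingroup_profile(aln: ReferenceAlignment,
                            code: Optional[GeneticCode] = None) -> ConservationProfile:
    """Ingroup residue frequencies per column, outgroup excluded.

    For a codon alignment the frequencies are computed on the translated
    amino-acid columns (the search and scoring operate in protein space in
    prot/codon modes).
    """
    work = aln
    if aln.alphabet == "codon":
        work = aln.translated(code or GeneticCode.from_ncbi(1))
    ingroup = work.ingroup_ids
    if not ingroup:
        raise ValueError(f"{aln.locus_id}: no ingroup rows to profile")
    no_mass = _NO_MASS_DNA if work.alphabet == "dna" else _NO_MASS_PROT
    denom = float(len(ingroup))
    columns: List[Dict[str, float]] = []
    for c in range(work.n_columns):
        counts: Dict[str, int] = {}
        for t in ingroup:
            r = work.rows[t][c]
            if r not in no_mass:
                counts[r] = counts.get(r, 0) + 1
        columns.append({r: n / denom for r, n in counts.items()})
    return ConservationProfile(locus_id=aln.locus_id, columns=columns)


def split_reference_msa(aln: ReferenceAlignment, window: int,
                        step: Optional[int] = None) -> List[ReferenceAlignment]:
    """Tile a long reference MSA into column windows.

    Each window remembers its original column offset (``col_offset``) and
    parent locus so per-window results can be re-concatenated losslessly.
    With ``step == window`` (the default) the windows are disjoint.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    step = window if step is None else step
    if step < 1 or step > window:
        raise ValueError("step must satisfy 1 <= step <= window")
    if aln.alphabet == "codon" and (window % 3 or step % 3):
        raise ValueError("codon alignments require codon-multiple window/step")
    n = aln.n_columns
    if window >= n:
        return [aln]
    starts = list(range(0, n - window + 1, step))
    if starts[-1] + window < n:
        # Disjoint tiling keeps a short terminal window; overlapping tiling
        # shifts the last window so it ends exactly at the final column.
        starts.append(starts[-1] + step if step == window else n - window)
    windows = []
    for s in starts:
        e = min(s + window, n)
        windows.append(
            ReferenceAlignment(
                locus_id=f"{aln.locus_id}.w{s}",
                rows={t: r[s:e] for t, r in aln.rows.items()},
                n_columns=e - s,
                alphabet=aln.alphabet,
                outgroup_id=aln.outgroup_id,
                col_offset=aln.col_offset + s,
                parent_locus=aln.parent_locus or aln.locus_id,
            )
        )
    return windows


def join_split_msas(windows: Sequence[ReferenceAlignment]) -> ReferenceAlignment:
    """Re-concatenate disjoint windows of one parent MSA (round trip of
    :func:`split_reference_msa` with ``step == window``)."""
    ws = sorted(windows, key=lambda w: w.col_offset)
    parent = ws[0].parent_locus or ws[0].locus_id
    taxa = ws[0].taxa
    rows = {t: "".join(w.rows[t] for w in ws) for t in taxa}
    return ReferenceAlignment(
        locus_id=parent,
        rows=rows,
        n_columns=sum(w.n_columns for w in ws),
        alphabet=ws[0].alphabet,
        outgroup_id=ws[0].outgroup_id,
    )


def concatenate_msas(loci: Sequence[Tuple[str, Dict[str, str]]],
                     taxa: Optional[Sequence[str]] = None):
    """Concatenate per-locus row maps into a supermatrix.

    Parameters
    ----------
    loci:
        Ordered ``(locus_id, {taxon: aligned row})`` pairs.  Rows within a
        locus must share one length; a taxon may be absent from some loci
        (filled with gaps).
    taxa:
        Optional explicit taxon universe/ordering; defaults to first-seen
        order across loci.

    Returns
    -------
    (rows, partitions):
        ``rows`` maps taxon -> concatenated sequence; ``partitions`` is a
        list of ``(locus_id, start, end)`` with 1-based inclusive columns.
    """
    if taxa is None:
        seen: List[str] = []
        for _, rows in loci:
            for t in rows:
                if t not in seen:
                    seen.append(t)
        taxa = seen
    out = {t: [] for t in taxa}
    partitions = []
    pos = 0
    for locus_id, rows in loci:
        lengths = {len(r) for r in rows.values()}
        if len(lengths) != 1:
            raise ValueError(f"{locus_id}: rows of unequal length {sorted(lengths)}")
        if len(rows) != len(set(rows)):  # dict keys are unique by construction
            raise ValueError(f"{locus_id}: duplicate taxon")
        (length,) = lengths
        for t in taxa:
            out[t].append(rows.get(t, GAP * length))
        partitions.append((locus_id, pos + 1, pos + length))
        pos += length
    return {t: "".join(parts) for t, parts in out.items()}, partitions


def write_partition_table(partitions, path) -> None:
    """RAxML-style partition table: one ``locus = start-end`` line each."""
    with open(path, "w") as out:
        for locus_id, start, end in partitions:
            out.write(f"{locus_id} = {start}-{end}\n")


def write_alignment(rows: Dict[str, str], path) -> None:
    write_fasta(rows.items(), path)
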