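"""Per-source consensus calling and output MSA writing.

Each source's surviving items at one locus collapse into a single row of
exactly the reference column count: per column, the read-count-weighted
plurality among covering non-gap symbols (alphabetic tie-break), with ``-``
at uncovered or all-gap columns so downstream trimming treats them as
missing data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence

from .reference_model import ReferenceAlignment
from .seq_io import GAP, GeneticCode, translate, write_fasta


@dataclass
class ConsensusSequence:
    """One source's consensus row at one locus, in reference coordinates."""

    source: str
    locus_id: str
    residues: str
    read_ids: frozenset

    @property
    def read_count(self) -> int:
        return len(self.read_ids)

    # duck-typing so a consensus can flow through the cross-contamination
    # detector (no-assembly path) like any coordinate-anchored item
    @property
    def start(self) -> int:
        stripped = self.residues.lstrip(GAP)
        return len(self.residues) - len(stripped)

    @property
    def end(self) -> int:
        return len(self.residues.rstrip(GAP))

    def symbol_at(self, column: int) -> Optional[str]:
        if self.start <= column < self.end:
            return self.residues[column]
        return None


def consensus_per_source(items: Sequence, n_columns: int, source: str,
                         locus_id: str) -> ConsensusSequence:
    """Weighted plurality consensus over all items of one locus and source.

    Per column the residue is the read-count-weighted plurality among
    covering items' non-gap symbols; ties break to the alphabetically first
    residue; columns covered only by gaps, or not at all, emit ``-``.
    Empty input yields an all-gap consensus.
    """
    votes: List[Dict[str, int]] = [dict() for _ in range(n_columns)]
    read_ids: set = set()
    for item in items:
        w = item.read_count
        for k, r in enumerate(item.residues):
            if r == GAP:
                continue
            col = item.start + k
            votes[col][r] = votes[col].get(r, 0) + w
        read_ids |= set(item.read_ids)
    out = []
    for col_votes in votes:
        if not col_votes:
            out.append(GAP)
        else:
            out.append(max(sorted(col_votes), key=lambda r: col_votes[r]))
    return ConsensusSequence(source=source, locus_id=locus_id,
                             residues="".join(out), read_ids=frozenset(read_ids))


def translate_msa_row(residues: str, code: GeneticCode) -> str:
    """Codon-wise translation of an aligned nucleotide row.

    ``---`` becomes ``-``; any other untranslatable codon (partial gaps,
    ambiguity) becomes ``X``; stops stay ``*``.
    """
    return translate(residues, code, 0)


def emit_output_msas(consensus: Dict[str, Dict[str, ConsensusSequence]],
                     references: Dict[str, ReferenceAlignment],
                     mode: str, include_refs: bool, out_dir,
                     code: Optional[GeneticCode] = None) -> List[Path]:
    """Write one MSA FASTA per locus (plus a protein MSA in codon-like modes).

    ``consensus`` maps locus -> source -> consensus row.  Reference rows are
    prepended when ``include_refs``.  In codon and dna_codon modes an
    additional ``<locus>.aa.fa`` holds the codon-wise translation of every
    output row.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    code = code or GeneticCode.from_ncbi(1)
    written: List[Path] = []
    for locus_id in sorted(consensus):
        aln = references[locus_id]
        rows: List = []
        if include_refs:
            rows.extend(aln.rows.items())
        for source in sorted(consensus[locus_id]):
            cons = consensus[locus_id][source]
            if len(cons.residues) != aln.n_columns:
                raise ValueError(
                    f"{locus_id}/{source}: consensus length {len(cons.residues)} "
                    f"!= reference columns {aln.n_columns}")
            rows.append((source, cons.residues))
        path = out_dir / f"{locus_id}.fa"
        write_fasta(rows, path)
        written.append(path)
        if mode in ("codon", "dna_codon"):
            aa_rows = [(name, translate_msa_row(seq, code)) for name, seq in rows]
            aa_path = out_dir / f"{locus_id}.aa.fa"
            write_fasta(aa_rows, aa_path)
            written.append(aa_path)
    return written


def write_run_summary(summary: dict, path) -> None:
    with open(path, "w") as out:
        json.dump(summary, out, indent=2, sort_keys=True)
        out.write("\n")
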