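"""End-to-end pipeline: configuration, orchestration, determinism.

Stage order (fixed per mode):

* assembly enabled:  search -> map -> assemble -> foreign removal ->
  cross removal -> consensus
* assembly disabled: search -> map -> foreign removal -> consensus ->
  cross removal (cross-contamination is then judged on whole consensus
  rows, which lack per-read counts; the segment count stands in for the
  read count and is logged as a proxy)

In prot and codon modes the search runs in protein space over six
translation frames; in codon mode hits are then back-mapped to codons and
all downstream items live on nucleotide columns, while foreign scoring
translates items to the amino-acid columns where the conservation profile
lives.  Outputs are byte-identical for any thread count and for the
low-memory (streaming) query path.
"""

from __future__ import annotations

import glob as _glob
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, Iterator, List, Optional, Tuple

import yaml

from . import consensus_output as co
from . import decontamination as decon
from . import mapping_assembly as ma
from . import profile_search as ps
from . import reference_model as rm
from . import seq_io
from .seq_io import GAP, GeneticCode, SeqRecord

_MODE_REF_ALPHABET = {
    "dna": ("dna", "protein"),
    "prot": ("protein",),
    "codon": ("codon",),
    "dna_codon": ("codon",),
}


@dataclass
class RunConfig:
    """Validated run parameters (see :func:`parse_config` for the file format)."""

    mode: str
    references: List[str]
    sources: Dict[str, List[str]]
    outgroup_id: Optional[str] = None
    reference_alphabet: Optional[str] = None  # inferred from mode if None
    genetic_code: int = 1
    revcomp: bool = True
    fragment: Optional[Tuple[int, int]] = None  # query (window, step)
    split_references: Optional[Tuple[int, int]] = None  # column (window, step)
    assemble: bool = True
    asm_min_overlap: Optional[float] = None  # default 30 nt / 10 aa columns
    asm_min_identity: float = 0.98
    foreign_removal: bool = True
    cross_removal: bool = True
    outgroup_weight: float = 0.9
    cross_min_overlap: Optional[int] = None  # default 30 nt / 10 aa columns
    cross_min_identity: float = 0.95
    rpkm_fold: float = 2.0
    min_score: Optional[float] = None
    include_refs: bool = False
    consensus: bool = True
    out_dir: str = "refaln_out"
    seed: int = 0
    threads: int = 1
    low_memory: bool = False
    engine: str = "hmmer"

    @property
    def item_space(self) -> str:
        """Column space downstream items live in (nt for codon modes)."""
        return "amino" if self.mode == "prot" else "dna"

    def resolved_asm_min_overlap(self) -> float:
        if self.asm_min_overlap is not None:
            return self.asm_min_overlap
        return 10 if self.item_space == "amino" else 30

    def resolved_cross_min_overlap(self) -> int:
        if self.cross_min_overlap is not None:
            return self.cross_min_overlap
        return 10 if self.item_space == "amino" else 30

    def validate(self) -> None:
        errors = []
        if self.mode not in ps.SEARCH_MODES:
            errors.append(f"unknown mode {self.mode!r}")
        else:
            alphabet = self.reference_alphabet or _MODE_REF_ALPHABET[self.mode][0]
            if alphabet not in _MODE_REF_ALPHABET[self.mode]:
                errors.append(
                    f"mode {self.mode!r} requires reference alphabet in "
                    f"{_MODE_REF_ALPHABET[self.mode]}, got {alphabet!r}")
        if not self.references:
            errors.append("no reference MSAs configured")
        if not self.sources:
            errors.append("no sources configured")
        for name, files in self.sources.items():
            if not files:
                errors.append(f"source {name!r} has no files")
            for f in files:
                if not Path(f).exists():
                    errors.append(f"source {name!r}: missing file {f}")
        if self.foreign_removal and not self.outgroup_id:
            errors.append("foreign removal enabled but no outgroup named")
        if self.threads < 1:
            errors.append("threads must be >= 1")
        if self.fragment is not None:
            w, s = self.fragment
            if not (w >= s >= 1):
                errors.append("fragment window must be >= step >= 1")
        if errors:
            raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))


_CONFIG_KEYS = {
    "mode", "references", "sources", "outgroup", "reference_alphabet",
    "genetic_code", "revcomp", "fragment", "split_references", "assemble",
    "asm_min_overlap", "asm_min_identity", "foreign_removal", "cross_removal",
    "outgroup_weight", "cross_min_overlap", "cross_min_identity", "rpkm_fold",
    "min_score", "include_refs", "consensus", "out_dir", "seed", "threads",
    "low_memory", "engine",
}


def parse_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration.

    Top-level keys mirror :class:`RunConfig` (``outgroup`` names the
    outgroup taxon); ``references`` entries may be glob patterns;
    ``sources`` maps each source name to a list of read/sequence files.
    Unknown keys and validation violations are reported together.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    refs: List[str] = []
    for entry in raw.get("references", []) or []:
        matches = sorted(_glob.glob(str(entry)))
        refs.extend(matches if matches else [str(entry)])
    sources = {str(k): [str(f) for f in v]
               for k, v in (raw.get("sources") or {}).items()}

    def pair(v):
        return tuple(int(x) for x in v) if v else None

    cfg = RunConfig(
        mode=raw.get("mode", "codon"),
        references=refs,
        sources=sources,
        outgroup_id=raw.get("outgroup"),
        reference_alphabet=raw.get("reference_alphabet"),
        genetic_code=int(raw.get("genetic_code", 1)),
        revcomp=bool(raw.get("revcomp", True)),
        fragment=pair(raw.get("fragment")),
        split_references=pair(raw.get("split_references")),
        assemble=bool(raw.get("assemble", True)),
        asm_min_overlap=raw.get("asm_min_overlap"),
        asm_min_identity=float(raw.get("asm_min_identity", 0.98)),
        foreign_removal=bool(raw.get("foreign_removal", True)),
        cross_removal=bool(raw.get("cross_removal", True)),
        outgroup_weight=float(raw.get("outgroup_weight", 0.9)),
        cross_min_overlap=raw.get("cross_min_overlap"),
        cross_min_identity=float(raw.get("cross_min_identity", 0.95)),
        rpkm_fold=float(raw.get("rpkm_fold", 2.0)),
        min_score=raw.get("min_score"),
        include_refs=bool(raw.get("include_refs", False)),
        consensus=bool(raw.get("consensus", True)),
        out_dir=str(raw.get("out_dir", "refaln_out")),
        seed=int(raw.get("seed", 0)),
        threads=int(raw.get("threads", 1)),
        low_memory=bool(raw.get("low_memory", False)),
        engine=str(raw.get("engine", "hmmer")),
    )
    cfg.validate()
    return cfg


def serialize_config(cfg: RunConfig) -> str:
    data = asdict(cfg)
    data["outgroup"] = data.pop("outgroup_id")
    for key in ("fragment", "split_references"):
        if data[key] is not None:
            data[key] = list(data[key])
    return yaml.safe_dump(data, sort_keys=True)


@dataclass
class RunResult:
    config: RunConfig
    references: Dict[str, rm.ReferenceAlignment]
    consensus: Dict[str, Dict[str, co.ConsensusSequence]]  # locus -> source
    outcomes: Dict[str, Dict[str, str]]  # source -> read id -> outcome
    total_reads: Dict[str, int]
    summary: dict
    output_files: List[Path]


class _AAView:
    """Amino-acid view of a codon-coordinate item, for conservative scoring."""

    def __init__(self, item, code: GeneticCode):
        self.start = item.start // 3
        self.residues = seq_io.translate(item.residues, code, 0)

    @property
    def end(self) -> int:
        return self.start + len(self.residues)


def _codon_as_dna(aln: rm.ReferenceAlignment) -> rm.ReferenceAlignment:
    """Reinterpret a codon alignment on plain nucleotide columns."""
    return rm.ReferenceAlignment(
        locus_id=aln.locus_id, rows=aln.rows, n_columns=aln.n_columns,
        alphabet="dna", outgroup_id=aln.outgroup_id,
        col_offset=aln.col_offset, parent_locus=aln.parent_locus,
    )


def _load_references(cfg: RunConfig) -> Dict[str, rm.ReferenceAlignment]:
    alphabet = cfg.reference_alphabet or _MODE_REF_ALPHABET[cfg.mode][0]
    refs: Dict[str, rm.ReferenceAlignment] = {}
    for path in cfg.references:
        aln = rm.load_reference_msa(path, alphabet, outgroup_id=cfg.outgroup_id)
        if aln.locus_id in refs:
            raise ValueError(f"duplicate locus id {aln.locus_id!r}")
        refs[aln.locus_id] = aln
    if cfg.split_references:
        w, s = cfg.split_references
        split: Dict[str, rm.ReferenceAlignment] = {}
        for aln in refs.values():
            for win in rm.split_reference_msa(aln, w, s):
                split[win.locus_id] = win
        refs = split
    return refs


def _detect_format(path: str) -> str:
    name = Path(path).name.lower()
    if name.endswith(".gz"):
        name = name[:-3]
    return "fastq" if name.endswith((".fastq", ".fq")) else "fasta"


def _iter_source_queries(cfg: RunConfig, source: str) -> Iterator[SeqRecord]:
    for path in cfg.sources[source]:
        for rec in seq_io.read_sequences(path, _detect_format(path), source):
            if cfg.fragment:
                w, s = cfg.fragment
                yield from seq_io.fragment_sequence(rec, w, s)
            else:
                yield rec


def _chunks(it: Iterator, size: int) -> Iterator[list]:
    buf = []
    for x in it:
        buf.append(x)
        if len(buf) >= size:
            yield buf
            buf = []
    if buf:
        yield buf


def _apply_foreign(items, profile, outgroup_row, weight, view):
    """Foreign-removal decisions on items via their scoring views.

    Returns (kept, removed, rows) where rows are per-item report entries
    (item, decision, conservative score, weighted outgroup score).
    """
    kept, removed, rows = [], [], []
    for item in items:
        v = view(item)
        own = decon.conservative_score(v, profile)
        out = decon.outgroup_score(v, profile, outgroup_row)
        foreign = own < weight * out
        (removed if foreign else kept).append(item)
        rows.append((item, "foreign" if foreign else "kept", own, weight * out))
    return kept, removed, rows


def run_pipeline(cfg: RunConfig) -> RunResult:
    """Execute the full reference-guided mapping pipeline."""
    cfg.validate()
    code = GeneticCode.from_ncbi(cfg.genetic_code)
    references = _load_references(cfg)
    loci = sorted(references)

    work = {l: (_codon_as_dna(references[l]) if cfg.mode == "dna_codon"
                else references[l]) for l in loci}
    engine = ps.SearchEngine(references, cfg.mode, code=code,
                             revcomp=cfg.revcomp, min_score=cfg.min_score,
                             engine=cfg.engine)
    profiles = {l: rm.compute_ingroup_profile(work[l], code=code) for l in loci}
    outgroup_rows: Dict[str, Optional[str]] = {}
    for l in loci:
        if cfg.outgroup_id:
            row = work[l].rows[cfg.outgroup_id]
            if work[l].alphabet == "codon":
                row = seq_io.translate(row, code, 0)
            outgroup_rows[l] = row
        else:
            outgroup_rows[l] = None

    # --- search (chunked when low_memory; identical results either way) ---
    chunk_size = 2000 if cfg.low_memory else 10 ** 9
    hits_per_locus: Dict[str, List[ps.SearchHit]] = {l: [] for l in loci}
    total_reads: Dict[str, int] = {}
    mapped_reads: Dict[str, set] = {s: set() for s in cfg.sources}
    for source in sorted(cfg.sources):
        seen_parents = set()
        for chunk in _chunks(_iter_source_queries(cfg, source), chunk_size):
            seen_parents.update(rec.parent_id or rec.id for rec in chunk)
            found = engine.search(chunk, threads=cfg.threads)
            for l in loci:
                hits_per_locus[l].extend(found[l])
        total_reads[source] = len(seen_parents)

    # --- lay hits onto reference columns ---
    segments: Dict[str, Dict[str, List[ma.MappedSegment]]] = {
        l: {s: [] for s in cfg.sources} for l in loci}
    insertion_log: Dict[str, int] = {l: 0 for l in loci}
    for l in loci:
        n_states = engine.n_match_states(l)
        for hit in hits_per_locus[l]:
            seg = ma.map_hit_to_columns(hit, n_states)
            insertion_log[l] += seg.n_insertions
            if cfg.mode == "codon":
                seg = ma.backmap_codons(seg, hit.nucleotides, hit.frame)
            segments[l][hit.source].append(seg)
            mapped_reads[hit.source] |= set(seg.read_ids)

    outcomes: Dict[str, Dict[str, str]] = {
        s: {rid: "retained" for rid in mapped_reads[s]} for s in cfg.sources}

    def mark(item, source: str, outcome: str) -> None:
        for rid in item.read_ids:
            outcomes[source][rid] = outcome

    params = decon.DecontamParams(
        outgroup_weight=cfg.outgroup_weight,
        cross_min_overlap=cfg.resolved_cross_min_overlap(),
        cross_min_identity=cfg.cross_min_identity,
        rpkm_fold_threshold=cfg.rpkm_fold,
    )

    def scoring_view(item):
        return _AAView(item, code) if cfg.mode == "codon" else item

    consensus: Dict[str, Dict[str, co.ConsensusSequence]] = {}
    removal_tally = {l: {"foreign": 0, "cross": 0} for l in loci}
    n_cols = {l: references[l].n_columns for l in loci}
    report_rows: List[dict] = []

    for l in loci:
        if cfg.assemble:
            per_source_items = {
                s: ma.assemble_segments(segments[l][s],
                                        cfg.resolved_asm_min_overlap(),
                                        cfg.asm_min_identity)
                if segments[l][s] else []
                for s in sorted(cfg.sources)}
        else:
            per_source_items = {s: list(segments[l][s]) for s in sorted(cfg.sources)}

        if cfg.foreign_removal:
            for s in sorted(cfg.sources):
                kept, removed, rows = _apply_foreign(
                    per_source_items[s], profiles[l], outgroup_rows[l],
                    cfg.outgroup_weight, scoring_view)
                for item, decision, own, wout in rows:
                    report_rows.append({
                        "locus": l, "source": s,
                        "item": getattr(item, "query_id", None) or
                                ",".join(sorted(item.read_ids)[:1]),
                        "decision": decision, "score": round(own, 4),
                        "weighted_outgroup_score": round(wout, 4),
                        "read_count": item.read_count,
                        "est_rpkm": round(decon.estimated_rpkm(
                            item.read_count, item.end - item.start,
                            total_reads[s]), 10),
                        "donor": "",
                    })
                for item in removed:
                    mark(item, s, "removed_foreign")
                removal_tally[l]["foreign"] += len(removed)
                per_source_items[s] = kept

        if ((cfg.assemble or not cfg.consensus) and cfg.cross_removal
                and len(cfg.sources) > 1):
            removals = decon.detect_cross_contamination(
                per_source_items, params, total_reads)
            for r in removals:
                mark(r.item, r.source, "removed_cross")
                removal_tally[l]["cross"] += 1
                report_rows.append({
                    "locus": l, "source": r.source,
                    "item": getattr(r.item, "query_id", None) or
                            ",".join(sorted(r.item.read_ids)[:1]),
                    "decision": "cross", "score": float("nan"),
                    "weighted_outgroup_score": float("nan"),
                    "read_count": r.item.read_count,
                    "est_rpkm": round(decon.estimated_rpkm(
                        r.item.read_count, r.item.end - r.item.start,
                        total_reads[r.source]), 10),
                    "donor": r.donor,
                })
                per_source_items[r.source] = [
                    i for i in per_source_items[r.source] if i is not r.item]

        if not cfg.consensus:
            # one padded row per surviving item instead of a collapsed row
            locus_consensus = {}
            for s in sorted(cfg.sources):
                for k, item in enumerate(per_source_items[s]):
                    row = (GAP * item.start + item.residues
                           + GAP * (n_cols[l] - item.end))
                    locus_consensus[f"{s}|{k}"] = co.ConsensusSequence(
                        source=s, locus_id=l, residues=row,
                        read_ids=frozenset(item.read_ids))
            consensus[l] = locus_consensus
            continue
        locus_consensus = {
            s: co.consensus_per_source(per_source_items[s], n_cols[l],
                                       source=s, locus_id=l)
            for s in sorted(cfg.sources)}
        if (not cfg.assemble and cfg.cross_removal
                and len(cfg.sources) > 1):
            removals = decon.detect_cross_contamination(
                {s: [c] for s, c in locus_consensus.items() if c.read_count},
                params, total_reads)
            for r in removals:
                mark(r.item, r.source, "removed_cross")
                removal_tally[l]["cross"] += 1
                locus_consensus[r.source] = co.ConsensusSequence(
                    source=r.source, locus_id=l,
                    residues=GAP * n_cols[l], read_ids=frozenset())
        consensus[l] = locus_consensus

    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = co.emit_output_msas(consensus, references, cfg.mode,
                                cfg.include_refs, out_dir, code=code)
    summary = {
        "mode": cfg.mode,
        "loci": {
            l: {
                "n_columns": n_cols[l],
                "sources": {s: consensus[l][s].read_count for s in consensus[l]},
                "removed_foreign_items": removal_tally[l]["foreign"],
                "removed_cross_items": removal_tally[l]["cross"],
                "dropped_insertions": insertion_log[l],
            } for l in loci
        },
        "total_reads": total_reads,
        "mapped_reads": {s: len(mapped_reads[s]) for s in sorted(cfg.sources)},
    }
    co.write_run_summary(summary, out_dir / "run_summary.json")
    files.append(out_dir / "run_summary.json")
    import pandas as pd

    report = pd.DataFrame(
        report_rows,
        columns=["locus", "source", "item", "decision", "score",
                 "weighted_outgroup_score", "read_count", "est_rpkm", "donor"])
    report.to_csv(out_dir / "decontamination.tsv", sep="\t", index=False)
    files.append(out_dir / "decontamination.tsv")
    return RunResult(
        config=cfg, references=references, consensus=consensus,
        outcomes=outcomes, total_reads=total_reads, summary=summary,
        output_files=files,
    )
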