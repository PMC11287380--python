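"""Seeded synthetic contaminated-transcriptome datasets.

The generator emulates a contaminated RNA-seq study design: a reference
clade of five species (four ingroup plus a named outgroup) provides per-locus
reference MSAs; three target species inside the clade provide short-read
sources; distant foreign species and the other co-processed targets
contaminate each source at a few percent of its reads.  At a handful of
designated loci the focal target's own reads are deleted while the
contamination is retained, modelling genes whose signal is pure
contamination.  Every read carries a truth label, so pipeline decisions can
be scored read-by-read.

Evolution is substitution-only along a star phylogeny (each taxon evolves
independently from one ancestor at its stated per-site divergence), which
preserves the divergence ranks the contamination logic depends on.  Coding
sequences are kept free of in-frame stop codons so codon-mode translation is
clean.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .reference_model import ReferenceAlignment
from .seq_io import SeqRecord, write_fasta, write_fastq

_BASES = np.array(list("ACGT"))
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class SimulationDesign:
    """Parameters of the contaminated-transcriptome simulation.

    Divergences are per-site substitution probabilities from the common
    ancestor.  Contamination fractions are relative to each source's own
    read count and are split evenly over the contaminant species of that
    kind.  ``n_removed_loci`` loci lose the targets' own reads while
    keeping the contamination.
    """

    n_loci: int = 40
    locus_length: int = 900  # nucleotides, codon multiple
    ingroup_divergences: Tuple[float, ...] = (0.10, 0.15, 0.20, 0.25)
    outgroup_divergence: float = 0.35
    target_divergences: Tuple[float, ...] = (0.05, 0.125, 0.20)
    foreign_divergences: Tuple[float, ...] = (0.60, 0.675, 0.75)
    read_length: int = 100
    coverage: float = 10.0
    error_rate: float = 0.001
    contamination_fraction: Tuple[float, float] = (0.02, 0.05)
    n_removed_loci: int = 5
    #: gamma shape for among-site (per-codon) rate heterogeneity, shared by
    #: all taxa at a locus; None disables it (uniform rates).  Mean per-site
    #: divergence always equals the stated divergence.
    rate_shape: Optional[float] = 0.4
    seed: int = 0

    def __post_init__(self):
        if self.locus_length % 3:
            raise ValueError("locus_length must be a codon multiple")
        divs = (self.outgroup_divergence, *self.ingroup_divergences,
                *self.target_divergences, *self.foreign_divergences)
        if any(not 0 <= d <= 1 for d in divs):
            raise ValueError("divergences must lie in [0, 1]")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.n_removed_loci > self.n_loci:
            raise ValueError("more removal loci than loci")

    @property
    def reference_taxa(self) -> List[str]:
        return [f"ref{i+1}" for i in range(len(self.ingroup_divergences))] + ["outgroup"]

    @property
    def target_names(self) -> List[str]:
        return [f"target{chr(65+i)}" for i in range(len(self.target_divergences))]

    @property
    def foreign_names(self) -> List[str]:
        return [f"foreign{i+1}" for i in range(len(self.foreign_divergences))]


@dataclass
class SimulatedRead:
    id: str
    residues: str
    species: str  # true species of origin
    locus: str
    start: int  # origin coordinate within the species' locus sequence
    kind: str  # own | foreign | cross


@dataclass
class ContaminatedDataset:
    design: SimulationDesign
    references: Dict[str, ReferenceAlignment]  # locus -> MSA (codon alphabet)
    truth_sequences: Dict[str, Dict[str, str]]  # species -> locus -> sequence
    reads: Dict[str, List[SimulatedRead]]  # source (target name) -> reads
    removed_loci: List[str]

    @property
    def loci(self) -> List[str]:
        return sorted(self.references)

    def read_labels(self, source: str) -> Dict[str, str]:
        return {r.id: r.species for r in self.reads[source]}

    def write(self, out_dir) -> None:
        """Materialise references (FASTA), reads (FASTQ) and truth (TSV)."""
        out_dir = Path(out_dir)
        (out_dir / "references").mkdir(parents=True, exist_ok=True)
        for locus, aln in self.references.items():
            write_fasta(aln.rows.items(), out_dir / "references" / f"{locus}.fa")
        for source, reads in self.reads.items():
            write_fastq(
                (SeqRecord(id=r.id, source=source, residues=r.residues)
                 for r in reads),
                out_dir / f"{source}.fastq",
            )
            with open(out_dir / f"{source}.truth.tsv", "w") as fh:
                fh.write("read_id\tspecies\tlocus\tstart\tkind\n")
                for r in reads:
                    fh.write(f"{r.id}\t{r.species}\t{r.locus}\t{r.start}\t{r.kind}\n")
        with open(out_dir / "removed_loci.txt", "w") as fh:
            for locus in self.removed_loci:
                fh.write(locus + "\n")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def evolve_sequence(ancestor: str, divergence: float, seed,
                    site_probs: Optional[np.ndarray] = None) -> str:
    """Substitute each site with probability ``divergence``.

    A substituted site changes to one of the three other bases uniformly
    (Jukes-Cantor-style observable divergence, no indels).  Deterministic
    for a given seed.  ``site_probs`` optionally replaces the flat
    probability with per-site substitution probabilities (among-site rate
    heterogeneity); their mean should equal ``divergence``.
    """
    if not 0 <= divergence <= 1:
        raise ValueError("divergence must lie in [0, 1]")
    rng = _rng(seed)
    seq = np.array(list(ancestor))
    probs = site_probs if site_probs is not None else divergence
    hits = rng.random(len(seq)) < probs
    idx = np.flatnonzero(hits)
    for i in idx:
        choices = [b for b in "ACGT" if b != seq[i]]
        seq[i] = choices[rng.integers(3)]
    return "".join(seq)


def _site_probs(divergence: float, rates: np.ndarray, shape: float) -> np.ndarray:
    """Per-site substitution probabilities under gamma rate multipliers.

    With rates r ~ Gamma(shape a, mean 1) the probability 1 - exp(-mu * r)
    has mean 1 - (1 + mu/a)^(-a); mu is solved so that the mean equals the
    stated divergence, keeping the stated value exact in expectation.
    """
    if divergence <= 0:
        return np.zeros_like(rates)
    if divergence >= 1:
        return np.ones_like(rates)
    mu = shape * ((1.0 - divergence) ** (-1.0 / shape) - 1.0)
    return 1.0 - np.exp(-mu * rates)


def _repair_stops(seq: str, rng: np.random.Generator) -> str:
    """Replace in-frame stop codons by re-drawing their third position."""
    codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
    for k, codon in enumerate(codons):
        while codon in _STOPS:
            third = "ACGT"[rng.integers(4)]
            codon = codon[:2] + third
        codons[k] = codon
    return "".join(codons)


def _random_coding_sequence(length: int, rng: np.random.Generator) -> str:
    seq = "".join(_BASES[rng.integers(4, size=length)])
    return _repair_stops(seq, rng)


def simulate_reads(sequence: str, read_length: int, coverage: float,
                   error_rate: float, seed, label: str,
                   locus: str = "", kind: str = "own",
                   id_prefix: str = "read",
                   both_strands: bool = False) -> List[SimulatedRead]:
    """Uniform shotgun reads with per-base substitution errors.

    The number of reads is ``ceil(coverage * len / read_length)``; start
    positions are uniform over the valid range; each base is substituted
    with probability ``error_rate``.  With ``both_strands`` half the reads
    are reverse complemented (``start`` stays a plus-strand coordinate).
    Every read records its true origin.
    """
    if read_length > len(sequence):
        raise ValueError("read_length exceeds sequence length")
    rng = _rng(seed)
    n_reads = int(np.ceil(coverage * len(sequence) / read_length))
    starts = rng.integers(0, len(sequence) - read_length + 1, size=n_reads)
    reads = []
    for i, s in enumerate(starts):
        frag = np.array(list(sequence[s:s + read_length]))
        errs = np.flatnonzero(rng.random(read_length) < error_rate)
        for e in errs:
            choices = [b for b in "ACGT" if b != frag[e]]
            frag[e] = choices[rng.integers(3)]
        res = "".join(frag)
        if both_strands and rng.random() < 0.5:
            res = res[::-1].translate(str.maketrans("ACGT", "TGCA"))
        reads.append(SimulatedRead(
            id=f"{id_prefix}_{i}", residues=res, species=label,
            locus=locus, start=int(s), kind=kind,
        ))
    return reads


def _contaminant_reads(dataset_seqs: Dict[str, str], n_reads: int,
                       read_length: int, error_rate: float,
                       rng: np.random.Generator, species: str, kind: str,
                       id_prefix: str) -> List[SimulatedRead]:
    """n reads sampled from a species' loci, weighted by locus length."""
    loci = sorted(dataset_seqs)
    lengths = np.array([len(dataset_seqs[l]) - read_length + 1 for l in loci], dtype=float)
    probs = lengths / lengths.sum()
    picks = rng.choice(len(loci), size=n_reads, p=probs)
    reads = []
    for i, li in enumerate(picks):
        locus = loci[li]
        seq = dataset_seqs[locus]
        s = int(rng.integers(0, len(seq) - read_length + 1))
        frag = np.array(list(seq[s:s + read_length]))
        errs = np.flatnonzero(rng.random(read_length) < error_rate)
        for e in errs:
            choices = [b for b in "ACGT" if b != frag[e]]
            frag[e] = choices[rng.integers(3)]
        res = "".join(frag)
        if rng.random() < 0.5:
            res = res[::-1].translate(str.maketrans("ACGT", "TGCA"))
        reads.append(SimulatedRead(
            id=f"{id_prefix}_{i}", residues=res, species=species,
            locus=locus, start=s, kind=kind,
        ))
    return reads


def build_contaminated_dataset(design: SimulationDesign,
                               contamination: bool = True) -> ContaminatedDataset:
    """Generate references, per-source labelled reads and truth tables.

    Fully reproducible from ``design.seed``.  With ``contamination=False``
    every source contains only its own species' reads (and no loci are
    emptied), which is the clean baseline for end-to-end recovery checks.
    """
    root = np.random.SeedSequence(design.seed)
    (anc_ss, evo_ss, reads_ss, contam_ss, pick_ss) = root.spawn(5)
    anc_rng = np.random.default_rng(anc_ss)
    evo_rng = np.random.default_rng(evo_ss)
    pick_rng = np.random.default_rng(pick_ss)

    loci = [f"locus{str(i+1).zfill(2)}" for i in range(design.n_loci)]
    species_div: List[Tuple[str, float]] = (
        [(t, d) for t, d in zip(design.reference_taxa, design.ingroup_divergences)]
        + [("outgroup", design.outgroup_divergence)]
        + list(zip(design.target_names, design.target_divergences))
        + list(zip(design.foreign_names, design.foreign_divergences))
    )
    # reference_taxa already ends with "outgroup"; drop the duplicate entry
    seen = set()
    uniq = []
    for name, div in species_div:
        if name not in seen:
            uniq.append((name, div))
            seen.add(name)
    species_div = uniq

    truth: Dict[str, Dict[str, str]] = {name: {} for name, _ in species_div}
    references: Dict[str, ReferenceAlignment] = {}
    for locus in loci:
        ancestor = _random_coding_sequence(design.locus_length, anc_rng)
        if design.rate_shape is not None:
            # per-codon rate multipliers, shared by every taxon at this
            # locus: conserved positions are conserved in all lineages
            codon_rates = anc_rng.gamma(design.rate_shape,
                                        1.0 / design.rate_shape,
                                        size=design.locus_length // 3)
            rates = np.repeat(codon_rates, 3)
        else:
            rates = None
        for name, div in species_div:
            probs = (_site_probs(div, rates, design.rate_shape)
                     if rates is not None else None)
            seq = evolve_sequence(ancestor, div, evo_rng, site_probs=probs)
            seq = _repair_stops(seq, evo_rng)
            truth[name][locus] = seq
        rows = {t: truth[t][locus] for t in design.reference_taxa}
        references[locus] = ReferenceAlignment(
            locus_id=locus, rows=rows, n_columns=design.locus_length,
            alphabet="codon", outgroup_id="outgroup",
        )

    if contamination and design.n_removed_loci:
        removed = sorted(pick_rng.choice(design.n_loci, size=design.n_removed_loci,
                                         replace=False))
        removed_loci = [loci[i] for i in removed]
    else:
        removed_loci = []

    reads_rng = np.random.default_rng(reads_ss)
    contam_rng = np.random.default_rng(contam_ss)
    reads: Dict[str, List[SimulatedRead]] = {}
    lo, hi = design.contamination_fraction
    for source in design.target_names:
        own: List[SimulatedRead] = []
        for locus in loci:
            if locus in removed_loci:
                continue
            own.extend(simulate_reads(
                truth[source][locus], design.read_length, design.coverage,
                design.error_rate, reads_rng, label=source, locus=locus,
                kind="own", id_prefix=f"{source}|{locus}", both_strands=True,
            ))
        source_reads = list(own)
        if contamination:
            n_own = len(own)
            foreign_frac = lo + (hi - lo) * contam_rng.random()
            cross_frac = lo + (hi - lo) * contam_rng.random()
            others = [t for t in design.target_names if t != source]
            for donors, frac, kind in ((design.foreign_names, foreign_frac, "foreign"),
                                       (others, cross_frac, "cross")):
                n_per = int(round(frac * n_own / len(donors)))
                for donor in donors:
                    source_reads.extend(_contaminant_reads(
                        truth[donor], n_per, design.read_length,
                        design.error_rate, contam_rng, species=donor,
                        kind=kind, id_prefix=f"{source}|{kind}|{donor}",
                    ))
        reads[source] = source_reads
    return ContaminatedDataset(
        design=design, references=references, truth_sequences=truth,
        reads=reads, removed_loci=removed_loci,
    )
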