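# Methods

This note documents the models, parameter choices and numerical conventions
behind `refaln`, and what the synthetic benchmark does and does not show.

## Profile model and search

Each reference MSA is turned into a profile HMM with exactly one match state
per alignment column. This deviates from the usual hmmbuild behaviour of
selecting consensus columns; the reason is coordinate fidelity: output MSAs
must preserve the reference column set bijectively, so no column may be
dropped by the model-building step.

Two engines share these semantics:

* **Internal engine.** Match emissions use Laplace pseudocounts,
  `e_j(b) = (n_j(b) + κ) / (N_j + κK)` with κ = 1, `n_j(b)` the residue
  count at column j, `N_j` the non-gap count and K the alphabet size; an
  all-gap column degrades to a uniform emission whose probability mass
  flows through the delete states. Transitions are estimated from the
  match/delete runs of the reference rows with Laplace smoothing; insert
  transitions, unobservable in a one-state-per-column model, are fixed at
  I→M = I→I = 1/2. Alignment is Viterbi with free entry into and exit from
  any match state (local in both query and model), scores in log2-odds
  against a uniform background, insert emissions at background (0 bits).
  Ties prefer the earlier entry state, then the earlier query start, making
  results deterministic. The engine is verified against exhaustive
  enumeration of all local paths on a seeded grid of 200 tiny
  profile/query pairs, plus self-recovery of reference rows.
* **HMMER3 engine** (default). Per-locus plan7 models are estimated by
  pyhmmer's builder in *hand architecture* — every column annotated as a
  match column — which keeps the one-state-per-column guarantee while using
  HMMER's priors, sequence weighting and statistical calibration, so the
  standard acceleration filters behave as in stock `hmmsearch`. Hit
  acceptance is by per-domain bit score only (defaults: 10 bits in protein
  space, 15 in nucleotide space; E-values are never used, so results do not
  depend on batch size — a prerequisite for the streaming query path being
  byte-identical to the in-memory path).

Both engines produce the same residue-to-column pair lists; a cross-engine
test asserts identical mapped column sets on a shared fixture. Per query
only the single best (locus, frame, strand) hit is kept, with deterministic
tie-breaks (lexicographic locus, then frame order); whether one read may
serve several loci is a paralog-policy question we resolve conservatively in
favour of a single locus.

## Mapping, assembly, consensus

Insertions relative to the reference are discarded (and tallied per locus)
because the output coordinate system is frozen; deletions appear as gaps
inside the covered interval. In `codon` mode the amino-acid hit is
back-mapped: aa column c occupies nucleotide columns [3c, 3c+3), codons
taken from the read (reverse-complemented first on minus-strand frames).

Assembly merges segments greedily in (start, end, query id) order into the
first contig sharing ≥ `min_overlap` non-gap columns at ≥ `min_identity`
identity; defaults 30 nt / 10 aa columns and 0.98, chosen to merge
same-haplotype reads (sequencing error ~0.1–1%) while keeping sequences from
different samples apart (in-clade samples differ by several percent).
Conflicts resolve by read-count-weighted plurality with an alphabetic
tie-break; read counts accumulate, with fragments of one parent sequence
counted once. Consensus applies the same weighted plurality per column over
a whole sample's surviving items; uncovered columns emit `-` (not N/X) so
downstream trimming treats them as missing data.

Stage order is fixed: with assembly, assemble → foreign removal → cross
removal → consensus; without assembly, foreign removal → consensus → cross
removal (cross-contamination is then judged on whole consensus rows, whose
"read count" is the number of contributing segments — a logged proxy, since
true per-contig read counts only exist when assembly ran).

## Decontamination parameters

* `outgroup_weight` (default **0.9**): an item is foreign iff its
  conservative score is below 0.9× the outgroup's score over the same
  residue positions. Weight 0 disables removal; larger weights are more
  aggressive. The outgroup score counts only columns where the item has a
  residue and the outgroup is ungapped.
* `cross_min_overlap` / `cross_min_identity` (defaults 30 nt or 10 aa
  columns / **0.95**): the flagging condition for cross-sample pairs.
  Identity is computed over columns where both items carry residues.
* `rpkm_fold_threshold` (default **2.0**, strict inequality): abundance
  asymmetry required before the low-abundance copy of a flagged pair is
  removed. Estimated RPKM divides the read count by the item length in
  reference columns and the sample's total read count, so the fold is
  invariant to common rescaling of sequencing depth.

All cross decisions are computed on the pre-removal abundance table and
applied at once, so they are independent of sample ordering; the
higher-abundance member of a flagged pair is never removed.

## The synthetic study design

`SimulationDesign` defaults encode the benchmark conditions: 40 loci × 900
nt codon MSAs over a 5-taxon reference clade (ingroup divergences
0.10–0.25 from the common ancestor, outgroup 0.35); three target samples
inside the clade (0.05–0.20); three foreign contaminant species far beyond
the outgroup (0.60–0.75); 100 bp reads at 10× coverage with 0.1%
substitution error, drawn from both strands; foreign and cross
contamination each a uniform 2–5% of a sample's own reads, split evenly
over the contaminant species; and 5 loci where the targets' own reads are
deleted while contamination is retained. Everything derives from one seed
through independent numpy substreams, and regeneration is byte-identical.

Evolution is substitution-only along a star phylogeny: each taxon evolves
independently from the locus ancestor at its stated divergence, which
preserves the divergence ladder (targets < ingroup < outgroup < foreign)
that the contamination logic depends on, without simulating a full species
tree. Two refinements keep the coding context honest:

* in-frame stop codons created by substitution are re-drawn (a stand-in for
  purifying selection, keeping codon-mode translation clean);
* per-codon rate multipliers r ~ Gamma(shape 0.4, mean 1), shared by all
  taxa at a locus, modulate the per-site substitution probability as
  `p = 1 − exp(−μr)` with μ solved so the mean equals the stated
  divergence. Without among-site rate variation, sequences at foreign
  divergences are effectively random and produce no profile hits at all,
  which fails to emulate the real situation where conserved stretches of
  distant orthologs still align; shape 0.4 is a typical value for
  protein-coding genes.

What the simulator does **not** model: indels (so reference MSAs are
gap-free and valid-region logic is exercised by hand fixtures), coverage
biases, quality-score structure, paired-end reads, paralogy, and — most
consequentially for the benchmark — contaminant reads from genes *outside*
the reference loci. Every synthetic foreign read is an ortholog of a
reference locus, so the foreign reads that map are exclusively the hardest
cases (hyper-conserved windows where foreign, ingroup and outgroup are
nearly identical and no score can separate them). The measured foreign
removal rate (~85–90% of mapped foreign reads) is therefore a conservative
floor; with realistic transcriptome-wide contamination the mapped pool also
contains spurious matches from unrelated genes, which the conservative
score removes essentially always. Passing benchmarks on this simulator show
the machinery is correct under the stated conditions, not that real
contaminated datasets will reach the same numbers.

## Problem sizes and numerics

The benchmark (acceptance script and tests) uses the default design at
three seeds — roughly 10,000 reads per run against 40 profiles of 300 amino
acid columns, under a minute per seed on one CPU; end-to-end unit tests use
a 6-locus version of the same design. Floating-point conventions:
probability distributions validate to 1 within 1e-9; scores compare exactly
at the documented tie-breaks; the RPKM fold uses strict inequality at the
threshold. Degenerate inputs are defined rather than erroneous: empty
consensus input yields an all-gap row, an all-gap column carries no
frequency mass, zero-length translation frames are skipped, and undefined
precision/recall (zero denominator) is reported as NaN with an explicit
flag.

## Known limitations

Paired-end mates are treated as independent reads. One query contributes to
at most one locus. The no-assembly path cannot see read-count asymmetry and
so detects cross-contamination only at consensus granularity. Reference
columns absent from the target (or target regions absent from the
reference) are invisible by construction — this is a reference-based tool
and is not a substitute for de novo assembly when novel sequence matters.
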