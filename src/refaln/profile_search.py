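"""Profile-HMM construction and local search of queries against reference MSAs.

Two engines share one profile parameterisation:

* an internal Viterbi local aligner (pure Python, exhaustively verified
  against brute-force path enumeration on small profiles), and
* HMMER3 via :mod:`pyhmmer`, the default for real workloads.  The
  :class:`ProfileHMM` built here is copied verbatim into a plan7 model with a
  uniform background, so both engines score the same model and produce the
  same residue-to-column coordinates.

Profiles keep **one match state per reference column** (no consensus-column
filtering), so match-state indices map bijectively onto output MSA columns
and no column is ever silently dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pyhmmer
from pyhmmer.easel import Alphabet, DigitalSequenceBlock, TextSequence
from pyhmmer.plan7 import HMM as PlanHMM
from pyhmmer.plan7 import Background, Pipeline, Transitions

from .reference_model import ConservationProfile, ReferenceAlignment
from .seq_io import GAP, GeneticCode, SeqRecord, reverse_complement, six_frame_translations

# plan7 transition column order (module-local aliases)
MM, MI, MD, IM, II, DM, DD = (
    int(Transitions.MM), int(Transitions.MI), int(Transitions.MD),
    int(Transitions.IM), int(Transitions.II), int(Transitions.DM),
    int(Transitions.DD),
)

DNA_SYMBOLS = "ACGT"
AMINO_SYMBOLS = "ACDEFGHIKLMNPQRSTVWY"

#: Default per-hit bit-score thresholds by search space.
DEFAULT_MIN_SCORE = {"amino": 10.0, "dna": 15.0}

SEARCH_MODES = ("dna", "prot", "codon", "dna_codon")

#: Search space (profile alphabet) per mode.
MODE_SPACE = {"dna": None, "prot": "amino", "codon": "amino", "dna_codon": "dna"}


@dataclass
class ProfileHMM:
    """A profile HMM with one match state per reference column.

    ``match_emissions`` has shape (M+1, K) with row 0 unused; ``transitions``
    has shape (M+1, 7) in plan7 column order (MM, MI, MD, IM, II, DM, DD),
    row 0 holding the begin-state transitions and row M the exit.  The
    background is uniform, so emission log-odds are ``log2(K * e)``.
    """

    locus_id: str
    alphabet: str  # "dna" | "amino"
    symbols: str
    match_emissions: np.ndarray
    insert_emissions: np.ndarray
    transitions: np.ndarray
    background: np.ndarray

    @property
    def n_match_states(self) -> int:
        return self.match_emissions.shape[0] - 1

    def validate(self, tol: float = 1e-9) -> None:
        M = self.n_match_states
        if M < 1:
            raise ValueError("profile needs >= 1 match state")
        if not np.allclose(self.match_emissions[1:].sum(axis=1), 1.0, atol=tol):
            raise ValueError("match emissions do not sum to 1")
        if abs(self.insert_emissions.sum() - 1.0) > tol:
            raise ValueError("insert emissions do not sum to 1")
        t = self.transitions
        for j in range(M + 1):
            if abs(t[j, MM] + t[j, MI] + t[j, MD] - 1.0) > tol:
                raise ValueError(f"node {j}: M transitions do not sum to 1")
            if abs(t[j, IM] + t[j, II] - 1.0) > tol:
                raise ValueError(f"node {j}: I transitions do not sum to 1")
            if abs(t[j, DM] + t[j, DD] - 1.0) > tol:
                raise ValueError(f"node {j}: D transitions do not sum to 1")


@dataclass
class SearchHit:
    """A query-to-profile local alignment.

    ``aligned_pairs`` is an ordered list of ``(query_index, state_index)``
    tuples where ``query_index is None`` marks a deletion (reference column
    with no query residue) and ``state_index is None`` marks an insertion
    (query residue between reference columns).  Match-state indices are
    0-based and strictly increasing; query indices are strictly increasing
    over non-deletion pairs.  ``residues`` is the searched string the query
    indices refer to (e.g. one translation frame of a read).
    """

    query_id: str
    source: str
    frame: Optional[Tuple[str, int]]
    locus_id: str
    score: float
    aligned_pairs: List[Tuple[Optional[int], Optional[int]]]
    residues: str
    parent_id: Optional[str] = None
    offset: int = 0
    #: original nucleotide sequence of the query when ``residues`` is a
    #: translation frame (needed for codon back-mapping)
    nucleotides: Optional[str] = None

    def __post_init__(self):
        last_q = -1
        last_s = -1
        for qi, sj in self.aligned_pairs:
            if qi is None and sj is None:
                raise ValueError("aligned pair cannot be (None, None)")
            if sj is not None:
                if sj <= last_s:
                    raise ValueError("match-state indices must strictly increase")
                last_s = sj
            if qi is not None:
                if qi <= last_q:
                    raise ValueError("query indices must strictly increase")
                last_q = qi


def build_profile_hmm(aln: ReferenceAlignment, pseudocount: float = 1.0,
                      code: Optional[GeneticCode] = None) -> ProfileHMM:
    """Estimate a profile HMM from a reference MSA.

    Emissions use Laplace-style pseudocounts:
    ``(count + pseudocount) / (non-gap residues + pseudocount * K)``; an
    all-gap column therefore falls back to a uniform emission with its
    delete transitions carrying most of the probability mass.  Transitions
    are estimated from the per-row match/delete runs (gaps) with Laplace
    smoothing; insert transitions, unobservable from an alignment with one
    match state per column, are fixed at I->M = I->I = 1/2.
    """
    if not aln.rows:
        raise ValueError("empty alignment")
    work = aln.translated(code or GeneticCode.from_ncbi(1)) if aln.alphabet == "codon" else aln
    symbols = DNA_SYMBOLS if work.alphabet == "dna" else AMINO_SYMBOLS
    sym_index = {s: i for i, s in enumerate(symbols)}
    K = len(symbols)
    M = work.n_columns
    rows = list(work.rows.values())
    n_rows = len(rows)

    counts = np.zeros((M + 1, K))
    for row in rows:
        for j, r in enumerate(row):
            k = sym_index.get(r)
            if k is not None:
                counts[j + 1, k] += 1
    denom = counts[1:].sum(axis=1, keepdims=True) + pseudocount * K
    emis = np.empty((M + 1, K))
    emis[0] = 1.0 / K
    emis[1:] = (counts[1:] + pseudocount) / denom

    # Per-node transition counts from match/delete runs.  Column j of a row
    # is an M state if it carries a residue-or-ambiguity, a D state if it is
    # a gap; node 0 is the begin state (treated as M), node M+1 the end.
    mm = np.zeros(M + 1)
    md = np.zeros(M + 1)
    dm = np.zeros(M + 1)
    dd = np.zeros(M + 1)
    for row in rows:
        states = [True] + [r != GAP for r in row] + [True]
        for j in range(M + 1):
            if states[j]:
                (mm if states[j + 1] else md)[j] += 1
            else:
                (dm if states[j + 1] else dd)[j] += 1
    trans = np.zeros((M + 1, 7))
    for j in range(M + 1):
        m_tot = mm[j] + md[j] + 3.0  # Laplace over {MM, MI, MD}
        trans[j, MM] = (mm[j] + 1.0) / m_tot
        trans[j, MI] = 1.0 / m_tot
        trans[j, MD] = (md[j] + 1.0) / m_tot
        d_tot = dm[j] + dd[j] + 2.0
        trans[j, DM] = (dm[j] + 1.0) / d_tot
        trans[j, DD] = (dd[j] + 1.0) / d_tot
        trans[j, IM] = 0.5
        trans[j, II] = 0.5
    # Boundary conventions: no delete state at node 0; no D/MD out of node M.
    trans[0, DM], trans[0, DD] = 1.0, 0.0
    m_tot = mm[M] + 2.0
    trans[M, MM] = (mm[M] + 1.0) / m_tot
    trans[M, MI] = 1.0 / m_tot
    trans[M, MD] = 0.0
    trans[M, DM], trans[M, DD] = 1.0, 0.0

    hmm = ProfileHMM(
        locus_id=aln.locus_id,
        alphabet=work.alphabet if work.alphabet == "dna" else "amino",
        symbols=symbols,
        match_emissions=emis,
        insert_emissions=np.full(K, 1.0 / K),
        transitions=trans,
        background=np.full(K, 1.0 / K),
    )
    hmm.validate()
    return hmm


# ---------------------------------------------------------------------------
# internal Viterbi engine
# ---------------------------------------------------------------------------

def viterbi_local_align(hmm: ProfileHMM, residues: str,
                        min_score: Optional[float] = None) -> Optional[SearchHit]:
    """Best local alignment of a query to the profile, in log2-odds bits.

    Entry into and exit from any match state are free (Smith-Waterman-style
    locality); insert states emit at background (zero log-odds); residues
    outside the profile alphabet (ambiguity codes) emit at background.
    Returns ``None`` when the best score is below ``min_score``.  Ties are
    broken deterministically: prefer the earlier entry state, then the
    earlier query start.
    """
    residues = residues.upper()
    hmm.validate()
    sym_index = {s: i for i, s in enumerate(hmm.symbols)}
    unknown_dna = set("RYSWKMBVDHNU")
    unknown_prot = set("XBJZOU")
    unknown = unknown_dna if hmm.alphabet == "dna" else unknown_prot
    for c in residues:
        if c not in sym_index and c not in unknown:
            raise ValueError(f"residue {c!r} outside profile alphabet")
    L, M = len(residues), hmm.n_match_states
    with np.errstate(divide="ignore"):
        lo = np.log2(hmm.match_emissions / hmm.background)  # (M+1, K)
        lt = np.log2(hmm.transitions)

    NEG = float("-inf")
    # cell value: (score, entry_j, entry_i, backpointer); backpointer is
    # (state, i, j) or ("entry",)
    def empty():
        return [[(NEG, 0, 0, None)] * (M + 1) for _ in range(L + 1)]

    VM, VI, VD = empty(), empty(), empty()

    def better(a, b):
        """True if candidate a beats b (higher score, then earlier entry)."""
        if a[0] != b[0]:
            return a[0] > b[0]
        return (a[1], a[2]) < (b[1], b[2])

    for i in range(1, L + 1):
        k = sym_index.get(residues[i - 1])
        for j in range(1, M + 1):
            em = lo[j, k] if k is not None else 0.0
            best = (em, j, i - 1, ("entry",))
            prev = VM[i - 1][j - 1]
            if prev[0] > NEG:
                cand = (prev[0] + lt[j - 1, MM] + em, prev[1], prev[2], ("M", i - 1, j - 1))
                if better(cand, best):
                    best = cand
            prev = VI[i - 1][j - 1]
            if prev[0] > NEG:
                cand = (prev[0] + lt[j - 1, IM] + em, prev[1], prev[2], ("I", i - 1, j - 1))
                if better(cand, best):
                    best = cand
            prev = VD[i - 1][j - 1]
            if prev[0] > NEG:
                cand = (prev[0] + lt[j - 1, DM] + em, prev[1], prev[2], ("D", i - 1, j - 1))
                if better(cand, best):
                    best = cand
            VM[i][j] = best
            # insert state at node j (emission at background: 0 bits)
            besti = (NEG, 0, 0, None)
            prev = VM[i - 1][j]
            if prev[0] > NEG:
                cand = (prev[0] + lt[j, MI], prev[1], prev[2], ("M", i - 1, j))
                if better(cand, besti):
                    besti = cand
            prev = VI[i - 1][j]
            if prev[0] > NEG:
                cand = (prev[0] + lt[j, II], prev[1], prev[2], ("I", i - 1, j))
                if better(cand, besti):
                    besti = cand
            VI[i][j] = besti
            # delete state at node j (no query consumption)
            bestd = (NEG, 0, 0, None)
            prev = VM[i][j - 1]
            if prev[0] > NEG:
                cand = (prev[0] + lt[j - 1, MD], prev[1], prev[2], ("M", i, j - 1))
                if better(cand, bestd):
                    bestd = cand
            prev = VD[i][j - 1]
            if prev[0] > NEG:
                cand = (prev[0] + lt[j - 1, DD], prev[1], prev[2], ("D", i, j - 1))
                if better(cand, bestd):
                    bestd = cand
            VD[i][j] = bestd

    end = None
    end_ij = None
    for i in range(1, L + 1):
        for j in range(1, M + 1):
            cell = VM[i][j]
            if cell[0] == NEG:
                continue
            if end is None or better(cell, end):
                end = cell
                end_ij = (i, j)
    if end is None:
        return None
    score = end[0]
    if min_score is not None and score < min_score:
        return None

    # traceback
    pairs: List[Tuple[Optional[int], Optional[int]]] = []
    state, (i, j) = "M", end_ij
    while True:
        if state == "M":
            cell = VM[i][j]
            pairs.append((i - 1, j - 1))
        elif state == "I":
            cell = VI[i][j]
            pairs.append((i - 1, None))
        else:
            cell = VD[i][j]
            pairs.append((None, j - 1))
        bp = cell[3]
        if bp is None or bp == ("entry",):
            break
        state, i, j = bp
    pairs.reverse()
    return SearchHit(
        query_id="", source="", frame=None, locus_id=hmm.locus_id,
        score=float(score), aligned_pairs=pairs, residues=residues,
    )


# ---------------------------------------------------------------------------
# plan7 (pyhmmer) engine
# ---------------------------------------------------------------------------

def _easel_alphabet(alphabet: str) -> Alphabet:
    return Alphabet.dna() if alphabet == "dna" else Alphabet.amino()


def to_plan7(hmm: ProfileHMM) -> PlanHMM:
    """Copy a :class:`ProfileHMM` into a pyhmmer plan7 model verbatim."""
    abc = _easel_alphabet(hmm.alphabet)
    if abc.K != len(hmm.symbols) or abc.symbols[: abc.K] != hmm.symbols:
        raise ValueError("alphabet mismatch between profile and easel")
    M = hmm.n_match_states
    plan = PlanHMM(abc, M, hmm.locus_id)
    me = np.asarray(plan.match_emissions)
    me[1:] = hmm.match_emissions[1:]
    me[0] = 0.0
    me[0, 0] = 1.0
    np.asarray(plan.insert_emissions)[:] = hmm.insert_emissions
    np.asarray(plan.transition_probabilities)[:] = hmm.transitions
    # Statistical calibration parameters are required by the search pipeline
    # but unused here: hit acceptance is by bit score, never E-value.
    ep = plan.evalue_parameters
    ep.v_mu, ep.v_lambda = -6.6, 0.72
    ep.f_tau, ep.f_lambda = -4.4, 0.72
    plan.set_consensus()
    plan.set_composition()
    plan.validate()
    return plan


def _pairs_from_alignment_strings(hmm_seq: str, target_seq: str,
                                  hmm_from: int, target_from: int):
    """Residue/state pairs from a pair of aligned strings.

    ``hmm_from``/``target_from`` are 1-based (HMMER convention).  A ``.`` or
    ``-`` in the profile string marks an insertion; a ``-`` in the target
    string marks a deletion.
    """
    if len(hmm_seq) != len(target_seq):
        raise ValueError("aligned strings differ in length")
    pairs = []
    sj = hmm_from - 1
    qi = target_from - 1
    for hc, tc in zip(hmm_seq, target_seq):
        h_gap = hc in ".-"
        t_gap = tc == "-"
        if h_gap and t_gap:
            raise ValueError("gap aligned to gap in alignment strings")
        if h_gap:
            pairs.append((qi, None))
            qi += 1
        elif t_gap:
            pairs.append((None, sj))
            sj += 1
        else:
            pairs.append((qi, sj))
            qi += 1
            sj += 1
    return pairs


def build_plan7_from_msa(aln: ReferenceAlignment, alphabet: str,
                         code: Optional[GeneticCode] = None,
                         seed: int = 42) -> PlanHMM:
    """HMMER-estimated plan7 model with one match state per column.

    Uses hand architecture (every column annotated as a reference/match
    column), so hit coordinates map bijectively onto output columns while
    HMMER's own priors, sequence weighting and statistical calibration make
    the heuristic filter pipeline behave as in a stock hmmsearch.
    """
    from pyhmmer.easel import TextMSA
    from pyhmmer.plan7 import Builder

    work = aln.translated(code or GeneticCode.from_ncbi(1)) \
        if aln.alphabet == "codon" else aln
    abc = _easel_alphabet(alphabet)
    seqs = [TextSequence(name=t, sequence=r.replace("*", "X").replace("?", "-"))
            for t, r in work.rows.items()]
    msa = TextMSA(name=aln.locus_id, sequences=seqs)
    msa.reference = "x" * work.n_columns
    plan, _, _ = Builder(abc, architecture="hand", seed=seed).build_msa(
        msa.digitize(abc), Background(abc))
    if plan.M != work.n_columns:  # pragma: no cover - hand arch guarantees this
        raise RuntimeError(f"{aln.locus_id}: plan7 M {plan.M} != columns")
    return plan


# ---------------------------------------------------------------------------
# multi-locus query search
# ---------------------------------------------------------------------------

def _check_mode_alphabet(mode: str, alignments: Dict[str, ReferenceAlignment]) -> str:
    """Validate mode/reference compatibility; return the search space."""
    if mode not in SEARCH_MODES:
        raise ValueError(f"unknown mode {mode!r}")
    alphabets = {a.alphabet for a in alignments.values()}
    if len(alphabets) != 1:
        raise ValueError(f"references mix alphabets {sorted(alphabets)}")
    (alphabet,) = alphabets
    required = {"prot": ("protein",), "codon": ("codon",),
                "dna_codon": ("codon",), "dna": ("dna", "protein")}[mode]
    if alphabet not in required:
        raise ValueError(
            f"mode {mode!r} requires reference alphabet in {required}, "
            f"got {alphabet!r}")
    if mode in ("prot", "codon"):
        return "amino"
    if mode == "dna" and alphabet == "protein":
        return "amino"
    return "dna"


class SearchEngine:
    """Per-locus profile models plus the query-dispatch logic of one run.

    Models are built once; :meth:`search` may then be called repeatedly on
    query chunks (the streaming path) with results identical to a single
    in-memory call, since per-query best-locus selection never crosses
    queries.
    """

    def __init__(self, references: Dict[str, ReferenceAlignment], mode: str,
                 code: Optional[GeneticCode] = None, revcomp: bool = True,
                 min_score: Optional[float] = None, engine: str = "hmmer",
                 pseudocount: float = 1.0):
        if engine not in ("hmmer", "internal"):
            raise ValueError(f"unknown engine {engine!r}")
        self.mode = mode
        self.code = code or GeneticCode.from_ncbi(1)
        self.revcomp = revcomp
        self.engine = engine
        self.space = _check_mode_alphabet(mode, references)
        self.min_score = DEFAULT_MIN_SCORE[self.space] if min_score is None else min_score
        work = {}
        for locus, aln in sorted(references.items()):
            if mode == "dna_codon":
                aln = ReferenceAlignment(
                    locus_id=aln.locus_id, rows=aln.rows, n_columns=aln.n_columns,
                    alphabet="dna", outgroup_id=aln.outgroup_id,
                    col_offset=aln.col_offset, parent_locus=aln.parent_locus)
            work[locus] = aln
        self.hmms: Dict[str, ProfileHMM] = {
            l: build_profile_hmm(a, pseudocount=pseudocount, code=self.code)
            for l, a in work.items()}
        if engine == "hmmer":
            self.abc = _easel_alphabet(self.space)
            self.bg = Background(self.abc)
            self.plans = {l: build_plan7_from_msa(a, self.space, code=self.code)
                          for l, a in work.items()}

    def n_match_states(self, locus_id: str) -> int:
        return self.hmms[locus_id].n_match_states

    # -- query preparation --------------------------------------------------
    def _variants(self, record: SeqRecord):
        """(frame, residues) search variants of one query."""
        if self.mode in ("prot", "codon"):
            out = []
            for frame, aa in six_frame_translations(record, self.code):
                if aa:
                    out.append((frame, aa.replace("*", "X")))
            return out
        if self.space == "amino":  # dna mode over protein references
            return [(None, record.residues)]
        out = [(None, record.residues)]
        if self.revcomp:
            out.append((("-", 0), reverse_complement(record.residues)))
        return out

    # -- search -------------------------------------------------------------
    def search(self, records: Iterable[SeqRecord], threads: int = 1,
               ) -> Dict[str, List[SearchHit]]:
        """Search a batch of queries; one best hit per query, grouped by locus.

        Only the best-scoring (locus, frame, strand) combination per query
        is retained; ties break to the lexicographically smaller locus id,
        then the earlier frame.  Per-locus searches are independent, so the
        result is byte-identical for any ``threads`` value.
        """
        records = list(records)
        variants = []  # (record index, frame, residues)
        for ri, rec in enumerate(records):
            for frame, res in self._variants(rec):
                variants.append((ri, frame, res))
        best: Dict[int, Tuple] = {}

        def frame_rank(frame):
            if frame is None:
                return 0
            strand, phase = frame
            return 1 + (3 if strand == "-" else 0) + phase

        def consider(ri, frame, residues, locus_id, score, pairs):
            key = (-score, locus_id, frame_rank(frame))
            cur = best.get(ri)
            if cur is None or key < cur[0]:
                best[ri] = (key, frame, residues, locus_id, score, pairs)

        loci = sorted(self.hmms)
        if self.engine == "hmmer":
            block = DigitalSequenceBlock(self.abc, [
                TextSequence(name=str(v), sequence=res).digitize(self.abc)
                for v, (_, _, res) in enumerate(variants)])

            def run(locus_id):
                pli = Pipeline(self.abc, self.bg,
                               T=self.min_score, domT=self.min_score,
                               incT=self.min_score, incdomT=self.min_score)
                found = {}
                for hit in pli.search_hmm(self.plans[locus_id], block):
                    name = hit.name
                    if isinstance(name, bytes):
                        name = name.decode()
                    for dom in hit.domains:
                        if dom.score < self.min_score:
                            continue
                        cur = found.get(name)
                        if cur is None or dom.score > cur[0]:
                            found[name] = (float(dom.score), dom.alignment)
                return locus_id, found

            if threads > 1:
                from concurrent.futures import ThreadPoolExecutor

                with ThreadPoolExecutor(max_workers=threads) as pool:
                    results = dict(pool.map(run, loci))
            else:
                results = dict(run(l) for l in loci)
            for locus_id in loci:
                for name, (score, ali) in results[locus_id].items():
                    ri, frame, res = variants[int(name)]
                    pairs = _pairs_from_alignment_strings(
                        ali.hmm_sequence, ali.target_sequence,
                        ali.hmm_from, ali.target_from)
                    consider(ri, frame, res, locus_id, score, pairs)
        else:
            for locus_id in loci:
                hmm = self.hmms[locus_id]
                for ri, frame, res in variants:
                    hit = viterbi_local_align(hmm, res, min_score=self.min_score)
                    if hit is not None:
                        consider(ri, frame, res, locus_id, hit.score,
                                 hit.aligned_pairs)

        out: Dict[str, List[SearchHit]] = {locus: [] for locus in loci}
        for ri in sorted(best):
            _, frame, res, locus_id, score, pairs = best[ri]
            rec = records[ri]
            out[locus_id].append(SearchHit(
                query_id=rec.id, source=rec.source, frame=frame,
                locus_id=locus_id, score=score, aligned_pairs=pairs,
                residues=res, parent_id=rec.parent_id, offset=rec.offset,
                nucleotides=rec.residues if frame is not None and self.space == "amino" else None,
            ))
        return out


def search_queries(records: Iterable[SeqRecord],
                   references: Dict[str, ReferenceAlignment], mode: str,
                   code: Optional[GeneticCode] = None, revcomp: bool = True,
                   min_score: Optional[float] = None, engine: str = "hmmer",
                   threads: int = 1) -> Dict[str, List[SearchHit]]:
    """One-shot convenience wrapper around :class:`SearchEngine`."""
    eng = SearchEngine(references, mode, code=code, revcomp=revcomp,
                       min_score=min_score, engine=engine)
    return eng.search(records, threads=threads)


# ---------------------------------------------------------------------------
# external-report adapter
# ---------------------------------------------------------------------------

_REPORT_COLUMNS = ["query_id", "source", "locus_id", "frame", "score",
                   "hmm_from", "target_from", "hmm_seq", "target_seq"]


def write_hits_report(hits: Iterable[SearchHit], path) -> None:
    """Dump hits in the engine-agnostic tabular report format."""
    with open(path, "w") as out:
        out.write("\t".join(_REPORT_COLUMNS) + "\n")
        for h in hits:
            frame = "." if h.frame is None else f"{h.frame[0]}{h.frame[1]}"
            hmm_seq = []
            tgt_seq = []
            first_state = next(s for _, s in h.aligned_pairs if s is not None)
            first_q = next(q for q, _ in h.aligned_pairs if q is not None)
            for qi, sj in h.aligned_pairs:
                hmm_seq.append("." if sj is None else "x")
                tgt_seq.append("-" if qi is None else h.residues[qi])
            out.write("\t".join([
                h.query_id, h.source, h.locus_id, frame, f"{h.score:.2f}",
                str(first_state + 1), str(first_q + 1),
                "".join(hmm_seq), "".join(tgt_seq),
            ]) + "\n")


def parse_external_hits(path, hmms: Dict[str, ProfileHMM]) -> List[SearchHit]:
    """Parse an alignment-bearing tabular report into :class:`SearchHit`s.

    The report is one row per domain with 1-based ``hmm_from``/``target_from``
    coordinates and a pair of aligned strings (profile / target), the layout
    HMMER3's per-domain alignment output reduces to.  Downstream stages are
    thereby engine-agnostic.
    """
    hits = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _REPORT_COLUMNS:
            raise ValueError(f"{path}: unexpected report header {header}")
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(_REPORT_COLUMNS):
                raise ValueError(f"{path}:{lineno}: expected {len(_REPORT_COLUMNS)} fields")
            (query_id, source, locus_id, frame_s, score_s,
             hmm_from_s, target_from_s, hmm_seq, target_seq) = fields
            if locus_id not in hmms:
                raise ValueError(f"{path}:{lineno}: unknown locus {locus_id!r}")
            frame = None if frame_s == "." else (frame_s[0], int(frame_s[1:]))
            pairs = _pairs_from_alignment_strings(
                hmm_seq, target_seq, int(hmm_from_s), int(target_from_s))
            max_state = max((s for _, s in pairs if s is not None), default=-1)
            if max_state >= hmms[locus_id].n_match_states:
                raise ValueError(
                    f"{path}:{lineno}: match state {max_state + 1} exceeds "
                    f"profile length {hmms[locus_id].n_match_states}"
                )
            residues = target_seq.replace("-", "")
            # target_from may start past 0; pad so query indices line up
            residues = " " * (int(target_from_s) - 1) + residues
            hits.append(SearchHit(
                query_id=query_id, source=source, frame=frame,
                locus_id=locus_id, score=float(score_s),
                aligned_pairs=pairs, residues=residues,
            ))
    return hits
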