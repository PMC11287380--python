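import math

import numpy as np
import pytest

from refaln.profile_search import (DD, DM, II, IM, MD, MI, MM, ProfileHMM,
                                   SearchEngine, build_profile_hmm,
                                   parse_external_hits, search_queries,
                                   to_plan7, viterbi_local_align,
                                   write_hits_report)
from refaln.reference_model import ReferenceAlignment
from refaln.seq_io import SeqRecord, reverse_complement
from refaln.synth_data import evolve_sequence


def make_aln(rows, alphabet="dna", outgroup=None, locus="L"):
    rows = dict(rows)
    return ReferenceAlignment(
        locus_id=locus, rows=rows,
        n_columns=len(next(iter(rows.values()))),
        alphabet=alphabet, outgroup_id=outgroup)


def conserved_dna_msa(n_rows=4, n_cols=30, seed=0, locus="L"):
    """Rows derived from one ancestor, mutated only away from the ends."""
    rng = np.random.default_rng(seed)
    anc = "".join(rng.choice(list("ACGT"), size=n_cols))
    rows = {}
    for i in range(n_rows):
        row = list(anc)
        for p in rng.choice(np.arange(3, n_cols - 3), size=max(1, n_cols // 10),
                            replace=False):
            row[p] = rng.choice([b for b in "ACGT" if b != row[p]])
        rows[f"t{i}"] = "".join(row)
    return make_aln(rows, locus=locus)


# ---------------------------------------------------------------------------
# profile construction
# ---------------------------------------------------------------------------

class TestBuildProfile:
    def test_emission_pseudocount_formula(self):
        aln = make_aln({"a": "A", "b": "A", "c": "A", "d": "T"})
        hmm = build_profile_hmm(aln, pseudocount=1.0)
        a_idx = hmm.symbols.index("A")
        assert hmm.match_emissions[1, a_idx] == pytest.approx((3 + 1) / (4 + 4))

    def test_all_gap_column_uniform_with_delete_mass(self):
        aln = make_aln({"a": "A-A", "b": "C-C"})
        hmm = build_profile_hmm(aln)
        assert np.allclose(hmm.match_emissions[2], 0.25)
        # every row deletes through node 2: D-transitions dominate
        assert hmm.transitions[1, MD] > hmm.transitions[1, MM]
        assert hmm.transitions[2, DM] > 0.5

    def test_one_match_state_per_column(self):
        rng = np.random.default_rng(2)
        for _ in range(15):
            n, m = rng.integers(2, 6), rng.integers(1, 12)
            rows = {f"t{i}": "".join(rng.choice(list("ACGT-"), size=m))
                    for i in range(n)}
            hmm = build_profile_hmm(make_aln(rows))
            assert hmm.n_match_states == m
            hmm.validate()

    def test_empty_alignment_rejected(self):
        aln = make_aln({"a": "A"})
        aln.rows.clear()
        with pytest.raises(ValueError):
            build_profile_hmm(aln)


# ---------------------------------------------------------------------------
# brute-force oracle for the Viterbi engine
# ---------------------------------------------------------------------------

def brute_force_best_score(hmm: ProfileHMM, query: str) -> float:
    """Exhaustive enumeration of all local paths (entry/exit at match states).

    Mirrors the model definition only: match emissions in log2-odds against
    the background, insert emissions at background (0 bits), transitions in
    log2; free entry into and exit from any match state.
    """
    with np.errstate(divide="ignore"):
        lo = np.log2(hmm.match_emissions / hmm.background)
        lt = np.log2(hmm.transitions)
    L, M = len(query), hmm.n_match_states
    sym = {s: i for i, s in enumerate(hmm.symbols)}
    best = [-math.inf]

    def emit(j, i):
        k = sym.get(query[i])
        return lo[j, k] if k is not None else 0.0

    def step(state, i, j, score):
        # i = residues consumed so far, j = current node
        if state == "M":
            best[0] = max(best[0], score)
            if j < M and i < L:
                step("M", i + 1, j + 1, score + lt[j, MM] + emit(j + 1, i))
            if i < L:
                step("I", i + 1, j, score + lt[j, MI])
            if j < M:
                step("D", i, j + 1, score + lt[j, MD])
        elif state == "I":
            if i < L:
                step("I", i + 1, j, score + lt[j, II])
            if j < M and i < L:
                step("M", i + 1, j + 1, score + lt[j, IM] + emit(j + 1, i))
        else:  # D
            if j < M:
                step("D", i, j + 1, score + lt[j, DD])
            if j < M and i < L:
                step("M", i + 1, j + 1, score + lt[j, DM] + emit(j + 1, i))

    for i0 in range(L):
        for j0 in range(1, M + 1):
            step("M", i0 + 1, j0, emit(j0, i0))
    return best[0]


class TestViterbi:
    def test_matches_exhaustive_enumeration_on_seeded_grid(self):
        """Viterbi == brute force on 200 random tiny profile/query pairs."""
        rng = np.random.default_rng(42)
        for case in range(200):
            m = int(rng.integers(1, 6))  # <= 5 match states
            n = int(rng.integers(2, 5))
            rows = {f"t{i}": "".join(rng.choice(list("ACGT-"), size=m,
                                                p=[0.22] * 4 + [0.12]))
                    for i in range(n)}
            if all(set(r) == {"-"} for r in rows.values()):
                continue
            hmm = build_profile_hmm(make_aln(rows))
            query = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 7))))
            hit = viterbi_local_align(hmm, query)
            expected = brute_force_best_score(hmm, query)
            assert hit is not None
            assert hit.score == pytest.approx(expected, abs=1e-9), \
                f"case {case}: {rows} vs {query}"

    def test_self_recovery_of_reference_rows(self):
        aln = conserved_dna_msa(seed=5)
        hmm = build_profile_hmm(aln)
        for row in aln.rows.values():
            hit = viterbi_local_align(hmm, row)
            assert hit.aligned_pairs == [(i, i) for i in range(len(row))]

    def test_score_invariant_under_flanking_padding(self):
        aln = conserved_dna_msa(seed=8)
        hmm = build_profile_hmm(aln)
        core = next(iter(aln.rows.values()))
        base = viterbi_local_align(hmm, core).score
        rng = np.random.default_rng(1)
        pad = lambda k: "".join(rng.choice(list("ACGT"), size=k))
        padded = viterbi_local_align(hmm, pad(8) + core + pad(8))
        assert padded.score == pytest.approx(base, abs=1e-9)

    def test_unrelated_query_below_threshold(self):
        aln = conserved_dna_msa(seed=3, n_cols=40)
        hmm = build_profile_hmm(aln)
        rng = np.random.default_rng(99)
        junk = "".join(rng.choice(list("ACGT"), size=25))
        assert viterbi_local_align(hmm, junk, min_score=15.0) is None

    def test_alphabet_mismatch_rejected(self):
        hmm = build_profile_hmm(conserved_dna_msa())
        with pytest.raises(ValueError):
            viterbi_local_align(hmm, "ACFG")


# ---------------------------------------------------------------------------
# multi-locus dispatch
# ---------------------------------------------------------------------------

class TestSearchQueries:
    def test_best_locus_wins(self):
        a = conserved_dna_msa(seed=11, locus="A")
        rng = np.random.default_rng(4)
        b_rows = {t: "".join(rng.choice(list("ACGT"), size=a.n_columns))
                  for t in a.rows}
        b = make_aln(b_rows, locus="B")
        query = SeqRecord(id="q", source="s",
                          residues=next(iter(a.rows.values())))
        found = search_queries([query], {"A": a, "B": b}, "dna",
                               engine="internal", min_score=5.0)
        assert len(found["A"]) == 1 and found["B"] == []

    def test_revcomp_option_semantics(self):
        a = conserved_dna_msa(seed=12, n_cols=40)
        minus = SeqRecord(id="q", source="s",
                          residues=reverse_complement(next(iter(a.rows.values()))))
        on = search_queries([minus], {"L": a}, "dna", engine="internal",
                            revcomp=True, min_score=5.0)
        off = search_queries([minus], {"L": a}, "dna", engine="internal",
                             revcomp=False, min_score=5.0)
        assert len(on["L"]) == 1 and on["L"][0].frame == ("-", 0)
        assert off["L"] == []

    def test_codon_mode_records_single_frame(self):
        rng = np.random.default_rng(6)
        anc = evolve_sequence("ATG" + "".join(rng.choice(list("ACGT"), size=87)), 0.0, 1)
        from refaln.synth_data import _repair_stops
        anc = _repair_stops(anc, rng)
        rows = {f"t{i}": _repair_stops(evolve_sequence(anc, 0.05, 10 + i), rng)
                for i in range(4)}
        aln = make_aln(rows, alphabet="codon")
        # query: an interior slice of one row, shifted by one base
        query = SeqRecord(id="q", source="s",
                          residues=next(iter(rows.values()))[7:67])
        found = search_queries([query], {"L": aln}, "codon",
                               engine="internal", min_score=5.0)
        (hit,) = found["L"]
        assert hit.frame == ("+", 2)  # offset 7 -> next codon boundary at +2
        assert hit.nucleotides == query.residues

    def test_mode_alphabet_mismatch_rejected_before_search(self):
        aln = conserved_dna_msa()
        with pytest.raises(ValueError, match="alphabet"):
            search_queries([], {"L": aln}, "prot", engine="internal")


# ---------------------------------------------------------------------------
# engines agree; external report adapter
# ---------------------------------------------------------------------------

class TestEngineAgreement:
    def test_internal_and_hmmer_map_identical_columns(self):
        rng = np.random.default_rng(21)
        anc = "".join(rng.choice(list("ACGT"), size=60))
        rows = {}
        for i in range(5):
            row = list(anc)
            for p in rng.choice(np.arange(5, 55), size=4, replace=False):
                row[p] = rng.choice([b for b in "ACGT" if b != row[p]])
            rows[f"t{i}"] = "".join(row)
        aln = make_aln(rows)
        queries = [SeqRecord(id=f"q{i}", source="s", residues=r[5:55])
                   for i, r in enumerate(rows.values())]
        by_engine = {}
        for engine in ("internal", "hmmer"):
            found = search_queries(queries, {"L": aln}, "dna", engine=engine,
                                   min_score=10.0)
            by_engine[engine] = {
                h.query_id: {sj for _, sj in h.aligned_pairs if sj is not None}
                for h in found["L"]}
        assert by_engine["internal"] == by_engine["hmmer"]


class TestExternalReport:
    def test_report_round_trip(self, tmp_path):
        aln = conserved_dna_msa(seed=30)
        hmm = build_profile_hmm(aln)
        hits = []
        for i, row in enumerate(aln.rows.values()):
            h = viterbi_local_align(hmm, row)
            h.query_id = f"q{i}"
            hits.append(h)
        path = tmp_path / "report.tsv"
        write_hits_report(hits, path)
        parsed = parse_external_hits(path, {"L": hmm})
        assert len(parsed) == len(hits)
        for a, b in zip(hits, parsed):
            assert a.aligned_pairs == b.aligned_pairs
            assert a.query_id == b.query_id

    def test_unknown_locus_rejected(self, tmp_path):
        path = tmp_path / "report.tsv"
        path.write_text(
            "query_id\tsource\tlocus_id\tframe\tscore\thmm_from\ttarget_from"
            "\thmm_seq\ttarget_seq\nq\ts\tNOPE\t.\t10.0\t1\t1\txx\tAC\n")
        hmm = build_profile_hmm(conserved_dna_msa())
        with pytest.raises(ValueError, match="unknown locus"):
            parse_external_hits(path, {"L": hmm})

    def test_state_beyond_profile_rejected(self, tmp_path):
        hmm = build_profile_hmm(make_aln({"a": "ACG", "b": "ACG"}))
        path = tmp_path / "report.tsv"
        path.write_text(
            "query_id\tsource\tlocus_id\tframe\tscore\thmm_from\ttarget_from"
            "\thmm_seq\ttarget_seq\nq\ts\tL\t.\t10.0\t3\t1\txx\tAC\n")
        with pytest.raises(ValueError, match="exceeds"):
            parse_external_hits(path, {"L": hmm})


class TestPlan7Adapter:
    def test_parameter_copy_is_verbatim(self):
        hmm = build_profile_hmm(conserved_dna_msa(seed=17))
        plan = to_plan7(hmm)
        assert plan.M == hmm.n_match_states
        assert np.allclose(np.asarray(plan.match_emissions)[1:],
                           hmm.match_emissions[1:])
        assert np.allclose(np.asarray(plan.transition_probabilities),
                           hmm.transitions)
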