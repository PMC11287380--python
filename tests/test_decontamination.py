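import numpy as np
import pytest

from refaln.decontamination import (DecontamParams, conservative_score,
                                    detect_cross_contamination,
                                    estimated_rpkm, outgroup_score,
                                    remove_foreign)
from refaln.reference_model import ConservationProfile, compute_ingroup_profile
from refaln.synth_data import evolve_sequence
from test_mapping_assembly import make_segment
from test_profile_search import make_aln


def profile_of(columns):
    return ConservationProfile(locus_id="L", columns=columns)


class TestConservativeScore:
    def test_sum_of_frequencies(self):
        prof = profile_of([{"A": 0.8}, {"G": 0.6}])
        item = make_segment(0, "AG")
        assert conservative_score(item, prof) == pytest.approx(1.4)

    def test_all_gap_item_scores_zero(self):
        prof = profile_of([{"A": 0.8}, {"G": 0.6}])
        assert conservative_score(make_segment(0, "--"), prof) == 0.0

    def test_ingroup_row_scores_its_own_frequencies(self):
        rng = np.random.default_rng(7)
        rows = {f"t{i}": "".join(rng.choice(list("ACGT"), size=30))
                for i in range(4)}
        aln = make_aln(rows)
        prof = compute_ingroup_profile(aln)
        for row in rows.values():
            expected = sum(prof.freq(c, row[c]) for c in range(30))
            assert conservative_score(make_segment(0, row), prof) == \
                pytest.approx(expected)

    def test_modal_substitution_never_decreases_score(self):
        rng = np.random.default_rng(17)
        rows = {f"t{i}": "".join(rng.choice(list("ACGT"), size=20))
                for i in range(5)}
        prof = compute_ingroup_profile(make_aln(rows))
        item_res = "".join(rng.choice(list("ACGT"), size=20))
        base = conservative_score(make_segment(0, item_res), prof)
        for c in range(20):
            modal = prof.modal_residue(c)
            if modal is None:
                continue
            mutated = item_res[:c] + modal + item_res[c + 1:]
            assert conservative_score(make_segment(0, mutated), prof) >= base - 1e-12


class TestForeignRemoval:
    def test_weighted_comparison_arithmetic(self):
        # item scores 1.40, outgroup scores 1.60 in the same region:
        # 1.40 < 0.9 * 1.60 = 1.44 -> removed
        prof = profile_of([{"A": 0.8, "C": 0.9}, {"G": 0.6, "T": 0.7}])
        item = make_segment(0, "AG")  # 0.8 + 0.6 = 1.4
        kept, removed = remove_foreign([item], prof, "CT", weight=0.9)
        assert removed == [item] and kept == []

    def test_weight_zero_removes_nothing(self):
        prof = profile_of([{"A": 0.1}])
        item = make_segment(0, "A")
        kept, removed = remove_foreign([item], prof, "A", weight=0.0)
        assert kept == [item] and removed == []

    def test_missing_outgroup_is_an_error(self):
        with pytest.raises(ValueError):
            remove_foreign([], profile_of([]), None)

    def test_outgroup_score_restricted_to_item_region(self):
        prof = profile_of([{"A": 0.5}, {"C": 0.5}, {"G": 0.5}])
        item = make_segment(1, "C")
        assert outgroup_score(item, prof, "ACG") == pytest.approx(0.5)
        assert outgroup_score(item, prof, "A-G") == 0.0

    def test_distant_contaminant_removed_target_kept(self):
        """Simulation oracle: beyond-outgroup sequences fail the weighted
        outgroup comparison while in-clade targets pass it."""
        rng = np.random.default_rng(23)
        anc = "".join(rng.choice(list("ACGT"), size=300))
        ingroup = {f"t{i}": evolve_sequence(anc, d, 100 + i)
                   for i, d in enumerate((0.10, 0.15, 0.20, 0.25))}
        outgroup_row = evolve_sequence(anc, 0.35, 200)
        aln = make_aln({**ingroup, "out": outgroup_row}, outgroup="out")
        prof = compute_ingroup_profile(aln)
        target = make_segment(0, evolve_sequence(anc, 0.12, 300), query_id="tgt")
        foreign = make_segment(0, evolve_sequence(anc, 0.7, 301), query_id="for")
        kept, removed = remove_foreign([target, foreign], prof, outgroup_row,
                                       weight=0.9)
        assert kept == [target]
        assert removed == [foreign]


class TestEstimatedRpkm:
    def test_quotient(self):
        assert estimated_rpkm(10, 100, 1000) == pytest.approx(1e-4)

    def test_scale_invariance(self):
        assert estimated_rpkm(20, 100, 2000) == estimated_rpkm(10, 100, 1000)

    def test_fold_invariant_to_common_total_scaling(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            rc1, rc2 = rng.integers(1, 100, size=2)
            L1, L2 = rng.integers(10, 500, size=2)
            t1, t2 = rng.integers(1000, 10**6, size=2)
            k = int(rng.integers(2, 10))
            f1 = estimated_rpkm(rc1, L1, t1) / estimated_rpkm(rc2, L2, t2)
            f2 = estimated_rpkm(rc1, L1, t1 * k) / estimated_rpkm(rc2, L2, t2 * k)
            assert f1 == pytest.approx(f2)

    def test_zero_denominators_rejected(self):
        with pytest.raises(ValueError):
            estimated_rpkm(1, 0, 10)
        with pytest.raises(ValueError):
            estimated_rpkm(1, 10, 0)


class TestCrossContamination:
    params = DecontamParams(cross_min_overlap=3, cross_min_identity=0.9,
                            rpkm_fold_threshold=2.0)

    def test_lower_abundance_copy_removed(self):
        seq = "ACGTACGTAC"
        a = make_segment(0, seq, source="A", query_id="a",
                         read_ids=[f"r{i}" for i in range(4)])
        b = make_segment(0, seq, source="B", query_id="b", read_ids=["r9"])
        removals = detect_cross_contamination(
            {"A": [a], "B": [b]}, self.params, {"A": 1000, "B": 1000})
        (r,) = removals
        assert r.source == "B" and r.donor == "A"

    def test_fold_exactly_at_threshold_keeps_both(self):
        seq = "ACGTACGTAC"
        a = make_segment(0, seq, source="A", query_id="a", read_ids=["r1", "r2"])
        b = make_segment(0, seq, source="B", query_id="b", read_ids=["r9"])
        removals = detect_cross_contamination(
            {"A": [a], "B": [b]}, self.params, {"A": 1000, "B": 1000})
        assert removals == []  # fold == 2.0 is not > 2.0

    def test_single_source_is_noop(self):
        a = make_segment(0, "ACGT", source="A")
        assert detect_cross_contamination({"A": [a]}, self.params, {"A": 10}) == []

    def test_one_origin_two_recipients(self):
        seq = "ACGTACGTACGTACG"
        origin = make_segment(0, seq, source="A", query_id="a",
                              read_ids=[f"r{i}" for i in range(10)])
        rec_b = make_segment(0, seq, source="B", query_id="b", read_ids=["x1"])
        rec_c = make_segment(0, seq, source="C", query_id="c", read_ids=["y1"])
        removals = detect_cross_contamination(
            {"A": [origin], "B": [rec_b], "C": [rec_c]},
            self.params, {"A": 1000, "B": 1000, "C": 1000})
        removed = {(r.source, r.donor) for r in removals}
        assert removed == {("B", "A"), ("C", "A")}

    def test_higher_abundance_member_never_removed(self):
        rng = np.random.default_rng(31)
        seq = "".join(rng.choice(list("ACGT"), size=20))
        for na, nb in [(8, 1), (1, 8), (5, 1)]:
            a = make_segment(0, seq, source="A", query_id="a",
                             read_ids=[f"a{i}" for i in range(na)])
            b = make_segment(0, seq, source="B", query_id="b",
                             read_ids=[f"b{i}" for i in range(nb)])
            removals = detect_cross_contamination(
                {"A": [a], "B": [b]}, self.params, {"A": 500, "B": 500})
            for r in removals:
                assert r.item.read_count == min(na, nb)

    def test_decisions_independent_of_source_naming_order(self):
        seq = "ACGTACGTACGTACG"
        a = make_segment(0, seq, source="A", query_id="a",
                         read_ids=[f"r{i}" for i in range(6)])
        b = make_segment(0, seq, source="B", query_id="b", read_ids=["x"])
        r1 = detect_cross_contamination({"A": [a], "B": [b]}, self.params,
                                        {"A": 100, "B": 100})
        r2 = detect_cross_contamination({"B": [b], "A": [a]}, self.params,
                                        {"B": 100, "A": 100})
        assert [(r.source, r.donor) for r in r1] == \
               [(r.source, r.donor) for r in r2]

    def test_low_identity_pair_not_flagged(self):
        a = make_segment(0, "ACGTACGTAC", source="A", query_id="a",
                         read_ids=["r1", "r2", "r3", "r4"])
        b = make_segment(0, "TGCATGCATG", source="B", query_id="b", read_ids=["x"])
        assert detect_cross_contamination(
            {"A": [a], "B": [b]}, self.params, {"A": 100, "B": 100}) == []
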