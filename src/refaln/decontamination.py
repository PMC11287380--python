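"""Foreign- and cross-contamination removal.

Foreign contamination (reads from organisms outside the studied clade) is
detected by a conservative score: the sum, over an item's covered columns,
of the ingroup frequency of the residue the item carries there.  An item is
removed when its score falls below the outgroup's score over the same
region, scaled by a weight (default 0.9).  The outgroup thus acts as the
"worst acceptable ingroup-like sequence" baseline.

Cross-contamination (reads leaked between samples of one sequencing batch)
is detected across sources: two items from different sources that overlap
nearly identically are compared by estimated RPKM (read count / length in
reference columns / total source reads); if their abundance ratio exceeds a
fold threshold, the lower-abundance item is removed and attributed to the
higher-abundance source.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .mapping_assembly import overlap_identity
from .reference_model import ConservationProfile
from .seq_io import GAP


@dataclass
class DecontamParams:
    """Thresholds for both decontamination steps.

    ``cross_min_overlap`` is in columns of the working alphabet (amino-acid
    columns in prot/codon modes, nucleotide columns in dna modes).
    """

    outgroup_weight: float = 0.9
    cross_min_overlap: int = 10
    cross_min_identity: float = 0.95
    rpkm_fold_threshold: float = 2.0

    def __post_init__(self):
        if self.outgroup_weight < 0:
            raise ValueError("outgroup_weight must be >= 0")
        if self.rpkm_fold_threshold < 1:
            raise ValueError("rpkm_fold_threshold must be >= 1")


@dataclass
class AbundanceRecord:
    source: str
    locus: str
    read_count: int
    ref_length_columns: int
    total_reads_in_source: int

    @property
    def est_rpkm(self) -> float:
        return estimated_rpkm(self.read_count, self.ref_length_columns,
                              self.total_reads_in_source)


def conservative_score(item, profile: ConservationProfile) -> float:
    """Sum of ingroup frequencies of the item's residues at their columns.

    Gap columns and columns outside the item contribute 0.  Higher scores
    mean the item looks more like the ingroup consensus.
    """
    score = 0.0
    for k, r in enumerate(item.residues):
        if r != GAP:
            score += profile.freq(item.start + k, r)
    return score


def outgroup_score(item, profile: ConservationProfile, outgroup_row: str) -> float:
    """Conservative score of the outgroup restricted to the item's residues.

    Only columns where the item itself carries a residue are counted (the
    comparison is within the item's covered region); outgroup gaps
    contribute 0.
    """
    score = 0.0
    for k, r in enumerate(item.residues):
        if r == GAP:
            continue
        col = item.start + k
        og = outgroup_row[col]
        if og != GAP:
            score += profile.freq(col, og)
    return score


def remove_foreign(items: Sequence, profile: ConservationProfile,
                   outgroup_row: Optional[str], weight: float = 0.9,
                   ) -> Tuple[list, list]:
    """Split items into (kept, removed) by the weighted outgroup comparison.

    An item is foreign iff its conservative score is strictly below
    ``weight`` times the outgroup's score over the same region.  With
    weight 0 nothing is removed (scores are non-negative).
    """
    if outgroup_row is None:
        raise ValueError("foreign removal requires an outgroup row")
    kept, removed = [], []
    for item in items:
        own = conservative_score(item, profile)
        out = outgroup_score(item, profile, outgroup_row)
        (removed if own < weight * out else kept).append(item)
    return kept, removed


def estimated_rpkm(read_count: int, ref_length_columns: int, total_reads: int) -> float:
    """Abundance proxy: read count / item length in columns / total reads."""
    if ref_length_columns <= 0:
        raise ValueError("ref_length_columns must be > 0")
    if total_reads <= 0:
        raise ValueError("total_reads must be > 0")
    return read_count / (ref_length_columns * total_reads)


@dataclass
class CrossRemoval:
    source: str
    item: object
    donor: str
    fold: float


def detect_cross_contamination(per_source_items: Dict[str, Sequence],
                               params: DecontamParams,
                               total_reads: Dict[str, int],
                               ) -> List[CrossRemoval]:
    """Flag cross-contaminated items at one locus across sources.

    Every cross-source pair of items whose shared non-gap overlap is at
    least ``cross_min_overlap`` columns with identity >=
    ``cross_min_identity`` is compared by estimated RPKM; when the fold
    (max/min) strictly exceeds ``rpkm_fold_threshold`` the lower-abundance
    item is marked for removal with the higher-abundance source as donor.
    Decisions are computed on the original abundance table and applied at
    once, so they are independent of source order; with a single source the
    step is a no-op.  An item flagged against several donors keeps the
    attribution with the largest fold.
    """
    sources = sorted(per_source_items)
    if len(sources) < 2:
        return []
    flagged: Dict[Tuple[str, int], CrossRemoval] = {}
    for i, sa in enumerate(sources):
        for sb in sources[i + 1:]:
            for ia, a in enumerate(per_source_items[sa]):
                for ib, b in enumerate(per_source_items[sb]):
                    shared, ident = overlap_identity(a, b)
                    if shared < params.cross_min_overlap or ident < params.cross_min_identity:
                        continue
                    rpkm_a = estimated_rpkm(a.read_count, a.end - a.start, total_reads[sa])
                    rpkm_b = estimated_rpkm(b.read_count, b.end - b.start, total_reads[sb])
                    if min(rpkm_a, rpkm_b) == 0:
                        continue
                    fold = max(rpkm_a, rpkm_b) / min(rpkm_a, rpkm_b)
                    if fold <= params.rpkm_fold_threshold:
                        continue
                    if rpkm_a < rpkm_b:
                        victim, donor, vid = a, sb, (sa, ia)
                    else:
                        victim, donor, vid = b, sa, (sb, ib)
                    cur = flagged.get(vid)
                    if cur is None or fold > cur.fold:
                        flagged[vid] = CrossRemoval(source=vid[0], item=victim,
                                                    donor=donor, fold=fold)
    return [flagged[k] for k in sorted(flagged)]
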