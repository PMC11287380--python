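"""Alignment-quality and decontamination metrics.

Completeness and percent identity are computed against a standard MSA in
shared coordinates.  Only *valid regions* count: columns with a residue, or
gaps strictly between a row's first and last residues; leading/trailing gaps
and unknown symbols (N/X) are ignored.  Completeness is the fraction of the
standard's valid region that the test row also covers; identity is the
fraction of matching symbols within the shared valid region.

Decontamination quality is summarised as confusion counts over read labels
for three aspects (clean / foreign / cross), following the positive and
negative class definitions used for contamination benchmarking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .seq_io import GAP

#: Symbols treated as unknown (never part of a valid region).
UNKNOWN = set("NXnx?")

OUTCOMES = ("retained", "removed_foreign", "removed_cross")


@dataclass
class ComparisonResult:
    completeness: float  # percent
    identity: float  # percent
    n_standard_valid: int
    n_overlap: int


@dataclass
class ConfusionCounts:
    aspect: str
    TP: int = 0
    TN: int = 0
    FP: int = 0
    FN: int = 0

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class PrecisionRecall:
    precision: float
    recall: float
    precision_defined: bool
    recall_defined: bool


def valid_region_mask(aligned_residues: str) -> List[bool]:
    """Valid columns of one aligned row.

    True at residue columns and at gap columns strictly between the first
    and last residue; False at leading/trailing gaps and at unknown symbols
    (which also do not anchor the region ends).
    """
    is_residue = [c != GAP and c not in UNKNOWN for c in aligned_residues]
    if not any(is_residue):
        return [False] * len(aligned_residues)
    first = is_residue.index(True)
    last = len(is_residue) - 1 - is_residue[::-1].index(True)
    mask = []
    for i, c in enumerate(aligned_residues):
        if i < first or i > last:
            mask.append(False)
        elif c in UNKNOWN:
            mask.append(False)
        else:
            mask.append(True)
    return mask


def completeness(test_row: str, standard_row: str) -> float:
    """Percent of the standard's valid region also valid in the test row."""
    if len(test_row) != len(standard_row):
        raise ValueError("rows differ in length")
    std = valid_region_mask(standard_row)
    tst = valid_region_mask(test_row)
    n_std = sum(std)
    if n_std == 0:
        return 0.0
    n_overlap = sum(1 for s, t in zip(std, tst) if s and t)
    return 100.0 * n_overlap / n_std


def percent_identity(test_row: str, standard_row: str) -> float:
    """Percent matching symbols within the shared valid region.

    Case-insensitive; a gap aligned to a residue inside the overlap is a
    mismatch; gap-vs-gap inside the overlap matches (equal symbols).
    Returns 0 when the overlap is empty.
    """
    if len(test_row) != len(standard_row):
        raise ValueError("rows differ in length")
    std = valid_region_mask(standard_row)
    tst = valid_region_mask(test_row)
    n_overlap = 0
    n_match = 0
    for s, t, cs, ct in zip(std, tst, standard_row.upper(), test_row.upper()):
        if s and t:
            n_overlap += 1
            if cs == ct:
                n_match += 1
    if n_overlap == 0:
        return 0.0
    return 100.0 * n_match / n_overlap


def compare_rows(test_row: str, standard_row: str) -> ComparisonResult:
    std = valid_region_mask(standard_row)
    tst = valid_region_mask(test_row)
    n_std = sum(std)
    n_overlap = sum(1 for s, t in zip(std, tst) if s and t)
    return ComparisonResult(
        completeness=completeness(test_row, standard_row),
        identity=percent_identity(test_row, standard_row),
        n_standard_valid=n_std,
        n_overlap=n_overlap,
    )


def decontam_confusion(read_labels: Dict[str, str], outcomes: Dict[str, str],
                       aspect: str, focal_species: str,
                       target_species: Set[str], foreign_species: Set[str],
                       ) -> ConfusionCounts:
    """Confusion counts over labelled reads for one aspect.

    ``read_labels`` maps read id -> true species of origin; ``outcomes``
    maps read id -> one of ``retained``, ``removed_foreign``,
    ``removed_cross`` (reads that never mapped have no outcome and are out
    of scope).  Aspect definitions:

    * ``clean``: positives are reads of the focal source's own species,
      negatives all other reads; observed positive = retained.
    * ``foreign``: positives are foreign-species reads, negatives reads of
      the target species; observed positive = removed at the foreign step.
    * ``cross``: positives are reads of the *other* target species,
      negatives reads of the focal species (foreign reads are out of
      scope); observed positive = removed at the cross step.
    """
    if aspect not in ("clean", "foreign", "cross"):
        raise ValueError(f"unknown aspect {aspect!r}")
    counts = ConfusionCounts(aspect=aspect)
    for read_id, outcome in outcomes.items():
        label = read_labels.get(read_id)
        if label is None:
            raise ValueError(f"read {read_id!r} has no label")
        if outcome not in OUTCOMES:
            raise ValueError(f"read {read_id!r} has unknown outcome {outcome!r}")
        if aspect == "clean":
            positive = label == focal_species
            observed = outcome == "retained"
        elif aspect == "foreign":
            if label not in foreign_species and label not in target_species:
                continue
            positive = label in foreign_species
            observed = outcome == "removed_foreign"
        else:  # cross
            if label in foreign_species:
                continue
            positive = label in target_species and label != focal_species
            if not positive and label != focal_species:
                continue
            observed = outcome == "removed_cross"
        if positive and observed:
            counts.TP += 1
        elif positive:
            counts.FN += 1
        elif observed:
            counts.FP += 1
        else:
            counts.TN += 1
    return counts


def precision_recall(counts: ConfusionCounts) -> PrecisionRecall:
    """Precision TP/(TP+FP) and recall TP/(TP+FN); NaN when undefined."""
    p_def = (counts.TP + counts.FP) > 0
    r_def = (counts.TP + counts.FN) > 0
    precision = counts.TP / (counts.TP + counts.FP) if p_def else math.nan
    recall = counts.TP / (counts.TP + counts.FN) if r_def else math.nan
    return PrecisionRecall(precision=precision, recall=recall,
                           precision_defined=p_def, recall_defined=r_def)


def compare_msas(test_rows: Dict[str, str], standard_rows: Dict[str, str],
                 ) -> Dict[str, ComparisonResult]:
    """Row-by-row comparison of two MSAs sharing coordinates."""
    out = {}
    for name in test_rows:
        if name in standard_rows:
            out[name] = compare_rows(test_rows[name], standard_rows[name])
    return out
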