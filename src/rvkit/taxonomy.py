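"""Taxonomy assignment rules for vOTUs.

Family-level taxonomy follows the majority rule: a vOTU is assigned to a
reference family when a strict majority (>50%) of its predicted proteins
have their best hit (bit score >= 50) in that family.  crAss-like vOTUs are
flagged by nucleotide similarity to a reference set (>=80% identity blocks
covering >=50% of a reference genome).  A vOTU is lysogenic when it derives
from an excised prophage or encodes an integrase.  The marker-gene matrix
filter retains concatenated marker-gene rows with >3 markers and marker
columns present in >5% of the retained rows, iterated to a fixed point.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .ani import AlignmentBlock, union_length

__all__ = [
    "ProteinHit",
    "FamilyCall",
    "assign_family_majority",
    "flag_crass_like",
    "classify_lysogenic",
    "filter_marker_concatemers",
]


@dataclass(frozen=True)
class ProteinHit:
    votu_id: str
    protein_index: int
    reference_family: str
    bitscore: float

    def __post_init__(self) -> None:
        if self.bitscore < 0:
            raise ValueError("bitscore must be >= 0")


@dataclass(frozen=True)
class FamilyCall:
    votu_id: str
    family: str  # family name or "unclassified"
    supporting_fraction: float


def assign_family_majority(hits: Iterable[ProteinHit], n_proteins: int,
                           min_bitscore: float = 50.0) -> FamilyCall:
    """Majority-rule family call over the proteins of one vOTU.

    Hits below ``min_bitscore`` are discarded (the boundary value is kept);
    each protein votes for the family of its best remaining hit, abstaining
    on a cross-family bitscore tie; a family is called only when matched by
    strictly more than half of *all* ``n_proteins``.
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    hits = [h for h in hits if h.bitscore >= min_bitscore]
    votu_ids = {h.votu_id for h in hits}
    if len(votu_ids) > 1:
        raise ValueError("hits must belong to a single vOTU")
    votu_id = votu_ids.pop() if votu_ids else ""

    by_protein: dict[int, list[ProteinHit]] = defaultdict(list)
    for h in hits:
        by_protein[h.protein_index].append(h)
    if len(by_protein) > n_proteins:
        raise ValueError("more matched proteins than n_proteins")

    votes: Counter[str] = Counter()
    for phits in by_protein.values():
        best = max(h.bitscore for h in phits)
        fams = {h.reference_family for h in phits if h.bitscore == best}
        if len(fams) == 1:  # cross-family tie -> abstain
            votes[fams.pop()] += 1
    if votes:
        family, count = votes.most_common(1)[0]
        frac = count / n_proteins
        if frac > 0.5:
            return FamilyCall(votu_id, family, frac)
    return FamilyCall(votu_id, "unclassified", 0.0)


def flag_crass_like(blocks: Iterable[AlignmentBlock], ref_lengths: Mapping[str, int],
                    min_identity: float = 80.0, min_ref_coverage: float = 0.5
                    ) -> dict[str, bool]:
    """Per-query crAss-like flags from alignments against the reference set.

    A query is flagged when, for some reference, the union of its blocks
    with identity >= ``min_identity`` covers >= ``min_ref_coverage`` of that
    reference's length.  Coverage is measured on the reference.
    """
    ints: dict[tuple[str, str], list[tuple[int, int]]] = defaultdict(list)
    queries: set[str] = set()
    for bl in blocks:
        queries.add(bl.query_id)
        if bl.subject_id not in ref_lengths:
            raise ValueError(f"unknown crAss reference: {bl.subject_id}")
        if bl.percent_identity >= min_identity:
            ints[(bl.query_id, bl.subject_id)].append(bl.subject_interval())
    flags = {q: False for q in queries}
    for (q, ref), ivs in ints.items():
        if union_length(ivs) >= min_ref_coverage * ref_lengths[ref]:
            flags[q] = True
    return flags


def classify_lysogenic(provenance: str, gene_labels: Iterable[Iterable[str]]) -> bool:
    """Lysogenic iff prophage-derived or any gene is labeled ``integrase``."""
    if provenance == "prophage":
        return True
    return any("integrase" in set(labels) for labels in gene_labels)


def filter_marker_concatemers(matrix: pd.DataFrame, min_markers: int = 3,
                              min_prevalence: float = 0.05
                              ) -> tuple[list[str], list[str]]:
    """Retention filter for marker-gene concatemers, iterated to fixed point.

    Rows (vOTU concatemers) must carry strictly more than ``min_markers``
    present markers; columns (marker genes) must be present in strictly more
    than ``min_prevalence`` of the remaining rows.  Rows are filtered first,
    then columns, and the two passes repeat until nothing changes.
    """
    if matrix.empty:
        raise ValueError("marker matrix is empty")
    m = matrix.astype(bool)
    while True:
        rows = m.index[m.sum(axis=1) > min_markers]
        m2 = m.loc[rows]
        if len(m2):
            cols = m2.columns[m2.mean(axis=0) > min_prevalence]
        else:
            cols = m2.columns[:0]
        m2 = m2.loc[:, cols]
        if m2.shape == m.shape:
            break
        m = m2
        if m.empty:
            warnings.warn("marker filter eliminated all rows", stacklevel=2)
            break
    return list(m.index), list(m.columns)
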