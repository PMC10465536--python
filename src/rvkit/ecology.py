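"""Virome ecology: abundance, richness, core virome, shared vOTUs.

Per-sample vOTU abundance follows the trimmed-mean contract of read-mapping
coverage tools: read alignments are kept at >=95% identity and >=75% of the
read aligned; a vOTU must have >=70% of its positions covered, else its
abundance is 0; otherwise the per-position depths are sorted and the top and
bottom 5% of positions discarded before averaging.  Richness is normalized
per billion base pairs sequenced.  The core virome of a sample group is the
set of vOTUs whose prevalence in that group exceeds 50% (strict by default;
an inclusive switch is provided because both readings appear in practice).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

__all__ = [
    "ReadAlignment",
    "CoreResult",
    "StudyClustering",
    "filter_read_alignments",
    "trimmed_mean_coverage",
    "richness_per_gbp",
    "classify_core",
    "shared_votus",
    "cluster_studies",
]


@dataclass(frozen=True)
class ReadAlignment:
    read_id: str
    votu_id: str
    percent_identity: float
    aligned_fraction_of_read: float  # [0, 1]
    start: int = 0  # covered interval on the vOTU, 0-based half-open
    end: int = 0


def filter_read_alignments(alignments: Iterable[ReadAlignment],
                           min_identity: float = 95.0,
                           min_aligned_frac: float = 0.75) -> list[ReadAlignment]:
    """Keep alignments at >= ``min_identity`` %id and >= ``min_aligned_frac``."""
    return [a for a in alignments
            if a.percent_identity >= min_identity
            and a.aligned_fraction_of_read >= min_aligned_frac]


def trimmed_mean_coverage(depth: Sequence[int] | np.ndarray,
                          trim_frac: float = 0.05,
                          min_covered_frac: float = 0.70) -> float:
    """Trimmed-mean abundance of one vOTU in one sample.

    Returns 0 when fewer than ``min_covered_frac`` of positions have nonzero
    depth; otherwise discards ``floor(trim_frac * L)`` positions from each
    extreme of the sorted depth vector and returns the mean of the rest.
    """
    depth = np.asarray(depth)
    if depth.size == 0:
        raise ValueError("empty depth vector")
    if np.any(depth < 0):
        raise ValueError("depths must be non-negative")
    covered = np.count_nonzero(depth) / depth.size
    if covered < min_covered_frac:
        return 0.0
    n_trim = int(np.floor(trim_frac * depth.size))
    ordered = np.sort(depth)
    kept = ordered[n_trim : depth.size - n_trim] if n_trim else ordered
    return float(kept.mean())


def richness_per_gbp(n_detected_votus: int, sample_bases: int) -> float:
    """Detected vOTUs per billion base pairs sequenced."""
    if sample_bases <= 0:
        raise ValueError("sample_bases must be positive")
    return n_detected_votus * 1e9 / sample_bases


_CLASS_WORDS = {1: "one_level", 2: "two_levels", 3: "three_levels"}


@dataclass
class CoreResult:
    table: pd.DataFrame  # per-vOTU class, per-group core flags, global_core
    core_sets: dict[str, set[str]]  # group -> core vOTU ids
    venn_counts: dict[str, int]  # "g1+g2" -> vOTUs core in exactly that set
    params: dict = field(default_factory=dict)


def classify_core(matrix: pd.DataFrame, groups: Mapping[str, str],
                  core_threshold: float = 0.5, strict: bool = True) -> CoreResult:
    """Prevalence classes and per-group core sets from a binary matrix.

    ``matrix`` is vOTU x sample with entries in {0, 1}; ``groups`` maps every
    sample to its group label.  A vOTU is core in a group when its prevalence
    there is > ``core_threshold`` (``strict=True``) or >= it; global core
    means core in every group.  Classes: ``individualized`` (exactly one
    occurrence overall), else by the number of groups with >=1 occurrence.
    """
    missing = [s for s in matrix.columns if s not in groups]
    if missing:
        raise ValueError(f"samples without group label: {missing}")
    m = (matrix > 0).astype(int)
    group_labels = sorted(set(groups[s] for s in m.columns))
    samples_of = {g: [s for s in m.columns if groups[s] == g] for g in group_labels}
    for g, cols in samples_of.items():
        if not cols:
            raise ValueError(f"empty group: {g}")

    total = m.sum(axis=1)
    rows = pd.DataFrame(index=m.index)
    core_sets: dict[str, set[str]] = {}
    for g in group_labels:
        prev = m[samples_of[g]].mean(axis=1)
        core = prev > core_threshold if strict else prev >= core_threshold
        rows[f"core_{g}"] = core
        core_sets[g] = set(m.index[core])
    n_groups_present = sum((m[samples_of[g]].sum(axis=1) > 0).astype(int)
                           for g in group_labels)

    def classify(votu: str) -> str:
        if total[votu] == 0:
            return "absent"
        if total[votu] == 1:
            return "individualized"
        k = int(n_groups_present[votu])
        return _CLASS_WORDS.get(k, f"{k}_levels")

    rows.insert(0, "class", [classify(v) for v in m.index])
    rows["global_core"] = rows[[f"core_{g}" for g in group_labels]].all(axis=1)

    venn: dict[str, int] = {}
    for r in range(1, len(group_labels) + 1):
        for combo in combinations(group_labels, r):
            inside = set.intersection(*(core_sets[g] for g in combo))
            outside = set.union(*(core_sets[g] for g in group_labels
                                  if g not in combo), set())
            venn["+".join(combo)] = len(inside - outside)

    return CoreResult(
        table=rows,
        core_sets=core_sets,
        venn_counts=venn,
        params={"core_threshold": core_threshold,
                "strict": strict,
                "threshold_note": ("prevalence must exceed the threshold"
                                   if strict else
                                   "prevalence at or above the threshold")},
    )


def shared_votus(matrix: pd.DataFrame,
                 sample_pairs: Iterable[tuple[str, str]],
                 pair_labels: Iterable[str]) -> pd.DataFrame:
    """Long-format table of vOTUs shared by each labeled sample pair."""
    m = matrix > 0
    records = []
    for (a, b), label in zip(sample_pairs, pair_labels):
        if a not in m.columns or b not in m.columns:
            raise ValueError(f"unknown sample in pair ({a}, {b})")
        shared = int((m[a] & m[b]).sum())
        records.append({"sample_a": a, "sample_b": b,
                        "pair_label": label, "shared_votus": shared})
    return pd.DataFrame(records)


@dataclass
class StudyClustering:
    studies: list[str]
    shared: pd.DataFrame  # study x study shared-vOTU counts
    dissimilarity: pd.DataFrame
    linkage: np.ndarray  # scipy linkage matrix (deterministic merge order)


def cluster_studies(matrix: pd.DataFrame, study_labels: Mapping[str, str],
                    min_samples: int = 12, method: str = "average") -> StudyClustering:
    """Hierarchical clustering of studies by shared-vOTU counts.

    Studies with strictly more than ``min_samples`` samples are retained.
    Between-study sharing counts vOTUs present in at least one sample of
    each study; the dissimilarity fed to average-linkage clustering is
    ``1 - shared / min(richness_a, richness_b)``.
    """
    missing = [s for s in matrix.columns if s not in study_labels]
    if missing:
        raise ValueError(f"samples without study label: {missing}")
    counts: dict[str, list[str]] = {}
    for s in matrix.columns:
        counts.setdefault(study_labels[s], []).append(s)
    studies = sorted(st for st, cols in counts.items() if len(cols) > min_samples)
    if len(studies) < 2:
        raise ValueError("fewer than 2 studies survive the sample-count filter")

    m = matrix > 0
    presence = {st: m[counts[st]].any(axis=1) for st in studies}
    n = len(studies)
    shared = np.zeros((n, n), dtype=int)
    for i, a in enumerate(studies):
        for j, b in enumerate(studies):
            shared[i, j] = int((presence[a] & presence[b]).sum())
    richness = shared.diagonal()
    dis = np.ones((n, n))
    for i in range(n):
        dis[i, i] = 0.0
        for j in range(i + 1, n):
            floor = min(richness[i], richness[j])
            d = 1.0 - shared[i, j] / floor if floor else 1.0
            dis[i, j] = dis[j, i] = d
    Z = linkage(squareform(dis, checks=False), method=method)
    return StudyClustering(
        studies=studies,
        shared=pd.DataFrame(shared, index=studies, columns=studies),
        dissimilarity=pd.DataFrame(dis, index=studies, columns=studies),
        linkage=Z,
    )
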