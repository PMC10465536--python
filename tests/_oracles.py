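"""Independent brute-force oracles used by the test suite.

These deliberately re-implement contracts in the most literal way possible
(direct quadratic scans, naive string search, textbook average linkage) so
they share no code path with the package.
"""

from __future__ import annotations

import numpy as np

from rvkit.ani import Contig, PairwiseANI


def make_random_ani_instance(rng: np.random.Generator, max_n: int = 8
                             ) -> tuple[list[Contig], list[PairwiseANI]]:
    """A random small clustering instance (contigs + symmetric ANI table)."""
    n = int(rng.integers(2, max_n + 1))
    contigs = [
        Contig(id=f"c{i}", _length=int(rng.integers(5001, 50001)),
               completeness=float(rng.integers(0, 101)))
        for i in range(n)
    ]
    table = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.55:
                table.append(PairwiseANI(
                    query_id=f"c{i}", subject_id=f"c{j}",
                    ani=float(rng.uniform(80, 100)),
                    af_query=float(rng.uniform(50, 100)),
                    af_subject=float(rng.uniform(50, 100))))
    return contigs, table


def brute_force_greedy_clusters(contigs: list[Contig], table: list[PairwiseANI],
                                ani_min: float = 95.0, af_min: float = 85.0
                                ) -> set[frozenset[str]]:
    """Literal re-statement of the greedy centroid contract."""
    lengths = {c.id: c.length for c in contigs}
    lookup = {}
    for p in table:
        lookup[(p.query_id, p.subject_id)] = p
        lookup[(p.subject_id, p.query_id)] = p

    def af_shorter(p: PairwiseANI, a: str, b: str) -> float:
        lq, ls = lengths[p.query_id], lengths[p.subject_id]
        if lq < ls:
            return p.af_query
        if ls < lq:
            return p.af_subject
        return max(p.af_query, p.af_subject)

    def order(c: Contig):
        comp = -1.0 if c.completeness is None else c.completeness
        return (-c.length, -comp, c.id)

    clusters: list[list[str]] = []
    for c in sorted(contigs, key=order):
        placed = False
        for cluster in clusters:
            centroid = cluster[0]
            p = lookup.get((c.id, centroid))
            if p and p.ani >= ani_min and af_shorter(p, c.id, centroid) >= af_min:
                cluster.append(c.id)
                placed = True
                break
        if not placed:
            clusters.append([c.id])
    return {frozenset(cl) for cl in clusters}


def nw_identity(a: str, b: str) -> float:
    """Global-alignment percent identity via Biopython (independent aligner)."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    aligned_cols = counts.identities + counts.mismatches
    return 100.0 * counts.identities / aligned_cols


def naive_spacer_match(spacer: str, target: str) -> bool:
    """Exact occurrence of the spacer or its reverse complement, by scan."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rc = "".join(comp[b] for b in reversed(spacer))
    n, m = len(target), len(spacer)
    for i in range(n - m + 1):
        window = target[i : i + m]
        if window == spacer or window == rc:
            return True
    return False


def average_linkage_merges(dis: np.ndarray) -> list[tuple[frozenset, frozenset, float]]:
    """Textbook agglomerative average linkage on a small dissimilarity matrix."""
    items = [frozenset([i]) for i in range(len(dis))]
    merges = []
    while len(items) > 1:
        best = None
        for x in range(len(items)):
            for y in range(x + 1, len(items)):
                d = np.mean([dis[i, j] for i in items[x] for j in items[y]])
                if best is None or d < best[0]:
                    best = (d, x, y)
        d, x, y = best
        merges.append((items[x], items[y], d))
        merged = items[x] | items[y]
        items = [it for k, it in enumerate(items) if k not in (x, y)] + [merged]
    return merges
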