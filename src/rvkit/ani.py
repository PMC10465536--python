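"""Species-level vOTU clustering from nucleotide alignments.

Viral contigs are grouped into viral operational taxonomic units (vOTUs)
at >=95% average nucleotide identity (ANI) over >=85% aligned fraction of
the shorter contig of each pair, using greedy centroid clustering: contigs
are processed longest-first and each contig either joins the first centroid
it matches or founds a new one.  Membership is only ever tested against
centroids, so the partition is deterministic and order-independent.

ANI here is the alignment-length-weighted mean identity over the local
alignment blocks of a pair; the aligned fraction (AF) of a sequence is the
share of it covered by the union of the block intervals.  Alignment blocks
use the BLAST tabular convention (1-based inclusive coordinates, subject
start > end on the minus strand); everything internal is 0-based half-open.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

__all__ = [
    "MIN_CONTIG_LENGTH",
    "Contig",
    "AlignmentBlock",
    "PairwiseANI",
    "VOtu",
    "reverse_complement",
    "admit_contigs",
    "local_align",
    "compute_pairwise_ani",
    "build_ani_table",
    "cluster_votus",
    "select_representative",
]

#: admission floor for putative viral contigs (strictly greater than)
MIN_CONTIG_LENGTH = 5000

QUALITY_TIERS = ("complete", "high", "medium", "low", "unknown")

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Contig:
    """A nucleotide contig with provenance and quality annotations."""

    id: str
    sequence: str = ""
    completeness: float | None = None  # percent, None when unknown
    quality_tier: str = "unknown"
    sample_id: str = ""
    provenance: str = "free"  # "free" or "prophage"
    _length: int | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.completeness is not None and not 0 <= self.completeness <= 100:
            raise ValueError(f"completeness out of [0,100]: {self.completeness}")
        if self.quality_tier not in QUALITY_TIERS:
            raise ValueError(f"unknown quality tier: {self.quality_tier!r}")

    @property
    def length(self) -> int:
        if self.sequence:
            return len(self.sequence)
        return self._length or 0


@dataclass(frozen=True)
class AlignmentBlock:
    """One local alignment in BLAST outfmt-6 convention (1-based inclusive).

    ``subject_start > subject_end`` marks a minus-strand match.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    mismatches: int = 0
    gap_opens: int = 0
    evalue: float = 0.0
    bitscore: float = 0.0

    def __post_init__(self) -> None:
        if self.alignment_length < 1:
            raise ValueError("alignment_length must be >= 1")
        if not 0 <= self.percent_identity <= 100:
            raise ValueError("percent_identity out of [0,100]")

    @property
    def is_minus(self) -> bool:
        return self.subject_start > self.subject_end

    def query_interval(self) -> tuple[int, int]:
        """0-based half-open interval on the query."""
        lo, hi = sorted((self.query_start, self.query_end))
        return lo - 1, hi

    def subject_interval(self) -> tuple[int, int]:
        """0-based half-open interval on the subject (strand-normalized)."""
        lo, hi = sorted((self.subject_start, self.subject_end))
        return lo - 1, hi


@dataclass(frozen=True)
class PairwiseANI:
    query_id: str
    subject_id: str
    ani: float  # [0, 100]
    af_query: float  # [0, 100]
    af_subject: float  # [0, 100]


@dataclass
class VOtu:
    representative_id: str
    member_ids: set[str]

    @property
    def n_members(self) -> int:
        return len(self.member_ids)


def admit_contigs(contigs: list[Contig], min_length: int = MIN_CONTIG_LENGTH) -> list[Contig]:
    """Admission filter: keep contigs strictly longer than ``min_length``."""
    return [c for c in contigs if c.length > min_length]


def union_length(intervals: list[tuple[int, int]]) -> int:
    """Total length of the union of 0-based half-open intervals."""
    if not intervals:
        return 0
    total = 0
    cur_lo, cur_hi = None, None
    for lo, hi in sorted(intervals):
        if cur_hi is None or lo > cur_hi:
            if cur_hi is not None:
                total += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
        else:
            cur_hi = max(cur_hi, hi)
    total += cur_hi - cur_lo
    return total


# ---------------------------------------------------------------------------
# seed-and-extend local aligner (internal stand-in for an external all-vs-all
# nucleotide search; gapless x-drop extension from exact k-mer seeds)
# ---------------------------------------------------------------------------

def _extend_gapless(a: str, b: str, i: int, j: int, k: int,
                    match: int, mismatch: int, x_drop: int) -> tuple[int, int, int]:
    """Extend an exact seed ``a[i:i+k] == b[j:j+k]`` in both directions.

    Returns (query_start, query_end, n_matches) with 0-based half-open
    query coordinates; subject coordinates follow from the shared diagonal.
    """
    # right extension
    score = best = k * match
    qe = best_qe = i + k
    p, q = i + k, j + k
    while p < len(a) and q < len(b):
        score += match if a[p] == b[q] else mismatch
        p += 1
        q += 1
        if score > best:
            best, best_qe = score, p
        elif best - score > x_drop:
            break
    qe = best_qe
    # left extension
    score = best = 0
    qs = best_qs = i
    p, q = i - 1, j - 1
    while p >= 0 and q >= 0:
        score += match if a[p] == b[q] else mismatch
        if score > best:
            best, best_qs = score, p
        elif best - score > x_drop:
            break
        p -= 1
        q -= 1
    qs = best_qs
    n_match = sum(1 for off in range(qe - qs) if a[qs + off] == b[j - i + qs + off])
    return qs, qe, n_match


def local_align(a: Contig, b: Contig, k: int = 15, x_drop: int = 20,
                match: int = 1, mismatch: int = -2) -> list[AlignmentBlock]:
    """All gapless local alignments between two contigs, both strands."""
    if k < 11:
        raise ValueError("seed length k must be >= 11")
    if len(a.sequence) < k or len(b.sequence) < k:
        raise ValueError("sequences must be at least k long")
    blocks: list[AlignmentBlock] = []
    for strand in (1, -1):
        bseq = b.sequence if strand == 1 else reverse_complement(b.sequence)
        index: dict[str, list[int]] = defaultdict(list)
        for j in range(len(bseq) - k + 1):
            index[bseq[j : j + k]].append(j)
        # per-diagonal extents already absorbed into a block
        done: dict[int, list[tuple[int, int]]] = defaultdict(list)
        aseq = a.sequence
        for i in range(len(aseq) - k + 1):
            hits = index.get(aseq[i : i + k])
            if not hits:
                continue
            for j in hits:
                diag = i - j
                if any(lo <= i and i + k <= hi for lo, hi in done[diag]):
                    continue
                qs, qe, n_match = _extend_gapless(aseq, bseq, i, j, k, match, mismatch, x_drop)
                done[diag].append((qs, qe))
                length = qe - qs
                ss, se = qs - diag, qe - diag  # 0-based half-open on bseq
                if strand == 1:
                    sstart, send = ss + 1, se
                else:
                    sstart = len(b.sequence) - ss
                    send = len(b.sequence) - se + 1
                blocks.append(
                    AlignmentBlock(
                        query_id=a.id,
                        subject_id=b.id,
                        percent_identity=round(100.0 * n_match / length, 2),
                        alignment_length=length,
                        query_start=qs + 1,
                        query_end=qe,
                        subject_start=sstart,
                        subject_end=send,
                        mismatches=length - n_match,
                        bitscore=float(n_match * match + (length - n_match) * mismatch),
                    )
                )
    # deduplicate identical extents found from different seeds
    uniq = {(bl.query_start, bl.query_end, bl.subject_start, bl.subject_end): bl for bl in blocks}
    return sorted(uniq.values(), key=lambda bl: (bl.query_start, bl.subject_start))


# ---------------------------------------------------------------------------
# pairwise ANI / aligned fraction
# ---------------------------------------------------------------------------

def compute_pairwise_ani(blocks: list[AlignmentBlock], len_q: int, len_s: int) -> PairwiseANI:
    """Length-weighted ANI and merged-interval aligned fractions for one pair."""
    if not blocks:
        raise ValueError("empty block list; caller must supply query/subject ids")
    pair = {(bl.query_id, bl.subject_id) for bl in blocks}
    if len(pair) != 1:
        raise ValueError("blocks must share a single (query, subject) pair")
    q_ints, s_ints = [], []
    wsum = lsum = 0.0
    for bl in blocks:
        qlo, qhi = bl.query_interval()
        slo, shi = bl.subject_interval()
        if qhi > len_q or shi > len_s or qlo < 0 or slo < 0:
            raise ValueError(f"block interval exceeds stated sequence length: {bl}")
        q_ints.append((qlo, qhi))
        s_ints.append((slo, shi))
        wsum += bl.percent_identity * bl.alignment_length
        lsum += bl.alignment_length
    (query_id, subject_id), = pair
    return PairwiseANI(
        query_id=query_id,
        subject_id=subject_id,
        ani=wsum / lsum,
        af_query=100.0 * union_length(q_ints) / len_q,
        af_subject=100.0 * union_length(s_ints) / len_s,
    )


def _swap_block(bl: AlignmentBlock) -> AlignmentBlock:
    return AlignmentBlock(
        query_id=bl.subject_id,
        subject_id=bl.query_id,
        percent_identity=bl.percent_identity,
        alignment_length=bl.alignment_length,
        query_start=min(bl.subject_start, bl.subject_end),
        query_end=max(bl.subject_start, bl.subject_end),
        subject_start=bl.query_start,
        subject_end=bl.query_end,
        mismatches=bl.mismatches,
        gap_opens=bl.gap_opens,
        evalue=bl.evalue,
        bitscore=bl.bitscore,
    )


def build_ani_table(blocks: list[AlignmentBlock], lengths: dict[str, int]) -> list[PairwiseANI]:
    """Group blocks by unordered pair (canonical lexicographic orientation)."""
    grouped: dict[tuple[str, str], list[AlignmentBlock]] = defaultdict(list)
    for bl in blocks:
        if bl.query_id == bl.subject_id:
            continue  # self hits carry no clustering information
        a, b = sorted((bl.query_id, bl.subject_id))
        grouped[(a, b)].append(bl if bl.query_id == a else _swap_block(bl))
    return [
        compute_pairwise_ani(blks, lengths[a], lengths[b])
        for (a, b), blks in sorted(grouped.items())
    ]


# ---------------------------------------------------------------------------
# greedy centroid clustering
# ---------------------------------------------------------------------------

def _order_key(c: Contig) -> tuple:
    comp = c.completeness if c.completeness is not None else -1.0
    return (-c.length, -comp, c.id)


def _af_shorter(p: PairwiseANI, len_q: int, len_s: int) -> float:
    if len_q < len_s:
        return p.af_query
    if len_s < len_q:
        return p.af_subject
    return max(p.af_query, p.af_subject)


def cluster_votus(contigs: list[Contig], ani_table: list[PairwiseANI],
                  ani_min: float = 95.0, af_min: float = 85.0) -> list[VOtu]:
    """Greedy centroid clustering into species-level vOTUs.

    Contigs are processed in deterministic order (length desc, completeness
    desc, id asc).  A contig joins the first centroid with ANI >= ``ani_min``
    and aligned fraction of the shorter contig of the pair >= ``af_min``;
    otherwise it founds a new centroid.
    """
    ids = [c.id for c in contigs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate contig ids")
    by_id = {c.id: c for c in contigs}
    for p in ani_table:
        if p.query_id not in by_id or p.subject_id not in by_id:
            raise ValueError(f"ANI table references unknown contig: {p.query_id}/{p.subject_id}")
    pairs = {tuple(sorted((p.query_id, p.subject_id))): p for p in ani_table}

    centroids: list[str] = []
    members: dict[str, list[str]] = {}
    for c in sorted(contigs, key=_order_key):
        home = None
        for cen in centroids:
            p = pairs.get(tuple(sorted((c.id, cen))))
            if p is None:
                continue
            af = _af_shorter(p, by_id[p.query_id].length, by_id[p.subject_id].length)
            if p.ani >= ani_min and af >= af_min:
                home = cen
                break
        if home is None:
            centroids.append(c.id)
            members[c.id] = [c.id]
        else:
            members[home].append(c.id)

    votus = []
    for cen in centroids:
        votu = VOtu(representative_id=cen, member_ids=set(members[cen]))
        votu.representative_id = select_representative(votu, contigs)
        votus.append(votu)
    return votus


def select_representative(votu: VOtu, contigs: list[Contig]) -> str:
    """Longest member, then most complete, then lexicographically smallest id."""
    if not votu.member_ids:
        raise ValueError("empty vOTU")
    pool = [c for c in contigs if c.id in votu.member_ids]
    return min(pool, key=_order_key).id
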