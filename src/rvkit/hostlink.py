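"""Virus-host linkage from prophage alignments and CRISPR spacer matches.

Two independent evidence channels connect a vOTU to a prokaryotic genome:

* prophage evidence - the vOTU aligns to the host genome with at least one
  block longer than 2,500 bp, all counted blocks above 90% nucleotide
  identity, and the qualifying blocks jointly covering at least 75% of the
  vOTU sequence;
* spacer evidence - a CRISPR spacer of the host occurs verbatim (100%
  identity, 100% coverage) in the vOTU sequence on either strand.

Downstream summaries aggregate linked host taxa per vOTU (multi-species and
cross-phylum host ranges) and per-genus infection statistics (phages per
genus, phages per genome, lysogeny rate).
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .ani import AlignmentBlock, reverse_complement, union_length

__all__ = [
    "GTDB_RANKS",
    "Spacer",
    "HostLink",
    "HostRangeSummary",
    "GenusStats",
    "parse_gtdb_lineage",
    "call_prophage_link",
    "detect_crispr_arrays",
    "call_spacer_link",
    "aggregate_host_range",
    "genus_stats",
]

GTDB_RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
_RANK_PREFIXES = dict(zip("dpcofgs", GTDB_RANKS))


def parse_gtdb_lineage(lineage: str) -> dict[str, str]:
    """Parse a 7-rank GTDB lineage string (``d__...;p__...;...;s__...``)."""
    out: dict[str, str] = {}
    for token in lineage.split(";"):
        token = token.strip()
        if len(token) >= 3 and token[1:3] == "__" and token[0] in _RANK_PREFIXES:
            out[_RANK_PREFIXES[token[0]]] = token[3:]
    missing = [r for r in GTDB_RANKS if r not in out]
    if missing:
        raise ValueError(f"lineage missing ranks {missing}: {lineage!r}")
    return out


@dataclass(frozen=True)
class Spacer:
    spacer_id: str
    genome_id: str
    sequence: str
    start: int = 0  # 0-based half-open locus on the genome
    end: int = 0


@dataclass(frozen=True)
class HostLink:
    votu_id: str
    genome_id: str
    evidence: str  # "prophage" | "spacer"
    detail: dict = field(default_factory=dict, compare=False)


@dataclass
class HostRangeSummary:
    votu_id: str
    species: set[str]
    genera: set[str]
    phyla: set[str]

    @property
    def multi_species(self) -> bool:
        return len(self.species) >= 2

    @property
    def cross_phylum(self) -> bool:
        return len(self.phyla) >= 2


@dataclass(frozen=True)
class GenusStats:
    genus: str
    n_phages: int
    n_genomes: int
    phages_per_genome: float
    lysogeny_rate: float  # percent of linked vOTUs that are lysogenic


def call_prophage_link(blocks: list[AlignmentBlock], votu_length: int,
                       min_identity: float = 90.0, min_block_length: int = 2500,
                       min_votu_coverage: float = 0.75) -> HostLink | None:
    """Prophage-evidence host call for one (vOTU, genome) pair.

    The vOTU is the query of every block.  Blocks at identity strictly above
    ``min_identity`` are retained; a link requires at least one retained
    block strictly longer than ``min_block_length`` and the union of
    retained-block query intervals to cover >= ``min_votu_coverage`` of the
    vOTU.
    """
    if votu_length <= 0:
        raise ValueError("votu_length must be positive")
    if not blocks:
        return None
    pairs = {(bl.query_id, bl.subject_id) for bl in blocks}
    if len(pairs) != 1:
        raise ValueError("blocks must share one (vOTU, genome) pair")
    (votu_id, genome_id), = pairs
    kept = [bl for bl in blocks if bl.percent_identity > min_identity]
    if not kept or not any(bl.alignment_length > min_block_length for bl in kept):
        return None
    covered = union_length([bl.query_interval() for bl in kept])
    coverage = covered / votu_length
    if coverage < min_votu_coverage:
        return None
    total = sum(bl.alignment_length for bl in kept)
    mean_id = sum(bl.percent_identity * bl.alignment_length for bl in kept) / total
    return HostLink(
        votu_id=votu_id,
        genome_id=genome_id,
        evidence="prophage",
        detail={
            "n_blocks": len(kept),
            "matched_bp": total,
            "votu_coverage": round(coverage, 4),
            "mean_identity": round(mean_id, 2),
        },
    )


def detect_crispr_arrays(genome_id: str, sequence: str, min_repeats: int = 2,
                         repeat_len: tuple[int, int] = (23, 47),
                         spacer_len: tuple[int, int] = (26, 50)) -> list[Spacer]:
    """Minimal CRISPR array finder (constant-period, exact-repeat arrays).

    Scans for loci where an exact repeat of length within ``repeat_len``
    recurs with inter-repeat gaps within ``spacer_len``; loci with at least
    ``min_repeats`` repeats yield the gap sequences as spacers.  Arrays with
    degenerate repeats or variable spacer lengths are not detected - the
    planted arrays this package simulates are exact and constant-period.
    """
    rl_min, rl_max = repeat_len
    sp_min, sp_max = spacer_len
    k = rl_min
    n = len(sequence)
    if n < 2 * rl_min + sp_min:
        return []
    occurrences: dict[str, list[int]] = defaultdict(list)
    for i in range(n - k + 1):
        occurrences[sequence[i : i + k]].append(i)

    spacers: list[Spacer] = []
    next_free = 0
    counter = 0
    for i in range(n - k + 1):
        if i < next_free:
            continue
        occ = occurrences[sequence[i : i + k]]
        if len(occ) < 2:
            continue
        for j in occ:
            if j <= i:
                continue
            period = j - i
            if not rl_min + sp_min <= period <= rl_max + sp_max:
                continue
            # longest common prefix (capped so repeats cannot overlap)
            lcp = 0
            while i + lcp < j and j + lcp < n and sequence[i + lcp] == sequence[j + lcp]:
                lcp += 1
            rl_lo = max(rl_min, period - sp_max)
            if lcp < rl_lo:
                continue
            # chance matches at either edge can shift the apparent repeat;
            # search start offsets and repeat lengths for the longest chain
            # (ties: longer repeat, then earlier start)
            mismatch_at = i + lcp
            best: tuple[int, int, int, list[int]] | None = None
            for s in range(i, min(i + lcp - rl_lo, mismatch_at) + 1):
                rl_hi = min(mismatch_at - s, rl_max, period - sp_min)
                for rl in range(rl_hi, rl_lo - 1, -1):
                    repeat = sequence[s : s + rl]
                    starts = [s, s + period]
                    while True:
                        nxt = starts[-1] + period
                        if nxt + rl <= n and sequence[nxt : nxt + rl] == repeat:
                            starts.append(nxt)
                        else:
                            break
                    key = (len(starts), rl, -s)
                    if best is None or key > (best[0], best[1], -best[2]):
                        best = (len(starts), rl, s, starts)
            if best is None:
                continue
            _, rl, _, starts = best
            if len(starts) < min_repeats:
                continue
            for m in range(len(starts) - 1):
                s0, s1 = starts[m] + rl, starts[m + 1]
                counter += 1
                spacers.append(
                    Spacer(
                        spacer_id=f"{genome_id}_sp{counter:03d}",
                        genome_id=genome_id,
                        sequence=sequence[s0:s1],
                        start=s0,
                        end=s1,
                    )
                )
            next_free = starts[-1] + rl
            break
    return spacers


def call_spacer_link(spacer: Spacer, votu_id: str, votu_sequence: str) -> HostLink | None:
    """Spacer-evidence host call: exact full-length match on either strand."""
    if not spacer.sequence:
        raise ValueError("empty spacer")
    s = spacer.sequence
    if s in votu_sequence or reverse_complement(s) in votu_sequence:
        return HostLink(
            votu_id=votu_id,
            genome_id=spacer.genome_id,
            evidence="spacer",
            detail={"spacer_id": spacer.spacer_id, "spacer_length": len(s)},
        )
    return None


def aggregate_host_range(links: Iterable[HostLink],
                         taxonomy: Mapping[str, Mapping[str, str]]
                         ) -> dict[str, HostRangeSummary]:
    """Distinct host species/genus/phylum sets per vOTU.

    Links whose genome lacks taxonomy are excluded with a warning.
    """
    out: dict[str, HostRangeSummary] = {}
    for link in links:
        lin = taxonomy.get(link.genome_id)
        if lin is None:
            warnings.warn(f"no taxonomy for genome {link.genome_id}; link excluded",
                          stacklevel=2)
            continue
        summ = out.setdefault(link.votu_id,
                              HostRangeSummary(link.votu_id, set(), set(), set()))
        summ.species.add(lin["species"])
        summ.genera.add(lin["genus"])
        summ.phyla.add(lin["phylum"])
    return out


def genus_stats(links: Iterable[HostLink],
                taxonomy: Mapping[str, Mapping[str, str]],
                lysogeny: Mapping[str, bool]) -> list[GenusStats]:
    """Per-genus infection statistics over all genomes in the taxonomy table."""
    genomes_per_genus: dict[str, int] = defaultdict(int)
    for lin in taxonomy.values():
        genomes_per_genus[lin["genus"]] += 1
    votus_per_genus: dict[str, set[str]] = defaultdict(set)
    for link in links:
        lin = taxonomy.get(link.genome_id)
        if lin is None:
            raise KeyError(f"no taxonomy for genome {link.genome_id}")
        if link.votu_id not in lysogeny:
            raise KeyError(f"no lysogeny call for linked vOTU {link.votu_id}")
        votus_per_genus[lin["genus"]].add(link.votu_id)
    stats = []
    for genus in sorted(votus_per_genus):
        votus = votus_per_genus[genus]
        n_lys = sum(1 for v in votus if lysogeny[v])
        n_gen = genomes_per_genus[genus]
        stats.append(
            GenusStats(
                genus=genus,
                n_phages=len(votus),
                n_genomes=n_gen,
                phages_per_genome=len(votus) / n_gen,
                lysogeny_rate=100.0 * n_lys / len(votus),
            )
        )
    return stats
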