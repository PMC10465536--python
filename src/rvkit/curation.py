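"""AMG and ARG curation on annotated viral contigs.

Auxiliary metabolic gene (AMG) candidates are only trusted on complete viral
genomes (vMAGs) longer than 10 kb, must sit in a convincing viral context
(not at a contig end; flanked by two viral hallmark genes or by one hallmark
and one viral-like gene; annotation confidence category 1 or 2), and the
carrying vMAG must survive a genomic-island screen: it needs at least one
bona fide viral gene beyond mobile elements (integrase/transposase/tail
fiber), at least one recognized structural gene, and no island-marker gene
(endonuclease, plasmid-stability protein, LPS biosynthesis enzyme, GT11/
GT25 glycosyltransferase, nucleotidyltransferase, carbohydrate kinase,
nucleotide-sugar epimerase).

Antimicrobial resistance gene (ARG) hits are retained at >=80% identity and
>=40% reference coverage, and calls on a terminal gene are dropped unless
the single inward neighbor is viral.  Every drop carries one reason code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "GeneFeature",
    "ArgHit",
    "CATEGORIES",
    "STRUCTURAL_LABELS",
    "ISLAND_MARKER_LABELS",
    "REASONS",
    "select_vmags",
    "screen_amg_context",
    "filter_genomic_islands",
    "call_args",
    "pick_representative_arg_contig",
    "distinct_amg_functions",
]

CATEGORIES = ("viral_hallmark", "viral_like", "cellular", "unannotated")

STRUCTURAL_LABELS = frozenset(
    f"structural:{name}"
    for name in ("capsid", "portal", "coat", "baseplate", "head", "tail",
                 "virion_structural", "terminase")
)

ISLAND_MARKER_LABELS = frozenset(
    f"island_marker:{name}"
    for name in ("endonuclease", "plasmid_stability", "lps_biosynthesis",
                 "GT11", "GT25", "nucleotidyltransferase",
                 "carbohydrate_kinase", "nucleotide_sugar_epimerase")
)

MOBILE_LABELS = frozenset({"integrase", "transposase", "tail_fiber"})

#: machine-readable drop/keep reason codes
REASONS = {
    "keep": "keep",
    "amg_end": "amg_at_contig_end",
    "amg_flank": "amg_flank_rule_failed",
    "amg_category": "amg_category_not_1_or_2",
    "island_mobile": "island_only_mobile_viral_genes",
    "island_structural": "island_no_structural_gene",
    "island_marker": "island_marker_gene_present",
    "arg_identity": "arg_identity_below_threshold",
    "arg_coverage": "arg_coverage_below_threshold",
    "arg_end": "arg_at_contig_end_without_viral_neighbor",
}

_KNOWN_LABELS = (MOBILE_LABELS | STRUCTURAL_LABELS | ISLAND_MARKER_LABELS
                 | {"amg_candidate"})


@dataclass(frozen=True)
class GeneFeature:
    """A gene interval on a contig (0-based half-open coordinates)."""

    contig_id: str
    start: int
    end: int
    strand: str = "+"
    category: str = "unannotated"
    labels: frozenset[str] = field(default_factory=frozenset)
    amg_category: int | None = None
    function: str = ""
    gene_id: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start or self.start < 0:
            raise ValueError(f"invalid gene interval [{self.start}, {self.end})")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown gene category: {self.category!r}")
        for label in self.labels:
            if label not in _KNOWN_LABELS and not label.startswith("arg:"):
                raise ValueError(f"label outside controlled vocabulary: {label!r}")

    @property
    def is_viral(self) -> bool:
        return self.category in ("viral_hallmark", "viral_like")

    @property
    def is_amg_candidate(self) -> bool:
        return "amg_candidate" in self.labels


@dataclass(frozen=True)
class ArgHit:
    contig_id: str
    start: int  # gene interval, 0-based half-open
    end: int
    arg_class: str
    percent_identity: float
    reference_coverage: float  # percent of the reference covered

    def __post_init__(self) -> None:
        if not 0 <= self.percent_identity <= 100:
            raise ValueError("percent_identity out of [0,100]")
        if not 0 <= self.reference_coverage <= 100:
            raise ValueError("reference_coverage out of [0,100]")


def select_vmags(contigs, min_length: int = 10000) -> set[str]:
    """Contigs eligible for AMG screening: complete and strictly > 10 kb."""
    return {c.id for c in contigs
            if c.quality_tier == "complete" and c.length > min_length}


def _sorted_genes(genes: Iterable[GeneFeature]) -> list[GeneFeature]:
    return sorted(genes, key=lambda g: (g.start, g.end, g.gene_id))


def screen_amg_context(genes: Iterable[GeneFeature]
                       ) -> list[tuple[GeneFeature, bool, str]]:
    """Flanking-context screen for the AMG candidates of one vMAG.

    Returns one ``(gene, keep, reason)`` triple per AMG candidate.  A
    candidate is dropped when it is the first or last gene of the contig,
    when its immediate neighbors are not (hallmark, hallmark) or (hallmark,
    viral-like), or when its annotation category is not 1 or 2.
    """
    ordered = _sorted_genes(genes)
    decisions = []
    for idx, gene in enumerate(ordered):
        if not gene.is_amg_candidate:
            continue
        if idx == 0 or idx == len(ordered) - 1:
            decisions.append((gene, False, REASONS["amg_end"]))
            continue
        flank = sorted((ordered[idx - 1].category, ordered[idx + 1].category))
        if flank not in (["viral_hallmark", "viral_hallmark"],
                         ["viral_hallmark", "viral_like"]):
            decisions.append((gene, False, REASONS["amg_flank"]))
            continue
        if gene.amg_category not in (1, 2):
            decisions.append((gene, False, REASONS["amg_category"]))
            continue
        decisions.append((gene, True, REASONS["keep"]))
    return decisions


def filter_genomic_islands(genes: Iterable[GeneFeature]) -> tuple[bool, str]:
    """Genomic-island screen for one vMAG: ``(keep, reason)``.

    Dropped when (a) every viral-annotated gene is a mobile element
    (integrase/transposase/tail fiber) - including the vacuous case of no
    viral genes at all; (b) no gene carries a recognized structural label;
    or (c) any gene carries an island-marker label.
    """
    genes = list(genes)
    viral = [g for g in genes if g.is_viral]
    if all(g.labels & MOBILE_LABELS for g in viral):  # vacuously true when empty
        return False, REASONS["island_mobile"]
    if not any(g.labels & STRUCTURAL_LABELS for g in genes):
        return False, REASONS["island_structural"]
    if any(g.labels & ISLAND_MARKER_LABELS for g in genes):
        return False, REASONS["island_marker"]
    return True, REASONS["keep"]


def call_args(hits: Iterable[ArgHit], genes_by_contig: Mapping[str, Sequence[GeneFeature]],
              min_identity: float = 80.0, min_coverage: float = 40.0
              ) -> list[tuple[ArgHit, bool, str]]:
    """Threshold + end-of-contig curation of ARG hits.

    A hit passes at identity >= 80% and reference coverage >= 40%; a passing
    hit on the first/last gene of its contig is dropped unless the single
    inward neighboring gene is viral (hallmark or viral-like).
    """
    import warnings

    decisions = []
    for hit in hits:
        if hit.percent_identity < min_identity:
            decisions.append((hit, False, REASONS["arg_identity"]))
            continue
        if hit.reference_coverage < min_coverage:
            decisions.append((hit, False, REASONS["arg_coverage"]))
            continue
        ordered = _sorted_genes(genes_by_contig.get(hit.contig_id, ()))
        idx = next((i for i, g in enumerate(ordered)
                    if g.start == hit.start and g.end == hit.end), None)
        if idx is None:
            warnings.warn(f"ARG hit without resolvable gene on {hit.contig_id} "
                          f"[{hit.start},{hit.end}); skipped", stacklevel=2)
            continue
        at_start, at_end = idx == 0, idx == len(ordered) - 1
        if at_start or at_end:
            inward = ordered[idx + 1] if at_start else ordered[idx - 1]
            if len(ordered) == 1 or not inward.is_viral:
                decisions.append((hit, False, REASONS["arg_end"]))
                continue
        decisions.append((hit, True, REASONS["keep"]))
    return decisions


def pick_representative_arg_contig(candidates: Iterable[str],
                                   completeness: Mapping[str, float],
                                   genes_by_contig: Mapping[str, Sequence[GeneFeature]]
                                   ) -> str:
    """Representative per ARG class: most complete, then fewest cellular genes."""
    pool = list(candidates)
    if not pool:
        raise ValueError("empty candidate set")

    def key(cid: str) -> tuple:
        n_cellular = sum(1 for g in genes_by_contig.get(cid, ())
                         if g.category == "cellular")
        return (-completeness.get(cid, 0.0), n_cellular, cid)

    return min(pool, key=key)


def distinct_amg_functions(kept_amgs: Iterable[GeneFeature]) -> dict[str, int]:
    """Occurrence count per distinct AMG functional category label."""
    counts: dict[str, int] = {}
    for g in kept_amgs:
        if g.function:
            counts[g.function] = counts.get(g.function, 0) + 1
    return dict(sorted(counts.items()))
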