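"""Seeded synthetic rumen-virome communities with planted ground truth.

Every downstream stage of the package is testable without external data:
the generator emits viral contigs (5-200 kb), host genomes carrying
integrated prophages at controlled nucleotide divergence, CRISPR arrays
whose spacers are exact protospacer copies, annotated gene tables with
planted AMG/ARG/structural/island-marker genes, per-position depth
profiles, and a binary prevalence matrix with diet-group structure - plus
one truth record per planted feature stating the decision the pipeline is
expected to reach.

The mutation model is substitution-only (no indels), so the identity of a
planted prophage equals exactly ``1 - floor(divergence*L)/L`` and its true
alignment block can be written analytically into a BLAST-tabular hit table;
the host-linkage rules are thereby testable with no aligner in the loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .ani import AlignmentBlock, Contig, reverse_complement
from .curation import ArgHit, GeneFeature
from .hostlink import Spacer
from .taxonomy import ProteinHit
from . import io as rio

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "CommunityBundle",
    "random_sequence",
    "mutate_sequence",
    "plant_prophage",
    "plant_crispr_array",
    "generate_community",
    "write_bundle",
]

TRUTH_KINDS = ("prophage", "spacer", "amg", "arg", "core_votu")

_FAMILIES = ("Siphoviridae", "Myoviridae", "Podoviridae", "Microviridae")
_BREEDS = ("holstein", "jersey", "angus")
_PHYLA = (
    ("Bacteria", "Bacillota", "Clostridia", "Lachnospirales", "Lachnospiraceae",
     "Butyrivibrio", "Butyrivibrio fibrisolvens"),
    ("Bacteria", "Bacteroidota", "Bacteroidia", "Bacteroidales", "Prevotellaceae",
     "Prevotella", "Prevotella ruminicola"),
    ("Archaea", "Methanobacteriota", "Methanobacteria", "Methanobacteriales",
     "Methanobacteriaceae", "Methanobrevibacter", "Methanobrevibacter ruminantium"),
    ("Bacteria", "Fibrobacterota", "Fibrobacteria", "Fibrobacterales",
     "Fibrobacteraceae", "Fibrobacter", "Fibrobacter succinogenes"),
)


@dataclass
class SimulationConfig:
    """Stated world of one synthetic community (all randomness from ``seed``)."""

    seed: int = 0
    n_viruses: int = 24
    virus_length_range: tuple[int, int] = (5000, 200000)
    n_hosts: int = 8
    host_length_range: tuple[int, int] = (50000, 300000)
    prophage_divergence: float = 0.02
    n_spacers_per_array: int = 3
    spacer_length: int = 32
    group_labels: tuple[str, ...] = ("low", "medium", "high")
    samples_per_group: int = 16
    #: per-vOTU, per-group occurrence probabilities; built from the seed when None
    prevalence_profile: dict[str, dict[str, float]] | None = None
    variant_fraction: float = 0.25
    variant_divergence: float = 0.02
    gc_content: float = 0.5
    depth_panel_size: int = 4

    def __post_init__(self) -> None:
        for name in ("virus_length_range", "host_length_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be positive and ordered: ({lo}, {hi})")
        for name in ("prophage_divergence", "variant_divergence"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_viruses < 1 or self.n_hosts < 1:
            raise ValueError("need at least one virus and one host")
        if self.samples_per_group < 1:
            raise ValueError("samples_per_group must be >= 1")
        if not self.group_labels:
            raise ValueError("group_labels must be non-empty")
        if len(set(self.group_labels)) != len(self.group_labels):
            raise ValueError("group_labels must be unique")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0, 1)")
        if self.n_spacers_per_array < 2:
            raise ValueError("n_spacers_per_array must be >= 2")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one planted feature (intervals 0-based half-open)."""

    kind: str
    virus_id: str
    host_id: str = ""
    start: int | None = None
    end: int | None = None
    expected_decision: bool | str = True
    feature_id: str = ""
    note: str = ""

    def __post_init__(self) -> None:
        if self.kind not in TRUTH_KINDS:
            raise ValueError(f"unknown truth kind: {self.kind!r}")


@dataclass
class CommunityBundle:
    config: SimulationConfig
    contigs: list[Contig]  # viral contigs incl. near-identical variants
    sequences: dict[str, str]  # viral contig id -> sequence
    hosts: dict[str, str]
    host_taxonomy: dict[str, str]  # genome_id -> GTDB lineage string
    viral_hits: list[AlignmentBlock]  # virus-vs-virus (variant) blocks
    host_hits: list[AlignmentBlock]  # vOTU-vs-host prophage blocks + decoys
    spacers: list[Spacer]
    genes: dict[str, list[GeneFeature]]
    arg_hits: list[ArgHit]
    protein_hits: list[ProteinHit]
    n_proteins: dict[str, int]
    marker_matrix: pd.DataFrame
    depth: dict[tuple[str, str], np.ndarray]  # (votu, sample) -> depth vector
    prevalence: pd.DataFrame  # vOTU x sample, {0,1}
    metadata: pd.DataFrame
    truth: list[TruthRecord] = field(default_factory=list)


_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_sequence(length: int, rng: np.random.Generator, gc: float = 0.5) -> str:
    if length < 1:
        raise ValueError("length must be positive")
    if gc == 0.5:
        idx = rng.integers(0, 4, size=length)
    else:
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        idx = rng.choice(4, size=length, p=p)
    return _ACGT[idx].tobytes().decode()


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def mutate_sequence(seq: str, divergence: float, seed: int | np.random.Generator) -> str:
    """Point-substitute exactly ``floor(divergence * len(seq))`` positions.

    Positions are drawn without replacement and every drawn position receives
    a base different from the original, so the mismatch fraction is exact.
    """
    if not seq:
        raise ValueError("empty sequence")
    if not 0.0 <= divergence <= 1.0:
        raise ValueError("divergence must be in [0, 1]")
    if set(seq) - set("ACGT"):
        raise ValueError("sequence must be over {A,C,G,T}")
    rng = _as_rng(seed)
    n_sub = math.floor(divergence * len(seq))
    if n_sub == 0:
        return seq
    positions = rng.choice(len(seq), size=n_sub, replace=False)
    offsets = rng.integers(1, 4, size=n_sub)  # 1..3: skip the original base
    order = "ACGT"
    base_index = {b: i for i, b in enumerate(order)}
    out = bytearray(seq, "ascii")
    for pos, off in zip(positions, offsets):
        out[pos] = ord(order[(base_index[seq[pos]] + off) % 4])
    return out.decode()


def expected_prophage_decision(virus_length: int, divergence: float,
                               min_identity: float = 90.0,
                               min_block_length: int = 2500) -> bool:
    """Decision the prophage rule must reach on an ideal full-length block."""
    n_sub = math.floor(divergence * virus_length)
    identity = 100.0 * (1 - n_sub / virus_length)
    return identity > min_identity and virus_length > min_block_length


def plant_prophage(host: Contig, virus: Contig, divergence: float, position: int,
                   seed: int | np.random.Generator) -> tuple[Contig, TruthRecord]:
    """Insert a mutated copy of ``virus`` into ``host`` at ``position``."""
    if position < 0:
        raise ValueError("position must be non-negative")
    if position > len(host.sequence):
        raise ValueError("position beyond host end")
    mutated = mutate_sequence(virus.sequence, divergence, seed)
    new_seq = host.sequence[:position] + mutated + host.sequence[position:]
    truth = TruthRecord(
        kind="prophage",
        virus_id=virus.id,
        host_id=host.id,
        start=position,
        end=position + len(mutated),
        expected_decision=expected_prophage_decision(len(virus.sequence), divergence),
        note=f"divergence={divergence}",
    )
    new_host = Contig(id=host.id, sequence=new_seq, completeness=host.completeness,
                      quality_tier=host.quality_tier, sample_id=host.sample_id,
                      provenance=host.provenance)
    return new_host, truth


def plant_crispr_array(host: Contig, protospacer_source: Contig, n_spacers: int,
                       spacer_length: int, repeat: str,
                       seed: int | np.random.Generator
                       ) -> tuple[Contig, list[TruthRecord]]:
    """Append a CRISPR array whose spacers are exact copies from the source.

    The array is ``repeat + (spacer + repeat) * n_spacers`` appended at the
    end of the host; each spacer is a verbatim substring of the protospacer
    source on a strand chosen with probability 0.5 (recorded in the truth).
    """
    if n_spacers < 2:
        raise ValueError("n_spacers must be >= 2")
    if spacer_length > len(protospacer_source.sequence):
        raise ValueError("spacer_length exceeds protospacer source length")
    rng = _as_rng(seed)
    locus = len(host.sequence)
    parts = [repeat]
    truths = []
    offset = locus + len(repeat)
    src = protospacer_source.sequence
    for i in range(n_spacers):
        start = int(rng.integers(0, len(src) - spacer_length + 1))
        spacer = src[start : start + spacer_length]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            spacer = reverse_complement(spacer)
        parts.append(spacer)
        parts.append(repeat)
        truths.append(TruthRecord(
            kind="spacer",
            virus_id=protospacer_source.id,
            host_id=host.id,
            start=offset,
            end=offset + spacer_length,
            expected_decision=True,
            feature_id=f"{host.id}_sp{i + 1:03d}",
            note=f"strand={strand}",
        ))
        offset += spacer_length + len(repeat)
    new_host = Contig(id=host.id, sequence=host.sequence + "".join(parts),
                      completeness=host.completeness, quality_tier=host.quality_tier,
                      sample_id=host.sample_id, provenance=host.provenance)
    return new_host, truths


# ---------------------------------------------------------------------------
# gene-table builders for the curation scenarios
# ---------------------------------------------------------------------------

def _gene_span(contig_length: int, n_slots: int) -> tuple[int, int]:
    """(pitch, gene length) so ``n_slots`` genes fit inside the contig."""
    pitch = min(1000, (contig_length - 200) // n_slots)
    if pitch < 120:
        raise ValueError(f"contig of {contig_length} bp too short for "
                         f"{n_slots} genes")
    return pitch, pitch - 100


def _gene(contig: str, idx: int, pitch: int, glen: int, category: str,
          labels: frozenset[str] = frozenset(),
          amg_category: int | None = None, function: str = "") -> GeneFeature:
    start = 100 + idx * pitch
    return GeneFeature(contig_id=contig, start=start, end=start + glen,
                       strand="+" if idx % 2 == 0 else "-", category=category,
                       labels=labels, amg_category=amg_category,
                       function=function, gene_id=f"{contig}_g{idx + 1:02d}")


_AMG_FUNCTIONS = ("DNMT1", "GH16", "asparagine_synthase", "cobaltochelatase_CobS",
                  "chorismate_mutase", "GH5")

# (category, labels, amg_category, is_planted_amg) per gene slot; scenario key ->
# (layout, cascade decision expected for the planted AMG, expected reason)
_CAPSID = frozenset({"structural:capsid"})
_TERMINASE = frozenset({"structural:terminase"})
_PORTAL = frozenset({"structural:portal"})
_AMG_LBL = frozenset({"amg_candidate"})
_NONE = frozenset()

_AMG_SCENARIOS: dict[int, tuple[list[tuple], bool, str]] = {
    0: ([("viral_hallmark", _CAPSID), ("viral_like", _NONE), ("viral_hallmark", _NONE),
         ("AMG", 1), ("viral_like", _NONE), ("viral_hallmark", _TERMINASE),
         ("cellular", _NONE), ("viral_like", _NONE)],
        True, "keep"),
    1: ([("viral_hallmark", _CAPSID), ("viral_like", _NONE),
         ("viral_hallmark", _TERMINASE), ("cellular", _NONE), ("AMG", 1)],
        False, "amg_at_contig_end"),
    2: ([("viral_hallmark", _CAPSID), ("cellular", _NONE), ("AMG", 1),
         ("cellular", _NONE), ("viral_hallmark", _TERMINASE), ("viral_like", _NONE)],
        False, "amg_flank_rule_failed"),
    3: ([("viral_hallmark", _CAPSID), ("viral_hallmark", _NONE), ("AMG", 3),
         ("viral_like", _NONE), ("viral_hallmark", _TERMINASE), ("cellular", _NONE)],
        False, "amg_category_not_1_or_2"),
    4: ([("viral_hallmark", _CAPSID), ("viral_hallmark", _NONE), ("AMG", 1),
         ("viral_like", _NONE), ("viral_hallmark", _TERMINASE),
         ("cellular", frozenset({"island_marker:GT25"}))],
        False, "island_marker_gene_present"),
    5: ([("viral_hallmark", frozenset({"tail_fiber"})), ("AMG", 1),
         ("viral_like", frozenset({"integrase"})), ("cellular", _NONE),
         ("unannotated", _NONE)],
        False, "island_only_mobile_viral_genes"),
}

_ARG_CLASSES = ("tetW", "tetO", "vanG", "vanW-G", "mefA")

# scenario -> (gene slot of the ARG, layout categories, hit identity, hit
# coverage, expected keep, expected reason)
_ARG_SCENARIOS: dict[int, tuple[int, list[str], float, float, bool, str]] = {
    0: (2, ["viral_hallmark", "viral_like", "cellular", "viral_hallmark", "cellular"],
        90.0, 60.0, True, "keep"),
    1: (2, ["viral_hallmark", "viral_like", "cellular", "viral_hallmark", "cellular"],
        70.0, 60.0, False, "arg_identity_below_threshold"),
    2: (2, ["viral_hallmark", "viral_like", "cellular", "viral_hallmark", "cellular"],
        90.0, 30.0, False, "arg_coverage_below_threshold"),
    3: (4, ["cellular", "viral_like", "cellular", "viral_hallmark", "cellular"],
        90.0, 60.0, True, "keep"),
    4: (0, ["cellular", "cellular", "viral_like", "viral_hallmark", "cellular"],
        90.0, 60.0, False, "arg_at_contig_end_without_viral_neighbor"),
}


def _build_amg_table(contig: str, contig_length: int, scenario: int, rank: int
                     ) -> tuple[list[GeneFeature], list[TruthRecord]]:
    layout, decision, reason = _AMG_SCENARIOS[scenario]
    pitch, glen = _gene_span(contig_length, len(layout))
    genes, truths = [], []
    for idx, (category, extra) in enumerate(layout):
        if category == "AMG":
            fn = _AMG_FUNCTIONS[rank % len(_AMG_FUNCTIONS)]
            g = _gene(contig, idx, pitch, glen, "cellular", _AMG_LBL,
                      amg_category=extra, function=fn)
            genes.append(g)
            truths.append(TruthRecord(kind="amg", virus_id=contig, start=g.start,
                                      end=g.end, expected_decision=decision,
                                      feature_id=g.gene_id, note=reason))
        else:
            genes.append(_gene(contig, idx, pitch, glen, category, extra))
    return genes, truths


def _build_arg_table(contig: str, contig_length: int, scenario: int, rank: int
                     ) -> tuple[list[GeneFeature], ArgHit, TruthRecord]:
    slot, layout, identity, coverage, decision, reason = _ARG_SCENARIOS[scenario]
    arg_class = _ARG_CLASSES[rank % len(_ARG_CLASSES)]
    pitch, glen = _gene_span(contig_length, len(layout))
    genes = []
    for idx, category in enumerate(layout):
        labels = frozenset({f"arg:{arg_class}"}) if idx == slot else _NONE
        if scenario == 1 and category == "viral_like" and idx == 1:
            labels = frozenset({"integrase"})  # lysogeny-channel variety
        genes.append(_gene(contig, idx, pitch, glen,
                           category if idx != slot else "cellular", labels))
    g = genes[slot]
    hit = ArgHit(contig_id=contig, start=g.start, end=g.end, arg_class=arg_class,
                 percent_identity=identity, reference_coverage=coverage)
    truth = TruthRecord(kind="arg", virus_id=contig, start=g.start, end=g.end,
                        expected_decision=decision, feature_id=g.gene_id, note=reason)
    return genes, hit, truth


# ---------------------------------------------------------------------------
# community generation
# ---------------------------------------------------------------------------

_QUALITY_CYCLE = (("complete", 100.0), ("high", 92.5), ("medium", 75.0), ("low", 40.0))


def _ideal_block(virus_id: str, genome_id: str, q_start0: int, q_end0: int,
                 s_start0: int, n_sub: int) -> AlignmentBlock:
    """Analytic BLAST-convention block for a planted, substitution-only insert."""
    length = q_end0 - q_start0
    return AlignmentBlock(
        query_id=virus_id, subject_id=genome_id,
        percent_identity=round(100.0 * (length - n_sub) / length, 2),
        alignment_length=length, mismatches=n_sub,
        query_start=q_start0 + 1, query_end=q_end0,
        subject_start=s_start0 + 1, subject_end=s_start0 + length,
        bitscore=float(length - 3 * n_sub),
    )


def generate_community(config: SimulationConfig) -> CommunityBundle:
    """Generate one deterministic community bundle with planted truth."""
    rng = np.random.default_rng(config.seed)
    truth: list[TruthRecord] = []

    # --- viral contigs -----------------------------------------------------
    lo, hi = config.virus_length_range
    n = config.n_viruses
    lengths = rng.integers(lo + 1, hi + 1, size=n)  # admission floor is strict
    virus_ids = [f"v{i + 1:04d}" for i in range(n)]
    sequences: dict[str, str] = {}
    contigs: list[Contig] = []
    for i, vid in enumerate(virus_ids):
        tier, comp = _QUALITY_CYCLE[i % 4]
        seq = random_sequence(int(lengths[i]), rng, config.gc_content)
        sequences[vid] = seq
        contigs.append(Contig(id=vid, sequence=seq, completeness=comp,
                              quality_tier=tier, sample_id=f"s{i % 3 + 1:02d}",
                              provenance="prophage" if i % 5 == 4 else "free"))

    # --- near-identical variants (exercise vOTU clustering) ----------------
    viral_hits: list[AlignmentBlock] = []
    n_variants = math.floor(config.variant_fraction * n)
    for i in range(n_variants):
        src = virus_ids[i]
        dup_id = f"{src}d"
        dup_seq = mutate_sequence(sequences[src], config.variant_divergence, rng)
        sequences[dup_id] = dup_seq
        contigs.append(Contig(id=dup_id, sequence=dup_seq, completeness=60.0,
                              quality_tier="medium", sample_id="s99"))
        n_sub = math.floor(config.variant_divergence * len(dup_seq))
        viral_hits.append(_ideal_block(src, dup_id, 0, len(dup_seq), 0, n_sub))

    # --- hosts, prophages, decoy fragments ---------------------------------
    hlo, hhi = config.host_length_range
    host_ids = [f"h{j + 1:03d}" for j in range(config.n_hosts)]
    host_seqs = {hid: random_sequence(int(rng.integers(hlo, hhi + 1)), rng,
                                      config.gc_content)
                 for hid in host_ids}
    host_taxonomy = {}
    for j, hid in enumerate(host_ids):
        d, p, c, o, f, g, s = _PHYLA[j % len(_PHYLA)]
        host_taxonomy[hid] = (f"d__{d};p__{p};c__{c};o__{o};f__{f};g__{g};"
                              f"s__{s} {hid}")

    host_hits: list[AlignmentBlock] = []
    inserts: dict[str, list[tuple[int, str, str, int, int, int]]] = {h: [] for h in host_ids}
    # (original position, insert seq, virus id, query start0, query end0, n_sub)
    for i, vid in enumerate(virus_ids):
        hid = host_ids[i % config.n_hosts]
        L = len(sequences[vid])
        if i % 3 in (0, 1):  # full prophage at configured divergence
            pos = int(rng.integers(0, len(host_seqs[hid]) + 1))
            mutated = mutate_sequence(sequences[vid], config.prophage_divergence, rng)
            n_sub = math.floor(config.prophage_divergence * L)
            inserts[hid].append((pos, mutated, vid, 0, L, n_sub))
            truth.append(TruthRecord(
                kind="prophage", virus_id=vid, host_id=hid,
                expected_decision=expected_prophage_decision(
                    L, config.prophage_divergence),
                note=f"divergence={config.prophage_divergence}"))
        else:  # short exact decoy fragment: fails block-length and coverage
            frag_len = 1500
            qs = int(rng.integers(0, L - frag_len + 1))
            pos = int(rng.integers(0, len(host_seqs[hid]) + 1))
            inserts[hid].append((pos, sequences[vid][qs : qs + frag_len],
                                 vid, qs, qs + frag_len, 0))
            truth.append(TruthRecord(
                kind="prophage", virus_id=vid, host_id=hid,
                expected_decision=False, note="decoy_fragment_1500bp"))

    prophage_truth_idx = {(t.virus_id, t.host_id): k for k, t in enumerate(truth)
                          if t.kind == "prophage"}
    for hid in host_ids:
        seq = host_seqs[hid]
        offset = 0
        for pos, ins, vid, qs, qe, n_sub in sorted(inserts[hid],
                                                   key=lambda t: (t[0], t[2])):
            final = pos + offset
            seq = seq[:final] + ins + seq[final:]
            offset += len(ins)
            host_hits.append(_ideal_block(vid, hid, qs, qe, final, n_sub))
            k = prophage_truth_idx[(vid, hid)]
            truth[k] = TruthRecord(kind="prophage", virus_id=vid, host_id=hid,
                                   start=final, end=final + len(ins),
                                   expected_decision=truth[k].expected_decision,
                                   note=truth[k].note)
        host_seqs[hid] = seq

    # --- CRISPR arrays (exact planted spacers + one-mismatch decoys) -------
    spacers: list[Spacer] = []
    by_id = {c.id: c for c in contigs}
    for j, hid in enumerate(host_ids):
        repeat = random_sequence(28, rng)
        source = virus_ids[j % n]
        host_contig = Contig(id=hid, sequence=host_seqs[hid])
        host_contig, sp_truth = plant_crispr_array(
            host_contig, by_id[source], config.n_spacers_per_array,
            config.spacer_length, repeat, rng)
        host_seqs[hid] = host_contig.sequence
        truth.extend(sp_truth)
        for t in sp_truth:
            spacers.append(Spacer(spacer_id=t.feature_id, genome_id=hid,
                                  sequence=host_seqs[hid][t.start : t.end],
                                  start=t.start, end=t.end))
        if j % 2 == 0:  # decoy array: every spacer mutated at one position
            decoy_src = virus_ids[(j + 1) % n]
            repeat2 = random_sequence(28, rng)
            base = len(host_seqs[hid])
            parts = [repeat2]
            off = base + len(repeat2)
            src_seq = sequences[decoy_src]
            for i in range(config.n_spacers_per_array):
                start = int(rng.integers(0, len(src_seq) - config.spacer_length + 1))
                spacer = mutate_sequence(
                    src_seq[start : start + config.spacer_length],
                    1.0 / config.spacer_length, rng)  # exactly one substitution
                parts.extend((spacer, repeat2))
                sid = f"{hid}_dsp{i + 1:03d}"
                spacers.append(Spacer(spacer_id=sid, genome_id=hid, sequence=spacer,
                                      start=off, end=off + config.spacer_length))
                truth.append(TruthRecord(kind="spacer", virus_id=decoy_src,
                                         host_id=hid, start=off,
                                         end=off + config.spacer_length,
                                         expected_decision=False, feature_id=sid,
                                         note="one_mismatch_decoy"))
                off += config.spacer_length + len(repeat2)
            host_seqs[hid] += "".join(parts)

    # --- gene tables, AMG and ARG scenarios ---------------------------------
    genes: dict[str, list[GeneFeature]] = {}
    arg_hits: list[ArgHit] = []
    eligible = [c.id for c in contigs
                if c.quality_tier == "complete" and c.length > 10000
                and not c.id.endswith("d")]
    amg_rank = arg_rank = 0
    for i, vid in enumerate(virus_ids):
        L = len(sequences[vid])
        if vid in eligible:
            table, amg_truth = _build_amg_table(vid, L, amg_rank % 6, amg_rank)
            truth.extend(amg_truth)
            amg_rank += 1
        else:
            table, hit, arg_truth = _build_arg_table(vid, L, arg_rank % 5, arg_rank)
            arg_hits.append(hit)
            truth.append(arg_truth)
            arg_rank += 1
        genes[vid] = table

    # --- protein hits for the family majority rule --------------------------
    protein_hits: list[ProteinHit] = []
    n_proteins: dict[str, int] = {}
    for i, vid in enumerate(virus_ids):
        n_prot = len(genes[vid])
        n_proteins[vid] = n_prot
        family = _FAMILIES[i % len(_FAMILIES)]
        k = n_prot // 2 if i % 4 == 3 else n_prot // 2 + 1  # ==3: not a majority
        for pi in range(k):
            protein_hits.append(ProteinHit(vid, pi, family, 80.0))
        protein_hits.append(ProteinHit(vid, n_prot - 1,
                                       _FAMILIES[(i + 1) % len(_FAMILIES)], 40.0))

    # --- marker-gene matrix --------------------------------------------------
    marker_cols = [f"m{c + 1:02d}" for c in range(77)]
    marker_rows = [c.id for c in contigs
                   if c.completeness is not None and c.completeness > 50
                   and not c.id.endswith("d")]
    mm = pd.DataFrame(0, index=marker_rows, columns=marker_cols, dtype=int)
    for r, vid in enumerate(marker_rows):
        count = 3 if r % 5 == 4 else 4 + r % 8  # every 5th row is too sparse
        cols = rng.choice(77, size=count, replace=False)
        mm.iloc[r, sorted(cols)] = 1

    # --- samples, prevalence, depth -----------------------------------------
    samples, meta_rows = [], []
    for g in config.group_labels:
        for s_idx in range(config.samples_per_group):
            sid = f"{g}_{s_idx + 1:02d}"
            samples.append(sid)
            meta_rows.append({
                "sample_id": sid,
                "animal": f"animal_{len(samples):03d}",
                "group": g,
                "study": f"study_{g}",
                "breed": _BREEDS[len(samples) % len(_BREEDS)],
                "sample_bases": int(rng.integers(1_000_000_000, 5_000_000_000)),
            })
    metadata = pd.DataFrame(meta_rows)

    profile = config.prevalence_profile
    if profile is None:
        profile = {}
        for i, vid in enumerate(virus_ids):
            if i in (0, 1):
                profile[vid] = {g: 1.0 for g in config.group_labels}
            elif i == 2 and len(config.group_labels) > 1:
                profile[vid] = {g: (0.9 if g == config.group_labels[0] else 0.0)
                                for g in config.group_labels}
            else:
                profile[vid] = {g: float(rng.uniform(0.1, 0.6))
                                for g in config.group_labels}
    prevalence = pd.DataFrame(0, index=virus_ids, columns=samples, dtype=int)
    group_of = dict(zip(metadata.sample_id, metadata.group))
    for vid in virus_ids:
        for sid in samples:
            p = profile.get(vid, {}).get(group_of[sid], 0.0)
            present = 1 if p >= 1.0 else (0 if p <= 0.0 else int(rng.random() < p))
            prevalence.loc[vid, sid] = present
    for i, vid in enumerate(virus_ids):
        if config.prevalence_profile is None:
            if i in (0, 1):
                truth.append(TruthRecord(kind="core_votu", virus_id=vid,
                                         expected_decision=True,
                                         note="forced_present_all_groups"))
            elif i == 2 and len(config.group_labels) > 1:
                truth.append(TruthRecord(kind="core_votu", virus_id=vid,
                                         expected_decision=False,
                                         note="absent_outside_first_group"))

    depth: dict[tuple[str, str], np.ndarray] = {}
    panel = sorted(virus_ids, key=lambda v: (len(sequences[v]), v))
    panel = panel[: min(config.depth_panel_size, len(panel))]
    depth_samples = [f"{g}_01" for g in config.group_labels]
    for rank, vid in enumerate(panel):
        L = len(sequences[vid])
        for sid in depth_samples:
            vec = rng.poisson(lam=6 + 2 * rank, size=L).astype(np.int64)
            if rank == 1:  # below the covered-fraction gate on purpose
                vec[: int(0.4 * L)] = 0
            depth[(vid, sid)] = vec

    return CommunityBundle(
        config=config, contigs=contigs, sequences=sequences, hosts=host_seqs,
        host_taxonomy=host_taxonomy, viral_hits=viral_hits, host_hits=host_hits,
        spacers=spacers, genes=genes, arg_hits=arg_hits,
        protein_hits=protein_hits, n_proteins=n_proteins, marker_matrix=mm,
        depth=depth, prevalence=prevalence, metadata=metadata, truth=truth,
    )


# ---------------------------------------------------------------------------
# bundle writer (all plain text)
# ---------------------------------------------------------------------------

def write_bundle(bundle: CommunityBundle, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def p(name: str) -> Path:
        paths[name] = outdir / name
        return paths[name]

    rio.write_fasta(bundle.sequences, p("viruses.fna"))
    rio.write_fasta(bundle.hosts, p("hosts.fna"))
    rio.write_contig_table(bundle.contigs, p("contigs.tsv"))
    rio.write_tsv(p("host_taxonomy.tsv"), ("genome_id", "lineage"),
                  sorted(bundle.host_taxonomy.items()))
    rio.write_blast6(bundle.viral_hits, p("viral_hits.tsv"))
    rio.write_blast6(bundle.host_hits, p("host_hits.tsv"))
    rio.write_spacer_table(bundle.spacers, p("spacers.tsv"))
    rio.write_gene_table(bundle.genes, p("genes.tsv"))
    rio.write_arg_hits(bundle.arg_hits, p("arg_hits.tsv"))
    rio.write_tsv(p("protein_hits.tsv"),
                  ("votu_id", "protein_index", "reference_family", "bitscore"),
                  [(h.votu_id, h.protein_index, h.reference_family,
                    f"{h.bitscore:.1f}") for h in bundle.protein_hits])
    rio.write_tsv(p("protein_counts.tsv"), ("votu_id", "n_proteins"),
                  sorted(bundle.n_proteins.items()))
    bundle.marker_matrix.to_csv(p("marker_matrix.tsv"), sep="\t",
                                index_label="votu_id")
    rio.write_tsv(p("depth.tsv"), ("contig", "sample", "position", "depth"),
                  ((vid, sid, pos + 1, int(d))
                   for (vid, sid) in sorted(bundle.depth)
                   for pos, d in enumerate(bundle.depth[(vid, sid)])))
    bundle.prevalence.to_csv(p("prevalence.tsv"), sep="\t", index_label="votu_id")
    bundle.metadata.to_csv(p("metadata.tsv"), sep="\t", index=False)
    rio.write_tsv(p("truth.tsv"),
                  ("kind", "virus_id", "host_id", "start", "end",
                   "expected_decision", "feature_id", "note"),
                  [(t.kind, t.virus_id, t.host_id,
                    "" if t.start is None else t.start,
                    "" if t.end is None else t.end,
                    t.expected_decision, t.feature_id, t.note)
                   for t in bundle.truth])
    cfg = asdict(bundle.config)
    cfg["virus_length_range"] = list(cfg["virus_length_range"])
    cfg["host_length_range"] = list(cfg["host_length_range"])
    cfg["group_labels"] = list(cfg["group_labels"])
    with open(p("config.yaml"), "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return paths


def read_truth(path: str | Path) -> list[TruthRecord]:
    _, rows = rio.read_tsv(path)
    return [TruthRecord(kind=r[0], virus_id=r[1], host_id=r[2],
                        start=int(r[3]) if r[3] else None,
                        end=int(r[4]) if r[4] else None,
                        expected_decision=(r[5] == "True"),
                        feature_id=r[6], note=r[7]) for r in rows]
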