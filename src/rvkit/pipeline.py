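"""Pipeline orchestration: stage graph, run manifest, config validation.

Stages run in dependency order (simulate -> cluster -> taxonomy -> host ->
curate -> ecology).  Every stage declares its input and output files; a
run manifest records their SHA-256 checksums, and a stage is skipped on
re-run when its inputs and outputs are unchanged.  All randomness flows
from the single config seed, so a manifest plus config fully determines
the outputs of every stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, fields
from itertools import combinations
from pathlib import Path

import pandas as pd
import yaml

from . import io as rio
from .ani import admit_contigs, build_ani_table, cluster_votus
from .curation import (call_args, filter_genomic_islands, screen_amg_context,
                       select_vmags)
from .ecology import classify_core, cluster_studies, richness_per_gbp, \
    shared_votus, trimmed_mean_coverage
from .hostlink import (aggregate_host_range, call_prophage_link,
                       call_spacer_link, genus_stats, parse_gtdb_lineage)
from .synth import SimulationConfig, generate_community, write_bundle
from .taxonomy import (assign_family_majority, classify_lysogenic,
                       filter_marker_concatemers)

__all__ = ["ConfigError", "PipelineConfig", "RunManifest", "run_pipeline",
           "run_stage", "STAGES", "load_config"]

log = logging.getLogger("rvkit")


class ConfigError(ValueError):
    """Invalid pipeline configuration; message names the offending field."""


@dataclass
class PipelineConfig:
    seed: int = 0
    simulate: SimulationConfig = field(default_factory=SimulationConfig)
    ani_min: float = 95.0
    af_min: float = 85.0
    core_threshold: float = 0.5
    core_strict: bool = True
    min_study_samples: int = 12

    def __post_init__(self) -> None:
        for name in ("ani_min", "af_min"):
            v = getattr(self, name)
            if not 0 < v <= 100:
                raise ConfigError(f"cluster.{name}: must be in (0, 100], got {v}")
        if not 0 < self.core_threshold < 1:
            raise ConfigError(
                f"ecology.core_threshold: must be in (0, 1), got {self.core_threshold}")
        if self.min_study_samples < 0:
            raise ConfigError("ecology.min_study_samples: must be >= 0")


def load_config(path: str | Path | None = None, seed: int | None = None,
                overrides: dict | None = None) -> PipelineConfig:
    """Build a validated PipelineConfig from a YAML file and/or overrides."""
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    if overrides:
        raw.update(overrides)
    if seed is not None:
        raw["seed"] = seed

    known = {"seed", "simulate", "cluster", "ecology"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config section(s): {sorted(unknown)}")

    sim_kwargs = dict(raw.get("simulate") or {})
    sim_fields = {f.name for f in fields(SimulationConfig)}
    bad = set(sim_kwargs) - sim_fields
    if bad:
        raise ConfigError(f"simulate.{sorted(bad)[0]}: unknown field")
    for key in ("virus_length_range", "host_length_range", "group_labels"):
        if key in sim_kwargs and isinstance(sim_kwargs[key], list):
            sim_kwargs[key] = tuple(sim_kwargs[key])
    sim_kwargs["seed"] = raw.get("seed", 0)
    try:
        sim = SimulationConfig(**sim_kwargs)
    except ValueError as exc:
        raise ConfigError(f"simulate: {exc}") from exc

    cluster = raw.get("cluster") or {}
    ecology = raw.get("ecology") or {}
    for section, allowed in (("cluster", {"ani_min", "af_min"}),
                             ("ecology", {"core_threshold", "strict",
                                          "min_study_samples"})):
        bad = set(raw.get(section) or {}) - allowed
        if bad:
            raise ConfigError(f"{section}.{sorted(bad)[0]}: unknown field")
    return PipelineConfig(
        seed=raw.get("seed", 0),
        simulate=sim,
        ani_min=float(cluster.get("ani_min", 95.0)),
        af_min=float(cluster.get("af_min", 85.0)),
        core_threshold=float(ecology.get("core_threshold", 0.5)),
        core_strict=bool(ecology.get("strict", True)),
        min_study_samples=int(ecology.get("min_study_samples", 12)),
    )


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: PipelineConfig, outdir: Path) -> None:
    bundle = generate_community(cfg.simulate)
    write_bundle(bundle, outdir / "synth")
    log.info("simulate: %d viral contigs, %d hosts, %d truth records",
             len(bundle.contigs), len(bundle.hosts), len(bundle.truth))


def _read_prevalence(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="votu_id")


def _stage_cluster(cfg: PipelineConfig, outdir: Path) -> None:
    contigs = rio.read_contig_table(outdir / "synth" / "contigs.tsv")
    admitted = admit_contigs(contigs)
    log.info("cluster: %d contigs in, %d admitted (>5 kb)",
             len(contigs), len(admitted))
    blocks = rio.read_blast6(outdir / "synth" / "viral_hits.tsv")
    lengths = {c.id: c.length for c in admitted}
    table = build_ani_table(
        [b for b in blocks if b.query_id in lengths and b.subject_id in lengths],
        lengths)
    votus = cluster_votus(admitted, table, cfg.ani_min, cfg.af_min)
    log.info("cluster: %d contigs -> %d vOTUs", len(admitted), len(votus))
    stage = outdir / "cluster"
    stage.mkdir(exist_ok=True)
    rio.write_tsv(stage / "clusters.tsv", ("representative_id", "member_id"),
                  sorted((v.representative_id, m)
                         for v in votus for m in sorted(v.member_ids)))
    rio.write_tsv(stage / "ani_table.tsv",
                  ("query_id", "subject_id", "ani", "af_query", "af_subject"),
                  [(p.query_id, p.subject_id, f"{p.ani:.3f}",
                    f"{p.af_query:.3f}", f"{p.af_subject:.3f}") for p in table])


def _representatives(outdir: Path) -> list[str]:
    _, rows = rio.read_tsv(outdir / "cluster" / "clusters.tsv")
    return sorted({r[0] for r in rows})


def _stage_taxonomy(cfg: PipelineConfig, outdir: Path) -> None:
    from .taxonomy import ProteinHit

    reps = _representatives(outdir)
    _, hit_rows = rio.read_tsv(outdir / "synth" / "protein_hits.tsv")
    hits: dict[str, list[ProteinHit]] = {}
    for r in hit_rows:
        hits.setdefault(r[0], []).append(
            ProteinHit(r[0], int(r[1]), r[2], float(r[3])))
    _, count_rows = rio.read_tsv(outdir / "synth" / "protein_counts.tsv")
    n_proteins = {r[0]: int(r[1]) for r in count_rows}
    genes = rio.read_gene_table(outdir / "synth" / "genes.tsv")
    provenance = {c.id: c.provenance
                  for c in rio.read_contig_table(outdir / "synth" / "contigs.tsv")}

    tax_rows, lys_rows = [], []
    for votu in reps:
        call = assign_family_majority(hits.get(votu, []), n_proteins.get(votu, 1))
        method = "family_majority" if call.family != "unclassified" else "unclassified"
        tax_rows.append((votu, "family", call.family,
                         f"{call.supporting_fraction:.3f}", method))
        lys = classify_lysogenic(provenance.get(votu, "free"),
                                 [g.labels for g in genes.get(votu, [])])
        lys_rows.append((votu, lys))
    log.info("taxonomy: %d vOTUs, %d classified", len(reps),
             sum(1 for r in tax_rows if r[2] != "unclassified"))

    mm = pd.read_csv(outdir / "synth" / "marker_matrix.tsv", sep="\t",
                     index_col="votu_id")
    rows, cols = filter_marker_concatemers(mm)
    stage = outdir / "taxonomy"
    stage.mkdir(exist_ok=True)
    rio.write_tsv(stage / "taxonomy.tsv",
                  ("votu_id", "rank", "name", "supporting_fraction", "method"),
                  tax_rows)
    rio.write_tsv(stage / "lysogeny.tsv", ("votu_id", "lysogenic"), lys_rows)
    rio.write_tsv(stage / "marker_retained.tsv", ("kind", "id"),
                  [("row", r) for r in rows] + [("column", c) for c in cols])


def _stage_host(cfg: PipelineConfig, outdir: Path) -> None:
    reps = set(_representatives(outdir))
    contigs = {c.id: c for c in rio.read_contig_table(outdir / "synth" / "contigs.tsv")}
    blocks = rio.read_blast6(outdir / "synth" / "host_hits.tsv")
    by_pair: dict[tuple[str, str], list] = {}
    for b in blocks:
        if b.query_id in reps:
            by_pair.setdefault((b.query_id, b.subject_id), []).append(b)
    links = []
    for (votu, _genome), pair_blocks in sorted(by_pair.items()):
        link = call_prophage_link(pair_blocks, contigs[votu].length)
        if link:
            links.append(link)

    sequences = rio.read_fasta(outdir / "synth" / "viruses.fna")
    spacers = rio.read_spacer_table(outdir / "synth" / "spacers.tsv")
    for spacer in spacers:
        for votu in sorted(reps):
            link = call_spacer_link(spacer, votu, sequences[votu])
            if link:
                links.append(link)
    log.info("host: %d prophage+spacer links from %d pairs / %d spacers",
             len(links), len(by_pair), len(spacers))

    _, tax_rows = rio.read_tsv(outdir / "synth" / "host_taxonomy.tsv")
    taxonomy = {r[0]: parse_gtdb_lineage(r[1]) for r in tax_rows}
    _, lys_rows = rio.read_tsv(outdir / "taxonomy" / "lysogeny.tsv")
    lysogeny = {r[0]: r[1] == "True" for r in lys_rows}

    ranges = aggregate_host_range(links, taxonomy)
    stats = genus_stats(links, taxonomy, lysogeny)

    stage = outdir / "host"
    stage.mkdir(exist_ok=True)
    rio.write_tsv(stage / "links.tsv",
                  ("votu_id", "genome_id", "evidence", "detail"),
                  [(l.votu_id, l.genome_id, l.evidence, json.dumps(l.detail))
                   for l in sorted(links, key=lambda l: (l.votu_id, l.genome_id,
                                                         l.evidence, str(l.detail)))])
    rio.write_tsv(stage / "host_range.tsv",
                  ("votu_id", "n_species", "n_genera", "n_phyla",
                   "multi_species", "cross_phylum"),
                  [(v, len(s.species), len(s.genera), len(s.phyla),
                    s.multi_species, s.cross_phylum)
                   for v, s in sorted(ranges.items())])
    rio.write_tsv(stage / "genus_stats.tsv",
                  ("genus", "n_phages", "n_genomes", "phages_per_genome",
                   "lysogeny_rate"),
                  [(g.genus, g.n_phages, g.n_genomes,
                    f"{g.phages_per_genome:.4f}", f"{g.lysogeny_rate:.2f}")
                   for g in stats])


def _stage_curate(cfg: PipelineConfig, outdir: Path) -> None:
    contigs = rio.read_contig_table(outdir / "synth" / "contigs.tsv")
    genes = rio.read_gene_table(outdir / "synth" / "genes.tsv")
    arg_hits = rio.read_arg_hits(outdir / "synth" / "arg_hits.tsv")
    vmags = select_vmags(contigs)
    completeness = {c.id: c.completeness or 0.0 for c in contigs}

    amg_rows, island_rows = [], []
    for contig in sorted(vmags):
        table = genes.get(contig, [])
        keep_island, island_reason = filter_genomic_islands(table)
        island_rows.append((contig, keep_island, island_reason))
        for gene, keep, reason in screen_amg_context(table):
            final = keep and keep_island
            final_reason = reason if not keep else (
                "keep" if keep_island else island_reason)
            amg_rows.append((contig, gene.gene_id, gene.start, gene.end,
                             gene.function, final, final_reason))
    arg_decisions = call_args(arg_hits, genes)
    kept_by_class: dict[str, list[str]] = {}
    for hit, keep, _reason in arg_decisions:
        if keep:
            kept_by_class.setdefault(hit.arg_class, []).append(hit.contig_id)
    from .curation import pick_representative_arg_contig
    rep_rows = [(klass, pick_representative_arg_contig(cands, completeness, genes))
                for klass, cands in sorted(kept_by_class.items())]
    log.info("curate: %d vMAGs screened, %d AMG candidates, %d ARG hits",
             len(vmags), len(amg_rows), len(arg_decisions))

    stage = outdir / "curate"
    stage.mkdir(exist_ok=True)
    rio.write_tsv(stage / "amg_calls.tsv",
                  ("contig_id", "gene_id", "start", "end", "function",
                   "keep", "reason"), amg_rows)
    rio.write_tsv(stage / "island_decisions.tsv",
                  ("contig_id", "keep", "reason"), island_rows)
    rio.write_tsv(stage / "arg_calls.tsv",
                  ("contig_id", "start", "end", "arg_class",
                   "percent_identity", "reference_coverage", "keep", "reason"),
                  [(h.contig_id, h.start, h.end, h.arg_class,
                    f"{h.percent_identity:.1f}", f"{h.reference_coverage:.1f}",
                    keep, reason) for h, keep, reason in arg_decisions])
    rio.write_tsv(stage / "arg_representatives.tsv",
                  ("arg_class", "representative_contig"), rep_rows)
    rio.write_tsv(stage / "diagram.tsv",
                  ("contig", "gene", "start", "end", "strand", "label"),
                  [(cid, g.gene_id, g.start, g.end, g.strand,
                    ",".join(sorted(g.labels)) or g.category)
                   for cid in sorted(genes) for g in genes[cid]])


def _stage_ecology(cfg: PipelineConfig, outdir: Path) -> None:
    synth = outdir / "synth"
    depth = pd.read_csv(synth / "depth.tsv", sep="\t", comment="#",
                        names=["contig", "sample", "position", "depth"])
    abundance_rows = []
    for (votu, sample), grp in depth.groupby(["contig", "sample"], sort=True):
        vec = grp.sort_values("position")["depth"].to_numpy()
        abundance_rows.append((votu, sample, f"{trimmed_mean_coverage(vec):.4f}"))

    prevalence = _read_prevalence(synth / "prevalence.tsv")
    metadata = pd.read_csv(synth / "metadata.tsv", sep="\t")
    groups = dict(zip(metadata.sample_id, metadata.group))
    studies = dict(zip(metadata.sample_id, metadata.study))
    bases = dict(zip(metadata.sample_id, metadata.sample_bases))

    richness_rows = []
    for sample in prevalence.columns:
        n_detected = int((prevalence[sample] > 0).sum())
        richness_rows.append((sample, n_detected, bases[sample],
                              f"{richness_per_gbp(n_detected, bases[sample]):.3f}"))

    core = classify_core(prevalence, groups, cfg.core_threshold, cfg.core_strict)
    group_labels = sorted(set(groups.values()))

    pairs = list(combinations(sorted(prevalence.columns), 2))
    labels = ["same_group" if groups[a] == groups[b] else "different_group"
              for a, b in pairs]
    shared = shared_votus(prevalence, pairs, labels)

    stage = outdir / "ecology"
    stage.mkdir(exist_ok=True)
    rio.write_tsv(stage / "abundance.tsv",
                  ("votu_id", "sample_id", "trimmed_mean"), abundance_rows)
    rio.write_tsv(stage / "richness.tsv",
                  ("sample_id", "n_detected", "sample_bases", "richness_per_gbp"),
                  richness_rows)
    core_cols = ["votu_id", "class"] + [f"core_{g}" for g in group_labels] \
        + ["global_core"]
    rio.write_tsv(stage / "core.tsv", core_cols,
                  [[votu] + [row["class"]] + [row[f"core_{g}"] for g in group_labels]
                   + [row["global_core"]]
                   for votu, row in core.table.iterrows()])
    rio.write_tsv(stage / "core_venn.tsv", ("group_set", "n_core_votus"),
                  sorted(core.venn_counts.items()))
    shared.to_csv(stage / "shared_counts.tsv", sep="\t", index=False)
    try:
        sc = cluster_studies(prevalence, studies, cfg.min_study_samples)
        rio.write_tsv(stage / "study_linkage.tsv",
                      ("cluster_a", "cluster_b", "height", "size"),
                      [(int(a), int(b), f"{h:.6f}", int(s))
                       for a, b, h, s in sc.linkage])
        sc.shared.to_csv(stage / "study_shared.tsv", sep="\t",
                         index_label="study")
    except ValueError as exc:
        log.warning("ecology: study clustering skipped (%s)", exc)
        with open(stage / "study_linkage.tsv", "w") as fh:
            fh.write(f"# skipped: {exc}\n")
    n_core = int(core.table["global_core"].sum())
    log.info("ecology: %d vOTUs, %d global core", len(prevalence), n_core)


STAGES: dict[str, tuple] = {
    # name -> (function, input paths relative to outdir, output dir name)
    "simulate": (_stage_simulate, (), "synth"),
    "cluster": (_stage_cluster,
                ("synth/contigs.tsv", "synth/viral_hits.tsv"), "cluster"),
    "taxonomy": (_stage_taxonomy,
                 ("synth/protein_hits.tsv", "synth/protein_counts.tsv",
                  "synth/genes.tsv", "synth/contigs.tsv",
                  "synth/marker_matrix.tsv", "cluster/clusters.tsv"), "taxonomy"),
    "host": (_stage_host,
             ("synth/host_hits.tsv", "synth/contigs.tsv", "synth/viruses.fna",
              "synth/spacers.tsv", "synth/host_taxonomy.tsv",
              "cluster/clusters.tsv", "taxonomy/lysogeny.tsv"), "host"),
    "curate": (_stage_curate,
               ("synth/contigs.tsv", "synth/genes.tsv", "synth/arg_hits.tsv"),
               "curate"),
    "ecology": (_stage_ecology,
                ("synth/depth.tsv", "synth/prevalence.tsv",
                 "synth/metadata.tsv"), "ecology"),
}

_STAGE_ORDER = tuple(STAGES)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _checksum_tree(outdir: Path, subdir: str) -> dict[str, str]:
    root = outdir / subdir
    if not root.is_dir():
        return {}
    return {str(f.relative_to(outdir)): _sha256(f)
            for f in sorted(root.iterdir()) if f.is_file()}


@dataclass
class RunManifest:
    config: dict
    version: str = rio.RULESET_VERSION
    stages: dict = field(default_factory=dict)

    def save(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump({"config": self.config, "version": self.version,
                       "stages": self.stages}, fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path: Path) -> "RunManifest":
        with open(path) as fh:
            data = json.load(fh)
        return cls(config=data["config"], version=data.get("version", ""),
                   stages=data.get("stages", {}))


def _config_echo(cfg: PipelineConfig) -> dict:
    sim = {f.name: getattr(cfg.simulate, f.name) for f in fields(SimulationConfig)}
    for key in ("virus_length_range", "host_length_range", "group_labels"):
        sim[key] = list(sim[key])
    return {"seed": cfg.seed, "simulate": sim,
            "cluster": {"ani_min": cfg.ani_min, "af_min": cfg.af_min},
            "ecology": {"core_threshold": cfg.core_threshold,
                        "strict": cfg.core_strict,
                        "min_study_samples": cfg.min_study_samples}}


def run_stage(name: str, cfg: PipelineConfig, outdir: Path) -> None:
    func, inputs, _outsub = STAGES[name]
    for rel in inputs:
        if not (outdir / rel).is_file():
            raise FileNotFoundError(
                f"stage '{name}' is missing input {rel}; run the producing "
                f"stage first")
    func(cfg, outdir)


def run_pipeline(cfg: PipelineConfig, outdir: str | Path,
                 stages: tuple[str, ...] = _STAGE_ORDER) -> RunManifest:
    """Run the stage graph, skipping stages whose inputs are unchanged."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    previous = (RunManifest.load(manifest_path).stages
                if manifest_path.is_file() else {})
    echo = _config_echo(cfg)
    manifest = RunManifest(config=echo)

    for name in stages:
        func, inputs, outsub = STAGES[name]
        in_sums = {rel: _sha256(outdir / rel) for rel in inputs
                   if (outdir / rel).is_file()}
        if len(in_sums) < len(inputs):
            missing = sorted(set(inputs) - set(in_sums))
            raise FileNotFoundError(
                f"stage '{name}' is missing input {missing[0]}")
        prev = previous.get(name)
        cached = (
            prev is not None
            and prev.get("inputs") == in_sums
            and prev.get("config") == echo
            and prev.get("outputs")
            and all((outdir / rel).is_file()
                    and _sha256(outdir / rel) == sha
                    for rel, sha in prev["outputs"].items())
        )
        started = time.time()
        if cached:
            log.info("%s: inputs unchanged, skipped (cache hit)", name)
            outputs = prev["outputs"]
        else:
            func(cfg, outdir)
            outputs = _checksum_tree(outdir, outsub)
        manifest.stages[name] = {
            "inputs": in_sums,
            "outputs": outputs,
            "config": echo,
            "skipped": bool(cached),
            "started": started,
            "finished": time.time(),
        }
        manifest.save(manifest_path)
    return manifest
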