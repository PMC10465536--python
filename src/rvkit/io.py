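"""Plain-text format readers and writers shared by all pipeline stages.

Coordinates are 0-based half-open inside the package; the 1-based inclusive
formats (BLAST tabular, GFF-like gene tables) are converted here and only
here.  Every TSV written carries a commented header line with the column
names and the ruleset version so outputs are self-describing.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .ani import AlignmentBlock, Contig
from .curation import ArgHit, GeneFeature
from .hostlink import Spacer

__all__ = [
    "RULESET_VERSION",
    "read_fasta",
    "write_fasta",
    "read_blast6",
    "write_blast6",
    "read_gene_table",
    "write_gene_table",
    "read_contig_table",
    "write_contig_table",
    "read_spacer_table",
    "write_spacer_table",
    "read_arg_hits",
    "write_arg_hits",
    "write_tsv",
    "read_tsv",
]

RULESET_VERSION = "rvkit-ruleset-1.0"


def _header_line(columns: Sequence[str]) -> str:
    return "# " + "\t".join(columns) + f"\t[{RULESET_VERSION}]"


def write_tsv(path: str | Path, columns: Sequence[str],
              rows: Iterable[Sequence]) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(_header_line(columns) + "\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for row in rows:
            writer.writerow(row)


def read_tsv(path: str | Path) -> tuple[list[str], list[list[str]]]:
    """Read a TSV with an optional commented header; returns (columns, rows)."""
    columns: list[str] = []
    rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if not columns:
                    fields = line.lstrip("# ").split("\t")
                    columns = [f for f in fields if not f.startswith("[")]
                continue
            rows.append(line.split("\t"))
    return columns, rows


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Sequences by id (first whitespace-delimited header token)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="")
            for name, seq in records.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


# ---------------------------------------------------------------------------
# BLAST outfmt-6 (12 columns, 1-based inclusive coordinates)
# ---------------------------------------------------------------------------

_BLAST6_COLUMNS = ("qseqid", "sseqid", "pident", "length", "mismatch",
                   "gapopen", "qstart", "qend", "sstart", "send",
                   "evalue", "bitscore")


def read_blast6(path: str | Path) -> list[AlignmentBlock]:
    blocks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}")
            try:
                blocks.append(AlignmentBlock(
                    query_id=fields[0],
                    subject_id=fields[1],
                    percent_identity=float(fields[2]),
                    alignment_length=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    query_start=int(fields[6]),
                    query_end=int(fields[7]),
                    subject_start=int(fields[8]),
                    subject_end=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                ))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return blocks


def write_blast6(blocks: Iterable[AlignmentBlock], path: str | Path) -> None:
    with open(path, "w") as fh:
        for bl in blocks:
            fh.write("\t".join((
                bl.query_id,
                bl.subject_id,
                f"{bl.percent_identity:.2f}",
                str(bl.alignment_length),
                str(bl.mismatches),
                str(bl.gap_opens),
                str(bl.query_start),
                str(bl.query_end),
                str(bl.subject_start),
                str(bl.subject_end),
                f"{bl.evalue:.2g}",
                f"{bl.bitscore:.1f}",
            )) + "\n")


# ---------------------------------------------------------------------------
# GFF3-like gene table (1-based inclusive; key=value attributes in column 9)
# ---------------------------------------------------------------------------

def write_gene_table(genes_by_contig: Mapping[str, Sequence[GeneFeature]],
                     path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"##gff-version 3-like [{RULESET_VERSION}]\n")
        for contig in sorted(genes_by_contig):
            for g in sorted(genes_by_contig[contig],
                            key=lambda g: (g.start, g.end, g.gene_id)):
                attrs = [f"ID={g.gene_id}", f"category={g.category}"]
                if g.labels:
                    attrs.append("labels=" + ",".join(sorted(g.labels)))
                if g.amg_category is not None:
                    attrs.append(f"amg_category={g.amg_category}")
                if g.function:
                    attrs.append(f"function={g.function}")
                fh.write("\t".join((
                    contig, "rvkit", "gene",
                    str(g.start + 1), str(g.end), ".", g.strand, ".",
                    ";".join(attrs),
                )) + "\n")


def read_gene_table(path: str | Path) -> dict[str, list[GeneFeature]]:
    out: dict[str, list[GeneFeature]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns")
            attrs = dict(kv.split("=", 1) for kv in fields[8].split(";") if kv)
            labels = frozenset(attrs.get("labels", "").split(",")) - {""}
            out.setdefault(fields[0], []).append(GeneFeature(
                contig_id=fields[0],
                start=int(fields[3]) - 1,
                end=int(fields[4]),
                strand=fields[6],
                category=attrs.get("category", "unannotated"),
                labels=labels,
                amg_category=(int(attrs["amg_category"])
                              if "amg_category" in attrs else None),
                function=attrs.get("function", ""),
                gene_id=attrs.get("ID", ""),
            ))
    return out


# ---------------------------------------------------------------------------
# simple entity tables
# ---------------------------------------------------------------------------

_CONTIG_COLUMNS = ("contig_id", "length", "completeness", "quality_tier",
                   "sample_id", "provenance")


def write_contig_table(contigs: Iterable[Contig], path: str | Path) -> None:
    rows = [(c.id, c.length,
             "" if c.completeness is None else f"{c.completeness:.1f}",
             c.quality_tier, c.sample_id, c.provenance)
            for c in sorted(contigs, key=lambda c: c.id)]
    write_tsv(path, _CONTIG_COLUMNS, rows)


def read_contig_table(path: str | Path) -> list[Contig]:
    _, rows = read_tsv(path)
    return [Contig(id=r[0], _length=int(r[1]),
                   completeness=float(r[2]) if r[2] else None,
                   quality_tier=r[3], sample_id=r[4], provenance=r[5])
            for r in rows]


_SPACER_COLUMNS = ("spacer_id", "genome_id", "sequence", "start", "end")


def write_spacer_table(spacers: Iterable[Spacer], path: str | Path) -> None:
    rows = [(s.spacer_id, s.genome_id, s.sequence, s.start, s.end)
            for s in spacers]
    write_tsv(path, _SPACER_COLUMNS, rows)


def read_spacer_table(path: str | Path) -> list[Spacer]:
    _, rows = read_tsv(path)
    return [Spacer(spacer_id=r[0], genome_id=r[1], sequence=r[2],
                   start=int(r[3]), end=int(r[4])) for r in rows]


_ARG_COLUMNS = ("contig_id", "start", "end", "arg_class",
                "percent_identity", "reference_coverage")


def write_arg_hits(hits: Iterable[ArgHit], path: str | Path) -> None:
    rows = [(h.contig_id, h.start, h.end, h.arg_class,
             f"{h.percent_identity:.1f}", f"{h.reference_coverage:.1f}")
            for h in hits]
    write_tsv(path, _ARG_COLUMNS, rows)


def read_arg_hits(path: str | Path) -> list[ArgHit]:
    _, rows = read_tsv(path)
    return [ArgHit(contig_id=r[0], start=int(r[1]), end=int(r[2]),
                   arg_class=r[3], percent_identity=float(r[4]),
                   reference_coverage=float(r[5])) for r in rows]
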