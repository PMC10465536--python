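# Methods

This note documents the rules `rvkit` implements, the parameters that
matter, what the synthetic-data generator does and does not emulate, and the
design choices made where the underlying conventions are genuinely open.

## Scope and provenance of the rules

The package covers the analysis layer of a bulk-metagenome virome study
*downstream* of raw viral detection: detection, assembly, and annotation
tools (VirSorter2, CheckV, VIBRANT, vConTACT2, DRAMv, GTDB-Tk, MinCED,
CoverM and kin) are treated as external producers whose outputs arrive as
plain-text tables.  What `rvkit` owns are the decision rules applied to
those tables, re-implemented as pure functions so that each threshold and
boundary is explicit and testable.

## vOTU clustering

* **ANI** between two contigs is the alignment-length-weighted mean identity
  over their local alignment blocks; no per-block identity floor is applied.
* **Aligned fraction** is computed on the *union* of block intervals (merged
  0-based half-open intervals), so overlapping blocks are not double
  counted, and AF ≤ 100 by construction.
* **Clustering** is greedy centroid clustering: contigs are ordered by
  length (desc), completeness (desc, unknown last), id (asc); each contig
  joins the first centroid with ANI ≥ `ani_min` (95) and AF of the *shorter*
  contig of the pair ≥ `af_min` (85), else founds a centroid.  Membership is
  tested only against centroids — a contig that matches a non-centroid
  member but fails its centroid founds its own vOTU.  Because the order is
  recomputed internally, the partition is invariant to input order.
* **Admission**: contigs of exactly 5,000 bp are rejected (strict >5 kb),
  since short contigs carry a high viral-detection false-positive rate.
* **Representative**: longest member, then most complete, then smallest id.
  Length-first is a choice; the source convention ("longest and most
  complete") does not state which ranks first.
* The equal-length AF tie (neither contig is shorter) takes the larger of
  the two AFs; it can only matter on exact length ties.
* `local_align` is a deliberately small gapless seed-and-extend aligner
  (k ≥ 11 exact seeds, x-drop 20, match +1 / mismatch −2, both strands,
  BLAST-convention coordinates).  It exists so the package is self-contained
  on synthetic data; production inputs are expected to arrive as BLAST
  tabular files.

## Taxonomy rules

* **Family majority rule**: hits below bit score 50 are discarded (50 itself
  is kept); each protein votes for the family of its best remaining hit and
  abstains on a cross-family bit-score tie; a family is called only when
  matched by strictly more than half of *all* predicted proteins of the
  vOTU, not just the matched ones.
* **crAss-like flag**: blocks at ≥80% identity are merged on the *reference*
  and the flag requires ≥50% coverage of the reference length — coverage is
  measured on the reference, not the query.
* **Lysogeny**: prophage provenance OR any integrase gene.
* **Marker concatemer filter**: rows (concatemers) must show >3 markers,
  columns (markers) must appear in >5% of remaining rows; rows are filtered
  first, then columns, and the pair of passes repeats to a fixed point.  The
  original description is ambiguous about ordering; the fixed point makes
  the result well defined and idempotent, and is not claimed to be the
  source's exact order.

## Virus–host linkage

* **Prophage rule** (three thresholds, each bound to its natural object):
  per-block identity strictly >90%; at least one block strictly >2,500 bp;
  union of qualifying-block vOTU intervals ≥75% of the vOTU length.  Whether
  the 2,500 bp applies per block or to summed blocks is not stated in the
  conventions this follows; per-block is adopted.  The 75% boundary is
  inclusive.  Eukaryotic endogenous viral elements in single-cell assemblies
  reuse the same rule unchanged.
* **Spacer rule**: literal full-length string equality on either strand;
  ambiguity codes never match; a single mismatch breaks the link.
* **CRISPR mini-detector**: finds constant-period arrays of exact repeats
  (repeat 23–47 bp, spacer 26–50 bp, ≥2 repeats).  Chance matches at the
  repeat edges are resolved by searching start offsets and repeat lengths
  for the assignment that sustains the longest repeat chain (ties: longer
  repeat, earlier start).  Degenerate repeats and variable-length spacers
  are out of scope — real detection is MinCED's job; this exists to close
  the loop on planted arrays.  An array with *n* spacers has *n*+1 repeats;
  the detector reports exactly the *n* gap sequences.
* **Genus statistics**: phages per genome averages distinct linked vOTUs
  over all genomes of the genus in the taxonomy table; the lysogeny rate is
  the percentage of linked vOTUs flagged lysogenic.  A linked vOTU without a
  lysogeny call is a contract error, not a silent zero.

## AMG and ARG curation

* **Eligibility**: complete viral genomes strictly >10 kb.
* **Context screen** per candidate: not the first or last gene; immediate
  neighbors (hallmark, hallmark) or (hallmark, viral-like) in either order;
  annotation confidence category 1 or 2.  "At an end" is read as first/last
  gene rather than a fixed distance from the contig terminus.
* **Genomic-island screen** per genome, evaluated in order: (a) no viral
  gene beyond mobile elements (integrase/transposase/tail fiber) — this is
  the adopted reading of the island criterion, since a literal "any
  non-viral gene" would delete every AMG carrier; (b) no recognized
  structural gene (capsid, portal, coat, baseplate, head, tail, virion
  structural, terminase); (c) any island-marker gene (endonuclease, plasmid
  stability, LPS biosynthesis, GT11, GT25, nucleotidyltransferase,
  carbohydrate kinase, nucleotide-sugar epimerase).  The first failing
  clause is the reason code.
* **ARG rule**: identity ≥80% and reference coverage ≥40% (inclusive
  thresholds); a terminal ARG survives only if the single inward neighbor is
  viral.  Per ARG class, the representative contig maximizes completeness,
  then fewest cellular genes, then smallest id.
* Both screens are pure per-contig predicates, so the cascade is
  order-stable; this is asserted on random fixtures.

## Ecology

* **Read filter**: identity ≥95% and aligned fraction of the read ≥0.75,
  both inclusive.
* **Trimmed mean**: abundance is 0 unless ≥70% of positions have nonzero
  depth; otherwise `floor(0.05·L)` positions are removed from each extreme
  of the sorted depth vector and the remainder averaged.  The floor-per-tail
  count follows the positional reading of "regions"; the statistic is
  translation-equivariant and permutation-invariant, which the suite
  asserts.
* **Richness**: detected vOTUs × 10⁹ / bases sequenced.
* **Core virome**: per group, prevalence strictly >50% by default.  The two
  published phrasings disagree ("exceeded 50%" vs "at least 50%"), so the
  boundary is a switch (`strict=False` for ≥) and the choice is echoed in
  the result metadata.  Classes: `individualized` (exactly one occurrence
  overall), else `one/two/three_levels` by the number of groups with at
  least one occurrence; `absent` for all-zero rows.
* **Study clustering**: studies with strictly more than 12 samples are
  retained; between-study sharing counts vOTUs present in ≥1 sample of each
  study; the dissimilarity is `1 − shared/min(richness_a, richness_b)` under
  average linkage.  Neither the transform nor the linkage is fixed by the
  conventions this mirrors; both are configurable, and the tests pin the
  merge order against a textbook agglomerative oracle.  Wilcoxon/
  Kruskal–Wallis/PERMANOVA testing is left to standard statistics packages;
  the module emits tidy tables for them.

## The synthetic community generator

The generator's purpose is falsifiable testing, not realism.  It emulates:
viral genomes of 5–200 kb (uniform lengths, GC 0.5 unless configured);
near-identical variant contigs (2% divergence) that must collapse in
clustering; host genomes (50–300 kb at desk scale; real MAGs are ~2 Mb, but
host length does not enter any rule) carrying planted prophages at
controlled divergence plus 1.5 kb decoy fragments; CRISPR arrays whose
spacers are exact protospacer copies (32 bp × 3 per array, 28 bp repeats)
plus one-mismatch decoy arrays; gene tables cycling through every AMG/ARG
curation scenario; Poisson depth profiles (one per panel vOTU deliberately
below the coverage gate); and a binary prevalence matrix over three diet
groups × 16 samples with two forced-core vOTUs and one group-restricted
vOTU.

The mutation model is substitution-only with exactly `floor(d·L)` changed
positions, so planted identity is `1 − d` *exactly* and the true alignment
block of every planted feature can be emitted analytically into a
BLAST-tabular hit table.  Consequently a green host-linkage test establishes
that the decision rules are implemented correctly on ideal evidence — it
does not establish robustness to indels, chimeric assembly, repeat-induced
spurious alignments, or aligner-specific block fragmentation, none of which
the generator produces.  Read-level simulation (FASTQ, error models,
assembly) is explicitly out of scope.

Sizes the conventions do not fix (24 viruses, 8 hosts, 2% prophage
divergence, 3 spacers of 32 bp per array, 3 diet groups × 16 samples) were
chosen once as desk-scale defaults: large enough that every curation
scenario and both linkage channels occur in a default run, small enough
that the full pipeline runs in ~1 s.  Under the defaults, 2% divergence
puts planted prophages comfortably above the 90% identity rule and 20%
divergence (used in the recovery suite) puts them categorically below it.

## Numerical and engineering choices

* Coordinates are 0-based half-open everywhere inside the package;
  BLAST-tabular and the GFF-like gene table (1-based inclusive) are
  converted only at the I/O boundary, and minus-strand subject blocks are
  normalized before interval unions.
* All thresholds are explicit keyword parameters with the defaults above;
  boundary semantics (strict vs inclusive) follow the quoted rules and are
  unit-tested at the boundary value.
* All randomness flows from one integer seed through a single
  `numpy.random.Generator`; identical configs produce byte-identical
  bundles and pipeline outputs (asserted by checksum).
* Ties are always broken deterministically, ending in lexicographic id
  order.
* The run manifest records SHA-256 checksums of every stage input and
  output; a stage re-runs only when its inputs or the config changed.

## Known limitations

* The aligner is gapless; indel-containing homology is fragmented into
  multiple blocks and will under-estimate AF near the 85% boundary.
* The CRISPR detector requires exact, constant-period repeats.
* Genus-level taxonomy from gene-sharing networks is consumed, not
  recomputed; the family majority rule is the only taxonomy computed here.
* The core-virome and study-clustering statistics describe the synthetic
  world's binary matrices; no compositional or rarefaction corrections are
  applied.
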