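# Methods

## Canonical gene model

All readers normalise to one record per **transcript** (not per gene):
published per-gene structure tables list single `.1` transcripts, and BED12
input has no gene-level row at all, so the transcript is the only unit
reproducible from every supported format. Multi-isoform genes yield multiple
rows; `subset_by_ids` selects among them. Coordinates are 1-based inclusive
(the GFF3 convention); BED12's 0-based half-open blocks are converted on
read and back-converted bit-exactly on write.

GTF rows typed merely `UTR` carry no 5′/3′ designation; they are classified
by position relative to the CDS extent and strand, with a UTR overlapping
the CDS extent assigned to the nearer CDS edge. Unknown feature types
(e.g. `signal_peptide`) are retained as `other` segments with their type as
label so they can be drawn as overlays; they never contribute to spans or
counts. Files are read as UTF-8 with CRLF tolerated.

## Exon blocks, introns and statistics

Exon blocks are the merged union of explicit exon segments when present,
otherwise of CDS+UTR segments; intervals merge when the gap between them is
≤ 0 (touching intervals are one block). Introns are the strict gaps between
consecutive blocks, so `n_introns = blocks − 1` holds identically and
intron lengths + block lengths = gene length (span conservation).

CDS and UTR counts are **raw annotated segments**, not merged blocks. This
is the only reading consistent with reference rows such as a transcript
with 2 introns but 2 CDS + 3 UTR segments; it also means a UTR split across
two exons counts as 2, which is a documented choice rather than a fact
recoverable from the published table alone.

Intron classes follow the standard three-way rule (0 / 1–3 / >3 introns).
Means and percentages are rounded half-up to two decimals — the convention
that reproduces a printed mean of 2802.62 from a total of 117710 bp over 42
genes; max/min are exact integers.

## Protein → genome projection

Amino acids [a₁,a₂] map to coding nucleotides [3a₁−2, 3a₂]; CDS segments are
walked in translation order (ascending genomic coordinates on +, descending
on −) and the covered genomic pieces returned split at CDS junctions, each
as an ascending (start, end) pair sorted by start. Amino acid 1 is assumed
to begin at the first coding base: annotated CDS phase is ignored, which is
correct for complete gene models and documented as a limitation for
5′-truncated ones. The test oracle enumerates every coding nucleotide and
groups runs; because a run-grouping oracle would merge two CDS segments
that happen to be genomically adjacent, the randomized comparison suite
generates models with introns ≥ 1 bp and one CDS piece per exon block,
where both definitions coincide.

## Trees

Newick parsing and serialisation delegate to Bio.Phylo, wrapped with a
pre-scan that reports unbalanced parentheses and a missing terminator with
character offsets, and a post-check rejecting duplicate leaf labels. Leaf
order is file order — no re-rooting, no default ladderization — because the
leaf order defines row alignment for every other panel and must be
reproducible. Layout is rectangular: leaf *i* of *n* sits at
y = (i+0.5)·height/n, internal nodes at the mean of their children's y;
x comes from node depth (cladogram, default) or cumulative branch length
(phylogram, missing lengths treated as 0), scaled so the deepest node
reaches the panel width. Cladogram is the default because branch-length
information is often absent from the trees users feed in; a flag switches
modes. Group coloring uses a fixed 12-color cycle assigned in
first-appearance order; edges are colored only for monophyletic groups
(the subtended clade), labels always.

## Motif, domain and promoter tracks

MEME XML and plain-text reports are both supported (the text report carries
no Scanned Sites section, so scanned sites come from XML only). Motif
identity is canonicalised to "motif k" in discovery order; XML site
positions are 0-based and converted. The published description of motif
drawing fixes only that box height is negatively correlated with the site
p-value; the concrete map used here is clamped-linear in −log₁₀p with
h_min = 0.2, h_max = 1.0 and saturation at p = 10⁻³⁰, all three
configurable — only monotonicity is treated as normative, and the property
suite tests exactly that. Scanned sites default to opacity 0.4. The
per-site p-value (not the motif E-value) drives height, so two occurrences
of the same motif can differ in height.

Domain tables are read through per-dialect column maps (generic TSV,
NCBI-CDD hitdata, pfam_scan, SMART); exact duplicate rows are dropped,
distinct overlapping hits kept. Cis-element tables are PlantCARE-style
(id, name, position, length, strand) on promoters of a stated length, with
position 1 the upstream-most base and exact duplicates removed.

Selective display (`filter_items`) restricts items by name or kind; an
empty selection means show-all, and a selection matching nothing anywhere
is a warning, never an error.

## Figure composition and rendering

A figure is an ordered panel list with width fractions summing to 1 on a
canvas measured in inches. Row order comes from the tree (default) or input
order; mismatches between panel ids and rows are warnings in lenient mode
and an enumerated error in strict mode. Horizontal scaling is a global
bp-per-inch (or aa-per-inch) factor shared by all rows of a panel, so
lengths are comparable down a column; per-row normalization is available by
flag. Minus-strand genes are drawn 5′→3′ left-to-right (flipped) with a
"(−)" marker, disable-able. Z-order within a row: baseline < intron lines <
UTR < CDS/exon < domain outline < text; on the motif panel, scanned sites
draw beneath motifs and domain outlines above them, outline-only so the
motifs stay visible.

SVG is written by a small dedicated serialiser with fixed number formatting
and no timestamps, which is what makes byte-identical output across runs a
contract rather than an accident; element ids encode the source item
(`struct.<id>.cds.0`, `motif.<id>.motif.3`, `tree.leaf.<id>`) so vector
output stays editable. PDF and PNG render through matplotlib from the same
scene graph; a W×H-inch canvas at dpi *d* yields exactly (W·d)×(H·d)
pixels. PDF carries vector geometry but no element ids (the format has no
equivalent); determinism is guaranteed for SVG only.

## Synthetic data

The generators emit coordinates and metadata only — no sequence content —
because nothing downstream reads bases or residues. Defaults mirror the
reference workload: 42 genes in clades of 26 and 16, 0–5 introns per gene,
exon lengths 80–600 bp, introns 60–500 bp, UTRs up to 300 bp per side, 12
motifs (15–40 aa) with site p-values 10⁻³–10⁻³⁰, 2 kb promoters, and at
least 250 codons of CDS so every protein can host an inhibitory (PMEI-like)
domain ahead of the core (pectinesterase-like) domain. First-clade proteins
carry both domains and two clade-specific motifs (one constrained inside
the PMEI domain); second-clade proteins carry the core domain only, with
sporadic motif loss — emulating the qualitative pattern such families show.
Ground-truth statistics are computed from the construction itself, not via
the statistics code, so generator/analyzer round-trips are genuine checks.

The bundled 42-row reference table fixes span, intron count and raw
CDS/UTR counts per gene but not internal segment lengths; materialization
reconstructs those deterministically (100 bp introns, near-even segment
lengths packed into introns+1 blocks). Any materialization satisfying the
counts reproduces the table's statistics, so this choice is free.

What the synthetic data does **not** emulate: real intron length
distributions, alternative splicing, overlapping genes, malformed
real-world annotation quirks, MEME E-value structure, or sequence-driven
motif placement. Passing tests therefore demonstrate correctness of
parsing, counting, projection, layout and rendering logic — not robustness
to every wild-type annotation file.

## Problem sizes and numerical choices

The randomized suites use 500 models for the projection/oracle comparison,
100 genes × 3 formats for format equivalence, 200 configurations for the
generator round-trip and 200 random trees for Newick round-tripping —
sizes at which the suites complete in seconds while exercising every code
path; all are seeded and deterministic. Geometric assertions use 1e-6
drawing-unit tolerances; statistics comparisons are exact (integer counts,
fixed 2-decimal rounding). Degenerate inputs are defined errors: an empty
model collection cannot be summarised, a model with only `other` segments
has no drawable structure, and a projection beyond coding capacity reports
the capacity.

## Known limitations

* CDS phase is ignored in projection (see above).
* Non-monophyletic groups color labels only, never edges.
* PDF/PNG determinism is best-effort (matplotlib internals), SVG is the
  deterministic interchange format.
* BED12 round-trips are bit-exact for writer-produced lines; foreign BED
  files with scores/itemRgb round-trip coordinates, not cosmetic fields.
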