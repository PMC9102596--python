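"""Synthetic input generation and the bundled rice PME reference table.

Everything the readers consume (GFF3/GTF/BED12, Newick, MEME XML/text, domain
and cis-element TSVs) can be generated here, seed-deterministically, so the
whole package is testable without any downloads.  The generators emit
coordinates and metadata only — no sequence content is simulated, because none
of the drawing or statistics code ever looks at bases or residues.

The module also ships, as plain data, the published per-gene structure table
of the 42-member rice pectin methylesterase (PME) family (26 genes in an
intron-poor clade "Group 1", 16 in an intron-rich clade "Group 2").  That
table is the reference workload for the statistics code: every row can be
materialized as a consistent :class:`~genepanel.model.GeneModel` whose
recomputed statistics reproduce the printed numbers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .gene_structure import StructureStats, classify_intron_content
from .model import FeatureSegment, GeneModel, SegmentKind

# --------------------------------------------------------------------------
# The published rice PME structure table (42 transcripts)
# --------------------------------------------------------------------------

#: (transcript_id, gene_length, n_introns, n_cds, n_utrs, group)
TABLE1_ROWS: tuple[tuple[str, int, int, int, int, str], ...] = (
    ("LOC_Os01g13320.1", 2103, 1, 2, 1, "Group 1"),
    ("LOC_Os02g18650.1", 3372, 1, 2, 2, "Group 1"),
    ("LOC_Os01g57854.1", 6655, 1, 2, 2, "Group 1"),
    ("LOC_Os06g09340.1", 2739, 1, 2, 2, "Group 1"),
    ("LOC_Os11g07090.1", 1602, 0, 1, 0, "Group 1"),
    ("LOC_Os01g15039.1", 4076, 1, 2, 2, "Group 1"),
    ("LOC_Os08g34900.1", 4290, 1, 2, 2, "Group 1"),
    ("LOC_Os09g37360.1", 1098, 2, 3, 0, "Group 1"),
    ("LOC_Os02g54190.1", 2328, 1, 2, 2, "Group 1"),
    ("LOC_Os01g20980.1", 2620, 1, 2, 2, "Group 1"),
    ("LOC_Os05g29790.1", 3339, 1, 2, 2, "Group 1"),
    ("LOC_Os01g21034.1", 8802, 1, 2, 2, "Group 1"),
    ("LOC_Os07g47830.1", 4342, 1, 2, 2, "Group 1"),
    ("LOC_Os11g08750.1", 2145, 1, 2, 2, "Group 1"),
    ("LOC_Os11g36240.1", 2646, 1, 2, 0, "Group 1"),
    ("LOC_Os08g12410.1", 2634, 1, 2, 2, "Group 1"),
    ("LOC_Os03g18860.1", 2097, 0, 1, 2, "Group 1"),
    ("LOC_Os07g49100.1", 2074, 1, 2, 2, "Group 1"),
    ("LOC_Os04g38560.1", 2035, 0, 1, 2, "Group 1"),
    ("LOC_Os04g54850.1", 3333, 1, 2, 2, "Group 1"),
    ("LOC_Os03g28090.1", 2335, 1, 2, 2, "Group 1"),
    ("LOC_Os04g43370.1", 557, 1, 2, 0, "Group 1"),
    ("LOC_Os08g34910.1", 3415, 2, 3, 2, "Group 1"),
    ("LOC_Os09g26360.1", 2443, 1, 2, 2, "Group 1"),
    ("LOC_Os01g65790.1", 4928, 1, 2, 2, "Group 1"),
    ("LOC_Os04g35770.1", 1844, 0, 1, 2, "Group 1"),
    ("LOC_Os10g26680.1", 2398, 5, 6, 2, "Group 2"),
    ("LOC_Os01g19440.1", 1702, 3, 4, 0, "Group 2"),
    ("LOC_Os07g46190.1", 2126, 3, 4, 2, "Group 2"),
    ("LOC_Os03g19610.1", 2021, 4, 5, 2, "Group 2"),
    ("LOC_Os11g45720.1", 2159, 1, 2, 2, "Group 2"),
    ("LOC_Os11g45730.1", 2154, 1, 2, 2, "Group 2"),
    ("LOC_Os12g37660.1", 3901, 4, 5, 2, "Group 2"),
    ("LOC_Os11g43830.1", 2546, 2, 2, 3, "Group 2"),
    ("LOC_Os01g44340.1", 1791, 4, 5, 2, "Group 2"),
    ("LOC_Os07g41650.1", 3216, 4, 5, 2, "Group 2"),
    ("LOC_Os01g53990.1", 2883, 4, 5, 2, "Group 2"),
    ("LOC_Os05g44600.1", 3095, 4, 5, 2, "Group 2"),
    ("LOC_Os04g46740.1", 2197, 3, 4, 2, "Group 2"),
    ("LOC_Os09g39760.1", 2382, 0, 1, 2, "Group 2"),
    ("LOC_Os02g46310.1", 1722, 5, 6, 0, "Group 2"),
    ("LOC_Os08g10604.1", 1565, 4, 5, 1, "Group 2"),
)

_INTRON_LEN = 100  # fixed intron size used when materializing table rows


class FixtureError(ValueError):
    """Infeasible fixture configuration."""


def table1_fixture() -> tuple[list[StructureStats], dict[str, str]]:
    """The bundled 42-row PME structure table plus its gene -> group mapping."""
    stats = [
        StructureStats(
            transcript_id=tid,
            gene_length=length,
            n_introns=introns,
            n_cds=cds,
            n_utrs=utrs,
            intron_class=classify_intron_content(introns),
            group=group,
        )
        for tid, length, introns, cds, utrs, group in TABLE1_ROWS
    ]
    groups = {tid: group for tid, *_rest, group in TABLE1_ROWS}
    return stats, groups


def _chrom_of(transcript_id: str) -> str:
    m = re.search(r"Os(\d{2})g", transcript_id)
    return f"Chr{int(m.group(1))}" if m else "Chr1"


def table1_gene_models() -> list[GeneModel]:
    """Materialize each table row as a consistent gene model.

    The published table fixes span, intron count and raw CDS/UTR segment
    counts but not the internal segment lengths; those are reconstructed
    deterministically (fixed 100 bp introns, near-even segment lengths,
    segments packed into ``introns + 1`` exon blocks).  Recomputing the
    statistics from the materialized models reproduces the table exactly.
    """
    models = []
    for idx, (tid, length, introns, n_cds, n_utrs, _group) in enumerate(TABLE1_ROWS):
        models.append(
            _materialize_row(tid, length, introns, n_cds, n_utrs, offset=1 + idx * 20000)
        )
    return models


def _materialize_row(
    tid: str, length: int, introns: int, n_cds: int, n_utrs: int, offset: int
) -> GeneModel:
    n_blocks = introns + 1
    u5 = (n_utrs + 1) // 2 if n_cds else n_utrs
    u3 = n_utrs - u5
    kinds = (
        [SegmentKind.FIVE_UTR] * u5
        + [SegmentKind.CDS] * n_cds
        + [SegmentKind.THREE_UTR] * u3
    )
    nsegs = len(kinds)
    if nsegs < n_blocks:
        raise FixtureError(
            f"{tid}: {nsegs} segments cannot form {n_blocks} exon blocks"
        )
    exonic = length - _INTRON_LEN * introns
    if exonic < nsegs:
        raise FixtureError(f"{tid}: span {length} too short for {nsegs} segments")
    base, rem = divmod(exonic, nsegs)
    seg_lens = [base + rem] + [base] * (nsegs - 1)
    q, r = divmod(nsegs, n_blocks)
    block_sizes = [q + 1] * r + [q] * (n_blocks - r)

    segments: list[FeatureSegment] = []
    pos = offset
    i = 0
    for bi, bsize in enumerate(block_sizes):
        block_lo = pos
        for _ in range(bsize):
            seg_end = pos + seg_lens[i] - 1
            segments.append(FeatureSegment(kinds[i], pos, seg_end))
            pos = seg_end + 1
            i += 1
        segments.append(FeatureSegment(SegmentKind.EXON, block_lo, pos - 1))
        pos += _INTRON_LEN  # gap to the next block
    gene_id = tid.rsplit(".", 1)[0]
    return GeneModel(
        gene_id=gene_id,
        transcript_id=tid,
        chrom=_chrom_of(tid),
        strand="+",
        segments=segments,
        source_format="gff3",
    )


# --------------------------------------------------------------------------
# Random synthetic data
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class FixtureConfig:
    """Knobs for the synthetic generators.

    Defaults mirror the reference workload: 42 genes split 26/16 into two
    clades, up to 5 introns per gene, 12 motifs with site p-values spanning
    1e-3 .. 1e-30, and 2 kb promoters.
    """

    n_genes: int = 42
    seed: int = 0
    intron_count_range: tuple[int, int] = (0, 5)
    exon_length_range: tuple[int, int] = (80, 600)
    intron_length_range: tuple[int, int] = (60, 500)
    utr_length_range: tuple[int, int] = (0, 300)
    n_motifs: int = 12
    p_value_exp_range: tuple[float, float] = (3.0, 30.0)
    groups: tuple[tuple[str, int], ...] = (("Group 1", 26), ("Group 2", 16))
    promoter_length: int = 2000
    min_coding_nt: int = 750  # keeps proteins long enough to host both domains

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise FixtureError("n_genes must be >= 1")
        for name, (lo, hi) in (
            ("intron_count_range", self.intron_count_range),
            ("exon_length_range", self.exon_length_range),
            ("intron_length_range", self.intron_length_range),
            ("utr_length_range", self.utr_length_range),
        ):
            if lo > hi or lo < 0:
                raise FixtureError(f"{name} {lo}..{hi} is empty or negative")
        if self.exon_length_range[1] < 3:
            raise FixtureError("exons must be able to hold at least one codon")
        if self.intron_length_range[0] < 1:
            raise FixtureError("introns must be at least 1 bp")
        if self.groups and sum(size for _n, size in self.groups) != self.n_genes:
            raise FixtureError("group sizes must sum to n_genes")
        lo, hi = self.p_value_exp_range
        if not (0 < lo <= hi):
            raise FixtureError("p_value_exp_range must be positive")


def _synth_ids(rng: np.random.Generator, n: int) -> list[str]:
    ids: list[str] = []
    seen: set[str] = set()
    while len(ids) < n:
        name = f"LOC_Os{int(rng.integers(1, 13)):02d}g{int(rng.integers(10000, 60000)):05d}.1"
        if name not in seen:
            seen.add(name)
            ids.append(name)
    return ids


def synth_gene_models(
    config: FixtureConfig,
) -> tuple[list[GeneModel], list[StructureStats], dict[str, str]]:
    """Seed-deterministic random gene models with exact ground-truth stats.

    Ground truth is computed from the construction itself (block layout and
    coding-region split), independently of the statistics code, so the
    round-trip ``compute_stats(synth) == ground truth`` is a real check.
    """
    rng = np.random.default_rng(config.seed)
    ids = _synth_ids(rng, config.n_genes)
    group_of: dict[str, str] = {}
    cursor = 0
    for gname, size in config.groups:
        for tid in ids[cursor : cursor + size]:
            group_of[tid] = gname
        cursor += size

    models: list[GeneModel] = []
    truth: list[StructureStats] = []
    for i, tid in enumerate(ids):
        n_introns = int(
            rng.integers(config.intron_count_range[0], config.intron_count_range[1] + 1)
        )
        n_blocks = n_introns + 1
        block_lens = [
            int(rng.integers(config.exon_length_range[0] or 3, config.exon_length_range[1] + 1))
            for _ in range(n_blocks)
        ]
        total = sum(block_lens)
        if total < config.min_coding_nt + 6:
            block_lens[-1] += config.min_coding_nt + 6 - total
            total = sum(block_lens)
        u5 = int(rng.integers(config.utr_length_range[0], config.utr_length_range[1] + 1))
        u3 = int(rng.integers(config.utr_length_range[0], config.utr_length_range[1] + 1))
        max_utr = max(total - config.min_coding_nt, 0)
        if u5 + u3 > max_utr:
            u5 = min(u5, max_utr // 2)
            u3 = min(u3, max_utr - u5)
        coding = total - u5 - u3
        u3 += coding % 3  # keep the CDS a whole number of codons
        coding = total - u5 - u3
        intron_lens = [
            int(rng.integers(config.intron_length_range[0], config.intron_length_range[1] + 1))
            for _ in range(n_introns)
        ]
        strand = "+" if rng.random() < 0.5 else "-"
        start = 1 + i * 50000

        # transcript-coordinate regions (left to right on the genome)
        left_utr_len, right_utr_len = (u5, u3) if strand == "+" else (u3, u5)
        left_kind = SegmentKind.FIVE_UTR if strand == "+" else SegmentKind.THREE_UTR
        right_kind = SegmentKind.THREE_UTR if strand == "+" else SegmentKind.FIVE_UTR

        segments: list[FeatureSegment] = []
        n_cds = n_left = n_right = 0
        g = start  # genomic cursor
        t = 0  # transcript offset of the block start
        cds_lo, cds_hi = left_utr_len + 1, left_utr_len + coding
        for bi, blen in enumerate(block_lens):
            b_lo_t, b_hi_t = t + 1, t + blen
            segments.append(FeatureSegment(SegmentKind.EXON, g, g + blen - 1))
            for lo_t, hi_t, kind in (
                (b_lo_t, min(b_hi_t, cds_lo - 1), left_kind),
                (max(b_lo_t, cds_lo), min(b_hi_t, cds_hi), SegmentKind.CDS),
                (max(b_lo_t, cds_hi + 1), b_hi_t, right_kind),
            ):
                if lo_t > hi_t:
                    continue
                seg = FeatureSegment(kind, g + (lo_t - b_lo_t), g + (hi_t - b_lo_t))
                segments.append(seg)
                if kind is SegmentKind.CDS:
                    n_cds += 1
                elif kind is left_kind:
                    n_left += 1
                else:
                    n_right += 1
            g += blen
            if bi < n_introns:
                g += intron_lens[bi]
            t += blen

        span = sum(block_lens) + sum(intron_lens)
        truth.append(
            StructureStats(
                transcript_id=tid,
                gene_length=span,
                n_introns=n_introns,
                n_cds=n_cds,
                n_utrs=n_left + n_right,
                intron_class=classify_intron_content(n_introns),
                group=group_of.get(tid),
            )
        )
        models.append(
            GeneModel(
                gene_id=tid.rsplit(".", 1)[0],
                transcript_id=tid,
                chrom=_chrom_of(tid),
                strand=strand,
                segments=segments,
                source_format="gff3",
            )
        )
    return models, truth, group_of


def synth_annotation(
    config: FixtureConfig, format: str = "gff3"
) -> tuple[str, list[StructureStats]]:
    """Annotation text in the requested format plus its ground-truth stats."""
    from . import annotation_io

    writers = {
        "gff3": annotation_io.write_gff3,
        "gtf": annotation_io.write_gtf,
        "bed12": annotation_io.write_bed12,
    }
    if format not in writers:
        raise ValueError(f"unknown format {format!r}; expected gff3, gtf or bed12")
    models, truth, _groups = synth_gene_models(config)
    return writers[format](models), truth


# --------------------------------------------------------------------------
# MEME / domain / tree / cis-element bundle
# --------------------------------------------------------------------------

_CIS_NAMES = ("TATA-box", "CAAT-box", "ABRE", "G-box", "MYB")

#: motifs present only in the first group (inside the PMEI domain),
#: mirroring a family whose first clade carries an extra inhibitory domain
GROUP1_ONLY_MOTIFS = (8, 10)
PMEI_DOMAIN = "PMEI"
CORE_DOMAIN = "pectinesterase"


@dataclass
class FixtureBundle:
    """A consistent synthetic dataset: every file names the same sequences."""

    ids: list[str]
    group_of: dict[str, str]
    models: list[GeneModel]
    ground_truth: list[StructureStats]
    protein_lengths: dict[str, int]
    newick: str
    meme_xml: str
    meme_text: str
    domains_tsv: str
    cis_tsv: str
    groups_tsv: str
    #: ground-truth motif sites: (sequence, motif index, start, end, p_value)
    motif_sites: list[tuple[str, int, int, int, float]] = field(default_factory=list)
    #: ground-truth domains: (sequence, name, start, end)
    domain_hits: list[tuple[str, str, int, int]] = field(default_factory=list)


def _random_subtree(rng: np.random.Generator, leaves: Sequence[str]) -> str:
    nodes = list(leaves)
    while len(nodes) > 1:
        i = int(rng.integers(0, len(nodes)))
        a = nodes.pop(i)
        j = int(rng.integers(0, len(nodes)))
        b = nodes.pop(j)
        la, lb = rng.uniform(0.01, 0.5, size=2)
        nodes.append(f"({a}:{la:.4f},{b}:{lb:.4f})")
    return nodes[0]


def synth_meme_and_domains(config: FixtureConfig) -> FixtureBundle:
    """Generate the consistent tree + motif + domain (+ promoter) bundle.

    Protein lengths derive from the coding length of the synthetic gene
    models.  Group-1 proteins carry a PMEI domain followed by the core
    pectinesterase domain; group-2 proteins only the core domain.  Motifs 8
    and 10 are placed only on group-1 sequences, with motif 10 constrained
    inside the PMEI domain; all other motifs land inside the core domain.
    """
    models, truth, group_of = synth_gene_models(config)
    rng = np.random.default_rng(config.seed + 1)
    ids = [m.transcript_id for m in models]
    first_group = config.groups[0][0] if config.groups else None

    protein_lengths = {
        m.transcript_id: sum(s.length for s in m.cds_segments()) // 3 for m in models
    }

    # --- domains ---
    domain_hits: list[tuple[str, str, int, int]] = []
    pmei_span: dict[str, tuple[int, int]] = {}
    core_span: dict[str, tuple[int, int]] = {}
    for tid in ids:
        plen = protein_lengths[tid]
        in_first = group_of.get(tid) == first_group
        pmei_end = min(95, plen // 3)
        core_start = pmei_end + 15
        core_end = min(plen - 2, core_start + 300)
        if in_first:
            pmei_span[tid] = (10, pmei_end)
            domain_hits.append((tid, PMEI_DOMAIN, 10, pmei_end))
        core_span[tid] = (core_start, core_end)
        domain_hits.append((tid, CORE_DOMAIN, core_start, core_end))

    # --- motifs ---
    widths = [int(rng.integers(15, 41)) for _ in range(config.n_motifs)]
    e_lo, e_hi = config.p_value_exp_range
    motif_sites: list[tuple[str, int, int, int, float]] = []
    for tid in ids:
        in_first = group_of.get(tid) == first_group
        for k in range(1, config.n_motifs + 1):
            if k in GROUP1_ONLY_MOTIFS and not in_first:
                continue
            if k not in GROUP1_ONLY_MOTIFS and rng.random() < 0.15:
                continue  # sporadic motif loss
            w = widths[k - 1]
            if k in GROUP1_ONLY_MOTIFS and tid in pmei_span:
                lo, hi = pmei_span[tid]
            else:
                lo, hi = core_span[tid]
            if hi - lo + 1 <= w:
                continue
            start = int(rng.integers(lo, hi - w + 1))
            p = float(10.0 ** -rng.uniform(e_lo, e_hi))
            motif_sites.append((tid, k, start, start + w - 1, p))

    meme_xml = _write_meme_xml(ids, protein_lengths, widths, motif_sites)
    meme_text = _write_meme_text(ids, protein_lengths, widths, motif_sites)

    domains_tsv = "\n".join(
        f"{tid}\t{name}\t{lo}\t{hi}\t1e-{int(rng.integers(20, 80))}"
        for tid, name, lo, hi in domain_hits
    ) + "\n"

    # --- cis elements ---
    cis_rows = []
    for tid in ids:
        for _ in range(int(rng.integers(2, 6))):
            name = _CIS_NAMES[int(rng.integers(0, len(_CIS_NAMES)))]
            size = int(rng.integers(6, 13))
            pos = int(rng.integers(1, config.promoter_length - size + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            cis_rows.append(f"{tid}\t{name}\t{pos}\t{size}\t{strand}")
    cis_tsv = "\n".join(cis_rows) + "\n"

    # --- tree: each configured group is a monophyletic clade ---
    clades = []
    cursor = 0
    if config.groups:
        for _gname, size in config.groups:
            clades.append(_random_subtree(rng, ids[cursor : cursor + size]))
            cursor += size
    else:
        clades.append(_random_subtree(rng, ids))
    while len(clades) > 1:
        b = clades.pop()
        a = clades.pop()
        clades.append(f"({a}:0.2500,{b}:0.2500)")
    newick = clades[0] + ";"

    groups_tsv = "\n".join(f"{tid}\t{group_of[tid]}" for tid in ids if tid in group_of)
    groups_tsv = groups_tsv + "\n" if groups_tsv else ""

    return FixtureBundle(
        ids=ids,
        group_of=group_of,
        models=models,
        ground_truth=truth,
        protein_lengths=protein_lengths,
        newick=newick,
        meme_xml=meme_xml,
        meme_text=meme_text,
        domains_tsv=domains_tsv,
        cis_tsv=cis_tsv,
        groups_tsv=groups_tsv,
        motif_sites=motif_sites,
        domain_hits=domain_hits,
    )


def _write_meme_xml(
    ids: Sequence[str],
    lengths: dict[str, int],
    widths: Sequence[int],
    sites: Sequence[tuple[str, int, int, int, float]],
) -> str:
    seq_key = {tid: f"sequence_{i}" for i, tid in enumerate(ids)}
    out = ['<?xml version="1.0" encoding="UTF-8"?>', '<MEME version="5.4.1">']
    out.append("<training_set>")
    for tid in ids:
        out.append(
            f'<sequence id="{seq_key[tid]}" name="{tid}" length="{lengths[tid]}" weight="1.0"/>'
        )
    out.append("</training_set>")
    out.append("<motifs>")
    for k, w in enumerate(widths, start=1):
        out.append(f'<motif id="motif_{k}" name="MOTIF{k}" alt="MEME-{k}" width="{w}">')
        out.append("<contributing_sites>")
        for tid, mk, start, _end, p in sites:
            if mk != k:
                continue
            out.append(
                f'<contributing_site sequence_id="{seq_key[tid]}" '
                f'position="{start - 1}" strand="plus" pvalue="{p:.2e}"/>'
            )
        out.append("</contributing_sites>")
        out.append("</motif>")
    out.append("</motifs>")
    # scanned sites mirror the training sites (a self-rescan)
    out.append('<scanned_sites_summary p_thresh="0.0001">')
    for tid in ids:
        mine = [s for s in sites if s[0] == tid]
        out.append(
            f'<scanned_sites sequence_id="{seq_key[tid]}" pvalue="1e-10" '
            f'num_sites="{len(mine)}">'
        )
        for _tid, mk, start, _end, p in mine:
            out.append(
                f'<scanned_site motif_id="motif_{mk}" strand="plus" '
                f'position="{start - 1}" pvalue="{p:.2e}"/>'
            )
        out.append("</scanned_sites>")
    out.append("</scanned_sites_summary>")
    out.append("</MEME>")
    return "\n".join(out) + "\n"


def _write_meme_text(
    ids: Sequence[str],
    lengths: dict[str, int],
    widths: Sequence[int],
    sites: Sequence[tuple[str, int, int, int, float]],
) -> str:
    bar = "*" * 80
    out = [bar, "MEME - Motif discovery tool", bar, "", "TRAINING SET", "-" * 70]
    out.append("Sequence name            Weight Length")
    out.append("-------------            ------ ------")
    for tid in ids:
        out.append(f"{tid:<24} 1.0000 {lengths[tid]:>6}")
    out.append("")
    for k, w in enumerate(widths, start=1):
        mine = [s for s in sites if s[1] == k]
        out.append(bar)
        out.append(
            f"MOTIF MOTIF{k} MEME-{k}\twidth = {w:3d}  sites = {len(mine):3d}  "
            f"llr = 0  E-value = 1.0e-10"
        )
        out.append(bar)
        out.append(f"\tMotif MOTIF{k} MEME-{k} sites sorted by position p-value")
        out.append("-" * 70)
        out.append("Sequence name            Strand  Start   P-value               Site")
        out.append("-------------            ------  -----  ---------            ------")
        for tid, _mk, start, _end, p in mine:
            out.append(f"{tid:<24} +      {start:>6}  {p:.2e}            X")
        out.append("-" * 70)
        out.append("")
    return "\n".join(out) + "\n"
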