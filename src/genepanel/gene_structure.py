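"""Exon/intron inference, per-gene structure statistics and coordinate projection.

The statistics mirror what a gene-family "Statistics" table reports for each
transcript: structural span in bp, number of introns, number of annotated CDS
and UTR segments, and an intron-content class.  Intron classes follow the
standard three-way rule for eukaryotic genes: intronless (0 introns),
intron-poor (1-3) and intron-rich (>3).

CDS/UTR segments are counted as annotated (raw), not merged: a transcript can
legitimately carry more UTR pieces than exon blocks minus CDS pieces when a
UTR is split across exons.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

from .model import GeneModel, ModelError, SegmentKind, merge_intervals

Interval = tuple[int, int]

METRICS = ("gene_length", "n_introns", "n_cds", "n_utrs")


class IntronClass(str, enum.Enum):
    INTRONLESS = "intronless"
    INTRON_POOR = "intron_poor"
    INTRON_RICH = "intron_rich"

    @property
    def display(self) -> str:
        return {
            IntronClass.INTRONLESS: "Intronless gene",
            IntronClass.INTRON_POOR: "Intron-poor gene",
            IntronClass.INTRON_RICH: "Intron-rich gene",
        }[self]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class StructureError(ValueError):
    """Model cannot be rendered/summarised as an exon-intron structure."""


def classify_intron_content(n_introns: int) -> IntronClass:
    """Classify a gene by intron count: 0 / 1-3 / more than 3."""
    if n_introns < 0:
        raise ValueError(f"intron count must be >= 0, got {n_introns}")
    if n_introns == 0:
        return IntronClass.INTRONLESS
    if n_introns <= 3:
        return IntronClass.INTRON_POOR
    return IntronClass.INTRON_RICH


@dataclass(frozen=True)
class StructureStats:
    """Per-transcript structural statistics (one Statistics-table row)."""

    transcript_id: str
    gene_length: int
    n_introns: int
    n_cds: int
    n_utrs: int
    intron_class: IntronClass
    group: Optional[str] = None

    def __post_init__(self) -> None:
        if self.gene_length < 1:
            raise ValueError("gene_length must be >= 1")
        if self.n_introns < 0:
            raise ValueError("n_introns must be >= 0")


def infer_exon_blocks(model: GeneModel) -> list[Interval]:
    """Merged exon blocks of a transcript, sorted by start.

    Explicit exon segments take precedence; otherwise the union of CDS and
    UTR segments is used.  Intervals that touch or overlap (gap <= 0, i.e.
    ``next.start <= prev.end + 1``) coalesce into a single block.
    """
    exons = model.segments_of(SegmentKind.EXON)
    if exons:
        return merge_intervals((s.start, s.end) for s in exons)
    coding = model.cds_segments() + model.utr_segments()
    if not coding:
        raise StructureError(
            f"{model.transcript_id}: no drawable structure "
            "(no exon, cds or utr segments)"
        )
    return merge_intervals((s.start, s.end) for s in coding)


def infer_introns(model: GeneModel) -> list[Interval]:
    """Intervals strictly between consecutive exon blocks."""
    blocks = infer_exon_blocks(model)
    return [
        (prev[1] + 1, nxt[0] - 1) for prev, nxt in zip(blocks, blocks[1:])
    ]


def compute_stats(model: GeneModel, group: Optional[str] = None) -> StructureStats:
    """Per-transcript statistics row.

    Gene length is the structural span (first to last structural base);
    CDS/UTR counts are raw annotated segments, intron count comes from the
    merged exon blocks.
    """
    introns = infer_introns(model)
    lo, hi = model.span
    return StructureStats(
        transcript_id=model.transcript_id,
        gene_length=hi - lo + 1,
        n_introns=len(introns),
        n_cds=len(model.cds_segments()),
        n_utrs=len(model.utr_segments()),
        intron_class=classify_intron_content(len(introns)),
        group=group,
    )


# --------------------------------------------------------------------------
# Summaries
# --------------------------------------------------------------------------


def _round2(value: Decimal) -> float:
    return float(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SummaryStats:
    """Mean/max/min per metric, plus per-group intron-class tallies.

    Means and percentages are rounded half-up to 2 decimals, matching how
    such tables are conventionally printed.
    """

    mean: Mapping[str, float]
    max: Mapping[str, int]
    min: Mapping[str, int]
    n: int
    group_tallies: Mapping[str, Mapping[IntronClass, tuple[int, float]]]


def summarize(stats: Sequence[StructureStats]) -> SummaryStats:
    """Summarise a collection of per-gene rows (errors on empty input)."""
    stats = list(stats)
    if not stats:
        raise ValueError("cannot summarise an empty collection")
    values = {m: [getattr(s, m) for s in stats] for m in METRICS}
    n = len(stats)
    mean = {m: _round2(Decimal(sum(v)) / Decimal(n)) for m, v in values.items()}
    vmax = {m: max(v) for m, v in values.items()}
    vmin = {m: min(v) for m, v in values.items()}

    tallies: dict[str, dict[IntronClass, tuple[int, float]]] = {}
    grouped = [s for s in stats if s.group is not None]
    groups: dict[str, list[StructureStats]] = {}
    for s in grouped:
        groups.setdefault(s.group, []).append(s)
    for gname, members in groups.items():
        counts: dict[IntronClass, int] = {}
        for s in members:
            counts[s.intron_class] = counts.get(s.intron_class, 0) + 1
        tallies[gname] = {
            cls: (cnt, _round2(Decimal(cnt * 100) / Decimal(len(members))))
            for cls, cnt in counts.items()
        }
    return SummaryStats(mean=mean, max=vmax, min=vmin, n=n, group_tallies=tallies)


def write_stats_table(
    stats: Sequence[StructureStats], summary: Optional[SummaryStats] = None
) -> str:
    """Statistics report TSV: one row per gene plus Mean/Max/Min summary rows
    and, when groups are present, per-group class tallies."""
    if summary is None:
        summary = summarize(stats)
    lines = [
        "Group\tGene\tLength of gene\tNumber of intron\tNumber of CDS\t"
        "Number of UTR\tType of gene"
    ]
    for s in stats:
        lines.append(
            "\t".join(
                [
                    s.group or "",
                    s.transcript_id,
                    str(s.gene_length),
                    str(s.n_introns),
                    str(s.n_cds),
                    str(s.n_utrs),
                    s.intron_class.display,
                ]
            )
        )
    for label, source in (("Mean", summary.mean), ("Max", summary.max), ("Min", summary.min)):
        vals = [source[m] for m in METRICS]
        cells = [f"{v:.2f}" if isinstance(v, float) else str(v) for v in vals]
        lines.append("\t".join(["", label] + cells + [""]))
    for gname in sorted(summary.group_tallies):
        for cls in IntronClass:
            if cls not in summary.group_tallies[gname]:
                continue
            cnt, pct = summary.group_tallies[gname][cls]
            lines.append(f"# {gname}\t{cls.display}\t{cnt}\t({pct:.2f}%)")
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# Protein -> genome projection
# --------------------------------------------------------------------------


class ProjectionRangeError(ValueError):
    """Requested amino-acid interval exceeds the coding capacity."""


def map_protein_interval_to_genome(
    model: GeneModel, aa_start: int, aa_end: int
) -> list[Interval]:
    """Project a 1-based protein interval onto genomic CDS sub-intervals.

    The amino-acid interval maps to coding nucleotides
    ``[3*aa_start - 2, 3*aa_end]``; CDS segments are walked in translation
    order (ascending genomic on +, descending on -), and the genomic pieces
    covered are returned split at CDS junctions, each as an ascending
    ``(start, end)`` pair, sorted by genomic start.  The first coding base is
    taken to be amino acid 1 (annotated CDS phase is not applied).
    """
    if aa_start < 1 or aa_end < aa_start:
        raise ValueError(f"invalid amino-acid interval [{aa_start},{aa_end}]")
    cds = model.cds_segments()
    if not cds:
        raise ModelError(f"{model.transcript_id}: no cds segments")
    total = sum(s.length for s in cds)
    capacity = total // 3
    if 3 * aa_end > total:
        raise ProjectionRangeError(
            f"{model.transcript_id}: amino acid {aa_end} exceeds coding "
            f"capacity of {capacity} aa ({total} nt)"
        )
    nt_lo, nt_hi = 3 * aa_start - 2, 3 * aa_end
    walk = cds if model.strand == "+" else list(reversed(cds))
    out: list[Interval] = []
    offset = 0  # coding nucleotides consumed before the current segment
    for seg in walk:
        seg_lo_nt = offset + 1
        seg_hi_nt = offset + seg.length
        lo = max(nt_lo, seg_lo_nt)
        hi = min(nt_hi, seg_hi_nt)
        if lo <= hi:
            if model.strand == "+":
                g1 = seg.start + (lo - seg_lo_nt)
                g2 = seg.start + (hi - seg_lo_nt)
            else:
                g1 = seg.end - (hi - seg_lo_nt)
                g2 = seg.end - (lo - seg_lo_nt)
            out.append((min(g1, g2), max(g1, g2)))
        offset = seg_hi_nt
        if offset >= nt_hi:
            break
    return sorted(out)
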