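"""Readers and writers for GFF3 / GTF / BED12 gene annotation.

All three readers normalise to the same canonical :class:`~genepanel.model.GeneModel`
records (1-based inclusive coordinates, one model per transcript), so the
downstream statistics and drawing code never sees the input dialect.

Readers return a :class:`ParseResult`; recoverable anomalies (orphan children,
unresolvable identifiers) are collected as warnings rather than silently
dropped, while structural violations of the format raise
:class:`AnnotationParseError` with the offending line number.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, TextIO, Union

from .model import FeatureSegment, GeneModel, SegmentKind, UTR_KINDS

Stream = Union[str, TextIO, Iterable[str]]


class AnnotationParseError(ValueError):
    """Malformed annotation input; carries the 1-based line number."""

    def __init__(self, message: str, line_no: int | None = None):
        self.line_no = line_no
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)


@dataclass
class ParseResult:
    """Parsed models plus non-fatal anomalies encountered on the way."""

    models: list[GeneModel] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def __iter__(self):
        return iter(self.models)

    def __len__(self) -> int:
        return len(self.models)


def _lines(stream: Stream) -> Iterable[str]:
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    for line in stream:
        yield line.rstrip("\r\n")


# --------------------------------------------------------------------------
# GFF3
# --------------------------------------------------------------------------

_GFF3_KIND = {
    "exon": SegmentKind.EXON,
    "cds": SegmentKind.CDS,
    "five_prime_utr": SegmentKind.FIVE_UTR,
    "three_prime_utr": SegmentKind.THREE_UTR,
}

_TRANSCRIPT_TYPES = {"mrna", "transcript"}


def _gff3_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in text.split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            key, _, value = part.partition("=")
            attrs[key.strip()] = value.strip()
    return attrs


def read_gff3(stream: Stream) -> ParseResult:
    """Parse GFF3 into one :class:`GeneModel` per mRNA/transcript feature.

    Child ``exon``/``CDS``/``*_UTR`` rows attach to their transcript via the
    ``Parent`` attribute; unknown feature types become ``other`` segments with
    the type preserved as label.  Children whose Parent is never defined are
    reported as warnings, never dropped silently.
    """
    transcripts: dict[str, dict] = {}
    gene_of: dict[str, str] = {}  # feature ID -> its own gene id (for Parent=gene)
    orphans: list[tuple[int, str, str]] = []  # (line, parent, type)
    warnings: list[str] = []
    order: list[str] = []

    for line_no, line in enumerate(_lines(stream), start=1):
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise AnnotationParseError(
                f"expected 9 tab-separated columns, found {len(cols)}", line_no
            )
        _, _, ftype, start_s, end_s, _, strand, phase_s, attr_s = cols
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise AnnotationParseError(
                f"non-integer coordinates {start_s!r}/{end_s!r}", line_no
            ) from None
        attrs = _gff3_attributes(attr_s)
        ltype = ftype.lower()

        if ltype == "gene":
            fid = attrs.get("ID")
            if fid:
                gene_of[fid] = fid
            continue
        if ltype in _TRANSCRIPT_TYPES:
            tid = attrs.get("ID")
            if not tid:
                raise AnnotationParseError("transcript feature without ID", line_no)
            transcripts[tid] = {
                "gene_id": attrs.get("Parent", tid),
                "chrom": cols[0],
                "strand": strand if strand in "+-" else "+",
                "segments": [],
            }
            order.append(tid)
            continue

        parents = attrs.get("Parent")
        if not parents:
            warnings.append(
                f"line {line_no}: {ftype} feature without Parent attribute skipped"
            )
            continue
        kind = _GFF3_KIND.get(ltype, SegmentKind.OTHER)
        phase = None
        if kind is SegmentKind.CDS and phase_s in ("0", "1", "2"):
            phase = int(phase_s)
        seg = FeatureSegment(
            kind=kind,
            start=start,
            end=end,
            phase=phase,
            label=ftype if kind is SegmentKind.OTHER else None,
        )
        for parent in parents.split(","):
            if parent in transcripts:
                transcripts[parent]["segments"].append((seg, cols[0], strand))
            else:
                orphans.append((line_no, parent, ftype, seg, cols[0], strand))

    # forward references (children printed before their mRNA) are tolerated:
    # re-dispatch once all transcripts are known, then report true orphans
    for line_no, parent, ftype, seg, chrom, strand in orphans:
        if parent in transcripts:
            transcripts[parent]["segments"].append((seg, chrom, strand))
        else:
            warnings.append(
                f"line {line_no}: {ftype} child references undefined Parent "
                f"{parent!r}; feature dropped"
            )
    models = []
    for tid in order:
        rec = transcripts[tid]
        segs = [s for s, chrom, strand in rec["segments"]]
        for s, chrom, strand in rec["segments"]:
            if chrom != rec["chrom"]:
                warnings.append(
                    f"{tid}: child on {chrom} differs from transcript "
                    f"chrom {rec['chrom']}"
                )
        models.append(
            GeneModel(
                gene_id=rec["gene_id"],
                transcript_id=tid,
                chrom=rec["chrom"],
                strand=rec["strand"],
                segments=segs,
                source_format="gff3",
            )
        )
    return ParseResult(models=models, warnings=warnings)


# --------------------------------------------------------------------------
# GTF
# --------------------------------------------------------------------------

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"\s*;')

_GTF_KIND = {
    "exon": SegmentKind.EXON,
    "cds": SegmentKind.CDS,
    "five_prime_utr": SegmentKind.FIVE_UTR,
    "three_prime_utr": SegmentKind.THREE_UTR,
    "5utr": SegmentKind.FIVE_UTR,
    "3utr": SegmentKind.THREE_UTR,
}


def read_gtf(stream: Stream) -> ParseResult:
    """Parse GTF (attribute dialect ``key "value";``) into gene models.

    Generic ``UTR`` rows carry no 5'/3' designation; they are classified
    positionally relative to the transcript's CDS extent and strand (a UTR
    left of all CDS on the + strand is 5'), with ties broken by the nearest
    CDS edge.
    """
    transcripts: dict[str, dict] = {}
    order: list[str] = []
    warnings: list[str] = []

    for line_no, line in enumerate(_lines(stream), start=1):
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise AnnotationParseError(
                f"expected 9 tab-separated columns, found {len(cols)}", line_no
            )
        chrom, _, ftype, start_s, end_s, _, strand, phase_s, attr_s = cols
        ltype = ftype.lower()
        if ltype == "gene":
            continue
        attrs = dict(_GTF_ATTR.findall(attr_s))
        if "transcript_id" not in attrs:
            raise AnnotationParseError(
                'missing transcript_id attribute (expected key "value"; pairs)',
                line_no,
            )
        tid = attrs["transcript_id"]
        if tid not in transcripts:
            transcripts[tid] = {
                "gene_id": attrs.get("gene_id", tid),
                "chrom": chrom,
                "strand": strand if strand in "+-" else "+",
                "segments": [],
                "generic_utrs": [],
            }
            order.append(tid)
        if ltype == "transcript":
            continue
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise AnnotationParseError(
                f"non-integer coordinates {start_s!r}/{end_s!r}", line_no
            ) from None
        if ltype == "utr":
            transcripts[tid]["generic_utrs"].append((start, end))
            continue
        kind = _GTF_KIND.get(ltype, SegmentKind.OTHER)
        phase = None
        if kind is SegmentKind.CDS and phase_s in ("0", "1", "2"):
            phase = int(phase_s)
        transcripts[tid]["segments"].append(
            FeatureSegment(
                kind=kind,
                start=start,
                end=end,
                phase=phase,
                label=ftype if kind is SegmentKind.OTHER else None,
            )
        )

    models = []
    for tid in order:
        rec = transcripts[tid]
        segs = list(rec["segments"])
        cds = [s for s in segs if s.kind is SegmentKind.CDS]
        for start, end in rec["generic_utrs"]:
            segs.append(
                FeatureSegment(
                    kind=_classify_generic_utr(start, end, cds, rec["strand"], warnings, tid),
                    start=start,
                    end=end,
                )
            )
        models.append(
            GeneModel(
                gene_id=rec["gene_id"],
                transcript_id=tid,
                chrom=rec["chrom"],
                strand=rec["strand"],
                segments=segs,
                source_format="gtf",
            )
        )
    return ParseResult(models=models, warnings=warnings)


def _classify_generic_utr(
    start: int,
    end: int,
    cds: list[FeatureSegment],
    strand: str,
    warnings: list[str],
    tid: str,
) -> SegmentKind:
    if not cds:
        warnings.append(
            f"{tid}: generic UTR [{start},{end}] with no CDS; assuming 5' UTR"
        )
        return SegmentKind.FIVE_UTR
    cds_lo = min(s.start for s in cds)
    cds_hi = max(s.end for s in cds)
    if end < cds_lo:
        upstream = True
    elif start > cds_hi:
        upstream = False
    else:
        # overlaps the CDS extent: tie broken by the nearest CDS edge
        upstream = abs(start - cds_lo) <= abs(cds_hi - end)
    if strand == "+":
        return SegmentKind.FIVE_UTR if upstream else SegmentKind.THREE_UTR
    return SegmentKind.THREE_UTR if upstream else SegmentKind.FIVE_UTR


# --------------------------------------------------------------------------
# BED12
# --------------------------------------------------------------------------


def read_bed12(stream: Stream) -> ParseResult:
    """Parse BED12 lines into gene models.

    BED coordinates are 0-based half-open and converted to the canonical
    1-based inclusive convention.  Blocks become exon segments; the
    thickStart/thickEnd coding region splits each block into UTR and CDS
    pieces (left UTRs are 5' on the + strand, 3' on the - strand).  A
    degenerate thick region (thickStart == thickEnd) marks a non-coding
    transcript: blocks are emitted as exons only.
    """
    models = []
    warnings: list[str] = []
    for line_no, line in enumerate(_lines(stream), start=1):
        if not line or line.startswith(("#", "track", "browser")):
            continue
        cols = line.split("\t")
        if len(cols) != 12:
            raise AnnotationParseError(
                f"expected 12 tab-separated columns, found {len(cols)}", line_no
            )
        chrom, cstart_s, cend_s, name, _score, strand = cols[:6]
        tstart_s, tend_s, _rgb, bcount_s, bsizes_s, bstarts_s = cols[6:]
        try:
            cstart, thick_start, thick_end = int(cstart_s), int(tstart_s), int(tend_s)
            bcount = int(bcount_s)
            bsizes = [int(x) for x in bsizes_s.rstrip(",").split(",")]
            bstarts = [int(x) for x in bstarts_s.rstrip(",").split(",")]
        except ValueError:
            raise AnnotationParseError("non-integer BED12 field", line_no) from None
        if len(bsizes) != bcount or len(bstarts) != bcount:
            raise AnnotationParseError(
                f"blockCount {bcount} inconsistent with "
                f"{len(bsizes)} blockSizes / {len(bstarts)} blockStarts",
                line_no,
            )
        if strand not in "+-":
            strand = "+"
        segments: list[FeatureSegment] = []
        coding = thick_end > thick_start
        # thick region in 1-based inclusive coordinates
        t_lo, t_hi = thick_start + 1, thick_end
        for size, boff in zip(bsizes, bstarts):
            b_lo = cstart + boff + 1  # 1-based inclusive block interval
            b_hi = cstart + boff + size
            segments.append(FeatureSegment(SegmentKind.EXON, b_lo, b_hi))
            if not coding:
                continue
            left_utr = (b_lo, min(b_hi, t_lo - 1))
            cds_part = (max(b_lo, t_lo), min(b_hi, t_hi))
            right_utr = (max(b_lo, t_hi + 1), b_hi)
            five, three = (
                (SegmentKind.FIVE_UTR, SegmentKind.THREE_UTR)
                if strand == "+"
                else (SegmentKind.THREE_UTR, SegmentKind.FIVE_UTR)
            )
            if left_utr[0] <= left_utr[1]:
                segments.append(FeatureSegment(five, *left_utr))
            if cds_part[0] <= cds_part[1]:
                segments.append(FeatureSegment(SegmentKind.CDS, *cds_part))
            if right_utr[0] <= right_utr[1]:
                segments.append(FeatureSegment(three, *right_utr))
        models.append(
            GeneModel(
                gene_id=name,
                transcript_id=name,
                chrom=chrom,
                strand=strand,
                segments=segments,
                source_format="bed12",
            )
        )
    return ParseResult(models=models, warnings=warnings)


# --------------------------------------------------------------------------
# Subsetting
# --------------------------------------------------------------------------


def subset_by_ids(models: Iterable[GeneModel], ids: set[str]) -> ParseResult:
    """Select models whose gene or transcript id is in ``ids``.

    Input order is preserved; requested ids matching no model are reported as
    warnings, never errors.
    """
    ids = set(ids)
    kept = [m for m in models if m.gene_id in ids or m.transcript_id in ids]
    seen: set[str] = set()
    for m in kept:
        seen.update({m.gene_id, m.transcript_id} & ids)
    missing = sorted(ids - seen)
    warnings = [f"id {i!r} matched no model" for i in missing]
    return ParseResult(models=kept, warnings=warnings)


# --------------------------------------------------------------------------
# Writers
# --------------------------------------------------------------------------


def write_gene_table(models: Iterable[GeneModel]) -> str:
    """Emit the canonical per-segment TSV."""
    out = ["transcript_id\tchrom\tstrand\tkind\tstart\tend\tphase\tlabel"]
    for m in models:
        for s in m.segments:
            out.append(
                "\t".join(
                    [
                        m.transcript_id,
                        m.chrom,
                        m.strand,
                        s.kind.value,
                        str(s.start),
                        str(s.end),
                        "" if s.phase is None else str(s.phase),
                        s.label or "",
                    ]
                )
            )
    return "\n".join(out) + "\n"


def write_gff3(models: Iterable[GeneModel]) -> str:
    """Serialise models as GFF3 (gene + mRNA + child feature rows)."""
    lines = ["##gff-version 3"]
    for m in models:
        lo, hi = m.span
        lines.append(
            f"{m.chrom}\tgenepanel\tgene\t{lo}\t{hi}\t.\t{m.strand}\t.\tID={m.gene_id}"
        )
        lines.append(
            f"{m.chrom}\tgenepanel\tmRNA\t{lo}\t{hi}\t.\t{m.strand}\t.\t"
            f"ID={m.transcript_id};Parent={m.gene_id}"
        )
        for s in m.segments:
            ftype = {
                SegmentKind.EXON: "exon",
                SegmentKind.CDS: "CDS",
                SegmentKind.FIVE_UTR: "five_prime_UTR",
                SegmentKind.THREE_UTR: "three_prime_UTR",
            }.get(s.kind, s.label or "region")
            phase = "." if s.phase is None else str(s.phase)
            lines.append(
                f"{m.chrom}\tgenepanel\t{ftype}\t{s.start}\t{s.end}\t.\t"
                f"{m.strand}\t{phase}\tParent={m.transcript_id}"
            )
    return "\n".join(lines) + "\n"


def write_gtf(models: Iterable[GeneModel]) -> str:
    """Serialise models as GTF with typed UTR rows."""
    lines = []
    for m in models:
        lo, hi = m.span
        attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
        lines.append(
            f"{m.chrom}\tgenepanel\ttranscript\t{lo}\t{hi}\t.\t{m.strand}\t.\t{attrs}"
        )
        for s in m.segments:
            ftype = {
                SegmentKind.EXON: "exon",
                SegmentKind.CDS: "CDS",
                SegmentKind.FIVE_UTR: "five_prime_utr",
                SegmentKind.THREE_UTR: "three_prime_utr",
            }.get(s.kind, s.label or "region")
            phase = "." if s.phase is None else str(s.phase)
            lines.append(
                f"{m.chrom}\tgenepanel\t{ftype}\t{s.start}\t{s.end}\t.\t"
                f"{m.strand}\t{phase}\t{attrs}"
            )
    return "\n".join(lines) + "\n"


def write_bed12(models: Iterable[GeneModel]) -> str:
    """Serialise models as BED12 (blocks from merged exon structure)."""
    from .gene_structure import infer_exon_blocks  # local import, avoids cycle

    lines = []
    for m in models:
        blocks = infer_exon_blocks(m)
        chrom_start = blocks[0][0] - 1
        chrom_end = blocks[-1][1]
        cds = m.cds_segments()
        if cds:
            thick_start = min(s.start for s in cds) - 1
            thick_end = max(s.end for s in cds)
        else:
            thick_start = thick_end = chrom_start
        sizes = ",".join(str(hi - lo + 1) for lo, hi in blocks)
        starts = ",".join(str(lo - 1 - chrom_start) for lo, hi in blocks)
        lines.append(
            "\t".join(
                [
                    m.chrom,
                    str(chrom_start),
                    str(chrom_end),
                    m.transcript_id,
                    "0",
                    m.strand,
                    str(thick_start),
                    str(thick_end),
                    "0",
                    str(len(blocks)),
                    sizes,
                    starts,
                ]
            )
        )
    return "\n".join(lines) + "\n"
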