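"""Canonical in-memory gene models.

All genomic coordinates in this package are 1-based inclusive base pairs
(the GFF3 convention); BED input is converted on read.  One :class:`GeneModel`
represents one *transcript*: the unit drawn as a row in a structure panel and
the unit the per-gene statistics are computed over.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional


class SegmentKind(str, enum.Enum):
    """Feature classes a transcript row is built from."""

    EXON = "exon"
    CDS = "cds"
    FIVE_UTR = "five_prime_utr"
    THREE_UTR = "three_prime_utr"
    OTHER = "other"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: kinds that define the drawable/statistical extent of a transcript
STRUCTURAL_KINDS = frozenset(
    {SegmentKind.EXON, SegmentKind.CDS, SegmentKind.FIVE_UTR, SegmentKind.THREE_UTR}
)

UTR_KINDS = frozenset({SegmentKind.FIVE_UTR, SegmentKind.THREE_UTR})


class ModelError(ValueError):
    """A gene model violating its structural invariants."""


@dataclass(frozen=True)
class FeatureSegment:
    """One typed, stranded genomic interval of a transcript.

    ``phase`` is the CDS reading-frame offset (0-2) and is only meaningful for
    ``cds`` segments.  ``label`` carries free text for ``other`` annotations
    such as signal peptides.
    """

    kind: SegmentKind
    start: int
    end: int
    phase: Optional[int] = None
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ModelError(f"segment start {self.start} > end {self.end}")
        if self.start < 1:
            raise ModelError(f"segment start {self.start} < 1")
        if self.phase is not None:
            if self.kind is not SegmentKind.CDS:
                raise ModelError("phase is only defined for cds segments")
            if self.phase not in (0, 1, 2):
                raise ModelError(f"phase must be 0-2, got {self.phase}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GeneModel:
    """One transcript with its ordered feature segments.

    Invariants enforced on construction: segments sorted by start, CDS
    segments pairwise non-overlapping, non-empty identifiers.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    segments: list[FeatureSegment] = field(default_factory=list)
    source_format: str = "gff3"

    def __post_init__(self) -> None:
        if not self.gene_id or not self.transcript_id:
            raise ModelError("gene_id and transcript_id must be non-empty")
        if self.strand not in ("+", "-"):
            raise ModelError(f"strand must be '+' or '-', got {self.strand!r}")
        self.segments = sorted(
            self.segments, key=lambda s: (s.start, s.end, s.kind.value)
        )
        cds = self.cds_segments()
        for a, b in zip(cds, cds[1:]):
            if b.start <= a.end:
                raise ModelError(
                    f"{self.transcript_id}: overlapping cds segments "
                    f"[{a.start},{a.end}] and [{b.start},{b.end}]"
                )

    # -- convenience accessors -------------------------------------------------

    def segments_of(self, *kinds: SegmentKind) -> list[FeatureSegment]:
        wanted = set(kinds)
        return [s for s in self.segments if s.kind in wanted]

    def cds_segments(self) -> list[FeatureSegment]:
        return self.segments_of(SegmentKind.CDS)

    def utr_segments(self) -> list[FeatureSegment]:
        return [s for s in self.segments if s.kind in UTR_KINDS]

    def structural_segments(self) -> list[FeatureSegment]:
        return [s for s in self.segments if s.kind in STRUCTURAL_KINDS]

    @property
    def span(self) -> tuple[int, int]:
        """(min start, max end) over structural segments."""
        struct = self.structural_segments()
        if not struct:
            raise ModelError(f"{self.transcript_id}: no structural segments")
        return min(s.start for s in struct), max(s.end for s in struct)


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Coalesce 1-based inclusive intervals that touch or overlap.

    Two intervals merge when the gap between them is <= 0, i.e.
    ``next.start <= prev.end + 1`` (touching counts as one block).
    """
    ivs = sorted(intervals)
    if not ivs:
        return []
    merged = [ivs[0]]
    for start, end in ivs[1:]:
        pstart, pend = merged[-1]
        if start <= pend + 1:
            merged[-1] = (pstart, max(pend, end))
        else:
            merged.append((start, end))
    return merged
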