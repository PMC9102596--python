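"""Protein and promoter feature tracks.

Consumes the output files of the standard gene-family toolchain — MEME motif
discovery results (XML or plain text), domain-hit tables from NCBI-CDD,
pfam_scan or SMART, and PlantCARE-style cis-element position tables — and
normalises everything into positioned :class:`TrackItem` boxes on per-sequence
:class:`SequenceTrack` containers.

Motif boxes are drawn with a height negatively correlated with the site
p-value: a clamped linear map in -log10(p) (see :func:`motif_height`), so a
marginal site is visibly shallower than a highly significant one.  MEME
"Scanned Sites" rescans are kept as separate semi-transparent items.
"""

from __future__ import annotations

import enum
import io
import math
import re
import warnings as _warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, TextIO, Union

import pandas as pd

Stream = Union[str, TextIO]

#: default opacity for MEME scanned-site boxes ("transparent rectangles")
SCANNED_SITE_OPACITY = 0.4


class TrackKind(str, enum.Enum):
    MOTIF = "motif"
    SCANNED_SITE = "scanned_site"
    DOMAIN = "domain"
    CIS_ELEMENT = "cis_element"
    SIGNAL_PEPTIDE = "signal_peptide"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class TrackParseError(ValueError):
    """Malformed track input file."""


class TrackWarning(UserWarning):
    pass


@dataclass(frozen=True)
class TrackItem:
    """One positioned box on a protein or promoter track.

    Coordinates are 1-based inclusive: amino acids for protein tracks,
    upstream base pairs (1 = upstream-most base, 5'->3' left to right) for
    promoter tracks.
    """

    sequence_id: str
    kind: TrackKind
    name: str
    start: int
    end: int
    p_value: Optional[float] = None
    strand: Optional[str] = None
    opacity: float = 1.0

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValueError(f"invalid item interval [{self.start},{self.end}]")
        if self.p_value is not None and not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p-value must be in (0,1], got {self.p_value}")
        if not (0.0 < self.opacity <= 1.0):
            raise ValueError(f"opacity must be in (0,1], got {self.opacity}")


@dataclass
class SequenceTrack:
    """All items on one sequence (protein or promoter).

    Items may overlap freely: domains are deliberately superimposed on
    motifs when drawn.
    """

    sequence_id: str
    length: int
    items: list[TrackItem] = field(default_factory=list)

    def __post_init__(self) -> None:
        for item in self.items:
            if item.end > self.length:
                raise ValueError(
                    f"{self.sequence_id}: item {item.name} ends at {item.end} "
                    f"beyond sequence length {self.length}"
                )


@dataclass
class TrackParseResult:
    tracks: list[SequenceTrack] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def __iter__(self):
        return iter(self.tracks)

    def __len__(self) -> int:
        return len(self.tracks)


def _text_of(stream: Stream) -> str:
    if isinstance(stream, str):
        return stream
    return stream.read()


# --------------------------------------------------------------------------
# MEME results
# --------------------------------------------------------------------------


def read_meme(stream: Stream, dialect: str = "xml") -> TrackParseResult:
    """Parse a MEME result file into one track per input sequence.

    Training (discovery) sites become ``motif`` items carrying their site
    p-value; the "Scanned Sites" rescan, when present (XML dialect), becomes
    separate ``scanned_site`` items with default opacity 0.4.  Motif identity
    is canonicalised to ``"motif k"`` in discovery order.
    """
    if dialect == "xml":
        return _read_meme_xml(_text_of(stream))
    if dialect == "text":
        return _read_meme_text(_text_of(stream))
    raise ValueError(f"unknown MEME dialect {dialect!r}; expected 'xml' or 'text'")


def _read_meme_xml(text: str) -> TrackParseResult:
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        raise TrackParseError(f"not well-formed MEME XML: {exc}") from exc
    warn: list[str] = []

    seq_name: dict[str, str] = {}
    seq_len: dict[str, int] = {}
    order: list[str] = []
    for seq in root.iter("sequence"):
        sid = seq.get("id")
        seq_name[sid] = seq.get("name", sid)
        seq_len[sid] = int(seq.get("length", "0"))
        order.append(sid)
    if not order:
        raise TrackParseError("no sequences found in MEME XML training set")

    motif_name: dict[str, str] = {}
    motif_width: dict[str, int] = {}
    items: dict[str, list[TrackItem]] = {sid: [] for sid in order}
    k = 0
    for motif in root.iter("motif"):
        k += 1
        mid = motif.get("id", f"motif_{k}")
        motif_name[mid] = f"motif {k}"
        motif_width[mid] = int(motif.get("width", "0"))
        for site in motif.iter("contributing_site"):
            sid = site.get("sequence_id")
            pos = int(site.get("position", "0"))  # 0-based
            pval = float(site.get("pvalue", "1"))
            if sid not in items:
                warn.append(f"contributing site references unknown sequence {sid!r}")
                continue
            items[sid].append(
                TrackItem(
                    sequence_id=seq_name[sid],
                    kind=TrackKind.MOTIF,
                    name=motif_name[mid],
                    start=pos + 1,
                    end=pos + motif_width[mid],
                    p_value=pval,
                )
            )
    if k == 0:
        raise TrackParseError("no motifs found")

    scanned = list(root.iter("scanned_site"))
    if scanned:
        for ss_parent in root.iter("scanned_sites"):
            sid = ss_parent.get("sequence_id")
            for site in ss_parent.iter("scanned_site"):
                mid = site.get("motif_id")
                pos = int(site.get("position", "0"))
                pval = site.get("pvalue")
                if sid not in items or mid not in motif_width:
                    warn.append(
                        f"scanned site references unknown sequence/motif "
                        f"({sid!r}, {mid!r})"
                    )
                    continue
                items[sid].append(
                    TrackItem(
                        sequence_id=seq_name[sid],
                        kind=TrackKind.SCANNED_SITE,
                        name=motif_name[mid],
                        start=pos + 1,
                        end=pos + motif_width[mid],
                        p_value=float(pval) if pval else None,
                        opacity=SCANNED_SITE_OPACITY,
                    )
                )
    else:
        warn.append("no scanned-sites section; tracks emitted without scanned_site items")

    tracks = [
        SequenceTrack(
            sequence_id=seq_name[sid],
            length=seq_len[sid],
            items=sorted(items[sid], key=lambda i: (i.kind.value, i.start, i.name)),
        )
        for sid in order
    ]
    return TrackParseResult(tracks=tracks, warnings=warn)


_MOTIF_RE = re.compile(r"^MOTIF\s+(\S+)\s+MEME-(\d+)\s+.*width\s*=\s*(\d+)")
_TRAINING_HEADER = re.compile(r"^Sequence name\s+Weight\s+Length")


def _read_meme_text(text: str) -> TrackParseResult:
    """Plain-text MEME report: TRAINING SET lengths plus per-motif
     'sites sorted by position p-value' tables.  Scanned Sites are not part
    of the text report, so only motif items are produced (with a warning)."""
    lines = text.splitlines()
    seq_len: dict[str, int] = {}
    order: list[str] = []
    items: dict[str, list[TrackItem]] = {}
    warn: list[str] = []

    i = 0
    n = len(lines)
    # training set lengths (possibly two name/weight/length column pairs per row)
    while i < n:
        if _TRAINING_HEADER.match(lines[i].strip()):
            i += 2  # skip the dashes line
            while i < n and lines[i].strip() and not lines[i].startswith("***"):
                parts = lines[i].split()
                for j in range(0, len(parts) - 2, 3):
                    name, _w, length = parts[j], parts[j + 1], parts[j + 2]
                    try:
                        seq_len[name] = int(length)
                    except ValueError:
                        break
                    if name not in order:
                        order.append(name)
                        items[name] = []
                i += 1
            break
        i += 1

    n_motifs = 0
    i = 0
    while i < n:
        m = _MOTIF_RE.match(lines[i])
        if m:
            n_motifs += 1
            k = int(m.group(2))
            width = int(m.group(3))
            name = f"motif {k}"
            # advance to the sites table for this motif
            j = i + 1
            while j < n and "sites sorted by position p-value" not in lines[j]:
                nm = _MOTIF_RE.match(lines[j])
                if nm:
                    break
                j += 1
            if j < n and "sites sorted by position p-value" in lines[j]:
                j += 1
                while j < n and not lines[j].lstrip().startswith("Sequence name"):
                    j += 1
                j += 2  # header + dashes
                while j < n:
                    row = lines[j].strip()
                    if not row or row.startswith("---") or row.startswith("***"):
                        break
                    parts = row.split()
                    if len(parts) < 4:
                        break
                    sname, strand, start_s, pval_s = parts[:4]
                    try:
                        start = int(start_s)
                        pval = float(pval_s)
                    except ValueError:
                        raise TrackParseError(
                            f"unparsable site row for {name}: {row!r}"
                        ) from None
                    if sname not in items:
                        order.append(sname)
                        items[sname] = []
                        seq_len.setdefault(sname, start + width - 1)
                    items[sname].append(
                        TrackItem(
                            sequence_id=sname,
                            kind=TrackKind.MOTIF,
                            name=name,
                            start=start,
                            end=start + width - 1,
                            p_value=pval,
                            strand=strand if strand in "+-" else None,
                        )
                    )
                    j += 1
            i = j
        else:
            i += 1
    if n_motifs == 0:
        raise TrackParseError("no motifs found")
    warn.append("no scanned-sites section; tracks emitted without scanned_site items")
    tracks = [
        SequenceTrack(
            sequence_id=name,
            length=seq_len.get(name, max((it.end for it in items[name]), default=1)),
            items=sorted(items[name], key=lambda i: (i.kind.value, i.start, i.name)),
        )
        for name in order
    ]
    return TrackParseResult(tracks=tracks, warnings=warn)


# --------------------------------------------------------------------------
# Domain tables
# --------------------------------------------------------------------------

#: dialect -> (separator, column indices for sequence/name/from/to, header rows)
_DOMAIN_DIALECTS = {
    # generic TSV: sequence_id, name, start, end, evalue
    "generic": dict(sep="\t", seq=0, name=1, lo=2, hi=3),
    # NCBI-CDD hitdata.txt: Query, Hit type, PSSM-ID, From, To, E-Value,
    # Bitscore, Accession, Short name, ...
    "cdd": dict(sep="\t", seq=0, name=8, lo=3, hi=4),
    # pfam_scan.pl: seq id, aln start, aln end, env start, env end, hmm acc,
    # hmm name, type, ... (whitespace separated)
    "pfam_scan": dict(sep=None, seq=0, name=6, lo=1, hi=2),
    # SMART batch TSV: sequence_id, domain, start, end, evalue
    "smart": dict(sep="\t", seq=0, name=1, lo=2, hi=3),
}


def read_domain_table(stream: Stream, dialect: str = "generic") -> list[TrackItem]:
    """Parse a domain-hit table into ``domain`` items (1-based inclusive aa).

    Rows identical in (sequence, name, coordinates) are deduplicated;
    distinct overlapping hits are all kept so they superimpose when drawn.
    """
    if dialect not in _DOMAIN_DIALECTS:
        raise ValueError(
            f"unknown domain dialect {dialect!r}; supported: "
            + ", ".join(sorted(_DOMAIN_DIALECTS))
        )
    spec = _DOMAIN_DIALECTS[dialect]
    text = _text_of(stream)
    out: list[TrackItem] = []
    seen: set[tuple] = set()
    for line_no, line in enumerate(text.splitlines(), start=1):
        row = line.rstrip("\r\n")
        if not row.strip() or row.startswith("#"):
            continue
        parts = row.split(spec["sep"]) if spec["sep"] else row.split()
        needed = max(spec["seq"], spec["name"], spec["lo"], spec["hi"]) + 1
        if len(parts) < needed:
            raise TrackParseError(
                f"line {line_no}: expected >= {needed} columns, found {len(parts)}"
            )
        lo_s, hi_s = parts[spec["lo"]].strip(), parts[spec["hi"]].strip()
        if not (lo_s.lstrip("-").isdigit() and hi_s.lstrip("-").isdigit()):
            continue  # header row
        lo, hi = int(lo_s), int(hi_s)
        if lo > hi:
            raise TrackParseError(
                f"line {line_no}: domain start {lo} > end {hi}"
            )
        key = (parts[spec["seq"]].strip(), parts[spec["name"]].strip(), lo, hi)
        if key in seen:
            continue
        seen.add(key)
        out.append(
            TrackItem(
                sequence_id=key[0],
                kind=TrackKind.DOMAIN,
                name=key[1],
                start=lo,
                end=hi,
            )
        )
    return out


# --------------------------------------------------------------------------
# Cis-acting elements (promoter tracks)
# --------------------------------------------------------------------------


def read_cis_elements(stream: Stream, promoter_length: int) -> TrackParseResult:
    """Parse a PlantCARE-style element table into promoter tracks.

    Columns: sequence id, element name, 1-based position, length, strand.
    Position 1 is the upstream-most base; duplicate rows are deduplicated
    exactly; an element running past ``promoter_length`` is a per-row error.
    """
    text = _text_of(stream)
    if not text.strip():
        return TrackParseResult(tracks=[], warnings=[])
    df = pd.read_csv(
        io.StringIO(text),
        sep="\t",
        header=None,
        comment="#",
        names=["sequence_id", "name", "position", "length", "strand"],
        dtype=str,
        skip_blank_lines=True,
    )
    # tolerate a header row
    if len(df) and not str(df.iloc[0]["position"]).strip().isdigit():
        df = df.iloc[1:]
    df = df.drop_duplicates()
    per_seq: dict[str, list[TrackItem]] = {}
    order: list[str] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        start = int(row.position)
        size = int(row.length)
        end = start + size - 1
        if end > promoter_length:
            raise TrackParseError(
                f"row {row_no}: element {row.name!r} [{start},{end}] exceeds "
                f"promoter length {promoter_length}"
            )
        sid = str(row.sequence_id)
        if sid not in per_seq:
            per_seq[sid] = []
            order.append(sid)
        per_seq[sid].append(
            TrackItem(
                sequence_id=sid,
                kind=TrackKind.CIS_ELEMENT,
                name=str(row.name),
                start=start,
                end=end,
                strand=row.strand if row.strand in ("+", "-") else None,
            )
        )
    tracks = [
        SequenceTrack(sequence_id=sid, length=promoter_length, items=per_seq[sid])
        for sid in order
    ]
    return TrackParseResult(tracks=tracks, warnings=[])


# --------------------------------------------------------------------------
# Height scaling and selective display
# --------------------------------------------------------------------------


def motif_height(
    p: float, h_min: float = 0.2, h_max: float = 1.0, cap: float = 30.0
) -> float:
    """Box height fraction for a motif site with p-value ``p``.

    A clamped linear map in -log10(p): ``h_min`` at p = 1, rising to
    ``h_max`` at p = 10**-cap and saturating beyond.  Strictly decreasing in
    p until saturation, so weaker sites are visibly shallower.
    """
    if not (0.0 < p <= 1.0):
        raise ValueError(f"p-value must be in (0,1], got {p}")
    if not (0.0 < h_min < h_max <= 1.0):
        raise ValueError("require 0 < h_min < h_max <= 1")
    if cap <= 0:
        raise ValueError("cap must be positive")
    return h_min + (h_max - h_min) * min(1.0, (-math.log10(p)) / cap)


def filter_items(
    tracks: Iterable[SequenceTrack], selection: Optional[set] = None
) -> list[SequenceTrack]:
    """Restrict track items to a selection of item names and/or kinds.

    An empty (or None) selection means show everything.  Track set and order
    are unchanged; a selection entry matching nothing anywhere triggers a
    warning, not an error.  Coordinates are never altered.
    """
    tracks = list(tracks)
    if not selection:
        return [replace_track(t, list(t.items)) for t in tracks]
    sel = {s.value if isinstance(s, TrackKind) else str(s) for s in selection}
    matched: set[str] = set()
    out = []
    for t in tracks:
        kept = []
        for item in t.items:
            hit = {item.name, item.kind.value} & sel
            if hit:
                matched |= hit
                kept.append(item)
        out.append(replace_track(t, kept))
    for miss in sorted(sel - matched):
        _warnings.warn(
            f"selection {miss!r} matched no item on any track", TrackWarning,
            stacklevel=2,
        )
    return out


def replace_track(track: SequenceTrack, items: list[TrackItem]) -> SequenceTrack:
    return SequenceTrack(
        sequence_id=track.sequence_id, length=track.length, items=items
    )


def attach_items(
    tracks: Sequence[SequenceTrack], items: Iterable[TrackItem]
) -> list[SequenceTrack]:
    """Overlay loose items (e.g. domain hits) onto existing protein tracks."""
    by_seq: dict[str, list[TrackItem]] = {}
    for item in items:
        by_seq.setdefault(item.sequence_id, []).append(item)
    out = []
    for t in tracks:
        extra = by_seq.get(t.sequence_id, [])
        out.append(replace_track(t, list(t.items) + extra))
    return out
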