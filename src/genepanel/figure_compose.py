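"""Panel stitching and rendering.

A figure is an ordered list of panels (tree, gene structure, motif, domain,
promoter) sharing one row per gene/protein, the row order coming from the
tree's leaf order (or plain input order).  Building is a pure function from
inputs to a :class:`SceneGraph` of absolutely-positioned primitives — no
global state, no timestamps — so identical inputs always produce
byte-identical SVG.

Canvas units are inches: a 10 x 4 canvas rendered as PNG at 300 dpi is
exactly 3000 x 1200 pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence, Union

import yaml

from . import protein_tracks as pt
from .gene_structure import infer_exon_blocks, infer_introns
from .model import GeneModel, SegmentKind
from .protein_tracks import SequenceTrack, TrackKind, motif_height
from .tree_model import Tree, layout_tree, monophyletic_leaf_sets

PANEL_KINDS = ("tree", "gene_structure", "motif", "domain", "promoter")

#: per-feature default styles; every value overridable via FigureSpec.style
DEFAULT_STYLE: dict[str, dict] = {
    "exon": {"color": "#4daf4a", "shape": "rect", "thickness": 0.55, "opacity": 1.0},
    "cds": {"color": "#377eb8", "shape": "rect", "thickness": 0.55, "opacity": 1.0},
    "utr": {"color": "#ff7f00", "shape": "rect", "thickness": 0.35, "opacity": 1.0},
    "intron": {"color": "#555555", "shape": "line", "thickness": 0.02, "opacity": 1.0},
    "other": {"color": "#999999", "shape": "rect", "thickness": 0.7, "opacity": 1.0},
    "motif": {"shape": "rect", "thickness": 0.8, "opacity": 1.0},
    "scanned_site": {"shape": "rect", "thickness": 0.8, "opacity": 0.4},
    "domain": {"color": "#d62728", "shape": "rect", "thickness": 0.85, "opacity": 1.0},
    "cis_element": {"shape": "rect", "thickness": 0.4, "opacity": 1.0},
    "baseline": {"color": "#333333", "thickness": 0.012},
    "edge": {"color": "#000000", "thickness": 0.02},
    "label": {"color": "#000000", "size": 0.62},  # fraction of row height
}

#: fixed cycle used for motif and cis-element coloring (keyed by name order)
ITEM_PALETTE = (
    "#66c2a5", "#fc8d62", "#8da0cb", "#e78ac3", "#a6d854", "#ffd92f",
    "#e5c494", "#b3b3b3", "#1b9e77", "#d95f02", "#7570b3", "#e7298a",
)


class FigureError(ValueError):
    """Invalid figure specification or missing panel data."""


class AlignmentError(ValueError):
    """Strict row alignment failed; ``mismatched`` lists the offending ids."""

    def __init__(self, message: str, mismatched: Sequence[str]):
        super().__init__(message)
        self.mismatched = list(mismatched)


# --------------------------------------------------------------------------
# Specification
# --------------------------------------------------------------------------


@dataclass
class PanelSpec:
    kind: str
    width: float
    style: dict = field(default_factory=dict)
    scale_bar: bool = False

    def __post_init__(self) -> None:
        if self.kind not in PANEL_KINDS:
            raise FigureError(
                f"unknown panel kind {self.kind!r}; expected one of {PANEL_KINDS}"
            )
        if self.width <= 0:
            raise FigureError("panel width fraction must be positive")


@dataclass
class FigureSpec:
    """Declarative figure description (mirrors the YAML config file)."""

    panels: list[PanelSpec]
    row_source: str = "tree_leaf_order"
    style: dict = field(default_factory=dict)
    canvas: tuple[float, float] = (12.0, 8.0)
    per_row_scaling: bool = False
    flip_minus_strand: bool = True
    tree_mode: str = "cladogram"
    strict: bool = False

    def __post_init__(self) -> None:
        if not self.panels:
            raise FigureError("figure needs at least one panel")
        total = sum(p.width for p in self.panels)
        if abs(total - 1.0) > 1e-9:
            raise FigureError(f"panel width fractions sum to {total}, expected 1")
        if sum(1 for p in self.panels if p.kind == "tree") > 1:
            raise FigureError("at most one tree panel is allowed")
        if self.row_source not in ("tree_leaf_order", "input_order"):
            raise FigureError(f"unknown row_source {self.row_source!r}")

    def style_for(self, key: str) -> dict:
        merged = dict(DEFAULT_STYLE.get(key, {}))
        merged.update(self.style.get(key, {}))
        return merged

    @classmethod
    def from_dict(cls, data: Mapping) -> "FigureSpec":
        panels = [
            PanelSpec(
                kind=p["kind"],
                width=float(p["width"]),
                style=dict(p.get("style", {})),
                scale_bar=bool(p.get("scale_bar", False)),
            )
            for p in data.get("panels", [])
        ]
        canvas = data.get("canvas", (12.0, 8.0))
        return cls(
            panels=panels,
            row_source=data.get("row_source", "tree_leaf_order"),
            style=dict(data.get("style", {})),
            canvas=(float(canvas[0]), float(canvas[1])),
            per_row_scaling=bool(data.get("per_row_scaling", False)),
            flip_minus_strand=bool(data.get("flip_minus_strand", True)),
            tree_mode=data.get("tree_mode", "cladogram"),
            strict=bool(data.get("strict", False)),
        )

    @classmethod
    def from_yaml(cls, text: str) -> "FigureSpec":
        return cls.from_dict(yaml.safe_load(text) or {})


# --------------------------------------------------------------------------
# Scene graph primitives
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Rect:
    id: str
    x: float
    y: float
    w: float
    h: float
    fill: Optional[str] = None  # None -> outline-only
    stroke: Optional[str] = None
    stroke_width: float = 0.0
    opacity: float = 1.0
    rx: float = 0.0


@dataclass(frozen=True)
class Line:
    id: str
    x1: float
    y1: float
    x2: float
    y2: float
    stroke: str = "#000000"
    width: float = 0.01
    opacity: float = 1.0


@dataclass(frozen=True)
class Polyline:
    id: str
    points: tuple[tuple[float, float], ...]
    stroke: str = "#000000"
    width: float = 0.01
    opacity: float = 1.0


@dataclass(frozen=True)
class Text:
    id: str
    x: float
    y: float
    text: str
    size: float = 0.12
    anchor: str = "start"  # start | middle | end
    fill: str = "#000000"


Primitive = Union[Rect, Line, Polyline, Text]


@dataclass
class SceneGraph:
    width: float
    height: float
    elements: list[Primitive] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def by_prefix(self, prefix: str) -> list[Primitive]:
        return [e for e in self.elements if e.id.startswith(prefix)]


# --------------------------------------------------------------------------
# Row alignment
# --------------------------------------------------------------------------


def align_rows(
    leaf_order: Sequence[str],
    panel_ids: Mapping[str, Iterable[str]],
    strict: bool = False,
) -> tuple[dict[str, int], list[str]]:
    """Map every id to its row index (= leaf rank).

    Ids present in a panel but absent from the row order (and vice versa)
    are mismatches: strict mode raises :class:`AlignmentError` enumerating
    them, lenient mode reports warnings and leaves blanks.
    """
    rows = {name: i for i, name in enumerate(leaf_order)}
    leafset = set(leaf_order)
    warnings: list[str] = []
    mismatched: set[str] = set()
    for panel, ids in panel_ids.items():
        ids = set(ids)
        for extra in sorted(ids - leafset):
            mismatched.add(extra)
            warnings.append(f"{panel}: id {extra!r} has no row (not in row order)")
        for missing in sorted(leafset - ids):
            mismatched.add(missing)
            warnings.append(f"{panel}: row {missing!r} has no data; left blank")
    if strict and mismatched:
        raise AlignmentError(
            "row alignment mismatch: " + ", ".join(sorted(mismatched)),
            sorted(mismatched),
        )
    return rows, warnings


# --------------------------------------------------------------------------
# Scene building
# --------------------------------------------------------------------------

_PAD = 0.25  # horizontal padding inside each panel, canvas units


def _fmt_num(x: float) -> str:
    s = f"{x:.6f}".rstrip("0").rstrip(".")
    return s if s not in ("-0", "") else "0"


def _nice_round(limit: float) -> float:
    """Largest 1/2/5 x 10^k value not exceeding ``limit``."""
    import math

    if limit <= 0:
        return 1.0
    exp = math.floor(math.log10(limit))
    for mult in (5, 2, 1):
        cand = mult * 10.0**exp
        if cand <= limit:
            return cand
    return 10.0 ** (exp - 1) * 5


def build_scene(
    spec: FigureSpec,
    tree: Optional[Tree] = None,
    models: Optional[Sequence[GeneModel]] = None,
    tracks: Optional[Sequence[SequenceTrack]] = None,
    promoter_tracks: Optional[Sequence[SequenceTrack]] = None,
) -> SceneGraph:
    """Assemble the multi-panel scene.

    Every panel must have its data: the tree panel a tree, gene_structure
    the models, motif/domain the protein tracks, promoter the promoter
    tracks.  Row order comes from the tree leaves (``tree_leaf_order``) or
    from the order of the structure/track inputs (``input_order``).
    """
    W, H = spec.canvas
    need = {p.kind for p in spec.panels}
    if "tree" in need and tree is None:
        raise FigureError("tree panel requires a parsed tree")
    if "gene_structure" in need and not models:
        raise FigureError("gene_structure panel requires gene models")
    if ("motif" in need or "domain" in need) and not tracks:
        raise FigureError("motif/domain panels require protein tracks")
    if "promoter" in need and not promoter_tracks:
        raise FigureError("promoter panel requires promoter tracks")

    if spec.row_source == "tree_leaf_order":
        if tree is None:
            raise FigureError("row_source=tree_leaf_order requires a tree")
        row_order = list(tree.leaves)
    else:
        if models:
            row_order = [m.transcript_id for m in models]
        elif tracks:
            row_order = [t.sequence_id for t in tracks]
        elif promoter_tracks:
            row_order = [t.sequence_id for t in promoter_tracks]
        else:
            raise FigureError("no inputs to derive row order from")

    panel_ids: dict[str, set[str]] = {}
    if models is not None and "gene_structure" in need:
        panel_ids["gene_structure"] = {m.transcript_id for m in models}
    if tracks is not None and ("motif" in need or "domain" in need):
        panel_ids["protein"] = {t.sequence_id for t in tracks}
    if promoter_tracks is not None and "promoter" in need:
        panel_ids["promoter"] = {t.sequence_id for t in promoter_tracks}

    rows, warnings = align_rows(row_order, panel_ids, strict=spec.strict)
    n_rows = max(len(row_order), 1)
    row_h = H / n_rows

    scene = SceneGraph(width=W, height=H, warnings=warnings)
    model_by_id = {m.transcript_id: m for m in models or []}
    track_by_id = {t.sequence_id: t for t in tracks or []}
    prom_by_id = {t.sequence_id: t for t in promoter_tracks or []}

    x0 = 0.0
    for panel in spec.panels:
        pw = panel.width * W
        if panel.kind == "tree":
            _build_tree_panel(scene, spec, tree, x0, pw, H, row_h)
        elif panel.kind == "gene_structure":
            _build_structure_panel(
                scene, spec, panel, row_order, rows, model_by_id, x0, pw, row_h
            )
        elif panel.kind == "motif":
            _build_track_panel(
                scene, spec, panel, row_order, rows, track_by_id, x0, pw, row_h,
                kinds=(TrackKind.SCANNED_SITE, TrackKind.MOTIF, TrackKind.DOMAIN),
                prefix="motif", unit="aa",
            )
        elif panel.kind == "domain":
            _build_track_panel(
                scene, spec, panel, row_order, rows, track_by_id, x0, pw, row_h,
                kinds=(TrackKind.DOMAIN, TrackKind.SIGNAL_PEPTIDE),
                prefix="domain", unit="aa",
            )
        elif panel.kind == "promoter":
            _build_track_panel(
                scene, spec, panel, row_order, rows, prom_by_id, x0, pw, row_h,
                kinds=(TrackKind.CIS_ELEMENT,),
                prefix="promoter", unit="bp",
            )
        x0 += pw
    return scene


def _build_tree_panel(scene, spec, tree, x0, pw, H, row_h):
    label_style = spec.style_for("label")
    edge_style = spec.style_for("edge")
    label_w = min(pw * 0.45, 0.12 * row_h * 0.62 * 18 + 0.1)
    layout = layout_tree(tree, height=H, width=max(pw - label_w - 2 * _PAD, 0.1),
                         mode=spec.tree_mode)
    mono = monophyletic_leaf_sets(tree) if tree.groups else {}
    group_leaves: dict[str, frozenset] = {}
    for leaf, g in tree.groups.items():
        group_leaves.setdefault(g, frozenset())
    for g in group_leaves:
        group_leaves[g] = frozenset(
            leaf for leaf, gg in tree.groups.items() if gg == g
        )

    for (child_key, points), leafset in zip(layout.edges, layout.edge_leafsets):
        color = edge_style["color"]
        for g, leaves in group_leaves.items():
            if g != "ungrouped" and mono.get(g) and leafset <= leaves:
                color = tree.group_styles.get(g, color)
                break
        scene.elements.append(
            Polyline(
                id=f"tree.edge.{child_key}",
                points=tuple((x0 + _PAD + px, py) for px, py in points),
                stroke=color,
                width=edge_style["thickness"],
            )
        )
    font = row_h * label_style["size"]
    for name in tree.leaves:
        color = label_style["color"]
        g = tree.groups.get(name)
        if g and g != "ungrouped":
            color = tree.group_styles.get(g, color)
        scene.elements.append(
            Text(
                id=f"tree.leaf.{name}",
                x=x0 + pw - 0.05,
                y=layout.leaf_y[name] + font * 0.35,
                text=name,
                size=font,
                anchor="end",
                fill=color,
            )
        )


def _structure_scale(spec, row_order, model_by_id, pw):
    spans = {}
    for tid in row_order:
        m = model_by_id.get(tid)
        if m is not None:
            lo, hi = m.span
            spans[tid] = hi - lo + 1
    if not spans:
        return {}, 1.0
    inner = pw - 2 * _PAD
    global_scale = inner / max(spans.values())
    per_row = {
        tid: (inner / span if spec.per_row_scaling else global_scale)
        for tid, span in spans.items()
    }
    return per_row, max(spans.values())


def _build_structure_panel(
    scene, spec, panel, row_order, rows, model_by_id, x0, pw, row_h
):
    base_style = spec.style_for("baseline")
    intron_style = spec.style_for("intron")
    scales, max_span = _structure_scale(spec, row_order, model_by_id, pw)
    for tid in row_order:
        m = model_by_id.get(tid)
        if m is None:
            continue
        sx = scales[tid]
        lo, hi = m.span
        cy = (rows[tid] + 0.5) * row_h
        flipped = spec.flip_minus_strand and m.strand == "-"

        def gx(g: int) -> float:
            t = (hi - g) if flipped else (g - lo)
            return x0 + _PAD + t * sx

        blocks = infer_exon_blocks(m)
        x_start = min(gx(lo), gx(hi))
        x_end = max(gx(lo), gx(hi))
        scene.elements.append(
            Line(
                id=f"struct.{tid}.baseline",
                x1=x_start, y1=cy, x2=x_end, y2=cy,
                stroke=base_style["color"], width=base_style["thickness"],
            )
        )
        for i, (ilo, ihi) in enumerate(infer_introns(m)):
            xa, xb = sorted((gx(ilo), gx(ihi)))
            scene.elements.append(
                Line(
                    id=f"struct.{tid}.intron.{i}",
                    x1=xa, y1=cy, x2=xb, y2=cy,
                    stroke=intron_style["color"],
                    width=intron_style["thickness"] * row_h,
                )
            )
        has_coding = bool(m.cds_segments() or m.utr_segments())
        drawn = (
            [(s.kind, s.start, s.end, None) for s in m.segments
             if s.kind is not SegmentKind.EXON and s.kind is not SegmentKind.OTHER]
            if has_coding
            else [(SegmentKind.EXON, blo, bhi, None) for blo, bhi in blocks]
        )
        # z-order: utr below cds/exon
        order = {SegmentKind.FIVE_UTR: 0, SegmentKind.THREE_UTR: 0,
                 SegmentKind.CDS: 1, SegmentKind.EXON: 1}
        counters: dict[str, int] = {}
        for kind, slo, shi, _ in sorted(drawn, key=lambda d: (order[d[0]], d[1])):
            skey = ("utr" if kind in (SegmentKind.FIVE_UTR, SegmentKind.THREE_UTR)
                    else "cds" if kind is SegmentKind.CDS else "exon")
            st = {**spec.style_for(skey), **panel.style.get(skey, {})}
            hh = st["thickness"] * row_h
            xa, xb = sorted((gx(slo), gx(shi + 1)))
            idx = counters.get(skey, 0)
            counters[skey] = idx + 1
            scene.elements.append(
                Rect(
                    id=f"struct.{tid}.{skey}.{idx}",
                    x=xa, y=cy - hh / 2, w=xb - xa, h=hh,
                    fill=st["color"], opacity=st["opacity"],
                    rx=0.3 * hh if st.get("shape") == "rounded_rect" else 0.0,
                )
            )
        # free annotations (signal peptides etc.): outline boxes above
        for j, s in enumerate(m.segments_of(SegmentKind.OTHER)):
            st = spec.style_for("other")
            hh = st["thickness"] * row_h
            xa, xb = sorted((gx(s.start), gx(s.end + 1)))
            scene.elements.append(
                Rect(
                    id=f"struct.{tid}.other.{j}",
                    x=xa, y=cy - hh / 2, w=xb - xa, h=hh,
                    fill=None, stroke=st["color"], stroke_width=0.015,
                )
            )
        if flipped:
            scene.elements.append(
                Text(
                    id=f"struct.{tid}.strandmark",
                    x=x_end + 0.06, y=cy + 0.25 * row_h,
                    text="(-)", size=row_h * 0.5, anchor="start",
                    fill="#777777",
                )
            )
    if panel.scale_bar and scales and not spec.per_row_scaling:
        _add_scale_bar(scene, "struct", x0, pw, scene.height,
                       units_per_x=1.0 / next(iter(set(scales.values()))),
                       unit="bp")


def _item_color(name: str, palette_index: dict[str, int], style: dict) -> str:
    if "color" in style:
        return style["color"]
    if name not in palette_index:
        palette_index[name] = len(palette_index)
    return ITEM_PALETTE[palette_index[name] % len(ITEM_PALETTE)]


def _build_track_panel(
    scene, spec, panel, row_order, rows, track_by_id, x0, pw, row_h,
    kinds, prefix, unit,
):
    base_style = spec.style_for("baseline")
    lengths = {
        tid: track_by_id[tid].length for tid in row_order if tid in track_by_id
    }
    if not lengths:
        return
    inner = pw - 2 * _PAD
    global_scale = inner / max(lengths.values())
    palette_index: dict[str, int] = {}
    kind_rank = {k: i for i, k in enumerate(kinds)}
    for tid in row_order:
        track = track_by_id.get(tid)
        if track is None:
            continue
        sx = inner / track.length if spec.per_row_scaling else global_scale
        cy = (rows[tid] + 0.5) * row_h
        scene.elements.append(
            Line(
                id=f"{prefix}.{tid}.baseline",
                x1=x0 + _PAD, y1=cy, x2=x0 + _PAD + track.length * sx, y2=cy,
                stroke=base_style["color"], width=base_style["thickness"],
            )
        )
        # stable draw order: configured kind z-order, then coordinates
        items = [it for it in track.items if it.kind in kind_rank]
        items.sort(key=lambda it: (kind_rank[it.kind], it.start, it.end, it.name))
        for idx, it in enumerate(items):
            skey = it.kind.value
            st = {**spec.style_for(skey), **panel.style.get(skey, {})}
            xa = x0 + _PAD + (it.start - 1) * sx
            xb = x0 + _PAD + it.end * sx
            if it.kind in (TrackKind.MOTIF, TrackKind.SCANNED_SITE):
                frac = (
                    motif_height(it.p_value) if it.p_value is not None else 1.0
                )
                hh = st["thickness"] * row_h * frac
            else:
                hh = st["thickness"] * row_h
            y = cy - hh / 2
            if it.kind is TrackKind.CIS_ELEMENT and it.strand == "-":
                y = cy  # minus-strand elements hang below the baseline
            elif it.kind is TrackKind.CIS_ELEMENT:
                y = cy - hh
            if it.kind is TrackKind.DOMAIN and prefix == "motif":
                # superimposed outline so motifs beneath stay visible
                scene.elements.append(
                    Rect(
                        id=f"{prefix}.{tid}.{skey}.{idx}",
                        x=xa, y=y, w=xb - xa, h=hh,
                        fill=None,
                        stroke=_item_color(it.name, palette_index, st),
                        stroke_width=0.02,
                        opacity=st["opacity"],
                    )
                )
            else:
                scene.elements.append(
                    Rect(
                        id=f"{prefix}.{tid}.{skey}.{idx}",
                        x=xa, y=y, w=xb - xa, h=hh,
                        fill=_item_color(it.name, palette_index, st),
                        opacity=it.opacity if it.kind is TrackKind.SCANNED_SITE
                        else st["opacity"],
                        rx=0.3 * hh if st.get("shape") == "rounded_rect" else 0.0,
                    )
                )
    if panel.scale_bar and not spec.per_row_scaling:
        _add_scale_bar(scene, prefix, x0, pw, scene.height,
                       units_per_x=1.0 / global_scale, unit=unit)


def _add_scale_bar(scene, prefix, x0, pw, H, units_per_x, unit):
    target_units = _nice_round(units_per_x * pw * 0.25)
    bar_w = target_units / units_per_x
    y = H - 0.12
    scene.elements.append(
        Line(
            id=f"{prefix}.scalebar",
            x1=x0 + _PAD, y1=y, x2=x0 + _PAD + bar_w, y2=y,
            stroke="#000000", width=0.015,
        )
    )
    label = (
        f"{target_units / 1000:g} kb"
        if unit == "bp" and target_units >= 1000
        else f"{target_units:g} {unit}"
    )
    scene.elements.append(
        Text(
            id=f"{prefix}.scalebar.label",
            x=x0 + _PAD + bar_w / 2, y=y - 0.03,
            text=label, size=0.1, anchor="middle",
        )
    )


# --------------------------------------------------------------------------
# Rendering
# --------------------------------------------------------------------------


def render(scene: SceneGraph, format: str = "svg", dpi: int = 300) -> bytes:
    """Serialise a scene as SVG (deterministic, id-preserving), PDF or PNG.

    SVG output is produced by a dedicated writer so that two runs on
    identical inputs are byte-identical; PDF and PNG are rasterised/drawn via
    matplotlib at the requested dpi (PNG pixel size = canvas inches x dpi).
    """
    if format == "svg":
        return _render_svg(scene)
    if format in ("pdf", "png"):
        return _render_matplotlib(scene, format, dpi)
    raise ValueError(f"unsupported format {format!r}; expected svg, pdf or png")


def _esc(text: str) -> str:
    return (
        text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
        .replace('"', "&quot;")
    )


def _render_svg(scene: SceneGraph) -> bytes:
    f = _fmt_num
    out = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{f(scene.width)}in" '
        f'height="{f(scene.height)}in" '
        f'viewBox="0 0 {f(scene.width)} {f(scene.height)}">',
    ]
    for e in scene.elements:
        if isinstance(e, Rect):
            attrs = [
                f'id="{_esc(e.id)}"', f'x="{f(e.x)}"', f'y="{f(e.y)}"',
                f'width="{f(e.w)}"', f'height="{f(e.h)}"',
            ]
            if e.rx:
                attrs.append(f'rx="{f(e.rx)}"')
            if e.fill is not None:
                attrs.append(f'fill="{e.fill}"')
            else:
                attrs.append('fill="none"')
            if e.stroke:
                attrs.append(f'stroke="{e.stroke}" stroke-width="{f(e.stroke_width)}"')
            if e.opacity != 1.0:
                attrs.append(f'opacity="{f(e.opacity)}"')
            out.append(f"<rect {' '.join(attrs)}/>")
        elif isinstance(e, Line):
            out.append(
                f'<line id="{_esc(e.id)}" x1="{f(e.x1)}" y1="{f(e.y1)}" '
                f'x2="{f(e.x2)}" y2="{f(e.y2)}" stroke="{e.stroke}" '
                f'stroke-width="{f(e.width)}"'
                + (f' opacity="{f(e.opacity)}"' if e.opacity != 1.0 else "")
                + "/>"
            )
        elif isinstance(e, Polyline):
            pts = " ".join(f"{f(px)},{f(py)}" for px, py in e.points)
            out.append(
                f'<polyline id="{_esc(e.id)}" points="{pts}" fill="none" '
                f'stroke="{e.stroke}" stroke-width="{f(e.width)}"/>'
            )
        elif isinstance(e, Text):
            out.append(
                f'<text id="{_esc(e.id)}" x="{f(e.x)}" y="{f(e.y)}" '
                f'font-size="{f(e.size)}" text-anchor="{e.anchor}" '
                f'fill="{e.fill}" font-family="DejaVu Sans, sans-serif">'
                f"{_esc(e.text)}</text>"
            )
    out.append("</svg>")
    return ("\n".join(out) + "\n").encode("utf-8")


def _render_matplotlib(scene: SceneGraph, format: str, dpi: int) -> bytes:
    import io as _io

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib import patches

    fig = plt.figure(figsize=(scene.width, scene.height), dpi=dpi)
    ax = fig.add_axes([0, 0, 1, 1])
    ax.set_xlim(0, scene.width)
    ax.set_ylim(scene.height, 0)  # scene y runs downwards
    ax.axis("off")
    for e in scene.elements:
        if isinstance(e, Rect):
            patch = patches.FancyBboxPatch(
                (e.x, e.y), e.w, e.h,
                boxstyle=f"round,pad=0,rounding_size={e.rx}" if e.rx else "square,pad=0",
                facecolor=e.fill if e.fill is not None else "none",
                edgecolor=e.stroke or "none",
                linewidth=e.stroke_width * 72,
                alpha=e.opacity,
            )
            patch.set_gid(e.id)
            ax.add_patch(patch)
        elif isinstance(e, Line):
            (ln,) = ax.plot(
                [e.x1, e.x2], [e.y1, e.y2],
                color=e.stroke, linewidth=e.width * 72, alpha=e.opacity,
                solid_capstyle="butt",
            )
            ln.set_gid(e.id)
        elif isinstance(e, Polyline):
            xs, ys = zip(*e.points)
            (ln,) = ax.plot(
                xs, ys, color=e.stroke, linewidth=e.width * 72,
                alpha=e.opacity, solid_joinstyle="miter",
            )
            ln.set_gid(e.id)
        elif isinstance(e, Text):
            txt = ax.text(
                e.x, e.y, e.text,
                fontsize=e.size * 72, color=e.fill,
                ha={"start": "left", "middle": "center", "end": "right"}[e.anchor],
                va="baseline",
            )
            txt.set_gid(e.id)
    buf = _io.BytesIO()
    fig.savefig(
        buf, format=format, dpi=dpi,
        metadata={"CreationDate": None} if format == "pdf" else None,
    )
    plt.close(fig)
    return buf.getvalue()
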