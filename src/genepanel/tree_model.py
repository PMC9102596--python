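"""Newick tree parsing, grouping/coloring and rectangular layout.

The tree drives row alignment of every other panel: leaf order is the
left-to-right order of the Newick string (no re-rooting, no ladderizing by
default), so a figure built from the same inputs always assigns the same row
to the same gene.  Parsing and serialisation delegate to Bio.Phylo; this
module adds offset-bearing error reporting, group/color bookkeeping and the
layout used by :mod:`genepanel.figure_compose`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from Bio import Phylo
from Bio.Phylo.BaseTree import Clade

#: fixed default palette; assigned to groups in first-appearance order and
#: wrapped (with a warning) when more groups than colors exist
DEFAULT_PALETTE = (
    "#e41a1c", "#377eb8", "#4daf4a", "#984ea3", "#ff7f00", "#a65628",
    "#f781bf", "#1b9e77", "#7570b3", "#66a61e", "#e6ab02", "#666666",
)

UNGROUPED = "ungrouped"


class NewickParseError(ValueError):
    """Malformed Newick input; carries a character offset when known."""

    def __init__(self, message: str, offset: Optional[int] = None):
        self.offset = offset
        if offset is not None:
            message = f"offset {offset}: {message}"
        super().__init__(message)


class GroupError(ValueError):
    """Group mapping referencing leaves absent from the tree."""


@dataclass
class Tree:
    """Parsed rooted topology plus display grouping.

    ``leaves`` is the authoritative row order.  ``groups`` maps every leaf to
    a group name (``"ungrouped"`` when unassigned); ``group_styles`` maps
    group name to a hex color.
    """

    root: Clade
    leaves: list[str]
    groups: dict[str, str] = field(default_factory=dict)
    group_styles: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def serialize(self) -> str:
        """Write the topology back out as a Newick string."""
        handle = io.StringIO()
        tree = Phylo.BaseTree.Tree(root=self.root, rooted=True)
        Phylo.write(tree, handle, "newick")
        return handle.getvalue().strip()


def _prevalidate(text: str) -> None:
    depth = 0
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError("unbalanced ')'", offset=i)
    if depth != 0:
        raise NewickParseError(
            f"unbalanced parentheses ({depth} '(' unclosed)", offset=len(text)
        )
    stripped = text.rstrip()
    if not stripped.endswith(";"):
        raise NewickParseError("missing terminating ';'", offset=len(text))


def parse_newick(text: str) -> Tree:
    """Parse a single rooted Newick statement.

    Quoted labels, branch lengths and internal support labels are accepted.
    Leaf order is the file order.  Unbalanced parentheses, a missing ';' and
    duplicate leaf labels raise :class:`NewickParseError`.
    """
    _prevalidate(text)
    try:
        tree = Phylo.read(io.StringIO(text), "newick")
    except Exception as exc:  # Bio.Phylo raises several error types
        raise NewickParseError(str(exc)) from exc
    leaves = [t.name for t in tree.get_terminals()]
    if any(name is None for name in leaves):
        raise NewickParseError("unlabeled leaf")
    seen: set[str] = set()
    for name in leaves:
        if name in seen:
            raise NewickParseError(
                f"duplicate leaf label {name!r}", offset=text.find(name)
            )
        seen.add(name)
    for leaf in tree.get_terminals():
        if leaf.branch_length is not None and leaf.branch_length < 0:
            raise NewickParseError(f"negative branch length on {leaf.name!r}")
    return Tree(root=tree.root, leaves=leaves)


def assign_groups(
    tree: Tree,
    mapping: Mapping[str, str],
    styles: Optional[Mapping[str, str]] = None,
) -> Tree:
    """Attach group labels and colors to the tree's leaves.

    ``mapping`` must reference only existing leaves (offenders are listed in
    the raised error).  Ungrouped leaves get the group ``"ungrouped"``; groups
    are colored from the default 12-color cycle in first-appearance order
    (over leaf order) unless explicit styles are given.
    """
    unknown = sorted(set(mapping) - set(tree.leaves))
    if unknown:
        raise GroupError(
            "group mapping references leaves absent from the tree: "
            + ", ".join(repr(u) for u in unknown)
        )
    groups = {leaf: mapping.get(leaf, UNGROUPED) for leaf in tree.leaves}
    tree.groups = groups
    order: list[str] = []
    for leaf in tree.leaves:
        g = groups[leaf]
        if g != UNGROUPED and g not in order:
            order.append(g)
    if styles:
        tree.group_styles = dict(styles)
        missing = [g for g in order if g not in tree.group_styles]
    else:
        tree.group_styles = {}
        missing = order
    if len(missing) > len(DEFAULT_PALETTE):
        tree.warnings.append(
            f"{len(missing)} groups exceed the {len(DEFAULT_PALETTE)}-color "
            "palette; colors will repeat"
        )
    for i, g in enumerate(missing):
        tree.group_styles[g] = DEFAULT_PALETTE[i % len(DEFAULT_PALETTE)]
    tree.group_styles.setdefault(UNGROUPED, "#000000")
    return tree


# --------------------------------------------------------------------------
# Layout
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TreeLayout:
    """Node coordinates and orthogonal edge polylines for drawing.

    ``leaf_y`` maps leaf label to its row center; ``nodes`` lists
    ``(node_key, x, y)`` with leaf keys equal to their labels and internal
    keys ``"node<i>"`` in preorder; ``edges`` holds per-edge polylines as
    point lists.
    """

    leaf_y: Mapping[str, float]
    nodes: Sequence[tuple[str, float, float]]
    edges: Sequence[tuple[str, list[tuple[float, float]]]]
    #: per-edge frozenset of leaf labels below the child node (for clade coloring)
    edge_leafsets: Sequence[frozenset] = ()


def layout_tree(
    tree: Tree, height: float, width: float, mode: str = "cladogram"
) -> TreeLayout:
    """Rectangular layout: leaf ``i`` (top to bottom) at
    ``y = (i + 0.5) * height / n_leaves``; internal node y = mean of its
    children's y; x from cumulative branch length (``mode="phylogram"``,
    missing lengths treated as 0) or node depth in edges (``"cladogram"``),
    scaled so the deepest node sits at ``width``.
    """
    if mode not in ("cladogram", "phylogram"):
        raise ValueError(f"unknown layout mode {mode!r}")
    n = tree.n_leaves
    if n == 0:
        raise ValueError("cannot lay out an empty tree")
    row_h = height / n
    leaf_y = {name: (i + 0.5) * row_h for i, name in enumerate(tree.leaves)}

    raw_x: dict[int, float] = {}
    ys: dict[int, float] = {}
    keys: dict[int, str] = {}
    order: list[Clade] = []
    counter = [0]

    def visit(clade: Clade, depth: float) -> float:
        order.append(clade)
        if clade.is_terminal():
            keys[id(clade)] = clade.name
            raw_x[id(clade)] = depth
            ys[id(clade)] = leaf_y[clade.name]
            return ys[id(clade)]
        keys[id(clade)] = f"node{counter[0]}"
        counter[0] += 1
        child_ys = []
        for child in clade.clades:
            step = 1.0
            if mode == "phylogram":
                step = child.branch_length or 0.0
            child_ys.append(visit(child, depth + step))
        raw_x[id(clade)] = depth
        ys[id(clade)] = sum(child_ys) / len(child_ys)
        return ys[id(clade)]

    visit(tree.root, 0.0)
    max_depth = max(raw_x.values()) or 1.0
    scale = width / max_depth
    xs = {k: v * scale for k, v in raw_x.items()}

    nodes = [(keys[id(c)], xs[id(c)], ys[id(c)]) for c in order]

    leafsets: dict[int, frozenset] = {}

    def collect_leaves(clade: Clade) -> frozenset:
        if clade.is_terminal():
            s = frozenset({clade.name})
        else:
            s = frozenset().union(*(collect_leaves(c) for c in clade.clades))
        leafsets[id(clade)] = s
        return s

    collect_leaves(tree.root)

    edges: list[tuple[str, list[tuple[float, float]]]] = []
    edge_leafsets: list[frozenset] = []

    def collect_edges(clade: Clade) -> None:
        for child in clade.clades:
            # vertical drop from parent x at child's row, then horizontal run
            edges.append(
                (
                    keys[id(child)],
                    [
                        (xs[id(clade)], ys[id(clade)]),
                        (xs[id(clade)], ys[id(child)]),
                        (xs[id(child)], ys[id(child)]),
                    ],
                )
            )
            edge_leafsets.append(leafsets[id(child)])
            collect_edges(child)

    collect_edges(tree.root)
    return TreeLayout(
        leaf_y=leaf_y, nodes=nodes, edges=edges, edge_leafsets=edge_leafsets
    )


def monophyletic_leaf_sets(tree: Tree) -> dict[str, bool]:
    """For each assigned group, whether its leaves form a monophyletic clade."""
    result: dict[str, bool] = {}
    group_leaves: dict[str, set[str]] = {}
    for leaf, g in tree.groups.items():
        if g != UNGROUPED:
            group_leaves.setdefault(g, set()).add(leaf)

    clade_sets: list[set[str]] = []

    def visit(clade: Clade) -> set[str]:
        if clade.is_terminal():
            s = {clade.name}
        else:
            s = set()
            for child in clade.clades:
                s |= visit(child)
        clade_sets.append(s)
        return s

    visit(tree.root)
    for g, leaves in group_leaves.items():
        result[g] = any(leaves == s for s in clade_sets)
    return result
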