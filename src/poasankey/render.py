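"""SVG rendering: Sankey panel, column-synchronized matrix panel, tree panel.

The three panels share one absolute coordinate system so that the
synchronization contracts hold exactly: Sankey columns and matrix columns
have identical x coordinates and widths, and tree leaves sit at the same
y-centers as their matrix rows.  Output is deterministic byte-for-byte:
floats are formatted to fixed precision, iteration orders are explicit,
and no timestamps or random ids are embedded.

Static hover information is embedded as SVG ``<title>``/``<desc>``
children (column, symbol, member ids) instead of scripted bubbles.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .errors import PoaSankeyError
from .layout import Layout, LinkGeometry, link_path, sublink_path, z_order
from .msa_io import GAP, Alignment, PhyloTree, check_tree_alignment
from .poa_graph import POAGraph
from .selection import SelectionState

# fixed metrics table — keeps output byte-identical across platforms
FONT_SIZE = 12.0
CHAR_WIDTH = 7.2  # monospace advance at FONT_SIZE
ROW_HEIGHT = 18.0
LABEL_PAD = 6.0
PANEL_GAP = 24.0
TREE_WIDTH = 140.0
MARGIN = 10.0


def _fmt(v: float) -> str:
    return f"{v:.3f}"


@dataclass(frozen=True)
class ColorScheme:
    """Symbol/group → fill color, total via a fallback color."""

    mapping: Mapping[str, str]
    name: str = "custom"
    highlight_color: str = "#e6194b"
    dim_opacity: float = 0.25
    fallback: str = "#b0b0b0"

    def color_for(self, symbol: str) -> str:
        return self.mapping.get(symbol, self.fallback)


@dataclass(frozen=True)
class RenderOptions:
    show_column_separators: bool = False
    show_column_numbers: bool = True
    column_label_map: Optional[Mapping[int, str]] = None  # 0-based → label
    panels: tuple[str, ...] = ("sankey", "matrix", "tree")
    tooltip: bool = True
    html: bool = False

    def validate(self) -> "RenderOptions":
        if not self.panels:
            raise PoaSankeyError("at least one panel must be enabled")
        unknown = set(self.panels) - {"sankey", "matrix", "tree"}
        if unknown:
            raise PoaSankeyError(f"unknown panels: {sorted(unknown)}")
        return self


_NUCLEOTIDE_COLORS = {
    "A": "#4daf4a",
    "C": "#377eb8",
    "G": "#ff7f00",
    "T": "#e41a1c",
    "U": "#e41a1c",
    "N": "#999999",
    GAP: "#e8e8e8",
}

# Clustal-like protein palette
_PROTEIN_COLORS = {
    "A": "#80a0f0", "I": "#80a0f0", "L": "#80a0f0", "M": "#80a0f0",
    "F": "#80a0f0", "W": "#80a0f0", "V": "#80a0f0",
    "K": "#f01505", "R": "#f01505",
    "E": "#c048c0", "D": "#c048c0",
    "N": "#15c015", "Q": "#15c015", "S": "#15c015", "T": "#15c015",
    "C": "#f08080",
    "G": "#f09048",
    "P": "#c0c000",
    "H": "#15a4a4", "Y": "#15a4a4",
    GAP: "#e8e8e8",
}

_GROUP_COLORS = {
    "electrically charged": "#e41a1c",
    "polar uncharged": "#377eb8",
    "hydrophobic": "#4daf4a",
    "special": "#ff7f00",
    "other": "#999999",
    GAP: "#e8e8e8",
}


def default_schemes() -> dict[str, ColorScheme]:
    """Built-in palettes: nucleotide (4+N), Clustal-like protein, and the
    four physicochemical groups + other.  All overridable from config."""
    return {
        "nucleotide": ColorScheme(_NUCLEOTIDE_COLORS, name="nucleotide"),
        "protein": ColorScheme(_PROTEIN_COLORS, name="protein"),
        "group": ColorScheme(_GROUP_COLORS, name="group"),
    }


def scheme_for_graph(g: POAGraph, simplified: bool = False) -> ColorScheme:
    schemes = default_schemes()
    if simplified:
        return schemes["group"]
    return schemes[g.alphabet] if g.alphabet in schemes else schemes["protein"]


# ---------------------------------------------------------------------------
# Tree panel


def _ordered_children(clade) -> list:
    """Ladderized child order: fewer descendant leaves first, ties broken
    by the lexicographically smallest descendant label."""
    def key(c):
        leaves = [l.name for l in c.get_terminals()]
        return (len(leaves), min(leaves))

    return sorted(clade.clades, key=key)


def tree_leaf_order(tree: PhyloTree) -> list[str]:
    """Top-to-bottom leaf order of the ladderized cladogram."""
    order: list[str] = []

    def walk(clade) -> None:
        if not clade.clades:
            order.append(clade.name)
            return
        for child in _ordered_children(clade):
            walk(child)

    walk(tree.root)
    return order


def render_tree_panel(
    tree: PhyloTree,
    aln: Alignment,
    selection: SelectionState,
    row_y: Optional[Mapping[str, float]] = None,
    scheme: Optional[ColorScheme] = None,
    x0: float = MARGIN,
    x1: float = TREE_WIDTH - MARGIN,
) -> tuple[ET.Element, list[str]]:
    """Draw a rectangular cladogram whose leaves sit at the given row
    y-centers; returns the fragment and the top-to-bottom leaf order.

    When ``row_y`` is omitted, leaves are placed on a uniform row grid in
    ladderized order.  Selected leaves and the edges of their spanning
    subtree (the paths from their most recent common ancestor down to each
    selected leaf) are drawn in the highlight color.
    """
    check_tree_alignment(tree, aln)
    scheme = scheme or default_schemes()["nucleotide"]
    if row_y is None:
        row_y = {
            lbl: i * ROW_HEIGHT + ROW_HEIGHT / 2.0
            for i, lbl in enumerate(tree_leaf_order(tree))
        }
    order = tree_leaf_order(tree)
    index = {sid: i for i, sid in enumerate(aln.ids)}
    selected_ids = {aln.ids[i] for i in selection.selected}

    # depth = edge count from root; cladogram ignores branch lengths
    depth: dict[int, int] = {}
    max_depth = 0

    def measure(clade, d: int) -> None:
        nonlocal max_depth
        depth[id(clade)] = d
        max_depth = max(max_depth, d)
        for child in clade.clades:
            measure(child, d + 1)

    measure(tree.root, 0)
    span = max(max_depth, 1)

    def x_of(clade) -> float:
        if not clade.clades:
            return x1  # all leaves flush right, aligned with the matrix
        return x0 + (x1 - x0) * depth[id(clade)] / span

    # spanning subtree of the selection
    highlighted: set[int] = set()
    if selected_ids:
        leaf_clades = [tree.find(lbl) for lbl in sorted(selected_ids)]
        if len(leaf_clades) == 1:
            mrca = leaf_clades[0]
        else:
            mrca = tree.tree.common_ancestor(leaf_clades)
        for leaf in leaf_clades:
            if leaf is mrca:
                continue
            for clade in mrca.get_path(leaf):
                highlighted.add(id(clade))

    y_of: dict[int, float] = {}

    def assign_y(clade) -> float:
        if not clade.clades:
            y = row_y[clade.name]
        else:
            ys = [assign_y(c) for c in _ordered_children(clade)]
            y = (min(ys) + max(ys)) / 2.0
        y_of[id(clade)] = y
        return y

    assign_y(tree.root)

    grp = ET.Element("g", {"id": "tree", "fill": "none"})

    def draw(clade) -> None:
        cx, cy = x_of(clade), y_of[id(clade)]
        for child in _ordered_children(clade):
            hx, hy = x_of(child), y_of[id(child)]
            hl = id(child) in highlighted
            color = scheme.highlight_color if hl else "#333333"
            width = "2" if hl else "1"
            # vertical connector at the parent x, then horizontal run
            ET.SubElement(grp, "path", {
                "d": f"M {_fmt(cx)},{_fmt(cy)} V {_fmt(hy)} H {_fmt(hx)}",
                "stroke": color,
                "stroke-width": width,
            })
            draw(child)

    draw(tree.root)
    for lbl in order:
        if lbl in selected_ids:
            ET.SubElement(grp, "circle", {
                "cx": _fmt(x1),
                "cy": _fmt(row_y[lbl]),
                "r": "3",
                "fill": scheme.highlight_color,
                "stroke": "none",
            })
    return grp, order


# ---------------------------------------------------------------------------
# Main renderer


def _tooltip(parent: ET.Element, title: str, desc: str) -> None:
    t = ET.SubElement(parent, "title")
    t.text = title
    d = ET.SubElement(parent, "desc")
    d.text = desc


def _consensus_edges(consensus: Optional[Sequence[str]]) -> set[tuple[str, str]]:
    if not consensus:
        return set()
    return set(zip(consensus, consensus[1:]))


def render_svg(
    g: POAGraph,
    layout: Layout,
    aln: Alignment,
    tree: Optional[PhyloTree] = None,
    selection: Optional[SelectionState] = None,
    scheme: Optional[ColorScheme] = None,
    opts: Optional[RenderOptions] = None,
    consensus: Optional[Sequence[str]] = None,
) -> str:
    """Render the panels into one standalone SVG document string.

    ``consensus`` is an optional node-id chain; its nodes and connecting
    links are outlined in the highlight color.
    """
    opts = (opts or RenderOptions()).validate()
    selection = selection or SelectionState()
    scheme = scheme or scheme_for_graph(g)
    for nid in layout.placements:
        if nid not in g.nodes:
            raise PoaSankeyError(f"layout references unknown node {nid!r}")
    if tree is not None and "tree" in opts.panels:
        check_tree_alignment(tree, aln)

    lo, hi = layout.column_range
    cfg = layout.config
    has_tree = tree is not None and "tree" in opts.panels
    has_matrix = "matrix" in opts.panels
    has_sankey = "sankey" in opts.panels

    label_w = (max(len(s) for s in aln.ids) * CHAR_WIDTH + 2 * LABEL_PAD) if has_matrix else 0.0
    left = MARGIN + (TREE_WIDTH if has_tree else 0.0) + label_w
    header_h = (FONT_SIZE + 8.0) if opts.show_column_numbers else 0.0

    y_cursor = MARGIN + header_h
    sankey_y0 = y_cursor
    if has_sankey:
        y_cursor += cfg.canvas_height + PANEL_GAP
    matrix_y0 = y_cursor
    if has_matrix:
        y_cursor += aln.n_sequences * ROW_HEIGHT
    total_w = left + cfg.canvas_width + MARGIN
    total_h = y_cursor + MARGIN

    svg = ET.Element("svg", {
        "xmlns": "http://www.w3.org/2000/svg",
        "version": "1.1",
        "width": _fmt(total_w),
        "height": _fmt(total_h),
        "viewBox": f"0 0 {_fmt(total_w)} {_fmt(total_h)}",
        "font-family": "monospace",
        "font-size": _fmt(FONT_SIZE),
    })
    ET.SubElement(svg, "rect", {
        "x": "0", "y": "0",
        "width": _fmt(total_w), "height": _fmt(total_h),
        "fill": "#ffffff",
    })

    col_left_x = {c: left + x for c, x in layout.column_x.items()}

    if opts.show_column_numbers:
        hdr = ET.SubElement(svg, "g", {"id": "column-header", "fill": "#333333"})
        for c in range(lo, hi + 1):
            label = (
                opts.column_label_map.get(c, str(c + 1))
                if opts.column_label_map
                else str(c + 1)
            )
            ET.SubElement(hdr, "text", {
                "x": _fmt(col_left_x[c] + cfg.node_width / 2),
                "y": _fmt(MARGIN + FONT_SIZE),
                "text-anchor": "middle",
            }).text = label

    if opts.show_column_separators:
        sep = ET.SubElement(svg, "g", {
            "id": "column-separators",
            "stroke": "#dddddd",
            "stroke-width": "1",
        })
        for c in range(lo, hi):
            x = (col_left_x[c] + cfg.node_width + col_left_x[c + 1]) / 2.0
            ET.SubElement(sep, "line", {
                "x1": _fmt(x), "y1": _fmt(sankey_y0),
                "x2": _fmt(x), "y2": _fmt(total_h - MARGIN),
            })

    cons_nodes = set(consensus or ())
    cons_edges = _consensus_edges(consensus)
    sel_active = bool(selection.selected)

    if has_sankey:
        sankey = ET.SubElement(svg, "g", {"id": "sankey"})
        band_bottom = sankey_y0 + max(
            (p.bottom for p in layout.placements.values()), default=0.0
        )
        for link in z_order(layout.links):
            base_color = scheme.color_for(g.nodes[link.src].symbol)
            for sub in link.sublinks:
                shifted = sublink_path(
                    _offset_link(link, left, sankey_y0), sub,
                    band_bottom=band_bottom,
                )
                attrs = {"d": shifted.d, "stroke": "none"}
                if sub.selected:
                    attrs["fill"] = scheme.highlight_color
                    attrs["fill-opacity"] = "0.85"
                else:
                    attrs["fill"] = base_color
                    attrs["fill-opacity"] = (
                        _fmt(scheme.dim_opacity) if sel_active else "0.55"
                    )
                path = ET.SubElement(sankey, "path", attrs)
                if (link.src, link.dst) in cons_edges:
                    path.set("stroke", scheme.highlight_color)
                    path.set("stroke-width", "1.5")
                if opts.tooltip:
                    ids = ", ".join(g.ids[i] for i in sorted(sub.members))
                    _tooltip(
                        path,
                        f"{link.src} → {link.dst}",
                        f"link {link.src} → {link.dst}; sequences: {ids}",
                    )
        for nid in sorted(layout.placements):
            p = layout.placements[nid]
            node = g.nodes[nid]
            attrs = {
                "x": _fmt(left + p.x),
                "y": _fmt(sankey_y0 + p.y),
                "width": _fmt(p.width),
                "height": _fmt(p.height),
                "fill": scheme.color_for(node.symbol),
            }
            if nid in cons_nodes:
                attrs["stroke"] = scheme.highlight_color
                attrs["stroke-width"] = "2"
            rect = ET.SubElement(sankey, "rect", attrs)
            if opts.tooltip:
                ids = ", ".join(g.ids[i] for i in sorted(node.members))
                _tooltip(
                    rect,
                    f"column {node.column + 1}: {node.symbol}",
                    f"column {node.column + 1}, symbol {node.symbol}, "
                    f"sequences: {ids}",
                )

    row_order = list(aln.ids)
    if has_tree:
        row_order = tree_leaf_order(tree)  # type: ignore[arg-type]

    if has_matrix:
        row_y = {
            sid: matrix_y0 + i * ROW_HEIGHT + ROW_HEIGHT / 2.0
            for i, sid in enumerate(row_order)
        }
        matrix = ET.SubElement(svg, "g", {"id": "matrix"})
        row_index = {sid: i for i, sid in enumerate(aln.ids)}
        for sid in row_order:
            seq = row_index[sid]
            row = aln.rows[seq]
            y = row_y[sid] - ROW_HEIGHT / 2.0
            is_sel = seq in selection.selected
            label = ET.SubElement(matrix, "text", {
                "x": _fmt(left - LABEL_PAD),
                "y": _fmt(row_y[sid] + FONT_SIZE * 0.35),
                "text-anchor": "end",
                "fill": scheme.highlight_color if is_sel else "#333333",
                "font-weight": "bold" if is_sel else "normal",
            })
            label.text = sid
            for c in range(lo, hi + 1):
                sym = row[c]
                cell = ET.SubElement(matrix, "rect", {
                    "x": _fmt(col_left_x[c]),
                    "y": _fmt(y + 1),
                    "width": _fmt(cfg.node_width),
                    "height": _fmt(ROW_HEIGHT - 2),
                    "fill": scheme.color_for(sym),
                })
                if sel_active and not is_sel:
                    cell.set("fill-opacity", _fmt(scheme.dim_opacity))
                if cfg.node_width >= CHAR_WIDTH + 2:
                    txt = ET.SubElement(matrix, "text", {
                        "x": _fmt(col_left_x[c] + cfg.node_width / 2),
                        "y": _fmt(row_y[sid] + FONT_SIZE * 0.35),
                        "text-anchor": "middle",
                        "fill": "#222222",
                    })
                    txt.text = sym

        if has_tree:
            tree_grp, _ = render_tree_panel(
                tree, aln, selection, row_y, scheme,  # type: ignore[arg-type]
                x0=MARGIN * 2,
                x1=MARGIN + TREE_WIDTH - LABEL_PAD,
            )
            svg.append(tree_grp)

    return ET.tostring(svg, encoding="unicode", xml_declaration=False)


def _offset_link(link: LinkGeometry, dx: float, dy: float) -> LinkGeometry:
    from dataclasses import replace

    from .layout import Anchor

    return replace(
        link,
        source=Anchor(link.source.x + dx, link.source.y + dy, link.source.thickness),
        target=Anchor(link.target.x + dx, link.target.y + dy, link.target.thickness),
    )


_HTML_TEMPLATE = """<!DOCTYPE html>
<html>
<head><meta charset="utf-8"><title>{title}</title></head>
<body style="margin:0">
{svg}
</body>
</html>
"""


def wrap_html(svg_text: str, title: str = "POA Sankey view") -> str:
    """Embed the SVG unchanged in a minimal single-file HTML page."""
    return _HTML_TEMPLATE.format(title=title, svg=svg_text)
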