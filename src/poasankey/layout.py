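"""Deterministic Sankey geometry for a column range of a POA graph.

Columns are placed left to right with exactly uniform spacing; within a
column, node heights are proportional to member count (``flow_unit``
canvas units per member sequence) and vertical order comes from a two-pass
barycenter sweep.  Links are ribbons whose thickness is proportional to
edge member count; at every node side the attached ribbons tile the node
height without overlap, so flow is conserved visually as well as
numerically.

Besides the ordinary forward ribbon the engine can draw feedback arcs
(target column left of source) and reversing joins (two left or two right
sides), which general Sankey inputs need even though POA graphs, being
DAGs, never produce them.

All coordinates are abstract canvas units with the origin at the top left
and y growing downward, matching SVG.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .errors import LayoutRangeError
from .poa_graph import POAEdge, POAGraph, POANode
from .selection import SelectionState

Point = tuple[float, float]
Cubic = tuple[Point, Point, Point, Point]


@dataclass(frozen=True)
class LayoutConfig:
    """Layout parameters, in abstract canvas units.

    ``flow_unit`` (height per member sequence) is auto-scaled when unset so
    the tallest in-range column exactly fits ``canvas_height``.
    ``y_overrides`` maps node_id → vertical offset added after automatic
    placement (manual position adjustment).
    """

    canvas_width: float = 960.0
    canvas_height: float = 540.0
    node_width: float = 14.0
    min_node_gap: float = 8.0
    column_range: Optional[tuple[int, int]] = None
    flow_unit: Optional[float] = None
    y_overrides: dict[str, float] = field(default_factory=dict)

    def validate(self) -> "LayoutConfig":
        if self.canvas_width <= 0 or self.canvas_height <= 0:
            raise LayoutRangeError("canvas dimensions must be positive")
        if self.node_width <= 0:
            raise LayoutRangeError("node_width must be positive")
        if self.min_node_gap < 0:
            raise LayoutRangeError("min_node_gap must be non-negative")
        return self


@dataclass(frozen=True)
class NodePlacement:
    node_id: str
    x: float
    y: float
    width: float
    height: float

    @property
    def y_center(self) -> float:
        return self.y + self.height / 2.0

    @property
    def bottom(self) -> float:
        return self.y + self.height


@dataclass(frozen=True)
class Anchor:
    x: float
    y: float  # top of the ribbon at this side
    thickness: float


@dataclass(frozen=True)
class SubLink:
    members: frozenset[int]
    offset: float  # vertical offset from the parent ribbon top, both sides
    thickness: float
    selected: bool = False


@dataclass(frozen=True)
class LinkGeometry:
    src: str
    dst: str
    members: frozenset[int]
    shape: str  # forward | feedback | reverse_left | reverse_right
    source: Anchor
    target: Anchor
    span: int  # |column(dst) - column(src)|
    stub: Optional[str] = None  # None, "left" (from outside range), "right"
    sublinks: tuple[SubLink, ...] = ()

    @property
    def thickness(self) -> float:
        return self.source.thickness


@dataclass(frozen=True)
class Layout:
    placements: dict[str, NodePlacement]
    links: tuple[LinkGeometry, ...]
    column_x: dict[int, float]
    column_range: tuple[int, int]
    flow_unit: float
    config: LayoutConfig

    def to_json(self) -> str:
        doc = {
            "column_range": list(self.column_range),
            "flow_unit": self.flow_unit,
            "column_x": {str(c): x for c, x in sorted(self.column_x.items())},
            "placements": [
                {
                    "id": p.node_id,
                    "x": p.x,
                    "y": p.y,
                    "width": p.width,
                    "height": p.height,
                }
                for p in sorted(self.placements.values(), key=lambda p: p.node_id)
            ],
            "links": [
                {
                    "src": l.src,
                    "dst": l.dst,
                    "members": sorted(l.members),
                    "shape": l.shape,
                    "stub": l.stub,
                    "source": [l.source.x, l.source.y, l.source.thickness],
                    "target": [l.target.x, l.target.y, l.target.thickness],
                    "sublinks": [
                        {
                            "members": sorted(s.members),
                            "offset": s.offset,
                            "thickness": s.thickness,
                            "selected": s.selected,
                        }
                        for s in l.sublinks
                    ],
                }
                for l in self.links
            ],
        }
        return json.dumps(doc, indent=2)


# ---------------------------------------------------------------------------
# Node placement


def _stack_column(
    nodes: Sequence[POANode],
    order: Sequence[str],
    x: float,
    fu: float,
    cfg: LayoutConfig,
) -> dict[str, NodePlacement]:
    """Stack a column's nodes top to bottom in the given id order,
    separated by min_node_gap and vertically centered as a block."""
    by_id = {n.node_id: n for n in nodes}
    heights = {nid: len(by_id[nid].members) * fu for nid in order}
    block = sum(heights.values()) + cfg.min_node_gap * max(0, len(order) - 1)
    y = (cfg.canvas_height - block) / 2.0
    out: dict[str, NodePlacement] = {}
    for nid in order:
        out[nid] = NodePlacement(nid, x, y, cfg.node_width, heights[nid])
        y += heights[nid] + cfg.min_node_gap
    return out


def compute_layout(g: POAGraph, cfg: Optional[LayoutConfig] = None) -> Layout:
    """Place nodes and route links for the configured column range.

    Node order within a column: initial order by descending member count
    (ties by symbol), refined by one left-to-right pass sorting by the mean
    y-center of in-range predecessors and one right-to-left pass by
    successors.  Edges with exactly one endpoint in range become boundary
    stubs; edges fully outside are dropped.
    """
    cfg = (cfg or LayoutConfig()).validate()
    if g.n_columns == 0 or not g.nodes:
        raise LayoutRangeError("cannot lay out an empty graph")
    lo, hi = cfg.column_range if cfg.column_range is not None else (0, g.n_columns - 1)
    if not (0 <= lo <= hi < g.n_columns):
        raise LayoutRangeError(
            f"column range {lo}..{hi} outside graph columns 0..{g.n_columns - 1}"
        )

    all_columns = g.columns()
    columns = {c: all_columns[c] for c in range(lo, hi + 1)}

    # uniform x spacing
    k = hi - lo + 1
    usable = cfg.canvas_width - cfg.node_width
    if k > 1:
        # quantize to 2^-20 canvas units so integer multiples (and hence all
        # consecutive column gaps) are exact in binary floating point
        spacing = round(usable / (k - 1) * 1048576) / 1048576
        column_x = {c: spacing * (c - lo) for c in range(lo, hi + 1)}
    else:
        column_x = {lo: usable / 2.0}

    # flow unit: tallest column fits the canvas exactly
    if cfg.flow_unit is not None:
        fu = cfg.flow_unit
        if fu <= 0:
            raise LayoutRangeError("flow_unit must be positive")
    else:
        fu = float("inf")
        for c, nodes in columns.items():
            if not nodes:
                continue
            total = sum(len(n.members) for n in nodes)
            avail = cfg.canvas_height - cfg.min_node_gap * (len(nodes) - 1)
            if avail <= 0:
                raise LayoutRangeError(
                    f"canvas too small for {len(nodes)} nodes in column {c}"
                )
            fu = min(fu, avail / total)
        if fu == float("inf"):
            raise LayoutRangeError("column range contains no nodes")
        # snap to a dyadic value (multiple of 2^-20) so every thickness
        # len(members) * fu is exact and flow sums conserve bit-for-bit
        quantized = int(fu * 1048576) / 1048576
        if quantized > 0:
            fu = quantized

    # initial order: descending member count, ties by symbol (g.columns())
    orders: dict[int, list[str]] = {
        c: [n.node_id for n in nodes] for c, nodes in columns.items()
    }
    placements: dict[str, NodePlacement] = {}
    for c in range(lo, hi + 1):
        placements.update(_stack_column(columns[c], orders[c], column_x[c], fu, cfg))

    in_range = set(placements)
    preds: dict[str, list[tuple[str, int]]] = {nid: [] for nid in in_range}
    succs: dict[str, list[tuple[str, int]]] = {nid: [] for nid in in_range}
    for e in g.edges.values():
        if e.src in in_range and e.dst in in_range:
            preds[e.dst].append((e.src, len(e.members)))
            succs[e.src].append((e.dst, len(e.members)))

    def barycenter_pass(neighbor_map: dict[str, list[tuple[str, int]]],
                        col_sequence: Sequence[int]) -> None:
        for c in col_sequence:
            nodes = columns[c]
            if len(nodes) < 2:
                continue

            def key(nid: str) -> float:
                nbrs = neighbor_map[nid]
                if not nbrs:
                    return placements[nid].y_center
                w = sum(cnt for _, cnt in nbrs)
                return sum(placements[n].y_center * cnt for n, cnt in nbrs) / w

            orders[c] = sorted(orders[c], key=lambda nid: (key(nid), nid))
            placements.update(_stack_column(nodes, orders[c], column_x[c], fu, cfg))

    barycenter_pass(preds, range(lo, hi + 1))
    barycenter_pass(succs, range(hi, lo - 1, -1))

    # manual vertical adjustment, applied last
    for nid, dy in cfg.y_overrides.items():
        if nid in placements:
            p = placements[nid]
            placements[nid] = replace(p, y=p.y + float(dy))

    links = _route_links(g, placements, column_x, lo, hi, fu, cfg)
    return Layout(
        placements=placements,
        links=links,
        column_x=column_x,
        column_range=(lo, hi),
        flow_unit=fu,
        config=cfg,
    )


def _route_links(
    g: POAGraph,
    placements: dict[str, NodePlacement],
    column_x: dict[int, float],
    lo: int,
    hi: int,
    fu: float,
    cfg: LayoutConfig,
) -> tuple[LinkGeometry, ...]:
    in_range = set(placements)
    kept: list[tuple[POAEdge, Optional[str]]] = []  # (edge, stub side)
    for key in sorted(g.edges):
        e = g.edges[key]
        s_in, d_in = e.src in in_range, e.dst in in_range
        if s_in and d_in:
            kept.append((e, None))
        elif s_in and not d_in:
            kept.append((e, "right"))  # leaves the range to the right
        elif d_in and not s_in:
            kept.append((e, "left"))  # enters the range from the left
    # stack outgoing ribbons on each node's right side (and incoming on the
    # left side) ordered by the far end's y-center for low crossing counts
    out_by_node: dict[str, list[tuple[POAEdge, Optional[str]]]] = {}
    in_by_node: dict[str, list[tuple[POAEdge, Optional[str]]]] = {}
    for e, stub in kept:
        if stub != "left":
            out_by_node.setdefault(e.src, []).append((e, stub))
        if stub != "right":
            in_by_node.setdefault(e.dst, []).append((e, stub))

    def far_key(item: tuple[POAEdge, Optional[str]], side: str) -> tuple:
        e, stub = item
        if side == "out":
            if stub == "right":
                return (placements[e.src].y_center, 1, e.dst)
            return (placements[e.dst].y_center, 0, e.dst)
        if stub == "left":
            return (placements[e.dst].y_center, 1, e.src)
        return (placements[e.src].y_center, 0, e.src)

    src_offset: dict[tuple[str, str], float] = {}
    dst_offset: dict[tuple[str, str], float] = {}
    for nid, items in out_by_node.items():
        items.sort(key=lambda it: far_key(it, "out"))
        off = 0.0
        for e, _ in items:
            src_offset[(e.src, e.dst)] = off
            off += len(e.members) * fu
    for nid, items in in_by_node.items():
        items.sort(key=lambda it: far_key(it, "in"))
        off = 0.0
        for e, _ in items:
            dst_offset[(e.src, e.dst)] = off
            off += len(e.members) * fu

    left_edge_x = column_x[lo]
    right_edge_x = column_x[hi] + cfg.node_width
    links: list[LinkGeometry] = []
    for e, stub in kept:
        thick = len(e.members) * fu
        if stub != "left":
            sp = placements[e.src]
            source = Anchor(sp.x + sp.width, sp.y + src_offset[(e.src, e.dst)], thick)
        if stub != "right":
            tp = placements[e.dst]
            target = Anchor(tp.x, tp.y + dst_offset[(e.src, e.dst)], thick)
        if stub == "right":
            target = Anchor(right_edge_x, source.y, thick)
        elif stub == "left":
            source = Anchor(left_edge_x, target.y, thick)
        src_col = g.nodes[e.src].column
        dst_col = g.nodes[e.dst].column
        shape = "forward" if dst_col > src_col else "feedback"
        links.append(
            LinkGeometry(
                src=e.src,
                dst=e.dst,
                members=e.members,
                shape=shape,
                source=source,
                target=target,
                span=abs(dst_col - src_col),
                stub=stub,
                sublinks=(SubLink(e.members, 0.0, thick, False),),
            )
        )
    return tuple(links)


# ---------------------------------------------------------------------------
# Link curves


@dataclass(frozen=True)
class LinkPath:
    """Drawable ribbon outline: an SVG path string plus the two boundary
    curves (top and bottom) as cubic Bezier chains, for geometric tests."""

    d: str
    top: tuple[Cubic, ...]
    bottom: tuple[Cubic, ...]

    def sample(self, boundary: str = "top", per_segment: int = 64) -> list[Point]:
        curves = self.top if boundary == "top" else self.bottom
        pts: list[Point] = []
        for p0, p1, p2, p3 in curves:
            for i in range(per_segment + 1):
                t = i / per_segment
                mt = 1 - t
                x = (
                    mt**3 * p0[0] + 3 * mt**2 * t * p1[0]
                    + 3 * mt * t**2 * p2[0] + t**3 * p3[0]
                )
                y = (
                    mt**3 * p0[1] + 3 * mt**2 * t * p1[1]
                    + 3 * mt * t**2 * p2[1] + t**3 * p3[1]
                )
                pts.append((x, y))
        return pts


def _cubic(p0: Point, p3: Point, horizontal: bool = True) -> Cubic:
    """S-shaped cubic with horizontal tangents at both ends."""
    if horizontal:
        mx = (p0[0] + p3[0]) / 2.0
        return (p0, (mx, p0[1]), (mx, p3[1]), p3)
    my = (p0[1] + p3[1]) / 2.0
    return (p0, (p0[0], my), (p3[0], my), p3)


def _line(p0: Point, p3: Point) -> Cubic:
    third = ((p3[0] - p0[0]) / 3.0, (p3[1] - p0[1]) / 3.0)
    return (
        p0,
        (p0[0] + third[0], p0[1] + third[1]),
        (p0[0] + 2 * third[0], p0[1] + 2 * third[1]),
        p3,
    )


def _chain_to_d(top: Sequence[Cubic], bottom: Sequence[Cubic]) -> str:
    def fmt(p: Point) -> str:
        return f"{p[0]:.3f},{p[1]:.3f}"

    parts = [f"M {fmt(top[0][0])}"]
    for _, p1, p2, p3 in top:
        parts.append(f"C {fmt(p1)} {fmt(p2)} {fmt(p3)}")
    parts.append(f"L {fmt(bottom[-1][3])}")
    for p0, p1, p2, p3 in reversed(bottom):
        parts.append(f"C {fmt(p2)} {fmt(p1)} {fmt(p0)}")
    parts.append("Z")
    return " ".join(parts)


def link_path(link: LinkGeometry, band_bottom: Optional[float] = None,
              clearance: float = 24.0) -> LinkPath:
    """Build the drawable outline of a link.

    Forward links are cubic ribbons from the right side of the source to
    the left side of the target.  Feedback links (target placed left of
    source) loop below ``band_bottom`` (the lowest node bottom the ribbon
    must clear) plus ``clearance``.  Reversing joins connect two same-side
    anchors with a loop on that side.
    """
    s, t = link.source, link.target
    st, tt = s.thickness, t.thickness
    if link.shape == "forward":
        top = (_cubic((s.x, s.y), (t.x, t.y)),)
        bottom = (_cubic((s.x, s.y + st), (t.x, t.y + tt)),)
    elif link.shape == "feedback":
        lane = (band_bottom if band_bottom is not None else max(s.y + st, t.y + tt)) + clearance
        ext = clearance
        top = (
            _line((s.x, s.y), (s.x + ext, s.y)),
            _cubic((s.x + ext, s.y), (s.x + ext + ext, lane), horizontal=False),
            _line((s.x + ext + ext, lane), (t.x - 2 * ext, lane)),
            _cubic((t.x - 2 * ext, lane), (t.x - ext, t.y), horizontal=False),
            _line((t.x - ext, t.y), (t.x, t.y)),
        )
        lane_b = lane + max(st, tt)
        bottom = (
            _line((s.x, s.y + st), (s.x + ext, s.y + st)),
            _cubic((s.x + ext, s.y + st), (s.x + ext + ext, lane_b), horizontal=False),
            _line((s.x + ext + ext, lane_b), (t.x - 2 * ext, lane_b)),
            _cubic((t.x - 2 * ext, lane_b), (t.x - ext, t.y + tt), horizontal=False),
            _line((t.x - ext, t.y + tt), (t.x, t.y + tt)),
        )
    elif link.shape in ("reverse_left", "reverse_right"):
        sign = -1.0 if link.shape == "reverse_left" else 1.0
        apex = (min(s.x, t.x) - clearance) if sign < 0 else (max(s.x, t.x) + clearance)
        top = (
            _line((s.x, s.y), (apex, s.y)),
            _line((apex, s.y), (apex, t.y)),
            _line((apex, t.y), (t.x, t.y)),
        )
        apex_b = apex + sign * max(st, tt)
        bottom = (
            _line((s.x, s.y + st), (apex_b, s.y + st)),
            _line((apex_b, s.y + st), (apex_b, t.y + tt)),
            _line((apex_b, t.y + tt), (t.x, t.y + tt)),
        )
    else:
        raise ValueError(f"unknown link shape {link.shape!r}")
    return LinkPath(d=_chain_to_d(top, bottom), top=top, bottom=bottom)


def sublink_path(link: LinkGeometry, sub: SubLink, band_bottom: Optional[float] = None) -> LinkPath:
    """Outline of one sublink strip: the parent shape shifted by its offset."""
    shifted = replace(
        link,
        source=Anchor(link.source.x, link.source.y + sub.offset, sub.thickness),
        target=Anchor(link.target.x, link.target.y + sub.offset, sub.thickness),
    )
    return link_path(shifted, band_bottom=band_bottom)


def z_order(links: Sequence[LinkGeometry]) -> list[LinkGeometry]:
    """Drawing order: longest column span first (underneath), then thicker
    first; stable for equal keys."""
    return sorted(links, key=lambda l: (-l.span, -l.thickness))


def nest_by_selection(layout: Layout, selection: SelectionState) -> Layout:
    """Split every link into ≤ 2 stacked sublinks: the selected fraction
    first, then the unselected remainder; empty fractions are omitted.
    Sublink thicknesses are exact count fractions of the parent."""
    sel = selection.selected
    fu = layout.flow_unit
    new_links = []
    for l in layout.links:
        parts = [
            (part, flag)
            for part, flag in ((l.members & sel, True), (l.members - sel, False))
            if part
        ]
        subs: list[SubLink] = []
        off = 0.0
        for part, flag in parts:
            # count * flow_unit: exact because the auto-scaled flow unit is
            # dyadic, so strip thicknesses sum bit-for-bit to the parent
            th = len(part) * fu
            subs.append(SubLink(frozenset(part), off, th, flag and bool(sel)))
            off += th
        new_links.append(replace(l, sublinks=tuple(subs)))
    return replace(layout, links=tuple(new_links))
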