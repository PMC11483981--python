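"""Partial order alignment graphs.

A POA graph is the column-partitioned DAG view of a gapped alignment:
each alignment column is a cluster of nodes, identical residues within a
column collapse into one node, and each sequence traces a path through the
graph.  Edges connect consecutive non-gap positions of a sequence; when a
sequence has gaps between two residues, the edge spans several columns
("long link").  Flow is unweighted sequence count: the number of member
sequences of a node or edge.

This module builds the graph from an :class:`~poasankey.msa_io.Alignment`,
inverts the construction (used as a structural self-check), simplifies a
protein graph by physicochemical residue classes, and extracts a consensus
path by heaviest-edge dynamic programming.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Optional

from .errors import GraphIntegrityError, LookupErrorPoa
from .msa_io import GAP, Alignment


def node_id(column: int, symbol: str) -> str:
    """Stable node identifier: ``"<column>/<symbol>"`` (0-based column)."""
    return f"{column}/{symbol}"


@dataclass(frozen=True)
class POANode:
    node_id: str
    column: int
    symbol: str
    members: frozenset[int]


@dataclass(frozen=True)
class POAEdge:
    src: str
    dst: str
    members: frozenset[int]


@dataclass(frozen=True)
class POAGraph:
    """Column-partitioned DAG over alignment columns.

    ``nodes`` maps node_id → :class:`POANode`; ``edges`` maps
    (src_id, dst_id) → :class:`POAEdge`.  ``ids`` is the alignment's
    identifier list; sequence indices refer into it.
    """

    n_columns: int
    n_sequences: int
    ids: tuple[str, ...]
    alphabet: str
    nodes: dict[str, POANode]
    edges: dict[tuple[str, str], POAEdge]

    # -- derived lookups -------------------------------------------------

    def node(self, nid: str) -> POANode:
        try:
            return self.nodes[nid]
        except KeyError:
            raise LookupErrorPoa(f"unknown node id {nid!r}") from None

    def columns(self) -> list[list[POANode]]:
        """Nodes grouped by column, each group sorted by (−members, symbol)."""
        cols: list[list[POANode]] = [[] for _ in range(self.n_columns)]
        for n in self.nodes.values():
            cols[n.column].append(n)
        for group in cols:
            group.sort(key=lambda n: (-len(n.members), n.symbol))
        return cols

    def out_edges(self, nid: str) -> list[POAEdge]:
        return [e for (s, _), e in self.edges.items() if s == nid]

    def in_edges(self, nid: str) -> list[POAEdge]:
        return [e for (_, d), e in self.edges.items() if d == nid]

    def sequence_path(self, seq: int) -> list[str]:
        """Node ids visited by one sequence, in column order."""
        path = [n.node_id for n in sorted(self.nodes.values(), key=lambda n: n.column)
                if seq in n.members]
        return path

    # -- serialization ---------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "n_columns": self.n_columns,
            "n_sequences": self.n_sequences,
            "ids": list(self.ids),
            "alphabet": self.alphabet,
            "nodes": [
                {
                    "id": n.node_id,
                    "column": n.column,
                    "symbol": n.symbol,
                    "members": sorted(n.members),
                }
                for n in sorted(self.nodes.values(), key=lambda n: (n.column, n.symbol))
            ],
            "edges": [
                {"src": e.src, "dst": e.dst, "members": sorted(e.members)}
                for e in sorted(self.edges.values(), key=lambda e: (e.src, e.dst))
            ],
        }
        return json.dumps(doc, indent=2)

    @staticmethod
    def from_json(text: str) -> "POAGraph":
        doc = json.loads(text)
        nodes = {
            n["id"]: POANode(n["id"], n["column"], n["symbol"], frozenset(n["members"]))
            for n in doc["nodes"]
        }
        edges = {
            (e["src"], e["dst"]): POAEdge(e["src"], e["dst"], frozenset(e["members"]))
            for e in doc["edges"]
        }
        return POAGraph(
            n_columns=doc["n_columns"],
            n_sequences=doc["n_sequences"],
            ids=tuple(doc["ids"]),
            alphabet=doc["alphabet"],
            nodes=nodes,
            edges=edges,
        )


def build_poa(aln: Alignment) -> POAGraph:
    """Build the POA graph of an alignment.

    One node per (column, distinct non-gap symbol); one edge per ordered
    pair of consecutive non-gap positions of a sequence, with parallel
    per-sequence edges between the same node pair merged (member sets
    unioned).  Gap stretches produce edges spanning more than one column.
    """
    node_members: dict[tuple[int, str], set[int]] = {}
    edge_members: dict[tuple[str, str], set[int]] = {}
    for seq, row in enumerate(aln.rows):
        prev: Optional[tuple[int, str]] = None
        for col, sym in enumerate(row):
            if sym == GAP:
                continue
            node_members.setdefault((col, sym), set()).add(seq)
            if prev is not None:
                key = (node_id(*prev), node_id(col, sym))
                edge_members.setdefault(key, set()).add(seq)
            prev = (col, sym)
    nodes = {
        node_id(c, s): POANode(node_id(c, s), c, s, frozenset(m))
        for (c, s), m in node_members.items()
    }
    edges = {
        key: POAEdge(key[0], key[1], frozenset(m)) for key, m in edge_members.items()
    }
    return POAGraph(
        n_columns=aln.n_columns,
        n_sequences=aln.n_sequences,
        ids=aln.ids,
        alphabet=aln.alphabet,
        nodes=nodes,
        edges=edges,
    )


def reconstruct_alignment(g: POAGraph) -> Alignment:
    """Invert :func:`build_poa`.

    Emits, for each sequence, the node symbol at every column whose node
    contains the sequence and ``-`` elsewhere.  Verifies that each
    sequence's nodes form a connected edge path; a broken path raises
    :class:`GraphIntegrityError`.
    """
    rows = []
    for seq in range(g.n_sequences):
        visited = sorted(
            (n for n in g.nodes.values() if seq in n.members), key=lambda n: n.column
        )
        if not visited:
            raise GraphIntegrityError(f"sequence {seq} appears in no node")
        for a, b in zip(visited, visited[1:]):
            edge = g.edges.get((a.node_id, b.node_id))
            if edge is None or seq not in edge.members:
                raise GraphIntegrityError(
                    f"sequence {seq} has no edge {a.node_id} -> {b.node_id}"
                )
        row = [GAP] * g.n_columns
        for n in visited:
            row[n.column] = n.symbol
        rows.append("".join(row))
    return Alignment(
        ids=g.ids, rows=tuple(rows), n_columns=g.n_columns, alphabet=g.alphabet
    ).validate()


# ---------------------------------------------------------------------------
# Residue grouping


@dataclass(frozen=True)
class ResidueGrouping:
    """Mapping from residue symbol to physicochemical group label.

    Symbols absent from the mapping fall into group ``"other"``.
    """

    mapping: Mapping[str, str]
    name: str = "custom"

    OTHER = "other"

    def group_of(self, symbol: str) -> str:
        # group labels are fixed points, making simplification idempotent
        if symbol == self.OTHER or symbol in self.mapping.values():
            return symbol
        return self.mapping.get(symbol, self.OTHER)

    def labels(self) -> list[str]:
        seen: list[str] = []
        for lbl in self.mapping.values():
            if lbl not in seen:
                seen.append(lbl)
        if self.OTHER not in seen:
            seen.append(self.OTHER)
        return seen


_DEFAULT_GROUPS = {
    "electrically charged": "DEKRH",
    "polar uncharged": "STNQY",
    "hydrophobic": "AVLIMFW",
    "special": "CGP",
}


def default_grouping() -> ResidueGrouping:
    """The four-class physicochemical scheme used to simplify protein graphs.

    Electrically charged {D,E,K,R,H}; polar uncharged {S,T,N,Q,Y};
    hydrophobic {A,V,L,I,M,F,W}; special {C,G,P}.  Ambiguity codes and any
    other symbol map to ``other``.  Fully overridable by the user.
    """
    mapping = {
        aa: label for label, residues in _DEFAULT_GROUPS.items() for aa in residues
    }
    return ResidueGrouping(mapping=mapping, name="physicochemical-4")


def identity_grouping(symbols: Iterable[str]) -> ResidueGrouping:
    """Each symbol is its own group — simplification becomes a no-op."""
    return ResidueGrouping(mapping={s: s for s in symbols}, name="identity")


def grouping_from_dict(doc: Mapping[str, Iterable[str]], name: str = "custom") -> ResidueGrouping:
    """Build a grouping from ``{group label: [residues...]}``."""
    mapping: dict[str, str] = {}
    for label, residues in doc.items():
        for sym in residues:
            mapping[str(sym).upper()] = label
    return ResidueGrouping(mapping=mapping, name=name)


def simplify_poa(g: POAGraph, grouping: Optional[ResidueGrouping] = None) -> POAGraph:
    """Merge, within each column, nodes whose symbols share a group label.

    Member sets are unioned; edges are re-derived between merged nodes with
    member sets unioned.  The result satisfies all POA graph invariants
    with group labels as symbols, and the operation is idempotent.
    """
    grouping = grouping or default_grouping()
    remap: dict[str, str] = {}
    node_members: dict[tuple[int, str], set[int]] = {}
    for n in g.nodes.values():
        label = grouping.group_of(n.symbol)
        new_id = node_id(n.column, label)
        remap[n.node_id] = new_id
        node_members.setdefault((n.column, label), set()).update(n.members)
    edge_members: dict[tuple[str, str], set[int]] = {}
    for e in g.edges.values():
        key = (remap[e.src], remap[e.dst])
        edge_members.setdefault(key, set()).update(e.members)
    nodes = {
        node_id(c, s): POANode(node_id(c, s), c, s, frozenset(m))
        for (c, s), m in node_members.items()
    }
    edges = {
        key: POAEdge(key[0], key[1], frozenset(m)) for key, m in edge_members.items()
    }
    return replace(g, nodes=nodes, edges=edges)


# ---------------------------------------------------------------------------
# Consensus


def _sequence_endpoints(g: POAGraph) -> tuple[dict[str, int], dict[str, int]]:
    """Per-node counts of sequences starting / ending there."""
    starts: dict[str, int] = {}
    ends: dict[str, int] = {}
    for seq in range(g.n_sequences):
        path = g.sequence_path(seq)
        starts[path[0]] = starts.get(path[0], 0) + 1
        ends[path[-1]] = ends.get(path[-1], 0) + 1
    return starts, ends


def consensus_path(g: POAGraph) -> list[str]:
    """Heaviest source-to-sink path through the graph, as a node-id list.

    A virtual start connects to every node at which at least one sequence
    starts (arc weight = number of sequences starting there), and likewise
    a virtual end from every node at which a sequence ends.  The path
    maximizes the summed edge member counts over a single forward dynamic
    programming pass in column order.  Ties are broken deterministically:
    prefer the predecessor with the larger node member count, then the
    lexicographically smaller symbol, then the smaller column.
    """
    if not g.nodes:
        raise GraphIntegrityError("empty graph has no consensus path")
    starts, ends = _sequence_endpoints(g)
    order = sorted(g.nodes.values(), key=lambda n: (n.column, n.symbol))
    incoming: dict[str, list[POAEdge]] = {nid: [] for nid in g.nodes}
    for e in g.edges.values():
        incoming[e.dst].append(e)

    NEG = float("-inf")
    best: dict[str, float] = {}
    back: dict[str, Optional[str]] = {}

    def pred_rank(nid: Optional[str]) -> tuple:
        # larger member count first, then symbol asc, then column asc;
        # the virtual start ranks last among equal scores
        if nid is None:
            return (0, "", -1)
        n = g.nodes[nid]
        return (len(n.members), "￿" if not n.symbol else n.symbol, -n.column)

    def better(score_a: float, pred_a: Optional[str], score_b: float, pred_b: Optional[str]) -> bool:
        """True if candidate a beats candidate b."""
        if score_a != score_b:
            return score_a > score_b
        ra, rb = pred_rank(pred_a), pred_rank(pred_b)
        if ra[0] != rb[0]:
            return ra[0] > rb[0]
        if ra[1] != rb[1]:
            return ra[1] < rb[1]
        return ra[2] > rb[2]

    for n in order:
        cand_score: float = NEG
        cand_pred: Optional[str] = None
        if n.node_id in starts:
            cand_score = float(starts[n.node_id])
            cand_pred = None
        for e in incoming[n.node_id]:
            s = best.get(e.src, NEG)
            if s == NEG:
                continue
            sc = s + len(e.members)
            if cand_score == NEG or better(sc, e.src, cand_score, cand_pred):
                cand_score = sc
                cand_pred = e.src
        if cand_score == NEG:
            continue  # unreachable from any sequence start
        best[n.node_id] = cand_score
        back[n.node_id] = cand_pred

    end_score: float = NEG
    end_node: Optional[str] = None
    for nid, cnt in ends.items():
        if nid not in best:
            continue
        sc = best[nid] + cnt
        if end_node is None or better(sc, nid, end_score, end_node):
            end_score = sc
            end_node = nid
    if end_node is None:
        raise GraphIntegrityError("no source-to-sink path found")
    path = [end_node]
    while back[path[-1]] is not None:
        path.append(back[path[-1]])  # type: ignore[arg-type]
    path.reverse()
    return path


def consensus_weight(g: POAGraph, path: list[str]) -> int:
    """Weight of a node-id path: summed edge members plus start/end counts."""
    starts, ends = _sequence_endpoints(g)
    w = starts.get(path[0], 0) + ends.get(path[-1], 0)
    for a, b in zip(path, path[1:]):
        w += len(g.edges[(a, b)].members)
    return w


def node_sequences(g: POAGraph, nid: str) -> dict[int, str]:
    """Member sequence indices of a node, with their identifier strings."""
    n = g.node(nid)
    return {seq: g.ids[seq] for seq in sorted(n.members)}
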