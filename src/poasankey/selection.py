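"""Sequence-subset selection state and its three toggle actions.

Selections are how subgraphs induced by sequence subsets get highlighted
across all panels.  Three toggles mirror the interactive actions of a
viewer: toggling a single sequence, toggling a tree clade (all descendant
leaves), and toggling a POA node (all sequences passing through it).

Group toggles follow an "add unless already fully selected" rule: if the
target set is entirely selected it is removed, otherwise it is added.
Applied twice from a clean containment state, every toggle is an
involution.

Selections serialize to a one-line expression syntax::

    seq:ID           a single sequence by identifier
    clade:LABEL      all descendant leaves of the labelled tree node
    node:COL/SYMBOL  all members of the POA node (COL is 1-based)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .errors import LookupErrorPoa
from .msa_io import Alignment, PhyloTree
from .poa_graph import POAGraph, node_id


@dataclass(frozen=True)
class SelectionState:
    selected: frozenset[int] = frozenset()
    history: tuple[str, ...] = ()

    def _with(self, selected: frozenset[int], action: str) -> "SelectionState":
        return SelectionState(selected=selected, history=self.history + (action,))


def _toggle_set(selected: frozenset[int], target: frozenset[int]) -> frozenset[int]:
    if target <= selected:
        return selected - target
    return selected | target


def toggle_sequence(state: SelectionState, n_sequences: int, seq_index: int) -> SelectionState:
    """Flip membership of one sequence index."""
    if not 0 <= seq_index < n_sequences:
        raise LookupErrorPoa(
            f"sequence index {seq_index} out of range 0..{n_sequences - 1}"
        )
    return state._with(
        state.selected ^ {seq_index}, f"seq_index:{seq_index}"
    )


def toggle_clade(state: SelectionState, tree: PhyloTree, aln: Alignment, tree_node) -> SelectionState:
    """Toggle all descendant leaves of a tree node.

    If every descendant is already selected the clade is removed from the
    selection; otherwise it is added.
    """
    if not tree.contains(tree_node):
        raise LookupErrorPoa("tree node not in tree")
    index = {sid: i for i, sid in enumerate(aln.ids)}
    try:
        target = frozenset(index[lbl] for lbl in tree.descendant_leaves(tree_node))
    except KeyError as exc:
        raise LookupErrorPoa(f"tree leaf {exc.args[0]!r} not in alignment") from None
    action = "set:" + ",".join(map(str, sorted(target)))
    return state._with(_toggle_set(state.selected, target), action)


def toggle_node(state: SelectionState, g: POAGraph, nid: str) -> SelectionState:
    """Toggle all sequences passing through one POA node (same add/remove rule)."""
    n = g.node(nid)  # raises LookupErrorPoa if unknown
    action = "set:" + ",".join(map(str, sorted(n.members)))
    return state._with(_toggle_set(state.selected, n.members), action)


# ---------------------------------------------------------------------------
# Text syntax


def parse_selection_expr(
    expr: str,
    aln: Alignment,
    g: POAGraph,
    tree: Optional[PhyloTree] = None,
) -> frozenset[int]:
    """Resolve one ``seq:`` / ``clade:`` / ``node:`` expression to an index set."""
    kind, _, arg = expr.partition(":")
    if not arg:
        raise LookupErrorPoa(f"malformed selection expression {expr!r}")
    if kind == "seq":
        try:
            return frozenset({aln.ids.index(arg)})
        except ValueError:
            raise LookupErrorPoa(f"unknown sequence id {arg!r}") from None
    if kind == "clade":
        if tree is None:
            raise LookupErrorPoa("clade selection requires a tree")
        clade = tree.find(arg)
        index = {sid: i for i, sid in enumerate(aln.ids)}
        return frozenset(index[lbl] for lbl in tree.descendant_leaves(clade))
    if kind == "node":
        col_s, _, symbol = arg.partition("/")
        if not symbol or not col_s.isdigit() or int(col_s) < 1:
            raise LookupErrorPoa(
                f"malformed node selector {arg!r} (expected COL/SYMBOL, 1-based column)"
            )
        return g.node(node_id(int(col_s) - 1, symbol.upper())).members
    raise LookupErrorPoa(f"unknown selection kind {kind!r} in {expr!r}")


def apply_expressions(
    exprs: list[str],
    aln: Alignment,
    g: POAGraph,
    tree: Optional[PhyloTree] = None,
) -> SelectionState:
    """Fold a list of selection expressions into a state, toggle semantics."""
    state = SelectionState()
    for expr in exprs:
        target = parse_selection_expr(expr, aln, g, tree)
        action = "set:" + ",".join(map(str, sorted(target)))
        state = state._with(_toggle_set(state.selected, target), action)
    return state


def replay(history: tuple[str, ...]) -> SelectionState:
    """Re-run a recorded history from the empty state.

    History actions are stored in a resolved form (``seq_index:i`` or
    ``set:i,j,k``) so replay needs neither graph nor tree.
    """
    state = SelectionState()
    for action in history:
        kind, _, arg = action.partition(":")
        if kind == "seq_index":
            target = frozenset({int(arg)})
            state = state._with(state.selected ^ target, action)
        elif kind == "set":
            target = frozenset(int(x) for x in arg.split(",") if x != "")
            state = state._with(_toggle_set(state.selected, target), action)
        else:
            raise LookupErrorPoa(f"unknown history action {action!r}")
    return state
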