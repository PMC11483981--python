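"""POA graph construction, reconstruction, simplification and consensus."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from poasankey.errors import GraphIntegrityError, LookupErrorPoa
from poasankey.fixtures import generate_msa_fixture
from poasankey.msa_io import GAP, Alignment
from poasankey.poa_graph import (
    POAGraph,
    build_poa,
    consensus_path,
    consensus_weight,
    default_grouping,
    grouping_from_dict,
    identity_grouping,
    node_id,
    node_sequences,
    reconstruct_alignment,
    simplify_poa,
)

from conftest import random_alignments


def _aln(*rows, alphabet="nucleotide"):
    ids = tuple(f"s{i}" for i in range(len(rows)))
    return Alignment(ids, tuple(rows), len(rows[0]), alphabet).validate()


# Hypothesis strategy: small well-formed alignments (no all-gap row).
_row = st.text(alphabet="ACG-", min_size=1, max_size=12).filter(
    lambda r: set(r) != {"-"}
)


@st.composite
def alignments(draw):
    n_cols = draw(st.integers(1, 12))
    n_rows = draw(st.integers(1, 6))
    rows = tuple(
        draw(
            st.text(alphabet="ACG-", min_size=n_cols, max_size=n_cols).filter(
                lambda r: set(r) != {"-"}
            )
        )
        for _ in range(n_rows)
    )
    ids = tuple(f"s{i}" for i in range(n_rows))
    return Alignment(ids, rows, n_cols, "nucleotide").validate()


class TestBuildPoa:
    def test_identical_rows_collapse_to_one_path(self):
        g = build_poa(_aln("AC", "AC", "AC"))
        assert set(g.nodes) == {"0/A", "1/C"}
        assert g.nodes["0/A"].members == frozenset({0, 1, 2})
        assert set(g.edges) == {("0/A", "1/C")}
        assert g.edges[("0/A", "1/C")].members == frozenset({0, 1, 2})

    def test_divergent_column_splits_nodes_and_edges(self):
        g = build_poa(_aln("AC", "AG"))
        assert set(g.nodes) == {"0/A", "1/C", "1/G"}
        assert g.edges[("0/A", "1/C")].members == frozenset({0})
        assert g.edges[("0/A", "1/G")].members == frozenset({1})

    def test_gap_produces_long_link(self):
        g = build_poa(_aln("A-C", "ABC", alphabet="protein"))
        assert set(g.nodes) == {"0/A", "1/B", "2/C"}
        assert g.edges[("0/A", "2/C")].members == frozenset({0})
        assert g.edges[("0/A", "1/B")].members == frozenset({1})
        assert g.edges[("1/B", "2/C")].members == frozenset({1})

    def test_column_completeness(self):
        for aln in random_alignments(20, seed0=300):
            g = build_poa(aln)
            cols = g.columns()
            for c in range(aln.n_columns):
                expected = {row[c] for row in aln.rows} - {GAP}
                assert {n.symbol for n in cols[c]} == expected

    def test_flow_conservation_at_every_node(self, random_graph):
        aln, g = random_graph
        starts = {}
        ends = {}
        for s in range(g.n_sequences):
            path = g.sequence_path(s)
            starts[path[0]] = starts.get(path[0], 0) + 1
            ends[path[-1]] = ends.get(path[-1], 0) + 1
        for nid, n in g.nodes.items():
            incoming = sum(len(e.members) for e in g.in_edges(nid))
            outgoing = sum(len(e.members) for e in g.out_edges(nid))
            assert len(n.members) == incoming + starts.get(nid, 0)
            assert len(n.members) == outgoing + ends.get(nid, 0)

    def test_edge_span_columns_are_gaps(self, random_graph):
        aln, g = random_graph
        for e in g.edges.values():
            c0 = g.nodes[e.src].column
            c1 = g.nodes[e.dst].column
            assert c0 < c1
            for s in e.members:
                assert all(aln.rows[s][c] == GAP for c in range(c0 + 1, c1))


class TestReconstruct:
    @pytest.mark.parametrize(
        "rows", [("AC", "AC", "AC"), ("AC", "AG"), ("A-C", "ABC")]
    )
    def test_inverse_on_worked_examples(self, rows):
        alphabet = "protein" if "B" in "".join(rows) else "nucleotide"
        aln = _aln(*rows, alphabet=alphabet)
        assert reconstruct_alignment(build_poa(aln)) == aln

    def test_round_trip_on_200_random_alignments(self):
        for aln in random_alignments(200, seed0=1000):
            assert reconstruct_alignment(build_poa(aln)) == aln

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(alignments())
    def test_round_trip_property(self, aln):
        assert reconstruct_alignment(build_poa(aln)) == aln

    def test_broken_path_raises_integrity_error(self):
        g = build_poa(_aln("AC", "AC"))
        broken = POAGraph(
            n_columns=g.n_columns,
            n_sequences=g.n_sequences,
            ids=g.ids,
            alphabet=g.alphabet,
            nodes=g.nodes,
            edges={},
        )
        with pytest.raises(GraphIntegrityError):
            reconstruct_alignment(broken)


class TestGrouping:
    def test_default_four_classes(self):
        grp = default_grouping()
        assert grp.group_of("K") == "electrically charged"
        assert grp.group_of("L") == "hydrophobic"
        assert grp.group_of("S") == "polar uncharged"
        assert grp.group_of("G") == "special"
        assert grp.group_of("X") == "other"

    def test_total_over_standard_amino_acids(self):
        grp = default_grouping()
        assert set(grp.mapping) == set("ACDEFGHIKLMNPQRSTVWY")

    def test_class_membership(self):
        grp = default_grouping()
        by_label = {}
        for aa, lbl in grp.mapping.items():
            by_label.setdefault(lbl, set()).add(aa)
        assert by_label["electrically charged"] == set("DEKRH")
        assert by_label["polar uncharged"] == set("STNQY")
        assert by_label["hydrophobic"] == set("AVLIMFW")
        assert by_label["special"] == set("CGP")

    def test_grouping_from_dict_uppercases(self):
        grp = grouping_from_dict({"tiny": ["a", "g"]})
        assert grp.group_of("A") == "tiny"
        assert grp.group_of("W") == "other"


class TestSimplify:
    def test_same_group_nodes_merge(self):
        g = build_poa(_aln("V", "L", alphabet="protein"))
        sg = simplify_poa(g, default_grouping())
        assert set(sg.nodes) == {"0/hydrophobic"}
        assert sg.nodes["0/hydrophobic"].members == frozenset({0, 1})

    def test_identity_grouping_is_isomorphism(self, protein_aln):
        g = build_poa(protein_aln)
        symbols = {n.symbol for n in g.nodes.values()}
        sg = simplify_poa(g, identity_grouping(symbols))
        assert set(sg.nodes) == set(g.nodes)
        assert set(sg.edges) == set(g.edges)
        for nid in g.nodes:
            assert sg.nodes[nid].members == g.nodes[nid].members

    def test_membership_conserved_and_column_count_bounded(self):
        grp = default_grouping()
        for aln in random_alignments(
            50, seed0=4000, alphabets=("protein",), max_seqs=10, max_cols=25
        ):
            g = build_poa(aln)
            sg = simplify_poa(g, grp)
            gcols, scols = g.columns(), sg.columns()
            for c in range(aln.n_columns):
                union_g = frozenset().union(*(n.members for n in gcols[c])) \
                    if gcols[c] else frozenset()
                union_s = frozenset().union(*(n.members for n in scols[c])) \
                    if scols[c] else frozenset()
                assert union_g == union_s
                assert len(scols[c]) <= 5

    def test_reconstruct_matches_rowwise_group_mapping(self, protein_aln):
        grp = default_grouping()
        g = simplify_poa(build_poa(protein_aln), grp)
        for s in range(g.n_sequences):
            path = {g.nodes[nid].column: g.nodes[nid].symbol
                    for nid in g.sequence_path(s)}
            for c, sym in enumerate(protein_aln.rows[s]):
                if sym == GAP:
                    assert c not in path
                else:
                    assert path[c] == grp.group_of(sym)

    def test_idempotent(self, protein_aln):
        grp = default_grouping()
        g = build_poa(protein_aln)
        once = simplify_poa(g, grp)
        twice = simplify_poa(once, grp)
        assert set(once.nodes) == set(twice.nodes)
        assert once.edges == twice.edges


# ---------------------------------------------------------------------------
# Consensus


def brute_force_best_weight(g: POAGraph) -> int:
    """Independent oracle: enumerate every source-to-sink path."""
    starts, ends = {}, {}
    for s in range(g.n_sequences):
        p = g.sequence_path(s)
        starts[p[0]] = starts.get(p[0], 0) + 1
        ends[p[-1]] = ends.get(p[-1], 0) + 1
    out = {}
    for e in g.edges.values():
        out.setdefault(e.src, []).append(e)
    best = 0

    def dfs(nid, weight):
        nonlocal best
        if nid in ends:
            best = max(best, weight + ends[nid])
        for e in out.get(nid, []):
            dfs(e.dst, weight + len(e.members))

    for nid, cnt in starts.items():
        dfs(nid, cnt)
    return best


class TestConsensus:
    def test_single_sequence_returns_its_path(self):
        aln = _aln("AC-GT")
        g = build_poa(aln)
        assert consensus_path(g) == ["0/A", "1/C", "3/G", "4/T"]

    def test_matches_brute_force_on_random_small_graphs(self):
        for aln in random_alignments(60, seed0=7000, max_seqs=6, max_cols=10):
            g = build_poa(aln)
            path = consensus_path(g)
            assert consensus_weight(g, path) == brute_force_best_weight(g)

    def test_path_is_connected_by_edges(self, random_graph):
        _, g = random_graph
        path = consensus_path(g)
        for a, b in zip(path, path[1:]):
            assert (a, b) in g.edges

    def test_tie_break_prefers_lexicographically_smaller_symbol(self):
        # two equal-weight paths differing only at the middle column
        aln = _aln("TAC", "TGC")
        g = build_poa(aln)
        path = consensus_path(g)
        assert path == ["0/T", "1/A", "2/C"]

    def test_deterministic_across_runs(self, random_graph):
        _, g = random_graph
        assert consensus_path(g) == consensus_path(g)


class TestNodeSequences:
    def test_members_with_ids(self):
        g = build_poa(_aln("AC", "AG"))
        assert node_sequences(g, "0/A") == {0: "s0", 1: "s1"}
        assert node_sequences(g, "1/G") == {1: "s1"}

    def test_unknown_node_raises(self, random_graph):
        _, g = random_graph
        with pytest.raises(LookupErrorPoa):
            node_sequences(g, "999/Z")


class TestJsonRoundTrip:
    def test_graph_json_round_trip(self, random_graph):
        _, g = random_graph
        again = POAGraph.from_json(g.to_json())
        assert again == g
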