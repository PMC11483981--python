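# Methods

## The POA model as implemented here

The package builds partial order alignment graphs from *existing*
alignments; it never aligns sequences.  The alignment is the ground truth:
each column is a node cluster, each distinct non-gap symbol in a column is
one node, and each sequence's consecutive non-gap positions define edges.
Parallel per-sequence edges between the same node pair are merged with
member sets unioned, so edge "flow" is the count of sequences taking that
transition.  Sequences are unweighted throughout — flow rate is always a
sequence count.  Because membership is recorded per node and per edge, the
construction is invertible; `reconstruct_alignment` recovers the input
exactly and doubles as a structural integrity check (every sequence's nodes
must form a connected edge path).

Gap handling: `-` and `.` are both accepted and normalized to `-` (Stockholm
commonly uses `.`); symbols are upper-cased on read.  Ambiguity codes
(N, X, B, Z, …) are ordinary symbols and form their own nodes.  The
alphabet is called nucleotide when at least 95% of non-gap symbols lie in
{A,C,G,T,U,N}, else protein; the caller can override.  A tree supplied with
an alignment must have exactly the alignment's ids as leaf labels — a
strict-subset tree is rejected rather than silently sub-setting, because
there is no principled row order for the uncovered sequences.

## Residue grouping

Protein columns are busy: low sequence identity means many nodes per
column.  Simplification merges, within each column, nodes whose residues
share a physicochemical class.  The default four classes are

| class                | residues        |
|----------------------|-----------------|
| electrically charged | D E K R H       |
| polar uncharged      | S T N Q Y       |
| hydrophobic          | A V L I M F W   |
| special              | C G P           |

with everything else (ambiguity codes, nonstandard letters) in `other`.
This particular division is a package default following common
physicochemical classification practice, and is fully overridable via a
`{group label: [residues]}` mapping in YAML/JSON.  Group labels are fixed
points of the mapping, which makes simplification idempotent.  Per-column
membership unions are invariant under simplification, and the per-column
node count is bounded by the number of classes plus `other`.

## Consensus

The consensus is the heaviest source-to-sink path: a virtual start connects
to every node where at least one sequence begins (arc weight = number of
sequences beginning there) and symmetrically for ends; interior arc weight
is the edge member count.  One forward dynamic-programming pass in column
order suffices because edges always point to later columns.  The weight
is deliberately **per-edge**, not per-node: it rewards transitions that many
sequences share, which matches how consensus is commonly extracted from POA
graphs in read-correction pipelines.  Ties are broken locally and
deterministically when comparing predecessors of equal score: larger
predecessor member count, then lexicographically smaller symbol, then
smaller column; the same rule picks the final end node.  On all small
graphs the DP optimum is checked in tests against exhaustive enumeration of
every source-to-sink path.

## Sankey layout

Geometry lives in abstract canvas units, origin top-left, y downward
(matching SVG).  Parameters with defaults:

* `canvas_width` 960, `canvas_height` 540 — drawing area of the Sankey band.
* `node_width` 14 — constant for all nodes and matrix cells.
* `min_node_gap` 8 — vertical separation between nodes of a column.
* `flow_unit` — canvas height per member sequence.  When unset it is
  auto-scaled so the tallest in-range column exactly fills the canvas, then
  snapped down to a multiple of 2⁻²⁰.  The snap makes every height and
  thickness (`count × flow_unit`) an exact binary multiple, so tiling and
  conservation checks hold bit-for-bit rather than to a tolerance.
* `column_range` — inclusive 0-based window (1-based on the CLI); edges with
  one endpoint outside become boundary stubs, edges fully outside are
  dropped.
* `y_overrides` — per-node vertical offsets applied after automatic
  placement, the batch equivalent of dragging nodes.

Column x positions are uniform; the spacing is likewise quantized to 2⁻²⁰
units so consecutive gaps are exactly equal in floating point.

Vertical node order is a two-pass barycenter sweep: initial order by
descending member count (ties by symbol), one left-to-right pass ordering
each column by the member-weighted mean y-center of its predecessors, one
right-to-left pass by successors, each column re-stacked and re-centered
after reordering.  This is a deliberately simple crossing-reduction
heuristic — no ILP, no force simulation — chosen because the column
constraint already fixes most of the structure and the result must be
deterministic and fast on tens of thousands of nodes.

At each node side the attached ribbons are stacked from the node top,
ordered by the far endpoint's y-center, so they tile the side without
overlap; the tiled extent equals `continuing members × flow_unit` exactly.
Forward ribbons are cubic Bezier bands with horizontal end tangents; their
x-coordinate is monotone, so a long link crosses each intermediate column
exactly once.  Feedback arcs (target left of source) route below the
occupied band with a configurable clearance, and reversing joins loop
beyond the leftmost/rightmost of their two same-side anchors.  POA graphs
are DAGs and never produce these two shapes; they exist because the layout
engine is usable for general column-assigned flow graphs and are covered by
engine-level tests only.  Draw order puts the longest spans underneath,
then thicker links first, stably.

Selections split each link into at most two nested sublinks — the selected
fraction stacked first, then the remainder — with thicknesses
`count × flow_unit`, so sublinks partition the parent exactly.

## Rendering

One SVG document contains up to three panels in a single absolute
coordinate system: Sankey on top, matrix below it, cladogram to the left of
the matrix.  The synchronization contracts are exact equalities, not
approximations: matrix cells reuse the Sankey column x and `node_width`,
and tree leaves sit at the matrix row y-centers.  The matrix row order is
the ladderized tree leaf order when a tree is present (children ordered by
ascending leaf count, ties by smallest leaf label), else file order.  The
cladogram ignores branch lengths — row alignment is the contract, not
phylogenetic distance.

Determinism is a hard requirement: fixed float formatting (three decimals),
explicit iteration orders, a built-in font-metrics constant instead of
platform font measurement, and no timestamps.  Identical inputs give
byte-identical SVG.  Hover bubbles of an interactive viewer are replaced by
embedded `<title>`/`<desc>` elements listing column, symbol and member ids.
Column labels are 1-based in all rendered text; internal indices are
0-based and converted once at the CLI boundary.

Palettes: nucleotide (per-base + N + gap), a Clustal-like protein scheme,
and four group colors + other for simplified graphs; unknown symbols fall
back to a neutral grey, so coloring is total over any alphabet.  All colors,
the highlight color and the dim opacity are configurable.

## Synthetic data

The fixture generator emulates a family of related sequences: a random
ancestral row, per-column substitution with probability
`substitution_rate` (uniform over the other residues) and independent gap
conversion with probability `gap_rate`, then repair of any all-gap row or
column.  Defaults (8 sequences × 40 columns, substitution 0.1, gap 0.05)
give the moderately divergent, lightly gapped alignments typical of a
curated nucleotide family.  The generator does **not** emulate indel
blocks (gaps are independent per cell), rate heterogeneity across sites,
or phylogenetically correlated substitutions — the companion random tree is
topology only and unrelated to the simulated characters.  Passing tests
therefore demonstrate structural and geometric correctness of the pipeline
on realistic shapes and densities, not biological plausibility of any
particular alignment.

Problem sizes used by the test suite and the acceptance script: 200 varied
alignments up to 30×120 for round-trip checks; ~3,700 enumerated or sampled
tiny alignments (≤4 sequences × ≤6 columns over {A,C,-}) for the consensus
oracle; 50 random layouts for geometry; and one 60×600 protein alignment
(≈11k nodes, ≈32k links) as the large-graph smoke run.  These sizes were
chosen to exercise every code path at desk scale while keeping a full run
in the seconds-to-a-minute range.

## Known limitations

* No progressive alignment of new sequences into an existing graph.
* The tree must cover the alignment exactly; no pruning or grafting.
* Barycenter ordering is a heuristic; pathological graphs can still cross
  heavily (manual `y_overrides` are the escape hatch).
* No rasterization; SVG (optionally wrapped in HTML) is the only output.
* Selections are static per run; there is no event loop.
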