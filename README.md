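# poasankey

Partial order alignment (POA) graphs rendered as column-constrained Sankey
diagrams, as a batch library and CLI.

A multiple sequence alignment (MSA) shows homology as rows in a matrix.  The
POA view of the same alignment is a directed acyclic graph: each alignment
column is a cluster of nodes, identical residues within a column collapse
into a single node, and every sequence traces a path through the graph.
Shared nodes are shared residues; bubbles are substitutions; long edges skip
over gapped columns.  `poasankey` draws this graph as a Sankey diagram —
node heights and ribbon thicknesses proportional to the number of sequences
flowing through them — side by side with the classic matrix view and an
optional phylogenetic tree, all column- and row-synchronized, written to a
deterministic standalone SVG.

It is intended for people who inspect alignments: method developers who
want to see what their aligner produced, and analysts exploring variation
(e.g. read overlaps during consensus calling, or conserved cores in protein
families).

## What it computes

Given an alignment `A` with `n` sequences and `L` columns:

* **POA graph** `G = (V, E)` with `V = {(c, s)}` for every column `c` and
  distinct non-gap symbol `s` in that column, carrying the member set
  `M(c,s) = {i : A[i,c] = s}`; edges connect consecutive non-gap positions
  of each sequence, merged over sequences, so `M(e) ⊆ M(src) ∩ M(dst)`.
  Flow is conserved: `|M(v)| = Σ_in |M(e)| + starts(v) = Σ_out |M(e)| + ends(v)`.
* **Simplification** (protein alignments): within each column, nodes whose
  residues share a physicochemical class — electrically charged {D,E,K,R,H},
  polar uncharged {S,T,N,Q,Y}, hydrophobic {A,V,L,I,M,F,W}, special {C,G,P} —
  merge into one node; the division is user-overridable.
* **Consensus path**: the source-to-sink path maximizing the summed edge
  member counts, by a single forward dynamic-programming pass in column
  order, with deterministic tie-breaks.
* **Sankey layout**: uniform column spacing, node height
  `= |M(v)| × flow_unit`, vertical order by a two-pass barycenter sweep,
  ribbons tiling each node side exactly; links can be split into nested
  sublinks showing the selected vs. unselected fraction of a flow.
* **Selections**: toggling a sequence, a tree clade, or a POA node
  highlights the induced subgraph synchronously in all panels.

## Worked example

```sh
# make a small synthetic alignment + matching random tree
poasankey fixtures --n-seqs 6 --n-columns 24 --seed 42 \
    --gap-rate 0.1 --substitution-rate 0.25 -o demo.fasta --tree-out demo.nwk

poasankey inspect demo.fasta
```

prints

```json
{
  "n_sequences": 6,
  "n_columns": 24,
  "alphabet": "nucleotide",
  "n_nodes": 55,
  "n_edges": 86,
  "max_nodes_per_column": 4,
  "n_long_links": 12,
  "consensus_length": 24
}
```

55 nodes over 24 columns means the six sequences disagree in most columns
(identical sequences would give 24 nodes); the 12 long links are edges that
jump over gapped columns; the consensus path touches all 24 columns.

```sh
poasankey render demo.fasta --tree demo.nwk \
    --select seq:seq2 --highlight-consensus -o demo.svg -v
```

```
INFO poasankey: alignment: 6 sequences x 24 columns (nucleotide)
INFO poasankey: POA graph: 55 nodes, 86 edges
INFO poasankey: wrote demo.svg in 0.02s
```

`demo.svg` contains the Sankey panel (consensus chain outlined, seq2's flow
highlighted and the rest dimmed), the matrix panel underneath with identical
column x-positions, and the cladogram on the left with leaf rows aligned to
the matrix.  Input may be aligned FASTA, Clustal, MSF, Phylip or Stockholm
(auto-detected); `--range LO:HI` shows a column window, `--simplify`
activates residue grouping for proteins, `--config` takes a YAML/JSON file
with palettes, grouping, layout numbers and panel toggles, and `--html`
wraps the SVG in a single-file page.

Library use mirrors the CLI:

```python
from poasankey import (read_alignment, build_poa, compute_layout, render_svg)

aln = read_alignment("demo.fasta")
g = build_poa(aln)
svg = render_svg(g, compute_layout(g), aln)
```

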