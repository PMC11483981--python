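"""Synthetic alignments and trees for testing and demonstration.

The MSA generator draws a random ancestral row and derives each sequence
by independent per-column substitution and gap insertion, then repairs
any all-gap row or column so the result always satisfies the alignment
invariants.  The tree generator joins leaves by sequential random pairing
into a rooted binary tree.  Both are fully deterministic under a seed.

This module also provides the format encoders used by the test suite
(the package itself only ever reads alignments): the four formats with
Biopython writers go through ``Bio.AlignIO``; MSF, which Biopython reads
but does not write, has a small hand-written encoder here.
"""

from __future__ import annotations

import io
import random
from typing import Optional, Sequence

from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Phylo.BaseTree import Clade, Tree
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import PoaSankeyError
from .msa_io import GAP, Alignment, PhyloTree

NUCLEOTIDES = "ACGT"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def generate_msa_fixture(
    n_seqs: int = 8,
    n_columns: int = 40,
    alphabet: str = "nucleotide",
    substitution_rate: float = 0.1,
    gap_rate: float = 0.05,
    seed: int = 0,
    ids: Optional[Sequence[str]] = None,
) -> Alignment:
    """Generate a random gapped alignment.

    Each sequence copies a random ancestral row, substituting a column's
    residue with probability ``substitution_rate`` (uniformly over the
    other residues) and replacing it with a gap with probability
    ``gap_rate``.  No row and no column ends up entirely gapped.
    """
    if n_seqs < 1 or n_columns < 1:
        raise PoaSankeyError("n_seqs and n_columns must be >= 1")
    for name, rate in (("substitution_rate", substitution_rate), ("gap_rate", gap_rate)):
        if not 0.0 <= rate < 1.0:
            raise PoaSankeyError(f"{name} must lie in [0, 1), got {rate}")
    if alphabet not in ("nucleotide", "protein"):
        raise PoaSankeyError(f"unknown alphabet {alphabet!r}")
    residues = NUCLEOTIDES if alphabet == "nucleotide" else AMINO_ACIDS
    rng = random.Random(seed)
    ancestor = [rng.choice(residues) for _ in range(n_columns)]
    rows: list[list[str]] = []
    for _ in range(n_seqs):
        row = []
        for c in range(n_columns):
            if rng.random() < gap_rate:
                row.append(GAP)
            elif rng.random() < substitution_rate:
                others = residues.replace(ancestor[c], "")
                row.append(rng.choice(others))
            else:
                row.append(ancestor[c])
        rows.append(row)
    # repair degenerate rows/columns so alignment invariants always hold
    for row in rows:
        if all(s == GAP for s in row):
            c = rng.randrange(n_columns)
            row[c] = ancestor[c]
    for c in range(n_columns):
        if all(row[c] == GAP for row in rows):
            rows[rng.randrange(n_seqs)][c] = ancestor[c]
    if ids is None:
        ids = tuple(f"seq{i + 1}" for i in range(n_seqs))
    else:
        ids = tuple(ids)
        if len(ids) != n_seqs:
            raise PoaSankeyError("ids length must equal n_seqs")
    return Alignment(
        ids=ids,
        rows=tuple("".join(r) for r in rows),
        n_columns=n_columns,
        alphabet=alphabet,
    ).validate()


def generate_tree_fixture(ids: Sequence[str], seed: int = 0) -> PhyloTree:
    """Random rooted binary tree over the given leaf labels.

    Built by sequential random joins: repeatedly pick two subtrees at
    random and join them under a new internal node, until one remains.
    """
    if len(ids) < 2:
        raise PoaSankeyError("a tree fixture needs at least 2 leaf ids")
    rng = random.Random(seed)
    forest: list[Clade] = [
        Clade(name=str(label), branch_length=1.0) for label in ids
    ]
    while len(forest) > 1:
        i, j = rng.sample(range(len(forest)), 2)
        a, b = forest[i], forest[j]
        joined = Clade(branch_length=1.0, clades=[a, b])
        forest = [c for k, c in enumerate(forest) if k not in (i, j)]
        forest.append(joined)
    root = forest[0]
    root.branch_length = None
    return PhyloTree(Tree(root=root, rooted=True))


# ---------------------------------------------------------------------------
# Format encoders (tests/fixtures only)


def _to_biopython(aln: Alignment) -> MultipleSeqAlignment:
    return MultipleSeqAlignment(
        SeqRecord(Seq(row), id=sid, description="")
        for sid, row in zip(aln.ids, aln.rows)
    )


def _write_msf(aln: Alignment) -> str:
    """Minimal GCG MSF encoder (gaps as '.', 50-residue blocks)."""
    kind = "NA" if aln.alphabet == "nucleotide" else "AA"
    type_code = "N" if kind == "NA" else "P"
    lines = [
        f"!!{kind}_MULTIPLE_ALIGNMENT 1.0",
        "",
        f" fixture.msf MSF: {aln.n_columns} Type: {type_code} Check: 0 ..",
        "",
    ]
    for sid in aln.ids:
        lines.append(
            f" Name: {sid} Len: {aln.n_columns} Check: 0 Weight: 1.00"
        )
    lines.append("")
    lines.append("//")
    lines.append("")
    width = max(len(s) for s in aln.ids)
    for start in range(0, aln.n_columns, 50):
        for sid, row in zip(aln.ids, aln.rows):
            chunk = row[start:start + 50].replace(GAP, ".")
            blocks = " ".join(chunk[i:i + 10] for i in range(0, len(chunk), 10))
            lines.append(f"{sid:<{width}}  {blocks}")
        lines.append("")
    return "\n".join(lines) + "\n"


_ALIGNIO_WRITERS = {
    "fasta": "fasta",
    "clustal": "clustal",
    "phylip": "phylip-relaxed",
    "stockholm": "stockholm",
}


def write_alignment(aln: Alignment, format: str) -> str:
    """Encode an alignment in one of the five supported formats."""
    if format == "msf":
        return _write_msf(aln)
    try:
        writer = _ALIGNIO_WRITERS[format]
    except KeyError:
        raise PoaSankeyError(f"unknown alignment format {format!r}") from None
    buf = io.StringIO()
    AlignIO.write(_to_biopython(aln), buf, writer)
    return buf.getvalue()


def write_newick(tree: PhyloTree) -> str:
    return tree.to_newick()
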