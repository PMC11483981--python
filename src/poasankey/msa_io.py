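"""Reading and validating multiple sequence alignments and phylogenetic trees.

Five alignment formats are accepted — aligned FASTA, Clustal, MSF, Phylip
(strict or relaxed, sequential or interleaved) and Stockholm — plus rooted
trees in Newick.  Everything is normalized into a single :class:`Alignment`
value: symbols upper-cased, ``.`` gaps rewritten to ``-``, sequence order
preserved as encountered in the file (it defines the sequence indices used
by every downstream module).

Parsing itself is delegated to Biopython (``Bio.AlignIO`` / ``Bio.Phylo``);
this module owns format detection, validation and normalization.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Optional, Union

from Bio import AlignIO, Phylo
from Bio.Phylo.BaseTree import Clade, Tree

from .errors import (
    AlignmentValidationError,
    FormatDetectionError,
    TreeAlignmentMismatchError,
    TreeParseError,
)

GAP = "-"

#: Symbols counted as nucleotide evidence during alphabet inference.
_NUC_SYMBOLS = frozenset("ACGTUN")

#: Fraction of non-gap symbols that must be nucleotide-like to call an
#: alignment nucleotide.
_NUC_THRESHOLD = 0.95

FORMATS = ("fasta", "clustal", "msf", "phylip", "stockholm")

Source = Union[str, Path, IO[str]]


@dataclass(frozen=True)
class Alignment:
    """A rectangular gapped alignment.

    Attributes
    ----------
    ids:
        Sequence identifiers, in file order.  Their positions define the
        sequence indices ``0..n-1`` used everywhere downstream.
    rows:
        One symbol string per id, all of length :attr:`n_columns`.
    n_columns:
        Number of alignment columns.
    alphabet:
        ``"nucleotide"`` or ``"protein"``.
    """

    ids: tuple[str, ...]
    rows: tuple[str, ...]
    n_columns: int
    alphabet: str

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    def validate(self) -> "Alignment":
        if len(self.ids) != len(self.rows):
            raise AlignmentValidationError(
                f"{len(self.ids)} ids but {len(self.rows)} rows"
            )
        if not self.ids:
            raise AlignmentValidationError("alignment has no sequences")
        seen: set[str] = set()
        for sid in self.ids:
            if not sid:
                raise AlignmentValidationError("empty sequence identifier")
            if sid in seen:
                raise AlignmentValidationError(f"duplicate sequence id {sid!r}")
            seen.add(sid)
        bad = [
            (sid, len(row))
            for sid, row in zip(self.ids, self.rows)
            if len(row) != self.n_columns
        ]
        if bad:
            detail = ", ".join(f"{sid}:{length}" for sid, length in bad)
            raise AlignmentValidationError(
                f"ragged rows (expected {self.n_columns} columns): {detail}"
            )
        if self.alphabet not in ("nucleotide", "protein"):
            raise AlignmentValidationError(f"unknown alphabet {self.alphabet!r}")
        for sid, row in zip(self.ids, self.rows):
            if set(row) <= {GAP}:
                raise AlignmentValidationError(f"row {sid!r} is entirely gaps")
            for sym in row:
                if sym != GAP and not ("A" <= sym <= "Z" or sym == "*"):
                    raise AlignmentValidationError(
                        f"row {sid!r} contains illegal symbol {sym!r}"
                    )
        return self


def infer_alphabet(rows: Iterable[str]) -> str:
    """Infer ``nucleotide`` vs ``protein`` from symbol content.

    Nucleotide iff at least 95% of non-gap symbols are in ``{A,C,G,T,U,N}``.
    """
    total = 0
    nuc = 0
    for row in rows:
        for sym in row:
            if sym == GAP:
                continue
            total += 1
            if sym in _NUC_SYMBOLS:
                nuc += 1
    if total == 0:
        return "protein"
    return "nucleotide" if nuc / total >= _NUC_THRESHOLD else "protein"


def _first_nonblank_line(text: str) -> str:
    for line in text.splitlines():
        if line.strip():
            return line
    return ""


def detect_format(text: str) -> str:
    """Detect the alignment format from raw file content.

    Detection keys on unambiguous header signatures of the first non-blank
    line; it never guesses between two candidate formats.
    """
    if not text.strip():
        raise FormatDetectionError("empty input")
    line = _first_nonblank_line(text)
    stripped = line.strip()
    if stripped.startswith(">"):
        return "fasta"
    if stripped.upper().startswith("# STOCKHOLM"):
        return "stockholm"
    first_word = stripped.split()[0].upper()
    if first_word.startswith("CLUSTAL") or first_word == "MUSCLE":
        return "clustal"
    if (
        stripped.startswith("!!AA_MULTIPLE_ALIGNMENT")
        or stripped.startswith("!!NA_MULTIPLE_ALIGNMENT")
        or first_word == "PILEUP"
        or (" MSF: " in f" {stripped} " and stripped.endswith(".."))
    ):
        return "msf"
    parts = stripped.split()
    if len(parts) == 2 and all(p.isdigit() for p in parts):
        return "phylip"
    raise FormatDetectionError(f"unrecognized alignment format; first line: {line!r}")


def _read_text(source: Source) -> str:
    if hasattr(source, "read"):
        return source.read()  # type: ignore[union-attr]
    return Path(source).read_text()


# AlignIO format names tried, in order, for each of our tags.  Relaxed
# Phylip is tried before strict because relaxed dominates modern usage.
_ALIGNIO_NAMES = {
    "fasta": ["fasta"],
    "clustal": ["clustal"],
    "msf": ["msf"],
    "phylip": ["phylip-relaxed", "phylip", "phylip-sequential"],
    "stockholm": ["stockholm"],
}


def read_alignment(
    source: Source,
    format: Optional[str] = None,
    alphabet: Optional[str] = None,
) -> Alignment:
    """Read and validate an alignment from a path or text stream.

    Parameters
    ----------
    source:
        Path or open text stream.
    format:
        One of ``fasta``, ``clustal``, ``msf``, ``phylip``, ``stockholm``.
        Auto-detected from the content when omitted.
    alphabet:
        Override alphabet inference (``nucleotide`` / ``protein``).
    """
    text = _read_text(source)
    if not text.strip():
        raise AlignmentValidationError("empty alignment file")
    tag = format or detect_format(text)
    if tag not in FORMATS:
        raise FormatDetectionError(f"unknown format tag {tag!r}")
    last_error: Optional[Exception] = None
    msa = None
    for name in _ALIGNIO_NAMES[tag]:
        try:
            msa = AlignIO.read(io.StringIO(text), name)
            break
        except Exception as exc:  # Bio raises plain ValueError on bad input
            last_error = exc
    if msa is None:
        raise AlignmentValidationError(
            f"could not parse {tag} alignment: {last_error}"
        )
    ids = tuple(rec.id for rec in msa)
    rows = tuple(str(rec.seq).upper().replace(".", GAP) for rec in msa)
    n_columns = max((len(r) for r in rows), default=0)
    aln = Alignment(
        ids=ids,
        rows=rows,
        n_columns=n_columns,
        alphabet=alphabet or infer_alphabet(rows),
    )
    return aln.validate()


@dataclass
class PhyloTree:
    """A rooted tree with uniquely-labelled leaves.

    Thin wrapper over a ``Bio.Phylo`` tree providing the label-centric
    queries the selection and rendering code needs.
    """

    tree: Tree
    _label_index: dict[str, Clade] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        labels = [leaf.name for leaf in self.tree.get_terminals()]
        if any(lbl is None or lbl == "" for lbl in labels):
            raise TreeParseError("tree contains an unlabelled leaf")
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise TreeParseError(
                f"duplicate leaf labels: {', '.join(sorted(dupes))}"
            )
        self._label_index = {}
        for clade in self.tree.find_clades():
            if clade.name:
                self._label_index[clade.name] = clade

    @property
    def root(self) -> Clade:
        return self.tree.root

    def leaf_labels(self) -> list[str]:
        return [leaf.name for leaf in self.tree.get_terminals()]

    def find(self, label: str) -> Clade:
        try:
            return self._label_index[label]
        except KeyError:
            raise TreeParseError(f"no tree node labelled {label!r}") from None

    def descendant_leaves(self, clade: Clade) -> list[str]:
        return [leaf.name for leaf in clade.get_terminals()]

    def contains(self, clade: Clade) -> bool:
        return any(c is clade for c in self.tree.find_clades())

    def to_newick(self) -> str:
        buf = io.StringIO()
        Phylo.write(self.tree, buf, "newick", plain=False)
        return buf.getvalue().strip()


def _check_parentheses(text: str) -> None:
    depth = 0
    for offset, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise TreeParseError(
                    f"unbalanced parenthesis at character {offset}"
                )
    if depth != 0:
        raise TreeParseError(
            f"unbalanced parentheses: {depth} unclosed '(' at end of input"
        )


def read_newick(source: Source) -> PhyloTree:
    """Parse a rooted Newick tree.

    Supports quoted labels, branch lengths and absent internal labels.
    Unbalanced parentheses are reported with a character offset; duplicate
    leaf labels are rejected.
    """
    text = _read_text(source)
    if not text.strip():
        raise TreeParseError("empty tree file")
    _check_parentheses(text)
    try:
        tree = Phylo.read(io.StringIO(text), "newick")
    except Exception as exc:
        raise TreeParseError(f"Newick parse error: {exc}") from exc
    tree.rooted = True
    return PhyloTree(tree)


def check_tree_alignment(tree: PhyloTree, aln: Alignment) -> None:
    """Require the tree leaf label set to equal the alignment id set."""
    leaves = set(tree.leaf_labels())
    ids = set(aln.ids)
    if leaves == ids:
        return
    missing_in_tree = sorted(ids - leaves)
    missing_in_aln = sorted(leaves - ids)
    parts = []
    if missing_in_tree:
        parts.append(f"ids absent from tree: {', '.join(missing_in_tree)}")
    if missing_in_aln:
        parts.append(f"tree leaves absent from alignment: {', '.join(missing_in_aln)}")
    raise TreeAlignmentMismatchError("; ".join(parts))
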