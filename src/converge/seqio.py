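"""Sequence and tree I/O: FASTA, PHYLIP interleaved, and Newick.

The two central containers of the pipeline live here: :class:`ProteinAlignment`
(an aligned block of amino-acid sequences) and :class:`PhyloTree` (a thin,
validated wrapper around a :class:`dendropy.Tree`).  Readers accept either a
file path or an open text stream; writers likewise.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterator, Union

import dendropy
import numpy as np
from Bio import SeqIO

#: Canonical amino-acid order used throughout (matrix rows/columns, codes).
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
#: Characters treated as missing data; both map to code :data:`MISSING_CODE`.
MISSING_CHARS = frozenset("-X")
MISSING_CODE = 20

_AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}
_ALLOWED = set(AA_ORDER) | MISSING_CHARS

PathOrStream = Union[str, Path, IO[str]]


class SeqFormatError(ValueError):
    """Malformed sequence/tree input."""


def _open_read(src: PathOrStream):
    if isinstance(src, (str, Path)):
        return open(src, "r", encoding="utf-8", newline=None), True
    return src, False


def _open_write(dst: PathOrStream):
    if isinstance(dst, (str, Path)):
        return open(dst, "w", encoding="utf-8"), True
    return dst, False


@dataclass
class ProteinAlignment:
    """Taxa-labelled, equal-length amino-acid sequences with gaps.

    Parameters
    ----------
    taxa : list of str
        Unique, non-empty taxon names, in file order.
    rows : list of str
        One sequence per taxon over the alphabet of the 20 standard amino
        acids plus ``-`` (gap) and ``X`` (unknown); stored upper-case.
    """

    taxa: list[str]
    rows: list[str]
    _codes: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise SeqFormatError(
                f"{len(self.taxa)} taxa but {len(self.rows)} sequence rows"
            )
        seen: set[str] = set()
        for name in self.taxa:
            if not name:
                raise SeqFormatError("empty taxon name")
            if name in seen:
                raise SeqFormatError(f"duplicate taxon name: {name!r}")
            seen.add(name)
        self.rows = [r.upper() for r in self.rows]
        if not self.rows or not self.rows[0]:
            raise SeqFormatError("alignment must have at least one site")
        n = len(self.rows[0])
        for name, row in zip(self.taxa, self.rows):
            if len(row) != n:
                raise SeqFormatError(
                    f"unequal sequence lengths: {name!r} has {len(row)}, "
                    f"{self.taxa[0]!r} has {n}"
                )
            for pos, ch in enumerate(row):
                if ch not in _ALLOWED:
                    raise SeqFormatError(
                        f"illegal character {ch!r} in sequence {name!r} "
                        f"at position {pos + 1}"
                    )

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return len(self.rows[0])

    @property
    def codes(self) -> np.ndarray:
        """(n_taxa, n_sites) int8 array; amino acids 0–19, missing 20."""
        if self._codes is None:
            table = np.full(128, -1, dtype=np.int8)
            for aa, i in _AA_INDEX.items():
                table[ord(aa)] = i
            for ch in MISSING_CHARS:
                table[ord(ch)] = MISSING_CODE
            buf = np.frombuffer("".join(self.rows).encode("ascii"), dtype=np.uint8)
            self._codes = table[buf].reshape(self.n_taxa, self.n_sites)
        return self._codes

    @classmethod
    def from_codes(cls, taxa: list[str], codes: np.ndarray) -> "ProteinAlignment":
        alpha = AA_ORDER + "-"
        rows = ["".join(alpha[c] for c in row) for row in codes]
        return cls(list(taxa), rows)

    def take_sites(self, idx: np.ndarray) -> "ProteinAlignment":
        """Column subset/resample (used by bootstrap and mixtures)."""
        return ProteinAlignment.from_codes(self.taxa, self.codes[:, idx])


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(src: PathOrStream) -> ProteinAlignment:
    """Read an aligned protein FASTA file (>= 2 records).

    The header text up to the first whitespace becomes the taxon name.
    """
    handle, close = _open_read(src)
    try:
        records = list(SeqIO.parse(handle, "fasta"))
    finally:
        if close:
            handle.close()
    if len(records) < 2:
        raise SeqFormatError(f"alignment FASTA needs >= 2 records, got {len(records)}")
    taxa = [rec.id for rec in records]
    rows = [str(rec.seq) for rec in records]
    return ProteinAlignment(taxa, rows)


def write_fasta(aln: ProteinAlignment, dst: PathOrStream, width: int = 60) -> None:
    handle, close = _open_write(dst)
    try:
        for name, row in zip(aln.taxa, aln.rows):
            handle.write(f">{name}\n")
            for i in range(0, len(row), width):
                handle.write(row[i : i + width] + "\n")
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# PHYLIP interleaved
# ---------------------------------------------------------------------------

_BLOCK = 60  # residues per line


def write_phylip_interleaved(
    aln: ProteinAlignment,
    dst: PathOrStream,
    name_width: int | None = None,
    strict: bool = False,
) -> None:
    """Write interleaved PHYLIP.

    The default "relaxed" dialect writes full names padded to a common width
    and separated from the sequence by at least one space.  ``strict=True``
    enforces the classic 10-character name field and raises if truncation
    makes two names collide.
    """
    if strict:
        width = 10
        names = [t[:width] for t in aln.taxa]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise SeqFormatError(
                f"strict PHYLIP 10-character truncation collides names: {dupes}"
            )
    else:
        width = name_width if name_width is not None else max(len(t) for t in aln.taxa)
        if any(len(t) > width for t in aln.taxa):
            raise SeqFormatError(f"taxon name longer than name_width={width}")
        names = list(aln.taxa)
    handle, close = _open_write(dst)
    try:
        handle.write(f"{aln.n_taxa} {aln.n_sites}\n")
        for start in range(0, aln.n_sites, _BLOCK):
            for i, row in enumerate(aln.rows):
                chunk = row[start : start + _BLOCK]
                if start == 0:
                    handle.write(f"{names[i]:<{width}} {chunk}\n")
                else:
                    handle.write(f"{chunk}\n")
            if start + _BLOCK < aln.n_sites:
                handle.write("\n")
    finally:
        if close:
            handle.close()


def read_phylip_interleaved(src: PathOrStream, strict: bool = False) -> ProteinAlignment:
    """Read interleaved PHYLIP (relaxed by default, strict 10-char optional)."""
    handle, close = _open_read(src)
    try:
        lines = [ln.rstrip("\n").rstrip("\r") for ln in handle]
    finally:
        if close:
            handle.close()
    it: Iterator[str] = iter(lines)
    header = next((ln for ln in it if ln.strip()), None)
    if header is None:
        raise SeqFormatError("empty PHYLIP file")
    parts = header.split()
    if len(parts) != 2:
        raise SeqFormatError(f"bad PHYLIP header line: {header!r}")
    try:
        n_taxa, n_sites = int(parts[0]), int(parts[1])
    except ValueError as exc:
        raise SeqFormatError(f"bad PHYLIP header line: {header!r}") from exc

    taxa: list[str] = []
    seqs: list[list[str]] = [[] for _ in range(n_taxa)]
    row = 0
    first_block = True
    for ln in it:
        if not ln.strip():
            continue
        if first_block:
            if strict:
                name, seq = ln[:10].strip(), ln[10:]
            else:
                stripped = ln.strip()
                name, _, seq = stripped.partition(" ")
            if not name:
                raise SeqFormatError(f"missing taxon name in line {ln!r}")
            taxa.append(name)
        else:
            seq = ln
        seqs[row].append("".join(seq.split()))
        row += 1
        if row == n_taxa:
            row = 0
            first_block = False
    if first_block and len(taxa) < n_taxa:
        raise SeqFormatError(
            f"header declares {n_taxa} taxa but only {len(taxa)} found"
        )
    rows = ["".join(chunks) for chunks in seqs]
    for name, r in zip(taxa, rows):
        if len(r) != n_sites:
            raise SeqFormatError(
                f"taxon {name!r} has {len(r)} sites, header declares {n_sites}"
            )
    return ProteinAlignment(taxa, rows)


# ---------------------------------------------------------------------------
# Newick / PhyloTree
# ---------------------------------------------------------------------------

@dataclass
class PhyloTree:
    """Binary phylogeny with non-negative branch lengths.

    Wraps a :class:`dendropy.Tree`.  A rooted tree has a degree-2 seed node;
    an unrooted tree is represented with a degree-3 basal node.  Internal node
    labels, when numeric, are interpreted as bootstrap support in [0, 100].
    """

    tree: dendropy.Tree
    had_missing_lengths: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = self.leaf_names()
        if len(set(names)) != len(names):
            raise SeqFormatError("duplicate leaf names in tree")
        for edge in self.tree.preorder_edge_iter():
            if edge.tail_node is None:
                continue
            if edge.length is not None and edge.length < 0:
                raise SeqFormatError(f"negative branch length: {edge.length}")

    def leaf_names(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def is_rooted(self) -> bool:
        return len(self.tree.seed_node.child_nodes()) == 2

    def copy(self) -> "PhyloTree":
        return PhyloTree(
            self.tree.clone(depth=1),
            had_missing_lengths=self.had_missing_lengths,
            meta=dict(self.meta),
        )

    def branch_lengths(self) -> list[float]:
        return [
            e.length if e.length is not None else 0.0
            for e in self.tree.preorder_edge_iter()
            if e.tail_node is not None
        ]

    def path_length_matrix(self) -> tuple[list[str], np.ndarray]:
        """Leaf-to-leaf patristic distances (order: sorted leaf names)."""
        pdm = self.tree.phylogenetic_distance_matrix()
        names = sorted(self.leaf_names())
        taxon = {t.label: t for t in self.tree.taxon_namespace}
        d = np.zeros((len(names), len(names)))
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                if i < j:
                    d[i, j] = d[j, i] = pdm.patristic_distance(taxon[a], taxon[b])
        return names, d

    def newick(self) -> str:
        return (
            self.tree.as_string(
                schema="newick",
                suppress_rooting=True,
                unquoted_underscores=True,
                suppress_internal_node_labels=False,
            ).strip()
        )


def read_newick(src: PathOrStream) -> PhyloTree:
    """Parse a Newick tree; absent branch lengths become 0 (flagged)."""
    handle, close = _open_read(src)
    try:
        text = handle.read()
    finally:
        if close:
            handle.close()
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise SeqFormatError(f"malformed Newick: {exc}") from exc
    missing = False
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        if edge.length is None:
            edge.length = 0.0
            missing = True
    return PhyloTree(tree, had_missing_lengths=missing)


def write_newick(tree: PhyloTree, dst: PathOrStream) -> None:
    handle, close = _open_write(dst)
    try:
        handle.write(tree.newick() + "\n")
    finally:
        if close:
            handle.close()


def tree_from_newick_string(text: str) -> PhyloTree:
    return read_newick(io.StringIO(text))
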