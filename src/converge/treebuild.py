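"""Distance-based gene trees: p-distance, Neighbor-Joining, bootstrap.

The p-distance is the proportion of differing residues among comparable
columns (units: amino-acid differences per site).  Neighbor-Joining is the
classic Saitou-Nei agglomeration on the Q-criterion; nonparametric bootstrap
support resamples alignment columns with replacement, rebuilds the NJ tree
per replicate, and annotates each internal edge of the full-data tree with
the percentage of replicates containing the same bipartition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np

from .seqio import MISSING_CODE, PhyloTree, ProteinAlignment

logger = logging.getLogger(__name__)

PAIRWISE_DELETION = "pairwise_deletion"
COMPLETE_DELETION = "complete_deletion"


class DistanceError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    """Pairwise distances with the per-pair compared-site counts."""

    taxa: list[str]
    d: np.ndarray
    denominators: np.ndarray

    @property
    def n(self) -> int:
        return len(self.taxa)


def _p_distance_codes(
    codes: np.ndarray, taxa: list[str], gap_mode: str
) -> DistanceMatrix:
    if gap_mode not in (PAIRWISE_DELETION, COMPLETE_DELETION):
        raise DistanceError(f"unknown gap_mode {gap_mode!r}")
    missing = codes == MISSING_CODE
    if gap_mode == COMPLETE_DELETION:
        keep = ~missing.any(axis=0)
        codes = codes[:, keep]
        missing = missing[:, keep]
    n = len(taxa)
    d = np.zeros((n, n))
    denom = np.zeros((n, n), dtype=np.int64)
    np.fill_diagonal(denom, codes.shape[1])
    for i in range(n):
        for j in range(i + 1, n):
            both = ~missing[i] & ~missing[j]
            m = int(both.sum())
            if m == 0:
                raise DistanceError(
                    f"no comparable sites between {taxa[i]!r} and {taxa[j]!r}"
                )
            diff = int((codes[i, both] != codes[j, both]).sum())
            d[i, j] = d[j, i] = diff / m
            denom[i, j] = denom[j, i] = m
    return DistanceMatrix(list(taxa), d, denom)


def p_distance(
    aln: ProteinAlignment, gap_mode: str = PAIRWISE_DELETION
) -> DistanceMatrix:
    """Proportion of differing residues per pair of sequences.

    Under ``pairwise_deletion`` each pair is compared over the sites where
    both residues are non-missing; ``complete_deletion`` first removes every
    column containing any missing residue.
    """
    if aln.n_taxa < 2:
        raise DistanceError("p_distance needs >= 2 taxa")
    return _p_distance_codes(aln.codes, aln.taxa, gap_mode)


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Classic Saitou-Nei Neighbor-Joining; returns an unrooted tree.

    Ties in the Q-criterion break toward the lowest (i, j) index pair.
    A negative branch length is clamped to 0 with the deficit shifted onto
    the sister edge, the usual remedy for slightly non-additive input.
    """
    if dm.n < 3:
        raise DistanceError("neighbor_joining needs >= 3 taxa")
    taxon_ns = dendropy.TaxonNamespace()
    nodes = []
    for name in dm.taxa:
        node = dendropy.Node()
        node.taxon = taxon_ns.new_taxon(name)
        nodes.append(node)
    D = dm.d.astype(float).copy()
    active = list(range(len(nodes)))

    def clamp_pair(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # row-major argmin = lowest (i, j) tie-break
        ai, aj = divmod(int(np.argmin(Q)), m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = clamp_pair(li, lj)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        nodes.append(parent)
        k = len(nodes) - 1
        newd = np.zeros(k + 1)
        D = np.pad(D, ((0, 1), (0, 1)))
        for ax in active:
            if ax in (i, j):
                continue
            D[k, ax] = D[ax, k] = 0.5 * (D[i, ax] + D[j, ax] - dij)
        active = [a for a in active if a not in (i, j)] + [k]

    # final three-point join (the unique unrooted resolution)
    a, b, c = active
    root = dendropy.Node()
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for idx, ln in ((a, la), (b, lb), (c, lc)):
        root.add_child(nodes[idx])
        nodes[idx].edge.length = max(ln, 0.0)
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    tree.seed_node = root
    return PhyloTree(tree)


def bipartitions(tree: PhyloTree) -> set[frozenset[str]]:
    """Nontrivial splits, each normalized to the side without the first leaf
    (alphabetically) so that rooted and unrooted encodings agree."""
    leaves = set(tree.leaf_names())
    anchor = min(leaves)
    splits: set[frozenset[str]] = set()
    for node in tree.tree.preorder_internal_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if anchor in side:
            side = frozenset(leaves - side)
        if 2 <= len(side) <= len(leaves) - 2:
            splits.add(side)
    return splits


def bootstrap_support(
    aln: ProteinAlignment,
    n_reps: int,
    seed: int,
    gap_mode: str = PAIRWISE_DELETION,
) -> PhyloTree:
    """NJ tree from the full data with bootstrap percentages on internal edges.

    Columns are resampled with replacement ``n_reps`` times; each internal
    edge of the full-data tree is annotated (node label, and
    ``meta['support']``) with the percentage of replicate trees containing
    the same bipartition.  A replicate in which some pair has no comparable
    site under pairwise deletion is redrawn, at most 10 times.
    """
    if n_reps < 1:
        raise DistanceError("n_reps must be >= 1")
    full = neighbor_joining(p_distance(aln, gap_mode))
    target = {s: 0 for s in bipartitions(full)}
    rng = np.random.default_rng(seed)
    codes = aln.codes
    n_sites = aln.n_sites
    for _ in range(n_reps):
        for attempt in range(10):
            idx = rng.integers(0, n_sites, size=n_sites)
            try:
                dm = _p_distance_codes(codes[:, idx], aln.taxa, gap_mode)
            except DistanceError:
                logger.warning("bootstrap replicate redrawn (incomparable pair)")
                continue
            break
        else:
            raise DistanceError(
                "10 consecutive bootstrap replicates had incomparable pairs"
            )
        rep_splits = bipartitions(neighbor_joining(dm))
        for s in target:
            if s in rep_splits:
                target[s] += 1

    leaves = set(full.leaf_names())
    anchor = min(leaves)
    support = {}
    for node in full.tree.preorder_internal_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        key = frozenset(leaves - side) if anchor in side else side
        if key in target:
            pct = 100.0 * target[key] / n_reps
            node.label = f"{pct:.0f}"
            support[key] = pct
    full.meta["support"] = support
    full.meta["n_reps"] = n_reps
    full.meta["seed"] = seed
    return full
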