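"""Simulation of protein alignments, random trees, and demo fixtures.

Everything the pipeline consumes can be generated here: alignments evolved
site-independently along a known tree under a reversible amino-acid model
(optionally a two-topology mixture in which a fraction ``f`` of sites follows
an alternative, "convergent" tree), random coalescent-style topologies for
oracle suites, and a small named-taxon fixture that mirrors the shape of a
horizontal-transfer question — one focal "mosquito" taxon whose true history
either stays with the insects (species tree H0) or jumps into the plant
clade (convergent tree H1).

All generators are pure functions of their integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np

from .seqio import PhyloTree, ProteinAlignment, tree_from_newick_string, write_fasta, write_newick
from .submodels import SubstitutionModel, load_model


@dataclass
class SimulationSpec:
    """Everything needed to simulate one alignment, reproducibly.

    ``convergent_mix`` is ``None`` or a pair ``(alt_tree, f)``: each site
    independently follows ``alt_tree`` with probability ``f`` (sites are
    exchangeable; no autocorrelation of convergent sites).
    """

    tree: PhyloTree
    model: SubstitutionModel
    n_sites: int
    seed: int
    convergent_mix: tuple[PhyloTree, float] | None = None

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.convergent_mix is not None:
            alt, f = self.convergent_mix
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"convergent fraction f={f} outside [0, 1]")
            if set(alt.leaf_names()) != set(self.tree.leaf_names()):
                raise ValueError("mixture trees must share a leaf set")


def _edge_list(tree: PhyloTree):
    """Preorder (parent_idx, child_idx, length) triples plus leaf labels."""
    nodes = list(tree.tree.preorder_node_iter())
    index = {id(n): i for i, n in enumerate(nodes)}
    edges = []
    for n in nodes:
        for c in n.child_nodes():
            ln = c.edge.length if c.edge.length is not None else 0.0
            edges.append((index[id(n)], index[id(c)], max(float(ln), 0.0)))
    leaves = {index[id(n)]: n.taxon.label for n in nodes if n.is_leaf()}
    return len(nodes), edges, leaves


def _sample_states(P_rows: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Vector draw from per-site categorical rows (inverse CDF)."""
    cum = np.cumsum(P_rows, axis=1)
    cum[:, -1] = 1.0
    return (u[:, None] > cum).sum(axis=1).astype(np.int64)


def _P_matrix(model: SubstitutionModel, t: float) -> np.ndarray:
    evals, left, right = model.spectral()
    P = (left * np.exp(evals * t)) @ right
    P = np.maximum(P, 0.0)
    return P / P.sum(axis=1, keepdims=True)


def simulate_alignment(spec: SimulationSpec) -> ProteinAlignment:
    """Evolve ``n_sites`` independent sites along the tree.

    Per site: a rate category is drawn from the model's (+G/+I) category
    weights, the root state from the equilibrium frequencies, and states
    propagate along each edge by sampling from the rows of P(rate * t).
    With a convergent mixture, a Bernoulli(f) flag per site selects the
    alternative topology.  Identical seeds give identical alignments.
    """
    rng = np.random.default_rng(spec.seed)
    model, n = spec.model, spec.n_sites
    from .submodels import discrete_gamma_rates

    cats = discrete_gamma_rates(model.alpha, model.k, model.p_inv)
    rates = np.array([r for r, _ in cats])
    weights = np.array([w for _, w in cats])

    alt_tree, f = (None, 0.0)
    if spec.convergent_mix is not None:
        alt_tree, f = spec.convergent_mix
    flags = rng.random(n) < f  # drawn even at f=0: keeps streams aligned

    cat_idx = _sample_states(np.tile(weights, (n, 1)), rng.random(n))
    root_states = _sample_states(np.tile(model.pi, (n, 1)), rng.random(n))

    trees = [spec.tree] + ([alt_tree] if alt_tree is not None else [])
    taxa_order = spec.tree.leaf_names()
    out_codes = np.zeros((len(taxa_order), n), dtype=np.int64)
    row_of = {t: i for i, t in enumerate(taxa_order)}

    for which, tree in enumerate(trees):
        mask = flags if which == 1 else ~flags if alt_tree is not None else np.ones(n, bool)
        sites = np.flatnonzero(mask)
        if sites.size == 0:
            continue
        n_nodes, edges, leaves = _edge_list(tree)
        states = np.zeros((n_nodes, sites.size), dtype=np.int64)
        states[0] = root_states[sites]
        for parent, child, t in edges:
            child_states = states[parent].copy()
            for c in np.unique(cat_idx[sites]):
                r = rates[c]
                sel = np.flatnonzero(cat_idx[sites] == c)
                u = rng.random(sel.size)
                if r == 0.0 or t == 0.0:
                    continue  # invariant category / zero branch: state copies
                P = _P_matrix(model, r * t)
                child_states[sel] = _sample_states(P[states[parent][sel]], u)
            states[child] = child_states
        for node, label in leaves.items():
            out_codes[row_of[label], sites] = states[node]

    return ProteinAlignment.from_codes(taxa_order, out_codes)


def random_tree(
    n_taxa: int,
    branch_length_dist=None,
    seed: int | None = None,
) -> PhyloTree:
    """Uniform coalescent-style random unrooted topology, leaves t1..tn.

    ``branch_length_dist`` is a callable ``(rng, size) -> lengths``;
    the default draws i.i.d. Exponential(mean 0.1) lengths.
    """
    if n_taxa < 3:
        raise ValueError("random_tree needs n_taxa >= 3")
    rng = np.random.default_rng(seed)
    if branch_length_dist is None:
        branch_length_dist = lambda r, size: r.exponential(0.1, size)

    taxon_ns = dendropy.TaxonNamespace()
    nodes = []
    for i in range(n_taxa):
        leaf = dendropy.Node()
        leaf.taxon = taxon_ns.new_taxon(f"t{i + 1}")
        nodes.append(leaf)
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    root = dendropy.Node()
    for x in nodes:
        root.add_child(x)
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    tree.seed_node = root
    edges = [e for e in tree.preorder_edge_iter() if e.tail_node is not None]
    lengths = np.asarray(branch_length_dist(rng, len(edges)), dtype=float)
    for e, ln in zip(edges, lengths):
        e.length = float(abs(ln))
    out = PhyloTree(tree)
    # collapse the degree-2 root so the tree is unrooted (basal degree 3)
    if len(tree.seed_node.child_nodes()) == 2:
        out.tree.deroot()
    return out


# ---------------------------------------------------------------------------
# Paper-like end-to-end fixture
# ---------------------------------------------------------------------------

_PLANTS = ["tomato", "potato", "arabidopsis", "wheat"]
_INSECTS = ["drosophila", "aedes", "culex", "bombyx"]
_FOCAL = "mosquito"

_H0_NEWICK = (
    "(((tomato:0.1,potato:0.1):0.1,(arabidopsis:0.15,wheat:0.15):0.1):0.3,"
    "((mosquito:0.1,aedes:0.1):0.1,(culex:0.15,(drosophila:0.2,bombyx:0.2):0.05):0.1):0.3);"
)
_H1_NEWICK = (
    "((((mosquito:0.1,tomato:0.1):0.05,potato:0.1):0.1,"
    "(arabidopsis:0.15,wheat:0.15):0.1):0.3,"
    "((aedes:0.15,culex:0.15):0.1,(drosophila:0.2,bombyx:0.2):0.1):0.3);"
)


@dataclass
class FixtureBundle:
    """Inputs for one end-to-end demo run of the convergence test."""

    alignment: ProteinAlignment
    h0: PhyloTree
    h1: PhyloTree
    model: SubstitutionModel
    convergent_fraction: float
    seed: int
    n_sites: int

    def write(self, outdir: str | Path) -> dict:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.alignment, outdir / "alignment.fasta")
        write_newick(self.h0, outdir / "h0.nwk")
        write_newick(self.h1, outdir / "h1.nwk")
        manifest = {
            "seed": self.seed,
            "n_sites": self.n_sites,
            "convergent_fraction": self.convergent_fraction,
            "model": self.model.describe(),
            "taxa": self.alignment.taxa,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        return manifest


def make_paper_like_fixture(
    seed: int,
    convergent_fraction: float = 1.0,
    n_sites: int = 200,
    model: SubstitutionModel | None = None,
) -> FixtureBundle:
    """A 9-taxon toy data set for the full pipeline.

    One focal mosquito taxon, four plants and four other insects.  H0 places
    the mosquito with the insects (the species tree); H1 places it inside the
    plant clade, sister to tomato — the topology a horizontally transferred,
    convergently evolving transcript would support.  The alignment is
    simulated under H0 with a fraction ``convergent_fraction`` of sites
    following H1 instead.
    """
    if model is None:
        model = load_model("WAG", alpha=0.8, k=4)
    h0 = tree_from_newick_string(_H0_NEWICK)
    h1 = tree_from_newick_string(_H1_NEWICK)
    spec = SimulationSpec(
        tree=h0,
        model=model,
        n_sites=n_sites,
        seed=seed,
        convergent_mix=(h1, convergent_fraction),
    )
    aln = simulate_alignment(spec)
    return FixtureBundle(
        aln, h0, h1, model, convergent_fraction, seed, n_sites
    )


def random_hit_table(n_queries: int, seed: int) -> str:
    """Synthetic 12-column similarity-search output for screen tests.

    Each query receives 1–4 hits against plant_/insect_/other_-prefixed
    subjects with random identities; roughly a quarter of the rows carry an
    E-value above the conventional 1e-3 cutoff so that parser filtering is
    exercised.  Returns the tab-separated text.
    """
    rng = np.random.default_rng(seed)
    groups = ["plant", "insect", "other"]
    lines = []
    for q in range(n_queries):
        for _ in range(int(rng.integers(1, 5))):
            group = groups[int(rng.integers(0, 3))]
            ident = float(np.round(rng.uniform(30, 100), 1))
            weak = rng.random() < 0.25
            evalue = 10.0 ** rng.uniform(-1.5, 0) if weak else 10.0 ** rng.uniform(-80, -4)
            length = int(rng.integers(50, 400))
            mismatch = int(round(length * (100 - ident) / 100))
            bits = float(np.round(length * 2 - mismatch, 1))
            lines.append(
                "\t".join(
                    str(x)
                    for x in (
                        f"q{q + 1}", f"{group}_{rng.integers(1, 1000)}", ident,
                        length, mismatch, 0, 1, length, 1, length,
                        f"{evalue:.2e}", bits,
                    )
                )
            )
    return "\n".join(lines) + "\n"


def random_ct_table(n_genes: int, seed: int):
    """Synthetic qPCR Ct table (target/reference, test/calibrator samples).

    Reference-gene Ct values sit near 18 cycles; target genes vary around
    24 with sample effects, giving 2^-ddCt fold changes spread around 1.
    Returns a pandas DataFrame with one row per gene.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    for g in range(n_genes):
        ct_ref_calib = rng.normal(18.0, 0.5)
        ct_ref_test = ct_ref_calib + rng.normal(0.0, 0.3)
        ct_target_calib = rng.normal(24.0, 1.5)
        ct_target_test = ct_target_calib + rng.normal(0.0, 1.5)
        rows.append(
            {
                "gene": f"gene{g + 1}",
                "ct_target_test": round(float(ct_target_test), 2),
                "ct_ref_test": round(float(ct_ref_test), 2),
                "ct_target_calib": round(float(ct_target_calib), 2),
                "ct_ref_calib": round(float(ct_ref_calib), 2),
            }
        )
    return pd.DataFrame(rows)


__all__ = [
    "SimulationSpec",
    "simulate_alignment",
    "random_tree",
    "FixtureBundle",
    "make_paper_like_fixture",
    "random_hit_table",
    "random_ct_table",
]
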