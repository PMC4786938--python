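"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from converge.seqio import tree_from_newick_string
from converge.submodels import (
    build_rate_matrix,
    discrete_gamma_rates,
    load_model,
    transition_probabilities,
)


@pytest.fixture(scope="session")
def wag():
    """WAG, homogeneous rates."""
    return load_model("WAG")


@pytest.fixture(scope="session")
def wag_g4():
    """WAG with 4-category discrete gamma (shape 0.7)."""
    return load_model("WAG", alpha=0.7, k=4)


@pytest.fixture(scope="session")
def dayhoff():
    return load_model("DAYHOFF")


@pytest.fixture
def quartet_trees():
    """Two conflicting unrooted quartets over the same leaf set."""
    h0 = tree_from_newick_string("(a:0.2,b:0.2,(c:0.2,d:0.2):0.2);")
    h1 = tree_from_newick_string("(a:0.2,c:0.2,(b:0.2,d:0.2):0.2);")
    return h0, h1


def exhaustive_sitewise_lnl(aln, tree, model):
    """Site log-likelihoods by explicit summation over every assignment of
    internal-node states — an oracle independent of the pruning recursion.

    Only feasible for small trees (cost 20^n_internal per category).
    """
    nodes = list(tree.tree.preorder_node_iter())
    idx = {id(n): i for i, n in enumerate(nodes)}
    edges = [
        (idx[id(n)], idx[id(c)], float(c.edge.length))
        for n in nodes
        for c in n.child_nodes()
    ]
    leaves = {idx[id(n)]: aln.taxa.index(n.taxon.label) for n in nodes if n.is_leaf()}
    internal = [i for i in range(len(nodes)) if i not in leaves]
    assert 0 in internal, "oracle expects an internal root"
    pos = {node: i for i, node in enumerate(internal)}
    grids = np.indices((20,) * len(internal)).reshape(len(internal), -1)
    codes = aln.codes
    Q = build_rate_matrix(model)
    cats = discrete_gamma_rates(model.alpha, model.k, model.p_inv)
    n = aln.n_sites
    lik = np.zeros(n)
    for rate, w in cats:
        if rate == 0.0:
            for i in range(n):
                col = codes[:, i]
                obs = col[col != 20]
                if obs.size == 0:
                    lik[i] += w
                elif np.all(obs == obs[0]):
                    lik[i] += w * model.pi[obs[0]]
            continue
        # scalar part: root prior and internal-internal edge factors,
        # one value per joint internal-state assignment
        scal = model.pi[grids[pos[0]]].copy()
        leaf_fac = np.ones((grids.shape[1], n))
        for (p, c, t) in edges:
            P = transition_probabilities(Q, rate * t, model.pi)
            sp = grids[pos[p]]
            if c in leaves:
                P_ext = np.hstack([P, np.ones((20, 1))])
                leaf_fac *= P_ext[sp][:, codes[leaves[c]]]
            else:
                scal = scal * P[sp, grids[pos[c]]]
        lik += w * (scal[:, None] * leaf_fac).sum(axis=0)
    return np.log(lik)


@pytest.fixture(scope="session")
def exhaustive_oracle():
    return exhaustive_sitewise_lnl
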