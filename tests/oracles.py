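"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: costs and likelihoods
are computed by exhaustive enumeration over ancestral state assignments,
distances by explicit root-path arithmetic.
"""

import itertools

import numpy as np

import phylogcn as pg
from phylogcn.simulate import SimConfig, simulate_tree


def random_tree(n_tips, rng, polytomy=False):
    """Random pure-birth tree, optionally with one internal edge collapsed
    into a polytomy."""
    t = simulate_tree(SimConfig(n_tips=n_tips, depth=None),
                      int(rng.integers(1 << 30)))
    if polytomy and n_tips >= 3:
        internal = [v for v in range(t.n_nodes)
                    if not t.is_tip[v] and v != t.root]
        if internal:
            v = int(rng.choice(internal))
            parent = t.parent.copy()
            for c in t.children(v):
                parent[c] = t.parent[v]
            keep = np.ones(t.n_nodes, bool)
            keep[v] = False
            remap = np.cumsum(keep) - 1
            t = pg.PhyloTree(
                [(-1 if parent[i] < 0 else int(remap[parent[i]]))
                 for i in range(t.n_nodes) if keep[i]],
                [t.branch_length[i] for i in range(t.n_nodes) if keep[i]],
                [t.labels[i] for i in range(t.n_nodes) if keep[i]],
            )
    return t


def root_path_distance(tree, a, b):
    """Patristic distance via explicit root paths (shared prefix subtracted)."""

    def path(v):
        out = []
        while v >= 0:
            out.append(v)
            v = int(tree.parent[v])
        return out[::-1]

    pa, pb = path(tree.tip_index[a]), path(tree.tip_index[b])
    k = 0
    while k < min(len(pa), len(pb)) and pa[k] == pb[k]:
        k += 1
    return (sum(tree.branch_length[v] for v in pa[k:])
            + sum(tree.branch_length[v] for v in pb[k:]))


def brute_nstd(tree, known):
    """Per-tip minimum over all pairwise patristic distances to known tips."""
    tips = tree.tip_labels
    return {
        t: min(root_path_distance(tree, t, k) for k in known) for t in tips
    }


def enum_sankoff(tree, known, n_states, cost_matrix):
    """Minimal total parsimony cost conditional on each node's state, by
    exhaustive enumeration over all unfixed node assignments."""
    free = [v for v in range(tree.n_nodes)
            if not (tree.is_tip[v] and tree.labels[v] in known)]
    fixed = {v: known[tree.labels[v]] - 1 for v in range(tree.n_nodes)
             if tree.is_tip[v] and tree.labels[v] in known}
    edges = [(int(tree.parent[v]), v) for v in range(tree.n_nodes)
             if tree.parent[v] >= 0]
    best = np.full((tree.n_nodes, n_states), np.inf)
    for assign in itertools.product(range(n_states), repeat=len(free)):
        st = dict(zip(free, assign))
        st.update(fixed)
        cost = sum(cost_matrix[st[p], st[c]] for p, c in edges)
        for v in range(tree.n_nodes):
            if cost < best[v, st[v]]:
                best[v, st[v]] = cost
    return best


def enum_mk(tree, known, n_states, rate, prior):
    """Total likelihood and marginal node posteriors of the ER Mk model by
    summation over all ancestral (and unknown-tip) state assignments."""
    S = n_states
    alpha = rate * S / (S - 1)

    def P(i, j, t):
        e = np.exp(-alpha * t)
        return 1 / S + (1 - 1 / S) * e if i == j else 1 / S - e / S

    free = [v for v in range(tree.n_nodes)
            if not (tree.is_tip[v] and tree.labels[v] in known)]
    fixed = {v: known[tree.labels[v]] - 1 for v in range(tree.n_nodes)
             if tree.is_tip[v] and tree.labels[v] in known}
    edges = [(int(tree.parent[v]), v, float(tree.branch_length[v]))
             for v in range(tree.n_nodes) if tree.parent[v] >= 0]
    total = 0.0
    marg = np.zeros((tree.n_nodes, S))
    for assign in itertools.product(range(S), repeat=len(free)):
        st = dict(zip(free, assign))
        st.update(fixed)
        lh = prior[st[tree.root]]
        for p, c, bl in edges:
            lh *= P(st[p], st[c], bl)
        total += lh
        for v in range(tree.n_nodes):
            marg[v, st[v]] += lh
    return np.log(total), marg / total


def random_partial_traits(tree, n_states, rng, n_unknown=None):
    """Random integer trait with a few unknown tips."""
    labs = tree.tip_labels
    if n_unknown is None:
        n_unknown = int(rng.integers(0, min(3, len(labs))))
    unknown = set(rng.choice(labs, size=n_unknown, replace=False)) \
        if n_unknown else set()
    known = {l: int(rng.integers(1, n_states + 1))
             for l in labs if l not in unknown}
    if not known:
        known = {labs[0]: 1}
        unknown.discard(labs[0])
    values = {l: known.get(l) for l in labs}
    return pg.TraitTable(values), known
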