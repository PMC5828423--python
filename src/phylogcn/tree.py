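"""Rooted phylogeny container and distance primitives.

Trees are stored as flat integer-indexed arrays (parent pointers, branch
lengths, child adjacency) so that the traversals used by the reconstruction
algorithms and the pair-distance machinery are cache-friendly and can be
vectorised with numpy.  Newick reading and writing is delegated to dendropy;
this module owns only the in-memory representation.

Branch lengths are in expected nucleotide substitutions per site.  A branch
length absent from the newick source is read as 0.0; operations that divide
by a branch length substitute :data:`EPSILON`.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import dendropy
import numpy as np

#: Substituted for zero branch lengths wherever an algorithm divides by a
#: branch length (substitutions/site).
EPSILON = 1e-8


class NewickParseError(ValueError):
    """Malformed newick input (message includes the parser's position)."""


class TreeValidationError(ValueError):
    """Structurally invalid tree (duplicate/empty tip labels, bad lengths)."""


class UnknownTipError(KeyError):
    """A queried label is not a tip of the tree."""


class PhyloTree:
    """A rooted phylogeny with branch lengths and labelled tips.

    Parameters
    ----------
    parent
        ``parent[i]`` is the parent node id of node ``i``; -1 for the root.
        Exactly one root is required and every node must be reachable from it.
    branch_length
        Length of the edge above each node (0 for the root). Non-negative.
    labels
        Per-node label or ``None``. Every tip (childless node) must carry a
        unique non-empty label; internal labels are preserved but never used
        for trait lookup.
    """

    def __init__(
        self,
        parent: Sequence[int],
        branch_length: Sequence[float],
        labels: Sequence[str | None],
    ):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.branch_length = np.asarray(branch_length, dtype=np.float64)
        self.labels = list(labels)
        n = self.parent.size
        if n == 0:
            raise TreeValidationError("a tree must contain at least one node")
        if not (self.branch_length.size == n and len(self.labels) == n):
            raise TreeValidationError("parent/branch_length/labels length mismatch")
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise TreeValidationError(f"expected exactly one root, found {roots.size}")
        self.root = int(roots[0])
        if np.any(self.branch_length < 0):
            raise TreeValidationError("negative branch length")

        # child adjacency in CSR form, preserving child insertion order
        order = np.argsort(self.parent[self.parent >= 0], kind="stable")
        kids = np.flatnonzero(self.parent >= 0)[order]
        counts = np.bincount(self.parent[kids], minlength=n)
        self._child_start = np.concatenate([[0], np.cumsum(counts)])
        self._child_flat = kids
        self.n_children = counts

        self.is_tip = counts == 0
        self.n_tips = int(self.is_tip.sum())

        self.preorder = self._compute_preorder()
        if self.preorder.size != n:
            raise TreeValidationError("nodes unreachable from the root")
        self.postorder = self.preorder[::-1].copy()

        # cumulative branch-length depth and integer level from the root
        self.depth = np.zeros(n)
        self.level = np.zeros(n, dtype=np.int64)
        for v in self.preorder:
            p = self.parent[v]
            if p >= 0:
                self.depth[v] = self.depth[p] + self.branch_length[v]
                self.level[v] = self.level[p] + 1

        self.tip_index: dict[str, int] = {}
        for v in np.flatnonzero(self.is_tip):
            lab = self.labels[v]
            if not lab:
                raise TreeValidationError(f"tip node {v} has an empty label")
            if lab in self.tip_index:
                raise TreeValidationError(f"duplicate tip label {lab!r}")
            self.tip_index[lab] = int(v)

        self._lca: _EulerLCA | None = None

    # -- construction ------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def tip_labels(self) -> list[str]:
        """Tip labels in node-id order."""
        return [self.labels[v] for v in np.flatnonzero(self.is_tip)]

    def children(self, v: int) -> np.ndarray:
        return self._child_flat[self._child_start[v] : self._child_start[v + 1]]

    def _compute_preorder(self) -> np.ndarray:
        order = np.empty(self.parent.size, dtype=np.int64)
        stack = [self.root]
        k = 0
        while stack:
            v = stack.pop()
            order[k] = v
            k += 1
            cs = self.children(v)
            # reversed so that children come off the stack in insertion order
            stack.extend(cs[::-1].tolist())
            if k > order.size:  # cycle guard
                raise TreeValidationError("cycle detected")
        return order[:k]

    # -- distances ---------------------------------------------------------

    def _ensure_lca(self) -> "_EulerLCA":
        if self._lca is None:
            self._lca = _EulerLCA(self)
        return self._lca

    def tip_ids(self, labels: Iterable[str]) -> np.ndarray:
        ids = []
        for lab in labels:
            try:
                ids.append(self.tip_index[lab])
            except KeyError:
                raise UnknownTipError(f"{lab!r} is not a tip of this tree") from None
        return np.asarray(ids, dtype=np.int64)

    def node_distances(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        """Patristic distances between paired node-id arrays ``u`` and ``v``."""
        u = np.asarray(u, dtype=np.int64)
        v = np.asarray(v, dtype=np.int64)
        a = self._ensure_lca().lca(u, v)
        return self.depth[u] + self.depth[v] - 2.0 * self.depth[a]

    def total_branch_length(self) -> float:
        return float(self.branch_length.sum())

    def scale_branch_lengths(self, factor: float) -> None:
        """Multiply all branch lengths (and cached depths) by ``factor``."""
        self.branch_length *= factor
        self.depth *= factor

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PhyloTree {self.n_tips} tips, {self.n_nodes} nodes>"


class _EulerLCA:
    """Euler-tour + sparse-table structure for O(1) batched LCA queries."""

    def __init__(self, tree: PhyloTree):
        n = tree.n_nodes
        m = 2 * n - 1
        euler = np.empty(m, dtype=np.int64)
        first = np.full(n, -1, dtype=np.int64)
        # iterative Euler tour
        k = 0
        stack: list[tuple[int, int]] = [(tree.root, 0)]
        while stack:
            v, ci = stack.pop()
            if ci == 0:
                first[v] = k
            euler[k] = v
            k += 1
            cs = tree.children(v)
            if ci < cs.size:
                stack.append((v, ci + 1))
                stack.append((int(cs[ci]), 0))
        assert k == m
        self.first = first
        levels = tree.level[euler]
        # sparse table of positions of the minimum level in each power-of-two block
        K = max(1, int(np.floor(np.log2(m))) + 1)
        pos = np.arange(m, dtype=np.int64)
        table = [pos]
        cur = pos
        j = 1
        while (1 << j) <= m:
            half = 1 << (j - 1)
            left = cur[: m - (1 << j) + 1]
            right = cur[half : half + m - (1 << j) + 1]
            take_right = levels[right] < levels[left]
            cur = np.where(take_right, right, left)
            table.append(cur)
            j += 1
        self._table = table
        self._levels = levels
        self._euler = euler

    def lca(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        l = self.first[u]
        r = self.first[v]
        lo = np.minimum(l, r)
        hi = np.maximum(l, r)
        length = hi - lo + 1
        k = np.zeros_like(length)
        nz = length > 1
        k[nz] = np.floor(np.log2(length[nz])).astype(np.int64)
        # gather from the k-level table; loop over the distinct ks present
        res = np.empty_like(lo)
        for kk in np.unique(k):
            mask = k == kk
            tab = self._table[kk]
            a = tab[lo[mask]]
            b = tab[hi[mask] - (1 << int(kk)) + 1]
            res[mask] = np.where(self._levels[b] < self._levels[a], b, a)
        return self._euler[res]


# -- newick I/O (dendropy-backed) -----------------------------------------


def parse_newick(text: str) -> PhyloTree:
    """Parse a single rooted newick statement into a :class:`PhyloTree`.

    Quoted labels, internal-node labels, missing branch lengths (read as 0)
    and polytomies are supported. Raises :class:`NewickParseError` on
    malformed input and :class:`TreeValidationError` on duplicate tips.
    """
    if not text.strip():
        raise NewickParseError("empty newick string")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        if "Duplicate taxon labels" in str(exc):
            raise TreeValidationError(f"duplicate tip labels: {exc}") from None
        raise NewickParseError(f"malformed newick: {exc}") from None
    return _from_dendropy(dtree)


def read_newick(path) -> PhyloTree:
    with open(path, encoding="utf-8") as fh:
        content = "".join(
            line for line in fh if not line.lstrip().startswith("#")
        )
    return parse_newick(content)


def _from_dendropy(dtree: "dendropy.Tree") -> PhyloTree:
    nodes = list(dtree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    parent = np.full(len(nodes), -1, dtype=np.int64)
    blen = np.zeros(len(nodes))
    labels: list[str | None] = [None] * len(nodes)
    for i, nd in enumerate(nodes):
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
            blen[i] = nd.edge.length if nd.edge.length is not None else 0.0
        if nd.taxon is not None:
            labels[i] = nd.taxon.label
        elif nd.label is not None:
            labels[i] = nd.label
    return PhyloTree(parent, blen, labels)


def write_newick(tree: PhyloTree, path=None, header: str | None = None) -> str:
    """Serialise to newick (branch lengths at 12 significant digits).

    If ``path`` is given the string is also written there; ``header`` lines
    (already '#'-prefixed) are prepended in the file only.
    """
    dtree = _to_dendropy(tree)
    text = dtree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        preserve_spaces=True,
        real_value_format_specifier=".12g",
    ).strip() + "\n"
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            if header:
                fh.write(header)
            fh.write(text)
    return text


def _to_dendropy(tree: PhyloTree) -> "dendropy.Tree":
    ns = dendropy.TaxonNamespace()
    dtree = dendropy.Tree(taxon_namespace=ns)
    dnodes = [dendropy.Node() for _ in range(tree.n_nodes)]
    for v in tree.preorder:
        v = int(v)
        nd = dnodes[v]
        if tree.is_tip[v]:
            nd.taxon = ns.new_taxon(tree.labels[v])
        elif tree.labels[v]:
            nd.label = tree.labels[v]
        p = int(tree.parent[v])
        if p >= 0:
            dnodes[p].add_child(nd)
            nd.edge.length = float(tree.branch_length[v])
    dtree.seed_node = dnodes[tree.root]
    return dtree


# -- scalar convenience ----------------------------------------------------


def patristic_distance(tree: PhyloTree, tip1: str, tip2: str) -> float:
    """Sum of branch lengths along the unique path between two tips."""
    ids = tree.tip_ids([tip1, tip2])
    return float(tree.node_distances(ids[:1], ids[1:])[0])


def resolve_polytomies(tree: PhyloTree) -> PhyloTree:
    """Binary version of ``tree``: polytomies become right-ladders of
    zero-length edges. Tip labels and patristic distances are unchanged."""
    parent = tree.parent.tolist()
    blen = tree.branch_length.tolist()
    labels = list(tree.labels)
    for v in range(tree.n_nodes):
        kids = [int(c) for c in tree.children(v)]
        while len(kids) > 2:
            # pull the last two children under a fresh zero-length node
            a, b = kids.pop(), kids.pop()
            new = len(parent)
            parent.append(v)
            blen.append(0.0)
            labels.append(None)
            parent[a] = new
            parent[b] = new
            kids.append(new)
    return PhyloTree(parent, blen, labels)
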