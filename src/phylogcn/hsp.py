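"""Hidden-state prediction (HSP) of a discrete tip trait from a phylogeny.

Five reconstruction families, each mapping (tree, partially known trait
table) to a prediction for every tip:

* Sankoff maximum parsimony with all-equal / proportional / exponential
  transition costs (``hsp_sankoff``);
* maximum likelihood under the equal-rates Mk model with exact marginal
  posteriors (``hsp_mk_er``);
* phylogenetic independent contrasts (``hsp_pic``);
* weighted squared-change parsimony (``hsp_wscp``);
* subtree averaging (``hsp_subtree_avg``).

All methods are exact interpolators: tips whose trait is known are returned
unchanged.  States are positive integers 1..S; predictions are real numbers
in [1, S].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .tables import TraitTable
from .tree import EPSILON, PhyloTree, resolve_polytomies


class HSPError(ValueError):
    """Invalid HSP input (no known tips, state out of range, ...)."""


@dataclass
class CostScheme:
    """Symmetric transition-cost function over states 1..S.

    ``all_equal``: cost 1 for any change; ``proportional``: |i-j|;
    ``exponential``: exp(|i-j|) for i != j.  Diagonal cost is 0.
    """

    name: str

    _BUILDERS = {
        "all_equal": lambda d: (d > 0).astype(float),
        "proportional": lambda d: d.astype(float),
        "exponential": lambda d: np.where(d > 0, np.exp(d), 0.0),
    }

    def matrix(self, n_states: int) -> np.ndarray:
        if self.name not in self._BUILDERS:
            raise HSPError(f"unknown cost scheme {self.name!r}")
        i = np.arange(n_states)
        d = np.abs(i[:, None] - i[None, :])
        return self._BUILDERS[self.name](d)


@dataclass
class PredictionSet:
    """Tip label -> predicted trait value, plus method metadata."""

    predictions: dict[str, float]
    method: str
    params: dict = field(default_factory=dict)
    state_support: dict[str, np.ndarray] | None = None  # MPR sets / posteriors

    def __getitem__(self, tip: str) -> float:
        return self.predictions[tip]

    def values_for(self, tips) -> np.ndarray:
        return np.array([self.predictions[t] for t in tips])


@dataclass
class MkFit:
    """Fitted equal-rates Mk model."""

    rate: float
    log_likelihood: float
    root_prior: np.ndarray
    n_trials: int
    at_boundary: bool = False


def _known_arrays(tree: PhyloTree, traits: TraitTable, n_states: int | None):
    known = traits.known
    known = {k: v for k, v in known.items() if k in tree.tip_index}
    if not known:
        raise HSPError("hidden-state prediction requires at least one known tip")
    smax = max(known.values())
    S = n_states if n_states is not None else smax
    if smax > S:
        raise HSPError(f"observed state {smax} outside 1..{S}")
    idx = np.array([tree.tip_index[k] for k in known], dtype=np.int64)
    states = np.array(list(known.values()), dtype=np.int64) - 1  # 0-based
    return idx, states, S, known


# -- Sankoff maximum parsimony --------------------------------------------


def sankoff_scores(tree: PhyloTree, traits: TraitTable, scheme: CostScheme | str,
                   n_states: int | None = None):
    """Per-node parsimony cost vectors.

    Returns ``(up, total)``: ``up[v, s]`` is the minimal cost of the subtree
    below v given v is in state s (unknown tips contribute a zero vector);
    ``total[v, s]`` is the minimal cost of the whole tree conditional on
    node v being in state s (up-pass plus rest-of-tree costs).
    """
    if isinstance(scheme, str):
        scheme = CostScheme(scheme)
    idx, states, S, _ = _known_arrays(tree, traits, n_states)
    C = scheme.matrix(S)
    n = tree.n_nodes
    INF = np.inf
    up = np.zeros((n, S))
    known_state = np.full(n, -1, dtype=np.int64)
    known_state[idx] = states
    contrib = np.zeros((n, S))  # min_t(C[s,t] + up[child,t]) stored per child

    for v in tree.postorder:
        if tree.is_tip[v]:
            if known_state[v] >= 0:
                up[v] = INF
                up[v, known_state[v]] = 0.0
            # unknown tip: zero vector
        else:
            acc = np.zeros(S)
            for c in tree.children(v):
                contrib[c] = (C + up[c][None, :]).min(axis=1)
                acc += contrib[c]
            up[v] = acc

    rest = np.zeros((n, S))
    for v in tree.preorder:
        if v == tree.root:
            continue
        p = tree.parent[v]
        # cost of everything outside the subtree of v, conditional on v's state
        other = rest[p] + up[p] - contrib[v]
        rest[v] = (C + other[:, None]).min(axis=0)
    total = up + rest
    return up, total


def hsp_sankoff(tree: PhyloTree, traits: TraitTable, scheme: CostScheme | str = "all_equal",
                n_states: int | None = None, tie_policy: str = "mean") -> PredictionSet:
    """Sankoff parsimony prediction for every tip.

    For each unknown tip the MPR set is the set of states attaining the
    minimal conditional total cost; the point prediction is the arithmetic
    mean of the MPR set (``tie_policy="mean"``) or its smallest member
    (``"min_state"``).  Known tips are returned unchanged.
    """
    if isinstance(scheme, str):
        scheme = CostScheme(scheme)
    _, _, S, known = _known_arrays(tree, traits, n_states)
    _, total = sankoff_scores(tree, traits, scheme, S)
    preds: dict[str, float] = {}
    support: dict[str, np.ndarray] = {}
    for v in np.flatnonzero(tree.is_tip):
        lab = tree.labels[v]
        if lab in known:
            preds[lab] = float(known[lab])
            continue
        row = total[v]
        m = row.min()
        mpr = np.flatnonzero(row <= m + 1e-9 * max(1.0, abs(m))) + 1
        support[lab] = mpr
        preds[lab] = float(mpr.mean() if tie_policy == "mean" else mpr.min())
    return PredictionSet(preds, f"mpr_{scheme.name}",
                         {"n_states": S, "tie_policy": tie_policy}, support)


# -- Mk equal-rates maximum likelihood ------------------------------------


def _er_propagate(vec: np.ndarray, decay: float) -> np.ndarray:
    """Apply the ER transition matrix exp(Q t) to ``vec``; ``decay``
    is exp(-r*S/(S-1)*t).  Works for likelihood messages in both directions
    because the ER matrix is symmetric."""
    m = vec.sum() / vec.size
    return m + decay * (vec - m)


def mk_log_likelihood(tree: PhyloTree, traits: TraitTable, n_states: int,
                      rate: float, root_prior: np.ndarray) -> float:
    """Felsenstein pruning log-likelihood of the ER Mk model."""
    up, scale_log = _mk_up_pass(tree, traits, n_states, rate)
    if up is None:
        return -np.inf
    root_lh = float(root_prior @ up[tree.root])
    if root_lh <= 0:
        return -np.inf
    return float(np.log(root_lh) + scale_log)


def _mk_up_pass(tree: PhyloTree, traits: TraitTable, S: int, rate: float):
    idx, states, S, _ = _known_arrays(tree, traits, S)
    alpha = rate * S / (S - 1)
    decay = np.exp(-alpha * tree.branch_length)
    n = tree.n_nodes
    up = np.ones((n, S))
    for i, v in zip(states, idx):
        up[v] = 0.0
        up[v, i] = 1.0
    scale_log = 0.0
    msg = np.ones((n, S))  # message from each node to its parent
    for v in tree.postorder:
        if not tree.is_tip[v]:
            acc = np.ones(S)
            for c in tree.children(v):
                acc = acc * msg[c]
            s = acc.sum()
            if s <= 0:
                return None, -np.inf  # impossible data at this rate
            acc /= s
            scale_log += np.log(s)
            up[v] = acc
        if v != tree.root:
            msg[v] = _er_propagate(up[v], decay[v])
    return up, scale_log


def mk_marginal_posteriors(tree: PhyloTree, traits: TraitTable, n_states: int,
                           rate: float, root_prior: np.ndarray) -> np.ndarray:
    """Exact marginal posterior state probabilities at every node.

    Outside messages are combined with the inside (pruning) vectors; for the
    reversible ER chain this equals the rerooting construction with the
    given prior placed at the root.
    """
    idx, states, S, _ = _known_arrays(tree, traits, n_states)
    alpha = rate * S / (S - 1)
    decay = np.exp(-alpha * tree.branch_length)
    up, _ = _mk_up_pass(tree, traits, S, rate)
    n = tree.n_nodes
    msg = np.ones((n, S))
    for v in tree.postorder:
        if v != tree.root:
            msg[v] = _er_propagate(up[v], decay[v])
    out = np.ones((n, S))
    out[tree.root] = root_prior
    for v in tree.preorder:
        cs = tree.children(v)
        if cs.size == 0:
            continue
        # prefix/suffix products of child messages for sibling exclusion
        k = cs.size
        prefix = np.ones((k + 1, S))
        for i, c in enumerate(cs):
            prefix[i + 1] = prefix[i] * msg[c]
        suffix = np.ones((k + 1, S))
        for i in range(k - 1, -1, -1):
            suffix[i] = suffix[i + 1] * msg[cs[i]]
        for i, c in enumerate(cs):
            base = out[v] * prefix[i] * suffix[i + 1]
            s = base.sum()
            if s > 0:
                base = base / s
            out[c] = _er_propagate(base, decay[c])
    post = out * up
    norm = post.sum(axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return post / norm


def hsp_mk_er(tree: PhyloTree, traits: TraitTable, n_states: int | None = None,
              n_trials: int = 5, seed: int = 0,
              rate_bounds_scale=(1e-6, 1e3)) -> tuple[MkFit, PredictionSet]:
    """ML fit of the equal-rates Mk model plus posterior-mean predictions.

    The transition rate is profiled in log space with ``n_trials`` restarts
    (one moment-matching start, the rest log-uniform over the bounds); the
    root prior is the empirical state frequency among known tips.  Unknown
    tips are predicted by their marginal posterior expectation.
    """
    idx, states, S, known = _known_arrays(tree, traits, n_states)
    if S < 2:
        S = 2
    freqs = np.bincount(states, minlength=S).astype(float)
    prior = freqs / freqs.sum()
    mean_bl = max(float(tree.branch_length[tree.branch_length > 0].mean())
                  if np.any(tree.branch_length > 0) else EPSILON, EPSILON)
    lo, hi = rate_bounds_scale[0] / mean_bl, rate_bounds_scale[1] / mean_bl

    if np.unique(states).size < 2:
        # all known tips identical: rate pinned at the lower bound
        fit = MkFit(lo, mk_log_likelihood(tree, traits, S, lo, prior), prior,
                    0, at_boundary=True)
        value = float(states[0] + 1)
        preds = {lab: float(known.get(lab, value)) for lab in tree.tip_index}
        return fit, PredictionSet(preds, "mk_er", {"n_states": S, "rate": lo})

    def neg_ll(logr):
        r = float(np.exp(np.asarray(logr).reshape(-1)[0]))
        return -mk_log_likelihood(tree, traits, S, r, prior)

    starts = [np.log(_mk_moment_rate(tree, idx, states, S, lo, hi))]
    rng = np.random.default_rng(seed)
    starts += list(rng.uniform(np.log(lo), np.log(hi), size=max(0, n_trials - 1)))
    best = None
    for x0 in starts:
        res = optimize.minimize(neg_ll, x0=[x0], method="L-BFGS-B",
                                bounds=[(np.log(lo), np.log(hi))],
                                options={"ftol": 1e-8, "gtol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
    rate = float(np.exp(best.x[0]))
    ll = -float(best.fun)
    at_bound = bool(np.isclose(np.log(rate), np.log(lo), atol=1e-6))
    fit = MkFit(rate, ll, prior, len(starts), at_boundary=at_bound)

    post = mk_marginal_posteriors(tree, traits, S, rate, prior)
    svals = np.arange(1, S + 1)
    preds: dict[str, float] = {}
    support: dict[str, np.ndarray] = {}
    for v in np.flatnonzero(tree.is_tip):
        lab = tree.labels[v]
        if lab in known:
            preds[lab] = float(known[lab])
        else:
            preds[lab] = float(post[v] @ svals)
            support[lab] = post[v].copy()
    return fit, PredictionSet(preds, "mk_er", {"n_states": S, "rate": rate},
                              support)


def _mk_moment_rate(tree, idx, states, S, lo, hi, max_pairs=1000):
    """Moment start: match the fraction of equal-state random known pairs to
    the ER two-tip identity probability at the mean pair distance."""
    rng = np.random.default_rng(12345)
    k = idx.size
    m = min(max_pairs, 4 * k)
    a = rng.integers(k, size=m)
    b = rng.integers(k, size=m)
    ok = a != b
    if not np.any(ok):
        return np.sqrt(lo * hi)
    d = tree.node_distances(idx[a[ok]], idx[b[ok]])
    same = (states[a[ok]] == states[b[ok]]).mean()
    dbar = max(d.mean(), EPSILON)
    x = np.clip((same - 1.0 / S) / (1.0 - 1.0 / S), 1e-3, 0.999)
    alpha = -np.log(x) / dbar
    return float(np.clip(alpha * (S - 1) / S, lo, hi))


# -- phylogenetic independent contrasts -----------------------------------


def hsp_pic(tree: PhyloTree, traits: TraitTable) -> PredictionSet:
    """Felsenstein independent-contrasts ancestral estimates, pushed to tips.

    The upward pass is restricted to subtrees containing data: each internal
    node with at least one known descending tip receives the
    inverse-branch-length-weighted estimate and an inflated effective branch
    length.  Unknown tips are predicted by the estimate of their nearest
    ancestor that has one.  Polytomies are resolved internally into
    zero-length right-ladder bifurcations.
    """
    _known_arrays(tree, traits, None)
    work = tree if np.all(tree.n_children[~tree.is_tip] <= 2) else resolve_polytomies(tree)
    known = traits.known
    n = work.n_nodes
    est = np.full(n, np.nan)
    elen = np.full(n, np.nan)
    for v in work.postorder:
        bl = max(float(work.branch_length[v]), EPSILON)
        if work.is_tip[v]:
            lab = work.labels[v]
            if lab in known:
                est[v] = known[lab]
                elen[v] = bl
            continue
        kids = [int(c) for c in work.children(v) if not np.isnan(est[c])]
        if not kids:
            continue
        if len(kids) == 1:
            est[v] = est[kids[0]]
            elen[v] = bl + elen[kids[0]]
        else:
            a, b = kids
            wa, wb = 1.0 / elen[a], 1.0 / elen[b]
            est[v] = (wa * est[a] + wb * est[b]) / (wa + wb)
            elen[v] = bl + 1.0 / (wa + wb)
    # unknown tips inherit from their nearest estimated ancestor in the
    # ORIGINAL tree (ladder nodes introduced by the resolution are skipped,
    # so predictions do not depend on the arbitrary resolution order);
    # original node ids coincide between the two trees.
    preds: dict[str, float] = {}
    for v in np.flatnonzero(tree.is_tip):
        lab = tree.labels[v]
        if lab in known:
            preds[lab] = float(known[lab])
            continue
        u = int(tree.parent[v])
        while u >= 0 and np.isnan(est[u]):
            u = int(tree.parent[u])
        preds[lab] = float(est[u])
    return PredictionSet(preds, "pic", {})


# -- weighted squared-change parsimony ------------------------------------


def wscp_values(tree: PhyloTree, traits: TraitTable) -> np.ndarray:
    """Exact minimiser of sum_edges (x_parent - x_child)^2 / length with the
    known tip values held fixed; returns the optimal value at every node.

    The objective is a tree-structured positive-definite quadratic, solved
    by one upward Gaussian-elimination pass (each subtree reduces to an
    equivalent observation with a precision weight) and one downward
    substitution pass.  Zero branch lengths use the epsilon policy.
    """
    known = {k: v for k, v in traits.known.items() if k in tree.tip_index}
    if not known:
        raise HSPError("WSCP requires at least one known tip")
    n = tree.n_nodes
    w_edge = 1.0 / np.maximum(tree.branch_length, EPSILON)
    m_up = np.zeros(n)   # equivalent-observation mean from below
    w_up = np.zeros(n)   # equivalent-observation weight (0 = no data below)
    fixed = np.full(n, np.nan)
    for v in np.flatnonzero(tree.is_tip):
        lab = tree.labels[v]
        if lab in known:
            fixed[v] = known[lab]
    msg_m = np.zeros(n)  # message through the edge above each node
    msg_w = np.zeros(n)
    for v in tree.postorder:
        if tree.is_tip[v]:
            if not np.isnan(fixed[v]):
                m_up[v], w_up[v] = fixed[v], np.inf
        else:
            cs = tree.children(v)
            W = msg_w[cs].sum()
            if W > 0:
                m_up[v] = (msg_w[cs] * msg_m[cs]).sum() / W
                w_up[v] = W
        if v != tree.root and w_up[v] > 0:
            if np.isinf(w_up[v]):
                msg_w[v] = w_edge[v]
            else:
                msg_w[v] = w_up[v] * w_edge[v] / (w_up[v] + w_edge[v])
            msg_m[v] = m_up[v]
    x = np.full(n, np.nan)
    for v in tree.preorder:
        if not np.isnan(fixed[v]):
            x[v] = fixed[v]
            continue
        if v == tree.root:
            if w_up[v] <= 0:
                raise HSPError("WSCP requires at least one known tip")
            x[v] = m_up[v]
        else:
            p = tree.parent[v]
            if w_up[v] > 0 and np.isfinite(w_up[v]):
                x[v] = (w_up[v] * m_up[v] + w_edge[v] * x[p]) / (w_up[v] + w_edge[v])
            elif w_up[v] > 0:  # fixed tip, already handled
                x[v] = m_up[v]
            else:
                x[v] = x[p]
    return x


def hsp_wscp(tree: PhyloTree, traits: TraitTable) -> PredictionSet:
    """Weighted squared-change parsimony prediction for every tip."""
    x = wscp_values(tree, traits)
    known = traits.known
    preds = {}
    for v in np.flatnonzero(tree.is_tip):
        lab = tree.labels[v]
        preds[lab] = float(known[lab]) if lab in known else float(x[v])
    return PredictionSet(preds, "wscp", {})


# -- subtree averaging -----------------------------------------------------


def hsp_subtree_avg(tree: PhyloTree, traits: TraitTable) -> PredictionSet:
    """Arithmetic mean of known descending tip values, inherited by unknown
    tips from their nearest ancestor that has any known descendant."""
    known = {k: v for k, v in traits.known.items() if k in tree.tip_index}
    if not known:
        raise HSPError("subtree averaging requires at least one known tip")
    n = tree.n_nodes
    tot = np.zeros(n)
    cnt = np.zeros(n)
    for v in tree.postorder:
        if tree.is_tip[v]:
            lab = tree.labels[v]
            if lab in known:
                tot[v] = known[lab]
                cnt[v] = 1
        else:
            cs = tree.children(v)
            tot[v] = tot[cs].sum()
            cnt[v] = cnt[cs].sum()
    preds = {}
    for v in np.flatnonzero(tree.is_tip):
        lab = tree.labels[v]
        if lab in known:
            preds[lab] = float(known[lab])
            continue
        u = int(tree.parent[v])
        while u >= 0 and cnt[u] == 0:
            u = int(tree.parent[u])
        preds[lab] = float(tot[u] / cnt[u])
    return PredictionSet(preds, "sa", {})


# -- registry --------------------------------------------------------------


def run_method(name: str, tree: PhyloTree, traits: TraitTable, **kwargs) -> PredictionSet:
    """Run an HSP method by its short code (mpr_ae, mpr_pr, mpr_exp, mk_er,
    pic, wscp, sa) and return its PredictionSet."""
    if name in ("mpr_ae", "mpr_pr", "mpr_exp"):
        scheme = {"mpr_ae": "all_equal", "mpr_pr": "proportional",
                  "mpr_exp": "exponential"}[name]
        return hsp_sankoff(tree, traits, scheme, **kwargs)
    if name == "mk_er":
        return hsp_mk_er(tree, traits, **kwargs)[1]
    if name == "pic":
        return hsp_pic(tree, traits, **kwargs)
    if name == "wscp":
        return hsp_wscp(tree, traits, **kwargs)
    if name == "sa":
        return hsp_subtree_avg(tree, traits, **kwargs)
    raise HSPError(f"unknown HSP method {name!r}")


METHOD_CODES = ("mpr_ae", "mpr_pr", "mpr_exp", "mk_er", "pic", "wscp", "sa")
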