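"""Synthetic trees, trait histories, coverage masks, and OTU tables.

The generators emulate the statistical structure the downstream analyses
assume: birth(-death) trees whose patristic distances span roughly 0-1
substitutions/site, an integer copy-number-like trait on states 1..S whose
autocorrelation decays with patristic distance, partial trait coverage with
a broad nearest-sequenced-taxon-distance (NSTD) spectrum, and log-normal
OTU read-count tables.  Every output is a pure function of (config, seed).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np

from .tables import TraitTable, AbundanceTable
from .tree import PhyloTree

import pandas as pd


class SimulationError(RuntimeError):
    """Simulation could not satisfy its contract (e.g. repeated extinction)."""


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent, reproducible RNG stream derived from (seed, name)."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed) % (2**31), spawn_key=(key,)))


def er_rate_for_acf(n_states: int, distance: float, target_corr: float) -> float:
    """Equal-rates Markov rate giving trait autocorrelation ``target_corr``
    at patristic distance ``distance``.

    For the S-state equal-rates chain started at stationarity, the Pearson
    correlation between the states of two tips at patristic distance d is
    exp(-r*S/(S-1)*d) for any state scoring, because all non-constant
    eigenmodes share the eigenvalue -r*S/(S-1).
    """
    if not (0 < target_corr < 1) or distance <= 0:
        raise ValueError("need 0 < target_corr < 1 and distance > 0")
    alpha = -np.log(target_corr) / distance
    return alpha * (n_states - 1) / n_states


@dataclass
class SimConfig:
    """Study conditions for the desk-scale benchmark ("benchmark-small").

    Defaults: a 2000-tip pure-birth tree rescaled to depth 0.5
    substitutions/site (pair distances span ~0-1); an equal-rates Markov
    trait on states 1..15 with the rate calibrated so that the trait
    autocorrelation is 0.5 at distance 0.15 (the decay scale reported for
    16S copy numbers); clade-drop masking down to 50% known tips; and
    log-normal OTU tables of 50 samples x 2000 reads.
    """

    n_tips: int = 2000
    tree_model: str = "yule"  # "yule" or "birth_death"
    birth: float = 1.0
    death: float = 0.0
    depth: float = 0.5
    trait_model: str = "mk_er"  # or "bounded_walk"
    n_states: int = 15
    rate: float | None = None  # None -> calibrated from the ACF closed form
    root_policy: str = "stationary"  # or an integer state
    mask_policy: str = "clade_drop"  # or "random"
    known_fraction: float = 0.5
    n_samples: int = 50
    reads_per_sample: int = 2000
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 2.0
    present_fraction: float = 0.075
    nstd_bias_max: float = 8.0

    def resolved_rate(self) -> float:
        if self.rate is not None:
            return self.rate
        return er_rate_for_acf(self.n_states, distance=0.15, target_corr=0.5)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["resolved_rate"] = self.resolved_rate()
        return d


# -- trees -----------------------------------------------------------------


def simulate_tree(config: SimConfig, seed: int) -> PhyloTree:
    """Binary rooted tree with exactly ``config.n_tips`` tips, labelled
    t1..tN in node order, branch lengths > 0, rescaled to ``config.depth``."""
    rng = substream(seed, "tree")
    n = config.n_tips
    if n < 1:
        raise ValueError("n_tips must be >= 1")
    if n == 1:
        return PhyloTree([-1], [0.0], ["t1"])
    if config.tree_model == "yule":
        tree = _birth_death(n, config.birth, 0.0, rng)
    elif config.tree_model == "birth_death":
        if not config.death < config.birth:
            raise ValueError("birth-death model requires death < birth")
        tree = _birth_death(n, config.birth, config.death, rng)
    else:
        raise ValueError(f"unknown tree model {config.tree_model!r}")
    if config.depth is not None:
        maxdepth = tree.depth[tree.is_tip].max()
        if maxdepth > 0:
            tree.scale_branch_lengths(config.depth / maxdepth)
    return tree


def _birth_death(n: int, birth: float, death: float, rng: np.random.Generator,
                 max_attempts: int = 100) -> PhyloTree:
    for _ in range(max_attempts):
        tree = _birth_death_once(n, birth, death, rng)
        if tree is not None:
            return tree
    raise SimulationError(
        f"lineages went extinct before reaching {n} tips in {max_attempts} attempts"
    )


def _birth_death_once(n, birth, death, rng):
    # Gillespie forward simulation until n live lineages, then extend the
    # pendant branches by the waiting time to the next (uncommitted) event.
    parent = [-1]
    start = [0.0]
    blen = [0.0]
    alive = [0]
    t = 0.0
    while len(alive) < n:
        if not alive:
            return None
        total = len(alive) * (birth + death)
        t += rng.exponential(1.0 / total)
        i = rng.integers(len(alive))
        v = alive[i]
        if rng.random() < birth / (birth + death):
            blen[v] = t - start[v]
            for _ in range(2):
                parent.append(v)
                start.append(t)
                blen.append(0.0)
                alive.append(len(parent) - 1)
            alive.pop(i)
        else:
            blen[v] = t - start[v]
            alive.pop(i)
    t += rng.exponential(1.0 / (len(alive) * (birth + death)))
    for v in alive:
        blen[v] = t - start[v]
    return _prune_to(parent, blen, set(alive))


def _prune_to(parent, blen, survivors):
    """Spanning tree of the survivors with unary nodes suppressed."""
    n = len(parent)
    keep = np.zeros(n, dtype=bool)
    for v in survivors:
        while v >= 0 and not keep[v]:
            keep[v] = True
            v = parent[v]
    children: list[list[int]] = [[] for _ in range(n)]
    for v in range(1, n):
        if keep[v]:
            children[parent[v]].append(v)
    # find the new root: topmost kept node with >=2 children (or a lone tip)
    root = 0
    while len(children[root]) == 1:
        root = children[root][0]
    new_parent: list[int] = []
    new_blen: list[float] = []
    labels: list[str | None] = []
    tip_counter = [0]

    stack: list[tuple[int, int, float]] = [(root, -1, 0.0)]
    order: list[tuple[int, int, float]] = []
    while stack:
        v, p_new, acc = stack.pop()
        # suppress unary chains, accumulating branch length
        while len(children[v]) == 1:
            c = children[v][0]
            acc += blen[c]
            v = c
        idx = len(new_parent)
        new_parent.append(p_new)
        new_blen.append(acc)
        if not children[v]:
            tip_counter[0] += 1
            labels.append(f"t{tip_counter[0]}")
        else:
            labels.append(None)
        for c in children[v]:
            stack.append((c, idx, blen[c]))
        order.append((v, idx, acc))
    return PhyloTree(new_parent, new_blen, labels)


# -- traits ----------------------------------------------------------------


def _root_state(policy, n_states, rng) -> int:
    if policy == "stationary":
        return int(rng.integers(1, n_states + 1))
    state = int(policy)
    if not 1 <= state <= n_states:
        raise ValueError(f"root state {state} outside 1..{n_states}")
    return state


def simulate_trait_mk(tree: PhyloTree, n_states: int, rate: float, seed: int,
                      root_policy="stationary") -> TraitTable:
    """Evolve an equal-rates Markov trait on states 1..S along the tree.

    Every off-diagonal transition has rate r/(S-1) (total leaving rate r).
    Exact per-branch sampling: with probability exp(-r*S/(S-1)*t) the state
    is kept, otherwise it is redrawn uniformly from 1..S -- this reproduces
    the ER transition matrix exactly, no time discretisation involved.
    """
    if n_states < 2 or rate < 0:
        raise ValueError("need n_states >= 2 and rate >= 0")
    rng = substream(seed, "trait_mk")
    alpha = rate * n_states / (n_states - 1)
    state = np.zeros(tree.n_nodes, dtype=np.int64)
    state[tree.root] = _root_state(root_policy, n_states, rng)
    keep = rng.random(tree.n_nodes) < np.exp(-alpha * tree.branch_length)
    redraw = rng.integers(1, n_states + 1, size=tree.n_nodes)
    for v in tree.preorder:
        p = tree.parent[v]
        if p < 0:
            continue
        state[v] = state[p] if keep[v] else redraw[v]
    return TraitTable(
        {tree.labels[v]: int(state[v]) for v in np.flatnonzero(tree.is_tip)}
    )


def simulate_trait_bounded_walk(tree: PhyloTree, n_states: int, rate: float,
                                seed: int, root_policy="stationary") -> TraitTable:
    """Stepwise +-1 trait walk on 1..S, reflecting at the boundaries.

    Jumps to each admissible neighbouring state occur at rate ``rate``
    (interior states leave at 2*rate, boundary states at rate), which makes
    the stationary distribution uniform and reduces to the S=2 equal-rates
    Markov chain with total rate ``rate``.
    """
    if n_states < 2 or rate < 0:
        raise ValueError("need n_states >= 2 and rate >= 0")
    rng = substream(seed, "trait_walk")
    state = np.zeros(tree.n_nodes, dtype=np.int64)
    state[tree.root] = _root_state(root_policy, n_states, rng)
    for v in tree.preorder:
        p = tree.parent[v]
        if p < 0:
            continue
        s = int(state[p])
        remaining = float(tree.branch_length[v])
        if rate > 0:
            while True:
                leave = rate * ((1 if s == 1 else 1 if s == n_states else 2)
                                if n_states > 1 else 0)
                wait = rng.exponential(1.0 / leave)
                if wait >= remaining:
                    break
                remaining -= wait
                if s == 1:
                    s = 2
                elif s == n_states:
                    s = n_states - 1
                else:
                    s += 1 if rng.random() < 0.5 else -1
        state[v] = s
    return TraitTable(
        {tree.labels[v]: int(state[v]) for v in np.flatnonzero(tree.is_tip)}
    )


# -- masking ---------------------------------------------------------------


def mask_known(trait: TraitTable, tree: PhyloTree, policy: str,
               fraction: float, seed: int) -> TraitTable:
    """Hide trait values to emulate partial genome coverage.

    ``random``: each tip kept known independently with probability
    ``fraction``.  ``clade_drop``: whole clades are unlabelled until at most
    ``fraction`` of the initially known tips remain, producing contiguous
    high-NSTD regions.  Raises if no known tip would remain.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    rng = substream(seed, f"mask_{policy}")
    known = [lab for lab in trait.known_tips if lab in tree.tip_index]
    if policy == "random":
        keep = {lab for lab in known if rng.random() < fraction}
    elif policy == "clade_drop":
        keep = _clade_drop(tree, known, fraction, rng)
    else:
        raise ValueError(f"unknown masking policy {policy!r}")
    if not keep:
        raise SimulationError("masking would leave zero known tips")
    return trait.mask(keep)


def _clade_drop(tree, known, fraction, rng):
    known_set = set(known)
    target = int(round(fraction * len(known)))
    target = max(target, 1)
    while len(known_set) > target:
        excess = len(known_set) - target
        # per-node count of still-known descending tips
        cnt = np.zeros(tree.n_nodes, dtype=np.int64)
        for v in tree.postorder:
            if tree.is_tip[v]:
                cnt[v] = 1 if tree.labels[v] in known_set else 0
            else:
                cnt[v] = cnt[tree.children(v)].sum()
        # cap each drop at half the remaining excess and draw the clade size
        # log-uniformly, so both shallow singletons and deep clades are
        # removed -- this is what spreads the NSTD spectrum
        cap = max(1, excess // 2)
        candidates = np.flatnonzero((cnt >= 1) & (cnt <= cap))
        if candidates.size == 0:
            candidates = np.flatnonzero((cnt == 1) & tree.is_tip)
        sizes = cnt[candidates]
        drop_size = np.exp(rng.uniform(0.0, np.log(sizes.max())))
        close = candidates[np.abs(np.log(sizes) - np.log(drop_size))
                           <= np.log(2.0)]
        if close.size == 0:
            close = candidates[[int(np.argmin(np.abs(np.log(sizes)
                                                     - np.log(drop_size))))]]
        v = int(rng.choice(close))
        for u in _subtree_tips(tree, v):
            known_set.discard(tree.labels[u])
    return known_set


def _subtree_tips(tree, v):
    out = []
    stack = [v]
    while stack:
        u = stack.pop()
        if tree.is_tip[u]:
            out.append(u)
        else:
            stack.extend(int(c) for c in tree.children(u))
    return out


# -- abundances ------------------------------------------------------------


def simulate_abundances(tree: PhyloTree, config: SimConfig, seed: int,
                        tip_scores: dict[str, float] | None = None,
                        biases: np.ndarray | None = None) -> AbundanceTable:
    """Log-normal OTU read-count tables over the tree's tips.

    Per sample: a fraction of OTUs is drawn as present, each present OTU
    receives a log-normal weight, and ``reads_per_sample`` reads are drawn
    multinomially.  If ``tip_scores`` (e.g. per-tip NSTDs) and per-sample
    ``biases`` are given, OTU presence probabilities are tilted by
    exp(-bias*score), so samples with large bias are enriched for low-score
    (well-covered) OTUs -- emulating the coverage gradient between, say,
    animal-associated and environmental communities.  Bias 0 recovers the
    unbiased model.  Samples with bias above the median are labelled
    "proximal", the rest "distal".
    """
    rng = substream(seed, "abundances")
    tips = tree.tip_labels
    n = len(tips)
    n_present = max(1, int(round(config.present_fraction * n)))
    scores = np.zeros(n)
    if tip_scores is not None:
        scores = np.array([float(tip_scores.get(lab, 0.0)) for lab in tips])
    if biases is None:
        biases = np.zeros(config.n_samples)
    biases = np.asarray(biases, dtype=float)
    if biases.size != config.n_samples:
        raise ValueError("biases must have one entry per sample")

    counts = np.zeros((n, config.n_samples), dtype=np.int64)
    for s in range(config.n_samples):
        logp = -biases[s] * scores
        p = np.exp(logp - logp.max())
        p /= p.sum()
        present = rng.choice(n, size=min(n_present, n), replace=False, p=p)
        weights = rng.lognormal(config.lognormal_mu, config.lognormal_sigma,
                                size=present.size)
        probs = weights / weights.sum()
        counts[present, s] = rng.multinomial(config.reads_per_sample, probs)
    cols = [f"s{j + 1}" for j in range(config.n_samples)]
    med = np.median(biases)
    groups = {
        c: ("proximal" if biases[j] > med else "distal")
        for j, c in enumerate(cols)
    }
    frame = pd.DataFrame(counts, index=pd.Index(tips, name="otu_id"), columns=cols)
    return AbundanceTable(frame, groups)


# -- bundled fixture -------------------------------------------------------


@dataclass
class SimBundle:
    config: SimConfig
    seed: int
    tree: PhyloTree
    traits: TraitTable
    traits_masked: TraitTable


def generate_benchmark(config: SimConfig | None = None, seed: int = 42) -> SimBundle:
    """Generate the benchmark tree + trait + mask triple for a seed."""
    config = config or SimConfig()
    tree = simulate_tree(config, seed)
    rate = config.resolved_rate()
    if config.trait_model == "mk_er":
        traits = simulate_trait_mk(tree, config.n_states, rate, seed,
                                   config.root_policy)
    elif config.trait_model == "bounded_walk":
        traits = simulate_trait_bounded_walk(tree, config.n_states, rate, seed,
                                             config.root_policy)
    else:
        raise ValueError(f"unknown trait model {config.trait_model!r}")
    masked = mask_known(traits, tree, config.mask_policy,
                        config.known_fraction, seed)
    return SimBundle(config, seed, tree, traits, masked)
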