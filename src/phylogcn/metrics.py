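"""Predictability statistics: R², trait autocorrelation, NSTD, NSTI.

The coefficient of determination used throughout is 1 - SS_res/SS_tot,
which is negative when predictions are worse than the reference mean; the
squared Pearson correlation is provided separately (``pearson_r2``) and the
two are never interchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .tables import TraitTable
from .tree import PhyloTree


class UndefinedResultError(ValueError):
    """A statistic is undefined for this input (e.g. zero reference variance)."""


def coefficient_of_determination(reference, predicted) -> float:
    """Fraction of variance in ``reference`` explained by ``predicted``.

    R² = 1 - Σ(y-ŷ)²/Σ(y-ȳ)².  Asymmetric: the first argument is the
    quantity being explained.  May be negative.
    """
    y = np.asarray(reference, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size < 2:
        raise ValueError("need at least 2 values")
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise UndefinedResultError("reference has zero variance")
    return 1.0 - float(((y - yhat) ** 2).sum()) / ss_tot


r_squared = coefficient_of_determination


def pearson_r2(x, y) -> float:
    """Squared Pearson correlation (symmetric, in [0, 1])."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise UndefinedResultError("constant input to Pearson correlation")
    return float(stats.pearsonr(x, y).statistic ** 2)


def relative_deviation(a: float, b: float) -> float:
    """|A-B| / ((A+B)/2): symmetric relative disagreement, in [0, 2)."""
    if a <= 0 or b <= 0:
        raise ValueError("relative deviation requires positive inputs")
    return abs(a - b) / ((a + b) / 2.0)


# -- phylogenetic trait autocorrelation -----------------------------------


@dataclass
class ACFCurve:
    """Binned Pearson autocorrelation of a tip trait vs patristic distance."""

    bin_lower: np.ndarray
    bin_upper: np.ndarray
    mean_distance: np.ndarray
    correlation: np.ndarray  # NaN where undefined (flagged)
    n_pairs: np.ndarray
    npairs_requested: int
    nbins: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lower": self.bin_lower,
                "bin_upper": self.bin_upper,
                "mean_distance": self.mean_distance,
                "correlation": self.correlation,
                "n_pairs": self.n_pairs,
            }
        )

    def correlation_at(self, distance: float) -> float:
        """Linear interpolation of the curve at a distance (defined bins)."""
        ok = ~np.isnan(self.correlation)
        return float(np.interp(distance, self.mean_distance[ok],
                               self.correlation[ok]))

    def half_correlation_distance(self) -> float:
        """Smallest binned distance where the ACF drops below 0.5."""
        ok = ~np.isnan(self.correlation)
        d = self.mean_distance[ok]
        c = self.correlation[ok]
        below = np.flatnonzero(c < 0.5)
        if below.size == 0:
            return float("nan")
        i = below[0]
        if i == 0:
            return float(d[0])
        # linear interpolation between the straddling bins
        d0, d1, c0, c1 = d[i - 1], d[i], c[i - 1], c[i]
        if c0 == c1:
            return float(d1)
        return float(d0 + (c0 - 0.5) * (d1 - d0) / (c0 - c1))


def trait_acf(tree: PhyloTree, traits: TraitTable, n_pairs: int = 10**6,
              n_bins: int = 100, seed: int = 0) -> ACFCurve:
    """Pearson autocorrelation function of a tip trait over patristic distance.

    Samples ``n_pairs`` ordered tip pairs uniformly with replacement among
    tips with known trait, bins them into ``n_bins`` equal-width distance
    intervals spanning [0, max sampled distance], and computes the Pearson
    correlation within each bin over the symmetrised pair set (each pair
    contributes both orderings, so the two margins share their moments).
    Bins with zero trait variance carry a NaN (flagged undefined)
    correlation but keep their pair counts.
    """
    if n_pairs < 1 or n_bins < 1:
        raise ValueError("need n_pairs >= 1 and n_bins >= 1")
    known = traits.known
    labels = [k for k in known if k in tree.tip_index]
    if len(labels) < 2:
        raise ValueError("trait ACF requires at least 2 known tips")
    ids = tree.tip_ids(labels)
    vals = np.array([float(known[k]) for k in labels])
    rng = np.random.default_rng(seed)

    k = ids.size
    cnt = np.zeros(n_bins, dtype=np.int64)
    sum_d = np.zeros(n_bins)
    sum_x = np.zeros(n_bins)
    sum_xx = np.zeros(n_bins)
    sum_xy = np.zeros(n_bins)

    # two passes: first to find the maximum sampled distance (deterministic
    # given the seed), then binned accumulation over the same pairs
    chunks = []
    chunk_size = 1 << 19
    remaining = int(n_pairs)
    while remaining > 0:
        m = min(chunk_size, remaining)
        a = rng.integers(k, size=m)
        b = rng.integers(k, size=m)
        chunks.append((a, b, tree.node_distances(ids[a], ids[b])))
        remaining -= m
    dmax = max(float(d.max()) for _, _, d in chunks)
    for a, b, d in chunks:
        if dmax > 0:
            bins = np.minimum((d / dmax * n_bins).astype(np.int64), n_bins - 1)
        else:
            bins = np.zeros(d.size, dtype=np.int64)
        x = vals[a]
        y = vals[b]
        cnt += np.bincount(bins, minlength=n_bins)
        sum_d += np.bincount(bins, weights=d, minlength=n_bins)
        sum_x += np.bincount(bins, weights=x + y, minlength=n_bins)
        sum_xx += np.bincount(bins, weights=x * x + y * y, minlength=n_bins)
        sum_xy += np.bincount(bins, weights=x * y, minlength=n_bins)

    with np.errstate(invalid="ignore", divide="ignore"):
        mean = sum_x / (2 * cnt)
        var = sum_xx / (2 * cnt) - mean**2
        cov = sum_xy / cnt - mean**2
        corr = np.where(var > 1e-12 * np.maximum(1.0, mean**2), cov / var, np.nan)
        mean_d = sum_d / cnt
    width = dmax / n_bins if dmax > 0 else 0.0
    lower = np.arange(n_bins) * width
    upper = lower + width
    keep = cnt > 0
    return ACFCurve(lower[keep], upper[keep], mean_d[keep], corr[keep],
                    cnt[keep], int(n_pairs), int(n_bins))


# -- nearest-sequenced-taxon distance / index ------------------------------


@dataclass
class NSTDMap:
    """Tip label -> distance to the nearest 'known' tip (0 for known tips)."""

    values: dict[str, float]
    known: set[str] = field(default_factory=set)

    def __getitem__(self, tip: str) -> float:
        return self.values[tip]

    def array_for(self, tips) -> np.ndarray:
        return np.array([self.values[t] for t in tips])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"tip_id": list(self.values), "nstd": list(self.values.values())}
        )


def compute_nstd(tree: PhyloTree, known: Iterable[str]) -> NSTDMap:
    """Minimum patristic distance from every tip to any known tip.

    Linear-time two-pass message passing: a rootward pass collects the
    nearest known tip within each subtree, a leafward pass propagates the
    nearest known tip reachable through each node's parent.
    """
    known = set(known)
    if not known:
        raise ValueError("NSTD requires a non-empty known tip set")
    bad = [k for k in known if k not in tree.tip_index]
    if bad:
        raise ValueError(f"unknown tips in known set (first: {bad[:3]})")
    n = tree.n_nodes
    down = np.full(n, np.inf)
    for lab in known:
        down[tree.tip_index[lab]] = 0.0
    for v in tree.postorder:
        cs = tree.children(v)
        if cs.size:
            d = down[cs] + tree.branch_length[cs]
            m = d.min()
            if m < down[v]:
                down[v] = m
    up = np.full(n, np.inf)
    for v in tree.preorder:
        cs = tree.children(v)
        if cs.size == 0:
            continue
        d = down[cs] + tree.branch_length[cs]
        # two smallest child contributions, for sibling exclusion
        if d.size == 1:
            best1, best2, arg1 = d[0], np.inf, 0
        else:
            order = np.argsort(d)
            best1, best2, arg1 = d[order[0]], d[order[1]], order[0]
        base = up[v]
        if tree.is_tip[v] and down[v] == 0.0:
            base = 0.0  # a known tip is its own nearest neighbour upward
        for i, c in enumerate(cs):
            other = best2 if i == arg1 else best1
            up[c] = tree.branch_length[c] + min(base, other)
    nstd = np.minimum(down, up)
    values = {
        tree.labels[v]: (0.0 if tree.labels[v] in known else float(nstd[v]))
        for v in np.flatnonzero(tree.is_tip)
    }
    return NSTDMap(values, known)


def compute_nsti(nstd: NSTDMap, counts: Mapping[str, float]) -> float:
    """Abundance-weighted mean NSTD over the OTUs present in one sample."""
    otus = [o for o, c in counts.items() if c > 0 and o in nstd.values]
    if not otus:
        raise ValueError("NSTI requires at least one positive count")
    w = np.array([float(counts[o]) for o in otus])
    d = np.array([nstd.values[o] for o in otus])
    return float((w * d).sum() / w.sum())


# -- NSTD-binned R² --------------------------------------------------------


@dataclass
class BinnedR2:
    """Per-NSTD-bin coefficients of determination."""

    bin_lower: np.ndarray
    bin_upper: np.ndarray
    n: np.ndarray
    r2: np.ndarray  # NaN where flagged undefined (zero reference variance)
    min_count: int
    bin_width: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin_lower": self.bin_lower, "bin_upper": self.bin_upper,
             "n": self.n, "r2": self.r2}
        )


def bin_r2_by_nstd(reference, predicted, nstd, bin_width: float,
                   min_count: int = 10) -> BinnedR2:
    """R² computed separately within equal-width NSTD bins [k·w, (k+1)·w).

    Bins with fewer than ``min_count`` items are omitted; bins with zero
    reference variance are kept but flagged with NaN.
    """
    y = np.asarray(reference, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    d = np.asarray(nstd, dtype=float)
    if not (y.size == yhat.size == d.size):
        raise ValueError("reference, predicted and nstd must be aligned")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    idx = (d / bin_width).astype(np.int64)
    lowers, uppers, ns, r2s = [], [], [], []
    for b in np.unique(idx):
        mask = idx == b
        if mask.sum() < min_count:
            continue
        lowers.append(b * bin_width)
        uppers.append((b + 1) * bin_width)
        ns.append(int(mask.sum()))
        try:
            r2s.append(coefficient_of_determination(y[mask], yhat[mask]))
        except UndefinedResultError:
            r2s.append(np.nan)
    return BinnedR2(np.array(lowers), np.array(uppers), np.array(ns),
                    np.array(r2s), min_count, bin_width)


def average_nstd(*maps: NSTDMap) -> dict[str, float]:
    """Arithmetic average of per-tip NSTDs across calibration sets.

    When two prediction sets carry different NSTDs for one item (because
    their calibration sets differ), the item's effective NSTD is the mean
    of the available values.
    """
    out: dict[str, list[float]] = {}
    for m in maps:
        for k, v in m.values.items():
            out.setdefault(k, []).append(v)
    return {k: float(np.mean(v)) for k, v in out.items()}
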