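"""Composite experiments: NSTD-stratified cross-validation of HSP methods,
pairwise comparison of prediction sets across communities (R² vs NSTI), the
permutation significance test, and copy-number correction of read counts.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import metrics
from .hsp import PredictionSet, run_method
from .metrics import NSTDMap, UndefinedResultError, compute_nstd
from .simulate import SimBundle, SimConfig, generate_benchmark, simulate_abundances, substream
from .tables import AbundanceTable, TraitTable, write_abundance_table, write_table, write_trait_table
from .tree import PhyloTree, write_newick


@dataclass
class CVResult:
    """Cross-validated R² per NSTD cutoff for one HSP method."""

    method: str
    cutoffs: np.ndarray
    r2: np.ndarray          # (repeats, cutoffs), NaN where skipped
    test_sizes: np.ndarray  # (repeats,)
    train_sizes: np.ndarray  # (repeats, cutoffs)
    test_fraction: float
    repeats: int
    seed: int
    #: per repeat, (test set, {cutoff: training set}); kept only on request
    sets: list[tuple[set, dict]] | None = None

    @property
    def mean_r2(self) -> np.ndarray:
        n = np.sum(~np.isnan(self.r2), axis=0)
        s = np.nansum(self.r2, axis=0)
        return np.where(n > 0, s / np.maximum(n, 1), np.nan)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cutoff": self.cutoffs,
                "mean_r2_cv": self.mean_r2,
                "n_repeats_used": np.sum(~np.isnan(self.r2), axis=0),
                "mean_train_size": self.train_sizes.mean(axis=0),
            }
        )


def crossval_r2_curve(tree: PhyloTree, traits: TraitTable, method: str,
                      cutoffs, test_fraction: float = 0.02, repeats: int = 3,
                      seed: int = 0, method_kwargs: dict | None = None,
                      record_sets: bool = False) -> CVResult:
    """NSTD-stratified cross-validation of one HSP method.

    Per repeat, a random test set (``test_fraction`` of the known tips,
    without replacement, shared across cutoffs) is hidden; per cutoff c, the
    training set additionally excludes every known tip whose minimum
    distance to the test set is below c.  The method is re-run on the
    training labels only and scored by the coefficient of determination on
    the test tips.  Cutoffs whose training set is empty, or whose test truth
    is constant, are flagged (NaN) rather than fatal.
    """
    method_kwargs = method_kwargs or {}
    cutoffs = np.asarray(sorted(cutoffs), dtype=float)
    if np.any(cutoffs < 0):
        raise ValueError("cutoffs must be >= 0")
    known = traits.known
    known_labels = [k for k in known if k in tree.tip_index]
    K = len(known_labels)
    n_test = max(1, int(round(test_fraction * K)))
    if n_test >= K:
        raise ValueError("test fraction leaves no training tips")
    rng = substream(seed, f"cv_{method}")
    r2 = np.full((repeats, cutoffs.size), np.nan)
    train_sizes = np.zeros((repeats, cutoffs.size))
    test_sizes = np.zeros(repeats, dtype=int)
    sets: list[tuple[set, dict]] | None = [] if record_sets else None

    for rep in range(repeats):
        test = list(rng.choice(known_labels, size=n_test, replace=False))
        test_sizes[rep] = len(test)
        truth = np.array([float(known[t]) for t in test])
        dist_to_test = compute_nstd(tree, test)
        test_set = set(test)
        if sets is not None:
            sets.append((set(test), {}))
        for j, c in enumerate(cutoffs):
            train = {
                k for k in known_labels
                if k not in test_set and dist_to_test.values[k] >= c
            }
            train_sizes[rep, j] = len(train)
            if sets is not None:
                sets[rep][1][float(c)] = set(train)
            if not train:
                continue
            preds = run_method(method, tree, traits.mask(train), **method_kwargs)
            try:
                r2[rep, j] = metrics.coefficient_of_determination(
                    truth, preds.values_for(test)
                )
            except UndefinedResultError:
                pass
    if np.all(np.isnan(r2)):
        raise RuntimeError("all cutoff/repeat cells were skipped")
    return CVResult(method, cutoffs, r2, test_sizes, train_sizes,
                    test_fraction, repeats, seed, sets)


# -- per-sample comparison of two prediction sets --------------------------


@dataclass
class SampleComparison:
    sample: str
    group: str
    n_otus: int
    r2: float
    nsti: float
    mean_a: float
    mean_b: float
    excluded: bool = False
    reason: str = ""


def compare_prediction_sets(pred_a: PredictionSet, pred_b: PredictionSet,
                            abundances: AbundanceTable,
                            nstd_a: NSTDMap, nstd_b: NSTDMap,
                            log_scale: bool = False) -> list[SampleComparison]:
    """Per-sample agreement between two prediction sets.

    For each sample, OTUs with at least one read and a prediction from both
    sets are compared: R² is the variance in the first set explained by the
    second; the NSTI weights each OTU's calibration-set-averaged NSTD by its
    relative abundance.  Samples with fewer than 2 eligible OTUs or zero
    variance in the first set are flagged excluded.
    """
    overlap = set(pred_a.predictions) & set(pred_b.predictions)
    common = [o for o in abundances.otus if o in overlap]
    if not common:
        raise ValueError("prediction sets share no OTUs with the table")
    nstd_avg = metrics.average_nstd(nstd_a, nstd_b)
    out: list[SampleComparison] = []
    for s in abundances.samples:
        col = abundances.counts[s]
        otus = [o for o in common if col[o] > 0]
        group = abundances.groups.get(s, "")
        if len(otus) < 2:
            out.append(SampleComparison(s, group, len(otus), np.nan, np.nan,
                                        np.nan, np.nan, True, "fewer than 2 OTUs"))
            continue
        a = pred_a.values_for(otus)
        b = pred_b.values_for(otus)
        if log_scale:
            a, b = np.log(a), np.log(b)
        w = col[otus].to_numpy(dtype=float)
        d = np.array([nstd_avg[o] for o in otus])
        nsti = float((w * d).sum() / w.sum())
        try:
            r2 = metrics.coefficient_of_determination(a, b)
        except UndefinedResultError:
            out.append(SampleComparison(s, group, len(otus), np.nan, nsti,
                                        float(a.mean()), float(b.mean()),
                                        True, "zero variance"))
            continue
        out.append(SampleComparison(s, group, len(otus), r2, nsti,
                                    float(a.mean()), float(b.mean())))
    return out


def comparisons_frame(comparisons: list[SampleComparison]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in comparisons])


@dataclass
class TrendResult:
    """Pearson trend between per-sample R² and NSTI within one group."""

    group: str
    n: int
    r: float
    r2: float
    p_value: float
    permutations: int
    slope: float
    intercept: float


def nsti_r2_trend(comparisons: list[SampleComparison], group: str | None = None,
                  permutations: int = 1000, seed: int = 0) -> TrendResult:
    """Pearson correlation between NSTI and per-sample R², with a
    permutation P value: P = (b+1)/(m+1) where b counts permutations whose
    |r| meets or exceeds the observed |r| after shuffling R² against NSTI.
    """
    kept = [c for c in comparisons
            if not c.excluded and (group is None or c.group == group)]
    if len(kept) < 3:
        raise ValueError("trend requires at least 3 non-excluded samples")
    nsti = np.array([c.nsti for c in kept])
    r2s = np.array([c.r2 for c in kept])
    if np.std(nsti) == 0 or np.std(r2s) == 0:
        raise UndefinedResultError("constant NSTI or R² in group")
    r_obs = float(stats.pearsonr(nsti, r2s).statistic)
    rng = substream(seed, f"trend_{group}")
    # vectorised permutation null: shuffle the R² vector m times
    m = int(permutations)
    perm = np.empty(m)
    x = (nsti - nsti.mean()) / nsti.std()
    y = (r2s - r2s.mean()) / r2s.std()
    n = x.size
    for i in range(m):
        perm[i] = float(x @ rng.permutation(y)) / n
    b = int(np.sum(np.abs(perm) >= abs(r_obs) - 1e-15))
    p = (b + 1) / (m + 1)
    lin = stats.linregress(nsti, r2s)
    return TrendResult(group or "all", n, r_obs, r_obs**2, p, m,
                       float(lin.slope), float(lin.intercept))


# -- copy-number correction ------------------------------------------------


def correct_abundances(abundances: AbundanceTable, predictions: PredictionSet,
                       renormalize: bool = False) -> pd.DataFrame:
    """Divide read counts by predicted copy numbers.

    Every OTU with a positive count must carry a prediction >= 1; with
    ``renormalize`` the corrected columns are scaled to sum to 1 (relative
    cell-abundance estimates).
    """
    counts = abundances.counts
    present = counts.index[(counts > 0).any(axis=1)]
    missing = [o for o in present if o not in predictions.predictions]
    if missing:
        raise ValueError(
            f"{len(missing)} OTUs with reads lack predictions (first: {missing[:5]})"
        )
    bad = [o for o in present if predictions.predictions[o] < 1]
    if bad:
        raise ValueError(f"predictions < 1 for OTUs (first: {bad[:5]})")
    gcn = np.array([predictions.predictions.get(o, 1.0) for o in counts.index])
    corrected = counts.astype(float).div(gcn, axis=0)
    if renormalize:
        sums = corrected.sum(axis=0)
        sums[sums == 0] = 1.0
        corrected = corrected.div(sums, axis=1)
    return corrected


# -- end-to-end benchmark driver ------------------------------------------


@dataclass
class BenchmarkReport:
    bundle: SimBundle
    abundances: AbundanceTable
    acf: "metrics.ACFCurve"
    nstd: NSTDMap
    cv: dict[str, CVResult]
    comparisons: list[SampleComparison]
    trends: dict[str, TrendResult]
    summary: dict = field(default_factory=dict)


def run_benchmark(config: SimConfig | None = None, methods=("mpr_exp", "pic", "sa"),
                  cutoffs=np.arange(0.0, 0.45, 0.05), out_dir: str | None = None,
                  seed: int = 42, compare_pair=("mpr_ae", "pic"),
                  acf_pairs: int = 10**6, acf_bins: int = 20,
                  permutations: int = 1000) -> BenchmarkReport:
    """Run the full synthetic pipeline and (optionally) write its reports.

    Stages: simulate tree+trait+mask; trait ACF and NSTD spectrum;
    NSTD-stratified cross-validation per method; two-method comparison over
    simulated communities with NSTI trends; summary JSON.  Deterministic
    given (config, seed).  On failure, partially written outputs are removed.
    """
    config = config or SimConfig()
    bundle = generate_benchmark(config, seed)
    tree, traits, masked = bundle.tree, bundle.traits, bundle.traits_masked

    nstd = compute_nstd(tree, masked.known_tips)
    acf = metrics.trait_acf(tree, masked, n_pairs=acf_pairs, n_bins=acf_bins,
                            seed=seed)
    cv = {
        m: crossval_r2_curve(tree, masked, m, cutoffs, seed=seed)
        for m in methods
    }

    rng = substream(seed, "sample_bias")
    biases = rng.uniform(0.0, config.nstd_bias_max, size=config.n_samples)
    abundances = simulate_abundances(tree, config, seed,
                                     tip_scores=nstd.values, biases=biases)
    pred_a = run_method(compare_pair[0], tree, masked)
    pred_b = run_method(compare_pair[1], tree, masked)
    comparisons = compare_prediction_sets(pred_a, pred_b, abundances,
                                          nstd, nstd)
    trends = {}
    for grp in (None, "proximal", "distal"):
        try:
            t = nsti_r2_trend(comparisons, grp, permutations, seed)
            trends[t.group] = t
        except (ValueError, UndefinedResultError):
            pass

    nstd_vals = np.array(list(nstd.values.values()))
    kept = [c for c in comparisons if not c.excluded]
    summary = {
        "seed": seed,
        "config": config.to_dict(),
        "acf_half_correlation_distance": acf.half_correlation_distance(),
        "frac_tips_nstd_gt_15pct": float(np.mean(nstd_vals > 0.15)),
        "frac_tips_nstd_gt_30pct": float(np.mean(nstd_vals > 0.30)),
        "r2cv": {m: cv[m].mean_r2.tolist() for m in cv},
        "cutoffs": list(map(float, cutoffs)),
        "compare_pair": list(compare_pair),
        "mean_sample_r2": float(np.mean([c.r2 for c in kept])) if kept else None,
        "frac_samples_r2_below_0.5": float(np.mean([c.r2 < 0.5 for c in kept]))
        if kept else None,
        "trends": {
            g: {"r": t.r, "r2": t.r2, "p": t.p_value, "n": t.n}
            for g, t in trends.items()
        },
    }
    report = BenchmarkReport(bundle, abundances, acf, nstd, cv, comparisons,
                             trends, summary)
    if out_dir is not None:
        _write_report(report, out_dir)
    return report


def _write_report(report: BenchmarkReport, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    written: list[str] = []

    def path(name):
        p = os.path.join(out_dir, name)
        written.append(p)
        return p

    head = (f"# phylogcn benchmark | seed={report.bundle.seed} | "
            f"n_tips={report.bundle.config.n_tips}\n")
    try:
        write_newick(report.bundle.tree, path("tree.nwk"), header=head)
        write_trait_table(report.bundle.traits, path("traits.tsv"), header=head)
        write_trait_table(report.bundle.traits_masked, path("traits_masked.tsv"),
                          header=head)
        write_abundance_table(report.abundances, path("abundances.tsv"),
                              header=head)
        write_table(report.acf.to_frame(), path("acf.tsv"), header=head)
        write_table(report.nstd.to_frame(), path("nstd.tsv"), header=head)
        for m, res in report.cv.items():
            write_table(res.to_frame(), path(f"cv_{m}.tsv"), header=head)
        write_table(comparisons_frame(report.comparisons),
                    path("sample_comparisons.tsv"), header=head)
        with open(path("summary.json"), "w", encoding="utf-8") as fh:
            json.dump(report.summary, fh, indent=2)
    except Exception:
        for p in written:
            if os.path.exists(p):
                os.remove(p)
        raise
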