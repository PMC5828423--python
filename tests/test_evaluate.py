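import json

import numpy as np
import pandas as pd
import pytest

import phylogcn as pg
from phylogcn.evaluate import SampleComparison, comparisons_frame
from phylogcn.hsp import PredictionSet
from phylogcn.metrics import UndefinedResultError
from phylogcn.simulate import SimConfig
from oracles import random_tree, root_path_distance


def cherry_forest(n_cherries, rng):
    """Tree of zero-length cherries: every tip has an exact duplicate."""
    parent, blen, labels = [-1], [0.0], [None]
    values = {}
    for i in range(n_cherries):
        c = len(parent)
        parent.append(0)
        blen.append(rng.uniform(0.05, 0.5))
        labels.append(None)
        v = int(rng.integers(1, 16))
        for j in range(2):
            parent.append(c)
            blen.append(0.0)
            labels.append(f"p{i}_{j}")
            values[f"p{i}_{j}"] = v
    return pg.PhyloTree(parent, blen, labels), pg.TraitTable(values)


class TestCrossValidation:
    def test_no_leakage_and_cutoff_exclusion(self, rng):
        """Training sets never intersect the test set, and every retained
        training tip is at least the cutoff away from it (brute force)."""
        t = random_tree(60, rng)
        tr, _ = __import__("oracles").random_partial_traits(t, 6, rng, 0)
        cutoffs = [0.0, 0.5, 1.5]
        res = pg.crossval_r2_curve(t, tr, "sa", cutoffs, test_fraction=0.1,
                                   repeats=2, seed=3, record_sets=True)
        for test, trains in res.sets:
            for c, train in trains.items():
                assert not (train & test)
                for k in train:
                    d = min(root_path_distance(t, k, x) for x in test)
                    assert d >= c - 1e-12

    def test_duplicated_tips_make_prediction_trivial(self, rng):
        """With an exact duplicate of every tip in the training set,
        subtree averaging at cutoff 0 is near-perfect (R2 > 0.9)."""
        t, tr = cherry_forest(120, rng)
        res = pg.crossval_r2_curve(t, tr, "sa", [0.0], test_fraction=0.05,
                                   repeats=3, seed=1)
        assert res.mean_r2[0] > 0.9

    def test_cutoff_beyond_diameter_flagged_not_fatal(self, rng):
        t = random_tree(40, rng)
        tr, _ = __import__("oracles").random_partial_traits(t, 5, rng, 0)
        diameter = 2 * t.depth.max()
        res = pg.crossval_r2_curve(t, tr, "pic", [0.0, diameter + 1],
                                   test_fraction=0.1, repeats=2, seed=2)
        assert np.isfinite(res.mean_r2[0])
        assert np.isnan(res.mean_r2[1])
        assert res.train_sizes[:, 1].max() == 0

    def test_all_cutoffs_skipped_is_an_error(self, rng):
        t = random_tree(20, rng)
        tr, _ = __import__("oracles").random_partial_traits(t, 5, rng, 0)
        with pytest.raises(RuntimeError):
            pg.crossval_r2_curve(t, tr, "pic", [1e6], test_fraction=0.1,
                                 repeats=1, seed=0)

    def test_decay_in_expectation_over_seeds(self, benchmark):
        """Seed-averaged R2cv at a large cutoff does not exceed cutoff 0
        (the decay stated as an expectation, checked as a trend over 10 replicates)."""
        lo, hi = [], []
        for seed in range(10):
            res = pg.crossval_r2_curve(benchmark.tree, benchmark.traits_masked,
                                       "sa", [0.0, 0.4], seed=seed)
            lo.append(res.mean_r2[0])
            hi.append(res.mean_r2[1])
        assert np.nanmean(hi) < np.nanmean(lo)


class TestComparePredictionSets:
    def _setup(self, benchmark):
        tree, masked = benchmark.tree, benchmark.traits_masked
        nstd = pg.compute_nstd(tree, masked.known_tips)
        cfg = SimConfig(n_samples=12, reads_per_sample=500)
        ab = pg.simulate_abundances(tree, cfg, seed=5, tip_scores=nstd.values,
                                    biases=np.linspace(0, 8, 12))
        return tree, masked, nstd, ab

    def test_identical_sets_give_r2_one(self, benchmark):
        tree, masked, nstd, ab = self._setup(benchmark)
        p = pg.run_method("sa", tree, masked)
        comps = pg.compare_prediction_sets(p, p, ab, nstd, nstd)
        for c in comps:
            if not c.excluded:
                assert c.r2 == pytest.approx(1.0)

    def test_single_otu_sample_flagged(self):
        t = pg.parse_newick("((A:1,B:1):1,C:1);")
        preds = PredictionSet({"A": 1.0, "B": 2.0, "C": 3.0}, "x")
        counts = pd.DataFrame({"s1": [5, 0, 0], "s2": [1, 2, 0]},
                              index=["A", "B", "C"])
        ab = pg.AbundanceTable(counts)
        nstd = pg.compute_nstd(t, ["A"])
        comps = pg.compare_prediction_sets(preds, preds, ab, nstd, nstd)
        by = {c.sample: c for c in comps}
        assert by["s1"].excluded and not by["s2"].excluded

    def test_no_overlap_is_an_error(self):
        a = PredictionSet({"x": 1.0}, "a")
        b = PredictionSet({"y": 1.0}, "b")
        ab = pg.AbundanceTable(pd.DataFrame({"s1": [3]}, index=["z"]))
        with pytest.raises(ValueError):
            pg.compare_prediction_sets(a, b, ab, pg.NSTDMap({"z": 0.1}),
                                       pg.NSTDMap({"z": 0.1}))

    def test_high_nstd_samples_agree_less(self, benchmark):
        """Samples enriched for high-NSTD OTUs show lower between-method
        agreement than samples dominated by known tips."""
        tree, masked, nstd, ab = self._setup(benchmark)
        pa = pg.run_method("mpr_ae", tree, masked)
        pb = pg.run_method("pic", tree, masked)
        comps = [c for c in
                 pg.compare_prediction_sets(pa, pb, ab, nstd, nstd)
                 if not c.excluded]
        hi = [c.r2 for c in comps if c.nsti > np.median([x.nsti for x in comps])]
        lo = [c.r2 for c in comps if c.nsti <= np.median([x.nsti for x in comps])]
        assert np.mean(lo) > np.mean(hi)


class TestTrend:
    def test_monotone_data_give_negative_significant_trend(self):
        comps = [SampleComparison(f"s{i}", "g", 10, r2=1 - 0.05 * i,
                                  nsti=0.01 * i, mean_a=2, mean_b=2)
                 for i in range(20)]
        t = pg.nsti_r2_trend(comps, "g", permutations=1000, seed=1)
        assert t.r < 0
        assert t.p_value <= 0.05

    def test_two_samples_rejected(self):
        comps = [SampleComparison("a", "g", 5, 0.5, 0.1, 2, 2),
                 SampleComparison("b", "g", 5, 0.4, 0.2, 2, 2)]
        with pytest.raises(ValueError):
            pg.nsti_r2_trend(comps, "g")

    def test_constant_nsti_undefined(self):
        comps = [SampleComparison(f"s{i}", "g", 5, 0.1 * i, 0.2, 2, 2)
                 for i in range(5)]
        with pytest.raises(UndefinedResultError):
            pg.nsti_r2_trend(comps, "g")

    def test_null_calibration_of_permutation_p(self):
        """Under independence the permutation P value is super-uniform:
        P > 0.05 in at least 90% of replicate null data sets (100 replicates
        keep the Monte-Carlo error of the 90% bound itself small), and the
        P distribution is consistent with uniform."""
        from scipy import stats

        ps = []
        for seed in range(100):
            r = np.random.default_rng(1000 + seed)
            comps = [SampleComparison(f"s{i}", "g", 5, float(r.normal()),
                                      float(r.normal()), 2, 2)
                     for i in range(100)]
            t = pg.nsti_r2_trend(comps, "g", permutations=400, seed=seed)
            ps.append(t.p_value)
        ps = np.array(ps)
        assert np.mean(ps > 0.05) >= 0.90
        assert stats.kstest(ps, "uniform").pvalue > 0.001

    def test_deterministic(self):
        comps = [SampleComparison(f"s{i}", "g", 5, 1 - 0.02 * i + 0.1 * ((i * 7) % 3),
                                  0.01 * i, 2, 2) for i in range(30)]
        a = pg.nsti_r2_trend(comps, "g", 500, seed=4)
        b = pg.nsti_r2_trend(comps, "g", 500, seed=4)
        assert a.p_value == b.p_value and a.r == b.r


class TestCorrectAbundances:
    def _table(self):
        counts = pd.DataFrame({"s1": [6, 2], "s2": [3, 3]}, index=["a", "b"])
        return pg.AbundanceTable(counts)

    def test_unit_gcn_is_identity(self):
        ab = self._table()
        preds = PredictionSet({"a": 1.0, "b": 1.0}, "x")
        out = pg.correct_abundances(ab, preds)
        assert (out == ab.counts).all().all()

    def test_renormalized_example(self):
        ab = self._table()
        preds = PredictionSet({"a": 3.0, "b": 2.0}, "x")
        out = pg.correct_abundances(ab, preds, renormalize=True)
        assert out.loc["a", "s1"] == pytest.approx(2 / 3)
        assert out.loc["b", "s1"] == pytest.approx(1 / 3)
        assert out.sum(axis=0).round(9).eq(1).all()

    def test_uniform_gcn_scale_invariance(self):
        ab = self._table()
        preds = PredictionSet({"a": 4.0, "b": 4.0}, "x")
        out = pg.correct_abundances(ab, preds, renormalize=True)
        raw = ab.counts / ab.counts.sum(axis=0)
        assert np.allclose(out, raw)

    def test_missing_prediction_listed(self):
        ab = self._table()
        with pytest.raises(ValueError, match="b"):
            pg.correct_abundances(ab, PredictionSet({"a": 2.0}, "x"))

    def test_prediction_below_one_rejected(self):
        ab = self._table()
        with pytest.raises(ValueError):
            pg.correct_abundances(ab, PredictionSet({"a": 0.5, "b": 2.0}, "x"))


class TestRunBenchmark:
    CFG = dict(n_tips=250, n_samples=8, reads_per_sample=300)

    def test_outputs_and_determinism(self, tmp_path):
        cfg = SimConfig(**self.CFG)
        out1 = tmp_path / "run1"
        out2 = tmp_path / "run2"
        out3 = tmp_path / "run3"
        for out, seed in ((out1, 7), (out2, 7), (out3, 8)):
            pg.run_benchmark(cfg, methods=("sa", "pic"), cutoffs=[0.0, 0.2],
                             out_dir=str(out), seed=seed, acf_pairs=20000,
                             acf_bins=5, permutations=200)
        names = ["tree.nwk", "traits.tsv", "traits_masked.tsv",
                 "abundances.tsv", "acf.tsv", "nstd.tsv", "cv_sa.tsv",
                 "cv_pic.tsv", "sample_comparisons.tsv", "summary.json"]
        for n in names:
            assert (out1 / n).exists()
            assert (out1 / n).read_bytes() == (out2 / n).read_bytes()
        assert (out1 / "traits.tsv").read_bytes() != (out3 / "traits.tsv").read_bytes()
        summary = json.loads((out1 / "summary.json").read_text())
        assert summary["seed"] == 7
        assert set(summary["r2cv"]) == {"sa", "pic"}
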