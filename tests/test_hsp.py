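import numpy as np
import pytest
from scipy import optimize

import phylogcn as pg
from phylogcn.hsp import (CostScheme, HSPError, hsp_mk_er, hsp_pic,
                          hsp_sankoff, hsp_subtree_avg, hsp_wscp,
                          mk_log_likelihood, mk_marginal_posteriors,
                          run_method, sankoff_scores, wscp_values)
from oracles import enum_mk, enum_sankoff, random_partial_traits, random_tree


class TestCostSchemes:
    @pytest.mark.parametrize("name,expected_12,expected_13", [
        ("all_equal", 1.0, 1.0),
        ("proportional", 1.0, 2.0),
        ("exponential", np.e, np.e**2),
    ])
    def test_costs(self, name, expected_12, expected_13):
        C = CostScheme(name).matrix(3)
        assert C[0, 0] == 0
        assert C[0, 1] == pytest.approx(expected_12)
        assert C[0, 2] == pytest.approx(expected_13)
        assert np.allclose(C, C.T)


class TestSankoff:
    def test_unanimous_known_tips(self):
        t = pg.parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        tr = pg.TraitTable({"A": 1, "B": 1, "C": 1, "D": None})
        preds = hsp_sankoff(t, tr, "all_equal")
        assert preds["D"] == 1.0

    def test_minimal_total_cost_two_changes(self):
        """A=1,B=2,C=4,D=4 under all_equal needs exactly 2 changes."""
        t = pg.parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        known = {"A": 1, "B": 2, "C": 4, "D": 4}
        tr = pg.TraitTable(known)
        _, total = sankoff_scores(t, tr, "all_equal", n_states=4)
        assert total[t.root].min() == pytest.approx(2.0)
        ref = enum_sankoff(t, known, 4, CostScheme("all_equal").matrix(4))
        assert np.allclose(total, ref)

    def test_root_mpr_tie_gives_mean(self):
        """Root MPR set {1,2} both at cost 1; tie policy averages to 1.5."""
        t = pg.parse_newick("((A:1,B:1):1,C:1);")
        tr = pg.TraitTable({"A": 1, "B": 1, "C": 2})
        _, total = sankoff_scores(t, tr, "all_equal", n_states=2)
        row = total[t.root]
        mpr = np.flatnonzero(row <= row.min() + 1e-9) + 1
        assert list(mpr) == [1, 2]
        assert mpr.mean() == pytest.approx(1.5)

    @pytest.mark.parametrize("scheme", ["all_equal", "proportional", "exponential"])
    def test_conditional_costs_match_enumeration(self, scheme, rng):
        """Dynamic-programming costs equal exhaustive enumeration on random
        small trees with polytomies and unknown tips."""
        for _ in range(25):
            t = random_tree(int(rng.integers(3, 8)), rng,
                            polytomy=bool(rng.integers(2)))
            S = int(rng.integers(2, 5))
            tr, known = random_partial_traits(t, S, rng)
            _, total = sankoff_scores(t, tr, scheme, S)
            ref = enum_sankoff(t, known, S, CostScheme(scheme).matrix(S))
            assert np.allclose(total, ref, atol=1e-9)

    def test_state_outside_range_rejected(self):
        t = pg.parse_newick("(A:1,B:1);")
        with pytest.raises(HSPError):
            hsp_sankoff(t, pg.TraitTable({"A": 5, "B": 1}), "all_equal",
                        n_states=3)

    def test_no_known_tips_rejected(self):
        t = pg.parse_newick("(A:1,B:1);")
        with pytest.raises(HSPError):
            hsp_sankoff(t, pg.TraitTable({"A": None, "B": None}), "all_equal")


class TestMkER:
    def test_two_tip_symmetric_root_posterior(self):
        """ER symmetry + symmetric data make the root posterior (1/2, 1/2)
        for any branch length and rate."""
        for t_len in (0.1, 0.7, 3.0):
            t = pg.parse_newick(f"(A:{t_len},B:{t_len});")
            tr = pg.TraitTable({"A": 1, "B": 2})
            post = mk_marginal_posteriors(t, tr, 2, 1.3, np.array([0.5, 0.5]))
            assert post[t.root] == pytest.approx([0.5, 0.5], abs=1e-12)

    def test_identical_known_states_pin_rate_and_predict_constant(self):
        t = pg.parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        tr = pg.TraitTable({"A": 3, "B": 3, "C": 3, "D": None})
        fit, preds = hsp_mk_er(t, tr, n_states=4)
        assert fit.at_boundary
        assert preds["D"] == 3.0

    def test_likelihood_and_marginals_match_enumeration(self, rng):
        """Pruning log-likelihood and outside-message marginals equal the
        brute-force sum over all ancestral assignments."""
        for _ in range(8):
            t = random_tree(int(rng.integers(2, 7)), rng)
            S = int(rng.integers(2, 4))
            tr, known = random_partial_traits(t, S, rng)
            f = np.bincount([v - 1 for v in known.values()], minlength=S) + 0.0
            prior = f / f.sum()
            for rate in rng.uniform(0.05, 3.0, size=3):
                ll = mk_log_likelihood(t, tr, S, rate, prior)
                post = mk_marginal_posteriors(t, tr, S, rate, prior)
                ll_ref, marg_ref = enum_mk(t, known, S, rate, prior)
                assert ll == pytest.approx(ll_ref, abs=1e-8)
                assert np.allclose(post, marg_ref, atol=1e-8)
                assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_fitted_rate_recovers_simulated_order_of_magnitude(self):
        bun = pg.generate_benchmark(pg.SimConfig(n_tips=400), seed=5)
        fit, _ = hsp_mk_er(bun.tree, bun.traits, n_states=15, seed=0)
        true = bun.config.resolved_rate()
        assert true / 3 < fit.rate < true * 3


class TestPIC:
    def test_star_root_estimate_is_plain_mean(self):
        """Equal branches weight equally: an unknown tip inherits the root
        estimate (1+2+3)/3 = 2."""
        t = pg.parse_newick("(A:1,B:1,C:1,D:1);")
        tr = pg.TraitTable({"A": 1, "B": 2, "C": 3, "D": None})
        assert hsp_pic(t, tr)["D"] == pytest.approx(2.0)

    def test_cherry_inverse_length_weights(self):
        """Cherry (A:1,B:3): node estimate (3a+b)/4."""
        t = pg.parse_newick("((A:1,B:3):1,C:5);")
        tr = pg.TraitTable({"A": 1, "B": 3, "C": None})
        assert hsp_pic(t, tr)["C"] == pytest.approx((3 * 1 + 3) / 4)

    def test_only_known_sibling_is_copied(self):
        t = pg.parse_newick("((A:2,B:1):1,C:1);")
        tr = pg.TraitTable({"A": 7, "B": None, "C": None})
        assert hsp_pic(t, tr)["B"] == 7.0


class TestWSCP:
    def test_symmetric_cherry_root_is_midpoint(self):
        t = pg.parse_newick("(A:1,B:1);")
        x = wscp_values(t, pg.TraitTable({"A": 2, "B": 6}))
        assert x[t.root] == pytest.approx(4.0)

    def test_asymmetric_cherry_root(self):
        """Minimise (x-a)^2/1 + (x-b)^2/3 -> x = (3a+b)/4."""
        t = pg.parse_newick("(A:1,B:3);")
        x = wscp_values(t, pg.TraitTable({"A": 1, "B": 5}))
        assert x[t.root] == pytest.approx((3 * 1 + 5) / 4)

    def test_matches_generic_numeric_minimizer(self, rng):
        """Two-pass elimination equals L-BFGS-B on the quadratic objective
        and beats random perturbations."""
        for _ in range(10):
            t = random_tree(10, rng)
            tr, known = random_partial_traits(t, 9, rng, n_unknown=3)
            x = wscp_values(t, tr)
            free = [v for v in range(t.n_nodes)
                    if not (t.is_tip[v] and t.labels[v] in known)]
            fixed = {v: float(known[t.labels[v]]) for v in range(t.n_nodes)
                     if t.is_tip[v] and t.labels[v] in known}
            w = 1.0 / np.maximum(t.branch_length, pg.EPSILON)
            edges = [(int(t.parent[v]), v) for v in range(t.n_nodes)
                     if t.parent[v] >= 0]

            def obj(z):
                val = dict(zip(free, z))
                val.update(fixed)
                return sum(w[c] * (val[p] - val[c]) ** 2 for p, c in edges)

            res = optimize.minimize(
                obj, x0=np.full(len(free), np.mean(list(known.values()))),
                method="L-BFGS-B", options={"ftol": 1e-15, "gtol": 1e-12})
            assert np.allclose(x[free], res.x, atol=1e-5)
            base = obj(x[free])
            for _ in range(50):
                assert base <= obj(x[free] + rng.normal(0, 0.1, len(free))) + 1e-12


class TestSubtreeAveraging:
    def test_root_average_propagates_down(self):
        t = pg.parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        tr = pg.TraitTable({"A": 2, "B": 4, "C": None, "D": None})
        preds = hsp_subtree_avg(t, tr)
        assert preds["C"] == 3.0 and preds["D"] == 3.0

    def test_all_known_identity(self, rng):
        t = random_tree(12, rng)
        tr, known = random_partial_traits(t, 6, rng, n_unknown=0)
        preds = hsp_subtree_avg(t, tr)
        assert preds.predictions == {k: float(v) for k, v in known.items()}

    def test_known_sibling_average(self):
        t = pg.parse_newick("((A:1,B:1):1,C:1);")
        tr = pg.TraitTable({"A": 7, "B": None, "C": None})
        preds = hsp_subtree_avg(t, tr)
        assert preds["B"] == 7.0  # parent's only datum


class TestCrossMethodInvariants:
    @pytest.mark.parametrize("method", pg.METHOD_CODES)
    def test_exact_interpolation(self, method, rng):
        """Known tips are returned exactly unchanged by every method."""
        t = random_tree(30, rng, polytomy=True)
        tr, known = random_partial_traits(t, 8, rng, n_unknown=8)
        preds = run_method(method, t, tr)
        for k, v in known.items():
            assert preds[k] == float(v)
        assert set(preds.predictions) == set(t.tip_labels)

    @pytest.mark.parametrize("method", pg.METHOD_CODES)
    def test_permutation_equivariance(self, method, rng):
        """Relabelling tips and permuting newick child order leaves all
        predictions unchanged."""
        t = random_tree(15, rng, polytomy=True)
        tr, known = random_partial_traits(t, 5, rng, n_unknown=4)
        preds = run_method(method, t, tr)
        # reversed child order + renamed tips
        mapping = {lab: f"x{i}" for i, lab in enumerate(t.tip_labels)}
        parent, blen, labels = [], [], []
        order = {}
        stack = [(t.root, -1)]
        while stack:
            v, p = stack.pop()
            idx = len(parent)
            order[v] = idx
            parent.append(p)
            blen.append(float(t.branch_length[v]))
            lab = t.labels[v]
            labels.append(mapping.get(lab, lab) if t.is_tip[v] else None)
            for c in t.children(v):  # push in order -> popped reversed
                stack.append((int(c), idx))
        t2 = pg.PhyloTree(parent, blen, labels)
        tr2 = pg.TraitTable({mapping[k]: v for k, v in tr.values.items()})
        preds2 = run_method(method, t2, tr2)
        # the Mk pipeline refits its rate; child-order changes perturb the
        # floating-point likelihood path, so its fitted predictions are only
        # equivariant to optimizer precision (exact-rate equivariance is
        # asserted separately below)
        tol = 1e-5 if method == "mk_er" else 1e-10
        for lab in t.tip_labels:
            assert preds2[mapping[lab]] == pytest.approx(preds[lab], abs=tol)
        if method == "mk_er":
            p1 = mk_marginal_posteriors(t, tr, 8, 0.9, np.full(8, 1 / 8))
            p2 = mk_marginal_posteriors(t2, tr2, 8, 0.9, np.full(8, 1 / 8))
            for lab in t.tip_labels:
                v1 = t.tip_index[lab]
                v2 = t2.tip_index[mapping[lab]]
                assert np.allclose(p1[v1], p2[v2], atol=1e-10)

    def test_predictions_bounded_by_state_range(self, rng):
        t = random_tree(40, rng)
        tr, _ = random_partial_traits(t, 15, rng, n_unknown=15)
        for method in pg.METHOD_CODES:
            vals = np.array(list(run_method(method, t, tr).predictions.values()))
            assert np.all(vals >= 1.0 - 1e-9)
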