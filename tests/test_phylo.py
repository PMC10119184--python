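"""Trait-evolution models: simulation, fitting, selection, ancestral states."""

import itertools
import re

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from cortevo.phylo import (PhyloTree, TraitMatrix, _kernel, ancestral_states,
                           fit_model, fit_scou_shifts, gic, lineage_divergence,
                           make_ultrametric, phylo_pca, select_model,
                           simulate_traits)


def balanced_tree(depth: int, blen: float = 1.0) -> PhyloTree:
    def rec(d):
        return "x" if d == 0 else f"({rec(d - 1)}:{blen},{rec(d - 1)}:{blen})"
    counter = itertools.count()
    nwk = re.sub("x", lambda m: f"t{next(counter)}", rec(depth) + ";")
    return PhyloTree.from_newick(nwk)


def star_tree(n: int, blen: float = 1.0) -> PhyloTree:
    inner = ",".join(f"t{i}:{blen}" for i in range(n))
    return PhyloTree.from_newick(f"({inner});")


@pytest.fixture(scope="module")
def tree32():
    return balanced_tree(5)


class TestTreeContainer:
    def test_newick_round_trip(self, tree32):
        again = PhyloTree.from_newick(tree32.to_newick())
        assert again.tip_labels == tree32.tip_labels
        assert np.allclose(sorted(again.blen), sorted(tree32.blen))

    def test_ultrametric_and_binary(self, tree32):
        assert tree32.is_ultrametric()
        assert tree32.is_binary()
        assert tree32.tip_depth() == pytest.approx(5.0)

    def test_star_tree_not_binary(self):
        assert not star_tree(5).is_binary()


class TestSimulateTraits:
    def test_bm_two_tip_variance(self):
        t = PhyloTree([2, 2, -1], [1.0, 1.0, 0.0], ["a", "b"])
        rng = np.random.default_rng(1)
        diffs = []
        for _ in range(6000):
            tm, _ = simulate_traits(t, "BM", {"sigma2": 2.0}, seed=rng)
            diffs.append(tm.values[0, 0] - tm.values[1, 0])
        assert np.var(diffs) == pytest.approx(2.0 * 2.0, rel=0.05)

    def test_ou_alpha_zero_limit_is_bm(self, tree32):
        k_bm = _kernel(tree32, "BM")
        k_ou = _kernel(tree32, "OU", alpha=1e-12)
        assert np.abs(k_bm - k_ou).max() < 1e-8

    def test_seed_reproducibility(self, tree32):
        a, sa = simulate_traits(tree32, "OU", {"sigma2": 1.0, "alpha": 0.3}, p=2, seed=9)
        b, sb = simulate_traits(tree32, "OU", {"sigma2": 1.0, "alpha": 0.3}, p=2, seed=9)
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(sa, sb)


class TestFitModel:
    def test_star_tree_bm_equals_iid_formulas(self):
        t = star_tree(20, blen=2.0)
        rng = np.random.default_rng(2)
        y = rng.normal(3.0, 1.5, size=(20, 1))
        fit = fit_model(t, TraitMatrix(y, t.tip_labels), "BM")
        assert fit.root_state[0] == pytest.approx(y.mean(), rel=1e-8)
        # ML variance (no Bessel correction) per unit branch length
        assert fit.sigma2 == pytest.approx(y.var() / 2.0, rel=1e-6)

    def test_loglik_matches_dense_mvn_oracle(self):
        t = balanced_tree(3)
        tm, _ = simulate_traits(t, "BM", {"sigma2": 0.7}, seed=5)
        fit = fit_model(t, tm, "BM")
        K = _kernel(t, "BM") * fit.sigma2
        mu = np.full(t.n_tips, fit.root_state[0])
        oracle = multivariate_normal(mu, K).logpdf(tm.values[:, 0])
        assert fit.loglik == pytest.approx(oracle, abs=1e-6)

    def test_ou_loglik_matches_dense_mvn_oracle(self):
        t = balanced_tree(3)
        tm, _ = simulate_traits(t, "OU", {"sigma2": 1.0, "alpha": 0.4}, seed=6)
        fit = fit_model(t, tm, "OU")
        K = _kernel(t, "OU", alpha=fit.alpha) * fit.sigma2
        mu = np.full(t.n_tips, fit.root_state[0])
        oracle = multivariate_normal(mu, K).logpdf(tm.values[:, 0])
        assert fit.loglik == pytest.approx(oracle, abs=1e-6)

    def test_ou_nests_bm(self, tree32):
        """On BM data the OU fit collapses to ~BM: loglik within 2 units."""
        hits = 0
        n_rep = 40
        for rep in range(n_rep):
            tm, _ = simulate_traits(tree32, "BM", {"sigma2": 1.0}, seed=100 + rep)
            f_bm = fit_model(tree32, tm, "BM")
            f_ou = fit_model(tree32, tm, "OU")
            if f_ou.loglik - f_bm.loglik < 2.0 and f_ou.loglik >= f_bm.loglik - 1e-6:
                hits += 1
        assert hits >= 0.9 * n_rep

    def test_bm_rate_recovery(self, tree32):
        est = []
        for rep in range(50):
            tm, _ = simulate_traits(tree32, "BM", {"sigma2": 1.5}, seed=200 + rep)
            est.append(fit_model(tree32, tm, "BM").sigma2)
        est = np.array(est)
        assert abs(est.mean() - 1.5) / 1.5 < 0.15


class TestScouShifts:
    def test_max_shifts_zero_is_plain_scou(self, tree32):
        tm, _ = simulate_traits(tree32, "OU", {"sigma2": 1.0, "alpha": 0.2}, seed=7)
        f0 = fit_scou_shifts(tree32, tm, max_shifts=0)
        assert f0.shift_edges == []
        assert f0.family == "scOU_shift"

    def test_planted_shift_recovered(self):
        tree = balanced_tree(4)  # 16 tips
        hit = 0
        n_rep = 15
        for rep in range(n_rep):
            tm, _ = simulate_traits(tree, "OU", {"sigma2": 1.0, "alpha": 0.1},
                                    seed=300 + rep)
            cand = [int(e) for e in tree.edges()
                    if 3 <= tree.descendant_tips(e).size <= 8]
            e0 = cand[rep % len(cand)]
            y = tm.values.copy()
            y[tree.descendant_tips(e0)] += 5 * tm.values.std()
            fit = fit_scou_shifts(tree, TraitMatrix(y, tm.tip_labels), max_shifts=2)
            ch = tree.children()
            ok_edges = {e0} | set(ch[e0])
            if any(e in ok_edges for e in fit.shift_edges):
                hit += 1
        assert hit / n_rep >= 0.8

    def test_null_selects_no_shift_mostly(self):
        tree = balanced_tree(4)
        none = 0
        n_rep = 15
        for rep in range(n_rep):
            tm, _ = simulate_traits(tree, "OU", {"sigma2": 1.0, "alpha": 0.1},
                                    seed=400 + rep)
            fit = fit_scou_shifts(tree, tm, max_shifts=2)
            none += (len(fit.shift_edges) == 0)
        assert none / n_rep >= 0.8

    def test_greedy_matches_exhaustive_oracle_small(self):
        t = balanced_tree(2)  # 4 tips, 6 edges
        tm, _ = simulate_traits(t, "OU", {"sigma2": 1.0, "alpha": 0.2}, seed=8)
        y = tm.values.copy()
        y[t.descendant_tips(4)] += 4 * y.std()
        tm2 = TraitMatrix(y, tm.tip_labels)
        greedy = fit_scou_shifts(t, tm2, max_shifts=1)
        exact = fit_scou_shifts(t, tm2, max_shifts=1, exhaustive=True)
        assert greedy.gic_value == pytest.approx(exact.gic_value, rel=1e-6)

    def test_non_ultrametric_rejected(self):
        t = PhyloTree([2, 2, -1], [1.0, 3.0, 0.0], ["a", "b"])
        tm = TraitMatrix(np.array([[0.0], [1.0]]), ["a", "b"])
        with pytest.raises(ValueError):
            fit_scou_shifts(t, tm)


class TestGIC:
    def test_penalty_monotone_in_parameters(self, tree32):
        tm, _ = simulate_traits(tree32, "BM", {"sigma2": 1.0}, seed=9)
        f_bm = fit_model(tree32, tm, "BM")
        f_ou = fit_model(tree32, tm, "OU")
        # same loglik => more kernel parameters => strictly larger GIC
        if abs(f_ou.loglik - f_bm.loglik) < 1e-9:
            assert gic(f_ou) > gic(f_bm)
        # constructed: identical fits except parameter count
        import dataclasses
        f_more = dataclasses.replace(f_bm, n_kernel_params=f_bm.n_kernel_params + 2)
        assert gic(f_more) > gic(f_bm)

    def test_select_model_argmin(self, tree32):
        tm, _ = simulate_traits(tree32, "BM", {"sigma2": 1.0}, seed=10)
        fits = [fit_model(tree32, tm, f) for f in ("BM", "OU", "EB")]
        assert select_model(fits).gic_value == min(f.gic_value for f in fits)


class TestMakeUltrametric:
    def test_already_ultrametric_unchanged(self, tree32):
        out = make_ultrametric(tree32)
        assert np.allclose(out.blen, tree32.blen)

    def test_fossil_tip_extended(self):
        t = PhyloTree([2, 2, -1], [5.0, 10.0, 0.0], ["fossil", "extant"])
        out = make_ultrametric(t, ["fossil"])
        assert out.blen[0] == pytest.approx(10.0)
        d = out.node_depths()[:2]
        assert d.max() - d.min() < 1e-9

    def test_output_contract_tip_spread(self):
        rng = np.random.default_rng(11)
        t = balanced_tree(3)
        t.blen[: t.n_tips] += rng.uniform(0, 0.5, t.n_tips)
        out = make_ultrametric(PhyloTree(t.parent, t.blen, t.tip_labels))
        d = out.node_depths()[: out.n_tips]
        assert d.max() - d.min() < 1e-9


class TestAncestralStates:
    def test_two_tip_equal_branches(self):
        t = PhyloTree([2, 2, -1], [1.0, 1.0, 0.0], ["a", "b"])
        tm = TraitMatrix(np.array([[0.0], [4.0]]), ["a", "b"])
        st, var = ancestral_states(t, tm, fit_model(t, tm, "BM"))
        assert st[2, 0] == pytest.approx(2.0)

    def test_two_tip_unequal_branches_gls_closed_form(self):
        t = PhyloTree([2, 2, -1], [1.0, 3.0, 0.0], ["a", "b"])
        tm = TraitMatrix(np.array([[0.0], [4.0]]), ["a", "b"])
        st, _ = ancestral_states(t, tm, fit_model(t, tm, "BM"))
        # root = (x1/t1 + x2/t2)/(1/t1 + 1/t2) = (0 + 4/3)/(1 + 1/3) = 1
        assert st[2, 0] == pytest.approx(1.0, abs=1e-6)

    def test_matches_brute_force_gls_conditional(self):
        """BLUP equals the dense Gaussian conditional expectation (8 tips)."""
        t = balanced_tree(3)
        tm, _ = simulate_traits(t, "BM", {"sigma2": 1.3}, seed=12)
        fit = fit_model(t, tm, "BM")
        st, _ = ancestral_states(t, tm, fit)
        K = _kernel(t, "BM", nodes=np.arange(t.n_nodes))
        tips = np.arange(t.n_tips)
        internals = np.arange(t.n_tips, t.n_nodes)
        Koo = K[np.ix_(tips, tips)] + 1e-10 * np.eye(t.n_tips) * K.max()
        Kio = K[np.ix_(internals, tips)]
        mu = fit.root_state[0]
        cond = mu + Kio @ np.linalg.solve(Koo, tm.values[:, 0] - mu)
        assert np.abs(st[internals, 0] - cond).max() < 1e-8

    def test_missing_tip_imputed(self):
        t = balanced_tree(3)
        tm, _ = simulate_traits(t, "BM", {"sigma2": 1.0}, seed=13)
        y = tm.values.copy()
        y[2, 0] = np.nan
        st, var = ancestral_states(t, TraitMatrix(y, tm.tip_labels),
                                   fit_model(t, TraitMatrix(y, tm.tip_labels), "BM"))
        assert np.isfinite(st[2, 0])
        assert var[2, 0] > 0

    def test_root_estimate_unbiased(self):
        t = balanced_tree(3)
        errs = []
        for rep in range(200):
            tm, states = simulate_traits(t, "BM", {"sigma2": 1.0}, seed=500 + rep)
            fit = fit_model(t, tm, "BM")
            st, _ = ancestral_states(t, tm, fit)
            errs.append(st[t.root, 0] - states[t.root, 0])
        depth = t.tip_depth()
        assert abs(np.mean(errs)) < 0.05 * np.sqrt(depth) + 3 * np.std(errs) / np.sqrt(200)


class TestPhyloPCA:
    def test_star_tree_equals_ordinary_pca(self):
        t = star_tree(30)
        rng = np.random.default_rng(14)
        y = rng.normal(size=(30, 5)) @ np.diag([3, 2, 1, 0.5, 0.2])
        res = phylo_pca(t, TraitMatrix(y, t.tip_labels), ridge=0.0)
        yc = y - y.mean(axis=0)
        _, _, vt = np.linalg.svd(yc, full_matrices=False)
        for c in range(2):
            assert abs(np.corrcoef(res["modes"][:, c], vt[c])[0, 1]) > 0.999

    def test_modes_orthonormal(self, tree32):
        tm, _ = simulate_traits(tree32, "BM", {"sigma2": 1.0}, p=6, seed=15)
        res = phylo_pca(tree32, tm)
        mtm = res["modes"].T @ res["modes"]
        assert np.abs(mtm - np.eye(len(mtm))).max() < 1e-8

    def test_planted_low_rank_subspace_recovered(self):
        t = balanced_tree(5)  # 32 tips
        rng = np.random.default_rng(16)
        p = 12
        basis, _ = np.linalg.qr(rng.normal(size=(p, 2)))
        tmz, _ = simulate_traits(t, "BM", {"sigma2": 1.0}, p=2, seed=17)
        y = tmz.values @ (basis.T * np.array([3.0, 2.0])[:, None]) \
            + 0.05 * rng.normal(size=(32, p))
        res = phylo_pca(t, TraitMatrix(y, t.tip_labels))
        est = res["modes"][:, :2]
        # principal angles between planted and estimated subspaces < 10 deg
        sv = np.linalg.svd(basis.T @ est, compute_uv=False)
        angles = np.degrees(np.arccos(np.clip(sv, -1, 1)))
        assert angles.max() < 10.0


class TestLineageDivergence:
    def test_identical_lineages_zero(self):
        t = np.linspace(0, 10, 6)
        rng = np.random.default_rng(18)
        areas = rng.uniform(1, 2, size=(6, 20))
        out = lineage_divergence(areas, t, areas, t, t)
        assert np.abs(out["divergence"]).max() < 1e-12

    def test_growing_noise_monotone(self):
        from scipy.stats import spearmanr
        t = np.linspace(0, 10, 12)
        rng = np.random.default_rng(19)
        base = rng.uniform(1, 2, size=80)
        A = np.tile(base, (12, 1))
        B = A + rng.normal(size=A.shape) * (0.02 + 0.1 * t)[:, None]
        out = lineage_divergence(A, t, B, t, t)
        rho, _ = spearmanr(out["divergence"], t)
        assert rho > 0.9

    def test_covariate_self_correlation_one(self):
        t = np.linspace(0, 10, 8)
        rng = np.random.default_rng(20)
        A = np.tile(rng.uniform(1, 2, 15), (8, 1))
        B = A + rng.normal(size=A.shape) * np.linspace(0.01, 0.3, 8)[:, None]
        out1 = lineage_divergence(A, t, B, t, t)
        out2 = lineage_divergence(A, t, B, t, t, covariate=out1["divergence"])
        assert out2["covariate_r"] == pytest.approx(1.0)

    def test_too_few_timepoints_rejected(self):
        with pytest.raises(ValueError):
            lineage_divergence(np.ones((2, 3)), [0, 1], np.ones((2, 3)), [0, 1], [0, 1])
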