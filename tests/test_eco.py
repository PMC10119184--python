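"""Ecology associations, FDR procedures, rmcorr, decoding, clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cortevo import mesh as M
from cortevo.eco import (HabitatScale, benjamini_hochberg, benjamini_yekutieli,
                         cluster_trajectories, decode_map, habitat_scale_estimate,
                         inferential_suite, parcel_tests, rmcorr, screen_modes,
                         synthesize_expansion)


class TestFDR:
    def test_bh_step_up_by_hand(self):
        reject, q = benjamini_hochberg(np.array([0.01, 0.02, 0.03, 0.5]), alpha=0.05)
        assert list(reject) == [True, True, True, False]
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.5])

    def test_by_harmonic_factor(self):
        p = np.array([0.01, 0.02, 0.03, 0.5])
        _, q_bh = benjamini_hochberg(p)
        _, q_by = benjamini_yekutieli(p)
        cm = sum(1.0 / i for i in range(1, 5))  # 2.0833...
        assert np.allclose(q_by, np.minimum(q_bh * cm, 1.0))

    def test_matches_statsmodels_oracle(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        _, q_bh = benjamini_hochberg(p)
        _, q_by = benjamini_yekutieli(p)
        assert np.allclose(q_bh, multipletests(p, method="fdr_bh")[1])
        assert np.allclose(q_by, multipletests(p, method="fdr_by")[1])


class TestScreenModes:
    def _ecology(self, rng, n):
        return pd.DataFrame({
            "diurnal": rng.integers(0, 2, n),
            "arboreal": rng.integers(0, 2, n),
        })

    def test_null_fdr_calibrated(self):
        """Independent scores: average discovery proportion stays near alpha."""
        rng = np.random.default_rng(1)
        any_disc = 0
        n_rep = 300
        for _ in range(n_rep):
            scores = rng.normal(size=(24, 6))
            eco = self._ecology(rng, 24)
            if eco.nunique().min() < 2:
                continue
            df = screen_modes(scores, eco)
            any_disc += df["significant"].any()
        assert any_disc / n_rep <= 0.10  # FDR across the family controls FWER-ish here

    def test_planted_shift_recovered(self):
        rng = np.random.default_rng(2)
        hits = 0
        n_rep = 30
        for _ in range(n_rep):
            n = 40
            g = np.r_[np.zeros(20, int), np.ones(20, int)]
            scores = rng.normal(size=(n, 5))
            scores[g == 1, 2] += 2.0  # 2 SD shift on mode 2
            eco = pd.DataFrame({"diurnal": g, "arboreal": rng.integers(0, 2, n)})
            df = screen_modes(scores, eco)
            sig = df[(df["mode"] == 2) & (df["variable"] == "diurnal")]
            hits += bool(sig["significant"].iloc[0])
        assert hits / n_rep >= 0.9

    def test_identical_groups_p_near_one(self):
        scores = np.tile(np.arange(10.0)[:, None], (2, 3))
        g = np.r_[np.zeros(10, int), np.ones(10, int)]
        eco = pd.DataFrame({"diurnal": g})
        df = screen_modes(scores, eco)
        assert (df["p"] > 0.9).all()

    def test_constant_variable_skipped(self):
        rng = np.random.default_rng(3)
        eco = pd.DataFrame({"diurnal": np.ones(10, int)})
        with pytest.warns(UserWarning):
            df = screen_modes(rng.normal(size=(10, 3)), eco)
        assert df.empty


class TestSynthesizeExpansion:
    def test_uniform_scale_mode_constant_map(self, ico2):
        base = ico2.vertices.ravel()
        mode = base / np.linalg.norm(base)  # pure scaling direction
        modes = mode[:, None]
        scores = np.r_[np.full(5, -2.0), np.full(5, 2.0)][:, None]
        group = np.r_[np.zeros(5, bool), np.ones(5, bool)]
        e = synthesize_expansion(modes, base, scores, group, [0], ico2.faces)
        assert e.values.std() / abs(e.values.mean()) < 0.01

    def test_equal_centroids_zero_map(self, ico2):
        base = ico2.vertices.ravel()
        rng = np.random.default_rng(4)
        modes = rng.normal(size=(len(base), 2))
        scores = rng.normal(size=(10, 2))
        group = np.r_[np.zeros(5, bool), np.ones(5, bool)]
        scores[group] = scores[~group]  # identical centroids
        e = synthesize_expansion(modes, base, scores, group, [0, 1], ico2.faces)
        assert np.abs(e.values).max() < 1e-9

    def test_patch_mode_localized(self, ico2):
        v = ico2.vertices
        center = v[0] / np.linalg.norm(v[0])
        ang = np.arccos(np.clip(v @ center, -1, 1))
        bump = np.exp(-0.5 * (ang / 0.4) ** 2)
        mode = (v * bump[:, None]).ravel()
        base = v.ravel()
        scores = np.r_[np.full(5, 0.0), np.full(5, 0.3)][:, None]
        group = np.r_[np.zeros(5, bool), np.ones(5, bool)]
        e = synthesize_expansion(mode[:, None], base, scores, group, [0], ico2.faces)
        from sklearn.metrics import roc_auc_score
        assert roc_auc_score(bump > 0.3, e.values) > 0.9

    def test_empty_significant_set_rejected(self, ico2):
        with pytest.raises(ValueError):
            synthesize_expansion(np.zeros((ico2.n_vertices * 3, 1)),
                                 ico2.vertices.ravel(), np.zeros((4, 1)),
                                 np.array([0, 0, 1, 1], bool), [], ico2.faces)


class TestParcelTests:
    @pytest.fixture(scope="class")
    def setup(self, ico2, ico2_dists):
        rng = np.random.default_rng(5)
        parc = np.argmin(M.geodesic_distances(
            M.icosphere(2), np.array([0, 30, 60, 90, 120, 150])), axis=0)
        W = np.exp(-ico2_dists ** 2 / (2 * (0.2 * ico2_dists.max()) ** 2))
        W /= W.sum(axis=1, keepdims=True)
        surr = np.stack([W @ rng.standard_normal(162) for _ in range(700)])
        surr = (surr - surr.mean(1, keepdims=True)) / surr.std(1, keepdims=True)
        return {"parc": parc, "surr": surr}

    def test_surrogate_draw_calibrated(self, setup):
        """A map drawn from the surrogate generator has uniform region p."""
        ps = []
        for i in range(100):
            obs = setup["surr"][i]
            null = np.delete(setup["surr"], i, axis=0)[:400]
            out = parcel_tests(obs, setup["parc"], null)
            ps.append(out["regions"]["p"].iloc[0])
        frac = np.mean(np.array(ps) < 0.05)
        assert 0.0 <= frac <= 0.12

    def test_planted_region_detected(self, setup):
        # enough surrogates that the BY-corrected q can reach below alpha:
        # with m regions the smallest attainable q is ~ m c(m) / (n_surr + 1)
        hits = 0
        for i in range(20):
            obs = setup["surr"][650 + i % 50].copy()
            obs[setup["parc"] == 2] += 3.0
            out = parcel_tests(obs, setup["parc"], setup["surr"][:600])
            row = out["regions"].set_index("region").loc[2]
            hits += bool(row["significant"])
        assert hits >= 19

    def test_small_region_excluded(self, setup, ico2):
        parc = setup["parc"].copy()
        parc[parc == 5] = 4
        parc[:3] = 9  # tiny region
        with pytest.warns(UserWarning):
            out = parcel_tests(setup["surr"][0], parc, setup["surr"][:50])
        assert 9 not in set(out["regions"]["region"])


class TestRmcorr:
    def test_perfect_linear_r_one(self):
        y = np.array([[1.0, 2, 3], [11, 12, 13], [21, 22, 23]])
        assert rmcorr(y, np.array([0.0, 1, 2]))["r"] == pytest.approx(1.0)

    def test_two_level_paired_difference_oracle(self):
        """Balanced two-condition design: r_rm from the paired differences."""
        rng = np.random.default_rng(6)
        y = rng.normal(size=(12, 2))
        xs = np.array([0.0, 1.0])
        res = rmcorr(y, xs)
        d = y[:, 1] - y[:, 0]
        # centered within subject: residuals are ±d/2 against ±1/2
        r_oracle = np.sum(d) / np.sqrt(len(d) * np.sum(d ** 2))
        assert res["r"] == pytest.approx(r_oracle, abs=1e-10)

    def test_negated_scale_flips_sign(self):
        rng = np.random.default_rng(7)
        y = rng.normal(size=(8, 3))
        xs = np.array([0.0, 0.5, 1.0])
        a = rmcorr(y, xs)
        b = rmcorr(y, -xs)
        assert b["r"] == pytest.approx(-a["r"])
        assert abs(b["p"] - a["p"]) < 1e-12

    def test_matches_pingouin(self):
        import pingouin as pg
        rng = np.random.default_rng(8)
        k, m = 7, 4
        y = rng.normal(size=(k, m))
        xs = np.linspace(0, 1, m)
        mine = rmcorr(y, xs)
        long = pd.DataFrame({"s": np.repeat(np.arange(k), m),
                             "x": np.tile(xs, k), "y": y.ravel()})
        theirs = pg.rm_corr(data=long, x="x", y="y", subject="s")
        assert mine["r"] == pytest.approx(float(theirs["r"].iloc[0]), abs=1e-10)
        assert mine["p"] == pytest.approx(float(theirs["pval"].iloc[0]), abs=1e-10)

    def test_zero_within_variance_flagged(self):
        y = np.tile(np.array([1.0, 2, 3])[:, None], (1, 3))
        assert rmcorr(y, np.array([0.0, 1, 2]))["undefined"]


class TestHabitatScale:
    def test_mirror_gives_minus_one(self):
        eff = {"arboreal": np.array([1.0, 2.0]), "terrestrial": np.array([0.0, 0.0]),
               "fossorial": np.array([-1.0, -2.0])}
        assert habitat_scale_estimate(eff).fossorial == pytest.approx(-1.0)

    def test_equal_to_terrestrial_gives_zero(self):
        eff = {"arboreal": np.array([1.0, 0.0]), "terrestrial": np.array([0.2, 0.1]),
               "fossorial": np.array([0.2, 0.1])}
        s = habitat_scale_estimate(eff)
        assert s.fossorial == pytest.approx(0.0, abs=1e-6)

    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            HabitatScale(arboreal=0.0, terrestrial=1.0, fossorial=-1.0)

    def test_degenerate_effects_rejected(self):
        eff = {"arboreal": np.zeros(3), "terrestrial": np.zeros(3),
               "fossorial": np.ones(3)}
        with pytest.raises(ValueError):
            habitat_scale_estimate(eff)


class TestDecodeMap:
    def test_self_retrieval(self):
        rng = np.random.default_rng(9)
        lib = {f"term{i:03d}": rng.normal(size=80) for i in range(120)}
        target = lib["term007"].copy()
        df = decode_map(target, lib)
        assert df["term"].iloc[0] == "term007"
        assert df["r"].iloc[0] == pytest.approx(1.0)

    def test_retained_count_is_ceil(self):
        rng = np.random.default_rng(10)
        lib = {f"t{i}": rng.normal(size=50) for i in range(300)}
        df = decode_map(rng.normal(size=50), lib, keep_fraction=0.01)
        assert len(df) == 3  # ceil(0.01 * 300)
        df2 = decode_map(rng.normal(size=50), lib, keep_fraction=0.002)
        assert len(df2) == 1

    def test_planted_term_retrieved_under_noise(self, ico2, ico2_dists):
        W = np.exp(-ico2_dists ** 2 / (2 * (0.15 * ico2_dists.max()) ** 2))
        W /= W.sum(axis=1, keepdims=True)
        rng = np.random.default_rng(11)
        hits = 0
        n_rep = 40
        for _ in range(n_rep):
            lib = {f"null{i:03d}": W @ rng.standard_normal(162) for i in range(200)}
            signal = W @ rng.standard_normal(162)
            noise = W @ rng.standard_normal(162)
            target = signal + noise * signal.std() / noise.std() / 3.0  # SNR 3
            lib["planted"] = signal
            df = decode_map(target, lib, keep_fraction=0.01)
            hits += "planted" in set(df["term"])
        assert hits / n_rep >= 0.95

    def test_constant_map_rejected(self):
        with pytest.raises(ValueError):
            decode_map(np.ones(30), {"a": np.arange(30.0)})


class TestClusterTrajectories:
    def _planted(self, rng, n_per=8):
        t = np.linspace(0, 3, 12)
        a = [np.sin(t) + rng.normal(0, 0.05, len(t)) for _ in range(n_per)]
        b = [np.cos(t) + rng.normal(0, 0.05, len(t)) for _ in range(n_per)]
        return np.vstack(a + b)

    def test_two_planted_groups_recovered(self):
        rng = np.random.default_rng(12)
        X = self._planted(rng)
        res = cluster_trajectories(X)
        assert res["k"] == 2
        assert res["silhouette"] > 0.7
        labels = res["labels"]
        assert len(set(labels[:8])) == 1 and len(set(labels[8:])) == 1

    def test_identical_rows_single_cluster(self):
        X = np.tile(np.arange(6.0), (5, 1))
        with pytest.warns(UserWarning):
            res = cluster_trajectories(X)
        assert res["k"] == 1

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(13)
        X = self._planted(rng)
        res1 = cluster_trajectories(X)
        perm = rng.permutation(len(X))
        res2 = cluster_trajectories(X[perm])
        # same partition up to relabeling
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(res1["labels"][perm], res2["labels"]) == 1.0


class TestInferentialSuite:
    def _long(self, rng, k=10, shift=0.0):
        rows = []
        for s in range(k):
            base = rng.normal()
            for c, name in enumerate(["a", "b", "c"]):
                rows.append({"subject": s, "cond": name,
                             "y": base + rng.normal() + shift * c})
        return pd.DataFrame(rows)

    def test_battery_runs_and_reports(self):
        rng = np.random.default_rng(14)
        out = inferential_suite(self._long(rng, shift=1.0), "y", "cond", "subject")
        assert set(out) >= {"normality_ks_p", "bartlett_p", "mauchly_p",
                            "ranova_p", "games_howell"}
        assert out["ranova_p"] < 0.05  # strong planted condition effect

    def test_games_howell_equal_variance_close_to_tukey(self):
        """With equal variances and large equal n, Games–Howell converges to
        Tukey HSD (the Welch degrees of freedom approach the pooled ones)."""
        import pingouin as pg
        rng = np.random.default_rng(15)
        rows = [{"cond": name, "y": rng.normal() + 0.06 * c}
                for _ in range(500) for c, name in enumerate(["a", "b", "c"])]
        df = pd.DataFrame(rows)
        gh = pg.pairwise_gameshowell(data=df, dv="y", between="cond")
        tk = pg.pairwise_tukey(data=df, dv="y", between="cond")
        assert np.abs(gh["pval"].to_numpy() - tk["p_tukey"].to_numpy()).max() < 0.01
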