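import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coexnet import association as assoc
from coexnet.model import CoexpressionNetwork, ModuleTraitModel
from coexnet.network import compute_eigengenes


def bh_stepup_oracle(p):
    """Hand step-up: sorted p_i * m / i, cumulative min from the largest rank."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    out = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(out, 1.0)
    return adj


class TestPartialPearson:
    def test_no_covariates_equals_pearsonr(self, rng):
        x, y = rng.standard_normal((2, 50))
        r, p, n = assoc.partial_pearson(x, y)
        r0, p0 = stats.pearsonr(x, y)
        assert abs(r - r0) < 1e-12 and abs(p - p0) < 1e-10
        assert n == 50

    def test_adjustment_recovers_masked_relation(self, rng):
        n = 200
        x = rng.standard_normal(n)
        c = rng.standard_normal(n)
        y = x + 5 * c
        r_plain, _, _ = assoc.partial_pearson(x, y)
        r_part, _, _ = assoc.partial_pearson(x, y, c[:, None])
        assert r_part >= 0.99
        assert r_plain < r_part - 0.3

    def test_matches_explicit_residualization(self, rng):
        n = 80
        c = rng.standard_normal((n, 3))
        x, y = rng.standard_normal((2, n))
        r, _, _ = assoc.partial_pearson(x, y, c)
        design = np.column_stack([np.ones(n), c])
        proj = design @ np.linalg.solve(design.T @ design, design.T)
        rx, ry = x - proj @ x, y - proj @ y
        assert abs(r - np.corrcoef(rx, ry)[0, 1]) < 1e-10

    def test_covariate_identical_to_x_errors(self, rng):
        x = rng.standard_normal(30)
        y = rng.standard_normal(30)
        with pytest.raises(ValueError, match="residual variance"):
            assoc.partial_pearson(x, y, x[:, None])

    def test_collinear_covariates_error(self, rng):
        x, y = rng.standard_normal((2, 30))
        c = rng.standard_normal(30)
        with pytest.raises(ValueError, match="rank deficient"):
            assoc.partial_pearson(x, y, np.column_stack([c, 2 * c]))

    def test_pairwise_complete_handling(self, rng):
        x, y = rng.standard_normal((2, 40))
        y = y.copy()
        y[:5] = np.nan
        r, p, n = assoc.partial_pearson(x, y)
        r0, _ = stats.pearsonr(x[5:], y[5:])
        assert n == 35 and abs(r - r0) < 1e-12


class TestBenjaminiHochberg:
    def test_worked_example(self):
        np.testing.assert_allclose(
            assoc.benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_and_boundary(self):
        assert assoc.benjamini_hochberg([0.37])[0] == pytest.approx(0.37)
        np.testing.assert_allclose(assoc.benjamini_hochberg([1.0, 1.0]), 1.0)

    def test_matches_stepup_oracle_on_random_vectors(self, rng):
        for _ in range(50):
            p = rng.uniform(0, 1, rng.integers(1, 40))
            np.testing.assert_allclose(assoc.benjamini_hochberg(p),
                                       bh_stepup_oracle(p), atol=1e-12)

    def test_rank_monotone_under_reordering(self, rng):
        p = rng.uniform(0, 1, 25)
        perm = rng.permutation(25)
        adj = assoc.benjamini_hochberg(p)
        np.testing.assert_allclose(assoc.benjamini_hochberg(p[perm]), adj[perm])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            assoc.benjamini_hochberg([0.5, 1.5])


class TestBootstrapCI:
    def test_perfect_correlation_collapses(self, rng):
        x = rng.standard_normal(30)
        lo, hi = assoc.bootstrap_correlation_ci(x, x, B=100, seed=0)
        assert lo == pytest.approx(1.0) and hi == pytest.approx(1.0)

    def test_same_seed_reproducible(self, rng):
        x, y = rng.standard_normal((2, 60))
        a = assoc.bootstrap_correlation_ci(x, y, B=200, seed=5)
        b = assoc.bootstrap_correlation_ci(x, y, B=200, seed=5)
        assert a == b

    def test_interval_brackets_estimate(self, rng):
        n = 90
        e = rng.standard_normal(n)
        x = 0.5 * e + np.sqrt(0.75) * rng.standard_normal(n)
        lo, hi = assoc.bootstrap_correlation_ci(x, e, B=300, seed=1)
        r, _, _ = assoc.partial_pearson(x, e)
        assert lo <= r <= hi

    def test_small_b_rejected(self, rng):
        x, y = rng.standard_normal((2, 20))
        with pytest.raises(ValueError, match="B"):
            assoc.bootstrap_correlation_ci(x, y, B=50)


class TestModuleTraitTable:
    def test_coupled_cell_detected_with_sign(self, small_study):
        truth = small_study.truth_modules.replace("background", "grey")
        me = compute_eigengenes(small_study.expression, truth)
        table = assoc.module_trait_table(me, small_study.traits,
                                         small_study.covariates)
        for _, row in small_study.trait_coupling.iterrows():
            if row["gamma"] == 0:
                continue
            cell = table[(table["module"] == f"ME{row['module']}") &
                         (table["trait"] == row["trait"])].iloc[0]
            assert cell["significant"]
            assert np.sign(cell["r"]) == np.sign(row["gamma"])

    def test_bh_applied_over_whole_family(self, small_study):
        truth = small_study.truth_modules.replace("background", "grey")
        me = compute_eigengenes(small_study.expression, truth)
        table = assoc.module_trait_table(me, small_study.traits)
        ok = table["p"].notna()
        np.testing.assert_allclose(table.loc[ok, "p_adj"],
                                   bh_stepup_oracle(table.loc[ok, "p"]),
                                   atol=1e-12)

    def test_constant_trait_reported_missing(self, small_study):
        truth = small_study.truth_modules.replace("background", "grey")
        me = compute_eigengenes(small_study.expression, truth)
        traits = small_study.traits.copy()
        traits["flat"] = 1.0
        with pytest.warns(UserWarning, match="missing"):
            table = assoc.module_trait_table(me, traits)
        flat = table[table["trait"] == "flat"]
        assert flat["r"].isna().all()

    def test_bootstrap_ci_brackets_r(self, small_study):
        truth = small_study.truth_modules.replace("background", "grey")
        me = compute_eigengenes(small_study.expression, truth)
        table = assoc.module_trait_table(me, small_study.traits[["T1"]],
                                         bootstrap_B=100, seed=3)
        ok = table.dropna(subset=["r"])
        assert ((ok["ci_low"] <= ok["r"]) & (ok["r"] <= ok["ci_high"])).all()


class TestGeneStatistics:
    def test_gs_self_correlation(self, rng):
        t = rng.standard_normal(40)
        expr = pd.DataFrame([t, rng.standard_normal(40)], index=["G1", "G2"],
                            columns=[f"S{j}" for j in range(40)])
        trait = pd.Series(t, index=expr.columns, name="T")
        gs = assoc.gene_significance(expr, trait)
        assert gs["G1"] == pytest.approx(1.0)
        assert ((gs >= 0) & (gs <= 1)).all()

    def test_mm_of_me_column_is_one(self, small_study):
        truth = small_study.truth_modules.replace("background", "grey")
        me = compute_eigengenes(small_study.expression, truth)
        expr = pd.concat([small_study.expression,
                          pd.DataFrame({"GME": me["MEmod1"]}).T])
        mm = assoc.module_membership(expr, me)
        assert mm.loc["GME", "MEmod1"] == pytest.approx(1.0, abs=1e-9)

    def test_mm_tracks_planted_loadings(self, small_study):
        truth = small_study.truth_modules.replace("background", "grey")
        me = compute_eigengenes(small_study.expression, truth)
        mm = assoc.module_membership(small_study.expression, me)
        genes = truth.index[truth == "mod1"]
        est = mm.loc[genes, "MEmod1"].abs()
        lam = small_study.loadings.loc[genes]
        assert np.corrcoef(est, lam)[0, 1] >= 0.8
        assert (est - lam).abs().median() < 0.1

    def test_mm_shape(self, small_study):
        truth = small_study.truth_modules.replace("background", "grey")
        me = compute_eigengenes(small_study.expression, truth)
        mm = assoc.module_membership(small_study.expression, me)
        assert mm.shape == (small_study.expression.shape[0], 3)


class TestGsMmCoupling:
    def test_coupled_module_positive_association(self, small_study):
        truth = small_study.truth_modules.replace("background", "grey")
        me = compute_eigengenes(small_study.expression, truth)
        mm = assoc.module_membership(small_study.expression, me)
        gs = assoc.gene_significance(small_study.expression,
                                     small_study.traits["T1"])
        r, p = assoc.gs_mm_test(gs, mm, truth, "mod1")
        assert r > 0 and p < 0.05

    def test_coupled_module_stronger_than_uncoupled(self):
        """The coupled module's GS-MM correlation dominates the uncoupled
        one's; the uncoupled module still shows a mild chance coupling
        through the sampling correlation of its factor with the trait."""
        from coexnet.synthetic import SyntheticConfig, TraitSpec, simulate_study
        r_coupled, r_uncoupled = [], []
        for seed in range(10):
            cfg = SyntheticConfig(module_sizes=[100, 60], n_genes=200,
                                  n_samples=90,
                                  traits=[TraitSpec("T1", 1, 0.5)], seed=seed)
            s = simulate_study(cfg)
            truth = s.truth_modules.replace("background", "grey")
            me = compute_eigengenes(s.expression, truth)
            mm = assoc.module_membership(s.expression, me)
            gs = assoc.gene_significance(s.expression, s.traits["T1"])
            r_coupled.append(assoc.gs_mm_test(gs, mm, truth, "mod2")[0])
            r_uncoupled.append(assoc.gs_mm_test(gs, mm, truth, "mod1")[0])
        assert np.mean(r_coupled) > np.mean(np.abs(r_uncoupled))
        assert np.mean(r_coupled) > 0.4

    def test_zero_variance_errors(self, rng):
        gs = pd.Series(0.5, index=[f"G{i}" for i in range(5)])
        mm = pd.DataFrame({"MEa": 0.9}, index=gs.index)
        assign = pd.Series("a", index=gs.index)
        with pytest.raises(ValueError, match="constant"):
            assoc.gs_mm_test(gs, mm, assign, "a")


class TestHubSelection:
    def setup_frames(self):
        genes = [f"G{i}" for i in range(4)]
        mm = pd.DataFrame({"MEa": [0.9, 0.9, -0.85, 0.5]}, index=genes)
        gs = pd.Series([0.4, 0.2, 0.35, 0.9], index=genes)
        assign = pd.Series("a", index=genes)
        return gs, mm, assign

    def test_threshold_rules(self):
        gs, mm, assign = self.setup_frames()
        hub = assoc.select_hub_genes(gs, mm, assign, ["a"])
        # G0 passes both; G1 fails GS; G2 passes via |MM|; G3 fails MM
        assert hub.genes == ["G0", "G2"]

    def test_unknown_module_errors(self):
        gs, mm, assign = self.setup_frames()
        with pytest.raises(KeyError):
            assoc.select_hub_genes(gs, mm, assign, ["nope"])

    def test_selected_genes_have_high_loadings(self, small_study):
        truth = small_study.truth_modules.replace("background", "grey")
        me = compute_eigengenes(small_study.expression, truth)
        mm = assoc.module_membership(small_study.expression, me)
        gs = assoc.gene_significance(small_study.expression,
                                     small_study.traits["T1"])
        hub = assoc.select_hub_genes(gs, mm, truth, ["mod1"])
        assert len(hub.genes) > 0
        lam = small_study.loadings
        med = lam[truth == "mod1"].median()
        frac = (lam.loc[hub.genes] > med).mean()
        assert frac >= 0.9


class TestModuleClustering:
    def make_results(self, profiles, significant=True):
        rows = []
        for mod, prof in profiles.items():
            for t, r in enumerate(prof):
                rows.append((mod, f"T{t}", r, 60, 0.001, 0.001, significant))
        return pd.DataFrame(rows, columns=["module", "trait", "r", "n", "p",
                                           "p_adj", "significant"])

    def test_sign_groups_separate(self):
        res = self.make_results({
            "m1": [0.5, 0.4, 0.6], "m2": [0.45, 0.5, 0.55], "m3": [0.6, 0.45, 0.5],
            "m4": [-0.5, -0.4, -0.6], "m5": [-0.45, -0.5, -0.55],
            "m6": [-0.6, -0.45, -0.5]})
        tree = assoc.cluster_modules_by_trait_profile(res, k=2)
        pos = {tree.clusters[m] for m in ["m1", "m2", "m3"]}
        neg = {tree.clusters[m] for m in ["m4", "m5", "m6"]}
        assert len(pos) == 1 and len(neg) == 1 and pos != neg

    def test_identical_profiles_same_cluster(self):
        res = self.make_results({"a": [0.3, 0.3], "b": [0.3, 0.3],
                                 "c": [-0.9, 0.8]})
        tree = assoc.cluster_modules_by_trait_profile(res, k=2)
        assert tree.clusters["a"] == tree.clusters["b"]

    def test_input_order_invariance(self):
        res = self.make_results({"m1": [0.5, 0.1], "m2": [0.4, 0.2],
                                 "m3": [-0.5, -0.1]})
        shuffled = res.sample(frac=1.0, random_state=0).reset_index(drop=True)
        a = assoc.cluster_modules_by_trait_profile(res, k=2).clusters
        b = assoc.cluster_modules_by_trait_profile(shuffled, k=2).clusters
        assert a.to_dict() == b.to_dict()

    def test_too_few_modules_errors(self):
        res = self.make_results({"only": [0.5]})
        with pytest.raises(ValueError, match=">= 2"):
            assoc.cluster_modules_by_trait_profile(res)


class TestModelFrontEnd:
    def test_fit_summary_and_hub_sets(self, small_study):
        net = CoexpressionNetwork(small_study.expression).fit()
        assert net.n_modules >= 2
        assert "modules:" in net.summary()
        res = ModuleTraitModel(net, small_study.traits,
                               small_study.covariates).fit(
            bootstrap_B=0, seed=0)
        assert len(res.significant_modules) >= 2
        hubs = res.hub_gene_sets()
        for h in hubs:
            assert (h.table["MM"].abs() > 0.8).all()
            assert (h.table["GS"] > 0.3).all()
        assert "partial correlations" in res.summary()
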