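import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import linalg

from cuephylo import phylocomp as pc
from cuephylo import synthetic_data as sd
from cuephylo.calibration import reroot_tip_estimate
from conftest import star_vcv


class TestVcv:
    def test_star_tree_is_diagonal(self):
        tree = pc.read_tree("(a:1,b:1,c:1,d:1);")
        V, labels = pc.vcv_matrix(tree)
        assert np.allclose(V, np.eye(4))

    def test_two_tips_joined_at_root(self):
        tree = pc.read_tree("(a:2,b:3);")
        V, labels = pc.vcv_matrix(tree)
        order = [labels.index("a"), labels.index("b")]
        assert V[order[0], order[0]] == pytest.approx(2.0)
        assert V[order[1], order[1]] == pytest.approx(3.0)
        assert V[order[0], order[1]] == pytest.approx(0.0)

    def test_balanced_tree_matches_hand_computation(self, balanced_tree):
        V, labels = pc.vcv_matrix(balanced_tree)
        idx = {l: i for i, l in enumerate(labels)}
        assert np.allclose(np.diag(V), 2.0)
        assert V[idx["a"], idx["b"]] == pytest.approx(1.0)
        assert V[idx["c"], idx["d"]] == pytest.approx(1.0)
        assert V[idx["a"], idx["c"]] == pytest.approx(0.0)

    def test_negative_branch_length_rejected(self):
        with pytest.raises(ValueError):
            pc.vcv_matrix(pc.read_tree("(a:1,b:-0.5);"))


class TestLambdaTransform:
    def test_identity_at_one(self, yule16_vcv):
        V, _ = yule16_vcv
        assert np.allclose(pc.lambda_transform(V, 1.0), V)

    def test_diagonal_at_zero(self, yule16_vcv):
        V, _ = yule16_vcv
        assert np.allclose(pc.lambda_transform(V, 0.0), np.diag(np.diag(V)))

    def test_halfway_elementwise(self, balanced_tree):
        V, _ = pc.vcv_matrix(balanced_tree)
        Vl = pc.lambda_transform(V, 0.5)
        off = ~np.eye(4, dtype=bool)
        assert np.allclose(Vl[off], 0.5 * V[off])
        assert np.allclose(np.diag(Vl), np.diag(V))

    def test_out_of_range_rejected(self, yule16_vcv):
        with pytest.raises(ValueError):
            pc.lambda_transform(yule16_vcv[0], 1.2)


class TestBlombergK:
    def test_star_tree_gives_unity(self, rng):
        V, labels = star_vcv(12)
        y = pd.Series(rng.normal(size=12), index=labels)
        assert pc.blomberg_k(V, y, labels) == pytest.approx(1.0)

    def test_constant_trait_rejected(self, yule16_vcv):
        V, labels = yule16_vcv
        with pytest.raises(ValueError):
            pc.blomberg_k(V, pd.Series(1.0, index=labels), labels)

    def test_permutation_p_reproducible_and_detects_clustering(self, two_clade_tree):
        V, labels = pc.vcv_matrix(two_clade_tree)
        y = pd.Series([0, 0.1, -0.1, 0.05, 3.0, 3.1, 2.9, 3.05], index=labels)
        k1, p1 = pc.blomberg_k_pvalue(V, y, n_perm=999, seed=5, labels=labels)
        k2, p2 = pc.blomberg_k_pvalue(V, y, n_perm=999, seed=5, labels=labels)
        assert (k1, p1) == (k2, p2)
        assert p1 <= 0.05

    def test_matches_phytools_oracle(self, tmp_path):
        tree = sd.simulate_tree(sd.TreeSimParams(n_tips=12, seed=7))
        trait = sd.simulate_trait_bm(tree, sd.TraitSimParams(lambda_sim=0.7, seed=3))
        tree.write(path=str(tmp_path / "t.nwk"), schema="newick",
                   suppress_rooting=True)
        trait.to_csv(tmp_path / "x.csv", header=["x"])
        V, labels = pc.vcv_matrix(tree)
        k = pc.blomberg_k(V, trait, labels)
        lam = pc.pagel_lambda_ml(V, trait, labels=labels)
        script = f"""
        suppressMessages(library(phytools))
        tr <- read.tree("{tmp_path}/t.nwk")
        d <- read.csv("{tmp_path}/x.csv", row.names=1)
        x <- setNames(d$x, rownames(d))
        fit <- phylosig(tr, x, method="lambda")
        cat(phylosig(tr, x, method="K"), fit$lambda, fit$logL, "\\n")
        """
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True).stdout.split()
        k_r, lam_r, ll_r = map(float, out[:3])
        assert k == pytest.approx(k_r, abs=1e-5)
        assert lam.lambda_hat == pytest.approx(lam_r, abs=1e-3)
        assert lam.loglik == pytest.approx(ll_r, abs=1e-3)


class TestPagelLambda:
    def test_boundary_estimate_has_unit_pvalue(self, yule16_vcv, rng):
        V, labels = yule16_vcv
        # white-noise trait: lambda_hat at 0 -> LRT p of 1
        y = pd.Series(rng.normal(size=len(labels)), index=labels)
        res = pc.pagel_lambda_ml(V, y, labels=labels)
        if res.lambda_hat <= 1e-8:
            assert res.lrt_p == 1.0

    def test_loglik_at_one_matches_direct_mvn_likelihood(self, yule16_vcv, rng):
        V, labels = yule16_vcv
        n = len(labels)
        y = pc.simulate_bm_on_vcv(V, 1, rng)[:, 0]
        dec = pc.PhyloDecomp(V)
        ll = dec.loglik_lambda(dec.transform(y), 1.0)
        # independent dense-matrix route
        ones = np.ones(n)
        Vinv_1 = linalg.solve(V, ones, assume_a="pos")
        a = float(Vinv_1 @ y) / float(ones @ Vinv_1)
        dev = y - a
        sigma2 = float(dev @ linalg.solve(V, dev, assume_a="pos")) / n
        sign, logdet = np.linalg.slogdet(V)
        ll_direct = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
        assert ll == pytest.approx(ll_direct, abs=1e-8)


class TestBmSignalCi:
    def test_interval_contains_bm_expectation(self, yule16_vcv):
        V, labels = yule16_vcv
        (k_lo, k_hi), (l_lo, l_hi) = pc.bm_signal_ci(V, n_sim=300, seed=2,
                                                     labels=labels)
        assert k_lo < 1.0 < k_hi
        assert l_hi == pytest.approx(1.0, abs=1e-6)

    def test_fixed_seed_reproducible(self, yule16_vcv):
        V, labels = yule16_vcv
        a = pc.bm_signal_ci(V, n_sim=150, seed=3, labels=labels)
        b = pc.bm_signal_ci(V, n_sim=150, seed=3, labels=labels)
        assert a == b

    def test_small_n_sim_warns(self, yule16_vcv):
        V, labels = yule16_vcv
        with pytest.warns(UserWarning):
            pc.bm_signal_ci(V, n_sim=99, seed=1, labels=labels)


class TestTipPrediction:
    def test_star_tree_predicts_mean_of_remaining(self, rng):
        V, labels = star_vcv(6)
        y = pd.Series(rng.normal(size=6), index=labels)
        table, _ = pc.predict_tip_loo(V, y, use_lambda_rescale=False,
                                      labels=labels)
        for lab in labels:
            rest = y.drop(lab).mean()
            assert table.loc[lab, "predicted"] == pytest.approx(rest)

    def test_constant_trait_predicted_exactly(self, two_clade_tree):
        V, labels = pc.vcv_matrix(two_clade_tree)
        y = pd.Series(0.4, index=labels)
        table, _ = pc.predict_tip_loo(V, y, use_lambda_rescale=False,
                                      labels=labels)
        assert np.allclose(table["error"], 0.0)

    def test_agrees_with_reroot_oracle(self, yule16_vcv):
        V, labels = yule16_vcv
        y = sd.simulate_trait_bm(
            sd.simulate_tree(sd.TreeSimParams(n_tips=16, seed=42)),
            sd.TraitSimParams(seed=9)).reindex(labels)
        table, _ = pc.predict_tip_loo(V, y, use_lambda_rescale=False,
                                      labels=labels)
        for i, lab in enumerate(labels):
            assert table.loc[lab, "predicted"] == pytest.approx(
                reroot_tip_estimate(V, y.to_numpy(), i), abs=1e-10)

    def test_too_few_tips_rejected(self):
        V, labels = star_vcv(3)
        with pytest.raises(ValueError):
            pc.predict_tip_loo(V, pd.Series([1.0, 2.0, 3.0], index=labels),
                               labels=labels)


class TestPgls:
    def test_identity_covariance_reproduces_ols(self, rng):
        n = 20
        V, labels = star_vcv(n)
        y = rng.normal(size=n)
        X = rng.normal(size=(n, 2))
        fit = pc.pgls_fit(V, y, X, lam=1.0, labels=labels)
        beta = np.linalg.lstsq(np.column_stack([np.ones(n), X]), y, rcond=None)[0]
        assert np.allclose(fit.params.to_numpy(), beta, atol=1e-10)

    def test_intercept_only_model_recovers_gls_mean(self, yule16_vcv, rng):
        V, labels = yule16_vcv
        y = pc.simulate_bm_on_vcv(V, 1, rng)[:, 0]
        fit = pc.pgls_fit(V, y, None, lam=1.0, labels=labels)
        assert fit.params["intercept"] == pytest.approx(pc.gls_mean(V, y))

    def test_rank_deficient_design_rejected(self, yule16_vcv, rng):
        V, labels = yule16_vcv
        x = rng.normal(size=16)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(ValueError):
            pc.pgls_fit(V, rng.normal(size=16), X, lam=0.5, labels=labels)

    def test_scan_matches_single_fits(self, yule16_vcv, rng):
        V, labels = yule16_vcv
        y = pd.Series(pc.simulate_bm_on_vcv(V, 1, rng)[:, 0], index=labels)
        F = pd.DataFrame(rng.normal(size=(16, 5)),
                         index=labels, columns=list("abcde"))
        grid = np.linspace(0, 1, 101)
        scan = pc.pgls_scan(V, y, F, lambda_grid=grid, labels=labels)
        for col in F.columns:
            fit = pc.pgls_fit(V, y, F[[col]], lam="ml", labels=labels)
            assert scan.loc[col, "slope"] == pytest.approx(
                fit.params.iloc[1], rel=1e-2, abs=1e-8)
            assert scan.loc[col, "p"] == pytest.approx(
                fit.pvalues.iloc[1], rel=0.05, abs=1e-4)

    def test_constant_feature_yields_nan_row(self, yule16_vcv, rng):
        V, labels = yule16_vcv
        y = pd.Series(rng.normal(size=16), index=labels)
        F = pd.DataFrame({"const": np.ones(16), "ok": rng.normal(size=16)},
                         index=labels)
        scan = pc.pgls_scan(V, y, F, labels=labels)
        assert np.isnan(scan.loc["const", "p"])
        assert np.isfinite(scan.loc["ok", "p"])


class TestResidualCheck:
    def test_iid_residuals_pass(self, yule16_vcv, rng):
        V, labels = yule16_vcv
        x = rng.normal(size=16)
        y = 0.5 * x + rng.normal(size=16)
        fit = pc.pgls_fit(V, y, x[:, None], lam="ml", labels=labels)
        chk = pc.residual_phylosig_check(fit, V, seed=1)
        assert chk["passed"]

    def test_model_ignoring_phylogeny_fails(self, two_clade_tree, rng):
        V, labels = pc.vcv_matrix(two_clade_tree)
        # strongly clustered response, unrelated predictor, no lambda
        # correction: residuals keep the clade structure
        y = pd.Series([0, 0.05, -0.05, 0.02, 3.0, 3.05, 2.95, 3.02],
                      index=labels)
        x = pd.Series(rng.normal(size=8), index=labels)
        fit = pc.pgls_fit(V, y, x.to_frame("x"), lam=0.0, labels=labels)
        chk = pc.residual_phylosig_check(fit, V, seed=1)
        assert not chk["passed"]

    def test_constant_residuals_degenerate_pass(self, yule16_vcv):
        V, labels = yule16_vcv
        y = pd.Series(np.linspace(0, 1, 16), index=labels)
        fit = pc.pgls_fit(V, y, y.to_frame("x"), lam=0.0, labels=labels)
        chk = pc.residual_phylosig_check(fit, V, seed=1)
        assert chk["passed"] and chk["degenerate"]
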