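import numpy as np
import pandas as pd
import pytest

from rumenpred.data_io import GenotypeMatrix
from rumenpred.kernels import grm_scaled
from rumenpred.mixed_models import blup_predict, reml_fit
from rumenpred.nn_gblup import (
    GRMEigen,
    McmcSettings,
    NNGBLUPModel,
    derive_pc_seed,
    fit_layer1,
    fit_layer2,
    fit_nn_gblup,
    gibbs_gblup_single,
    predict_gebv,
)
from rumenpred.preprocess import AdjustedPhenotypes, FeatureMatrix, pca_reduce


def _geno(rng, n, k):
    freqs = rng.uniform(0.1, 0.9, k)
    M = rng.binomial(2, freqs, size=(n, k)).astype(float)
    return GenotypeMatrix([f"s{i}" for i in range(n)], [f"m{j}" for j in range(k)], M)


@pytest.fixture(scope="module")
def eig_small():
    rng = np.random.default_rng(0)
    geno = _geno(rng, 40, 120)
    return geno, GRMEigen.from_genotypes(geno)


class TestGibbsSingle:
    def test_null_feature_gives_null_genetic_values(self, eig_small):
        _, eig = eig_small
        out = gibbs_gblup_single(np.zeros(40), eig, McmcSettings(seed=1))
        assert np.max(np.abs(out["g"])) <= 0.05

    def test_same_seed_bit_identical(self, eig_small):
        _, eig = eig_small
        rng = np.random.default_rng(2)
        y = rng.normal(size=40)
        a = gibbs_gblup_single(y, eig, McmcSettings(seed=3))
        b = gibbs_gblup_single(y, eig, McmcSettings(seed=3))
        np.testing.assert_array_equal(a["g"], b["g"])
        assert a["mu"] == b["mu"] and a["sigma2_g"] == b["sigma2_g"]

    def test_posterior_mean_matches_reml_blup(self):
        """Conditional on the REML variances, the Gibbs mean of g is the BLUP.

        The full sampler integrates over the (wide, at n=50) variance posterior
        and so differs from the plug-in BLUP in shrinkage scale but not in
        direction; with the variances held at the REML estimates the identity
        is exact up to Monte-Carlo error.
        """
        rng = np.random.default_rng(4)
        n = 50
        geno = _geno(rng, n, 300)
        G = grm_scaled(geno)
        eig = GRMEigen.from_genotypes(geno)
        L = np.linalg.cholesky(G.values + 1e-6 * np.eye(n))
        g_true = L @ rng.normal(size=n) * np.sqrt(0.5)
        y = g_true + rng.normal(size=n) * np.sqrt(0.5)
        y_adj = AdjustedPhenotypes(geno.sample_ids, "pc", y)
        fit = reml_fit(y_adj, [G])
        blup = blup_predict(fit, y_adj, [G], geno.sample_ids, geno.sample_ids)
        settings = McmcSettings(chain_length=200_000, burn_in=20_000, thinning=10, seed=5)
        fixed = gibbs_gblup_single(
            y, eig, settings,
            fix_variances=(fit.varcomps.components[G.label], fit.varcomps.residual),
        )
        rms = np.sqrt(np.mean((fixed["g"] - blup.gebv) ** 2))
        assert rms <= 0.02
        full = gibbs_gblup_single(y, eig, settings)
        assert np.corrcoef(full["g"], blup.gebv)[0, 1] >= 0.99

    def test_chain_shorter_than_burn_in_rejected(self):
        with pytest.raises(ValueError, match="burn-in"):
            McmcSettings(chain_length=100, burn_in=200)

    def test_doubling_chain_moves_less_than_mc_error(self, eig_small):
        _, eig = eig_small
        rng = np.random.default_rng(6)
        y = rng.normal(size=40)
        short = gibbs_gblup_single(
            y, eig, McmcSettings(chain_length=12_000, burn_in=2_000, thinning=5, seed=7))
        long = gibbs_gblup_single(
            y, eig, McmcSettings(chain_length=24_000, burn_in=2_000, thinning=5, seed=7))
        mc_se = short["g_sd"] / np.sqrt(short["n_kept"] / 20)  # crude batch-means scale
        assert np.all(np.abs(short["g"] - long["g"]) <= 3 * mc_se + 1e-3)


class TestLayer1:
    def test_equals_separate_single_fits(self, eig_small):
        geno, eig = eig_small
        rng = np.random.default_rng(8)
        S = rng.normal(size=(40, 2))
        st = McmcSettings(chain_length=2000, burn_in=400, thinning=2, seed=9)
        fit = fit_layer1(geno, S, st, eig_G=eig)
        for j in range(2):
            single = gibbs_gblup_single(S[:, j], eig, st, seed=derive_pc_seed(9, j))
            np.testing.assert_array_equal(fit.genetic_values[:, j], single["g"])
            assert fit.mu[j] == single["mu"]

    def test_pure_genetic_signal_recovered(self):
        rng = np.random.default_rng(10)
        n, k = 100, 500
        geno = _geno(rng, n, k)
        Xc = geno.dosages - geno.dosages.mean(axis=0)
        pc = Xc @ rng.standard_normal(k) / np.sqrt(k)  # heritability ~1, no noise
        fit = fit_layer1(geno, pc[:, None], McmcSettings(seed=11))
        r = np.corrcoef(fit.genetic_values[:, 0], pc)[0, 1]
        assert r >= 0.95

    def test_permuting_pc_columns_permutes_results(self, eig_small):
        geno, eig = eig_small
        rng = np.random.default_rng(12)
        S = rng.normal(size=(40, 3))
        st = McmcSettings(chain_length=1500, burn_in=300, seed=13)
        fit = fit_layer1(geno, S, st, eig_G=eig)
        # seeds follow the column index, so values are reproduced per position
        fit_swapped = fit_layer1(geno, S[:, [1, 0, 2]], st, eig_G=eig)
        single0 = gibbs_gblup_single(S[:, 1], eig, st, seed=derive_pc_seed(13, 0))
        np.testing.assert_array_equal(fit_swapped.genetic_values[:, 0], single0["g"])
        del fit


class TestLayer2:
    def test_strong_signal_weight_recovered(self):
        rng = np.random.default_rng(14)
        n = 150
        pc = rng.normal(size=(n, 1))
        y = 3.0 * pc[:, 0] + rng.normal(size=n) * 0.01
        fit = fit_layer2(pc, y, McmcSettings(seed=15))
        assert 2.9 <= fit.weights[0] <= 3.1

    def test_null_weights_shrink(self):
        rng = np.random.default_rng(16)
        n, J = 200, 10
        pc = rng.normal(size=(n, J))
        maxw = 0.0
        for seed in range(5):
            y = rng.standard_normal(n)
            fit = fit_layer2(pc, y, McmcSettings(seed=seed))
            maxw = max(maxw, np.max(np.abs(fit.weights)))
        assert maxw <= 0.15

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(17)
        pc = rng.normal(size=(60, 4))
        y = rng.normal(size=60)
        a = fit_layer2(pc, y, McmcSettings(seed=18))
        b = fit_layer2(pc, y, McmcSettings(seed=18))
        np.testing.assert_array_equal(a.weights, b.weights)
        assert a.mu == b.mu

    def test_too_many_predictors_rejected(self):
        rng = np.random.default_rng(19)
        pc = rng.normal(size=(30, 25))
        y = rng.normal(size=30)
        with pytest.raises(ValueError, match="post-burn-in"):
            fit_layer2(pc, y, McmcSettings(chain_length=120, burn_in=100, seed=0))


def _toy_model(rng, n=40, k=100, J=3):
    geno = _geno(rng, n, k)
    eig = GRMEigen.from_genotypes(geno)
    S = rng.normal(size=(n, J))
    st = McmcSettings(chain_length=1500, burn_in=300, seed=21)
    layer1 = fit_layer1(geno, S, st, eig_G=eig)
    y = S @ np.array([1.0, -0.5, 0.25][:J]) + rng.normal(size=n) * 0.3
    layer2 = fit_layer2(S, y, st)
    model = NNGBLUPModel(layer1, layer2, st, J, geno.sample_ids, eig)
    return geno, model


class TestPredictGebv:
    def test_zero_weights_give_zero_gebv(self):
        rng = np.random.default_rng(20)
        geno, model = _toy_model(rng)
        model.layer2.weights = np.zeros(model.J)
        gebv = predict_gebv(model, geno)
        np.testing.assert_allclose(gebv["gebv"], 0.0, atol=1e-12)

    def test_marker_and_kernel_routes_agree(self):
        rng = np.random.default_rng(22)
        geno, model = _toy_model(rng)
        a = predict_gebv(model, geno, route="kernel")["gebv"].to_numpy()
        b = predict_gebv(model, geno, route="marker")["gebv"].to_numpy()
        np.testing.assert_allclose(a, b, rtol=1e-6, atol=1e-9)

    def test_gebv_linear_in_weights(self):
        rng = np.random.default_rng(23)
        geno, model = _toy_model(rng, J=1)
        model.layer2.weights = np.array([1.0])
        g1 = predict_gebv(model, geno)["gebv"].to_numpy()
        model.layer2.weights = np.array([2.0])
        g2 = predict_gebv(model, geno)["gebv"].to_numpy()
        np.testing.assert_allclose(g2, 2.0 * g1, rtol=1e-12)

    def test_superposition_over_genetic_values(self):
        rng = np.random.default_rng(24)
        geno, model = _toy_model(rng, J=2)
        full = predict_gebv(model, geno)["gebv"].to_numpy()
        parts = []
        for j in range(2):
            gv = np.zeros_like(model.layer1.genetic_values)
            gv[:, j] = model.layer1.genetic_values[:, j]
            sub = NNGBLUPModel(
                type(model.layer1)(model.layer1.pc_ids, model.layer1.mu, gv,
                                   model.layer1.sigma2_g, model.layer1.sigma2_eps),
                model.layer2, model.settings, 2, model.train_ids, model.eig_G)
            parts.append(predict_gebv(sub, geno)["gebv"].to_numpy())
        np.testing.assert_allclose(full, parts[0] + parts[1], rtol=1e-8, atol=1e-10)


class TestFitNNGblup:
    def test_rank_one_features_give_single_pc(self):
        rng = np.random.default_rng(25)
        n = 30
        geno = _geno(rng, n, 60)
        u = rng.normal(size=n)
        v = rng.normal(size=5)
        fm = FeatureMatrix(geno.sample_ids, [f"f{j}" for j in range(5)],
                           np.outer(u, v), "standardized")
        pca = pca_reduce(fm)
        y = AdjustedPhenotypes(geno.sample_ids, "t", rng.normal(size=n))
        st = McmcSettings(chain_length=1200, burn_in=200, seed=26)
        for threshold in (0.25, 0.95):
            model, gebv = fit_nn_gblup(geno, pca, y, geno.sample_ids, st,
                                       threshold=threshold)
            assert model.J == 1
            assert len(gebv) == n

    def test_null_pcs_give_negligible_gebv_variance(self):
        rng = np.random.default_rng(27)
        n = 60
        geno = _geno(rng, n, 100)
        fm = FeatureMatrix(geno.sample_ids, [f"f{j}" for j in range(10)],
                           rng.normal(size=(n, 10)), "standardized")
        pca = pca_reduce(fm)
        y_vals = rng.standard_normal(n)
        y = AdjustedPhenotypes(geno.sample_ids, "t", y_vals)
        st = McmcSettings(chain_length=3000, burn_in=500, seed=28)
        model, gebv = fit_nn_gblup(geno, pca, y, geno.sample_ids, st, threshold=0.95)
        ratio = np.var(gebv["gebv"]) / np.var(y_vals)
        assert ratio <= 0.02
        del model

    def test_transductive_mode_uses_all_samples_in_layer1(self):
        rng = np.random.default_rng(29)
        n = 30
        geno = _geno(rng, n, 50)
        fm = FeatureMatrix(geno.sample_ids, [f"f{j}" for j in range(6)],
                           rng.normal(size=(n, 6)), "standardized")
        pca = pca_reduce(fm)
        y = AdjustedPhenotypes(geno.sample_ids, "t", rng.normal(size=n))
        st = McmcSettings(chain_length=1000, burn_in=200, seed=30)
        train = geno.sample_ids[:20]
        m_train, _ = fit_nn_gblup(geno, pca, y, train, st, threshold=0.5)
        m_trans, _ = fit_nn_gblup(geno, pca, y, train, st, threshold=0.5,
                                  mode="transductive")
        assert m_train.train_ids == train
        assert m_trans.train_ids == geno.sample_ids
        assert m_trans.layer1.genetic_values.shape[0] == n
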