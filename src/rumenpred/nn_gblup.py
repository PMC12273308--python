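"""Two-layer Bayesian NN-GBLUP with microbiome PCs as observed intermediate traits.

Layer 1 fits one Bayesian GBLUP per microbiome PC (genotypes -> PC), layer 2 a
Bayesian ridge regression of the phenotype on the PCs with a linear activation.
Because the omics layer is fully observed and the activation linear, the two
layers decouple and are fitted sequentially; the genomic estimated breeding
value composes them: GEBV = X W_hat^(0) w^(1), equivalently (and by default)
through kernel cross-blocks g_hat[target] = G[target,train] G[train,train]^-1
g_hat[train] followed by the layer-2 weights.

Both samplers are conjugate Gibbs schemes run in an eigenbasis (of the scaled
GRM for layer 1, of S'S for layer 2) so each sweep costs O(n) / O(nJ).
Variances carry scaled-inverse-chi-square priors with nu = 4 and scale chosen
so the prior mode equals half the variance of that sampler's response.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, eigh

from .data_io import GenotypeMatrix
from .kernels import _scaled_grm_parts
from .preprocess import AdjustedPhenotypes, PCAResult

logger = logging.getLogger("rumenpred")


@dataclass(frozen=True)
class McmcSettings:
    """Gibbs chain controls; ``paper_scale()`` restores the long published chain."""

    chain_length: int = 6000
    burn_in: int = 1000
    thinning: int = 5
    seed: int = 0
    prior_df: float = 4.0

    def __post_init__(self) -> None:
        if self.burn_in >= self.chain_length:
            raise ValueError("burn-in must be shorter than the chain")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")

    @property
    def n_kept(self) -> int:
        return (self.chain_length - self.burn_in) // self.thinning

    def paper_scale(self) -> "McmcSettings":
        return replace(self, chain_length=60000, burn_in=10000, thinning=10)


def derive_pc_seed(master_seed: int, pc_index: int) -> np.random.SeedSequence:
    """Deterministic per-PC seed so chains are independent of execution order."""
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(pc_index,))


def _prior_scale(var_obs: float, nu: float) -> float:
    """Scale s2 of a scaled-inv-chi2 prior whose mode is half the observed variance."""
    return 0.5 * max(var_obs, 1e-12) * (nu + 2.0) / nu


def _draw_sichi2(rng: np.random.Generator, df: float, scale: float) -> float:
    return df * scale / rng.chisquare(df)


@dataclass
class GRMEigen:
    """Eigendecomposition of the scaled GRM on the training samples."""

    sample_ids: list[str]
    evals: np.ndarray
    evecs: np.ndarray
    col_means: np.ndarray
    col_sds: np.ndarray
    snp_mask: np.ndarray

    @classmethod
    def from_genotypes(cls, genotypes: GenotypeMatrix) -> "GRMEigen":
        G, mu, sd, keep = _scaled_grm_parts(genotypes)
        d, U = eigh(G)
        d = np.clip(d, 0.0, None)
        return cls(list(genotypes.sample_ids), d, U, mu, sd, keep)


def gibbs_gblup_single(
    feature: np.ndarray,
    eig_G: GRMEigen,
    settings: McmcSettings,
    seed: np.random.SeedSequence | int | None = None,
    fix_variances: tuple[float, float] | None = None,
) -> dict:
    """Gibbs sampler for  y = mu + g + eps,  g ~ N(0, G sigma2_g).

    Sampling happens in the eigenbasis of G: with G = U D U', g = U gamma and
    gamma_i ~ N(0, d_i sigma2_g) independently, so every conditional is scalar.
    Returns post-burn-in thinned posterior means (and the posterior SD of g).

    ``fix_variances=(sigma2_g, sigma2_eps)`` holds the variances fixed instead
    of sampling them — a diagnostic mode in which the posterior mean of g is
    exactly the BLUP at those variances.
    """
    y = np.asarray(feature, dtype=float)
    n = y.size
    if n != len(eig_G.sample_ids):
        raise ValueError("feature length does not match the GRM")
    if not np.isfinite(y).all():
        raise ValueError("feature contains non-finite values")
    if seed is None:
        seed = settings.seed
    rng = np.random.default_rng(seed)

    d = eig_G.evals
    U = eig_G.evecs
    pos = d > d.max() * 1e-10 if d.max() > 0 else d > 0
    q = int(pos.sum())
    yt = U.T @ y
    it_one = U.T @ np.ones(n)

    var_y = float(np.var(y, ddof=1)) if n > 1 else 1.0
    nu = settings.prior_df
    s2_g_prior = _prior_scale(var_y, nu)
    s2_e_prior = _prior_scale(var_y, nu)

    mu = float(np.mean(y))
    gamma = np.zeros(n)
    if fix_variances is not None:
        s2g, s2e = fix_variances
        if s2g <= 0 or s2e <= 0:
            raise ValueError("fixed variances must be positive")
    else:
        s2g = 0.5 * var_y + 1e-12
        s2e = 0.5 * var_y + 1e-12

    keep = 0
    mean_gamma = np.zeros(n)
    m2_gamma = np.zeros(n)
    mean_mu = 0.0
    mean_s2g = 0.0
    mean_s2e = 0.0

    dpos = d[pos]
    for it in range(settings.chain_length):
        # gamma | rest  (independent scalars in the eigenbasis)
        prec = 1.0 / s2e + 1.0 / (dpos * s2g)
        cmean = (yt[pos] - mu * it_one[pos]) / s2e / prec
        gamma[pos] = cmean + rng.standard_normal(q) / np.sqrt(prec)
        # mu | rest  (flat prior; 1'1 = n in either basis)
        r_mu = float(it_one @ (yt - gamma)) / n
        mu = r_mu + rng.standard_normal() * np.sqrt(s2e / n)
        # variances | rest
        if fix_variances is None:
            ss_g = float(np.sum(gamma[pos] ** 2 / dpos))
            s2g = _draw_sichi2(rng, nu + q, (nu * s2_g_prior + ss_g) / (nu + q))
            resid = yt - mu * it_one - gamma
            ss_e = float(resid @ resid)
            s2e = _draw_sichi2(rng, nu + n, (nu * s2_e_prior + ss_e) / (nu + n))
        if it >= settings.burn_in and (it - settings.burn_in) % settings.thinning == 0:
            keep += 1
            delta = gamma - mean_gamma
            mean_gamma += delta / keep
            m2_gamma += delta * (gamma - mean_gamma)
            mean_mu += (mu - mean_mu) / keep
            mean_s2g += (s2g - mean_s2g) / keep
            mean_s2e += (s2e - mean_s2e) / keep

    g_mean = U @ mean_gamma
    # rotation is orthogonal, so per-coordinate variances map through U**2
    g_var = (U**2) @ (m2_gamma / max(keep - 1, 1))
    return {
        "mu": mean_mu,
        "g": g_mean,
        "g_sd": np.sqrt(np.maximum(g_var, 0.0)),
        "sigma2_g": mean_s2g,
        "sigma2_eps": mean_s2e,
        "n_kept": keep,
    }


@dataclass
class Layer1Fit:
    """Per-PC posterior means from the genotype -> PC GBLUP samplers."""

    pc_ids: list[str]
    mu: np.ndarray
    genetic_values: np.ndarray  # n_train x J
    sigma2_g: np.ndarray
    sigma2_eps: np.ndarray


@dataclass
class Layer2Fit:
    """Posterior means of the PC -> phenotype Bayesian ridge regression."""

    mu: float
    weights: np.ndarray
    sigma2_w: float
    sigma2_e: float


@dataclass
class NNGBLUPModel:
    layer1: Layer1Fit
    layer2: Layer2Fit
    settings: McmcSettings
    J: int
    train_ids: list[str]
    eig_G: GRMEigen

    def __post_init__(self) -> None:
        if self.layer1.genetic_values.shape[1] != self.J or self.layer2.weights.size != self.J:
            raise ValueError("layer dimensions inconsistent with J")


def fit_layer1(
    genotypes_train: GenotypeMatrix,
    pc_scores_train: np.ndarray,
    settings: McmcSettings,
    pc_ids: list[str] | None = None,
    eig_G: GRMEigen | None = None,
) -> Layer1Fit:
    """Independent GBLUP samplers for each PC, sharing one GRM eigendecomposition.

    Per-PC seeds derive deterministically from the master seed and PC index, so
    fitting J PCs equals J separate ``gibbs_gblup_single`` calls.
    """
    S = np.atleast_2d(np.asarray(pc_scores_train, dtype=float))
    if S.ndim != 2 or S.shape[0] != genotypes_train.n_samples:
        raise ValueError("pc_scores_train must be n_train x J")
    J = S.shape[1]
    if J < 1:
        raise ValueError("need at least one PC column")
    if eig_G is None:
        eig_G = GRMEigen.from_genotypes(genotypes_train)
    ids = pc_ids if pc_ids is not None else [f"PC{j + 1}" for j in range(J)]
    mus = np.empty(J)
    gvals = np.empty((S.shape[0], J))
    s2g = np.empty(J)
    s2e = np.empty(J)
    for j in range(J):
        out = gibbs_gblup_single(
            S[:, j], eig_G, settings, seed=derive_pc_seed(settings.seed, j)
        )
        mus[j] = out["mu"]
        gvals[:, j] = out["g"]
        s2g[j] = out["sigma2_g"]
        s2e[j] = out["sigma2_eps"]
    return Layer1Fit(list(ids), mus, gvals, s2g, s2e)


def fit_layer2(
    pc_scores_train: np.ndarray,
    y_adj_train: np.ndarray,
    settings: McmcSettings,
    seed: np.random.SeedSequence | int | None = None,
) -> Layer2Fit:
    """Gibbs sampler for  y = mu + S w + e,  w_j ~ N(0, sigma2_w) iid.

    The design is rotated into the eigenbasis of S'S, where the weight
    conditional factorizes into independent scalars (the prior is rotation
    invariant), making each sweep an exact joint draw.
    """
    S = np.atleast_2d(np.asarray(pc_scores_train, dtype=float))
    y = np.asarray(y_adj_train, dtype=float)
    n, J = S.shape
    if y.size != n:
        raise ValueError("scores and phenotype not aligned")
    if J >= settings.n_kept:
        raise ValueError(
            f"J={J} >= post-burn-in sample count {settings.n_kept}; "
            "lengthen the chain or override the prior scale"
        )
    if seed is None:
        seed = np.random.SeedSequence(entropy=settings.seed, spawn_key=(1 << 20,))
    rng = np.random.default_rng(seed)

    lam, Q = eigh(S.T @ S)
    lam = np.clip(lam, 0.0, None)
    B = S @ Q  # B'B = diag(lam)

    var_y = float(np.var(y, ddof=1))
    nu = settings.prior_df
    # prior mode of the fitted-value variance sum_j lam_j sigma2_w / n = var_y/2
    mean_lam = float(np.sum(lam)) / n
    s2_w_prior = _prior_scale(var_y / max(mean_lam, 1e-12), nu)
    s2_e_prior = _prior_scale(var_y, nu)

    mu = float(np.mean(y))
    wt = np.zeros(J)
    s2w = s2_w_prior * nu / (nu + 2.0)
    s2e = 0.5 * var_y + 1e-12

    keep = 0
    mean_wt = np.zeros(J)
    mean_mu = 0.0
    mean_s2w = 0.0
    mean_s2e = 0.0

    for it in range(settings.chain_length):
        prec = lam / s2e + 1.0 / s2w
        cmean = (B.T @ (y - mu)) / s2e / prec
        wt = cmean + rng.standard_normal(J) / np.sqrt(prec)
        fitted = B @ wt
        mu_hat = float(np.mean(y - fitted))
        mu = mu_hat + rng.standard_normal() * np.sqrt(s2e / n)
        ss_w = float(wt @ wt)
        s2w = _draw_sichi2(rng, nu + J, (nu * s2_w_prior + ss_w) / (nu + J))
        resid = y - mu - fitted
        ss_e = float(resid @ resid)
        s2e = _draw_sichi2(rng, nu + n, (nu * s2_e_prior + ss_e) / (nu + n))
        if it >= settings.burn_in and (it - settings.burn_in) % settings.thinning == 0:
            keep += 1
            mean_wt += (wt - mean_wt) / keep
            mean_mu += (mu - mean_mu) / keep
            mean_s2w += (s2w - mean_s2w) / keep
            mean_s2e += (s2e - mean_s2e) / keep

    return Layer2Fit(mean_mu, Q @ mean_wt, mean_s2w, mean_s2e)


def _scaled_genotypes(model_eig: GRMEigen, genotypes: GenotypeMatrix) -> np.ndarray:
    """Center/scale genotypes with the training-set statistics stored in the model."""
    M = genotypes.dosages[:, model_eig.snp_mask]
    return (M - model_eig.col_means[model_eig.snp_mask]) / model_eig.col_sds[
        model_eig.snp_mask
    ]


def predict_gebv(
    model: NNGBLUPModel,
    genotypes_all: GenotypeMatrix,
    route: str = "kernel",
) -> pd.DataFrame:
    """GEBV for every sample in ``genotypes_all`` by kernel or marker route.

    Both routes evaluate the same linear map X_s X_s_train' A w1 with
    A = (X_s_train X_s_train' )^+ g_hat, so they agree to solver precision.
    """
    missing = set(model.train_ids) - set(genotypes_all.sample_ids)
    if missing:
        raise KeyError(f"genotypes missing for training samples {sorted(missing)[:5]}")
    Xs_all = _scaled_genotypes(model.eig_G, genotypes_all)
    train_idx = pd.Index(genotypes_all.sample_ids).get_indexer(model.train_ids)
    Xs_train = Xs_all[train_idx]
    K = Xs_train.shape[1]
    G_tt = (Xs_train @ Xs_train.T) / K
    Ghat = model.layer1.genetic_values  # n_train x J
    ridge = 1e-6 * float(np.mean(np.diag(G_tt)))
    A = np.linalg.solve(G_tt + ridge * np.eye(G_tt.shape[0]), Ghat) / K
    if route == "marker":
        W0 = Xs_train.T @ A  # K x J back-solved marker effects
        gall = Xs_all @ W0
    elif route == "kernel":
        gall = (Xs_all @ Xs_train.T) @ A
    else:
        raise ValueError("route must be 'kernel' or 'marker'")
    gebv = gall @ model.layer2.weights
    return pd.DataFrame({"gebv": gebv}, index=genotypes_all.sample_ids)


def fit_nn_gblup(
    genotypes: GenotypeMatrix,
    pca: PCAResult,
    y_adj: AdjustedPhenotypes,
    train_ids: list[str],
    settings: McmcSettings,
    threshold: float = 0.25,
    mode: str = "train-only",
) -> tuple[NNGBLUPModel, pd.DataFrame]:
    """Orchestrate J = components_for(threshold), layer 1, layer 2 and prediction.

    ``mode='train-only'`` fits layer 1 on training samples only; ``mode=
    'transductive'`` also uses test-sample PC scores (their phenotypes are
    never touched — layer 2 always trains on training phenotypes).
    """
    if mode not in ("train-only", "transductive"):
        raise ValueError("mode must be 'train-only' or 'transductive'")
    if pca.sample_ids != y_adj.sample_ids:
        raise ValueError("PCA scores and phenotypes not aligned")
    J = pca.components_for(threshold)
    idx = pd.Index(pca.sample_ids)
    ti = idx.get_indexer(train_ids)
    if (ti < 0).any():
        raise KeyError("train ids missing from the PCA sample set")
    layer1_ids = list(pca.sample_ids) if mode == "transductive" else list(train_ids)
    l1_rows = idx.get_indexer(layer1_ids)
    geno_l1 = genotypes.subset(layer1_ids)
    eig_G = GRMEigen.from_genotypes(geno_l1)
    logger.info("NN-GBLUP: threshold %.2f -> J=%d PCs, %d layer-1 samples (%s)",
                threshold, J, len(layer1_ids), mode)
    layer1 = fit_layer1(
        geno_l1,
        pca.scores[l1_rows, :J],
        settings,
        pc_ids=[f"PC{j + 1}" for j in range(J)],
        eig_G=eig_G,
    )
    layer2 = fit_layer2(pca.scores[ti, :J], y_adj.values[ti], settings)
    model = NNGBLUPModel(layer1, layer2, settings, J, layer1_ids, eig_G)
    gebv = predict_gebv(model, genotypes)
    return model, gebv
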