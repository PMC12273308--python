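"""Synthetic genotype-microbiome-phenotype studies with host-heritable microbes.

The generator encodes the causal structure the estimators assume: a minority of
community axes (low-rank factors) are under host genetic control and load on a
large block of heritable tags; tag counts are observed through library-size and
overdispersion noise; the phenotype is the sum of fixed effects, a direct
additive genetic term, a microbiome-mediated term and residual noise.

The mediated term is drawn as a linear functional of the realized transformed,
cohort-standardized tag features with iid weights across tags — i.e. consistent
with the microbiome similarity kernel used downstream — so the microbiability
estimand equals the mediated variance fraction by construction.  Its
host-genetic share is whatever the heritable-tag design realizes (measured by
projection onto the realized genetic factor scores, capped for feasibility);
the direct genetic term is then scaled so the *total* additive genetic variance
hits the target heritability.  All variance fractions are calibrated on the
realized sample, because the count-level nonlinearity has no usable closed form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_io import AlignedDataset, GenotypeMatrix, MicrobiomeCounts, PhenoTable
from .preprocess import log_proportion_transform, standardize_within_cohort

logger = logging.getLogger("rumenpred")


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for one synthetic population."""

    n: int = 1000
    n_snps: int = 2000
    n_tags: int = 3000
    n_heritable: int | None = None  # default: half the tags
    n_factors: int = 40
    family_size: int = 10  # paternal half-sib family size; 1 = unrelated
    tag_h2: float = 0.8
    h2: float = 0.25  # target total additive genetic variance fraction
    m2: float = 0.40  # target microbiome-mediated variance fraction
    genetic_mediation_cap: float = 0.9  # of h2/m2, for variance bookkeeping
    n_years: int = 3
    n_flocks: int = 2
    cohort_sd: float = 0.5  # SD of cohort effects on tag latents
    count_scale: float = 1.0  # latent-to-log-abundance slope
    dispersion: float = 10.0  # negative-binomial size parameter
    lib_size_mean: float = 3.0e5
    lib_size_sigma: float = 0.3
    seed: int = 0
    preset_name: str = "custom"

    def __post_init__(self) -> None:
        if self.n_heritable is None:
            object.__setattr__(self, "n_heritable", self.n_tags // 2)
        if not (0 <= self.h2 <= 1 and 0 <= self.m2 <= 1):
            raise ValueError("variance fractions must lie in [0, 1]")
        if self.n_heritable > self.n_tags:
            raise ValueError("more heritable tags than tags")
        if not 0 <= self.tag_h2 <= 1:
            raise ValueError("per-tag heritability outside [0, 1]")
        # h2 counts total additive variance, part of which can flow through the
        # microbiome; the most optimistic overlap is min(cap*h2, m2)
        overlap = min(self.genetic_mediation_cap * self.h2, self.m2)
        if 1.0 - self.h2 - self.m2 + overlap < 0.03:
            raise ValueError("infeasible targets: no residual variance left")

    @property
    def n_cohorts(self) -> int:
        return self.n_years * self.n_flocks


_PRESETS: dict[str, dict] = {
    # heritability / microbiability anchors for the emulated trait classes
    "methane": {"h2": 0.18, "m2": 0.47},
    "rfi": {"h2": 0.33, "m2": 0.70},
    # CO2: essentially non-mediated and weakly heritable, so that neither a
    # genomic nor a microbiome-aware predictor attains appreciable accuracy
    "co2": {"h2": 0.05, "m2": 0.0},
    "custom": {},
}


def preset(name: str, **overrides) -> SimConfig:
    """Named study presets; ``custom`` requires explicit h2 and m2."""
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; available: {sorted(_PRESETS)}")
    params = dict(_PRESETS[name])
    if name == "custom" and not {"h2", "m2"} <= set(overrides):
        raise ValueError("preset 'custom' requires explicit h2= and m2= fractions")
    params.update(overrides)
    return SimConfig(preset_name=name, **params)


@dataclass
class SimTruth:
    """Ground truth for recovery tests."""

    sample_ids: list[str]
    breeding_values: np.ndarray  # direct + mediated-genetic, per sample
    direct_genetic: np.ndarray
    mediated: np.ndarray
    mediated_genetic: np.ndarray
    tag_effects: np.ndarray  # weights of the mediated functional on the tag features
    factor_scores: np.ndarray | None = None  # realized genetic community axes (n x R)
    realized: dict[str, float] = field(default_factory=dict)


def _unit(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise ValueError("degenerate direction in calibration")
    return (v - v.mean()) / sd


def simulate_population(config: SimConfig) -> tuple[AlignedDataset, SimTruth]:
    """Generate one aligned study; fixed seed gives bit-identical output."""
    rng = np.random.default_rng(config.seed)
    n, K, p = config.n, config.n_snps, config.n_tags
    q_h, R = config.n_heritable, config.n_factors

    sample_ids = [f"S{i + 1:05d}" for i in range(n)]
    snp_ids = [f"SNP{k + 1:05d}" for k in range(K)]
    tag_ids = [f"TAG{j + 1:06d}" for j in range(p)]

    # --- design structure: flocks, years, cohorts, fixed-effect classes ---
    years = 2014 + (np.arange(n) * config.n_years) // n
    flocks = rng.integers(0, config.n_flocks, n)
    years = rng.permuted(years)
    cohort_labels = np.array(
        [f"Y{y}-F{f + 1}" for y, f in zip(years, flocks)], dtype=object
    )
    cohort_index = pd.factorize(cohort_labels, sort=True)[0]

    # --- genotypes: paternal half-sib families nested within birth year ---
    # (each sire serves one lamb crop, so animals from different years are
    # unrelated and a year-based train-test split carries no family links)
    freqs = rng.uniform(0.05, 0.95, K)
    if config.family_size > 1:
        fam = np.empty(n, dtype=int)
        next_fam = 0
        for y in np.unique(years):
            members = np.flatnonzero(years == y)
            labels = np.arange(members.size) // config.family_size
            fam[members] = next_fam + labels
            next_fam += labels[-1] + 1
        sires = rng.binomial(2, freqs, size=(next_fam, K))
        paternal = rng.binomial(1, sires[fam] / 2.0)
        maternal = rng.binomial(1, freqs, size=(n, K))
        X = (paternal + maternal).astype(float)
    else:
        X = rng.binomial(2, freqs, size=(n, K)).astype(float)
    Xc = X - X.mean(axis=0)

    # genetic community factors: low-rank host control over the microbiome
    B = rng.standard_normal((K, R)) / np.sqrt(K)
    T = Xc @ B
    T = (T - T.mean(axis=0)) / T.std(axis=0)

    # --- latent tag features ---
    Lam = rng.standard_normal((R, q_h))
    gen = T @ Lam
    gen /= gen.std(axis=0)
    latent = rng.standard_normal((n, p))
    latent[:, :q_h] = (
        np.sqrt(config.tag_h2) * gen + np.sqrt(1.0 - config.tag_h2) * latent[:, :q_h]
    )
    cohort_eff = rng.normal(0.0, config.cohort_sd, size=(config.n_cohorts, p))
    latent += cohort_eff[cohort_index]

    # --- counts: compositional with library-size and overdispersion noise ---
    base = rng.normal(0.0, 1.0, p)
    eta = base + config.count_scale * latent
    eta -= eta.max(axis=1, keepdims=True)
    w = np.exp(eta)
    pi = w / w.sum(axis=1, keepdims=True)
    lib = rng.lognormal(np.log(config.lib_size_mean), config.lib_size_sigma, n)
    mean = lib[:, None] * pi
    lam_nb = rng.gamma(config.dispersion, mean / config.dispersion)
    counts_arr = rng.poisson(lam_nb)
    counts = MicrobiomeCounts(sample_ids, tag_ids, counts_arr)

    # --- the realized feature scale the estimators see ---
    feats = standardize_within_cohort(
        log_proportion_transform(counts), pd.Series(cohort_labels, index=sample_ids)
    )
    Z = feats.values

    # --- mediated component: kernel-consistent functional of the features ---
    # A single iid weight draw over all tags makes the mediated effect a
    # typical draw under the microbiome similarity kernel, so Eq.-2-style REML
    # recovers the mediated variance fraction without spectral bias.  Its
    # host-genetic part is the projection onto the realized factor scores
    # (exactly X-linear); with many community axes the genetic share is
    # chi^2_R-concentrated around the tag design's mean, and is only shrunk
    # when it would overrun the heritability budget.
    if config.m2 > 0:
        b = rng.standard_normal(p)
        m_raw = (Z @ b) / np.sqrt(p)
        Qt, _ = np.linalg.qr(np.column_stack([np.ones(n), T]))
        m_gen = Qt @ (Qt.T @ m_raw)
        m_env = m_raw - m_gen
        # the raw projection share over-counts by the chance capture of the
        # environmental content in an (R+1)-dimensional subspace; debiting it
        # keeps the direct-genetic budget honest
        rho_proj = float(np.var(m_gen) / np.var(m_raw))
        chance = (R + 1) / n
        rho = max((rho_proj - chance) / (1.0 - chance), 0.0)
        cap = config.genetic_mediation_cap * config.h2 / config.m2
        if rho > cap:
            shrink = np.sqrt(cap / rho * (1.0 - rho) / (1.0 - cap))
            m_gen = m_gen * shrink
            m_raw = m_gen + m_env
            rho_proj = float(np.var(m_gen) / np.var(m_raw))
            rho = max((rho_proj - chance) / (1.0 - chance), 0.0)
        scale = np.sqrt(config.m2 / np.var(m_raw))
        mediated = (m_raw - m_raw.mean()) * scale
        mediated_gen = (m_gen - m_gen.mean()) * scale
        tag_effects = b / np.sqrt(p) * scale
        rho_real = rho
    else:
        mediated = np.zeros(n)
        mediated_gen = np.zeros(n)
        tag_effects = np.zeros(p)
        rho_real = 0.0

    direct_var = config.h2 - rho_real * config.m2
    resid_var = 1.0 - config.h2 - (1.0 - rho_real) * config.m2
    if direct_var < 0 or resid_var <= 0.01:
        raise ValueError(
            f"infeasible realized variance split: direct={direct_var:.3f}, "
            f"residual={resid_var:.3f}"
        )

    # u and e are independent draws scaled to their exact variance shares;
    # they are deliberately NOT orthogonalized against the factor scores —
    # forcing exact in-sample orthogonality would make train- and test-block
    # covariances cancel and anti-correlate chance effects across splits
    gamma = rng.standard_normal(K) / np.sqrt(K)
    u = _unit(Xc @ gamma) * np.sqrt(direct_var)
    e = _unit(rng.standard_normal(n)) * np.sqrt(resid_var)

    # --- fixed effects and phenotype ---
    cg_effects = rng.normal(0.0, 0.5, config.n_cohorts)
    brr = rng.integers(1, 4, n)  # birth/rearing rank class
    brr_effects = rng.normal(0.0, 0.2, 3)
    dam_age = rng.integers(1, 4, n)  # 1, 2, 3+
    dam_effects = rng.normal(0.0, 0.15, 3)
    bday_dev = rng.normal(0.0, 10.0, n)  # days from flock-year mean birthdate
    bday_slope = 0.02

    y = (
        cg_effects[cohort_index]
        + brr_effects[brr - 1]
        + dam_effects[dam_age - 1]
        + bday_slope * bday_dev
        + u
        + mediated
        + e
    )

    trait = config.preset_name if config.preset_name != "custom" else "trait"
    pheno = PhenoTable(
        pd.DataFrame(
            {
                trait: y,
                "birth_rearing_rank": brr,
                "dam_age": dam_age,
                "contemporary_group": cohort_labels,
                "birthday_dev": bday_dev,
                "cohort": cohort_labels,
                "year": years,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        ),
        traits=[trait],
        class_cols=["birth_rearing_rank", "dam_age", "contemporary_group"],
        covariate_cols=["birthday_dev"],
        cohort_col="cohort",
        year_col="year",
    )

    dataset = AlignedDataset(
        GenotypeMatrix(sample_ids, snp_ids, X), counts, pheno
    )
    realized = {
        "h2": direct_var + rho_real * config.m2,
        "m2": float(np.var(mediated)),
        "direct": float(np.var(u)),
        "mediated_genetic": rho_real * config.m2,
        "genetic_mediation_share": rho_real,
        "residual": float(np.var(e)),
    }
    logger.info("simulated %s preset: realized fractions %s", config.preset_name,
                {k: round(v, 3) for k, v in realized.items()})
    truth = SimTruth(
        sample_ids=sample_ids,
        breeding_values=u + mediated_gen,
        direct_genetic=u,
        mediated=mediated,
        mediated_genetic=mediated_gen,
        tag_effects=tag_effects,
        factor_scores=T,
        realized=realized,
    )
    return dataset, truth


def simulate_replicates(
    config: SimConfig, seeds: list[int]
) -> list[tuple[AlignedDataset, SimTruth]]:
    """Replicate datasets differing only in seed."""
    return [simulate_population(replace(config, seed=s)) for s in seeds]
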