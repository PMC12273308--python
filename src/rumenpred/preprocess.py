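"""Phenotype adjustment, microbiome count transforms and PCA reduction.

Phenotypes are pre-adjusted once for fixed effects by ordinary least squares
(birth/rearing rank, dam-age class, contemporary group, birthday deviation);
all downstream mixed models then carry an intercept only.  Microbiome tag
counts are made comparable across animals either by a pseudo-count
log10-proportion transform or by the centered log-ratio (CLR), followed by
column standardization within rumen cohorts, and reduced by PCA with scores
kept at a set of cumulative-variance thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import MicrobiomeCounts, PhenoTable

logger = logging.getLogger("rumenpred")


@dataclass
class AdjustedPhenotypes:
    """OLS residuals y - X beta_hat for one trait, in trait units."""

    sample_ids: list[str]
    trait: str
    values: np.ndarray
    beta: pd.Series | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids),):
            raise ValueError("residual vector length mismatch")


@dataclass
class FeatureMatrix:
    """Transformed / standardized microbiome features (tags or PC scores)."""

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    provenance: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError("feature matrix shape inconsistent with id lists")
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains non-finite values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)


@dataclass
class PCAResult:
    """Thin-SVD PCA of a column-centered feature matrix.

    ``scores[:, r] = U[:, r] * s_r`` so ``scores @ loadings.T`` reconstructs the
    centered input; ``threshold_map[t]`` is the smallest J whose cumulative
    variance fraction reaches t.
    """

    sample_ids: list[str]
    feature_ids: list[str]
    scores: np.ndarray
    loadings: np.ndarray
    variance_fractions: np.ndarray
    threshold_map: dict[float, int] = field(default_factory=dict)
    column_means: np.ndarray | None = None

    @property
    def cumulative_fractions(self) -> np.ndarray:
        return np.cumsum(self.variance_fractions)

    @property
    def rank(self) -> int:
        return self.scores.shape[1]

    def components_for(self, threshold: float) -> int:
        if threshold in self.threshold_map:
            return self.threshold_map[threshold]
        cum = self.cumulative_fractions
        return int(np.searchsorted(cum, threshold - 1e-12) + 1)

    def score_features(self, J: int | None = None) -> FeatureMatrix:
        J = self.rank if J is None else J
        ids = [f"PC{r + 1}" for r in range(J)]
        return FeatureMatrix(self.sample_ids, ids, self.scores[:, :J], "pc-scores")


@dataclass
class FixedEffectSpec:
    """Names of class (factor) and covariate columns entering Eq.-1-style adjustment."""

    class_cols: list[str] = field(default_factory=list)
    covariate_cols: list[str] = field(default_factory=list)


def _design_matrix(table: pd.DataFrame, spec: FixedEffectSpec) -> tuple[np.ndarray, list[str]]:
    cols: list[np.ndarray] = [np.ones(len(table))]
    names: list[str] = ["intercept"]
    for c in spec.class_cols:
        dummies = pd.get_dummies(table[c].astype("category"), prefix=c, drop_first=True)
        for name in dummies.columns:
            cols.append(dummies[name].to_numpy(float))
            names.append(str(name))
    for c in spec.covariate_cols:
        vals = pd.to_numeric(table[c], errors="raise").to_numpy(float)
        cols.append(vals)
        names.append(c)
    return np.column_stack(cols), names


def adjust_phenotypes(
    pheno: PhenoTable, trait: str, fixed_spec: FixedEffectSpec
) -> AdjustedPhenotypes:
    """OLS residuals of ``trait`` on the fixed-effect design (with intercept)."""
    if trait not in pheno.table.columns:
        raise ValueError(f"unknown trait {trait!r}")
    y = pd.to_numeric(pheno.table[trait], errors="raise").to_numpy(float)
    if np.isnan(y).all():
        raise ValueError(f"trait {trait!r} entirely missing")
    if np.isnan(y).any():
        raise ValueError(f"trait {trait!r} has missing values")
    X, names = _design_matrix(pheno.table, fixed_spec)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns involved in the collinearity via pivoted QR
        from scipy.linalg import qr

        _, _, piv = qr(X, mode="economic", pivoting=True)
        dropped = [names[i] for i in piv[rank:]]
        raise ValueError(f"rank-deficient fixed-effect design; collinear columns: {dropped}")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    logger.info("adjusted trait %s for %d fixed-effect columns", trait, X.shape[1])
    return AdjustedPhenotypes(
        pheno.sample_ids, trait, resid, pd.Series(beta, index=names, name=trait)
    )


def log_proportion_transform(counts: MicrobiomeCounts) -> FeatureMatrix:
    """Pseudo-count log10 proportion: log10((c+1) / (row total + n columns)).

    The denominator is the row total after the +1 increment, so each row of
    10**t is a proper probability vector.
    """
    c = counts.counts.astype(float)
    p = c.shape[1]
    denom = c.sum(axis=1, keepdims=True) + p
    vals = np.log10((c + 1.0) / denom)
    return FeatureMatrix(counts.sample_ids, counts.tag_ids, vals, "log-proportion")


def clr_transform(counts: MicrobiomeCounts) -> FeatureMatrix:
    """Centered log-ratio with a +1 pseudo count: ln(c+1) minus the row mean ln(c+1)."""
    logc = np.log(counts.counts.astype(float) + 1.0)
    vals = logc - logc.mean(axis=1, keepdims=True)
    return FeatureMatrix(counts.sample_ids, counts.tag_ids, vals, "clr")


def standardize_within_cohort(
    features: FeatureMatrix, cohorts: pd.Series | dict | list | np.ndarray
) -> FeatureMatrix:
    """Scale each column to mean 0, sample variance 1 within each cohort.

    Columns constant within a cohort are set to 0 there (a warning counts them).
    """
    if isinstance(cohorts, pd.Series):
        labels = cohorts.reindex(features.sample_ids)
        if labels.isna().any():
            raise ValueError("cohort labels missing for some samples")
        labels = labels.to_numpy()
    elif isinstance(cohorts, dict):
        labels = np.array([cohorts[s] for s in features.sample_ids])
    else:
        labels = np.asarray(cohorts)
        if labels.shape[0] != len(features.sample_ids):
            raise ValueError("cohort vector length mismatch")

    out = np.empty_like(features.values)
    n_constant = 0
    for lab in pd.unique(labels):
        mask = labels == lab
        if mask.sum() < 2:
            raise ValueError(f"cohort {lab!r} has fewer than 2 samples; cannot scale")
        block = features.values[mask]
        mu = block.mean(axis=0)
        sd = block.std(axis=0, ddof=1)
        const = sd == 0
        n_constant += int(const.sum())
        sd_safe = np.where(const, 1.0, sd)
        z = (block - mu) / sd_safe
        z[:, const] = 0.0
        out[mask] = z
    if n_constant:
        logger.warning("%d column/cohort blocks were constant; set to 0", n_constant)
    return FeatureMatrix(features.sample_ids, features.feature_ids, out, "standardized")


def pca_reduce(
    features: FeatureMatrix, thresholds: tuple[float, ...] = (0.25, 0.5, 0.75, 0.95, 1.0)
) -> PCAResult:
    """Thin SVD of the column-centered matrix with a deterministic sign convention.

    Columns are centered but not re-scaled (the input is already standardized).
    The sign of each component is fixed so its largest-magnitude loading element
    is positive, making runs reproducible across platforms.
    """
    if features.values.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    for t in thresholds:
        if not 0.0 < t <= 1.0:
            raise ValueError(f"threshold {t} outside (0, 1]")
    X = features.values
    mu = X.mean(axis=0)
    Xc = X - mu
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # drop numerically-zero directions (centering removes at least one)
    keep = s > s[0] * 1e-12 if s.size and s[0] > 0 else s > 0
    U, s, Vt = U[:, keep], s[keep], Vt[keep]
    # sign convention: largest-|loading| element positive per component
    for r in range(s.size):
        j = np.argmax(np.abs(Vt[r]))
        if Vt[r, j] < 0:
            Vt[r] *= -1.0
            U[:, r] *= -1.0
    var = s**2
    fractions = var / var.sum()
    cum = np.cumsum(fractions)
    tmap = {float(t): int(np.searchsorted(cum, t - 1e-12) + 1) for t in thresholds}
    logger.info(
        "PCA: %d samples, %d features, rank %d; threshold map %s",
        X.shape[0],
        X.shape[1],
        s.size,
        tmap,
    )
    return PCAResult(
        sample_ids=list(features.sample_ids),
        feature_ids=list(features.feature_ids),
        scores=U * s,
        loadings=Vt.T,
        variance_fractions=fractions,
        threshold_map=tmap,
        column_means=mu,
    )
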