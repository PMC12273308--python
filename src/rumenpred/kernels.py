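"""Genomic relationship matrices and microbiome similarity kernels.

Two GRM conventions are kept side by side: VanRaden method 1 (used by the
single- and two-kernel REML models) and the centered-and-scaled ``XX'/K`` form
(used inside the NN-GBLUP layer-1 sampler).  On common SNP panels they are
nearly identical; both are exposed because each model is defined with its own
convention.  The microbiome kernel is the row-cosine of column-standardized
features, which equals Pearson correlation when row means are zero and makes
the full-rank PC-score kernel coincide exactly with the full-tag kernel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data_io import GenotypeMatrix
from .preprocess import FeatureMatrix, PCAResult

logger = logging.getLogger("rumenpred")


@dataclass
class Kernel:
    """Symmetric PSD similarity matrix over samples."""

    sample_ids: list[str]
    values: np.ndarray
    label: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("kernel must be square over the sample ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kernel not symmetric")
        self.values = 0.5 * (self.values + self.values.T)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset(self, rows: list[str], cols: list[str] | None = None) -> np.ndarray:
        import pandas as pd

        idx = pd.Index(self.sample_ids)
        ri = idx.get_indexer(rows)
        ci = ri if cols is None else idx.get_indexer(cols)
        if (ri < 0).any() or (ci < 0).any():
            raise KeyError("unknown sample ids in kernel subset")
        return self.values[np.ix_(ri, ci)]


def grm_vanraden(genotypes: GenotypeMatrix) -> Kernel:
    """VanRaden method-1 GRM: G = ZZ' / (2 sum p(1-p)), Z = dosages - 2p.

    Allele frequencies come from the provided samples; monomorphic SNPs are
    dropped (their term in the denominator would be zero).
    """
    M = genotypes.dosages
    p = M.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    n_dropped = int((~poly).sum())
    if n_dropped:
        logger.info("grm_vanraden: dropping %d monomorphic SNPs", n_dropped)
    if not poly.any():
        raise ValueError("all SNPs monomorphic; cannot build GRM")
    Z = M[:, poly] - 2.0 * p[poly]
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    G = (Z @ Z.T) / denom
    return Kernel(list(genotypes.sample_ids), G, "G-vanraden")


def grm_scaled(genotypes: GenotypeMatrix) -> Kernel:
    """Centered-and-scaled GRM: G = XX'/K with unit-variance genotype columns."""
    G, _, _, _ = _scaled_grm_parts(genotypes)
    return Kernel(list(genotypes.sample_ids), G, "G-scaled")


def _scaled_grm_parts(
    genotypes: GenotypeMatrix,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(G, column means, column sds, retained-SNP mask) for the scaled GRM."""
    M = genotypes.dosages
    mu = M.mean(axis=0)
    sd = M.std(axis=0, ddof=1)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("grm_scaled: dropping %d zero-variance SNP columns", n_dropped)
    if not keep.any():
        raise ValueError("all SNP columns have zero variance")
    X = (M[:, keep] - mu[keep]) / sd[keep]
    K = int(keep.sum())
    return (X @ X.T) / K, mu, sd, keep


def microbiome_similarity(features: FeatureMatrix) -> Kernel:
    """Row-cosine similarity of standardized features; diagonal exactly 1."""
    if features.provenance not in ("standardized", "pc-scores"):
        raise ValueError(
            "microbiome_similarity expects standardized features or PC scores, "
            f"got provenance {features.provenance!r}"
        )
    X = features.values
    norms = np.linalg.norm(X, axis=1)
    if (norms == 0).any():
        bad = [features.sample_ids[i] for i in np.flatnonzero(norms == 0)]
        raise ValueError(f"zero-norm feature rows for samples {bad[:5]}")
    M = (X / norms[:, None]) @ (X / norms[:, None]).T
    np.fill_diagonal(M, 1.0)
    return Kernel(list(features.sample_ids), M, "M-tags")


def pc_kernel(pca: PCAResult, J: int) -> Kernel:
    """Correlation-form kernel from the first J PC scores: D^-1/2 (S_J S_J') D^-1/2."""
    if not 1 <= J <= pca.rank:
        raise ValueError(f"J={J} outside [1, {pca.rank}]")
    S = pca.scores[:, :J]
    K = S @ S.T
    d = np.sqrt(np.diag(K))
    if (d == 0).any():
        bad = [pca.sample_ids[i] for i in np.flatnonzero(d == 0)]
        raise ValueError(f"zero-norm score rows for samples {bad[:5]}")
    K = K / np.outer(d, d)
    np.fill_diagonal(K, 1.0)
    return Kernel(list(pca.sample_ids), K, f"M-pc({J})")
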