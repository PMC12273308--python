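"""Validation schemes (year-based train-test, cohort-based k-fold) and metrics.

Accuracy is the Pearson correlation between adjusted phenotypes and GEBVs in
the test set, with SE (1 - r^2)/sqrt(n).  Dispersion bias is the slope of the
regression of adjusted phenotypes on GEBVs (1 = correctly dispersed); its SE is
reported either from that same regression (default) or, behind a flag, from
the reversed regression of GEBVs on adjusted phenotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import PhenoTable

logger = logging.getLogger("rumenpred")


@dataclass
class Split:
    train_ids: list[str]
    test_ids: list[str]
    scheme: str

    def __post_init__(self) -> None:
        if not self.train_ids or not self.test_ids:
            raise ValueError("both sides of a split must be non-empty")
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test sets overlap")


@dataclass
class EvaluationResult:
    accuracy: float
    accuracy_se: float
    bias: float
    bias_se: float
    n_test: int
    scheme: str
    model: str = ""
    threshold: float | None = None

    def __post_init__(self) -> None:
        if not -1.0 <= self.accuracy <= 1.0:
            raise ValueError("accuracy outside [-1, 1]")

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "scheme": self.scheme,
            "threshold": self.threshold,
            "accuracy": self.accuracy,
            "accuracy_se": self.accuracy_se,
            "bias": self.bias,
            "bias_se": self.bias_se,
            "n_test": self.n_test,
        }


def split_by_group(
    pheno: PhenoTable,
    group_col: str,
    train_values: list,
    test_values: list,
) -> Split:
    """Deterministic membership split, e.g. train on years {2014, 2015}, test 2016."""
    if group_col not in pheno.table.columns:
        raise ValueError(f"group column {group_col!r} not in phenotype table")
    if set(train_values) & set(test_values):
        raise ValueError("train and test value sets overlap")
    g = pheno.table[group_col]
    n_missing = int(g.isna().sum())
    if n_missing:
        logger.warning("split_by_group: %d samples with missing %s excluded",
                       n_missing, group_col)
    train = list(pheno.table.index[g.isin(train_values)])
    test = list(pheno.table.index[g.isin(test_values)])
    logger.info("split_by_group: %d train / %d test", len(train), len(test))
    return Split(train, test, "train-test")


def cohort_kfold(
    pheno: PhenoTable,
    cohort_col: str | None = None,
    k: int = 5,
    seed: int = 0,
) -> list[Split]:
    """Within each cohort, deal a seeded shuffle round-robin into k sub-groups.

    Fold i's test set is the union of sub-group i across cohorts, so sub-group
    sizes within a cohort differ by at most one and every sample is tested
    exactly once.  Cohorts smaller than k simply contribute to fewer folds.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    cohort_col = cohort_col or pheno.cohort_col
    if cohort_col not in pheno.table.columns:
        raise ValueError(f"cohort column {cohort_col!r} not in phenotype table")
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    for _, block in pheno.table.groupby(cohort_col, sort=True):
        ids = list(block.index)
        perm = rng.permutation(len(ids))
        for pos, idx in enumerate(perm):
            assignment[ids[idx]] = pos % k
    all_ids = list(pheno.table.index)
    splits = []
    for fold in range(k):
        test = [s for s in all_ids if assignment[s] == fold]
        train = [s for s in all_ids if assignment[s] != fold]
        splits.append(Split(train, test, f"kfold:{fold + 1}"))
    return splits


def _validate_pair(y: np.ndarray, gebv: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, float)
    gebv = np.asarray(gebv, float)
    if y.shape != gebv.shape or y.ndim != 1:
        raise ValueError("adjusted phenotypes and GEBVs must be aligned vectors")
    if y.size < 3:
        raise ValueError("need at least 3 test samples")
    return y, gebv


def accuracy(y_adj_test: np.ndarray, gebv_test: np.ndarray) -> tuple[float, float]:
    """(Pearson r, SE) with SE = (1 - r^2)/sqrt(n)."""
    y, g = _validate_pair(y_adj_test, gebv_test)
    if np.std(y) == 0 or np.std(g) == 0:
        raise ValueError("constant vector; accuracy undefined")
    r = float(np.corrcoef(y, g)[0, 1])
    se = (1.0 - r**2) / np.sqrt(y.size)
    return r, float(se)


def _slope_and_se(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope of y on x and its standard error."""
    n = x.size
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    b = float(xc @ yc) / sxx
    resid = yc - b * xc
    s2 = float(resid @ resid) / (n - 2)
    return b, float(np.sqrt(s2 / sxx))


def dispersion_bias(
    y_adj_test: np.ndarray, gebv_test: np.ndarray, paper_bias_se: bool = False
) -> tuple[float, float]:
    """Slope of adjusted phenotypes on GEBVs, with SE from that regression.

    ``paper_bias_se=True`` instead reports the slope SE of the reversed
    regression (GEBVs on adjusted phenotypes), the published procedure.
    """
    y, g = _validate_pair(y_adj_test, gebv_test)
    if np.std(g) == 0:
        raise ValueError("zero-variance GEBV; dispersion bias undefined")
    b, se = _slope_and_se(g, y)
    if paper_bias_se:
        if np.std(y) == 0:
            raise ValueError("zero-variance phenotype; reversed-regression SE undefined")
        _, se = _slope_and_se(y, g)
    return b, se


def evaluate_split(
    y_adj_test: np.ndarray,
    gebv_test: np.ndarray,
    scheme: str,
    model: str = "",
    threshold: float | None = None,
    paper_bias_se: bool = False,
) -> EvaluationResult:
    r, r_se = accuracy(y_adj_test, gebv_test)
    b, b_se = dispersion_bias(y_adj_test, gebv_test, paper_bias_se=paper_bias_se)
    return EvaluationResult(r, r_se, b, b_se, len(y_adj_test), scheme, model, threshold)


def summarize_cv(results: list[EvaluationResult]) -> EvaluationResult:
    """Pool folds: mean of r and b, SE = across-fold standard deviation (n-1)."""
    if len(results) < 2:
        raise ValueError("need at least 2 folds to summarize")
    base = results[0].scheme.split(":")[0]
    if any(r.scheme.split(":")[0] != base for r in results):
        raise ValueError("cannot pool results from mixed schemes")
    rs = np.array([r.accuracy for r in results])
    bs = np.array([r.bias for r in results])
    return EvaluationResult(
        accuracy=float(rs.mean()),
        accuracy_se=float(rs.std(ddof=1)),
        bias=float(bs.mean()),
        bias_se=float(bs.std(ddof=1)),
        n_test=int(sum(r.n_test for r in results)),
        scheme=f"{base}:pooled",
        model=results[0].model,
        threshold=results[0].threshold,
    )


def results_table(results: list[EvaluationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])
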