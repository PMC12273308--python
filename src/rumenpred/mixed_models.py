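"""REML variance components and BLUP prediction for kernel mixed models.

Models are of the form  y_adj = 1 mu + sum_r Z_r a_r + e  with a_r ~ N(0, K_r
sigma2_r), the phenotype having been pre-adjusted for fixed effects so the
intercept is the only fixed term.  Microbiability is sigma2_m / (sigma2_m +
sigma2_e) from the microbiome-kernel model; heritability is sigma2_u over the
total variance of the fitted model.

The single-kernel fit is exact: the restricted likelihood is profiled over the
variance ratio in the kernel eigenbasis and maximized by scalar optimization.
The two-kernel fit uses average-information updates with step-halving and an
expectation-maximization fallback.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, eigh
from scipy.optimize import minimize_scalar

from .kernels import Kernel
from .preprocess import AdjustedPhenotypes

logger = logging.getLogger("rumenpred")

_RIDGE = 1e-6  # times mean kernel diagonal, added before inversions


@dataclass
class VarianceComponents:
    """Per-kernel variances plus the residual, in squared trait units."""

    components: dict[str, float]
    residual: float

    def __post_init__(self) -> None:
        for label, v in self.components.items():
            if v < 0:
                raise ValueError(f"negative variance for {label}")
        if self.residual <= 0:
            raise ValueError("residual variance must be positive")

    @property
    def total(self) -> float:
        return sum(self.components.values()) + self.residual

    def by_prefix(self, prefix: str) -> float | None:
        for label, v in self.components.items():
            if label.startswith(prefix):
                return v
        return None


@dataclass
class REMLFit:
    varcomps: VarianceComponents
    loglik: float
    n_iter: int
    converged: bool
    mu: float
    kernel_labels: list[str] = field(default_factory=list)


@dataclass
class BLUPPrediction:
    sample_ids: list[str]
    effects: dict[str, np.ndarray]

    @property
    def gebv(self) -> np.ndarray:
        for label, v in self.effects.items():
            if label.startswith("G"):
                return v
        raise ValueError("no genetic term in prediction")


def _check_alignment(y_adj: AdjustedPhenotypes, kernels: list[Kernel]) -> None:
    for k in kernels:
        if k.sample_ids != y_adj.sample_ids:
            raise ValueError(f"kernel {k.label} not aligned to phenotype samples")


def _check_psd(kernel: Kernel) -> None:
    w = np.linalg.eigvalsh(kernel.values)
    scale = max(abs(w[-1]), 1.0)
    if w[0] < -1e-8 * scale:
        raise ValueError(f"kernel {kernel.label} is not PSD (min eigenvalue {w[0]:.3g})")


def _reml_loglik_direct(y: np.ndarray, V: np.ndarray) -> float:
    """Restricted log-likelihood (up to a constant) with intercept-only X."""
    n = len(y)
    c, low = cho_factor(V, lower=True)
    logdetV = 2.0 * np.sum(np.log(np.diag(c)))
    Vi_y = cho_solve((c, low), y)
    ones = np.ones(n)
    Vi_1 = cho_solve((c, low), ones)
    xvx = ones @ Vi_1
    mu = (ones @ Vi_y) / xvx
    r = y - mu
    Vi_r = cho_solve((c, low), r)
    return -0.5 * (logdetV + np.log(xvx) + r @ Vi_r)


def _fit_single_kernel(y: np.ndarray, kernel: Kernel) -> REMLFit:
    n = len(y)
    d, U = eigh(kernel.values)
    d = np.clip(d, 0.0, None)
    yt = U.T @ y
    xt = U.T @ np.ones(n)

    def profile(lam: float) -> tuple[float, float, float]:
        w = 1.0 / (1.0 + lam * d)
        xwx = np.sum(w * xt * xt)
        beta = np.sum(w * xt * yt) / xwx
        r = yt - xt * beta
        q = np.sum(w * r * r)
        s2e = q / (n - 1)
        ll = -0.5 * (
            (n - 1) * (np.log(s2e) + 1.0)
            + np.sum(np.log1p(lam * d))
            + np.log(xwx)
        )
        return ll, s2e, beta

    def neg(log_lam: float) -> float:
        return -profile(np.exp(log_lam))[0]

    # coarse grid then local refinement over log variance ratio
    grid = np.linspace(-12.0, 12.0, 49)
    vals = [neg(g) for g in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(neg, bounds=(lo, hi), method="bounded", options={"xatol": 1e-12})
    lam = float(np.exp(res.x))
    ll0, s2e0, _ = profile(0.0)  # boundary: no kernel variance
    ll, s2e, beta = profile(lam)
    if ll0 >= ll:
        lam, ll, s2e, beta = 0.0, ll0, s2e0, profile(0.0)[2]
    s2k = lam * s2e
    floor = 1e-8 * np.var(y)
    if s2k < floor:
        s2k = 0.0
    vc = VarianceComponents({kernel.label: s2k}, s2e)
    return REMLFit(vc, float(ll), n_iter=1, converged=True, mu=float(beta),
                   kernel_labels=[kernel.label])


def _fit_two_kernels(
    y: np.ndarray, kernels: list[Kernel], max_iter: int = 200, tol: float = 1e-6
) -> REMLFit:
    n = len(y)
    Ks = [k.values for k in kernels] + [np.eye(n)]
    vary = float(np.var(y, ddof=1))
    floor = 1e-8 * vary
    theta = np.array([vary / 3.0] * 3)
    ones = np.ones(n)

    def pieces(th: np.ndarray):
        V = th[0] * Ks[0] + th[1] * Ks[1] + th[2] * Ks[2]
        c, low = cho_factor(V, lower=True)
        Vi = cho_solve((c, low), np.eye(n))
        Vi_1 = Vi @ ones
        xvx = ones @ Vi_1
        P = Vi - np.outer(Vi_1, Vi_1) / xvx
        logdetV = 2.0 * np.sum(np.log(np.diag(c)))
        Py = P @ y
        ll = -0.5 * (logdetV + np.log(xvx) + y @ Py)
        mu = (Vi_1 @ y) / xvx
        return P, Py, ll, mu

    P, Py, ll, mu = pieces(theta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        KPy = [K @ Py for K in Ks]
        score = np.array(
            [-0.5 * (np.trace(P @ K) - Py @ Kp) for K, Kp in zip(Ks, KPy)]
        )
        PKPy = [P @ Kp for Kp in KPy]
        AI = 0.5 * np.array([[KPy[i] @ PKPy[j] for j in range(3)] for i in range(3)])
        try:
            delta = np.linalg.solve(AI, score)
        except np.linalg.LinAlgError:
            delta = None
        stepped = False
        if delta is not None and np.all(np.isfinite(delta)):
            step = 1.0
            for _ in range(12):  # step-halving; clamp to the parameter space
                cand = np.maximum(theta + step * delta, floor)
                try:
                    P2, Py2, ll2, mu2 = pieces(cand)
                except np.linalg.LinAlgError:
                    step *= 0.5
                    continue
                if ll2 >= ll - 1e-10:
                    stepped = True
                    break
                step *= 0.5
        if not stepped:
            # EM update: sigma_i' = sigma_i + sigma_i^2 (y'PK_iPy - tr(PK_i)) / n
            cand = np.maximum(
                theta
                + theta**2 * np.array(
                    [(Py @ Kp) - np.trace(P @ K) for K, Kp in zip(Ks, KPy)]
                )
                / n,
                floor,
            )
            P2, Py2, ll2, mu2 = pieces(cand)
        dll = abs(ll2 - ll)
        dpar = np.max(np.abs(cand - theta) / max(vary, 1e-12))
        theta, P, Py, ll, mu = cand, P2, Py2, ll2, mu2
        if dll < tol and dpar < tol:
            converged = True
            break
    if not converged:
        logger.warning("two-kernel REML did not converge in %d iterations", max_iter)
    comps = {kernels[0].label: float(max(theta[0] - 0, 0)),
             kernels[1].label: float(max(theta[1], 0))}
    comps = {k: (0.0 if v <= floor * 1.01 else v) for k, v in comps.items()}
    vc = VarianceComponents(comps, float(theta[2]))
    return REMLFit(vc, float(ll), it, converged, float(mu),
                   kernel_labels=[k.label for k in kernels])


def reml_fit(
    y_adj: AdjustedPhenotypes,
    kernels: list[Kernel],
    max_iter: int = 200,
    tol: float = 1e-6,
) -> REMLFit:
    """Restricted maximum likelihood for 0, 1 or 2 kernels plus residual."""
    _check_alignment(y_adj, kernels)
    y = y_adj.values
    if len(kernels) > 2:
        raise ValueError("at most two kernels supported")
    for k in kernels:
        _check_psd(k)
    if len(kernels) == 0:
        s2e = float(np.var(y, ddof=1))
        vc = VarianceComponents({}, s2e)
        return REMLFit(vc, 0.0, 0, True, float(np.mean(y)), [])
    if len(kernels) == 1:
        return _fit_single_kernel(y, kernels[0])
    return _fit_two_kernels(y, kernels, max_iter=max_iter, tol=tol)


def microbiability(fit: REMLFit) -> float:
    """sigma2_m / (sigma2_m + sigma2_e) from a fit containing a microbiome kernel."""
    s2m = fit.varcomps.by_prefix("M")
    if s2m is None:
        raise ValueError("fit has no microbiome (M) kernel term")
    return s2m / (s2m + fit.varcomps.residual)


def heritability(fit: REMLFit) -> float:
    """sigma2_u over the total variance of the fitted model."""
    s2u = fit.varcomps.by_prefix("G")
    if s2u is None:
        raise ValueError("fit has no genomic (G) kernel term")
    return s2u / fit.varcomps.total


def blup_predict(
    fit: REMLFit,
    y_adj: AdjustedPhenotypes,
    kernels: list[Kernel],
    train_ids: list[str],
    target_ids: list[str],
) -> BLUPPrediction:
    """BLUP of each random term for ``target_ids`` from training phenotypes.

    u_hat[target] = sigma2_r K_r[target, train] V^-1 (y_train - mu_hat) with
    V built on the training block; kernels must cover train and target samples.
    """
    labels = [k.label for k in kernels]
    if set(fit.kernel_labels) != set(labels):
        raise ValueError("kernels do not match the fitted model")
    import pandas as pd

    idx = pd.Index(y_adj.sample_ids)
    ti = idx.get_indexer(train_ids)
    if (ti < 0).any():
        raise KeyError("train ids missing from phenotype vector")
    y_train = y_adj.values[ti]
    nt = len(train_ids)
    V = fit.varcomps.residual * np.eye(nt)
    for k in kernels:
        s2 = fit.varcomps.components[k.label]
        V += s2 * k.subset(train_ids)
    V[np.diag_indices_from(V)] += _RIDGE * np.mean(np.diag(V))
    try:
        c, low = cho_factor(V, lower=True)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("training V singular even after ridge") from exc
    ones = np.ones(nt)
    Vi_1 = cho_solve((c, low), ones)
    mu = (Vi_1 @ y_train) / (ones @ Vi_1)
    alpha = cho_solve((c, low), y_train - mu)
    effects = {}
    for k in kernels:
        s2 = fit.varcomps.components[k.label]
        effects[k.label] = s2 * (k.subset(target_ids, train_ids) @ alpha)
    return BLUPPrediction(list(target_ids), effects)
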