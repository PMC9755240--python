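"""Gaussian mixture fitting by EM and Gaussian-vs-mixture model selection.

A region whose patients split into sub-groups shows up as a multimodal
data distribution; the pipeline probes this with a K = 2 Gaussian
mixture.  The mixture is fitted by expectation-maximization: the E-step
computes responsibilities ``gamma_sk`` proportional to
``pi_k N(x_s | mu_k, sigma_k)`` (row-normalized), the M-step re-estimates
weighted means, covariances and mixing proportions, and iteration stops
when the relative log-likelihood change falls below ``tol``.  Because a
K = 2 mixture always attains at least the single-Gaussian in-sample
likelihood, the two models are compared by leave-one-out cross-validation
instead: both are refitted on every S-1 subset and evaluated on the
held-out point; the summed held-out log-likelihoods decide, with ties
going to the single Gaussian (parsimony).

The first EM restart is deterministic (a hard split at the median of the
first principal-axis projection); the remaining restarts use random soft
responsibilities.  Near-singular components receive a relative ridge; a
component that stays degenerate triggers a logged re-initialization.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.special import logsumexp

from .gaussian import DegenerateFitError, GaussianFit, fit_gaussian, loglik_points
from .registry import RegionRecord, feature_columns

__all__ = [
    "GMMFit",
    "em_fit_gmm",
    "gmm_loglik_point",
    "gmm_loglik_data",
    "ModelComparison",
    "loo_compare",
    "compare_all",
]

_LOG_2PI = np.log(2.0 * np.pi)


@dataclasses.dataclass
class GMMFit:
    K: int
    pi: np.ndarray
    components: list[GaussianFit]
    loglik: float
    ll_trace: np.ndarray
    n_iter: int
    converged: bool
    n_restarts_used: int
    n_reinits: int = 0

    @property
    def d(self) -> int:
        return self.components[0].d


def _component_logdens(X: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    d = X.shape[1]
    with np.errstate(over="ignore"):  # near-collapsed components give -inf density
        if d == 1:
            var = sigma[0, 0]
            if var <= 0:
                raise linalg.LinAlgError("non-positive variance")
            return -0.5 * (_LOG_2PI + np.log(var) + (X[:, 0] - mu[0]) ** 2 / var)
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            raise linalg.LinAlgError("covariance not positive definite")
        prec = np.linalg.inv(sigma)
        Xc = X - mu
        maha = np.einsum("si,ij,sj->s", Xc, prec, Xc)
        return -0.5 * (d * _LOG_2PI + logdet + maha)


def _e_step(X: np.ndarray, pi, mus, sigmas):
    """Responsibilities and total log-likelihood at the given parameters.

    Rows of the returned responsibility matrix sum to one exactly (up to
    floating point); the log-likelihood uses a stable log-sum-exp.
    """
    K = len(mus)
    logdens = np.empty((X.shape[0], K))
    for k in range(K):
        logdens[:, k] = np.log(pi[k]) + _component_logdens(X, mus[k], sigmas[k])
    m = logdens.max(axis=1)
    with np.errstate(invalid="ignore"):
        per_point = m + np.log(np.exp(logdens - m[:, None]).sum(axis=1))
    gamma = np.exp(logdens - per_point[:, None])
    return gamma, float(per_point.sum())


def _m_step(X: np.ndarray, gamma: np.ndarray, ridge: float):
    S, d = X.shape
    if not np.all(np.isfinite(gamma)):
        raise DegenerateFitError("non-finite responsibilities (collapsed component)")
    nk = gamma.sum(axis=0)
    pi = nk / S
    mus, sigmas = [], []
    for k in range(gamma.shape[1]):
        if nk[k] <= 0:
            raise DegenerateFitError(f"component {k} collapsed to zero weight")
        mu = gamma[:, k] @ X / nk[k]
        Xc = X - mu
        sigma = (Xc.T * gamma[:, k]) @ Xc / nk[k]
        try:
            np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            sigma = sigma + ridge * (np.trace(sigma) / d + np.finfo(float).tiny) * np.eye(d)
            np.linalg.cholesky(sigma)  # may still raise -> caught by caller
        mus.append(mu)
        sigmas.append(sigma)
    return pi, mus, sigmas


def _initial_responsibilities(
    X: np.ndarray, K: int, restart: int, rng: np.random.Generator
) -> np.ndarray:
    S, d = X.shape
    if restart == 0 and K == 2:
        # deterministic: hard split at the median of the first principal
        # axis projection (for d=1 this is a plain median split)
        Xc = X - X.mean(axis=0)
        if d == 1:
            proj = Xc[:, 0]
        else:
            _, _, vt = np.linalg.svd(Xc, full_matrices=False)
            proj = Xc @ vt[0]
        gamma = np.zeros((S, K))
        lower = proj <= np.median(proj)
        gamma[lower, 0] = 1.0
        gamma[~lower, 1] = 1.0
        if gamma.sum(axis=0).min() == 0:  # all points tied at the median
            gamma[:] = 1.0 / K
        return gamma
    gamma = rng.gamma(1.0, 1.0, size=(S, K))
    return gamma / gamma.sum(axis=1, keepdims=True)


def em_fit_gmm(
    X: np.ndarray,
    K: int = 2,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_restarts: int = 20,
    ridge: float = 1e-6,
    seed: int | np.random.Generator | None = None,
) -> GMMFit:
    """Fit a K-component Gaussian mixture by EM, best of ``n_restarts``.

    The log-likelihood trace recorded for the winning restart is
    non-decreasing (EM's ascent property).  ``ridge`` is the relative
    regularization added to a near-singular component covariance.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    S, d = X.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if S < K * (d + 1):
        raise DegenerateFitError(f"need >= K*(d+1)={K * (d + 1)} samples, got {S}")
    if K == 1:
        fit = fit_gaussian(X)
        ll = float(np.sum(loglik_points(X, fit)))
        return GMMFit(K=1, pi=np.array([1.0]), components=[fit], loglik=ll,
                      ll_trace=np.array([ll]), n_iter=0, converged=True,
                      n_restarts_used=1)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    best: GMMFit | None = None
    n_reinits = 0
    restart = 0
    attempts = 0
    while restart < n_restarts and attempts < 4 * n_restarts:
        attempts += 1
        gamma = _initial_responsibilities(X, K, restart, rng)
        try:
            pi, mus, sigmas = _m_step(X, gamma, ridge)
            trace = []
            converged = False
            for it in range(max_iter):
                gamma, ll = _e_step(X, pi, mus, sigmas)
                trace.append(ll)
                if len(trace) > 1:
                    denom = abs(trace[-2]) + np.finfo(float).eps
                    if abs(trace[-1] - trace[-2]) / denom < tol:
                        converged = True
                        break
                pi, mus, sigmas = _m_step(X, gamma, ridge)
        except (linalg.LinAlgError, np.linalg.LinAlgError, DegenerateFitError,
                FloatingPointError):
            # degenerate restart: re-initialize with fresh randomness
            n_reinits += 1
            if restart == 0:
                restart += 1  # do not retry the deterministic init
            continue
        finite = (
            np.all(np.isfinite(pi))
            and all(np.all(np.isfinite(m)) for m in mus)
            and all(np.all(np.isfinite(s)) for s in sigmas)
            and np.all(np.isfinite(trace))
        )
        if not finite:
            n_reinits += 1
            if restart == 0:
                restart += 1
            continue
        try:
            comps = [GaussianFit(mu=mus[k], sigma=sigmas[k], S=S, d=d) for k in range(K)]
        except DegenerateFitError:
            n_reinits += 1
            if restart == 0:
                restart += 1
            continue
        cand = GMMFit(K=K, pi=np.asarray(pi), components=comps, loglik=trace[-1],
                      ll_trace=np.asarray(trace), n_iter=len(trace),
                      converged=converged, n_restarts_used=restart + 1,
                      n_reinits=n_reinits)
        if best is None or cand.loglik > best.loglik:
            best = cand
        restart += 1
    if best is None:
        raise DegenerateFitError("every EM restart degenerated")
    best.n_restarts_used = restart
    best.n_reinits = n_reinits
    return best


def gmm_loglik_point(z: np.ndarray, fit: GMMFit) -> float:
    """Log-density of one point under the mixture, via log-sum-exp."""
    z = np.atleast_1d(np.asarray(z, dtype=float))
    if z.shape != (fit.d,):
        raise ValueError(f"point has dimension {z.shape}, fit has d={fit.d}")
    terms = [
        np.log(fit.pi[k]) + _component_logdens(z[None, :], c.mu, c.sigma)[0]
        for k, c in enumerate(fit.components)
        if fit.pi[k] > 0
    ]
    return float(logsumexp(terms))


def gmm_loglik_data(X: np.ndarray, fit: GMMFit) -> float:
    """Total mixture log-likelihood of a dataset."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    logdens = np.column_stack(
        [np.log(fit.pi[k]) + _component_logdens(X, c.mu, c.sigma)
         for k, c in enumerate(fit.components) if fit.pi[k] > 0]
    )
    return float(logsumexp(logdens, axis=1).sum())


@dataclasses.dataclass
class ModelComparison:
    """Leave-one-out comparison of the single Gaussian and the K=2 mixture."""

    ll_gaussian_cv: float
    ll_gmm_cv: float
    preferred: str  # "gaussian" or "gmm"
    n_folds: int
    n_failed: int
    inconclusive: bool
    region: str | None = None


def loo_compare(
    X: np.ndarray,
    K: int = 2,
    seed: int = 0,
    region: str | None = None,
    **em_opts,
) -> ModelComparison:
    """Compare Gaussian and mixture fits by leave-one-out cross-validation.

    Each point is held out once; both models are refitted on the
    remaining S-1 points and evaluated on the held-out point.  Both sums
    run over the identical fold set; folds where either refit degenerates
    are dropped from both and counted, and the region is flagged
    inconclusive when at least 10 % of folds fail.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    S = X.shape[0]
    if S < 8:
        raise ValueError("need at least 8 samples for a meaningful LOO comparison")
    ss = np.random.SeedSequence(entropy=seed)
    ll_g = 0.0
    ll_m = 0.0
    n_failed = 0
    from .gaussian import loglik_point  # local to avoid clutter above

    for fold in range(S):
        Xtr = np.delete(X, fold, axis=0)
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(fold,)))
        try:
            gfit = fit_gaussian(Xtr)
            mfit = em_fit_gmm(Xtr, K=K, seed=rng, **em_opts)
        except DegenerateFitError:
            n_failed += 1
            continue
        ll_g += loglik_point(X[fold], gfit)
        ll_m += gmm_loglik_point(X[fold], mfit)
    n_ok = S - n_failed
    preferred = "gmm" if ll_m > ll_g else "gaussian"
    return ModelComparison(
        ll_gaussian_cv=ll_g,
        ll_gmm_cv=ll_m,
        preferred=preferred,
        n_folds=S,
        n_failed=n_failed,
        inconclusive=n_failed >= 0.1 * S,
        region=region,
    )


def compare_all(
    resid: pd.DataFrame,
    regions: list[RegionRecord],
    K: int = 2,
    seed: int = 0,
    **em_opts,
) -> pd.DataFrame:
    """Run the LOO model comparison for every region of a registry."""
    rows = []
    for ri, region in enumerate(regions):
        X = resid[feature_columns(region)].to_numpy(float)
        res = loo_compare(X, K=K, seed=int(np.random.SeedSequence(
            entropy=seed, spawn_key=(ri,)).generate_state(1)[0] % (2**31)),
            region=region.name, **em_opts)
        rows.append(
            {
                "region": region.name,
                "ll_gaussian_cv": res.ll_gaussian_cv,
                "ll_gmm_cv": res.ll_gmm_cv,
                "preferred": res.preferred,
                "n_failed": res.n_failed,
                "inconclusive": res.inconclusive,
            }
        )
    return pd.DataFrame(rows)
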