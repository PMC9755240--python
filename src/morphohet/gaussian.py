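"""Multivariate Gaussian fitting, log-likelihood evaluation and conformity scores.

A region's per-group data is an ``S x d`` matrix (d = 3 for cortical
regions, CT/SA/MC; d = 1 for non-cortical volumes).  The group model is a
single multivariate normal with the maximum-likelihood estimators: the
arithmetic mean and the 1/S-normalized covariance (an unbiased 1/(S-1)
switch is available via ``ddof``).  Conformity scores quantify how
typical an individual patient is of the patient group: the log-likelihood
of the subject's regional data point under the patient-group fit, higher
meaning more typical.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import linalg

from .registry import RegionRecord, feature_columns

__all__ = [
    "GaussianFit",
    "DegenerateFitError",
    "fit_gaussian",
    "loglik_point",
    "loglik_data",
    "conformity_scores",
]

_LOG_2PI = np.log(2.0 * np.pi)

#: Relative ridge applied only when the ML covariance is numerically singular.
RIDGE_EPS = 1e-8


class DegenerateFitError(ValueError):
    """Raised when a Gaussian fit is impossible or numerically degenerate."""


@dataclasses.dataclass
class GaussianFit:
    """Fitted multivariate normal: mean ``mu``, covariance ``sigma``, sample size ``S``."""

    mu: np.ndarray
    sigma: np.ndarray
    S: int
    d: int
    ridge: float = 0.0

    def __post_init__(self) -> None:
        self.mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        self.sigma = np.atleast_2d(np.asarray(self.sigma, dtype=float))
        if self.sigma.shape != (self.d, self.d) or self.mu.shape != (self.d,):
            raise ValueError("inconsistent GaussianFit shapes")
        # cache the Cholesky factor for likelihood evaluation
        try:
            self._chol = linalg.cholesky(self.sigma, lower=True)
        except linalg.LinAlgError as exc:
            raise DegenerateFitError("covariance is not positive definite") from exc
        self.logdet = 2.0 * float(np.sum(np.log(np.diag(self._chol))))


def _as_matrix(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise ValueError("data must be an S x d matrix")
    return X


def fit_gaussian(X: np.ndarray, ddof: int = 0) -> GaussianFit:
    """Maximum-likelihood Gaussian fit of an ``S x d`` data matrix.

    ``ddof=0`` (default) divides the covariance by S, the estimator that
    maximizes the likelihood; ``ddof=1`` gives the unbiased version.  A
    tiny ridge ``1e-8 * (trace/d) * I`` is added only when the estimated
    covariance is numerically singular; genuinely degenerate data (too few
    samples, or a constant column) raises :class:`DegenerateFitError`.
    """
    X = _as_matrix(X)
    S, d = X.shape
    if S < d + 1:
        raise DegenerateFitError(f"need at least d+1={d + 1} samples, got {S}")
    if np.any(np.ptp(X, axis=0) == 0.0):
        cols = np.nonzero(np.ptp(X, axis=0) == 0.0)[0].tolist()
        raise DegenerateFitError(f"zero-variance dimensions {cols}")
    mu = X.mean(axis=0)
    Xc = X - mu
    sigma = (Xc.T @ Xc) / (S - ddof)
    ridge = 0.0
    try:
        linalg.cholesky(sigma, lower=True)
    except linalg.LinAlgError:
        ridge = RIDGE_EPS * (np.trace(sigma) / d)
        sigma = sigma + ridge * np.eye(d)
    try:
        return GaussianFit(mu=mu, sigma=sigma, S=S, d=d, ridge=ridge)
    except DegenerateFitError as exc:
        raise DegenerateFitError(f"degenerate covariance even after ridge: {exc}") from exc


def loglik_point(z: np.ndarray, fit: GaussianFit) -> float:
    """Exact log-density ``ln N(z | mu, sigma)`` of a single data point."""
    z = np.atleast_1d(np.asarray(z, dtype=float))
    if z.shape != (fit.d,):
        raise ValueError(f"point has dimension {z.shape}, fit has d={fit.d}")
    w = linalg.solve_triangular(fit._chol, z - fit.mu, lower=True)
    maha = float(w @ w)
    return -0.5 * (fit.d * _LOG_2PI + fit.logdet + maha)


def loglik_data(X: np.ndarray, fit: GaussianFit) -> float:
    """Total log-likelihood of a dataset (sum of per-point terms)."""
    X = _as_matrix(X)
    if X.shape[1] != fit.d:
        raise ValueError("dimension mismatch")
    W = linalg.solve_triangular(fit._chol, (X - fit.mu).T, lower=True)
    maha = np.sum(W * W, axis=0)
    return float(-0.5 * np.sum(fit.d * _LOG_2PI + fit.logdet + maha))


def loglik_points(X: np.ndarray, fit: GaussianFit) -> np.ndarray:
    """Vector of per-point log-densities (row-wise :func:`loglik_point`)."""
    X = _as_matrix(X)
    if X.shape[1] != fit.d:
        raise ValueError("dimension mismatch")
    W = linalg.solve_triangular(fit._chol, (X - fit.mu).T, lower=True)
    maha = np.sum(W * W, axis=0)
    return -0.5 * (fit.d * _LOG_2PI + fit.logdet + maha)


def conformity_scores(
    residuals: pd.DataFrame,
    regions: list[RegionRecord],
    ddof: int = 0,
    leave_one_out: bool = False,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-subject, per-region conformity log-likelihoods for one group.

    ``residuals`` holds the patient rows (subjects x region-feature
    columns, plus ``subject_id``).  For every region the group Gaussian is
    fitted on the full sample -- including the evaluated subject, unless
    ``leave_one_out`` is set -- and each subject's regional data point is
    scored by its log-likelihood under that fit.  Higher scores denote
    more typical subjects.  Regions with degenerate fits are flagged and
    their scores withheld (NaN).
    """
    subjects = residuals["subject_id"].astype(str).tolist()
    scores = pd.DataFrame(index=subjects, columns=[r.name for r in regions], dtype=float)
    scores.index.name = "subject_id"
    flagged: list[str] = []
    for region in regions:
        X = residuals[feature_columns(region)].to_numpy(dtype=float)
        try:
            if leave_one_out:
                vals = np.empty(len(subjects))
                for i in range(len(subjects)):
                    fit = fit_gaussian(np.delete(X, i, axis=0), ddof=ddof)
                    vals[i] = loglik_point(X[i], fit)
            else:
                fit = fit_gaussian(X, ddof=ddof)
                vals = loglik_points(X, fit)
        except DegenerateFitError:
            flagged.append(region.name)
            continue
        scores[region.name] = vals
    return scores, flagged
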