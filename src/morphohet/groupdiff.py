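"""Parameter-wise Gaussian group comparison with permutation significance.

For a region modelled in ``d`` dimensions, each group's Gaussian fit has
``2d + d(d-1)/2`` parameters: the ``d`` means, the ``d`` variances and
the ``d(d-1)/2`` covariances in (j, k), j < k order.  The statistic of
interest for each parameter is the plain difference, control minus
patient (HC - ET).  Significance is assessed by randomly re-assigning
the pooled data points to the two groups and re-estimating the
difference; the two-tailed p-value is the plain fraction of null draws
whose absolute difference reaches the observed one (ties count as
exceedances; a +1-smoothed variant is available).  When the number of
distinct group splits does not exceed the permutation budget, the null is
enumerated exhaustively instead.
"""

from __future__ import annotations

import dataclasses
import itertools
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd

from .gaussian import GaussianFit
from .registry import RegionRecord, feature_columns

__all__ = [
    "param_names",
    "gaussian_param_vector",
    "param_difference_vector",
    "ParamDiffResult",
    "permutation_test",
    "bonferroni_correct",
    "group_difference_all",
]

#: Number of regions the study corrects over.
DEFAULT_N_REGIONS = 87


def param_names(d: int, features: Sequence[str] | None = None) -> list[str]:
    """Ordered parameter labels: d means, d variances, d(d-1)/2 covariances."""
    if features is None:
        features = [str(j) for j in range(d)]
    names = [f"mean_{f}" for f in features] + [f"var_{f}" for f in features]
    for j in range(d):
        for k in range(j + 1, d):
            names.append(f"cov_{features[j]}_{features[k]}")
    return names


def gaussian_param_vector(mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Flatten (mu, sigma) into the documented parameter order."""
    mu = np.atleast_1d(np.asarray(mu, float))
    sigma = np.atleast_2d(np.asarray(sigma, float))
    d = mu.shape[0]
    iu = np.triu_indices(d, k=1)
    return np.concatenate([mu, np.diag(sigma), sigma[iu]])


def param_difference_vector(fit_hc: GaussianFit, fit_et: GaussianFit) -> np.ndarray:
    """HC-minus-ET difference for every distribution parameter."""
    if fit_hc.d != fit_et.d:
        raise ValueError(f"dimension mismatch: {fit_hc.d} vs {fit_et.d}")
    return gaussian_param_vector(fit_hc.mu, fit_hc.sigma) - gaussian_param_vector(
        fit_et.mu, fit_et.sigma
    )


def bonferroni_correct(p_raw, n_tests: int = DEFAULT_N_REGIONS):
    """Bonferroni correction: ``min(1, n_tests * p)`` elementwise."""
    p = np.asarray(p_raw, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.minimum(1.0, n_tests * p)
    return float(out) if np.isscalar(p_raw) else out


@dataclasses.dataclass
class ParamDiffResult:
    """Per-parameter HC-ET differences with permutation p-values."""

    param_names: list[str]
    delta: np.ndarray
    p_raw: np.ndarray
    p_corr: np.ndarray
    n_perm: int
    method: str  # "exhaustive" or "monte-carlo"
    seed: int | None
    n_resampled: int = 0
    region: str | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region": self.region,
                "parameter": self.param_names,
                "delta": self.delta,
                "p_raw": self.p_raw,
                "p_corr": self.p_corr,
            }
        )


def _batch_deltas(pooled: np.ndarray, idx: np.ndarray, n_hc: int) -> np.ndarray:
    """Parameter-difference vectors for a batch of group assignments.

    ``idx`` is a (P, n) matrix of row permutations of the pooled sample;
    the first ``n_hc`` columns form the control group of each draw.
    Covariances use the maximum-likelihood 1/S normalization, matching
    :func:`morphohet.gaussian.fit_gaussian`.
    """
    d = pooled.shape[1]
    iu = np.triu_indices(d, k=1)

    def params(block: np.ndarray) -> np.ndarray:
        # block: (P, S, d)
        m = block.mean(axis=1)
        second = np.einsum("psi,psj->pij", block, block) / block.shape[1]
        cov = second - np.einsum("pi,pj->pij", m, m)
        var = np.diagonal(cov, axis1=1, axis2=2)
        return np.concatenate([m, var, cov[:, iu[0], iu[1]]], axis=1)

    grouped = pooled[idx]
    return params(grouped[:, :n_hc]) - params(grouped[:, n_hc:])


def permutation_test(
    X_hc: np.ndarray,
    X_et: np.ndarray,
    n_perm: int = 10_000,
    seed: int | np.random.Generator | None = None,
    method: str = "auto",
    smoothed: bool = False,
    features: Sequence[str] | None = None,
    region: str | None = None,
) -> ParamDiffResult:
    """Two-tailed permutation test on every Gaussian parameter difference.

    ``method="auto"`` enumerates all distinct group splits when their
    count is at most ``n_perm``, otherwise draws ``n_perm`` random
    reassignments.  Random draws yielding a degenerate fit (a
    zero-variance group dimension) are redrawn and counted.
    """
    X_hc = np.asarray(X_hc, float)
    X_et = np.asarray(X_et, float)
    if X_hc.ndim == 1:
        X_hc = X_hc[:, None]
    if X_et.ndim == 1:
        X_et = X_et[:, None]
    if X_hc.shape[1] != X_et.shape[1]:
        raise ValueError("group dimensionalities differ")
    n_hc, d = X_hc.shape
    n_et = X_et.shape[0]
    n = n_hc + n_et
    pooled = np.concatenate([X_hc, X_et], axis=0)
    if method not in ("auto", "exhaustive", "monte-carlo"):
        raise ValueError(f"unknown method {method!r}")

    obs = _batch_deltas(pooled, np.arange(n)[None, :], n_hc)[0]
    n_splits = comb(n, n_hc)
    use_exhaustive = method == "exhaustive" or (method == "auto" and n_splits <= n_perm)

    if use_exhaustive:
        all_idx = np.empty((n_splits, n), dtype=np.intp)
        full = frozenset(range(n))
        for i, combo in enumerate(itertools.combinations(range(n), n_hc)):
            rest = sorted(full.difference(combo))
            all_idx[i, :n_hc] = combo
            all_idx[i, n_hc:] = rest
        null = _batch_deltas(pooled, all_idx, n_hc)
        n_eff = n_splits
        method_used = "exhaustive"
        n_resampled = 0
        seed_val = None
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        seed_val = None if isinstance(seed, np.random.Generator) else seed
        null = np.empty((n_perm, obs.shape[0]))
        n_resampled = 0
        pending = np.arange(n_perm)
        for _ in range(100):  # resample degenerate draws, bounded
            idx = np.argsort(rng.random((len(pending), n)), axis=1)
            block = _batch_deltas(pooled, idx, n_hc)
            grouped = pooled[idx]
            degen = (
                np.any(np.ptp(grouped[:, :n_hc], axis=1) == 0.0, axis=1)
                | np.any(np.ptp(grouped[:, n_hc:], axis=1) == 0.0, axis=1)
            )
            null[pending[~degen]] = block[~degen]
            pending = pending[degen]
            n_resampled += int(degen.sum())
            if len(pending) == 0:
                break
        else:
            raise RuntimeError("could not draw non-degenerate permutations")
        n_eff = n_perm
        method_used = "monte-carlo"

    exceed = (np.abs(null) >= np.abs(obs)[None, :]).sum(axis=0)
    if smoothed:
        p_raw = (1.0 + exceed) / (1.0 + n_eff)
    else:
        p_raw = exceed / n_eff
    names = param_names(d, features)
    return ParamDiffResult(
        param_names=names,
        delta=obs,
        p_raw=p_raw,
        p_corr=bonferroni_correct(p_raw),
        n_perm=n_eff,
        method=method_used,
        seed=seed_val,
        n_resampled=n_resampled,
        region=region,
    )


def group_difference_all(
    resid_hc: pd.DataFrame,
    resid_et: pd.DataFrame,
    regions: list[RegionRecord],
    n_perm: int = 10_000,
    seed: int = 0,
    n_regions_correction: int = DEFAULT_N_REGIONS,
    smoothed: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Run the permutation comparison for every region of a registry.

    Per-region RNG streams are derived from ``(seed, region index)`` so
    results do not depend on execution order.  Returns a tidy frame (one
    row per region-parameter) and run metadata.
    """
    frames = []
    meta: dict = {"seed": seed, "n_perm": n_perm, "exhaustive_regions": [],
                  "resampled_draws": {}}
    for ri, region in enumerate(regions):
        cols = feature_columns(region)
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(ri,)))
        res = permutation_test(
            resid_hc[cols].to_numpy(float),
            resid_et[cols].to_numpy(float),
            n_perm=n_perm,
            seed=rng,
            smoothed=smoothed,
            features=region.features,
            region=region.name,
        )
        res.p_corr = bonferroni_correct(res.p_raw, n_regions_correction)
        if res.method == "exhaustive":
            meta["exhaustive_regions"].append(region.name)
        if res.n_resampled:
            meta["resampled_draws"][region.name] = res.n_resampled
        frames.append(res.to_frame())
    table = pd.concat(frames, ignore_index=True)
    return table, meta
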