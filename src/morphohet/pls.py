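"""Behavioural Partial Least Squares: covariance modes between imaging and clinical data.

Given a subjects-by-variables imaging matrix ``I`` (S x M) and a clinical
score matrix ``B`` (S x B, M >= B), both z-scored across subjects, the
cross-covariance ``R = I^T B`` is decomposed by SVD, ``R = U S V^T``.
Each mode pairs an imaging salience column of ``U`` with a clinical
salience column of ``V``; squared singular values over their sum give the
fraction of cross-modality covariance a mode explains.

Mode significance comes from permutations: subject rows of one set are
shuffled, the decomposition repeated, and the k-th observed singular
value compared with the k-th null singular values (index-matched by
default; a max-based comparison is available).  Being a multivariate
test, no further multiple-comparison correction is applied.  Salience
robustness comes from a bootstrap in which 80 % of the subjects are
resampled with replacement; after aligning each bootstrap solution to the
original (sign and, if needed, mode order, by maximal absolute salience
correlation), percentile confidence intervals are built per weight, and
weights whose 99 % CI excludes zero are deemed significant.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = [
    "zscore_columns",
    "pls_modes",
    "permutation_mode_pvalues",
    "bootstrap_salience_ci",
    "pls_analysis",
    "PLSResult",
]


def zscore_columns(X, ddof: int = 1) -> np.ndarray:
    """Normalize each column across subjects to mean 0, SD 1 (ddof=1).

    Raises on constant columns, naming them when the input is a DataFrame.
    """
    names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=0, ddof=ddof)
    if np.any(sd == 0):
        bad = np.nonzero(sd == 0)[0]
        labels = [names[i] for i in bad] if names else bad.tolist()
        raise ValueError(f"constant columns cannot be z-scored: {labels}")
    return (X - X.mean(axis=0)) / sd


def _svd_modes(I: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    R = I.T @ B
    U, s, Vt = np.linalg.svd(R, full_matrices=False)
    V = Vt.T
    # deterministic sign convention: the largest-magnitude element of each
    # clinical salience column is made positive
    for k in range(V.shape[1]):
        j = int(np.argmax(np.abs(V[:, k])))
        if V[j, k] < 0:
            V[:, k] *= -1.0
            U[:, k] *= -1.0
    return U, s, V


def pls_modes(I: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """SVD of the imaging-clinical cross-covariance of z-scored matrices.

    Returns ``(U, singular_values, V)`` with modes ordered by decreasing
    singular value and a deterministic sign convention.
    """
    I = np.asarray(I, float)
    B = np.asarray(B, float)
    if I.shape[0] != B.shape[0]:
        raise ValueError("imaging and clinical matrices must share the subject axis")
    if I.shape[1] < B.shape[1]:
        raise ValueError(
            f"expected at least as many imaging variables ({I.shape[1]}) "
            f"as clinical scores ({B.shape[1]})"
        )
    return _svd_modes(I, B)


def explained_covariance(singular_values: np.ndarray) -> np.ndarray:
    """Fraction of cross-covariance explained per mode (squared s.v. over sum)."""
    s2 = np.asarray(singular_values, float) ** 2
    return s2 / s2.sum()


def permutation_mode_pvalues(
    I: np.ndarray,
    B: np.ndarray,
    n_perm: int = 10_000,
    seed: int | np.random.Generator | None = None,
    comparison: str = "per-mode",
) -> np.ndarray:
    """Permutation p-value per covariance mode.

    Rows of the clinical matrix are shuffled ``n_perm`` times; the p-value
    of mode k is the plain fraction of permutations whose k-th largest
    null singular value reaches the observed k-th singular value
    (``comparison="max"`` compares every mode against the largest null
    value instead).
    """
    if comparison not in ("per-mode", "max"):
        raise ValueError(f"unknown comparison {comparison!r}")
    I = np.asarray(I, float)
    B = np.asarray(B, float)
    _, s_obs, _ = pls_modes(I, B)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    exceed = np.zeros_like(s_obs)
    for _ in range(n_perm):
        Bp = B[rng.permutation(B.shape[0])]
        s_null = np.linalg.svd(I.T @ Bp, compute_uv=False)
        if comparison == "per-mode":
            exceed += s_null >= s_obs
        else:
            exceed += s_null[0] >= s_obs
    return exceed / n_perm


def _align_to_reference(
    U_ref: np.ndarray, V_ref: np.ndarray, U_b: np.ndarray, V_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Match bootstrap modes to the reference by maximal absolute salience
    correlation, permuting and sign-flipping the bootstrap columns."""
    ref = np.vstack([U_ref, V_ref])
    boot = np.vstack([U_b, V_b])
    ref_c = ref - ref.mean(axis=0)
    boot_c = boot - boot.mean(axis=0)
    denom = np.outer(np.linalg.norm(ref_c, axis=0), np.linalg.norm(boot_c, axis=0))
    denom[denom == 0] = 1.0
    corr = (ref_c.T @ boot_c) / denom
    rows, cols = linear_sum_assignment(-np.abs(corr))
    order = np.empty_like(cols)
    order[rows] = cols
    signs = np.sign(corr[rows, cols])
    signs[signs == 0] = 1.0
    signs_ordered = np.empty_like(signs)
    signs_ordered[rows] = signs
    return U_b[:, order] * signs_ordered, V_b[:, order] * signs_ordered


def bootstrap_salience_ci(
    I: np.ndarray,
    B: np.ndarray,
    n_boot: int = 10_000,
    frac: float = 0.8,
    alpha: float = 0.01,
    seed: int | np.random.Generator | None = None,
) -> dict:
    """Percentile bootstrap confidence intervals for every salience weight.

    Each draw resamples ``floor(frac * S)`` subjects with replacement,
    re-normalizes and re-decomposes, aligns the solution to the original,
    and contributes one replicate per weight.  Draws producing a constant
    column are redrawn (counted in ``n_redrawn``).
    """
    I = np.asarray(I, float)
    B = np.asarray(B, float)
    S = I.shape[0]
    m = int(np.floor(frac * S))
    if m < 3:
        raise ValueError("bootstrap sample too small")
    U0, s0, V0 = pls_modes(I, B)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    U_acc = np.empty((n_boot, *U0.shape))
    V_acc = np.empty((n_boot, *V0.shape))
    n_redrawn = 0
    b = 0
    guard = 0
    while b < n_boot:
        guard += 1
        if guard > 20 * n_boot:
            raise RuntimeError("too many degenerate bootstrap draws")
        idx = rng.integers(0, S, size=m)
        try:
            Ib = zscore_columns(I[idx])
            Bb = zscore_columns(B[idx])
        except ValueError:
            n_redrawn += 1
            continue
        Ub, _, Vb = _svd_modes(Ib, Bb)
        Ub, Vb = _align_to_reference(U0, V0, Ub, Vb)
        U_acc[b] = Ub
        V_acc[b] = Vb
        b += 1
    lo, hi = 100 * alpha / 2.0, 100 * (1.0 - alpha / 2.0)
    U_ci = np.percentile(U_acc, [lo, hi], axis=0)
    V_ci = np.percentile(V_acc, [lo, hi], axis=0)
    return {
        "U_ci_low": U_ci[0], "U_ci_high": U_ci[1],
        "V_ci_low": V_ci[0], "V_ci_high": V_ci[1],
        "n_redrawn": n_redrawn,
    }


@dataclasses.dataclass
class PLSResult:
    """Full behavioural-PLS output: saliences, modes, inference."""

    U: np.ndarray
    singular_values: np.ndarray
    V: np.ndarray
    explained: np.ndarray
    p_modes: np.ndarray
    U_ci_low: np.ndarray
    U_ci_high: np.ndarray
    V_ci_low: np.ndarray
    V_ci_high: np.ndarray
    imaging_names: list[str]
    clinical_names: list[str]
    n_perm: int
    n_boot: int
    seed: int | None
    n_redrawn: int = 0
    n_imputed: int = 0

    @property
    def significant_modes(self) -> np.ndarray:
        return np.nonzero(self.p_modes < 0.05)[0]

    def U_significant(self, mode: int = 0) -> np.ndarray:
        return (self.U_ci_low[:, mode] > 0) | (self.U_ci_high[:, mode] < 0)

    def V_significant(self, mode: int = 0) -> np.ndarray:
        return (self.V_ci_low[:, mode] > 0) | (self.V_ci_high[:, mode] < 0)

    def mode_summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mode": np.arange(len(self.singular_values)),
                "singular_value": self.singular_values,
                "explained_covariance": self.explained,
                "p_value": self.p_modes,
            }
        )


def pls_analysis(
    imaging: pd.DataFrame,
    clinical: pd.DataFrame,
    n_perm: int = 10_000,
    n_boot: int = 10_000,
    frac: float = 0.8,
    alpha: float = 0.01,
    seed: int | None = None,
    comparison: str = "per-mode",
    missing_clinical: str = "impute",
) -> PLSResult:
    """End-to-end behavioural PLS on aligned imaging and clinical tables.

    Both inputs are subjects-by-variables DataFrames indexed identically.
    Missing clinical cells are mean-imputed (``missing_clinical="impute"``,
    count reported) or the subjects dropped (``"drop"``).
    """
    if list(imaging.index) != list(clinical.index):
        raise ValueError("imaging and clinical tables must be row-aligned")
    clinical = clinical.copy()
    n_imputed = int(clinical.isna().sum().sum())
    if n_imputed:
        if missing_clinical == "impute":
            clinical = clinical.fillna(clinical.mean())
        elif missing_clinical == "drop":
            keep = ~clinical.isna().any(axis=1)
            clinical = clinical.loc[keep]
            imaging = imaging.loc[keep]
        else:
            raise ValueError(f"unknown missing_clinical {missing_clinical!r}")
    Iz = zscore_columns(imaging)
    Bz = zscore_columns(clinical)
    U, s, V = pls_modes(Iz, Bz)
    rng_perm = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0,)))
    rng_boot = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1,)))
    p = permutation_mode_pvalues(Iz, Bz, n_perm=n_perm, seed=rng_perm, comparison=comparison)
    ci = bootstrap_salience_ci(Iz, Bz, n_boot=n_boot, frac=frac, alpha=alpha, seed=rng_boot)
    return PLSResult(
        U=U,
        singular_values=s,
        V=V,
        explained=explained_covariance(s),
        p_modes=p,
        U_ci_low=ci["U_ci_low"],
        U_ci_high=ci["U_ci_high"],
        V_ci_low=ci["V_ci_low"],
        V_ci_high=ci["V_ci_high"],
        imaging_names=list(imaging.columns),
        clinical_names=list(clinical.columns),
        n_perm=n_perm,
        n_boot=n_boot,
        seed=seed,
        n_redrawn=ci["n_redrawn"],
        n_imputed=n_imputed,
    )
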