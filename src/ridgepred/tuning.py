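"""Choosing the ridge penalty: cross-validation, heritability, variance ratios.

Three routes to λ are provided:

* K-fold cross-validation on a held-out-test design (a test fraction is set
  aside first; λ̂ maximizes pooled CV accuracy on the remainder, then the
  model is refit on the whole CV set and scored on the test set);
* nested cross-validation, which wraps the above in S "super"-folds to show
  how stable λ̂ and the test accuracy are;
* closed forms from prior knowledge: λ = P(1/h² - 1) from a SNP-heritability
  estimate (equivalently λ_GRM = 1/h² - 1), or λ = σ²_ε/σ²_β from externally
  estimated variance components — the penalty at which ridge prediction
  coincides with the mixed-model BLUP.

All CV accuracy curves are computed for the whole λ grid from a single
eigendecomposition per fold; the full-sample GRM is built once and folds use
its submatrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .preprocess import eigendecompose
from .ridge import LambdaGrid, _multi_lambda, squared_correlation

__all__ = ["CVResult", "kfold_cv", "nested_cv", "lambda_from_h2",
           "lambda_from_varcomp"]


@dataclass
class CVResult:
    """Outcome of one CV split: accuracy curve, selected λ, test accuracy."""

    lambda_grid: LambdaGrid
    cv_r2: np.ndarray            # pooled CV accuracy per λ
    selected_index: int
    selected_lambda: float
    test_r2: float
    folds: list = field(default_factory=list)
    test_indices: np.ndarray | None = None
    seed: int | None = None

    @property
    def selected_lambda_grm(self) -> float:
        return self.selected_lambda


def _grm(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    A = X @ X.T / X.shape[1]
    return (A + A.T) / 2.0


def _predict_block(A: np.ndarray, train: np.ndarray, test: np.ndarray,
                   y: np.ndarray, lambdas: np.ndarray) -> np.ndarray:
    """Multi-λ ridge predictions for ``test`` given ``train``, via submatrices."""
    eig = eigendecompose(A[np.ix_(train, train)])
    return _multi_lambda(A[np.ix_(test, train)], eig.Q, eig.theta,
                         y[train], lambdas)


def _cv_on_split(A: np.ndarray, y: np.ndarray, grid: LambdaGrid,
                 cv_idx: np.ndarray, test_idx: np.ndarray, K: int,
                 rng: np.random.Generator, seed) -> CVResult:
    lambdas = grid.values
    folds = np.array_split(rng.permutation(cv_idx), K)
    pooled_pred: list[np.ndarray] = []
    pooled_y: list[np.ndarray] = []
    kept_folds = []
    for fold in folds:
        if fold.size == 0:
            continue
        if np.var(y[fold]) == 0:
            warnings.warn("CV fold skipped: zero outcome variance",
                          stacklevel=3)
            continue
        train = np.setdiff1d(cv_idx, fold)
        pooled_pred.append(_predict_block(A, train, fold, y, lambdas))
        pooled_y.append(y[fold])
        kept_folds.append(fold)
    preds = np.vstack(pooled_pred)
    yobs = np.concatenate(pooled_y)
    cv_r2 = np.array([squared_correlation(preds[:, j], yobs)
                      for j in range(len(grid))])
    best = int(np.argmax(cv_r2))  # first maximum → smallest λ on ties
    test_pred = _predict_block(A, cv_idx, test_idx, y, lambdas[[best]])
    test_r2 = squared_correlation(test_pred[:, 0], y[test_idx])
    return CVResult(grid, cv_r2, best, float(lambdas[best]), test_r2,
                    folds=kept_folds, test_indices=test_idx, seed=seed)


def kfold_cv(X: np.ndarray, y: np.ndarray, lambda_grid: LambdaGrid,
             K: int = 10, test_frac: float = 0.10,
             seed: int | None = 0) -> CVResult:
    """Select λ by K-fold CV after holding out a final test fraction.

    The grid is interpreted on (or converted to) the GRM scale. λ̂ maximizes
    the pooled CV R² (all CV-fold predictions concatenated before the
    correlation); ties break toward the smallest λ. Apply any confounder
    projection to X and y before calling.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < 2 * K:
        raise ValueError(f"need at least 2K={2 * K} samples for {K}-fold CV")
    grid = lambda_grid.on_scale("grm", np.asarray(X).shape[1])
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = max(1, int(round(test_frac * n)))
    test_idx, cv_idx = perm[:n_test], np.sort(perm[n_test:])
    return _cv_on_split(_grm(X), y, grid, cv_idx, test_idx, K, rng, seed)


def nested_cv(X: np.ndarray, y: np.ndarray, lambda_grid: LambdaGrid,
              S: int = 10, K: int = 10,
              seed: int | None = 0) -> list[CVResult]:
    """Nested CV: S superfolds, each serving as the final test set once.

    Returns one :class:`CVResult` per superfold; the spread of
    ``selected_lambda`` and ``test_r2`` across them measures the stability
    of plain CV.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < S * K:
        raise ValueError(f"need at least S·K={S * K} samples")
    grid = lambda_grid.on_scale("grm", np.asarray(X).shape[1])
    rng = np.random.default_rng(seed)
    blocks = np.array_split(rng.permutation(n), S)
    A = _grm(X)
    results = []
    for s, block in enumerate(blocks):
        cv_idx = np.sort(np.setdiff1d(np.arange(n), block))
        results.append(_cv_on_split(A, y, grid, cv_idx, np.sort(block), K,
                                    rng, seed))
    return results


def lambda_from_h2(h2: float, P: int) -> tuple[float, float]:
    """Penalty implied by SNP heritability: λ = P(1/h² - 1), λ_GRM = 1/h² - 1.

    Follows from h² = Pσ²_β/(Pσ²_β + σ²_ε) with standardized SNPs. h² = 1
    gives λ = 0 (no shrinkage). Returns ``(raw, grm)`` scales.
    """
    if not 0 < h2 <= 1:
        raise ValueError(f"h² must lie in (0, 1], got {h2!r}")
    lam_grm = 1.0 / h2 - 1.0
    return P * lam_grm, lam_grm


def lambda_from_varcomp(sigma2_eps: float, sigma2_beta: float) -> float:
    """λ = σ²_ε/σ²_β, the penalty at which ridge equals the mixed-model BLUP."""
    if sigma2_eps <= 0 or sigma2_beta <= 0:
        raise ValueError("variance components must be strictly positive")
    return sigma2_eps / sigma2_beta
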