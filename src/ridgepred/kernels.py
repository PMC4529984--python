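"""Kernel ridge regression for nonadditive (dominance/epistasis) prediction.

Linear ridge measures genetic similarity in the space of additive SNP
effects, k(x_i, x_j) = x_iᵀx_j. Replacing that inner product with a kernel
evaluates the same machinery in a richer feature space:

* polynomial kernels (c + a_ij)^d, applied elementwise to the entries of the
  GRM a_ij = P⁻¹x_iᵀx_j, span all d-way products of SNPs — the homogeneous
  d = 2, c = 0 case is exactly the Gram matrix of every ordered pairwise
  product x_ip·x_iq, scaled by P⁻²;
* the Gaussian kernel exp(-‖x_i - x_j‖²/η) spans interactions of every
  order.

Prediction with confounders follows the projected kernel system
ŷ₂ = M_Z₂ K21 M_Z (M_Z K M_Z + λI)⁻¹ y, reusing the multi-λ
eigendecomposition path of the linear ridge module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import EigenGRM, ProjectedGRMPair, Projector, eigendecompose
from .ridge import LambdaGrid, RidgePredictionSet, _multi_lambda

__all__ = ["KernelPair", "polynomial_kernel", "gaussian_kernel", "krr_predict"]


@dataclass
class KernelPair:
    """Training kernel K (N×N, PSD) and test-vs-training kernel K21 (N2×N)."""

    K: np.ndarray
    K21: np.ndarray | None
    spec: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        k = np.asarray(self.K, dtype=float)
        if np.abs(k - k.T).max() > 1e-10 * max(1.0, np.abs(k).max()):
            raise ValueError("kernel matrix is not symmetric")
        self.K = (k + k.T) / 2.0


def polynomial_kernel(grms: ProjectedGRMPair, d: int, c: float = 0.0) -> KernelPair:
    """Polynomial kernel k_ij = (c + a_ij)^d on (unprojected) GRM entries.

    d = 1, c = 0 reduces to the linear GRM kernel; integer d ≥ 1 and c ≥ 0
    keep the kernel positive semidefinite. Confounder projection belongs to
    :func:`krr_predict`, after the nonlinearity, so build the GRMs
    unprojected.
    """
    if not float(d).is_integer() or d < 1:
        raise ValueError(f"polynomial degree must be a positive integer, got {d!r}")
    if c < 0:
        raise ValueError("polynomial offset c must be nonnegative")
    d = int(d)
    K = (c + grms.A_star) ** d
    K21 = None if grms.A21_star is None else (c + grms.A21_star) ** d
    return KernelPair(K, K21, {"name": "poly", "degree": d, "offset": c})


def gaussian_kernel(X: np.ndarray, X2: np.ndarray | None, eta: float) -> KernelPair:
    """Gaussian (RBF) kernel k_ij = exp(-‖x_i - x_j‖²/η) with unit diagonal."""
    if eta <= 0:
        raise ValueError("Gaussian bandwidth eta must be positive")
    X = np.asarray(X, dtype=float)
    sq = (X ** 2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.fill_diagonal(d2, 0.0)
    K = np.exp(-np.clip(d2, 0.0, None) / eta)
    np.fill_diagonal(K, 1.0)
    K21 = None
    if X2 is not None:
        X2 = np.asarray(X2, dtype=float)
        sq2 = (X2 ** 2).sum(axis=1)
        d2x = sq2[:, None] + sq[None, :] - 2.0 * (X2 @ X.T)
        K21 = np.exp(-np.clip(d2x, 0.0, None) / eta)
    return KernelPair(K, K21, {"name": "gaussian", "eta": eta})


def median_heuristic_eta(X: np.ndarray, multipliers=(0.5, 1.0, 2.0, 4.0, 8.0)) -> np.ndarray:
    """Default bandwidth grid: multiples of the median pairwise squared distance."""
    X = np.asarray(X, dtype=float)
    sq = (X ** 2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    med = float(np.median(d2[np.triu_indices_from(d2, k=1)]))
    return med * np.asarray(multipliers, dtype=float)


def krr_predict(kp: KernelPair, y: np.ndarray, lambda_grid: LambdaGrid,
                Z: np.ndarray | None = None,
                Z2: np.ndarray | None = None) -> RidgePredictionSet:
    """Multi-λ kernel ridge prediction ŷ₂ = K21*(K* + λI)⁻¹y.

    With confounders the kernels are projected on both sides
    (K* = M_Z K M_Z, K21* = M_Z₂ K21 M_Z) before the eigendecomposition.
    The grid is interpreted on the kernel's own scale (pass ``grm``-scale
    values for GRM-derived kernels to match linear ridge).
    """
    if kp.K21 is None:
        raise ValueError("KernelPair has no out-of-sample block K21")
    y = np.asarray(y, dtype=float).ravel()
    K, K21 = kp.K, kp.K21
    if Z is not None:
        proj = Projector(Z)
        K = proj.apply(proj.apply(K).T).T
        K21 = proj.apply(K21.T).T
    if Z2 is not None:
        K21 = Projector(Z2).apply(K21)
    try:
        eig = eigendecompose((K + K.T) / 2.0)
    except ValueError as exc:
        raise ValueError(f"kernel {kp.spec!r} is not PSD: {exc}") from None
    yhat2 = _multi_lambda(K21, eig.Q, eig.theta, y, lambda_grid.values)
    return RidgePredictionSet(yhat2, lambda_grid, projected=Z is not None,
                              metadata={"kernel": dict(kp.spec)})
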