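"""Genotype standardization, shrinkage weights, projection, and GRMs.

The additive model works on a standardized dosage matrix X = G·D where G is
the mean-centered count matrix and D a positive diagonal. Two conventions are
supported:

* ``empirical`` — D_p = sqrt((N-1) / Σ_i (g_ip - ḡ_p)²), so every column
  satisfies x_pᵀx_p = N-1 and the genetic relationship matrix (GRM)
  A = P⁻¹XXᵀ has trace N-1 (the GCTA convention);
* ``true_frequency`` — x_ip = (g_ip - 2f_p) / sqrt(2 f_p (1 - f_p)) with the
  known allele frequency f_p, the convention of the simulator's generating
  model (the same f_p standardizes training and test data).

Heteroskedastic shrinkage is carried by a diagonal penalty Λ = diag(λ_p):
ridge with penalty λ·βᵀΛβ on data X is identical to homoskedastic ridge on
the reweighted data XΛ^{-1/2}, so weighted GRMs are built from Λ^{-1/2}-scaled
columns. With Λ = D^α, α = -2 on raw counts reproduces plain ridge on
standardized data; α = 0 is a frequency-independent architecture.

Confounders Z (age, sex, principal components, ...) are removed by the
residual-forming projector M_Z = I - Z(ZᵀZ)⁻¹Zᵀ, applied to GRMs from both
sides without ever materializing an N×N matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .io_formats import CovariateMatrix, GenotypeMatrix

__all__ = [
    "StandardizedGenotypes",
    "ShrinkWeights",
    "Projector",
    "ProjectedGRMPair",
    "EigenGRM",
    "standardize",
    "frequency_weights",
    "make_projector",
    "build_grms",
    "eigendecompose",
]


@dataclass
class StandardizedGenotypes:
    """Centered/scaled dosages X = G·D with the scaling actually applied."""

    X: np.ndarray
    scale_diag: np.ndarray       # D, length P, strictly positive
    column_means: np.ndarray     # subtracted per-SNP means (2f_p under true_frequency)
    convention: str              # "empirical" | "true_frequency"

    def transform(self, gm: GenotypeMatrix) -> np.ndarray:
        """Standardize new samples with *this* centering and scaling.

        Out-of-sample data must reuse the training means and D — never its
        own statistics — so train and test scores live on the same scale.
        """
        return (gm.imputed() - self.column_means) * self.scale_diag


@dataclass
class ShrinkWeights:
    """Diagonal of the per-SNP penalty matrix Λ."""

    lambda_p: np.ndarray

    def __post_init__(self) -> None:
        self.lambda_p = np.asarray(self.lambda_p, dtype=float).ravel()
        if (self.lambda_p < 0).any():
            raise ValueError("per-SNP penalties must be nonnegative")

    def column_scaling(self) -> np.ndarray:
        """Λ^{-1/2}: the multiplicative SNP weights that absorb the penalty."""
        if (self.lambda_p == 0).any():
            raise ValueError("zero penalty cannot be absorbed as a column weight")
        return 1.0 / np.sqrt(self.lambda_p)


def standardize(gm: GenotypeMatrix, convention: str = "empirical") -> StandardizedGenotypes:
    """Standardize genotype counts (after per-SNP mean imputation)."""
    g = gm.imputed()
    n = g.shape[0]
    if convention == "empirical":
        means = g.mean(axis=0)
        centered = g - means
        ssq = (centered ** 2).sum(axis=0)
        if (ssq <= 0).any():
            j = int(np.flatnonzero(ssq <= 0)[0])
            raise ValueError(f"SNP {gm.snp_ids[j]!r} is constant in sample; "
                             "remove it before standardizing")
        scale = np.sqrt((n - 1) / ssq)
    elif convention == "true_frequency":
        if gm.allele_freqs is None:
            raise ValueError("true_frequency standardization requires allele_freqs")
        f = gm.allele_freqs
        means = 2.0 * f
        centered = g - means
        scale = 1.0 / np.sqrt(2.0 * f * (1.0 - f))
    else:
        raise ValueError(f"unknown standardization convention {convention!r}")
    return StandardizedGenotypes(centered * scale, scale, means, convention)


def frequency_weights(scale_diag: np.ndarray, alpha: float) -> ShrinkWeights:
    """Frequency-based penalties Λ = D^α.

    α = -2 recovers the shrinkage implied by standardization (plain ridge on
    X = GD equals heteroskedastic ridge on raw G with Λ = D⁻²); α between -2
    and 0 interpolates; positive α favours common variants.
    """
    d = np.asarray(scale_diag, dtype=float).ravel()
    if (d <= 0).any():
        raise ValueError("scale diagonal must be strictly positive")
    return ShrinkWeights(d ** alpha)


class Projector:
    """The residual-forming operator M_Z = I - Z(ZᵀZ)⁻¹Zᵀ.

    Applies by solving the K-dimensional normal equations (via a thin QR of
    Z), so cost is O(NK) per vector and the N×N matrix is never formed.
    """

    def __init__(self, Z: np.ndarray | CovariateMatrix):
        if isinstance(Z, CovariateMatrix):
            Z = Z.values
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        n, k = Z.shape
        q, r = np.linalg.qr(Z)
        rank = int(np.sum(np.abs(np.diag(r)) > np.abs(r).max() * n * np.finfo(float).eps))
        if rank < k:
            dep = list(np.argsort(np.abs(np.diag(r)))[: k - rank])
            raise ValueError(f"covariate matrix is rank deficient; dependent "
                             f"column index(es): {sorted(int(i) for i in dep)}")
        self.Z = Z
        self._q = q

    @property
    def n_covariates(self) -> int:
        return self.Z.shape[1]

    def apply(self, mat: np.ndarray) -> np.ndarray:
        """M_Z · mat for a vector or an N×m matrix."""
        mat = np.asarray(mat, dtype=float)
        vec = mat.ndim == 1
        cols = mat[:, None] if vec else mat
        out = cols - self._q @ (self._q.T @ cols)
        return out[:, 0] if vec else out

    def apply_right(self, mat: np.ndarray) -> np.ndarray:
        """mat · M_Z for an m×N matrix (M_Z is symmetric)."""
        return self.apply(np.asarray(mat, dtype=float).T).T

    __call__ = apply


def make_projector(Z: np.ndarray | CovariateMatrix) -> Projector:
    """Build the confounder projector M_Z from a full-column-rank Z."""
    return Projector(Z)


@dataclass
class ProjectedGRMPair:
    """In-sample GRM A* (N×N) and cross GRM A21* (N2×N), with provenance."""

    A_star: np.ndarray
    A21_star: np.ndarray | None
    P_used: int
    weighted: bool = False
    projected: bool = False

    def __post_init__(self) -> None:
        a = np.asarray(self.A_star, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("A_star must be square")
        asym = np.abs(a - a.T).max()
        if asym > 1e-10 * max(1.0, np.abs(a).max()):
            raise ValueError(f"A_star asymmetric beyond tolerance ({asym:g})")
        self.A_star = (a + a.T) / 2.0


def build_grms(X: np.ndarray, X2: np.ndarray | None = None,
               weights: ShrinkWeights | None = None,
               projector: Projector | None = None,
               projector2: Projector | None = None) -> ProjectedGRMPair:
    """Genetic relationship matrices A = P⁻¹XXᵀ and A21 = P⁻¹X₂Xᵀ.

    ``weights`` (per-SNP penalties Λ) reweight columns by Λ^{-1/2} before the
    cross-products, so ridge on the weighted GRM solves the heteroskedastic
    problem. ``projector`` (training Z) and ``projector2`` (test Z₂) apply
    A* = M_Z A M_Z and A21* = M_Z₂ A21 M_Z.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if X2 is not None:
        X2 = np.asarray(X2, dtype=float)
        if X2.shape[1] != p:
            raise ValueError(f"X and X2 disagree on SNP count ({p} vs {X2.shape[1]})")
    if weights is not None:
        if weights.lambda_p.size != p:
            raise ValueError("weights length must equal SNP count")
        w = weights.column_scaling()
        X = X * w
        X2 = None if X2 is None else X2 * w
    if projector is not None:
        X = projector.apply(X)
    if projector2 is not None and X2 is not None:
        X2 = projector2.apply(X2)
    A = (X @ X.T) / p
    A21 = None if X2 is None else (X2 @ X.T) / p
    return ProjectedGRMPair((A + A.T) / 2.0, A21, p,
                            weighted=weights is not None,
                            projected=projector is not None)


@dataclass
class EigenGRM:
    """Eigenpairs of A*: A* = Q Θ Qᵀ with θ descending and clipped at zero."""

    Q: np.ndarray
    theta: np.ndarray


def eigendecompose(A_star: np.ndarray | ProjectedGRMPair) -> EigenGRM:
    """Full symmetric eigendecomposition of a (projected) GRM.

    The GRM is positive semidefinite in exact arithmetic; eigenvalues below
    -1e-8·θ_max indicate a malformed input and are rejected, while small
    negative round-off is clipped to zero.
    """
    if isinstance(A_star, ProjectedGRMPair):
        A_star = A_star.A_star
    a = np.asarray(A_star, dtype=float)
    if np.isnan(a).any():
        raise ValueError("GRM contains NaN entries")
    asym = np.abs(a - a.T).max()
    if asym > 1e-6:
        raise ValueError(f"GRM asymmetric beyond 1e-6 (max deviation {asym:g})")
    theta, q = scipy.linalg.eigh((a + a.T) / 2.0)
    theta, q = theta[::-1], q[:, ::-1]
    tmax = max(theta[0], 0.0)
    if theta[-1] < -1e-8 * max(tmax, 1.0):
        raise ValueError(f"GRM is not positive semidefinite "
                         f"(eigenvalue {theta[-1]:g})")
    theta = np.clip(theta, 0.0, None)
    theta[theta < a.shape[0] * np.finfo(float).eps * tmax] = 0.0
    return EigenGRM(q, theta)
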