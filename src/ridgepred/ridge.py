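"""Ridge regression for polygenic prediction: primal, dual, and multi-λ paths.

For a trait y (N×1), standardized dosages X (N×P), and confounders Z, the
penalized problem min ‖y - Xβ - Zγ‖² + λ βᵀΛβ has the closed form

    β̂ = (Xᵀ M_Z X + λΛ)⁻¹ Xᵀ M_Z y,

solvable for any λ > 0 even when P ≫ N. Writing X* = M_Z X Λ^{-1/2}, the
Woodbury identity turns the P×P solve into the N×N dual form

    ŷ₂ = A21* (A* + λ_GRM I)⁻¹ y,        λ_GRM = λ / P,

where A* = P⁻¹X*X*ᵀ is the genetic relationship matrix (GRM) and A21* its
test-vs-training counterpart. One eigendecomposition A* = QΘQᵀ then prices a
whole grid of penalties at once:

    Ŷ₂ = A21* Q [ (θ_i + λ_ℓ)⁻¹ ]∘(Qᵀy ιᵀ),

one column per λ_ℓ. When N > P the same trick runs on the P×P matrix XᵀM_Z X
instead. The classical GWAS score — one simple regression per SNP, summed —
is the λ→∞ limit of ridge up to scale and is provided as :func:`rsr_score`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .io_formats import SummaryStats
from .preprocess import (EigenGRM, ProjectedGRMPair, Projector, ShrinkWeights,
                         eigendecompose)

__all__ = [
    "LambdaGrid",
    "RidgeFit",
    "RidgePredictionSet",
    "default_lambda_grid",
    "rr_primal",
    "rr_dual_predict",
    "ridge_predict",
    "rsr_score",
    "hrr_from_tstats",
    "squared_correlation",
]


def squared_correlation(yhat: np.ndarray, y: np.ndarray) -> float:
    """Accuracy R²: squared Pearson correlation between score and outcome.

    Scale- and shift-invariant, so it compares ridge and GWAS-sum scores on
    equal footing. A zero-variance score (or outcome) defines R² = 0.
    """
    yhat = np.asarray(yhat, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    vh = yhat - yhat.mean()
    vy = y - y.mean()
    denom = np.sqrt((vh ** 2).sum() * (vy ** 2).sum())
    if denom == 0:
        return 0.0
    return float((vh @ vy) ** 2 / denom ** 2)

T_STAT_FLOOR = 1e-3


@dataclass
class LambdaGrid:
    """A strictly increasing grid of positive penalties.

    ``scale`` records whether the values multiply βᵀΛβ directly (``raw``) or
    apply to the GRM system (``grm``, i.e. divided by the SNP count P).
    """

    values: np.ndarray
    scale: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size < 1:
            raise ValueError("lambda grid must contain at least one value")
        if (self.values <= 0).any():
            raise ValueError("lambda grid values must be strictly positive")
        if (np.diff(self.values) <= 0).any():
            raise ValueError("lambda grid must be strictly increasing")
        if self.scale not in ("raw", "grm"):
            raise ValueError(f"unknown lambda scale {self.scale!r}")

    def __len__(self) -> int:
        return self.values.size

    def on_scale(self, scale: str, n_snps: int) -> "LambdaGrid":
        if scale == self.scale:
            return self
        if scale == "grm":
            return LambdaGrid(self.values / n_snps, "grm")
        return LambdaGrid(self.values * n_snps, "raw")


def default_lambda_grid() -> LambdaGrid:
    """151 log-uniform penalties on [1e-6, 1e9] (10 points per decade)."""
    return LambdaGrid(np.logspace(-6.0, 9.0, 151), "raw")


@dataclass
class RidgeFit:
    """A fitted ridge model at a single penalty."""

    lam: float
    beta_hat: np.ndarray
    gamma_hat: np.ndarray | None = None
    weights: ShrinkWeights | None = None

    def predict(self, X2: np.ndarray, Z2: np.ndarray | None = None) -> np.ndarray:
        yhat = np.asarray(X2, dtype=float) @ self.beta_hat
        if Z2 is not None and self.gamma_hat is not None:
            yhat = yhat + np.asarray(Z2, dtype=float) @ self.gamma_hat
        return yhat


@dataclass
class RidgePredictionSet:
    """Out-of-sample predictions, one column per penalty on a grid."""

    yhat2: np.ndarray            # N2 × L
    lambda_grid: LambdaGrid
    P_used: int | None = None
    projected: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.yhat2 = np.atleast_2d(np.asarray(self.yhat2, dtype=float))
        if not np.isfinite(self.yhat2).all():
            raise ValueError("predictions contain non-finite values")
        if self.yhat2.shape[1] != len(self.lambda_grid):
            raise ValueError("prediction columns must match the lambda grid")


def rr_primal(X: np.ndarray, y: np.ndarray, lam: float,
              Z: np.ndarray | None = None,
              weights: ShrinkWeights | None = None) -> RidgeFit:
    """Solve the P×P normal equations β̂ = (XᵀM_Z X + λΛ)⁻¹XᵀM_Z y.

    λ = 0 is permitted only when XᵀM_Z X is full rank (the OLS limit);
    otherwise the system is singular and a positive λ is required.
    Confounder effects γ̂ are recovered post hoc by OLS of y - Xβ̂ on Z.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    proj = Projector(Z) if Z is not None else None
    Xs = proj.apply(X) if proj is not None else X
    ys = proj.apply(y) if proj is not None else y
    gram = X.T @ Xs
    rhs = X.T @ ys
    if weights is not None:
        penalty = lam * weights.lambda_p
    else:
        penalty = np.full(p, lam)
    system = gram + np.diag(penalty)
    if lam == 0:
        if np.linalg.matrix_rank(gram) < p:
            raise np.linalg.LinAlgError(
                "XᵀM_ZX is singular at λ=0 (P > N or collinear SNPs); "
                "ridge requires λ > 0 here")
        beta = np.linalg.solve(system, rhs)
    else:
        beta = scipy.linalg.solve(system, rhs, assume_a="pos")
    gamma = None
    if Z is not None:
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        gamma, *_ = np.linalg.lstsq(Z, y - X @ beta, rcond=None)
    return RidgeFit(lam, beta, gamma, weights)


def _multi_lambda(A21: np.ndarray, Q: np.ndarray, theta: np.ndarray,
                  y: np.ndarray, lambdas: np.ndarray) -> np.ndarray:
    """Ŷ₂ = A21 Q [(θ_i+λ_ℓ)⁻¹ ∘ (Qᵀy ιᵀ)] for all λ jointly."""
    denom = theta[:, None] + lambdas[None, :]
    if (denom == 0).any():
        raise np.linalg.LinAlgError("θ_min + λ = 0: singular ridge system")
    W = (Q.T @ y)[:, None] / denom
    return (A21 @ Q) @ W


def rr_dual_predict(grms: ProjectedGRMPair | EigenGRM, y: np.ndarray,
                    lambda_grid: LambdaGrid,
                    A21_star: np.ndarray | None = None,
                    eig: EigenGRM | None = None) -> RidgePredictionSet:
    """Dual-form multi-λ prediction from GRMs (or a cached eigendecomposition).

    ``lambda_grid`` must be on the ``grm`` scale (λ_GRM = λ/P). The y passed
    in is the raw outcome: any confounder correction is already carried by
    the M_Z factors inside A* and A21*, and the component of y lying in
    col(Z) is annihilated by them.
    """
    if lambda_grid.scale != "grm":
        raise ValueError("rr_dual_predict expects a grid on the 'grm' scale; "
                         "use LambdaGrid.on_scale('grm', P)")
    y = np.asarray(y, dtype=float).ravel()
    if isinstance(grms, EigenGRM):
        if A21_star is None:
            raise ValueError("A21_star is required when passing an EigenGRM")
        eig, p_used, projected = grms, None, False
    else:
        if A21_star is None:
            A21_star = grms.A21_star
        if A21_star is None:
            raise ValueError("no out-of-sample GRM (A21*) available")
        if eig is None:
            eig = eigendecompose(grms)
        p_used, projected = grms.P_used, grms.projected
    yhat2 = _multi_lambda(np.asarray(A21_star, dtype=float), eig.Q, eig.theta,
                          y, lambda_grid.values)
    return RidgePredictionSet(yhat2, lambda_grid, P_used=p_used,
                              projected=projected)


def ridge_predict(X: np.ndarray, X2: np.ndarray, y: np.ndarray,
                  lambda_grid: LambdaGrid,
                  Z: np.ndarray | None = None, Z2: np.ndarray | None = None,
                  weights: ShrinkWeights | None = None) -> RidgePredictionSet:
    """Multi-λ out-of-sample ridge prediction with automatic path choice.

    Uses the N×N dual (GRM) eigendecomposition when N ≤ P, and the P×P
    eigendecomposition of XᵀM_Z X when N > P. The grid may be on either
    scale; output is returned with the grid as given.
    """
    X = np.asarray(X, dtype=float)
    X2 = np.asarray(X2, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    proj = Projector(Z) if Z is not None else None
    proj2 = Projector(Z2) if Z2 is not None else None
    if n <= p:
        from .preprocess import build_grms
        grms = build_grms(X, X2, weights=weights, projector=proj,
                          projector2=proj2)
        grid_grm = lambda_grid.on_scale("grm", p)
        preds = rr_dual_predict(grms, y, grid_grm)
        return RidgePredictionSet(preds.yhat2, lambda_grid, P_used=p,
                                  projected=proj is not None)
    # primal path: eigendecompose the P×P cross-product instead
    if weights is not None:
        w = weights.column_scaling()
        X = X * w
        X2 = X2 * w
    if proj is not None:
        X = proj.apply(X)
    if proj2 is not None:
        X2 = proj2.apply(X2)
    gram = X.T @ X
    s, v = scipy.linalg.eigh((gram + gram.T) / 2.0)
    s = np.clip(s[::-1], 0.0, None)
    v = v[:, ::-1]
    grid_raw = lambda_grid.on_scale("raw", p)
    # β(λ) = V (S+λ)⁻¹ Vᵀ Xᵀy ; Ŷ₂ = (X₂V) [(s_j+λ_ℓ)⁻¹ ∘ (VᵀXᵀy ιᵀ)]
    vxy = v.T @ (X.T @ y)
    denom = s[:, None] + grid_raw.values[None, :]
    if (denom == 0).any():
        raise np.linalg.LinAlgError("singular ridge system at λ=0")
    yhat2 = (X2 @ v) @ (vxy[:, None] / denom)
    return RidgePredictionSet(yhat2, lambda_grid, P_used=p,
                              projected=proj is not None)


def rsr_score(X: np.ndarray, X2: np.ndarray, y: np.ndarray,
              Z: np.ndarray | None = None,
              Z2: np.ndarray | None = None) -> np.ndarray:
    """Classical GWAS polygenic score: one simple regression per SNP, summed.

    With standardized SNPs the per-SNP estimate is β̂_p = x_pᵀy up to a
    common factor, so the score is ŷ₂ = X₂Xᵀy. The score is defined only up
    to positive scale and must be consumed through scale-invariant accuracy
    measures (squared correlation). When confounders are supplied, X, X₂,
    and y are projected first so the comparison with ridge is like-for-like.
    """
    X = np.asarray(X, dtype=float)
    X2 = np.asarray(X2, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    norms = np.sqrt((X ** 2).sum(axis=0))
    if norms.max() - norms.min() > 1e-6 * max(norms.max(), 1.0):
        raise ValueError("rsr_score requires standardized SNPs "
                         "(unequal column norms detected)")
    if Z is not None:
        proj = Projector(Z)
        X = proj.apply(X)
        y = proj.apply(y)
    if Z2 is not None:
        X2 = Projector(Z2).apply(X2)
    return X2 @ (X.T @ y)


def hrr_from_tstats(stats: SummaryStats | np.ndarray,
                    floor: float = T_STAT_FLOOR) -> ShrinkWeights:
    """Per-SNP penalties λ_p = t_p⁻² from external GWAS t statistics.

    Squared t statistics are proportional to a consistent estimate of the
    per-SNP effect variance, so their inverse is the natural heteroskedastic
    penalty; equivalently, SNP p is scaled by |t_p| before building the
    weighted GRM. |t| below ``floor`` is floored to keep penalties finite;
    the number of floored SNPs is reported via a warning.
    """
    t = stats.t_stats if isinstance(stats, SummaryStats) else np.asarray(stats, dtype=float)
    at = np.abs(t)
    n_floored = int((at < floor).sum())
    if n_floored:
        warnings.warn(f"{n_floored} SNP(s) with |t| < {floor:g} floored",
                      stacklevel=2)
    at = np.maximum(at, floor)
    return ShrinkWeights(at ** -2.0)
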