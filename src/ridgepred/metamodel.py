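"""Linear meta-models explaining simulation accuracy from log-factors.

The simulation metrics (log accuracy ratio, logit relative accuracy) are
regressed on log N, log P, log C, log f_C, and log h², with interaction
terms up to three-way, and the interaction order is selected by the Bayes
information criterion. Because log C = log f_C + log P exactly, the design
is rank deficient by construction; fitting uses minimum-norm least squares
and the BIC penalty counts the numerical rank, not the raw column count.
The selected model extrapolates the accuracy measures to larger studies
with mean-prediction confidence intervals.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

__all__ = ["MetaDesign", "MetaFit", "build_design", "fit_bic",
           "model_comparison", "predict_ci"]

BASE_REGRESSORS = ("log_N", "log_P", "log_C", "log_fC", "log_h2")
_SOURCE = {"log_N": "N", "log_P": "P", "log_C": "C", "log_fC": "fC",
           "log_h2": "h2"}


def _monomials(order: int, include_squares: bool) -> list[tuple[str, ...]]:
    terms: list[tuple[str, ...]] = []
    for k in range(1, order + 1):
        combo = (itertools.combinations_with_replacement if include_squares
                 else itertools.combinations)
        terms.extend(combo(BASE_REGRESSORS, k))
    return terms


@dataclass
class MetaDesign:
    """A design matrix of log-factor products up to a given interaction order."""

    matrix: np.ndarray
    column_names: list[str]
    order: int
    include_squares: bool = False
    factor_ranges: dict = field(default_factory=dict)

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]


def _log_factors(table: pd.DataFrame) -> pd.DataFrame:
    cols = {}
    for name, src in _SOURCE.items():
        if src == "C" and "C" not in table:
            cols[name] = np.log(table["fC"].to_numpy(dtype=float)
                                * table["P"].to_numpy(dtype=float))
        else:
            cols[name] = np.log(table[src].to_numpy(dtype=float))
    return pd.DataFrame(cols, index=table.index)


def build_design(table: pd.DataFrame, order: int,
                 include_squares: bool = False) -> MetaDesign:
    """Design of all products of the log-factors up to ``order``.

    ``order`` 0 is intercept-only; 1 adds the five base regressors; 2 and 3
    add the distinct-factor interactions (with pure powers too when
    ``include_squares`` is set, since the published column counts suggest
    squared terms were present but their exact construction is not
    recoverable).
    """
    if order not in (0, 1, 2, 3):
        raise ValueError("interaction order must be 0, 1, 2 or 3")
    if table.empty:
        raise ValueError("empty table")
    logs = _log_factors(table)
    cols = [np.ones(len(table))]
    names = ["intercept"]
    for term in _monomials(order, include_squares):
        cols.append(np.prod([logs[t].to_numpy() for t in term], axis=0))
        names.append("*".join(term))
    ranges = {name: (float(logs[name].min()), float(logs[name].max()))
              for name in BASE_REGRESSORS}
    return MetaDesign(np.column_stack(cols), names, order, include_squares,
                      ranges)


@dataclass
class MetaFit:
    """A fitted meta-model: minimum-norm coefficients plus fit diagnostics."""

    design: MetaDesign
    coefficients: np.ndarray
    rss: float
    r2_model: float
    bic: float
    n_obs: int
    rank: int
    sigma2: float
    xtx_pinv: np.ndarray

    @property
    def order(self) -> int:
        return self.design.order


def _fit_one(y: np.ndarray, design: MetaDesign) -> MetaFit:
    X = design.matrix
    n = len(y)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    if rss <= 1e-12 * max(tss, 1.0):  # numerically perfect fit
        warnings.warn("RSS = 0: BIC reported as -inf", stacklevel=3)
        bic = -np.inf
    else:
        bic = n * np.log(rss / n) + rank * np.log(n)
    dof = max(n - rank, 1)
    sigma2 = rss / dof
    xtx_pinv = np.linalg.pinv(X.T @ X)
    return MetaFit(design, beta, rss, r2, float(bic), n, int(rank), sigma2,
                   xtx_pinv)


def fit_bic(y: np.ndarray, designs: list[MetaDesign]) -> tuple[MetaFit, list[MetaFit]]:
    """Fit every candidate design and return (BIC-best, all fits).

    Gaussian BIC = n·ln(RSS/n) + k·ln(n) with k the numerical rank of the
    design. The first design attaining the minimum wins, so duplicated
    candidates keep the earlier one.
    """
    if len(designs) < 2:
        raise ValueError("need at least two candidate designs")
    y = np.asarray(y, dtype=float).ravel()
    fits = [_fit_one(y, d) for d in designs]
    best = int(np.argmin([f.bic for f in fits]))
    return fits[best], fits


def model_comparison(fits: list[MetaFit]) -> pd.DataFrame:
    """One row per candidate: order, columns, rank, R², BIC."""
    return pd.DataFrame([{"order": f.order, "n_columns": f.design.n_columns,
                          "rank": f.rank, "n_obs": f.n_obs,
                          "R2_model": f.r2_model, "BIC": f.bic}
                         for f in fits])


def predict_ci(fit: MetaFit, new_table: pd.DataFrame, level: float = 0.95,
               response: str | None = None) -> pd.DataFrame:
    """Point predictions with mean-prediction confidence intervals.

    The interval is xᵀβ̂ ± t_{df} · sqrt(σ̂² xᵀ(XᵀX)⁺x). Rows whose factors
    fall more than 10× (on the log scale) outside the fitted range are
    flagged ``extrapolated``. When ``response`` is ``"log_ratio"`` or
    ``"logit_rel"``, monotone back-transforms of the endpoints are appended
    (exp, giving the accuracy ratio; inverse logit, giving R²/h²).
    """
    if not 0 <= level < 1:
        raise ValueError("confidence level must lie in [0, 1)")
    new_design = build_design(new_table, fit.design.order,
                              fit.design.include_squares)
    Xn = new_design.matrix
    point = Xn @ fit.coefficients
    se = np.sqrt(np.maximum(fit.sigma2 * np.einsum(
        "ij,jk,ik->i", Xn, fit.xtx_pinv, Xn), 0.0))
    if level == 0:
        half = np.zeros_like(se)
    else:
        tq = scipy.stats.t.ppf(0.5 + level / 2.0, df=max(fit.n_obs - fit.rank, 1))
        half = tq * se

    logs = _log_factors(new_table)
    extrapolated = np.zeros(len(new_table), dtype=bool)
    for name, (lo, hi) in fit.design.factor_ranges.items():
        width = np.log(10.0)
        vals = logs[name].to_numpy()
        extrapolated |= (vals < lo - width) | (vals > hi + width)
    if extrapolated.any():
        warnings.warn(f"{int(extrapolated.sum())} prediction row(s) lie far "
                      "outside the fitted factor range", stacklevel=2)

    out = pd.DataFrame({"predicted": point, "ci_low": point - half,
                        "ci_high": point + half, "extrapolated": extrapolated},
                       index=new_table.index)
    if response == "log_ratio":
        for col in ("predicted", "ci_low", "ci_high"):
            out[f"ratio_{col}"] = np.exp(out[col])
    elif response == "logit_rel":
        from scipy.special import expit
        for col in ("predicted", "ci_low", "ci_high"):
            out[f"rel_{col}"] = expit(out[col])
    return out
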