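"""The ridge-vs-GWAS factorial experiment and its summary tables.

For every (run, N, P, f_C, h²) cell the study computes the out-of-sample
accuracy (squared correlation with the trait) of

* the classical GWAS sum score (repeated simple regression, RSR), and
* ridge regression over a whole penalty grid at once.

Per (run, N, P) a single eigendecomposition is computed — of the N×N GRM
when N ≤ P, of the P×P cross-product otherwise — and reused for every
(f_C, h²) cell and every λ. The ridge penalty is then tuned per cell by the
median-over-runs rule: λ̂ maximizes the median over runs of R²_RR(λ), a
CV-like choice that needs no refitting.

Derived metrics follow the study's conventions: the relative-performance
measure log(R²_RR/R²_RSR) (records outside (-1, +1) flagged as outliers)
and the absolute measure logit(R²_RSR/h²) (records with R²_RSR ≥ h² flagged
as uninformative).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.linalg

from .ridge import LambdaGrid, default_lambda_grid
from .simulate import SimConfig, SimulatedCohort, simulate_cohort, split_train_test

__all__ = ["ScenarioResultTable", "run_scenario", "run_study",
           "select_lambda_median", "compute_metrics", "summarize"]

CELL_KEYS = ["N", "P", "fC", "h2"]


@dataclass
class ScenarioResultTable:
    """Per-(run, N, P, f_C, h²) accuracies plus the full ridge λ curves.

    ``records`` has one row per key with the RSR accuracy; ``r2_rr`` holds
    the aligned ridge accuracy curves (rows match ``records``, columns match
    ``lambda_grid``).
    """

    records: pd.DataFrame
    r2_rr: np.ndarray
    lambda_grid: LambdaGrid

    def __post_init__(self) -> None:
        if len(self.records) != self.r2_rr.shape[0]:
            raise ValueError("records and r2_rr row counts disagree")
        if self.r2_rr.shape[1] != len(self.lambda_grid):
            raise ValueError("r2_rr columns must match the lambda grid")


def _columnwise_r2(preds: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation of each prediction column with y."""
    pc = preds - preds.mean(axis=0)
    yc = y - y.mean()
    num = pc.T @ yc
    denom2 = (pc ** 2).sum(axis=0) * (yc ** 2).sum()
    out = np.zeros(preds.shape[1])
    ok = denom2 > 0
    out[ok] = num[ok] ** 2 / denom2[ok]
    return out


class _SlicePredictor:
    """Caches the one eigendecomposition shared by all cells of an (N, P) slice."""

    def __init__(self, Xtr: np.ndarray, Xte: np.ndarray, lambdas_raw: np.ndarray):
        n, p = Xtr.shape
        self.lambdas_raw = np.asarray(lambdas_raw, dtype=float)
        if n <= p:
            A = Xtr @ Xtr.T / p
            theta, Q = scipy.linalg.eigh((A + A.T) / 2.0)
            self._theta = np.clip(theta, 0.0, None)
            self._left = (Xte @ Xtr.T / p) @ Q       # A21 Q
            self._QT = Q.T
            self._denoms = self._theta[:, None] + self.lambdas_raw[None, :] / p
        else:
            gram = Xtr.T @ Xtr
            s, V = scipy.linalg.eigh((gram + gram.T) / 2.0)
            self._theta = np.clip(s, 0.0, None)
            self._left = Xte @ V
            self._QT = (Xtr @ V).T                   # VᵀXtrᵀ
            self._denoms = self._theta[:, None] + self.lambdas_raw[None, :]

    def predict(self, ytr: np.ndarray) -> np.ndarray:
        """Ridge test-set predictions for every λ on the grid at once."""
        return self._left @ ((self._QT @ ytr)[:, None] / self._denoms)


def run_scenario(cohort: SimulatedCohort, N: int, P: int, fC: float, h2: float,
                 lambda_grid: LambdaGrid | None = None) -> tuple[float, np.ndarray]:
    """Accuracies for one cell of one run: (R²_RSR, R²_RR per λ).

    Convenience wrapper over the slice machinery; :func:`run_study` amortizes
    the eigendecomposition across cells instead of calling this per cell.
    """
    lambda_grid = lambda_grid or default_lambda_grid()
    cfg = cohort.config
    iP = cfg.P_list.index(P)
    iF = cfg.fC_list.index(fC)
    iH = cfg.h2_list.index(h2)
    train, test = split_train_test(N, cohort.X.shape[0])
    Xtr, Xte = cohort.X[train, :P], cohort.X[test, :P]
    y = cohort.phenotypes[:, iP, iF, iH]
    pred = _SlicePredictor(Xtr, Xte, lambda_grid.on_scale("raw", P).values)
    r2_rr = _columnwise_r2(pred.predict(y[train]), y[test])
    rsr = Xte @ (Xtr.T @ y[train])
    r2_rsr = _columnwise_r2(rsr[:, None], y[test])[0]
    return float(r2_rsr), r2_rr


def run_study(config: SimConfig, lambda_grid: LambdaGrid | None = None,
              checkpoint_dir=None, progress=None) -> ScenarioResultTable:
    """Run the full factorial study: runs → (N, P) slices → (f_C, h²) cells.

    One cohort is simulated per run (genotypes reused across every scenario),
    one eigendecomposition is computed per (run, N, P), and the whole λ grid
    is evaluated jointly. ``checkpoint_dir`` stores one ``.npz`` per run so
    an interrupted study resumes where it stopped.
    """
    lambda_grid = lambda_grid or default_lambda_grid()
    lambdas_raw = lambda_grid.on_scale("raw", 1).values if lambda_grid.scale == "raw" \
        else None
    if lambdas_raw is None:
        raise ValueError("run_study expects the grid on the raw scale")
    ckpt = Path(checkpoint_dir) if checkpoint_dir else None
    if ckpt:
        ckpt.mkdir(parents=True, exist_ok=True)

    rows: list[tuple] = []
    curves: list[np.ndarray] = []
    run_seeds = config.run_seeds()
    for r, run_seed in enumerate(run_seeds):
        ck = ckpt / f"run{r:03d}.npz" if ckpt else None
        if ck and ck.exists():
            data = np.load(ck, allow_pickle=False)
            rows.extend(map(tuple, data["rows"]))
            curves.extend(data["curves"])
            continue
        cohort = simulate_cohort(config, run_seed)
        run_rows: list[tuple] = []
        run_curves: list[np.ndarray] = []
        for N in config.N_list:
            train, test = split_train_test(N, cohort.X.shape[0])
            for iP, P in enumerate(config.P_list):
                Xtr = cohort.X[train, :P]
                Xte = cohort.X[test, :P]
                pred = _SlicePredictor(Xtr, Xte, lambdas_raw)
                rsr_weights_base = Xtr.T  # reused below per phenotype
                for iF, fC in enumerate(config.fC_list):
                    for iH, h2 in enumerate(config.h2_list):
                        y = cohort.phenotypes[:, iP, iF, iH]
                        ytr, yte = y[train], y[test]
                        r2_rr = _columnwise_r2(pred.predict(ytr), yte)
                        rsr = Xte @ (rsr_weights_base @ ytr)
                        r2_rsr = _columnwise_r2(rsr[:, None], yte)[0]
                        run_rows.append((r, N, P, fC, h2,
                                         int(cohort.causal_counts[iP, iF]),
                                         float(r2_rsr)))
                        run_curves.append(r2_rr)
                if progress:
                    progress(r, N, P)
        if ck:
            np.savez_compressed(ck, rows=np.array(run_rows, dtype=float),
                                curves=np.array(run_curves))
        rows.extend(run_rows)
        curves.extend(run_curves)

    records = pd.DataFrame(rows, columns=["run", "N", "P", "fC", "h2", "C",
                                          "R2_RSR"])
    for col in ("run", "N", "P", "C"):
        records[col] = records[col].astype(int)
    return ScenarioResultTable(records, np.asarray(curves), lambda_grid)


def select_lambda_median(table: ScenarioResultTable) -> pd.DataFrame:
    """Tune λ per (N, P, f_C, h²) cell by the median-over-runs rule.

    λ̂ = argmax over the grid of median_r R²_RR(λ, r); ties break toward the
    smallest λ. Returns the records with ``lambda_hat`` and the per-run
    ``R2_RR`` at λ̂ appended.
    """
    records = table.records.copy()
    r2_rr = table.r2_rr
    lambdas = table.lambda_grid.values
    records["lambda_hat"] = np.nan
    records["R2_RR"] = np.nan
    for _, idx in records.groupby(CELL_KEYS).groups.items():
        idx = np.asarray(idx)
        med = np.median(r2_rr[idx], axis=0)
        best = int(np.argmax(med))        # first max → smallest λ
        records.loc[idx, "lambda_hat"] = lambdas[best]
        records.loc[idx, "R2_RR"] = r2_rr[idx, best]
    return records


def compute_metrics(records: pd.DataFrame) -> pd.DataFrame:
    """Append the relative and absolute accuracy measures and outlier flags.

    ``log_ratio`` = log(R²_RR/R²_RSR); ``logit_rel`` = logit(R²_RSR/h²).
    Records where either R² is 0 get non-finite values and are flagged via
    ``flag_nonfinite`` (excluded from ratio summaries); ``flag_logratio``
    marks log-ratios outside (-1, +1) and ``flag_rsr_ge_h2`` marks records
    with R²_RSR ≥ h² (scores "explaining" more genetic variance than
    exists).
    """
    out = records.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        out["log_ratio"] = np.log(out["R2_RR"] / out["R2_RSR"])
        rel = out["R2_RSR"] / out["h2"]
        out["logit_rel"] = np.log(rel / (1.0 - rel))
    out["flag_nonfinite"] = ~np.isfinite(out["log_ratio"])
    out["flag_logratio"] = out["flag_nonfinite"] | (out["log_ratio"] <= -1) \
        | (out["log_ratio"] >= 1)
    out["flag_rsr_ge_h2"] = out["R2_RSR"] >= out["h2"]
    return out


def _summary_row(x: pd.Series, total: int, outcome: str, restriction: str) -> dict:
    x = x[np.isfinite(x)]
    return {
        "outcome": outcome,
        "restriction": restriction,
        "count": int(len(x)),
        "pct_total": 100.0 * len(x) / total,
        "mean": float(x.mean()),
        "var": float(x.var(ddof=1)) if len(x) > 1 else np.nan,
        "min": float(x.min()),
        "max": float(x.max()),
    }


def summarize(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summary tables: overall metric statistics and per-cell medians.

    The first table gives count/%/mean/variance/min/max of the log-ratio
    (all records, then restricted to (-1, +1)) and of R²_RSR (all records,
    then excluding R²_RSR ≥ h²). The second gives, per cell, the median
    R²_RSR and the ratio of the median R²_RR to it.
    """
    if records.empty:
        raise ValueError("empty result table")
    total = len(records)
    lr = records["log_ratio"]
    overall = pd.DataFrame([
        _summary_row(lr, total, "log_ratio", "none"),
        _summary_row(lr[~records["flag_logratio"]], total, "log_ratio",
                     "in(-1,+1)"),
        _summary_row(records["R2_RSR"], total, "R2_RSR", "none"),
        _summary_row(records.loc[~records["flag_rsr_ge_h2"], "R2_RSR"], total,
                     "R2_RSR", "R2<h2"),
    ])
    per_cell = (records.groupby(CELL_KEYS)
                .agg(median_R2_RSR=("R2_RSR", "median"),
                     median_R2_RR=("R2_RR", "median"),
                     lambda_hat=("lambda_hat", "first"),
                     n_runs=("run", "size"))
                .reset_index())
    with np.errstate(divide="ignore", invalid="ignore"):
        per_cell["median_ratio"] = (per_cell["median_R2_RR"]
                                    / per_cell["median_R2_RSR"])
    return overall, per_cell
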