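"""Penalized least-squares estimation of fixed-time and scaled-time waveforms.

Solves ``min ||X b - y||^2 + lambda ||L b||^2`` per channel from the normal
equations ``(X'X + lambda L'L) b = X'y``, where ``L`` is a half-scaled first
difference restricted to run within component blocks.  ``lambda`` is chosen
by k-fold cross-validation on a single target channel.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse as sp

from .design import DesignMatrix

__all__ = [
    "DEFAULT_LAMBDA_GRID",
    "PenaltyOperator",
    "RerpEstimate",
    "CvReport",
    "ModelComparison",
    "make_first_derivative_operator",
    "solve",
    "cross_validate_lambda",
    "fixed_active_rows",
    "compare_models",
]

logger = logging.getLogger(__name__)

#: candidate regularization weights tried on every CV fold
DEFAULT_LAMBDA_GRID = (0.001, 0.01, 0.0, 1.0, 10.0, 100.0, 1000.0, 10_000.0, 100_000.0)


@dataclass
class PenaltyOperator:
    """Half-scaled first-difference operator confined within blocks."""

    L: sp.csr_matrix
    lam: float = 0.0
    block_boundaries: tuple[int, ...] = (0,)

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")

    def with_lambda(self, lam: float) -> "PenaltyOperator":
        return PenaltyOperator(self.L, lam, self.block_boundaries)

    @property
    def LtL(self) -> sp.csr_matrix:
        return (self.L.T @ self.L).tocsr()


def make_first_derivative_operator(
    p: int, block_boundaries=(0,), lam: float = 0.0
) -> PenaltyOperator:
    """Rows of the form 0.5*(e_j - e_{j+1}) within each block; no row straddles
    a block boundary.  Width-1 blocks contribute no rows."""
    if p < 2:
        raise ValueError("p must be >= 2")
    bounds = sorted(set(int(b) for b in block_boundaries) | {0})
    if any(b < 0 or b >= p for b in bounds):
        raise ValueError("block boundaries must lie in [0, p)")
    edges = bounds + [p]
    rows, cols, data = [], [], []
    r = 0
    for lo, hi in zip(edges[:-1], edges[1:]):
        for j in range(lo, hi - 1):
            rows += [r, r]
            cols += [j, j + 1]
            data += [0.5, -0.5]
            r += 1
    L = sp.coo_matrix((data, (rows, cols)), shape=(r, p)).tocsr()
    return PenaltyOperator(L=L, lam=lam, block_boundaries=tuple(bounds))


@dataclass
class RerpEstimate:
    """Fit result: ``beta`` is channels x predictors, partitioned by the
    column metadata into per-component waveforms."""

    beta: np.ndarray
    columns: pd.DataFrame
    fitted: np.ndarray
    residual: np.ndarray
    lambda_used: float
    row_index: np.ndarray | None = None

    def component_beta(self, component: str) -> np.ndarray:
        cols = np.flatnonzero((self.columns["component"] == component).to_numpy())
        return self.beta[:, cols]

    def fixed_waveform(self, component: str) -> tuple[np.ndarray, np.ndarray]:
        """(lags_ms, channels x lags waveform) for one fixed component."""
        sel = (self.columns["component"] == component).to_numpy()
        if not sel.any():
            raise KeyError(component)
        return (
            self.columns.loc[sel, "lag_ms"].to_numpy(dtype=float),
            self.beta[:, np.flatnonzero(sel)],
        )

    def scaled_waveform(self) -> tuple[np.ndarray, np.ndarray]:
        """(elapsed fractions, channels x points waveform) of the scaled block."""
        sel = (self.columns["component"] == "scaled").to_numpy()
        if not sel.any():
            raise KeyError("no scaled block in this design")
        return (
            self.columns.loc[sel, "elapsed_fraction"].to_numpy(dtype=float),
            self.beta[:, np.flatnonzero(sel)],
        )

    def waveform_table(self) -> pd.DataFrame:
        out = self.columns.copy()
        for c in range(self.beta.shape[0]):
            out[f"beta_ch{c}"] = self.beta[c]
        return out


def _normal_equations(X: sp.spmatrix, Y: np.ndarray):
    G = (X.T @ X).toarray()
    B = X.T @ Y.T  # p x channels
    return G, np.asarray(B)


def _solve_system(A: np.ndarray, B: np.ndarray, lam: float) -> np.ndarray:
    """Solve A beta = B; fall back to the pseudoinverse path (minimum-norm
    least squares) when the system is singular at lambda=0."""
    try:
        if lam > 0:
            return scipy.linalg.solve(A, B, assume_a="pos")
        c, low = scipy.linalg.cho_factor(A)
        return scipy.linalg.cho_solve((c, low), B)
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError):
        logger.warning(
            "normal equations singular (lambda=%g); using minimum-norm solution", lam
        )
        warnings.warn("rank-deficient design: returning minimum-norm solution")
        sol, *_ = np.linalg.lstsq(A, B, rcond=None)
        return sol


def solve(
    X: DesignMatrix | sp.spmatrix,
    Y: np.ndarray,
    penalty: PenaltyOperator,
    literal: bool = False,
) -> RerpEstimate:
    """Unique minimizer of ``||Xb - Y||^2 + lam ||Lb||^2`` per channel.

    ``literal=True`` reproduces, for audit, the variant normal equations
    ``(X'X + lam L0)`` where ``L0`` is the square zero-padded first-difference
    operator (dimensionally consistent reading of adding ``lam L`` itself);
    this is NOT the minimizer of the stated objective.
    """
    if isinstance(X, DesignMatrix):
        dm, Xs = X, X.X
        columns, row_index = X.columns, X.row_index
    else:
        Xs = X
        columns = pd.DataFrame({"component": ["?"] * Xs.shape[1],
                                "lag_ms": np.nan, "elapsed_fraction": np.nan})
        row_index = None
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[1] != Xs.shape[0]:
        raise ValueError(
            f"Y has {Y.shape[1]} samples but X has {Xs.shape[0]} rows"
        )
    if not np.all(np.isfinite(Y)):
        raise ValueError("Y contains non-finite values")
    lam = penalty.lam
    G, B = _normal_equations(Xs, Y)
    if lam > 0:
        if literal:
            # square zero-padded L: one difference row per column, last column
            # of each block left as a zero row
            p = Xs.shape[1]
            Lsq = np.zeros((p, p))
            edges = list(penalty.block_boundaries) + [p]
            for lo, hi in zip(edges[:-1], edges[1:]):
                for j in range(lo, hi - 1):
                    Lsq[j, j] = 0.5
                    Lsq[j, j + 1] = -0.5
            A = G + lam * Lsq
            beta = np.linalg.solve(A, B)
        else:
            A = G + lam * penalty.LtL.toarray()
            beta = _solve_system(A, B, lam)
    else:
        beta = _solve_system(G, B, lam)
    beta = beta.T  # channels x p
    fitted = (Xs @ beta.T).T
    residual = Y - fitted
    return RerpEstimate(
        beta=beta,
        columns=columns,
        fitted=fitted,
        residual=residual,
        lambda_used=lam,
        row_index=row_index,
    )


@dataclass
class CvReport:
    grid: tuple[float, ...]
    fold_mse: np.ndarray  # folds x grid, NaN where a fold was unusable
    chosen_lambda: float
    fold_assignment: np.ndarray  # fold id per retained sample

    @property
    def mean_mse(self) -> np.ndarray:
        return np.nanmean(self.fold_mse, axis=0)


def cross_validate_lambda(
    X: DesignMatrix | sp.spmatrix,
    y: np.ndarray,
    grid=DEFAULT_LAMBDA_GRID,
    k: int = 10,
    penalty: PenaltyOperator | None = None,
    scheme: str = "contiguous",
    seed: int | None = None,
) -> CvReport:
    """k-fold CV of lambda at one channel; folds are contiguous sample blocks
    by default (respecting temporal autocorrelation), ``scheme='random'`` for
    shuffled assignment.  Ties in mean MSE break toward the larger lambda."""
    if k < 2:
        raise ValueError("k must be >= 2")
    grid = tuple(grid)
    if not grid:
        raise ValueError("grid must be nonempty")
    Xs = X.X if isinstance(X, DesignMatrix) else X
    y = np.asarray(y, dtype=float).ravel()
    n, p = Xs.shape
    if y.size != n:
        raise ValueError("y length mismatch")
    if penalty is None:
        bounds = X.block_boundaries() if isinstance(X, DesignMatrix) else (0,)
        penalty = make_first_derivative_operator(p, bounds)
    LtL = penalty.LtL.toarray()

    fold_of = np.zeros(n, dtype=int)
    if scheme == "contiguous":
        for f, idx in enumerate(np.array_split(np.arange(n), k)):
            fold_of[idx] = f
    elif scheme == "random":
        rng = np.random.default_rng(seed)
        fold_of = rng.permutation(np.arange(n) % k)
    else:
        raise ValueError("scheme must be 'contiguous' or 'random'")

    G_full = (Xs.T @ Xs).toarray()
    b_full = np.asarray(Xs.T @ y).ravel()
    fold_mse = np.full((k, len(grid)), np.nan)
    for f in range(k):
        test = np.flatnonzero(fold_of == f)
        Xf = Xs[test]
        if Xf.nnz == 0:
            continue  # no active regressor rows held out: cell stays missing
        yf = y[test]
        Gf = (Xf.T @ Xf).toarray()
        bf = np.asarray(Xf.T @ yf).ravel()
        G_tr = G_full - Gf
        b_tr = b_full - bf
        for gi, lam in enumerate(grid):
            A = G_tr + lam * LtL if lam > 0 else G_tr
            beta = _solve_system(A, b_tr, lam)
            pred = Xf @ beta
            fold_mse[f, gi] = float(np.mean((yf - pred) ** 2))

    means = np.nanmean(fold_mse, axis=0)
    best = np.nanmin(means)
    candidates = [grid[i] for i in range(len(grid)) if means[i] == best]
    chosen = max(candidates)
    return CvReport(grid=grid, fold_mse=fold_mse, chosen_lambda=chosen,
                    fold_assignment=fold_of)


def fixed_active_rows(X: DesignMatrix) -> np.ndarray:
    """Boolean over retained rows: any fixed-block regressor nonzero there."""
    cols = X.fixed_columns()
    if cols.size == 0:
        raise ValueError("design has no fixed columns")
    sub = X.X[:, cols]
    return np.asarray(sub.getnnz(axis=1) > 0)


@dataclass
class ModelComparison:
    mse_full: float
    mse_fixed_only: float
    active_mask: np.ndarray

    @property
    def difference(self) -> float:
        return self.mse_full - self.mse_fixed_only


def compare_models(
    estimate_full: RerpEstimate,
    estimate_fixed_only: RerpEstimate,
    fixed_active_mask: np.ndarray,
) -> ModelComparison:
    """MSE of both models restricted to samples where fixed regressors are active."""
    mask = np.asarray(fixed_active_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty active mask")
    if estimate_full.residual.shape != estimate_fixed_only.residual.shape:
        raise ValueError("estimates were not fitted on identical rows")
    mse_full = float(np.mean(estimate_full.residual[:, mask] ** 2))
    mse_fixed = float(np.mean(estimate_fixed_only.residual[:, mask] ** 2))
    return ModelComparison(mse_full=mse_full, mse_fixed_only=mse_fixed,
                           active_mask=mask)
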