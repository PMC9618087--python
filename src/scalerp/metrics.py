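"""Method-validation quantities: VIF profiles, unmixed reconstructions, and
the scaling index."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .design import DesignMatrix, resize_box
from .solver import RerpEstimate

__all__ = [
    "VifProfile",
    "UnmixedDatasets",
    "ScalingIndexResult",
    "compute_vif",
    "reconstruct_unmixed",
    "scaling_index",
]

VIF_FLAG_LEVEL = 10.0  # conventional collinearity flag threshold


@dataclass
class VifProfile:
    vif: np.ndarray
    columns: pd.DataFrame

    @property
    def fraction_flagged(self) -> float:
        return float(np.mean(self.vif >= VIF_FLAG_LEVEL))

    def to_frame(self) -> pd.DataFrame:
        out = self.columns.copy()
        out["vif"] = self.vif
        return out


def compute_vif(X: DesignMatrix | sp.spmatrix | np.ndarray) -> VifProfile:
    """VIF_j = 1 / (1 - R^2_j) from regressing (centered) column j on all others.

    Computed from the centered Gram matrix, so the data pass is a single
    sparse product.  Constant columns and perfectly predictable columns
    (R^2 >= 1 - 1e-12) are reported as +inf rather than raising.
    """
    if isinstance(X, DesignMatrix):
        columns, Xs = X.columns, X.X
    else:
        Xs = X
        p_ = Xs.shape[1]
        columns = pd.DataFrame({"component": ["?"] * p_,
                                "lag_ms": np.nan, "elapsed_fraction": np.nan})
    n, p = Xs.shape
    if p < 2:
        raise ValueError("VIF needs at least 2 columns")
    if sp.issparse(Xs):
        m = np.asarray(Xs.mean(axis=0)).ravel()
        G = (Xs.T @ Xs).toarray()
    else:
        Xs = np.asarray(Xs, dtype=float)
        m = Xs.mean(axis=0)
        G = Xs.T @ Xs
    Gc = G - n * np.outer(m, m)  # centered cross-products
    var = np.diag(Gc).copy()
    good = var > 1e-12 * max(1.0, float(var.max()))

    vif = np.full(p, np.inf)
    if good.sum() >= 2:
        idx = np.flatnonzero(good)
        D = np.sqrt(var[idx])
        R = Gc[np.ix_(idx, idx)] / np.outer(D, D)
        try:
            Rinv = np.linalg.inv(R)
            v = np.diag(Rinv).copy()
        except np.linalg.LinAlgError:
            v = np.empty(idx.size)
            for a in range(idx.size):
                others = np.delete(np.arange(idx.size), a)
                Ro = R[np.ix_(others, others)]
                ro = R[others, a]
                coef, *_ = np.linalg.lstsq(Ro, ro, rcond=None)
                r2 = float(coef @ ro)
                v[a] = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
        v = np.where(v >= 1e12, np.inf, v)
        # numerical slack: estimable columns satisfy vif >= 1 up to round-off
        v = np.maximum(v, 1.0)
        vif[idx] = v
    return VifProfile(vif=vif, columns=columns)


@dataclass
class UnmixedDatasets:
    """fixed-only = X_fixed b_fixed + residual; scaled-only = X_scaled b_scaled
    + residual; both on retained rows (``row_index`` marks the gaps)."""

    fixed_only: np.ndarray  # channels x retained samples
    scaled_only: np.ndarray
    residual: np.ndarray
    row_index: np.ndarray

    def check_identity(self, Y: np.ndarray, atol: float = 1e-9) -> None:
        """fixed_only + scaled_only - residual must reproduce the fitted + residual = Y."""
        recon = self.fixed_only + self.scaled_only - self.residual
        if not np.allclose(recon, Y, atol=atol):
            raise AssertionError("unmixed identity violated")


def reconstruct_unmixed(
    Y: np.ndarray, X: DesignMatrix, estimate: RerpEstimate
) -> UnmixedDatasets:
    """Recombine the residual with either component family (per channel)."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if estimate.beta.shape[1] != X.n_predictors:
        raise ValueError("estimate/design partition mismatch")
    if Y.shape[1] != X.n_rows:
        raise ValueError("Y row mismatch with design")
    fixed_cols = X.fixed_columns()
    scaled_cols = X.scaled_columns()
    fixed_pred = (X.X[:, fixed_cols] @ estimate.beta[:, fixed_cols].T).T
    scaled_pred = (X.X[:, scaled_cols] @ estimate.beta[:, scaled_cols].T).T
    residual = Y - fixed_pred - scaled_pred
    out = UnmixedDatasets(
        fixed_only=fixed_pred + residual,
        scaled_only=scaled_pred + residual,
        residual=residual,
        row_index=X.row_index,
    )
    out.check_identity(Y)
    return out


@dataclass
class ScalingIndexResult:
    index: float
    per_pair: list[float]
    common_length: int


def scaling_index(
    waveforms: list[np.ndarray],
    common_length: int | None = None,
) -> ScalingIndexResult:
    """Coefficient of determination between condition means after stretching.

    Each 1-D condition mean (variable native length) is box-resampled to
    ``common_length`` (default: the longest condition's length); each shorter
    condition predicts the longest via simple linear regression with
    intercept, and the resulting R^2 values are averaged.
    """
    waves = [np.asarray(w, dtype=float).ravel() for w in waveforms]
    if len(waves) < 2:
        raise ValueError("need at least 2 condition waveforms")
    lengths = [w.size for w in waves]
    longest = int(np.argmax(lengths))
    if common_length is None:
        common_length = lengths[longest]
    stretched = [resize_box(w.size, common_length) @ w for w in waves]
    target = stretched[longest]
    if np.var(target) == 0:
        return ScalingIndexResult(index=np.nan, per_pair=[], common_length=common_length)
    per_pair = []
    for i, w in enumerate(stretched):
        if i == longest:
            continue
        if np.var(w) == 0:
            per_pair.append(np.nan)
            continue
        r = np.corrcoef(w, target)[0, 1]
        per_pair.append(float(r * r))  # R^2 of simple linear regression
    index = float(np.nanmean(per_pair)) if per_pair else np.nan
    return ScalingIndexResult(index=index, per_pair=per_pair,
                              common_length=common_length)
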