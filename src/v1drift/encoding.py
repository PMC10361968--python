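"""Per-voxel linear encoding: OLS fitting, prediction, and goodness of fit.

Two complementary generalization metrics are exposed: cross-validated R^2
(sensitive to baseline and gain mismatches of the prediction) and Pearson
correlation (invariant to them).  The contrast between the two is what the
downstream drift analysis exploits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
import scipy.linalg

from .pyramid_features import VoxelFeatures

__all__ = [
    "WeightVector",
    "PredictionResult",
    "GofScore",
    "RankDeficientDesignError",
    "fit_ols",
    "predict",
    "cv_r2",
    "pearson_gof",
]

ArrayLike = Union[np.ndarray, list]


class RankDeficientDesignError(ValueError):
    """Raised when the design matrix has linearly dependent columns."""

    def __init__(self, deficient_columns: list[int]):
        self.deficient_columns = deficient_columns
        super().__init__(
            "design matrix is rank-deficient; dependent columns: "
            f"{deficient_columns}"
        )


@dataclass(frozen=True)
class WeightVector:
    """Estimated regression weights; last entry is the intercept."""

    beta: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.beta, dtype=float)
        if b.ndim != 1:
            raise ValueError("beta must be a vector")
        if not np.all(np.isfinite(b)):
            raise ValueError("beta contains non-finite values")
        object.__setattr__(self, "beta", b)

    @property
    def intercept(self) -> float:
        return float(self.beta[-1])

    def __len__(self) -> int:
        return self.beta.shape[0]


@dataclass
class PredictionResult:
    """Model prediction on a (test) response vector, with error sums."""

    y_pred: np.ndarray
    y: np.ndarray | None = None
    y_resid: np.ndarray | None = None
    y_mean: float | None = None
    ss_resid: float | None = None
    ss_total: float | None = None

    def __post_init__(self) -> None:
        if self.y is not None:
            y = np.asarray(self.y, dtype=float)
            self.y = y
            self.y_resid = y - self.y_pred
            self.y_mean = float(y.mean())
            self.ss_resid = float(np.sum(self.y_resid**2))
            self.ss_total = float(np.sum((y - self.y_mean) ** 2))


@dataclass(frozen=True)
class GofScore:
    metric: str  # "cvR2" | "pearson"
    value: float


def _as_design(X: Union[VoxelFeatures, ArrayLike]) -> np.ndarray:
    if isinstance(X, VoxelFeatures):
        return X.matrix
    return np.asarray(X, dtype=float)


def fit_ols(X: Union[VoxelFeatures, ArrayLike], y: ArrayLike) -> WeightVector:
    """Ordinary least-squares fit via a QR-based solver.

    Raises :class:`RankDeficientDesignError` (naming the dependent columns,
    found by pivoted QR) instead of silently regularizing.
    """
    A = _as_design(X)
    y = np.asarray(y, dtype=float)
    if A.shape[0] != y.shape[0]:
        raise ValueError(
            f"design has {A.shape[0]} rows but y has {y.shape[0]} entries"
        )
    if A.shape[0] < A.shape[1]:
        raise ValueError(
            f"need at least as many observations ({A.shape[0]}) as "
            f"predictors ({A.shape[1]}) for a unique OLS solution"
        )
    beta, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < A.shape[1]:
        _, r, piv = scipy.linalg.qr(A, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(A.shape) * np.finfo(float).eps
        deficient = sorted(int(p) for p in piv[diag <= tol])
        if not deficient:  # lstsq and QR disagree at the tolerance edge
            deficient = sorted(int(p) for p in piv[rank:])
        raise RankDeficientDesignError(deficient)
    return WeightVector(beta=beta)


def predict(
    X: Union[VoxelFeatures, ArrayLike],
    beta: Union[WeightVector, ArrayLike],
    y: ArrayLike | None = None,
) -> PredictionResult:
    """Linear prediction X @ beta; pass test responses y to populate errors."""
    A = _as_design(X)
    b = beta.beta if isinstance(beta, WeightVector) else np.asarray(beta, float)
    if A.shape[1] != b.shape[0]:
        raise ValueError(
            f"design has {A.shape[1]} columns but beta has {b.shape[0]} entries"
        )
    y_pred = A @ b
    return PredictionResult(y_pred=y_pred, y=None if y is None else np.asarray(y, float))


def cv_r2(pred: PredictionResult) -> GofScore:
    """1 - SS(resid) / SS(y - mean(y)), with mean taken over the TEST set.

    Unbounded below; negative values are legal and meaningful (worse than
    predicting the test mean).
    """
    if pred.y is None:
        raise ValueError("prediction carries no test responses")
    if pred.ss_total == 0:
        raise ValueError("undefined cvR²: test responses are constant")
    return GofScore(metric="cvR2", value=1.0 - pred.ss_resid / pred.ss_total)


def pearson_gof(pred: PredictionResult) -> GofScore:
    """Pearson correlation between prediction and measured responses."""
    if pred.y is None:
        raise ValueError("prediction carries no test responses")
    y, yp = pred.y, pred.y_pred
    if np.ptp(y) == 0 or np.ptp(yp) == 0:
        raise ValueError("Pearson correlation undefined for a constant vector")
    r = float(np.corrcoef(y, yp)[0, 1])
    return GofScore(metric="pearson", value=r)


# vectorized forms used by the cross-session machinery -----------------------

def batch_cv_r2(Y: np.ndarray, Y_pred: np.ndarray) -> np.ndarray:
    """cvR² along the last axis for stacked (voxels x trials) arrays."""
    resid = Y - Y_pred
    ss_resid = np.sum(resid**2, axis=-1)
    centered = Y - Y.mean(axis=-1, keepdims=True)
    ss_total = np.sum(centered**2, axis=-1)
    if np.any(ss_total == 0):
        raise ValueError("undefined cvR²: constant test responses")
    return 1.0 - ss_resid / ss_total


def batch_pearson(Y: np.ndarray, Y_pred: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation for stacked (voxels x trials) arrays."""
    yc = Y - Y.mean(axis=-1, keepdims=True)
    pc = Y_pred - Y_pred.mean(axis=-1, keepdims=True)
    denom = np.sqrt(np.sum(yc**2, axis=-1) * np.sum(pc**2, axis=-1))
    if np.any(denom == 0):
        raise ValueError("Pearson correlation undefined for a constant vector")
    return np.sum(yc * pc, axis=-1) / denom
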