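"""Cross-session generalization and drift statistics.

A model is fit independently on every session and tested on every other
session; the resulting sessions x sessions goodness-of-fit matrix is
summarized by interval profiles (mean over matrix diagonals) and by the
drift statistic: the correlation between off-diagonal cells and the number
of intervening sessions, averaged across subjects.  Significance comes
from a session-order permutation test.  Normalization interventions
(per-session mean subtraction, per-session variance equalization) localize
the drift to mean-response changes versus variance changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .encoding import WeightVector, batch_cv_r2, batch_pearson, fit_ols

__all__ = [
    "BetaPanel",
    "GOFMatrix",
    "IntervalProfile",
    "DriftStat",
    "SessionSeriesStats",
    "fit_all_sessions",
    "cross_session_gof",
    "interval_profile",
    "adjacent_profile",
    "drift_statistic",
    "permutation_test",
    "subtract_session_mean",
    "normalize_session_variance",
    "session_series_stats",
]


# --------------------------------------------------------------------------
# data containers
# --------------------------------------------------------------------------

@dataclass
class BetaPanel:
    """Single-trial response amplitudes for one subject.

    ``betas`` is voxels x trials; every trial belongs to exactly one
    session (``sessions``, 0-based labels) and shows one image
    (``image_ids``).  ``prf_r2`` carries the per-voxel inclusion score.
    """

    betas: np.ndarray
    sessions: np.ndarray
    image_ids: np.ndarray
    prf_r2: np.ndarray

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        self.sessions = np.asarray(self.sessions, dtype=int)
        self.image_ids = np.asarray(self.image_ids)
        self.prf_r2 = np.asarray(self.prf_r2, dtype=float)
        if self.betas.ndim != 2:
            raise ValueError("betas must be voxels x trials")
        n_trials = self.betas.shape[1]
        if self.sessions.shape != (n_trials,) or self.image_ids.shape[0] != n_trials:
            raise ValueError("sessions and image_ids must align with trials")
        if self.prf_r2.shape != (self.betas.shape[0],):
            raise ValueError("prf_r2 must have one entry per voxel")

    @property
    def n_voxels(self) -> int:
        return self.betas.shape[0]

    @property
    def n_sessions(self) -> int:
        return int(self.sessions.max()) + 1

    @property
    def included_voxels(self) -> np.ndarray:
        return np.flatnonzero(self.prf_r2 > 0)

    def session_trials(self, s: int) -> np.ndarray:
        idx = np.flatnonzero(self.sessions == s)
        if idx.size == 0:
            raise ValueError(f"session {s} has no trials")
        return idx

    def session_betas(self, s: int) -> np.ndarray:
        return self.betas[:, self.session_trials(s)]


@dataclass(frozen=True)
class GOFMatrix:
    """Sessions x sessions goodness of fit, median across included voxels."""

    values: np.ndarray
    metric: str
    subject: str = "sim"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("GOF matrix must be square")
        off = ~np.eye(v.shape[0], dtype=bool)
        if not np.all(np.isfinite(v[off])):
            raise ValueError("GOF matrix has non-finite off-diagonal entries")
        object.__setattr__(self, "values", v)

    @property
    def n_sessions(self) -> int:
        return self.values.shape[0]

    def permuted(self, perm: np.ndarray) -> "GOFMatrix":
        """Jointly reorder rows and columns by one session permutation."""
        v = self.values[np.ix_(perm, perm)]
        return replace(self, values=v)


@dataclass(frozen=True)
class IntervalProfile:
    """Mean GOF per number of intervening sessions d = |train - test|."""

    means: np.ndarray  # index 0 <-> d = 1
    counts: np.ndarray

    @property
    def intervals(self) -> np.ndarray:
        return np.arange(1, self.means.shape[0] + 1)


@dataclass(frozen=True)
class DriftStat:
    """Empirical drift correlation with a permutation null distribution."""

    r_empirical: float
    null: np.ndarray | None = None
    p: float | None = None
    seed: int | None = None

    @property
    def n_perm(self) -> int:
        return 0 if self.null is None else self.null.shape[0]


# --------------------------------------------------------------------------
# fitting and the GOF matrix
# --------------------------------------------------------------------------

def fit_all_sessions(
    designs: np.ndarray, panel: BetaPanel
) -> np.ndarray:
    """OLS weights per session per voxel.

    ``designs[s]`` is voxels x images_per_session x (channels + 1), row
    order matching the trial order of session s in the panel.  Returns an
    (S, voxels, channels + 1) weight array.
    """
    S = panel.n_sessions
    if len(designs) != S:
        raise ValueError(f"need {S} session designs, got {len(designs)}")
    n_vox = panel.n_voxels
    p = designs[0].shape[-1]
    fits = np.empty((S, n_vox, p))
    for s in range(S):
        Y = panel.session_betas(s)
        for v in range(n_vox):
            fits[s, v] = fit_ols(designs[s][v], Y[v]).beta
    return fits


def _score(metric: str, Y: np.ndarray, Y_pred: np.ndarray) -> np.ndarray:
    if metric == "cvR2":
        return batch_cv_r2(Y, Y_pred)
    if metric == "pearson":
        return batch_pearson(Y, Y_pred)
    raise ValueError(f"unknown metric {metric!r}")


def cross_session_gof(
    fits: np.ndarray,
    designs: np.ndarray,
    panel: BetaPanel,
    metric: str = "cvR2",
    subject: str = "sim",
) -> GOFMatrix:
    """Evaluate every train-session x test-session combination.

    Cell (j, k) is the median, across voxels with prf_r2 > 0, of the
    chosen metric for weights trained on session j and tested on session
    k.  The diagonal holds in-sample scores (displayed but excluded from
    all drift statistics downstream).
    """
    S = panel.n_sessions
    if fits.shape[0] != S:
        missing = sorted(set(range(S)) - set(range(fits.shape[0])))
        raise ValueError(f"missing session fits for sessions {missing}")
    keep = panel.included_voxels
    if keep.size == 0:
        raise ValueError("no voxels pass the prf_r2 > 0 inclusion rule")
    M = np.empty((S, S))
    for k in range(S):
        Xk = np.asarray(designs[k])[keep]  # (V, n, p)
        Yk = panel.session_betas(k)[keep]
        for j in range(S):
            Y_pred = np.einsum("vnp,vp->vn", Xk, fits[j][keep])
            M[j, k] = np.median(_score(metric, Yk, Y_pred))
    return GOFMatrix(values=M, metric=metric, subject=subject)


# --------------------------------------------------------------------------
# interval profiles and the drift statistic
# --------------------------------------------------------------------------

def interval_profile(M: GOFMatrix) -> IntervalProfile:
    """Mean over the 2(S - d) cells at each diagonal distance d >= 1."""
    S = M.n_sessions
    if S < 2:
        raise ValueError("need at least 2 sessions")
    j, k = np.indices((S, S))
    d = np.abs(j - k)
    means = np.array([M.values[d == dd].mean() for dd in range(1, S)])
    counts = np.array([(d == dd).sum() for dd in range(1, S)])
    return IntervalProfile(means=means, counts=counts)


def adjacent_profile(M: GOFMatrix, mode: str = "average") -> np.ndarray:
    """d = 1 generalization as a function of the earlier session index.

    ``mode`` selects cells (i, i+1) ("upper"), (i+1, i) ("lower"), or
    their average (default) — the text leaves this choice open.
    """
    v = M.values
    upper = np.diagonal(v, offset=1)
    lower = np.diagonal(v, offset=-1)
    if mode == "upper":
        return upper.copy()
    if mode == "lower":
        return lower.copy()
    if mode == "average":
        return (upper + lower) / 2.0
    raise ValueError(f"unknown mode {mode!r}")


def _offdiag_pairs(M: GOFMatrix) -> tuple[np.ndarray, np.ndarray]:
    S = M.n_sessions
    j, k = np.indices((S, S))
    off = j != k
    return M.values[off], np.abs(j - k)[off].astype(float)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("degenerate matrix: zero variance in GOF values")
    return float(np.corrcoef(a, b)[0, 1])


def drift_statistic(matrices: list[GOFMatrix]) -> DriftStat:
    """Per-subject correlation of off-diagonal GOF with interval, averaged."""
    rs = []
    for M in matrices:
        vals, d = _offdiag_pairs(M)
        rs.append(_pearson(vals, d))
    return DriftStat(r_empirical=float(np.mean(rs)))


def permutation_test(
    matrices: list[GOFMatrix], n_perm: int = 1000, seed: int = 0
) -> DriftStat:
    """Session-order permutation null for the drift statistic.

    Each iteration draws one random session permutation, applies it
    jointly to rows and columns of every subject's matrix, and recomputes
    the statistic.  p is the proportion of null values not greater than
    the empirical correlation (no add-one correction, so p = 0 is
    reportable).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    S = matrices[0].n_sessions
    if any(M.n_sessions != S for M in matrices):
        raise ValueError("all subjects must share the session count")
    empirical = drift_statistic(matrices).r_empirical
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(S)
        null[i] = drift_statistic([M.permuted(perm) for M in matrices]).r_empirical
    p = float(np.mean(null <= empirical))
    return DriftStat(r_empirical=empirical, null=null, p=p, seed=seed)


# --------------------------------------------------------------------------
# normalization interventions
# --------------------------------------------------------------------------

def _session_slices(panel: BetaPanel) -> list[np.ndarray]:
    return [panel.session_trials(s) for s in range(panel.n_sessions)]


def subtract_session_mean(panel: BetaPanel) -> BetaPanel:
    """Remove each voxel's per-session mean beta (idempotent)."""
    out = panel.betas.copy()
    for idx in _session_slices(panel):
        out[:, idx] -= out[:, idx].mean(axis=1, keepdims=True)
    return replace(panel, betas=out)


def normalize_session_variance(panel: BetaPanel) -> BetaPanel:
    """Z-score each voxel's session, then restore the original mean.

    Leaves every per-voxel per-session mean untouched while forcing the
    per-session SD to 1.
    """
    out = panel.betas.copy()
    for s, idx in enumerate(_session_slices(panel)):
        block = out[:, idx]
        m = block.mean(axis=1, keepdims=True)
        sd = block.std(axis=1, keepdims=True)
        if np.any(sd == 0):
            bad = np.flatnonzero(sd[:, 0] == 0)
            raise ValueError(
                f"zero-variance voxel(s) {bad.tolist()} in session {s}"
            )
        out[:, idx] = (block - m) / sd + m
    return replace(panel, betas=out)


# --------------------------------------------------------------------------
# session-series statistics
# --------------------------------------------------------------------------

@dataclass
class SessionSeriesStats:
    """Per-voxel session-mean series and their temporal statistics."""

    mean_series: np.ndarray          # voxels x sessions
    autocorr: np.ndarray             # voxels x (sessions - 1), lag 1..S-1
    cross_correlations: np.ndarray   # flattened upper-triangle voxel pairs
    n_excluded: int                  # constant-series voxels dropped


def _sample_autocorr(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Standard (biased-denominator) sample autocorrelation estimator."""
    xc = x - x.mean()
    denom = np.sum(xc**2)
    return np.array(
        [np.sum(xc[:-h] * xc[h:]) / denom for h in range(1, max_lag + 1)]
    )


def session_series_stats(panel: BetaPanel) -> SessionSeriesStats:
    S = panel.n_sessions
    if S < 3:
        raise ValueError("need at least 3 sessions for series statistics")
    series = np.stack(
        [panel.session_betas(s).mean(axis=1) for s in range(S)], axis=1
    )
    ok = np.ptp(series, axis=1) > 0
    n_excluded = int(np.sum(~ok))
    if n_excluded:
        warnings.warn(
            f"excluding {n_excluded} constant mean-beta series", stacklevel=2
        )
    kept = series[ok]
    if kept.shape[0] == 0:
        raise ValueError("all mean-beta series are constant")
    autocorr = np.stack([_sample_autocorr(x, S - 1) for x in kept])
    if kept.shape[0] >= 2:
        cc = np.corrcoef(kept)
        iu = np.triu_indices(kept.shape[0], k=1)
        cross = cc[iu]
    else:
        cross = np.empty(0)
    return SessionSeriesStats(
        mean_series=series,
        autocorr=autocorr,
        cross_correlations=cross,
        n_excluded=n_excluded,
    )
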