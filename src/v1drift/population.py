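"""Population-level analyses of simulated responses.

Session fits are used to simulate responses of the whole voxel population
to a fixed probe-image set.  Two complementary summaries are computed:
per-image cross-session correlations (sensitive to spatially heterogeneous
amplitude changes) and within-session representational dissimilarity
matrices whose cross-session Spearman stability is insensitive to them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr

from .drift import DriftStat, GOFMatrix, drift_statistic, permutation_test

__all__ = [
    "PopulationTensor",
    "RDM",
    "simulate_population_responses",
    "image_similarity_matrix",
    "session_rdm",
    "rdm_stability",
]


@dataclass
class PopulationTensor:
    """Simulated responses: sessions x probe images x voxels."""

    values: np.ndarray
    probe_image_ids: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3:
            raise ValueError("population tensor must be 3-D (S, P, V)")
        if not np.all(np.isfinite(v)):
            raise ValueError("population tensor has non-finite values")
        self.values = v

    @property
    def n_sessions(self) -> int:
        return self.values.shape[0]

    @property
    def n_images(self) -> int:
        return self.values.shape[1]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[2]


@dataclass(frozen=True)
class RDM:
    """1 - Pearson distances between population responses to image pairs."""

    values: np.ndarray
    session: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("RDM must be square")
        object.__setattr__(self, "values", v)

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.values.shape[0], k=1)
        return self.values[iu]


def simulate_population_responses(
    fits: np.ndarray,
    probe_designs: np.ndarray,
    include_intercept: bool = True,
    probe_image_ids: np.ndarray | None = None,
    seed: int | None = None,
) -> PopulationTensor:
    """Predict every voxel's response to every probe image from each
    session's weights.

    ``fits`` is (S, V, p); ``probe_designs`` is (V, P, p), one design row
    per probe image per voxel.  With ``include_intercept`` (default) the
    constant-term coefficient contributes, so baseline drift propagates
    into the population analyses; disabling it simulates amplitude-free
    tuning responses.
    """
    fits = np.asarray(fits, dtype=float)
    probe_designs = np.asarray(probe_designs, dtype=float)
    if fits.ndim != 3 or probe_designs.ndim != 3:
        raise ValueError("fits must be (S, V, p), probe_designs (V, P, p)")
    if fits.shape[1] != probe_designs.shape[0] or fits.shape[2] != probe_designs.shape[2]:
        raise ValueError("fits and probe designs are inconsistent")
    if not include_intercept:
        fits = fits.copy()
        fits[:, :, -1] = 0.0
    tensor = np.einsum("vpc,svc->spv", probe_designs, fits)
    return PopulationTensor(
        values=tensor, probe_image_ids=probe_image_ids, seed=seed
    )


def image_similarity_matrix(pop: PopulationTensor) -> np.ndarray:
    """Mean over probe images of session x session population correlations.

    For each image the population response vectors (across voxels) of all
    session pairs are Pearson-correlated; the per-image matrices are then
    averaged.  Diagonal is exactly 1.
    """
    if pop.n_voxels < 2:
        raise ValueError("need at least 2 voxels for population correlations")
    S = pop.n_sessions
    acc = np.zeros((S, S))
    for j in range(pop.n_images):
        resp = pop.values[:, j, :]  # (S, V)
        if np.any(np.ptp(resp, axis=1) == 0):
            raise ValueError(
                f"constant population vector for probe image {j}"
            )
        acc += np.corrcoef(resp)
    M = acc / pop.n_images
    np.fill_diagonal(M, 1.0)
    return M


def session_rdm(pop_slice: np.ndarray, session: int = 0) -> RDM:
    """Within-session RDM: entry (a, b) = 1 - Pearson r across voxels."""
    resp = np.asarray(pop_slice, dtype=float)
    if resp.ndim != 2:
        raise ValueError("expected a (probe images x voxels) slice")
    bad = np.flatnonzero(np.ptp(resp, axis=1) == 0)
    if bad.size:
        raise ValueError(
            f"constant population vector for probe image(s) {bad.tolist()}"
        )
    d = 1.0 - np.corrcoef(resp)
    np.fill_diagonal(d, 0.0)
    return RDM(values=d, session=session)


def rdm_stability(
    rdms: list[RDM], n_perm: int = 1000, seed: int = 0
) -> tuple[np.ndarray, DriftStat]:
    """Spearman correlation between every pair of session RDMs.

    Uses the upper-triangle entries of each RDM; the resulting S x S
    matrix is then fed through the drift statistic and its permutation
    test.
    """
    triangles = np.stack([r.upper_triangle() for r in rdms])
    degenerate = np.flatnonzero(np.ptp(triangles, axis=1) == 0)
    if degenerate.size:
        raise ValueError(
            "degenerate RDM (all distances equal) for session(s) "
            f"{degenerate.tolist()}"
        )
    S = len(rdms)
    rho, _ = spearmanr(triangles.T)
    rho = np.atleast_2d(rho)
    if rho.shape != (S, S):  # spearmanr collapses the S = 2 case
        r = float(rho.squeeze())
        rho = np.array([[1.0, r], [r, 1.0]])
    np.fill_diagonal(rho, 1.0)
    M = GOFMatrix(values=rho, metric="spearman_rdm")
    off = ~np.eye(S, dtype=bool)
    if np.ptp(rho[off]) == 0:
        # perfectly stable RDMs leave no variance to correlate with interval
        stat = DriftStat(r_empirical=float("nan"), null=None, p=None, seed=seed)
    else:
        stat = permutation_test([M], n_perm=n_perm, seed=seed)
    return rho, stat
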