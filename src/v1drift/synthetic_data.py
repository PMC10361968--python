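"""Synthetic multi-session experiments with known ground truth.

Everything the real study takes as given — stimulus images, receptive
fields, spectral weights, single-trial response amplitudes — is generated
here with full seed provenance, so the whole pipeline can be exercised and
scored against ground truth without any external data.

Two generation paths share the same ground truth:

* the image-level slow path renders 1/f-noise images and pushes them
  through the filter-bank / pRF-sampling chain;
* the feature-level fast path draws design-matrix entries directly
  (nonnegative, like the magnitude features), which is what the
  statistical tests use.

Session-to-session drift is injected into the generative weights:
an intercept random walk with cross-voxel correlated increments (low-rank
spatial factor on pRF positions, producing mixed-sign cross-correlations
between voxels' mean-response series), an optional multiplicative gain
walk on the oriented weights, and an optional cumulative jitter of the
tuning profile at fixed overall gain.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .drift import BetaPanel
from .pyramid_features import (
    PRF,
    PyramidConfig,
    StimulusImage,
    build_design_matrices,
)

__all__ = [
    "DriftSpec",
    "ExperimentConfig",
    "GroundTruth",
    "Experiment",
    "generate_image_library",
    "generate_ground_truth_voxels",
    "generate_experiment",
    "generate_multi_subject",
    "select_probe_designs",
]


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DriftSpec:
    """Session-wise drift processes applied to the generative weights.

    baseline_walk_sd    SD of the per-session intercept random-walk step.
    baseline_corr       share (0..1) of step variance carried by a common
                        spatial factor; produces cross-voxel correlated,
                        mixed-sign baseline changes.
    baseline_uniform    every voxel receives the identical step (overrides
                        baseline_corr); the 'uniform additive change' null
                        scenario.
    gain_walk_sd        SD of the per-session log-gain step multiplying
                        the oriented weights.
    gain_mean_preserving
                        compensate the intercept so the gain walk changes
                        only response variability, not the session mean
                        (keeps the gain and baseline scenarios orthogonal).
    tuning_jitter_sd    SD of a cumulative perturbation of the oriented
                        weight profile, renormalized to constant gain.
    """

    baseline_walk_sd: float = 0.0
    baseline_corr: float = 0.5
    baseline_uniform: bool = False
    gain_walk_sd: float = 0.0
    gain_mean_preserving: bool = True
    tuning_jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        for name in ("baseline_walk_sd", "gain_walk_sd", "tuning_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.baseline_corr <= 1.0:
            raise ValueError("baseline_corr must be in [0, 1]")

    @property
    def is_static(self) -> bool:
        return (
            self.baseline_walk_sd == 0
            and self.gain_walk_sd == 0
            and self.tuning_jitter_sd == 0
        )


@dataclass(frozen=True)
class ExperimentConfig:
    n_subjects: int = 8
    n_sessions: int = 30
    images_per_session: int = 100
    n_voxels: int = 50
    image_side: int = 64
    n_channels: int = 20      # feature-path channel count
    seed: int = 0
    distinct_images: bool = True  # no image repeats across sessions

    def __post_init__(self) -> None:
        for name in (
            "n_subjects", "n_sessions", "images_per_session", "n_voxels",
            "image_side", "n_channels",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class GroundTruth:
    """Everything needed to reproduce the generative process."""

    prfs: list[PRF]
    base_weights: np.ndarray             # (V, C + 1), intercept last
    n_channels: int
    seed: int
    session_weights: np.ndarray | None = None  # (S, V, C + 1) after drift
    drift_spec: DriftSpec | None = None
    noise_sd: float | None = None

    @property
    def n_voxels(self) -> int:
        return self.base_weights.shape[0]

    @property
    def prf_r2(self) -> np.ndarray:
        return np.array([p.prf_r2 for p in self.prfs])

    def manifest(self) -> dict:
        out = {
            "n_voxels": self.n_voxels,
            "n_channels": self.n_channels,
            "seed": self.seed,
            "prfs": [
                {"x0": p.x0, "y0": p.y0, "sigma": p.sigma, "prf_r2": p.prf_r2}
                for p in self.prfs
            ],
            "base_weights": self.base_weights.tolist(),
        }
        if self.drift_spec is not None:
            out["drift_spec"] = asdict(self.drift_spec)
        if self.noise_sd is not None:
            out["noise_sd"] = self.noise_sd
        return out


@dataclass
class Experiment:
    """One subject's generated experiment: data, designs and truth."""

    panel: BetaPanel
    designs: np.ndarray      # (S, V, images_per_session, C + 1)
    gt: GroundTruth
    config: ExperimentConfig
    subject: str = "sim"


# --------------------------------------------------------------------------
# images
# --------------------------------------------------------------------------

def generate_image_library(
    n: int,
    side: int,
    spectral_exponent: float = 1.0,
    seed: int = 0,
    pyramid_cfg: PyramidConfig | None = None,
) -> np.ndarray:
    """Grayscale 1/f^alpha noise images, each normalized to [0, 1].

    The amplitude spectrum of each image falls off as f^-alpha
    (``spectral_exponent``), emulating the spectral statistics of natural
    scenes at alpha = 1.
    """
    if pyramid_cfg is not None and side < pyramid_cfg.min_side():
        import warnings

        warnings.warn(
            f"side {side} is too small for the configured pyramid depth "
            f"(needs >= {pyramid_cfg.min_side()})",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    f = np.fft.fftfreq(side)
    fx, fy = np.meshgrid(f, f, indexing="xy")
    r = np.hypot(fx, fy)
    r[0, 0] = 1.0  # DC untouched; removed by per-image normalization anyway
    scale = r ** (-spectral_exponent)
    imgs = np.empty((n, side, side))
    for i in range(n):
        white = rng.standard_normal((side, side))
        shaped = np.fft.ifft2(np.fft.fft2(white) * scale).real
        lo, hi = shaped.min(), shaped.max()
        imgs[i] = (shaped - lo) / (hi - lo) if hi > lo else 0.5
    return imgs


# --------------------------------------------------------------------------
# ground truth
# --------------------------------------------------------------------------

def generate_ground_truth_voxels(
    n_voxels: int,
    n_channels: int = 20,
    field_of_view_deg: float = 8.4,
    n_active_channels: int = 3,
    sigma_range: tuple[float, float] = (0.3, 1.2),
    intercept_scale: float = 1.0,
    seed: int = 0,
) -> GroundTruth:
    """Draw pRFs and sparse base spectral weights for a voxel population.

    Centers fall inside the stimulus extent; sigmas are uniform over
    ``sigma_range``; each voxel's oriented weights are nonzero on
    ``n_active_channels`` random channels; prf_r2 is strictly positive so
    all voxels pass the inclusion rule.
    """
    rng = np.random.default_rng(seed)
    half = field_of_view_deg / 2.0
    xs = rng.uniform(-0.9 * half, 0.9 * half, n_voxels)
    ys = rng.uniform(-0.9 * half, 0.9 * half, n_voxels)
    sigmas = rng.uniform(*sigma_range, n_voxels)
    r2 = rng.uniform(0.1, 0.9, n_voxels)
    prfs = [
        PRF(x0=float(x), y0=float(y), sigma=float(s), prf_r2=float(q))
        for x, y, s, q in zip(xs, ys, sigmas, r2)
    ]
    k = min(n_active_channels, n_channels)
    weights = np.zeros((n_voxels, n_channels + 1))
    for v in range(n_voxels):
        active = rng.choice(n_channels, size=k, replace=False)
        weights[v, active] = np.abs(rng.normal(1.0, 0.3, k))
    weights[:, -1] = rng.normal(0.0, intercept_scale, n_voxels)
    return GroundTruth(
        prfs=prfs, base_weights=weights, n_channels=n_channels, seed=seed
    )


def _spatial_loading(prfs: list[PRF]) -> np.ndarray:
    """Low-rank factor on pRF positions, standardized; carries both signs."""
    x = np.array([p.x0 for p in prfs])
    x = x - x.mean()
    sd = x.std()
    return x / sd if sd > 0 else np.ones_like(x)


def _evolve_weights(
    gt: GroundTruth, n_sessions: int, spec: DriftSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Apply the drift processes.

    Returns (session_weights, pre_gain_oriented): the (S, V, C + 1)
    effective weights and the (S, V, C) oriented weights before the gain
    walk (used for mean-preserving gain compensation).
    """
    V, C = gt.n_voxels, gt.n_channels
    W = np.tile(gt.base_weights, (n_sessions, 1, 1))

    base_orient = gt.base_weights[:, :C]
    norms = np.linalg.norm(base_orient, axis=1, keepdims=True)

    tuning_off = np.zeros((V, C))
    log_gain = np.zeros(V)
    baseline_off = np.zeros(V)
    loading = _spatial_loading(gt.prfs)
    pre_gain = np.empty((n_sessions, V, C))

    for s in range(n_sessions):
        if s > 0:
            if spec.baseline_walk_sd > 0:
                if spec.baseline_uniform:
                    step = spec.baseline_walk_sd * rng.standard_normal() * np.ones(V)
                else:
                    c = spec.baseline_corr
                    shared = np.sqrt(c) * loading * rng.standard_normal()
                    private = np.sqrt(1 - c) * rng.standard_normal(V)
                    step = spec.baseline_walk_sd * (shared + private)
                baseline_off += step
            if spec.gain_walk_sd > 0:
                log_gain += spec.gain_walk_sd * rng.standard_normal(V)
            if spec.tuning_jitter_sd > 0:
                tuning_off += spec.tuning_jitter_sd * rng.standard_normal((V, C))

        orient = base_orient + tuning_off
        if spec.tuning_jitter_sd > 0:
            cur = np.linalg.norm(orient, axis=1, keepdims=True)
            cur[cur == 0] = 1.0
            orient = orient / cur * norms
        pre_gain[s] = orient
        W[s, :, :C] = orient * np.exp(log_gain)[:, None]
        W[s, :, C] = gt.base_weights[:, C] + baseline_off
    return W, pre_gain


# --------------------------------------------------------------------------
# experiments
# --------------------------------------------------------------------------

def _feature_designs(
    cfg: ExperimentConfig, gt: GroundTruth, rng: np.random.Generator
) -> np.ndarray:
    """Fast path: draw nonnegative feature values directly."""
    S, V, n, C = cfg.n_sessions, gt.n_voxels, cfg.images_per_session, gt.n_channels
    if cfg.distinct_images:
        feats = np.abs(rng.standard_normal((S, V, n, C)))
    else:
        base = np.abs(rng.standard_normal((V, n, C)))
        feats = np.tile(base, (S, 1, 1, 1))
    const = np.ones((S, V, n, 1))
    return np.concatenate([feats, const], axis=-1)


def _image_designs(
    cfg: ExperimentConfig,
    gt: GroundTruth,
    rng: np.random.Generator,
    pyramid_cfg: PyramidConfig,
    spectral_exponent: float,
) -> np.ndarray:
    """Slow path: render images and run the filter-bank / pRF chain."""
    S, n = cfg.n_sessions, cfg.images_per_session
    lib_seed = int(rng.integers(2**31))
    library = generate_image_library(
        S * n, cfg.image_side, spectral_exponent, seed=lib_seed
    )
    designs = np.empty(
        (S, gt.n_voxels, n, gt.n_channels + 1)
    )
    for s in range(S):
        imgs = [
            StimulusImage.from_array(library[s * n + j]) for j in range(n)
        ]
        vf = build_design_matrices(imgs, gt.prfs, pyramid_cfg)
        for v in range(gt.n_voxels):
            designs[s, v] = vf[v].matrix
    return designs


def generate_experiment(
    gt: GroundTruth,
    cfg: ExperimentConfig,
    drift_spec: DriftSpec | None = None,
    noise_sd: float = 0.0,
    mode: str = "features",
    pyramid_cfg: PyramidConfig | None = None,
    spectral_exponent: float = 1.0,
    subject: str = "sim",
    seed: int | None = None,
) -> Experiment:
    """Generate one subject's multi-session experiment.

    Responses follow the generative model: session-s betas are the
    session-s design times the session-s effective weights plus
    N(0, noise_sd^2) noise.  ``mode`` selects the feature-level fast path
    ("features") or the image-level slow path ("images").
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    drift_spec = drift_spec or DriftSpec()
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    if mode == "features":
        designs = _feature_designs(cfg, gt, rng)
    elif mode == "images":
        if pyramid_cfg is None:
            raise ValueError("image mode needs a PyramidConfig")
        if pyramid_cfg.n_channels != gt.n_channels:
            raise ValueError(
                f"ground truth has {gt.n_channels} channels but the pyramid "
                f"produces {pyramid_cfg.n_channels}"
            )
        designs = _image_designs(cfg, gt, rng, pyramid_cfg, spectral_exponent)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    session_weights, pre_gain = _evolve_weights(
        gt, cfg.n_sessions, drift_spec, rng
    )
    if drift_spec.gain_walk_sd > 0 and drift_spec.gain_mean_preserving:
        # fold the mean-response change caused by the gain into the
        # intercept, so gain drift lives purely in the variance
        C = gt.n_channels
        m_gained = np.einsum(
            "svnc,svc->sv", designs[..., :C], session_weights[:, :, :C]
        ) / cfg.images_per_session
        m_pre = np.einsum(
            "svnc,svc->sv", designs[..., :C], pre_gain
        ) / cfg.images_per_session
        session_weights[:, :, C] += m_pre - m_gained

    S, n = cfg.n_sessions, cfg.images_per_session
    signal = np.einsum("svnp,svp->svn", designs, session_weights)
    noise = noise_sd * rng.standard_normal(signal.shape) if noise_sd > 0 else 0.0
    betas = (signal + noise).transpose(1, 0, 2).reshape(gt.n_voxels, S * n)

    sessions = np.repeat(np.arange(S), n)
    if cfg.distinct_images:
        image_ids = np.arange(S * n)
    else:
        image_ids = np.tile(np.arange(n), S)

    panel = BetaPanel(
        betas=betas, sessions=sessions, image_ids=image_ids, prf_r2=gt.prf_r2
    )
    gt_full = GroundTruth(
        prfs=gt.prfs,
        base_weights=gt.base_weights,
        n_channels=gt.n_channels,
        seed=gt.seed,
        session_weights=session_weights,
        drift_spec=drift_spec,
        noise_sd=noise_sd,
    )
    return Experiment(
        panel=panel, designs=designs, gt=gt_full, config=cfg, subject=subject
    )


def generate_multi_subject(
    cfg: ExperimentConfig,
    drift_spec: DriftSpec | None = None,
    noise_sd: float = 0.0,
    mode: str = "features",
    **kwargs,
) -> list[Experiment]:
    """One independent :func:`generate_experiment` per subject."""
    out = []
    for i in range(cfg.n_subjects):
        gt = generate_ground_truth_voxels(
            cfg.n_voxels, cfg.n_channels, seed=cfg.seed + 1000 * i
        )
        out.append(
            generate_experiment(
                gt,
                cfg,
                drift_spec,
                noise_sd,
                mode=mode,
                subject=f"subj{i:02d}",
                seed=cfg.seed + 1000 * i + 1,
                **kwargs,
            )
        )
    return out


def select_probe_designs(
    exp: Experiment, n_probe: int = 100, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Draw probe images without replacement from the pooled library.

    Returns (probe_designs, probe_image_ids) where probe_designs is
    (V, n_probe, C + 1): for each selected trial-image, the corresponding
    design row of every voxel.
    """
    S, V, n, p = exp.designs.shape
    total = S * n
    if n_probe > total:
        raise ValueError(f"cannot draw {n_probe} probes from {total} images")
    rng = np.random.default_rng(seed)
    flat = rng.choice(total, size=n_probe, replace=False)
    s_idx, j_idx = flat // n, flat % n
    probes = exp.designs[s_idx, :, j_idx, :]  # (n_probe, V, p)
    probes = probes.transpose(1, 0, 2)
    trial_order = np.argsort(exp.panel.sessions, kind="stable")
    image_ids = exp.panel.image_ids[trial_order].reshape(S, n)[s_idx, j_idx]
    return probes, image_ids
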