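"""Image-computable V1 feature extraction.

Pipeline: raw RGB stimulus -> prepared grayscale grid -> multi-scale,
multi-orientation filter-bank magnitude maps -> Gaussian receptive-field
sampling -> per-voxel design matrices (channels + constant term).

The filter bank is a frequency-domain complex steerable pyramid: oriented
band-pass channels are log-radial raised-cosine annuli multiplied by
one-sided angular cos^(K-1) windows, so the inverse transform yields an
analytic (quadrature-pair) response whose magnitude is the square root of
local spectral energy.  All channel maps are computed at full grid
resolution (no subsampling), which is equivalent to building the pyramid
and upsampling every level back to the finest grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.fft import fft2, ifft2

__all__ = [
    "StimulusGeometry",
    "StimulusImage",
    "PyramidConfig",
    "FeatureMapSet",
    "PRF",
    "VoxelFeatures",
    "prepare_stimulus",
    "decompose",
    "sample_prf",
    "sample_features",
    "build_design_matrix",
    "build_design_matrices",
]


# --------------------------------------------------------------------------
# geometry
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusGeometry:
    """Degrees <-> pixels mapping for a square stimulus grid.

    The stimulus proper occupies the central ``stimulus_side_px`` pixels of
    a ``grid_side`` x ``grid_side`` grid; the rest is uniform surround.
    Origin is at the grid center; x increases rightward, y upward, both in
    degrees of visual angle.
    """

    grid_side: int = 512
    stimulus_extent_deg: float = 8.4
    stimulus_side_px: int = 357

    def __post_init__(self) -> None:
        if self.grid_side < self.stimulus_side_px:
            raise ValueError(
                f"grid_side ({self.grid_side}) must be >= stimulus_side_px "
                f"({self.stimulus_side_px})"
            )
        if self.stimulus_extent_deg <= 0 or self.stimulus_side_px <= 0:
            raise ValueError("stimulus extent and pixel span must be positive")

    @property
    def pixels_per_degree(self) -> float:
        return self.stimulus_side_px / self.stimulus_extent_deg

    def pixel_grid_deg(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x_deg, y_deg) 1-D coordinate arrays for columns and rows.

        ``x_deg[c]`` is the horizontal position of column c, ``y_deg[r]``
        the vertical position of row r (row 0 is the top, hence positive y).
        """
        c = (self.grid_side - 1) / 2.0
        idx = np.arange(self.grid_side, dtype=float)
        x_deg = (idx - c) / self.pixels_per_degree
        y_deg = (c - idx) / self.pixels_per_degree
        return x_deg, y_deg

    @classmethod
    def for_unpadded(cls, side: int, extent_deg: float = 8.4) -> "StimulusGeometry":
        """Geometry for synthetic images that fill the whole grid."""
        return cls(grid_side=side, stimulus_extent_deg=extent_deg, stimulus_side_px=side)


@dataclass(frozen=True)
class StimulusImage:
    """A prepared grayscale image on a fixed square grid."""

    values: np.ndarray
    geometry: StimulusGeometry

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"stimulus must be square 2-D, got shape {v.shape}")
        if v.shape[0] != self.geometry.grid_side:
            raise ValueError(
                f"image side {v.shape[0]} does not match geometry grid_side "
                f"{self.geometry.grid_side}"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("stimulus contains non-finite values")
        object.__setattr__(self, "values", v)

    @property
    def side(self) -> int:
        return self.values.shape[0]

    @classmethod
    def from_array(
        cls, gray: np.ndarray, extent_deg: float = 8.4
    ) -> "StimulusImage":
        """Wrap a ready-made grayscale array that fills its grid."""
        gray = np.asarray(gray, dtype=float)
        geom = StimulusGeometry.for_unpadded(gray.shape[0], extent_deg)
        return cls(values=gray, geometry=geom)


# --------------------------------------------------------------------------
# stimulus preparation
# --------------------------------------------------------------------------

def _resize_bilinear(img: np.ndarray, out_side: int) -> np.ndarray:
    """Bilinear resample of a square image to out_side x out_side."""
    in_side = img.shape[0]
    if in_side == out_side:
        return img.copy()
    # map output pixel centers into input pixel coordinates
    pos = (np.arange(out_side) + 0.5) * in_side / out_side - 0.5
    pos = np.clip(pos, 0, in_side - 1)
    i0 = np.floor(pos).astype(int)
    i1 = np.minimum(i0 + 1, in_side - 1)
    w = pos - i0
    rows = img[i0, :] * (1 - w)[:, None] + img[i1, :] * w[:, None]
    out = rows[:, i0] * (1 - w)[None, :] + rows[:, i1] * w[None, :]
    return out


def _overlay_fixation(img: np.ndarray, radius_px: int = 4, alpha: float = 0.5,
                      level: float = 0.5) -> np.ndarray:
    """Blend a small semitransparent disc at the grid center."""
    n = img.shape[0]
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    mask = (yy - c) ** 2 + (xx - c) ** 2 <= radius_px**2
    out = img.copy()
    out[mask] = (1 - alpha) * out[mask] + alpha * level
    return out


def prepare_stimulus(
    rgb: np.ndarray,
    gray_level: float = 0.5,
    *,
    upsampled_side: int = 714,
    padded_side: int = 1024,
    final_side: int = 512,
    stimulus_extent_deg: float = 8.4,
    add_fixation: bool = False,
    return_intermediates: bool = False,
):
    """Convert an RGB stimulus to the model's grayscale grid.

    Steps: average the 3 color channels, bilinearly upsample (425 -> 714 by
    default), pad with a uniform gray border to ``padded_side``, then
    bilinearly downsample to ``final_side``.

    Parameters
    ----------
    rgb:
        Square ``n x n x 3`` array of intensities.
    gray_level:
        Intensity of the padded border, in the same units as ``rgb``.
    add_fixation:
        Overlay a small semitransparent central fixation disc (off by
        default; irrelevant for synthetic ground-truth work).
    return_intermediates:
        Also return a dict with the grayscale, upsampled and padded stages.

    Returns
    -------
    StimulusImage, or ``(StimulusImage, dict)`` when
    ``return_intermediates`` is set.
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(
            f"expected an n x n x 3 array, got shape {rgb.shape}"
        )
    if rgb.shape[0] != rgb.shape[1]:
        raise ValueError(f"input image must be square, got {rgb.shape[:2]}")
    if not np.all(np.isfinite(rgb)):
        raise ValueError("input image contains non-finite values")

    gray = rgb.mean(axis=2)
    up = _resize_bilinear(gray, upsampled_side)

    pad_total = padded_side - upsampled_side
    if pad_total < 0:
        raise ValueError("padded_side must be >= upsampled_side")
    lo = pad_total // 2
    hi = pad_total - lo
    padded = np.pad(up, ((lo, hi), (lo, hi)), constant_values=gray_level)
    if add_fixation:
        padded = _overlay_fixation(padded, level=gray_level)

    final = _resize_bilinear(padded, final_side)

    down_factor = padded_side / final_side
    stim_px = int(round(upsampled_side / down_factor))
    geom = StimulusGeometry(
        grid_side=final_side,
        stimulus_extent_deg=stimulus_extent_deg,
        stimulus_side_px=stim_px,
    )
    img = StimulusImage(values=final, geometry=geom)
    if return_intermediates:
        return img, {"grayscale": gray, "upsampled": up, "padded": padded}
    return img


# --------------------------------------------------------------------------
# steerable pyramid filter bank
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PyramidConfig:
    """Filter-bank layout.

    Channels are enumerated level-major (finest level first), orientation
    minor, with the two non-oriented residual channels (lowpass then
    highpass) appended last when ``include_residuals`` is set.
    ``sqrt_on_maps`` controls whether the square-root (magnitude) step is
    applied to the spatial maps before receptive-field sampling (default)
    or to the sampled energies afterwards.
    """

    n_orientations: int = 8
    n_levels: int = 7
    bandwidth_octaves: float = 1.0
    include_residuals: bool = True
    sqrt_on_maps: bool = True

    def __post_init__(self) -> None:
        if self.n_orientations < 1 or self.n_levels < 1:
            raise ValueError("n_orientations and n_levels must be >= 1")
        if self.bandwidth_octaves <= 0:
            raise ValueError("bandwidth must be positive")

    @property
    def n_channels(self) -> int:
        n = self.n_orientations * self.n_levels
        if self.include_residuals:
            n += 2
        return n

    def channel_labels(self) -> list[str]:
        labels = [
            f"L{lv}_O{o}"
            for lv in range(1, self.n_levels + 1)
            for o in range(self.n_orientations)
        ]
        if self.include_residuals:
            labels += ["lowpass", "highpass"]
        return labels

    def min_side(self) -> int:
        # lowest band center pi/2^(L*bw) must be resolvable on the DFT grid
        return int(2 ** np.ceil(self.n_levels * self.bandwidth_octaves + 2))


@dataclass
class FeatureMapSet:
    """Per-channel nonnegative magnitude maps for one image."""

    maps: np.ndarray  # (n_channels, side, side)
    config: PyramidConfig
    geometry: StimulusGeometry

    def __post_init__(self) -> None:
        if self.maps.ndim != 3:
            raise ValueError("maps must be (n_channels, side, side)")
        if self.maps.shape[0] != self.config.n_channels:
            raise ValueError(
                f"expected {self.config.n_channels} channel maps, got "
                f"{self.maps.shape[0]}"
            )
        if self.maps.shape[1] != self.maps.shape[2]:
            raise ValueError("channel maps must be square")

    @property
    def n_channels(self) -> int:
        return self.maps.shape[0]


def _raised_cosine_lo(log_r: np.ndarray, log_cut: float, bw: float) -> np.ndarray:
    """Lowpass mask: 1 below log_cut - bw, 0 above log_cut, cosine ramp."""
    t = (log_r - log_cut) / bw  # -1 -> passband edge, 0 -> stopband edge
    t = np.clip(t, -1.0, 0.0)
    return np.cos(np.pi / 2.0 * (t + 1.0))


def _angular_windows(theta: np.ndarray, n_orientations: int) -> np.ndarray:
    """One-sided cos^(K-1) angular windows, centers at k*pi/K."""
    k = n_orientations
    windows = np.empty((k,) + theta.shape)
    for i in range(k):
        d = np.mod(theta - np.pi * i / k + np.pi, 2 * np.pi) - np.pi
        w = np.where(np.abs(d) < np.pi / 2, np.cos(d) ** (k - 1), 0.0)
        windows[i] = w
    return windows


def _transfer_functions(side: int, cfg: PyramidConfig) -> np.ndarray:
    """Frequency-domain transfer functions, one per channel, on the DFT grid."""
    f = np.fft.fftfreq(side) * 2 * np.pi  # radians / sample
    fx, fy = np.meshgrid(f, f, indexing="xy")
    # row index runs top->bottom: flip so angle matches y-up image convention
    r = np.hypot(fx, fy)
    theta = np.arctan2(-fy, fx)
    r[0, 0] = (2 * np.pi / side) * 1e-6  # avoid log(0) at DC
    log_r = np.log2(r)

    bw = cfg.bandwidth_octaves
    cuts = [np.log2(np.pi) - lv * bw for lv in range(cfg.n_levels + 1)]

    ang = _angular_windows(theta, cfg.n_orientations)

    tfs = []
    for lv in range(1, cfg.n_levels + 1):
        lo_prev = _raised_cosine_lo(log_r, cuts[lv - 1], bw)
        hi_this = np.sqrt(1.0 - _raised_cosine_lo(log_r, cuts[lv], bw) ** 2)
        radial = lo_prev * hi_this
        for o in range(cfg.n_orientations):
            tfs.append(radial * ang[o] * 2.0)  # x2: analytic-signal amplitude
    if cfg.include_residuals:
        lowpass = _raised_cosine_lo(log_r, cuts[cfg.n_levels], bw)
        highpass = np.sqrt(1.0 - _raised_cosine_lo(log_r, cuts[0], bw) ** 2)
        tfs.append(lowpass)
        tfs.append(highpass)
    return np.stack(tfs)


def decompose(img: StimulusImage, cfg: PyramidConfig | None = None) -> FeatureMapSet:
    """Run the filter bank on a prepared image.

    Oriented channels return the magnitude of the complex (quadrature-pair)
    band-pass coefficient at every pixel — the square root of local energy.
    Residual channels return the absolute value of the (real) lowpass /
    highpass response.  All maps live on the input grid.
    """
    cfg = cfg or PyramidConfig()
    side = img.side
    if side < cfg.min_side():
        raise ValueError(
            f"image side {side} too small for {cfg.n_levels} levels at "
            f"{cfg.bandwidth_octaves}-octave bandwidth (need >= {cfg.min_side()})"
        )
    tfs = _transfer_functions(side, cfg)
    spectrum = fft2(img.values)
    maps = np.abs(ifft2(spectrum[None, :, :] * tfs, axes=(-2, -1)))
    return FeatureMapSet(maps=maps, config=cfg, geometry=img.geometry)


# --------------------------------------------------------------------------
# pRF sampling
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PRF:
    """Isotropic 2-D Gaussian receptive field in degrees of visual angle."""

    x0: float
    y0: float
    sigma: float
    prf_r2: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite([self.x0, self.y0, self.sigma, self.prf_r2]).all():
            raise ValueError("PRF parameters must be finite")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")

    @property
    def included(self) -> bool:
        return self.prf_r2 > 0

    def weights_1d(self, geom: StimulusGeometry) -> tuple[np.ndarray, np.ndarray]:
        """Separable (row, column) Gaussian weight vectors on the grid."""
        x_deg, y_deg = geom.pixel_grid_deg()
        wx = np.exp(-((self.x0 - x_deg) ** 2) / (2 * self.sigma**2))
        wy = np.exp(-((self.y0 - y_deg) ** 2) / (2 * self.sigma**2))
        return wy, wx


def sample_prf(map2d: np.ndarray, prf: PRF, geom: StimulusGeometry) -> float:
    """Dot product of one channel map with the (unnormalized) pRF Gaussian.

    The Gaussian weight at the pRF center is exactly 1; no normalization
    constant is applied, so the output scales with sigma^2 for a uniform
    map.
    """
    map2d = np.asarray(map2d, dtype=float)
    if map2d.shape != (geom.grid_side, geom.grid_side):
        raise ValueError(
            f"map shape {map2d.shape} does not match geometry grid "
            f"({geom.grid_side})"
        )
    wy, wx = prf.weights_1d(geom)
    return float(wy @ map2d @ wx)


def sample_features(fms: FeatureMapSet, prf: PRF) -> np.ndarray:
    """Sample every channel map of one image with one pRF (length C vector)."""
    wy, wx = prf.weights_1d(fms.geometry)
    sampled = np.einsum("r,crk,k->c", wy, fms.maps, wx)
    if not fms.config.sqrt_on_maps:
        # alternative reading: pool energy under the pRF, then square-root
        energy = np.einsum("r,crk,k->c", wy, fms.maps**2, wx)
        sampled = np.sqrt(energy)
    return sampled


# --------------------------------------------------------------------------
# design matrices
# --------------------------------------------------------------------------

@dataclass
class VoxelFeatures:
    """Design matrix for one voxel: images x (channels + constant)."""

    matrix: np.ndarray
    image_ids: list

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2:
            raise ValueError("design matrix must be 2-D")
        if len(self.image_ids) != m.shape[0]:
            raise ValueError("image_ids must align with matrix rows")
        if not np.all(np.isfinite(m)):
            raise ValueError("design matrix contains non-finite values")
        if not np.allclose(m[:, -1], 1.0):
            raise ValueError("last design column must be the constant 1")
        object.__setattr__(self, "matrix", m)

    @property
    def n_images(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[1] - 1


def build_design_matrices(
    images: list[StimulusImage],
    prfs: list[PRF],
    cfg: PyramidConfig | None = None,
    image_ids: list | None = None,
) -> list[VoxelFeatures]:
    """Build one design matrix per pRF, decomposing each image only once."""
    if not images:
        raise ValueError("need at least one image")
    cfg = cfg or PyramidConfig()
    sides = {img.side for img in images}
    if len(sides) != 1:
        raise ValueError(f"inconsistent image grids: sides {sorted(sides)}")
    if image_ids is None:
        image_ids = list(range(len(images)))

    n_img, n_vox = len(images), len(prfs)
    rows = np.empty((n_vox, n_img, cfg.n_channels))
    for j, img in enumerate(images):
        fms = decompose(img, cfg)
        for i, prf in enumerate(prfs):
            rows[i, j] = sample_features(fms, prf)

    out = []
    const = np.ones((n_img, 1))
    for i in range(n_vox):
        out.append(
            VoxelFeatures(
                matrix=np.hstack([rows[i], const]), image_ids=list(image_ids)
            )
        )
    return out


def build_design_matrix(
    images: list[StimulusImage],
    prf: PRF,
    cfg: PyramidConfig | None = None,
    image_ids: list | None = None,
) -> VoxelFeatures:
    """Design matrix for a single voxel (see :func:`build_design_matrices`)."""
    return build_design_matrices(images, [prf], cfg, image_ids)[0]
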