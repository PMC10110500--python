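"""Image restoration: PSF modelling, Nyquist calculator, deconvolution, quality metrics.

The imaging model is ``y = H x + n``: the observed stack ``y`` is the true
fluorophore distribution ``x`` blurred by the microscope's point spread
function ``H`` plus noise. This module provides

* a Nyquist sampling calculator (how finely to sample given NA, excitation
  wavelength and immersion refractive index),
* a scalar-diffraction (Born–Wolf class) widefield theoretical PSF,
* three deconvolution solvers: Regularized Inverse Filter (one-shot,
  Fourier domain), Landweber (projected gradient descent) and
  Richardson–Lucy (multiplicative updates under a Poisson noise model), and
* ROI-based contrast-to-noise (CNR) and signal-to-noise (SNR) metrics.

The iterative solvers use the exact adjoint pair of the zero-padded
convolution operator, which makes Richardson–Lucy conserve total flux to
floating-point precision for a normalized PSF.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, special
from scipy.fft import next_fast_len

from .volimage import VoxelGrid3D

__all__ = [
    "AcquisitionParams",
    "PSFModel",
    "DeconvSettings",
    "RoiIntensityStats",
    "CircularROI",
    "nyquist_sampling",
    "theoretical_psf",
    "convolve_psf",
    "rif_deconvolve",
    "landweber_deconvolve",
    "richardson_lucy",
    "cnr",
    "snr",
    "roi_stats_from_image",
]


@dataclass(frozen=True)
class AcquisitionParams:
    """Optical acquisition parameters.

    na: objective numerical aperture; lambda_ex / lambda_em: excitation and
    emission wavelengths in nm; ri: lens immersion refractive index;
    photons: excitation photon count (1 = single photon); detector: array
    (e.g. 32-element) or plain confocal point detector.
    """

    na: float
    lambda_ex: float
    lambda_em: float
    ri: float = 1.338
    photons: int = 1
    detector: str = "array"

    def __post_init__(self):
        if not (0 < self.na <= self.ri):
            raise ValueError(f"need 0 < NA <= refractive index, got NA={self.na}, ri={self.ri}")
        for lam, name in ((self.lambda_ex, "lambda_ex"), (self.lambda_em, "lambda_em")):
            if not (300 < lam < 800):
                raise ValueError(f"{name} must be in (300, 800) nm, got {lam}")


@dataclass
class PSFModel:
    """Normalized 3D PSF kernel (sum = 1), indexed (z, y, x), odd shape."""

    kernel: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self):
        self.kernel = np.asarray(self.kernel, dtype=np.float64)
        if self.kernel.ndim != 3:
            raise ValueError("PSF kernel must be 3D")
        if np.any(self.kernel < 0):
            raise ValueError("PSF kernel must be non-negative")
        s = self.kernel.sum()
        if s <= 0:
            raise ValueError("PSF kernel sums to zero")
        if abs(s - 1.0) > 1e-9:
            self.kernel = self.kernel / s

    @classmethod
    def delta(cls, shape=(1, 1, 1), voxel_size=(1.0, 1.0, 1.0)) -> "PSFModel":
        k = np.zeros(shape)
        k[tuple(s // 2 for s in shape)] = 1.0
        return cls(k, voxel_size)


@dataclass(frozen=True)
class DeconvSettings:
    """Solver choice and hyperparameters.

    lambda_reg: Tikhonov/Laplacian regularization weight for the inverse
    filter (default 1e-18, i.e. numerically almost unregularized).
    m_iter: iteration count (Landweber default 15; Richardson–Lucy 1 or 5).
    gamma: Landweber step size (default 1.5).
    """

    algorithm: str = "rl"
    lambda_reg: float = 1.0e-18
    m_iter: int = 15
    gamma: float = 1.5

    def __post_init__(self):
        if self.algorithm not in ("rif", "landweber", "rl"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.m_iter < 1 or self.gamma <= 0 or self.lambda_reg < 0:
            raise ValueError("need m_iter >= 1, gamma > 0, lambda_reg >= 0")


@dataclass(frozen=True)
class RoiIntensityStats:
    """mu_s: mean signal; mu_ns: mean non-signal (inside tissue, no cellular
    signal); sigma_bg: sd of the background (outside the tissue)."""

    mu_s: float
    mu_ns: float
    sigma_bg: float

    def __post_init__(self):
        if self.sigma_bg < 0:
            raise ValueError("sigma_bg must be >= 0")


# -- Nyquist ------------------------------------------------------------------

def nyquist_sampling(params: AcquisitionParams) -> tuple[int, int, int]:
    """Nyquist voxel spacing (dx, dy, dz) in integer nanometres.

    Half-angle alpha = arcsin(NA / ri); lateral spacing
    lambda_ex / (8 ri sin alpha) = lambda_ex / (8 NA); axial spacing
    lambda_ex / (4 ri (1 - cos alpha)). Values are truncated to whole nm.
    """
    if params.na >= params.ri:
        raise ValueError("NA must be < refractive index (half-angle undefined)")
    alpha = math.asin(params.na / params.ri)
    lateral = params.lambda_ex / (8.0 * params.ri * math.sin(alpha))
    axial = params.lambda_ex / (4.0 * params.ri * (1.0 - math.cos(alpha)))
    return (int(lateral), int(lateral), int(axial))


# -- theoretical PSF ----------------------------------------------------------

def theoretical_psf(
    params: AcquisitionParams,
    voxel_size: tuple[float, float, float],
    shape: tuple[int, int, int] = (9, 15, 15),
    n_quad: int = 96,
) -> PSFModel:
    """Scalar-diffraction widefield intensity PSF sampled on a voxel grid.

    Evaluates the Born–Wolf pupil integral
    ``h(r, z) = | \\int_0^1 J0(k NA r rho) exp(-i k NA^2 z rho^2 / (2 ri)) rho drho |^2``
    with ``k = 2 pi / lambda_em``, by Gauss–Legendre quadrature, then
    normalizes the kernel to sum 1. ``shape`` must be odd in every
    dimension so the peak sits on a grid point.
    """
    if any(s % 2 == 0 for s in shape):
        raise ValueError(f"PSF shape must be odd in all dimensions, got {shape}")
    dx, dy, dz = (float(v) for v in voxel_size)
    lam_um = params.lambda_em * 1e-3  # nm -> µm
    nyq = nyquist_sampling(params) if params.na < params.ri else None
    if nyq is not None and (dx * 1e3 > 2 * nyq[0] or dz * 1e3 > 2 * nyq[2]):
        warnings.warn(
            f"voxel size ({dx:.3f}, {dy:.3f}, {dz:.3f}) µm is much coarser than "
            f"Nyquist {nyq} nm; the sampled PSF is close to a delta",
            stacklevel=2,
        )
    k = 2.0 * math.pi / lam_um
    nz, ny, nx = shape
    zc, yc, xc = nz // 2, ny // 2, nx // 2
    z = (np.arange(nz) - zc) * dz
    y = (np.arange(ny) - yc) * dy
    x = (np.arange(nx) - xc) * dx
    r = np.sqrt(y[:, None] ** 2 + x[None, :] ** 2)  # (ny, nx)

    nodes, wts = np.polynomial.legendre.leggauss(n_quad)
    rho = 0.5 * (nodes + 1.0)  # map [-1,1] -> [0,1]
    w = 0.5 * wts
    bessel = special.j0(k * params.na * r[..., None] * rho)  # (ny, nx, K)
    kernel = np.empty(shape, dtype=np.float64)
    for iz in range(nz):
        phase = np.exp(-1j * k * params.na**2 * z[iz] * rho**2 / (2.0 * params.ri))
        amp = np.tensordot(bessel, w * rho * phase, axes=([2], [0]))
        kernel[iz] = np.abs(amp) ** 2
    return PSFModel(kernel / kernel.sum(), (dx, dy, dz))


# -- convolution operator and adjoint ----------------------------------------

def _conv(data: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    return ndimage.convolve(data, kernel, mode="constant", cval=0.0)


def _conv_adjoint(data: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    # the adjoint of zero-padded convolution is zero-padded correlation
    return ndimage.correlate(data, kernel, mode="constant", cval=0.0)


def convolve_psf(x: VoxelGrid3D, psf: PSFModel) -> VoxelGrid3D:
    """Blur a grid with the PSF (linear, shift-invariant, zero-padded edges)."""
    if any(k > s for k, s in zip(psf.kernel.shape, x.shape)):
        raise ValueError(f"PSF {psf.kernel.shape} larger than image {x.shape}")
    return x.with_data(_conv(x.data.astype(np.float64), psf.kernel))


# -- Regularized Inverse Filter ----------------------------------------------

_LAPLACIAN_3D = np.zeros((3, 3, 3))
_LAPLACIAN_3D[1, 1, 1] = -6.0
for _off in ((0, 1, 1), (2, 1, 1), (1, 0, 1), (1, 2, 1), (1, 1, 0), (1, 1, 2)):
    _LAPLACIAN_3D[_off] = 1.0


def _otf(kernel: np.ndarray, shape) -> np.ndarray:
    """Kernel embedded at the origin (wrap-around) and FFT'd."""
    padded = np.zeros(shape)
    padded[tuple(slice(0, s) for s in kernel.shape)] = kernel
    padded = np.roll(padded, [-(s // 2) for s in kernel.shape], axis=(0, 1, 2))
    return np.fft.fftn(padded)


def rif_deconvolve(
    y: VoxelGrid3D, psf: PSFModel, lambda_reg: float = 1.0e-18
) -> VoxelGrid3D:
    """Regularized Inverse Filter.

    Minimizes ``||H x - y||^2 + lambda ||L x||^2`` (L = discrete 3D
    Laplacian) in the Fourier domain:
    ``X = conj(H) Y / (|H|^2 + lambda |L|^2)``.
    Frequencies where the denominator underflows are zeroed (with a
    warning) — with ``lambda = 0`` and a band-limited PSF the problem is
    ill-posed there.
    """
    data = y.data.astype(np.float64)
    full = [next_fast_len(s + k - 1) for s, k in zip(data.shape, psf.kernel.shape)]
    ydft = np.fft.fftn(data, s=full)
    hdft = _otf(psf.kernel, full)
    ldft = _otf(_LAPLACIAN_3D, full) if lambda_reg > 0 else 0.0
    denom = np.abs(hdft) ** 2 + lambda_reg * np.abs(ldft) ** 2
    bad = denom <= np.finfo(np.float64).tiny
    if np.any(bad):
        warnings.warn(
            f"{int(bad.sum())} spectral coefficients have zero gain "
            "(ill-posed without regularization); they were suppressed",
            stacklevel=2,
        )
        denom = np.where(bad, 1.0, denom)
    xdft = np.conj(hdft) * ydft / denom
    if np.any(bad):
        xdft[bad] = 0.0
    x = np.real(np.fft.ifftn(xdft))[tuple(slice(0, s) for s in data.shape)]
    return y.with_data(x)


# -- Landweber ----------------------------------------------------------------

def landweber_deconvolve(
    y: VoxelGrid3D, psf: PSFModel, m_iter: int = 15, gamma: float = 1.5
) -> VoxelGrid3D:
    """Projected Landweber iteration.

    ``x_{k+1} = P+[ x_k + gamma H^T (y - H x_k) ]`` from ``x_0 = 0``, where
    ``P+`` clamps to non-negative values. Stable for
    ``gamma < 2 / ||H||^2``; divergence (norm growth beyond 1e6 of the
    data norm) raises, naming the step size.
    """
    data = y.data.astype(np.float64)
    k = psf.kernel
    x = np.zeros_like(data)
    ynorm = np.linalg.norm(data) + np.finfo(np.float64).tiny
    for _ in range(m_iter):
        residual = data - _conv(x, k)
        x = np.clip(x + gamma * _conv_adjoint(residual, k), 0.0, None)
        if np.linalg.norm(x) > 1e6 * ynorm:
            raise FloatingPointError(
                f"Landweber diverged: step size gamma={gamma} too large for this PSF"
            )
    return y.with_data(x)


# -- Richardson–Lucy ----------------------------------------------------------

def richardson_lucy(y: VoxelGrid3D, psf: PSFModel, m_iter: int = 5) -> VoxelGrid3D:
    """Richardson–Lucy deconvolution (maximum likelihood under Poisson noise).

    Multiplicative updates ``x_{k+1} = x_k * H^T( y / (H x_k) )`` starting
    from ``x_0 = y``; zero denominators are guarded with an epsilon of
    1e-12 of the data maximum. A normalized PSF makes every iterate
    conserve total flux.
    """
    data = y.data.astype(np.float64)
    if np.any(data < 0):
        raise ValueError("Richardson–Lucy requires non-negative input")
    k = psf.kernel
    eps = 1e-12 * (data.max() if data.max() > 0 else 1.0)
    x = data.copy()
    for _ in range(m_iter):
        blurred = _conv(x, k)
        ratio = data / np.maximum(blurred, eps)
        # voxels where the model predicts ~0 but the data is 0 contribute 0/0
        ratio[(blurred <= eps) & (data <= eps)] = 0.0
        x = x * _conv_adjoint(ratio, k)
    return y.with_data(x)


# -- quality metrics ----------------------------------------------------------

def cnr(stats: RoiIntensityStats) -> float:
    """Contrast-to-noise ratio: (mu_s - mu_ns) / sigma_bg."""
    if stats.sigma_bg == 0:
        raise ValueError("sigma_bg is zero: CNR undefined")
    return (stats.mu_s - stats.mu_ns) / stats.sigma_bg


def snr(stats: RoiIntensityStats) -> float:
    """Signal-to-noise ratio: mu_s / sigma_bg."""
    if stats.sigma_bg == 0:
        raise ValueError("sigma_bg is zero: SNR undefined")
    return stats.mu_s / stats.sigma_bg


@dataclass(frozen=True)
class CircularROI:
    """Circular ROI on one z slice: center (x, y) px, diameter in µm."""

    x: float
    y: float
    z: int
    diameter_um: float


def _roi_pixels(grid: VoxelGrid3D, roi: CircularROI) -> np.ndarray:
    dx, dy, _ = grid.require_calibration()
    nz, h, w = grid.shape
    if not (0 <= roi.z < nz):
        raise ValueError(f"ROI z={roi.z} outside stack (0..{nz - 1})")
    r_px = roi.diameter_um / 2.0 / dx
    if not (0 <= roi.x < w and 0 <= roi.y < h):
        raise ValueError("ROI center outside image bounds")
    if roi.x - r_px < -0.5 or roi.x + r_px > w - 0.5 or roi.y - r_px < -0.5 or roi.y + r_px > h - 0.5:
        raise ValueError("ROI extends outside image bounds")
    yy, xx = np.mgrid[0:h, 0:w]
    mask = (xx - roi.x) ** 2 + (yy - roi.y) ** 2 <= r_px**2
    if not mask.any():  # radius below half a pixel: use the nearest pixel
        mask[int(round(roi.y)), int(round(roi.x))] = True
    return grid.data[roi.z][mask].astype(np.float64)


def roi_stats_from_image(
    grid: VoxelGrid3D,
    roi_signal: CircularROI,
    roi_nonsignal: CircularROI,
    roi_background: CircularROI,
) -> RoiIntensityStats:
    """Measure CNR/SNR statistics from three circular ROIs (3–5 µm diameter):
    signal on a cell structure, non-signal inside the tissue, background
    outside it. sigma_bg is the population sd of the background ROI.
    """
    mu_s = float(_roi_pixels(grid, roi_signal).mean())
    mu_ns = float(_roi_pixels(grid, roi_nonsignal).mean())
    sigma_bg = float(_roi_pixels(grid, roi_background).std(ddof=0))
    return RoiIntensityStats(mu_s=mu_s, mu_ns=mu_ns, sigma_bg=sigma_bg)
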