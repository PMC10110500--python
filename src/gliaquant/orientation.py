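"""Fibre orientation and alignment analysis by windowed Fourier transform.

Radial glia form a near-parallel fibre array along the apicobasal axis;
how well aligned the fibres are is a developmental readout. The image
(a 2D maximum projection of a standardized stack) is tiled into
overlapping windows; in each window the 2D FFT power spectrum's
second-moment tensor gives the dominant real-space fibre orientation
(perpendicular to the spectral major axis), an angle θ in [0°, 180°).
Local alignment is then scored per window as the nematic order parameter
S = ⟨cos 2(θ_i − θ_j)⟩ over the neighborhood of windows within a given
(Chebyshev) radius: S = 1 for perfectly parallel fibres, S ≈ 0 for an
isotropic field. Background windows (mean intensity at or below a cutoff)
and windows without spectral anisotropy are excluded throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "OrientationField",
    "OrderMap",
    "normalize_image_sizes",
    "local_orientation",
    "order_parameter",
    "apicobasal_order_profile",
]


@dataclass
class OrientationField:
    """Per-window dominant orientations.

    angles: θ in degrees, [0, 180), NaN where invalid; valid: which
    windows carry a defined orientation; centers_y/x: window center pixel
    coordinates; mean_intensity: per-window mean of the source image
    (used later for background masking)."""

    angles: np.ndarray
    valid: np.ndarray
    centers_y: np.ndarray
    centers_x: np.ndarray
    mean_intensity: np.ndarray
    window_px: int
    overlap: float


@dataclass
class OrderMap:
    """Per-window nematic order S in [-1, 1]; NaN where the window is
    excluded (background, blank, or undefined orientation)."""

    values: np.ndarray
    valid: np.ndarray
    neighbor_radius: int


def normalize_image_sizes(images, saturation: float = 0.35):
    """Make a batch of 2D images comparable in size.

    Each image gets a linear percentile contrast stretch (``saturation``
    percent clipped at each tail), then is padded with zeros at the bottom
    (top-to-top alignment preserves the apical edge) and at the right, up
    to the largest height/width in the batch. Returns
    ``(padded_list, (target_h, target_w))``.
    """
    images = [np.asarray(im, dtype=np.float64) for im in images]
    if not images:
        raise ValueError("no images given")
    target_h = max(im.shape[0] for im in images)
    target_w = max(im.shape[1] for im in images)
    out = []
    for im in images:
        lo, hi = np.percentile(im, [saturation, 100.0 - saturation])
        if hi > lo:
            im = np.clip((im - lo) / (hi - lo), 0.0, 1.0) * 255.0
        padded = np.zeros((target_h, target_w), dtype=np.float64)
        padded[: im.shape[0], : im.shape[1]] = im
        out.append(padded)
    return out, (target_h, target_w)


def _window_orientation(tile: np.ndarray) -> float:
    """Dominant real-space orientation of one tile, degrees in [0, 180).

    The Hann-windowed power spectrum's second-moment tensor is computed
    over centred frequencies (DC removed); its major eigenvector is the
    direction of dominant spectral energy, which lies perpendicular to
    the real-space fibre direction. NaN if the spectrum is isotropic or
    empty (constant tile).
    """
    tile = tile - tile.mean()
    if np.allclose(tile, 0.0):
        return float("nan")
    h, w = tile.shape
    hann = np.outer(np.hanning(h), np.hanning(w))
    power = np.abs(np.fft.fftshift(np.fft.fft2(tile * hann))) ** 2
    cy, cx = h // 2, w // 2
    fy = (np.arange(h) - cy)[:, None].astype(np.float64)
    fx = (np.arange(w) - cx)[None, :].astype(np.float64)
    power[cy, cx] = 0.0  # remove DC
    total = power.sum()
    if total <= 0:
        return float("nan")
    # second moments of spectral energy about the origin
    mxx = (power * fx * fx).sum() / total
    myy = (power * fy * fy).sum() / total
    mxy = (power * fx * fy).sum() / total
    # anisotropy check: eigenvalue gap of the 2x2 tensor
    tr = mxx + myy
    det = mxx * myy - mxy * mxy
    disc = max(tr * tr / 4.0 - det, 0.0)
    lam1 = tr / 2.0 + np.sqrt(disc)
    lam2 = tr / 2.0 - np.sqrt(disc)
    if lam1 <= 0 or (lam1 - lam2) / lam1 < 1e-6:
        return float("nan")  # isotropic spectrum: orientation undefined
    # major-axis angle of the spectral tensor, in pixel-frequency coords
    theta_spec = 0.5 * np.degrees(np.arctan2(2.0 * mxy, mxx - myy))
    # fibres run perpendicular to the dominant spectral direction;
    # negate to convert the y-down pixel frame to the conventional
    # y-up angle frame
    theta = -(theta_spec + 90.0)
    return float(theta % 180.0)


def local_orientation(
    image: np.ndarray, window_px: int = 100, overlap: float = 0.5
) -> OrientationField:
    """Tile the image and measure the dominant orientation per tile.

    Stride is ``window_px * (1 - overlap)``. Tiles that are constant or
    spectrally isotropic are marked invalid.
    """
    image = np.asarray(image, dtype=np.float64)
    h, w = image.shape
    if h < window_px or w < window_px:
        raise ValueError(
            f"image {image.shape} smaller than one {window_px}-px window"
        )
    stride = max(1, int(round(window_px * (1.0 - overlap))))
    ys = np.arange(0, h - window_px + 1, stride)
    xs = np.arange(0, w - window_px + 1, stride)
    angles = np.full((len(ys), len(xs)), np.nan)
    meanint = np.zeros((len(ys), len(xs)))
    for i, y0 in enumerate(ys):
        for j, x0 in enumerate(xs):
            tile = image[y0 : y0 + window_px, x0 : x0 + window_px]
            meanint[i, j] = tile.mean()
            angles[i, j] = _window_orientation(tile)
    valid = ~np.isnan(angles)
    return OrientationField(
        angles=angles,
        valid=valid,
        centers_y=ys + window_px / 2.0,
        centers_x=xs + window_px / 2.0,
        mean_intensity=meanint,
        window_px=window_px,
        overlap=overlap,
    )


def order_parameter(
    field: OrientationField,
    neighbor_radius: int = 3,
    mask_background_mean: float = 5.0,
    ignore_blank: bool = True,
) -> OrderMap:
    """Nematic order per window over its Chebyshev-radius neighborhood.

    A window is excluded if its mean intensity is at or below
    ``mask_background_mean`` (background), if it is blank, or if its own
    orientation is undefined. For an included window i,
    ``S_i = mean_j cos(2 (θ_i − θ_j))`` over included neighbors j with
    ``max(|Δrow|, |Δcol|) <= neighbor_radius`` (j ≠ i).
    """
    usable = field.valid.copy()
    usable &= field.mean_intensity > mask_background_mean
    if ignore_blank:
        usable &= field.mean_intensity > 0
    if not usable.any():
        raise ValueError("no valid windows above the background cutoff")

    nrows, ncols = field.angles.shape
    theta = np.radians(field.angles)
    values = np.full((nrows, ncols), np.nan)
    for i in range(nrows):
        for j in range(ncols):
            if not usable[i, j]:
                continue
            r0, r1 = max(0, i - neighbor_radius), min(nrows, i + neighbor_radius + 1)
            c0, c1 = max(0, j - neighbor_radius), min(ncols, j + neighbor_radius + 1)
            nb_mask = usable[r0:r1, c0:c1].copy()
            nb_mask[i - r0, j - c0] = False
            if not nb_mask.any():
                values[i, j] = 1.0  # lone window: trivially self-aligned
                continue
            d = theta[r0:r1, c0:c1][nb_mask] - theta[i, j]
            values[i, j] = float(np.cos(2.0 * d).mean())
    return OrderMap(values=values, valid=~np.isnan(values), neighbor_radius=neighbor_radius)


def apicobasal_order_profile(ordermap: OrderMap) -> np.ndarray:
    """Mean order per window-row (x averaged, iterated over y, apical
    first); rows with no valid window yield NaN."""
    vals = ordermap.values
    out = np.full(vals.shape[0], np.nan)
    for i in range(vals.shape[0]):
        row = vals[i][ordermap.valid[i]]
        if row.size:
            out[i] = row.mean()
    return out
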