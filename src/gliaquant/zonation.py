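"""Apicobasal zonation profiling.

A standardized stack is reduced to a single intensity value per apicobasal
position: projecting along ``z`` and then along ``x`` leaves a 1D profile
over ``y`` (apical at index 0). Radial glia show a stereotyped layered
intensity pattern along this axis — honeycomb-like apical processes, soma
band, plexiform protrusions, basal endfeet — so the profile is a compact,
comparable readout of tissue zonation. Profiles from stacks of different
heights are rescaled to a common length (1920 samples by default) by
linear interpolation before aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volimage import VoxelGrid3D, project, to_8bit

__all__ = [
    "ZonationProfile",
    "ZonationMeasurements",
    "zonation_profile",
    "normalize_profile",
    "zonation_measurements",
    "aggregate_profiles",
    "profile_heatmap",
]

NORMALIZED_LENGTH = 1920


@dataclass
class ZonationProfile:
    """1D apicobasal intensity vector (index 0 = apical)."""

    values: np.ndarray
    reducer: str = "max"
    normalized_to: int | None = None
    source: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("profile values must be 1D")
        if np.any(self.values < 0):
            raise ValueError("profile intensities must be non-negative")

    @property
    def length_px(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class ZonationMeasurements:
    """Total image height I_N and retina height R_N, µm.

    R_N subtracts the sigma extension that the subregion step attached
    basally, so it measures tissue rather than box."""

    I_N: float
    R_N: float

    def __post_init__(self):
        if not (0 < self.R_N <= self.I_N):
            raise ValueError(f"need 0 < R_N <= I_N, got R_N={self.R_N}, I_N={self.I_N}")


def zonation_profile(
    grid: VoxelGrid3D, reducer: str = "max", convert_8bit: bool = True, source: str = ""
) -> ZonationProfile:
    """Double projection to a 1D apicobasal profile: p[y] = reduce over (z, x).

    The stack is min–max converted to 8-bit first (so profiles from
    different bit depths are comparable); ``max`` matches MIP semantics
    and is the default, ``mean`` is offered for saturation-prone data.
    """
    if grid.data.size == 0:
        raise ValueError("empty grid")
    g = to_8bit(grid) if convert_8bit else grid
    plane = project(g, axis="z", reducer=reducer)  # (y, x)
    if reducer == "max":
        values = plane.max(axis=1)
    elif reducer == "mean":
        values = plane.mean(axis=1)
    else:
        raise ValueError(f"reducer must be 'max' or 'mean', got {reducer!r}")
    return ZonationProfile(values.astype(np.float64), reducer=reducer, source=source)


def normalize_profile(profile: ZonationProfile, target: int = NORMALIZED_LENGTH) -> ZonationProfile:
    """Resample to ``target`` samples by linear interpolation, endpoints kept.

    (The 2D bilinear rescale degenerates to 1D linear interpolation on a
    profile.)"""
    if target < 2:
        raise ValueError(f"target length must be >= 2, got {target}")
    n = profile.length_px
    if n < 2:
        raise ValueError("profile must have at least 2 samples")
    x_new = np.linspace(0.0, n - 1.0, target)
    values = np.interp(x_new, np.arange(n), profile.values)
    return ZonationProfile(
        values, reducer=profile.reducer, normalized_to=target, source=profile.source
    )


def zonation_measurements(grid: VoxelGrid3D, sigma_um: float) -> ZonationMeasurements:
    """I_N = image height in µm; R_N = I_N minus the basal sigma extension."""
    _, dy, _ = grid.require_calibration()
    i_n = grid.shape[1] * dy
    if sigma_um >= i_n:
        raise ValueError(f"sigma ({sigma_um} µm) must be smaller than image height ({i_n} µm)")
    return ZonationMeasurements(I_N=i_n, R_N=i_n - sigma_um)


def aggregate_profiles(profiles) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-position mean and sample sd (ddof=1) across profiles.

    Returns ``(summary, matrix)``: summary has columns position/mean/sd/n;
    matrix holds one column per sample. All profiles must share a length —
    normalize first otherwise.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles given")
    lengths = {p.length_px for p in profiles}
    if len(lengths) > 1:
        raise ValueError(
            f"profiles have mixed lengths {sorted(lengths)}; "
            "apply normalize_profile first"
        )
    names = [p.source or f"sample{i}" for i, p in enumerate(profiles)]
    # column_stack keeps duplicate sample names as separate columns
    matrix = pd.DataFrame(np.column_stack([p.values for p in profiles]), columns=names)
    matrix.index.name = "position"
    mean = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=1) if len(profiles) > 1 else pd.Series(0.0, index=matrix.index)
    summary = pd.DataFrame(
        {"position": matrix.index, "mean": mean.values, "sd": sd.fillna(0.0).values,
         "n": len(profiles)}
    )
    return summary, matrix


def profile_heatmap(
    profile: ZonationProfile, colormap: str = "afmhot", strip_width: int = 32
) -> np.ndarray:
    """Render a profile as a vertical color strip (RGB uint8, apical at top).

    ``afmhot`` approximates the classic black-red-yellow-white "fire" LUT.
    The underlying grayscale values equal the profile values, so the strip
    is invertible up to 8-bit quantization.
    """
    import matplotlib
    cmap = matplotlib.colormaps[colormap]
    norm = profile.values / 255.0 if profile.values.max() <= 255 else (
        profile.values / profile.values.max()
    )
    rgba = cmap(np.clip(norm, 0.0, 1.0))  # (L, 4)
    rgb = (rgba[:, :3] * 255).astype(np.uint8)
    return np.repeat(rgb[:, None, :], strip_width, axis=1)  # (L, W, 3)
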