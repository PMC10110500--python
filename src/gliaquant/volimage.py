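"""Calibrated 3D image containers and TIFF I/O.

All stacks in this package are carried as :class:`VoxelGrid3D`: a scalar
array indexed ``(z, y, x)`` with a physical voxel size in micrometres.
The ``y`` axis is the apicobasal tissue axis, apical at ``y = 0`` and
basal at ``y = max`` — every downstream module (subregion cropping,
zonation profiling, orientation profiles) relies on this convention.

Multi-channel images are a :class:`ChannelStack`: an ordered list of
grids sharing shape and calibration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "VoxelGrid3D",
    "ChannelStack",
    "load_stack",
    "save_stack",
    "project",
    "to_8bit",
]

_AXES = {"z": 0, "y": 1, "x": 2}


@dataclass
class VoxelGrid3D:
    """A calibrated 3D scalar grid indexed (z, y, x).

    Parameters
    ----------
    data:
        3D array; dtype uint8, uint16 or floating.
    voxel_size:
        ``(dx, dy, dz)`` in µm, all strictly positive. ``None`` marks an
        uncalibrated grid; operations that report µm refuse to run on it.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D (z, y, x) data, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError("all dimensions must be >= 1")
        if self.voxel_size is not None:
            vs = tuple(float(v) for v in self.voxel_size)
            if len(vs) != 3 or any(v <= 0 for v in vs):
                raise ValueError(f"voxel_size must be three positive lengths, got {self.voxel_size}")
            self.voxel_size = vs

    # -- convenience accessors ------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def dx(self) -> float:
        return self.require_calibration()[0]

    @property
    def dy(self) -> float:
        return self.require_calibration()[1]

    @property
    def dz(self) -> float:
        return self.require_calibration()[2]

    @property
    def voxel_volume(self) -> float:
        dx, dy, dz = self.require_calibration()
        return dx * dy * dz

    def require_calibration(self) -> tuple[float, float, float]:
        if self.voxel_size is None:
            raise ValueError(
                "grid is uncalibrated: voxel size in µm is required for this "
                "operation (pass voxel_override when loading)"
            )
        return self.voxel_size

    def with_data(self, data: np.ndarray) -> "VoxelGrid3D":
        """New grid with the same calibration and replacement data."""
        return VoxelGrid3D(data, self.voxel_size)

    def copy(self) -> "VoxelGrid3D":
        return VoxelGrid3D(self.data.copy(), self.voxel_size)


@dataclass
class ChannelStack:
    """Ordered channels sharing shape and calibration."""

    channels: list[VoxelGrid3D]
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.channels) < 1:
            raise ValueError("ChannelStack needs at least one channel")
        ref = self.channels[0]
        for ch in self.channels[1:]:
            if ch.shape != ref.shape:
                raise ValueError("channels differ in shape")
            if ch.voxel_size != ref.voxel_size:
                raise ValueError("channels differ in calibration")
        if not self.names:
            self.names = [f"ch{i}" for i in range(len(self.channels))]
        if len(self.names) != len(self.channels):
            raise ValueError("names/channels length mismatch")

    def __len__(self) -> int:
        return len(self.channels)

    def __getitem__(self, i: int) -> VoxelGrid3D:
        return self.channels[i]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.channels[0].shape

    @property
    def voxel_size(self):
        return self.channels[0].voxel_size

    def map(self, fn) -> "ChannelStack":
        """Apply ``fn`` grid-by-grid, keeping channel names."""
        return ChannelStack([fn(ch) for ch in self.channels], list(self.names))

    @classmethod
    def single(cls, grid: VoxelGrid3D, name: str = "ch0") -> "ChannelStack":
        return cls([grid], [name])


# -- TIFF I/O -----------------------------------------------------------------

def _calibration_from_tiff(tf: tifffile.TiffFile):
    """(dx, dy, dz) µm from ImageJ metadata / resolution tags, else None."""
    dx = dy = dz = None
    ij = tf.imagej_metadata or {}
    if "spacing" in ij:
        dz = float(ij["spacing"])
    page = tf.pages[0]
    # ImageJ writes XResolution/YResolution as pixels per unit.
    xres = page.tags.get("XResolution")
    yres = page.tags.get("YResolution")
    if xres is not None:
        num, den = xres.value
        if num:
            dx = den / num
    if yres is not None:
        num, den = yres.value
        if num:
            dy = den / num
    unit = (ij.get("unit") or "").lower()
    if unit in ("micron", "um", "µm", "\\u00b5m", ""):
        pass  # already µm (or unknown — accept as µm, ImageJ convention)
    elif unit in ("mm",):
        dx = dx * 1000 if dx else dx
        dy = dy * 1000 if dy else dy
        dz = dz * 1000 if dz else dz
    if dx and dy and dz:
        return (dx, dy, dz)
    return None


def load_stack(path, voxel_override: tuple[float, float, float] | None = None) -> ChannelStack:
    """Load a TIFF as a calibrated :class:`ChannelStack`.

    Accepts 2D ``(y, x)``, 3D ``(z, y, x)`` and 4D ``(z, c, y, x)`` or
    ``(c, z, y, x)`` layouts (axis roles taken from TIFF axes metadata when
    present). Calibration is read from ImageJ tags; ``voxel_override``
    replaces or supplies it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"file not found: {path}")
    try:
        with tifffile.TiffFile(path) as tf:
            series = tf.series[0]
            data = series.asarray()
            axes = series.axes  # e.g. 'YX', 'ZYX', 'ZCYX'
            cal = _calibration_from_tiff(tf)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - tifffile error classes vary
        raise ValueError(f"unreadable or unsupported TIFF: {path}: {exc}") from exc

    if voxel_override is not None:
        cal = tuple(float(v) for v in voxel_override)
    if cal is None:
        raise ValueError(
            f"{path}: no voxel calibration in TIFF metadata — pass "
            "voxel_override=(dx, dy, dz) in µm"
        )

    axes = axes.upper()
    if data.ndim == 2:
        data = data[None]  # z=1
        axes = "ZYX"
    if data.ndim == 3 and "C" in axes and "Z" not in axes:
        # (c, y, x): channels of single-slice images
        grids = [VoxelGrid3D(data[c][None], cal) for c in range(data.shape[0])]
        return ChannelStack(grids)
    if data.ndim == 3:
        return ChannelStack.single(VoxelGrid3D(data, cal))
    if data.ndim == 4:
        c_axis = axes.index("C") if "C" in axes else 1
        data = np.moveaxis(data, c_axis, 0)
        grids = [VoxelGrid3D(data[c], cal) for c in range(data.shape[0])]
        return ChannelStack(grids)
    raise ValueError(f"unsupported TIFF dimensionality {data.ndim} (axes {axes})")


def save_stack(stack: ChannelStack | VoxelGrid3D, path) -> None:
    """Write an ImageJ-compatible TIFF with µm calibration metadata.

    Integer data round-trips bit-exactly through :func:`load_stack`;
    float data is written as 32-bit float.
    """
    if isinstance(stack, VoxelGrid3D):
        stack = ChannelStack.single(stack)
    path = Path(path)
    data = np.stack([ch.data for ch in stack.channels], axis=1)  # (z, c, y, x)
    if data.dtype.kind == "f":
        data = data.astype(np.float32)
    dx, dy, dz = stack.channels[0].require_calibration()
    tifffile.imwrite(
        path,
        data,
        imagej=True,
        resolution=(1.0 / dx, 1.0 / dy),
        metadata={
            "spacing": dz,
            "unit": "micron",
            "axes": "ZCYX",
            "Info": json.dumps({"axis_order": "zyx", "apical": "y=0"}),
        },
    )


# -- projection / bit depth ---------------------------------------------------

def project(grid: VoxelGrid3D, axis: str = "z", reducer: str = "max") -> np.ndarray:
    """Project a grid along one axis (Fiji MIP semantics by default).

    Returns a plain 2D array; the two remaining axes keep their order, e.g.
    projecting along ``z`` yields ``(y, x)``.
    """
    if axis not in _AXES:
        raise ValueError(f"axis must be one of {sorted(_AXES)}, got {axis!r}")
    if reducer == "max":
        return grid.data.max(axis=_AXES[axis])
    if reducer == "mean":
        return grid.data.mean(axis=_AXES[axis])
    raise ValueError(f"reducer must be 'max' or 'mean', got {reducer!r}")


def to_8bit(grid: VoxelGrid3D, mode: str = "minmax") -> VoxelGrid3D:
    """Linear min–max conversion to uint8.

    [min, max] maps to [0, 255] with round-half-away-from-zero; a constant
    grid maps to all zeros. Deliberately per-stack (not per-slice, not
    display-range dependent) so results are reproducible across viewers.
    """
    if mode != "minmax":
        raise ValueError(f"unknown mode {mode!r}")
    data = grid.data.astype(np.float64)
    lo, hi = data.min(), data.max()
    if hi == lo:
        return grid.with_data(np.zeros(grid.shape, dtype=np.uint8))
    scaled = (data - lo) * (255.0 / (hi - lo))
    # round half away from zero (values are >= 0 here, so floor(v + .5))
    out = np.floor(scaled + 0.5).astype(np.uint8)
    return grid.with_data(out)
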