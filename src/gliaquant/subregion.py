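"""Standardize stacks to comparable 3D ROIs from a manual line selection.

Retinal stacks arrive at arbitrary orientation and field of view. A single
manual line ROI — start point at the glial endfeet (basal), end point at
the apical surface — drawn on a 2D projection defines (a) the rotation that
brings the apicobasal axis onto the image ``y`` axis (apical up), and (b) a
bounding box of fixed physical width anchored at the apical endpoint and
extended basally by ``sigma`` µm, so that every processed stack covers the
same tissue window. The stack is finally reduced to a fixed physical depth
in ``z``. Output shapes depend only on line length, parameters and
calibration, which is what makes downstream group comparisons valid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volimage import ChannelStack, VoxelGrid3D

__all__ = [
    "LineROI",
    "SubregionParams",
    "rotation_angle_from_line",
    "standardize_subregion",
    "rotate90",
    "mirror_for_eye",
]


@dataclass(frozen=True)
class LineROI:
    """Manual apicobasal line: start at the endfeet (basal), end apical.

    Coordinates are (x, y) pixels on the stack's z-projection.
    """

    start: tuple[float, float]
    end: tuple[float, float]
    context: str = "z-projection"

    def __post_init__(self):
        if tuple(self.start) == tuple(self.end):
            raise ValueError("line ROI has zero length (start == end)")

    @property
    def length_px(self) -> float:
        return math.hypot(self.end[0] - self.start[0], self.end[1] - self.start[1])


@dataclass
class SubregionParams:
    """Bounding-box parameters, all in µm.

    width_um: box width along x (default 60). sigma_um: basal extension
    below the line start, included to cover the underlying vasculature and
    retinal curvature (default 10). depth_um: output z thickness (default
    10). eye_side: left eyes are x-mirrored to a common nasal/temporal
    orientation.
    """

    width_um: float = 60.0
    sigma_um: float = 10.0
    depth_um: float = 10.0
    eye_side: str = "right"

    def __post_init__(self):
        if self.width_um <= 0 or self.depth_um <= 0 or self.sigma_um < 0:
            raise ValueError("width/depth must be > 0 and sigma >= 0")
        if self.eye_side not in ("right", "left"):
            raise ValueError(f"eye_side must be 'right' or 'left', got {self.eye_side!r}")


def rotation_angle_from_line(roi: LineROI) -> float:
    """Angle (degrees, CCW-positive in pixel coordinates) that verticalizes
    the line with the apical end above the basal start (smaller y)."""
    vx = roi.end[0] - roi.start[0]
    vy = roi.end[1] - roi.start[1]
    if vx == 0 and vy == 0:
        raise ValueError("zero-length line")
    phi = math.degrees(math.atan2(vy, vx))
    angle = -90.0 - phi
    # normalize to (-180, 180]
    while angle <= -180.0:
        angle += 360.0
    while angle > 180.0:
        angle -= 360.0
    return angle


def rotate_point(pt, angle_deg: float, center) -> tuple[float, float]:
    """Apply the image-plane rotation (about ``center``) to an (x, y) point."""
    c = math.cos(math.radians(angle_deg))
    s = math.sin(math.radians(angle_deg))
    x = pt[0] - center[0]
    y = pt[1] - center[1]
    return (c * x - s * y + center[0], s * x + c * y + center[1])


def _rotate_slices(data: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate every (y, x) slice about the slice center, bilinear, zero fill."""
    c = math.cos(math.radians(angle_deg))
    s = math.sin(math.radians(angle_deg))
    # point map on (y, x) index vectors is [[c, s], [-s, c]]; affine_transform
    # needs the inverse (its transpose)
    minv = np.array([[c, -s], [s, c]])
    h, w = data.shape[1:]
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    offset = center - minv @ center
    out = np.empty_like(data, dtype=np.float64)
    for z in range(data.shape[0]):
        out[z] = ndimage.affine_transform(
            data[z].astype(np.float64), minv, offset=offset, order=1, cval=0.0,
            mode="constant", output_shape=(h, w),
        )
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        out = np.clip(np.rint(out), info.min, info.max)
    return out.astype(data.dtype)


def standardize_subregion(
    stack: ChannelStack,
    roi: LineROI,
    params: SubregionParams | None = None,
    filename: str = "input",
) -> tuple[ChannelStack, dict]:
    """Rotate, crop and depth-reduce a stack to a standardized subregion.

    Steps: (1) rotate every slice so the manual line is vertical, apical
    end up; (2) place a box of ``width_um`` centred horizontally on the
    rotated apical endpoint, running from the apical endpoint down over
    the line length plus ``sigma_um``; (3) resolve box overflow against
    the image edges; (4) crop xy; (5) cut a centred z substack of
    ``depth_um``. Returns the cropped stack and an audit report.
    """
    if params is None:
        params = SubregionParams()
    dx, dy, dz = stack.channels[0].require_calibration()
    nz, h, w = stack.shape

    angle = rotation_angle_from_line(roi)
    center = ((w - 1) / 2.0, (h - 1) / 2.0)
    apical = rotate_point(roi.end, angle, center)
    basal = rotate_point(roi.start, angle, center)

    bt = int(round(params.width_um / dx))
    if bt > w:
        raise ValueError(
            f"File {filename}: bounding box ({bt} px) wider than image ({w} px)"
        )
    line_px = int(round(roi.length_px))
    sigma_px = int(round(params.sigma_um / dy))

    # box anchored at the rotated apical endpoint
    x0 = int(round(apical[0] - bt / 2.0))
    box_case = "fits"
    if x0 + bt > w:  # overflows right
        x0 = w - bt
        box_case = "overflow_right"
    if x0 < 0:  # overflows left
        x0 = 0
        box_case = "overflow_left"
    y0 = int(round(apical[1]))
    y0 = min(max(y0, 0), h - 1)
    height = line_px + sigma_px
    sigma_attached = True
    if y0 + height > h:  # overflows bottom: drop the sigma extension
        height = line_px
        sigma_attached = False
        if y0 + height > h:
            height = h - y0
    n_slices = int(round(params.depth_um / dz))
    if n_slices < 1:
        n_slices = 1
    if n_slices > nz:
        raise ValueError(f"File {filename} not enough slices for substack")
    z0 = (nz - n_slices) // 2

    def _process(grid: VoxelGrid3D) -> VoxelGrid3D:
        rot = _rotate_slices(grid.data, angle)
        crop = rot[z0 : z0 + n_slices, y0 : y0 + height, x0 : x0 + bt]
        return VoxelGrid3D(crop.copy(), grid.voxel_size)

    out = stack.map(_process)
    if params.eye_side == "left":
        out = mirror_for_eye(out, "left")

    report = {
        "file": filename,
        "angle_deg": angle,
        "box_case": box_case,
        "box_origin_xy": (x0, y0),
        "box_width_px": bt,
        "box_height_px": height,
        "z_origin": z0,
        "n_slices": n_slices,
        "sigma_attached": sigma_attached,
        "apical_xy_rotated": apical,
        "basal_xy_rotated": basal,
        "axis_note": "apical at y=0, basal at y=max",
    }
    if not sigma_attached:
        report["warning"] = f"File {filename} sigma could not be attached"
    return out, report


def rotate90(stack: ChannelStack, direction: str) -> ChannelStack:
    """Rotate every slice 90° left (CCW) or right (CW); swaps dx and dy.

    Used ahead of subregion standardization when stacks are acquired
    rotated (rectangular rather than upright)."""
    if direction not in ("left", "right"):
        raise ValueError(f"direction must be 'left' or 'right', got {direction!r}")
    k = 1 if direction == "left" else -1

    def _rot(grid: VoxelGrid3D) -> VoxelGrid3D:
        data = np.rot90(grid.data, k=k, axes=(1, 2)).copy()
        vs = grid.voxel_size
        if vs is not None:
            vs = (vs[1], vs[0], vs[2])
        return VoxelGrid3D(data, vs)

    return stack.map(_rot)


def mirror_for_eye(stack: ChannelStack, side: str) -> ChannelStack:
    """Flip left eyes along x so nasal/temporal orientation matches right eyes."""
    if side not in ("right", "left"):
        raise ValueError(f"side must be 'right' or 'left', got {side!r}")
    if side == "right":
        return stack
    return stack.map(lambda g: g.with_data(g.data[:, :, ::-1].copy()))
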