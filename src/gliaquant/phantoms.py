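"""Deterministic geometric fixtures and radial-glia-like phantoms.

Every processing stage in this package is tested against synthetic stacks
with known ground truth, so no raw microscopy data is needed. Two tiers:

* :func:`geometric_fixture` — boxes, spheres, cylinders, Y-tubes, slabs,
  tori, stripe/ramp/banded intensity patterns, with analytic voxel counts
  where closed-form;
* :func:`make_mg_phantom` — a field of radial-glia-like cells: vertical
  trunks spanning the apicobasal axis, soma ellipsoids in a mid band,
  apical caps, basal endfoot pads, and seed-controlled lateral branches
  in an inner-plexiform band. A ``maturity`` knob increases branch count
  and thins branches, mimicking developmental elaboration.

:func:`apply_imaging_model` turns a ground-truth stack into a plausible
acquisition: PSF blur, per-slice geometric intensity decay with depth
(bleaching), and seeded Gaussian/Poisson noise.

All randomness flows through one `numpy` Generator seeded by the caller;
identical seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .restoration import PSFModel, convolve_psf
from .segmentation import BinaryMask3D
from .volimage import VoxelGrid3D

__all__ = [
    "GroundTruth",
    "CellTruth",
    "geometric_fixture",
    "make_mg_phantom",
    "apply_imaging_model",
    "DEFAULT_VOXEL",
    "DEFAULT_SHAPE",
]

DEFAULT_VOXEL = (0.5, 0.5, 0.5)  # (dx, dy, dz) µm
DEFAULT_SHAPE = (20, 240, 120)   # (z, y, x) voxels

FOREGROUND = 200
BACKGROUND = 20


@dataclass
class CellTruth:
    soma_center: tuple        # (z, y, x) voxels
    soma_radii: tuple         # (rz, ry, rx) voxels
    trunk_x: int
    trunk_z: int
    trunk_y_range: tuple
    trunk_radius: int
    branches: list            # (y, direction, length, radius)
    endfoot_center: tuple


@dataclass
class GroundTruth:
    """What the phantom actually contains; feature values are recomputed
    from the emitted mask (never asserted from geometry alone)."""

    n_cells: int
    seed: int | None
    maturity: float
    cells: list = field(default_factory=list)
    bands: dict = field(default_factory=dict)
    analytic: dict = field(default_factory=dict)


# -- coordinate helpers -------------------------------------------------------

def _grids(shape):
    return np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")


def _ellipsoid(shape, center, radii) -> np.ndarray:
    zz, yy, xx = _grids(shape)
    cz, cy, cx = center
    rz, ry, rx = radii
    return ((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _cylinder_y(shape, zc, xc, y0, y1, radius) -> np.ndarray:
    """Cylinder with axis along y from y0..y1 inclusive."""
    zz, yy, xx = _grids(shape)
    return ((zz - zc) ** 2 + (xx - xc) ** 2 <= radius**2) & (yy >= y0) & (yy <= y1)


def _cylinder_x(shape, zc, yc, x0, x1, radius) -> np.ndarray:
    zz, yy, xx = _grids(shape)
    return ((zz - zc) ** 2 + (yy - yc) ** 2 <= radius**2) & (xx >= x0) & (xx <= x1)


# -- geometric fixtures -------------------------------------------------------

def geometric_fixture(name: str, params: dict | None = None, voxel_size=(1.0, 1.0, 1.0)):
    """Rasterize a named test shape.

    Binary shapes (box, sphere, cylinder, y_tube, slab, torus) return
    ``(BinaryMask3D, GroundTruth)``; intensity patterns (stripes, ramp,
    banded) return ``(VoxelGrid3D, GroundTruth)``. GroundTruth.analytic
    carries exact counts where closed-form (e.g. box volume).
    """
    p = dict(params or {})
    gt = GroundTruth(n_cells=0, seed=None, maturity=0.0)

    if name == "box":
        size = tuple(p.get("size", (5, 5, 5)))
        margin = int(p.get("margin", 3))
        shape = tuple(s + 2 * margin for s in size)
        data = np.zeros(shape, dtype=bool)
        data[margin : margin + size[0], margin : margin + size[1], margin : margin + size[2]] = True
        gt.analytic["volume_vox"] = int(np.prod(size))
        interior = tuple(max(s - 2, 0) for s in size)
        gt.analytic["surface_vox"] = int(np.prod(size) - np.prod(interior))
        return BinaryMask3D(data, voxel_size, {"fixture": "box"}), gt

    if name == "sphere":
        r = float(p.get("radius", 6))
        margin = int(p.get("margin", 3))
        n = int(2 * np.ceil(r) + 1 + 2 * margin)
        c = n // 2
        data = _ellipsoid((n, n, n), (c, c, c), (r, r, r))
        gt.analytic["radius_vox"] = r
        return BinaryMask3D(data, voxel_size, {"fixture": "sphere"}), gt

    if name == "cylinder":
        r = float(p.get("radius", 4))
        length = int(p.get("length", 50))
        margin = int(p.get("margin", 4))
        side = int(2 * np.ceil(r) + 1 + 2 * margin)
        shape = (side, length + 2 * margin, side)
        data = _cylinder_y(shape, side // 2, side // 2, margin, margin + length - 1, r)
        gt.analytic["radius_vox"] = r
        gt.analytic["length_vox"] = length
        gt.analytic["volume_continuum"] = float(np.pi * r * r * length)
        return BinaryMask3D(data, voxel_size, {"fixture": "cylinder"}), gt

    if name == "y_tube":
        arm = int(p.get("arm_length", 10))
        r = float(p.get("radius", 0))  # 0 → one-voxel-wide centreline
        margin = 3
        side = 2 * (arm + margin) + 1
        shape = (2 * margin + 1 + 2 * int(np.ceil(r)), side, side)
        zc = shape[0] // 2
        cy, cx = side // 2, side // 2
        data = np.zeros(shape, dtype=bool)
        if r == 0:
            data[zc, cy - arm : cy + 1, cx] = True            # stem up
            for k in range(1, arm + 1):                        # two diagonal arms down
                data[zc, cy + k, cx - k] = True
                data[zc, cy + k, cx + k] = True
        else:
            rr = int(np.ceil(r))
            data |= _cylinder_y(shape, zc, cx, cy - arm, cy, rr)
            for k in range(1, arm + 1):
                for dxs in (-k, k):
                    blob = _ellipsoid(shape, (zc, cy + k, cx + dxs), (rr, rr, rr))
                    data |= blob
        gt.analytic["endpoints"] = 3
        gt.analytic["junctions"] = 1
        return BinaryMask3D(data, voxel_size, {"fixture": "y_tube"}), gt

    if name == "slab":
        thickness = int(p.get("thickness", 5))
        side = int(p.get("side", 21))
        margin = int(p.get("margin", 4))
        shape = (side, thickness + 2 * margin, side)
        data = np.zeros(shape, dtype=bool)
        data[:, margin : margin + thickness, :] = True
        gt.analytic["thickness_vox"] = thickness
        return BinaryMask3D(data, voxel_size, {"fixture": "slab"}), gt

    if name == "torus":
        big_r = float(p.get("big_radius", 8))
        small_r = float(p.get("small_radius", 2))
        margin = 3
        side = int(2 * np.ceil(big_r + small_r) + 1 + 2 * margin)
        depth = int(2 * np.ceil(small_r) + 1 + 2 * margin)
        shape = (depth, side, side)
        zz, yy, xx = _grids(shape)
        cz, cy, cx = depth // 2, side // 2, side // 2
        rad = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
        data = (rad - big_r) ** 2 + (zz - cz) ** 2 <= small_r**2
        gt.analytic["endpoints"] = 0
        gt.analytic["cycles"] = 1
        return BinaryMask3D(data, voxel_size, {"fixture": "torus"}), gt

    if name == "stripes":
        shape = tuple(p.get("shape", (1, 200, 200)))
        period = float(p.get("period", 10))
        angle = float(p.get("angle_deg", 90.0))  # fibre orientation, 90 = vertical
        lo, hi = p.get("levels", (0, 255))
        zz, yy, xx = _grids(shape)
        # gradient runs perpendicular to the fibre direction
        g = np.radians(90.0 - angle)
        phase = 2 * np.pi * (xx * np.cos(g) + yy * np.sin(g)) / period
        data = (lo + (hi - lo) * 0.5 * (1 + np.sin(phase))).astype(np.float64)
        gt.analytic["angle_deg"] = angle % 180.0
        return VoxelGrid3D(data, voxel_size), gt

    if name == "ramp":
        shape = tuple(p.get("shape", (1, 64, 64)))
        axis = int(p.get("axis", 1))
        zz, yy, xx = _grids(shape)
        data = (zz, yy, xx)[axis].astype(np.float64)
        return VoxelGrid3D(data, voxel_size), gt

    if name == "banded":
        shape = tuple(p.get("shape", (10, 240, 120)))
        bands = p.get("bands", [(10, 25), (60, 80), (100, 130), (150, 170), (210, 230)])
        level = float(p.get("level", 255))
        data = np.zeros(shape, dtype=np.float64)
        for y0, y1 in bands:
            data[:, y0:y1, :] = level
        gt.bands = {f"band{i + 1}": b for i, b in enumerate(bands)}
        gt.analytic["band_centers_y"] = [int((y0 + y1) // 2) for y0, y1 in bands]
        return VoxelGrid3D(data, voxel_size), gt

    raise ValueError(f"unknown fixture {name!r}")


# -- radial-glia phantom ------------------------------------------------------

def make_mg_phantom(
    seed: int = 0,
    n_cells: int = 5,
    shape: tuple[int, int, int] = DEFAULT_SHAPE,
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL,
    maturity: float = 0.0,
    trunk_radius: int = 3,
) -> tuple[VoxelGrid3D, BinaryMask3D, GroundTruth]:
    """Build a deterministic radial-glia-like phantom.

    Returns ``(intensity grid, truth mask, ground truth)``. The intensity
    grid is the truth mask at foreground level 200 on background 20
    (uint8); feed it to :func:`apply_imaging_model` for a realistic
    acquisition. ``maturity`` in [0, 1] adds lateral branches and thins
    them (more endpoints, lower mean thickness) — the direction of
    developmental elaboration.
    """
    if n_cells < 1:
        raise ValueError("need n_cells >= 1")
    nz, ny, nx = shape
    spacing = nx / n_cells
    if spacing < 14:
        raise ValueError(f"{n_cells} cells do not fit a {nx}-px field of view")
    rng = np.random.default_rng(seed)
    zc = nz // 2

    bands = {
        "apical_cap": (4, 18),
        "outer": (18, int(0.33 * ny)),
        "soma": (int(0.33 * ny), int(0.54 * ny)),
        "ipl": (int(0.54 * ny), int(0.83 * ny)),
        "endfeet": (int(0.92 * ny), ny - 3),
    }
    soma_y0, soma_y1 = bands["soma"]
    ipl_y0, ipl_y1 = bands["ipl"]
    ef_y0, ef_y1 = bands["endfeet"]

    n_branches = 4 + int(round(4 * maturity))
    branch_radius = 3 if maturity < 0.5 else 2
    # branch levels interleave between neighbouring cells so protrusions
    # never fuse laterally (distinct y rails per cell parity)
    level_pitch = max(8, (ipl_y1 - ipl_y0 - 12) // max(n_branches, 1))

    mask = np.zeros(shape, dtype=bool)
    zz, yy, xx = _grids(shape)

    # apical band: the continuous cap plate all cells share at the outer
    # limiting membrane (the honeycomb lattice, rasterized solid at this
    # resolution so its centreline is a stable single rail); spans the
    # whole substack depth, as the tissue does
    cap_y0, cap_y1 = bands["apical_cap"]
    mask |= (yy >= cap_y0 + 2) & (yy < cap_y0 + 9)

    # basal endfoot sheet: the continuous inner-limiting-membrane pad the
    # individual endfeet merge into
    mask |= (yy >= ef_y1 - 4) & (yy < ef_y1)

    cells = []
    for i in range(n_cells):
        xi = int((i + 0.5) * spacing)
        # neighbouring cells of the tiled sheet sit at different depths
        zi = int(rng.integers(max(trunk_radius + 2, nz // 2 - 4),
                              min(nz - trunk_radius - 1, nz // 2 + 5)))
        soma_y = int((soma_y0 + soma_y1) / 2 + rng.integers(-4, 5))
        soma_radii = (min(5, zi - 1, nz - 1 - zi), 9, min(5, int(spacing / 2) - 2))
        trunk_y = (bands["apical_cap"][0] + 2, ef_y1 - 2)
        mask |= _cylinder_y(shape, zi, xi, trunk_y[0], trunk_y[1], trunk_radius)
        mask |= _ellipsoid(shape, (zi, soma_y, xi), soma_radii)
        # basal endfoot pad, merging into the shared basal sheet
        ef_center = (zi, (ef_y0 + ef_y1) // 2, xi)
        mask |= _ellipsoid(shape, ef_center, (5, (ef_y1 - ef_y0) // 2 + 1, 8))
        branches = []
        for k in range(n_branches):
            by = int(min(ipl_y0 + 6 + k * level_pitch, ipl_y1 - 5))
            # one direction per level: parallel protrusions never meet
            # tip-to-tip, whatever depth neighbouring cells sit at
            direction = 1 if k % 2 == 0 else -1
            length = int(rng.integers(10, 15))
            x_end = int(np.clip(xi + direction * length, 1, nx - 2))
            mask |= _cylinder_x(shape, zi, by, min(xi, x_end), max(xi, x_end), branch_radius)
            branches.append((by, direction, length, branch_radius))
        cells.append(
            CellTruth(
                soma_center=(zi, soma_y, xi),
                soma_radii=soma_radii,
                trunk_x=xi,
                trunk_z=zi,
                trunk_y_range=trunk_y,
                trunk_radius=trunk_radius,
                branches=branches,
                endfoot_center=ef_center,
            )
        )

    grid = np.full(shape, BACKGROUND, dtype=np.uint8)
    grid[mask] = FOREGROUND
    truth = BinaryMask3D(mask, voxel_size, {"phantom": "mg", "seed": seed})
    gt = GroundTruth(n_cells=n_cells, seed=seed, maturity=maturity, cells=cells, bands=bands)
    return VoxelGrid3D(grid, voxel_size), truth, gt


def apply_imaging_model(
    truth: VoxelGrid3D,
    psf: PSFModel | None = None,
    gaussian_sd: float = 0.0,
    poisson_scale: float = 0.0,
    z_decay: float = 0.0,
    seed: int = 0,
) -> VoxelGrid3D:
    """Simulate acquisition of a ground-truth stack.

    Order: PSF blur → per-slice decay ``(1 - z_decay)^z`` (photobleaching
    with depth) → seeded noise (additive Gaussian sd, and/or Poisson with
    counts scaled by ``poisson_scale``) → clip to the input dtype range.
    With a delta PSF, zero noise and zero decay this is the identity.
    """
    rng = np.random.default_rng(seed)
    data = truth.data.astype(np.float64)
    if psf is not None:
        data = convolve_psf(VoxelGrid3D(data, truth.voxel_size), psf).data
    if z_decay:
        factors = (1.0 - z_decay) ** np.arange(data.shape[0])
        data = data * factors[:, None, None]
    if poisson_scale:
        data = rng.poisson(np.clip(data, 0, None) * poisson_scale) / poisson_scale
    if gaussian_sd:
        data = data + rng.normal(0.0, gaussian_sd, size=data.shape)
    if np.issubdtype(truth.dtype, np.integer):
        info = np.iinfo(truth.dtype)
        data = np.clip(np.rint(data), info.min, info.max).astype(truth.dtype)
    return VoxelGrid3D(data, truth.voxel_size)


def smooth_truth_mask(mask: BinaryMask3D, iterations: int = 1) -> BinaryMask3D:
    """Morphological closing of a truth mask (used to compare against
    segmentations, which cannot recover single-voxel surface detail)."""
    closed = ndimage.binary_closing(mask.data, iterations=iterations)
    return mask.with_data(closed, smoothed=True)
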