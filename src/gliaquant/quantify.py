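"""3D feature extraction from binary glia masks.

Computes the morphometric feature set: image height, object volume (V_N)
and volume coverage (VC_N, %), surface voxels expressed as a volume (S_N)
and surface-to-volume ratio (SV_N), skeleton network length (L_N),
junction/endpoint counts (J_N, EP_N) and mean branch length (BL_N),
EDM-based average thickness (T_N, a radius-like quantity: the Euclidean
distance map sampled at the centreline), and an optional cell count (N_N)
via distance-transform watershed in a soma-band ROI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import h_maxima, skeletonize
from skimage.segmentation import watershed

from .segmentation import BinaryMask3D
from .volimage import VoxelGrid3D

__all__ = [
    "SkeletonGraph",
    "FeatureReport",
    "EDMGrid",
    "volume_metrics",
    "extract_surface",
    "skeletonize3d",
    "analyze_skeleton",
    "edm3d",
    "thickness",
    "count_cells",
    "full_report",
]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)

# all 26 neighbor offsets
_NEIGH = np.array(
    [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
     if (dz, dy, dx) != (0, 0, 0)]
)


@dataclass
class Branch:
    """A traced skeleton branch between two nodes (or a closed cycle)."""

    path: list
    length_um: float
    closed: bool = False


@dataclass
class SkeletonGraph:
    """Classified skeleton voxels plus traced branches.

    Voxel classes by 26-neighbor count: 1 = endpoint, 2 = slab,
    >2 = junction; 26-connected junction voxels merge into one junction
    node (cluster)."""

    endpoints: np.ndarray          # (E, 3) voxel coords
    junction_voxels: np.ndarray    # (Jv, 3)
    slab_voxels: np.ndarray        # (S, 3)
    n_junctions: int               # junction clusters
    branches: list = field(default_factory=list)
    n_cycles: int = 0

    @property
    def ep_n(self) -> int:
        return len(self.endpoints)

    @property
    def j_n(self) -> int:
        return self.n_junctions

    @property
    def bl_n(self) -> float:
        if not self.branches:
            return 0.0
        return float(np.mean([b.length_um for b in self.branches]))


@dataclass
class EDMGrid:
    """Euclidean distance map in µm; exactly zero on background."""

    distances: np.ndarray
    voxel_size: tuple[float, float, float]


@dataclass
class FeatureReport:
    """One stack's feature set; ``to_row`` yields the fixed CSV column order."""

    file: str
    height_um: float
    V_N: float
    VC_N: float
    S_N: float
    SV_N: float
    L_N: float
    J_N: int
    EP_N: int
    BL_N: float
    T_N: float
    N_N: int | None = None

    COLUMNS = ["file", "height_um", "V_N", "VC_N", "S_N", "SV_N",
               "L_N", "J_N", "EP_N", "BL_N", "T_N", "N_N"]

    def to_row(self) -> dict:
        return {c: getattr(self, c) for c in self.COLUMNS}


# -- volume and surface -------------------------------------------------------

def volume_metrics(mask: BinaryMask3D) -> tuple[float, float]:
    """V_N = foreground voxels × voxel volume (µm³); VC_N = % of image
    voxels covered."""
    vol = mask.require_calibration()
    voxvol = vol[0] * vol[1] * vol[2]
    n_fg = mask.count()
    v_n = n_fg * voxvol
    vc_n = 100.0 * n_fg / mask.data.size
    return v_n, vc_n


def extract_surface(mask: BinaryMask3D) -> tuple[BinaryMask3D, float]:
    """Surface voxels (foreground with a 6-neighbor background voxel; the
    image border counts as background), reported as a volume S_N in µm³."""
    voxvol = np.prod(mask.require_calibration())
    fg = np.pad(mask.data, 1, mode="constant", constant_values=False)
    interior = fg.copy()
    for axis in (0, 1, 2):
        for shift in (-1, 1):
            interior &= np.roll(fg, shift, axis=axis)
    surface = fg & ~interior
    surface = surface[1:-1, 1:-1, 1:-1]
    s_n = float(surface.sum() * voxvol)
    return mask.with_data(surface, derived="surface"), s_n


# -- skeletonization and analysis --------------------------------------------

def skeletonize3d(mask: BinaryMask3D) -> BinaryMask3D:
    """Topology-preserving 3D thinning (Lee-class) to a one-voxel centreline."""
    skel = skeletonize(mask.data)  # skimage dispatches to the 3D Lee method
    return mask.with_data(skel.astype(bool), derived="skeleton")


def _neighbor_map(coords: np.ndarray):
    """Index map and per-voxel neighbor index lists (26-connectivity)."""
    index = {tuple(c): i for i, c in enumerate(coords)}
    neighbors = []
    for c in coords:
        nb = []
        for off in _NEIGH:
            j = index.get((c[0] + off[0], c[1] + off[1], c[2] + off[2]))
            if j is not None:
                nb.append(j)
        neighbors.append(nb)
    return index, neighbors


def _step_len(a, b, voxel_size) -> float:
    dx, dy, dz = voxel_size
    return float(np.sqrt(((a[0] - b[0]) * dz) ** 2 + ((a[1] - b[1]) * dy) ** 2
                         + ((a[2] - b[2]) * dx) ** 2))


def analyze_skeleton(
    skel: BinaryMask3D, voxel_size: tuple[float, float, float] | None = None
) -> tuple[SkeletonGraph, tuple[float, int, int, float]]:
    """Classify skeleton voxels, trace branches, and measure the network.

    Returns ``(graph, (L_N, J_N, EP_N, BL_N))``. L_N follows the
    voxel-count convention (skeleton voxels × lateral voxel size); branch
    lengths sum diagonal-aware Euclidean steps in µm, so BL_N and L_N use
    slightly different length conventions (both documented). An isolated
    voxel counts as one endpoint and no branch.
    """
    if voxel_size is None:
        voxel_size = skel.require_calibration()
    coords = np.argwhere(skel.data)
    if len(coords) == 0:
        graph = SkeletonGraph(coords.reshape(0, 3), coords.reshape(0, 3),
                              coords.reshape(0, 3), 0, [], 0)
        return graph, (0.0, 0, 0, 0.0)

    index, neighbors = _neighbor_map(coords)
    degree = np.array([len(nb) for nb in neighbors])
    is_end = degree <= 1        # isolated voxel counts as an endpoint
    is_junc = degree > 2
    is_node = is_end | is_junc

    # merge 26-connected junction voxels into clusters
    junc_cluster = {}
    n_junctions = 0
    junc_idx = np.nonzero(is_junc)[0]
    if len(junc_idx):
        jset = set(junc_idx.tolist())
        seen = set()
        for start in junc_idx:
            if start in seen:
                continue
            stack_ = [int(start)]
            seen.add(int(start))
            while stack_:
                v = stack_.pop()
                junc_cluster[v] = n_junctions
                for nb in neighbors[v]:
                    if nb in jset and nb not in seen:
                        seen.add(nb)
                        stack_.append(nb)
            n_junctions += 1

    def same_cluster(a: int, b: int) -> bool:
        return (a in junc_cluster and b in junc_cluster
                and junc_cluster[a] == junc_cluster[b])

    # trace branches from node voxels through slab chains
    visited_edges = set()
    branches: list[Branch] = []

    def edge_key(a: int, b: int):
        return (a, b) if a < b else (b, a)

    node_idx = np.nonzero(is_node)[0]
    for start in node_idx:
        for first in neighbors[start]:
            if same_cluster(int(start), first):
                continue  # intra-cluster adjacency is not a branch
            if edge_key(int(start), first) in visited_edges:
                continue
            path = [int(start), first]
            visited_edges.add(edge_key(int(start), first))
            prev, cur = int(start), first
            while not is_node[cur]:
                nxt = [nb for nb in neighbors[cur] if nb != prev]
                if not nxt:
                    break
                visited_edges.add(edge_key(cur, nxt[0]))
                prev, cur = cur, nxt[0]
                path.append(cur)
            length = sum(
                _step_len(coords[path[i]], coords[path[i + 1]], voxel_size)
                for i in range(len(path) - 1)
            )
            branches.append(Branch([tuple(coords[i]) for i in path], length))

    # closed cycles (no node voxels on them, e.g. a ring skeleton)
    n_cycles = 0
    on_branch = set()
    for b in branches:
        for p in b.path:
            on_branch.add(index[p])
    for i in np.nonzero(degree == 2)[0]:
        if int(i) in on_branch:
            continue
        covered = all(edge_key(int(i), nb) in visited_edges for nb in neighbors[i])
        if covered:
            continue
        # walk the cycle
        path = [int(i)]
        prev, cur = int(i), neighbors[i][0]
        visited_edges.add(edge_key(int(i), cur))
        while cur != int(i):
            path.append(cur)
            on_branch.add(cur)
            nxt = [nb for nb in neighbors[cur] if nb != prev]
            if not nxt:
                break
            visited_edges.add(edge_key(cur, nxt[0]))
            prev, cur = cur, nxt[0]
        length = sum(
            _step_len(coords[path[k]], coords[path[(k + 1) % len(path)]], voxel_size)
            for k in range(len(path))
        )
        branches.append(Branch([tuple(coords[k]) for k in path], length, closed=True))
        on_branch.add(int(i))
        n_cycles += 1

    graph = SkeletonGraph(
        endpoints=coords[is_end & (degree >= 1)] if len(coords) else coords,
        junction_voxels=coords[is_junc],
        slab_voxels=coords[degree == 2],
        n_junctions=n_junctions,
        branches=branches,
        n_cycles=n_cycles,
    )
    # isolated voxels: degree 0, count as endpoints too
    iso = coords[degree == 0]
    if len(iso):
        graph.endpoints = np.vstack([graph.endpoints, iso]) if len(graph.endpoints) else iso

    l_n = float(len(coords) * voxel_size[0])  # voxel-count convention
    return graph, (l_n, graph.j_n, graph.ep_n, graph.bl_n)


# -- distance map and thickness ----------------------------------------------

def edm3d(mask: BinaryMask3D, voxel_size: tuple[float, float, float] | None = None) -> EDMGrid:
    """Exact Euclidean distance (µm) from each foreground voxel to the
    nearest background voxel, anisotropy-aware; background stays 0.
    Voxels beyond the image border are not treated as background."""
    if voxel_size is None:
        voxel_size = mask.require_calibration()
    dx, dy, dz = voxel_size
    dist = ndimage.distance_transform_edt(mask.data, sampling=(dz, dy, dx))
    return EDMGrid(distances=dist, voxel_size=voxel_size)


def thickness(skel: BinaryMask3D, edm: EDMGrid) -> float:
    """T_N: mean EDM value over skeleton voxels — the average local radius
    (µm) of the network, sampled along the centreline."""
    vals = edm.distances[skel.data]
    if vals.size == 0:
        raise ValueError("empty skeleton: thickness undefined")
    return float(vals.mean())


# -- cell counting ------------------------------------------------------------

def _soma_band(mask: BinaryMask3D, half_width_um: float = 12.5) -> tuple[int, int]:
    """y-range around the soma layer, located as the apicobasal row where
    the object is thickest (per-row maximum of the EDM).

    Cell bodies are the widest structures of a radial glia mask, so the
    EDM row-max profile peaks at the soma layer; the search is restricted
    to the central 25–75% of the height because the apical lattice and
    basal endfoot sheet at the tissue surfaces can rival the somas."""
    if not mask.data.any():
        raise ValueError("empty ROI: mask has no foreground")
    dx, dy, dz = mask.require_calibration()
    dist = ndimage.distance_transform_edt(mask.data, sampling=(dz, dy, dx))
    profile = ndimage.gaussian_filter1d(dist.max(axis=(0, 2)), sigma=3.0)
    ny = profile.size
    lo, hi = ny // 4, max(ny // 4 + 1, (3 * ny) // 4)
    peak = lo + int(np.argmax(profile[lo:hi]))
    half = int(round(half_width_um / dy))
    return max(0, peak - half), min(mask.shape[1], peak + half + 1)


def count_cells(
    mask: BinaryMask3D,
    roi_strategy: str = "auto_band",
    roi_spec=None,
    min_volume_vox: int = 8,
    h_um: float = 0.5,
) -> int:
    """Count cell bodies by distance-transform watershed inside a soma ROI.

    ``auto_band`` derives a y-band around the soma peak of the mask's own
    apicobasal profile (roi_spec: optional band half-width, µm);
    ``rectangle`` crops to a user box roi_spec = (y0, y1, x0, x1). Within
    the ROI the EDM is computed; its h-maxima (regional maxima after
    suppressing dynamics below ``h_um``, which merges shallow plateau
    bumps into their parent soma) seed a watershed on the inverted EDM,
    and labelled particles of at least ``min_volume_vox`` voxels are
    counted.
    """
    if roi_strategy == "auto_band":
        if mask.count() == 0:
            return 0
        half = roi_spec if roi_spec is not None else 12.5
        y0, y1 = _soma_band(mask, half_width_um=half)
        sub = mask.data[:, y0:y1, :]
    elif roi_strategy == "rectangle":
        if roi_spec is None:
            raise ValueError("rectangle strategy needs roi_spec=(y0, y1, x0, x1)")
        y0, y1, x0, x1 = roi_spec
        if y1 <= y0 or x1 <= x0:
            raise ValueError(f"empty ROI: {roi_spec}")
        sub = mask.data[:, y0:y1, x0:x1]
    else:
        raise ValueError(f"unknown roi_strategy {roi_strategy!r}")
    if sub.size == 0:
        raise ValueError("empty ROI after cropping")
    if not sub.any():
        return 0

    dx, dy, dz = mask.require_calibration()
    dist = ndimage.distance_transform_edt(sub, sampling=(dz, dy, dx))
    smooth = ndimage.gaussian_filter(dist, sigma=1.0)
    seeds = h_maxima(smooth, h_um, footprint=np.ones((3, 3, 3)))
    seeds &= sub
    if not seeds.any():
        return 0
    markers, _ = ndimage.label(seeds, structure=np.ones((3, 3, 3)))
    labels = watershed(-dist, markers=markers, mask=sub)
    counts = np.bincount(labels.ravel())[1:]
    return int((counts >= min_volume_vox).sum())


# -- orchestration ------------------------------------------------------------

def full_report(
    stack: VoxelGrid3D | None,
    mask: BinaryMask3D,
    filename: str = "sample",
    count_cells_roi: str | None = "auto_band",
) -> FeatureReport:
    """Run every feature extractor on one mask and assemble the report.

    ``stack`` is accepted for provenance symmetry with the segmentation
    recipes; all measurements are taken on the mask. Set
    ``count_cells_roi=None`` to skip the (comparatively brittle) cell
    count."""
    dx, dy, dz = mask.require_calibration()
    stage = "volume_metrics"
    try:
        v_n, vc_n = volume_metrics(mask)
        stage = "extract_surface"
        _, s_n = extract_surface(mask)
        stage = "skeletonize3d"
        skel = skeletonize3d(mask)
        stage = "analyze_skeleton"
        _, (l_n, j_n, ep_n, bl_n) = analyze_skeleton(skel)
        stage = "edm3d"
        edm = edm3d(mask)
        stage = "thickness"
        t_n = thickness(skel, edm) if skel.data.any() else 0.0
        n_n = None
        if count_cells_roi is not None:
            stage = "count_cells"
            n_n = count_cells(mask, roi_strategy=count_cells_roi)
    except Exception as exc:
        raise type(exc)(f"[stage {stage}] {exc}") from exc

    return FeatureReport(
        file=filename,
        height_um=mask.shape[1] * dy,
        V_N=v_n,
        VC_N=vc_n,
        S_N=s_n,
        SV_N=s_n / v_n if v_n > 0 else 0.0,
        L_N=l_n,
        J_N=j_n,
        EP_N=ep_n,
        BL_N=bl_n,
        T_N=t_n,
        N_N=n_n,
    )


def reports_to_frame(reports) -> pd.DataFrame:
    """Stack FeatureReports into a CSV-ready DataFrame (stable column order)."""
    return pd.DataFrame([r.to_row() for r in reports], columns=FeatureReport.COLUMNS)
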