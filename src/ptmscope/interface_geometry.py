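"""Representative-conformation selection and static interface geometry.

Two static descriptors are computed on a single representative
conformation: the enclosed inter-chain volume (gap-sphere construction)
and the gap index, the ratio of that volume to the interface accessible
surface area. Poorly packed or detaching interfaces have large gap
indices; tight interfaces small ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from ._geometry import fitted_rmsd
from .descriptors import buried_sas
from .model_io import StructureModel, TrajectoryEnsemble

__all__ = [
    "ConformationClusters",
    "GapRegion",
    "gromos_cluster",
    "representative_structure",
    "gap_analysis",
]


@dataclass
class ConformationClusters:
    """GROMOS-style clustering of trajectory frames.

    ``labels[f]`` is the cluster of frame ``f`` (0 = largest cluster);
    ``representative`` is the center frame of cluster 0.
    """

    labels: np.ndarray
    sizes: list[int]
    representative: int
    cutoff: float  # nm

    def __post_init__(self) -> None:
        if sum(self.sizes) != len(self.labels):
            raise ValueError("cluster sizes must sum to the frame count")


def _pairwise_ca_rmsd(t: TrajectoryEnsemble) -> np.ndarray:
    ca = t.topology.atom_indices("CA")
    if ca.size == 0:
        raise ValueError("no Cα atoms in topology")
    lo, hi = t.eq_window
    frames = t.frames[lo:hi, ca, :]
    n = len(frames)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = fitted_rmsd(frames[j], frames[i]) / 10.0  # nm
    return d


def gromos_cluster(t: TrajectoryEnsemble, cutoff: float = 0.3) -> ConformationClusters:
    """Neighbor-counting conformational clustering on Cα RMSD.

    Pairwise Cα RMSD (nm, after superposition) is computed over the
    equilibrated window. Iteratively, the frame with the most neighbors
    within ``cutoff`` becomes a cluster center; it and its neighbors are
    assigned and removed; repeat until all frames are assigned. Ties go to
    the lowest frame index. Clusters are numbered in decreasing size, and
    the representative is the center of the largest cluster (an absolute
    frame index into the trajectory).
    """
    dist = _pairwise_ca_rmsd(t)
    n = len(dist)
    lo, _ = t.eq_window
    unassigned = np.ones(n, dtype=bool)
    labels = np.full(n, -1, dtype=int)
    clusters: list[tuple[int, np.ndarray]] = []  # (center, members)
    while unassigned.any():
        within = (dist <= cutoff) & unassigned[None, :] & unassigned[:, None]
        counts = within.sum(axis=1)
        counts[~unassigned] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.nonzero(within[center])[0]
        clusters.append((center, members))
        unassigned[members] = False

    # renumber by decreasing size; stable for ties (formation order)
    order = sorted(range(len(clusters)), key=lambda k: -len(clusters[k][1]))
    sizes = []
    for new_id, k in enumerate(order):
        center, members = clusters[k]
        labels[members] = new_id
        sizes.append(len(members))
    top_center = clusters[order[0]][0]
    return ConformationClusters(
        labels=labels,
        sizes=sizes,
        representative=lo + top_center,
        cutoff=cutoff,
    )


def representative_structure(
    t: TrajectoryEnsemble, cutoff: float = 0.3
) -> StructureModel:
    """Central structure of the largest conformational cluster."""
    clusters = gromos_cluster(t, cutoff)
    return t.frame_structure(clusters.representative)


@dataclass
class GapRegion:
    """The inter-chain gap: its filling spheres and derived quantities."""

    spheres: list[tuple[np.ndarray, float]] = field(default_factory=list)
    gap_volume: float = 0.0  # Å^3
    interface_asa: float = 0.0  # Å^2
    gap_index: float = 0.0  # Å
    grid_interval: float = 0.8
    distance_cutoff: float = 5.0


def _canonical_frame(centers: np.ndarray) -> np.ndarray:
    """Orthonormal axes derived from the sphere centers themselves.

    The first axis points to the center farthest from the centroid, the
    second to the center farthest from that axis (Gram-Schmidt), the third
    completes a right-handed frame. Because the construction is exactly
    equivariant under rigid motion of the centers, rasterizing in this
    frame makes the voxel count a function of the sphere set's internal
    geometry only — gap volumes are invariant under rotation/translation
    of the input structure.
    """
    c = centers - centers.mean(axis=0)
    if len(c) < 2:
        return np.eye(3)
    d = np.linalg.norm(c, axis=1)
    u = c[int(np.argmax(d))]
    if np.linalg.norm(u) < 1e-9:
        return np.eye(3)
    e1 = u / np.linalg.norm(u)
    perp = c - np.outer(c @ e1, e1)
    pn = np.linalg.norm(perp, axis=1)
    if pn.max() < 1e-9:
        # collinear centers: any perpendicular completes the frame
        helper = np.eye(3)[int(np.argmin(np.abs(e1)))]
        v = helper - (helper @ e1) * e1
    else:
        v = perp[int(np.argmax(pn))]
    e2 = v / np.linalg.norm(v)
    e3 = np.cross(e1, e2)
    return np.vstack([e1, e2, e3])


def _rasterized_volume(
    spheres: list[tuple[np.ndarray, float]], h: float
) -> float:
    centers = np.array([c for c, _ in spheres])
    radii = np.array([r for _, r in spheres])
    axes = _canonical_frame(centers)
    origin = centers.mean(axis=0)
    local = (centers - origin) @ axes.T
    lo = (local - radii[:, None]).min(axis=0)
    hi = (local + radii[:, None]).max(axis=0)
    grids = [np.arange(lo[k] + h / 2.0, hi[k], h) for k in range(3)]
    if any(len(g) == 0 for g in grids):
        return 0.0
    gx, gy, gz = np.meshgrid(*grids, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    occupied = np.zeros(len(pts), dtype=bool)
    vox_tree = cKDTree(pts)
    for center, radius in zip(local, radii):
        idx = vox_tree.query_ball_point(center, radius)
        occupied[idx] = True
    return float(occupied.sum()) * h**3


def gap_analysis(
    s: StructureModel,
    grid_interval: float = 0.8,
    distance_cutoff: float = 5.0,
    min_gap_radius: float = 1.0,
    asa_mode: str = "per_side",
    probe: float = 1.4,
    n_points: int = 960,
) -> GapRegion:
    """Gap-sphere analysis of a two-chain interface.

    For every inter-chain atom pair whose surface-to-surface separation is
    positive and at most ``distance_cutoff`` (Å), a trial sphere is placed
    at the midpoint of the inter-surface segment with radius half the
    separation, then shrunk against the nearest clashing atom until it
    penetrates none. Spheres with radius ≥ ``min_gap_radius`` are kept and
    rasterized on a grid of spacing ``grid_interval``; their union volume
    is the gap volume. The gap index divides that volume by the interface
    accessible surface area — half the buried SAS per side
    (``asa_mode="per_side"``, the ΔASA convention) or the full buried SAS
    (``asa_mode="total"``).
    """
    if len(s.chains) != 2:
        raise ValueError("interface requires two chains")
    if asa_mode not in ("per_side", "total"):
        raise ValueError("asa_mode must be 'per_side' or 'total'")

    coords = s.coords
    radii = s.radii
    mask_a = s.chain_mask(s.chains[0])
    ia = np.nonzero(mask_a)[0]
    ib = np.nonzero(~mask_a)[0]

    tree_b = cKDTree(coords[ib])
    max_rb = float(radii[ib].max())
    spheres: list[tuple[np.ndarray, float]] = []
    all_tree = cKDTree(coords)
    max_r = float(radii.max())
    for i in ia:
        near = tree_b.query_ball_point(coords[i], distance_cutoff + radii[i] + max_rb)
        for jb in near:
            j = ib[jb]
            d = float(np.linalg.norm(coords[j] - coords[i]))
            gap = d - radii[i] - radii[j]
            if gap <= 0 or gap > distance_cutoff:
                continue
            u = (coords[j] - coords[i]) / d
            center = coords[i] + u * (radii[i] + gap / 2.0)
            radius = gap / 2.0
            # shrink against every clashing atom
            neigh = all_tree.query_ball_point(center, radius + max_r)
            for k in neigh:
                dk = float(np.linalg.norm(coords[k] - center))
                radius = min(radius, dk - radii[k])
            if radius >= min_gap_radius:
                spheres.append((center, radius))

    region = GapRegion(
        spheres=spheres,
        grid_interval=grid_interval,
        distance_cutoff=distance_cutoff,
    )
    b = buried_sas(s, probe=probe, n_points=n_points)
    region.interface_asa = max(b, 0.0) / (2.0 if asa_mode == "per_side" else 1.0)
    if not spheres:
        warnings.warn("no inter-chain gap within the distance cutoff")
        return region
    region.gap_volume = _rasterized_volume(spheres, grid_interval)
    if region.interface_asa > 0:
        region.gap_index = region.gap_volume / region.interface_asa
    return region
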