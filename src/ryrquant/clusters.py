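"""Cluster and Ca2+-release-unit (CRU) statistics, and whole-cell extrapolation.

Neighbouring RyR clusters whose edge-to-edge separation is within 100 nm
are believed to gate Ca2+ sparks cooperatively; grouping clusters by that
criterion (single linkage, i.e. dilating every cluster by 50 nm and fusing
the regions that touch) defines CRUs. Edge-to-edge distance between two
clusters is the minimum distance between their member voxel centers minus
one voxel size, floored at zero — a resolution-consistent convention that
makes the dilation and distance-threshold formulations equivalent.

Whole-cell RyR totals are extrapolated from measured surface (areal) and
interior (volumetric) densities on an idealized elliptic-cylinder myocyte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .volumes import Cluster, ClusterSet

__all__ = [
    "CRU",
    "CRUSet",
    "CellGeometry",
    "nearest_neighbour_distances",
    "group_crus",
    "cru_statistics",
    "extrapolate_whole_cell",
    "cell_volume_um3",
]


@dataclass
class CRU:
    """A Ca2+ release unit: one or more clusters within the grouping gap."""

    id: int
    member_cluster_ids: list[int]
    total_ryr: float
    n_clusters: int


@dataclass
class CRUSet:
    crus: list[CRU]
    gap_nm: float
    mode: str  # "2d" or "3d"

    def __len__(self) -> int:
        return len(self.crus)

    def __iter__(self):
        return iter(self.crus)


@dataclass
class CellGeometry:
    """Idealized cardiomyocyte: an elliptic cylinder with an RyR-free shell.

    Interior RyR clusters are assumed excluded from the outermost
    ``shell_um`` of the geometry.
    """

    short_radius_um: float = 6.0
    long_radius_um: float = 10.0
    length_um: float = 130.0
    shell_um: float = 1.5

    def __post_init__(self) -> None:
        if min(self.short_radius_um, self.long_radius_um, self.length_um, self.shell_um) <= 0:
            raise ValueError("all cell geometry dimensions must be positive")
        if self.shell_um >= self.short_radius_um:
            raise ValueError("shell must be thinner than the short radius")


def _cluster_points(clusters: ClusterSet, mode: str) -> list[np.ndarray]:
    """Member voxel-center coordinates per cluster, projected for 2D mode."""
    voxel = np.asarray(clusters.voxel_nm, dtype=float)
    origin = np.asarray(clusters.origin_nm, dtype=float)
    pts = []
    for c in clusters:
        p = origin + (c.voxels.astype(float) + 0.5) * voxel
        if mode == "2d" and p.shape[1] == 3:
            p = np.unique(p[:, :2], axis=0)
        pts.append(p)
    return pts


def _edge_distance(pa: np.ndarray, pb: np.ndarray, voxel_nm: float) -> float:
    """Edge-to-edge distance: min center-to-center minus one voxel, >= 0."""
    d = cKDTree(pa).query(pb, k=1)[0].min()
    return max(0.0, float(d) - voxel_nm)


def _mode(mode: str) -> str:
    m = mode.lower()
    if m not in ("2d", "3d"):
        raise ValueError("mode must be '2d' or '3d'")
    return m


def nearest_neighbour_distances(
    clusters: ClusterSet, mode: str = "3d", metric: str = "edge"
) -> np.ndarray:
    """Per-cluster nearest-neighbour distance (nm).

    ``metric="edge"`` (default, consistent with CRU grouping) measures
    edge-to-edge; ``metric="center"`` measures centroid-to-centroid. In 2D
    mode clusters are first projected onto the xy plane, which can only
    shrink distances; 2D NND <= 3D NND for every cluster.
    """
    mode = _mode(mode)
    if metric not in ("edge", "center"):
        raise ValueError("metric must be 'edge' or 'center'")
    n = len(clusters)
    if n < 2:
        return np.empty(0)
    if metric == "center":
        cent = np.vstack([c.centroid_nm for c in clusters])
        if mode == "2d":
            cent = cent[:, :2]
        d = np.linalg.norm(cent[:, None] - cent[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        return d.min(axis=1)
    pts = _cluster_points(clusters, mode)
    voxel = float(clusters.voxel_nm[0])
    out = np.full(n, np.inf)
    for i in range(n):
        tree = cKDTree(pts[i])
        for j in range(i + 1, n):
            d = max(0.0, float(tree.query(pts[j], k=1)[0].min()) - voxel)
            if d < out[i]:
                out[i] = d
            if d < out[j]:
                out[j] = d
    return out


def group_crus(clusters: ClusterSet, gap_nm: float = 100.0, mode: str = "3d") -> CRUSet:
    """Single-linkage grouping of clusters into CRUs.

    Clusters with edge-to-edge distance <= ``gap_nm`` share a CRU
    (transitive closure) — equivalent to dilating each cluster by
    ``gap_nm/2`` and fusing the regions that touch. CRU ``total_ryr`` sums
    the members' calibrated estimates when available, else counts members.
    """
    if gap_nm < 0:
        raise ValueError("gap_nm must be non-negative")
    mode = _mode(mode)
    n = len(clusters)
    if n == 0:
        return CRUSet([], gap_nm, mode)
    pts = _cluster_points(clusters, mode)
    voxel = float(clusters.voxel_nm[0])

    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    # coarse prefilter on cluster extents to skip far pairs
    centroids = np.vstack([p.mean(axis=0) for p in pts])
    radii = np.array(
        [np.linalg.norm(p - c, axis=1).max() for p, c in zip(pts, centroids)]
    )
    for i in range(n):
        tree = cKDTree(pts[i])
        for j in range(i + 1, n):
            if find(i) == find(j):
                continue
            lower = np.linalg.norm(centroids[i] - centroids[j]) - radii[i] - radii[j]
            if lower - voxel > gap_nm:
                continue
            d = max(0.0, float(tree.query(pts[j], k=1)[0].min()) - voxel)
            if d <= gap_nm:
                union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    crus = []
    for cid, members in enumerate(sorted(groups.values(), key=min)):
        total = 0.0
        for m in members:
            c = clusters.clusters[m]
            total += c.ryr_count if c.ryr_count is not None else 1.0
        crus.append(
            CRU(
                id=cid,
                member_cluster_ids=[clusters.clusters[m].id for m in members],
                total_ryr=total,
                n_clusters=len(members),
            )
        )
    return CRUSet(crus, gap_nm, mode)


def cru_statistics(
    crus: CRUSet,
    roi_footprint_um2: float,
    slab_um: float = 0.6,
    single_ryr_threshold: float = 1.5,
    clusters: ClusterSet | None = None,
) -> dict:
    """Descriptive CRU summary over an analyzed region.

    Density is CRU count per analyzed volume, with the analyzed volume
    taken as the xy ROI footprint times the 600 nm axial analysis slab —
    the same per-um^3 convention is applied to surface and interior data.
    A CRU (or cluster) counts as "single RyR" if its calibrated estimate is
    below ``single_ryr_threshold``.
    """
    if not len(crus):
        raise ValueError("empty CRU set")
    if roi_footprint_um2 <= 0 or slab_um <= 0:
        raise ValueError("analyzed region must have positive volume")
    volume_um3 = roi_footprint_um2 * slab_um
    ryrs = np.array([c.total_ryr for c in crus])
    ncl = np.array([c.n_clusters for c in crus])
    singles = ryrs < single_ryr_threshold
    out = {
        "n_crus": len(crus),
        "mean_ryrs_per_cru": float(ryrs.mean()),
        "mean_clusters_per_cru": float(ncl.mean()),
        "cru_density_per_um3": len(crus) / volume_um3,
        "fraction_single_ryr_crus": float(singles.mean()),
        "analyzed_volume_um3": volume_um3,
        "mode": crus.mode,
    }
    if clusters is not None and len(clusters):
        est = np.array(
            [c.ryr_count if c.ryr_count is not None else 1.0 for c in clusters]
        )
        out["fraction_single_ryr_clusters"] = float((est < single_ryr_threshold).mean())
    return out


def _ellipse_perimeter_um(a: float, b: float) -> float:
    """Ramanujan's approximation for the perimeter of an ellipse."""
    h = ((a - b) / (a + b)) ** 2
    return math.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + math.sqrt(4.0 - 3.0 * h)))


def cell_volume_um3(geom: CellGeometry | None = None) -> float:
    """Volume of the idealized elliptic-cylinder myocyte (um^3)."""
    geom = geom or CellGeometry()
    return math.pi * geom.short_radius_um * geom.long_radius_um * geom.length_um


def extrapolate_whole_cell(
    surface_density_per_um2: float,
    interior_density_per_um3: float,
    geom: CellGeometry | None = None,
) -> dict:
    """Extrapolate measured RyR densities to whole-cell totals.

    Surface RyRs = areal density x total sarcolemmal surface (lateral
    surface of the elliptic cylinder, Ramanujan perimeter, plus the two
    elliptical end faces). Interior RyRs = volumetric density x the
    interior volume after excluding the outermost ``shell_um`` shell.
    """
    geom = geom or CellGeometry()
    if surface_density_per_um2 < 0 or interior_density_per_um3 < 0:
        raise ValueError("densities must be non-negative")
    a, b, L, s = geom.short_radius_um, geom.long_radius_um, geom.length_um, geom.shell_um
    lateral = _ellipse_perimeter_um(a, b) * L
    ends = 2.0 * math.pi * a * b
    surface_area_um2 = lateral + ends
    interior_volume_um3 = math.pi * (a - s) * (b - s) * (L - 2.0 * s)
    surface_total = surface_density_per_um2 * surface_area_um2
    interior_total = interior_density_per_um3 * interior_volume_um3
    total = surface_total + interior_total
    return {
        "surface_ryrs": surface_total,
        "interior_ryrs": interior_total,
        "total_ryrs": total,
        "interior_fraction": interior_total / total if total > 0 else 0.0,
        "surface_area_um2": surface_area_um2,
        "interior_volume_um3": interior_volume_um3,
        "cell_volume_um3": cell_volume_um3(geom),
    }
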