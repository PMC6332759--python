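"""Voxel rendering of localization tables, thresholding, and cluster segmentation.

Rendering follows the standard SMLM reconstruction recipe: each blink event
contributes a unit-mass anisotropic Gaussian whose sigmas are the event's
lateral and axial localization precision, accumulated on a 10 nm grid. For
quantitative cluster analysis the volume is re-binned to 30 nm voxels (one
RyR tetramer footprint per voxel), binarized with Otsu's threshold, and
segmented into connected components. Event counts ride along as a separate
integer grid binned directly from the raw coordinates, so the "events per
cluster" bookkeeping is independent of the Gaussian rendering.

Arrays are indexed ``[ix, iy, iz]`` (x fastest-varying axis first); voxel k
covers the half-open interval ``[origin + k*s, origin + (k+1)*s)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.special import erf

from .localizations import LocalizationTable

__all__ = [
    "AnalysisVolume",
    "Cluster",
    "ClusterSet",
    "render_gaussian",
    "downscale",
    "binarize_otsu",
    "segment_clusters",
    "project_2d",
    "project_mask",
]


class ThresholdError(ValueError):
    """Raised when a volume has no contrast to threshold."""


@dataclass
class AnalysisVolume:
    """Voxelized rendering of a localization field.

    ``intensity`` is the Gaussian-rendered density; ``event_count`` the raw
    per-voxel blink counts. Either 3D ``(nx, ny, nz)`` or, after projection,
    2D ``(nx, ny)``. ``voxel_nm`` and ``origin_nm`` have one entry per axis.
    """

    intensity: np.ndarray
    event_count: np.ndarray
    voxel_nm: tuple[float, ...]
    origin_nm: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.intensity.shape != self.event_count.shape:
            raise ValueError("intensity and event_count grids must share a shape")
        if len(self.voxel_nm) != self.intensity.ndim or len(self.origin_nm) != self.intensity.ndim:
            raise ValueError("voxel_nm/origin_nm must have one entry per array axis")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("non-finite intensity")

    @property
    def ndim(self) -> int:
        return self.intensity.ndim

    @property
    def n_events(self) -> int:
        return int(self.event_count.sum())

    def voxel_centers(self, indices: np.ndarray) -> np.ndarray:
        """Physical centers (nm) of the given ``(n, ndim)`` voxel indices."""
        idx = np.atleast_2d(indices).astype(float)
        return np.asarray(self.origin_nm) + (idx + 0.5) * np.asarray(self.voxel_nm)


@dataclass
class Cluster:
    """One connected component of RyR-occupied voxels."""

    id: int
    voxels: np.ndarray  # (n, ndim) integer indices
    event_count: int
    centroid_nm: np.ndarray
    z_extent_nm: float
    ryr_count: float | None = None  # filled in by calibration


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    voxel_nm: tuple[float, ...]
    origin_nm: tuple[float, ...]
    roi_volume_um3: float | None = None

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    @property
    def total_events(self) -> int:
        return sum(c.event_count for c in self.clusters)


def _bin_counts(xyz: np.ndarray, origin: np.ndarray, voxel: np.ndarray, shape) -> np.ndarray:
    """Half-open histogram of points onto the voxel grid."""
    idx = np.floor((xyz - origin) / voxel).astype(int)
    ok = np.all((idx >= 0) & (idx < np.asarray(shape)), axis=1)
    counts = np.zeros(shape, dtype=np.int64)
    np.add.at(counts, tuple(idx[ok].T), 1)
    return counts


def render_gaussian(
    table: LocalizationTable,
    voxel_nm: float = 10.0,
    truncate_sigma: float = 3.0,
    pad_nm: float | None = None,
) -> AnalysisVolume:
    """Render a localization table onto a voxel grid.

    Each event deposits a separable anisotropic Gaussian of unit mass
    (sigma_xy = its lateral precision, sigma_z = its axial precision),
    truncated at ``truncate_sigma`` standard deviations. Per-axis voxel
    masses are exact Gaussian integrals over voxel edges (erf differences),
    so a single event sums to ~0.992 after 3-sigma truncation. The
    ``event_count`` grid bins the raw coordinates directly.
    """
    if voxel_nm <= 0:
        raise ValueError("voxel_nm must be positive")
    if len(table) == 0:
        raise ValueError("cannot render an empty localization table")

    xyz = table.xyz
    prec = table.events[["precision_xy", "precision_xy", "precision_z"]].to_numpy(float)
    if pad_nm is None:
        pad_nm = truncate_sigma * float(prec.max())
    lo = np.floor((xyz.min(axis=0) - pad_nm) / voxel_nm) * voxel_nm
    hi = np.ceil((xyz.max(axis=0) + pad_nm) / voxel_nm) * voxel_nm
    shape = tuple(np.maximum(1, np.round((hi - lo) / voxel_nm)).astype(int))

    intensity = np.zeros(shape, dtype=np.float64)
    for pos, sig in zip(xyz, prec):
        profiles = []
        slices = []
        for ax in range(3):
            r = truncate_sigma * sig[ax]
            i0 = max(0, int(np.floor((pos[ax] - r - lo[ax]) / voxel_nm)))
            i1 = min(shape[ax], int(np.ceil((pos[ax] + r - lo[ax]) / voxel_nm)))
            if i1 <= i0:
                i0, i1 = 0, 0
            edges = lo[ax] + np.arange(i0, i1 + 1) * voxel_nm
            cdf = 0.5 * (1.0 + erf((edges - pos[ax]) / (np.sqrt(2.0) * sig[ax])))
            profiles.append(np.diff(cdf))
            slices.append(slice(i0, i1))
        if any(p.size == 0 for p in profiles):
            continue
        block = profiles[0][:, None, None] * profiles[1][None, :, None] * profiles[2][None, None, :]
        intensity[tuple(slices)] += block

    counts = _bin_counts(xyz, lo, np.full(3, voxel_nm), shape)
    return AnalysisVolume(intensity, counts, (voxel_nm,) * 3, tuple(lo))


def downscale(vol: AnalysisVolume, voxel_nm: float = 30.0) -> AnalysisVolume:
    """Re-bin a volume onto coarser voxels (default 30 nm, one RyR per voxel).

    For an integer size ratio both grids nest, so intensity is summed over
    blocks (zero-padded at the high edge) and event counts re-bin exactly;
    the total event count is conserved.
    """
    src = vol.voxel_nm[0]
    if any(abs(v - src) > 1e-9 for v in vol.voxel_nm):
        raise ValueError("downscale expects an isotropic source volume")
    if voxel_nm < src - 1e-9:
        raise ValueError("target voxel size must be >= source voxel size")
    ratio = voxel_nm / src
    f = int(round(ratio))
    if abs(ratio - f) > 1e-6:
        raise ValueError(
            f"target voxel {voxel_nm} nm is not an integer multiple of source {src} nm"
        )
    shape = vol.intensity.shape
    new_shape = tuple(-(-s // f) for s in shape)
    pad = [(0, n * f - s) for n, s in zip(new_shape, shape)]
    inten = np.pad(vol.intensity, pad)
    counts = np.pad(vol.event_count, pad)
    # block-sum via reshape
    resh = tuple(x for n in new_shape for x in (n, f))
    sum_axes = tuple(range(1, 2 * len(new_shape), 2))
    inten = inten.reshape(resh).sum(axis=sum_axes)
    counts = counts.reshape(resh).sum(axis=sum_axes)
    return AnalysisVolume(inten, counts, (voxel_nm,) * vol.ndim, vol.origin_nm)


def otsu_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Threshold maximizing between-class variance over an nbins histogram.

    The returned threshold is the *edge* of the winning split (not a bin
    center), so no occupied bin is ever cut in half; among tied splits the
    first is taken.
    """
    hist, edges = np.histogram(values, bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    w1 = np.cumsum(hist)
    w2 = w1[-1] - w1
    csum = np.cumsum(hist * centers)
    with np.errstate(invalid="ignore", divide="ignore"):
        m1 = csum / w1
        m2 = (csum[-1] - csum) / w2
        variance = w1 * w2 * (m1 - m2) ** 2
    variance[~np.isfinite(variance)] = -np.inf
    k = int(np.argmax(variance[:-1]))
    return float(edges[k + 1])


def binarize_otsu(vol: AnalysisVolume, nbins: int = 256) -> np.ndarray:
    """Otsu threshold on the nonzero intensity histogram; returns a boolean mask.

    Zero voxels (empty space, which dominates a rendered SMLM volume) are
    excluded from the histogram so the between-class variance criterion
    separates signal from rendered background rather than from emptiness.
    """
    values = vol.intensity[vol.intensity > 0]
    if values.size == 0 or np.isclose(values.min(), values.max()):
        raise ThresholdError("volume has no contrast to threshold")
    return vol.intensity > otsu_threshold(values, nbins)


def _structure(ndim: int) -> np.ndarray:
    """Full connectivity: 26-connected in 3D, 8-connected in 2D."""
    return np.ones((3,) * ndim, dtype=bool)


def segment_clusters(mask: np.ndarray, vol: AnalysisVolume) -> ClusterSet:
    """Label connected components of ``mask`` into RyR clusters.

    Uses 26-connectivity (8 in 2D) so diagonal voxel contacts at RyR scale
    are not split; single-voxel components are retained. Each cluster's
    event count is the sum of ``vol.event_count`` over its member voxels.
    """
    if mask.shape != vol.intensity.shape:
        raise ValueError("mask and volume shapes differ")
    labels, n = ndimage.label(mask, structure=_structure(mask.ndim))
    clusters: list[Cluster] = []
    if n:
        objects = ndimage.find_objects(labels)
        counts = ndimage.sum_labels(vol.event_count, labels, index=np.arange(1, n + 1))
        for cid in range(1, n + 1):
            sl = objects[cid - 1]
            local = np.argwhere(labels[sl] == cid)
            vox = local + np.array([s.start for s in sl])
            centers = vol.voxel_centers(vox)
            centroid = centers.mean(axis=0)
            if mask.ndim == 3:
                z_extent = float(centers[:, 2].max() - centers[:, 2].min() + vol.voxel_nm[2])
            else:
                z_extent = 0.0
            clusters.append(
                Cluster(cid, vox, int(counts[cid - 1]), centroid, z_extent)
            )
    return ClusterSet(clusters, vol.voxel_nm, vol.origin_nm)


def project_2d(vol: AnalysisVolume) -> AnalysisVolume:
    """Sum a 3D volume along z, emulating conventional 2D reconstruction."""
    if vol.ndim != 3:
        raise ValueError("project_2d expects a 3D volume")
    return AnalysisVolume(
        vol.intensity.sum(axis=2),
        vol.event_count.sum(axis=2),
        vol.voxel_nm[:2],
        vol.origin_nm[:2],
    )


def project_mask(mask: np.ndarray) -> np.ndarray:
    """Project a 3D binary mask along z (logical OR)."""
    if mask.ndim != 3:
        raise ValueError("project_mask expects a 3D mask")
    return mask.any(axis=2)


def project_clusters(clusters: ClusterSet, vol: AnalysisVolume) -> ClusterSet:
    """Re-segment a 3D cluster set after 2D projection.

    Vertically aligned clusters merge; the number of 2D clusters is always
    <= the number of 3D clusters.
    """
    mask = np.zeros(vol.intensity.shape, dtype=bool)
    for c in clusters:
        mask[tuple(c.voxels.T)] = True
    return segment_clusters(project_mask(mask), project_2d(vol))
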