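import numpy as np
import pandas as pd
import pytest

from ryrquant.localizations import COLUMNS, LocalizationTable
from ryrquant.volumes import Cluster, ClusterSet


def make_table(xyz, precisions=(20.0, 40.0), frames=None, n_frames=20_000):
    """Build a LocalizationTable from an (n, 3) position array."""
    xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
    n = len(xyz)
    if frames is None:
        frames = np.arange(n) % n_frames
    ev = pd.DataFrame(
        {
            "frame": np.asarray(frames, dtype=int),
            "x": xyz[:, 0],
            "y": xyz[:, 1],
            "z": xyz[:, 2],
            "precision_xy": precisions[0],
            "precision_z": precisions[1],
        }
    )[COLUMNS]
    return LocalizationTable(ev, n_frames=n_frames)


def make_clusters(voxel_lists, voxel_nm=30.0, origin=(0.0, 0.0, 0.0), event_counts=None):
    """Build a ClusterSet directly from per-cluster voxel index lists."""
    clusters = []
    ndim = len(np.atleast_2d(voxel_lists[0])[0])
    for cid, vox in enumerate(voxel_lists):
        vox = np.atleast_2d(np.asarray(vox, dtype=int))
        centers = np.asarray(origin[:ndim]) + (vox + 0.5) * voxel_nm
        z_extent = (
            float(centers[:, 2].max() - centers[:, 2].min() + voxel_nm) if ndim == 3 else 0.0
        )
        n_ev = event_counts[cid] if event_counts is not None else len(vox)
        clusters.append(
            Cluster(cid, vox, int(n_ev), centers.mean(axis=0), z_extent)
        )
    return ClusterSet(clusters, (voxel_nm,) * ndim, tuple(origin[:ndim]))


@pytest.fixture
def fig3_clusters():
    """Three single-voxel clusters: all pairwise 3D edge-to-edge distances
    exceed 100 nm while every 2D-projected pair is within 100 nm."""
    return make_clusters([[(0, 0, 5)], [(2, 0, 10)], [(0, 2, 0)]])


@pytest.fixture
def rng():
    return np.random.default_rng(0)
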