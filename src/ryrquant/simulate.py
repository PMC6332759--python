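"""Seeded synthetic-data generators with ground truth.

Every input the pipeline consumes can be generated here: localization
tables with known RyR positions and blinking statistics, confocal-like
t-tubule stacks with known skeletons, dyad scenes with known dyadic /
non-dyadic labels, and spark movies with known kinetics. Each generator is
a pure function of its parameters and a seed, and returns the ground truth
needed for parameter-recovery tests.

Default conditions mirror the acquisition being emulated: ~3.31 blink
events per RyR, log-normal localization precision with medians 32 nm
(lateral) and 64 nm (axial), RyRs on 30 nm lattices, surface sheets that
undulate by ~150 nm, interior clusters ordered on z-line planes 1.8 um
apart, 250 nm tubules, and sparks sampled at 1.85 ms/frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .localizations import COLUMNS, LocalizationTable
from .volumes import Cluster, ClusterSet
from .dyads import TubuleGeometry, dilate_skeleton

__all__ = [
    "GroundTruth",
    "generate_localization_field",
    "generate_tubule_stack",
    "generate_dyad_scene",
    "generate_spark_movie",
]


@dataclass
class GroundTruth:
    """Simulation bookkeeping for parameter-recovery tests."""

    ryr_positions: list[np.ndarray] = field(default_factory=list)  # per cluster, (n, 3) nm
    cluster_labels: np.ndarray | None = None  # per event -> cluster index
    cru_labels: np.ndarray | None = None  # per cluster -> CRU index
    events_per_ryr: float | None = None
    dyadic_labels: np.ndarray | None = None  # per cluster, bool
    tubule_skeleton: np.ndarray | None = None
    spark_params: list[dict] = field(default_factory=list)
    drift_nm_per_frame: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    @property
    def n_ryrs(self) -> int:
        return sum(len(p) for p in self.ryr_positions)


def _compact_lattice(n: int, spacing: float, rng: np.random.Generator) -> np.ndarray:
    """n lattice sites forming a compact, axis-aligned patch around the origin."""
    r = int(math.ceil(math.sqrt(n))) + 1
    ii, jj = np.mgrid[-r : r + 1, -r : r + 1]
    sites = np.column_stack([ii.ravel(), jj.ravel()]).astype(float)
    order = np.argsort((sites**2).sum(axis=1) + 1e-6 * rng.random(len(sites)))
    return sites[order[:n]] * spacing


def _true_cru_labels(ryr_positions: list[np.ndarray], gap_nm: float, edge_nm: float) -> np.ndarray:
    """Single-linkage CRU labels of true clusters (edge = min point dist - edge_nm)."""
    n = len(ryr_positions)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            d = np.sqrt(
                ((ryr_positions[i][:, None, :] - ryr_positions[j][None, :, :]) ** 2).sum(-1)
            ).min()
            if max(0.0, d - edge_nm) <= gap_nm:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    roots = {}
    labels = np.empty(n, dtype=int)
    for i in range(n):
        r = find(i)
        labels[i] = roots.setdefault(r, len(roots))
    return labels


def generate_localization_field(
    layout: str = "surface",
    n_clusters: int = 50,
    mean_ryrs: float = 10.0,
    pitch_nm: float = 600.0,
    jitter_nm: float = 100.0,
    undulation_amp_nm: float = 150.0,
    undulation_wavelength_nm: float = 2000.0,
    zline_spacing_nm: float = 1800.0,
    events_per_ryr: float = 3.31,
    precision_xy_median_nm: float = 32.0,
    precision_z_median_nm: float = 64.0,
    precision_log_sigma: float = 0.3,
    ryr_spacing_nm: float = 30.0,
    n_stacked_pairs: int = 0,
    stack_dz_nm: float = 400.0,
    drift_nm_per_frame: tuple[float, float, float] | None = None,
    n_frames: int = 20_000,
    seed: int = 0,
) -> tuple[LocalizationTable, GroundTruth]:
    """Generate a localization field of RyR clusters with known ground truth.

    Cluster anchors sit on a jittered grid (guaranteeing lateral
    isolation); cluster sizes follow a geometric law with the given mean
    (small clusters dominate, as observed experimentally); each cluster is
    a compact 30 nm lattice patch. ``surface`` layout places clusters on a
    sinusoidally undulating sheet; ``interior`` layout snaps them onto
    z-line planes ``zline_spacing_nm`` apart. Every RyR emits
    Poisson(``events_per_ryr``) blinks, displaced by anisotropic Gaussian
    noise whose sigmas are per-event log-normal precisions. Optional
    ``n_stacked_pairs`` plants axially aligned cluster pairs (same xy,
    offset ``stack_dz_nm``), and ``drift_nm_per_frame`` injects linear
    sample drift.
    """
    if layout not in ("surface", "interior"):
        raise ValueError("layout must be 'surface' or 'interior'")
    if n_clusters < 1 or mean_ryrs < 1 or events_per_ryr <= 0:
        raise ValueError("invalid generator parameters")
    rng = np.random.default_rng(seed)

    side = int(math.ceil(math.sqrt(n_clusters)))
    gx, gy = np.mgrid[0:side, 0:side]
    anchors_xy = (
        np.column_stack([gx.ravel(), gy.ravel()])[:n_clusters].astype(float) * pitch_nm
        + rng.uniform(-jitter_nm, jitter_nm, size=(n_clusters, 2))
    )

    ryr_positions: list[np.ndarray] = []
    for ax, ay in anchors_xy:
        n_ryr = int(rng.geometric(1.0 / mean_ryrs))
        patch = _compact_lattice(n_ryr, ryr_spacing_nm, rng)
        if layout == "surface":
            az = undulation_amp_nm * math.sin(
                2 * math.pi * ax / undulation_wavelength_nm
            ) * math.sin(2 * math.pi * ay / undulation_wavelength_nm)
        else:
            ax = round(ax / zline_spacing_nm) * zline_spacing_nm + rng.uniform(-60, 60)
            az = rng.uniform(-200.0, 200.0)
        pts = np.column_stack(
            [patch[:, 0] + ax, patch[:, 1] + ay, np.full(len(patch), az)]
        )
        ryr_positions.append(pts)

    for k in range(min(n_stacked_pairs, len(ryr_positions))):
        base = ryr_positions[k]
        ryr_positions.append(base + np.array([0.0, 0.0, stack_dz_nm]))

    # blinks
    rows = []
    cluster_of_event = []
    for ci, pts in enumerate(ryr_positions):
        counts = rng.poisson(events_per_ryr, size=len(pts))
        for p, c in zip(pts, counts):
            if c == 0:
                continue
            pxy = precision_xy_median_nm * np.exp(
                rng.normal(0.0, precision_log_sigma, size=c)
            )
            pz = precision_z_median_nm * np.exp(
                rng.normal(0.0, precision_log_sigma, size=c)
            )
            dx = rng.normal(0.0, 1.0, size=c) * pxy
            dy = rng.normal(0.0, 1.0, size=c) * pxy
            dz = rng.normal(0.0, 1.0, size=c) * pz
            fr = rng.integers(0, n_frames, size=c)
            for i in range(c):
                rows.append(
                    (fr[i], p[0] + dx[i], p[1] + dy[i], p[2] + dz[i], pxy[i], pz[i])
                )
                cluster_of_event.append(ci)
    if not rows:
        raise ValueError("generator produced no events; increase rate or cluster count")
    ev = pd.DataFrame(rows, columns=COLUMNS)
    labels = np.asarray(cluster_of_event)

    drift_vec = None
    if drift_nm_per_frame is not None:
        drift_vec = np.asarray(drift_nm_per_frame, dtype=float)
        shift = ev["frame"].to_numpy()[:, None] * drift_vec[None, :]
        ev[["x", "y", "z"]] = ev[["x", "y", "z"]].to_numpy() + shift

    order = np.argsort(ev["frame"].to_numpy(), kind="stable")
    ev = ev.iloc[order].reset_index(drop=True)
    labels = labels[order]

    truth = GroundTruth(
        ryr_positions=ryr_positions,
        cluster_labels=labels,
        cru_labels=_true_cru_labels(ryr_positions, gap_nm=100.0, edge_nm=ryr_spacing_nm),
        events_per_ryr=events_per_ryr,
        drift_nm_per_frame=drift_vec,
        extras={"layout": layout, "anchors_xy": anchors_xy},
    )
    table = LocalizationTable(ev, n_frames=n_frames)
    return table, truth


def generate_tubule_stack(
    shape_um: tuple[float, float, float] = (8.0, 8.0, 3.0),
    voxel_nm: tuple[float, float, float] = (100.0, 100.0, 200.0),
    tubule_spacing_um: float = 1.8,
    diameter_nm: float = 250.0,
    psf_sigma_nm: tuple[float, float, float] = (150.0, 150.0, 300.0),
    photons_per_voxel: float = 50.0,
    background: float = 2.0,
    branches_per_tubule: float = 0.5,
    seed: int = 0,
) -> tuple[np.ndarray, GroundTruth]:
    """Simulate a confocal t-tubule stack with a known skeleton.

    Straight tubules run along y on z-line planes ``tubule_spacing_um``
    apart, with occasional axial branch segments; the skeleton is dilated
    to ``diameter_nm`` cylinders (anisotropic Euclidean distance), blurred
    with a Gaussian PSF, and shot noise is added. Returns the stack
    (float, ``[ix, iy, iz]``) and the skeleton as ground truth.
    """
    rng = np.random.default_rng(seed)
    voxel = np.asarray(voxel_nm, dtype=float)
    shape = tuple(int(round(s * 1000.0 / v)) for s, v in zip(shape_um, voxel))
    skeleton = np.zeros(shape, dtype=bool)
    xs = np.arange(0.6, shape_um[0] - 0.3, tubule_spacing_um)
    z_mid = shape[2] // 2
    for x_um in xs:
        ix = int(round(x_um * 1000.0 / voxel[0]))
        iz = int(np.clip(z_mid + rng.integers(-1, 2), 0, shape[2] - 1))
        skeleton[ix, :, iz] = True
        if rng.random() < branches_per_tubule:
            iy = int(rng.integers(shape[1] // 4, 3 * shape[1] // 4))
            length = int(rng.integers(3, max(4, shape[0] // 4)))
            skeleton[max(0, ix - length) : ix, iy, iz] = True
    dist = ndimage.distance_transform_edt(~skeleton, sampling=voxel)
    tubules = dist <= diameter_nm / 2.0
    img = tubules.astype(float)
    sigma_vox = np.asarray(psf_sigma_nm) / voxel
    if np.any(sigma_vox > 0):
        img = ndimage.gaussian_filter(img, sigma=sigma_vox)
    expected = background + photons_per_voxel * img
    stack = rng.poisson(expected).astype(float)
    truth = GroundTruth(
        tubule_skeleton=skeleton,
        extras={"tubule_mask": tubules, "voxel_nm": tuple(voxel)},
    )
    return stack, truth


def generate_dyad_scene(
    n_clusters: int = 100,
    nondyadic_fraction: float = 0.15,
    voxel_nm: float = 20.0,
    scene_um: tuple[float, float, float] = (6.0, 6.0, 2.0),
    tubule_spacing_um: float = 1.8,
    diameter_nm: float = 250.0,
    cleft_nm: float = 10.0,
    cluster_voxel_nm: float = 30.0,
    seed: int = 0,
) -> tuple[ClusterSet, TubuleGeometry, GroundTruth]:
    """Build a tubule network plus RyR clusters with known dyadic labels.

    Dyadic clusters are planted in the cleft region just outside the
    tubule surface; non-dyadic clusters are placed at least 400 nm from
    every skeleton voxel (safely beyond the 250 nm classification
    threshold). Cluster voxels live on a 30 nm grid sharing the scene's
    nm coordinate frame.
    """
    rng = np.random.default_rng(seed)
    shape = tuple(int(round(s * 1000.0 / voxel_nm)) for s in scene_um)
    skeleton = np.zeros(shape, dtype=bool)
    xs = np.arange(0.9, scene_um[0] - 0.45, tubule_spacing_um)
    iz = shape[2] // 2
    for x_um in xs:
        ix = int(round(x_um * 1000.0 / voxel_nm))
        skeleton[ix, :, iz] = True
    geom = dilate_skeleton(skeleton, voxel_nm, diameter_nm, cleft_nm)
    skel_pts = geom.skeleton_points_nm()

    from scipy.spatial import cKDTree

    tree = cKDTree(skel_pts)
    bounds = np.asarray(scene_um) * 1000.0
    radius = diameter_nm / 2.0

    clusters: list[Cluster] = []
    labels = []
    cid = 0
    n_dyadic = int(round(n_clusters * (1.0 - nondyadic_fraction)))
    while cid < n_clusters:
        want_dyadic = cid < n_dyadic
        if want_dyadic:
            anchor = skel_pts[rng.integers(len(skel_pts))]
            theta = rng.uniform(0, 2 * math.pi)
            direction = np.array([math.cos(theta), 0.0, math.sin(theta)])
            center = anchor + direction * (radius + cleft_nm / 2.0)
        else:
            center = rng.uniform([200.0] * 3, bounds - 200.0)
            if tree.query(center)[0] < 400.0:
                continue
        if np.any(center < 100.0) or np.any(center > bounds - 100.0):
            continue
        base = np.floor(center / cluster_voxel_nm).astype(int)
        n_vox = int(rng.integers(1, 5))
        offsets = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]])[:n_vox]
        vox = base + offsets
        centers = (vox + 0.5) * cluster_voxel_nm
        clusters.append(
            Cluster(
                id=cid,
                voxels=vox,
                event_count=int(rng.poisson(10) + 1),
                centroid_nm=centers.mean(axis=0),
                z_extent_nm=cluster_voxel_nm,
            )
        )
        labels.append(want_dyadic)
        cid += 1
    cs = ClusterSet(clusters, (cluster_voxel_nm,) * 3, (0.0, 0.0, 0.0))
    truth = GroundTruth(
        dyadic_labels=np.asarray(labels),
        tubule_skeleton=skeleton,
        extras={"geometry_voxel_nm": voxel_nm},
    )
    return cs, geom, truth


def _spark_timecourse(t_ms: np.ndarray, t0: float, tau_rise: float, rise_ms: float, tau_decay: float) -> np.ndarray:
    """Unit-amplitude exponential rise to a peak at ``t0 + rise_ms``, then decay."""
    t_peak = t0 + rise_ms
    rise = 1.0 - np.exp(-np.clip(t_ms - t0, 0.0, None) / tau_rise)
    peak = 1.0 - math.exp(-rise_ms / tau_rise)
    decay = peak * np.exp(-np.clip(t_ms - t_peak, 0.0, None) / tau_decay)
    return np.where(t_ms <= t_peak, rise, decay)


def spark_fdhm_ms(amplitude: float, tau_rise: float, rise_ms: float, tau_decay: float) -> float:
    """Analytic full duration at half maximum of the generator's transient."""
    peak = 1.0 - math.exp(-rise_ms / tau_rise)
    frac = peak / 2.0
    t_half_rise = -tau_rise * math.log(1.0 - frac)
    t_half_decay = rise_ms + tau_decay * math.log(2.0)
    return t_half_decay - t_half_rise


def generate_spark_movie(
    n_frames: int = 400,
    shape_px: tuple[int, int] = (48, 256),
    pixel_um: float = 0.16,
    frame_interval_ms: float = 1.85,
    cell_margin_px: int = 6,
    baseline: float = 100.0,
    outside: float = 5.0,
    noise_sigma: float = 0.02,
    sparks: list[dict] | None = None,
    n_sparks: int = 8,
    amplitude: float = 0.8,
    sigma_um: float = 0.85,
    tau_rise_ms: float = 4.0,
    rise_ms: float = 10.0,
    tau_decay_ms: float = 30.0,
    min_separation_px: int = 24,
    seed: int = 0,
) -> tuple[np.ndarray, GroundTruth]:
    """Simulate a confocal spark movie with known spark kinetics.

    A rectangular cell on a dim background; sparks are separable
    space x time transients: 2D Gaussian (sigma ``sigma_um``) times an
    exponential rise (time constant ``tau_rise_ms``, rising for
    ``rise_ms`` to its peak) followed by exponential decay
    (``tau_decay_ms``). ``noise_sigma`` is Gaussian noise relative to the
    baseline. Explicit ``sparks`` dicts override the random placement;
    requests that cannot keep ``min_separation_px`` spacing are thinned
    with a warning.
    """
    if n_frames < 100:
        raise ValueError("need at least 100 frames")
    rng = np.random.default_rng(seed)
    ny, nx = shape_px
    mask = np.zeros((ny, nx), dtype=bool)
    mask[cell_margin_px : ny - cell_margin_px, cell_margin_px : nx - cell_margin_px] = True

    if sparks is None:
        sparks = []
        attempts = 0
        while len(sparks) < n_sparks and attempts < 200 * n_sparks:
            attempts += 1
            row = int(rng.integers(cell_margin_px + 4, ny - cell_margin_px - 4))
            col = int(rng.integers(cell_margin_px + 8, nx - cell_margin_px - 8))
            if any(
                abs(col - s["col"]) < min_separation_px and abs(row - s["row"]) < min_separation_px
                for s in sparks
            ):
                continue
            sparks.append(
                {
                    "row": row,
                    "col": col,
                    "t0_ms": float(rng.uniform(40.0, (n_frames - 60) * frame_interval_ms - 80.0)),
                    "amplitude": amplitude,
                    "sigma_um": sigma_um,
                    "tau_rise_ms": tau_rise_ms,
                    "rise_ms": rise_ms,
                    "tau_decay_ms": tau_decay_ms,
                }
            )
        if len(sparks) < n_sparks:
            import warnings

            warnings.warn(f"could only place {len(sparks)} of {n_sparks} requested sparks")

    t_ms = np.arange(n_frames) * frame_interval_ms
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    dff = np.zeros((n_frames, ny, nx))
    truth_params = []
    for s in sparks:
        sig_px = s["sigma_um"] / pixel_um
        spatial = np.exp(
            -(((yy - s["row"]) ** 2 + (xx - s["col"]) ** 2) / (2.0 * sig_px**2))
        )
        temporal = s["amplitude"] * _spark_timecourse(
            t_ms, s["t0_ms"], s["tau_rise_ms"], s["rise_ms"], s["tau_decay_ms"]
        )
        dff += temporal[:, None, None] * spatial[None, :, :]
        dist_px = min(
            s["row"] - cell_margin_px,
            ny - cell_margin_px - 1 - s["row"],
            s["col"] - cell_margin_px,
            nx - cell_margin_px - 1 - s["col"],
        )
        truth_params.append(
            dict(
                s,
                # the transient rises for a finite time, so the realized peak
                # dF/F0 is below the amplitude asymptote
                peak_dff=s["amplitude"] * (1.0 - math.exp(-s["rise_ms"] / s["tau_rise_ms"])),
                fwhm_um=2.0 * math.sqrt(2.0 * math.log(2.0)) * s["sigma_um"],
                fdhm_ms=spark_fdhm_ms(
                    s["amplitude"], s["tau_rise_ms"], s["rise_ms"], s["tau_decay_ms"]
                ),
                depth_um=dist_px * pixel_um,
            )
        )

    f0 = np.where(mask, baseline, outside)
    frames = f0[None, :, :] * (1.0 + dff * mask[None, :, :])
    if noise_sigma > 0:
        frames = frames + rng.normal(0.0, noise_sigma * baseline, size=frames.shape)
    truth = GroundTruth(
        spark_params=truth_params,
        extras={
            "cell_mask": mask,
            "pixel_um": pixel_um,
            "frame_interval_ms": frame_interval_ms,
            "baseline": baseline,
        },
    )
    return frames, truth
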