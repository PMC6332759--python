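# Methods

This note documents the models, conventions, and numerical choices behind
`ryrquant`, in the spirit of a methods supplement: what each stage assumes,
which parameters matter, and what the synthetic benchmarks do and do not
demonstrate.

## Coordinate and voxel conventions

Positions are right-handed nm floats with z increasing away from the
coverslip. Voxel grids are indexed `[ix, iy, iz]` with 0-based indices;
voxel `k` covers the half-open interval `[origin + k·s, origin + (k+1)·s)`.
Rendered volumes use 10 nm voxels; quantitative cluster analysis re-bins to
30 × 30 × 30 nm so that one voxel holds at most one RyR tetramer
(~29 × 29 × 12 nm).

## Localization tables and drift

A localization table holds one row per single-molecule blink: frame, (x, y,
z) in nm, and per-event lateral/axial precision. Acquisitions default to
20,000 frames at 50 ms exposure. Rows with non-finite coordinates are
dropped on read and counted in the log.

Drift correction is fiducial-free redundant cross-correlation: the
acquisition is cut into temporal bins (≈200 events per bin, at most 32
bins); each bin's localization histogram (2D in xy at 50 nm pixels, 1D in
z, Gaussian-smoothed by 1.5 pixels so sparse histograms produce a stable
correlation peak) is registered to the first bin by subpixel phase
correlation, and the per-bin shifts are fitted per axis with a continuous
piecewise-linear function over five equal spans of the frame range. The
fitted drift minus its event-weighted mean is subtracted, which preserves
the table's mean position and leaves a pure constant offset untouched.
Registering bin-to-bin rather than against the whole-table average matters:
a drift-smeared global reference biases the recovered slope toward zero by
tens of percent.

Only events within the central 600 nm of the axial capture range are kept
for quantitative analysis (larger |z| carries larger axial error).

## Rendering and segmentation

Each blink deposits a unit-mass anisotropic Gaussian (σxy = its lateral
precision, σz = its axial precision), truncated at 3σ; per-axis voxel
masses are exact erf integrals, so a single event integrates to ≈0.992.
Raw blink coordinates are additionally binned into an integer
`event_count` grid; all event bookkeeping downstream uses these counts,
never the rendered intensity. Re-binning to 30 nm block-sums both grids
(the grids nest), conserving the total event count exactly.

Binarization is Otsu's threshold on a 256-bin histogram of the *nonzero*
intensity voxels (empty space dominates a rendered SMLM volume and would
otherwise swamp the histogram). Connected components under 26-connectivity
(8 in 2D) become clusters; single-voxel components are retained; a
cluster's `event_count` is the sum over its member voxels. 2D analysis
projects intensity and counts along z and re-segments, which can only
merge clusters — the code asserts nothing else.

## Events-per-RyR calibration

Flat, laterally isolated surface clusters are selected, their RyR number is
counted by fitting a 30 × 30 nm grid to the 2D footprint (a cell counts if
its center falls inside the footprint; the grid is anchored at the
footprint bounding box, making the count translation-invariant), and the
per-cluster blink count is regressed against the RyR count with an
ordinary least-squares line through the origin (zero RyRs must give zero
events; R² uses the uncentered total sum of squares; an intercept mode
exists but is not the default). The package ships 3.3076 events/RyR as the
default constant; `estimate_ryr_count` divides any cluster's event count by
the slope.

Three design choices in the calibration path deserve explanation:

- **Flatness gate.** A physically flat cluster renders 180–390 nm thick in
  z because the rendered thickness is set by the axial precision (FWHM
  ≈ 213 nm at the 64 nm median, wider for event-rich clusters). The
  flatness cutoff is therefore 450 nm — about twice the rendered axial
  FWHM — rather than a single-tetramer height; clusters stacked a few
  hundred nm apart either segment separately (and are removed by the
  footprint-overlap rule: any cluster whose one-voxel-dilated projected
  footprint touches another cluster's footprint is excluded) or exceed the
  gate.
- **Blink assignment.** The Otsu mask hugs a contour well below the blink
  scatter's half-maximum, so counting only in-mask blinks loses ~30% of a
  cluster's events. For calibration, every event is instead assigned to the
  nearest cluster (distance to member voxel centers) within a 150 nm
  capture radius — physically, every blink belongs to some cluster.
- **Footprint for grid counting.** The global Otsu footprint overinflates
  by roughly the blur width (total lateral σ ≈ 45 nm: event scatter plus
  rendering kernel). Grid counting therefore uses each cluster's
  *half-maximum* projected footprint — the half-maximum contour of a
  blurred uniform patch sits on the true patch edge — and only footprints
  of at least 12 grid cells enter the fit, because a support smaller than
  ~2.5 blur σ across cannot be recovered by thresholding at any level.

With these choices the full pipeline recovers a generating rate of 3.31
events/RyR from ≥500 synthetic flat clusters to within ~3%; the residual
deficit is regression dilution from the noise in the measured grid counts.
Treating *all* surface clusters as flat (projecting first, as a 2D-only
analysis must) merges axially stacked clusters into single footprints that
carry both clusters' blinks, and biases the fitted slope upward — the
package reproduces that direction of bias on demand
(`calibrate_from_field(assume_flat=True)`).

## Cluster, CRU, and whole-cell statistics

Edge-to-edge distance between clusters is the minimum distance between
member voxel centers minus one voxel size, floored at zero. This makes the
"dilate by 50 nm and fuse" and "edge-to-edge ≤ 100 nm" formulations of CRU
grouping equivalent and avoids anisotropic structuring-element artifacts.
CRU grouping is single linkage (transitive closure) at a 100 nm gap;
nearest-neighbour distances use the same edge convention (a configuration
switch to center-to-center exists). 2D variants project voxel centers
first, so 2D NND ≤ 3D NND and 2D CRU count ≤ 3D CRU count hold by
construction.

CRU density divides the CRU count by the analyzed volume, defined as the
xy ROI footprint × the 600 nm analysis slab — the same per-µm³ convention
for surface and interior data, and every report states it.

Whole-cell extrapolation uses an idealized elliptic-cylinder myocyte
(short/long radii 6/10 µm, length 130 µm, volume ≈ 25,000 µm³). Interior
RyRs are excluded from the outermost 1.5 µm shell, so the interior volume
is π(a−s)(b−s)(L−2s); surface RyRs are an areal density times the lateral
surface (Ramanujan's perimeter approximation × length) plus the two
elliptical end faces.

## Dyad reconstruction

Confocal t-tubule stacks are resampled to isotropic 10 nm voxels (linear
interpolation), thresholded at the global mean intensity, pruned of
disconnected components smaller than 0.03 µm³ (strictly smaller; a
component of exactly 0.03 µm³ survives), and skeletonized by 3D
topology-preserving thinning. The skeleton is re-dilated via a Euclidean
distance transform to uniform 250 nm cylinders; a 10 nm cleft shell just
outside the tubule surface is the candidate junctional-SR (jSR) mask.

dSTORM-to-confocal alignment fits isotropic scale plus translation to
matched peripheral landmarks in closed form; when both modalities' RyR
images are supplied, the axial shift is refined by cross-correlating their
z-profiles.

A cluster is dyadic if it overlaps the jSR shell or its centroid lies
within 250 nm of the nearest *skeleton* voxel. An equivalent rule
could measure to the tubule surface instead; measuring to the skeleton is
deterministic and independent of the assumed diameter, and is exposed as
configuration. Dyadic interfaces are packed with RyRs on a square 30 nm
lattice: the interface patch (jSR voxels adjacent to the cluster, or — for
dyadic clusters that do not touch the shell — the nearest jSR patch the
cluster is projected onto, taken within the cluster's own radius of the
nearest shell point) is flattened by principal components and tiled; a
lattice site is kept when an interface voxel lies within half a spacing
in-plane. The packed count can be capped at the calibration estimate.
jSR terminals grow from the packed positions by iterative city-block
(cross-element) dilation, 80 nm of padding, geodesically confined to the
jSR shell. Geometry exports are marching-cubes meshes (STL/OBJ via
trimesh), vertices in nm; optional Laplacian smoothing is accepted only if
it changes mesh volume by <2%.

## Spark analysis

Frame series (default 1.85 ms/frame) are segmented on the median-filtered
temporal mean with Otsu's threshold followed by one isodata refinement
(midpoint of the two class means). The refinement matters: with two
strongly separated intensity classes, the histogram-bin Otsu value can
land *inside* the background mode and leak background pixels into the
mask. F0 is the per-pixel temporal 10th percentile. ΔF/F0 is zeroed
outside the cell (tiny F0 would amplify noise unboundedly), and both the
detection region and the threshold statistics use the cell mask eroded by
two pixels, because the segmented boundary can overshoot the true edge by
a pixel.

Detection thresholds the temporal Sobel response at mean + 3.5 SD
(configurable k) over in-cell voxels and groups supra-threshold voxels
into 26-connected spatiotemporal components; components smaller than 4
pixels or 3 frames are discarded. Per spark: amplitude is the peak ΔF/F0
in the component; FWHM is 2√(2 ln 2)·σ from a 2D Gaussian fit to the peak
frame (out-of-cell pixels excluded from the fit); time-to-peak runs from
component onset to the trace peak; FDHM is the width at half maximum of a
fitted exponential-rise-to-peak / exponential-decay temporal profile
(measured on the fit, not the raw trace, for noise robustness); spark mass
is the ΔF/F0 integral over the component × pixel area × frame interval —
a definition this package fixes explicitly since "mass" is otherwise
ambiguous. Sparks within 1.5 µm of the sarcolemma (distance transform of
the cell mask at the centroid) are "surface".

## Synthetic data

Generators are pure functions of (parameters, seed) and return ground
truth for recovery tests.

- **Localization fields.** Cluster anchors on a jittered grid (600 nm
  pitch, ±100 nm jitter — guaranteeing the lateral isolation the
  calibration selection assumes); cluster sizes geometric with mean 10
  RyRs (small-cluster dominance, matching the observed surface mean of
  ~10 RyRs/cluster); RyRs on compact, axis-aligned 30 nm lattice patches.
  Surface layout places clusters on a sinusoidally undulating sheet
  (amplitude 150 nm, wavelength 2 µm); interior layout snaps clusters to
  z-line planes 1.8 µm apart (sarcomere spacing; a configuration default,
  not a measured value). Each RyR emits Poisson(3.31) blinks; blink
  positions add anisotropic Gaussian noise with per-event log-normal
  precisions (medians 32/64 nm lateral/axial, log-σ 0.3). Optional
  axially stacked pairs are planted at a 400 nm offset — at the stated
  axial blur, pairs closer than ~300 nm merge into one component and no
  selection rule could separate them, while 400 nm is within the z-range
  real surface undulation produces. Optional linear drift in nm/frame.
- **Tubule stacks.** Straight tubules on z-line planes with random axial
  branches, dilated to 250 nm, Gaussian-PSF blurred (150/300 nm), shot
  noise added, sampled at 100 × 100 × 200 nm confocal voxels.
- **Dyad scenes.** A tubule network plus clusters planted either in the
  cleft (dyadic) or ≥400 nm from every skeleton voxel (non-dyadic, safely
  beyond the 250 nm rule), default 15% non-dyadic.
- **Spark movies.** A rectangular cell (~0.16 µm pixels), baseline 100
  counts, Gaussian noise of 2% of baseline; sparks are separable 2D
  Gaussian (σ 0.85 µm, i.e. FWHM 2.0 µm) × exponential rise (τ 4 ms,
  rising 10 ms to peak) / exponential decay (τ 30 ms) transients with
  ΔF/F0 amplitude 0.8; the analytic FDHM of that transient is ≈28 ms.

What the synthetic benchmarks do **not** emulate: fluorophore
photophysics beyond a Poisson blink count (no duty-cycle correlations or
multiple appearances across frames), labelling stochasticity and epitope
accessibility, background fluorescence and detector artifacts, curved or
tilted cluster patches, tortuous tubules, spark wave interactions, and
motion. Passing recovery tests therefore demonstrates the correctness and
internal consistency of the measurement chain under its stated noise
model, not instrument-grade performance on real recordings.

## Problem sizes in the shipped tests

The test suite and acceptance script run at desk scale: calibration
recovery pools 17 fields of 30 clusters (510 clusters, ≈200–350 pairs
entering the fit), drift recovery uses ~8,000 events, spark recovery uses
54 planted sparks across nine movies, and dyad recovery uses 200 planted
clusters. These sizes keep each check well-resolved statistically while
completing in minutes on one CPU.

## Known limitations

- Grid counting cannot resolve sub-blur footprints; calibration excludes
  them, and per-cluster RyR estimates below ~10 RyRs inherit the blur bias
  of whatever footprint rule is used.
- The through-origin calibration slope carries a small (-few %) regression
  dilution from noisy grid counts; a measurement-error-aware estimator was
  deliberately not substituted because the through-origin OLS definition
  is part of the method being implemented.
- The dyadic classification measures distance to the skeleton, not the
  membrane; with non-default tubule diameters the two rules diverge.
- Alignment fits scale+translation only (no rotation), which assumes the
  two modalities share an optical axis, as they do on a single-microscope
  correlative acquisition.
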