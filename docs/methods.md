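# Methods

`spikect` measures grain morphometry from X-ray micro-computed
tomography (µCT) scans of cereal spikes. A scan is a stack of
reconstructed 16-bit grey-value slices with an isotropic voxel pitch
(µm/pixel); dried grain attenuates X-rays much more strongly than air,
holder plastic or chaff, which is what every stage below exploits.

## Segmentation

The pooled grey-value histogram of a spike scan is bimodal: a dominant
low-density mode (air and soft background) and a high-density mode
(grain). The grain threshold is placed adaptively, per scan:

1. per-slice histograms are pooled into one 65 536-bin histogram and
   smoothed with a moving average (`histogram_smooth_bins`, default
   257 bins);
2. candidate modes are smoothed-histogram peaks separated by at least
   the smoothing width with prominence ≥ 1% of the tallest peak — the
   prominence gate rejects sampling wiggles on the flank of the
   background mode;
3. the plant mode is the topmost significant peak, and the threshold is
   the deepest valley between it and its nearest significant neighbour
   (midpoint of the minimal plateau when the valley is flat). Searching
   directly below the plant mode, rather than between the two tallest
   peaks, keeps intermediate low-density material (rachis, chaff) below
   the threshold, which is where it belongs: the rachis is deliberately
   recovered later at a relaxed threshold.

A histogram with fewer than two significant modes raises a
no-bimodality error — it signals an unusable scan, not a recoverable
condition.

Binarization (grey ≥ threshold) is followed by morphological cleanup:
erosion with a disk structuring element applied slice-wise (`se_radius`,
default 5 px), a 3D cubic median filter (edge `2·median_radius+1`,
default 5; realized as a majority vote, exact for binary images with an
odd window), and dilation with the same disk. The disk is a 2D element
because the scan is a stack of reconstructed slices; applying it per
slice matches how stack data are conventionally cleaned. The holder
tube is then removed as the largest 26-connected component — guarded:
removal happens only when the largest component is at least 4× the
second largest, so cropped or tube-less scans are not mutilated.
Components smaller than `min_object_size` voxels (default 1000,
inclusive bound) are dropped, and the surviving mask is used to mask the
original volume, so grey values inside the segmentation are bit-identical
to the recorded data. 26-connectivity is used for all 3D labelling
throughout the package.

Defaults `se_radius=5` and `min_object_size=1000` are the routine
settings for wheat-sized grain at ~69 µm/pixel; smaller-seeded species
need a smaller minimum object size.

## Separation of fused grains

At routine resolution, neighbouring grains can fuse into one component
during segmentation. Each foreground voxel is assigned its chessboard
(Chebyshev, L∞) distance to the nearest background voxel — volume faces
count as background just beyond the boundary — and a watershed on the
negated distance map splits the component along its thin necks. The
chessboard metric is the package's fidelity choice; a Euclidean variant
is available behind the `distance_metric` switch for comparison.

Seeding and tie-breaking are where design was genuinely open:

- seeds are the regional maxima of the integer distance map; maxima
  plateaus closer than `min_seed_separation` (default 5 voxels, tied to
  the structuring-element radius) are merged into one seed, since the
  integer-valued map fragments the central ridge of a single convex
  body into several plateaus;
- ties on the integer relief are resolved by the watershed's
  deterministic flooding order from fixed seed labels, so results are
  reproducible;
- after flooding, regions smaller than 0.25× the median region size are
  absorbed into the adjacent region they share the most boundary with.
  Shallow maxima in the middle of a fusion bridge otherwise shed small
  spurious regions. A prominence-based (h-maxima) seed filter was
  rejected: with thick bridges, the smaller grain core's prominence
  above the bridge saddle can be as small as the digitization noise it
  is meant to remove, so any usable h under-splits. Fragments with no
  neighbouring region are left untouched — isolated small objects are
  real, and discarding too-small material is the segmentation size
  filter's job.

The labels partition the foreground exactly; a single digitized
ellipsoid of aspect ratio ≤ 4 yields one label, and bridged pairs whose
bridge radius is at most half the smaller grain's minor semi-axis are
split with one planted center per label (verified over seeds in the
test suite). Splitting of more than ~3 mutually fused grains is
best-effort.

## Morphometry

Each labelled grain is measured on a local crop (which also makes
portion-wise and whole-spike measurements bit-comparable):

- **Orientation** — principal axes of the voxel-coordinate covariance,
  eigenvalue-ordered, signs fixed deterministically. Degenerate voxel
  sets (< 4 voxels, coplanar) are rejected.
- **Length** — extent of voxel-center projections on the major axis,
  plus one voxel to compensate for measuring between voxel centers
  (unbiased recovery of planted diameters).
- **Width / depth** — major and minor 2D extents of the
  one-voxel-thick cross-section through the intensity-weighted centroid
  perpendicular to the major axis. The triple is sorted so that
  length ≥ width ≥ depth; a pre-sort violation (possible when the two
  minor semi-axes are nearly equal) is logged.
- **Volume** — the exact voxel count.
- **Surface area** — summed triangle area of the 0.5-level marching
  cubes isosurface, extracted after Gaussian anti-aliasing with
  σ = 0.6 voxels. The raw binary isosurface overestimates a digitized
  sphere's area by ~9% (staircase effect); σ = 0.6 was chosen from an
  accuracy sweep on analytic shapes (sphere r=15: +1.9%, sphere r=8:
  −0.3%, 20×20×5 cuboid: −7.5%) as the best compromise between
  staircase removal and corner rounding. Objects too small to survive
  smoothing fall back to the raw isosurface.
- **Sphericity** — ψ = π^⅓·(6V)^⅔ / A, the area of the
  volume-equivalent sphere over the measured area, clipped to ≤ 1; the
  fitted axis ratios (b/a, c/a) are exported as auxiliary columns.
- **Units** — mm = pixel · pitch / 1000, with the square and cube of
  the per-edge factor for areas and volumes.

Records are ordered by ascending centroid z, then label; failing grains
are logged and skipped with a reported count.

## Spike-level processing

The rachis (the spike's axis) is less dense than grain and invisible at
the grain threshold; relaxing the threshold by 20%
(`rachis_relax_fraction`) makes it appear. The lowest and highest
z-slices containing relaxed-threshold material define the spike extent,
and spike height is `(z_high − z_low + 1) · pitch / 1000`. The holder
tube is identified at the *full* grain threshold — where the rachis is
invisible and the 4× dominance guard is meaningful — and its voxels are
subtracted from the relaxed-threshold mask; identifying it at the
relaxed threshold would risk confusing tube and rachis on tube-less or
tightly cropped scans.

Spikes too tall for the scanner holder are scanned as bottom and top
portions and rejoined in software: a portion acquired tip-down is first
re-oriented by `Z = (n_slices − 1) − Zi` (0-based slices; whether to
invert is per-portion acquisition metadata the image cannot supply, so
it is a config flag, defaulting to inverting the top portion), then
every top-portion z is incremented by the bottom portion's slice count.
More than two portions are handled by sequential offsetting. Rejoining
changes only z; every other trait is preserved bit-exactly.

Grains are binned into bottom / middle / top: with
p = (z − z_low)/(z_high − z_low) the normalized centroid position along
the spike, the middle band is p ∈ [0.5 − h, 0.5 + h] with inclusive
bounds and h = `region_half_width` = 0.16 by default (band widths
0.34 / 0.32 / 0.34). The band is centered on the midpoint of each
spike's own extent — the only definition computable per spike without
reference to other spikes. Positions outside the extent are clamped
with a warning. Per-spike summaries report grain count, total grain
volume (the proxy that tracks manual spike weight), height and
per-region counts and mean volumes.

## The phantom generator

`spikect.phantom` generates synthetic scans with analytic ground truth
so that every stage is testable without scanner data. A phantom is a
Gaussian-noise volume (background mode 5000 ± 800, plant mode
20000 ± 1500, clipped to [0, 65535]) containing:

- ellipsoidal grains (default semi-axes 3.2 × 1.6 × 1.4 mm with 10%
  per-axis variation, tilted up to 30° from the spike axis) in two
  opposed ranks along a central rachis cylinder, consecutive spikelet
  pairs alternating in y; grain sizes are fixed *before* placement
  retries so that crowding cannot bias accepted grains small;
- a rachis cylinder (radius 1.1 mm) whose grey level sits between the
  modes: its mean is 0.85× the histogram valley, found by fixed-point
  iteration on the realized histogram because the rachis mode itself
  shifts where the valley lands;
- optionally an enclosing holder-tube shell (the largest bright
  structure), bright specks emulating mounting-material fragments
  (removed by cleanup), cylindrical fusion bridges between the two
  grains of selected spikelet pairs, and a split into bottom/top
  portion volumes at a grain-free slice (with optional tip-down
  flipping of the top portion).

Ground truth records every grain's center, semi-axes, orientation,
analytic volume (4/3·π·abc) and Thomsen-approximate surface area, the
digitized voxel count, the rachis extent, fusion links and the split
point. `generate_cohort` plants group effects (count and volume
multipliers) across spikes for treatment-contrast studies.

What the phantom does *not* emulate: beam hardening, ring artefacts,
partial-volume blur at material boundaries, awns/glumes, and the
within-spikelet grain-size gradients of real spikes. Passing phantom
tests therefore demonstrates the correctness of the algorithms under
the stated noise model, not performance on any particular scanner's
artefacts.

## Problem sizes in the test and acceptance studies

Tests and the acceptance study run at reduced sampling chosen so grains
remain tens of voxels across: 137.6 µm pitch on (448, 96, 96) grids for
the single-spike studies (grain semi-axes ≈ 23 × 12 × 10 voxels), and
103.2 µm on (576, 128, 128) for the two-group cohort, where the
slice-wise opening's volume loss is small enough that planted
count/volume ratios are recovered cleanly. `PhantomSpec` defaults stay
at the routine-scan scale (68.8 µm, 512 slices).

## Numerical choices and degenerate inputs

- Threshold ties on a flat valley → midpoint of the minimal plateau.
- `remove_largest_component` ties → lowest minimum z, then label order.
- Single-component masks: `remove_largest_component` returns empty (the
  caller must guard); the pipeline's guard skips tube removal below 4×
  dominance.
- ISQ samples are signed 16-bit; negative values are clamped to 0 on
  load. Header extents are integer µm, so recovered pitch is exact only
  when extent × pitch is integral.
- The CSV schema (column names and order) is byte-stable; floats are
  written with 6 decimals.
- All randomness in the generator flows from one `numpy` Generator
  seeded from `PhantomSpec.seed`; pipelines themselves are fully
  deterministic, and identical inputs produce identical output bytes.

## Known limitations

- The slice-wise opening erodes grain end-caps, biasing pipeline-route
  volumes low — by roughly 5–20% on phantom grains depending on grain
  size relative to the structuring element (≈7% for the default
  20-grain study at 137.6 µm, ≈5% at 103.2 µm, worse for smaller
  grains); ratio comparisons between groups are much less affected.
  Clean-mask measurements (no morphology) agree with analytic volumes
  to < 1%.
- Chessboard distance is anisotropic; deeply interdigitated grains can
  be split off-center. The `euclidean` metric switch trades fidelity to
  the original method for isotropy.
- Crease volume, bran-layer thickness and embryo size are out of scope;
  they require higher-resolution scans than the routine setting.
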