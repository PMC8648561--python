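# Methods

This note documents the models, conventions and numerical choices behind
`hiptomo`, and what the synthetic-data validation does and does not
establish about real scans.

## Scope and overall model

The package emulates hierarchical phase-contrast tomography at desk
scale: an effective-monochromatic, parallel-beam scan of an organ
mounted in a cylindrical jar of agar–ethanol gel, followed by the
reconstruction chain used for such data (reference flat-fielding,
single-distance phase retrieval, extended-FOV stitching, filtered
back-projection, artefact corrections) and by quantitative analysis
(FSC resolution, SNR/SSIM/histogram quality metrics, 3D morphometry and
virtual-biopsy stereology).

Deliberate simplifications: the polychromatic bending-magnet spectrum is
replaced by a single effective energy (no beam hardening), the beam is
perfectly parallel and fully coherent (no source-size blur or detector
PSF beyond optional Gaussian terms), and detector electronics are
reduced to Poisson counting plus additive Gaussian read noise.

## Coordinates and containers

Volumes are `(z, y, x)` with `z` the rotation axis; voxel `(i, j, k)`
has physical centre `origin + voxel_size·(i, j, k)` (µm, isotropic).
Cylinder membership is evaluated at voxel centres, boundary-inclusive.
16-bit volumes carry an affine `(offset, slope)` grey scale, stored in a
JSON sidecar for TIFF stacks (TIFF tags are dialect-prone) and in
attributes for HDF5.

## Phantoms

**Jar.** Concentric air / PET wall / agar–ethanol regions, optional
coaxial tissue cylinder. Default wall thickness 2 mm (a realistic PET
mounting jar). The jar can be mounted eccentrically
(`centre_offset`), emulating zoom scans where the sample is translated
so an interior VOI sits on the rotation axis; it may then extend beyond
the sampled grid (the clipping is shared by the sample and its
reference twin and cancels in the flat-field ratio). Small dense
"feature spheres" can be embedded as SNR targets.

*Partial-volume maps.* The jar generator attaches antialiased µ and δ
volumes in which each analytic interface receives a one-voxel linear
coverage transition; these are the forward-model inputs, while the label
volume stays discrete. This is the physically faithful voxelization —
materials fill boundary voxels fractionally — and it is what makes
sub-2% round-trip RMSE a meaningful statement about the reconstruction
rather than about staircase edges.

**Kidney-like.** A cylindrical parenchyma shell studded with
non-overlapping spheres ("glomeruli") packed by rejection sampling,
radius-uniform in the interval given, centres area-uniform over the
shell (radial pdf ∝ r) so the number density is uniform in volume —
a requirement for the stereological estimator to be unbiased. Spheres
are kept inside the grid axially. Ground truth records every centre and
radius.

**Alveolar foam.** Poisson-disk seed points (minimum spacing 0.7× the
mean cell diameter) define Voronoi cells; voxels where the difference of
the two nearest-seed distances is below the wall thickness become
tissue (the difference grows by 2 per unit distance from the bisector,
so the carved wall has the nominal thickness). A seeded random fraction
of cells is consolidated. By default consolidation fills the whole cell;
with `consolidation_film_um > 0` a thin residual air film is kept along
the septa of consolidated cells — the small ventilated pockets seen in
consolidated parenchyma, which produce the characteristic bimodal
airspace-diameter distribution. Defaults used in the validation foams:
2.5 µm voxels, 50 µm cells, 5–10 µm walls — a scaled-down but
proportionate alveolar geometry.

**Materials.** At the default effective energy of 85 keV:
agar–ethanol µ = 0.018/mm, soft tissue 0.022/mm, PET 0.030/mm, dense
features 0.026/mm, with δ/β ≈ 10³ (phase contrast far more sensitive
than absorption). These are scenario placeholders with the right orders
of magnitude, not measured coefficients; β is always derived from µ via
µ = 4πβ/λ.

## Forward simulation

Line integrals are computed by rotating the µ/δ grids about the z axis
(first-order interpolation) and summing along rows; this was validated
against an independent Radon implementation (max deviation <1% of the
peak projection value at 45°). Detector column `c` samples lateral
position `(c − cor_col)·pixel` with `cor_col = (W−1)/2 + offset`. Rays
leaving the sampled grid inside the jar set a truncation flag (expected
in local tomography), not an error.

Fresnel propagation uses the FFT transfer function
`exp(−iπλD(u²+v²))` on the exit wave `exp(−A/2 + iΦ)` with symmetric
edge padding of a quarter of each dimension per side; `D = 0` returns
`exp(−A)` exactly. The hutch limit caps D at 3.5 m.

Counts are `Poisson(flux · I · h(x) · v(y) · gain)` plus Gaussian read
noise (default σ = 1 count); `gain` is an optional fixed per-column
error field used to drive ring artefacts. Sub-frame accumulation is an
arithmetic mean, keeping the grey scale independent of the sub-frame
count. Default flux is 4×10⁴ counts/pixel/sub-frame — a realistic
value for an accumulation-protocol scan, at which the full chain with
10 sub-frames resolves the 0.004/mm tissue–agar contrast at CNR ≈ 6.

The reference jar is simulated on the same angular grid, lateral offset
and noise model as the sample (independent noise streams). When it is
mounted on the rotation axis it is axisymmetric and a single clean
projection serves all angles; an eccentric reference is projected per
angle.

All random streams derive from `(seed, purpose-string)` via CRC32-keyed
`SeedSequence`s, so any artifact is bit-reproducible from its seed on a
given platform.

## Reconstruction chain

*Reference flat-fielding.* Each projection is divided by the mean of
the reference-jar frames in a centred window (default 100 projections).
The window is clamped at the scan ends by default; wrap-around is
selectable but mixes the beam state at the start and end of the scan
and defeats drift tracking there. Because the reference matches the
jar, the quotient's log equals the line integrals of `µ − µ_reference`,
which are compactly supported near the VOI — this is what removes the
low-frequency cupping of truncated scans. The reconstruction is then a
difference map relative to the mounting medium.

*Vertical-profile subtraction.* The per-detector-row median over all
angles and columns (log domain — chosen because the residual is
multiplicative in intensity) is subtracted, preserving the global mean.
No smoothing is applied to the row-median estimate by default: the
artefact being removed is itself high-frequency across rows.

*Phase retrieval.* The homogeneous-object single-distance filter
`1/(1 + πλD(δ/β)(u²+v²))` is applied under symmetric edge padding
before the logarithm; non-positive filter outputs are clipped at 1e-12.
Default δ/β = 1000, matching the phase-over-absorption sensitivity
ratio of soft tissue; exposed in configuration. The unsharp mask
(default σ = 2 px, amount 0 unless requested) operates on the retrieved
maps.

*Extended FOV.* For half acquisition, the θ row occupies stitched
columns [0, W) and the mirrored θ+180° row occupies [2o, 2o+W) — an
exact integer mapping for any detector parity — with linear ramp
weights over the doubly covered band (plain mean when o = 0). Annular
scans (o ≥ W/2) use the same machinery with the unmeasured central disc
left empty; quarter concatenation scales the annular data by the ratio
of means in the common area (recorded in provenance) and blends with a
linear transition.

*FBP.* The ramp filter is built from the band-limited spatial-domain
kernel (value 1/4 at lag 0, −1/(πk)² at odd lags); sampling |f|
directly zeroes the DC term and was measured to bias a 256² disc
reconstruction by ~6% — the kernel construction removes the bias to
<0.1%. A Hann apodization is the default window; pure ramp is
selectable (and used where the sharpest point response matters more
than noise). Backprojection uses bilinear interpolation at
`t = x·cosθ + y·sinθ + cor_col` and scales by the angular step. Pixels
outside the measured field-of-view disc, which no ray constrains, are
zeroed. Local reconstruction pads truncated sinogram edges with a
cosine decay over W/4 columns before filtering and masks to the VOI
disc.

*Vertical concatenation.* Integer per-junction z-shifts are found by
maximising the normalised cross-correlation of the overlapping slabs
within a search window (falling back to the nominal overlap below a
correlation threshold of 0.3), then blended with linear ("ponderate")
weights summing to one.

*16-bit conversion.* Percentiles (default 0.1–99.9) map linearly to
[0, 65535]; a constant volume maps to the midpoint 32768; the affine
scale is recorded. The windowing convention is this package's own.

*Ring correction.* The slice is binned by integer radius about the
rotation centre; the artefact profile is the per-radius angular median
minus a baseline obtained by median-filtering the *detrended* profile
(a wide Gaussian removes the radial slope first — a plain median
baseline is rank-biased on slopes and was measured to leave 2–3× larger
residuals). The profile is subtracted at each pixel's exact radius
(avoiding flank quantisation), preserving the slice mean. A radially
symmetric true background is fundamentally confounded with rings; the
median/detrend split resolves this for backgrounds smooth on the
baseline-window scale (default 41 radius bins).

*Stripe correction.* Constant-z plane offsets are the high-frequency
part of the per-slice median along z (Gaussian baseline, σ = 8 slices)
and are subtracted slice-wise; the operation is idempotent to ~1%.

## Quality metrics

FSC uses shells one frequency-voxel wide; the ½-bit threshold
`T(n) = (0.2071 + 1.9102/√n)/(1.2071 + 0.9102/√n)` is evaluated with
`n_eff` = (voxels in shell)/2 (Hermitian redundancy), scaled by the
effective-sample fraction of the window when a 3D Hann taper is applied
(the default for real, non-periodic volumes; `window="none"` is
appropriate for synthetic periodic fields and is what the band-limit
oracle uses, since the taper smears a hard spectral edge by several
percent). **Resolution convention:** the reported resolution is
`voxel_size / f_cross` — the full period of the crossing frequency —
under which a pair crossing at 0.25 cycles/voxel at 2.5 µm/voxel reads
10 µm. The subvolume protocol draws seeded positions (identical in both
volumes), excludes subvolumes without a crossing, and reports
mean ± sd.

SNR is `(µ_ft − µ_bg)/σ_bg` over disjoint ROIs and is invariant under
affine intensity maps. SSIM comparisons draw seeded slice pairs within
and across two volumes (four groups) and report a one-way ANOVA;
constants K1 = 0.01, K2 = 0.03, Gaussian window σ = 1.5, data range
from the pooled extrema. Histogram statistics use a fixed bin width;
the intersection is `100·Σ min(p_A, p_B)` on an aligned bin grid.

## Morphometry

Thresholding (triangle/Yen/Otsu) uses 256-bin histograms via
scikit-image; both triangle and Yen were cross-checked against
brute-force searches over all bins.

The ⟨3,4,5,7⟩ chamfer distance is a two-pass raster sweep over the
5×5×5 neighbourhood (face 3, edge 4, vertex 5, knight-type (1,1,2)
moves 7), normalised by the face weight; against the exact Euclidean
transform its relative deviation is bounded by ~±6–8% (measured 5.7%
max on random masks; exact on axis-aligned distances).

Local thickness follows the largest-inscribed-sphere definition:
Euclidean distance map, pruning of redundant sphere centres (a centre
is redundant when a neighbour's inscribed ball contains its own), and
sphere painting of the diameter `2·EDT − 1` voxels — the −1 accounts
for the EDT reaching the background voxel *centre*, half a voxel beyond
the phase surface. Slabs and voxel-centred digitized balls are
recovered within one voxel; off-lattice sphere centres can lose about
one further voxel to digitization.

Surface areas come from marching cubes on a lightly smoothed field
(σ = 0.6 voxels): raw binary meshing inflates a radius-20 ball's area
by ~9% (staircase facets) while smoothing rounds polyhedral edges; the
chosen σ keeps both the sphere (3/r) and cube (6/s) oracles within 5%.
Objects thinner than ~5 voxels are meshed unsmoothed. Two
surface-to-volume conventions are provided: per phase volume (the
convention with the 3/r sphere value) and per total VOI volume (surface
density, the lung-morphometry convention used in group comparisons,
under which septal thickening and consolidation reduce the ratio).

Connectivity is `1 − χ` with χ from 26-connected foreground (ball 0,
torus 1, two disjoint balls −1); its density divides by the VOI's
physical volume. Sphericity is `π^{1/3}(6V)^{2/3}/A` with voxel-counted
V and mesh A; border-touching objects are flagged.

Virtual biopsies count objects whose centroid lies inside the cylinder
(boundary-inclusive); the centroid rule avoids double counting at the
cylinder wall. Whole-organ totals scale the count by the
parenchyma-volume ratio, with a Poisson standard error scaled the same
way. Grouped VOI comparisons use one-way ANOVA with Tukey HSD adjusted
pairwise p-values and pooled airspace-diameter histograms (1-voxel
bins, modal value as bin centre).

## Validation scenarios and problem sizes

The validation suite runs at deliberately modest sizes chosen so the
whole suite completes in minutes on one CPU while each effect remains
well resolved: 256² slices / 720 projections for round trips, 384-px
grids for extended-FOV comparisons, 128-px detectors for
local-tomography studies, 48³–64³ masks for morphometry, and a
128×128×64 kidney with 2000 units for stereology. The lateral SNR
transect uses 10 offsets × 2 independent noise realisations: the
per-offset SNR shows no systematic trend, so the sample Pearson
correlation is null-distributed, and 20 points are needed for its
magnitude to concentrate below 0.5.

What passing these tests shows: the operators implement their
definitions correctly (oracle agreement), the chain is self-consistent
(round trips, stitching equivalence), and the statistical estimators
are unbiased on phantoms satisfying their assumptions. What it does not
show: performance on real organ data — real tissue contrast, beam
polychromaticity, detector non-idealities, sample drift and dose
effects are outside the simulation, and the published organ-scale
metric values (e.g. FSC resolutions of specific scans) depend on those
data and are not reproduced here.

## Known limitations

* The forward projector's rotation interpolation limits projection
  accuracy to ~0.1% of the peak value; self-reference flat-field ratios
  are flat to ~1e-3, not machine precision.
* Quarter-acquisition stitching assumes the half and annular scans
  share the angular grid.
* The ring corrector cannot distinguish genuinely axisymmetric image
  structure from artefact at scales below its baseline window.
* Packing-based generators (kidney spheres, foam seeds) are rejection
  samplers: infeasible densities raise errors rather than degrading
  silently.
* `simulate_scan` simulates one vertical station; vertical series are
  planned by `plan_vertical_series` and assembled by `concat_vertical`
  from per-station reconstructions.
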