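# Methods

This note documents the models, conventions and numerical choices
behind `habseg`, and what the synthetic phantoms do and do not
establish about real data.

## Coordinate conventions

All geometry is computed in world millimetres under RAS+ (+x right,
+y anterior, +z superior). Voxel indices are 0-based and the 4×4
affine maps voxel *centres* to world coordinates — the dominant NIfTI
convention. Files are canonicalized to RAS+ axis order on load; this
permutes/flips the data array and compensates in the affine, so the
world coordinate of every voxel centre is preserved (verified to
1e-5 mm in the tests). Masks are written as uint8 NIfTI with the
source image's affine verbatim and are never resampled on write.

## AC–PC reorientation

Given the AC midpoint, PC midpoint and one midsagittal point, the
frame is constructed directly: ŷ = (AC−PC)/|AC−PC|; ẑ is the
component of (midsagittal − AC) orthogonal to ŷ, normalized; and
x̂ = ŷ × ẑ. The rotation has these axes as rows, and the translation
brings the AC to the origin. By construction the transform is a proper
rigid motion (det = +1 to 1e-9), sends the PC to (0, −|AC−PC|, 0), and
zeroes the midsagittal x exactly — recovery of arbitrary rigid motions
is exact to ~1e-14 mm in practice, against a 1e-6 mm contract. The
convention that the midsagittal point lies superior to the AC–PC line
fixes the roll sign; no symmetry optimisation is attempted, keeping the
operation deterministic and landmark-driven.

The default workflow composes this transform into the header only, so
the acquired grid is untouched. Resampling (trilinear for intensities,
nearest-neighbour for masks so they stay binary) happens exactly once,
and only when an axis-aligned AC–PC grid is explicitly requested for
slice-wise tracing. The output grid covers the transformed input field
of view, anchored at its minimum corner (no snapping to voxel-size
multiples; snapping was found to introduce a systematic half-voxel
offset in nearest-neighbour paths). No symmetry tolerance is imposed
on the midsagittal residual |x|; it is exposed as a QC number.

## Geometric delineation

Posterior-slice construction, per hemisphere, in the (x, z) plane of a
coronal slice: the lateral edge is the infinite line through landmarks
B and C, the ventral edge the horizontal line through A, the apex
their intersection, and the ROI the triangle [A, B, apex]. Note on
edge naming: the lateral edge through B–C is referred to as line *x*,
the medial A–B segment as line *y*, and the ventral horizontal as
line *z*; this is the only labelling consistent with defining the apex
as the intersection of the lateral and ventral lines. Degenerate
configurations are rejected: B–C horizontal (|ΔZ| ≤ 1e-6 mm, no
intersection), apex medial to or coincident with A, landmark
separations ≤ 0.1 mm, or ordering violations (B must be dorsal to A, C
ventral to B).

Rasterization marks a voxel when its in-plane centre lies inside *or
on the boundary of* the triangle (a vectorised half-plane sign test
with inclusive comparisons). Inclusive boundaries implement the
protocol rule that ambiguous dark-grey voxels at the medial boundary
belong to the ROI; an optional one-voxel medial dilation restricted to
intensities between the CSF reference and the current ROI mean is also
provided (`dilate_medial_ambiguous`) and logged separately. The y →
slice mapping takes the nearest coronal slice, with exact midpoints
rounding toward posterior (deterministic, and biased toward the
PC-containing slices where the geometric rule is defined).

Anterior slices grow a 4-connected 2D region from a seed voxel over
intensities ≥ τ = (MD mean + seed-region mean)/2, where the
seed-region mean is taken over the 3×3 neighbourhood. Growth is
clipped to a box of half-width 4 mm (default) around the seed — about
twice the habenula's in-plane radius. If the grown region touches the
clip box on two or more sides the local contrast is deemed
insufficient and a leakage error is raised rather than returning a
silently wrong mask; a seed whose neighbourhood is darker than the MD
reference (i.e. placed in CSF) yields a warning and a seed-only mask.
The medial and lateral habenular nuclei are never distinguished; the
ROI is a single combined habenula region.

Assembly unions the slice masks, requires the occupied coronal slices
to be contiguous, and warns when the span leaves the protocol envelope
of 3–5 slices at 0.77 mm (rescaled proportionally for other slice
spacings). Anterior/posterior slice bounds are the user's anatomical
call on real data; the tool validates rather than infers them. On
phantoms, ground truth supplies them.

## Volumetry

Volume is foreground count × |det| of the affine's 3×3 block; the
centre of mass is the unweighted mean of foreground voxel-centre world
coordinates (ROIs are binary; intensity weighting is out of scope).
Both are exact and deterministic; volume is invariant under
header-only rigid motion and the centroid transforms exactly with it.

## ICC(2,1)

Reliability uses the two-way random-effects, absolute-agreement,
single-measures intraclass correlation. From the ANOVA mean squares of
an n-subjects × k-raters table (rows MSR, columns MSC, residual MSE):

    ICC(2,1) = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE))

Absolute agreement means a systematic offset between raters counts
against reliability (a large constant offset drives the estimate to 0
from above). The 95% interval is the standard F-based interval for
this model with a Satterthwaite approximation for the denominator
degrees of freedom; the implementation is cross-checked in the tests
against an independent variance-components oracle (1e-10) and against
`pingouin`'s ICC(A,1). Perfect agreement (MSE = MSC = 0) collapses the
interval to [1, 1]; an all-constant table is an error (undefined ICC).
Estimates are banded qualitatively with cut-points at 0.20 / 0.40 /
0.60 / 0.80, boundaries belonging to the upper band; negative
estimates are reported as computed and banded "slight".

## Smoothing contamination

For a label map, unit signal is placed on every labelled voxel and
smoothed with an isotropic Gaussian specified by FWHM in mm
(σ = FWHM/√(8 ln 2), applied separably with per-axis voxel sigmas, so
anisotropic grids smooth isotropically in mm). The contamination
fraction of a target ROI is the ROI-mean smoothed signal of non-target
origin divided by the ROI-mean smoothed signal of all-tissue origin:
the share of what is measured over the ROI that originated outside it.
Defining the quantity as this ratio (rather than the unnormalized
numerator alone) makes it independent of how much unlabelled
background surrounds the head and gives it the correct limits — 0 at
FWHM 0, and the complement's local volume share (→ 1 for a small ROI)
for kernels much larger than the ROI. Boundary handling is
constant-zero padding; because both numerator and denominator see the
same padding, edge effects largely cancel. The fraction is
signal-agnostic: it upper-bounds mixing without assuming any task
response, and no claim is made about the jointly optimal kernel given
inter-subject localisation spread — the contamination curve and that
spread are separate quantities.

## Synthetic phantoms

The generator builds an analytic model of the epithalamic
neighbourhood on an AC–PC-aligned grid (default 64×80×64 voxels at
0.77 mm, matching the protocol resolution): third-ventricle CSF slab
(|x| ≤ 0.7 mm), MD thalamus blocks laterally, PC/HC band ventrally
(crossing the midline, as commissures do), pineal posteriorly, stria
medullaris antero-dorsally, and a habenula pair whose coronal
cross-section transitions from a triangle (posterior, "pyramidal") to
a rectangle (anterior, "oblong"), rising slightly dorsally along the
way. Posterior cross-sections are generated from the same A/B/C
landmark construction the delineation protocol uses, so ground-truth
per-slice landmarks come for free. Default intensities are CSF 0.3,
MD grey 1.0, habenula 1.3, white matter 1.6, pineal 1.1 (arbitrary
units, preserving the T1 ordering CSF < grey < habenula < white);
default additive Gaussian noise is σ = 0.03, a high-SNR structural
level giving a habenula–MD contrast-to-noise of 10. The AC–PC distance
defaults to 25 mm.

The lateral width of the cross-sections is calibrated by bisection so
the voxelized per-side volume matches the target (default 30 mm³, the
human scale; plausible per-side range ~21–37 mm³), then nudged 1 µm off
the bisection point so no shape edge sits exactly on a voxel-centre
coordinate (floating-point robustness). The x/z lattices are exactly
antisymmetric about the midline and the left habenula is the index
flip of the right, so the hemispheres are bit-exact mirrors.

Simulated raters perturb a truth mask by a smooth random boundary
displacement field (Gaussian-filtered white noise, 1.5 mm correlation
length, scaled to the requested SD in mm) plus a systematic
dilation/erosion bias, thresholded against the signed distance to the
mask boundary surface (half-voxel offset from the voxel-centre
distance transform). Each coronal slice is reduced to its largest
4-connected component, as a human tracing would be. Because voxels
flip only where the field exceeds the local distance to the boundary,
rater noise acts in chunky patches — much like real tracing
disagreements. A boundary SD of 0.15 mm yields per-rating volume
errors of ~1–2 mm³, the precision scale reported for trained human
raters; this is the value used in the examples and the acceptance
script.

The slice-span simulation draws A–P extents uniformly from a range,
places them at uniform random offsets against a contiguous slab grid,
and counts intersected slabs; extents of 2–3 mm at 0.77 mm slabs give
a span of 3–5 slices.

### What phantom results do and do not show

Phantoms have piecewise-constant intensities, sharp analytic
boundaries, additive Gaussian (optionally no) noise, and no partial
volume effects, B1 inhomogeneity, motion or anatomy variation beyond
the parametrised shape. Exact pipeline recovery on a noise-free
phantom therefore demonstrates the *geometric and numerical*
correctness of the implementation — landmark construction,
rasterization, region growing, assembly, volumetry — not that the
protocol's anatomical judgements (landmark placement, slice bounds)
are easy on real scans. Conversely, the contamination analysis depends
only on the label geometry, which the phantom reproduces at the
correct physical scale, so its conclusions transfer directly.

## Problem sizes

Default test and acceptance runs use the 64×80×64 phantom (48×80×48
for rater simulations), 100-replicate oracle suites for rasterization
and transform recovery, n = 500 tables for the ICC Monte Carlo and 200
phantom subjects for the rater-simulation ICC check; these sizes make
the statistical checks stable at the stated tolerances while keeping a
full run to well under a minute for the acceptance script.
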