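# Methods

This note documents the models, numerical choices and validation logic of
`airwayrec`, in the order the pipeline runs.

## Coordinate conventions

World coordinates are DICOM LPS (x left, y posterior, z superior), in
millimetres.  Each stack carries a `PlaneFrame`: in-plane unit axes
`axis_u`, `axis_v`, a right-handed normal `axis_u x axis_v`, pixel spacing,
slice thickness and inter-slice gap.  Pixel (0, 0)'s *centre* sits at the
frame origin (half-voxel convention, matching `ImagePositionPatient`).
Slice centres are spaced `thickness + gap` apart, so the acquisition
protocol (2.5 mm thickness; 0.5 mm gap axial/sagittal, 1.5 mm coronal)
yields 3 mm and 4 mm section-curve spacing respectively.  Coronal slice
indices increase anterior → posterior.

Contours are stored as ordered 2-D in-plane point loops plus a frame
reference, normalised to counter-clockwise orientation; registration
corrections therefore stay strictly planar.  Discrete curvature is the
signed Menger curvature of triples spaced 2 samples apart (a 5-sample
window), which is exact on circles and robust to pixel-level jaggedness;
the window is configurable.

## Segmentation

The boundary model is a two-phase piecewise-constant region energy (inside
mean c1, outside mean c2) with a curve-length penalty, evolved on a signed
distance function phi (negative inside):

* the **region force** `-(I-c1)^2 + (I-c2)^2` acts on the *whole* grid, so
  the zero level can carve interior structures — e.g. the septum between
  the two nasal channels when one seed covers both — rather than waiting
  for the interface to arrive;
* the **length penalty** `mu * div(grad psi/|grad psi|)` acts through a
  smoothed delta (epsilon = 1.5 px) near the interface only.

Intensities are normalised to [0, 1] by the ROI's 1st-99th percentiles;
lengths are in grid pixels, so `lambda_region = 1`, `mu_length = 0.06` are
dimensionless defaults.  The time step adapts so the largest update is
0.45 px per iteration; phi is re-initialised to a signed distance (two
Euclidean distance transforms) every 25 iterations; convergence requires
the mean |delta phi| over a 4-px band to stay below 1e-3 for 5 consecutive
iterations (cap 300).  Under partial-volume mixing the converged zero level
sits at the half-intensity crossing — which *is* the true boundary — so
sub-pixel marching-squares extraction recovers areas to a fraction of a
percent at 512x512.  phi is padded with a positive ring before extraction
so lumina clipped by the ROI still close; components below 1 mm^2 (below
in-plane MRI resolution) are dropped.

For the narrow meatus the ROI around the seed polygon is cropped and
upsampled (default 3x, bilinear); on a ~2-px-wide channel this strictly
reduces boundary RMS error versus no upsampling (tested).

## Registration

All correction happens on contour coordinates.  *Crossing points* of a
contour polyline with another stack's slice plane are found by linear
interpolation along edges; a vertex exactly on the plane belongs to its
succeeding edge, so it is counted once (transversal or tangential).
Target/matched crossing sets are paired one-to-one by Hungarian assignment
gated at `max_dist` (default 4 mm, one coronal slice spacing — larger
mismatches indicate segmentation failure, not motion); the pairing is
verified against brute-force enumeration on small sets.

Each boundary piece between adjacent matched points (ordered by arc
length; the wrap-around arc of a closed contour is one segment) is mapped
by the unique orientation-preserving in-plane similarity taking its
endpoints onto the two target points; adjacent arcs share endpoint images,
so the corrected contour is continuous, stays planar, contains every
target exactly, and remains simple on all test phantoms.  Correspondence
sets that would invert the traversal order (opposite winding of targets vs
matched points) are rejected.

Pipeline order: (1) per-axial-slice in-plane displacement from the
axial-sagittal crossing gap (least-squares translation; slices without
crossings interpolate linearly from neighbours); (2) axial → coronal
piecewise correction; (3) sagittal → coronal.  The coronal set is the
fixed reference and is returned untouched.  After step (2) the axial set
agrees with coronal at all shared crossings, so coronal targets suffice
for step (3).  The piecewise stage is exactly idempotent; the displacement
pre-correction re-estimates a ~0.01-0.05 mm offset on a second run
(both moving sets having been warped toward coronal independently), so
re-running the full chain moves points by at most that residual — the
fixed-point property is tested with the displacement stage off and bounded
at 0.05 mm with it on.  Residual RMS at tangential crossings (extreme
sagittal slices grazing the lumen) is a measurement artifact, not a
registration error; recovery experiments use transversal crossings.

**Septum localisation.**  The posterior border of the nasal septum lies
between the first adjacent coronal slice pair whose airway count drops
from two to one *and stays one* (the persistence rule guards against
segmentation dropouts).  The anterior nasopharynx wall is then traced from
axial/sagittal boundary vertices inside that interval whose outward normal
faces anterior (component along -normal above 0.7); the trace is ordered
inferior → superior and its mean position estimates the merge plane to
within the axial in-plane resolution.  If no points fall in the interval
the interval midpoint is used, with a logged warning.

## NURBS reconstruction

Section polygons are resampled to a common sample count.  On smooth
stacks without landmarks, each slice's start sample is rotated to minimise
summed distance to the previous slice (prevents twist).  On anatomies with
curvature landmarks, contours are partitioned into labelled arcs (default
three, mirroring the inferior/middle/superior turbinate grouping) at the
landmarks nearest the previous slice's cuts, and samples are allocated to
arcs proportionally to mean arc length — sample j on slice i then
corresponds anatomically to sample j on slice i+1.  Landmarks are local
extrema of signed curvature with prominence >= 0.05 mm^-1, |kappa| >=
0.05 mm^-1 (suppressing flat-edge "minima"), non-maximum-suppressed in a
2 mm arc window.

Curves are clamped cubic B-splines from global interpolation with
chord-length parameters and knot averaging; closed sections repeat the
first point (C0 seam).  All sections of a loft are interpolated on a
*shared* knot vector (parameters averaged across sections), which makes
them skinning-compatible by construction — equivalent in effect to degree
elevation + knot merging, but it preserves the exact interpolation
guarantee trivially.  Skinning interpolates the control net across
sections in v (chord-length stations of the section centroids), so every
input section is reproduced as an iso-parameter curve to < 1e-6 mm.  All
weights default to 1; the data model and the evaluators are fully
rational, verified against an independent Cox-de Boor recursion and
against scipy's B-spline evaluation at 1e-12.

Each section represents a slab of one slice spacing, so lofts are extended
by half a spacing beyond the terminal sections (constant cross-section),
making the solid consistent with midpoint-rule slab integration; the
residual end error is at most half a spacing of cross-section where the
solid does not fill its end slab.  Where the merge plane is known (the
refined wall), the nasal and pharyngeal lofts are extended exactly to it
instead, so the three bodies partition the lumen.

**Guides.**  A guide trace (e.g. the wall trace) inserts synthesised
sections at guide stations along the loft axis: the two neighbouring
sections are blended linearly, then warped — a cosine-squared falloff over
a quarter-perimeter arc window — so the sample nearest the guide lands on
it.  Guide stations closer than 0.25 mm to an existing section are
skipped to keep the v-knot sequence well conditioned.

Tessellation evaluates a regular parameter grid, stitches the closed-u
seam, adds planar end-cap fans, and normalises winding to outward
(positive enclosed volume).

## Quantification

Mesh-plane sectioning uses `trimesh`; loop areas use `shapely`.  The area
profile samples uniform stations (default 0.2 mm) along an axis over the
mesh extent, split by connected component (left/right cavity); component
areas sum exactly to the total.  The minimal-section search excludes 2 mm
at each end so end caps cannot pose as the narrowest site; ties break to
the smallest position.  Volume is computed two independent ways — signed
tetrahedron sum (divergence theorem, origin-invariant; cross-checked
against `trimesh.volume`) and trapezoidal integration of the area profile
— which agree within 1 % on smooth phantoms and converge as the station
step shrinks.

## The phantom generator

The generator emulates the study conditions: per-orientation FOV (220 mm
axial, 280 sagittal, 240 coronal), 512x512 matrix, 2.5 mm slabs, 0.5/1.5 mm
gaps, slice centres placed symmetrically about the phantom (a centred
acquisition).  Voxel intensity is `background + (lumen-background) *
occupancy`, with occupancy from 4 slab offsets and, on boundary voxels,
4x4x4 supersampling; the lumen is dark on bright tissue (T2-like), with
polarity configurable.  Noise is Rician (magnitude of a complex Gaussian
perturbation), the correct model for MRI magnitude images, with sigma
expressed as a fraction of the lumen-tissue contrast; motion is a rigid
transform applied to the sampling points at voxelization (exact) or by
stack resampling after the fact.  Solids: cylinder, elliptical tube and
hourglass with closed-form volumes (the hourglass radius profile
r0 - amp*sin(pi t/L) integrates in closed form, verified against
quadrature), and a bi-channel cavity — two elliptic channels at +-7 mm
merging into a stadium-profile lumen at a configurable plane — whose
closed-form volume is cross-checked by Monte Carlo and voxel counting.

What the phantoms do *not* emulate: relaxation physics, bias fields,
k-space artifacts, breathing or swallowing motion within a slice, and the
fine turbinate convolutions of real nasal anatomy.  Passing phantom tests
therefore validates the geometry-processing chain (segmentation bias,
registration consistency, lofting and volumetry) under the protocol's
sampling and noise, not the segmentation of arbitrarily low-contrast
clinical images.

## Problem sizes and determinism

Default validation runs use the full 512x512 matrix with 15-17 coronal and
3-11 axial/sagittal slices per phantom; registration and septum
experiments use analytic section contours (marching squares on the
indicator at 0.1-0.2 mm), which isolates geometric recovery from
segmentation noise and keeps each experiment in seconds.  Every stage is
deterministic given its inputs; all randomness (noise, jitter, experiment
draws) flows from one top-level seed fanned out per stage, and a pipeline
rerun with the same config and seed reproduces the report byte for byte.

## Known limitations

* In-plane piecewise correction cannot recover out-of-plane motion
  components; they appear as residual shape error, not crossing mismatch.
* The displacement estimator sees only motion components that move
  crossing points (e.g. an axial slice's left-right shift is invisible to
  crossings with parallel-edged sagittal sections).
* Loft end handling assumes the solid roughly fills its terminal slabs;
  volumes of objects ending mid-slab carry up to half a spacing of
  cross-section error at each end.
* The guide warp is local and C^1-smooth but heuristic; guides far from
  the blended section (> a few mm) would distort sections rather than
  refine them.
* Real-data mode expects user-drawn seed polygons per slice; there is no
  automatic seeding.
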