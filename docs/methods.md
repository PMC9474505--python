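# Methods

This note documents the models, conventions, numerical choices and known
limitations of the `optomorph` analysis chain. Units are micrometres
(µm) throughout; 3D arrays are indexed (z, y, x) with the apical surface
at low z and z increasing basally; label 0 is background.

## Synthetic tissue model

The generator exists so that every downstream stage can be validated
against exact ground truth. It emulates membrane-labelled (CAAX-type)
columnar epithelial monolayers imaged on a confocal with 0.207 µm x-y
pixels and 0.7 µm z-steps — the acquisition geometry the analysis is
designed for.

**Geometry.** Cell footprints are the Voronoi cells of a jittered
lattice (jitter 25% of the 10 µm cell pitch), clipped to the tissue
rectangle; this approximates MDCK packing (~100 µm² apical areas, the
density at which ~12 cells fit a 35.3 µm square) with minimal machinery.
Each cell is a column between its apical polygon (top, z = 0) and basal
polygon (bottom, z = h). Cross-sections interpolate radially between the
two polygons and are rescaled per slice so the **cross-sectional area is
exactly linear in z**. Consequently every generated cell satisfies

    V = h (Aa + Ab) / 2    and    h = 2V / (Aa + Ab)

to machine precision — the ground-truth table is exact by construction,
and voxelisation is the only error source downstream measurements face.

**Constriction program.** Cells holding >50% of their apical area inside
the stimulation rectangle are "programmed". During stimulation their
total apical area follows `A0·(1 − r·(1 − exp(−t/τ_on)))` and relaxes
back with τ_off afterwards. Defaults are the study conditions: plateau
reduction r = 0.254, τ_on = 10 min (the plateau is effectively reached
within 50 min), τ_off = 5 min (recovery under way within minutes of
light-off), volume conserved, basal surface fixed.

**Neighbour accommodation.** The experiments do not constrain how
non-illuminated neighbours deform, so this is a declared modelling
choice: all apical-plane tessellation vertices are pulled toward the ROI
centre by a radial field that grows linearly with r inside the
stimulated radius (uniform compression of the illuminated patch) and
decays as R²/r with an exponential cut-off (two cell diameters) outside.
The strain is solved by bisection each frame so the stimulated apical
area matches the program exactly. Because the field is a function of
position, shared vertices move together and the apical tessellation
remains a partition. A consequence worth knowing: neighbours *expand*
slightly (the constricted area is redistributed to them), whereas in the
real experiments all layers constricted mildly — an effect attributed to
stray light, which the generator deliberately does not model.

**Image formation.** The membrane "object" is rendered on an isotropic
fine grid: lateral walls as each cell's boundary-voxel layer (two voxels
per shared wall, centred on the interface; rim walls receive a virtual
outer layer, as if the monolayer continued beyond the field), and
apical/basal face membranes as thin sheets deposited with sub-voxel
linear weights exactly at the cell's top/bottom plane. The object is
blurred with an anisotropic Gaussian PSF (σ_xy = 0.25 µm, σ_z = 0.45 µm),
box-averaged down to the 0.7 µm z-sampling (detector partial-volume
behaviour), and corrupted with Poisson shot noise (200 photons at the
membrane level) plus Gaussian read noise (σ = 0.03). Cytoplasm carries
10% of the membrane signal. The stack extends ~1.3 µm past the basal
faces, as an acquired stack would. Geometry and noise use separate
seeded random streams, so changing only the noise seed leaves the
ground-truth labels bit-identical.

**What the generator does not emulate:** photobleaching, drift, light
scattering and depth-dependent attenuation, cell divisions/extrusions,
membrane ruffling, and the stray-light layer constriction noted above.
Passing tests therefore demonstrate correctness of the measurement
chain, not robustness to every artifact of real microscopy.

## Segmentation

Stacks are rescaled to 1:1:1 voxels by linear interpolation
(`ndimage.zoom` in grid mode, which preserves physical extent — the
corner-aligned default would shrink the z-extent by ~5%). The tissue
mask is a 2D footprint (Otsu on the maximum projection, holes filled)
crossed with a per-column z-span between the first and last voxel above
a low signal threshold; that threshold comes from a second Otsu split of
the sub-membrane intensities, so dim cytoplasm counts as tissue but the
dark medium above/below does not. Watershed seeds are the h-maxima
(depth 0.3 of the maximum) of the distance transform of the cell
interiors; a background marker covers everything outside the tissue mask
so the medium competes in the flooding and no cell leaks into the
margin. Flooding runs on the lightly smoothed (σ = 0.2 µm) intensity, so
boundaries land on membrane ridges; labels smaller than 5 µm³ are
discarded as debris. All steps are deterministic. The watershed
parameters (h fraction, smoothing, thresholds) are exposed in the
configuration — the upstream experiments only specify "watershed", so
these are this package's choices, not claimed originals.

On noise-free-equivalent synthetic stacks this pipeline reaches per-cell
Jaccard ≥ 0.93 against ground truth, volumes within ~3%, areas within
~2% and heights within ~1 voxel.

## Morphometry conventions

- Volume: voxel count × voxel volume.
- Apical/basal contact: cell voxels whose z-neighbour toward the
  apical/basal side is background (out-of-volume counts as background);
  6-adjacency is the strictest testable reading of "contact".
- Contact area: contact voxels projected to x-y, pixel count × pixel
  area. Pixel count was chosen over outline-polygon area; on these cell
  sizes the difference is ~1–2%, within all stated tolerances.
- Height: distance between the mean apical-contact plane and the mean
  basal-contact plane, using voxel *faces* — a prism spanning n voxels
  measures n × voxel size. Means (not extrema) make tilted surfaces
  well-behaved.
- Normalization: per-frame series divided by the last pre-stimulation
  value.
- Feret (lumen) diameter: maximum pairwise distance between convex-hull
  boundary pixels plus one pixel (a single pixel has diameter one pixel).
- Thickness: mean of n (default 3) probes cast along local normals at
  seeded random positions on the apical boundary, formalising the
  measure-three-times-and-average protocol. Manual FIJI measurements
  cannot be replicated exactly; only the averaging protocol is.

A known bias, accepted deliberately: voxel-face areas and voxel-counting
volumes differ from surface-mesh estimates by O(voxel/cell-size); the
linear-taper consistency |h − 2V/(Aa+Ab)| stays within 2 voxel sizes.

## Tracking and quality control

Cells are linked frame-to-frame by maximum voxel overlap, greedily
one-to-one in descending overlap, with ties broken by centroid distance
then label id (determinism). Whether the original analysis enforced
one-to-one assignment is unknown; surplus labels simply start new tracks
and then fail QC. A track is rejected iff it misses any frame or any
consecutive-frame volume ratio leaves (0.7, 1.3) — "sudden changes in
volume higher than 30%", evaluated frame-to-frame with strict
inequality. Stimulated cells are classified either by any apical pixel
inside the ROI (contact rule, for stimulated-vs-outer comparisons) or by
>50% of apical pixels inside (majority rule, seeding the layer
analysis). Layers are breadth-first distances in the apical adjacency
graph (4-adjacent label pairs at the apical slice — the layer analysis
concerns apical-area effects, so adjacency is evaluated there, not in
3D).

## Linear-taper shape model

"Linear change in cross-sectional area" is taken literally: A(z) linear,
V = h(Aa+Ab)/2. The geometric frustum alternative (side length linear,
area quadratic, V = h(Aa+Ab+√(AaAb))/3) is available behind
`variant="frustum"` for sensitivity analysis; for the ~±25% area changes
here the two differ by <1%. Predictions from voxel-measured inputs track
the measured height dynamics with a small constant offset (voxelisation
biases volume and areas slightly differently); the offset is reported,
never corrected away.

## Curvature

Local curvature at B is the inverse circumradius of (A, B, C) spaced s
points apart along the curve: κ = 4K/(|AB|·|BC|·|CA|), K the triangle
area, signed by the turn direction. Curves are resampled to 1-px
arc-length steps first, so "s points" means a fixed arc-length span
regardless of the raw point density (the alternative — index spacing in
the raw skeleton list — is resolution-dependent). Collinear triples give
exactly 0. Open curves drop the ends without a full triple; closed
curves wrap. Skeletons are the longest path of the skeletonised band,
with each end trimmed by twice the local half-width (skeletonisation
grows hooks into square-cut band ends). Spacing defaults: 20 px for
skeletons, 320 px for organoid perimeters, where small features such as
delaminating cells must not register.

One geometric fact shapes the organoid analysis: the mean signed
curvature of a closed convex contour equals 2π/perimeter (total turning)
and is therefore invariant under local flattening. The "curvature
reduction" of a flattened organoid is consequently evaluated over the
stimulated angular window (|angle| ≤ 35° about the stimulation centre,
0° pointing at it); the full-perimeter mean is only a consistency check.
Sign conventions: concave-toward-apical positive for skeletons
(apical side declared by the caller); convex-positive for outward-apical
organoid perimeters (a circle reads +1/R), with a flag for
lumen-apical tissues.

## PIV and zonal analysis

Single-pass cross-correlation: 64-px interrogation windows tiled without
overlap, FFT correlation with the triangular window-overlap envelope
divided out (capped at 2× to avoid amplifying far-shift noise peaks) —
without this, finite windows bias displacements toward zero by ~0.07 px.
Sub-pixel refinement is a three-point Gaussian fit per axis (exact for
the Gaussian-shaped peaks of smooth textures; a parabolic fit under-reads
them by ~10%), with a parabolic fallback for non-positive correlations.
Vectors whose peak-to-second-peak ratio (second peak sought outside a
window/16 exclusion zone) falls below 1.5 are flagged invalid and
excluded from averages: genuine matches on realistic textures score
above 3.5, uncorrelated noise below 1.3. Pure translations are recovered
to ≲0.05 px.

Displacements are projected on the unit vector toward the stimulation
centre (positive = inward). Grid points are stimulated (inside the ROI),
adjacent (within one interrogation window, 64 px × pixel size, of its
boundary — the zones were defined pictorially upstream, so the width is
a reported parameter), or outer. Zonal series are per-frame means of
valid radial components with their running sum; the distance profile
bins points outside the ROI by Euclidean distance to its boundary in
5 µm bins. Note that PIV reports window-averaged motion: fields varying
within a window are recovered as their window mean, which is how the
synthetic study conditions are calibrated.

## Translocation and kinetics

Junction/cytoplasm ratios use 5×5-px ROI means, each junction ROI
divided by its nearest cytoplasm ROI, pairs averaged per time point; the
ROI size is specified in pixels with physical size taken from metadata
(the translocation acquisitions used a different pixel size than the 3D
stacks, so nothing is hard-coded in µm). The mask-based variant
segments junctions from a reference channel (Otsu on a smoothed copy,
percentile override available) and divides the target channel's mean
inside the mask by its mean over the complement. Both estimators are
invariant under global intensity scaling.

Kinetics: least-squares fit of a saturating exponential rise during the
stimulation window and a single-exponential decay after it. The
unbinding half-life is reported as τ_off·ln 2 from the fit — the
model-free half-crossing time is also available, since a "~30 s"
half-life does not single out either definition — and the time to return
to the off state as τ_off·ln 10 (decay to 10% of the end-of-stimulation
amplitude, ≈100 s for τ_off = 43.3 s). Flat series are returned flagged
unidentifiable rather than raising. No bleach correction and no
multi-exponential models.

## Problem sizes and determinism

The default study sizes keep every stage exact enough to validate while
running on a laptop: 5×5-cell monolayers (25 cells, ~260² × 65 voxels
isotropic per frame, 4 frames), 640² px PIV fields (10×10 windows, 10
frame intervals), 6000-point organoid contours at 0.2 µm/px, 200-point
kinetics series, 20-seed recovery ensembles. Every random choice flows
from explicit integer seeds; rerunning any stage with the same
configuration is bit-identical, and the geometry and noise streams are
separate.

## Known limitations

- Heights are quantised by the 0.7 µm z-sampling; the basal face can
  only be located to ~half a z-step, which dominates the ~1-voxel height
  accuracy and the small constant offset of model predictions.
- Segmentation parameters are package choices (the upstream method is
  described only as "watershed"); they are exposed in configuration and
  validated on the synthetic benchmark, not claimed to reproduce the
  original implementation bit-for-bit.
- The neighbour-accommodation rule and the displacement-field shapes are
  modelling choices consistent with, but not dictated by, the
  experiments.
- No gap-closing in tracking (tracks with missing frames are rejected by
  design), no division/merge handling, no multi-pass PIV, no
  deep-learning segmentation.
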