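# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind `bonemicrokit`, in the order the pipeline applies
them.

## Density calibration and resampling

CT intensities are mapped to hydroxyapatite-equivalent density by
ordinary least squares of known rod densities on mean observed
intensity per rod.  Rod regions are eroded by one voxel before
averaging so the summary is not biased by partial-volume rims.  The
fitted line is applied voxelwise; out-of-range densities are kept
(clamping happens later, in the fuzzy membership).

Resampling to isotropic voxels (default 150 μm) uses Lanczos-windowed
sinc interpolation with radius 4, the standard high-fidelity choice for
band-limited CT data, normalized by the resampled unit field so the
truncated kernel forms an exact partition of unity (constants are
reproduced exactly; a pure Lanczos kernel has ~0.1 % DC ripple at
half-voxel offsets).  Micro-CT-style inputs go through the same
resampler; there is no separate code path.

## Anatomy frame and ROIs

*Filled bone.* Threshold at 300 mg/cc, multiscale Euclidean closing
(radii 0.6 and 1.2 mm, computed via distance transforms with a
quarter-voxel erosion correction that makes the discrete closing
unbiased on convex bodies; the closing is kept extensive by union with
its input), largest 26-connected component, then 3-D hole filling with
both axial image faces treated as closed.  The face rule matters: the
marrow cavity of a scan-truncated shaft is connected to outside air
through the truncation plane and would otherwise never fill, while the
open articular rim at the distal end keeps its 2-D hole because the air
below the bone end connects it to the lateral background.

*End plateau.* Tracing axial slices from proximal to distal, the
plateau is the slice immediately proximal to the first slice whose
filled-bone cross-section contains a 2-D hole (4-connected background
enclosed by 8-connected foreground).  The topmost 3 mm are skipped:
scan truncation (or realignment clipping) can leave spurious 2-D holes
there, and the end plateau is by definition distal.

*Tibial axis.* The fit region is the 60 % peel of the filled bone
proximal to the 8 % percent-of-length site, excluding the top 2 mm.
The MSE-optimal line is fit through the per-slice 2-D centroids of the
peel region: cross-section centroids lie exactly on the shaft center
line, so the fit is unbiased by the elongation of oblique cross-
sections (a 3-D principal-component fit of the voxel cloud is biased by
peel-induced in-plane anisotropy; on a 10°-tilted phantom the centroid
fit recovers the axis to 0.01°, the PCA fit only to ~2°).  The volume
is then rigidly realigned so the axis is parallel to +z.  Realignment
uses linear interpolation: windowed-sinc preserves edges better but its
ringing perturbs the fuzzy membership around thin trabeculae and
destabilizes the topological class counts; cubic splines are worse.

*Percent peels and sites.* A peel keeps, per axial slice, the voxels
whose 2-D Euclidean distance to the mask boundary is at least the
stated fraction of that slice's maximum inscribed distance (a distance
fraction, not an area fraction).  Axial ROIs are slabs between
percent-of-tibial-length sites measured proximally from the plateau,
intersected with the inner peel (≥ 60 %) or the 30–60 % annulus.
Because the scan covers only the distal bone, `tibial_length_mm` is a
configuration input; the synthetic-phantom tests use 100 mm so that the
4–6 % and 14–16 % sites fall inside the imaged extent.  Spherical
accuracy ROIs (7.05 mm = 47 voxels at 150 μm) are sampled uniformly
over a region with seeded determinism; overlap is permitted by default.

## Fuzzy skeletonization

Bone membership is a clamped linear ramp, 0 at 0 mg/cc and 1 at
800 mg/cc (configurable).  The fuzzy distance transform (FDT) is the
Dijkstra shortest path to the background with each step weighted by the
mean membership of the voxels it joins.  Thinning erodes the support
(membership ≥ 0.5) in increasing FDT order with lexicographic
tie-breaks (deterministic output), deleting only *simple* voxels —
(26, 6) connectivity pairing, memoized 3×3×3 topology tests — and never
curve endpoints, in three phases:

1. voxels retained if medial: a center-of-maximal-ball test on the
   Euclidean distance field with a 0.25-step dominance slack.  The
   slack trades off two failure modes — a larger slack leaves small
   off-grid blobs entirely medial (diagonal EDT gradients are ~0.41 of
   a step), a smaller one erodes strongly oblique surfaces; 0.25 keeps
   surfaces tilted up to ~14° intact while thinning rods at arbitrary
   sub-voxel offsets;
2. residual two-voxel-thick sheets collapse: a voxel may then be
   deleted unless some axis already has background on both sides;
3. exactly-two-wide strips collapse via a 26-direction rim pattern
   (background · object · background along a direction), ordered
   in-plane-first so that of two parallel strips one is consumed whole
   and a single clean curve survives.

On contract phantoms this yields the exact mid-surface of a 5-voxel
slab (441 of 441 face voxels, one layer) and a 1-voxel axial curve for
rods of 3–5 voxel diameter at any sub-voxel offset and at 10° tilt.
Output is thin (no voxel with a full 26-neighborhood) and preserves the
Euler characteristic of the thresholded support.  Tie-breaking is
deterministic but not rotation-equivariant; under 90° rotation a few
rim tie voxels (< 2 %) may differ.

Tb.NA is the skeleton voxel count times one voxel face area divided by
the ROI volume, so a single plate of area A in volume V gives A/V.

## Tensor scale, classification, densities

At each skeleton voxel 45 antipodal ray pairs (deterministic golden-
angle hemisphere set) are marched in half-voxel steps to the 0.5-level
fuzzy boundary, capped at `max_scale` (default 3 mm; the tibia-phantom
tests use 1.5 mm to match their geometry).  Each pair's half-length is
the smaller of its two sides, keeping a centered ellipsoid inside the
structure.  The radial quadratic form u^T A u = 1/L(u)² is least-
squares fitted over the *unit* directions — every ray contributes with
equal weight, so long capped rays cannot dominate, and ideal slabs
(a₃ = t/2, a₁ = a₂ = cap) and rods (a₂ = a₃ = d/2) are represented
exactly.  Semi-axes are the reciprocal square roots of the eigenvalues,
clamped to [half voxel, max_scale]; plate width is 2·a₂ (reported as
capped when at the bound, not an error).

Plate/rod: plate if a₂/a₃ ≥ 2 (configurable).  Orientation (binary at
a 45° threshold, configurable): a rod is longitudinal when its dominant
direction lies within the threshold of the axis; a plate is transverse
when its *normal* (a₃ direction) lies within the threshold of the axis
— a horizontal plate is a transverse element.  Voxels at a plate's cut
edge legitimately classify as rod; this is an edge effect of finite
structures, not misclassification.

Tb.vBMD is the plain ROI mean.  Tb.tBMD sums BMD over the ROI
intersected with the transverse support and normalizes by the full ROI
volume, making it a partial density with Tb.tBMD ≤ Tb.vBMD by
construction.  The transverse support assigns every support voxel
(membership ≥ 0.25, capturing partial-volume bone) the class of its
nearest skeleton voxel via the Euclidean feature transform.  Tb.PW
averages plate width over all skeleton voxels in the ROI (a plates-only
flag exists).

## Star-line thickness and separation

For each phase voxel (bone for Tb.Th, marrow for Tb.Sp) full lines in
49 deterministic hemisphere directions are marched in 50 μm steps
through the *continuous* membership field, so phase boundaries
(0.5-crossings) are located with sub-voxel accuracy; the voxel's local
size is the minimum intercept over directions.  Values beyond the grid
are extended by edge replication, so scan truncation does not
artificially terminate an intercept (a fully degenerate single-phase
ROI therefore runs to the reported cap, the ROI bounding-box diagonal).
The ROI statistic is the membership-weighted mean over phase voxels
with weight ≥ 0.2 — weighting keeps the statistic stable when
interpolation (e.g. realignment) spreads partial-volume mass across
the boundary, which would otherwise shrink the hard support to
structure cores and bias the mean upward.  Results are stable within
5 % when the direction count doubles.

## Topological classes, EI, SMI

Each skeleton voxel is classified from its 3×3×3 neighborhood using the
number of 26-connected object components among its neighbors (ξ), the
number of 6-connected background components adjacent to it (δ), the
neighbor count and the component sizes, by the rule table in
`topology._classify_code` (isolated; profile; surface interior/edge;
curve interior/edge; curve–curve, surface–curve, surface–surface
junctions).  The erosion index is the ratio of curve-type counts
(curve interior + curve edge + curve–curve junctions + profile +
isolated) to surface-type counts (surface interior + edge + surface
junctions); both class lists are configuration-exposed since the
convention varies in the literature.  A pure plate census gives EI ≈ 0,
a rod lattice EI ≫ 1 (infinite, with a warning, when no surface voxels
exist).

SMI triangulates the 0.5-level surface by marching cubes after a
1-voxel Gaussian smoothing (suppressing voxelization stair-casing that
otherwise inflates the surface area), orients the mesh outward by its
signed volume, displaces vertices by dr = ¼ voxel along vertex normals,
and evaluates 6·V·S′/S².  Sphere/cylinder/plate phantoms give
4.02/3.11/0.16 against the analytic 4/3/0.  If the offset surface
degenerates, dr is halved once before erroring.

## Cortical segmentation

Per slice of the 14–16 % band: threshold at 600 mg/cc, keep the dense
components touching the periosteal contour (the outer boundary of the
filled bone) — this separates the cortical ring from trabecular
structures in the cavity without any scale assumption, where a
"largest component" rule fails once closing bridges trabeculae.  After
a 2-voxel disk closing regularizes the endosteal margin, low-density
regions enclosed by the ring and not connected to the marrow-cavity
component are pores (≥ 2 voxels in 3-D).  Cb.Th is the mean of twice
the 2-D distance transform evaluated on the per-slice medial skeleton
of the wall-with-pores-filled mask; Cb.Poro is the pore volume fraction
of the shell.  On tube phantoms the wall thickness is recovered within
a tenth of a voxel and the pore fraction within 0.01.

## Statistics

Accuracy calibration regresses the gold standard on the CT values
(Pearson r plus OLS line), so applying the line to a CT measurement
maps it onto the reference scale; predicting at the CT mean returns the
reference mean by the centroid identity.  The ICC is one-way random-
effects, single measurement — repeat scans are exchangeable replicates
— with an exact F-based 95 % interval.  Group comparisons use the
pooled-variance two-sample t-test with Cohen's d = difference / pooled
SD; adjusted comparisons fit a general linear model and evaluate
least-squares means with categorical covariates equally weighted across
levels and continuous covariates at the grand mean, effect size =
LS-mean difference / √MSE.  Power is exact via the noncentral t with
noncentrality d·√(n₁n₂/(n₁+n₂)).  All p-values are two-sided; no
multiple-testing correction is applied, matching how such pilot
analyses report unadjusted p-values.  The covariate list for adjusted
comparisons is an explicit argument (the canonical example adjusts for
a single comorbidity indicator).

## Synthetic phantoms

The generators define the test conditions: bone 800, marrow 100,
cortical 1200 mg/cc at 150 μm voxels — plausible magnitudes for the
application, documented as synthetic conditions rather than physiologic
claims; noise is additive Gaussian only, since artifact-laden scans are
excluded by quality control in practice.

The distal-tibia-like phantom is, from distal to proximal: an open
articular rim (annular cross-sections with a 2-D hole, 4.8 mm so a
ring survives slicing at up to ~20° tilt), a solid end-plateau cap
(1.5 mm), and a shaft truncated by the array top — outer radius 7 mm,
cortical wall 1.75 mm with non-overlapping spherical pores
(r = 0.55 mm) on a regular ring grid, a 0.65 mm endosteal marrow moat
(wider than twice the cortical closing radius, so the lattice never
bridges to the wall), and a mixed trabecular lattice: longitudinal rods
(0.6 mm diameter) and plate fins at a 1.05 mm pitch plus transverse
rods in a seeded fraction of (z, y) slots.  Two design choices make the
phantom a fair rigid-invariance oracle: (i) geometry is evaluated
analytically in tilted coordinates on a 2× supersampled grid and
box-averaged down, so tilted and untilted phantoms realize the *same*
continuum object with partial-volume voxel values; (ii) transverse-rod
planes and pore rings share the 1.05 mm pitch, which divides the fixed
14-slice (2.1 mm) site window exactly, making the window's transverse
and pore content invariant to where the plateau lands.  Ground truth
records realized (voxelized) quantities — porosity, transverse mass
fraction — rather than nominal targets.

Simulated measure tables draw from the stated linear model (group
effect, binary covariate effect with controllable imbalance, unit
random effects for replicate tables) with ground-truth parameters
attached to the table.

## What the phantom tests do and do not show

Passing tests demonstrate that each operation recovers known geometry
and that the full pipeline is invariant to rigid pose within 5 % for
the reported trabecular panel (inner 60 %-peel ROI) and within one
voxel / 0.01 for the cortical panel.  They do not demonstrate accuracy
on real scans: the phantoms have no beam hardening, no motion, no
scanner MTF, idealized lattice geometry, and clean two-density
composition.  Known limitations: the outer-annulus Tb.tBMD differs by
~10 % between tilted and untilted runs (orientation classification of
transverse-rod ends clipped at the lattice boundary under realignment
blur); EI is the least stable measure on small ROIs, consistent with
its low regional reproducibility in repeat-scan settings; and the
half-max boundary convention undercounts the volume of structures only
a few voxels across (curvature bias ∝ (voxel/r)²), which is precisely
the kind of systematic shift the accuracy-calibration stage exists to
absorb.

## Problem sizes

Default test and acceptance problem sizes are the package's choice of
study conditions: tibia phantoms of ~25 mm length / 14.7 mm diameter at
150 μm (≈ 1.9 M voxels, skeletonization restricted to the site band),
slab/rod/sphere fixtures of 4.5–15 mm extent, 200 units × 3 replicates
for ICC recovery, and 2000 simulation replicates for empirical power.
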