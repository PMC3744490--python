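# Methods

## The problem

Fossil charcoal abundance is the standard sedimentary proxy for past fire
activity, and it is almost always quantified by *counting* particles (or
measuring their 2D area) on slides. Counts are confounded by transport
history: the same mass of charcoal fragments into few large or many small
pieces depending on how it reached the basin, so two isotaphonomic samples
can rank oppositely by count and by actual amount of charcoal. Expressing
abundance as **total charcoal volume** removes that confound. charstack3d
implements the volumetric workflow: reflectance confocal z-stacks of
slide-mounted particles are segmented, each particle is rebuilt as a
closed triangle surface, and per-particle volume/area/shape feed
assemblage-level statistics and a total-volume estimate.

## Pipeline model and conventions

Voxel grids are `(z, y, x)`, 0-based, with a voxel-center convention:
physical coordinate = index × spacing (µm). Spacing is explicit
configuration, never parsed from vendor TIFF tags; the two acquisition
presets are (2.768, 2.768, 5.0) µm (10× mesofossil mode) and
(0.526, 0.526, 1.060) µm (20× microfossil mode). Anisotropy (dz ≠ dx) is
carried through every computation. Per-particle quantities are µm³/µm²;
assemblage totals are mm³ (1 mm³ = 10⁹ µm³).

**Segmentation.** Charcoal is bright on a dark background under reflected
laser light, so a single intensity threshold separates the classes. Fixed
thresholds are inclusive (foreground = intensity ≥ t); the automatic mode
is Otsu's two-class inter-class-variance split, with foreground > t
because Otsu reports the upper edge of the background class, and the
value used is logged for auditability. "Smoothing" is minimum-size
filtering (voxel count and/or projected area), not blurring; no upper
size limit is ever applied. An optional step deletes the *n* deepest
z-planes to remove the bright sheet that slide-surface reflection paints
under very thick particles (default 0: the artifact does not arise for
normally slide-mounted size fractions). Connected components use
26-connectivity by default (compact fragments; diagonal contact reads as
one particle) and are numbered in deterministic raster order of their
first voxel, so particle identity is stable across runs and "measure the
first 100 particles" is a reproducible stand-in for the operator's
transect protocol. Components touching a stack face are kept but flagged
by default (`border_policy=flag`).

**Surface reconstruction.** Each particle's binary indicator, padded by
one background voxel (guaranteeing closure even at stack faces), is
triangulated by marching cubes at level 0.5 on the physical grid.
Statistics come from the mesh itself: area as the triangle-area sum,
enclosed volume by the divergence theorem (sum of signed tetrahedra), with
a watertightness check (every edge shared by exactly two triangles)
rejecting malformed surfaces. The voxel-count × voxel-volume product is
kept as an independent oracle; the two volume estimates agree within a few
percent above ~100 voxels and converge as particles grow.

A numerical caveat, measured on digitized spheres: marching cubes on a
*binary* field recovers volume to well under 2% but overestimates surface
area by ~9–13% (staircase bias). Extraction therefore accepts a
`smoothing_sigma` (voxel units) applied to the indicator before
triangulation; σ ≈ 1 brings sphere area within 1% of the closed form at
both isotropic and anisotropic spacing while keeping volume within 2%.
The default remains σ = 0 because smoothing erodes particles only 2–3
slices thick (volume errors up to −14%), and volume is the primary
metric; use σ ≈ 1 when absolute mesh areas matter.

**Morphometrics.** Projected area is the x–y shadow (union over z).
Bounding boxes are axis-aligned (manual measurements are made on screen
axes), with extents = voxel span × spacing, L ≥ W in-plane and D the z
extent; the manual estimate is the L·W·D product, which by construction
bounds the mesh volume from above. Ellipsoid-equivalent semi-axes come
from the voxel second moments: a uniform solid ellipsoid with semi-axes
√(5λᵢ) has covariance eigenvalues λᵢ, so the sorted eigenvalues give
a ≥ b ≥ c; coplanar/collinear particles get affected axes clamped to half
a spacing and flagged. Shape classes use a relative tolerance τ = 0.2
(boundary-inclusive): sphere (all axes equal), oblate (a ≈ b ≫ c),
prolate (a ≫ b ≈ c), else triaxial. Circularity is 4πA/P² of the
projection, with P the marching-squares contour length on a σ = 1 px
smoothed field (raw contour as fallback for 1-px slivers) — the smoothing
undoes the digitized-outline staircase that otherwise depresses a perfect
disc to ~0.89.

**Assemblage statistics.** Summaries report mean, median (average of
central pair for even n), SE (sample SD/√n), min and max of volume and
area; "area" defaults to total mesh area but can be switched to projected
area for comparability with 2D workflows. Total volume is
count × median particle volume, computed in µm³ at full precision and
converted to mm³, rounding only at display (multiplying pre-rounded mm³
medians visibly corrupts totals). A mean-based total is reported alongside
as a sensitivity check: for right-skewed (lognormal) size distributions
count × median *systematically* underestimates the summed volume by the
median/mean ratio, e.g. e^(−σ²/2) ≈ −27% at σ_log = 0.8, while the
mean-based total is unbiased. The area–volume calibration is ordinary
least squares of volume on area (free intercept by default; the
through-origin variant reports the uncentered r²), and
`predict_volume_from_area` applies V = k·A with k = 13 µm³/µm² — the
thin-slab identity V = (t/2)·A_mesh at t = 26 µm, which holds because
flat flakes have mesh area ≈ twice their footprint. Group comparison is
the tie-corrected Kruskal–Wallis test with a chi-square p-value (reported
also as log₁₀ p for values below representable range); no multiple-testing
correction is applied. "Size sorting" is reported as two standard
dispersion metrics, CV and the quartile coefficient (Q3−Q1)/(Q3+Q1) —
both scale-free, lower = better sorted.

## The synthetic generator

No real stacks are publicly deposited, so validation uses generated
assemblages emulating a slide: sparse bright particles (foreground 200,
background 10, Gaussian noise SD 5 at 8 bit) in an anisotropic grid of
limited depth. Defaults are fixed at the mesofossil study conditions:
spacing (2.768, 2.768, 5.0) µm, 150 µm depth (slides ran ~40–215 µm),
100 particles with lognormal volumes (median 1.2×10⁶ µm³, σ_log = 0.8)
and oblate ratios b/a ∈ [0.82, 0.98], c/b ∈ [0.2, 0.5]. Flakes settle
flat on slides, so orientation is a random in-plane rotation about z.
Ground truth per particle is the analytic ellipsoid volume 4/3·π·abc and
Thomsen's surface-area approximation (p = 1.6075, max error ≈ 1.06%,
tolerances widened accordingly). Placement rejection-samples non-
overlapping footprints (enclosing circles padded by two voxels), so
rendered particles are disjoint under 26-connectivity and the component
count equals the truth count; particles too thick for the stack depth
have their ratios resampled, mimicking what can physically be mounted
(a mild truncation of the thickest tail).

Fidelity limits, hence what passing tests do *not* show: particles are
smooth convex ellipsoids, not angular fractured fragments — adequate for
volume/area/shape estimator validation, but convexity caps the manual
L·W·D overestimate near 8/(4π/3) ≈ 1.9×, below the 2.4–3.9× observed for
real fragments (tests of that behavior use concave unions of ellipsoids);
and there is no optical model (no point-spread function, depth
attenuation, or speckle), so segmentation robustness claims extend only
to additive Gaussian noise.

## Problem sizes and numerical choices

The default validation assemblage is 100 particles in a
30 × 1600 × 1600 stack (~77 Mvoxel), chosen to hold 100 mesofossil-scale
particles below a 30% footprint fraction; it runs end-to-end in well
under a minute. Closed-form checks use digitized spheres of 15–25 voxel
radius and 26 µm slabs of 300–650 µm radius (footprint ≫ thickness, so
the rim's area contribution stays below the 10% slope tolerance).
Isosurface level is 0.5 on the indicator; meshes are re-oriented so the
signed volume is positive; all-tied Kruskal–Wallis input returns H = 0,
p = 1 rather than 0/0; single-voxel particles yield the marching-cubes
octahedron (volume = 1/6 voxel) — closed and positive, recorded but not
asserted against a closed form.

## Known limitations

Touching particles are not split (slides are prepared dispersed; no
watershed); charcoal is not distinguished from other opaque reflective
material (impossible by thresholding alone); vendor microscope formats
(CZI/LSM) are out of scope — export to multi-page grayscale TIFF first;
and the k = 13 conversion is a single-study calibration for mesofossil
oblate charcoal, not a universal constant.
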