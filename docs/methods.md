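# Methods

This note documents the model, the parameter choices, the numerical
details and the known limitations of the `epifat` pipeline, in the order
the stages run.

## Coordinate and size conventions

Pixels are addressed 0-based as `(i, j)` = (row, column); the geometric
`x` axis is the row axis and `y` the column axis, so an orientation
`phi0 = 0` means "major axis along image rows".  Every morphological
structuring-element "size" is a **disk diameter in pixels** (the footprint
radius is `size // 2`).  All default pixel-valued parameters are
calibrated for 512-wide slices and are rescaled by `width/512` via
`PipelineConfig.scaled_for_width` for other matrix sizes.

## Preprocessing

Tone mapping is a percentile contrast stretch: luminance is clipped at the
1st/99th percentiles of the slice histogram and rescaled linearly to
[0, 1].  The map is monotone and deterministic, which downstream stages
rely on (Otsu thresholds and patch features are computed on the enhanced
scale).  CLAHE is available behind `preprocess.tone_method = "clahe"` but
is not the default, because adaptive equalization is not monotone in
luminance across the image.

ROI extraction: grayscale opening by reconstruction with a disk of
diameter `ms1 = 40` removes bright structures smaller than the element
(sternum fragments, vessels, bone islands) while exactly preserving the
shape of the surviving heart blob; the reconstruction is thresholded with
per-slice Otsu (256 bins), only the largest connected component is kept
(the heart is the dominant bright central blob; this prevents
sternum/spine leakage), and the component is dilated by a disk of
diameter `ms2 = 20` so the darker epicardial fat rim at the heart border
falls inside the mask.  The opening is applied to the enhanced slice and
the threshold to the reconstruction output — the ordering the operators
compose most naturally; a constant or empty result raises instead of
propagating garbage.

## Patch clustering

Defaults: patch size `R = 5` (odd; large enough for a stable variance,
small against the fat-layer thickness), stride 2 (overlapping coverage,
so the pixel-wise membership averaging is non-trivial), `C = 5` clusters
(fat, myocardium, contrast blood, lung fringe, transitional/edge
textures), fuzzifier `m = 2`, tolerance 1e-5, at most 300 iterations.
Features are z-scored per slice before clustering — patch mean and patch
variance live on very different scales — and the reference-patch feature
is mapped with the same slice transform.

Fuzzy c-means initializes its centers from `C` distinct data points drawn
with a seeded generator (plus a 1e-9 jitter to break exact duplicates),
so a fixed `clustering.rng_seed` makes the whole stage bit-reproducible.
The objective `J_m = sum mu^m d^2` is recorded each iteration and is
non-increasing; per-point membership sums are tracked as a numerical
self-check (worst deviation from 1 is kept in the result object).

Cluster selection compares the reference feature `u*` with each cluster's
membership-pondered mean.  Two normalizations are implemented:
`"as_printed"` divides the pondered sum by the total patch count `Q`;
`"normalized"` (the pipeline default) divides by the cluster's membership
mass.  The `1/Q` form shrinks every cluster mean toward the feature-space
origin in proportion to the cluster's mass, and the arg-min selection then
favors whichever *large* cluster lies in the same direction as `u*` —
on the phantom it reliably picks the lung-fringe cluster instead of the
fat cluster — so the conventional weighted mean is the default and the
literal form remains available for comparison.

The seed point is placed once per patient; the reference feature is
computed on the enhanced seed slice and reused on every slice (with each
slice's own standardization), so the fat cluster is re-selected per slice
without further interaction.

## Referent-ellipse estimation

The center is the weighted center of gravity with weights
`X(i,j) * mu(i,j)` (enhanced luminance times selected-cluster
membership).  The orientation is the principal direction of the soft
point cloud; two observation models are implemented:

- `"weighted_average"` (pipeline default): covariance of the raw
  coordinates weighted by membership;
- `"weighted_coords"`: covariance of membership-*scaled* coordinates
  `mu * [i, j]`.

The scaled form drags low-membership pixels toward the image origin
(row 0, column 0), which turns the principal direction into a function of
the cloud's position in the image rather than its shape; on the phantom
it mis-estimates a 17° orientation as 45°, so the weighted-average form
is the default.  The covariance is regularized by diagonal loading
`eps = 1e-6 * trace/2` before the eigendecomposition, and the dominant
eigenvector's angle is folded into [0, pi).  (A projection-based
`arccos(v_x)` cannot distinguish `+phi` from `-phi`; the folded
two-argument angle is used instead and equals the arccos form whenever
`v_y >= 0`.)

The semi-axes minimize the weighted parametric residual

    sum_ij X(i,j) mu(i,j) [ (a cos phi_ij - x~_ij)^2 + (b sin phi_ij - y~_ij)^2 ]

subject to `B_l < a, b < B_u`, in the frame translated to the center and
rotated by `-phi0`.  Each point's angle `phi_ij` is treated as its *own
ellipse parameter angle*, not the raw polar angle: for `a != b` the two
differ, and freezing the raw polar angle makes the generating ellipse a
non-stationary point of the objective (fitting noise-free (300, 250) data
that way biases the axes to roughly (287, 262)).  The solver is a bounded
block-coordinate descent: with angles fixed, each axis has a closed-form
clipped minimizer (the problem is separable and quadratic); with axes
fixed, each angle takes safeguarded per-point Newton steps toward the
projection parameter that are only accepted when they reduce that point's
residual.  Angles start at the raw polar angle (exact for circles), axes
at the clipped second-moment radii of the cloud; the scheme is
deterministic, monotone in the objective, and recovers noise-free
in-bounds ellipses to ~1e-9 px.  Default bounds are the study values
`(200, 450)` px at width 512, rescaled for other grids.

## Postfiltering

The alpha-cut is inclusive (`mu >= alpha`, default `alpha = 0.7`).  The
ring predicate compares the pixel's polar radius with the ellipse's polar
radius at the same polar angle,

    d = | sqrt(x~^2 + y~^2)  -  a b / sqrt(b^2 cos^2 phi + a^2 sin^2 phi) |,

and keeps pixels with `d <= epsilon` (default 20 px).  A literal variant
(`postfilter.distance_mode = "as_printed"`) that omits both square roots
is kept for comparison only — its output has units of px² and is not a
distance.  A pixel at the exact ellipse center (undefined angle) is
assigned `d = min(a, b)` by convention.  The arc predicate is inclusive
and wrap-aware: a window crossing 0 is expressed with `phi2 > 2*pi` and
membership is tested as `(phi - phi1) mod 2*pi <= phi2 - phi1`.  Control
angles are linearly interpolated between labelled slices and clamped
outside the covered range; five equidistant control slices are a sensible
default labelling effort.  The final closing uses a disk of diameter
`closure_size` (default `ms2 = 20`); the mask is padded by the element
radius first so the closing stays extensive at the image border.

## The phantom

Each slice emulates the statistical structure of a contrast cardiac CT at
the study's effective zoom (the heart nearly fills the 512 grid,
~0.25 mm/px): lung background, a bright heart ellipse
(semi-axes 210 × 185 px, 17.2° orientation) with two contrast blood-pool
blobs for internal texture, a fat ring of radial thickness 40 px (~10 mm)
hugging the heart boundary, bone distractor disks near the border
(smaller than `ms1`, so the opening removes them), and additive Gaussian
noise (default s.d. 80, about 2% of the 12-bit range).  Luminances follow
a CT-number = HU + 1024 rationale (lung 120, fat 920, myocardium 1080,
contrast blood 1330, bone 1930): fat sits just below soft tissue and far
above lung, which is what makes the adaptive ROI threshold keep the fat
rim — and what makes texture clustering necessary in the first place.

Fat-luminance tissue covers the **full ring** around the heart; only the
arc `[0.5, 3.8]` rad (in the heart frame's polar angle) is ground-truth
epicardial fat.  The remainder models pericardial/mediastinal fat-like
tissue that the fuzzy cluster inevitably contains and that the arc
constraint must remove — matching the data structure the method was
designed for (an arc-only phantom would make the center-of-gravity and
PCA estimators meaningless, since an arc cloud's centroid is far from the
ellipse center).  Geometry drifts linearly across slices (center and arc
angles) to exercise the control-angle interpolation.  A fixed seed makes
every output bit-reproducible; masks and the generating ellipse are exact.

What the phantom does **not** model: anatomically realistic chamber
shapes, partial-volume ramps at tissue boundaries (edges are hard),
contrast-agent gradients, breathing/cardiac motion, or beam-hardening
artifacts.  Passing phantom tests therefore demonstrates the pipeline's
mechanics (stage contracts, geometry recovery, parameter plumbing), not
clinical accuracy.

## Problem sizes in the test-suite and acceptance runs

End-to-end checks run single 512×512 slices with ten seeds per noise
level and one 4-slice drifting volume; geometric recovery uses 2–4 × 10³
sampled boundary points and 10⁴-point orientation clouds.  These sizes
put every quantity's sampling error well below the tolerances asserted.

## Known limitations

- **Edge under-segmentation.** Pixel memberships are means over all
  covering patches, so windows straddling a tissue boundary dilute the
  membership of pixels within ~R/2 + stride/2 of the rim edges; the
  0.7-cut then erodes roughly 2 px per side.  On the phantom's 40-px rim
  this caps the achievable Dice near 0.94 even at zero noise and with the
  *true* generating ellipse substituted for the fitted one — a structural
  property of patch-averaged defuzzification at this alpha, consistent
  with the method's modest clinical Dice range.  Volume is likewise
  systematically under-estimated by the eroded band (~15% on the
  phantom).
- The center/orientation estimators assume the selected cluster is
  distributed around the whole heart; strongly one-sided clusters bias
  both (see the phantom design above).
- The lower axis bound `B_l` binds when the true mid-ring minor axis is
  close to it; weight leakage into the heart interior pulls the fit
  slightly inward (a few px on the phantom).
- Control angles are interpolated linearly in slice index; rapid
  anatomical changes between labelled slices are not tracked.
- Clustering is 2D per slice by design; no volumetric regularization
  beyond the control-angle interpolation.
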