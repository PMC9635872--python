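# Methods

This note documents the models, algorithms and numerical choices behind
each pipeline stage, the assumptions they rest on, and what the phantom
tests do and do not demonstrate about real imaging data.

## Geometry conventions

All grids are numpy arrays indexed `(z, y, x)` with semantic axes
`(DV, ML, AP)`: embryos are assumed mounted dorsally with the anterior to
the left, so the z-step runs dorsoventral. The imaging calibration is
anisotropic (a typical confocal acquisition is 0.57 x 0.57 x 1.19 um per
voxel, giving a voxel volume of 0.386631 um³), and spacing is attached to
every grid and preserved by every operation. Physical positions follow
the center-of-voxel convention, `position(i) = (i + 0.5) * spacing`,
which matches the marching-cubes and resampling conventions used
downstream. Rigid transforms (rotation + translation, det +1, checked to
1e-9 orthonormality on load) act in physical um space — never in voxel
index space — so anisotropy is handled exactly once. Registration
returns the *pull-back* transform (fixed-space physical points to
moving-space physical points), which is the form resampling consumes;
recovering an applied perturbation therefore yields its inverse.

## Registration

Same-modality alignment (HuC channel to HuC reference) uses normalized
cross-correlation. The NCC is evaluated only over voxels the moving
stack actually covers after resampling; with full-grid NCC, zero-filled
out-of-field regions systematically bias the optimum whenever the
perturbation pushes structure outside the field of view (we measured
> 1-voxel translation bias along the tube axis on phantoms before
restricting the support). Candidate transforms with less than 25%
overlap score negative infinity.

The schedule is 2 coarse + 2 subpixel steps:

- **Coarse** (on a pyramid level reduced to ≤ 32 voxels per axis,
  anti-aliased halving): integer-voxel translation by FFT phase
  correlation given the current rotation, then a per-axis rotation scan
  (±12° in 3° steps, tightening each pass). The scan only needs to land
  inside the capture range of the continuous refinement.
- **Subpixel**: Powell minimization of negative NCC over the six rigid
  parameters (Euler angles in degrees about the physical axes,
  translations in um; rotation taken about the fixed stack's physical
  center so the parameters are decoupled), the first step on the pyramid
  level, the final step at full resolution (xtol 1e-3, ≤ 5 Powell
  cycles). Cost evaluations resample in float32 for speed; user-facing
  resampling is float64.

Every candidate — including each coarse scan's winner — is accepted only
if it improves the full-resolution similarity, so the per-step trace is
non-decreasing by construction and the procedure is fully deterministic
(no random initialization). Degenerate (constant-intensity) inputs and
zero-overlap coarse results raise errors, the latter with the best-found
transform attached.

On 64³ phantoms with perturbations up to 10 voxels / 10°, recovery is
typically ≤ 0.15 voxel and ≤ 0.35°, at ~6 s per registration on one CPU.
Masks are resampled by linear interpolation of the {0, 1} indicator and
re-thresholded at 0.5 (or nearest-neighbour on request).

## Segmentation

Features are deliberately minimal — local mean and local variance in
cubic windows of radius {1, 2, 4} voxels (variance as E[x²] − E[x]²,
clipped at zero; reflected edges; radius 0 degenerates to the raw
intensity) — keeping the stage cheap enough for consumer hardware and
matching the tissue-scale (not single-cell) aim. Anisotropy is ignored
at the feature level; at tissue scale the error this introduces is below
the inter-user disagreement the consensus stage absorbs. The classifier
family on top of these features is a 100-tree random decision forest
(scikit-learn, single-threaded, fixed seed), chosen for determinism and
serializability: the same pickled classifier reproduces bit-identical
predictions on every dataset, which the multi-user design requires. A
voxel is foreground when the predicted class probability reaches the
classifier's threshold (default 0.5).

**Outlier users.** Volumes segmented by each user across a panel of
specimens form a users x specimens table. A user is discarded when (a) a
one-way ANOVA (users as factor, specimens as replicates; sum-of-squares
formulas implemented directly so the rule is self-contained; an
all-identical table is defined as F = 0) is significant at α = 0.05 *and*
(b) that user's mean volume deviates more than 10% from the mean of the
remaining users. The conjunction operationalizes a "more than 10%
variability among users" rule that conflates significance with effect
size; both thresholds are exposed. Flagging is iterative: after each
removal the test reruns on the survivors. One-way (not repeated-measures)
ANOVA was chosen; with the additional deviation gate the two designs flag
the same gross outliers.

## Consensus fusion

Fusion is pure vote counting — no rater-performance modelling (no
EM/STAPLE) — because agreement counts keep thresholds exact and auditable.
Counts are stored as integers so embryos with different numbers of
retained users keep exact thresholds. Per embryo, user masks are summed
and thresholded (default "all users"; an integer k gives at-least-k);
per label, embryo consensus masks are summed and thresholded at
`embryo_k = 3`. Thresholded masks nest for increasing k, and the whole
construction is invariant to user and embryo order.

**Imprint diagnostic.** To choose the embryo threshold, the k-thresholded
signal is compared with its negative imprint on a reference domain: the
voxels of the reference that the *strictest* consensus (all raters) calls
signal-free. `overlap(k) = |signal_k ∩ imprint| / |signal_k|` (defined 0
and flagged when `signal_k` is empty) measures how far the loose signal
spills into that hole; it decreases with k, and a good threshold is the
smallest k at which it becomes marginal. Taking the imprint against the
k=1 support instead (configurable) makes the overlap identically zero, so
the strict-consensus hole is the default. The operator picks k from the
returned curve; the package does not auto-select.

## Quantification

Volumes are foreground voxel counts times the voxel volume. Axis
profiles reslice one voxel plane at a time along the chosen semantic axis
(bins can be widened to a physical um width); the per-slice ratio is
signal/reference within the slice (the alternative, per-slice signal over
the whole-domain total, is a flag) and slices with an empty reference are
flagged invalid and excluded from smoothing rather than zero-filled,
which would bias the smoother at the domain ends. Summed per-slice
volumes reproduce the total mask volume to numerical precision on every
axis.

The smoother is local *linear* kernel regression with the Epanechnikov
kernel K(u) = 0.75 (1 − u²) on |u| ≤ 1: at each query point a weighted
least-squares line is fitted with weights K((x_i − x0)/h) and the fitted
intercept is the smoothed value. Local linear fits reproduce straight
lines exactly for any bandwidth (a property the tests assert at 1e-9),
shrink to the global least-squares line as h → ∞, and approach
interpolation as h falls to the sample spacing. The bandwidth is either
fixed in um or selected by leave-one-out cross-validation over a
20-point log-spaced grid spanning [2 x median x-spacing, range(x)/2];
windows with fewer than two data points are widened locally by factors of
1.5 and flagged. On a noisy sine (n = 200, sd 0.1) the CV choice reaches
RMSE ≈ 0.03.

Interindividual variability is reported as
`100 |V_i − V_model| / V_model` per individual plus the mean.

## Birthdating

A photoconversion at time t permanently marks every neuron differentiated
before t, so time-ordered converted domains should be nested. Real masks
violate nesting through segmentation noise; nesting is therefore enforced
by cumulative union (`M'_i = (M_i ∪ M'_{i−1}) ∩ total`), on by default,
with the number of repaired voxels reported so violations stay visible
(a voxel that stays outside several later masks is counted once per mask
it is repaired against). Interval 1 is `M'_1`; interval i is
`M'_i \ M'_{i−1}`; the final interval is the residual `total \ M'_last`
(neurons born between the last conversion and acquisition). Conversion
masks are clipped to the total domain (a mask extending more than 20%
outside triggers a warning); labels are 1-based in time order with 0
reserved for outside-domain, keeping colour lookup tables trivial. The
labels partition the domain exactly — an integer identity asserted on
every map built. Population masks are intersected with the intervals and
normalized by the population volume inside the domain; out-of-domain
population voxels are reported separately.

## Shape comparison

Meshes are extracted by marching cubes at level 0.5 from the {0, 1}
field, upsampled 2x and blurred with a Gaussian of 0.5 original voxels
first: meshing a raw binary field overestimates surface area by ~10%
(staircase artifact), while the sub-voxel anti-aliasing brings a
digitized sphere's area within ~1% of analytic at a surface displacement
well under a voxel. Masks of only a few voxels that blur entirely below
the iso level fall back to the raw upsampled field. Vertices are in
physical um; outward orientation is enforced; optional smoothing uses the
volume-conserving Humphrey filter (volume drift < 2% per 10 iterations).

Signed distances are computed point-to-triangle (never point-to-vertex,
which would inherit tessellation bias): candidate triangles come from a
k-d tree over triangle centroids (k = 32 candidates, exact closest points
on each, best kept — exact in practice for meshes whose triangles are
small relative to query distances, as marching-cubes meshes are), and the
sign from angle-weighted vertex pseudonormals interpolated at the closest
point. The convention is positive where the comparison surface lies
outside the reference solid (the sampled reference point is inside the
comparison solid); a `sign_flip` flag inverts it. Sample points (default
400,000, reduced with a warning for very small meshes) are drawn uniformly
by area on the reference surface with a fixed seed, making the whole
comparison deterministic. Distances below 1e-9 um are snapped to zero so
self-comparisons are exactly degenerate. A per-vertex field and a
histogram accompany the samples for colour-coded display.

## Phantom generator

The phantom is an elliptical tube bent along AP with a dorsal notch —
enough asymmetry for registration to lock all three rotations — with
channel 1 carrying the domain signal (foreground 200, background 20,
additive Gaussian noise sd 36 = 20% of contrast by default) and channel 2
a striped, rhombomere-like sub-domain signal. Birthdate shells are cut
at quantiles of the normalized tube radius, hitting requested volume
fractions (default 30/30/40%) to within quantization error; the innermost
shell is "earliest" to mimic inside-out growth of the differentiation
domain.

Per-user noise flips voxels independently (default band: within 2 voxels
of the truth surface) because human segmentation disagreement
concentrates at boundaries — this, not uniform noise, is what consensus
fusion must tolerate. Per-embryo variability combines a radius-scale
jitter (N(1, 0.02) by default) with a random rigid transform inside
configurable bounds; the applied transforms are returned so registration
tests have exact ground truth, and replicates reuse the base phantom's
noise seed so that zero jitter reproduces the phantom bit-identically.

What the phantom does **not** emulate: optical point-spread anisotropy
and depth attenuation, intensity inhomogeneity, true deformable
embryo-to-embryo shape variation (the jitter is rigid plus isotropic
scale), correlated rater biases, and partial-volume effects at the
domain boundary. Passing phantom tests therefore demonstrates
algorithmic correctness and noise robustness of the fusion/quantification
machinery, not segmentation performance on real stains.

## Problem sizes and runtime

Defaults were chosen so the full property suite exercises study-scale
conditions on one CPU: 64³ stacks for registration recovery (20 random
perturbations ≤ 10 voxels / 10°), 5 seeds x 64³ for noisy segmentation,
50 seeds x {3, 5, 7} raters for consensus, and a full 5-embryo x 5-user
end-to-end birthdate build. The complete test suite runs in about six
minutes; `scripts/acceptance.py` recomputes the same quantities from
scratch in under four.

## Pipeline orchestration

The YAML-driven builds validate all referenced files and thresholds
before any computation, derive every stage seed from one root seed, and
write a provenance log (package version, seeds, thresholds, flagged
users, registration settings) sufficient to re-execute bit-identically;
re-running a config reproduces byte-identical model masks. Stages
execute serially; the CLI's `--threads` option is reserved for
per-embryo parallelism and does not change results. Stage failures halt
with a stage-tagged error and preserve partial outputs.

## Known limitations

- Rigid registration only (by design): embryo shape variability ends up
  in the consensus gradient rather than being removed by deformable
  alignment.
- The coarse rotation scan covers ±12° per axis; initial misorientations
  beyond that require a manual pre-rotation.
- The signed-distance candidate search (k = 32 centroids) is not a
  guaranteed nearest-triangle bound for pathological tessellations with
  highly non-uniform triangle sizes.
- ANOVA assumes independent specimens; repeated imaging of the same
  embryo would violate it.
- The LOO bandwidth search is O(n² x grid) and is intended for profile
  curves (hundreds of slices), not large point clouds.
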