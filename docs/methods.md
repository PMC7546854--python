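# Methods

This note records the models, the parameters that matter, the numerical
choices, and what the synthetic validation does and does not establish.

## Registration model

The registration is per-pair and unsupervised: nothing is pretrained, and
one optimization aligns one pre-ablation (moving) image to one
post-ablation (fixed) image.

**Transformation.**  A displacement field parameterized by a coarse
control-point lattice (default spacing 2 slices through-plane and 8 voxels
in-plane), materialized to a dense per-voxel field by separable cubic
(Catmull–Rom) interpolation with edge replication.  Displacements are
stored in voxel units; all reported distances are converted to mm through
the voxel spacing.  The interpolation and its adjoint are tensor products
of small per-axis weight matrices, so the gradient of anything downstream
with respect to the lattice is exact.

**Sampler.**  The tent-kernel (bilinear / trilinear) sampler with pixel
centres at integer coordinates, 0-based, and a border-zero convention:
coordinates outside the source simply contribute no terms.  The sampler
returns analytic derivatives with respect to the sampling coordinates;
unit tests compare them to central finite differences (tolerance 1e-4)
and the values to a naive kernel summation (1e-6 relative).

**Similarity.**  Both images are min–max normalized to [0, 1], partitioned
into regions (default 2×4×4 = 32 blocks in 3-D mode, 4×4 per slice in 2-D
mode), and passed through a convolutional feature stack: 3×3(×3) kernels,
channels doubling from 8, ReLU, max-pool 2 between levels (default 5
levels in the generic configuration; the phantom studies below use 3).
The filters are fixed random (seeded He-initialized) by default, which
keeps the procedure deterministic and desk-scale; random multiscale
projections preserve enough structure for a correlation-based similarity,
and a config flag (`train_features`) adapts them jointly with the field
when wanted.  Per region, the per-level feature maps are flattened and
concatenated into one fused vector (`block_pool="flat"`); a `"mean"`
option keeps only per-channel block means instead.  Flattening is the
default because global pooling erases within-block position and therefore
cannot drive sub-block alignment.

The loss is minus the sum over blocks of the normalized cross-correlation
of the paired fused vectors.  The `block_ncc_loss` operation implements
the plain dot-product form (range [−N, N], equal to −N iff every pair is
positively proportional).  During optimization the per-block vectors are
mean-centred first (`ncc_center=True`), i.e. a Pearson correlation per
block: uncentred ReLU features are non-negative and share a large common
offset, which compresses the similarity's dynamic range.

**Regularizer.**  A bending-energy penalty — the mean squared second
difference of the lattice displacements in mm — weighted by
`smoothness_weight` (default 0.1).  The weight is the main stiffness
control: lower values (0.01) track sharper fields slightly better away
from the ablation zone but leave the field near and inside the zone
several mm off; 0.1 keeps the near-zone field accurate without breaking
landmark recovery.  Weight 0 recovers the bare similarity objective.

**Optimizer.**  Adam-style per-parameter scaling (step `learning_rate`
voxels, default 0.1; the phantom protocol uses 0.2) on the lattice
displacements, starting from the identity (the Siamese head is
zero-initialized).  Plain momentum with a globally normalized gradient is
available (`optimizer="momentum"`) but converges poorly in low-texture
lattice regions, which is why per-parameter scaling is the default.  The
run stops when the relative loss change stays below `tolerance` (default
1e-5) for `patience` (8) consecutive iterations, or at `max_iters`; the
loss carries a large constant offset (−N at perfect correlation), so a
single-iteration relative-change test fires spuriously mid-run.  A
vanishing gradient (max |g| < 1e-9, e.g. for an already-aligned pair) also
counts as converged — per-parameter scaling would otherwise amplify
numerical noise to full-size steps.  The best-loss state is returned
(earliest on ties), so the accepted loss never exceeds the identity-field
loss.  Identical config and seed give bit-identical traces.

**Working resolution.**  The optimization runs on an in-plane
block-averaged copy of the images (`inplane_downsample`, default 2); the
through-plane axis, already coarse on thick-slice acquisitions, is never
downsampled.  The lattice lives on the working grid and is lifted exactly
to full resolution at the end (in-plane displacements and lattice spacing
scale by the factor), where the warped image is produced.

**2-D slice-wise mode.**  Mirrors thick-slice protocols: per-slice
in-plane warping with zero through-plane displacement, per-slice feature
stacks, and per-slice block partitions.  3-D is the default for margin
work since the margin is a 3-D quantity; the slice-wise mode exists
because very anisotropic acquisitions limit through-plane accuracy anyway.

**The ablation zone has no correspondence.**  The ablated tissue is
destroyed; its post-ablation appearance matches nothing in the
pre-ablation image.  If the similarity is allowed to act there it actively
corrupts the field (mean errors above 10 mm inside the zone in phantom
runs), and — less obviously — features *outside* a masked region still
backpropagate into it through their receptive fields.  `register_pair`
therefore accepts an exclusion mask (the pipeline passes the ablation
mask): the dilated region is blanked in both images, so its content
contributes neither similarity nor gradient, and lattice nodes without
data support are re-solved afterwards as the exact bending-energy
(biharmonic) interpolation of the surrounding field, via conjugate
gradients on the bending Hessian.  The displacement inside the zone is
thus explicitly an extrapolation of the surrounding anatomy — which is the
only defensible estimate there, and exactly what margin measurement
requires.

**Evaluation.**  `landmark_error` maps each fixed-frame landmark through
the field and reports the mean/SD mm distance to its moving-frame
counterpart (a target-registration-error construct on vessel-like
landmarks).

## Margin assessment

A voxel is boundary if it is foreground with a face-adjacent (6-connected)
background neighbour; the volume border counts as background.  Each tumor
boundary voxel gets the Euclidean distance (spacing-aware EDT) to the
nearest ablation-boundary voxel centre, signed positive where the tumor
voxel lies inside the ablation mask.  The minimal AM is the floored-at-0
minimum of the signed distances; the signed map is kept for
visualization.  Distances are voxel-centre to voxel-centre, so the
discretization error is at most half a voxel diagonal per surface (the
concentric-sphere check uses one full diagonal, since both surfaces
quantize).  Grading is inclusive: AM ≤ threshold (default 5 mm) is group
A, above it group B; "achieved" in `margin_sufficiency` means group B.
The tumor (moving side) is warped, consistent with aligning the
pre-ablation image to the post-ablation image.  The theoretical margin
contour is the spacing-aware dilation of the tumor by a ball of the
requested radius (voxels whose centre lies within the radius).

## Phantom generator

`make_phantom_pair` emulates the geometry of the measurement problem, not
MRI contrast: a liver-like ellipsoid (intensity 0.5) with bright
vessel-like spheres (0.9, radius 2.5 mm, placed ≥ 12 mm clear of the
ablation zone), a hypointense spherical tumor (0.25, default radius
11.5 mm ≈ the 2.3-cm mean lesion), and a hyperintense ablation zone (0.85,
default radius 19 mm ≈ the 3.8-cm mean zone) painted into the fixed image
at the *fixed-frame* tumor position — the ablation covers the tumor where
it lies post-ablation.  Default grid 64×128×128 at 5×1×1 mm mirrors a
thick-slice acquisition at desk scale.

The ground-truth field has two parts, named for what they emulate:
*breathing*, a global low-frequency displacement dominated by the
cranio-caudal axis whose magnitude stays close to the nominal amplitude
(default 6 mm) everywhere, plus small in-plane components; and *heating*,
a Gaussian-windowed radial displacement centred on the ablation zone with
peak amplitude (default 2 mm) at one zone radius.  The fixed image is the
moving image pulled back through this field; independent Gaussian noise
(default SD 0.02 on a unit intensity scale) is added to both.  Landmark
correspondences solve the pull-back fixed-point equation, so the identity
registration error equals the field magnitude at the landmark sites.

What passing phantom tests shows: the optimization recovers smooth fields
of the stated magnitude from vessel-scale structure, and the margin
chain measures warped distances correctly.  What it does not show:
robustness to real MRI contrast, intensity non-uniformity, sliding
motion at the liver boundary, segmentation error, or deformations far
outside the generator's smoothness class.

`make_cohort` draws covariates as independent Bernoulli variables with the
reference cohort's frequencies (43.3% margin ≤ 5 mm, 20.6% age ≥ 65,
87.9% male, …) and LTP times from an exponential proportional-hazards
model — hazard `baseline · hr_margin^[margin≤5] · hr_age^[age≥65]`,
default true hazard ratios 3.195 and 2.463, baseline 0.0012/month chosen
to give ≈ 13.5% events by the administrative censoring horizon (36
months).  The constant baseline loses no generality for Cox recovery,
which is baseline-free.

## Statistics

Kaplan–Meier, log-rank and Cox (Efron tie handling) are delegated to
lifelines; cumulative LTP rates are reported as 1 − KM.  Forward-stepwise
Cox is pure forward: starting from the null model, the candidate with the
smallest likelihood-ratio p-value enters while that value is below
`alpha_enter` (0.05); there is no removal step.  Complete separation or
non-convergence raises an explicit error rather than returning silent
estimates.  DeLong's AUC comparison is implemented here (midrank
structural components, ties counted ½, two-sided normal test; a zero
variance with zero difference reports p = 1).  Two-year LTP status for
AUC work counts events at or before the horizon as positives and subjects
followed past it as negatives; earlier censorings are dropped as
unknowable.  For two-group comparisons: Mann–Whitney U with tie-corrected
normal approximation and no continuity correction (identical samples give
p = 1 exactly); categorical tables use Pearson's χ² unless an expected
2×2 cell is strictly below 5, in which case Fisher's exact test is used
(both can be forced explicitly).  Cross-tabulation odds ratios apply the
Haldane–Anscombe 0.5 correction only when a cell is zero.

## Validation problem sizes

The heavier suites run at sizes chosen to exercise the stated conditions
at desk scale: registration recovery on five seeded 64×128×128 phantoms
(breathing 6 mm, heating 2 mm) with the 3-level / half-resolution /
Adam-0.2 protocol; Cox coverage on 100 replicate cohorts of n = 1000
(≈ 100 events each, enough for near-nominal Wald CIs on a 20%-prevalence
covariate); log-rank size on 500 null cohorts of n = 141; oracle suites
(sampler, NCC, margin, DeLong) on small random instances where brute
force is exact.

## Known limitations

- The field inside the ablation zone is an extrapolation; its error grows
  with zone size and with how sharply the true deformation varies there.
- Fixed random features assume both images share an intensity
  characteristic after min–max scaling; strong multi-modal contrast
  changes are out of scope.
- With `train_features=True` the best-loss state restores the lattice but
  not the filter weights of that iteration; the option is supported in
  3-D mode only.
- Surface distances are voxel-centre based; sub-voxel surface modelling
  (marching-cubes distances) is not attempted, and the half-diagonal
  error is material on 5-mm slices — thin-slice input reduces it
  directly.
- The cohort generator draws covariates independently; real cohorts have
  correlated risk factors, so covariate-confounding behaviour is not
  exercised.
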