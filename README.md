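# ablamark

Deformable registration of pre- and post-ablation liver images and
quantification of the **ablative margin** (AM) — the shortest distance from
the tumor boundary to the ablation-zone boundary — together with the
survival statistics that relate margin adequacy to **local tumor
progression** (LTP).

## Who this is for

After thermal ablation (e.g. microwave ablation of hepatocellular
carcinoma), the operator wants to know whether the ablation zone covered
the tumor with a 5-mm safety margin: lesions with AM ≤ 5 mm progress
locally far more often than lesions with AM > 5 mm.  Measuring the AM
requires overlaying the pre-ablation tumor outline on the post-ablation
image, but breathing motion and heat-induced tissue shrinkage misalign the
two scans — a naive overlay can make an adequate margin look breached (or
vice versa).  This package provides the full measurement chain: non-rigid
registration, margin quantification, and cohort-level outcome statistics,
plus synthetic phantoms and cohorts with known ground truth for validating
every step.

## The method

**Registration (STS-net).**  An unsupervised, per-pair spatial-transformer
registration.  A Siamese localization network (twin convolutional branches
with shared weights feeding a zero-initialized regression head) produces
the non-rigid transformation parameters: a coarse control-point lattice of
displacements, materialized to a dense field by cubic interpolation.  A
grid generator adds the field to the identity grid and a differentiable
tent-kernel sampler warps the moving image *U* into *V*:

```
V_i = Σ_n^H Σ_m^W  U_nm · max(0, 1 − |x_i − m|) · max(0, 1 − |y_i − n|)
```

(out-of-bounds samples contribute zero; a separable three-axis kernel is
used in 3-D mode).  Similarity is computed by a feature network: both the
warped and the fixed image are partitioned into regions, each region is
passed through a multiscale convolutional stack, and the per-region fused
feature vectors are compared with a block-wise normalized
cross-correlation,

```
LOSS = − Σ_{i=1}^N  D(F_wi, F_ai) / sqrt( D(F_wi, F_wi) · D(F_ai, F_ai) )
```

where *D* is the dot product and *F_wi*, *F_ai* are the *i*-th block
features of the warped and fixed image.  The loss (plus a bending-energy
penalty on the lattice) is backpropagated through the feature stack and
the sampler to the control points, which are updated until the
dissimilarity stops decreasing.  All forward and backward passes are
implemented in numpy with exact analytic adjoints (verified against finite
differences in the test-suite).

The ablation zone itself has no pre/post correspondence (the tissue is
destroyed and appears completely different), so it can be excluded: the
region is blanked in both images and the displacement inside it is the
bending-energy-minimizing interpolation of the surrounding anatomy.

**Margin assessment.**  The pre-ablation tumor mask is warped through the
estimated field; every tumor boundary voxel receives a signed Euclidean
distance (mm, spacing-aware) to the ablation-zone boundary, positive
inside the zone.  The minimal AM is floored at 0 mm and graded group A
(AM ≤ 5 mm) / group B (AM > 5 mm).

**Outcome statistics.**  Kaplan–Meier LTP-free curves and log-rank tests
by margin group, forward-stepwise Cox proportional-hazards modelling
(Efron ties, likelihood-ratio entry at p < 0.05), DeLong's test for
correlated ROC AUCs, cross-tabulation of two margin-assessment methods,
and Mann–Whitney / χ² / Fisher group comparisons.

## Worked example

Register a synthetic pre/post pair (6-mm breathing motion plus 2-mm
heat-shrinkage around a 3.2-cm ablation zone containing a 1.6-cm tumor)
and measure the margin:

```python
import numpy as np
from ablamark import (PhantomSpec, make_phantom_pair, RegistrationConfig,
                      register_pair, landmark_error, warp_mask, minimal_margin)

spec = PhantomSpec(shape=(32, 64, 64), spacing=(5.0, 1.0, 1.0),
                   tumor_radius_mm=8.0, ablation_radius_mm=16.0,
                   breathing_amplitude_mm=6.0, heating_amplitude_mm=2.0, seed=7)
pair = make_phantom_pair(spec)

before = np.linalg.norm(pair.landmarks.fixed_mm - pair.landmarks.moving_mm, axis=1).mean()
cfg = RegistrationConfig(mode="3d", feature_levels=3, max_iters=80,
                         learning_rate=0.2, seed=7)
result = register_pair(pair.moving, pair.fixed, cfg, exclude=pair.ablation)
after = landmark_error(result.field, pair.landmarks, spec.spacing, shape=spec.shape)

naive      = minimal_margin(pair.tumor, pair.ablation)
registered = minimal_margin(warp_mask(pair.tumor, result.field), pair.ablation)
truth      = minimal_margin(warp_mask(pair.tumor, pair.truth_field), pair.ablation)

print(f"landmark error: {before:.2f} mm -> {after.mean_mm:.2f} mm")
print(f"loss: {result.initial_loss:.3f} -> {result.best_loss:.3f} ({result.iterations_run} iterations)")
print(f"margin without registration: {naive.min_margin_mm:.2f} mm (group {naive.group})")
print(f"margin after registration:   {registered.min_margin_mm:.2f} mm (group {registered.group})")
print(f"margin under the true field: {truth.min_margin_mm:.2f} mm (group {truth.group})")
```

Output:

```
landmark error: 5.37 mm -> 0.73 mm
loss: -29.347 -> -31.721 (80 iterations)
margin without registration: 0.00 mm (group A)
margin after registration:   5.00 mm (group A)
margin under the true field: 5.00 mm (group A)
```

Registration cuts the vessel-landmark error from 5.4 mm to 0.7 mm.  The
unregistered overlay reports a breached margin (0 mm) purely because of
breathing misalignment; after registration the measured margin equals the
value obtained with the ground-truth deformation (5.00 mm).  The same
chain is available from the shell:

```bash
ablamark simulate pair --out-dir pair/
ablamark run --moving pair/moving.nii.gz --fixed pair/fixed.nii.gz \
             --tumor pair/tumor.nii.gz --ablation pair/ablation.nii.gz \
             --seed 7 --out-dir results/
ablamark simulate cohort --out cohort.csv
ablamark cohort-stats --cohort cohort.csv --out stats.json
```

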