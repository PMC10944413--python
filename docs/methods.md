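# Methods

## The model

`shapedent` detects missing mandibular teeth from surface shape alone. The
core object is a point-distribution model (PDM) over a reference triangle
mesh of the full lower jaw including teeth: a shape is

    u = mu + sum_{i=1..r} alpha_i * sqrt(lambda_i) * PC_i

with the mean `mu`, unit principal directions `PC_i` and eigenvalues
`lambda_i` (mm^2) estimated by PCA from a cohort of jaws in vertex-wise
correspondence (sample covariance, divisor n-1; eigenvalues below 1e-10 of
the leading one are dropped, so the rank is at most n-1). Components are
stored pre-scaled by `sqrt(lambda_i)`; the weights `alpha` are then
standard normal, the coefficient norm ‖alpha‖ is the Mahalanobis distance
of the shape to the mean, and the log-likelihood is the standard-normal
log-density −(r/2)·log 2π − ‖alpha‖²/2.

Because such a model is built from very few examples (nine in the reference
workflow), it is augmented with a smooth Gaussian-kernel deformation prior
in the spirit of Gaussian Process Morphable Models: the covariance gains a
low-rank approximation of `s² · exp(−‖x−x'‖²/b²) · I₃` evaluated on the
reference vertices. The scalar kernel matrix is eigendecomposed, each
scalar eigenpair is lifted to three axis-aligned deformation fields, the
expansion is truncated to `extra_rank` terms, and the combined column set
is re-orthogonalised (SVD) so the result is again a valid PDM. The dense
eigendecomposition is appropriate for the mesh sizes used here (2k–20k
vertices, with only the top ~`extra_rank/3` eigenpairs computed
iteratively); Nyström subsampling would be the route for much larger
meshes.

## Robust fitting with region growing

A target with missing teeth violates the correspondence assumption: some
model vertices have no counterpart on the target. The fit therefore only
uses regions believed healthy and grows that set outward:

1. **Initialisation.** Ten landmarks (two per condyle, one per coronoid,
   one per wisdom tooth, one on the interdental papilla between teeth 31
   and 41, one on the chin) are matched by name between model and target.
   The rigid pose (rotation + translation, deliberately no scaling — jaw
   size is biological signal) is the Procrustes/Kabsch alignment of the
   mean-shape landmark positions onto the target landmarks. The model is
   conditioned on the pose-normalised landmark positions by Gaussian
   process regression; the landmark vertices seed the healthy set.
2. **Growth.** Candidates are unhealthy vertices 1-ring adjacent to a
   healthy vertex. For each candidate, the closest target surface point to
   its posterior-mean position is found (exact point-to-triangle distances;
   ties broken by lowest triangle index for reproducibility). The candidate
   becomes healthy iff the Mahalanobis distance of the offset under the
   posterior 3×3 vertex marginal plus `sigma² I` is at most `tau`. Healthy
   vertices are never demoted, so the healthy count is non-decreasing and
   termination within N sweeps is guaranteed.
3. **Re-conditioning.** The parent model is re-conditioned on closest-point
   correspondences of all currently healthy vertices (landmark
   correspondences stay pinned to their clicked positions), with the MAP
   coefficients `alpha_hat = (AᵀA + sigma² I)⁻¹ Aᵀ (y − mu)` in the scaled
   parameterisation and posterior coefficient covariance
   `sigma² (AᵀA + sigma² I)⁻¹`. The pose is refined by Procrustes on the
   healthy correspondences. Steps 2–3 alternate until no vertex is added.

Vertices never reached are labelled unhealthy. Over a missing tooth the
posterior keeps predicting a tooth (the prior has no "toothless" mode and
the kernel is too smooth to erase a single crown), the offsets to the gum
below stay above threshold, and the tooth region remains unhealthy.

**Detection.** Each reference vertex is annotated once (on the mean shape)
with an FDI tooth code 31–38 / 41–48 or none. A tooth is called missing
when at least 70% (inclusive; the boundary belongs to "missing") of its
region's vertices are unhealthy, evaluated 31→38 then 41→48.

## Parameters that matter

| parameter | default | role |
|---|---|---|
| `noise_variance` σ² | 1.0 mm² (library) | observation noise in regression and in the growth criterion; the slack for model error |
| `mahalanobis_threshold` τ | 3.0 | growth acceptance; 3 admits ≈99.7% of a 3-DOF Gaussian |
| `landmark_noise_variance` | 1.0 mm² | confidence in clicked landmarks |
| `kernel_variance` s² | 25 mm² (library) | extra pointwise variance far from the training data |
| `kernel_bandwidth` b | 40 mm | correlation length of the added prior; large enough that it cannot fabricate or delete a single tooth |
| `extra_rank` | 50 | size of the low-rank kernel expansion |
| `missing_fraction_threshold` | 0.70 | the missing-tooth rule |

The library defaults are sized for scan-extracted meshes with
registration-level errors. The synthetic experiment
(`pipeline.ExperimentConfig`) instead uses σ² = 0.25 mm², τ = 2.0 and
s² = 4 mm², matched to the generator's noise model: its surface noise is
0.2 mm and its off-model shape residual is sub-millimetre, while the
acceptance band scales as τ·sqrt(σ² + marginal variance) and must stay
well below the height of a tooth crown (4.5–9 mm here) or the growth
creeps up the flanks of a genuinely missing tooth and partially "heals"
it. This creep is real and visible at the rearmost teeth, whose low, smooth
bumps sit closest to the band — which is exactly where the detector is
weakest (false positives at 38/48).

## The synthetic jaw generator

The generator emulates what the pipeline needs from clinical data and
nothing more. A jaw is a heightfield over a horseshoe band (elliptical
arch, uniform arc-length grid, mirrored half-arch so the layout is exactly
symmetric): an alveolar ridge, sixteen Gaussian tooth bumps at fixed arch
stations, and rami at both ends with condyle and coronoid protrusions.
Crown heights follow typical adult proportions — incisors 8 mm, canines
9 mm, premolars 7.5 mm, molars 6 mm — with the wisdom teeth deliberately
low and broad (4.5 mm, radius 4.5 mm) to reproduce their smooth transition
into the jaw. Because every mesh is evaluated on the same parameter grid,
cohorts and corrupted targets are in correspondence by construction; a
registration step, which real scans require, is out of scope and not
emulated. Per-subject variation multiplies parameters by seeded Gaussian
factors (baseline CVs: overall size 3%, arch 2%, ridge 5%, ramus 4%, tooth
heights 6%, radii 3%, scaled by `variation_scale`).

Corruption operates through per-tooth elevation channels recorded at
generation time: full removal subtracts exactly the tooth's bump at its
region vertices (so non-region vertices are untouched before noise), root
remnant keeps a height fraction, gap closure removes the tooth and shifts
the two flanking teeth toward the gap; seeded Gaussian surface noise and a
seeded rigid motion follow. Landmarks are transferred to targets by vertex
index, emulating a user clicking the same anatomical points (they carry
the target's noise and pose).

What passing tests on this generator do **not** show: robustness to
registration error between real scans and the reference, to segmentation
artefacts, metal streaks, enamel-level geometry, or genuinely toothless
ridge remodelling. They do show that the alternating
reconstruction/segmentation scheme, the growth criterion and the 70% rule
behave as designed when their assumptions hold.

## The reference experiment

`pipeline.run_detection_experiment(seed)` — also what
`scripts/acceptance.py` runs — builds the model from a 9-jaw cohort
(`variation_scale` 1.0), corrupts 30 fresh subjects with 0–4 uniformly
chosen full removals plus 0.2 mm noise and a rigid motion up to 5°/5 mm,
fits every target and scores the calls. Problem sizes (4825-vertex
reference, rank 8 + 50 model, 30 targets) are chosen so the whole
experiment runs in minutes on one core. Typical behaviour: anterior teeth
(31–33, 41–43) detected near-perfectly, molars slightly worse, wisdom
teeth worst — when a wisdom tooth is removed, its seeding landmark sits on
the gum and drags the model's tooth down, producing a false "present"
call. The detector remains binary; root remnant, implant, gap closure and
first dentition are annotation categories scored through their binary
truth and tallied separately.

## Numerical choices

- Closest-point queries are exact: k-nearest triangle centroids plus a
  conservative radius-bound fallback (vectorised ball query); ties go to
  the lowest triangle index.
- Posterior models are re-orthogonalised through an r×r eigendecomposition
  (not a 3N×r SVD), with columns renormalised to exact
  `sqrt(eigenvalue)` length.
- Degenerate inputs fail loudly: < 2 training meshes, zero covariance,
  collinear Procrustes clouds, empty observation sets, non-positive noise
  or kernel parameters, maxillary FDI codes.
- Fitting is deterministic given its inputs; every stochastic operation
  (sampling, cohort generation, corruption) takes an explicit seed.
- STL I/O welds bitwise-identical coordinates to recover shared topology
  and is documented as lossy (float32, vertex order not preserved); PLY is
  written in double precision precisely so geometry round-trips below
  1e-6 mm.

## Known limitations

- The growth criterion is per-vertex and purely geometric; no
  normal-compatibility filter is applied to correspondences (a documented
  extension point), which makes thin structures easier to creep over.
- Accepted-then-wrong vertices are never demoted; a final relabelling pass
  from the converged posterior could sharpen boundaries but would change
  the monotone-growth contract.
- The kernel augmentation assumes isotropic 3D output and a single
  bandwidth; anatomically informed multi-scale kernels are not provided.
- Detection quality degrades exactly where tooth height approaches the
  acceptance band (wisdom teeth), mirroring the behaviour reported for
  this class of method on clinical data.
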