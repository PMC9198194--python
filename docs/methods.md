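# Methods

## Overview

`vectex` classifies 3D lesions by the texture of their *derivative* fields
rather than of the raw intensity image. The motivation is contrast: in CT,
similar soft-tissue types have overlapping Hounsfield distributions, but
their first- and second-order spatial derivatives magnify local
heterogeneity differently. The pipeline is:

1. **Derivative fields.** The gradient `∇I = (∂I/∂x, ∂I/∂y, ∂I/∂z)` is
   computed with the separable 3D Sobel operator. The six unique entries of
   the Hessian are computed with Deriche exponential-family filters at
   scale α = 1, and the per-voxel symmetric 3×3 matrix is reduced to its
   sorted eigenvalues λ1 ≥ λ2 ≥ λ3. The eigenvalue triple is treated as a
   3-vector field, so the Hessian domain re-uses all gradient-domain
   machinery.
2. **Spherical coordinates.** Each 3-vector is expressed as
   (magnitude, azimuth θ ∈ [0, 2π], polar φ ∈ [0, π]), with
   θ = acos(vx/√(vx²+vy²)) for vy ≥ 0 and π + acos(·) otherwise, and
   φ = acos(vz/|v|).
3. **Quantization → VTIs.** Angles are quantized into equal fixed bins of
   their period (the value exactly at the period maps to the top bin).
   Magnitudes first pass a t-th-root remap (they are heavy-tailed; the root
   compresses the tail while preserving ranks, unlike histogram
   equalization which destroys the relative weight of image regions), then
   a uniform min–max scaling whose min/max are taken over ROI voxels only.
   This yields four vector texture images: GAV (gradient azimuth+polar),
   TGV (gradient magnitude+azimuth+polar), HAV and THV (the Hessian
   analogues).
4. **Vector co-occurrence matrices.** For each of 13 canonical lattice
   directions (one per ± pair of the 26 nearest-neighbour offsets) and
   displacement d = 1, the VCM counts ordered pairs of co-occurring vector
   states; the matrix is then symmetrized (counts + countsᵀ), the standard
   co-occurrence convention, making features independent of scan
   orientation along each axis. Both pair endpoints must lie inside the
   post-threshold ROI.
5. **Texture measures.** Each normalized VCM yields 28 scalar measures (14
   classic Haralick statistics + 14 widely used extensions; full list in
   `vectex.features.MEASURE_NAMES`), giving 13 × 28 = 364 features per
   lesion per VTI kind.
6. **Classification.** A random forest with GINI-importance forward
   selection: features are ranked by mean decrease in GINI on the training
   half, the forest is refit on the top k = 3, 4, … features, and the k
   maximizing test AUC is kept (smallest k on ties). Two CV schemes:
   stratified twofold repeated 100 times, and leave-one-out.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| air threshold | −450 HU | ROI voxels below this are lumen air and are excluded from quantization statistics and VCM pairs (the full volume still feeds the derivative kernels, so border voxels see true neighbours) |
| Deriche α | 1.0 | inverse spatial scale of the second-derivative filters (voxel⁻¹); the α = 1 smoother has variance 4 voxels², i.e. an effective Gaussian σ of 2 voxels |
| t-root | 2 (gradient), 4 (Hessian) | magnitude-histogram compression exponent |
| quantization | GAV 10×5, TGV 2×10×4, HAV 5×8, THV 5×3×8 | levels per channel (azimuth×polar, with magnitude first where present) |
| displacement d | 1 | voxel offset multiplier of the VCM direction |
| forest size | 5000 trees | classifier default; scaled-down runs use 500 |
| K_max | 50 | forward-selection cap; selection curves plateau early at the ~60-lesion scale |

The default quantizations are the best-performing rows of the parameter
study the method was developed with; `run_sweep` reproduces such studies on
any cohort.

## Numerical choices

- **Sobel boundary:** edge replication, so constants have exactly zero
  derivative everywhere; zero padding would create spurious boundary
  gradients.
- **Deriche realisation:** the continuous impulse responses
  s(x) = (1+α|x|)e^{−α|x|}, s′, s″ are sampled onto FIR kernels truncated
  where the envelope falls below 1e−12 (radius 28 voxels at α = 1) and
  applied separably. The discrete kernels are renormalised so the smoother
  has unit DC gain, the first derivative responds 1 to a unit ramp, and the
  second derivative responds 0 to constants (enforced exactly via the
  centre tap) and 2 to x². At this truncation the FIR route equals the
  recursive IIR realisation to machine precision while keeping the
  normalisation contracts exact. Any residual global scale would cancel in
  the min–max magnitude scaling anyway; only relative values reach the VTI.
- **Degenerate spherical voxels:** vx = vy = 0 ⇒ azimuth 0; |v| = 0 ⇒
  polar 0. Fixed conventions, never exceptions, so every ROI voxel carries
  a state.
- **Eigenvalue order:** by signed value (λ1 ≥ λ2 ≥ λ3), not magnitude. Ties
  need no tie-break because only the sorted values are used.
- **Degenerate quantization:** a constant magnitude field maps to all
  zeros; a VCM with no admissible pair produces 28 zero-sentinel measures
  with a warning rather than failing the lesion.
- **Measure conventions:** indices are 0-based; logs are base 2 with
  0·log 0 = 0; correlation-type measures return 0 when a variance they
  divide by is 0; the maximal correlation coefficient uses the
  second-largest eigenvalue of the Q matrix restricted to the marginal
  support, clipped to [0, 1].
- **Determinism:** one master seed spawns per-repetition child seeds
  (NumPy `SeedSequence`); forests run single-threaded; repeated runs are
  bit-identical.

## Synthetic phantoms

Real lesions are not redistributable, so the test bed is a phantom: a
spherical lesion (radius 11 voxels in a 32³ grid) of correlated Gaussian
texture at ~30 HU baseline, embedded in −1000 HU air. Texture = coarse
component (smoothed noise, σ = heterogeneity scale) + fine component
(smoothed noise, σ = correlation length, scaled to the contrast amplitude).
Class 0 uses correlation length 1.0 and amplitude 80 HU; class 1 uses 2.2
and 120 HU; cohorts jitter both by ±10% per lesion. These two axes shift
the gradient- and Hessian-magnitude and orientation distributions, which is
exactly the information the VTIs encode.

What the phantoms do **not** emulate: partial-volume ramps at an air–tissue
interface of realistic colonic geometry, anisotropic voxels, scanner noise
spectra, or the size/pathology mix of a clinical cohort. A passing phantom
test therefore shows the pipeline recovers class-dependent derivative
statistics it is designed to measure — not clinical performance.

## Scaled problem sizes

The full protocol (100 repetitions, 5000 trees, K_max 50) is the library
default. The shipped acceptance checks and the acceptance script run a
scaled protocol chosen as a realistic desk-scale experiment: 16+16 lesions,
twofold × 20 repetitions, 500 trees, and a selection cap of 10–20
(the phantom signal concentrates in a handful of features, and the
selection curve plateaus well before that).

## Known limitations and caveats

- **Selection optimism.** The reported AUC is the *maximum* over the
  forward-selection path of the test AUC, averaged over repetitions. This
  estimator is optimistically biased: under a true null (no class
  difference) the average of the per-repetition maxima sits above 0.5, and
  the bias grows with the selection cap and shrinks with test-set size.
  The null-cohort check bounds this bias empirically at the scaled problem
  size; studies needing unbiased error estimates should nest the selection
  inside an outer CV instead.
- **LOO forward selection.** A single held-out lesion has no per-fold ROC,
  so the per-k held-out scores are pooled across all n folds and one AUC is
  computed per k; the reported AUC is the max over k. Pooling mixes
  probability scales of n different forests, which slightly blurs the ROC.
- **mtry** (features per split) is left at the implementation default
  (√p); per-split tuning is not performed.
- Anisotropic voxel spacing is recorded but not used to rescale derivative
  kernels; resample to isotropic voxels first if spacing is strongly
  anisotropic.
- The 28-measure list is a fixed, documented set; co-occurrence literature
  varies in which extensions it includes. Two entries ("sum of squares:
  variance" and "joint variance") coincide numerically; both names are kept
  for contract stability, and tree ensembles are indifferent to duplicated
  columns.
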