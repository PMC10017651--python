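# Methods

## The quantity being measured

Serial chest CT pairs (baseline, follow-up) are aligned by a deformable
registration that maps baseline coordinates to follow-up coordinates,
T(x) = x + u(x) with u in mm on the baseline grid (pull-back convention:
warping the follow-up image through u reproduces the baseline anatomy).
The Jacobian determinant det(I + ∂u/∂x) is the local ratio of follow-up
to baseline volume; its natural log (log-Jacobian) is 0 where tissue is
unchanged, negative where it shrank, positive where it expanded. With
this field convention a lung that is smaller at follow-up yields a
negative masked mean log-Jacobian, which is the per-patient scalar used
for group comparison and correlation with lung function.

Derivatives are taken in world units (mm) with per-axis voxel spacing:
central differences at interior voxels, one-sided at volume faces. The
determinant of an exactly affine field is therefore constant to machine
precision. Non-positive determinants — occasional folding in real
registrations — are clamped at epsilon = 1e-6 before the log and the
clamped-voxel count travels with the map; clamping rather than erroring
keeps the analysis degrading gracefully and visibly (the per-map clamped
fraction is expected to be ≪ 1%).

Masked summaries erode the mask by 1 voxel by default (configurable)
because finite differences straddling the mask boundary are unreliable.
Regional means split the mask's craniocaudal bounding range into three
equal-extent thirds (basal / middle / apical); the craniocaudal axis is
array axis 2 in the package's canonical orientation, and must be given
explicitly when orientation metadata cannot establish it.

## Registration engine

The engine is deliberately standard: a dense, deterministic affine stage
(SimpleITK's registration framework, mean-squares or correlation metric,
3-level pyramid, no stochastic sampling) followed by a symmetric-forces
demons refinement with Gaussian regularization (update smoothing 1.0 mm,
total-field smoothing 1.5 mm) over a multi-resolution pyramid (3 levels,
100/60/30 iterations). The returned field is by default the *composite*
transform T(x) = A(x + d(x)), so global volume change captured by the
affine stage is included in the Jacobian — discarding it would silently
bias the shrinkage estimate toward zero; `jacobian_source="deformable"`
exposes the residual-only alternative. A pyramid level whose
full-resolution masked MSE is worse than the previous best is reverted,
making the logged per-level metric non-increasing by construction.

The demons stage is intensity-difference driven; the configurable metric
choice applies to the affine stage. This engine is not a reimplementation
of any particular published optimizer; for interoperability, displacement
fields from external tools can be imported (4-D NIfTI, vector components
last, mm, baseline grid, pull-back convention — voxel-unit fields are
converted via header spacing with a warning) and fed to the identical
downstream analysis.

## Synthetic phantoms

The phantom generator provides the ground truth every stage is tested
against. Anatomy: two ellipsoidal lungs (≈ −800 HU plus a smooth random
texture, sd 60 HU, correlation length ≈ 2.5 voxels — texture gives the
registration features to lock onto) inside an ellipsoidal body (≈ 40 HU)
in air (−1000 HU), with embedded bifurcating vessel trees (−300 HU) of
known topology. Ellipsoid centres sit half a voxel off the lattice so
that inclusive rasterization does not systematically inflate mask
volumes at equatorial planes.

Deformation: a contraction toward the lung centre whose amplitude varies
craniocaudally,

    u(x) = −alpha(z) (x − c),   alpha(z) = A · w(z)^g,

with w(z) a linear ramp normalized to 1 at the lung base and decaying
toward a reference height placed 30% above the imaged grid (so w and its
derivative stay smooth and finite for any exponent g ≥ 0, including
fractional). The Jacobian matrix of T is upper triangular, so the
determinant has the closed form (1−α)²(1−α−α′(z)(z−c_z)) — ground-truth
log-Jacobian maps are exact, not numerical. A = 0 with g = 0 is the
stable scenario (u ≡ 0); A > 0 shrinks (deteriorating), A < 0 expands
(improving); g > 0 makes shrinkage basal-predominant, mirroring the
basal predilection of fibrosis. Specs whose analytic determinant falls
below 0.05 anywhere in the lung are rejected as folding.

The follow-up volume is the baseline anatomy sampled through the exact
inverse warp (the axial inverse reduces to a monotone 1-D table along z)
plus independent additive noise on each time point (default sd 8 HU).
The follow-up lung mask is rasterized from the analytic geometry at the
pulled-back points rather than by resampling the voxelized baseline
mask, whose staircase boundary would alias against the near-commensurate
target lattice and bias volumes by a few percent.

Default phantom conditions: 64³ voxels at 1 mm isotropic, shrink
amplitude 0.05 (≈ 14% volume loss when uniform), noise sd 8 HU. Cohort
phantoms draw amplitudes uniformly from 0.03–0.08 with basal gradient
1.5 for the deforming groups — chosen to span mild-to-marked
progression at a magnitude where registration recovery is meaningfully
non-trivial but physical (no folding).

Synthetic lung-function cohorts couple FVC%/VC% declines to each
patient's true mean log-Jacobian through a Gaussian copula whose
correlation parameter is the `coupling` argument (a target Spearman ρ
maps to coupling 2 sin(πρ/6)); DLco% declines are independent noise.
Baseline percent-predicted values are drawn around typical IPF clinic
medians (FVC% ≈ 89, DLco% ≈ 51).

What the phantoms do *not* emulate: fibrotic texture (honeycombing,
ground-glass, traction bronchiectasis), respiratory-phase or cardiac
motion, inter-patient anatomical variability beyond affine differences,
slice-dependent noise, or segmentation failure modes around dense basal
consolidation. Passing phantom tests therefore demonstrates correctness
of the *measurement chain* — field → Jacobian → summaries → statistics —
and recovery of known deformations from realistic contrast and noise,
not clinical performance on fibrotic CT.

## Preprocessing

All inputs are resampled to a 1 mm isotropic grid (linear for
intensities, nearest for masks) before registration so fields, maps and
masks share one canonical grid; volumes are reoriented to the closest
canonical axis order on load and oblique affines are rejected rather
than silently mishandled. Lung masks are ordinarily *inputs* (clinical
segmentation quality is upstream of this package); the built-in
threshold segmenter (air below −500 HU, enclosed by the body, two
largest components above 2 mL, holes filled) is adequate for
phantom-like data and is idempotent on its own output.

## Group maps and statistics

Per-patient maps are transported to a common space by registering each
patient's baseline to a template — by default the first patient's
baseline, since no canonical template exists for this analysis — and
resampling the map linearly through the same transform, values carried
unchanged (no Jacobian reweighting), matching a plain group average.
Voxels a patient's map does not reach are missing (NaN) and excluded
per-voxel, with a contributing count emitted; contributions are sorted
before summation so group means are bit-for-bit order-independent.
Renders use a diverging colour scale symmetric about 0 (default ±0.3) so
shrinkage/expansion are visually centred.

Statistics follow the standard two-visit cohort plan: two-sided tests at
α = 0.05 throughout; Mann-Whitney with an exact null for tie-free
samples when min(n) ≤ 8 and the midrank normal approximation with tie
correction otherwise; two-sided Fisher exact p as the sum of
hypergeometric probabilities not exceeding the observed table's;
Spearman correlation (Pearson on midranks) with the interpretation bands
poor/weak/moderate/strong/very strong at |r| cutpoints 0.2/0.4/0.6/0.8
(right-open bins, so |r| = 0.39 is weak and 0.40 moderate). Medians and
IQRs use linear-interpolation quantiles — stated explicitly because
statistical packages differ. Functional deterioration is a decline of
≥ 10 percentage points of percent-predicted FVC or ≥ 15 of DLco between
visits; thresholds are inclusive at the boundary, and a
percent-of-baseline (relative) variant is available as a configurable
alternative since "absolute decrease" conventions vary between groups.
No multiple-testing correction is applied, matching the analysis plan
this package implements.

## Vessel metrics

Vessel masks (all-vessel, artery or vein — whichever segmentation is
supplied) are reduced to a one-voxel, topology-preserving medial
skeleton; voxels are classified by 26-neighbourhood degree (endpoint 1,
regular 2, branch point ≥ 3), adjacent branch-point voxels merge into
one junction, and a *branch* is a maximal degree-≤2 chain between
terminals. This counting rule is explicit and testable (commercial
tools' rules are unpublished); constructed tube/tree fixtures give exact
counts, and counts are invariant to 1-voxel dilation for tubes of radius
≥ 2 voxels. Vessel volume is voxel count × voxel volume in mL. An
optional spur-pruning length is available for noisy skeletons and is off
by default.

## Numerical choices and problem sizes

Tests and the demo run on 32³–64³ phantoms, the scale at which the
analytic properties under test (machine-precision affine determinants,
≤ 1e-3 agreement between 2nd- and 4th-order difference schemes on
band-limited fields, 1% volume conservation, ±0.03 registration
recovery) are already fully expressed; nothing in the pipeline is
specific to that scale, and clinical 512×512×Nz volumes differ only in
runtime. All randomness flows from single integer seeds through
`numpy.random.default_rng`; registration uses dense sampling and fixed
iteration counts, so reruns are bit-identical.

## Known limitations

- The registration engine trades accuracy at sharp deformation gradients
  for robustness (Gaussian regularization): on basal-gradient phantoms
  the apical field is over-smoothed toward the global affine, biasing
  apical regional means while leaving the masked mean within tolerance.
  Importing fields from a stronger external registration is the
  recommended path for clinical work.
- Threshold lung segmentation is not a clinical segmenter.
- Artery/vein separation is out of scope; vessel metrics describe
  whatever mask they are given.
- The common-space template is a designated patient, not an unbiased
  population template; map-level voxel-wise inference across groups is
  deliberately not provided.
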