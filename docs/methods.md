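# Methods

## Problem and scope

Per-lesion response assessment of brain metastases after stereotactic
radiosurgery compares five size-measurement methods — volumes and longest
axial diameters derived from manual or automatic 3D contours
(`vol-manseg`, `vol-autoseg`, `diam-manseg`, `diam-autoseg`) and manually
read diameters (`man-diam`) — and six response-assessment methods (RANO on
each size measurement, plus a clinician-style assessment). The analysis is
strictly lesion-based: no target-lesion sums, new-lesion rules or clinical
covariates. All analyses run on synthetic cohorts; the package makes no
claim of reproducing any real cohort's coefficients, only the structural
findings (which measurement is more stable, and why).

## Size measurement

A lesion is a binary occupancy array on a regular grid (axis 2 =
inferior–superior; axial slices are fixed-z planes), conformed to RAS and
1 mm isotropic spacing on read. Volume is the occupied-voxel count times
the voxel volume. The longest axial diameter is the maximum over axial
slices of the in-plane Feret maximum between voxel centres (production
path: per-slice convex hull + pairwise scan over hull vertices; the test
oracle is the exhaustive O(n²) scan). Voxel-centre convention: a
single-voxel slice has diameter 0; the alternative +1-voxel-extent reading
is deliberately not used. Multi-component masks are measured as one
object. Translation invariance and hull/brute-force equality are enforced
by tests.

## Response classification

RANO rules per follow-up (baseline carries no category): CR when size is
exactly 0; PD when size ≥ (1+0.20)·nadir, the nadir being the minimum over
all time points up to and including the assessed one (baseline included);
PR when size ≤ (1−0.30)·baseline; SD otherwise. Volumetric thresholds come
from the sphere extrapolation (65.7% decrease / 72.8% increase).
Conventions where the rules are silent (fixed here, configurable nowhere —
they define the method):

- **PD takes precedence over PR** when both fire (they use different
  references, so both can).
- **Regrowth after CR is PD** (nadir 0; any positive value is progression
  — this rule also removes the division by zero).
- Threshold comparisons use a 1e-9 relative tolerance so "at least 30%"
  includes exactly 30% under float rounding.
- CR means size exactly 0 (the synthetic truth makes disappearance
  well-defined); no minimum-measurable-size band is applied by default.

The clinician-style assessment references the **previous** time point
instead of baseline/nadir, and calls radio-necrosis (RN) on qualifying
growth with a gado-T1/T2 mismatch. Lesions ever labelled RN are excluded
from cross-method comparisons (RN is not a RANO category).

## Rotation stability

Each non-CR lesion's final contour is rigidly rotated about its centroid
over −20°…20° in 2° steps (21 contours including the unrotated one) about
the x-axis; an extreme variant composes the same angle about x, then y,
then z (order fixed; composition is non-commutative). Rotation uses
inverse-mapping nearest-neighbour resampling at native spacing, with the
centre snapped to the nearest voxel so axis-aligned quarter-turns are
exact lattice permutations; the grid is padded automatically and clipping
raises. The residual volume variation of a digitised sphere across the
angle set (CoV of cube-root volume < 0.01, pinned by test) is pure
interpolation error — the noise floor of the protocol.

Stability metrics: CoV = sample sd (n−1) / mean of the 21 re-measured
sizes, volumes entering as cube roots for comparability with diameters;
and a boolean "any rotation changes the final RANO category", with
baseline and nadir measured unrotated. Lesions whose final diameter is 0
(single-voxel slices) are excluded along with CR lesions.

## Temporal stability

Absolute Spearman correlation (average-rank ties) between time since
treatment and size, over lesions with ≥3 time points; a constant series is
defined as 0 (no evidence of monotone trend) with a warning. Response
churn is counted as adjacent unequal categories over consecutive
follow-ups — [PR, CR, CR] is 1 change of 2 pairs — and rates are pooled as
sum(changes)/sum(pairs) across lesions, not averaged per lesion.

A resolution effect worth knowing: voxel-quantised *diameters* of small
lesions can tie between consecutive time points even when the true size is
strictly monotone, capping |Spearman| below 1; volumes (thousands of
voxels change per step) do not show this. This is itself a facet of the
diameter's measurement instability, and the tests assert it accordingly
(volumes exactly 1 on noise-free monotone cohorts; diameters weakly
monotone).

## Statistical engines

- Paired Wilcoxon signed-rank, two-sided; zeros dropped; exact null for
  ≤25 untied informative pairs, normal approximation with continuity
  correction otherwise (validated against full 2ⁿ sign-flip enumeration
  and a 20 000-resample permutation oracle).
- McNemar, two-sided, from discordant counts: exact binomial below 25
  discordant pairs, continuity-corrected χ² above (validated against
  statsmodels' exact McNemar).
- Lin's CCC with population (1/n) moments (Lin's original definition);
  CCC ≤ |r| is property-tested.
- PABAK = (k·p₀ − 1)/(k − 1) for k categories; equals Cohen's κ under
  uniform marginals (tested).
- Pearson–Filon z for two dependent non-overlapping correlations, with
  the classical asymptotic covariance term
  Ψ = ½ r₁₂r₃₄(r₁₃²+r₁₄²+r₂₃²+r₂₄²) + r₁₃r₂₄ + r₁₄r₂₃ −
  (r₁₂r₁₃r₁₄ + r₁₂r₂₃r₂₄ + r₃₄r₁₃r₂₃ + r₃₄r₁₄r₂₄) and
  z = √n(r₁₂−r₃₄)/√((1−r₁₂²)² + (1−r₃₄²)² − 2Ψ). Because textbook
  presentations of Ψ differ, the implementation is validated three ways:
  Monte-Carlo variance agreement, type-I error within [0.03, 0.07] at
  α = 0.05 over 2000 null simulations (n = 100), and agreement with a
  10⁴-resample paired bootstrap within 0.02 on a fixed seeded dataset.
- No multiple-testing correction anywhere; all p-values are raw and
  two-sided.

## One-year outcome

The 1-year response is the category of the first follow-up strictly after
365 days; lesions without one are excluded. The detection day is the first
follow-up (within the window ending at that defining follow-up) whose
category equals the final one — no persistence requirement, so the minimum
is the first follow-up day and the maximum the defining follow-up's day.

## Synthetic cohort generator

What it emulates (defaults in `CohortConfig`): ~49 patients with 4–14
lesions each (≈450 lesions; the analysis drivers use a 25-patient,
≈200-lesion cohort to keep runtimes desk-scale); per-patient follow-up
schedules (1–6 follow-ups at 75 ± 25-day intervals, shared across a
patient's lesions, mirroring whole-head imaging sessions); ellipsoidal
lesions (lognormal base radius, mean 6 mm, axis ratios 0.6–1.0, optional
low-order spherical-harmonic surface perturbation) voxelized at voxel
centres, whose voxel volume converges to 4/3·π·abc as spacing shrinks; a
trajectory mix of shrink 0.35 / stable 0.25 / grow 0.15 /
pseudo-progression 0.10 / complete-response 0.15 with multiplicative
lognormal observation noise (sd 0.05); manual diameter readings biased by
0.75 with 0.5 mm noise on 80% of lesions; radio-necrosis labels drawn
Bernoulli(0.109) per lesion (RN lesions are forced onto a growing
trajectory with mismatch flags so the clinician-style classifier actually
produces RN calls — this slightly enriches the growing fraction among the
~11% RN lesions).

Contour pairs perturb the *same* rendered truth (matching the observed
near-identity of manual and automatic volumes, r ≈ 0.99 emerges):

- **manual**: an independent in-plane dilation/erosion offset per axial
  slice, uniform in ±1.0 mm — the sawtooth profile along z that
  slice-by-slice contouring leaves;
- **automatic**: a smooth Gaussian-correlated 3D boundary jitter, clipped
  at ±0.6 mm.

Both are applied by thresholding a half-voxel-corrected signed distance to
the mask surface, which guarantees every changed voxel lies within the
amplitude of the original boundary (morphological envelope). Note the
grid-resolution consequence: amplitudes ≤ 0.5 mm on a 1 mm grid change no
voxel, which is why the automatic amplitude sits above half a voxel.

Randomness: one master seed feeds a `SeedSequence` spawn tree
(patient → lesion), so identical (config, seed) reproduce the cohort bit
for bit and sub-streams are reproducible in isolation.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: MRI intensities and segmentation-model failure
modes (false positives/negatives, re-segmentation drift), inter-timepoint
registration error (cohorts are generated aligned), irregular real-world
scheduling, non-ellipsoidal lesion topology (rings, cavities), and any
real cohort's effect sizes. Distributions beyond the reported means
(lesion sizes, follow-up counts) are order-of-magnitude choices.

## Problem sizes and runtime choices

The default analysis cohort is 25 patients / ≈200 lesions at seed 1;
rotation stability covers all non-CR lesions at 21 angles (≈160 lesions ×
2 contour sources), the three-axis extreme mode runs on a 40-lesion
subset, and the Pearson–Filon calibration uses 2000 simulations at
n = 100. These sizes keep every driver and the full test suite in the
minutes range on one CPU while leaving all orderings strongly significant.

## Known limitations

- The rotation analysis inherits the nearest-neighbour interpolation noise
  floor; sub-voxel mesh-based measurement is out of scope.
- The manual-reading bias is purely multiplicative; real readers also
  choose different slices and endpoints.
- Stability is a necessary, not sufficient, criterion: a constant wrong
  measurement would be perfectly stable. The generator's known truth
  mitigates this in testing but the caveat transfers to any real use.
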