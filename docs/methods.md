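# Methods

## Pipeline model

For each subject we observe a 3-D intensity volume and a label map assigning
voxels to seven labyrinth substructures (1 cochlea, 2 reuniting-duct region,
3 vestibule, 4 anterior canal, 5 posterior canal, 6 horizontal canal,
7 common crus). For a region *r* (one substructure, or the union = whole
labyrinth) and its tight bounding-box crop, the feature grid is

    x[i, j](r) = statistic_j( filter_i(crop)[mask] ),   i = 1..26, j = 1..23,

598 cells per region. Filters see the full crop, including out-of-mask
context intensities (masking to zero first would inject artificial edges
that dominate the edge/entropy/Laplacian responses); statistics read mask
voxels only, in raster order. Normalization is the per-subject ratio

    x̃[i, j](sub) = x[i, j](sub) / x[i, j](labyrinth),

with a denominator guard: |denominator| < 1e-12, or a missing numerator or
denominator, yields an explicitly missing cell (NaN), never an infinity.
Binarizing filters make exact-zero denominators routine (the minimum of a
{0,1} image), so missingness is a normal, logged state, and inference deletes
missing subjects pairwise per cell.

Group comparison per cell: two-sided permutation test on
T = mean(case) − mean(control). When C(n, n_case) ≤ n_perm all label
assignments are enumerated and p is exact; otherwise n_perm uniform draws are
used with p = (1 + #{|T*| ≥ |T|}) / (1 + n_perm), so p is never 0 and the
test is valid (never anti-conservative beyond enumeration granularity).
Significance is strict p < α with α = 0.05 and deliberately **no**
multiple-testing correction; the informal guard is the *band*: a statistic
row (26 cells) or filter column (23 cells) holding ≥ 3 significant cells,
not necessarily adjacent. Per-cell RNG seeds derive from
SeedSequence([seed, filter_index, statistic_index]), so any cell is
reproducible by a standalone call.

The test statistic (difference of means), the default n_perm = 10,000, and
the choice of dividing *feature values* (rather than rescaling intensities
before feature computation) are this package's declared conventions where
the analysis design left them open; the statistic and permutation count are
arguments everywhere they matter.

## Filter and statistic parameter choices

The primary-feature names come from a proprietary toolbox and carry no
published parameters; every concrete definition here is this package's own,
chosen to be simple, deterministic, and natively 3-D, and recorded in the
filter registry (archivable as YAML alongside results):

- **FourierDCT** — orthonormal 3-D DCT-II, hard-threshold coefficients below
  0.05 × max|coefficient|, inverse transform.
- **EdgeDetect / MorphologicalBinarize** — Otsu threshold of the
  central-difference gradient magnitude / of the crop itself; constant
  inputs binarize to all-zero.
- **GradientOrientation** — azimuth atan2(g_y, g_x) mapped linearly from
  (−π, π] to [0, 1].
- **Entropy (ranges 1–6)** — local Shannon entropy (natural log) of the crop
  quantized to 32 equal bins over the mask's intensity range, in cubic
  windows of radius r = 1..6, reflective boundaries. A mask with zero
  intensity range yields zeros (single-bin degenerate case).
- **Laplacian** — 6-neighbour discrete Laplacian; **LoG** and **Ridge** use
  σ = 1 voxel (ridge response = max(0, −λ_min) of the smoothed Hessian).
- **ClusteringComponents** — deterministic 1-D Lloyd k-means on mask
  intensities, k = 3, centroids initialized at the 1/6, 3/6, 5/6 quantiles,
  ≤ 100 iterations, output = sorted-cluster index / (k−1). Fewer than k
  distinct values leave duplicate centroids (allowed, still deterministic);
  no randomness is consumed.
- **MorphologicalComponents** — 26-connected components of the Otsu-binarized
  crop, ranked by size (ties by label id), output = rank / #components.
- **Wavelets (1)–(8)** — the eight first-level sub-bands of a separable
  orthonormal Haar transform, ordered LLL, LLH, LHL, LHH, HLL, HLH, HHL,
  HHH (letter order = grid axis order). Odd-length axes pass their tail
  sample through unchanged (identity), which keeps the transform exactly
  orthonormal — energy is conserved to machine precision for every shape.
  The sub-band mask is a 2×2×2 majority vote over in-crop positions, ties
  → true; a sparse mask that would vote to empty falls back to any-true
  blocks so the mask is never empty.
- **Saliency** — |I − G_σ(I)| with σ = 3 voxels (centre–surround difference,
  a 3-D intensity-domain analogue of 2-D colour saliency).
- **ColorToneMapping** — ln(1 + 10·I′)/ln(11) with I′ the crop min–max
  rescaled over the mask and clipped to [0, 1] (a log tone curve re-specified
  for grayscale volumes).

Secondary features follow common-software conventions: SD/variance use n−1;
skewness m₃/m₂^1.5 and kurtosis m₄/m₂² are biased moment forms, kurtosis
non-excess (normal → 3), both missing on zero-variance input; the variance CI
is the 95% chi-square interval ((n−1)s²/χ²₀.₉₇₅, (n−1)s²/χ²₀.₀₂₅), missing
for n < 2; the trimmed mean drops floor(0.05·n) values per tail; entropy and
the histogram mode use a fixed 64-bin histogram over [min, max] (adaptive
binning was rejected for determinism; a constant sample has entropy 0 and
mode = the constant); "DominantColors" is k-means value-quantization with
k = 5 and an abundance floor of 5% of n; the autocorrelation test is the
Ljung–Box portmanteau at lag min(10, ⌊n/5⌋) on the raster-ordered sequence,
missing for constant series or n ≤ lag. The trim fraction, histogram bins,
k, abundance floor and maximum lag are registry parameters.

## Morphometry

Volume is voxel count × voxel volume (exactly additive over disjoint
labels). Surface area is the area of the 0.5 level-set mesh (marching
cubes, spacing applied) of the binary mask after one-voxel Gaussian
anti-aliasing. The smoothing matters: the level set of the *raw* binary
mask carries a staircase bias of roughly +8% on a digitized sphere that does
not shrink under grid refinement, whereas the anti-aliased mesh is accurate
to well under 1% at 0.4 mm spacing and converges monotonically (measured
sphere-area errors −1.5% / −0.4% / +0.1% at 0.8 / 0.4 / 0.2 mm). Structures
only a few voxels thin can smooth entirely below the 0.5 level; they fall
back to the raw binary mesh. Absolute comparability with areas from
interactive surface-rendering tools is unknowable (their smoothing is
unspecified), so between-group *comparisons*, not absolute values, are the
supported use.

## The phantom generator

The generator emulates the study conditions, not the anatomy. Defaults:
48³ grid at 0.4 mm isotropic spacing (within the 0.3–0.5 mm range of the
emulated acquisitions), background mean 100, lumen mean 200, additive
Gaussian noise SD 10 — i.e. a 10-SD lumen/background contrast typical of
heavily T2-weighted inner-ear imaging. The geometry is a stylized labyrinth
(~13 mm across): a 2.25-turn tapering spiral tube (cochlea), an ellipsoid
(vestibule), three 300° torus arcs in mutually orthogonal planes (canals), a
straight tube (common crus), and a small thin tube (reuniting-duct region —
deliberately the smallest structure, ~10–20 voxels, to exercise the
degenerate-input paths). Structures are painted in a fixed priority order
onto a single integer array, so labels are disjoint by construction; each
must rasterize non-empty or generation fails naming the substructure, as it
does when the geometry cannot fit the grid.

Cohorts draw, per subject, a rigid rotation (uniform 0–5° about a random
axis) and an isotropic size factor (uniform 0.95–1.05), identical in
distribution for both groups; per-subject RNG streams derive from
SeedSequence([cohort_seed, subject_index]). Case subjects additionally
receive each requested effect inside the named substructure: mean_shift adds
magnitude × noise_sd; variance_scale multiplies the noise deviation before it
is added; gradient_tilt adds a mean-free linear ramp (slope per voxel) along
axis 0. Effects consume no randomness, so a zero-magnitude effect is
bit-identical to no effect. Effect magnitudes are free parameters — nothing
calibrates them to the disease, whose imaging effect size is unknown.

What the phantom does **not** model: MRI physics (no k-space sampling, coil
bias fields, partial-volume blur beyond rasterization, or Rician noise),
anatomically accurate dimensions (the stylized labyrinth is ~4× smaller in
volume than the real organ), inter-subject anatomical variability beyond
rigid rotation + scaling, and segmentation error (label maps are exact).
Passing tests therefore demonstrate that the *pipeline machinery* is correct
and calibrated — not that the study's clinical findings replicate on real
scanners.

## Numerical choices and degenerate inputs

- All "missing" values are NaN with explicit missing flags in exports;
  normalized grids are checked free of ±inf.
- Permutation tie comparison uses |T*| ≥ |T| − 1e-12·max(1, |T|) so the
  observed assignment always counts itself under enumeration.
- k-means (both uses) is seed-free and deterministic; ties in the component
  ranking break by label id; maximal-count histogram bins average their
  centers.
- Single-voxel regions are legal: gradient filters return zero slope along
  degenerate axes, the Hessian-based ridge filter returns zeros for crops
  thinner than 2 voxels, and statistics degrade to their n = 1 values with
  CI/SD/variance/autocorrelation missing.

## Problem sizes used in the shipped checks

The end-to-end effect-recovery study runs 20 replicate cohorts of 20 + 20
subjects (mean shift 2 × noise_sd in the cochlea) with 500 permutations per
cell, and a 20 + 20 null cohort across all seven substructures; permutation
calibration uses 2,000 independent features at n = 15 per group and 2,000
permutations. These sizes give the binomial/Monte-Carlo error bars quoted in
the tests while keeping a full run of suite plus acceptance script in the
minutes range on one CPU. The inference default of n_perm = 10,000 applies
when callers do not choose otherwise.

## Known limitations

- The ratio normalization couples substructures through the shared
  labyrinth denominator: a strong effect confined to one substructure
  shifts the denominator and hence *every* substructure's normalized
  features (visible in the README example). This is a property of the
  normalization being modeled, not a bug; interpretation of per-substructure
  counts should keep it in mind.
- Band counts under the global null are heavier-tailed than an
  independent-binomial model suggests, because the 598 features of a region
  are strongly dependent (many statistics are monotone functionals of the
  same voxels). The null-calibration check bounds band counts accordingly.
- Filter definitions are faithful to their *names*, not to any particular
  proprietary implementation; numbers are not expected to match other
  toolboxes bit-for-bit.
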