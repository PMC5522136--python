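# Methods

This note records the models implemented in `petrad`, the conventions and
numerical choices that are not visible from the API, and what the synthetic
phantoms do and do not establish.

## Grid conventions

Volumes are regular anisotropic grids indexed `(x, y, z)`. Coordinates are
voxel-center based with 0-based indices: voxel `i` sits at
`origin + i * spacing`, and a grid of `n` voxels covers the physical extent
`n * spacing` (each voxel owns the cell centered on it). Masks are strictly
boolean and always share their parent grid.

### Resampling

`resample_grid` implements "bicubic" resampling of 3D volumes as separable
cubic-spline (order 3) interpolation along all three axes. The target grid
has `floor(extent / target_spacing)` voxels per axis, cell-aligned to the
low edge of the source extent, so the covered extent is preserved to within
one voxel. Samples outside the source support take the nearest edge value —
no extrapolation. Cubic-spline prefiltering is exact for polynomials up to
degree 3 in the interior; boundary effects decay geometrically (pole
|z₁| ≈ 0.27 per voxel), which is why interior-accuracy tests trim ~12
voxels from the edges. Masks are never interpolated: they transfer by
nearest-neighbor lookup and re-binarization at 0.5, keeping them binary.
When a reference sphere VOI is needed on a resampled grid it is re-generated
from its center and volume on the new grid rather than resampled.

## Segmentation

Tumor VOIs use the fixed-threshold rule: within a user-supplied seed region,
keep voxels with SUV ≥ 0.40 × (regional SUVmax). The comparison is
inclusive, so the hottest voxel is kept at any threshold. The result is
restricted to the 26-connected component containing that voxel — a
reproducible surrogate for the manual exclusion of nearby physiological
uptake (bladder spill-in); it guarantees the output is a single connected
lesion but is *not* a model of expert editing. Raising the threshold can
only shrink the mask (tested property).

The liver reference VOI is a sphere of prescribed physical volume (default
75.5 mL, radius `r = (3V/4π)^{1/3}` ≈ 26.2 mm) containing every voxel whose
center lies within `r`; the discretization error of the achieved volume is
below 5% for voxel sizes up to 5.3 mm.

## Feature definitions and choices

Absolute discretization maps SUV `x` to `round(n_bins · (x − lo)/(hi − lo))`
with `n_bins = 128`, bounds [0, 40] SUV. Rounding is half-away-from-zero;
values above the upper bound clamp to `n_bins`; negative inputs (residual
reconstruction noise) clamp to 0 with a warning. Level 0 is a valid gray
level everywhere except in the LGZE/HGZE sums, where i = 0 cells are
excluded (LGZE divides by i²) while still counting in the normalization.

GLCM: distance-1 neighbors, symmetric accumulation (each unordered pair
counts in (i,j) and (j,i)), one matrix per direction. GLRLM: maximal
same-level runs along each direction, broken at mask boundaries; a
direction and its negation are the same direction. Both use the 13
sign-unique nonzero offsets of {−1,0,1}³ and features are the *unweighted*
mean over directions; directions with an empty matrix (no in-mask pair along
that offset) are skipped, and a VOI with no pairs in any direction is an
error. GLZLM: zones are 26-connected components of constant level,
direction-independent. Offsets live in index space — no physical-distance
correction on anisotropic grids, matching common practice of extracting on
native grids. Entropy uses log base 2; the base only rescales Entropy and
any trained coefficient on it, and is fixed once for reproducibility.

SUVpeak maximizes, over candidate centers restricted to in-mask voxels, the
mean SUV in a 1 mL sphere of voxel centers around the candidate (radius
6.2035 mm, membership by center distance). The sphere may extend beyond the
mask but is truncated at the grid boundary (the mean is over in-grid
voxels), so SUVpeak is translation-invariant only while the sphere stays
inside the grid. Implemented by FFT convolution of the volume and of a ones
image with the sphere kernel.

## Statistics

Wilcoxon rank-sum tests are exact when the pooled sample has ≤ 20
observations and no ties, otherwise normal approximation with tie and
continuity correction (both methods can be forced). AUC is the Mann-Whitney
statistic with ties counted ½, oriented so that *higher score predicts
relapse* — never auto-flipped, so an inversely predictive feature shows
AUC < 0.5. Confidence intervals are percentile intervals over 2000
stratified bootstrap replicates (classes resampled independently); BCa was
deliberately not used — the percentile interval is the simplest faithful
default and is recorded in output metadata. No multiple-testing correction
is applied across the 11 features; the univariate table reports raw
p-values. The subset-stability experiment redraws subsets until both
outcome classes are present, which slightly biases it toward analyzable
subsets at extreme prevalences.

## Signature model and selection

The recurrence signature is a linear-probability model: ordinary least
squares of the 0/1 outcome on the chosen features, scored by the
residual-sum-of-squares AIC `N ln(SS/N) + 2(K+1)`. The printed selection
criterion is this least-squares AIC even though the resulting score is used
like a logistic discriminant; the package honors the least-squares form
literally, and a deviance-based logistic AIC is available behind
`criterion='logistic'` (off by default). Default selection is an exhaustive
search over all 330 4-subsets of the 11 features — cheap, and guaranteed to
find the best 4-feature model; bidirectional stepwise from the full model is
retained for comparison (by construction its AIC can never beat the
exhaustive optimum at the same size). Ill-conditioned subsets are skipped
with a warning. DeLong's test uses midrank placement values; the degenerate
zero-variance case (e.g. identical score vectors) returns p = 1 for a zero
AUC difference.

## Synthetic phantoms

The generator states a world and keeps it fixed:

* **Tumors** are ellipsoids with volume ~ N(39, 30²) mL truncated to
  [3, 160] mL and mildly randomized axis ratios, on a 1 mm isotropic truth
  grid. Foreground uptake is `base × exp(a · G)` with base ~ N(7, 1.5²) SUV
  (floored at 2), `G` a unit-variance Gaussian random field with
  correlation length ~ U(2, 6) mm, and log-amplitude a ~ U(0.15, 0.45);
  background is SUV 1 with a 1 mm-smoothed boundary outside the true mask.
  These heterogeneity bounds were chosen once to span visibly homogeneous to
  strongly textured lesions at clinically plausible uptake.
* **Scanners** are modeled as Gaussian PSF blur → grid-cell-average
  downsampling to the device grid → multiplicative Gaussian noise. Defaults:
  G1-like 5.3×5.3×3.4 mm, FWHM 6 mm, CV 0.12; G2-like 2.7×2.7×3.4 mm,
  FWHM 4.5 mm, CV 0.08 — voxel grids are the device values, blur and noise
  are generator choices ordered as the old/new device contrast.
* **Outcome** is Bernoulli(σ(β₀ + Σ β·f_true)) on features computed from the
  *truth*, before any scanner effect. The default model drives relapse
  through Entropy with slope 1.38 per Entropy-sd, calibrated once on 200
  generator draws (Entropy_true ≈ 7.05 ± 1.27 bits) to give a true-feature
  AUC ≈ 0.80 and a relapse rate near one third. Group sizes default to
  79 and 39.
* **Liver** phantoms are constant SUV-2 blocks imaged through a profile,
  with the 75.5 mL sphere re-drawn centrally on each grid.
* A **tabular generator** draws the 11 features from a three-factor Gaussian
  model at clinical scales (TLG is the exact product SUVmean × MV) for
  experiments where image formation is irrelevant — subset recovery,
  coefficient recovery, null calibrations.

What a green test establishes: that the pipeline detects planted effects of
stated size, controls its type-I rate, and reproduces the qualitative
cross-device stratification (device differences in liver texture that
survive common-grid resampling, because noise and PSF — not only voxel
size — differ). What it does not establish: anything about clinical
predictive performance; the phantoms have no anatomy, no bladder uptake, no
reconstruction physics beyond blur + noise, and the noise is spatially
white, unlike correlated OSEM noise.

## Degenerate inputs and tolerances

Empty masks, single-class outcomes, rank-deficient designs and non-positive
residual sums of squares raise `ValueError` with descriptive messages.
Texture extraction requires ≥ 2 in-mask voxels and at least one non-empty
co-occurrence direction. Interpolation identity and constant-preservation
are exact to ~1e-6 (float rounding in the spline pipeline); oracle
equivalence of the texture machinery is asserted cell-by-cell (integer
counts) and to 1e-10 on features.
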