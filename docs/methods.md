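# Methods

This note documents the models and numerical choices behind knobkit, in
the order the pipeline runs.

## Coordinate and unit conventions

Voxel grids are `(z, y, x)`, 0-based; the centre of voxel `(z, y, x)` is
at `((z+0.5)·dz, (y+0.5)·dy, (x+0.5)·dx)` nm. The default voxel size is
`(dz, dy, dx) = (125, 40, 40)` nm — typical for reconstructed 3D
structured-illumination stacks of this instrument class, and chosen so
the 0.2 µm grouping rule spans five lateral voxels. Every physical
threshold (distances, volumes, smoothing scales) is given in nm and
converted through the voxel size; nothing is hard-coded in voxel counts.

## Flexible iterative thresholding

The automatic threshold `t` is the isodata (iterative intermeans) fixed
point `t ← (mean(x ≤ t) + mean(x > t))/2`, started from the global mean
and iterated until `|Δt| < 1e-6·(max−min)` (guarded at 500 rounds; on
16-bit data convergence takes far fewer). `m1` is the mean of the pixels
strictly above `t`. The flexibility parameter `d ∈ [0, 1]` interpolates

    T = t + d·(m1 − t),

so `d = 0` is the plain automatic threshold and `d = 1` raises it to the
above-threshold mean. This linear form uses exactly the named quantities
`t`, `m1`, `d`, is the identity at `d = 0`, and keeps thresholds visually
stable across images at a fixed `d`; the exact printed equation of the
source analysis is not available, so this is the package's own
reconstruction from the quantities it names. "Above threshold" means
strictly greater throughout; iteration runs on raw values (the images
are small), while the test oracle uses an independent 1,000-bin
histogram variant.

## Channel registration

The alignment model has seven parameters: translations `(tz, ty, tx)` in
nm, rotation `θz` about the optical axis in degrees, and per-axis
magnifications `(mz, my, mx)` (astigmatism of per-channel focusing
optics makes two lateral magnifications necessary). Composition order is
scale → rotate(z) → translate, scale and rotation about the geometric
centre, in physical nm; the order is a package convention (the source
text does not fix one) and is serialized with the parameters so files
are self-describing. `apply_transform` pulls back through this map with
trilinear interpolation and zero fill. Because the exact inverse of the
map with `mx ≠ my` is not in the same parameter family, inversion is
applied as a matrix (`inverse=True`), not re-parameterized.

Estimation maximizes Pearson correlation between the reference and the
moving image resampled through the *inverse* of the candidate transform,
so the returned parameters describe the moving channel's distortion
directly (generating `moving = apply_transform(reference, p)` and
estimating recovers `p`). Numerical choices that matter:

* The correlation is evaluated over the reference's signal support (a
  smoothed copy thresholded at 15% of max, dilated two voxels) rather
  than the whole frame. Empty background contributes only noise to the
  correlation and dominates the voxel count; restricting to support both
  stabilizes the optimum and speeds every evaluation several-fold.
* The moving image is sampled through precomputed cubic-spline
  coefficients. Trilinear interpolation attenuates high frequencies in a
  sampling-phase-dependent way, which biases the magnification estimates
  by a few 1e-3 on bead-scale structure — larger than the target
  accuracy of 1e-3; cubic interpolation removes that bias.
* Translations are seeded at the integer-voxel cross-correlation peak;
  all requested parameters are then refined with Powell's direction-set
  method (derivative-free line searches, tolerance 1e-4 in a normalized
  space where one unit ≈ one voxel / one degree / 1% magnification).
  Powell's per-coordinate line searches resolve the weakly coupled
  magnification directions more reliably than a simplex in 7 dimensions.
* The returned optimum never scores below the supplied initial guess
  (both are kept as candidates).

Because chromatic aberration differs between bead slides and biological
samples, and between acquisitions (chiefly in z), `refine_translation`
re-optimizes only `(tz, ty, tx)` from the DAPI signal imaged through
both channels' optical paths, passing rotation and magnifications
through bit-exactly.

## Nucleus segmentation and grouping

DAPI is binarized at the flexible threshold, components are labelled
with 26-connectivity, and components smaller than a minimum volume
(default: a 400 nm-radius sphere) are dropped as speckle — the minimum
volume is this package's answer to speckle handling, exposed in config.
Objects from other channels are grouped to every nucleus whose DAPI mask
lies within 0.2 µm *edge-to-edge* (a Euclidean distance transform with
anisotropic sampling); centroid distance would mis-group large nuclei.
An object in range of two nuclei is assigned to both and flagged
ambiguous rather than arbitrated.

## Overlap statistic

Per nucleus and channel, images are cropped identically, optionally
thresholded (each channel gets its own flexible threshold at the shared
`d`), and normalized

    G_norm = clip(G − t, 0) / (max3 − t)

where `max3` averages the three brightest voxels of the nucleus object
(three voxels buffer residual noise; the single brightest voxel may
normalize slightly above 1 and is deliberately not clipped — the
statistic is scale-free). Both normalized images are zero-padded to
250× their voxel count, and the overlap is

    n = Cov(G′, B′) / sqrt(V(G′)·V(B′))

over the whole padded image. The padding drives the means toward zero,
so `n` approaches the Manders-style quantity
`Σ(GB)/sqrt(ΣG²·ΣB²)`; it is exactly 1.0 for a channel against itself
and ~0 for disjoint supports. The padding is evaluated in closed form
(sums over original voxels, padded count in the denominators), which
matches a materialized padded array to ~1e-12 and costs nothing. The
exact printed equation of the source analysis being unavailable, this
symmetric variance-ratio form is the package's reconstruction from the
ingredients it names (`V`, the padding, the Manders modification); the
possibly asymmetric Manders readings are recoverable from the reported
secondary outputs `k1 = Σ(GB)/ΣB²` and `k2 = Σ(GB)/ΣG²`. Tiny negative
values (disjoint supports) are clamped to 0. Summary tables report
mean ± s.d. across nuclei with the N−1 denominator; a single-nucleus
s.d. is reported as 0 with a flag.

## Knob calling, frequency and proximity

The original knob count was visual. The automated surrogate smooths
DAPI within the nucleus mask (normalized masked Gaussian, σ = 60 nm
lateral / 150 nm axial), keeps voxels ≥ mean + 2·sd of the within-mask
smoothed distribution, labels 26-connected candidates, and retains
those with volume between a 150 nm-radius sphere and 5% of the nucleus
whose mean raw intensity is ≥ 1.5× the within-mask median. Every
criterion is configurable and validated only against simulated ground
truth — the surrogate is never claimed to reproduce visual counts on
real mutant data. Raising the z-score cutoff can only shrink the
candidate set, so call counts are monotone non-increasing in it over
the working range; at very low cutoffs the merged candidate region can
instead be rejected by the maximum-volume window, so monotonicity of
the final count holds once candidates fit the window.

Knob-count frequencies are tabulated in classes {0, 1, 2, ≥3} with
percentages to one decimal, always computed from the counts. Locus
proximity is the percentage of *knob-containing* nuclei in which the
minimum edge-to-edge locus-to-knob distance is < 0.2 µm, using the same
distance convention as grouping.

## Synthetic scenes

A scene plants spherical nuclei (default diameter 2 µm, the size of the
fission-yeast interphase nucleus) filled with a Gaussian-smoothed
(120 nm) lognormal chromatin field; a knob is a spherical region
(default radius 300 nm) with local density multiplied by 2.5; a silent
focus is a 150 nm-radius region set to 0.6× the median density at the
nuclear rim. The texture log-sd default is 0.15: knobs in the source
imagery are conspicuous, isolated bodies, so the background texture
fluctuation must sit well below the 2.5× knob contrast; at log-sd 0.15
about 95% of nuclear voxels lie within 0.74–1.35× the median, leaving
knobs ~8 sd above texture after smoothing. Marker channels mix the DAPI
template with an independent field under weight `w` — the expected
overlap is strictly increasing in `w`. All channels get an anisotropic
Gaussian PSF (FWHM 120/120/300 nm, the stated lateral/axial SIM
resolution), marker channels are resampled under their true transform,
and Poisson (100 photons per unit intensity → SNR 10 at the nuclear
median) plus Gaussian read noise (sd 0.02) is applied. The generator
does not model SIM reconstruction artifacts, spectral bleed-through, or
non-spherical nuclei, so passing tests demonstrate correctness of the
computations under this idealized forward model, not performance on
real reconstructions.

Bead fields render each bead by trilinear sub-voxel splat plus the PSF;
the moving stack renders the same beads at their inverse-mapped
positions (equivalent to resampling the reference under the true
transform, but free of a second interpolation pass), with independent
Gaussian noise added to both stacks.

## Microarray chain

Per probe: median of spot `gProcessedSignal`; detected when the mean
spot `gIsWellAboveBG` exceeds 0.55. Intensities are scaled so the 75th
percentile (linear interpolation between order statistics) equals
2,500. Probes of duplicated genes are divided by integer copy number.
Paralog cross-hybridization assumes every mismatch attenuates
hybridization by a common factor α ∈ [0, 1): perfect-match probes see
`I_PA = s_A + α^m·s_B` (m mismatches between the paralogues), and a
correction probe with one extra mismatch sees `I_CA = α·I_PA`, so α is
estimated as the ratio of correction to perfect-match intensity
(averaged over the two alternate-base variants and both pair members
when present, or supplied globally) and the abundances follow from a
2×2 linear solve; negative solutions are floored at 0 and flagged; m = 0
is singular and rejected. The geometric α^mismatch attenuation is the
minimal model consistent with equal per-mismatch weakening; the original
platform's exact procedure is not public. Replicates combine by
geometric mean; ratios divide by the matched control strain; fold-change
sets use strict inequalities (`> fold`, `< 1/fold`) in every listed
strain. Category composition is tested with χ² = Σ(obs−exp)²/exp,
df = categories − 1, against user-supplied expected proportions;
per-category percentages round to the nearest integer. Surrogate-value
overrides (e.g. for histone genes deleted in a strain) are user-supplied
inputs, never hard-coded.

The array generator plants differential genes only among well-detected,
unpaired, single-copy genes whose scaled intensity stays strictly below
the 75th-percentile anchor of the control probe vector; this keeps the
normalization factor identical across strains, so with zero noise the
full chain reproduces planted fold changes to machine precision — the
basis of the chain-exactness test.

## Problem sizes and determinism

Default test scenes are 28×96×96 voxels (3.5×3.8×3.8 µm) with one
nucleus; multi-nucleus tests use up to 28×176×176. Bead recovery tests
use 60–300 beads on 24×64×64 to 32×128×128 grids. These sizes keep each
property suite to seconds-to-minutes on one CPU while leaving every
statistical conclusion unchanged at larger sizes. All generators take
explicit seeds and are bit-reproducible; the test suite and acceptance
script derive every random draw from fixed or CLI-provided seeds.

## Known limitations

* The flexible-threshold and overlap formulas are reconstructions from
  named quantities (see above); if the original differs (e.g. an
  asymmetric Manders split), `k1`/`k2` preserve the information needed
  to recompute it.
* The knob caller's defaults are tuned to the synthetic forward model;
  real SIM reconstructions (with residual fringes and intensity
  gradients) would need the exposed parameters revisited.
* Registration assumes a single rigid+magnification distortion per
  channel; field-dependent distortion is out of scope.
* The paralog correction is exact only under the common-α attenuation
  model; sequence-dependent mismatch effects violate it.
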